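"""Embedded case-study tables as typed, checksum-verified fixtures.

The packaged CSVs transcribe the case study's printed tables: the two
criterion-comparison panels (forward and inverse pass), the rating panel
for the six assessment methods, the published total gaps, the 6 x 23
operations score matrix, the published entropy table and the
cross-framework weight/rank comparison tables.  Decimal commas in the
source were converted to points at transcription time; the verbatim
strings live in ``data/tables/provenance.json``.

``load_fixture(name)`` returns a typed object ready for the pipeline;
each load re-verifies the file's sha256 against the manifest.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import pandas as pd

from .entropy import ScoreMatrix
from .fuzzy import DMWeights
from .mairca import RatingPanel
from .piprecia import ComparisonSeries

FIXTURE_FILES = {
    "piprecia_forward": "piprecia_forward.csv",
    "piprecia_inverse": "piprecia_inverse.csv",
    "rating_panel": "rating_panel.csv",
    "mairca_Q": "mairca_q.csv",
    "score_matrix": "score_matrix.csv",
    "entropy_table": "entropy_table.csv",
    "framework_weights": "framework_weights.csv",
    "framework_ranks": "framework_ranks.csv",
}


class FixtureError(ValueError):
    """Unknown fixture name, checksum mismatch or shape mismatch."""


def _tables_dir():
    return resources.files("ivffmcdm").joinpath("data", "tables")


def _read(fname: str) -> str:
    ref = _tables_dir().joinpath(fname)
    raw = ref.read_bytes()
    manifest = json.loads(_tables_dir().joinpath("manifest.json").read_text())
    entry = manifest.get(fname)
    if entry is None:
        raise FixtureError(f"{fname} not listed in manifest")
    digest = hashlib.sha256(raw).hexdigest()
    if digest != entry["sha256"]:
        raise FixtureError(
            f"checksum mismatch for {fname}: {digest} != {entry['sha256']}"
        )
    return raw.decode()


def _frame(fname: str, **kw) -> pd.DataFrame:
    import io

    df = pd.read_csv(io.StringIO(_read(fname)), **kw)
    manifest = json.loads(_tables_dir().joinpath("manifest.json").read_text())
    rows, cols = manifest[fname]["rows"], manifest[fname]["cols"]
    if df.shape[0] != rows or df.shape[1] + (1 if kw.get("index_col") is not None else 0) != cols:
        raise FixtureError(
            f"{fname}: shape {df.shape} inconsistent with manifest ({rows}, {cols})"
        )
    return df


def load_fixture(name: str):
    """Load a fixture by name.

    Returns a :class:`~ivffmcdm.piprecia.ComparisonSeries` for the two
    comparison panels (equal decision-maker weights), a
    :class:`~ivffmcdm.mairca.RatingPanel` for ``rating_panel``, a
    :class:`~ivffmcdm.entropy.ScoreMatrix` for ``score_matrix``, and a
    pandas object for the published result tables.
    """
    if name not in FIXTURE_FILES:
        raise FixtureError(
            f"unknown fixture {name!r}; known: {sorted(FIXTURE_FILES)}"
        )
    fname = FIXTURE_FILES[name]
    if name in ("piprecia_forward", "piprecia_inverse"):
        df = _frame(fname, index_col="criterion")
        return ComparisonSeries.from_frame(df, DMWeights.equal(df.shape[1]))
    if name == "rating_panel":
        df = _frame(fname)
        return RatingPanel.from_frame(df)
    if name == "score_matrix":
        df = _frame(fname, index_col="method")
        return ScoreMatrix(df)
    if name == "mairca_Q":
        return _frame(fname, index_col="alternative")["Q"]
    if name == "entropy_table":
        return _frame(fname, index_col="operation")
    if name == "framework_weights":
        return _frame(fname, index_col="criterion")
    if name == "framework_ranks":
        return _frame(fname, index_col="alternative")
    raise AssertionError(name)  # pragma: no cover


def fixture_checksums() -> dict:
    """Manifest contents (file -> shape and sha256)."""
    return json.loads(_tables_dir().joinpath("manifest.json").read_text())


def provenance() -> dict:
    """Verbatim pre-tokenization table strings and transcription notes."""
    return json.loads(_tables_dir().joinpath("provenance.json").read_text())
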