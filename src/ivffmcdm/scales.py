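"""Linguistic term scales mapping term codes to fuzzy numbers.

Two scale roles exist.  A *rating* scale orders adequacy/risk-level terms
(VL < L < ML < M < MH < H < VH) and must have a strictly increasing score
along that order.  A *comparison* scale carries relative-importance terms
partitioned into "more", "equal" and "less" groups whose scores must be
ordered accordingly (every "more" term above every "equal" term above
every "less" term).

Scales are data, not code: they load from JSON (or CSV) files.  The
packaged default scales are literature-style stand-ins (see the files
under ``ivffmcdm/data/scales`` and ``docs/methods.md``); user-supplied
scale files with the same format take their place transparently.

The module also provides the interval-width perturbation operator used
by the robustness analysis: every membership/non-membership interval is
rescaled about its midpoint by a factor ``k``, clipped to ``[0, 1]`` and
repaired to the rung-feasibility boundary if needed.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

from .fuzzy import IVOFN, TOL, FuzzyValidationError, _qroot

VALID_ROLES = ("comparison", "rating")
VALID_GROUPS = ("more", "equal", "less")


class UnknownTermError(KeyError):
    """Lookup of a term code that the scale does not define."""

    def __init__(self, term: str, scale_name: str):
        super().__init__(f"unknown linguistic term {term!r} in scale {scale_name!r}")
        self.term = term


class ScaleFormatError(ValueError):
    """Malformed or inconsistent scale definition."""


@dataclass(frozen=True)
class PerturbationScenario:
    """Proportional interval-width multiplier; k=1 is the base case."""

    k: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"width multiplier must be >= 0, got {self.k}")


@dataclass(frozen=True)
class LinguisticScale:
    """Ordered map from linguistic term codes to IVOFNs."""

    role: str
    entries: Mapping[str, IVOFN]
    q: int = 3
    name: str = "unnamed"
    #: comparison scales only: term code -> "more" | "equal" | "less"
    groups: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ScaleFormatError(f"role must be one of {VALID_ROLES}, got {self.role!r}")
        if not self.entries:
            raise ScaleFormatError(f"scale {self.name!r} has no entries")
        object.__setattr__(self, "entries", dict(self.entries))
        object.__setattr__(self, "groups", dict(self.groups))

    def validate(self, strict_order: bool = True) -> None:
        """Check entry validity and (optionally) score monotonicity."""
        for term, f in self.entries.items():
            if f.q != self.q:
                raise ScaleFormatError(
                    f"term {term!r} has q={f.q}, scale declares q={self.q}"
                )
            if not f.is_valid():
                raise ScaleFormatError(f"term {term!r} is not a valid IVOFN: {f}")
        if not strict_order:
            return
        if self.role == "rating":
            scores = [f.score() for f in self.entries.values()]
            if any(b <= a + TOL for a, b in zip(scores, scores[1:])):
                raise ScaleFormatError(
                    f"rating scale {self.name!r}: scores not strictly increasing "
                    f"along declared term order: {scores}"
                )
        else:
            missing = [t for t in self.entries if t not in self.groups]
            if missing:
                raise ScaleFormatError(
                    f"comparison scale {self.name!r}: terms without group: {missing}"
                )
            bad = [g for g in self.groups.values() if g not in VALID_GROUPS]
            if bad:
                raise ScaleFormatError(f"invalid groups: {bad}")
            by_group = {g: [] for g in VALID_GROUPS}
            for t, g in self.groups.items():
                by_group[g].append(self.entries[t].score())
            if by_group["more"] and by_group["equal"]:
                if min(by_group["more"]) <= max(by_group["equal"]):
                    raise ScaleFormatError(
                        f"comparison scale {self.name!r}: a 'more' term scores "
                        "below an 'equal' term"
                    )
            if by_group["equal"] and by_group["less"]:
                if min(by_group["equal"]) <= max(by_group["less"]):
                    raise ScaleFormatError(
                        f"comparison scale {self.name!r}: an 'equal' term scores "
                        "below a 'less' term"
                    )
            if by_group["more"] and by_group["less"] and not by_group["equal"]:
                if min(by_group["more"]) <= max(by_group["less"]):
                    raise ScaleFormatError(
                        f"comparison scale {self.name!r}: group score order violated"
                    )

    def __getitem__(self, term: str) -> IVOFN:
        try:
            return self.entries[term]
        except KeyError:
            raise UnknownTermError(term, self.name) from None

    def __contains__(self, term: str) -> bool:
        return term in self.entries

    def terms(self) -> list[str]:
        return list(self.entries)

    # -- transformations ----------------------------------------------------

    def perturb(self, scenario: PerturbationScenario) -> "LinguisticScale":
        """Rescale every interval's width about its midpoint by ``scenario.k``.

        Midpoints are preserved (up to clipping at 0/1).  If widening makes
        ``mu_high**q + nu_high**q`` exceed 1, the non-membership endpoints are
        shrunk to the feasibility boundary (``nu_high`` first, then ``nu_low``),
        leaving membership untouched.
        """
        k = scenario.k
        if k == 1.0:
            return self

        def stretch(lo: float, hi: float) -> tuple[float, float]:
            mid = 0.5 * (lo + hi)
            half = 0.5 * (hi - lo)
            return (
                min(max(mid - k * half, 0.0), 1.0),
                min(max(mid + k * half, 0.0), 1.0),
            )

        new_entries = {}
        for term, f in self.entries.items():
            mu_lo, mu_hi = stretch(f.mu_low, f.mu_high)
            nu_lo, nu_hi = stretch(f.nu_low, f.nu_high)
            mu_lo, mu_hi, nu_lo, nu_hi = _repair(mu_lo, mu_hi, nu_lo, nu_hi, self.q)
            new_entries[term] = IVOFN(mu_lo, mu_hi, nu_lo, nu_hi, self.q)
        out = LinguisticScale(
            role=self.role,
            entries=new_entries,
            q=self.q,
            name=f"{self.name}[k={k:g}]",
            groups=self.groups,
        )
        out.validate(strict_order=False)
        return out

    def with_q(self, q: int) -> "LinguisticScale":
        """Reinterpret the same interval endpoints under a different rung.

        Smaller rungs tighten the feasibility constraint, so entries that
        become infeasible are repaired exactly as in :meth:`perturb`.
        Monotonicity is not re-enforced (repair can flatten extreme terms).
        """
        if q == self.q:
            return self
        new_entries = {}
        for term, f in self.entries.items():
            mu_lo, mu_hi, nu_lo, nu_hi = _repair(
                f.mu_low, f.mu_high, f.nu_low, f.nu_high, q
            )
            new_entries[term] = IVOFN(mu_lo, mu_hi, nu_lo, nu_hi, q)
        out = LinguisticScale(
            role=self.role,
            entries=new_entries,
            q=q,
            name=f"{self.name}[q={q}]",
            groups=self.groups,
        )
        out.validate(strict_order=False)
        return out


def _repair(
    mu_lo: float, mu_hi: float, nu_lo: float, nu_hi: float, q: int
) -> tuple[float, float, float, float]:
    """Shrink non-membership to the rung-feasibility boundary if needed."""
    if mu_hi**q + nu_hi**q > 1.0 + TOL:
        nu_hi = _qroot(1.0 - mu_hi**q, q)
    if nu_lo > nu_hi:
        nu_lo = nu_hi
    return mu_lo, mu_hi, nu_lo, nu_hi


# ---------------------------------------------------------------------------
# loading


def load_scale(
    source, role: str, q: int = 3, name: str | None = None,
    strict_order: bool = True,
) -> LinguisticScale:
    """Load and validate a scale from a JSON/CSV file path or parsed dict.

    JSON layout::

        {"role": "rating", "q": 3,
         "terms": [{"term": "VL", "mu": [0.05, 0.15], "nu": [0.85, 0.95]}, ...]}

    Comparison-scale terms additionally carry ``"group"``.  CSV files need
    columns ``term, mu_low, mu_high, nu_low, nu_high`` (plus ``group`` for
    comparison scales); decimal points, not commas.  Term order in the file
    is the declared scale order.

    ``strict_order=False`` disables the monotonicity/group-order check
    (the violation is otherwise reported as :class:`ScaleFormatError`).
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        text = path.read_text()
        if name is None:
            name = path.stem
        if path.suffix.lower() == ".csv":
            data = _csv_to_dict(text, role, q)
        else:
            data = json.loads(text)
    elif isinstance(source, dict):
        data = source
    else:
        raise TypeError(f"cannot load scale from {type(source)}")

    role = data.get("role", role)
    q = int(data.get("q", q))
    name = data.get("name", name) or "unnamed"
    entries: dict[str, IVOFN] = {}
    groups: dict[str, str] = {}
    terms = data.get("terms", [])
    if not terms:
        raise ScaleFormatError(f"scale {name!r}: no terms defined")
    for row in terms:
        term = row["term"]
        if term in entries:
            raise ScaleFormatError(f"scale {name!r}: duplicate term {term!r}")
        try:
            mu = [float(v) for v in row["mu"]]
            nu = [float(v) for v in row["nu"]]
            entries[term] = IVOFN(mu[0], mu[1], nu[0], nu[1], q)
        except (KeyError, IndexError, TypeError, ValueError) as exc:
            raise ScaleFormatError(f"scale {name!r}: malformed entry {row}") from exc
        if "group" in row:
            groups[term] = row["group"]
    scale = LinguisticScale(role=role, entries=entries, q=q, name=name, groups=groups)
    scale.validate(strict_order=strict_order)
    return scale


def _csv_to_dict(text: str, role: str, q: int) -> dict:
    terms = []
    for row in csv.DictReader(io.StringIO(text)):
        entry = {
            "term": row["term"],
            "mu": [row["mu_low"], row["mu_high"]],
            "nu": [row["nu_low"], row["nu_high"]],
        }
        if row.get("group"):
            entry["group"] = row["group"]
        terms.append(entry)
    return {"role": role, "q": q, "terms": terms}


def builtin_scale(role: str, q: int = 3) -> LinguisticScale:
    """Packaged default scale for the given role.

    These are documented stand-in scales (symmetric 7-term rating ladder,
    9-term comparison ladder) constructed for the Fermatean rung; other
    rungs reuse the endpoints with feasibility repair via :meth:`with_q`.
    """
    if role not in VALID_ROLES:
        raise ValueError(f"role must be one of {VALID_ROLES}")
    fname = f"{role}_ivff_standin.json"
    ref = resources.files("ivffmcdm").joinpath("data", "scales", fname)
    scale = load_scale(json.loads(ref.read_text()), role=role, q=3)
    if q != 3:
        scale = scale.with_q(q)
    return scale
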