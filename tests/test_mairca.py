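"""Ideal-real gap (MAIRCA) ranking."""

import numpy as np
import pandas as pd
import pytest

import ivffmcdm as m


def brute_force_Q(crisp, weights, directions):
    """Independent plain-loop recomputation of the gap totals."""
    alts = list(crisp.index)
    crits = list(crisp.columns)
    mcount = len(alts)
    Q = {}
    for a in alts:
        total = 0.0
        for c in crits:
            col = [crisp.loc[b, c] for b in alts]
            hi, lo = max(col), min(col)
            if hi == lo:
                r = 1.0
            elif directions[c] == "benefit":
                r = (crisp.loc[a, c] - lo) / (hi - lo)
            else:
                r = (crisp.loc[a, c] - hi) / (lo - hi)
            tp = weights[c] / mcount
            total += tp - tp * r
        Q[a] = total
    return Q


@pytest.fixture
def random_instance(rng):
    def make(n_alt, n_crit):
        crisp = pd.DataFrame(
            rng.uniform(-1, 1, size=(n_alt, n_crit)),
            index=[f"A{i}" for i in range(n_alt)],
            columns=[f"C{j}" for j in range(n_crit)],
        )
        w = rng.uniform(0.1, 1.0, size=n_crit)
        weights = dict(zip(crisp.columns, w / w.sum()))
        directions = {
            c: ("benefit" if rng.random() < 0.5 else "cost")
            for c in crisp.columns
        }
        return crisp, weights, directions
    return make


def test_theoretical_matrix_values():
    spec = m.CriteriaSpec({"C1": 0.219, "C2": 0.781}, "benefit")
    t_P = m.theoretical_matrix(6, spec)
    assert t_P.shape == (6, 2)
    assert t_P["C1"].iloc[0] == pytest.approx(0.219 / 6)
    # all rows identical (equal a-priori preference)
    assert (t_P.nunique() == 1).all()


def test_normalize_extremes_and_directions():
    crisp = pd.DataFrame({"b": [0.2, 0.5, 0.8], "c": [0.2, 0.5, 0.8],
                          "const": [0.4, 0.4, 0.4]})
    spec = m.CriteriaSpec({"b": 0.4, "c": 0.4, "const": 0.2},
                          {"b": "benefit", "c": "cost", "const": "benefit"})
    r = m.normalize(crisp, spec)
    assert list(r["b"]) == pytest.approx([0.0, 0.5, 1.0])
    assert list(r["c"]) == pytest.approx([1.0, 0.5, 0.0])
    assert list(r["const"]) == pytest.approx([1.0, 1.0, 1.0])
    assert ((r >= 0) & (r <= 1)).all().all()


def test_negative_scores_are_harmless():
    crisp = pd.DataFrame({"b": [-0.9, -0.1, 0.3]})
    spec = m.CriteriaSpec({"b": 1.0}, "benefit")
    r = m.normalize(crisp, spec)
    assert list(r["b"]) == pytest.approx([0.0, 2 / 3, 1.0])


def test_column_best_everywhere_has_zero_gap():
    r = pd.DataFrame({"C1": [1.0, 0.2], "C2": [1.0, 0.0]}, index=["A", "B"])
    spec = m.CriteriaSpec({"C1": 0.5, "C2": 0.5}, "benefit")
    res = m.gaps_and_rank(m.theoretical_matrix(2, spec), r)
    assert res.Q["A"] == pytest.approx(0.0)
    assert res.ranks["A"] == 1
    assert res.ranks["B"] == 2


def test_gap_identity_and_bounds(random_instance):
    crisp, weights, directions = random_instance(5, 4)
    spec = m.CriteriaSpec(weights, directions)
    r = m.normalize(crisp, spec)
    res = m.gaps_and_rank(m.theoretical_matrix(5, spec), r)
    mcount = len(crisp.index)
    for a in crisp.index:
        identity = sum(
            (weights[c] / mcount) * (1.0 - r.loc[a, c]) for c in crisp.columns
        )
        assert res.Q[a] == pytest.approx(identity, abs=1e-12)
        assert 0.0 - 1e-12 <= res.Q[a] <= 1.0 / mcount + 1e-12
    assert ((res.gaps >= -1e-12) & (res.gaps <= res.theoretical + 1e-12)).all().all()
    assert res.ranks[res.Q.idxmin()] == 1


@pytest.mark.parametrize("shape", [(2, 2), (3, 3), (6, 12)])
def test_brute_force_oracle_equivalence(random_instance, shape):
    crisp, weights, directions = random_instance(*shape)
    spec = m.CriteriaSpec(weights, directions)
    res = m.gaps_and_rank(m.theoretical_matrix(shape[0], spec),
                          m.normalize(crisp, spec))
    oracle = brute_force_Q(crisp, weights, directions)
    for a in crisp.index:
        assert res.Q[a] == pytest.approx(oracle[a], abs=1e-12)


def test_rank_invariant_to_uniform_weight_rescaling(random_instance):
    crisp, weights, directions = random_instance(4, 3)
    spec = m.CriteriaSpec(weights, directions)
    r = m.normalize(crisp, spec)
    t_P = m.theoretical_matrix(4, spec)
    base = m.gaps_and_rank(t_P, r)
    scaled = m.gaps_and_rank(t_P * 7.5, r)
    assert (base.ranks == scaled.ranks).all()


def test_gap_tie_is_flagged():
    r = pd.DataFrame({"C1": [0.5, 0.5]}, index=["A", "B"])
    spec = m.CriteriaSpec({"C1": 1.0}, "benefit")
    res = m.gaps_and_rank(m.theoretical_matrix(2, spec), r)
    assert res.ranks["A"] == 1 and res.ranks["B"] == 2  # declaration order
    assert res.tie_note and "A" in res.tie_note


def test_aggregate_ratings_idempotent_and_single_dm(rating_scale):
    panel = m.RatingPanel(
        ["A1"], ["C1", "C2"],
        {"A1": {"C1": ["H", "H", "H"], "C2": ["ML", "ML", "ML"]}},
        m.DMWeights.equal(3),
    )
    agg = m.aggregate_ratings(panel, rating_scale)
    f = agg.loc["A1", "C1"]
    assert (f.mu_low, f.mu_high) == pytest.approx(
        (rating_scale["H"].mu_low, rating_scale["H"].mu_high))
    single = m.RatingPanel(
        ["A1"], ["C1"], {"A1": {"C1": ["MH"]}}, m.DMWeights([1.0]))
    g = m.aggregate_ratings(single, rating_scale).loc["A1", "C1"]
    assert g == rating_scale["MH"]


def test_fixture_panel_first_cell_endpoint_means(rating_panel, rating_scale):
    """First method / first criterion aggregates the panel's (MH, MH, H)
    terms to plain endpoint means under equal decision-maker weights."""
    assert rating_panel.ratings["EAM1"]["C1"] == ("MH", "MH", "H")
    agg = m.aggregate_ratings(rating_panel, rating_scale)
    f = agg.loc["EAM1", "C1"]
    mh, h = rating_scale["MH"], rating_scale["H"]
    assert f.mu_low == pytest.approx((2 * mh.mu_low + h.mu_low) / 3)
    assert f.nu_high == pytest.approx((2 * mh.nu_high + h.nu_high) / 3)


def test_incomplete_panel_rejected():
    with pytest.raises(ValueError, match="missing cell"):
        m.RatingPanel(["A1"], ["C1", "C2"], {"A1": {"C1": ["H"]}},
                      m.DMWeights([1.0]))


def test_rank_methods_end_to_end(rating_panel, rating_scale):
    weights = {c: 1.0 / 12 for c in rating_panel.criteria}
    res = m.rank_methods(rating_panel, m.CriteriaSpec(weights, "cost"),
                         rating_scale)
    assert sorted(res.ranks) == list(range(1, 7))
    assert res.Q.between(0, 1 / 6 + 1e-12).all()
    # spec criteria must exist in the panel
    bad = m.CriteriaSpec({"C99": 1.0}, "cost")
    with pytest.raises(ValueError, match="C99"):
        m.rank_methods(rating_panel, bad, rating_scale)
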