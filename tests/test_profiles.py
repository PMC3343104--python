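"""Relative quantitation and profile statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chctools import (
    ChcSampleTable,
    chain_length_regression,
    delta_correlation,
    delta_profile,
    expected_chance_significant,
    holm_correction,
    ln_transform,
    normalize_profile,
    pca_ancova,
    per_compound_anova,
)
from chctools.compounds import parse_compound_name, with_identified_flag
from conftest import balanced_two_way_anova_oracle, make_chc_table


# ---------------------------------------------------------------------------
# normalization

def test_single_compound_normalizes_to_one(make_table=make_chc_table):
    t = make_table({"s1": {"nC23": 4.0}}, {"s1": "control"}, {"s1": 6.0})
    n = normalize_profile(t)
    assert n.data["intensity"].tolist() == [1.0]
    assert n.state == "normalized"


def test_normalization_divides_by_identified_sum(toy_raw_table):
    n = normalize_profile(toy_raw_table)
    s1 = n.data[n.data.sample_id == "s1"].set_index("compound")["intensity"]
    assert np.allclose([s1["nC23"], s1["7-T"], s1["7,11-HD"]], [0.2, 0.3, 0.5])


def test_unidentified_compound_excluded_from_denominator():
    t = make_chc_table({"s1": {"nC23": 2.0, "7-T": 2.0, "C27H54O2": 6.0}},
                       {"s1": "control"}, {"s1": 6.0})
    desc = {nm: parse_compound_name(nm) for nm in ["nC23", "7-T", "C27H54O2"]}
    desc["C27H54O2"] = with_identified_flag(desc["C27H54O2"], False)
    n = normalize_profile(t, desc)
    vals = n.data.set_index("compound")["intensity"]
    assert np.allclose([vals["nC23"], vals["7-T"]], [0.5, 0.5])
    assert "C27H54O2" not in set(n.data["compound"])


def test_all_zero_sample_excluded_with_log():
    t = make_chc_table(
        {"s1": {"nC23": 0.0, "7-T": 0.0}, "s2": {"nC23": 1.0, "7-T": 3.0}},
        {"s1": "control", "s2": "control"}, {"s1": 6.0, "s2": 6.0})
    n = normalize_profile(t)
    assert set(n.data["sample_id"]) == {"s2"}
    assert n.meta["excluded_samples"][0]["sample_id"] == "s1"


def test_normalization_idempotent(toy_raw_table):
    n1 = normalize_profile(toy_raw_table)
    renormalized = normalize_profile(
        ChcSampleTable(n1.data.copy(), state="raw"))
    assert np.allclose(renormalized.data["intensity"].to_numpy(),
                       n1.data["intensity"].to_numpy(), atol=1e-12)


@settings(deadline=None, derandomize=True)
@given(c=st.floats(min_value=1e-6, max_value=1e6,
                   allow_nan=False, allow_infinity=False))
def test_per_sample_scale_invariance(c):
    """Multiplying one sample's raw intensities by c > 0 leaves its
    normalized profile unchanged — why per-compound detection efficiency
    cancels."""
    t = make_chc_table({"s1": {"nC23": 2.0, "7-T": 3.0, "7,11-HD": 5.0}},
                       {"s1": "control"}, {"s1": 6.0})
    scaled = ChcSampleTable(
        t.data.assign(intensity=t.data["intensity"] * c), state="raw")
    a = normalize_profile(t).data["intensity"].to_numpy()
    b = normalize_profile(scaled).data["intensity"].to_numpy()
    assert np.allclose(a, b, rtol=1e-9)


def test_normalized_sums_to_one(toy_raw_table):
    n = normalize_profile(toy_raw_table)
    sums = n.data.groupby("sample_id")["intensity"].sum()
    assert np.allclose(sums, 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# ln transform

def test_ln_transform_examples(toy_raw_table):
    one = make_chc_table({"s1": {"nC23": 4.0}}, {"s1": "control"}, {"s1": 6.0})
    ln = ln_transform(normalize_profile(one))
    assert ln.data["intensity"].tolist() == [0.0]  # ln 1 exactly

    n = normalize_profile(toy_raw_table)
    ln2 = ln_transform(n)
    assert np.allclose(ln2.data["intensity"].to_numpy(),
                       np.log(n.data["intensity"].to_numpy()))


def test_ln_transform_zero_uses_pseudocount():
    t = make_chc_table({"s1": {"nC23": 0.0, "7-T": 4.0}},
                       {"s1": "control"}, {"s1": 6.0})
    ln = ln_transform(normalize_profile(t))
    eps = ln.meta["epsilon"]
    assert eps == 0.5  # half of the smallest positive normalized value (1.0)
    vals = ln.data.set_index("compound")["intensity"]
    assert np.isfinite(vals["nC23"])
    assert vals["nC23"] == pytest.approx(np.log(eps))


# ---------------------------------------------------------------------------
# ANOVA + Holm

def _balanced_table(values):
    """2 genotypes x 2 ages x 3 reps, one compound; values in fixed order."""
    rows = []
    i = 0
    for geno in ("control", "mutant"):
        for age in (6.0, 23.0):
            for rep in range(3):
                rows.append((f"s{i}", geno, age, f"rep{rep}", "GCMS",
                             "nC23", values[i]))
                i += 1
    df = pd.DataFrame(rows, columns=[
        "sample_id", "genotype", "age_days", "replicate", "platform",
        "compound", "intensity"])
    return ChcSampleTable(df, state="ln_normalized")


def test_anova_matches_closed_form_oracle():
    values = [1.2, 1.5, 1.1, 2.0, 2.2, 1.9, 1.8, 1.6, 1.9, 2.9, 3.1, 2.8]
    t = _balanced_table(values)
    res = per_compound_anova(t, apply_holm=False)[0]
    oracle = balanced_two_way_anova_oracle(
        values,
        t.data["genotype"].tolist(),
        t.data["age_days"].tolist())
    assert res.F_genotype == pytest.approx(oracle["A"][0], abs=1e-8)
    assert res.p_genotype == pytest.approx(oracle["A"][1], abs=1e-8)
    assert res.F_age == pytest.approx(oracle["B"][0], abs=1e-8)
    assert res.F_interaction == pytest.approx(oracle["AB"][0], abs=1e-8)


def test_anova_zero_genotype_effect_gives_zero_F():
    # genotype cell means exactly equal at every age, nonzero noise
    values = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0,
              3.0, 2.0, 1.0, 6.0, 5.0, 4.0]
    res = per_compound_anova(_balanced_table(values), apply_holm=False)[0]
    assert res.F_genotype == pytest.approx(0.0, abs=1e-12)
    assert res.p_genotype == pytest.approx(1.0)


def test_anova_flags_zero_residual_df():
    rows = []
    for i, (geno, age) in enumerate(
            [("control", 6.0), ("control", 23.0),
             ("mutant", 6.0), ("mutant", 23.0)]):
        rows.append((f"s{i}", geno, age, "rep1", "GCMS", "nC23", float(i)))
    df = pd.DataFrame(rows, columns=[
        "sample_id", "genotype", "age_days", "replicate", "platform",
        "compound", "intensity"])
    res = per_compound_anova(ChcSampleTable(df, state="ln_normalized"))[0]
    assert res.flagged is not None
    assert np.isnan(res.p_genotype)
    assert res.holm_significant is None


def test_holm_step_down_examples():
    flags, thresholds = holm_correction([0.04], alpha=0.05)
    assert flags == [True]

    # 0.001 <= 0.05/4 passes; 0.02 > 0.05/3 stops the step-down there
    flags, thresholds = holm_correction([0.02, 0.001, 0.04, 0.03], alpha=0.05)
    assert flags == [False, True, False, False]
    assert thresholds == pytest.approx([0.05 / 4, 0.05 / 3, 0.05 / 2, 0.05])

    flags, _ = holm_correction([1.0, 1.0, 1.0], alpha=0.05)
    assert flags == [False, False, False]
    assert holm_correction([], alpha=0.05) == ([], [])


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=30))
def test_holm_between_bonferroni_and_unadjusted(pvals):
    """Holm rejects at least as much as Bonferroni, at most as much as the
    uncorrected tests; agrees with the statsmodels reference."""
    from statsmodels.stats.multitest import multipletests

    alpha = 0.05
    m = len(pvals)
    flags, _ = holm_correction(pvals, alpha)
    bonf = [p <= alpha / m for p in pvals]
    raw = [p <= alpha for p in pvals]
    assert all(h for h, b in zip(flags, bonf) if b)  # Bonferroni subset of Holm
    assert all(r for h, r in zip(flags, raw) if h)   # Holm subset of unadjusted
    assert sum(bonf) <= sum(flags) <= sum(raw)
    ref = multipletests(pvals, alpha=alpha, method="holm")[0]
    assert list(ref) == flags


def test_expected_chance_significant():
    assert expected_chance_significant(26, 0.05) == pytest.approx(1.3)
    assert expected_chance_significant(0, 0.05) == 0.0
    assert expected_chance_significant(12, 0.05) == pytest.approx(0.6)


# ---------------------------------------------------------------------------
# delta profiles / regressions / correlations

def _two_genotype_normalized():
    comps = {"nC23": 0.2, "7-T": 0.3, "7,11-HD": 0.5}
    values, geno, age = {}, {}, {}
    i = 0
    for g, mult in (("control", 1.0), ("mutant", 1.0)):
        for a in (6.0, 23.0):
            values[f"s{i}"] = {k: v * mult for k, v in comps.items()}
            geno[f"s{i}"] = g
            age[f"s{i}"] = a
            i += 1
    t = make_chc_table(values, geno, age)
    return normalize_profile(t)


def test_delta_profile_identical_groups_is_zero():
    n = _two_genotype_normalized()
    d = delta_profile(n, "mutant", "control")
    assert np.allclose(d.difference, 0.0)
    assert np.allclose(d.percent_change, 0.0)


def test_delta_profile_arithmetic():
    t = make_chc_table(
        {"s1": {"nC23": 0.2, "7-T": 0.8}, "s2": {"nC23": 0.1, "7-T": 0.9}},
        {"s1": "control", "s2": "mutant"}, {"s1": 6.0, "s2": 6.0})
    n = ChcSampleTable(t.data, state="normalized")
    d = delta_profile(n, "mutant", "control", mode="single_age")
    by = dict(zip(d.compounds, zip(d.difference, d.percent_change)))
    assert by["nC23"][0] == pytest.approx(-0.1)
    assert by["nC23"][1] == pytest.approx(-50.0)


def test_delta_profile_unbalanced_ages_rejected():
    t = make_chc_table(
        {"s1": {"nC23": 0.5}, "s2": {"nC23": 0.5}},
        {"s1": "control", "s2": "mutant"}, {"s1": 6.0, "s2": 23.0})
    n = ChcSampleTable(t.data, state="normalized")
    with pytest.raises(ValueError, match="same ages"):
        delta_profile(n, "mutant", "control")


def test_delta_profile_zero_control_mean_flagged():
    t = make_chc_table(
        {"s1": {"nC23": 0.0, "7-T": 1.0}, "s2": {"nC23": 0.3, "7-T": 0.7}},
        {"s1": "control", "s2": "mutant"}, {"s1": 6.0, "s2": 6.0})
    n = ChcSampleTable(t.data, state="normalized")
    d = delta_profile(n, "mutant", "control", mode="single_age")
    assert "nC23" in d.undefined_percent
    assert np.isnan(d.percent_change[d.compounds.index("nC23")])


def _delta_from_points(points):
    from chctools.profiles import DeltaProfile

    comps = [f"nC{c}" for c, _ in points]
    pct = np.array([p for _, p in points], dtype=float)
    return DeltaProfile("m", "c", "single_age", comps,
                        np.zeros(len(points)), pct)


def test_chain_length_regression_exact_line():
    d = _delta_from_points([(23, -10), (25, 0), (27, 10), (29, 20)])
    slope, intercept, p = chain_length_regression(d)
    assert slope == pytest.approx(5.0)          # exactly collinear points
    assert intercept == pytest.approx(5.0 - 5.0 * 26)
    assert p < 1e-6


def test_chain_length_regression_sign_flip_negates_slope():
    d = _delta_from_points([(23, -10), (25, 3), (27, 10), (29, 18)])
    s1, _, p1 = chain_length_regression(d)
    d2 = _delta_from_points([(23, 10), (25, -3), (27, -10), (29, -18)])
    s2, _, p2 = chain_length_regression(d2)
    assert s2 == pytest.approx(-s1)
    assert p2 == pytest.approx(p1)


def test_chain_length_regression_degenerate_inputs():
    flat = _delta_from_points([(23, 0), (25, 0), (27, 0), (29, 0)])
    slope, intercept, p = chain_length_regression(flat)
    assert slope == 0.0 and intercept == 0.0

    same_carbon = _delta_from_points([(25, 1), (25, 2), (25, 3)])
    with pytest.raises(ValueError, match="carbon"):
        chain_length_regression(same_carbon)


def test_delta_correlation_matches_product_moment_formula():
    a = _delta_from_points([(23, 0), (25, 0), (27, 0), (29, 0), (31, 0)])
    b = _delta_from_points([(23, 0), (25, 0), (27, 0), (29, 0), (31, 0)])
    a.difference = np.array([0.5, -1.0, 2.0, 0.3, -0.8])
    b.difference = np.array([1.1, -0.4, 1.5, 0.9, -1.2])
    r, slope, p = delta_correlation(a, b)
    x, y = a.difference, b.difference
    r_manual = (np.sum((x - x.mean()) * (y - y.mean()))
                / np.sqrt(np.sum((x - x.mean()) ** 2)
                          * np.sum((y - y.mean()) ** 2)))
    assert r == pytest.approx(float(r_manual), abs=1e-12)

    b.difference = a.difference.copy()
    assert delta_correlation(a, b)[0] == pytest.approx(1.0)
    b.difference = -a.difference
    assert delta_correlation(a, b)[0] == pytest.approx(-1.0)


def test_delta_correlation_needs_shared_compounds():
    a = _delta_from_points([(23, 0), (25, 0), (27, 0)])
    b = _delta_from_points([(31, 0), (33, 0), (35, 0)])
    with pytest.raises(ValueError, match="shared"):
        delta_correlation(a, b)


# ---------------------------------------------------------------------------
# PCA + ANCOVA

def _pca_table(matrix, genotypes, ages, compounds):
    rows = []
    for i, (row, g, a) in enumerate(zip(matrix, genotypes, ages)):
        for cpd, v in zip(compounds, row):
            rows.append((f"s{i}", g, a, "rep1", "GCMS", cpd, v))
    df = pd.DataFrame(rows, columns=[
        "sample_id", "genotype", "age_days", "replicate", "platform",
        "compound", "intensity"])
    return ChcSampleTable(df, state="ln_normalized")


def test_pca_variance_fractions_sum_to_one_and_decrease():
    rng = np.random.default_rng(7)
    mat = rng.normal(size=(12, 4))
    t = _pca_table(mat, ["control"] * 6 + ["mutant"] * 6,
                   [6, 23, 37, 48] * 3, ["nC23", "7-T", "7,11-HD", "nC25"])
    res = pca_ancova(t, n_components=2)
    assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(np.diff(res.variance_fractions) <= 1e-12)


def test_pca_rank_one_correlation():
    rng = np.random.default_rng(3)
    x = rng.normal(size=10)
    mat = np.column_stack([x, 2.0 * x + 1.0])  # perfectly correlated pair
    t = _pca_table(mat, ["control"] * 5 + ["mutant"] * 5,
                   [6, 23] * 5, ["nC23", "7-T"])
    res = pca_ancova(t, n_components=1)
    assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)


def test_pca_eigenvalues_match_independent_solver():
    """Compare against an SVD of the standardized matrix — an independent
    route to the correlation-matrix spectrum."""
    rng = np.random.default_rng(11)
    mat = rng.normal(size=(9, 3)) @ np.array(
        [[1.0, 0.4, 0.1], [0.0, 1.0, 0.3], [0.0, 0.0, 1.0]])
    t = _pca_table(mat, ["control"] * 5 + ["mutant"] * 4,
                   [6, 23, 37] * 3, ["nC23", "7-T", "7,11-HD"])
    res = pca_ancova(t, n_components=3)
    z = (mat - mat.mean(0)) / mat.std(0, ddof=1)
    s = np.linalg.svd(z, compute_uv=False)
    eig = (s ** 2) / (len(mat) - 1)
    assert np.allclose(res.variance_fractions * 3, np.sort(eig)[::-1],
                       atol=1e-8)


def test_pca_ancova_detects_genotype_shift_and_reports_interaction():
    rng = np.random.default_rng(5)
    n_per = 8
    ages = np.tile([6.0, 23.0, 37.0, 48.0], 4)
    geno = ["control"] * 16 + ["mutant"] * 16
    shift = np.where(np.array(geno) == "mutant", 3.0, 0.0)
    base = rng.normal(size=(32, 3)) * 0.3
    mat = base + shift[:, None] + 0.05 * np.tile(ages, 2)[:, None]
    t = _pca_table(mat, geno, np.tile(ages, 2), ["nC23", "7-T", "7,11-HD"])
    res = pca_ancova(t, n_components=2)
    pc1 = res.ancova[0]
    assert pc1.p_genotype < 0.01
    assert pc1.p_age < 0.05
    # shift and slope are parallel across genotypes by construction
    assert pc1.p_interaction > 0.01


def test_pca_drops_zero_variance_compound():
    rng = np.random.default_rng(9)
    mat = np.column_stack([rng.normal(size=8), rng.normal(size=8),
                           np.full(8, 2.5)])
    t = _pca_table(mat, ["control"] * 4 + ["mutant"] * 4,
                   [6, 23] * 4, ["nC23", "7-T", "flat"])
    res = pca_ancova(t, n_components=2)
    assert res.dropped_compounds == ["flat"]
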