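import itertools

import numpy as np
import pandas as pd
import pytest

from chctools import ChcSampleTable


def balanced_two_way_anova_oracle(values, factor_a, factor_b):
    """Closed-form balanced two-way ANOVA with interaction.

    Textbook decomposition for an a x b design with r replicates per cell:
    SS_A = br * sum_i (mean_Ai - GM)^2, SS_B likewise, SS_AB from the cell
    means, SS_E from within-cell deviations. Independent of any model-fit
    machinery. Returns dict of (F, p) per term.
    """
    from scipy import stats

    df = pd.DataFrame({"y": values, "A": factor_a, "B": factor_b})
    a_levels = sorted(set(factor_a))
    b_levels = sorted(set(factor_b))
    a, b = len(a_levels), len(b_levels)
    r = len(df) // (a * b)
    assert len(df) == a * b * r, "oracle requires a balanced design"
    gm = df["y"].mean()
    ss_a = b * r * sum((df[df.A == ai].y.mean() - gm) ** 2 for ai in a_levels)
    ss_b = a * r * sum((df[df.B == bi].y.mean() - gm) ** 2 for bi in b_levels)
    ss_cells = r * sum(
        (df[(df.A == ai) & (df.B == bi)].y.mean() - gm) ** 2
        for ai, bi in itertools.product(a_levels, b_levels))
    ss_ab = ss_cells - ss_a - ss_b
    ss_e = sum(
        ((df[(df.A == ai) & (df.B == bi)].y
          - df[(df.A == ai) & (df.B == bi)].y.mean()) ** 2).sum()
        for ai, bi in itertools.product(a_levels, b_levels))
    df_a, df_b, df_ab, df_e = a - 1, b - 1, (a - 1) * (b - 1), a * b * (r - 1)
    ms_e = ss_e / df_e
    out = {}
    for term, ss, dfn in (("A", ss_a, df_a), ("B", ss_b, df_b),
                          ("AB", ss_ab, df_ab)):
        f = (ss / dfn) / ms_e
        out[term] = (f, float(stats.f.sf(f, dfn, df_e)))
    return out


def exhaustive_flip_pvalues(preferences, statistic="mean"):
    """Enumerate all 2^k per-trial label flips; raw tail proportions.

    The unsmoothed oracle for the stratified permutation test: for every
    flip pattern each preference p either stays or becomes 100 - p; ties
    count as extreme.
    """
    prefs = np.asarray(preferences, dtype=float)
    k = prefs.size
    stat = np.mean if statistic == "mean" else np.median
    observed = stat(prefs)
    vals = []
    for pattern in itertools.product([False, True], repeat=k):
        flipped = np.where(pattern, 100.0 - prefs, prefs)
        vals.append(stat(flipped))
    vals = np.asarray(vals)
    upper = np.mean(vals >= observed)
    lower = np.mean(vals <= observed)
    return float(upper), float(lower)


@pytest.fixture
def toy_raw_table():
    """Two genotypes x one age, two samples, three identified compounds."""
    rows = []
    intensities = {"s1": {"nC23": 2.0, "7-T": 3.0, "7,11-HD": 5.0},
                   "s2": {"nC23": 1.0, "7-T": 1.0, "7,11-HD": 2.0}}
    genotype = {"s1": "control", "s2": "mutant"}
    for sid, comps in intensities.items():
        for cpd, val in comps.items():
            rows.append((sid, genotype[sid], 6.0, "rep1", "GCMS", cpd, val))
    df = pd.DataFrame(rows, columns=[
        "sample_id", "genotype", "age_days", "replicate", "platform",
        "compound", "intensity"])
    return ChcSampleTable(df, state="raw")


def make_chc_table(values_by_sample, genotype_by_sample, age_by_sample):
    """Build a raw-state table from nested dicts (used by several tests)."""
    rows = []
    for sid, comps in values_by_sample.items():
        for cpd, val in comps.items():
            rows.append((sid, genotype_by_sample[sid], age_by_sample[sid],
                         "rep1", "GCMS", cpd, val))
    df = pd.DataFrame(rows, columns=[
        "sample_id", "genotype", "age_days", "replicate", "platform",
        "compound", "intensity"])
    return ChcSampleTable(df, state="raw")
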