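"""Relative quantitation and profile-level statistics for CHC intensity tables.

Both GC/MS chromatographic peak areas and intact-fly LDI-MS ion signals
carry unknown compound-specific detection efficiencies, so absolute levels
are unrecoverable; every analysis here starts from per-sample relative
intensities (each identified hydrocarbon divided by the summed intensity of
all identified hydrocarbons in that sample). On top of the normalized table
the module provides the profile statistics used in insulin-signaling /
pheromone studies: per-compound two-factor ANOVA (genotype x age) with a
Holm step-down correction, chance-expectation accounting, genotype delta
profiles and their chain-length regression, cross-manipulation delta
correlations, and correlation-matrix PCA followed by per-component ANCOVA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .compounds import CompoundDescriptor, parse_compound_name

__all__ = [
    "ChcSampleTable",
    "CompoundTestResult",
    "DeltaProfile",
    "PcaAncovaResult",
    "normalize_profile",
    "ln_transform",
    "per_compound_anova",
    "holm_correction",
    "expected_chance_significant",
    "delta_profile",
    "chain_length_regression",
    "delta_correlation",
    "pca_ancova",
]

_REQUIRED_COLUMNS = [
    "sample_id", "genotype", "age_days", "replicate", "platform",
    "compound", "intensity",
]


@dataclass
class ChcSampleTable:
    """Long-format samples x compounds intensity table with metadata.

    ``state`` tracks the processing stage: ``raw`` intensities straight from
    the instrument, ``normalized`` per-sample relative intensities, or
    ``ln_normalized`` after the natural-log transform. ``meta`` records
    processing provenance (pseudo-count epsilon, excluded samples, ...).
    """

    data: pd.DataFrame
    state: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"ChcSampleTable missing columns: {missing}")
        if self.state not in ("raw", "normalized", "ln_normalized"):
            raise ValueError(f"unknown state {self.state!r}")
        if self.state in ("raw", "normalized"):
            if (self.data["intensity"] < 0).any():
                raise ValueError(f"negative intensities in {self.state} state")

    def pivot(self) -> pd.DataFrame:
        """Samples x compounds wide matrix (compounds in input order)."""
        order = list(dict.fromkeys(self.data["compound"]))
        wide = self.data.pivot_table(
            index="sample_id", columns="compound", values="intensity", sort=False
        )
        return wide.reindex(columns=order)

    def sample_metadata(self) -> pd.DataFrame:
        """One row per sample: genotype, age, replicate, platform."""
        cols = ["sample_id", "genotype", "age_days", "replicate", "platform"]
        return self.data[cols].drop_duplicates("sample_id").set_index("sample_id")


@dataclass
class CompoundTestResult:
    """Two-factor ANOVA outcome for one compound."""

    compound: str
    F_genotype: float
    p_genotype: float
    F_age: float
    p_age: float
    F_interaction: float
    p_interaction: float
    holm_significant: bool | None = None
    flagged: str | None = None


@dataclass
class DeltaProfile:
    """Per-compound effect of a genetic manipulation versus its control.

    ``difference`` is manipulation minus control in mean normalized
    intensity; ``percent_change`` is that difference as a percentage of the
    control mean (NaN, with the compound listed in ``undefined_percent``,
    when the control mean is zero).
    """

    manipulation: str
    control: str
    mode: str
    compounds: list[str]
    difference: np.ndarray
    percent_change: np.ndarray
    undefined_percent: list[str] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"compound": self.compounds,
             "difference": self.difference,
             "percent_change": self.percent_change}
        )


@dataclass
class AncovaReport:
    """Per-component ANCOVA terms: genotype, age covariate, interaction."""

    component: int
    genotype_effect: float
    p_genotype: float
    age_slope: float
    p_age: float
    p_interaction: float


@dataclass
class PcaAncovaResult:
    scores: pd.DataFrame               # samples x retained components
    loadings: pd.DataFrame             # compounds x retained components
    variance_fractions: np.ndarray     # over ALL components; sums to 1
    ancova: list[AncovaReport]
    dropped_compounds: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# relative quantitation

def normalize_profile(
    table: ChcSampleTable,
    descriptors: Mapping[str, CompoundDescriptor] | None = None,
) -> ChcSampleTable:
    """Divide each identified hydrocarbon by its sample's identified sum.

    Compounds not flagged as identified hydrocarbons are excluded from the
    denominator and dropped from the output. Samples whose identified
    intensities are all zero cannot be normalized; they are excluded and
    recorded in ``meta['excluded_samples']``.
    """
    if table.state != "raw":
        raise ValueError("normalize_profile expects a raw-state table")
    df = table.data.copy()
    if descriptors is None:
        descriptors = {name: parse_compound_name(name)
                       for name in df["compound"].unique()}
    identified = df["compound"].map(
        lambda nm: descriptors[nm].is_identified_hydrocarbon
        if nm in descriptors
        else (_ for _ in ()).throw(
            KeyError(f"no descriptor for compound {nm!r}"))
    )
    df = df[np.asarray(identified, dtype=bool)].copy()
    if df.empty:
        raise ValueError("no identified hydrocarbons in table")

    sums = df.groupby("sample_id")["intensity"].transform("sum")
    per_sample_total = df.groupby("sample_id")["intensity"].sum()
    bad = per_sample_total[per_sample_total <= 0].index.tolist()
    excluded = [
        {"sample_id": s, "reason": "all identified intensities zero"} for s in bad
    ]
    keep = ~df["sample_id"].isin(bad)
    df = df[keep].copy()
    df["intensity"] = df["intensity"] / sums[keep]
    meta = dict(table.meta)
    meta["excluded_samples"] = meta.get("excluded_samples", []) + excluded
    return ChcSampleTable(df.reset_index(drop=True), state="normalized", meta=meta)


def ln_transform(table: ChcSampleTable) -> ChcSampleTable:
    """Natural-log transform of a normalized table.

    Zero relative intensities (chromatographic non-detections) are floored
    at a pseudo-count epsilon equal to half the smallest positive normalized
    intensity in the table, so every value stays finite; epsilon is recorded
    in ``meta['epsilon']``. Values at or above epsilon are mapped by ln
    exactly, so a relative intensity of 1 transforms to 0.
    """
    if table.state != "normalized":
        raise ValueError("ln_transform expects a normalized-state table")
    df = table.data.copy()
    positive = df.loc[df["intensity"] > 0, "intensity"]
    if positive.empty:
        raise ValueError("table has no positive intensities")
    eps = 0.5 * float(positive.min())
    df["intensity"] = np.log(np.maximum(df["intensity"].to_numpy(), eps))
    meta = dict(table.meta)
    meta["epsilon"] = eps
    return ChcSampleTable(df, state="ln_normalized", meta=meta)


# ---------------------------------------------------------------------------
# per-compound ANOVA and multiplicity

def per_compound_anova(
    table: ChcSampleTable,
    alpha: float = 0.05,
    apply_holm: bool = True,
) -> list[CompoundTestResult]:
    """Two-factor ANOVA (genotype x age, with interaction) per compound.

    Fits on the ln scale with both factors categorical and Type II sums of
    squares (identical to Type I/III on balanced designs). Compounds whose
    model has no residual degrees of freedom are flagged, their p-values set
    missing, and they are excluded from the Holm correction.
    """
    if table.state != "ln_normalized":
        raise ValueError("per_compound_anova expects an ln_normalized table")
    df = table.data
    if df["genotype"].nunique() < 2 or df["age_days"].nunique() < 2:
        raise ValueError("need >=2 levels of genotype and age")

    results: list[CompoundTestResult] = []
    for compound in dict.fromkeys(df["compound"]):
        sub = df[df["compound"] == compound]
        n_cells = sub.groupby(["genotype", "age_days"]).ngroups
        if len(sub) - n_cells <= 0:
            results.append(CompoundTestResult(
                compound, math.nan, math.nan, math.nan, math.nan,
                math.nan, math.nan, flagged="no residual degrees of freedom"))
            continue
        model = smf.ols(
            "intensity ~ C(genotype) * C(age_days)", data=sub).fit()
        tab = sm.stats.anova_lm(model, typ=2)
        results.append(CompoundTestResult(
            compound,
            float(tab.loc["C(genotype)", "F"]),
            float(tab.loc["C(genotype)", "PR(>F)"]),
            float(tab.loc["C(age_days)", "F"]),
            float(tab.loc["C(age_days)", "PR(>F)"]),
            float(tab.loc["C(genotype):C(age_days)", "F"]),
            float(tab.loc["C(genotype):C(age_days)", "PR(>F)"]),
        ))
    if apply_holm:
        testable = [r for r in results if r.flagged is None]
        flags, _ = holm_correction([r.p_genotype for r in testable], alpha)
        for r, sig in zip(testable, flags):
            r.holm_significant = bool(sig)
    return results


def holm_correction(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[list[bool], list[float]]:
    """Holm step-down multiple-testing correction.

    Sort p ascending; compare the k-th smallest (1-based) to
    alpha / (m - k + 1); stop at the first failure; everything before it is
    significant. Returns flags in input order plus the per-rank thresholds
    (in sorted-rank order).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    m = len(p_values)
    if m == 0:
        return [], []
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    order = np.argsort(p, kind="stable")
    thresholds = [alpha / (m - k) for k in range(m)]
    flags = [False] * m
    for rank, idx in enumerate(order):
        if p[idx] <= thresholds[rank]:
            flags[idx] = True
        else:
            break
    return flags, thresholds


def expected_chance_significant(n_tests: int, alpha: float) -> float:
    """Expected number of false-positive tests under the global null."""
    if n_tests < 0:
        raise ValueError("n_tests must be >= 0")
    return n_tests * alpha


# ---------------------------------------------------------------------------
# delta profiles, chain-length regression, delta correlations

def delta_profile(
    table: ChcSampleTable,
    manipulation: str,
    control: str,
    mode: str = "main_effect_across_ages",
) -> DeltaProfile:
    """Per-compound change of a manipulation versus its control.

    ``main_effect_across_ages`` averages per-age group means with equal
    weight per age (an ANOVA main effect under equal cell weighting) and
    requires both genotypes to have been measured at the same ages;
    ``single_age`` uses plain group means over whatever rows are present.
    """
    if table.state != "normalized":
        raise ValueError("delta_profile expects a normalized-state table")
    if mode not in ("main_effect_across_ages", "single_age"):
        raise ValueError(f"unknown mode {mode!r}")
    df = table.data
    for label in (manipulation, control):
        if label not in set(df["genotype"]):
            raise ValueError(f"genotype {label!r} not present")
    sub = df[df["genotype"].isin([manipulation, control])]

    if mode == "main_effect_across_ages":
        ages_m = set(sub.loc[sub["genotype"] == manipulation, "age_days"])
        ages_c = set(sub.loc[sub["genotype"] == control, "age_days"])
        if ages_m != ages_c:
            raise ValueError(
                "main_effect_across_ages requires both genotypes measured "
                f"at the same ages (got {sorted(ages_m)} vs {sorted(ages_c)})")
        per_age = (sub.groupby(["compound", "genotype", "age_days"], sort=False)
                   ["intensity"].mean())
        means = per_age.groupby(["compound", "genotype"]).mean()
    else:
        means = sub.groupby(["compound", "genotype"], sort=False)["intensity"].mean()

    compounds = list(dict.fromkeys(sub["compound"]))
    diff = np.empty(len(compounds))
    pct = np.empty(len(compounds))
    undefined: list[str] = []
    for i, cpd in enumerate(compounds):
        m = means.get((cpd, manipulation), np.nan)
        c = means.get((cpd, control), np.nan)
        diff[i] = m - c
        if c == 0:
            pct[i] = np.nan
            undefined.append(cpd)
        else:
            pct[i] = 100.0 * (m - c) / c
    return DeltaProfile(manipulation, control, mode, compounds, diff, pct, undefined)


def chain_length_regression(
    delta: DeltaProfile,
    descriptors: Mapping[str, CompoundDescriptor] | None = None,
) -> tuple[float, float, float]:
    """OLS of per-compound percent change on carbon-chain length.

    Returns (slope in percent per carbon, intercept, two-sided p for a
    nonzero slope). Compounds with undefined percent change are dropped.
    """
    if descriptors is None:
        descriptors = {nm: parse_compound_name(nm) for nm in delta.compounds}
    xs, ys = [], []
    for cpd, pc in zip(delta.compounds, delta.percent_change):
        if np.isfinite(pc) and cpd in descriptors:
            xs.append(descriptors[cpd].carbon_count)
            ys.append(pc)
    if len(xs) < 3:
        raise ValueError("need >=3 compounds with defined percent change")
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("all carbon counts identical: degenerate design")
    if np.allclose(y, y[0]):
        # zero-variance response: slope 0, no evidence against the null
        return 0.0, float(y[0]), 1.0
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.pvalue)


def delta_correlation(
    delta_a: DeltaProfile, delta_b: DeltaProfile
) -> tuple[float, float, float]:
    """Correlate two manipulations' per-compound differences.

    Returns (Pearson r, OLS slope of B's differences on A's, two-sided p
    for the slope) over the compounds shared by both profiles.
    """
    shared = [c for c in delta_a.compounds if c in set(delta_b.compounds)]
    if len(shared) < 3:
        raise ValueError("need >=3 shared compounds")
    a_map = dict(zip(delta_a.compounds, delta_a.difference))
    b_map = dict(zip(delta_b.compounds, delta_b.difference))
    x = np.array([a_map[c] for c in shared])
    y = np.array([b_map[c] for c in shared])
    fit = stats.linregress(x, y)
    return float(fit.rvalue), float(fit.slope), float(fit.pvalue)


# ---------------------------------------------------------------------------
# PCA on correlations + ANCOVA

def pca_ancova(
    table: ChcSampleTable,
    n_components: int = 2,
) -> PcaAncovaResult:
    """Correlation-matrix PCA of CHC profiles, then per-component ANCOVA.

    Compounds are standardized to zero mean and unit variance, so the PCA
    diagonalizes the compound correlation matrix and every compound
    contributes equally regardless of abundance. For each retained
    component an ANCOVA with genotype (factor), age (continuous covariate)
    and their interaction is fitted; a non-significant interaction supports
    "parallel aging" of the genotypes in profile space.
    """
    if table.state not in ("normalized", "ln_normalized"):
        raise ValueError("pca_ancova expects normalized or ln_normalized data")
    wide = table.pivot()
    meta = table.sample_metadata().loc[wide.index]
    if meta["genotype"].value_counts().min() < 2:
        raise ValueError("need >=2 samples per genotype")
    if len(wide) <= n_components:
        raise ValueError("need more samples than requested components")

    sd = wide.std(axis=0, ddof=1)
    dropped = sd[(sd == 0) | sd.isna()].index.tolist()
    wide = wide.drop(columns=dropped)
    if wide.shape[1] < 2:
        raise ValueError("fewer than 2 variable compounds after dropping")
    z = (wide - wide.mean(axis=0)) / wide.std(axis=0, ddof=1)

    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    fractions = eigvals / eigvals.sum()

    k = min(n_components, len(eigvals))
    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(
        z.to_numpy() @ eigvecs[:, :k], index=wide.index, columns=comp_names)
    loadings = pd.DataFrame(
        eigvecs[:, :k] * np.sqrt(eigvals[:k]), index=wide.columns,
        columns=comp_names)

    reports: list[AncovaReport] = []
    two_genotypes = meta["genotype"].nunique() == 2
    for i, name in enumerate(comp_names):
        frame = pd.DataFrame({
            "score": scores[name],
            "genotype": meta["genotype"],
            "age_days": meta["age_days"].astype(float),
        })
        model = smf.ols("score ~ C(genotype) * age_days", data=frame).fit()
        tab = sm.stats.anova_lm(model, typ=2)
        geno_coef = math.nan
        if two_genotypes:
            geno_terms = [t for t in model.params.index
                          if t.startswith("C(genotype)")]
            if geno_terms:
                geno_coef = float(model.params[geno_terms[0]])
        reports.append(AncovaReport(
            component=i + 1,
            genotype_effect=geno_coef,
            p_genotype=float(tab.loc["C(genotype)", "PR(>F)"]),
            age_slope=float(model.params.get("age_days", math.nan)),
            p_age=float(tab.loc["age_days", "PR(>F)"]),
            p_interaction=float(tab.loc["C(genotype):age_days", "PR(>F)"]),
        ))
    return PcaAncovaResult(scores, loadings, fractions, reports, dropped)
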