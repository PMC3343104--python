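"""Relative qPCR expression by the ddCt method with replicate-based z-tests.

Cycle thresholds (Ct) are normalized to a reference gene (rp49 in fly
work): dCt = Ct_gene - Ct_reference per condition and biological replicate,
ddCt = dCt_manipulated - dCt_control, and the fold change is 2^-ddCt,
reported on the natural-log scale (ln FC = -ddCt * ln 2). Technical PCR
replicates are averaged to one Ct per extraction before any differencing.
Significance of a nonzero ln fold change is assessed with a z-test over
biological replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtTable",
    "FoldChangeResult",
    "delta_delta_ct",
    "z_test_fold_change",
    "analyze_gene",
]

MANIPULATED = "manipulated"
CONTROL = "control"

_REQUIRED = ["condition", "bio_rep", "tech_rep", "gene", "ct"]


@dataclass
class CtTable:
    """Long-format Ct table: condition, bio_rep, tech_rep, gene, ct."""

    data: pd.DataFrame
    reference_gene: str = "rp49"

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"CtTable missing columns: {missing}")
        bad = ~np.isfinite(self.data["ct"]) | (self.data["ct"] <= 0)
        if bad.any():
            raise ValueError("Ct values must be finite and > 0")
        conditions = set(self.data["condition"])
        if not conditions <= {MANIPULATED, CONTROL}:
            raise ValueError(f"conditions must be '{MANIPULATED}'/'{CONTROL}', "
                             f"got {sorted(conditions)}")
        if self.reference_gene not in set(self.data["gene"]):
            raise ValueError(f"reference gene {self.reference_gene!r} absent")

    def genes(self) -> list[str]:
        return [g for g in dict.fromkeys(self.data["gene"])]


@dataclass
class FoldChangeResult:
    gene: str
    ln_fold_change: float
    se: float
    z: float
    p_two_sided: float
    n_biological_replicates: int
    degenerate: bool = False


def _mean_ct(table: CtTable) -> pd.DataFrame:
    """Average technical replicates: one Ct per (condition, bio_rep, gene)."""
    return (table.data.groupby(["condition", "bio_rep", "gene"], sort=False)
            ["ct"].mean().reset_index())


def delta_delta_ct(
    table: CtTable,
    gene: str,
    reference: str | None = None,
    pairing: str = "auto",
) -> tuple[np.ndarray, list[str]]:
    """Per-biological-replicate ln fold changes for one gene.

    dCt = Ct_gene - Ct_reference within each (condition, biological
    replicate); ddCt = dCt_manipulated - dCt_control; ln fold change =
    -ddCt * ln 2. With ``pairing='auto'`` manipulated and control replicates
    sharing a label are paired; when the label sets differ each manipulated
    replicate is compared against the mean control dCt
    (``pairing='control-mean'`` forces the latter). Replicates missing a
    reference Ct are dropped and reported in the returned log.

    Returns (ln fold changes, one per usable manipulated replicate; log of
    dropped replicates).
    """
    reference = reference or table.reference_gene
    if gene == reference:
        raise ValueError("target gene must differ from the reference gene")
    if pairing not in ("auto", "paired", "control-mean"):
        raise ValueError(f"unknown pairing {pairing!r}")
    means = _mean_ct(table)
    log: list[str] = []

    def dcts(condition: str) -> dict[str, float]:
        sub = means[means["condition"] == condition]
        by_rep: dict[str, float] = {}
        for rep, grp in sub.groupby("bio_rep", sort=False):
            cts = dict(zip(grp["gene"], grp["ct"]))
            if reference not in cts:
                log.append(f"{condition}/{rep}: no reference Ct, dropped")
                continue
            if gene not in cts:
                log.append(f"{condition}/{rep}: no {gene} Ct, dropped")
                continue
            by_rep[rep] = cts[gene] - cts[reference]
        return by_rep

    dct_m = dcts(MANIPULATED)
    dct_c = dcts(CONTROL)
    if not dct_m or not dct_c:
        raise ValueError(f"no usable replicates for gene {gene!r}")

    labels_match = set(dct_m) == set(dct_c)
    if pairing == "paired" and not labels_match:
        raise ValueError("paired mode requires matching replicate labels")
    if (pairing == "paired") or (pairing == "auto" and labels_match):
        ddct = np.array([dct_m[r] - dct_c[r] for r in dct_m])
    else:
        control_mean = float(np.mean(list(dct_c.values())))
        ddct = np.array([v - control_mean for v in dct_m.values()])
    return -ddct * math.log(2.0), log


def z_test_fold_change(
    gene: str, ln_fold_changes: np.ndarray, use_t: bool = False
) -> FoldChangeResult:
    """z-test of the mean ln fold change over biological replicates.

    z = mean / (sd / sqrt(n)); two-sided p from the standard normal (the
    conventional choice in ddCt reports despite small n; ``use_t`` swaps in
    a t reference distribution with n-1 degrees of freedom). The SE
    reflects variability among biological replicates.
    """
    x = np.asarray(ln_fold_changes, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need >=2 biological replicates")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    se = sd / math.sqrt(n)
    if se == 0:
        if mean == 0:
            return FoldChangeResult(gene, 0.0, 0.0, 0.0, 1.0, n, degenerate=True)
        return FoldChangeResult(gene, mean, 0.0, math.inf, 0.0, n,
                                degenerate=True)
    z = mean / se
    if use_t:
        p = 2 * float(stats.t.sf(abs(z), df=n - 1))
    else:
        p = 2 * float(stats.norm.sf(abs(z)))
    return FoldChangeResult(gene, mean, se, z, p, n)


def analyze_gene(
    table: CtTable,
    gene: str,
    reference: str | None = None,
    pairing: str = "auto",
    use_t: bool = False,
) -> FoldChangeResult:
    """ddCt + z-test for one gene against the table's reference gene."""
    lnfc, _ = delta_delta_ct(table, gene, reference, pairing)
    return z_test_fold_change(gene, lnfc, use_t=use_t)
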