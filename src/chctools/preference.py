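"""Two-choice attractiveness scoring and preference statistics.

A single male is offered two immobilized target flies (one carrying the
genetic manipulation, one its control). Video trials score the time the
male spends inside a 3 mm circle around each target over a 30 min
recording; live trials score hand-timed courtship bouts over 10 min.
Preference is the percentage of target-attributed time spent with the
manipulated fly. The null of no preference (50%) is tested per experiment
with a one-sample Wilcoxon signed-rank test and, for pooled replicates,
with a stratified permutation test that randomizes treatment labels and
rebuilds the pooled statistic from thousands of randomizations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Arena",
    "Target",
    "Trajectory",
    "Bout",
    "BoutList",
    "TrialScore",
    "DwellTimes",
    "WilcoxonResult",
    "PermutationResult",
    "dwell_times",
    "score_trial",
    "score_trajectory",
    "score_courtship",
    "wilcoxon_vs_null",
    "stratified_permutation_test",
    "pool_replicates",
    "exclusion_threshold_pct",
]

MANIPULATED = "manipulated"
CONTROL = "control"


@dataclass(frozen=True)
class Arena:
    """Circular arena (center coordinates and radius, mm)."""

    center_x_mm: float = 0.0
    center_y_mm: float = 0.0
    radius_mm: float = 27.5


@dataclass(frozen=True)
class Target:
    label: str
    treatment: str  # "manipulated" or "control"
    x_mm: float
    y_mm: float


@dataclass
class Trajectory:
    """Frame-indexed positions of the choosing male plus the two targets."""

    trial_id: str
    replicate: str
    fps: float
    frames: np.ndarray  # (n, 3): time_s, x_mm, y_mm
    targets: tuple[Target, Target]
    arena: Arena = field(default_factory=Arena)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2 or self.frames.shape[1] != 3:
            raise ValueError("frames must be an (n, 3) array of time,x,y")
        t = self.frames[:, 0]
        finite = t[np.isfinite(t)]
        if np.any(np.diff(finite) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if len(self.targets) != 2:
            raise ValueError("exactly two targets required")
        treatments = {tg.treatment for tg in self.targets}
        if treatments != {MANIPULATED, CONTROL}:
            raise ValueError("targets must carry distinct treatments "
                             f"'{MANIPULATED}' and '{CONTROL}'")

    def target(self, treatment: str) -> Target:
        return next(t for t in self.targets if t.treatment == treatment)


@dataclass(frozen=True)
class Bout:
    treatment: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("bout must have positive duration")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class BoutList:
    """Hand-scored courtship bouts from a live two-choice trial."""

    trial_id: str
    replicate: str
    bouts: list[Bout]
    observation_s: float = 600.0

    def __post_init__(self) -> None:
        for treatment in (MANIPULATED, CONTROL):
            spans = sorted((b.start_s, b.end_s) for b in self.bouts
                           if b.treatment == treatment)
            for (s1, e1), (s2, _) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping {treatment} bouts in trial {self.trial_id}")


@dataclass
class TrialScore:
    """One trial's dwell/courtship totals and preference percentage."""

    trial_id: str
    replicate: str
    t_manipulated_s: float
    t_control_s: float
    preference_pct: float  # NaN when undefined
    kept: bool
    exclusion_reason: str | None = None

    @property
    def t_total_s(self) -> float:
        return self.t_manipulated_s + self.t_control_s


@dataclass(frozen=True)
class DwellTimes:
    t_manipulated_s: float
    t_control_s: float
    t_outside_s: float
    frames_used: int
    frames_skipped: int


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_two_sided: float
    n_used: int          # trials remaining after dropping exact-50 ties
    method: str
    degenerate: bool = False


@dataclass
class PermutationResult:
    observed_statistic: float
    n_randomizations: int
    p_one_sided: float
    p_two_sided: float
    sided: str
    scheme: str
    statistic: str
    seed: int | None
    degenerate: bool = False
    null_sample: np.ndarray | None = None


# ---------------------------------------------------------------------------
# trial scoring

def dwell_times(traj: Trajectory, circle_radius_mm: float = 3.0) -> DwellTimes:
    """Time spent inside each target's circle (boundary inclusive).

    A frame counts toward a target when the male's Euclidean distance to it
    is <= ``circle_radius_mm``; dwell time is frame count divided by the
    frame rate. Frames with missing coordinates are skipped (and counted in
    ``frames_skipped``). Raises if the two circles overlap, which makes a
    trial unusable.
    """
    a = traj.target(MANIPULATED)
    b = traj.target(CONTROL)
    sep = math.hypot(a.x_mm - b.x_mm, a.y_mm - b.y_mm)
    if sep <= 2 * circle_radius_mm:
        raise ValueError(
            f"target circles overlap (separation {sep:.2f} mm <= "
            f"{2 * circle_radius_mm:.2f} mm)")
    xy = traj.frames[:, 1:3]
    ok = np.all(np.isfinite(xy), axis=1)
    xy = xy[ok]
    da = np.hypot(xy[:, 0] - a.x_mm, xy[:, 1] - a.y_mm)
    db = np.hypot(xy[:, 0] - b.x_mm, xy[:, 1] - b.y_mm)
    in_a = int(np.sum(da <= circle_radius_mm))
    in_b = int(np.sum(db <= circle_radius_mm))
    used = int(ok.sum())
    return DwellTimes(
        t_manipulated_s=in_a / traj.fps,
        t_control_s=in_b / traj.fps,
        t_outside_s=(used - in_a - in_b) / traj.fps,
        frames_used=used,
        frames_skipped=int((~ok).sum()),
    )


def score_trial(
    t_manipulated_s: float,
    t_control_s: float,
    min_total_s: float = 50.0,
    trial_id: str = "",
    replicate: str = "",
) -> TrialScore:
    """Preference percentage from per-target dwell totals.

    preference = 100 * t_manipulated / (t_manipulated + t_control). Trials
    whose total target time is strictly less than ``min_total_s`` (50 s of a
    30 min video by default) are excluded; a zero total leaves the
    preference undefined.
    """
    if t_manipulated_s < 0 or t_control_s < 0:
        raise ValueError("dwell times must be non-negative")
    total = t_manipulated_s + t_control_s
    if total == 0:
        return TrialScore(trial_id, replicate, 0.0, 0.0, math.nan, False,
                          "no time at either target")
    pref = 100.0 * t_manipulated_s / total
    if total < min_total_s:
        return TrialScore(trial_id, replicate, t_manipulated_s, t_control_s,
                          pref, False, f"total target time {total:.1f} s < "
                          f"{min_total_s:g} s")
    return TrialScore(trial_id, replicate, t_manipulated_s, t_control_s,
                      pref, True)


def score_trajectory(
    traj: Trajectory,
    circle_radius_mm: float = 3.0,
    min_total_s: float = 50.0,
) -> TrialScore:
    """Score one video trial end to end (dwell times then preference)."""
    dt = dwell_times(traj, circle_radius_mm)
    return score_trial(dt.t_manipulated_s, dt.t_control_s, min_total_s,
                       trial_id=traj.trial_id, replicate=traj.replicate)


def score_courtship(bouts: BoutList, min_bout_s: float = 20.0) -> TrialScore:
    """Preference from a live-observation bout list.

    Only bouts strictly longer than ``min_bout_s`` count as courtship; the
    live assay has no minimum-total rule, but a trial with no retained bout
    has no defined preference and is excluded.
    """
    t = {MANIPULATED: 0.0, CONTROL: 0.0}
    retained = 0
    for b in bouts.bouts:
        if b.treatment not in t:
            raise ValueError(f"unknown treatment {b.treatment!r}")
        if b.duration_s > min_bout_s:
            t[b.treatment] += b.duration_s
            retained += 1
    if retained == 0:
        return TrialScore(bouts.trial_id, bouts.replicate, 0.0, 0.0,
                          math.nan, False, "no courtship bouts retained")
    total = t[MANIPULATED] + t[CONTROL]
    pref = 100.0 * t[MANIPULATED] / total
    return TrialScore(bouts.trial_id, bouts.replicate,
                      t[MANIPULATED], t[CONTROL], pref, True)


def exclusion_threshold_pct(
    min_total_s: float = 50.0, observation_s: float = 1800.0
) -> float:
    """The video exclusion threshold as a percentage of observation time."""
    if observation_s <= 0:
        raise ValueError("observation_s must be positive")
    return 100.0 * min_total_s / observation_s


# ---------------------------------------------------------------------------
# statistics

def wilcoxon_vs_null(
    preferences: Sequence[float], null_value: float = 50.0
) -> WilcoxonResult:
    """One-sample Wilcoxon signed-rank test against the no-preference null.

    Differences of exactly zero are dropped. The exact null distribution of
    the signed-rank statistic is used for n <= 25; beyond that, the normal
    approximation with continuity correction.
    """
    prefs = np.asarray(list(preferences), dtype=float)
    if prefs.size == 0:
        raise ValueError("need at least one kept trial")
    d = prefs - null_value
    d = d[d != 0]
    if d.size == 0:
        return WilcoxonResult(0.0, 1.0, 0, "degenerate", degenerate=True)
    has_ties = len(np.unique(np.abs(d))) < len(d)
    if d.size <= 25 and not has_ties:
        method = "exact"
        res = stats.wilcoxon(d, zero_method="wilcox", method="exact")
    else:
        method = "normal-approx"
        res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                             method="approx")
    return WilcoxonResult(float(res.statistic), float(res.pvalue),
                          int(d.size), method)


def pool_replicates(*score_lists: Iterable[TrialScore]) -> list[TrialScore]:
    """Concatenate trials from several replicates, keeping replicate labels.

    Trial ids must be globally unique so the permutation scheme can track
    each trial's provenance.
    """
    pooled: list[TrialScore] = []
    seen: set[str] = set()
    for scores in score_lists:
        for s in scores:
            if s.trial_id in seen:
                raise ValueError(f"duplicate trial id {s.trial_id!r}")
            seen.add(s.trial_id)
            pooled.append(s)
    return pooled


def _null_statistics_trial_flip(
    prefs: np.ndarray, n_rand: int, statistic: str, rng: np.random.Generator
) -> np.ndarray:
    flips = rng.random((n_rand, prefs.size)) < 0.5
    vals = np.where(flips, 100.0 - prefs, prefs)
    return vals.mean(axis=1) if statistic == "mean" else np.median(vals, axis=1)


def _null_statistics_pooled(
    trials: list[TrialScore], n_rand: int, statistic: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pooled-within-replicate scheme: permute the label multiset over all
    dwell-time slots of a replicate, so a trial may draw two identical
    labels (its randomized preference is then 0 or 100)."""
    by_rep: dict[str, list[TrialScore]] = {}
    for t in trials:
        by_rep.setdefault(t.replicate, []).append(t)
    columns = []
    for rep_trials in by_rep.values():
        m = len(rep_trials)
        vals = np.array([[t.t_manipulated_s, t.t_control_s]
                         for t in rep_trials]).ravel()          # (2m,)
        totals = vals.reshape(m, 2).sum(axis=1)                 # (m,)
        base = np.tile(np.tile([True, False], m), (n_rand, 1))  # m manip labels
        labels = rng.permuted(base, axis=1)                     # (n_rand, 2m)
        manip = (labels * vals).reshape(n_rand, m, 2).sum(axis=2)
        columns.append(100.0 * manip / totals)
    all_prefs = np.concatenate(columns, axis=1)
    return (all_prefs.mean(axis=1) if statistic == "mean"
            else np.median(all_prefs, axis=1))


def stratified_permutation_test(
    trials: Sequence[TrialScore],
    n_randomizations: int = 30_000,
    statistic: Literal["mean", "median"] = "mean",
    scheme: Literal["trial-flip", "pooled-within-replicate"] = "trial-flip",
    sided: Literal["greater", "less", "two-sided"] = "two-sided",
    seed: int | None = None,
    keep_null: bool = False,
) -> PermutationResult:
    """Replicate-stratified permutation test of pooled preference.

    Treatment labels are randomized within each trial (default scheme) or
    within each replicate's pooled label multiset; after each of
    ``n_randomizations`` randomizations the pooled statistic (mean, or
    median, preference over kept trials) is recomputed, and all randomized
    values form one null distribution. Tail probabilities use the add-one
    rule (1 + #extreme) / (n + 1) with ties counted as extreme, so p is
    always in (0, 1]; the two-sided p doubles the smaller tail (capped at 1).
    """
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    kept = [t for t in trials if t.kept]
    if not kept:
        raise ValueError("no kept trials")
    if any(not t.replicate for t in kept):
        raise ValueError("replicate labels are required for stratification")
    prefs = np.array([t.preference_pct for t in kept])
    observed = float(np.mean(prefs) if statistic == "mean" else np.median(prefs))

    if np.all(prefs == 50.0):
        return PermutationResult(observed, n_randomizations, 1.0, 1.0,
                                 sided, scheme, statistic, seed,
                                 degenerate=True)

    rng = np.random.default_rng(seed)
    if scheme == "trial-flip":
        null = _null_statistics_trial_flip(prefs, n_randomizations,
                                           statistic, rng)
    elif scheme == "pooled-within-replicate":
        null = _null_statistics_pooled(kept, n_randomizations, statistic, rng)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    n = n_randomizations
    p_upper = (1 + int(np.sum(null >= observed))) / (n + 1)
    p_lower = (1 + int(np.sum(null <= observed))) / (n + 1)
    if sided == "greater":
        p_one = p_upper
    elif sided == "less":
        p_one = p_lower
    else:
        p_one = min(p_upper, p_lower)
    p_two = min(1.0, 2 * min(p_upper, p_lower))
    return PermutationResult(observed, n, p_one, p_two, sided, scheme,
                             statistic, seed,
                             null_sample=null if keep_null else None)
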