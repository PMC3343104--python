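"""Synthetic data with known ground truth for the three analysis tracks.

Generates (1) CHC intensity tables with log-normal biological variation,
multiplicative genotype/age effects optionally tied to carbon-chain length,
and fixed per-compound detection efficiencies that are invisible to the
analysis (they cancel under per-sample normalization); (2) two-choice
trajectories as a discrete-time two-state walk whose in-circle visits are
allocated between the two targets with a configurable true preference; and
(3) qPCR Ct tables with replicate noise around known ln fold changes.
Every generator takes one explicit seed and returns the data together with
a ground-truth record, so recovery and null-calibration tests can compare
what the analyses estimate against what was injected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .compounds import CompoundDescriptor, default_panel
from .preference import Arena, Target, Trajectory, MANIPULATED, CONTROL
from .profiles import ChcSampleTable
from .qpcr import CtTable

__all__ = [
    "ConfigError",
    "ChcSimConfig",
    "TrialSimConfig",
    "CtSimConfig",
    "generate_chc_table",
    "generate_trial_set",
    "generate_ct_table",
    "load_config",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def load_config(path: str | Path, cls):
    """Build a *SimConfig from a flat YAML key/value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return cls(**raw)


# ---------------------------------------------------------------------------
# CHC tables


@dataclass
class ChcSimConfig:
    """Study conditions for a GC/MS-like CHC profiling experiment.

    Defaults mirror a two-genotype aging design: 26 compounds spanning
    C21-C29, four sampling ages, three replicate extractions per cell.
    ``genotype_effect_ln`` and ``chain_slope_ln`` act only on non-control
    genotypes (the first genotype listed is the control); ``chain_slope_ln``
    adds ``slope * (carbon_count - panel center)`` to the mutant effect, the
    long-chain shift seen under reduced insulin signaling.
    """

    n_compounds: int = 26
    carbon_range: tuple[int, int] = (21, 29)
    genotypes: tuple[str, ...] = ("control", "mutant")
    ages_days: tuple[float, ...] = (6.0, 23.0, 37.0, 48.0)
    replicates_per_cell: int = 3
    baseline_abundances: Mapping[str, float] | None = None
    detection_efficiency: Mapping[str, float] | None = None
    genotype_effect_ln: float | Mapping[str, float] = 0.0
    chain_slope_ln: float = 0.05
    age_slope_ln: float = 0.01
    noise_sd_ln: float = 0.3
    platform: str = "GCMS"
    seed: int = 0

    def validate(self) -> None:
        if self.n_compounds < 1:
            raise ConfigError("n_compounds must be >= 1")
        if not self.genotypes or not self.ages_days:
            raise ConfigError("empty design: need genotypes and ages")
        if self.replicates_per_cell < 1:
            raise ConfigError("replicates_per_cell must be >= 1")
        if self.noise_sd_ln < 0:
            raise ConfigError("noise_sd_ln must be >= 0")
        for name, mapping in (("baseline_abundances", self.baseline_abundances),
                              ("detection_efficiency", self.detection_efficiency)):
            if mapping is not None and any(v <= 0 for v in mapping.values()):
                raise ConfigError(f"{name} must be strictly positive")


def generate_chc_table(
    cfg: ChcSimConfig,
) -> tuple[ChcSampleTable, list[CompoundDescriptor], dict]:
    """Simulate one raw intensity per (sample, compound).

    raw = efficiency * exp(ln baseline + genotype effect + chain term
    + age drift + Normal(0, noise_sd_ln)). Returns the raw-state table, the
    compound panel, and a ground-truth record holding every injected
    parameter (including the per-compound efficiencies the analysis never
    sees).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    panel = default_panel(cfg.n_compounds, cfg.carbon_range)
    names = [d.name for d in panel]
    carbons = np.array([d.carbon_count for d in panel], dtype=float)
    center = 0.5 * (cfg.carbon_range[0] + cfg.carbon_range[1])

    if cfg.baseline_abundances is None:
        baselines = np.exp(rng.normal(0.0, 1.0, cfg.n_compounds))
    else:
        baselines = np.array([cfg.baseline_abundances[n] for n in names])
    if cfg.detection_efficiency is None:
        efficiency = np.exp(rng.normal(0.0, 0.5, cfg.n_compounds))
    else:
        efficiency = np.array([cfg.detection_efficiency[n] for n in names])

    if isinstance(cfg.genotype_effect_ln, Mapping):
        base_effect = np.array([cfg.genotype_effect_ln.get(n, 0.0) for n in names])
    else:
        base_effect = np.full(cfg.n_compounds, float(cfg.genotype_effect_ln))
    mutant_effect = base_effect + cfg.chain_slope_ln * (carbons - center)

    age0 = min(cfg.ages_days)
    rows = []
    sample_no = 0
    for genotype in cfg.genotypes:
        is_mutant = genotype != cfg.genotypes[0]
        for age in cfg.ages_days:
            for rep in range(1, cfg.replicates_per_cell + 1):
                sample_no += 1
                ln_mu = (np.log(baselines)
                         + (mutant_effect if is_mutant else 0.0)
                         + cfg.age_slope_ln * (age - age0))
                noise = rng.normal(0.0, cfg.noise_sd_ln, cfg.n_compounds)
                raw = efficiency * np.exp(ln_mu + noise)
                sid = f"S{sample_no:03d}"
                for name, value in zip(names, raw):
                    rows.append((sid, genotype, age, f"rep{rep}",
                                 cfg.platform, name, value))
    df = pd.DataFrame(rows, columns=[
        "sample_id", "genotype", "age_days", "replicate", "platform",
        "compound", "intensity"])
    truth = {
        "seed": cfg.seed,
        "compounds": names,
        "carbon_counts": carbons.tolist(),
        "baseline_abundances": baselines.tolist(),
        "detection_efficiency": efficiency.tolist(),
        "mutant_effect_ln": mutant_effect.tolist(),
        "chain_slope_ln": cfg.chain_slope_ln,
        "age_slope_ln": cfg.age_slope_ln,
        "noise_sd_ln": cfg.noise_sd_ln,
    }
    return ChcSampleTable(df, state="raw"), panel, truth


# ---------------------------------------------------------------------------
# two-choice trials


@dataclass
class TrialSimConfig:
    """Study conditions for a set of two-choice video trials.

    Defaults follow the video assay: 30 min at 2 frames/s in a 55 mm
    circular arena with decapitated targets 18 mm apart and 8.5 mm from the
    wall, scored with 3 mm circles. ``true_preference_pct`` allocates each
    in-circle visit to the manipulated target; ``dwell_fraction`` is the
    expected fraction of time spent inside either circle.
    """

    true_preference_pct: float = 50.0
    n_trials: int = 30
    n_replicates: int = 3
    duration_s: float = 1800.0
    fps: float = 2.0
    arena_radius_mm: float = 27.5
    target_separation_mm: float = 18.0
    target_wall_distance_mm: float = 8.5
    circle_radius_mm: float = 3.0
    dwell_fraction: float = 0.3
    mean_visit_s: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.true_preference_pct <= 100:
            raise ConfigError("true_preference_pct must be in [0, 100]")
        if not 0 <= self.dwell_fraction <= 1:
            raise ConfigError("dwell_fraction must be in [0, 1]")
        if self.n_trials < 1 or self.n_replicates < 1:
            raise ConfigError("need >=1 trial and >=1 replicate")
        if self.target_separation_mm <= 2 * self.circle_radius_mm:
            raise ConfigError("target circles overlap: separation must "
                              "exceed twice the circle radius")
        # targets must sit inside the arena with their circles clear of the wall
        half = self.target_separation_mm / 2.0
        r_pos = self.arena_radius_mm - self.target_wall_distance_mm
        if r_pos <= half or r_pos + self.circle_radius_mm >= self.arena_radius_mm:
            raise ConfigError("target circles collide with the arena boundary")


def _target_positions(cfg: TrialSimConfig) -> tuple[Target, Target]:
    half = cfg.target_separation_mm / 2.0
    r_pos = cfg.arena_radius_mm - cfg.target_wall_distance_mm
    y = -math.sqrt(r_pos**2 - half**2)
    return (Target("A", MANIPULATED, -half, y),
            Target("B", CONTROL, half, y))


def _wander_positions(
    n: int, arena: Arena, targets: tuple[Target, Target],
    radius: float, rng: np.random.Generator,
) -> np.ndarray:
    """Uniform positions in the arena, excluding both target circles."""
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 8)
        r = arena.radius_mm * np.sqrt(rng.random(m))
        theta = rng.random(m) * 2 * np.pi
        xy = np.column_stack([arena.center_x_mm + r * np.cos(theta),
                              arena.center_y_mm + r * np.sin(theta)])
        ok = np.ones(m, dtype=bool)
        for tg in targets:
            ok &= np.hypot(xy[:, 0] - tg.x_mm, xy[:, 1] - tg.y_mm) > radius
        good = xy[ok][: n - filled]
        out[filled:filled + len(good)] = good
        filled += len(good)
    return out


def generate_trial_set(
    cfg: TrialSimConfig,
) -> tuple[list[Trajectory], dict]:
    """Simulate biased two-state walks for a set of two-choice trials.

    Each trajectory alternates wandering bouts with in-circle visits; visit
    and wander durations are exponential with means chosen so the expected
    in-circle fraction equals ``dwell_fraction``, and each visit goes to the
    manipulated target with probability ``true_preference_pct / 100``.
    Trials are assigned round-robin to replicates.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    arena = Arena(0.0, 0.0, cfg.arena_radius_mm)
    targets = _target_positions(cfg)
    n_frames = int(round(cfg.duration_s * cfg.fps))
    dt = 1.0 / cfg.fps
    f = cfg.dwell_fraction
    mean_wander = (cfg.mean_visit_s * (1 - f) / f) if f > 0 else math.inf

    trials: list[Trajectory] = []
    visit_counts = []
    for i in range(cfg.n_trials):
        frames = np.empty((n_frames, 3))
        frames[:, 0] = np.arange(n_frames) * dt
        pos = 0
        in_visit = False  # start wandering
        n_visits_a = n_visits = 0
        while pos < n_frames:
            if in_visit and f > 0:
                length = max(1, int(round(rng.exponential(cfg.mean_visit_s)
                                          * cfg.fps)))
                length = min(length, n_frames - pos)
                go_a = rng.random() < cfg.true_preference_pct / 100.0
                tg = targets[0] if go_a else targets[1]
                n_visits += 1
                n_visits_a += int(go_a)
                # per-axis clip at 0.6r keeps the radial offset below r,
                # so every visit frame stays inside the scoring circle
                jitter = rng.normal(0.0, cfg.circle_radius_mm / 4.0, (length, 2))
                np.clip(jitter, -0.6 * cfg.circle_radius_mm,
                        0.6 * cfg.circle_radius_mm, out=jitter)
                frames[pos:pos + length, 1] = tg.x_mm + jitter[:, 0]
                frames[pos:pos + length, 2] = tg.y_mm + jitter[:, 1]
            else:
                if math.isinf(mean_wander):
                    length = n_frames - pos
                else:
                    length = max(1, int(round(rng.exponential(mean_wander)
                                              * cfg.fps)))
                    length = min(length, n_frames - pos)
                frames[pos:pos + length, 1:3] = _wander_positions(
                    length, arena, targets, cfg.circle_radius_mm, rng)
            pos += length
            in_visit = not in_visit
        trials.append(Trajectory(
            trial_id=f"T{i + 1:03d}",
            replicate=f"R{i % cfg.n_replicates + 1}",
            fps=cfg.fps,
            frames=frames,
            targets=targets,
            arena=arena,
        ))
        visit_counts.append((n_visits_a, n_visits))
    truth = {
        "seed": cfg.seed,
        "true_preference_pct": cfg.true_preference_pct,
        "dwell_fraction": cfg.dwell_fraction,
        "visits_to_manipulated": [a for a, _ in visit_counts],
        "visits_total": [n for _, n in visit_counts],
    }
    return trials, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables


@dataclass
class CtSimConfig:
    """Study conditions for a ddCt qPCR experiment.

    Defaults follow standard fly qPCR practice: rp49 as the endogenous
    reference, three independent RNA extractions (biological replicates)
    per condition, five technical PCR replicates each, and cycle noise of
    0.15 cycles. ``true_ln_fold_change`` maps gene -> injected ln fold
    change of the manipulated condition (the reference gene must be 0).
    """

    genes: tuple[str, ...] = ("rp49", "eloF", "desat1", "desat2", "desatF")
    reference_gene: str = "rp49"
    true_ln_fold_change: Mapping[str, float] = field(default_factory=dict)
    n_biological_replicates: int = 3
    n_technical_replicates: int = 5
    ct_noise_sd: float = 0.15
    baseline_ct: Mapping[str, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.reference_gene not in self.genes:
            raise ConfigError(f"reference gene {self.reference_gene!r} "
                              "missing from gene list")
        if self.true_ln_fold_change.get(self.reference_gene, 0.0) != 0.0:
            raise ConfigError("reference gene must have true fold change 0")
        if self.n_biological_replicates < 1 or self.n_technical_replicates < 1:
            raise ConfigError("need >=1 biological and technical replicate")
        if self.ct_noise_sd < 0:
            raise ConfigError("ct_noise_sd must be >= 0")


def generate_ct_table(cfg: CtSimConfig) -> tuple[CtTable, dict]:
    """Simulate a Ct table around known ln fold changes.

    Ct = baseline_ct(gene) - ln(expression)/ln 2 + Normal(0, ct_noise_sd),
    with ln(expression) = 0 in controls and the injected ln fold change in
    the manipulated condition. The reference gene's expression is constant
    across conditions up to noise.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    if cfg.baseline_ct is None:
        baseline = {g: (18.0 if g == cfg.reference_gene else 24.0)
                    for g in cfg.genes}
    else:
        baseline = dict(cfg.baseline_ct)
    rows = []
    for condition in (CONTROL, MANIPULATED):
        for bio in range(1, cfg.n_biological_replicates + 1):
            for gene in cfg.genes:
                ln_expr = (cfg.true_ln_fold_change.get(gene, 0.0)
                           if condition == MANIPULATED else 0.0)
                mu = baseline[gene] - ln_expr / math.log(2.0)
                for tech in range(1, cfg.n_technical_replicates + 1):
                    ct = mu + rng.normal(0.0, cfg.ct_noise_sd)
                    rows.append((condition, f"B{bio}", f"t{tech}", gene, ct))
    df = pd.DataFrame(rows, columns=["condition", "bio_rep", "tech_rep",
                                     "gene", "ct"])
    truth = {
        "seed": cfg.seed,
        "true_ln_fold_change": {g: cfg.true_ln_fold_change.get(g, 0.0)
                                for g in cfg.genes},
        "baseline_ct": baseline,
        "ct_noise_sd": cfg.ct_noise_sd,
    }
    return CtTable(df, reference_gene=cfg.reference_gene), truth
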