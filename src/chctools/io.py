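"""Plain-text readers and writers for the pipeline's table formats.

CHC and Ct tables travel as long-format TSV/CSV; trajectories as one CSV
per trial (``trial_id,replicate,frame,time_s,x_mm,y_mm``) with a shared
targets sidecar (``trial_id,target_label,treatment,x_mm,y_mm``); ground
truth and permutation results as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preference import Arena, Target, Trajectory, TrialScore, PermutationResult
from .profiles import ChcSampleTable
from .qpcr import CtTable

__all__ = [
    "write_chc_table", "read_chc_table",
    "write_trial_set", "read_trial_set",
    "write_bout_list_csv", "read_bout_lists",
    "write_ct_table", "read_ct_table",
    "write_scores", "write_permutation_result",
    "write_ground_truth",
]


def write_chc_table(table: ChcSampleTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def read_chc_table(path: str | Path, state: str = "raw") -> ChcSampleTable:
    df = pd.read_csv(path, sep="\t")
    return ChcSampleTable(df, state=state)


def write_trial_set(
    trials: list[Trajectory], out_dir: str | Path
) -> None:
    """One CSV per trajectory plus one targets sidecar for the whole set."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    target_rows = []
    for traj in trials:
        df = pd.DataFrame({
            "trial_id": traj.trial_id,
            "replicate": traj.replicate,
            "frame": np.arange(len(traj.frames)),
            "time_s": traj.frames[:, 0],
            "x_mm": traj.frames[:, 1],
            "y_mm": traj.frames[:, 2],
        })
        df.to_csv(out / f"{traj.trial_id}.csv", index=False)
        for tg in traj.targets:
            target_rows.append((traj.trial_id, tg.label, tg.treatment,
                                tg.x_mm, tg.y_mm))
    pd.DataFrame(target_rows, columns=[
        "trial_id", "target_label", "treatment", "x_mm", "y_mm",
    ]).to_csv(out / "targets.csv", index=False)


def read_trial_set(
    in_dir: str | Path, fps: float = 2.0, arena: Arena | None = None
) -> list[Trajectory]:
    in_dir = Path(in_dir)
    targets = pd.read_csv(in_dir / "targets.csv")
    trials = []
    for path in sorted(in_dir.glob("*.csv")):
        if path.name == "targets.csv":
            continue
        df = pd.read_csv(path)
        tid = str(df["trial_id"].iloc[0])
        rep = str(df["replicate"].iloc[0])
        tg_rows = targets[targets["trial_id"].astype(str) == tid]
        tgs = tuple(Target(str(r.target_label), str(r.treatment),
                           float(r.x_mm), float(r.y_mm))
                    for r in tg_rows.itertuples())
        frames = df[["time_s", "x_mm", "y_mm"]].to_numpy()
        trials.append(Trajectory(tid, rep, fps, frames, tgs,
                                 arena or Arena()))
    return trials


def write_bout_list_csv(bout_lists, path: str | Path) -> None:
    rows = [(bl.trial_id, bl.replicate, b.treatment, b.start_s, b.end_s)
            for bl in bout_lists for b in bl.bouts]
    pd.DataFrame(rows, columns=[
        "trial_id", "replicate", "treatment", "start_s", "end_s",
    ]).to_csv(path, index=False)


def read_bout_lists(path: str | Path, observation_s: float = 600.0):
    from .preference import Bout, BoutList

    df = pd.read_csv(path)
    out = []
    for (tid, rep), grp in df.groupby(["trial_id", "replicate"], sort=False):
        bouts = [Bout(str(r.treatment), float(r.start_s), float(r.end_s))
                 for r in grp.itertuples()]
        out.append(BoutList(str(tid), str(rep), bouts, observation_s))
    return out


def write_ct_table(table: CtTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def read_ct_table(path: str | Path, reference_gene: str = "rp49") -> CtTable:
    return CtTable(pd.read_csv(path), reference_gene=reference_gene)


def write_scores(scores: list[TrialScore], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(s) for s in scores]).to_csv(
        path, sep="\t", index=False)


def write_permutation_result(result: PermutationResult, path: str | Path,
                             include_null: bool = False) -> None:
    payload = dataclasses.asdict(result)
    null = payload.pop("null_sample")
    if include_null and null is not None:
        payload["null_sample"] = list(map(float, null))
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def write_ground_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=float)
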