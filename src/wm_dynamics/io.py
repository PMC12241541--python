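"""Plain-text readers and writers for events, BOLD matrices and betas.

Events are BIDS-style ``events.tsv`` (one file per participant, with day
and scan columns); BOLD runs are TSV matrices (regions x frames) with a
JSON sidecar carrying TR, identifiers and region labels; betas are tidy
TSV keyed by participant, condition, region and timepoint.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fir_model import FirBetas
from .synthetic_data import ParcellatedBold

EVENT_COLUMNS = [
    "onset",
    "duration",
    "trial_type",
    "difficulty",
    "response_time",
    "correct",
    "day",
    "scan",
    "trial_index",
]


def write_events(trials: pd.DataFrame, out_dir: Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    names = {0: "easy", 1: "medium", 2: "hard"}
    for pid, sub in trials.groupby("participant_id"):
        df = sub.copy()
        df["trial_type"] = df["difficulty"].map(names)
        df["correct"] = df["correct"].astype(int)
        path = out_dir / f"{pid}_events.tsv"
        df[EVENT_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6f")
        paths.append(path)
    return paths


def read_events(events_dir: Path) -> pd.DataFrame:
    frames = []
    for path in sorted(Path(events_dir).glob("*_events.tsv")):
        df = pd.read_csv(path, sep="\t")
        df.insert(0, "participant_id", path.name.replace("_events.tsv", ""))
        frames.append(df)
    if not frames:
        raise FileNotFoundError(f"no *_events.tsv under {events_dir}")
    out = pd.concat(frames, ignore_index=True)
    out["correct"] = out["correct"].astype(bool)
    return out


def write_bold(runs: list[ParcellatedBold], out_dir: Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for run in runs:
        stem = f"{run.participant_id}_day-{run.day}_scan-{run.scan:02d}_bold"
        data_path = out_dir / f"{stem}.tsv"
        np.savetxt(data_path, run.data, delimiter="\t", fmt="%.8g")
        sidecar = {
            "participant_id": run.participant_id,
            "day": run.day,
            "scan": run.scan,
            "tr": run.tr,
            "region_labels": run.region_labels,
            "region_groups": run.region_groups,
        }
        (out_dir / f"{stem}.json").write_text(json.dumps(sidecar))
        paths.append(data_path)
    return paths


def read_bold(bold_dir: Path) -> list[ParcellatedBold]:
    runs = []
    for data_path in sorted(Path(bold_dir).glob("*_bold.tsv")):
        sidecar = json.loads(data_path.with_suffix(".json").read_text())
        runs.append(
            ParcellatedBold(
                participant_id=sidecar["participant_id"],
                day=int(sidecar["day"]),
                scan=int(sidecar["scan"]),
                data=np.loadtxt(data_path, delimiter="\t"),
                tr=float(sidecar["tr"]),
                region_labels=sidecar.get("region_labels", []),
                region_groups=sidecar.get("region_groups", []),
            )
        )
    if not runs:
        raise FileNotFoundError(f"no *_bold.tsv under {bold_dir}")
    return runs


def write_betas(all_betas: list[FirBetas], path: Path) -> Path:
    rows = []
    for fb in all_betas:
        for cond, block in fb.betas.items():
            for r in range(block.shape[0]):
                label = fb.region_labels[r] if fb.region_labels else f"region_{r + 1:03d}"
                for t in range(block.shape[1]):
                    rows.append((fb.participant_id, cond, r, label, t + 1, block[r, t]))
    df = pd.DataFrame(
        rows,
        columns=["participant_id", "condition", "region", "region_label", "timepoint", "beta"],
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_betas(path: Path) -> list[FirBetas]:
    df = pd.read_csv(path, sep="\t")
    window = int(df["timepoint"].max())
    out = []
    for pid, sub in df.groupby("participant_id", sort=True):
        labels = (
            sub.drop_duplicates("region").sort_values("region")["region_label"].tolist()
        )
        betas = {}
        for cond, csub in sub.groupby("condition"):
            mat = (
                csub.pivot_table(index="region", columns="timepoint", values="beta")
                .sort_index()
                .to_numpy()
            )
            betas[cond] = mat
        out.append(
            FirBetas(participant_id=str(pid), betas=betas, window=window, region_labels=labels)
        )
    return out
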