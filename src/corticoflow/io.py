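"""Plain-text dataset I/O.

On-disk dialect, one directory per subject x condition:

* ``emg.csv`` — ``time_s, BIC_mV, TRI_mV`` at the EMG rate
* ``emg.json`` — rate, condition, side, block timeline
* ``nirs.csv`` — ``time_s, ch01_od730, ch01_od850, ...`` at the fNIRS rate
* ``nirs.json`` — rate, source-detector distance, channel -> region map,
  timeline

plus per-subject ``mvc_bic.csv`` / ``mvc_tri.csv`` (one column per maximal
effort), and cohort-level ``ground_truth.json`` and ``manifest.tsv``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .emg import EmgRecording
from .fnirs import OpticalRecording
from .protocol import DOMINANT, Timeline

FLOAT_FMT = "%.6g"


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def write_dataset(ds, dataset_dir: str | Path) -> Path:
    dataset_dir = Path(dataset_dir)
    dataset_dir.mkdir(parents=True, exist_ok=True)

    emg = ds.emg
    t = np.arange(emg.n_samples) / emg.rate
    df = pd.DataFrame({"time_s": t, "BIC_mV": emg.samples["BIC"], "TRI_mV": emg.samples["TRI"]})
    df.to_csv(dataset_dir / "emg.csv", index=False, float_format=FLOAT_FMT)
    _write_json(
        dataset_dir / "emg.json",
        {
            "rate_hz": emg.rate,
            "force": emg.force,
            "side": emg.side,
            "timeline": emg.timeline.to_records(),
        },
    )

    opt = ds.optical
    n = opt.od.shape[0]
    cols = {"time_s": np.arange(n) / opt.rate}
    for ci, entry in enumerate(opt.layout):
        cols[f"{entry['name']}_od730"] = opt.od[:, ci, 0]
        cols[f"{entry['name']}_od850"] = opt.od[:, ci, 1]
    pd.DataFrame(cols).to_csv(dataset_dir / "nirs.csv", index=False, float_format=FLOAT_FMT)
    _write_json(
        dataset_dir / "nirs.json",
        {
            "rate_hz": opt.rate,
            "distance_cm": opt.distance_cm,
            "force": opt.force,
            "side": opt.side,
            "layout": opt.layout,
            "timeline": opt.timeline.to_records(),
        },
    )
    _write_json(dataset_dir / "ground_truth.json", ds.truth)
    return dataset_dir


def read_dataset(dataset_dir: str | Path) -> tuple[EmgRecording, OpticalRecording]:
    dataset_dir = Path(dataset_dir)
    emg_meta = json.loads((dataset_dir / "emg.json").read_text())
    df = pd.read_csv(dataset_dir / "emg.csv")
    emg = EmgRecording(
        samples={"BIC": df["BIC_mV"].to_numpy(), "TRI": df["TRI_mV"].to_numpy()},
        rate=float(emg_meta["rate_hz"]),
        timeline=Timeline.from_records(emg_meta["timeline"]),
        force=emg_meta.get("force"),
        side=emg_meta.get("side"),
    )
    nirs_meta = json.loads((dataset_dir / "nirs.json").read_text())
    layout = nirs_meta["layout"]
    dfn = pd.read_csv(dataset_dir / "nirs.csv")
    od = np.stack(
        [
            np.stack(
                [dfn[f"{e['name']}_od730"].to_numpy(), dfn[f"{e['name']}_od850"].to_numpy()],
                axis=-1,
            )
            for e in layout
        ],
        axis=1,
    )
    optical = OpticalRecording(
        od=od,
        rate=float(nirs_meta["rate_hz"]),
        layout=layout,
        timeline=Timeline.from_records(nirs_meta["timeline"]),
        distance_cm=float(nirs_meta["distance_cm"]),
        force=nirs_meta.get("force"),
        side=nirs_meta.get("side"),
    )
    return emg, optical


def write_cohort(cohort, out_dir: str | Path, overwrite: bool = False) -> Path:
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        if not overwrite:
            raise FileExistsError(f"{out_dir} exists and is not empty (use overwrite)")
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_json(out_dir / "ground_truth.json", cohort.ground_truth())

    rows = []
    for subject in cohort.subjects:
        sub_dir = out_dir / f"sub-{subject:02d}"
        sub_dir.mkdir(exist_ok=True)
        for muscle in ("BIC", "TRI"):
            trials = cohort.mvc_trials(subject, muscle)
            pd.DataFrame(
                {f"trial_{i + 1}": tr for i, tr in enumerate(trials)}
            ).to_csv(sub_dir / f"mvc_{muscle.lower()}.csv", index=False, float_format=FLOAT_FMT)
        for force, side in cohort.protocol.conditions:
            ds = cohort.dataset(subject, side, force)
            ds_dir = sub_dir / ds.label.split("_", 1)[1]
            write_dataset(ds, ds_dir)
            rows.append(
                {
                    "subject": subject,
                    "side": side,
                    "force": force,
                    "path": str(ds_dir.relative_to(out_dir)),
                }
            )
    pd.DataFrame(rows).to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return out_dir


def read_manifest(cohort_dir: str | Path) -> pd.DataFrame:
    cohort_dir = Path(cohort_dir)
    return pd.read_csv(cohort_dir / "manifest.tsv", sep="\t")


def read_mvc_trials(cohort_dir: str | Path, subject: int, muscle: str) -> list[np.ndarray]:
    path = Path(cohort_dir) / f"sub-{subject:02d}" / f"mvc_{muscle.lower()}.csv"
    df = pd.read_csv(path)
    return [df[c].to_numpy() for c in df.columns]
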