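"""End-to-end orchestration: simulate -> EMG features -> fNIRS features ->
connectivity -> group statistics.

Each stage reads only the previous stage's outputs; ``run_all`` executes
the five stages against a run directory and records config hash, package
version and per-stage file checksums in ``run.json``. The per-dataset
analysis is also available in memory (``analyze_dataset`` /
``analyze_cohort``) for cohort-scale work without file round trips.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import (
    ConnectivityMatrix,
    compare_matrices,
    effective_connectivity,
    functional_connectivity,
    graph_metrics,
)
from .emg import (
    EmgRecording,
    FapenParams,
    MvcReference,
    compute_cci,
    compute_fapen,
    compute_mvc,
    linear_envelope,
    preprocess_offline,
    select_steady_segment,
)
from .fnirs import (
    DEFAULT_DPF,
    REGIONS,
    bandpass_hemo,
    glm_activation,
    mark_invalid_channels,
    mbll_convert,
    remove_motion_artifacts,
    task_regressor,
)
from .io import read_dataset, read_manifest, read_mvc_trials
from .protocol import DOMINANT, ProtocolSpec
from .synthetic import Cohort, EffectConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully serializable run settings; config + seed reproduces a run."""

    seed: int = 0
    n_subjects: int = 21
    out_dir: str = "corticoflow_run"
    fapen: FapenParams = field(default_factory=FapenParams)
    dpf: float = DEFAULT_DPF
    ec_max_lag: int = 12
    fdr_q: float = 0.05
    fc_window: str = "task"
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    overwrite: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["protocol"]["conditions"] = [list(c) for c in self.protocol.conditions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "fapen" in d and isinstance(d["fapen"], dict):
            d["fapen"] = FapenParams(**d["fapen"])
        if "protocol" in d and isinstance(d["protocol"], dict):
            p = dict(d["protocol"])
            if "conditions" in p:
                p["conditions"] = tuple(tuple(c) for c in p["conditions"])
            d["protocol"] = ProtocolSpec(**p)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


# ---------------------------------------------------------------------------
# per-dataset analysis


def analyze_emg(
    emg: EmgRecording,
    mvc: dict[str, MvcReference],
    fapen_params: FapenParams = FapenParams(),
) -> dict:
    """Offline filtering, steady 5-s segment, fApEn per muscle, CCI.

    The CCI window is the agonist's steady segment; both linear envelopes
    are MVC-normalized.
    """
    filtered = preprocess_offline(emg)
    seg_duration = fapen_params.N / emg.rate
    row: dict = {"side": emg.side, "force": emg.force}
    segs = {}
    for muscle in ("BIC", "TRI"):
        seg = select_steady_segment(filtered, muscle, duration_s=seg_duration)
        segs[muscle] = seg
        row[f"fapen_{muscle.lower()}"] = compute_fapen(seg, fapen_params)
    lo = segs["BIC"].start_index
    hi = lo + len(segs["BIC"].samples)
    env = {
        m: linear_envelope(filtered.samples[m][lo:hi], emg.rate, mvc=mvc[m])
        for m in ("BIC", "TRI")
    }
    row["cci"] = compute_cci(env["BIC"], env["TRI"], rate=emg.rate)
    row["mvc_bic"] = mvc["BIC"].amplitude_mv
    row["mvc_tri"] = mvc["TRI"].amplitude_mv
    return row


def analyze_nirs(optical, dpf: float = DEFAULT_DPF, fc_window: str = "task",
                 ec_max_lag: int = 12, q: float = 0.05) -> dict:
    """MBLL, channel QC, artifact removal, band-pass, activation,
    connectivity and graph metrics for one recording.

    Effective connectivity runs on region means decimated to ~1 Hz (the
    band-limited series are oversampled at 11 Hz, which degenerates the
    lag design) with the task-evoked regressor partialled out.
    """
    valid = mark_invalid_channels(optical)
    hemo = mbll_convert(optical, dpf=dpf)
    hemo.valid = valid
    hemo = remove_motion_artifacts(hemo)
    hemo = bandpass_hemo(hemo)
    activation = glm_activation(hemo)
    fc_chan = functional_connectivity(hemo, scope="channel", window=fc_window, q=q)
    fc_region = functional_connectivity(hemo, scope="region", window=fc_window, q=q)
    gm = graph_metrics(fc_chan, valid=hemo.valid, region_of=hemo.regions())
    region_series, region_names = hemo.region_means()
    decim = max(1, int(round(hemo.rate)))  # ~1 Hz effective rate
    ec = effective_connectivity(
        region_series, region_names, max_lag=ec_max_lag, q=q, decimate=decim,
        confounds=task_regressor(hemo.timeline, hemo.rate),
    )
    return {
        "hemo": hemo,
        "activation": activation,
        "fc_channel": fc_chan,
        "fc_region": fc_region,
        "graph": gm,
        "ec": ec,
    }


def analyze_dataset(ds, fapen_params: FapenParams, mvc: dict[str, MvcReference],
                    dpf: float = DEFAULT_DPF, fc_window: str = "task",
                    ec_max_lag: int = 12, q: float = 0.05) -> dict:
    row = analyze_emg(ds.emg, mvc, fapen_params)
    row["subject"] = ds.subject
    nirs = analyze_nirs(ds.optical, dpf=dpf, fc_window=fc_window, ec_max_lag=ec_max_lag, q=q)
    for r in REGIONS:
        row[f"integral_{r}"] = nirs["activation"].region_integral.get(r, np.nan)
        row[f"beta_{r}"] = nirs["activation"].region_beta.get(r, np.nan)
        row[f"clustering_{r}"] = nirs["graph"].region_clustering.get(r, np.nan)
        row[f"local_eff_{r}"] = nirs["graph"].region_local_efficiency.get(r, np.nan)
    row["global_eff"] = nirs["graph"].global_efficiency
    return {"row": row, "nirs": nirs}


@dataclass
class CohortResult:
    """Feature table plus per-dataset connectivity matrices."""

    features: pd.DataFrame
    fc_region: dict[tuple[int, str, float], ConnectivityMatrix]
    ec: dict[tuple[int, str, float], ConnectivityMatrix]


def analyze_cohort(cohort: Cohort, fapen_params: FapenParams | None = None,
                   dpf: float = DEFAULT_DPF, ec_max_lag: int = 12,
                   q: float = 0.05) -> CohortResult:
    """Run the full analysis over a cohort, generating datasets lazily."""
    fapen_params = fapen_params or FapenParams()
    rows = []
    fc_region: dict = {}
    ec: dict = {}
    mvc_cache: dict[int, dict[str, MvcReference]] = {}
    for ds in cohort.datasets():
        if ds.subject not in mvc_cache:
            mvc_cache[ds.subject] = {
                m: compute_mvc(cohort.mvc_trials(ds.subject, m), m, cohort.protocol.emg_rate)
                for m in ("BIC", "TRI")
            }
        out = analyze_dataset(ds, fapen_params, mvc_cache[ds.subject], dpf=dpf,
                              ec_max_lag=ec_max_lag, q=q)
        rows.append(out["row"])
        fc_region[ds.key] = out["nirs"]["fc_region"]
        ec[ds.key] = out["nirs"]["ec"]
        logger.info("analyzed %s", ds.label)
    return CohortResult(features=pd.DataFrame(rows), fc_region=fc_region, ec=ec)


# ---------------------------------------------------------------------------
# file-based stages


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _tree_checksums(root: Path) -> dict[str, str]:
    return {
        str(p.relative_to(root)): _sha256(p)
        for p in sorted(root.rglob("*"))
        if p.is_file()
    }


def stage_simulate(cfg: RunConfig, cohort_dir: Path) -> Path:
    generate_cohort(cfg.n_subjects, cfg.protocol, None, cfg.seed,
                    out_dir=cohort_dir, overwrite=cfg.overwrite)
    return cohort_dir


def stage_emg(cohort_dir: Path, out_path: Path, fapen_params: FapenParams) -> Path:
    manifest = read_manifest(cohort_dir)
    rows = []
    for _, entry in manifest.iterrows():
        emg, _ = read_dataset(Path(cohort_dir) / entry["path"])
        mvc = {
            m: compute_mvc(read_mvc_trials(cohort_dir, int(entry["subject"]), m), m, emg.rate)
            for m in ("BIC", "TRI")
        }
        row = analyze_emg(emg, mvc, fapen_params)
        row["subject"] = int(entry["subject"])
        rows.append(row)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out_path, sep="\t", index=False, float_format="%.8g")
    return out_path


def stage_nirs(cohort_dir: Path, out_dir: Path, dpf: float, fc_window: str,
               ec_max_lag: int, q: float) -> Path:
    """Write per-dataset activation rows, region series, FC and EC tables."""
    manifest = read_manifest(cohort_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    act_rows = []
    graph_rows = []
    for _, entry in manifest.iterrows():
        _, optical = read_dataset(Path(cohort_dir) / entry["path"])
        res = analyze_nirs(optical, dpf=dpf, fc_window=fc_window,
                           ec_max_lag=ec_max_lag, q=q)
        tag = Path(entry["path"]).name
        sub = int(entry["subject"])
        base = {"subject": sub, "side": entry["side"], "force": entry["force"]}
        act = res["activation"]
        for ci, layout_entry in enumerate(act.layout):
            act_rows.append({**base, "channel": layout_entry["name"],
                             "region": layout_entry["region"],
                             "beta": act.beta[ci], "integral_uM_s": act.integral_um_s[ci],
                             "valid": bool(act.valid[ci])})
        grow = dict(base)
        for r in REGIONS:
            grow[f"integral_{r}"] = act.region_integral.get(r, np.nan)
            grow[f"clustering_{r}"] = res["graph"].region_clustering.get(r, np.nan)
            grow[f"local_eff_{r}"] = res["graph"].region_local_efficiency.get(r, np.nan)
        grow["global_eff"] = res["graph"].global_efficiency
        graph_rows.append(grow)
        name = f"sub-{sub:02d}_{tag}"
        res["fc_region"].to_frame().to_csv(out_dir / f"fc_region_{name}.tsv", sep="\t",
                                           float_format="%.8g")
        pd.DataFrame(res["ec"].values, index=res["ec"].nodes,
                     columns=res["ec"].nodes).to_csv(out_dir / f"ec_{name}.tsv", sep="\t",
                                                     float_format="%.8g")
        pd.DataFrame(res["ec"].pvals, index=res["ec"].nodes,
                     columns=res["ec"].nodes).to_csv(out_dir / f"ec_p_{name}.tsv", sep="\t",
                                                     float_format="%.8g")
    pd.DataFrame(act_rows).to_csv(out_dir / "activation.tsv", sep="\t", index=False,
                                  float_format="%.8g")
    pd.DataFrame(graph_rows).to_csv(out_dir / "network.tsv", sep="\t", index=False,
                                    float_format="%.8g")
    return out_dir


def stage_connect(nirs_dir: Path, out_dir: Path, q: float) -> Path:
    """Group-level matrix comparisons (80% vs 20% per side) from the
    per-dataset FC tables."""
    out_dir.mkdir(parents=True, exist_ok=True)
    fc_files = sorted(Path(nirs_dir).glob("fc_region_*.tsv"))
    by_cond: dict[tuple[str, str], list[np.ndarray]] = {}
    nodes = None
    for f in fc_files:
        df = pd.read_csv(f, sep="\t", index_col=0)
        nodes = list(df.columns)
        # name: fc_region_sub-XX_<side>_f<force>.tsv
        parts = f.stem.split("_")
        side, force = parts[-2], parts[-1]
        by_cond.setdefault((side, force), []).append(df.to_numpy())
    for side in ("dom", "nondom"):
        lo, hi = by_cond.get((side, "f20")), by_cond.get((side, "f80"))
        if not lo or not hi or len(lo) < 2 or len(hi) < 2:
            continue
        edges = compare_matrices(lo, hi, paired=True, q=q, nodes=nodes)
        edges.to_csv(out_dir / f"edges_{side}_80v20.tsv", sep="\t", index=False,
                     float_format="%.8g")
    return out_dir


def stage_stats(features_path: Path, nirs_dir: Path, out_dir: Path, q: float) -> Path:
    from .stats import cross_modal_correlation, paired_compare, report

    features = pd.read_csv(features_path, sep="\t")
    network = pd.read_csv(Path(nirs_dir) / "network.tsv", sep="\t")
    table = features.merge(network, on=["subject", "side", "force"], how="left")
    paired = {}
    for metric in ("fapen_bic", "fapen_tri", "cci"):
        paired[metric] = paired_compare(table, metric, q=q)
    int_cols = [f"integral_{r}" for r in REGIONS]
    net_cols = [f"local_eff_{r}" for r in REGIONS] + [f"clustering_{r}" for r in REGIONS]
    corr = cross_modal_correlation(table, x="fapen_bic", y_cols=int_cols + net_cols, q=q)
    edge_cmp = {
        f.stem: pd.read_csv(f, sep="\t")
        for f in sorted(Path(nirs_dir).parent.glob("net/edges_*.tsv"))
    }
    report(out_dir, features=table, paired_results=paired, correlations=corr,
           edge_comparisons=edge_cmp or None)
    table.to_csv(out_dir / "cohort_table.tsv", sep="\t", index=False, float_format="%.8g")
    return out_dir


def run_all(cfg: RunConfig) -> Path:
    """Execute the five stages in order against ``cfg.out_dir``.

    Any stage failure raises with the stage name attached. ``run.json``
    records the config, package version and per-stage checksums; identical
    config + seed yields identical checksums.
    """
    root = Path(cfg.out_dir)
    root.mkdir(parents=True, exist_ok=True)
    stages = {}

    def run_stage(name, fn, *args):
        try:
            out = fn(*args)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        out = Path(out)
        stages[name] = (
            _tree_checksums(out) if out.is_dir() else {out.name: _sha256(out)}
        )
        logger.info("stage %s complete", name)
        return out

    cohort_dir = run_stage("simulate", stage_simulate, cfg, root / "cohort")
    features = run_stage("emg", stage_emg, cohort_dir, root / "features.tsv", cfg.fapen)
    nirs_dir = run_stage(
        "nirs", stage_nirs, cohort_dir, root / "nirs", cfg.dpf, cfg.fc_window,
        cfg.ec_max_lag, cfg.fdr_q,
    )
    run_stage("connect", stage_connect, nirs_dir, root / "net", cfg.fdr_q)
    run_stage("stats", stage_stats, features, nirs_dir, root / "results", cfg.fdr_q)

    cfg_dict = cfg.to_dict()
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    run_record = {
        "version": __version__,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "stages": stages,
    }
    (root / "run.json").write_text(json.dumps(run_record, indent=1, sort_keys=True) + "\n")
    return root


# ---------------------------------------------------------------------------
# validation against ground truth


def validate(run_dir: str | Path) -> dict:
    """Check every programmed effect direction against the run's estimates.

    With ground truth present: fApEn and CCI higher at 80% than 20% MVC
    (group means), HbO2 integral increasing with programmed gain, positive
    cross-modal correlation where drive variance was programmed, and
    programmed directed edges carrying larger Granger F than their
    reverses. Without ground truth only structural checks run.
    """
    run_dir = Path(run_dir)
    checks: dict[str, bool] = {}
    table_path = run_dir / "results" / "cohort_table.tsv"
    checks["cohort_table_present"] = table_path.exists()
    gt_path = run_dir / "cohort" / "ground_truth.json"
    if not table_path.exists():
        return {"passed": False, "checks": checks}
    table = pd.read_csv(table_path, sep="\t")
    checks["features_complete"] = not table[["fapen_bic", "fapen_tri", "cci"]].isna().any().any()
    if not gt_path.exists():
        return {"passed": all(checks.values()), "checks": checks, "note": "no ground truth"}
    truth = json.loads(gt_path.read_text())

    hi = table[table["force"] == 0.8]
    lo = table[table["force"] == 0.2]
    checks["fapen_bic_direction"] = hi["fapen_bic"].mean() > lo["fapen_bic"].mean()
    checks["fapen_tri_direction"] = hi["fapen_tri"].mean() > lo["fapen_tri"].mean()
    checks["cci_direction"] = hi["cci"].mean() > lo["cci"].mean()

    gains = pd.DataFrame(
        [
            {"subject": d["subject"], "side": d["side"], "force": d["force"],
             **{f"gain_{r}": g for r, g in d["region_gains"].items()}}
            for d in truth["datasets"]
        ]
    )
    merged = table.merge(gains, on=["subject", "side", "force"])
    for hemi, side in (("LMC", DOMINANT), ("RMC", "non-dominant")):
        sub = merged[merged["side"] == side]
        if len(sub) >= 3 and f"gain_{hemi}" in sub:
            r = np.corrcoef(sub[f"gain_{hemi}"], sub[f"integral_{hemi}"])[0, 1]
            checks[f"integral_tracks_gain_{hemi}"] = bool(r > 0)
    if truth.get("drive_sd", 0) > 0:
        for hemi, side in (("LMC", DOMINANT), ("RMC", "non-dominant")):
            sub = merged[merged["side"] == side]
            if len(sub) >= 3:
                r = np.corrcoef(sub["fapen_bic"], sub[f"integral_{hemi}"])[0, 1]
                checks[f"crossmodal_positive_{hemi}"] = bool(r > 0)
    else:
        checks["null_crossmodal"] = True

    # directed edges: programmed F exceeds reverse on average
    directed = {
        (d["side"], tuple(e[:2])): e[2]
        for d in truth["datasets"]
        for e in d["directed_edges"]
    }
    if directed:
        ec_files = sorted((run_dir / "nirs").glob("ec_sub-*.tsv"))
        fwd, rev = [], []
        for f in ec_files:
            side = "dominant" if "_dom_" in f.name else "non-dominant"
            df = pd.read_csv(f, sep="\t", index_col=0)
            for (s, edge), _ in directed.items():
                if s == side and edge[0] in df.index and edge[1] in df.columns:
                    fwd.append(df.loc[edge[0], edge[1]])
                    rev.append(df.loc[edge[1], edge[0]])
        if fwd:
            checks["directed_edges_recovered"] = float(np.mean(fwd)) > float(np.mean(rev))
    checks = {k: bool(v) for k, v in checks.items()}
    result = {"passed": all(checks.values()), "checks": checks}
    (run_dir / "validation.json").write_text(json.dumps(result, indent=1, sort_keys=True) + "\n")
    return result
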