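"""End-to-end orchestration: simulate -> preprocess -> connect -> compare -> subnet.

Each stage reads only what the previous stage declared as output inside one
working directory, writes CSV/JSON artifacts, and appends to a structured run
log. All randomness descends from the single seed in the manifest/config, so
a rerun with the same configuration reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import connectivity as conn
from . import netcompare, preprocess, subnet, synth
from .mbll import ExtinctionTable
from .probe import Probe, make_default_probe
from .scan import HB, Scan
from .snirf import read_snirf, write_snirf

HB_TYPES = ("HbO2", "HbR", "HbT")


@dataclass
class RunConfig:
    """Every tunable the pipeline consumes, validated up front."""

    qc: preprocess.QCParams = field(default_factory=preprocess.QCParams)
    band: tuple[float, float] = (0.01, 0.2)
    table: ExtinctionTable = field(default_factory=ExtinctionTable)
    max_ar_order: int | None = None        # default: ceil(2 fs) at run time
    kde_grid_size: int = 201
    q_max: float = 0.05
    r_min: float = 0.3
    dsi_hbt_threshold: float = 0.2         # mean DSI below this -> analyze HbT
    group_method: str = "lme"
    motion_correction: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError("invalid band edges")
        if not 0 < self.q_max < 1:
            raise ValueError("q_max must lie in (0, 1)")
        if self.r_min < 0 or self.r_min > 1:
            raise ValueError("r_min must lie in [0, 1]")
        if self.kde_grid_size < 3:
            raise ValueError("kde_grid_size too small")
        if self.group_method not in ("lme", "mean"):
            raise ValueError("group_method must be 'lme' or 'mean'")

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            return str(o)
        return json.dumps(dataclasses.asdict(self), default=enc, indent=2,
                          sort_keys=True)


def _scan_id(meta: dict) -> str:
    return f"{meta['subject']}_w{meta['week']}_{meta['stimulus']}"


# ---------------------------------------------------------------- intermediates

def save_hb_scan(path: Path, scan: Scan) -> None:
    with h5py.File(path, "w") as f:
        for k, v in scan.data.items():
            f.create_dataset(k, data=v)
        f.create_dataset("events", data=scan.events)
        f.attrs["sampling_rate"] = scan.sampling_rate
        f.attrs["regions"] = json.dumps(list(scan.probe.regions))
        f.attrs["meta"] = json.dumps({k: scan.meta.get(k) for k in
                                      ("subject", "group", "week", "stimulus")})
        f.attrs["channels"] = json.dumps([list(c) for c in scan.probe.channels])
        f.create_dataset("source_pos", data=scan.probe.source_pos)
        f.create_dataset("detector_pos", data=scan.probe.detector_pos)
        f.attrs["wavelengths"] = json.dumps(list(scan.probe.wavelengths))


def load_hb_scan(path: Path) -> Scan:
    with h5py.File(path, "r") as f:
        data = {k: np.asarray(f[k]) for k in HB_TYPES if k in f}
        probe = Probe(
            source_pos=np.asarray(f["source_pos"]),
            detector_pos=np.asarray(f["detector_pos"]),
            channels=tuple(tuple(c) for c in json.loads(f.attrs["channels"])),
            regions=tuple(json.loads(f.attrs["regions"])),
            wavelengths=tuple(json.loads(f.attrs["wavelengths"])),
        )
        return Scan(kind=HB, data=data, sampling_rate=float(f.attrs["sampling_rate"]),
                    probe=probe, events=np.asarray(f["events"]),
                    meta=json.loads(f.attrs["meta"]))


def networks_to_frame(networks: list[conn.ConnectivityNetwork]) -> pd.DataFrame:
    frames = []
    for net in networks:
        df = net.to_frame()
        for k, v in net.provenance.items():
            df[k] = v
        df["hb_type"] = net.hb_type
        df["n_effective"] = net.n_effective
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def frame_to_networks(df: pd.DataFrame) -> list[conn.ConnectivityNetwork]:
    nets = []
    keys = ["subject", "group", "week", "stimulus", "hb_type"]
    for vals, sub in df.groupby(keys, dropna=False, sort=True):
        chans = sorted(set(sub.ch_i) | set(sub.ch_j))
        idx = {c: i for i, c in enumerate(chans)}
        nc = len(chans)
        mats = {m: np.zeros((nc, nc)) for m in ("r", "t", "p", "q")}
        np.fill_diagonal(mats["r"], 1.0)
        for row in sub.itertuples(index=False):
            i, j = idx[row.ch_i], idx[row.ch_j]
            for m in ("r", "t", "p", "q"):
                v = getattr(row, m)
                mats[m][i, j] = mats[m][j, i] = v
        prov = dict(zip(keys[:4], vals[:4]))
        nets.append(conn.ConnectivityNetwork(
            channels=chans, r=mats["r"], t=mats["t"], p=mats["p"], q=mats["q"],
            n_effective=int(sub.n_effective.iloc[0]), hb_type=vals[4],
            provenance=prov))
    return nets


# ---------------------------------------------------------------- stages

def simulate_stage(manifest: synth.CohortManifest, outdir: Path,
                   design: synth.BlockDesign | None = None,
                   effects: synth.EffectSpec | None = None,
                   physiology: synth.PhysiologySpec | None = None,
                   motion_rate: float = 0.0) -> pd.DataFrame:
    """Generate the raw cohort: SNIRF files + ground-truth ledger + manifest."""
    raw = Path(outdir) / "raw"
    raw.mkdir(parents=True, exist_ok=True)
    ledger_rows = []
    for scan, row in synth.simulate_cohort(manifest, design=design,
                                           effects=effects, physiology=physiology,
                                           motion_rate=motion_rate):
        write_snirf(raw / f"{_scan_id(scan.meta)}.snirf", scan)
        ledger_rows.append(row)
    ledger = pd.DataFrame(ledger_rows)
    ledger.to_csv(Path(outdir) / "ledger.csv", index=False)
    with open(Path(outdir) / "ledger.json", "w") as fh:
        json.dump(ledger_rows, fh, indent=1)
    pd.DataFrame([{"subject": s, "group": g} for s, g in manifest.subjects]) \
        .to_csv(Path(outdir) / "manifest.csv", index=False)
    return ledger


def preprocess_stage(workdir: Path, config: RunConfig) -> pd.DataFrame:
    """Raw SNIRF -> preprocessed hemoglobin + QC report + triage manifest."""
    workdir = Path(workdir)
    hb_dir = workdir / "hb"
    hb_dir.mkdir(exist_ok=True)
    qc_rows, triage_rows = [], []
    for path in sorted((workdir / "raw").glob("*.snirf")):
        scan = read_snirf(path)
        hb, report, log = preprocess.preprocess_scan(
            scan, qc=config.qc, band=config.band, table=config.table,
            motion_correction=config.motion_correction)
        sid = _scan_id(scan.meta)
        for c in range(scan.n_channels):
            qc_rows.append({"scan": sid, "channel": scan.probe.channel_names[c],
                            "sci_mean": report.sci[:, c].mean(),
                            "psp_mean": report.psp[:, c].mean(),
                            "cqs": report.cqs[c],
                            "acceptable": bool(report.acceptable[c])})
        triage_rows.append({"scan": sid, "verdict": log["verdict"],
                            "n_acceptable": report.n_acceptable})
        if hb is not None:
            save_hb_scan(hb_dir / f"{sid}.h5", hb)
    pd.DataFrame(qc_rows).to_csv(workdir / "qc_report.csv", index=False)
    tri = pd.DataFrame(triage_rows)
    tri.to_csv(workdir / "triage.csv", index=False)
    return tri


def connect_stage(workdir: Path, config: RunConfig):
    """Hemoglobin scans -> scan-level + group-level networks + DSI summary."""
    workdir = Path(workdir)
    scan_nets: list[conn.ConnectivityNetwork] = []
    for path in sorted((workdir / "hb").glob("*.h5")):
        scan = load_hb_scan(path)
        for hb_type in HB_TYPES:
            scan_nets.append(conn.scan_connectivity(scan, hb_type=hb_type,
                                                    max_order=config.max_ar_order))
    networks_to_frame(scan_nets).to_csv(workdir / "scan_networks.csv", index=False)

    gdir = workdir / "group_networks"
    gdir.mkdir(exist_ok=True)
    stimuli = sorted({n.provenance["stimulus"] for n in scan_nets})
    group_nets: dict[tuple[str, str, str, int], conn.ConnectivityNetwork] = {}
    for stim in stimuli:
        for hb_type in HB_TYPES:
            sel = [n for n in scan_nets if n.hb_type == hb_type
                   and n.provenance["stimulus"] == stim]
            for (g, w), net in conn.group_connectivity(sel,
                                                       method=config.group_method).items():
                net.provenance["stimulus"] = stim
                group_nets[(stim, hb_type, g, w)] = net
                pd.DataFrame(net.r, index=net.channels, columns=net.channels) \
                    .to_csv(gdir / f"{stim}_{hb_type}_{g}_week{w}.csv")

    dsi_rows = []
    for stim in stimuli:
        cells = sorted({(g, w) for (s, h, g, w) in group_nets if s == stim})
        for g, w in cells:
            a = group_nets.get((stim, "HbO2", g, w))
            b = group_nets.get((stim, "HbR", g, w))
            if a is None or b is None:
                continue
            dsi_rows.append({"stimulus": stim, "group": g, "week": w,
                             "dsi": conn.compute_dsi(a, b, config.q_max)})
    dsi = pd.DataFrame(dsi_rows)
    dsi.to_csv(workdir / "dsi_summary.csv", index=False)
    mean_dsi = float(dsi["dsi"].mean()) if len(dsi) else float("nan")
    hb_choice = "HbT" if not np.isfinite(mean_dsi) or \
        mean_dsi < config.dsi_hbt_threshold else "HbO2"
    with open(workdir / "hb_choice.json", "w") as fh:
        json.dump({"mean_dsi": mean_dsi, "threshold": config.dsi_hbt_threshold,
                   "hb_for_analysis": hb_choice,
                   "rule": "analyze HbT when mean HbO2-HbR DSI is below threshold"},
                  fh, indent=2)
    return scan_nets, group_nets, hb_choice


def compare_stage(workdir: Path, config: RunConfig,
                  scan_nets=None, hb_choice: str = "HbT") -> pd.DataFrame:
    """Weekly active-vs-sham Hellinger distance tables per stimulus."""
    workdir = Path(workdir)
    if scan_nets is None:
        scan_nets = frame_to_networks(pd.read_csv(workdir / "scan_networks.csv"))
        hb_choice = json.load(open(workdir / "hb_choice.json"))["hb_for_analysis"]
    stimuli = sorted({n.provenance["stimulus"] for n in scan_nets})
    tables = []
    for stim in stimuli:
        tbl = netcompare.weekly_distance_table(scan_nets, stimulus=stim,
                                               hb_type=hb_choice,
                                               grid_size=config.kde_grid_size)
        tables.append(tbl)
    out = pd.concat(tables, ignore_index=True)
    out.to_csv(workdir / "hellinger_weekly.csv", index=False)
    return out


def subnet_stage(workdir: Path, config: RunConfig,
                 scan_nets=None, hb_choice: str = "HbT") -> pd.DataFrame:
    """Per-subject subnetwork summaries and the weekly group-comparison table."""
    workdir = Path(workdir)
    if scan_nets is None:
        scan_nets = frame_to_networks(pd.read_csv(workdir / "scan_networks.csv"))
        hb_choice = json.load(open(workdir / "hb_choice.json"))["hb_for_analysis"]
    probe = make_default_probe()
    region_of = dict(zip(probe.channel_names, probe.regions))
    summaries = []
    for net in scan_nets:
        if net.hb_type != hb_choice:
            continue
        regions = [region_of.get(c, "M1_S1") for c in net.channels]
        summaries.extend(subnet.summarize_network(net, regions,
                                                  q_max=config.q_max,
                                                  r_min=config.r_min))
    pd.DataFrame([vars(s) for s in summaries]).to_csv(
        workdir / "subnet_summaries.csv", index=False)
    report = subnet.weekly_report(summaries)
    report.to_csv(workdir / "subnet_report.csv", index=False)
    return report


def run_pipeline(manifest: synth.CohortManifest, config: RunConfig | None = None,
                 outdir: str | Path = "nirsconn_run",
                 design: synth.BlockDesign | None = None,
                 effects: synth.EffectSpec | None = None,
                 physiology: synth.PhysiologySpec | None = None,
                 motion_rate: float = 0.0) -> dict:
    """Execute every stage in order inside ``outdir``; returns a run summary."""
    config = config or RunConfig(seed=manifest.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "effective_config.json").write_text(config.to_json())

    log: dict = {"stages": []}
    simulate_stage(manifest, outdir, design=design, effects=effects,
                   physiology=physiology, motion_rate=motion_rate)
    log["stages"].append("simulate")
    tri = preprocess_stage(outdir, config)
    log["stages"].append("preprocess")
    log["n_scans"] = len(tri)
    log["n_dropped"] = int((tri["verdict"] == "drop").sum())
    scan_nets, group_nets, hb_choice = connect_stage(outdir, config)
    log["stages"].append("connect")
    log["n_scan_networks"] = len(scan_nets)
    log["n_group_networks"] = len(group_nets)
    log["hb_for_analysis"] = hb_choice
    compare_stage(outdir, config, scan_nets=scan_nets, hb_choice=hb_choice)
    log["stages"].append("compare")
    subnet_stage(outdir, config, scan_nets=scan_nets, hb_choice=hb_choice)
    log["stages"].append("subnet")
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return log
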