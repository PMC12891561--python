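"""End-to-end orchestration: simulate-or-read → segment → measure → pair → stats.

``run_pipeline`` executes the full quantification on one or more replicates,
writes per-stage CSV tables, label TIFFs, a JSON run manifest (config hash,
seed, library versions, per-stage counts) and a log.  Identical configuration
and seed produce identical output tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .core import ImageField
from .morphometrics import measure_labels, normalized_volume, overlap_percent
from .pairing import (aggregate_pairing, call_pairing, calls_to_frame)
from .segmentation import (nuclei_to_frame, segment_nuclei, segment_signals,
                           signals_to_frame)
from .simgen import SimulationConfig, generate_field
from .stats import detect_bimodality, levene, mann_whitney_u

log = logging.getLogger("ctmorph")


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs.

    Exactly one of ``simulation`` (a :class:`SimulationConfig` or its dict)
    and ``input_images`` (list of stack paths, one per replicate) must be set.
    """

    simulation: SimulationConfig | dict | None = None
    input_images: list | None = None
    voxel_size: tuple | None = None  # override for read stacks
    n_replicates: int = 1
    dna_channel: str = "dna"
    territory_channels: tuple[str, ...] | None = None
    intensity_channel: str | None = None
    min_nucleus_volume_um3: float = 5.0
    min_signal_volume_um3: float = 0.02
    exclude_border: bool = True
    smoothing_sigma_um: float = 0.2
    seed_min_distance_um: float = 1.5
    pairing_threshold_um: float = 0.8
    min_nuclei: int = 300
    min_replicates: int = 3
    output_dir: str = "ctmorph_out"
    seed: int = 0
    write_labels: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig.from_dict(self.simulation)

    def validate(self) -> None:
        if (self.simulation is None) == (self.input_images is None):
            raise ValueError(
                "set exactly one of 'simulation' and 'input_images'")
        if self.simulation is not None:
            self.simulation.validate()
            names = self.simulation.channel_names
            if self.dna_channel not in names:
                raise ValueError(
                    f"dna channel {self.dna_channel!r} not in {names}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**io.load_yaml(path))

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_jsonable(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _acquire(cfg: PipelineConfig, replicate: int):
    """One replicate's field (+ simulation truth when simulating)."""
    if cfg.simulation is not None:
        seed = int(cfg.seed) + replicate
        field_, truth_labels, truth = generate_field(cfg.simulation, seed=seed)
        return field_, truth
    path = cfg.input_images[replicate % len(cfg.input_images)]
    field_ = io.read_field(path, voxel_size=cfg.voxel_size)
    return field_, None


def _territory_channels(cfg: PipelineConfig, field_: ImageField):
    if cfg.territory_channels is not None:
        return tuple(cfg.territory_channels)
    skip = {cfg.dna_channel, cfg.intensity_channel}
    return tuple(c for c in field_.channel_names if c not in skip)


def run_replicate(cfg: PipelineConfig, replicate: int):
    """Segment, measure, and call pairing for one replicate.

    Returns a dict of DataFrames plus the nucleus LabelVolume and counts.
    """
    field_, truth = _acquire(cfg, replicate)
    vs = field_.voxel_size
    dna = field_.channel(cfg.dna_channel)
    nuc_labels, nuc_records = segment_nuclei(
        dna, vs, min_volume_um3=cfg.min_nucleus_volume_um3,
        exclude_border=cfg.exclude_border,
        smoothing_sigma_um=cfg.smoothing_sigma_um,
        seed_min_distance_um=cfg.seed_min_distance_um)
    nuclei_df = nuclei_to_frame(nuc_records)
    nuclei_df.insert(0, "replicate", replicate)
    included = {r.id for r in nuc_records if r.included}
    nuclear_vol = {r.id: r.volume_um3 for r in nuc_records}

    signal_frames, call_frames, metric_rows = [], [], []
    signal_volumes = {}
    for ch in _territory_channels(cfg, field_):
        sig_labels, sig_records, diag = segment_signals(
            field_.channel(ch), nuc_labels, vs,
            min_volume_um3=cfg.min_signal_volume_um3, channel_name=ch,
            included_ids=included)
        sig_df = signals_to_frame(sig_records)
        sig_df.insert(0, "replicate", replicate)
        signal_frames.append(sig_df)
        signal_volumes[ch] = sig_labels
        log.info("replicate %d channel %s: %d signals, %d voxels discarded "
                 "outside nuclei", replicate, ch, len(sig_records),
                 diag.discarded_voxels_outside_nuclei)

        nucleus_of = {r.component_id: r.nucleus_id for r in sig_records}
        metrics = measure_labels(
            sig_labels, intensity=field_.channel(ch), channel=ch,
            nucleus_of=nucleus_of, nuclear_volumes=nuclear_vol)
        for m in metrics:
            metric_rows.append({
                "replicate": replicate, "channel": ch,
                "nucleus_id": m.nucleus_id, "component_id": m.component_id,
                "volume_um3": m.volume_um3,
                "surface_area_um2": m.surface_area_um2,
                "sphericity": m.sphericity,
                "normalized_volume": m.normalized_volume,
                "mean_intensity": m.mean_intensity})

        by_nucleus: dict[int, list] = {}
        for r in sig_records:
            by_nucleus.setdefault(r.nucleus_id, []).append(r)
        calls = []
        for nid in sorted(included):
            calls.append(call_pairing(
                by_nucleus.get(nid, []), threshold_um=cfg.pairing_threshold_um,
                nucleus_id=nid, target=ch))
        call_frames.append(calls_to_frame(calls, replicate=replicate))

    result = {
        "field": field_,
        "nucleus_labels": nuc_labels,
        "signal_labels": signal_volumes,
        "nuclei": nuclei_df,
        "signals": (pd.concat(signal_frames, ignore_index=True)
                    if signal_frames else pd.DataFrame()),
        "metrics": pd.DataFrame(metric_rows),
        "calls": (pd.concat(call_frames, ignore_index=True)
                  if call_frames else pd.DataFrame()),
        "truth": truth,
    }
    return result


def paired_unpaired_volumes(metrics: pd.DataFrame,
                            calls: pd.DataFrame) -> pd.DataFrame:
    """Normalized territory volume per nucleus, split by pairing status.

    Paired nuclei contribute their (single or merged) signal volume; unpaired
    nuclei contribute the *combined* volume of the two homolog signals, both
    normalized to the host nuclear volume.
    """
    rows = []
    key = ["replicate", "channel", "nucleus_id"]
    grouped = metrics.groupby(key)
    call_idx = calls.set_index(["replicate", "target", "nucleus_id"])["status"]
    for (rep, ch, nid), grp in grouped:
        try:
            status = call_idx.loc[(rep, ch, nid)]
        except KeyError:
            continue
        if status not in ("paired", "unpaired"):
            continue
        norm = grp["normalized_volume"].dropna()
        if norm.empty:
            continue
        rows.append({"replicate": rep, "channel": ch, "nucleus_id": nid,
                     "status": status,
                     "combined_normalized_volume": float(norm.sum())})
    return pd.DataFrame(rows, columns=["replicate", "channel", "nucleus_id",
                                       "status", "combined_normalized_volume"])


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all replicates and write tables, labels, manifest, and log."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(cfg.log_level)
    manifest = {
        "config_hash": _config_hash(cfg),
        "seed": int(cfg.seed),
        "versions": _versions(),
        "replicates": [],
        "status": "FAILED",
    }
    try:
        all_nuclei, all_signals, all_metrics, all_calls = [], [], [], []
        for rep in range(cfg.n_replicates):
            res = run_replicate(cfg, rep)
            all_nuclei.append(res["nuclei"])
            all_signals.append(res["signals"])
            all_metrics.append(res["metrics"])
            all_calls.append(res["calls"])
            counts = {
                "replicate": rep,
                "n_nuclei": int(len(res["nuclei"])),
                "n_nuclei_included": int(res["nuclei"]["included"].sum())
                if len(res["nuclei"]) else 0,
                "n_signals": int(len(res["signals"])),
            }
            if res["truth"] is not None:
                counts["n_nuclei_truth"] = int(len(res["truth"].nuclei))
            manifest["replicates"].append(counts)
            if cfg.write_labels:
                io.write_labels(res["nucleus_labels"],
                                outdir / f"rep{rep}_nuclei_labels.tif")
                for ch, lv in res["signal_labels"].items():
                    io.write_labels(lv, outdir / f"rep{rep}_{ch}_labels.tif")

        nuclei = pd.concat(all_nuclei, ignore_index=True)
        signals = pd.concat(all_signals, ignore_index=True)
        metrics = pd.concat(all_metrics, ignore_index=True)
        calls = pd.concat(all_calls, ignore_index=True)

        summaries = []
        for ch, grp in calls.groupby("target"):
            s = aggregate_pairing(grp, min_nuclei=cfg.min_nuclei,
                                  min_replicates=cfg.min_replicates, target=ch)
            summaries.append({
                "target": s.target, "mean_percent_paired": s.mean_percent,
                "sd_percent_paired": s.sd_percent,
                "total_nuclei": s.total_nuclei,
                "n_replicates": s.n_replicates, "reportable": s.reportable})
        pairing_summary = pd.DataFrame(
            summaries, columns=["target", "mean_percent_paired",
                                "sd_percent_paired", "total_nuclei",
                                "n_replicates", "reportable"])

        volumes = paired_unpaired_volumes(metrics, calls)
        stats_rows = []
        for ch, grp in volumes.groupby("channel"):
            p_vals = grp.loc[grp["status"] == "paired",
                             "combined_normalized_volume"].to_numpy()
            u_vals = grp.loc[grp["status"] == "unpaired",
                             "combined_normalized_volume"].to_numpy()
            if len(p_vals) >= 2 and len(u_vals) >= 2:
                for res_ in (mann_whitney_u(p_vals, u_vals),
                             levene(p_vals, u_vals)):
                    stats_rows.append({
                        "channel": ch, "comparison": "paired_vs_unpaired",
                        "test": res_.test_name, "statistic": res_.statistic,
                        "p_value": res_.p_value, "n_a": res_.n_a,
                        "n_b": res_.n_b})
            if len(p_vals) >= 20:
                bim = detect_bimodality(p_vals)
                stats_rows.append({
                    "channel": ch, "comparison": "paired_bimodality",
                    "test": "kde_bimodality",
                    "statistic": float(bim.is_bimodal),
                    "p_value": np.nan, "n_a": len(p_vals), "n_b": 0})
        stats_df = pd.DataFrame(stats_rows, columns=[
            "channel", "comparison", "test", "statistic", "p_value",
            "n_a", "n_b"])

        for name, df in (("nuclei", nuclei), ("signals", signals),
                         ("metrics", metrics), ("pairing_calls", calls),
                         ("pairing_summary", pairing_summary),
                         ("paired_unpaired_volumes", volumes),
                         ("stats", stats_df)):
            df.to_csv(outdir / f"{name}.csv", index=False)
        manifest["tables"] = {
            "nuclei": len(nuclei), "signals": len(signals),
            "metrics": len(metrics), "pairing_calls": len(calls)}
        manifest["status"] = "OK"
        return manifest
    except Exception as exc:  # annotate the failing stage, keep partials
        manifest["error"] = repr(exc)
        (outdir / "FAILED").write_text(repr(exc))
        raise
    finally:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        log.removeHandler(handler)
        handler.close()


def _versions() -> dict:
    import scipy
    import skimage

    return {"ctmorph": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "scikit-image": skimage.__version__}
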