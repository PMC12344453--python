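"""End-to-end orchestration: simulate → segment → analyze → ps → classify.

A :class:`PipelineConfig` (flat INI file with one section per stage, CLI
flags overriding) drives the run; every stage writes machine-readable CSV/
JSON outputs plus a manifest with a checksum per file, the config hash and
package versions, so a completed deterministic run is byte-reproducible.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import Recording, Signal, normalize_max_abs, write_table
from .ps import PSOptions, windowed_ps
from .ratio import RegimeFeatures, classify_group, estimate_ratio, ratio_table, track_ratio
from .segmentation import SegmentationProfile, segment_area
from .spectral import (FoTrack, SpectrogramSpec, detect_biphonation,
                       detect_frequency_jump, detect_subharmonics, estimate_fo,
                       periodicity_index, stft_spectrogram)
from .synth import (CouplingSpec, FoTrajectory, OscillatorSpec, RenderSpec,
                    SceneSpec, ground_truth_to_csv, make_coupled_scene)

log = logging.getLogger("phonosync")


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    out_dir: Path
    scene: SceneSpec | None = None
    input_paths: dict | None = None          # alternative to scene
    seed: int = 0
    fmin: float = 30.0
    fmax: float = 1000.0
    analysis_interval: tuple[float, float] | None = None
    ps_group: str = "group2"
    glottis_visible: bool = True
    segment_profiles: dict = field(default_factory=dict)
    simulate_only: bool = False
    stft_window: int = 2048

    def __post_init__(self) -> None:
        if (self.scene is None) == (self.input_paths is None):
            raise ValueError("exactly one input source (scene or input_paths) required")
        if self.scene is not None and self.analysis_interval is not None:
            t0, t1 = self.analysis_interval
            if not (0 <= t0 < t1 <= self.scene.duration):
                raise ValueError(f"analysis interval {self.analysis_interval} "
                                 f"outside [0, {self.scene.duration}]")

    @classmethod
    def from_ini(cls, path, **overrides) -> "PipelineConfig":
        cp = configparser.ConfigParser()
        if not cp.read(path):
            raise FileNotFoundError(path)
        sc = cp["scene"] if "scene" in cp else {}
        scene = None
        if sc:
            fo = float(sc.get("fo_glottal", 136.0))
            traj = FoTrajectory.constant(fo)
            if "glissando_to" in sc:
                traj = FoTrajectory.glissando(
                    fo, float(sc["glissando_to"]),
                    float(sc.get("glissando_start", 0.5)),
                    float(sc.get("glissando_end", 1.5)))
            scene = SceneSpec(
                glottal=OscillatorSpec(fo=traj,
                                       open_quotient=float(sc.get("open_quotient", 0.6))),
                coupling=CouplingSpec(
                    ratio_n=int(sc.get("ratio_n", 2)),
                    regime=sc.get("regime", "locked"),
                    subharmonic_depth=float(sc.get("subharmonic_depth", 0.0)),
                    phase_offset=float(sc.get("phase_offset", 0.0)),
                    noise_snr_db=(float(sc["noise_snr_db"])
                                  if "noise_snr_db" in sc else None)),
                duration=float(sc.get("duration", 2.0)),
                fs=float(sc.get("fs", 20000.0)),
                render=(RenderSpec() if sc.get("render", "false").lower() == "true"
                        else None),
                seed=int(sc.get("seed", 0)))
        an = cp["analysis"] if "analysis" in cp else {}
        interval = None
        if "interval_start" in an:
            interval = (float(an["interval_start"]), float(an["interval_end"]))
        out = cp["output"] if "output" in cp else {}
        kwargs = dict(
            out_dir=Path(out.get("dir", "pipeline_out")),
            scene=scene,
            seed=int(sc.get("seed", 0)) if sc else 0,
            fmin=float(an.get("fmin", 30.0)),
            fmax=float(an.get("fmax", 1000.0)),
            analysis_interval=interval,
            ps_group=(cp["ps"].get("group", "group2") if "ps" in cp else "group2"),
            glottis_visible=(an.get("glottis_visible", "true").lower() == "true"),
            simulate_only=(an.get("simulate_only", "false").lower() == "true"),
        )
        kwargs.update(overrides)
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all configured stages; returns the manifest dict.

    Deterministic stages are byte-reproducible: rerunning an identical
    config rewrites identical files.
    """
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    log.info("stage simulate/load")
    if cfg.scene is not None:
        rec, gt = make_coupled_scene(cfg.scene)
        gt_path = out / "ground_truth.csv"
        ground_truth_to_csv(gt, gt_path)
        written.append(gt_path)
    else:
        from .io import read_recording
        rec = read_recording(**cfg.input_paths)
        gt = None
    ch_path = out / "channels.csv"
    write_table(ch_path, rec.channels)
    written.append(ch_path)

    report: dict = {"stages": ["simulate"]}
    if cfg.simulate_only:
        return _finish(cfg, out, written, report)

    if rec.frames is not None:
        log.info("stage segment")
        profiles = cfg.segment_profiles or {
            "glottal": SegmentationProfile(grey_threshold=0.7, target="glottal"),
            "supraglottic": SegmentationProfile(grey_threshold=0.3, target="supraglottic"),
        }
        for name, prof in profiles.items():
            aw = segment_area(rec.frames, prof)
            p = out / f"area_{name}.csv"
            aw.to_frame().to_csv(p, index=False)
            written.append(p)
        report["stages"].append("segment")

    log.info("stage analyze")
    interval = cfg.analysis_interval
    tracks: dict[str, FoTrack] = {}
    fo_rows = []
    for lab in ("iEGG", "audio", "SAW", "GAW"):
        if lab not in rec:
            continue
        try:
            sig = normalize_max_abs(rec[lab])
        except ValueError:
            log.warning("channel %s is silent; skipped", lab)
            continue
        tr = estimate_fo(sig, cfg.fmin, cfg.fmax)
        tracks[lab] = tr
        p = out / f"fo_{lab}.csv"
        tr.to_frame().to_csv(p, index=False, float_format="%.6g")
        written.append(p)
        mean, sd = tr.segment_stats(*(interval or (None, None)))
        fo_rows.append({"channel": lab, "fo_mean_hz": mean, "fo_sd_hz": sd})
    pd.DataFrame(fo_rows).to_csv(out / "fo_summary.csv", index=False,
                                 float_format="%.6g")
    written.append(out / "fo_summary.csv")

    events = []
    ref = "iEGG" if "iEGG" in rec else "audio"
    sspec = SpectrogramSpec(window_length=min(cfg.stft_window * 4, len(rec[ref])))
    events += detect_subharmonics(rec[ref], tracks.get(ref), spec=sspec)
    if ref in tracks and tracks[ref].voiced.any():
        events += detect_frequency_jump(tracks[ref])
    events += detect_biphonation(rec[ref], spec=sspec)
    ev_df = pd.DataFrame([{"kind": e.kind, "t_start": e.t_start, "t_end": e.t_end,
                           "strength": e.strength, **e.params} for e in events])
    ev_df.to_csv(out / "events.csv", index=False, float_format="%.6g")
    written.append(out / "events.csv")
    report["stages"].append("analyze")
    report["n_events"] = len(events)

    log.info("stage ps")
    ps_block = {}
    if "iEGG" in rec and "SAW" in rec:
        if cfg.ps_group == "group1" and "iEGG" in tracks and "audio" in tracks:
            fo_iegg = tracks["iEGG"].segment_stats()[0]
            fo_audio = tracks["audio"].segment_stats()[0]
            opts = PSOptions.group1(rec.fs, fo_iegg, fo_audio)
        else:
            opts = PSOptions.group2(rec.fs)
        series = windowed_ps(rec["iEGG"], rec["SAW"], opts)
        p = out / "ps_iEGG_SAW.csv"
        series.to_frame().to_csv(p, index=False, float_format="%.6g")
        written.append(p)
        miss = int(np.sum(~series.valid))
        if miss:
            log.warning("%d PS windows missing (silent channel)", miss)
        ps_block = {"nwin": series.nwin, "n_windows": len(series.t_center),
                    "n_missing": miss}
        report["stages"].append("ps")
    report["ps"] = ps_block

    log.info("stage classify")
    # the GAW carries the raw glottal oscillation rate; the iEGG fundamental
    # halves under period doubling, so prefer GAW for the ratio numerator
    g_lab = "GAW" if "GAW" in tracks else ("iEGG" if "iEGG" in tracks else None)
    label_block: dict = {}
    if g_lab and "SAW" in tracks:
        fo_ref = tracks[g_lab].segment_stats(*(interval or (None, None)))[0]
        win_s = max(0.2, 4.0 / cfg.fmin)
        _, pidx = periodicity_index(normalize_max_abs(rec["SAW"]), win_s,
                                    min_period_s=1.0 / cfg.fmax if not np.isfinite(fo_ref)
                                    else 0.5 / fo_ref)
        try:
            est = estimate_ratio(tracks[g_lab], tracks["SAW"], interval)
            ratio_n, ratio_conf = est.n, est.confidence
        except ValueError:
            ratio_n, ratio_conf = None, 0.0
        feats = RegimeFeatures(periodicity=float(np.mean(pidx)),
                               ratio_confidence=ratio_conf,
                               glottis_visible=cfg.glottis_visible)
        label = classify_group(feats)
        label_block = {"group": label.group, "ratio_n": ratio_n,
                       "ratio_confidence": round(ratio_conf, 4),
                       "periodicity": round(feats.periodicity, 4),
                       "glottis_visible": cfg.glottis_visible}
        lp = out / "label.json"
        lp.write_text(json.dumps(label_block, indent=2, sort_keys=True) + "\n")
        written.append(lp)
        report["stages"].append("classify")
    report["label"] = label_block
    return _finish(cfg, out, written, report)


def _finish(cfg: PipelineConfig, out: Path, written: list[Path], report: dict) -> dict:
    cfg_repr = repr({k: repr(v) for k, v in sorted(vars(cfg).items())})
    manifest = {
        "package": "phonosync",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(cfg_repr.encode()).hexdigest(),
        "files": {p.name: _sha256(p) for p in sorted(written)},
        "report": report,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
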