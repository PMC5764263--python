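"""End-to-end orchestration: replicate the analysis on synthetic cohorts.

Stage order: simulate -> preprocess -> ersp -> source_recon -> dcm (models x
subjects x streams) -> bms -> stats.  Every stage communicates through
serialized artifacts inside the run directory, and a manifest records stages,
seeds and input hashes (no timestamps, so reruns are byte-identical).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import bms as bms_mod
from . import dcm_core, ersp, group_stats, preprocess, source_recon, synthetic_data
from .errors import IntegrityError

logger = logging.getLogger("eegdcm")

STAGES = ("simulate", "preprocess", "ersp", "source_recon", "dcm", "bms", "stats")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/default"
    n_subjects: int = 4
    session_kinds: tuple = ("ME", "MI")
    model_indices: tuple = tuple(range(1, 17))
    n_blocks: int = 6
    fs_raw: float = 1024.0
    dcm_fs: float = 64.0
    dcm_duration: float = 4.0
    dcm_max_iter: int = 48
    inverse_lambda: float = 1e-2
    q_level: float = 0.05
    save_raw: bool = False
    simulate_overrides: dict = field(default_factory=dict)
    preprocess_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_toml(cls, path, seed=None) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        kw = {}
        for key in (
            "seed", "out_dir", "n_subjects", "n_blocks", "fs_raw", "dcm_fs",
            "dcm_duration", "dcm_max_iter", "inverse_lambda", "q_level", "save_raw",
        ):
            if key in raw:
                kw[key] = raw[key]
        if "session_kinds" in raw:
            kw["session_kinds"] = tuple(raw["session_kinds"])
        if "model_indices" in raw:
            kw["model_indices"] = tuple(raw["model_indices"])
        kw["simulate_overrides"] = raw.get("simulate", {})
        kw["preprocess_overrides"] = raw.get("preprocess", {})
        cfg = cls(**kw)
        if seed is not None:
            cfg.seed = seed
        return cfg


def split_streams(
    epochs: preprocess.Epochs,
    response_log: synthetic_data.ResponseLog,
    session_kind: str,
) -> dict:
    """Partition retained epochs by behavioural response."""
    responses = dict(response_log.entries)
    blocks = epochs.metadata["block_index"].to_numpy()
    missing = [int(b) for b in blocks if int(b) not in responses]
    if missing:
        raise IntegrityError(f"no response recorded for blocks {missing}")
    out = {}
    for resp in ("correct", "incorrect"):
        keep = np.array([responses[int(b)] == resp for b in blocks], dtype=bool)
        sub = preprocess.Epochs(
            data=epochs.data[keep],
            fs=epochs.fs,
            tmin=epochs.tmin,
            channel_labels=epochs.channel_labels,
            metadata=epochs.metadata[keep].reset_index(drop=True),
            rejection_log=list(epochs.rejection_log),
        )
        if sub.n_epochs == 0:
            logger.warning("stream %s_%s is empty", session_kind, resp)
        out[f"{session_kind}_{resp}"] = sub
    return out


def trial_inputs(
    fs: float,
    duration: float = 4.0,
    reps: int = 1,
    pulse_s: float = 0.2,
    dot_s: float = 0.8,
    iti: float = 1.3,
) -> dict:
    """Epoch-relative DCM inputs (first dot at t=0), tiled over ``reps`` blocks.

    The driving input is a brief pulse at each dot onset; the modulatory input
    is a boxcar over the full dot-performance window.  Keeping them distinct
    avoids collinearity between the C and B pathways.
    """
    n = int(round(duration * fs))
    drive = np.zeros(n)
    mod = np.zeros(n)
    t = 0.0
    while t < duration:
        i0 = int(round(t * fs))
        drive[i0 : min(int(round((t + pulse_s) * fs)), n)] = 1.0
        mod[i0 : min(int(round((t + dot_s) * fs)), n)] = 1.0
        t += iti
    return {"drive": np.tile(drive, reps), "mod": np.tile(mod, reps)}


def _dcm_inputs(timing: synthetic_data.TimingConfig, fs: float, duration: float):
    """Epoch-relative driving/modulatory inputs built from the task timing."""
    return trial_inputs(
        fs, duration, dot_s=timing.dot_duration, iti=timing.inter_trial_interval
    )


def roi_series_for_dcm(
    epochs: preprocess.Epochs,
    leadfield: synthetic_data.LeadField,
    roiset: source_recon.ROISet,
    lam: float,
    fs_out: float,
    duration: float,
) -> np.ndarray:
    """Average epochs, invert to sources, extract ROI series, window to
    [0, duration) and downsample; normalized to unit overall SD."""
    avg = epochs.data.mean(axis=0)  # (c, s)
    est = source_recon.minimum_norm_inverse(avg, leadfield.gain, lam)
    roits = source_recon.extract_roi_timeseries(
        est, leadfield.source_positions, roiset, epochs.fs
    )
    i0 = int(round(-epochs.tmin * epochs.fs))
    i1 = i0 + int(round(duration * epochs.fs))
    seg = roits.data[:, i0:i1]
    seg = preprocess.resample(seg, epochs.fs, fs_out)
    sd = seg.std()
    return seg / sd if sd > 0 else seg


def _hash(arr) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_all(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"stages": [], "seed": config.seed, "config": asdict(config)}
    (out / "config.json").write_text(json.dumps(asdict(config), indent=2, default=str))

    ss = np.random.SeedSequence(config.seed)
    subject_seeds = ss.spawn(config.n_subjects)
    space = bms_mod.build_model_space()
    partition = bms_mod.default_partition(space)
    roiset = source_recon.default_roiset()
    pconf = preprocess.PreprocConfig(**config.preprocess_overrides)
    timing = synthetic_data.TimingConfig()
    inputs = _dcm_inputs(timing, config.dcm_fs, config.dcm_duration)
    dt = 1.0 / config.dcm_fs

    stage_hashes = {}
    per_stream_F: dict[str, dict] = {}
    per_stream_fits: dict[str, dict] = {}
    ersp_tables = []

    try:
        for si, sub_ss in enumerate(subject_seeds):
            rngs = sub_ss.spawn(len(config.session_kinds))
            for kind, kind_ss in zip(config.session_kinds, rngs):
                seed = int(kind_ss.generate_state(1)[0] % (2**31))
                sim_cfg = synthetic_data.SimulationConfig(
                    session_kind=kind,
                    n_blocks=config.n_blocks,
                    fs_raw=config.fs_raw,
                    **config.simulate_overrides,
                )
                session = synthetic_data.simulate_session(sim_cfg, seed=seed)
                if config.save_raw:
                    synthetic_data.write_session(
                        session,
                        out / f"sub-{si:02d}_{kind}.edf",
                        out / f"sub-{si:02d}_{kind}_events.tsv",
                    )
                stage_hashes.setdefault("simulate", []).append(
                    _hash(session.recording.data)
                )

                eps = preprocess.run_preprocess(session.recording, pconf)
                stage_hashes.setdefault("preprocess", []).append(_hash(eps.data))
                for entry in eps.rejection_log:
                    logger.info("sub %d %s rejected: %s", si, kind, entry)

                emap = ersp.compute_ersp(eps)
                tbl = ersp.band_window_table(emap)
                tbl.insert(0, "subject", si)
                tbl.insert(1, "session", kind)
                ersp_tables.append(tbl)

                streams = split_streams(eps, session.responses, kind)
                for stream, sub_eps in streams.items():
                    if sub_eps.n_epochs == 0:
                        continue
                    roi = roi_series_for_dcm(
                        sub_eps, session.leadfield, roiset,
                        config.inverse_lambda, config.dcm_fs, config.dcm_duration,
                    )
                    stage_hashes.setdefault("source_recon", []).append(_hash(roi))
                    for mi in config.model_indices:
                        fit = dcm_core.invert(
                            space.model(mi), roi, inputs, dt,
                            max_iter=config.dcm_max_iter,
                        )
                        if not fit.converged:
                            logger.warning(
                                "non-converged fit: sub %d %s model %d", si, kind, mi
                            )
                        per_stream_F.setdefault(stream, {}).setdefault(si, {})[mi] = (
                            fit.free_energy
                        )
                        per_stream_fits.setdefault(stream, {}).setdefault(si, {})[mi] = fit

        for st in ("simulate", "preprocess", "ersp", "source_recon", "dcm"):
            manifest["stages"].append({"stage": st, "hashes": stage_hashes.get(st, [])})

        pd.concat(ersp_tables, ignore_index=True).to_csv(
            out / "ersp_band_windows.tsv", sep="\t", index=False
        )

        # BMS per stream (only when the full model space was fit)
        coupling_tables = {}
        bms_summary = {}
        full_space = tuple(config.model_indices) == tuple(range(1, 17))
        for stream, by_subject in per_stream_F.items():
            subjects = sorted(by_subject)
            F = np.array(
                [[by_subject[s][mi] for mi in config.model_indices] for s in subjects]
            )
            np.savetxt(
                out / f"summed_log_evidence_{stream}.tsv",
                F.sum(axis=0)[None, :],
                delimiter="\t",
            )
            if not full_space:
                continue
            table = bms_mod.EvidenceTable(F=F, subject_ids=tuple(subjects), stream=stream)
            res = bms_mod.run_bms(table, partition)
            bms_summary[stream] = {
                "family_posteriors": res.family_posteriors,
                "dominant_family": res.dominant_family,
                "best_model_index": res.best_model_index,
            }
            members = sorted(partition.families[res.dominant_family])
            rows = {}
            for s in subjects:
                fits = per_stream_fits[stream][s]
                bmat = bms_mod.bma_couplings(
                    {i: fits[i] for i in members},
                    res.within_family_posteriors,
                    space,
                    members,
                )
                rows[s] = {
                    f"{dcm_core.NODES[i]}<-{dcm_core.NODES[j]}": bmat[i, j]
                    for i in range(4)
                    for j in range(4)
                    if i != j
                }
            coupling_tables[stream] = pd.DataFrame.from_dict(rows, orient="index")
            coupling_tables[stream].to_csv(out / f"couplings_{stream}.tsv", sep="\t")
        (out / "bms_summary.json").write_text(json.dumps(bms_summary, indent=2))
        manifest["stages"].append({"stage": "bms", "streams": sorted(per_stream_F)})

        # group statistics between correct streams
        stats_written = []
        pairs = [("ME_correct", "MI_correct")]
        for a, b in pairs:
            if a in coupling_tables and b in coupling_tables:
                ta, tb = coupling_tables[a], coupling_tables[b]
                if len(ta) < 2 or len(tb) < 2:
                    logger.warning("stream %s/%s too small for statistics", a, b)
                    continue
                shared = [c for c in ta.columns if c in tb.columns]
                report = group_stats.compare_streams(
                    ta[shared], tb[shared], q=config.q_level
                )
                report.to_csv(out / f"stats_{a}_vs_{b}.tsv", sep="\t", index=False)
                stats_written.append(f"{a}_vs_{b}")
        manifest["stages"].append({"stage": "stats", "reports": stats_written})
    except Exception as exc:  # persist partial outputs, then re-raise with stage
        manifest["failed"] = repr(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
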