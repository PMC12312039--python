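"""End-to-end pipeline: eyelid scoring -> drowsigram -> spectra -> statistics.

The stage functions here tie the per-module operations together for one
participant or a whole (synthetic or real) cohort, and ``run_pipeline``
drives a complete file-producing run from a simulation configuration,
emitting every intermediate table plus a checksummed manifest.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import drowsigram as dg
from . import ocular, spectral, stats
from .io import RunManifest, write_table, write_timeseries
from .simulate import SimulatedDataset, SimulationConfig, simulate_dataset
from .states import STATE_NAMES

__all__ = [
    "score_eyes",
    "drowsigram_from_closure",
    "participant_state_psd",
    "cohort_state_psd_table",
    "occupancy_table",
    "run_pipeline",
]


def score_eyes(
    ear_trace: ocular.EarTrace, threshold: float = 0.8
) -> tuple[ocular.EarTrace, ocular.ClosureSignal]:
    """Blink-normalize an EAR trace and binarize it into a closure signal."""
    blinks = ocular.segment_blinks(ear_trace)
    norm = ocular.normalize_ear(ear_trace, blinks)
    return norm, ocular.binarize_closure(norm, threshold=threshold)


def drowsigram_from_closure(
    closure: ocular.ClosureSignal,
    window_s: float = 60.0,
    step_s: float = 1.0,
    microsleep_s: float = 5.0,
) -> dg.Drowsigram:
    """PERCLOS staging plus the sustained-closure microsleep override."""
    perclos = dg.compute_perclos(closure, window_s=window_s, step_s=step_s)
    runs = dg.detect_microsleep(closure, min_duration_s=microsleep_s)
    return dg.classify_drowsigram(perclos, runs)


def participant_state_psd(
    pid: str,
    ear_trace: ocular.EarTrace,
    bold: np.ndarray,
    atlas: pd.DataFrame,
    tr_s: float = 1.0,
    confounds=None,
    threshold: float = 0.8,
) -> tuple[pd.DataFrame, dg.Drowsigram, spectral.MultitaperSpectrogram]:
    """One participant through the whole scoring + spectral chain.

    Returns the per-(ROI, state) band-power rows, the recovered drowsigram,
    and the ROI-stacked spectrogram.
    """
    _, closure = score_eyes(ear_trace, threshold=threshold)
    d = drowsigram_from_closure(closure)
    series = spectral.regress_confounds(bold, confounds) if confounds is not None \
        else np.atleast_2d(np.asarray(bold, dtype=float))
    spec = spectral.multitaper_spectrogram(series, fs=1.0 / tr_s)
    table = spectral.state_psd_table(spec, d.t_s, d.state,
                                     roi_ids=atlas["roi_id"].tolist(),
                                     participant=pid, atlas=atlas)
    return table, d, spec


def cohort_state_psd_table(
    dataset: SimulatedDataset, confounds=None
) -> tuple[pd.DataFrame, dict[str, dg.Drowsigram]]:
    """State-conditioned band power for every participant of a cohort."""
    tables = []
    drowsigrams: dict[str, dg.Drowsigram] = {}
    for p in dataset.participants:
        table, d, _ = participant_state_psd(
            p.pid, p.ear, p.bold, dataset.atlas,
            tr_s=dataset.config.tr_s, confounds=confounds)
        tables.append(table)
        drowsigrams[p.pid] = d
    return pd.concat(tables, ignore_index=True), drowsigrams


def occupancy_table(drowsigrams: dict[str, dg.Drowsigram]) -> pd.DataFrame:
    """Long-format per-(participant, state) occupancy fractions."""
    recs = []
    for pid, d in drowsigrams.items():
        occ = dg.state_occupancy(d)
        for state in STATE_NAMES:
            recs.append({"participant": pid, "state": state,
                         "occupancy": float(occ[state])})
    return pd.DataFrame(recs)


def run_pipeline(config: SimulationConfig, outdir, atlas=None) -> RunManifest:
    """Full synthetic run: simulate, score, analyse, write tables + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset = simulate_dataset(config, atlas=atlas)
    manifest = RunManifest(
        config=dataclasses.asdict(config), seed=config.seed,
        decisions={
            "closure_threshold": 0.8,
            "perclos_window_s": 60, "perclos_step_s": 1,
            "microsleep_min_s": 5,
            "state_thresholds": [0.08, 0.15],
            "glm_family": "gaussian", "glm_reference": "F",
            "lmm_ddf": "containment",
        })

    atlas_path = write_table(dataset.atlas, outdir / "atlas.tsv")
    manifest.add_output("atlas", atlas_path)

    psd_table, drowsigrams = cohort_state_psd_table(dataset)
    for p in dataset.participants:
        t_vol = np.arange(p.bold.shape[1]) * config.tr_s
        write_timeseries(dataset.atlas["roi_id"], t_vol, p.bold,
                         outdir / "bold" / f"{p.pid}_bold.tsv")
        write_table(pd.DataFrame({"t_s": p.ear.t_s, "ear": p.ear.ear}),
                    outdir / "ear" / f"{p.pid}_ear.tsv")
        write_table(drowsigrams[p.pid].to_frame(),
                    outdir / "drowsigram" / f"{p.pid}_drowsigram.tsv")
    psd_path = write_table(psd_table, outdir / "state_psd.tsv")
    manifest.add_output("state_psd", psd_path)

    occ = occupancy_table(drowsigrams)
    manifest.add_output("occupancy", write_table(occ, outdir / "occupancy.tsv"))

    glm = stats.roi_glm_table(psd_table)
    manifest.add_output("roi_glm", write_table(glm, outdir / "roi_glm.tsv"))
    posthoc = stats.pairwise_posthoc(psd_table)
    manifest.add_output("roi_posthoc",
                        write_table(posthoc, outdir / "roi_posthoc.tsv"))
    lmm = stats.network_lmm(psd_table)
    manifest.add_output("network_anova",
                        write_table(lmm.anova, outdir / "network_anova.tsv"))
    manifest.add_output("network_posthoc",
                        write_table(lmm.posthoc, outdir / "network_posthoc.tsv"))
    anova = stats.rsq_anova(occ, dataset.rsq_labels)
    manifest.add_output(
        "rsq_anova",
        write_table(anova.table.reset_index(names="term"),
                    outdir / "rsq_anova.tsv"))
    manifest.decisions["bonferroni"] = {
        "roi_glm_alpha": glm.attrs["bonferroni_alpha"],
        "roi_posthoc_alpha": posthoc.attrs["bonferroni_alpha"],
        "network_posthoc_alpha": lmm.posthoc.attrs["bonferroni_alpha"],
    }
    manifest.write(outdir / "manifest.json")
    return manifest
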