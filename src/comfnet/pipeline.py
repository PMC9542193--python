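"""End-to-end orchestration of the comfort-network analysis.

``run_full`` drives the whole chain on a simulated cohort: simulate →
preprocess → source → connect → network → metrics → stats, plus the
questionnaire psychometrics battery, and writes a run manifest recording
the configuration, per-output digests and every warning raised along the
way.  All randomness flows from one master seed, split per stage, so a
config + seed pair pins every output byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import instantaneous_phase, plv_matrix
from .metrics import global_auc, global_metrics_table, nodal_auc, nodal_metrics_table
from .network import build_ensemble, sparsity_levels
from .preprocessing import (
    BANDS,
    condition_recording,
    epoch_recording,
    extract_band,
    label_comfort,
    reject_artifacts,
)
from .questionnaire import efa_varimax, item_statistics, spearman_matrix
from .source_imaging import aggregate_rois, apply_inverse, build_sloreta_operator
from .stats import compare_global_aucs, identify_key_nodes
from .synthetic import generate_cohort, generate_questionnaire, generate_toy_leadfield, two_condition_cohorts

STAGES = ("simulate", "preprocess", "source", "connect", "network",
          "metrics", "stats", "psychometrics")


@dataclass(frozen=True)
class RunConfig:
    """Flat configuration for a full simulated run.

    Defaults follow the study conditions: 20 subjects, 64 channels,
    beta band, 10–38 % sparsity sweep in 4 % steps, raw-p key-node tests.
    """

    seed: int = 0
    # cohort simulation
    n_subjects: int = 20
    n_channels: int = 64
    n_sources: int = 190
    fs: float = 250.0
    epoch_length: float = 2.0
    n_epochs: int = 10
    coupling_comfortable: float = 0.2
    coupling_uncomfortable: float = 0.8
    n_active: int = 20
    noise_sd: float = 0.1
    # preprocessing
    reref: str = "average"
    bp_low: float = 0.01
    bp_high: float = 40.0
    notch: float = 50.0
    peak_to_peak_max: float = 1e6
    band: str = "beta"
    # source imaging
    inverse_alpha: float = 0.0
    # connectivity / networks
    edge_frac: float = 0.05
    sparsity_low: float = 0.10
    sparsity_high: float = 0.38
    sparsity_step: float = 0.04
    # metrics / stats
    surrogates: int = 0
    stat_alpha: float = 0.05
    correction: str = "none"
    # questionnaire
    questionnaire_rows: int = 200

    def __post_init__(self) -> None:
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}")
        if self.correction not in ("none", "fdr"):
            raise ValueError("correction must be 'none' or 'fdr'")
        if not 0 < self.stat_alpha < 1:
            raise ValueError("stat_alpha must lie in (0, 1)")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class RunResult:
    manifest: dict
    global_comparison: pd.DataFrame
    key_nodes: dict[str, pd.DataFrame]
    auc_tables: dict[str, pd.DataFrame]
    psychometrics: dict
    out_dir: Path


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seeds(master: int) -> dict[str, int]:
    seqs = np.random.SeedSequence(master).spawn(len(STAGES))
    return {s: int(q.generate_state(1)[0] % (2**31)) for s, q in zip(STAGES, seqs)}


def _subject_condition_pipeline(rec, cfg: RunConfig, operator, atlas):
    """Sensor recording -> band-limited ROI epochs -> PLV matrix."""
    conditioned = condition_recording(
        rec, reref=cfg.reref, fs_target=None,
        bp=(cfg.bp_low, cfg.bp_high), notch=cfg.notch,
    )
    epochs = epoch_recording(conditioned, cfg.epoch_length)
    epochs = reject_artifacts(epochs, cfg.peak_to_peak_max)
    epochs = extract_band(epochs, cfg.band)
    src = apply_inverse(epochs, operator)
    roi = aggregate_rois(src, atlas, fs=epochs.fs, band=cfg.band)
    phases = instantaneous_phase(roi, edge_frac=cfg.edge_frac)
    return plv_matrix(phases)


def run_full(config: RunConfig, out_dir: str | Path) -> RunResult:
    """Execute every stage on a simulated two-condition cohort."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    caught: list[str] = []

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        # --- simulate -----------------------------------------------------
        leadfield, atlas = generate_toy_leadfield(
            config.n_channels, config.n_sources, seed=seeds["simulate"]
        )
        band = BANDS[config.band]
        spec_comf, spec_uncomf = two_condition_cohorts(
            n_subjects=config.n_subjects,
            coupling_comfortable=config.coupling_comfortable,
            coupling_uncomfortable=config.coupling_uncomfortable,
            n_active=config.n_active,
            seed=seeds["simulate"],
            fs=config.fs, epoch_length=config.epoch_length,
            n_epochs=config.n_epochs, band=(band.low, band.high),
            noise_sd=config.noise_sd,
        )
        cohorts = {
            "comfortable": generate_cohort(spec_comf, leadfield, atlas),
            "uncomfortable": generate_cohort(spec_uncomf, leadfield, atlas),
        }
        # each simulated condition is one questionnaire window per subject;
        # the VAS ratings pin the group labels through the labelling rule
        labels = label_comfort({0: 30.0, 1: -30.0})
        condition_of_window = {0: "comfortable", 1: "uncomfortable"}
        assert all(labels[w] == condition_of_window[w] for w in labels)

        # --- preprocess ... connect --------------------------------------
        operator = build_sloreta_operator(leadfield, alpha=config.inverse_alpha)
        matrices = {
            cond: [
                _subject_condition_pipeline(subj.recording, config, operator, atlas)
                for subj in cohort
            ]
            for cond, cohort in cohorts.items()
        }

        # --- network + metrics -------------------------------------------
        grid = sparsity_levels(config.sparsity_low, config.sparsity_high,
                               config.sparsity_step)
        global_rows, nodal_deg, nodal_bc = {}, {}, {}
        for cond, cms in matrices.items():
            g_auc, d_auc, b_auc = [], [], []
            for cm in cms:
                ensemble = build_ensemble(cm, grid)
                gtab = global_metrics_table(
                    ensemble, n_surrogates=config.surrogates, seed=seeds["metrics"]
                )
                ntab = nodal_metrics_table(ensemble, atlas.codes)
                g_auc.append(global_auc(gtab))
                na = nodal_auc(ntab)
                d_auc.append(na["deg"].to_numpy())
                b_auc.append(na["bc"].to_numpy())
            global_rows[cond] = pd.DataFrame(g_auc)
            nodal_deg[cond] = np.vstack(d_auc)
            nodal_bc[cond] = np.vstack(b_auc)

        # --- stats ---------------------------------------------------------
        comparison = compare_global_aucs(
            global_rows["uncomfortable"], global_rows["comfortable"],
            alpha=config.stat_alpha,
        )
        key_nodes = {
            "deg": identify_key_nodes(
                nodal_deg["uncomfortable"], nodal_deg["comfortable"], atlas,
                alpha=config.stat_alpha, correction=config.correction,
            ),
            "bc": identify_key_nodes(
                nodal_bc["uncomfortable"], nodal_bc["comfortable"], atlas,
                alpha=config.stat_alpha, correction=config.correction,
            ),
        }
        caught.append(
            f"key-node tests used correction={config.correction!r} across 95 regions"
        )
        caught.append(
            "documented discrepancy: global efficiency is non-decreasing in "
            "sparse density here (adding edges cannot lengthen shortest paths); "
            "a decreasing GE-vs-density direction is not reproduced"
        )
        caught.append(
            "documented discrepancy: assortativity is not monotone in sparse "
            "density on PLV-derived networks; an increasing AC-vs-density "
            "direction is not reproduced"
        )

        # --- psychometrics -------------------------------------------------
        table = generate_questionnaire(config.questionnaire_rows,
                                       seed=seeds["psychometrics"])
        reliability = item_statistics(table)
        validity = efa_varimax(table, n_factors=2)
        rho, pmat, masked = spearman_matrix(table, mask_alpha=config.stat_alpha)
        psychometrics = {
            "alpha": reliability.alpha,
            "item_stats": reliability.items,
            "kmo": validity.kmo,
            "sphericity_p": validity.sphericity_p,
            "loadings": validity.loadings,
            "flagged_items": validity.flagged_items,
            "spearman_rho": rho,
            "spearman_masked": masked,
        }
        caught.extend(f"{w.category.__name__}: {w.message}" for w in wrec)

    # --- persist ----------------------------------------------------------
    outputs = {}
    float_fmt = "%.10g"
    for cond in matrices:
        path = out_dir / f"global_auc_{cond}.csv"
        global_rows[cond].to_csv(path, index=False, float_format=float_fmt)
        outputs[path.name] = _digest(path)
    path = out_dir / "global_comparison.csv"
    comparison.to_csv(path, index=False, float_format=float_fmt)
    outputs[path.name] = _digest(path)
    for name, tab in key_nodes.items():
        path = out_dir / f"key_nodes_{name}.csv"
        tab.to_csv(path, index=False, float_format=float_fmt)
        outputs[path.name] = _digest(path)
    path = out_dir / "questionnaire_loadings.csv"
    psychometrics["loadings"].to_csv(path, float_format=float_fmt)
    outputs[path.name] = _digest(path)
    path = out_dir / "spearman_masked.csv"
    psychometrics["spearman_masked"].to_csv(path, float_format=float_fmt)
    outputs[path.name] = _digest(path)

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stage_seeds": seeds,
        "outputs": outputs,
        "warnings": caught,
        "psychometrics": {
            "alpha": psychometrics["alpha"],
            "kmo": psychometrics["kmo"],
            "sphericity_p": psychometrics["sphericity_p"],
        },
    }
    manifest_path = out_dir / "manifest.json"
    tmp = manifest_path.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    tmp.replace(manifest_path)  # atomic publish

    auc_tables = {
        "comfortable": global_rows["comfortable"],
        "uncomfortable": global_rows["uncomfortable"],
    }
    return RunResult(
        manifest=manifest, global_comparison=comparison, key_nodes=key_nodes,
        auc_tables=auc_tables, psychometrics=psychometrics, out_dir=out_dir,
    )
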