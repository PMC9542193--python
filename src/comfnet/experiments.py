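"""Packaged validation studies.

Self-contained, seeded experiments that exercise the whole analysis on
generator output and summarize how it behaves: statistical power and
direction of the planted comfort contrast, type-I error of the key-node
screen, the independent-phase PLV null level, source-localization accuracy
on the toy lead field, and metric monotonicity across the sparsity sweep.
They are used by the test suite and the reproduction script alike.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .connectivity import plv_from_phases
from .metrics import global_auc, global_metrics_table, node_degree
from .network import build_ensemble, sparsity_levels
from .source_imaging import build_sloreta_operator
from .stats import identify_key_nodes, paired_ttest
from .synthetic import generate_cohort_phases, generate_toy_leadfield, two_condition_cohorts


def _cohort_global_aucs(spec) -> pd.DataFrame:
    """Per-subject AUC of the global metrics, from ground-truth phases."""
    rows = []
    grid = sparsity_levels()
    for phases in generate_cohort_phases(spec):
        table = global_metrics_table(build_ensemble(plv_from_phases(phases), grid))
        rows.append(global_auc(table))
    return pd.DataFrame(rows)


def power_study(
    n_replicates: int = 20, n_subjects: int = 20, seed: int = 0,
    metrics: tuple[str, ...] = ("cc", "ac", "ge"),
) -> pd.DataFrame:
    """Replicated planted-contrast cohorts: paired tests per global metric.

    Each replicate simulates a comfortable and an uncomfortable cohort
    (focal coupling 0.2 vs 0.8, diffuse coupling 0.05 vs 0.25), runs the
    connectivity → network → metric → AUC chain per subject, and records
    the paired t-test of the uncomfortable-minus-comfortable contrast.
    """
    base_seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    rows = []
    for rep, ss in enumerate(base_seeds):
        rep_seed = int(ss.generate_state(1)[0] % (2**31))
        spec_c, spec_u = two_condition_cohorts(n_subjects=n_subjects,
                                               seed=rep_seed)
        auc_c = _cohort_global_aucs(spec_c)
        auc_u = _cohort_global_aucs(spec_u)
        for metric in metrics:
            r = paired_ttest(auc_u[metric].to_numpy(), auc_c[metric].to_numpy(),
                             metric=metric)
            rows.append({
                "replicate": rep, "metric": metric,
                "mean_difference": r.mean_difference, "t": r.t, "p": r.p,
                "greater_and_significant": bool(r.p < 0.05 and
                                                r.mean_difference > 0),
            })
    return pd.DataFrame(rows)


def type1_key_node_study(
    n_cohorts: int = 500, n_subjects: int = 20, seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Per-region false-positive rate of the key-node screen under the null.

    Both conditions' per-subject nodal AUC vectors are drawn from one
    common distribution, so every detection is a false positive; the rate
    should match the nominal alpha.
    """
    from .atlas import load_aal95

    atlas = load_aal95()
    rng = np.random.default_rng(seed)
    detections = 0
    for _ in range(n_cohorts):
        a = rng.normal(size=(n_subjects, 95))
        b = rng.normal(size=(n_subjects, 95))
        detections += len(identify_key_nodes(a, b, atlas, alpha=alpha))
    return detections / (n_cohorts * 95)


def plv_null_mean(n_pairs: int = 10_000, n_samples: int = 100,
                  seed: int = 0) -> float:
    """Mean PLV of independent iid-uniform phase pairs (Rayleigh null)."""
    rng = np.random.default_rng(seed)
    phases = rng.uniform(-np.pi, np.pi, size=(n_pairs, 2, n_samples))
    return float(np.mean([plv_from_phases(p[None])[0, 1] for p in phases]))


def localization_error_rate(n_channels: int = 64, n_sources: int = 190,
                            seed: int = 0) -> float:
    """Fraction of sources mislocalized from their own noiseless forward
    data with the unregularized standardized inverse (expected: 0)."""
    import warnings

    lf, _ = generate_toy_leadfield(n_channels, n_sources, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        op = build_sloreta_operator(lf, alpha=0.0)
    h = np.eye(n_channels) - 1.0 / n_channels
    resolution = op.kernel @ h @ lf.gain
    scores = (resolution / op.standardization[:, None]) ** 2
    predicted = np.argmax(scores, axis=0)
    return float(np.mean(predicted != np.arange(n_sources)))


def monotonicity_study(n_subjects: int = 6, seed: int = 0) -> dict[str, float]:
    """Fractions of monotone metric-vs-density curves on generator PLV
    networks, for both simulated comfort conditions.

    Group-mean CC, per-subject GE and per-subject degree sums are expected
    to be non-decreasing in density; assortativity is reported for
    completeness (it is not monotone in general).
    """
    spec_c, spec_u = two_condition_cohorts(n_subjects=n_subjects, seed=seed)
    grid = sparsity_levels()
    out = {}
    frac_ge, frac_deg, frac_ac, n_curves = 0, 0, 0, 0
    cc_mean_mono = []
    for spec in (spec_c, spec_u):
        cc_curves = []
        for phases in generate_cohort_phases(spec):
            ensemble = build_ensemble(plv_from_phases(phases), grid)
            table = global_metrics_table(ensemble)
            degsum = [node_degree(net).sum() for net in ensemble]
            cc_curves.append(table["cc"].to_numpy())
            frac_ge += np.all(np.diff(table["ge"]) >= -1e-12)
            frac_deg += np.all(np.diff(degsum) >= 0)
            frac_ac += np.all(np.diff(table["ac"]) >= -1e-12)
            n_curves += 1
        cc_mean_mono.append(
            bool(np.all(np.diff(np.mean(cc_curves, axis=0)) >= -1e-12)))
    out["cc_group_mean_monotone_fraction"] = float(np.mean(cc_mean_mono))
    out["ge_monotone_fraction"] = frac_ge / n_curves
    out["deg_sum_monotone_fraction"] = frac_deg / n_curves
    out["ac_monotone_fraction"] = frac_ac / n_curves
    return out
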