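"""Paired group statistics: comfortable vs. uncomfortable networks.

Per global metric, a classical paired t-test compares the two conditions'
per-subject AUC values.  Per region, the same test applied to nodal AUCs
(degree, betweenness) identifies "key" brain nodes; by default the 95
regional tests are reported at raw p < α without multiple-comparison
correction, with a Benjamini-Hochberg FDR option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .atlas import ROIAtlas


@dataclass(frozen=True)
class PairedComparison:
    metric: str
    n_pairs: int
    mean_difference: float
    t: float
    df: int
    p: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def paired_ttest(
    a: np.ndarray, b: np.ndarray, metric: str = "", alpha: float = 0.05
) -> PairedComparison:
    """Two-tailed paired t-test on per-subject differences ``a − b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D arrays (paired)")
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):  # identical samples: no evidence of a difference
            t, p = 0.0, 1.0
        else:
            raise ValueError(
                "paired differences are a nonzero constant; t statistic undefined"
            )
    else:
        t = d.mean() / (sd / np.sqrt(n))
        p = 2.0 * sstats.t.sf(abs(t), df=n - 1)
    return PairedComparison(
        metric=metric, n_pairs=n, mean_difference=float(d.mean()),
        t=float(t), df=n - 1, p=float(p), alpha=alpha,
    )


def compare_global_aucs(
    auc_a: pd.DataFrame, auc_b: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Paired tests for every shared metric column.

    Inputs are subjects x metrics AUC tables for condition a and b,
    indexed by subject; subjects missing one condition are dropped.
    """
    common = auc_a.index.intersection(auc_b.index)
    if len(common) < len(auc_a) or len(common) < len(auc_b):
        import warnings
        warnings.warn(f"dropping subjects without both conditions "
                      f"({len(common)} retained)", stacklevel=2)
    rows = []
    for metric in [c for c in auc_a.columns if c in auc_b.columns]:
        cmp = paired_ttest(auc_a.loc[common, metric].to_numpy(),
                           auc_b.loc[common, metric].to_numpy(),
                           metric=metric, alpha=alpha)
        rows.append({
            "metric": metric, "n_pairs": cmp.n_pairs,
            "mean_difference": cmp.mean_difference, "t": cmp.t,
            "df": cmp.df, "p": cmp.p, "significant": cmp.significant,
        })
    return pd.DataFrame(rows)


def nodal_paired_tests(auc_a: np.ndarray, auc_b: np.ndarray) -> pd.DataFrame:
    """Vectorized per-region paired t-tests.

    ``auc_a`` and ``auc_b`` are subjects x regions arrays for the two
    conditions, paired by row.  Returns one row per region with t and p.
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("inputs must be equal-shape subjects x regions arrays")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    d = a - b
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = d.mean(axis=0) / (sd / np.sqrt(n))
    p = np.where(sd > 0, 2.0 * sstats.t.sf(np.abs(t), df=n - 1), np.nan)
    return pd.DataFrame({"t": t, "p": p, "df": n - 1})


def identify_key_nodes(
    nodal_auc_a: np.ndarray,
    nodal_auc_b: np.ndarray,
    atlas: ROIAtlas,
    alpha: float = 0.05,
    correction: str = "none",
) -> pd.DataFrame:
    """Regions whose nodal AUC differs between conditions at p < α.

    Returns a table styled after a key-node report: coarse lobe grouping,
    region name, numeric code and p-value, sorted by code.  ``correction``
    is ``"none"`` (raw p, the conventional choice for this design) or
    ``"fdr"`` (Benjamini-Hochberg across the 95 regions).
    """
    if correction not in ("none", "fdr"):
        raise ValueError("correction must be 'none' or 'fdr'")
    if alpha < 0 or alpha > 1:
        raise ValueError("alpha must lie in [0, 1]")
    tests = nodal_paired_tests(nodal_auc_a, nodal_auc_b)
    if len(tests) != len(atlas.codes):
        raise ValueError("one test per atlas region required")
    p = tests["p"].to_numpy()
    if correction == "fdr":
        from statsmodels.stats.multitest import multipletests
        ok = np.isfinite(p)
        reject = np.zeros(len(p), dtype=bool)
        if ok.any():
            reject[ok] = multipletests(p[ok], alpha=alpha, method="fdr_bh")[0]
    else:
        reject = np.isfinite(p) & (p < alpha)

    out = atlas.regions.loc[reject, ["lobe", "name", "code"]].copy()
    out["p"] = p[reject]
    return out.sort_values("code").reset_index(drop=True)
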