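"""Psychometrics of the 9-item ride-comfort questionnaire.

The instrument asks for overall comfort, emotional valence and arousal,
static (seat) comfort and five cabin-environment comforts (noise,
vibration, aural pressure, visual, thermal), each on a −50..50 visual-
analog scale.  This module provides the classical battery used to vet such
an instrument: Cronbach's alpha with corrected item-total correlations and
alpha-if-item-deleted, Kaiser-Meyer-Olkin sampling adequacy with Bartlett's
sphericity test, principal-component extraction with varimax rotation (the
0.5-loading validity rule), and the Spearman correlation matrix with
significance masking.

Rows of a questionnaire table are respondent-windows (each rating occasion
treated as an independent sample).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.multivariate.factor_rotation import rotate_factors

#: Fixed item order of the instrument.
QUESTION_ITEMS: tuple[str, ...] = (
    "Overall comfort",
    "Emotion value",
    "Emotion arousal",
    "Static comfort",
    "Noise comfort",
    "Vibration comfort",
    "Aural pressure comfort",
    "Visual comfort",
    "Thermal comfort",
)


def _as_matrix(tbl: pd.DataFrame, items=None) -> tuple[np.ndarray, list[str]]:
    if items is not None:
        tbl = tbl[list(items)]
    x = tbl.to_numpy(dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("table contains missing or non-finite values")
    return x, list(tbl.columns)


def cronbach_alpha(tbl: pd.DataFrame, items=None) -> float:
    """α = k/(k−1) · (1 − Σ item variances / total-score variance)."""
    x, cols = _as_matrix(tbl, items)
    k = x.shape[1]
    if k < 2:
        raise ValueError("need at least 2 items")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 rows")
    item_var = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total score has zero variance")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


@dataclass(frozen=True)
class ReliabilityReport:
    alpha: float
    items: pd.DataFrame  # columns: item_total_corrected, alpha_if_deleted


def item_statistics(tbl: pd.DataFrame) -> ReliabilityReport:
    """Overall alpha plus the two per-item reliability diagnostics.

    Corrected item-total correlation is the Pearson correlation of an item
    with the sum of the *other* items; alpha-if-deleted is Cronbach's alpha
    recomputed without the item.
    """
    x, cols = _as_matrix(tbl)
    alpha = cronbach_alpha(tbl)
    rows = {}
    for i, col in enumerate(cols):
        others = np.delete(np.arange(x.shape[1]), i)
        rest_sum = x[:, others].sum(axis=1)
        r = float(np.corrcoef(x[:, i], rest_sum)[0, 1])
        rows[col] = {
            "item_total_corrected": r,
            "alpha_if_deleted": cronbach_alpha(tbl, items=[cols[j] for j in others]),
        }
    return ReliabilityReport(alpha=alpha, items=pd.DataFrame.from_dict(rows, orient="index"))


def kmo_and_sphericity(tbl: pd.DataFrame) -> tuple[float, float, float]:
    """Kaiser-Meyer-Olkin adequacy and Bartlett's test of sphericity.

    KMO = ΣΣ r² / (ΣΣ r² + ΣΣ q²) over off-diagonal cells, where q are the
    anti-image partial correlations.  Bartlett's statistic is
    −(n−1−(2p+5)/6)·ln det(R) on χ² with p(p−1)/2 degrees of freedom.
    """
    x, cols = _as_matrix(tbl)
    n, p = x.shape
    r = np.corrcoef(x, rowvar=False)
    sign_det = np.linalg.slogdet(r)
    if sign_det[0] <= 0 or not np.isfinite(sign_det[1]):
        raise ValueError("singular correlation matrix; remove redundant items")
    try:
        inv = np.linalg.inv(r)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular correlation matrix; remove redundant items") from exc
    d = np.sqrt(np.diag(inv))
    partial = -inv / np.outer(d, d)
    off = ~np.eye(p, dtype=bool)
    r2 = np.sum(r[off] ** 2)
    q2 = np.sum(partial[off] ** 2)
    kmo = float(r2 / (r2 + q2))

    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * sign_det[1]
    df = p * (p - 1) // 2
    pval = float(sstats.chi2.sf(chi2, df))
    return kmo, float(chi2), pval


@dataclass(frozen=True)
class ValidityReport:
    kmo: float
    sphericity_chi2: float
    sphericity_p: float
    loadings: pd.DataFrame  # items x factors, varimax-rotated
    communalities: pd.Series
    #: fraction of total variance carried by each *extracted* component
    #: (eigenvalue / n_items, before rotation, descending)
    explained_variance_ratio: np.ndarray
    flagged_items: tuple[str, ...]  # max |loading| < 0.5


def efa_varimax(tbl: pd.DataFrame, n_factors: int = 2) -> ValidityReport:
    """Principal-component extraction + varimax rotation.

    Components are extracted from the correlation matrix (so items are
    implicitly standardized), the first ``n_factors`` are rotated with the
    varimax criterion, and every item whose maximal absolute rotated
    loading falls below 0.5 is flagged as failing the validity rule.
    Column signs are fixed so each factor's dominant loading is positive.
    """
    x, cols = _as_matrix(tbl)
    p = x.shape[1]
    if not 1 <= n_factors < p:
        raise ValueError("need 1 <= n_factors < number of items")
    r = np.corrcoef(x, rowvar=False)
    eigval, eigvec = np.linalg.eigh(r)
    order = np.argsort(eigval)[::-1][:n_factors]
    loadings = eigvec[:, order] * np.sqrt(np.maximum(eigval[order], 0.0))
    if n_factors > 1:
        loadings, _ = rotate_factors(loadings, "varimax")
    for j in range(loadings.shape[1]):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] = -loadings[:, j]
    # order displayed factors by post-rotation sum of squared loadings
    ssq = np.sum(loadings**2, axis=0)
    loadings = loadings[:, np.argsort(ssq)[::-1]]

    load_df = pd.DataFrame(
        loadings, index=cols,
        columns=[f"factor_{j + 1}" for j in range(n_factors)],
    )
    communalities = pd.Series(np.sum(loadings**2, axis=1), index=cols)
    max_abs = np.max(np.abs(loadings), axis=1)
    flagged = tuple(c for c, m in zip(cols, max_abs) if m < 0.5)
    kmo, chi2, pval = kmo_and_sphericity(tbl)
    return ValidityReport(
        kmo=kmo, sphericity_chi2=chi2, sphericity_p=pval,
        loadings=load_df, communalities=communalities,
        explained_variance_ratio=np.maximum(eigval[order], 0.0) / p,
        flagged_items=flagged,
    )


# ---------------------------------------------------------------------------
# Spearman correlations with p-masking
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4)
def _rank_permutations(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(1, n + 1))), dtype=float)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for small samples (n < 10)."""
    n = len(x)
    rx = sstats.rankdata(x)
    ry = sstats.rankdata(y)
    obs = np.corrcoef(rx, ry)[0, 1]
    perms = _rank_permutations(n)
    xc = rx - rx.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        rho = (pc @ xc) / (np.linalg.norm(pc, axis=1) * np.linalg.norm(xc))
    return float(np.mean(np.abs(rho) >= abs(obs) - 1e-12))


def spearman_matrix(
    tbl: pd.DataFrame, mask_alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho, p-values, and a significance-masked display.

    p-values use the t approximation, except for very small samples
    (n < 10) where the exact permutation distribution is enumerated.
    Cells with p > ``mask_alpha`` are blanked (NaN) in the display matrix;
    the diagonal is kept.
    """
    x, cols = _as_matrix(tbl)
    n, p = x.shape
    if n < 5:
        raise ValueError("need at least 5 rows")
    rho, pval = sstats.spearmanr(x)
    if p == 2:  # scipy returns scalars for two columns
        rho = np.array([[1.0, rho], [rho, 1.0]])
        pval = np.array([[0.0, pval], [pval, 0.0]])
    if n < 10:
        for i in range(p):
            for j in range(i + 1, p):
                pe = _spearman_exact_p(x[:, i], x[:, j])
                pval[i, j] = pval[j, i] = pe
    np.fill_diagonal(pval, 0.0)
    masked = np.where(pval <= mask_alpha, rho, np.nan)
    idx = pd.Index(cols)
    return (
        pd.DataFrame(rho, index=idx, columns=idx),
        pd.DataFrame(pval, index=idx, columns=idx),
        pd.DataFrame(masked, index=idx, columns=idx),
    )
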