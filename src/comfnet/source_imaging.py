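"""sLORETA-style electric-source imaging.

The inverse operator is the standardized weighted-minimum-norm solution:
with a (row-centred) lead field ``K`` the minimum-norm kernel is
``T = Kᵀ (K Kᵀ + α H)⁺`` where ``H = I − 11ᵀ/m`` is the average-reference
centering operator, and every source estimate is standardized by the square
root of its resolution-matrix diagonal ``s_l = sqrt([T K]_ll)``.  The
standardization gives the estimator its defining property: a noiseless
single point source is always localized exactly (zero localization error).

Standardized per-source series are averaged within atlas regions to yield
the 95 regional time courses that form the network nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .atlas import N_REGIONS, ROIAtlas
from .preprocessing import EpochSet
from .synthetic import LeadField

#: Assumed amplitude SNR for the default regularization heuristic.
DEFAULT_SNR = 3.0


@dataclass(frozen=True)
class InverseOperator:
    """Linear inverse kernel plus per-source standardization factors."""

    kernel: np.ndarray  # sources x channels
    standardization: np.ndarray  # sources,
    alpha: float
    channel_labels: tuple[str, ...]
    valid_sources: np.ndarray  # bool mask, sources,

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.kernel)):
            raise ValueError("inverse kernel must be finite")
        if np.any(self.standardization[self.valid_sources] <= 0):
            raise ValueError("standardization factors must be positive")

    @property
    def n_sources(self) -> int:
        return self.kernel.shape[0]


@dataclass(frozen=True)
class ROITimeSeriesEpochs:
    """Source-space epochs aggregated to atlas regions."""

    data: np.ndarray  # epochs x 95 x samples
    fs: float
    region_codes: np.ndarray
    band: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[1] != N_REGIONS:
            raise ValueError(f"data must be epochs x {N_REGIONS} x samples")
        if len(self.region_codes) != N_REGIONS:
            raise ValueError(f"exactly {N_REGIONS} region codes required")


def centering_operator(m: int) -> np.ndarray:
    return np.eye(m) - np.full((m, m), 1.0 / m)


def default_alpha(lf: LeadField, snr: float = DEFAULT_SNR) -> float:
    """Minimum-norm heuristic: alpha = trace(KKᵀ) / (channels · SNR²)."""
    h = centering_operator(lf.n_channels)
    k = h @ lf.gain
    return float(np.trace(k @ k.T) / (lf.n_channels * snr**2))


def build_sloreta_operator(lf: LeadField, alpha: float = 0.0) -> InverseOperator:
    """Build the standardized minimum-norm inverse operator.

    ``alpha`` is the Tikhonov regularization weight; ``alpha = 0`` uses the
    Moore-Penrose pseudo-inverse of the (rank-deficient, average-referenced)
    gram matrix.  Sources whose resolution diagonal vanishes are flagged
    invalid and their standardization left at 1.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    m = lf.n_channels
    h = centering_operator(m)
    k = h @ lf.gain
    gram = k @ k.T + alpha * h
    if alpha == 0.0 and np.linalg.matrix_rank(gram) < m:
        warnings.warn(
            "unregularized gram matrix is singular (average reference removes "
            "one dimension); using the pseudo-inverse", stacklevel=2,
        )
    kernel = k.T @ np.linalg.pinv(gram, hermitian=True)
    resolution_diag = np.einsum("lc,cl->l", kernel, k)
    valid = resolution_diag > 1e-12 * resolution_diag.max()
    standardization = np.ones(lf.n_sources)
    standardization[valid] = np.sqrt(resolution_diag[valid])
    return InverseOperator(
        kernel=kernel,
        standardization=standardization,
        alpha=float(alpha),
        channel_labels=tuple(lf.channel_labels),
        valid_sources=valid,
    )


def apply_inverse(ep: EpochSet, op: InverseOperator) -> np.ndarray:
    """Standardized per-sample source estimates: epochs x sources x samples.

    Channels are aligned to the operator by label; a permuted but matching
    channel set gives identical output, a different set is an error.
    """
    if set(ep.channel_labels) != set(op.channel_labels):
        raise ValueError("epoch channel set does not match the inverse operator")
    order = [ep.channel_labels.index(ch) for ch in op.channel_labels]
    data = ep.data[:, order, :]
    src = np.einsum("lc,ecs->els", op.kernel, data)
    return src / op.standardization[None, :, None]


def standardized_power(sensor_data: np.ndarray, op: InverseOperator) -> np.ndarray:
    """Mean squared standardized source amplitude for a channels x samples array."""
    est = (op.kernel @ sensor_data) / op.standardization[:, None]
    return np.mean(est**2, axis=1)


def localize(sensor_data: np.ndarray, op: InverseOperator) -> int:
    """Index of the source with maximal standardized power."""
    return int(np.argmax(standardized_power(sensor_data, op)))


def aggregate_rois(
    src_epochs: np.ndarray,
    atlas: ROIAtlas,
    fs: float,
    band: str | None = None,
    meta: dict | None = None,
) -> ROITimeSeriesEpochs:
    """Average member-source standardized series within each atlas region.

    Output region order is ascending atlas code, independent of how sources
    are laid out in the lead field.
    """
    n_sources = src_epochs.shape[1]
    if atlas.n_sources != n_sources:
        raise ValueError(
            f"atlas maps {atlas.n_sources} sources but data has {n_sources}"
        )
    agg = np.zeros((N_REGIONS, n_sources))
    for row, (code, idx) in enumerate(sorted(atlas.region_indices().items())):
        if idx.size == 0:
            raise ValueError(f"region {code} has no sources")
        agg[row, idx] = 1.0 / idx.size
    roi = np.tensordot(agg, src_epochs, axes=(1, 1)).transpose(1, 0, 2)
    return ROITimeSeriesEpochs(
        data=np.ascontiguousarray(roi), fs=fs,
        region_codes=atlas.codes.copy(), band=band, meta=meta or {},
    )
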