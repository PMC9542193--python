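"""Phase-locking-value (PLV) functional connectivity.

For two narrow-band signals with instantaneous phases φ_x(t), φ_y(t) the
phase-locking value is the magnitude of the time-averaged unit phasor of
their difference::

    PLV = (1/N) | Σ_n exp(j (φ_x(t_n) − φ_y(t_n))) |

with N the (interior) time samples of an epoch; epoch PLVs are averaged
across epochs (or, optionally, all epochs are concatenated before
averaging).  Phases come from the analytic signal, with a configurable
fraction of edge samples excluded to limit Hilbert-transform edge effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .source_imaging import ROITimeSeriesEpochs


@dataclass(frozen=True)
class PhaseSeries:
    """Instantaneous phases (radians, wrapped to (−π, π])."""

    phase: np.ndarray  # epochs x regions x samples
    fs: float
    region_codes: np.ndarray
    band: str | None = None
    edge_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.phase.ndim != 3:
            raise ValueError("phase must be epochs x regions x samples")
        if not 0 <= self.edge_frac < 0.5:
            raise ValueError("edge_frac must lie in [0, 0.5)")

    @property
    def interior(self) -> slice:
        n = self.phase.shape[2]
        cut = int(np.floor(self.edge_frac * n))
        return slice(cut, n - cut)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric PLV matrix with unit diagonal."""

    plv: np.ndarray
    region_codes: np.ndarray
    n_epochs_used: int
    band: str | None = None
    subject_id: int | None = None
    condition: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = self.plv
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("plv must be square")
        if not np.allclose(p, p.T, atol=1e-12):
            raise ValueError("plv must be symmetric")
        if not np.allclose(np.diag(p), 1.0, atol=1e-9):
            raise ValueError("plv diagonal must be 1")
        if p.min() < -1e-12 or p.max() > 1 + 1e-9:
            raise ValueError("plv entries must lie in [0, 1]")

    @property
    def n_regions(self) -> int:
        return self.plv.shape[0]


def instantaneous_phase(
    roi_epochs: ROITimeSeriesEpochs, edge_frac: float = 0.05
) -> PhaseSeries:
    """Analytic-signal phase of each (band-limited) regional series."""
    if roi_epochs.band is None:
        raise ValueError("input must carry a band tag (narrow-band assumption)")
    analytic = hilbert(roi_epochs.data, axis=-1)
    return PhaseSeries(
        phase=np.angle(analytic), fs=roi_epochs.fs,
        region_codes=roi_epochs.region_codes, band=roi_epochs.band,
        edge_frac=edge_frac,
    )


def plv_matrix(
    ph: PhaseSeries,
    concatenate: bool = False,
    subject_id: int | None = None,
    condition: str | None = None,
) -> ConnectivityMatrix:
    """All-pairs PLV over the interior samples of every epoch."""
    interior = ph.phase[:, :, ph.interior]
    n_epochs, n_regions, n = interior.shape
    if n_epochs < 1 or n_regions < 2:
        raise ValueError("need >= 1 epoch and >= 2 regions")
    if n < 2:
        raise ValueError("need >= 2 interior samples per epoch")
    plv = _plv_from_phase_array(interior, concatenate)
    return ConnectivityMatrix(
        plv=plv, region_codes=ph.region_codes, n_epochs_used=n_epochs,
        band=ph.band, subject_id=subject_id, condition=condition,
        meta={"concatenated": concatenate, "edge_frac": ph.edge_frac},
    )


def plv_from_phases(phase: np.ndarray, concatenate: bool = False) -> np.ndarray:
    """PLV matrix for a raw phase array (epochs x signals x samples or
    signals x samples).  Used on generator ground-truth phases."""
    if phase.ndim == 2:
        phase = phase[None]
    if phase.shape[-1] < 2:
        raise ValueError("need >= 2 samples")
    return _plv_from_phase_array(phase, concatenate)


def _plv_from_phase_array(phase: np.ndarray, concatenate: bool) -> np.ndarray:
    n_epochs, _, n = phase.shape
    z = np.exp(1j * phase)
    cross = np.einsum("eis,ejs->eij", z, z.conj())
    if concatenate:
        plv = np.abs(cross.sum(axis=0)) / (n * n_epochs)
    else:
        plv = np.mean(np.abs(cross) / n, axis=0)
    plv = np.clip((plv + plv.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(plv, 1.0)
    return plv
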