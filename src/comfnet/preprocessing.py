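"""Sensor-space EEG conditioning, epoching and band extraction.

The conditioning chain mirrors a typical cabin-EEG protocol: common-average
re-reference, resampling, zero-phase band-pass (0.01–40 Hz) and mains notch
(50 Hz), division into fixed-length epochs grouped into questionnaire
windows, amplitude-based artifact rejection, and wavelet-packet extraction
of the five canonical frequency bands.  Epoch groups are labelled
comfortable / uncomfortable from the visual-analog overall-comfort rating
of their window.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pywt
from scipy import signal


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"invalid band limits ({self.low}, {self.high})")


#: The five canonical EEG bands (Hz).
BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 1.0, 3.0),
    "theta": BandDefinition("theta", 4.0, 7.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 14.0, 30.0),
    "gamma": BandDefinition("gamma", 31.0, 64.0),
}


@dataclass(frozen=True)
class MultichannelRecording:
    """Continuous sensor-space EEG: ``data`` is channels x samples (µV)."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass(frozen=True)
class EpochSet:
    """Epoched data: ``data`` is epochs x channels x samples."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    window_id: np.ndarray
    band: str | None = None
    comfort_label: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x channels x samples")
        if len(self.window_id) != self.data.shape[0]:
            raise ValueError("one window_id per epoch required")
        if self.band is not None and self.band not in BANDS:
            raise ValueError(f"unknown band tag {self.band!r}")
        if self.comfort_label is not None and len(self.comfort_label) != self.data.shape[0]:
            raise ValueError("one comfort label per epoch required")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def select(self, mask: np.ndarray) -> "EpochSet":
        return replace(
            self,
            data=self.data[mask],
            window_id=self.window_id[mask],
            comfort_label=None if self.comfort_label is None else self.comfort_label[mask],
        )

    def with_comfort_labels(self, window_labels: dict[int, str]) -> "EpochSet":
        labels = np.array([window_labels.get(int(w), "excluded") for w in self.window_id])
        return replace(self, comfort_label=labels)


def condition_recording(
    rec: MultichannelRecording,
    reref: str = "average",
    fs_target: float | None = None,
    bp: tuple[float, float] | None = (0.01, 40.0),
    notch: float | None = 50.0,
) -> MultichannelRecording:
    """Re-reference, resample and zero-phase filter a recording.

    Re-referencing happens first, then resampling to ``fs_target``, then a
    4th-order Butterworth band-pass and an IIR mains notch, both applied
    forward-backward (``filtfilt``) so the chain introduces no group delay.
    """
    data = np.asarray(rec.data, dtype=float)
    if reref == "average":
        data = data - data.mean(axis=0, keepdims=True)
    elif reref not in (None, "none"):
        raise ValueError(f"unknown re-reference scheme {reref!r}")

    fs = rec.fs
    if fs_target is not None and fs_target != fs:
        frac = Fraction(fs_target / fs).limit_denominator(1000)
        data = signal.resample_poly(data, frac.numerator, frac.denominator, axis=1)
        fs = fs_target

    if bp is not None:
        low, high = bp
        if not 0 < low < high:
            raise ValueError("band-pass limits must satisfy 0 < low < high")
        if high >= fs / 2:
            raise ValueError(f"band-pass high {high} Hz >= Nyquist ({fs / 2} Hz)")
        sos = signal.butter(4, [low, high], btype="bandpass", output="sos", fs=fs)
        data = signal.sosfiltfilt(sos, data, axis=1)

    if notch is not None:
        if not 0 < notch < fs / 2:
            raise ValueError(f"notch {notch} Hz outside (0, Nyquist)")
        b, a = signal.iirnotch(notch, Q=30.0, fs=fs)
        data = signal.filtfilt(b, a, data, axis=1)

    meta = dict(rec.meta)
    meta["conditioning"] = {
        "reref": reref, "fs": fs, "bandpass": bp, "notch": notch,
    }
    return MultichannelRecording(data, fs, list(rec.channel_labels), meta)


def epoch_recording(
    rec: MultichannelRecording,
    epoch_length: float,
    window_length: float | None = None,
) -> EpochSet:
    """Cut a recording into non-overlapping epochs tagged by rating window.

    ``window_length`` is the interval between questionnaire administrations
    (default: the whole recording is one window) and must be a multiple of
    ``epoch_length``.  A trailing partial epoch is dropped.
    """
    n_per_epoch = epoch_length * rec.fs
    if abs(n_per_epoch - round(n_per_epoch)) > 1e-9:
        raise ValueError("epoch_length * fs must be an integer sample count")
    n_per_epoch = int(round(n_per_epoch))
    if window_length is None:
        epochs_per_window = rec.data.shape[1] // n_per_epoch + 1  # one window
    else:
        ratio = window_length / epoch_length
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("window_length must be a multiple of epoch_length")
        epochs_per_window = int(round(ratio))

    n_epochs = rec.data.shape[1] // n_per_epoch
    if n_epochs == 0:
        raise ValueError("recording shorter than one epoch")
    data = rec.data[:, : n_epochs * n_per_epoch]
    data = data.reshape(rec.n_channels, n_epochs, n_per_epoch).transpose(1, 0, 2)
    window_id = np.arange(n_epochs) // epochs_per_window
    return EpochSet(
        data=np.ascontiguousarray(data), fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        window_id=window_id, meta=dict(rec.meta),
    )


def reject_artifacts(ep: EpochSet, peak_to_peak_max: float = 100.0) -> EpochSet:
    """Drop epochs whose any-channel peak-to-peak amplitude exceeds the cap."""
    if peak_to_peak_max <= 0:
        raise ValueError("peak_to_peak_max must be positive")
    ptp = ep.data.max(axis=2) - ep.data.min(axis=2)  # epochs x channels
    keep = np.all(ptp <= peak_to_peak_max, axis=1)
    out = ep.select(keep)
    meta = dict(out.meta)
    meta["artifact_rejection"] = {
        "peak_to_peak_max": peak_to_peak_max,
        "n_in": int(ep.n_epochs),
        "n_rejected": int(ep.n_epochs - out.n_epochs),
    }
    return replace(out, meta=meta)


def default_wpt_level(fs: float, min_band_width: float = 2.0) -> int:
    """Smallest decomposition level whose terminal bandwidth fits the
    narrowest band (delta, 2 Hz wide, by default)."""
    level = 1
    while fs / 2 ** (level + 1) > min_band_width:
        level += 1
    return level


def extract_band(
    ep: EpochSet,
    band: BandDefinition | str,
    wavelet: str = "db8",
    level: int | None = None,
) -> EpochSet:
    """Wavelet-packet band extraction.

    The signal is decomposed to ``level`` with the given wavelet and
    reconstructed from only those terminal nodes whose nominal frequency
    support ``[k, k+1) * fs / 2**(level+1)`` intersects the band.

    Default wavelet is Daubechies-8: at the decomposition depth needed to
    resolve the 2 Hz-wide delta band its transition bands are sharp enough
    to keep >= 90% of in-band tone energy, which shorter wavelets are not.
    """
    if isinstance(band, str):
        band = BANDS[band]
    if level is None:
        level = default_wpt_level(ep.fs)
    node_bw = ep.fs / 2 ** (level + 1)
    if node_bw > band.high - band.low:
        raise ValueError(
            f"terminal bandwidth {node_bw:.2f} Hz exceeds band width; increase level"
        )
    applied_bp = ep.meta.get("conditioning", {}).get("bandpass")
    if applied_bp is not None and band.high > applied_bp[1]:
        warnings.warn(
            f"band {band.name} ({band.low}-{band.high} Hz) extends above the "
            f"acquisition low-pass at {applied_bp[1]} Hz; upper part of the band "
            "carries no signal",
            stacklevel=2,
        )

    wp = pywt.WaveletPacket(ep.data, wavelet=wavelet, mode="symmetric",
                            maxlevel=level, axis=-1)
    nodes = wp.get_level(level, order="freq")
    for k, node in enumerate(nodes):
        node_low, node_high = k * node_bw, (k + 1) * node_bw
        if not (node_high > band.low and node_low < band.high):
            node.data = np.zeros_like(node.data)
    recon = wp.reconstruct(update=False)[..., : ep.data.shape[-1]]
    return replace(ep, data=np.ascontiguousarray(recon), band=band.name)


def label_comfort(
    window_ratings: dict[int, float], neutral_band: float = 0.0
) -> dict[int, str]:
    """Map per-window VAS overall-comfort ratings to group labels.

    Ratings above ``+neutral_band`` are comfortable, below ``−neutral_band``
    uncomfortable; the neutral strip in between is excluded from the
    group contrast.
    """
    if neutral_band < 0:
        raise ValueError("neutral_band must be >= 0")
    labels = {}
    for wid, score in window_ratings.items():
        if not -50.0 <= score <= 50.0:
            raise ValueError(f"VAS rating {score} outside [-50, 50]")
        if score > neutral_band:
            labels[int(wid)] = "comfortable"
        elif score < -neutral_band:
            labels[int(wid)] = "uncomfortable"
        else:
            labels[int(wid)] = "excluded"
    return labels


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_recording(rec: MultichannelRecording, prefix: str | Path) -> None:
    """Persist as a tab-delimited channels x samples matrix + JSON sidecar."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".tsv"), rec.data, delimiter="\t")
    sidecar = {"fs": rec.fs, "channel_labels": list(rec.channel_labels),
               "meta": _jsonable(rec.meta)}
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(prefix: str | Path) -> MultichannelRecording:
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    data = np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t", ndmin=2)
    return MultichannelRecording(
        data=data, fs=float(sidecar["fs"]),
        channel_labels=list(sidecar["channel_labels"]),
        meta=sidecar.get("meta", {}),
    )


def read_brainvision(vhdr_path: str | Path) -> MultichannelRecording:
    """Load a BrainVision triplet (.vhdr/.vmrk/.eeg) via MNE."""
    import mne  # heavyweight; imported only when needed

    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True, verbose="error")
    return MultichannelRecording(
        data=raw.get_data() * 1e6,  # volts -> microvolts
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        meta={"source": str(vhdr_path)},
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
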