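"""Synthetic inputs for the comfort-network pipeline.

Real cabin recordings from ride-comfort experiments are rarely released, so
every input the pipeline consumes can be simulated here:

* **EEG cohorts** — band-limited regional oscillators with a controllable
  phase-coupling level among an "active" region set, projected to the
  sensors through a linear lead field with additive Gaussian noise.  The
  coupling knob creates a ground-truth connectivity difference between two
  simulated comfort states.
* **Toy lead fields** — random full-row-rank gain matrices whose sources
  are partitioned near-evenly over the packaged 95-region atlas.
* **Questionnaire tables** — linear factor-model responses on the −50..50
  visual-analog scale, with a two-factor (environmental vs. affective)
  default structure.
* **Reference graphs** — small weighted graphs with known metric values,
  used as oracles for the network-metric routines.

All generators are seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd

from .atlas import N_REGIONS, ROIAtlas, load_aal95
from .preprocessing import MultichannelRecording
from .questionnaire import QUESTION_ITEMS

#: Wiener phase-increment standard deviation (radians per sample).  Large
#: enough that independent regional phases decorrelate within a 2 s epoch,
#: small enough that each oscillator stays narrow-band around the carrier.
DEFAULT_PHASE_STEP_SD = 0.1


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated EEG cohort (one comfort condition)."""

    n_subjects: int
    fs: float = 250.0
    n_regions: int = N_REGIONS
    epoch_length: float = 2.0
    n_epochs: int = 10
    band: tuple[float, float] = (14.0, 30.0)
    coupling_within: float = 0.5
    coupling_global: float = 0.0
    active_regions: tuple[int, ...] = ()
    noise_sd: float = 0.1
    amplitude: float = 1.0
    phase_step_sd: float = DEFAULT_PHASE_STEP_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0.0 <= self.coupling_within <= 1.0:
            raise ValueError("coupling_within must lie in [0, 1]")
        if not 0.0 <= self.coupling_global <= 1.0:
            raise ValueError("coupling_global must lie in [0, 1]")
        low, high = self.band
        if not 0.0 < low < high:
            raise ValueError("band must satisfy 0 < low < high")
        if high >= self.fs / 2.0:
            raise ValueError(
                f"band {self.band} outside Nyquist range for fs={self.fs} Hz "
                f"(high must be < {self.fs / 2:.1f} Hz)"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        bad = [r for r in self.active_regions if not 0 <= r < self.n_regions]
        if bad:
            raise ValueError(f"active_regions indices out of range: {bad}")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_length * self.fs)) * self.n_epochs


@dataclass(frozen=True)
class LeadField:
    """Linear forward model: ``sensors = gain @ sources``."""

    gain: np.ndarray  # channels x sources
    channel_labels: tuple[str, ...]
    source_positions: np.ndarray  # sources x 3

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("lead-field gain must be finite")
        if self.gain.shape[0] != len(self.channel_labels):
            raise ValueError("channel_labels length must match gain rows")
        col_norms = np.linalg.norm(self.gain, axis=0)
        if np.any(col_norms == 0):
            raise ValueError("lead field has an all-zero column (invisible source)")

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


@dataclass(frozen=True)
class SubjectRecording:
    """Sensor-space recording plus the ground-truth regional phases."""

    subject_id: int
    recording: MultichannelRecording
    region_phase: np.ndarray  # regions x samples, radians (unwrapped)


def generate_toy_leadfield(
    n_channels: int, n_sources: int, seed: int
) -> tuple[LeadField, ROIAtlas]:
    """Random unit-column-norm gain matrix + near-even atlas partition.

    Sources are assigned to the 95 packaged region codes in contiguous
    blocks of size ``n_sources // 95`` (+1 for the first remainder blocks).
    """
    if n_sources < N_REGIONS:
        raise ValueError(f"need at least {N_REGIONS} sources to cover the atlas")
    if n_channels < 8:
        raise ValueError("need at least 8 channels")
    rng = np.random.default_rng(seed)
    gain = rng.standard_normal((n_channels, n_sources))
    # Gaussian matrices are full row rank almost surely; guard regardless.
    while np.linalg.matrix_rank(gain) < min(n_channels, n_sources):  # pragma: no cover
        gain = rng.standard_normal((n_channels, n_sources))
    gain /= np.linalg.norm(gain, axis=0, keepdims=True)
    positions = rng.uniform(-1.0, 1.0, size=(n_sources, 3))
    labels = tuple(f"E{i + 1:03d}" for i in range(n_channels))
    lf = LeadField(gain=gain, channel_labels=labels, source_positions=positions)

    atlas = load_aal95()
    base, rem = divmod(n_sources, N_REGIONS)
    counts = np.full(N_REGIONS, base, dtype=int)
    counts[:rem] += 1
    source_to_region = np.repeat(atlas.codes, counts)
    return lf, atlas.with_sources(source_to_region)


def _region_phases(
    spec: CohortSpec, rng: np.random.Generator
) -> np.ndarray:
    """Unwrapped phase offsets for every region (regions x samples).

    Two shared Wiener processes shape the coupling: a *global* one mixed
    into every region in proportion ``coupling_global`` (diffuse cortical
    synchronization) and an *active-set* one mixed into the designated
    regions in proportion ``coupling_within`` (focal hyper-coupling)::

        base_i  = (1 − c_g)·W_i + c_g·W_global
        phase_i = (1 − c_w)·base_i + c_w·W_active     (active regions)
    """
    n = spec.n_samples
    steps = rng.normal(0.0, spec.phase_step_sd, size=(spec.n_regions + 2, n))
    walks = np.cumsum(steps, axis=1)
    shared_active, shared_global, independent = walks[0], walks[1], walks[2:]
    phase = (1.0 - spec.coupling_global) * independent \
        + spec.coupling_global * shared_global
    if spec.active_regions:
        idx = np.asarray(spec.active_regions, dtype=int)
        c = spec.coupling_within
        phase[idx] = (1.0 - c) * phase[idx] + c * shared_active
    return phase


def generate_cohort(
    spec: CohortSpec, leadfield: LeadField, atlas: ROIAtlas
) -> list[SubjectRecording]:
    """Simulate one cohort: per-subject sensor EEG + ground-truth phases.

    Each region oscillates at the band-centre frequency with a Wiener phase
    offset; regions in ``spec.active_regions`` share a common phase process
    in proportion ``coupling_within``.  Every source of a region carries the
    region signal; sensor data are ``gain @ sources`` plus white noise.
    """
    if leadfield.n_sources != atlas.n_sources:
        raise ValueError(
            f"lead field has {leadfield.n_sources} sources but atlas maps "
            f"{atlas.n_sources}"
        )
    if spec.n_regions != len(atlas.codes):
        raise ValueError("spec.n_regions must match the atlas region count")

    f_c = 0.5 * (spec.band[0] + spec.band[1])
    t = np.arange(spec.n_samples) / spec.fs
    carrier = 2.0 * np.pi * f_c * t

    region_of_source = np.searchsorted(atlas.codes, atlas.source_to_region)
    subject_seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_subjects)
    cohort = []
    for sid, ss in enumerate(subject_seeds):
        rng = np.random.default_rng(ss)
        phase = _region_phases(spec, rng)
        region_signal = spec.amplitude * np.sin(carrier[None, :] + phase)
        source_signal = region_signal[region_of_source]
        sensors = leadfield.gain @ source_signal
        if spec.noise_sd > 0:
            sensors = sensors + rng.normal(0.0, spec.noise_sd, size=sensors.shape)
        rec = MultichannelRecording(
            data=sensors,
            fs=spec.fs,
            channel_labels=list(leadfield.channel_labels),
            meta={"subject_id": sid, "simulated": True,
                  "coupling_within": spec.coupling_within},
        )
        cohort.append(SubjectRecording(sid, rec, carrier[None, :] + phase))
    return cohort


def generate_cohort_phases(spec: CohortSpec) -> list[np.ndarray]:
    """Ground-truth regional phases only (no sensor projection).

    Returns, per subject, an epochs x regions x samples array of total
    phases (carrier + offset) — exactly the phases a subject from
    :func:`generate_cohort` carries, cut into the spec's epochs.  Useful
    when a study design needs many cohort replicates and the sensor →
    inverse round trip is not under test.
    """
    f_c = 0.5 * (spec.band[0] + spec.band[1])
    t = np.arange(spec.n_samples) / spec.fs
    carrier = 2.0 * np.pi * f_c * t
    n_per_epoch = int(round(spec.epoch_length * spec.fs))
    out = []
    for ss in np.random.SeedSequence(spec.seed).spawn(spec.n_subjects):
        rng = np.random.default_rng(ss)
        phase = carrier[None, :] + _region_phases(spec, rng)
        out.append(
            phase.reshape(spec.n_regions, spec.n_epochs, n_per_epoch)
            .transpose(1, 0, 2)
        )
    return out


# ---------------------------------------------------------------------------
# Questionnaire generator
# ---------------------------------------------------------------------------

def comfort_survey_loadings() -> pd.DataFrame:
    """Default 9-item x 2-factor loading matrix.

    Factor ``environmental`` groups the cabin-environment items (noise,
    aural pressure, thermal, vibration, visual); factor ``affective``
    groups overall comfort, static comfort and the two emotion items.
    Cross-loadings are chosen so the implied correlations of the overall-
    comfort item rank: static > valence > arousal > aural > vibration >
    noise, with visual and thermal near zero.
    """
    rows = {
        "Overall comfort":        (0.20, 0.880),
        "Emotion value":          (0.05, 0.875),
        "Emotion arousal":        (0.05, 0.550),
        "Static comfort":         (0.10, 0.886),
        "Noise comfort":          (0.75, 0.227),
        "Vibration comfort":      (0.68, 0.289),
        "Aural pressure comfort": (0.72, 0.302),
        "Visual comfort":         (0.60, -0.080),
        "Thermal comfort":        (0.70, -0.125),
    }
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["environmental", "affective"]
    )
    return df.loc[list(QUESTION_ITEMS)]


def generate_questionnaire(
    n_rows: int,
    structure: pd.DataFrame | np.ndarray | None = None,
    noise_sd: float | np.ndarray | None = None,
    seed: int = 0,
    vas_scale: float = 20.0,
) -> pd.DataFrame:
    """Factor-model questionnaire responses on the −50..50 VAS scale.

    ``item = loadings @ factors + noise``, affinely scaled by ``vas_scale``
    and clipped to [−50, 50].  With ``noise_sd=None`` each item's unique
    variance is set to ``1 − communality`` so the population correlation
    matrix is exactly ``Λ Λᵀ`` off the diagonal.
    """
    if n_rows < 10:
        raise ValueError("n_rows must be >= 10")
    if structure is None:
        structure = comfort_survey_loadings()
    if isinstance(structure, pd.DataFrame):
        loadings = structure.to_numpy(dtype=float)
        items = list(structure.index)
    else:
        loadings = np.asarray(structure, dtype=float)
        items = list(QUESTION_ITEMS[: loadings.shape[0]])
    if not np.all(np.isfinite(loadings)):
        raise ValueError("loadings must be finite")
    n_items, n_factors = loadings.shape

    communality = np.sum(loadings**2, axis=1)
    if noise_sd is None:
        if np.any(communality > 1.0):
            raise ValueError("communalities exceed 1; pass noise_sd explicitly")
        unique_sd = np.sqrt(1.0 - communality)
    else:
        unique_sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), (n_items,))
        if np.any(unique_sd < 0):
            raise ValueError("noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    factors = rng.standard_normal((n_rows, n_factors))
    noise = rng.standard_normal((n_rows, n_items)) * unique_sd
    latent = factors @ loadings.T + noise
    values = np.clip(vas_scale * latent, -50.0, 50.0)
    return pd.DataFrame(values, columns=items)


# ---------------------------------------------------------------------------
# Reference graphs for metric oracles
# ---------------------------------------------------------------------------

def reference_graph(
    kind: str, n: int, param: float | tuple | None = None, seed: int = 0
) -> np.ndarray:
    """Small weighted graphs with known structure (symmetric, zero diag).

    Kinds: ``complete``, ``path``, ``star``, ``ring_lattice`` (param: even
    neighbour count k), ``er_random`` (param: edge probability p; random
    weights in (0.25, 1]), ``watts_strogatz`` (param: (k, p)).
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    rng = np.random.default_rng(seed)
    if kind == "complete":
        g = nx.complete_graph(n)
    elif kind == "path":
        g = nx.path_graph(n)
    elif kind == "star":
        g = nx.star_graph(n - 1)
    elif kind == "ring_lattice":
        k = int(param) if param is not None else 2
        g = nx.watts_strogatz_graph(n, k, 0.0)
    elif kind == "er_random":
        p = float(param) if param is not None else 0.2
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    elif kind == "watts_strogatz":
        if param is None:
            k = min(10, n - 2) - (min(10, n - 2) % 2)  # even, < n
            param = (k, 0.1)
        k, p = param
        g = nx.watts_strogatz_graph(n, int(k), float(p),
                                    seed=int(rng.integers(2**31)))
    else:
        raise ValueError(f"unknown reference graph kind: {kind!r}")

    adj = np.zeros((n, n))
    for i, j in g.edges():
        w = 1.0 if kind != "er_random" else float(rng.uniform(0.25, 1.0))
        adj[i, j] = adj[j, i] = w
    return adj


def two_condition_cohorts(
    n_subjects: int = 20,
    coupling_comfortable: float = 0.2,
    coupling_uncomfortable: float = 0.8,
    global_comfortable: float = 0.05,
    global_uncomfortable: float = 0.25,
    n_active: int = 20,
    seed: int = 0,
    **spec_kwargs,
) -> tuple[CohortSpec, CohortSpec]:
    """Paired cohort specs for the two comfort states.

    The "uncomfortable" condition carries stronger phase coupling within
    the same active-region set (focal hyper-coupling of an emotion/
    perception circuit) *and* a stronger diffuse global component,
    mirroring the reported broad increase in inter-regional
    synchronisation under discomfort.
    """
    rng = np.random.default_rng(seed)
    active = tuple(sorted(rng.choice(N_REGIONS, size=n_active, replace=False).tolist()))
    root = np.random.SeedSequence(seed)
    s_comf, s_uncomf = (int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(2))
    comfortable = CohortSpec(
        n_subjects=n_subjects, coupling_within=coupling_comfortable,
        coupling_global=global_comfortable,
        active_regions=active, seed=s_comf, **spec_kwargs,
    )
    uncomfortable = replace(
        comfortable, coupling_within=coupling_uncomfortable,
        coupling_global=global_uncomfortable, seed=s_uncomf,
    )
    return comfortable, uncomfortable
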