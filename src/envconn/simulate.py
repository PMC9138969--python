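"""Synthetic EEG and keypress data with known ground truth.

The signal model follows the generative assumptions of envelope-coupled
band-limited cortical activity: each source is a sum over carrier bands of a
narrowband carrier (band-limited white noise) modulated by a slowly varying
lognormal amplitude envelope.  Coupling between two sources in a band is a
prescribed Pearson correlation between their latent log-envelope Gaussian
processes; because every downstream measure correlates *log* power
envelopes, the latent correlation equals the target on that scale and needs
no further calibration.

Keypress logs for the bimanual six-element finger-tapping task follow an
exponential learning curve on the block-mean inter-key interval with a
per-press substitution-error process.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import butter, sosfiltfilt

from .behavior import TARGET_SEQUENCE, KeypressLog
from .inverse import LeadfieldModel
from .recording import SensorRecording
from .rois import HEAD_CENTER_MNI

#: Canonical frequency bands (Hz, half-open [lo, hi)).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 80.0),
}

ENVELOPE_CUTOFF_HZ = 0.5     # low-pass bandwidth of the latent log envelopes
ENVELOPE_GEN_RATE_HZ = 8.0   # internal sampling rate of envelope generation
LOG_ENVELOPE_SD = 0.5        # sd of the latent log-amplitude process


@dataclass
class CouplingSpec:
    """Target log-envelope correlation for one source pair in one band."""

    pair: tuple[int, int]
    band: str
    rho: float


@dataclass
class ArtifactSpec:
    """Amplitudes (uV RMS at the most affected channel) of the two artifacts."""

    ocular_amplitude: float = 0.0
    muscle_amplitude: float = 0.0
    ocular_band: tuple[float, float] = (0.3, 5.0)
    muscle_band: tuple[float, float] = (30.0, 80.0)


@dataclass
class SimulationConfig:
    """Ground-truth simulation parameters for one sensor-space recording."""

    n_sources: int
    source_positions_mni: np.ndarray        # (n_sources, 3) mm
    coupling_specs: list[CouplingSpec] = field(default_factory=list)
    carrier_bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(BANDS)
    )
    duration: float = 300.0                 # s
    rate: float = 250.0                     # Hz
    source_moment_nAm: float = 20.0
    sensor_noise_sigma: float = 1.0         # uV
    artifact_spec: ArtifactSpec = field(default_factory=ArtifactSpec)
    bad_channel_spec: list[tuple[int, str]] = field(default_factory=list)
    seed: int = 0
    #: Seed for the fixed source orientations.  Orientations model anatomy,
    #: so recordings of the same subject should share this value while
    #: ``seed`` varies per session.
    orientation_seed: int | None = None

    def __post_init__(self) -> None:
        self.source_positions_mni = np.atleast_2d(
            np.asarray(self.source_positions_mni, float)
        )
        if self.source_positions_mni.shape != (self.n_sources, 3):
            raise ValueError("source_positions_mni must be (n_sources, 3)")
        n_samp = self.duration * self.rate
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("duration x rate must be an integer sample count")
        for name, (lo, hi) in self.carrier_bands.items():
            if not (1.0 <= lo < hi <= 80.0):
                raise ValueError(f"band {name!r} must lie within 1-80 Hz")
        for spec in self.coupling_specs:
            i, j = spec.pair
            if not (0 <= i < self.n_sources and 0 <= j < self.n_sources) or i == j:
                raise ValueError(f"inconsistent pair indices {spec.pair}")
            if not (0.0 <= spec.rho < 1.0):
                raise ValueError(f"rho must be in [0, 1), got {spec.rho}")
            if spec.band not in self.carrier_bands:
                raise ValueError(f"unknown band label {spec.band!r}")
        for ch, mode in self.bad_channel_spec:
            if mode not in ("flat", "noisy"):
                raise ValueError(f"bad-channel mode must be flat|noisy, got {mode!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.rate))

    @property
    def source_positions_head(self) -> np.ndarray:
        return self.source_positions_mni - HEAD_CENTER_MNI


@dataclass
class GroundTruth:
    """What the generator actually planted, for downstream oracles."""

    envelope_corr: dict[str, np.ndarray]        # band -> (n_src, n_src), unit diag
    log_power_envelopes: dict[str, np.ndarray]  # band -> (n_src, n_samples)
    mixing: np.ndarray | None = None            # (n_sensors, n_sources)
    artifact_timecourses: dict[str, np.ndarray] = field(default_factory=dict)
    artifact_topographies: dict[str, np.ndarray] = field(default_factory=dict)
    bad_channels: list[tuple[int, str]] = field(default_factory=list)


def _target_corr_matrix(config: SimulationConfig, band: str) -> np.ndarray:
    C = np.eye(config.n_sources)
    for spec in config.coupling_specs:
        if spec.band == band:
            i, j = spec.pair
            C[i, j] = C[j, i] = spec.rho
    return C


def _correlated_log_envelopes(
    C: np.ndarray, n_samples: int, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Latent log-amplitude processes with instantaneous correlation C."""
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as err:
        raise ValueError("coupling correlation matrix is not positive definite") from err
    n_env = max(int(np.ceil(n_samples / rate * ENVELOPE_GEN_RATE_HZ)) + 8, 16)
    z = rng.standard_normal((C.shape[0], n_env))
    # identical low-pass on jointly white inputs preserves the correlations
    sos = butter(4, ENVELOPE_CUTOFF_HZ, fs=ENVELOPE_GEN_RATE_HZ, output="sos")
    g = sosfiltfilt(sos, L @ z, axis=1)
    g = g - g.mean(axis=1, keepdims=True)
    g = g / g.std(axis=1, keepdims=True) * LOG_ENVELOPE_SD
    t_env = np.arange(n_env) / ENVELOPE_GEN_RATE_HZ
    t = np.arange(n_samples) / rate
    return CubicSpline(t_env, g, axis=1)(t)


def _bandlimited_noise(
    band: tuple[float, float],
    n_samples: int,
    rate: float,
    rng: np.random.Generator,
    taper_hz: float = 1.0,
) -> np.ndarray:
    """Unit-variance band-pass white noise via frequency-domain shaping."""
    spec = np.fft.rfft(rng.standard_normal(n_samples))
    f = np.fft.rfftfreq(n_samples, 1.0 / rate)
    lo, hi = band
    mask = np.ones_like(f)
    mask[f < lo - taper_hz] = 0.0
    mask[f > hi + taper_hz] = 0.0
    rise = (f >= lo - taper_hz) & (f < lo)
    fall = (f > hi) & (f <= hi + taper_hz)
    mask[rise] = 0.5 * (1 - np.cos(np.pi * (f[rise] - lo + taper_hz) / taper_hz))
    mask[fall] = 0.5 * (1 + np.cos(np.pi * (f[fall] - hi) / taper_hz))
    x = np.fft.irfft(spec * mask, n_samples)
    return x / x.std()


def _blink_train(
    n_samples: int, rate: float, rng: np.random.Generator,
    mean_interval_s: float = 4.0, width_s: float = 0.25,
) -> np.ndarray:
    """Episodic positive blink pulses (raised cosine), unit RMS.

    Blinks are strongly non-Gaussian, which is what makes them separable by
    ICA; their spectrum falls in the canonical 0.3-5 Hz ocular range.
    """
    x = np.zeros(n_samples)
    w = int(width_s * rate)
    pulse = 0.5 * (1 - np.cos(2 * np.pi * np.arange(w) / w))
    t = int(rate * rng.exponential(mean_interval_s))
    while t + w < n_samples:
        x[t: t + w] += pulse * rng.uniform(0.7, 1.3)
        t += int(rate * max(rng.exponential(mean_interval_s), 0.5))
    if x.std() == 0:  # recording shorter than one blink interval
        x[: min(w, n_samples)] = pulse[: min(w, n_samples)]
    return x / x.std()


def _burst_noise(
    band: tuple[float, float], n_samples: int, rate: float,
    rng: np.random.Generator, burst_sigma: float = 1.0,
) -> np.ndarray:
    """Burst-modulated band-pass noise (kurtotic), unit RMS: EMG-like."""
    carrier = _bandlimited_noise(band, n_samples, rate, rng)
    n_env = max(int(np.ceil(n_samples / rate * ENVELOPE_GEN_RATE_HZ)) + 8, 16)
    sos = butter(4, ENVELOPE_CUTOFF_HZ, fs=ENVELOPE_GEN_RATE_HZ, output="sos")
    g = sosfiltfilt(sos, rng.standard_normal(n_env))
    g = (g - g.mean()) / g.std() * burst_sigma
    t_env = np.arange(n_env) / ENVELOPE_GEN_RATE_HZ
    t = np.arange(n_samples) / rate
    x = np.exp(CubicSpline(t_env, g)(t)) * carrier
    return x / x.std()


def simulate_coupled_sources(
    config: SimulationConfig,
) -> tuple[np.ndarray, GroundTruth]:
    """Generate source time courses with planted envelope coupling.

    Returns an (n_sources, n_samples) array (unit-scale waveforms; the dipole
    moment is applied at projection time) and the ground truth holding the
    per-band target correlation matrices and latent log-power envelopes.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sources = np.zeros((config.n_sources, n))
    env_corr: dict[str, np.ndarray] = {}
    log_envs: dict[str, np.ndarray] = {}
    for band, (lo, hi) in config.carrier_bands.items():
        C = _target_corr_matrix(config, band)
        g = _correlated_log_envelopes(C, n, config.rate, rng)
        env_corr[band] = C
        log_envs[band] = 2.0 * g  # log of the squared (power) envelope
        for i in range(config.n_sources):
            carrier = _bandlimited_noise((lo, hi), n, config.rate, rng)
            comp = np.exp(g[i]) * carrier
            sources[i] += comp / comp.std()
    sources /= np.sqrt(len(config.carrier_bands))
    return sources, GroundTruth(envelope_corr=env_corr, log_power_envelopes=log_envs)


def synthetic_montage(
    n_sensors: int = 32, scalp_radius: float = 92.0, min_z_frac: float = -0.2
) -> tuple[list[str], np.ndarray]:
    """Fibonacci-spiral electrode layout over the upper scalp sphere."""
    zmin = min_z_frac
    k = np.arange(n_sensors)
    z = zmin + (1.0 - zmin) * (k + 0.5) / n_sensors
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1.0 - z**2)
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), z]) * scalp_radius
    labels = [f"E{i + 1:03d}" for i in range(n_sensors)]
    return labels, pos


def project_to_sensors(
    sources: np.ndarray,
    leadfield: LeadfieldModel,
    config: SimulationConfig,
    ground_truth: GroundTruth | None = None,
    orientations: np.ndarray | None = None,
) -> SensorRecording:
    """Mix sources to sensors, add noise, artifacts and bad channels.

    Sensor data = leadfield-projected oriented dipoles + white sensor noise
    + artifact topographies x artifact time courses; channels listed in
    ``bad_channel_spec`` are then overwritten (flat: zeros, noisy:
    high-variance white noise).
    """
    sources = np.atleast_2d(np.asarray(sources, float))
    if sources.shape[0] != config.n_sources:
        raise ValueError(
            f"source axis mismatch: got {sources.shape[0]} time courses for "
            f"{config.n_sources} configured sources"
        )
    if sources.shape[1] != config.n_samples:
        raise ValueError(
            f"sample axis mismatch: got {sources.shape[1]} samples, "
            f"expected {config.n_samples}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5E75]))
    n_sens = leadfield.n_sensors
    if orientations is None:
        oseed = config.orientation_seed
        orient_rng = (
            rng
            if oseed is None
            else np.random.default_rng(np.random.SeedSequence([oseed, 0x08]))
        )
        orientations = orient_rng.standard_normal((config.n_sources, 3))
    orientations = np.asarray(orientations, float)
    orientations = orientations / np.linalg.norm(orientations, axis=1, keepdims=True)

    mixing = np.empty((n_sens, config.n_sources))
    for i, pos in enumerate(config.source_positions_head):
        node = leadfield.nearest_node(pos)
        mixing[:, i] = leadfield.gain_at(node) @ orientations[i]
    data = mixing @ (config.source_moment_nAm * sources)
    if config.sensor_noise_sigma > 0:
        data += config.sensor_noise_sigma * rng.standard_normal(data.shape)

    art = config.artifact_spec
    positions = leadfield.sensor_positions
    art_courses: dict[str, np.ndarray] = {}
    art_topos: dict[str, np.ndarray] = {}
    if art.ocular_amplitude > 0:
        topo = np.clip(positions[:, 1], 0.0, None) ** 2
        topo /= topo.max()
        course = art.ocular_amplitude * _blink_train(
            config.n_samples, config.rate, rng
        )
        data += np.outer(topo, course)
        art_courses["ocular"], art_topos["ocular"] = course, topo
    if art.muscle_amplitude > 0:
        vertex = np.array([0.0, 0.0, positions[:, 2].max()])
        topo = np.linalg.norm(positions - vertex, axis=1) ** 2
        topo /= topo.max()
        course = art.muscle_amplitude * _burst_noise(
            art.muscle_band, config.n_samples, config.rate, rng
        )
        data += np.outer(topo, course)
        art_courses["muscle"], art_topos["muscle"] = course, topo

    bad_mask = np.zeros(n_sens, bool)
    typical_sd = np.median(data.std(axis=1))
    for ch, mode in config.bad_channel_spec:
        bad_mask[ch] = True
        if mode == "flat":
            data[ch] = 0.0
        else:
            data[ch] = 20.0 * max(typical_sd, 1.0) * rng.standard_normal(
                config.n_samples
            )

    if ground_truth is not None:
        ground_truth.mixing = mixing
        ground_truth.artifact_timecourses = art_courses
        ground_truth.artifact_topographies = art_topos
        ground_truth.bad_channels = list(config.bad_channel_spec)

    labels = [f"E{i + 1:03d}" for i in range(n_sens)]
    return SensorRecording(
        data=data,
        rate=config.rate,
        labels=labels,
        positions=positions.copy(),
        bad_mask=bad_mask,
        reference="recording-ref",
        history=[f"simulated seed={config.seed}"],
    )


# ---------------------------------------------------------------------------
# keypress simulation
# ---------------------------------------------------------------------------

@dataclass
class LearningCurveParams:
    """Exponential learning curve on the block-mean inter-key interval.

    mu_b = mu_inf + (mu0 - mu_inf) * exp(-(b - 1) / tau), b = 1..n_blocks;
    intervals within a block are lognormal with that mean, and each press is
    replaced by a uniformly random wrong key with probability ``error_prob``.
    """

    mu0: float = 0.5           # initial mean inter-key interval, s
    mu_inf: float = 0.2        # asymptotic interval, s
    tau: float = 4.0           # time constant, blocks
    error_prob: float = 0.02
    n_blocks: int = 20
    presses_per_block: int = 60
    interval_cv: float = 0.25  # lognormal coefficient of variation
    rest_s: float = 20.0       # inter-block rest

    def block_mean(self, block: int) -> float:
        return self.mu_inf + (self.mu0 - self.mu_inf) * np.exp(
            -(block - 1) / self.tau
        )


def simulate_keypress_log(
    params: LearningCurveParams, seed: int, session: str = "training"
) -> KeypressLog:
    """One session of cyclic-sequence tapping with a stochastic error process."""
    if params.mu0 <= 0 or params.mu_inf <= 0:
        raise ValueError("mean inter-key intervals must be positive")
    rng = np.random.default_rng(seed)
    seq = TARGET_SEQUENCE
    sigma2 = np.log(1.0 + params.interval_cv**2)
    rows = []
    t = 0.0
    for b in range(1, params.n_blocks + 1):
        mu_b = params.block_mean(b)
        mu_log = np.log(mu_b) - sigma2 / 2  # lognormal mean == mu_b
        ivals = rng.lognormal(mu_log, np.sqrt(sigma2), params.presses_per_block)
        errors = rng.random(params.presses_per_block) < params.error_prob
        for p in range(params.presses_per_block):
            t += ivals[p] * 1000.0
            key = seq[p % len(seq)]
            if errors[p]:
                wrong = [k for k in range(1, 9) if k != key]
                key = wrong[rng.integers(len(wrong))]
            rows.append((session, b, p, key, t))
        t += params.rest_s * 1000.0
    events = pd.DataFrame(
        rows, columns=["session", "block", "press_idx", "key", "t_ms"]
    )
    return KeypressLog(events=events)
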