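"""Validation data generators with known ground truth.

Two simulators back the validation studies:

* a 2-D Gaussian toy problem: class prototypes at +/-[1.5, 0] contaminated
  by correlated Gaussian noise with covariance [[1.02, -0.3], [-0.3, 0.15]].
  Only the first coordinate is discriminative, so the true map is [1, 0] —
  while the accuracy-optimal (noise-aware) direction is [1, 2]/sqrt(5).
* simulated evoked MEG: a single current dipole in a spherical conductor,
  observed by 102 magnetometers on a hemispherical array.  The positive
  class carries a time-locked ERF (positive 3 Hz half-cycle peaking near
  150 ms, negative 5 Hz half-cycle near 250 ms, +/-10 ms per-trial jitter)
  on top of 1/f background activity (50 random sinusoids, 1-125 Hz) and
  RMS-scaled white noise; the negative class carries the noise components
  only.  The dipole topography outer the mean ERF waveform is the
  discriminative ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .decoding import EpochedDataset, SensorLayout
from .maps import MultivariateBrainMap, normalize_map

__all__ = [
    "ToyConfig",
    "MegSimConfig",
    "SimulatedGroundTruth",
    "make_toy",
    "toy_population_direction",
    "toy_bayes_accuracy",
    "hemispherical_layout",
    "dipole_topography",
    "erf_waveform",
    "simulate_meg",
]

TOY_CLASS_POINT = np.array([1.5, 0.0])
TOY_NOISE_COV = np.array([[1.02, -0.3], [-0.3, 0.15]])


@dataclass(frozen=True)
class ToyConfig:
    """2-D toy problem configuration (defaults are the study conditions)."""

    n_per_class: int = 1000
    class_point: np.ndarray = field(
        default_factory=lambda: TOY_CLASS_POINT.copy()
    )
    noise_covariance: np.ndarray = field(
        default_factory=lambda: TOY_NOISE_COV.copy()
    )
    seed: int = 0

    def __post_init__(self) -> None:
        cov = np.asarray(self.noise_covariance, float)
        if not np.allclose(cov, cov.T):
            raise ValueError("noise covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ValueError("noise covariance must be positive definite")
        object.__setattr__(self, "noise_covariance", cov)
        object.__setattr__(
            self, "class_point", np.asarray(self.class_point, float)
        )


def make_toy(config: ToyConfig = ToyConfig()):
    """Generate the toy dataset; returns ``(dataset, true_map)``.

    Labels are +1 at +class_point and -1 at -class_point; the true
    discriminative map is [1, 0] (the second coordinate is pure noise).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_per_class
    noise = rng.multivariate_normal(
        np.zeros(2), config.noise_covariance, size=2 * n,
        method="cholesky",
    )
    labels = np.concatenate([np.ones(n, int), -np.ones(n, int)])
    X = labels[:, None] * config.class_point[None, :] + noise
    true_map = normalize_map(np.array([1.0, 0.0]))
    data = EpochedDataset(X, labels, meta={"generator": "toy",
                                           "seed": int(config.seed)})
    return data, true_map


def toy_population_direction(config: ToyConfig = ToyConfig()) -> np.ndarray:
    """Population least-squares direction Sigma_X^{-1} E[X y], unit norm.

    With the default covariance this is [1, 2]/sqrt(5) ~ [0.4472, 0.8944]:
    the accuracy-optimal direction leans on the noise coordinate because
    the noise is correlated across coordinates.
    """
    mu = config.class_point
    sigma_x = np.outer(mu, mu) + config.noise_covariance
    d = np.linalg.solve(sigma_x, mu)
    return d / np.linalg.norm(d)


def toy_bayes_accuracy(config: ToyConfig = ToyConfig()) -> float:
    """Bayes accuracy Phi(d/2) with d the Mahalanobis class separation."""
    delta_mu = 2.0 * config.class_point
    d2 = delta_mu @ np.linalg.solve(config.noise_covariance, delta_mu)
    return float(stats.norm.cdf(np.sqrt(d2) / 2.0))


# ---------------------------------------------------------------------------
# simulated evoked MEG
# ---------------------------------------------------------------------------

def hemispherical_layout(n_channels: int = 102,
                         radius_cm: float = 12.0) -> np.ndarray:
    """Deterministic Fibonacci-lattice hemisphere of sensor positions (cm).

    Points are spread quasi-uniformly over the upper hemisphere (z > 0),
    emulating a helmet-style magnetometer array.
    """
    k = np.arange(n_channels)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    # z from just above the rim to near the pole, evenly spaced
    z = (k + 0.5) / n_channels
    phi = 2.0 * np.pi * k / golden
    rho = np.sqrt(1.0 - z**2)
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    return radius_cm * pts


def dipole_topography(position_cm, orientation, sensor_positions_cm,
                      moment: float = 1.0) -> np.ndarray:
    """Radial magnetic field of a current dipole in a spherical conductor.

    Uses the closed-form field of a current dipole inside a homogeneous
    conducting sphere (volume currents included), evaluated at each sensor
    and projected on the outward radial direction — the component a
    radially-oriented magnetometer measures.  A radially oriented dipole
    is magnetically silent in this model.

    Parameters
    ----------
    position_cm, orientation : 3-vectors
        Dipole location (inside the sensor sphere, nonzero radius) and
        moment direction (need not be normalized; ``moment`` scales it).
    sensor_positions_cm : (n_channels, 3)
        Sensor locations, all strictly farther from the origin than the
        dipole.
    """
    r0 = np.asarray(position_cm, float)
    q = np.asarray(orientation, float)
    if np.linalg.norm(q) == 0:
        raise ValueError("dipole orientation must be nonzero")
    q = moment * q / np.linalg.norm(q)
    sensors = np.atleast_2d(np.asarray(sensor_positions_cm, float))
    r0n = np.linalg.norm(r0)
    if r0n == 0:
        raise ValueError("dipole at the sphere center has no tangential part")
    rn = np.linalg.norm(sensors, axis=1)
    if np.any(rn <= r0n):
        raise ValueError("all sensors must lie outside the dipole radius")

    out = np.empty(sensors.shape[0])
    qxr0 = np.cross(q, r0)
    for i, r in enumerate(sensors):
        a_vec = r - r0
        a = np.linalg.norm(a_vec)
        rno = rn[i]
        F = a * (rno * a + rno**2 - r0 @ r)
        gradF = (
            (a**2 / rno + (a_vec @ r) / a + 2.0 * a + 2.0 * rno) * r
            - (a + 2.0 * rno + (a_vec @ r) / a) * r0
        )
        B = (F * qxr0 - (qxr0 @ r) * gradF) / F**2
        out[i] = B @ (r / rno)
    return out


@dataclass(frozen=True)
class MegSimConfig:
    """Simulated evoked-MEG configuration (defaults are the study conditions).

    The amplitude of every sinusoidal component — the two ERF half-cycles
    and each background sinusoid — follows the 1/f^gamma spectral law that
    emulates the broadband power profile of human brain activity.  White
    Gaussian noise is added per sensor sample with standard deviation
    ``white_noise_scale`` times the RMS of that epoch's projected dipole
    signal (``white_noise_at="dipole"`` instead superimposes it on the
    dipole time course, which leaves the sensor covariance rank one).
    """

    epochs_per_class: int = 250
    srate_hz: float = 300.0
    n_times: int = 100  # ~330 ms epochs
    n_channels: int = 102
    sensor_radius_cm: float = 12.0
    dipole_position_cm: tuple = (-4.7, -3.7, 5.3)  # RAS
    dipole_orientation: tuple = (1.0, 1.0, 0.0)
    erf_peaks_ms: tuple = (150.0, 250.0)
    erf_freqs_hz: tuple = (3.0, 5.0)
    erf_signs: tuple = (1.0, -1.0)
    jitter_ms: float = 10.0
    n_background: int = 50
    background_freq_range_hz: tuple = (1.0, 125.0)
    spectral_gamma: float = 1.0
    background_scale: float = 1.0
    white_noise_scale: float = 1.0
    white_noise_at: str = "sensors"  # or "dipole"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.background_freq_range_hz
        if not (0.0 < lo < hi < self.srate_hz / 2.0 + 1e-9):
            raise ValueError("background band must lie in (0, srate/2)")
        for pk in self.erf_peaks_ms:
            if not 0.0 <= pk <= self.epoch_ms:
                raise ValueError("ERF peaks must lie within the epoch")

    @property
    def epoch_ms(self) -> float:
        return self.n_times * 1000.0 / self.srate_hz

    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_times) * 1000.0 / self.srate_hz

    def amplitude(self, freq_hz) -> np.ndarray:
        """Spectral amplitude 1/f^gamma of a sinusoidal component."""
        return 1.0 / np.asarray(freq_hz, float) ** self.spectral_gamma


@dataclass(frozen=True)
class SimulatedGroundTruth:
    """A simulated dataset paired with its true discriminative map.

    ``true_map`` is the unit-norm flattening (channel-major) of the outer
    product of the dipole topography and the jitter-free ERF waveform.
    """

    dataset: EpochedDataset
    true_map: MultivariateBrainMap
    leadfield_topography: np.ndarray
    erf_waveform: np.ndarray
    config: object = None


def erf_waveform(config: MegSimConfig, jitters_ms=(0.0, 0.0)) -> np.ndarray:
    """ERF time course: two half-cycle sinusoids, zero elsewhere.

    Component k is a half-cycle of a sinusoid at ``erf_freqs_hz[k]``
    (duration 1/(2f)) whose extremum sits at ``erf_peaks_ms[k] +
    jitters_ms[k]``, signed by ``erf_signs[k]`` and scaled by the spectral
    amplitude law.
    """
    t = config.times_ms()
    wave = np.zeros_like(t)
    for peak, f, sign, jit in zip(
        config.erf_peaks_ms, config.erf_freqs_hz, config.erf_signs,
        jitters_ms,
    ):
        center = peak + jit
        half_ms = 1000.0 / (2.0 * f)  # half-cycle duration
        start = center - half_ms / 2.0
        inside = (t >= start) & (t <= start + half_ms)
        amp = sign * float(config.amplitude(f))
        wave[inside] += amp * np.sin(np.pi * (t[inside] - start) / half_ms)
    return wave


def _background(config: MegSimConfig, rng: np.random.Generator) -> np.ndarray:
    """One epoch of background activity: 50 random 1/f-weighted sinusoids."""
    lo, hi = config.background_freq_range_hz
    freqs = rng.uniform(lo, hi, size=config.n_background)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=config.n_background)
    amps = config.background_scale * config.amplitude(freqs)
    t_s = config.times_ms()[None, :] / 1000.0
    waves = amps[:, None] * np.sin(
        2.0 * np.pi * freqs[:, None] * t_s + phases[:, None]
    )
    return waves.sum(axis=0)


def simulate_meg(config: MegSimConfig = MegSimConfig()) -> SimulatedGroundTruth:
    """Simulate the two-class evoked-MEG dataset with known ground truth.

    Positive-class epochs carry ERF + background + white noise on the
    dipole time course; negative-class epochs carry background + white
    noise only.  All components are projected to the sensors through the
    dipole topography; features are flattened channel-major.  Bit
    reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    sensors = hemispherical_layout(config.n_channels, config.sensor_radius_cm)
    topo = dipole_topography(
        config.dipole_position_cm, config.dipole_orientation, sensors
    )
    topo = topo / np.linalg.norm(topo)

    erf_mean = erf_waveform(config)
    true_map = normalize_map(np.outer(topo, erf_mean).ravel(order="C"))

    n_each = config.epochs_per_class
    n = 2 * n_each
    p = config.n_channels * config.n_times
    trials = np.empty((n, p))
    labels = np.concatenate([np.ones(n_each, int), -np.ones(n_each, int)])

    if config.white_noise_at not in ("sensors", "dipole"):
        raise ValueError("white_noise_at must be 'sensors' or 'dipole'")
    for i in range(n):
        has_erf = labels[i] == 1
        if has_erf:
            jit = rng.uniform(-config.jitter_ms, config.jitter_ms, size=2)
            signal = erf_waveform(config, jitters_ms=jit) + _background(
                config, rng
            )
        else:
            signal = _background(config, rng)
        if config.white_noise_at == "dipole":
            rms = np.sqrt(np.mean(signal**2))
            white = rng.normal(
                0.0, config.white_noise_scale * rms, size=config.n_times
            )
            epoch = np.outer(topo, signal + white)
        else:
            epoch = np.outer(topo, signal)
            # epoch-level RMS of the projected signal sets the sensor
            # noise floor, so SNR tracks the epoch's own activity
            rms = np.sqrt(np.mean(epoch**2))
            epoch = epoch + rng.normal(
                0.0, config.white_noise_scale * rms,
                size=(config.n_channels, config.n_times),
            )
        trials[i] = epoch.ravel(order="C")

    layout = SensorLayout(
        n_channels=config.n_channels,
        n_times=config.n_times,
        sampling_rate_hz=config.srate_hz,
        channel_positions_cm=sensors,
    )
    dataset = EpochedDataset(
        trials, labels, layout=layout,
        meta={"generator": "simulated-meg", "seed": int(config.seed)},
    )
    return SimulatedGroundTruth(
        dataset=dataset,
        true_map=true_map,
        leadfield_topography=topo,
        erf_waveform=erf_mean,
        config=config,
    )
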