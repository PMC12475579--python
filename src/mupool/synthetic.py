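"""Synthetic motor-neuron-pool cohorts with known ground truth.

The generator embodies the statistical structure that the downstream
analyses assume: a pool of tonically active motor units receiving one or
two shared low-frequency inputs plus independent per-unit noise, firing as
inhomogeneous renewal processes, with force produced by convolving the
cumulative spike train with a motor-unit twitch.  Because the shared
input(s), mixing gains and per-trial realizations are recorded in a truth
ledger, every analysis stage can be exercised as a parameter-recovery
problem without any experimental data.

Discharge generation is deliberately lightweight: an inhomogeneous renewal
process driven through time rescaling, with Gaussian jitter on the
interval thresholds calibrated so that the empirical inter-spike-interval
coefficient of variation matches ``PoolSpec.isi_cov``.  The claims the
pipeline tests concern low-frequency rate covariation across units, which
this model reproduces without motoneuron biophysics (no conductances,
persistent inward currents, or recruitment modeling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import signal

from .recordings_io import DEFAULT_FS, CohortDataset, DischargeTrain, TrialRecording

__all__ = [
    "PoolSpec",
    "InputSpec",
    "TwitchSpec",
    "SyntheticCohort",
    "TargetTrajectory",
    "generate_common_input",
    "generate_target_trajectory",
    "simulate_discharges",
    "simulate_force",
    "generate_cohort",
]

#: instantaneous discharge rate is never allowed below this (pulses/s)
RATE_FLOOR_PPS = 0.5
#: renewal processes cannot produce intervals shorter than this
MIN_ISI_S = 0.020


class ParameterError(ValueError):
    pass


class DegenerateSimulationError(RuntimeError):
    pass


@dataclass
class PoolSpec:
    """Size and gain structure of the simulated motor-neuron pool.

    Defaults describe a steady submaximal isometric contraction: ~10 units
    discharging tonically at 8–15 pulses/s with ISI CoV ≈ 10%, a shared
    low-frequency input modulating all rates by ~±18% and weaker
    independent modulation per unit.  These settings place the plateau
    force CoV near 9–10% of the mean while a single component dominates
    the smoothed-rate covariance; the common/noise gain ratio sets the
    strength of that dominant component.
    """

    n_units: int = 10
    mean_rates: np.ndarray | float = None  # pulses/s; default spread over 8–15
    isi_cov: float = 0.10
    common_gain: np.ndarray | float = 0.18
    noise_gain: np.ndarray | float = 0.04

    def __post_init__(self) -> None:
        if self.n_units < 2:
            raise ParameterError("n_units must be >= 2")
        if self.mean_rates is None:
            self.mean_rates = np.linspace(8.0, 15.0, self.n_units)
        self.mean_rates = np.broadcast_to(
            np.asarray(self.mean_rates, dtype=float), (self.n_units,)
        ).copy()
        if np.any(self.mean_rates <= 0):
            raise ParameterError("mean_rates must be > 0")
        if not 0 <= self.isi_cov < 1:
            raise ParameterError("isi_cov must be in [0, 1)")
        self.common_gain = np.broadcast_to(
            np.asarray(self.common_gain, dtype=float), (self.n_units,)
        ).copy()
        self.noise_gain = np.broadcast_to(
            np.asarray(self.noise_gain, dtype=float), (self.n_units,)
        ).copy()
        if np.any(self.common_gain < 0) or np.any(self.noise_gain < 0):
            raise ParameterError("gains must be >= 0")


@dataclass
class InputSpec:
    """Shared-input structure: how many common drives and who receives them."""

    n_common: int = 1
    bandwidth_hz: float = 2.5
    mixing: np.ndarray | None = None  # (n_units, n_common); rows L2-normalized

    def __post_init__(self) -> None:
        if self.n_common not in (1, 2):
            raise ParameterError("n_common must be 1 or 2")
        if self.bandwidth_hz <= 0:
            raise ParameterError("bandwidth_hz must be > 0")
        if self.mixing is not None:
            self.mixing = np.asarray(self.mixing, dtype=float)

    def mixing_for(self, n_units: int) -> np.ndarray:
        """Row-normalized (n_units, n_common) weight matrix.

        Default: one input drives everyone; two inputs split the pool into
        two equal groups, each driven by one input.
        """
        if self.mixing is None:
            if self.n_common == 1:
                m = np.ones((n_units, 1))
            else:
                m = np.zeros((n_units, 2))
                m[: n_units // 2, 0] = 1.0
                m[n_units // 2:, 1] = 1.0
        else:
            m = self.mixing
            if m.shape != (n_units, self.n_common):
                raise ParameterError(
                    f"mixing shape {m.shape} != ({n_units}, {self.n_common})"
                )
        norms = np.linalg.norm(m, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return m / norms


@dataclass
class TwitchSpec:
    """Second-order critically damped twitch: h(t) = A (t/T) exp(1 - t/T).

    ``contraction_time`` is the time-to-peak T in seconds.  The default of
    130 ms sits in the slower half of the physiological tibialis-anterior
    range (~90-140 ms) and, together with the default pool gains, places
    the plateau force CoV in the reported 9-10% band.  ``amplitude`` is
    the peak force of a single twitch in arbitrary units (annihilated by
    %MVC rescaling).
    """

    contraction_time: float = 0.13
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.contraction_time <= 0:
            raise ParameterError("contraction_time must be > 0")

    def impulse_response(self, fs: float) -> np.ndarray:
        t = np.arange(0.0, 10.0 * self.contraction_time, 1.0 / fs)
        x = t / self.contraction_time
        return self.amplitude * x * np.exp(1.0 - x)


@dataclass
class TargetTrajectory:
    """Trapezoidal force target: ramp up, stochastic plateau, ramp down."""

    values: np.ndarray
    fs: float
    plateau: slice  # sample range of the constant-level region

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.fs


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth needed for recovery tests."""

    cohort: CohortDataset
    truth: dict[str, Any] = field(default_factory=dict)

    @property
    def analysis_window_s(self) -> tuple[float, float]:
        return self.truth["analysis_window_s"]


def generate_common_input(
    duration_s: float,
    fs: float = DEFAULT_FS,
    bandwidth_hz: float = 2.5,
    seed: int | np.random.Generator | None = None,
    order: int = 4,
) -> np.ndarray:
    """Zero-mean, unit-variance low-frequency drive.

    White Gaussian noise low-pass filtered (zero-phase Butterworth of the
    given order) at ``bandwidth_hz`` and re-standardized.
    """
    if duration_s <= 0:
        raise ParameterError("duration_s must be > 0")
    if bandwidth_hz >= fs / 2:
        raise ParameterError(
            f"bandwidth_hz {bandwidth_hz} must be below the Nyquist rate {fs / 2}"
        )
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    white = rng.standard_normal(n)
    sos = signal.butter(order, bandwidth_hz, btype="low", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    x = x - x.mean()
    sd = x.std()
    if sd == 0:
        raise DegenerateSimulationError("filtered input is constant")
    return x / sd


def generate_target_trajectory(
    plateau_level_pct: float = 10.0,
    duration_s: float = 30.0,
    ramp_rate_pct_per_s: float = 5.0,
    osc_bandwidth_hz: float = 1.5,
    osc_amplitude: float = 0.95,
    fs: float = DEFAULT_FS,
    seed: int | np.random.Generator | None = None,
) -> TargetTrajectory:
    """Force-matching target: linear ramps flanking a stochastic plateau.

    The plateau holds ``duration_s`` seconds of low-pass-filtered random
    oscillations (SD ``osc_amplitude`` %MVC) centered on the plateau level;
    ramps rise/fall at ``ramp_rate_pct_per_s``.  ``osc_amplitude == 0``
    degenerates to an exact trapezoid.
    """
    if osc_amplitude < 0:
        raise ParameterError("osc_amplitude must be >= 0")
    if plateau_level_pct <= 0 or duration_s <= 0 or ramp_rate_pct_per_s <= 0:
        raise ParameterError("levels, durations and rates must be > 0")
    n_ramp = int(round(plateau_level_pct / ramp_rate_pct_per_s * fs))
    n_plateau = int(round(duration_s * fs))
    up = np.linspace(0.0, plateau_level_pct, n_ramp, endpoint=False)
    down = np.linspace(plateau_level_pct, 0.0, n_ramp, endpoint=False)
    plateau = np.full(n_plateau, plateau_level_pct)
    if osc_amplitude > 0:
        osc = generate_common_input(duration_s, fs, osc_bandwidth_hz, seed)
        # ~0.5-s cosine taper at each end keeps the ramp junctions continuous
        taper = signal.windows.tukey(n_plateau, alpha=min(1.0, 1.0 * fs / n_plateau))
        osc = osc * taper
        plateau = plateau + osc_amplitude * (osc - osc.mean())
    values = np.concatenate([up, plateau, down])
    return TargetTrajectory(values, fs, slice(n_ramp, n_ramp + n_plateau))


def _renewal_spike_times(
    rate_pps: np.ndarray, fs: float, isi_cov: float, rng: np.random.Generator
) -> np.ndarray:
    """Spike times (seconds) of an inhomogeneous renewal process.

    Time rescaling: spikes occur when the integrated rate crosses a running
    sum of unit-mean thresholds with SD ``isi_cov`` (Gaussian, truncated
    positive).  With ``isi_cov == 0`` this is a deterministic clock.
    """
    cum = np.cumsum(rate_pps) / fs  # integrated rate at sample ends
    total = cum[-1]
    n_max = int(total + 10 * np.sqrt(max(total, 1.0)) + 10)
    if isi_cov == 0:
        thresholds = np.ones(n_max)
    else:
        thresholds = rng.normal(1.0, isi_cov, size=n_max)
        thresholds = np.clip(thresholds, 0.1, None)
    targets = np.cumsum(thresholds)
    targets = targets[targets <= total]
    t_grid = np.arange(1, len(cum) + 1) / fs
    times = np.interp(targets, cum, t_grid)
    if times.size > 1:  # reject implausibly short intervals
        keep = np.ones(times.size, dtype=bool)
        last = times[0]
        for i in range(1, times.size):
            if times[i] - last < MIN_ISI_S:
                keep[i] = False
            else:
                last = times[i]
        times = times[keep]
    return times


def simulate_discharges(
    pool: PoolSpec,
    inputs: InputSpec,
    drive: np.ndarray,
    fs: float = DEFAULT_FS,
    seed: int | np.random.Generator | None = None,
) -> list[DischargeTrain]:
    """Simulate one trial of pool discharges given shared drive(s).

    ``drive`` is (T,) or (n_common, T), standardized.  Unit *i* fires as a
    renewal process with instantaneous rate

        rate_i(t) = mean_rate_i * (1 + common_gain_i * (M @ drive)_i(t)
                                     + noise_gain_i * eta_i(t)),

    floored at 0.5 pulses/s, where eta_i is an independent low-frequency
    noise with the same bandwidth as the shared input.
    """
    rng = np.random.default_rng(seed)
    drive = np.atleast_2d(np.asarray(drive, dtype=float))
    if drive.shape[0] != inputs.n_common:
        raise ParameterError(
            f"drive has {drive.shape[0]} rows; InputSpec declares {inputs.n_common}"
        )
    n_samples = drive.shape[1]
    if n_samples == 0:
        raise ParameterError("drive is empty")
    mixing = inputs.mixing_for(pool.n_units)
    shared = mixing @ drive  # (n_units, T)

    trains: list[DischargeTrain] = []
    for i in range(pool.n_units):
        modulation = pool.common_gain[i] * shared[i]
        if pool.noise_gain[i] > 0:
            eta = generate_common_input(
                n_samples / fs, fs, inputs.bandwidth_hz, rng
            )
            modulation = modulation + pool.noise_gain[i] * eta
        rate = pool.mean_rates[i] * (1.0 + modulation)
        if np.all(rate <= 0):
            raise DegenerateSimulationError(
                f"unit {i}: modulation drives the rate non-positive everywhere"
            )
        rate = np.maximum(rate, RATE_FLOOR_PPS)
        times = _renewal_spike_times(rate, fs, pool.isi_cov, rng)
        samples = np.unique(np.floor(times * fs + 0.5).astype(np.int64))
        samples = samples[samples < n_samples]
        trains.append(DischargeTrain(f"MU{i + 1:02d}", samples, fs, n_samples))
    return trains


def simulate_force(
    trains: Sequence[DischargeTrain],
    twitch: TwitchSpec | None = None,
    noise_sd: float = 0.0,
    n_samples: int | None = None,
    plateau_pct: float | None = None,
    plateau: slice | None = None,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Force as twitch-convolved cumulative spiking plus measurement noise.

    With ``plateau_pct`` given, the convolved drive is rescaled so its mean
    over ``plateau`` (or the whole record) equals that %MVC level before
    noise is added; otherwise raw twitch units are returned.
    """
    if not trains:
        raise ParameterError("need at least one train")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    twitch = twitch or TwitchSpec()
    fs = trains[0].fs
    if n_samples is None:
        lengths = [t.trial_length for t in trains if t.trial_length is not None]
        if lengths:
            n_samples = max(lengths)
        else:
            last = max((int(t.discharge_samples[-1]) for t in trains
                        if t.n_discharges), default=0)
            n_samples = last + len(twitch.impulse_response(fs))
    cst = np.zeros(n_samples)
    for t in trains:
        s = t.discharge_samples
        cst[s[s < n_samples]] += 1.0
    h = twitch.impulse_response(fs)
    force = signal.fftconvolve(cst, h)[:n_samples]
    if plateau_pct is not None:
        region = force[plateau] if plateau is not None else force
        mean = region.mean()
        if mean <= 0:
            raise DegenerateSimulationError("no force produced on the plateau")
        force = force * (plateau_pct / mean)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        force = force + rng.normal(0.0, noise_sd, size=n_samples)
    return force


def generate_cohort(
    n_trials: int = 3,
    pool: PoolSpec | None = None,
    inputs: InputSpec | None = None,
    twitch: TwitchSpec | None = None,
    seed: int = 0,
    frozen_input: bool = False,
    plateau_level_pct: float = 10.0,
    plateau_s: float = 30.0,
    ramp_rate_pct_per_s: float = 5.0,
    force_noise_sd: float = 0.05,
    fs: float = DEFAULT_FS,
    participant: str = "S01",
    muscle: str = "TA",
) -> SyntheticCohort:
    """Generate a repeated-trial cohort with a shared target trajectory.

    Trials reuse one target (as in a force-matching protocol) but receive
    fresh shared-input realizations unless ``frozen_input`` is set, which
    replays the identical drive in every trial — a positive control for
    across-trial consistency analyses.  The truth ledger records per-trial
    drives, effective per-unit gains, the plateau window, and the analysis
    window (the last 25 s of the 30-s plateau, excluding the first 5 s
    where units may not yet discharge tonically).
    """
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    pool = pool or PoolSpec()
    inputs = inputs or InputSpec()
    twitch = twitch or TwitchSpec()
    ss = np.random.SeedSequence(seed)
    target_seed, *children = ss.spawn(1 + 2 * n_trials)
    drive_seeds, sim_seeds = children[:n_trials], children[n_trials:]
    target = generate_target_trajectory(
        plateau_level_pct,
        plateau_s,
        ramp_rate_pct_per_s,
        fs=fs,
        seed=np.random.default_rng(target_seed),
    )
    n_samples = len(target.values)
    duration_s = n_samples / fs
    plateau_start_s = target.plateau.start / fs
    analysis_window_s = (plateau_start_s + 5.0, plateau_start_s + plateau_s)

    trials = []
    drives = []
    for k in range(n_trials):
        # frozen: replay one drive realization; discharges/noise stay fresh
        drive_rng = np.random.default_rng(drive_seeds[0] if frozen_input else drive_seeds[k])
        rng = np.random.default_rng(sim_seeds[k])
        drive = np.vstack(
            [
                generate_common_input(duration_s, fs, inputs.bandwidth_hz, drive_rng)
                for _ in range(inputs.n_common)
            ]
        )
        trains = simulate_discharges(pool, inputs, drive, fs, rng)
        force = simulate_force(
            trains,
            twitch,
            noise_sd=force_noise_sd,
            n_samples=n_samples,
            plateau_pct=plateau_level_pct,
            plateau=target.plateau,
            seed=rng,
        )
        trials.append(
            TrialRecording(participant, muscle, k + 1, trains, force, target.values)
        )
        drives.append(drive)

    cohort = CohortDataset(
        trials,
        metadata={"generator": "mupool.synthetic", "seed": seed,
                  "frozen_input": frozen_input},
    )
    truth = {
        "seed": seed,
        "drives": drives,  # list of (n_common, T) standardized series
        "mixing": inputs.mixing_for(pool.n_units),
        "gains": pool.common_gain.copy(),
        "pool": pool,
        "inputs": inputs,
        "twitch": twitch,
        "target": target,
        "plateau": target.plateau,
        "analysis_window_s": analysis_window_s,
        "fs": fs,
    }
    return SyntheticCohort(cohort, truth)
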