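"""Stochastic unwinding simulators and the measurement model.

Two microscopic models generate the pause structure of an unwinding
trajectory with kinetic step size n:

* **simultaneous melting** — all n base pairs of a kinetic step open in one
  activated event, so the mean pause is A * exp(sum of the n opening
  energies);
* **delayed release** — base pairs open one at a time but the nascent ssDNA
  is released only after n bp, so the mean pause is the sum of n single-bp
  Boltzmann times A * exp(G_s).

Each kinetic step is a pause (drawn exponentially with the model mean, or
taken deterministically) followed by a translocation delay n/v_trans and an
instantaneous n-bp release.  The Boltzmann pre-factor A is calibrated so the
expected mean unwinding rate matches a target (46 nt/s for the core
helicase).  The measurement model maps base pairs unwound to a noisy
extension-vs-time trace: 2 nucleotides released per bp, worm-like-chain
fractional extension at the applied force, i.i.d. Gaussian position noise per
sample at the acquisition rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .substrates import HairpinSubstrate, ForkSubstrate
from .thermo import DuplexEnergyProfile, IonicConditions, KBT_PN_NM, compute_bp_energies
from . import mechchem

__all__ = [
    "SimulationConfig",
    "MeasurementConfig",
    "Trajectory",
    "MeasuredTrace",
    "wlc_extension_per_nt",
    "step_slices",
    "pause_time_mean",
    "expected_total_time",
    "calibrate_prefactor",
    "simulate_trajectory",
    "simulate_atpgs_trajectory",
    "render_measurement",
    "generate_trace_set",
]


def wlc_extension_per_nt(
    force_pN: float,
    persistence_nm: float = 1.0,
    interphosphate_nm: float = 0.65,
    kbt_pn_nm: float = KBT_PN_NM,
) -> float:
    """Extension per ssDNA nucleotide (nm) from the WLC interpolation formula.

    Solves ``F*Lp/kBT = x + 1/(4(1-x)^2) - 1/4`` for the fractional extension
    x in (0, 1) and returns ``x * interphosphate_nm``.  One unwound base pair
    releases two nucleotides, so the extension gain per bp is twice this.
    """
    if force_pN <= 0 or persistence_nm <= 0:
        raise ValueError("force and persistence length must be positive")
    target = force_pN * persistence_nm / kbt_pn_nm

    def f(x: float) -> float:
        return x + 0.25 / (1.0 - x) ** 2 - 0.25 - target

    lo, hi = 1e-12, 1.0 - 1e-9
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("no WLC solution in (0, 1) for these parameters")
    x = brentq(f, lo, hi, xtol=1e-14)
    return x * interphosphate_nm


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the stochastic unwinding simulation."""

    model: Literal["simultaneous", "delayed"] = "delayed"
    n: int = 5
    prefactor_s: float | None = None  # A_RecQ; None until calibrated
    v_trans: float = 100.0  # bp/s post-melt translocation rate
    target_mean_rate: float = 46.0  # bp/s, core-helicase reference
    pause_draw: Literal["exponential", "deterministic"] = "exponential"
    half_step: bool = False  # release two n/2-bp sub-steps per kinetic step

    def __post_init__(self) -> None:
        if self.model not in ("simultaneous", "delayed"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.n < 1:
            raise ValueError("kinetic step size n must be >= 1")
        if self.v_trans <= 0:
            raise ValueError("v_trans must be positive")
        if self.prefactor_s is not None and self.prefactor_s <= 0:
            raise ValueError("prefactor must be positive")


@dataclass(frozen=True)
class MeasurementConfig:
    """Magnetic-tweezers measurement model parameters."""

    force_pN: float = 8.0
    persistence_nm: float = 1.0
    interphosphate_nm: float = 0.65
    sampling_hz: float = 200.0
    noise_sigma_nm: float = 14.0

    def __post_init__(self) -> None:
        for name in ("force_pN", "persistence_nm", "interphosphate_nm", "sampling_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sigma_nm < 0:
            raise ValueError("noise_sigma_nm must be non-negative")

    @property
    def nm_per_bp(self) -> float:
        """Extension gain per unwound base pair (two released nucleotides)."""
        return 2.0 * wlc_extension_per_nt(
            self.force_pN, self.persistence_nm, self.interphosphate_nm
        )


@dataclass(frozen=True)
class Trajectory:
    """Ideal bp-vs-time unwinding record with its per-step ground truth.

    The position is piecewise constant: during the pause and the
    translocation delay of step i the helicase holds at the previous level,
    then releases the step's base pairs instantaneously.
    """

    substrate: HairpinSubstrate | ForkSubstrate
    event_times: np.ndarray  # times of instantaneous releases, s
    event_positions: np.ndarray  # bp unwound after each release
    step_start: np.ndarray  # per kinetic step
    pause_s: np.ndarray
    trans_s: np.ndarray
    bp_covered: np.ndarray
    config: SimulationConfig | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times, dtype=float)
        p = np.asarray(self.event_positions, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(np.diff(p) < 0):
            raise ValueError("positions must be non-decreasing")

    @property
    def length(self) -> int:
        seq = getattr(self.substrate, "stem_sequence", None) or self.substrate.duplex_sequence
        return len(seq)

    @property
    def total_time(self) -> float:
        return float(self.event_times[-1])

    @property
    def mean_rate(self) -> float:
        """Average unwinding rate over the event, bp/s."""
        return float(self.event_positions[-1] / self.event_times[-1])

    def position_at(self, t: np.ndarray) -> np.ndarray:
        """bp unwound at times ``t`` (staircase interpolation)."""
        idx = np.searchsorted(self.event_times, np.asarray(t, dtype=float), side="right")
        pos = np.concatenate([[0.0], self.event_positions])
        return pos[idx]


@dataclass(frozen=True)
class MeasuredTrace:
    """Uniformly sampled noisy extension-vs-time trace."""

    time_s: np.ndarray
    extension_nm: np.ndarray
    meas_config: MeasurementConfig
    trajectory: Trajectory | None = None

    def __post_init__(self) -> None:
        dt = np.diff(np.asarray(self.time_s, dtype=float))
        if len(dt) and not np.allclose(dt, 1.0 / self.meas_config.sampling_hz):
            raise ValueError("trace must be uniformly sampled at sampling_hz")

    def plot(self, ax=None, show_truth: bool = True, **kwargs):
        """Extension vs time; overlays the ground-truth staircase if known."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.time_s, self.extension_nm, lw=0.5, alpha=0.7, **kwargs)
        if show_truth and self.trajectory is not None:
            truth = self.meas_config.nm_per_bp * self.trajectory.position_at(self.time_s)
            ax.plot(self.time_s, truth, "r-", lw=1.5)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("extension (nm)")
        return ax


def step_slices(L: int, n: int) -> list[slice]:
    """0-based bp slices of the kinetic steps: step i covers bps
    n(i-1)+1 .. min(n*i, L) (1-based); the last step may be partial."""
    return [slice(lo, min(lo + n, L)) for lo in range(0, L, n)]


def pause_time_mean(
    i: int, config: SimulationConfig, profile: DuplexEnergyProfile
) -> float:
    """Mean pause duration of kinetic step ``i`` (1-based), in seconds."""
    if config.prefactor_s is None:
        raise ValueError("prefactor not set; calibrate or supply prefactor_s")
    slices = step_slices(len(profile), config.n)
    if not 1 <= i <= len(slices):
        raise IndexError(f"kinetic step {i} outside 1..{len(slices)}")
    g = profile.g1bp[slices[i - 1]]
    A = config.prefactor_s
    if config.model == "simultaneous":
        return A * float(np.exp(np.sum(g)))
    return A * float(np.sum(np.exp(g)))


def _pause_means(config: SimulationConfig, profile: DuplexEnergyProfile) -> np.ndarray:
    slices = step_slices(len(profile), config.n)
    A = config.prefactor_s
    if config.model == "simultaneous":
        return np.array([A * np.exp(np.sum(profile.g1bp[s])) for s in slices])
    return np.array([A * np.sum(np.exp(profile.g1bp[s])) for s in slices])


def expected_total_time(config: SimulationConfig, profile: DuplexEnergyProfile) -> float:
    """Closed-form expected trajectory duration: sum of mean pauses plus the
    (deterministic) translocation delays."""
    return float(np.sum(_pause_means(config, profile))) + len(profile) / config.v_trans


def calibrate_prefactor(
    substrate: HairpinSubstrate | ForkSubstrate,
    config: SimulationConfig,
    profile: DuplexEnergyProfile | None = None,
    conditions: IonicConditions = IonicConditions(),
) -> SimulationConfig:
    """Set A_RecQ so the expected mean unwinding rate equals the target.

    The expected trajectory duration is linear in A (both models), so the
    root of ``L / E[T](A) - target`` is found directly; the result is checked
    to reproduce the target within 0.5%.
    """
    if profile is None:
        profile = compute_bp_energies(substrate, conditions)
    L = len(profile)
    target = config.target_mean_rate
    if target <= 0:
        raise ValueError("target_mean_rate must be positive")
    t_trans = L / config.v_trans
    pause_budget = L / target - t_trans
    if pause_budget <= 0:
        raise ValueError(
            f"target rate {target} bp/s exceeds the translocation-limited bound "
            f"{config.v_trans} bp/s"
        )
    unit = replace(config, prefactor_s=1.0)
    per_unit_pause = float(np.sum(_pause_means(unit, profile)))
    A = pause_budget / per_unit_pause
    out = replace(config, prefactor_s=A)
    achieved = L / expected_total_time(out, profile)
    if abs(achieved - target) / target > 5e-3:
        raise RuntimeError("calibration failed to reach the target rate within 0.5%")
    return out


def _draw_pauses(
    means: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    if config.pause_draw == "deterministic":
        return means.copy()
    return rng.exponential(means)


def _assemble(
    substrate, config: SimulationConfig, bp_per_step: np.ndarray,
    pauses: np.ndarray, trans: np.ndarray,
) -> Trajectory:
    starts = np.concatenate([[0.0], np.cumsum(pauses + trans)[:-1]])
    completions = np.cumsum(pauses + trans)
    cumbp = np.cumsum(bp_per_step)
    if config.half_step:
        # two sub-releases per kinetic step, halfway through and at the end of
        # the translocation delay
        t_half = starts + pauses + trans / 2.0
        half_bp = bp_per_step / 2.0
        times = np.empty(2 * len(completions))
        pos = np.empty_like(times)
        times[0::2], times[1::2] = t_half, completions
        pos[1::2] = cumbp
        pos[0::2] = cumbp - half_bp
    else:
        times, pos = completions, cumbp
    return Trajectory(
        substrate=substrate, event_times=times, event_positions=pos,
        step_start=starts, pause_s=pauses, trans_s=trans,
        bp_covered=bp_per_step.astype(float), config=config,
    )


def simulate_trajectory(
    substrate: HairpinSubstrate | ForkSubstrate,
    config: SimulationConfig,
    profile: DuplexEnergyProfile | None = None,
    seed: int | np.random.Generator = 0,
    conditions: IonicConditions = IonicConditions(),
) -> Trajectory:
    """Simulate one full unwinding trajectory (terminates at position L)."""
    if profile is None:
        profile = compute_bp_energies(substrate, conditions)
    if config.prefactor_s is None:
        config = calibrate_prefactor(substrate, config, profile)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    means = _pause_means(config, profile)
    slices = step_slices(len(profile), config.n)
    bp_per_step = np.array([s.stop - s.start for s in slices])
    pauses = _draw_pauses(means, config, rng)
    trans = bp_per_step / config.v_trans
    return _assemble(substrate, config, bp_per_step, pauses, trans)


def simulate_atpgs_trajectory(
    substrate: HairpinSubstrate | ForkSubstrate,
    config: SimulationConfig,
    profile: DuplexEnergyProfile | None = None,
    atp_mM: float = 0.5,
    atpgs_mM: float = 0.5,
    k_ratio: float = 1.2,
    k_off_per_s: float = 2.5,
    C: float = 1.0,
    seed: int | np.random.Generator = 0,
    conditions: IonicConditions = IonicConditions(),
) -> Trajectory:
    """Unwinding with competitive binding of a slowly-released ATP analog.

    Each kinetic step involves ``m = C * n`` nucleotide-binding events (m must
    be a positive integer); each is the analog with probability P (competition
    of on-rates at the given concentrations) and then appends an exponential
    dwell of mean 1/k_off to the step's pause.  With no analog present this
    reduces exactly to :func:`simulate_trajectory`.
    """
    if atp_mM < 0 or atpgs_mM < 0:
        raise ValueError("concentrations must be non-negative")
    m_float = C * config.n
    m = int(round(m_float))
    if m < 1 or abs(m - m_float) > 1e-9:
        raise ValueError(f"C={C} with n={config.n} gives non-integer ATP count per step")
    if atpgs_mM == 0:
        return simulate_trajectory(substrate, config, profile, seed, conditions)
    if profile is None:
        profile = compute_bp_energies(substrate, conditions)
    if config.prefactor_s is None:
        config = calibrate_prefactor(substrate, config, profile)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    P = mechchem.binding_prob(atp_mM, atpgs_mM, k_ratio)
    means = _pause_means(config, profile)
    slices = step_slices(len(profile), config.n)
    bp_per_step = np.array([s.stop - s.start for s in slices])
    pauses = _draw_pauses(means, config, rng)
    n_bound = rng.binomial(m, P, size=len(pauses))
    extra = np.array(
        [rng.exponential(1.0 / k_off_per_s, size=k).sum() if k else 0.0 for k in n_bound]
    )
    trans = bp_per_step / config.v_trans
    return _assemble(substrate, config, bp_per_step, pauses + extra, trans)


def render_measurement(
    traj: Trajectory,
    meas_config: MeasurementConfig = MeasurementConfig(),
    seed: int | np.random.Generator = 0,
    pad_s: float = 1.0,
) -> MeasuredTrace:
    """Render a trajectory as a uniformly sampled noisy extension trace.

    ``pad_s`` seconds of post-completion hold are appended, mimicking the
    recording continuing after the substrate is fully open.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = 1.0 / meas_config.sampling_hz
    t_end = traj.total_time + pad_s
    t = np.arange(0.0, t_end, dt)
    clean = meas_config.nm_per_bp * traj.position_at(t)
    noise = (
        rng.normal(0.0, meas_config.noise_sigma_nm, size=len(t))
        if meas_config.noise_sigma_nm > 0
        else 0.0
    )
    return MeasuredTrace(
        time_s=t, extension_nm=clean + noise, meas_config=meas_config, trajectory=traj
    )


def generate_trace_set(
    substrate: HairpinSubstrate | ForkSubstrate,
    sim_config: SimulationConfig,
    meas_config: MeasurementConfig = MeasurementConfig(),
    n_traces: int = 100,
    seed: int = 0,
    atpgs: dict | None = None,
    conditions: IonicConditions = IonicConditions(),
) -> list[MeasuredTrace]:
    """Simulate and render a reproducible set of traces.

    Each trace carries its ground-truth :class:`Trajectory`.  ``atpgs``, if
    given, is a dict of keyword arguments for
    :func:`simulate_atpgs_trajectory` (atp_mM, atpgs_mM, k_ratio,
    k_off_per_s, C).
    """
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    profile = compute_bp_energies(substrate, conditions)
    if sim_config.prefactor_s is None:
        sim_config = calibrate_prefactor(substrate, sim_config, profile)
    traces = []
    for child in np.random.SeedSequence(seed).spawn(n_traces):
        rng = np.random.default_rng(child)
        if atpgs:
            traj = simulate_atpgs_trajectory(
                substrate, sim_config, profile, seed=rng, **atpgs
            )
        else:
            traj = simulate_trajectory(substrate, sim_config, profile, seed=rng)
        traces.append(render_measurement(traj, meas_config, seed=rng))
    return traces
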