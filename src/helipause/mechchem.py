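"""Mechano-chemical coupling via nucleotide-analog competition.

When ATP and a slowly-released, essentially non-hydrolysable analog (ATPgS)
compete for the nucleotide pocket at fixed total concentration, each binding
event is the analog with probability

    P = [ATPgS] / (k_ratio * [ATP] + [ATPgS]),        k_ratio = k_ATP/k_ATPgS.

With m binding events per n-bp kinetic step (coupling ratio C = m/n bp/ATP),
the number bound per step is Binomial(m, P) with mean l = m*P, and the mean
pause per kinetic step and mean unwinding rate are

    tau = l / k_off + 1 / k_step,        v = n / tau,

where 1/k_off is the analog release time and k_step the analog-free stepping
rate.  Globally fitting tau and v across analog fractions recovers C and
k_ratio.

Identifiability note: tau and v depend on m and k_off only through m/k_off,
so a joint fit with both free sits on an exact ridge.  The release rate k_off
is an independently measurable quantity (the pause-escape rate at high analog
fraction); :meth:`CouplingModel.fit` therefore takes it as an input by
default, and the all-free mode reports the ridge through its covariance.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import lmfit

__all__ = [
    "CouplingParams",
    "CouplingDataset",
    "CouplingModel",
    "CouplingResults",
    "binding_prob",
    "expected_bound",
    "binomial_mean_enumeration",
    "pause_and_rate",
    "fit_coupling",
    "make_coupling_dataset",
    "occupancy_simulation",
    "PAPER_ATPGS_HYDROLYSIS_BOUND",
]

#: Upper bound on the analog hydrolysis rate (1/s) used for the
#: hydrolysis-neglect validity check.
PAPER_ATPGS_HYDROLYSIS_BOUND = 0.2


@dataclass(frozen=True)
class CouplingParams:
    """Mechano-chemical coupling parameter set."""

    m: int = 5  # ATP binding events per kinetic step
    n: int = 5  # bp per kinetic step
    k_ratio: float = 1.2  # k_ATP / k_ATPgS on-rate ratio
    k_off: float = 2.5  # analog release rate, 1/s (1/k_off = 0.4 s)
    k_step: float = 9.2  # analog-free kinetic stepping rate, 1/s

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise ValueError("m and n must be positive integers")
        for f in ("k_ratio", "k_off", "k_step"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")

    @property
    def C(self) -> float:
        """Coupling ratio, bp advanced per ATP consumed."""
        return self.m / self.n


@dataclass(frozen=True)
class CouplingDataset:
    """Mean pause duration and unwinding rate versus analog fraction."""

    atp_mM: np.ndarray
    atpgs_mM: np.ndarray
    tau_s: np.ndarray
    rate_bp_s: np.ndarray
    tau_se: np.ndarray
    rate_se: np.ndarray
    k_off_measured: float | None = None  # independent pause-escape rate, 1/s
    k_off_measured_se: float | None = None

    def __post_init__(self) -> None:
        arrays = {
            f: np.asarray(getattr(self, f), dtype=float)
            for f in ("atp_mM", "atpgs_mM", "tau_s", "rate_bp_s", "tau_se", "rate_se")
        }
        for f, a in arrays.items():
            object.__setattr__(self, f, a)
        n = len(arrays["atp_mM"])
        if any(len(a) != n for a in arrays.values()):
            raise ValueError("all dataset columns must have equal length")
        if np.any(arrays["tau_s"] <= 0) or np.any(arrays["rate_bp_s"] <= 0):
            raise ValueError("tau and v must be positive")

    @property
    def fractions(self) -> np.ndarray:
        total = self.atp_mM + self.atpgs_mM
        return self.atpgs_mM / total

    def __len__(self) -> int:
        return len(self.atp_mM)


def binding_prob(atp_mM: float, atpgs_mM: float, k_ratio: float) -> float:
    """Probability that a binding event is the analog rather than ATP."""
    atp = np.asarray(atp_mM, dtype=float)
    gs = np.asarray(atpgs_mM, dtype=float)
    if np.any(atp < 0) or np.any(gs < 0):
        raise ValueError("concentrations must be non-negative")
    denom = k_ratio * atp + gs
    if np.any(denom == 0):
        raise ValueError("at least one nucleotide concentration must be positive")
    out = gs / denom
    return float(out) if out.ndim == 0 else out


def expected_bound(m: int, P: float) -> float:
    """Mean number of analog molecules bound per kinetic step: l = m*P."""
    if m < 0:
        raise ValueError("m must be non-negative")
    if not 0.0 <= P <= 1.0:
        raise ValueError("P must lie in [0, 1]")
    return m * P


def binomial_mean_enumeration(m: int, P: float) -> float:
    """Explicit binomial-mean sum; equals :func:`expected_bound` identically."""
    return sum(i * comb(m, i) * P**i * (1 - P) ** (m - i) for i in range(m + 1))


def pause_and_rate(P: float, params: CouplingParams) -> tuple[float, float]:
    """Mean pause per kinetic step (s) and mean unwinding rate (bp/s)."""
    l = expected_bound(params.m, P)
    tau = l / params.k_off + 1.0 / params.k_step
    return tau, params.n / tau


def make_coupling_dataset(
    params: CouplingParams = CouplingParams(),
    fractions: np.ndarray = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5),
    total_mM: float = 1.0,
    noise_frac: float = 0.05,
    seed: int = 0,
) -> CouplingDataset:
    """Synthetic tau/v measurements across analog fractions.

    Evaluates the coupling equations at each fraction of the fixed total
    nucleotide concentration and applies multiplicative Gaussian noise of
    relative size ``noise_frac``; the independent release-rate measurement
    carries the same relative noise.
    """
    rng = np.random.default_rng(seed)
    fr = np.asarray(fractions, dtype=float)
    gs = fr * total_mM
    atp = total_mM - gs
    tau = np.empty_like(fr)
    v = np.empty_like(fr)
    for j, (a, g) in enumerate(zip(atp, gs)):
        P = binding_prob(a, g, params.k_ratio)
        tau[j], v[j] = pause_and_rate(P, params)
    tau_obs = tau * (1.0 + noise_frac * rng.standard_normal(len(fr)))
    v_obs = v * (1.0 + noise_frac * rng.standard_normal(len(fr)))
    k_off_obs = params.k_off * (1.0 + noise_frac * rng.standard_normal())
    return CouplingDataset(
        atp_mM=atp, atpgs_mM=gs, tau_s=tau_obs, rate_bp_s=v_obs,
        tau_se=noise_frac * tau, rate_se=noise_frac * v,
        k_off_measured=float(k_off_obs), k_off_measured_se=noise_frac * params.k_off,
    )


class CouplingModel:
    """Global model of mean pause duration and unwinding rate vs analog dose.

    Parameters
    ----------
    dataset : CouplingDataset
        tau/v observations with standard errors across analog fractions.
    n : int
        Kinetic step size in bp, fixed from step-size analysis.

    Examples
    --------
    >>> data = make_coupling_dataset(seed=2)
    >>> res = CouplingModel(data, n=5).fit()
    >>> abs(res.C - 1.0) < 0.2
    True
    """

    def __init__(self, dataset: CouplingDataset, n: int = 5):
        if len(dataset) < 4:
            raise ValueError("need >= 4 concentration points for a meaningful fit")
        if len(np.unique(dataset.fractions)) < 2:
            raise ValueError("non-identifiable: a single analog fraction")
        self.dataset = dataset
        self.n = int(n)

    def _residual(self, p: lmfit.Parameters) -> np.ndarray:
        d = self.dataset
        # zero SEs (noise-free data) degrade gracefully to unit weights
        tau_se = np.where(d.tau_se > 0, d.tau_se, 1.0)
        rate_se = np.where(d.rate_se > 0, d.rate_se, 1.0)
        P = binding_prob(d.atp_mM, d.atpgs_mM, p["k_ratio"].value)
        tau = p["m"].value * P / p["k_off"].value + 1.0 / p["k_step"].value
        v = self.n / tau
        return np.concatenate(
            [(tau - d.tau_s) / tau_se, (v - d.rate_bp_s) / rate_se]
        )

    def fit(self, k_off: float | None = None) -> "CouplingResults":
        """Weighted joint least squares over tau and v.

        ``k_off`` fixes the analog release rate; when omitted, the dataset's
        independent measurement is used.  Passing ``k_off=float('nan')``
        requests the (ridge-degenerate) all-free fit.
        """
        d = self.dataset
        free_k_off = k_off is not None and np.isnan(k_off)
        if k_off is None or free_k_off:
            if d.k_off_measured is not None:
                k_off = d.k_off_measured
            elif free_k_off:
                k_off = 1.0  # starting guess only; the parameter is free
            else:
                raise ValueError(
                    "no k_off supplied and the dataset carries no independent "
                    "release-rate measurement"
                )
        params = lmfit.Parameters()
        params.add("m", value=float(self.n), min=1e-3)
        params.add("k_ratio", value=1.0, min=1e-3)
        params.add("k_step", value=float(np.max(d.rate_bp_s)) / self.n, min=1e-3)
        params.add("k_off", value=float(k_off), min=1e-3, vary=free_k_off)
        out = lmfit.minimize(self._residual, params, method="leastsq")
        return CouplingResults(self, out, k_off_fixed=None if free_k_off else float(k_off))


class CouplingResults:
    """Fit results: recovered coupling parameters with standard errors."""

    def __init__(self, model: CouplingModel, minimizer_result, k_off_fixed: float | None):
        self.model = model
        self.mle = minimizer_result
        self.k_off_fixed = k_off_fixed
        p = minimizer_result.params
        self.m = p["m"].value
        self.m_rounded = int(round(self.m))
        self.k_ratio = p["k_ratio"].value
        self.k_step = p["k_step"].value
        self.k_off = p["k_off"].value
        self.bse = {
            name: (p[name].stderr if p[name].stderr is not None else np.nan)
            for name in ("m", "k_ratio", "k_step", "k_off")
        }
        self.redchi = minimizer_result.redchi
        self.converged = bool(minimizer_result.success)

    @property
    def C(self) -> float:
        """Coupling ratio m/n, bp per ATP (unrounded)."""
        return self.m / self.model.n

    @property
    def C_rounded(self) -> float:
        return self.m_rounded / self.model.n

    @property
    def C_se(self) -> float:
        return self.bse["m"] / self.model.n

    @property
    def params(self) -> CouplingParams:
        return CouplingParams(
            m=max(self.m_rounded, 1), n=self.model.n,
            k_ratio=self.k_ratio, k_off=self.k_off, k_step=self.k_step,
        )

    @property
    def hydrolysis_negligible(self) -> bool:
        """True when the analog hydrolysis bound is well below fitted k_off,
        validating the no-hydrolysis simplification."""
        return PAPER_ATPGS_HYDROLYSIS_BOUND < 0.2 * self.k_off

    def predict(self, atp_mM, atpgs_mM) -> tuple[np.ndarray, np.ndarray]:
        P = binding_prob(np.asarray(atp_mM), np.asarray(atpgs_mM), self.k_ratio)
        tau = self.m * P / self.k_off + 1.0 / self.k_step
        return tau, self.model.n / tau

    def plot(self, ax=None):
        """Measured and fitted tau and v versus analog fraction."""
        import matplotlib.pyplot as plt

        d = self.model.dataset
        if ax is None:
            _, ax = plt.subplots()
        fr = d.fractions
        tau_fit, v_fit = self.predict(d.atp_mM, d.atpgs_mM)
        ax.errorbar(fr, d.tau_s, yerr=d.tau_se, fmt="^", color="g", label="pause (s)")
        ax.plot(fr, tau_fit, "g-")
        ax2 = ax.twinx()
        ax2.errorbar(fr, d.rate_bp_s, yerr=d.rate_se, fmt="o", color="r", label="rate (bp/s)")
        ax2.plot(fr, v_fit, "r-")
        ax.set_xlabel("ATPgS fraction")
        ax.set_ylabel("mean pause per kinetic step (s)")
        ax2.set_ylabel("mean unwinding rate (bp/s)")
        return ax

    def summary(self) -> str:
        lines = [
            "Mechano-chemical coupling fit",
            "=" * 46,
            f"observations (tau, v pairs): {len(self.model.dataset)}",
            f"kinetic step size n (fixed): {self.model.n} bp",
            f"k_off ({'fixed' if self.k_off_fixed is not None else 'fitted'}):"
            f" {self.k_off:.3f} 1/s",
            "-" * 46,
            f"C = m/n          {self.C:8.3f} +/- {self.C_se:.3f} bp/ATP"
            f"   (m rounded: {self.m_rounded})",
            f"k_ATP/k_ATPgS    {self.k_ratio:8.3f} +/- {self.bse['k_ratio']:.3f}",
            f"k_step           {self.k_step:8.3f} +/- {self.bse['k_step']:.3f} 1/s",
            f"reduced chi2     {self.redchi:8.3f}",
            f"hydrolysis negligible: {self.hydrolysis_negligible}",
        ]
        return "\n".join(lines)


def fit_coupling(
    dataset: CouplingDataset, n_fixed: int = 5, k_off: float | None = None
) -> CouplingResults:
    """Functional wrapper around :class:`CouplingModel`."""
    return CouplingModel(dataset, n=n_fixed).fit(k_off=k_off)


def occupancy_simulation(
    atp_mM: float,
    atpgs_mM: float,
    k_ratio: float = 1.2,
    n_bp: int = 100_000,
    seed: int = 0,
) -> float:
    """Mean analog incorporations per base pair at coupling C = 1.

    Each base pair consumes one nucleotide-binding event; the event is the
    analog with probability P.  The mean over ``n_bp`` events converges to P,
    so repeated analog binding at the same site is rare whenever P < 1.
    """
    if n_bp < 1:
        raise ValueError("n_bp must be positive")
    if atpgs_mM == 0:
        return 0.0
    P = binding_prob(atp_mM, atpgs_mM, k_ratio)
    rng = np.random.default_rng(seed)
    return float(np.mean(rng.random(n_bp) < P))
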