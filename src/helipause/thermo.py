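"""Nearest-neighbor duplex energetics and stability profiles.

The per-base-pair opening free energy G_1bp(j) (in units of kBT, positive =
cost to melt) is computed from the unified oligonucleotide nearest-neighbor
parameter set (dinucleotide stack enthalpies/entropies) with a per-stack
monovalent-salt entropy correction of the form +0.368*ln[Mon+] cal/(mol K).
Each interior base pair is assigned the mean of its two flanking stack
energies; terminal base pairs use their single available stack.  Divalent
Mg2+ is folded into an equivalent monovalent concentration
[Mon+] = [Na+] + 3.3*sqrt([Mg2+]) (concentrations in M), a standard
approximation in the absence of an explicit divalent treatment.

The position-resolved stability profile used for pause prediction is the
running mean over a w-bp window of exp(G_1bp) — exponentiate first, then
average, so the profile is a Boltzmann-weighted dwell propensity rather than
an averaged energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import lmfit

from .substrates import HairpinSubstrate, ForkSubstrate

__all__ = [
    "IonicConditions",
    "DuplexEnergyProfile",
    "StabilityProfile",
    "PeakSet",
    "compute_bp_energies",
    "stability_profile",
    "fit_gaussian_peaks",
    "KBT_PN_NM",
]

#: kB*T at 25 C in pN nm (assay temperature fixed at 25 C).
KBT_PN_NM = 4.11

#: Gas constant in kcal/(mol K).
_R_KCAL = 1.98720425864083e-3

# Unified oligonucleotide NN parameters: 5'->3' dinucleotide on the tracking
# strand -> (dH kcal/mol, dS cal/(mol K)) of duplex formation at 1 M NaCl.
_NN_DH_DS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
for _k in list(_NN_DH_DS):
    _rc = _k.translate(_COMPLEMENT)[::-1]
    _NN_DH_DS.setdefault(_rc, _NN_DH_DS[_k])

#: Per-stack salt entropy correction, cal/(mol K) per ln[Mon+].
_SALT_DS = 0.368

#: Equivalent-monovalent weight for Mg2+ (per sqrt molar).
_MG_EQUIV = 3.3


@dataclass(frozen=True)
class IonicConditions:
    """Ionic strength and temperature of the assay buffer."""

    na_mM: float = 50.0
    mg_mM: float = 5.0
    temperature_C: float = 25.0

    def __post_init__(self) -> None:
        if self.na_mM < 0 or self.mg_mM < 0:
            raise ValueError("concentrations must be non-negative")
        if not 0.0 <= self.temperature_C <= 100.0:
            raise ValueError("temperature outside 0-100 C")

    @property
    def temperature_K(self) -> float:
        return self.temperature_C + 273.15

    @property
    def monovalent_equivalent_M(self) -> float:
        """[Na+] plus the Mg2+ equivalent, in molar."""
        eq = self.na_mM / 1e3 + _MG_EQUIV * np.sqrt(self.mg_mM / 1e3)
        if eq <= 0:
            raise ValueError("zero ionic strength is outside the model's validity")
        return eq


@dataclass(frozen=True)
class DuplexEnergyProfile:
    """Per-position base-pair opening free energies, in kBT."""

    substrate: HairpinSubstrate | ForkSubstrate
    g1bp: np.ndarray
    conditions: IonicConditions

    def __post_init__(self) -> None:
        g = np.asarray(self.g1bp, dtype=float)
        object.__setattr__(self, "g1bp", g)
        if not np.all(np.isfinite(g)):
            raise ValueError("non-finite base-pair energy")

    def __len__(self) -> int:
        return len(self.g1bp)


@dataclass(frozen=True)
class StabilityProfile:
    """Running mean of exp(G_1bp) over a w-bp window.

    ``positions[k]`` is the 1-based bp position at which the window value is
    reported: the window covering bps ``[j, j + w - 1]`` is reported at
    ``j + w//2``.
    """

    positions: np.ndarray
    values: np.ndarray
    window_bp: int

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.values) <= 0):
            raise ValueError("stability values must be positive")


@dataclass(frozen=True)
class PeakSet:
    """Gaussian peak decomposition of a positive 1-D profile."""

    centers: np.ndarray
    widths: np.ndarray
    amplitudes: np.ndarray
    center_errors: np.ndarray
    baseline: float
    reduced_chi2: float
    converged: bool = True
    n_components: int = field(init=False)

    def __post_init__(self) -> None:
        order = np.argsort(np.asarray(self.centers, dtype=float))
        for name in ("centers", "widths", "amplitudes", "center_errors"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float)[order])
        object.__setattr__(self, "n_components", len(self.centers))


def _stack_g_open_kbt(stack: str, conditions: IonicConditions) -> float:
    """Opening free energy of one NN stack in kBT (positive for stable stacks)."""
    dh, ds = _NN_DH_DS[stack]
    t = conditions.temperature_K
    ds_corr = ds + _SALT_DS * np.log(conditions.monovalent_equivalent_M)
    dg_form = dh - t * ds_corr / 1e3  # kcal/mol, negative = stable
    rt = _R_KCAL * t
    return -dg_form / rt


def compute_bp_energies(
    substrate: HairpinSubstrate | ForkSubstrate,
    conditions: IonicConditions = IonicConditions(),
    mismatch_energy: float = 0.0,
) -> DuplexEnergyProfile:
    """Per-base-pair melting free energies G_1bp(j), j = 1..L, in kBT.

    Interior base pairs get the mean of their two flanking stack energies;
    the terminal base pairs use the single available stack.  Positions
    annotated as displaced-strand mismatches are overridden with
    ``mismatch_energy`` (default 0: a broken pair is free to open).
    """
    seq = (
        substrate.stem_sequence
        if isinstance(substrate, HairpinSubstrate)
        else substrate.duplex_sequence
    )
    L = len(seq)
    stacks = np.array(
        [_stack_g_open_kbt(seq[i : i + 2], conditions) for i in range(L - 1)]
    )
    g = np.empty(L)
    if L == 1:
        raise ValueError("substrate too short for nearest-neighbor energetics")
    g[0] = stacks[0]
    g[-1] = stacks[-1]
    g[1:-1] = 0.5 * (stacks[:-1] + stacks[1:])
    mm = getattr(substrate, "mismatch_positions", ())
    for p in mm:
        g[p - 1] = mismatch_energy
    return DuplexEnergyProfile(substrate=substrate, g1bp=g, conditions=conditions)


def stability_profile(profile: DuplexEnergyProfile, window_bp: int = 6) -> StabilityProfile:
    """Running w-bp mean of exp(G_1bp) (exponentiate, then average)."""
    w = int(window_bp)
    L = len(profile)
    if w < 1:
        raise ValueError("window must be >= 1")
    if w > L:
        raise ValueError(f"window ({w}) exceeds profile length ({L})")
    expg = np.exp(profile.g1bp)
    vals = np.convolve(expg, np.ones(w) / w, mode="valid")
    positions = np.arange(1, L - w + 2) + w // 2
    return StabilityProfile(positions=positions, values=vals, window_bp=w)


def _sum_of_gaussians(x: np.ndarray, params: lmfit.Parameters, k: int) -> np.ndarray:
    y = np.full_like(x, params["c0"].value, dtype=float)
    for j in range(k):
        a = params[f"a{j}"].value
        mu = params[f"mu{j}"].value
        s = params[f"s{j}"].value
        y = y + a * np.exp(-0.5 * ((x - mu) / s) ** 2)
    return y


def fit_gaussian_peaks(
    x: np.ndarray,
    y: np.ndarray,
    max_components: int = 6,
    min_prominence: float = 0.05,
) -> PeakSet:
    """Fit a sum of Gaussians plus a constant baseline to a positive profile.

    The component count is selected by BIC over 0..max_components components;
    candidate centers are seeded at the largest residual maxima.  Components
    whose amplitude falls below ``min_prominence`` times the data range are
    not counted as peaks (a flat profile therefore returns zero components).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    if np.any(y < 0):
        raise ValueError("y must be non-negative")
    n = len(x)
    span = x[-1] - x[0]
    yrange = float(np.ptp(y))

    best = None
    best_bic = np.inf
    # k = 0: baseline only
    resid0 = y - np.mean(y)
    rss0 = float(np.sum(resid0**2))
    best_bic = n * np.log(max(rss0, 1e-300) / n) + 1 * np.log(n)
    best = (0, None, rss0)

    residual = resid0.copy()
    seeds: list[float] = []
    for k in range(1, max_components + 1):
        seeds.append(float(x[np.argmax(residual)]))
        params = lmfit.Parameters()
        params.add("c0", value=float(np.min(y)))
        for j, mu in enumerate(seeds):
            params.add(f"a{j}", value=max(yrange, 1e-12), min=0)
            params.add(f"mu{j}", value=mu, min=x[0], max=x[-1])
            params.add(f"s{j}", value=max(span / 20.0, 1e-6), min=span / n, max=span)

        def _resid(p, k=k):
            return y - _sum_of_gaussians(x, p, k)

        try:
            out = lmfit.minimize(_resid, params, method="leastsq")
        except Exception:
            continue
        rss = float(np.sum(out.residual**2))
        nparam = 1 + 3 * k
        bic = n * np.log(max(rss, 1e-300) / n) + nparam * np.log(n)
        residual = y - _sum_of_gaussians(x, out.params, k)
        if bic < best_bic - 1e-9:
            best_bic = bic
            best = (k, out, rss)

    k, out, rss = best
    if k == 0 or out is None:
        return PeakSet(
            centers=np.empty(0), widths=np.empty(0), amplitudes=np.empty(0),
            center_errors=np.empty(0), baseline=float(np.mean(y)),
            reduced_chi2=rss / max(n - 1, 1), converged=True,
        )
    amp = np.array([out.params[f"a{j}"].value for j in range(k)])
    keep = amp >= min_prominence * max(yrange, 1e-300)
    centers = np.array([out.params[f"mu{j}"].value for j in range(k)])[keep]
    widths = np.array([out.params[f"s{j}"].value for j in range(k)])[keep]
    errs = np.array(
        [out.params[f"mu{j}"].stderr or np.nan for j in range(k)]
    )[keep]
    dof = max(n - (1 + 3 * k), 1)
    return PeakSet(
        centers=centers, widths=widths, amplitudes=amp[keep], center_errors=errs,
        baseline=float(out.params["c0"].value), reduced_chi2=rss / dof,
        converged=bool(getattr(out, "success", True)),
    )
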