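"""Promoter-melting thermodynamics under supercoiling and the resulting initiation rate laws.

The transcription initiation rate of a promoter on a supercoiled template is
modelled in two layers:

1. A statistical-mechanical (Benham-type) model of DNA strand separation in a
   circular domain of ``N`` base pairs.  A microstate has ``n`` melted base
   pairs arranged in ``n_j / 2`` bubbles (``n_j`` helix/coil junctions) and
   free energy

   ``G = n (eps - T dS) + (n_j/2) eps_o + G_s(n, sigma) +/- k_B T ln g(n, n_j)``

   where ``G_s`` is the torsional/bending energy of the residual superhelical
   stress and ``g`` is the number of ways of placing the bubbles on the ring.
   From the Boltzmann distribution over these microstates one obtains the free
   energy barrier ``dG(sigma)`` for melting the ``Np``-bp promoter, its shift
   ``ddG(sigma) = dG(sigma) - dG(0)`` and, via transition-state theory, a
   rate factor ``k(sigma) = k0 exp(-ddG/k_B T)``.

2. A Michaelis-Menten rate law for initiation where the supercoiling density
   only modulates the open-complex collapse rate ``k_off``:
   ``V(sigma) = k_on / (k' exp(w sigma) + 1)`` with ``k' = k_off(0)/k_cat``,
   together with its first-order (linear in sigma) approximation.

Sign conventions.  For positive supercoiling density the residual-stress term
``(n/N + sigma)^2`` grows when additional base pairs melt, so melting is
*suppressed*, the promoter barrier rises (``ddG > 0``) and the initiation
rate decays -- the behaviour seen when positive supercoils accumulate during
transcription.  The barrier shift is close to linear in sigma only while
``sigma`` is small compared with the turnover point
``sigma* = (Np/N) / ((alpha - 1) Np/N)`` of the dominant quadratic term;
the default fit grid therefore spans [0, 0.02] (about sigma*/2 for the
default geometry).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp

__all__ = [
    "K_B",
    "ThermoParams",
    "InitiationKinetics",
    "supercoil_energy",
    "log_degeneracy",
    "state_free_energy",
    "melt_number_distribution",
    "promoter_barrier",
    "barrier_shift",
    "rate_factor",
    "fit_exponential_w",
    "production_rate_full",
    "production_rate_linear",
    "linear_stall_sigma",
    "fit_production_rate",
    "default_sigma_grid",
    "barrier_shift_curve",
    "production_rate_curve",
]

#: Boltzmann constant in kcal/(mol K) (molar gas constant in thermochemical kcal).
K_B = 1.987204259e-3

#: Default supercoiling-density grid for the exponential/linear approximations.
SIGMA_GRID_MAX = 0.02
SIGMA_GRID_POINTS = 25

_DEGENERACY_SIGNS = ("entropic", "as_printed")


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamic constants of the melting model.

    Defaults are the published parameter set for duplex DNA at room
    temperature on a 180-bp circular template with an 8-bp promoter.
    """

    epsilon: float = 7.9        #: base-pairing energy, kcal/mol
    delta_S: float = 0.024      #: conformational entropy per melted bp, kcal/(K mol)
    epsilon_o: float = 2.5      #: base-stacking (junction) energy, kcal/mol
    C: float = 1638.0           #: torsional/bending constant, kcal/(mol rad^2)
    alpha: float = 23.4         #: helical-repeat ratio (melted vs duplex), dimensionless
    A: float = 10.4             #: bp per rad^2 in the relaxed state
    N: int = 180                #: total bp in the circular domain
    Np: int = 8                 #: promoter length, bp
    T: float = 298.15           #: temperature, K
    k_B: float = K_B            #: Boltzmann constant, kcal/(mol K)

    def __post_init__(self) -> None:
        for name in ("epsilon", "delta_S", "epsilon_o", "C", "alpha", "A", "N", "Np", "T", "k_B"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ThermoParams.{name} must be strictly positive")
        if self.Np > self.N:
            raise ValueError("promoter length Np cannot exceed domain size N")
        if self.alpha <= 1:
            raise ValueError("alpha must exceed 1 (melted DNA has a longer helical repeat)")

    @property
    def kBT(self) -> float:
        return self.k_B * self.T

    @property
    def default_n_max(self) -> int:
        """Truncation of the melt number; the bubble-placement combinatorics and
        the binomial promoter-sampling argument both require n/N < 0.06."""
        return int(math.floor(0.06 * self.N))


@dataclass(frozen=True)
class InitiationKinetics:
    """Rate constants of the initiation rate law V(sigma) = k_on/(k' e^{w sigma} + 1).

    ``k_f`` (open -> elongation) is stored for completeness but drops out of
    the steady-state rate law.  ``k_prime`` is derived from ``k_off0/k_cat``
    when both are given.
    """

    k_on: float
    w: float
    k_off0: float | None = None
    k_cat: float | None = None
    k_f: float | None = None
    k_prime: float | None = None

    def __post_init__(self) -> None:
        for name in ("k_on", "w", "k_off0", "k_cat", "k_f", "k_prime"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"InitiationKinetics.{name} must be nonnegative")
        if self.k_prime is None:
            if self.k_off0 is None or self.k_cat is None:
                raise ValueError("either k_prime or both k_off0 and k_cat must be given")
            if self.k_cat == 0:
                raise ValueError("k_cat must be positive to derive k_prime")
            object.__setattr__(self, "k_prime", self.k_off0 / self.k_cat)
        elif self.k_off0 is not None and self.k_cat not in (None, 0):
            if not math.isclose(self.k_prime, self.k_off0 / self.k_cat, rel_tol=1e-9):
                raise ValueError("inconsistent k_prime vs k_off0/k_cat")


def supercoil_energy(n: int, sigma: float, params: ThermoParams) -> float:
    """Torsional/bending energy G_s(n, sigma) of the residual superhelical stress,
    kcal/mol, for ``n`` melted base pairs at supercoiling density ``sigma``."""
    if n < 0 or n > params.N:
        raise ValueError(f"melted bp count n={n} outside [0, N={params.N}]")
    frac = n / params.N
    return params.C * params.N * (frac + sigma) ** 2 / (params.A**2 * (1.0 + (params.alpha - 1.0) * frac))


def _validate_bubble_state(n: int, nj: int, N: int) -> None:
    if n < 1 or n > N - 1:
        raise ValueError(f"n={n} outside valid melted range [1, N-1]")
    if nj % 2 != 0 or nj < 2 or nj > 2 * min(n, N - n):
        raise ValueError(f"invalid junction count nj={nj} for n={n}, N={N}")


def log_degeneracy(n: int, nj: int, params: ThermoParams) -> float:
    """ln of the number of ways of arranging ``n`` melted bp in ``nj/2`` bubbles
    on the N-bp ring.  Evaluated with log-gamma so large N never overflows."""
    N = params.N
    _validate_bubble_state(n, nj, N)
    h = nj / 2.0
    return (
        math.log(N)
        + gammaln(N - n)        # (N-n-1)!
        + gammaln(n)            # (n-1)!
        - gammaln(N - n - h + 1.0)
        - gammaln(n - h + 1.0)
        - gammaln(h)            # (nj/2 - 1)!
        - gammaln(h + 1.0)      # (nj/2)!
    )


def state_free_energy(
    n: int,
    nj: int,
    sigma: float,
    params: ThermoParams,
    degeneracy_sign: str = "entropic",
) -> float:
    """Free energy G(n, nj, sigma) of a melting microstate, kcal/mol.

    With ``degeneracy_sign="entropic"`` (default) the placement entropy lowers
    the free energy, i.e. the Boltzmann weight is ``g exp(-E/kBT)``.
    ``"as_printed"`` uses the opposite sign for comparison.
    """
    if degeneracy_sign not in _DEGENERACY_SIGNS:
        raise ValueError(f"degeneracy_sign must be one of {_DEGENERACY_SIGNS}")
    if n == 0:
        if nj != 0:
            raise ValueError("the fully paired state n=0 has no junctions")
        return supercoil_energy(0, sigma, params)
    energy = (
        n * (params.epsilon - params.T * params.delta_S)
        + (nj / 2.0) * params.epsilon_o
        + supercoil_energy(n, sigma, params)
    )
    ln_g = log_degeneracy(n, nj, params)
    sign = -1.0 if degeneracy_sign == "entropic" else 1.0
    return energy + sign * params.kBT * ln_g


def _log_weight_by_n(
    sigma: float, params: ThermoParams, n_max: int, degeneracy_sign: str
) -> np.ndarray:
    """ln of the Boltzmann weight of each melt number n (junctions summed out)."""
    out = np.empty(n_max + 1)
    out[0] = -state_free_energy(0, 0, sigma, params, degeneracy_sign) / params.kBT
    for n in range(1, n_max + 1):
        njs = range(2, 2 * min(n, params.N - n) + 1, 2)
        logs = [
            -state_free_energy(n, nj, sigma, params, degeneracy_sign) / params.kBT
            for nj in njs
        ]
        out[n] = logsumexp(logs)
    return out


def melt_number_distribution(
    sigma: float,
    params: ThermoParams,
    n_max: int | None = None,
    degeneracy_sign: str = "entropic",
) -> np.ndarray:
    """Boltzmann probability P(n | sigma) of having n melted base pairs, for
    n = 0..n_max (default floor(0.06 N))."""
    if n_max is None:
        n_max = params.default_n_max
    if n_max < 0 or n_max >= params.N:
        raise ValueError(f"n_max={n_max} outside [0, N-1]")
    logw = _log_weight_by_n(sigma, params, n_max, degeneracy_sign)
    p = np.exp(logw - logsumexp(logw))
    return p / p.sum()


def promoter_barrier(
    sigma: float,
    params: ThermoParams,
    n_max: int | None = None,
    degeneracy_sign: str = "entropic",
) -> float:
    """Free-energy barrier dG(sigma), kcal/mol, for fully melting the Np-bp promoter.

    Averages, over the melt-number distribution and a binomial draw of how many
    of the Np promoter base pairs are already melted, the pairing energy of the
    remaining bp plus the change in superhelical-stress energy of extending the
    melt by those bp.
    """
    if n_max is None:
        n_max = params.default_n_max
    p_n = melt_number_distribution(sigma, params, n_max, degeneracy_sign)
    Np, N = params.Np, params.N
    k = np.arange(Np + 1)
    total = 0.0
    for n, pn in enumerate(p_n):
        if pn == 0.0:
            continue
        binom_pmf = stats.binom.pmf(k, Np, n / N)
        dGs = np.array(
            [supercoil_energy(n + Np - ki, sigma, params) - supercoil_energy(n, sigma, params) for ki in k]
        )
        total += pn * float(np.sum(binom_pmf * ((Np - k) * params.epsilon + dGs)))
    return total


def barrier_shift(
    sigma: float,
    params: ThermoParams,
    n_max: int | None = None,
    degeneracy_sign: str = "entropic",
) -> float:
    """Barrier shift ddG(sigma) = dG(sigma) - dG(0), kcal/mol.  Exactly 0 at sigma=0."""
    if sigma == 0.0:
        return 0.0
    return promoter_barrier(sigma, params, n_max, degeneracy_sign) - promoter_barrier(
        0.0, params, n_max, degeneracy_sign
    )


def rate_factor(
    sigma: float,
    params: ThermoParams,
    k0: float = 1.0,
    n_max: int | None = None,
    degeneracy_sign: str = "entropic",
) -> float:
    """Transition-state rate k(sigma) = k0 exp(-ddG(sigma)/kBT)."""
    return k0 * math.exp(-barrier_shift(sigma, params, n_max, degeneracy_sign) / params.kBT)


@dataclass(frozen=True)
class ExponentialWFit:
    """Through-origin fit of -ln(k/k0) = w sigma."""

    w: float
    r_squared: float
    residuals: np.ndarray = field(repr=False)


def fit_exponential_w(sigmas: Sequence[float], factors: Sequence[float]) -> ExponentialWFit:
    """Least-squares estimate of the supercoiling sensitivity w from rate factors
    k(sigma)/k0, assuming the single-exponential form k = e^{-w sigma}.

    The line is constrained through the origin because k(0)/k0 = 1 by
    construction.
    """
    sigmas = np.asarray(sigmas, dtype=float)
    factors = np.asarray(factors, dtype=float)
    if sigmas.size < 3:
        raise ValueError("need at least 3 points to fit w")
    if np.any(factors <= 0):
        raise ValueError("rate factors must be strictly positive")
    y = -np.log(factors)
    denom = float(np.sum(sigmas**2))
    if denom == 0.0:
        raise ValueError("sigma grid is degenerate (all zero)")
    w = float(np.sum(sigmas * y) / denom)
    resid = y - w * sigmas
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return ExponentialWFit(w=w, r_squared=r2, residuals=resid)


def production_rate_full(sigma, kin: InitiationKinetics):
    """mRNA production rate V(sigma) = k_on / (k' e^{w sigma} + 1).

    Strictly decreasing in sigma for w, k' > 0; accepts scalars or arrays.
    """
    sigma = np.asarray(sigma, dtype=float)
    with np.errstate(over="ignore"):  # exp overflow -> V = 0, the correct limit
        v = kin.k_on / (kin.k_prime * np.exp(kin.w * sigma) + 1.0)
    return float(v) if v.ndim == 0 else v


def production_rate_linear(sigma, kin: InitiationKinetics):
    """First-order approximation of the rate law, clipped at zero beyond its
    x-intercept so it can serve as a propensity."""
    sigma = np.asarray(sigma, dtype=float)
    kp = kin.k_prime
    v0 = kin.k_on / (kp + 1.0)
    slope = kin.k_on * kin.w * kp / (kp + 1.0) ** 2
    v = np.maximum(v0 - slope * sigma, 0.0)
    return float(v) if v.ndim == 0 else v


def linear_stall_sigma(kin: InitiationKinetics) -> float:
    """x-intercept of the linear rate law: the supercoiling density at which
    transcription stalls, sigma* = (k' + 1)/(w k')."""
    if kin.w == 0 or kin.k_prime == 0:
        return math.inf
    return (kin.k_prime + 1.0) / (kin.w * kin.k_prime)


@dataclass(frozen=True)
class RateCurveFit:
    """Fit of the rate law to per-event initiation rates (sigma = c * event number)."""

    model: str
    params: dict
    r_squared: float

    def predict(self, event_index) -> np.ndarray:
        j = np.asarray(event_index, dtype=float)
        p = self.params
        if self.model == "full":
            return p["k_on"] / (p["k_prime"] * np.exp(p["wc"] * j) + 1.0)
        return np.maximum(p["intercept"] + p["slope"] * j, 0.0)


def fit_production_rate(event_index, rates, model: str = "full") -> RateCurveFit:
    """Fit the full (3 free parameters: k_on, k', w*c) or linear rate law to
    initiation rates indexed by transcription event number.

    The supercoiling increment per transcription event is unknown, so sigma is
    absorbed into the event index: sigma = c * j, and only the product w*c is
    identifiable.
    """
    j = np.asarray(event_index, dtype=float)
    r = np.asarray(rates, dtype=float)
    if j.size != r.size or j.size < 3:
        raise ValueError("need matching event indices and rates, at least 3 points")
    if model == "full":

        def f(x, k_on, k_prime, wc):
            return k_on / (k_prime * np.exp(wc * x) + 1.0)

        r0 = max(r.max(), 1e-12)
        popt, _ = optimize.curve_fit(
            f, j, r, p0=[2.0 * r0, 1.0, 1.0 / max(j.max(), 1.0)],
            bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]), maxfev=20000,
        )
        pred = f(j, *popt)
        params = {"k_on": popt[0], "k_prime": popt[1], "wc": popt[2]}
    elif model == "linear":
        res = stats.linregress(j, r)
        pred = res.intercept + res.slope * j
        params = {"intercept": res.intercept, "slope": res.slope}
    else:
        raise ValueError("model must be 'full' or 'linear'")
    ss_res = float(np.sum((r - pred) ** 2))
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return RateCurveFit(model=model, params=params, r_squared=r2)


def default_sigma_grid() -> np.ndarray:
    """Grid on which the barrier shift is close to linear (sigma well below the
    turnover point of the quadratic stress term)."""
    return np.linspace(0.0, SIGMA_GRID_MAX, SIGMA_GRID_POINTS)


def barrier_shift_curve(
    params: ThermoParams,
    sigmas: np.ndarray | None = None,
    degeneracy_sign: str = "entropic",
) -> pd.DataFrame:
    """ddG(sigma) tabulated over a sigma grid (columns: sigma, ddG_kcal_mol)."""
    if sigmas is None:
        sigmas = default_sigma_grid()
    vals = [barrier_shift(s, params, degeneracy_sign=degeneracy_sign) for s in sigmas]
    return pd.DataFrame({"sigma": np.asarray(sigmas, float), "ddG_kcal_mol": vals})


def production_rate_curve(
    kin: InitiationKinetics,
    sigmas: np.ndarray | None = None,
    model: str = "full",
) -> pd.DataFrame:
    """V(sigma) tabulated over a sigma grid (columns: sigma, rate)."""
    if sigmas is None:
        sigmas = default_sigma_grid()
    f = production_rate_full if model == "full" else production_rate_linear
    return pd.DataFrame({"sigma": np.asarray(sigmas, float), "rate": f(np.asarray(sigmas, float), kin)})
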