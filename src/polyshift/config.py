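"""Scenario parameterization and the delta-unit system.

The trait is measured internally in units of ``delta = sqrt(V_S/(2N))``, the
typical equilibrium fluctuation of the population mean phenotype around the
optimum under stabilizing selection and drift.  In these units the width
parameter of the Gaussian fitness function is ``V_S = 2N`` and an allele of
magnitude ``a`` has population-scaled selection coefficient
``S = 2N*s_e = a**2``.  Stating results in delta units makes them invariant
to simultaneous changes of ``N`` and ``V_S`` that preserve ``V_S = 2N``.

Assumption checks warn rather than error so that regimes outside the theory's
domain of validity can still be explored; warnings are returned as a list and
also emitted through :mod:`warnings`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy import integrate

__all__ = [
    "DeltaUnits",
    "ModelParams",
    "EffectSizeDistribution",
    "make_lande_preset",
    "make_non_lande_preset",
    "validate_assumptions",
    "load_scenario",
    "scenario_from_dict",
]


@dataclass(frozen=True)
class DeltaUnits:
    """Conversion between raw trait units and delta units.

    ``delta`` is the raw-unit value of one delta, i.e. ``sqrt(V_S/(2N))``.
    """

    delta: float

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError("delta must be positive")

    def to_delta(self, z):
        """Raw trait value -> delta units."""
        return np.asarray(z) / self.delta if np.ndim(z) else z / self.delta

    def from_delta(self, z):
        """Delta-unit trait value -> raw units."""
        return np.asarray(z) * self.delta if np.ndim(z) else z * self.delta

    def effect_to_S(self, a):
        """Raw effect magnitude -> population-scaled coefficient S = a^2 (delta units)."""
        return (np.asarray(a) / self.delta) ** 2 if np.ndim(a) else (a / self.delta) ** 2

    def S_to_effect(self, S):
        """Population-scaled coefficient S -> raw effect magnitude."""
        return np.sqrt(S) * self.delta


@dataclass(frozen=True)
class ModelParams:
    """Full parameterization of one optimum-shift scenario.

    Parameters
    ----------
    N : diploid population size.
    U : expected number of new trait-affecting mutations per gamete per
        generation.
    Lambda : shift in the optimal trait value at t = 0 (same units as VS).
    VS : width parameter of the Gaussian fitness function (squared trait
        units).  Defaults to ``2N``, i.e. delta units.
    seed : master RNG seed.
    burn_in : generations simulated before the shift (default ``10N``).
    horizon : generations simulated after the shift (default ``12N``).
    """

    N: int
    U: float
    Lambda: float
    VS: float | None = None
    seed: int = 0
    burn_in: int | None = None
    horizon: int | None = None

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if not self.U > 0:
            raise ValueError("U must be positive")
        if self.Lambda < 0:
            raise ValueError("Lambda must be non-negative")
        if self.VS is None:
            object.__setattr__(self, "VS", 2.0 * self.N)
        if not self.VS > 0:
            raise ValueError("VS must be positive")
        if self.burn_in is None:
            object.__setattr__(self, "burn_in", 10 * self.N)
        if self.horizon is None:
            object.__setattr__(self, "horizon", 12 * self.N)

    @property
    def twoNU(self) -> float:
        """Population-scaled mutational input 2NU (mutations per generation)."""
        return 2.0 * self.N * self.U

    @property
    def delta(self) -> float:
        """sqrt(VS/(2N)) in the units VS is expressed in (1 in delta units)."""
        return math.sqrt(self.VS / (2.0 * self.N))

    @property
    def units(self) -> DeltaUnits:
        return DeltaUnits(self.delta)

    def to_delta_units(self) -> "ModelParams":
        """Return an equivalent parameter set with VS = 2N (delta units)."""
        d = self.delta
        return replace(self, VS=2.0 * self.N, Lambda=self.Lambda / d)


class EffectSizeDistribution:
    """Distribution of squared allele magnitudes S = a^2 in delta^2 units.

    Families
    --------
    ``exponential_in_S``
        S ~ Exponential(mean_S); the distribution used throughout.
    ``point_mass``
        all mutations share one squared magnitude ``mean_S``.
    ``tabulated``
        discrete atoms ``S_values`` with probabilities ``weights``
        (must sum to 1 within 1e-8).
    """

    FAMILIES = ("exponential_in_S", "point_mass", "tabulated")

    def __init__(self, family: str, mean_S: float | None = None,
                 S_values=None, weights=None):
        if family not in self.FAMILIES:
            raise ValueError(f"unknown family {family!r}; expected one of {self.FAMILIES}")
        self.family = family
        if family == "tabulated":
            S = np.asarray(S_values, dtype=float)
            w = np.asarray(weights, dtype=float)
            if S.shape != w.shape or S.ndim != 1 or S.size == 0:
                raise ValueError("tabulated family needs matching 1-d S_values and weights")
            if np.any(S <= 0):
                raise ValueError("all S must be positive")
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
                raise ValueError("weights must be non-negative and sum to 1 (tol 1e-8)")
            self.S_values, self.weights = S, w
            self.mean_S = float(np.sum(S * w))
        else:
            if mean_S is None or not mean_S > 0:
                raise ValueError("mean_S must be positive")
            self.mean_S = float(mean_S)
            self.S_values = self.weights = None

    # -- densities and moments -------------------------------------------

    def pdf_S(self, s):
        """Density over S (continuous families only)."""
        s = np.asarray(s, dtype=float)
        if self.family == "exponential_in_S":
            return np.where(s >= 0, np.exp(-s / self.mean_S) / self.mean_S, 0.0)
        raise ValueError(f"{self.family} has no continuous density")

    def expect(self, func_of_a, rtol: float = 1e-10):
        """E_g[func(a)] with a = sqrt(S), by adaptive quadrature or direct sum.

        Raises RuntimeError with quadrature diagnostics on non-convergence.
        """
        if self.family == "point_mass":
            return float(func_of_a(math.sqrt(self.mean_S)))
        if self.family == "tabulated":
            return float(np.sum(self.weights * func_of_a(np.sqrt(self.S_values))))
        m = self.mean_S
        # integrands (v, f, ...) are bounded; the exponential tail beyond
        # 60*mean carries weight < 1e-26 and is dropped.
        val, err, info = integrate.quad(
            lambda s: float(func_of_a(math.sqrt(s))) * math.exp(-s / m) / m,
            0.0, 60.0 * m, limit=300, epsabs=0.0, epsrel=rtol, full_output=True)[:3]
        if err > max(rtol * 100 * abs(val), 1e-12):
            raise RuntimeError(
                f"quadrature over S did not converge: value={val}, abserr={err}, "
                f"neval={info.get('neval')}")
        return float(val)

    def sample_S(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "exponential_in_S":
            return rng.exponential(self.mean_S, n)
        if self.family == "point_mass":
            return np.full(n, self.mean_S)
        return rng.choice(self.S_values, size=n, p=self.weights)

    def quantile_S(self, q: float) -> float:
        if self.family == "exponential_in_S":
            return -self.mean_S * math.log1p(-q)
        if self.family == "point_mass":
            return self.mean_S
        order = np.argsort(self.S_values)
        cum = np.cumsum(self.weights[order])
        return float(self.S_values[order][np.searchsorted(cum, q)])

    def __repr__(self) -> str:  # pragma: no cover
        return f"EffectSizeDistribution({self.family!r}, mean_S={self.mean_S})"


# -- presets ---------------------------------------------------------------


def _preset(N: int, U: float, mean_S: float, shift_in_sd: float, seed: int):
    dist = EffectSizeDistribution("exponential_in_S", mean_S)
    from .equilibrium import equilibrium_variance  # deferred: avoids cycle

    probe = ModelParams(N=N, U=U, Lambda=0.0, seed=seed)
    VA0 = equilibrium_variance(probe, dist)
    params = ModelParams(N=N, U=U, Lambda=shift_in_sd * math.sqrt(VA0), seed=seed)
    return params, dist


def make_lande_preset(shift_in_sd: float = 4.0, N: int = 10_000, seed: int = 0):
    """Scenario in which the mean-phenotype response is essentially Lande's
    exponential: U = 0.03, S ~ Exponential(1), VS = 2N (delta units).

    ``shift_in_sd`` sets the optimum shift as a multiple of the equilibrium
    phenotypic standard deviation sqrt(V_A(0)).
    """
    return _preset(N, 0.03, 1.0, shift_in_sd, seed)


def make_non_lande_preset(shift_in_sd: float = 4.0, N: int = 10_000, seed: int = 0):
    """Scenario with marked deviations from Lande's solution: U = 0.01,
    S ~ Exponential(16).  Same equilibrium variance as the Lande preset."""
    return _preset(N, 0.01, 16.0, shift_in_sd, seed)


# -- assumption checks -----------------------------------------------------


def validate_assumptions(params: ModelParams, dist: EffectSizeDistribution,
                         VA0: float | None = None) -> list[str]:
    """Check the regime assumptions behind the analytic results.

    Returns the list of violated assumptions as human-readable warnings (also
    emitted via ``warnings.warn``); never raises.  Checks, in delta units:
    high polygenicity (2NU >> 1), modest genetic load (U <= 0.02), effect
    sizes small against the fitness-function width for the bulk of g, a shift
    above the drift scale but at most ~sqrt(VS), and a shift small enough
    that per-site frequency changes stay small
    (Lambda/sqrt(V_A(0)) <~ sqrt(2NU)/2).
    """
    p = params.to_delta_units()
    out: list[str] = []
    if p.twoNU <= 1:
        out.append(f"2NU = {p.twoNU:.3g} <= 1: polygenicity too low (2NU >> 1 assumed)")
    if p.U > 0.02:
        out.append(f"U = {p.U:.3g} exceeds 0.02: genetic load assumption violated")
    a_bulk = math.sqrt(dist.quantile_S(0.9))
    if a_bulk > 0.1 * math.sqrt(p.VS):
        out.append(
            f"bulk effect magnitude a90 = {a_bulk:.3g} delta is not small against "
            f"sqrt(VS) = {math.sqrt(p.VS):.3g}")
    if p.Lambda <= 1.0:  # delta = 1 in these units
        out.append("shift below equilibrium fluctuation scale delta (Lambda > delta assumed)")
    if p.Lambda > math.sqrt(p.VS):
        out.append(
            f"shift Lambda = {p.Lambda:.3g} exceeds sqrt(VS) = {math.sqrt(p.VS):.3g}")
    if VA0 is None:
        from .equilibrium import equilibrium_variance
        VA0 = equilibrium_variance(p, dist)
    if VA0 > 0 and p.Lambda / math.sqrt(VA0) > 0.5 * math.sqrt(p.twoNU):
        out.append(
            f"shift of {p.Lambda / math.sqrt(VA0):.3g} phenotypic SDs needs "
            f"per-site frequency changes that are not small "
            f"(bound 0.5*sqrt(2NU) = {0.5 * math.sqrt(p.twoNU):.3g})")
    for msg in out:
        warnings.warn(msg, stacklevel=2)
    return out


# -- scenario files --------------------------------------------------------

_SCENARIO_KEYS = {
    "N", "U", "VS", "Lambda", "shift_in_sd", "family", "mean_S",
    "S_values", "weights", "seed", "burn_in", "horizon",
    "n_replicates", "engine",
}


def load_scenario(path):
    """Read a YAML scenario file into a plain dict (unknown keys rejected)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - _SCENARIO_KEYS
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    return cfg


def scenario_from_dict(cfg: dict, overrides: dict | None = None):
    """Build (ModelParams, EffectSizeDistribution, extras) from a config dict.

    ``overrides`` (e.g. CLI flags) take precedence over file values.  The
    shift may be given directly (``Lambda``, trait units) or as
    ``shift_in_sd`` multiples of the equilibrium phenotypic SD.
    """
    merged = dict(cfg)
    for k, v in (overrides or {}).items():
        if v is not None:
            merged[k] = v
    dist = EffectSizeDistribution(
        merged.get("family", "exponential_in_S"),
        mean_S=merged.get("mean_S"),
        S_values=merged.get("S_values"),
        weights=merged.get("weights"),
    )
    base = dict(
        N=int(merged["N"]),
        U=float(merged["U"]),
        VS=merged.get("VS"),
        seed=int(merged.get("seed", 0)),
        burn_in=merged.get("burn_in"),
        horizon=merged.get("horizon"),
    )
    if merged.get("Lambda") is not None:
        params = ModelParams(Lambda=float(merged["Lambda"]), **base)
    else:
        from .equilibrium import equilibrium_variance
        probe = ModelParams(Lambda=0.0, **base)
        VA0 = equilibrium_variance(probe, dist)  # delta^2 units
        mult = float(merged.get("shift_in_sd", 0.0))
        params = ModelParams(Lambda=mult * math.sqrt(VA0) * probe.delta, **base)
    extras = {k: merged[k] for k in ("n_replicates", "engine") if k in merged}
    return params, dist, extras
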