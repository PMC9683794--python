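"""Allele-level theory: frequency-change moments, rapid-phase contributions,
diffusion fixation probabilities, and linear long-term contributions.

The response of a single site is governed by the first two moments of the
one-generation frequency change of an allele with signed effect ``a`` (positive
= aligned with the shift) at frequency ``x`` while the mean phenotype is at
distance ``D`` from the optimum:

    E(dx) = (a D / V_S) x(1-x) - (a^2/V_S)(1 - D^2/V_S) x(1-x)(1/2 - x)
    V(dx) = x(1-x) / (2N).

The first (directional) term transiently favors aligned alleles; the second
(underdominant, stabilizing) term selects against minor alleles throughout.
Short-term contributions are proportional to the equilibrium variance density
``v``; long-term (fixed) contributions are proportional to the fixation
gradient ``f``, amplified in the non-Lande case by the factors ``1+A``
(standing variation) and ``B`` (post-shift mutations) with ``A + B = C``.

All formulas here are the *linear* approximations, valid when
``a (1+A) Lambda / V_A(0) << 1``; a warning is emitted outside that regime.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .config import EffectSizeDistribution, ModelParams
from .equilibrium import (
    equilibrium_maf_density,
    equilibrium_variance,
    fixation_gradient,
    marginal_variance_density,
    variance_density,
)
from .phenotype import lande_distance

__all__ = [
    "AlleleContext",
    "freq_change_moments",
    "rapid_phase_pair_difference",
    "rapid_phase_contribution",
    "wright_fixation_prob",
    "longterm_contribution_lande",
    "longterm_contribution_nonlande",
    "estimate_amplification_A",
    "fixation_excess_table",
]


@dataclass(frozen=True)
class AlleleContext:
    """One allele's situation: signed effect a (delta units; positive =
    aligned with the shift), frequency x, current mean distance D, and VS."""

    a: float
    x: float
    D: float
    VS: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.x <= 1.0:
            raise ValueError("frequency x must lie in [0, 1]")
        if not self.VS > 0:
            raise ValueError("VS must be positive")
        sd = abs(2.0 * self.a * self.D / self.VS)
        if sd > 0.1:
            warnings.warn(
                f"directional selection coefficient s_d = {sd:.3g} is not small; "
                "the weak-selection moment expansion may be inaccurate")

    @property
    def s_d(self) -> float:
        """Directional selection coefficient 2 a D / V_S (signed)."""
        return 2.0 * self.a * self.D / self.VS

    @property
    def s_e(self) -> float:
        """Equilibrium (stabilizing) selection coefficient a^2 / V_S."""
        return self.a**2 / self.VS


def freq_change_moments(ctx: AlleleContext, N: int) -> tuple[float, float]:
    """Mean and variance of the one-generation frequency change."""
    a, x, D, VS = ctx.a, ctx.x, ctx.D, ctx.VS
    xx = x * (1.0 - x)
    mean = (a * D / VS) * xx - (a * a / VS) * (1.0 - D * D / VS) * xx * (0.5 - x)
    return mean, xx / (2.0 * N)


def rapid_phase_pair_difference(a: float, x0: float, Lambda: float, VA0: float,
                                t1: float, VS: float) -> float:
    """Expected frequency gap at t1 between a pair of opposite minor alleles
    of magnitude a starting at MAF x0:
    ``(Lambda - D_L(t1)) * 2 a x0 (1-x0) / V_A(0)``."""
    if a <= 0:
        raise ValueError("pair difference defined for magnitude a > 0")
    if not 0.0 < x0 <= 0.5:
        raise ValueError("x0 must lie in (0, 1/2]")
    DL1 = lande_distance(t1, Lambda, VA0, VS)
    return (Lambda - DL1) * 2.0 * a * x0 * (1.0 - x0) / VA0


def rapid_phase_contribution(a, x0=None, *, Lambda: float, VA0: float,
                             t1: float, VS: float):
    """Rapid-phase contribution to mean-phenotype change per unit mutational
    input (delta units): ``(Lambda - D_L(t1)) * v(a, x0) / V_A(0)`` pointwise
    in initial MAF, or with the marginal density v(a) when ``x0`` is None.

    Weighting by the mutational input 2NU g(a) and integrating over
    magnitudes recovers the total rapid-phase change Lambda - D_L(t1)."""
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ValueError("magnitude a must be positive")
    DL1 = lande_distance(t1, Lambda, VA0, VS)
    dens = marginal_variance_density(a) if x0 is None else variance_density(a, x0)
    out = (Lambda - DL1) * dens / VA0
    return out if np.ndim(out) else float(out)


def wright_fixation_prob(a, x):
    """Diffusion fixation probability of an allele of magnitude a starting at
    frequency x, under stationary stabilizing selection (D = 0) and drift:

        pi(a, x) = int_0^x exp(a^2 y(1-y)) dy / int_0^1 exp(a^2 y(1-y)) dy
                 = [erf(a(x - 1/2)) + erf(a/2)] / (2 erf(a/2)).

    Monotone increasing in x, with pi(a, x) + pi(a, 1-x) = 1 and the neutral
    limit pi -> x as a -> 0."""
    a = np.asarray(a, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any(a < 0):
        raise ValueError("magnitude a must be non-negative")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("frequency x must lie in [0, 1]")
    # evaluate on the folded lower half and reflect, so the symmetry
    # pi(a, x) + pi(a, 1-x) = 1 holds exactly; use the erfc form when the erf
    # arguments are large (difference of tails, no cancellation) and the erf
    # form when they are small
    xl = np.minimum(x, 1.0 - x)
    u = a * (0.5 - xl)
    num = np.where(u > 1.0,
                   special.erfc(u) - special.erfc(a / 2.0),
                   special.erf(a / 2.0) - special.erf(u))
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_low = num / (2.0 * special.erf(a / 2.0))
    out = np.where(x <= 0.5, pi_low, 1.0 - pi_low)
    out = np.where(a == 0.0, x, out)
    return out if out.ndim else float(out)


def longterm_contribution_lande(a, x0=None, *, Lambda: float, VA0: float):
    """Linear Lande approximation for the long-term (fixed) contribution per
    unit mutational input: ``2 Lambda f(a) / V_A(0)`` for a pair at any
    initial MAF (the x0 dependence cancels exactly), and
    ``Lambda f(a) / V_A(0)`` marginalized over the MAF distribution."""
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ValueError("magnitude a must be positive")
    scale = 2.0 if x0 is not None else 1.0
    out = scale * Lambda * fixation_gradient(a) / VA0
    return out if np.ndim(out) else float(out)


def _resolve_ABC(A, B, C):
    given = {k: v for k, v in dict(A=A, B=B, C=C).items() if v is not None}
    if len(given) < 2:
        if given.keys() == {"C"}:
            # only the total amplification is known; attribute none of it to
            # new mutations unless told otherwise
            raise ValueError(
                "C alone does not determine the standing/new split; supply A or B "
                "(A can be estimated with estimate_amplification_A)")
        raise ValueError("supply at least two of A, B, C (they satisfy A + B = C)")
    if len(given) == 3 and abs(A + B - C) > 1e-6:
        raise ValueError(f"inconsistent amplification factors: A + B - C = {A + B - C:.3g}")
    if A is None:
        A = C - B
    elif B is None:
        B = C - A
    else:
        C = A + B
    for name, val in dict(A=A, B=B, C=C).items():
        if val < -1e-9:
            raise ValueError(f"amplification factor {name} = {val:.3g} must be >= 0")
    return A, B, C


def longterm_contribution_nonlande(a, *, Lambda: float, VA0: float,
                                   A=None, B=None, C=None) -> dict:
    """Linear non-Lande long-term contributions per unit mutational input.

    Standing variation contributes ``(1+A) Lambda f(a) / V_A(0)``, post-shift
    mutations ``B Lambda f(a) / V_A(0)``, and their total
    ``(1+C) Lambda f(a) / V_A(0)`` with ``A + B = C`` enforced.  Weighted over
    the mutational input the grand total equals Lambda.  Returns a dict with
    keys ``standing``, ``new_mutations``, ``total`` and the resolved factors.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ValueError("magnitude a must be positive")
    A, B, C = _resolve_ABC(A, B, C)
    amax = float(np.max(a))
    if amax * (1.0 + A) * Lambda / VA0 >= 1.0:
        warnings.warn(
            "a (1+A) Lambda / V_A(0) >= 1: the linear long-term approximation "
            "is outside its validity range")
    base = Lambda * fixation_gradient(a) / VA0
    return {
        "standing": (1.0 + A) * base,
        "new_mutations": B * base,
        "total": (1.0 + C) * base,
        "A": A, "B": B, "C": C,
    }


def estimate_amplification_A(t, D, Lambda: float, VA0: float, VS: float) -> float:
    """Estimate the standing-variation amplification factor A from a mean
    distance trajectory: ``A = [int_0^inf D dt] V_A(0) / (V_S Lambda) - 1``.

    The integral is a trapezoid over the supplied trajectory plus an
    exponential tail correction using the decay rate fitted to the last
    decade of positive values.  A = 0 when D is exactly Lande's solution.
    Warns when the trajectory has not decayed (|D_end| > 0.05 Lambda)."""
    t = np.asarray(t, dtype=float)
    D = np.asarray(D, dtype=float)
    if t.shape != D.shape or t.size < 2:
        raise ValueError("t and D must be matching arrays with >= 2 points")
    if abs(D[-1]) > 0.05 * Lambda:
        warnings.warn(
            f"trajectory not decayed: |D_end| = {abs(D[-1]):.3g} > 0.05 Lambda; "
            "A will be underestimated")
    area = float(np.trapezoid(D, t))
    # exponential tail beyond the last sample, rate from the trailing 10%
    tail = slice(max(0, int(0.9 * t.size)), None)
    Dt, tt = D[tail], t[tail]
    pos = Dt > 0
    if D[-1] > 0 and pos.sum() >= 3:
        slope = np.polyfit(tt[pos], np.log(Dt[pos]), 1)[0]
        if slope < 0:
            area += D[-1] / (-slope)
    return area * VA0 / (VS * Lambda) - 1.0


def fixation_excess_table(params: ModelParams, dist: EffectSizeDistribution,
                          A: float = 0.0, S_bins=None, n_x: int = 2000,
                          VA0: float | None = None) -> pd.DataFrame:
    """Fixation probabilities of aligned vs opposing alleles per effect-size
    bin, averaged over the equilibrium MAF distribution.

    The effect of directional selection is modeled as an instantaneous pulse
    splitting a pair symmetrically around its initial MAF x0: the aligned
    allele moves to ``x0 + dx/2`` and the opposing one to ``x0 - dx/2`` with
    ``dx = 2 a x0 (1-x0) (1+A) Lambda / V_A(0)``.  Averages over x0 use
    quadrature against ell(a, x) truncated at 1/(2N).  The relative increase
    in total fixations, ``(pi_aligned + pi_opposed)/(2 pi_eq) - 1``, is
    identical whether the baseline counts sites or pairs, since at
    equilibrium both alleles of a pair fix with probability pi_eq.

    Returns one row per S-bin (geometric bin-center magnitude): fixation
    probabilities, the excess statistic (pi+ - pi-)/(pi+ + pi-), and the
    relative increase in total fixations over the equilibrium rate.
    """
    p = params.to_delta_units()
    if VA0 is None:
        VA0 = equilibrium_variance(p, dist)
    if S_bins is None:
        S_bins = np.geomspace(0.1, 100.0, 13)
    S_bins = np.asarray(S_bins, dtype=float)
    lo = 1.0 / (2.0 * p.N)
    x = np.geomspace(lo, 0.5, n_x)
    rows = []
    for Slo, Shi in zip(S_bins[:-1], S_bins[1:]):
        a = (Slo * Shi) ** 0.25  # magnitude at the geometric bin center of S
        ell = equilibrium_maf_density(a, x, p.N)
        norm = np.trapezoid(ell, x)
        dx = 2.0 * a * x * (1.0 - x) * (1.0 + A) * p.Lambda / VA0
        pi_plus = wright_fixation_prob(a, np.minimum(x + dx / 2.0, 1.0))
        pi_minus = wright_fixation_prob(a, np.maximum(x - dx / 2.0, 0.0))
        pi_eq = wright_fixation_prob(a, x)
        Pp = np.trapezoid(pi_plus * ell, x) / norm
        Pm = np.trapezoid(pi_minus * ell, x) / norm
        Pe = np.trapezoid(pi_eq * ell, x) / norm
        rows.append({
            "S_lo": Slo, "S_hi": Shi, "a": a,
            "pi_aligned": Pp, "pi_opposed": Pm, "pi_equilibrium": Pe,
            "excess": (Pp - Pm) / (Pp + Pm) if Pp + Pm > 0 else np.nan,
            "total_fixation_increase": (Pp + Pm) / (2.0 * Pe) - 1.0 if Pe > 0 else np.nan,
        })
    return pd.DataFrame(rows)
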