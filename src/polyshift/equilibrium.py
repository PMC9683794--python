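"""Equilibrium genetic architecture at mutation-selection-drift balance.

All quantities are per unit mutational input and expressed in delta units
(see :mod:`polyshift.config`), where an allele of magnitude ``a`` has
population-scaled selection coefficient ``S = a**2``.  For minor allele
frequency (MAF) ``x`` in ``(1/(2N), 1/2]``:

* ``ell(a, x) = 2 exp(-a^2 x(1-x)) / (x(1-x))`` — expected density of
  segregating sites (sojourn-time density of the underdominant diffusion),
* ``v(a, x) = 2 a^2 x(1-x) * ell(a, x) = 4 a^2 exp(-a^2 x(1-x))`` — density
  of genetic variance,
* ``v(a) = 4 a * D_+(a/2)`` — variance per unit input marginalized over MAF,
  with ``D_+`` the Dawson function,
* ``f(a) = 2 a^3 exp(-a^2/4) / (sqrt(pi) erf(a/2))`` — the fixation-gradient
  function, defined by ``dpi/dx(a, x) = 2 f(a) / v(a, x)`` where ``pi`` is
  the fixation probability under stationary stabilizing selection and drift.

Both ``v`` and ``f`` tend to ``2 a^2`` as ``a -> 0``; ``v(a) > f(a)`` for all
``a > 0``, and the mutational-input-weighted ratio of the two defines the
long-term amplification factor ``C = E_g[v]/E_g[f] - 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special

from .config import EffectSizeDistribution, ModelParams

__all__ = [
    "variance_density",
    "marginal_variance_density",
    "fixation_gradient",
    "equilibrium_variance",
    "amplification_factor",
    "equilibrium_maf_density",
    "sample_initial_mafs",
    "EquilibriumDensities",
]


def _check_maf(x, lo: float = 0.0) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x <= lo) or np.any(x > 0.5):
        raise ValueError(f"minor allele frequency must lie in ({lo}, 0.5]")
    return x


def variance_density(a, x):
    """Equilibrium density of genetic variance v(a, x) per unit mutational
    input per unit MAF: ``4 a^2 exp(-a^2 x (1-x))`` (delta^2 units)."""
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("magnitude a must be non-negative")
    x = _check_maf(x)
    out = 4.0 * a**2 * np.exp(-(a**2) * x * (1.0 - x))
    return out if out.ndim else float(out)

def marginal_variance_density(a):
    """v(a) = integral of v(a, x) over MAF in (0, 1/2]: ``4 a D_+(a/2)``.

    Scales as 2 a^2 for small effects, peaks near a^2 = 10 (v ~ 5.1) and
    tends to 4 for large effects.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("magnitude a must be non-negative")
    out = 4.0 * a * special.dawsn(a / 2.0)
    return out if out.ndim else float(out)


def fixation_gradient(a):
    """f(a) = 2 a^3 exp(-a^2/4) / (sqrt(pi) erf(a/2)).

    Satisfies dpi/dx(a, x) = 2 f(a) / v(a, x) for the diffusion fixation
    probability under stationary stabilizing selection; f(a) -> 2 a^2 as
    a -> 0 and f(a) < v(a) for all a > 0.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("magnitude a must be non-negative")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 2.0 * a**3 * np.exp(-(a**2) / 4.0) / (math.sqrt(math.pi) * special.erf(a / 2.0))
    out = np.where(a == 0.0, 0.0, out)
    return out if out.ndim else float(out)


def equilibrium_variance(params: ModelParams, dist: EffectSizeDistribution) -> float:
    """Equilibrium genetic variance V_A(0) = 2NU * E_g[v(a)] in delta^2 units."""
    return params.twoNU * dist.expect(marginal_variance_density)


def amplification_factor(dist: EffectSizeDistribution) -> float:
    """C = E_g[v(a)] / E_g[f(a)] - 1 (> 0 for every magnitude distribution).

    ``1 + C`` is the factor by which prolonged weak directional selection
    amplifies the long-term contribution of alleles relative to the linear
    Lande approximation; it depends only on the magnitude distribution g.
    """
    return dist.expect(marginal_variance_density) / dist.expect(fixation_gradient) - 1.0


def equilibrium_maf_density(a, x, N: int):
    """Expected density of segregating sites ell(a, x) per unit mutational
    input, for MAF x in (1/(2N), 1/2]: ``2 exp(-a^2 x(1-x)) / (x(1-x))``.

    This is the sojourn-time density of the Wright-Fisher diffusion under
    symmetric (underdominant-form) stabilizing selection, folded on MAF; it
    is the unique density consistent with v(a, x) = 2 a^2 x(1-x) ell(a, x).
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    a = np.asarray(a, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any(x < 1.0 / (2.0 * N)) or np.any(x > 0.5):
        raise ValueError("minor allele frequency must lie in [1/(2N), 0.5]")
    out = 2.0 * np.exp(-(a**2) * x * (1.0 - x)) / (x * (1.0 - x))
    return out if out.ndim else float(out)


def sample_initial_mafs(a: float, N: int, n_samples: int, seed):
    """Importance-sample initial MAFs from the variance-density proposal.

    Draws ``x0 ~ v(a, x)`` on ``(1/(2N), 1/2]`` via inverse-CDF on a dense
    grid and returns ``(x0, weights)`` with weights proportional to
    ``ell(a, x)/v(a, x) = 1/(2 a^2 x(1-x))`` and normalized to mean 1, so
    weighted averages of any statistic converge to its expectation under the
    site density ell.  Deterministic for a fixed seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if N < 2:
        raise ValueError("N must be >= 2")
    rng = np.random.default_rng(seed)
    lo = 1.0 / (2.0 * N)
    grid = np.linspace(lo, 0.5, 8193)
    pdf = np.exp(-(a**2) * grid * (1.0 - grid))  # proportional to v(a, x)
    cdf = integrate.cumulative_trapezoid(pdf, grid, initial=0.0)
    cdf /= cdf[-1]
    x0 = np.interp(rng.random(n_samples), cdf, grid)
    w = 1.0 / (x0 * (1.0 - x0))
    w /= w.mean()
    return x0, w


@dataclass(frozen=True)
class EquilibriumDensities:
    """Bundle of the equilibrium densities for one allele magnitude."""

    a: float
    N: int

    def site_density(self, x):
        return equilibrium_maf_density(self.a, x, self.N)

    def variance_density(self, x):
        return variance_density(self.a, x)

    def marginal_variance(self) -> float:
        return marginal_variance_density(self.a)

    def fixation_gradient(self) -> float:
        return fixation_gradient(self.a)
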