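"""Canned validation experiments at desk scale.

These bundle the simulation conditions used to check the analytic theory:
population sizes, replicate counts and horizons are scaled down from the
full-resolution study conditions (N = 10^4, 2500 all-alleles / 250,000
single-allele replicates, 12N horizons) to sizes a single CPU handles in
minutes, relying on the delta-unit invariance of the dynamics.  The problem
sizes used are recorded in each result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alleles import wright_fixation_prob
from .config import EffectSizeDistribution, ModelParams
from .equilibrium import equilibrium_variance
from .phenotype import lande_distance
from .simulate import (
    ExperimentConfig,
    ReplicateSet,
    fixed_distance_decay,
    orchestrate_experiment,
    replicate_seed,
    run_single_allele,
)

__all__ = [
    "smooth",
    "nonlande_response_experiment",
    "lande_fixed_distance_experiment",
    "fixation_probability_oracle",
]


def smooth(y: np.ndarray, width: int = 51) -> np.ndarray:
    """Centered moving average with edge renormalization.

    Utility for noisy replicate-mean trajectories.  The packaged response
    metrics use raw replicate means: at the default replicate counts their
    standard errors are an order of magnitude below the measured signals,
    while a boxcar wide enough to help would flatten the rapid phase.
    """
    if width <= 1:
        return y
    kern = np.ones(width)
    return np.convolve(y, kern, mode="same") / np.convolve(np.ones_like(y), kern, mode="same")


@dataclass
class NonLandeResponse:
    replicates: ReplicateSet
    VA0_analytic: float
    VA0_measured: float
    Lambda: float
    max_deviation_in_sd: float     # max_t |D(t) - D_L(t)| / sqrt(V_A(0))
    peak_variance_increase_pct: float
    max_abs_skewness: float
    N: int
    n_replicates: int


def nonlande_response_experiment(seed: int, N: int = 5000, n_replicates: int = 20,
                                 horizon_in_N: float = 2.0, shift_in_sd: float = 4.0,
                                 twoNU: float = 200.0,
                                 mean_S: float = 16.0) -> NonLandeResponse:
    """Phenotypic response in the non-Lande regime (all-alleles engine).

    Runs burn-in (10N) plus the post-shift horizon for a shift of
    ``shift_in_sd`` equilibrium phenotypic standard deviations, then measures
    the three deviation summaries of the mean trajectory: the maximum
    distance from Lande's solution in units of sqrt(V_A(0)), the peak
    relative increase of V_A(t), and the maximum absolute skewness.  D_L uses
    the equilibrium variance measured over the end of the burn-in.

    The population is scaled down by holding the *population-scaled*
    mutational input ``2NU`` fixed (the study condition; 2NU = 200 with
    exponential squared effects of mean 16) and reducing N.  In delta units
    the moment responses depend on the shift through ``Lambda/V_A(0)`` and on
    the architecture through ``2NU`` and ``g`` alone, so this scale-down
    leaves the measured quantities invariant, whereas reducing ``2NU`` itself
    would inflate them (the variance response is second order in the allelic
    pulse, hence proportional to ``Lambda^2/V_A(0)^2 ~ 1/(2NU)``).
    """
    U = twoNU / (2.0 * N)
    dist = EffectSizeDistribution("exponential_in_S", mean_S)
    probe = ModelParams(N=N, U=U, Lambda=0.0, seed=seed)
    VA0_analytic = equilibrium_variance(probe, dist)
    params = ModelParams(N=N, U=U, Lambda=shift_in_sd * math.sqrt(VA0_analytic),
                         seed=seed, horizon=int(horizon_in_N * N))
    rs = orchestrate_experiment(ExperimentConfig(
        params=params, dist=dist, engine="alleles", n_replicates=n_replicates))
    VA0 = rs.VA0_measured
    Dm = rs.mean("D")
    DL = lande_distance(rs.t, params.Lambda, VA0, params.VS)
    return NonLandeResponse(
        replicates=rs, VA0_analytic=VA0_analytic, VA0_measured=VA0,
        Lambda=params.Lambda,
        max_deviation_in_sd=float(np.max(np.abs(Dm - DL)) / math.sqrt(VA0)),
        peak_variance_increase_pct=float((np.max(rs.mean("VA")) / VA0 - 1.0) * 100.0),
        max_abs_skewness=float(np.nanmax(np.abs(rs.mean("skew")))),
        N=N, n_replicates=n_replicates)


@dataclass
class FixedDistanceDecay:
    rate: float
    ci_low: float
    ci_high: float
    expected_rate: float           # 1/(2N)
    N: int
    n_replicates: int


def lande_fixed_distance_experiment(seed: int, N: int = 2000, n_replicates: int = 10,
                                    horizon_in_N: float = 8.0, shift_in_sd: float = 4.0,
                                    U: float = 0.03, mean_S: float = 1.0) -> FixedDistanceDecay:
    """Decay of the fixed distance from the optimum in the Lande regime.

    After the shift, the replicate-mean fixed distance is fit to an
    exponential over t in [0.5N, 6N]; the theory anticipates a rate of
    1/(2N) per generation.
    """
    dist = EffectSizeDistribution("exponential_in_S", mean_S)
    probe = ModelParams(N=N, U=U, Lambda=0.0, seed=seed)
    VA0 = equilibrium_variance(probe, dist)
    params = ModelParams(N=N, U=U, Lambda=shift_in_sd * math.sqrt(VA0),
                         seed=seed, horizon=int(horizon_in_N * N))
    rs = orchestrate_experiment(ExperimentConfig(
        params=params, dist=dist, engine="alleles", n_replicates=n_replicates))
    fit = fixed_distance_decay(rs.t, rs.mean("fixed_distance"), N)
    return FixedDistanceDecay(rate=fit.rate, ci_low=fit.ci_low, ci_high=fit.ci_high,
                              expected_rate=1.0 / (2.0 * N), N=N,
                              n_replicates=n_replicates)


def fixation_probability_oracle(seed: int, N: int = 1000, n_replicas: int = 20000,
                                S_values=(1.0, 4.0, 16.0),
                                x0_values=(0.1, 0.25, 0.5)):
    """Single-allele Wright-Fisher fixation frequencies vs the diffusion
    formula, under stationary stabilizing selection (D = 0).

    Returns a list of dicts with the simulated probability, its binomial SE,
    and the diffusion prediction for each (S, x0) grid point.
    """
    rows = []
    for i, S in enumerate(S_values):
        for j, x0 in enumerate(x0_values):
            ss = replicate_seed(seed, 1000 * i + j)
            res = run_single_allele(math.sqrt(S), x0, lambda t: 0.0, N,
                                    n_replicas, ss)
            pi_hat = res.fixation_probability()
            rows.append({
                "S": S, "x0": x0, "pi_sim": pi_hat,
                "se": math.sqrt(max(pi_hat * (1 - pi_hat), 1e-12) / n_replicas),
                "pi_theory": wright_fixation_prob(math.sqrt(S), x0),
                "n_unabsorbed": res.n_unabsorbed,
            })
    return rows
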