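"""A-priori power for two-group negative-binomial RNA-seq designs under FDR control.

Computes the power to detect a fold change rho between two groups of n
samples each, for a gene with minimal average normalized count mu0 and NB
dispersion phi (variance = mu + phi mu^2), when m genes are tested and m1
are expected to be differentially expressed at FDR level f.

The per-test significance level alpha is tied to the FDR via the marginal
(expected-proportion) identity

    f = alpha (m - m1) / (alpha (m - m1) + power * m1)

which, solved for alpha, gives alpha = f * m1 * power / ((m - m1)(1 - f)).
Power for a two-sided Wald test of H0: log rho = 0 uses the delta-method
standard error of a log-mean difference between NB groups,

    SE^2 = (1/n) [ (1/mu0 + phi) + (1/(rho mu0) + phi) ],

and the (power, alpha) pair is iterated to a fixed point.  This is a Wald
approximation to the exact-test calculation performed by sample-size tools
such as RNASeqSampleSize; with large planted effects the two agree in the
regimes this module targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PowerParams:
    """Design parameters for the NB power computation.

    n_per_group: samples per group; dispersion: NB phi; fold_change: rho;
    fdr_level: target FDR f; m: genes tested; m1: expected DE genes;
    mu0: minimal average normalized count of the genes of interest.
    """

    n_per_group: int = 65
    dispersion: float = 0.5
    fold_change: float = 2.82
    fdr_level: float = 0.05
    m: int = 17740
    m1: int = 1000
    mu0: float = 10.0

    def __post_init__(self) -> None:
        if self.n_per_group <= 0:
            raise ValueError("n_per_group must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must lie in (0, 1)")
        if not 0 < self.m1 < self.m:
            raise ValueError("need 0 < m1 < m")
        if self.mu0 <= 0:
            raise ValueError("mu0 must be positive")


def fdr_alpha(f: float, m: int, m1: int, power: float) -> float:
    """Per-test alpha achieving marginal FDR ``f`` at the given power.

    alpha = f * m1 * power / ((m - m1) (1 - f)), clipped to (0, 1).
    """
    if not 0 < f < 1:
        raise ValueError("f must lie in (0, 1)")
    if not 0 < m1 < m:
        raise ValueError("need 0 < m1 < m")
    if not 0 < power <= 1:
        raise ValueError("power must lie in (0, 1]")
    alpha = f * m1 * power / ((m - m1) * (1.0 - f))
    return float(min(max(alpha, np.nextafter(0, 1)), 1.0 - 1e-12))


def _wald_power(params: PowerParams, alpha: float) -> float:
    """Two-sided Wald power for H0: log rho = 0 at level ``alpha``."""
    n, phi, rho, mu0 = (
        params.n_per_group,
        params.dispersion,
        params.fold_change,
        params.mu0,
    )
    se = np.sqrt((1.0 / n) * ((1.0 / mu0 + phi) + (1.0 / (rho * mu0) + phi)))
    z_crit = stats.norm.isf(alpha / 2.0)
    delta = abs(np.log(rho)) / se
    return float(stats.norm.sf(z_crit - delta) + stats.norm.cdf(-z_crit - delta))


def nb_power_fixed_point(
    params: PowerParams,
    tol: float = 1e-6,
    max_iter: int = 100,
    start: float = 0.8,
) -> tuple[float, float, int]:
    """Iterate the (power, alpha) pair to a fixed point.

    Alternates alpha = fdr_alpha(f, m, m1, power) and the Wald power at
    that alpha until the power changes by less than ``tol``.  Returns
    (power, alpha, iterations).
    """
    power = start
    for it in range(1, max_iter + 1):
        alpha = fdr_alpha(params.fdr_level, params.m, params.m1, power)
        new = _wald_power(params, alpha)
        if abs(new - power) < tol:
            return new, alpha, it
        power = new
    raise RuntimeError(f"power fixed point did not converge in {max_iter} iterations")


def nb_power(
    params: PowerParams,
    tol: float = 1e-6,
    max_iter: int = 100,
    start: float = 0.8,
) -> float:
    """Converged power of the (power, alpha) fixed point (see
    :func:`nb_power_fixed_point`)."""
    return nb_power_fixed_point(params, tol, max_iter, start)[0]
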