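"""Pólya-Gamma PG(1, z) sampler for logistic data augmentation.

A logistic likelihood becomes conditionally Gaussian given latent
Pólya-Gamma variables, which is what makes a Gibbs sampler for
Bayesian-lasso logistic regression possible.  This is the exact
alternating-series rejection sampler of Devroye for the exponentially
tilted Jacobi distribution J*(1, z), with PG(1, z) = J*(1, z/2) / 4.
The acceptance probability exceeds 0.99 uniformly in z, so the rejection
loops essentially run once.

Compiled with numba; draws come from the caller's
``numpy.random.Generator`` so a whole model fit shares one seeded stream.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_T = 0.64  # series crossover point
_SQRT2 = math.sqrt(2.0)
_LOG_2PI = math.log(2.0 * math.pi)


@njit(cache=True)
def _log_phi(v: float) -> float:
    # log of the standard normal CDF, with an asymptotic tail guard
    c = 0.5 * math.erfc(-v / _SQRT2)
    if c > 0.0:
        return math.log(c)
    return -0.5 * v * v - math.log(-v) - 0.5 * _LOG_2PI


@njit(cache=True)
def _a_coef(n: int, x: float) -> float:
    # alternating-series terms of the untilted J*(1) density
    nph = n + 0.5
    if x <= _T:
        return (
            math.pi * nph
            * (2.0 / (math.pi * x)) ** 1.5
            * math.exp(-2.0 * nph * nph / x)
        )
    return math.pi * nph * math.exp(-nph * nph * math.pi * math.pi * x / 2.0)


@njit(cache=True)
def _rtigauss(gen, z: float) -> float:
    # inverse-Gaussian(mu = 1/z, lambda = 1) truncated to (0, _T]
    mu = 1.0 / z if z > 1e-12 else 1e12
    while True:
        if mu > _T:
            # rejection with a truncated inverse-chi-square proposal
            e1 = gen.standard_exponential()
            e2 = gen.standard_exponential()
            while e1 * e1 > 2.0 * e2 / _T:
                e1 = gen.standard_exponential()
                e2 = gen.standard_exponential()
            x = _T / ((1.0 + _T * e1) ** 2)
            if gen.random() < math.exp(-0.5 * z * z * x):
                return x
        else:
            # draw IG(mu, 1) until it lands in (0, _T]
            y = gen.standard_normal()
            y = y * y
            x = mu + 0.5 * mu * mu * y - 0.5 * mu * math.sqrt(
                4.0 * mu * y + (mu * y) ** 2
            )
            if gen.random() > mu / (mu + x):
                x = mu * mu / x
            if x <= _T:
                return x


@njit(cache=True)
def _right_branch_mass(z: float) -> float:
    # probability that the mixture proposal uses the exponential tail
    fz = math.pi * math.pi / 8.0 + z * z / 2.0
    x0 = math.log(fz) + fz * _T
    rt = math.sqrt(1.0 / _T)
    xb = x0 - z + _log_phi(rt * (_T * z - 1.0))
    xa = x0 + z + _log_phi(-rt * (_T * z + 1.0))
    ratio = 4.0 / math.pi * (math.exp(xb) + math.exp(xa))
    return 1.0 / (1.0 + ratio)


@njit(cache=True)
def _sample_jstar(gen, z: float) -> float:
    # Devroye's mixture-of-tails rejection for tilted J*(1, z)
    z = abs(z)
    fz = math.pi * math.pi / 8.0 + z * z / 2.0
    p_right = _right_branch_mass(z)
    while True:
        if gen.random() < p_right:
            x = _T + gen.standard_exponential() / fz
        else:
            x = _rtigauss(gen, z)
        # alternating-series squeeze accept/reject
        s = _a_coef(0, x)
        y = gen.random() * s
        n = 0
        accept = False
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    accept = True
                    break
            else:
                s += _a_coef(n, x)
                if y > s:
                    break
        if accept:
            return x


@njit(cache=True)
def polya_gamma(gen, z: np.ndarray, out: np.ndarray) -> None:
    """Fill ``out`` with PG(1, z_i) draws using the Generator ``gen``."""
    for idx in range(z.size):
        out[idx] = 0.25 * _sample_jstar(gen, 0.5 * z[idx])


def polya_gamma_mean(z: np.ndarray) -> np.ndarray:
    """Closed form E[PG(1, z)] = tanh(z/2) / (2z), used for validation."""
    z = np.asarray(z, dtype=np.float64)
    out = np.full(z.shape, 0.25)
    big = np.abs(z) >= 1e-8
    out[big] = np.tanh(z[big] / 2.0) / (2.0 * z[big])
    return out
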