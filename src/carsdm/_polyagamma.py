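"""Exact Polya-Gamma PG(1, z) sampling (Devroye alternating-series scheme).

Used to augment the Bernoulli-logit likelihood so that the occupancy model's
regression coefficients and spatial effects have Gaussian full conditionals.
A PG(1, z) variate is J*(1, z/2) / 4 where J* is the tilted Jacobi
distribution; J* is sampled by a two-piece proposal (truncated
inverse-Gaussian body, exponential tail) with the alternating-series
accept/reject test. Compiled with numba; the per-call ``seed`` drives
numba's internal Mersenne-Twister state, so draws are reproducible.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_TRUNC = 0.64
_PI2_8 = math.pi**2 / 8.0


@njit(cache=True)
def _norm_cdf(x: float) -> float:
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


@njit(cache=True)
def _mass_texpon(z: float) -> float:
    """P(proposal falls in the exponential tail), i.e. p / (p + q)."""
    t = _TRUNC
    fz = _PI2_8 + 0.5 * z * z
    b = math.sqrt(1.0 / t) * (t * z - 1.0)
    a = -math.sqrt(1.0 / t) * (t * z + 1.0)
    x0 = math.log(fz) + fz * t
    phi_b = _norm_cdf(b)
    phi_a = _norm_cdf(a)
    xb = -1e300 if phi_b <= 0.0 else x0 - z + math.log(phi_b)
    xa = -1e300 if phi_a <= 0.0 else x0 + z + math.log(phi_a)
    qdivp = 4.0 / math.pi * (math.exp(xb) + math.exp(xa))
    return 1.0 / (1.0 + qdivp)


@njit(cache=True)
def _rtigauss(z: float) -> float:
    """Inverse-Gaussian(mu=1/z, lambda=1) truncated to (0, _TRUNC)."""
    t = _TRUNC
    x = t + 1.0
    if z < 1.0 / t:  # mu > t: rejection from truncated Levy
        alpha = 0.0
        while np.random.random() > alpha:
            while True:
                e1 = np.random.exponential(1.0)
                e2 = np.random.exponential(1.0)
                if e1 * e1 <= 2.0 * e2 / t:
                    break
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            alpha = math.exp(-0.5 * z * z * x)
    else:
        mu = 1.0 / z
        while x > t:
            y = np.random.standard_normal()
            y = y * y
            half_mu = 0.5 * mu
            mu_y = mu * y
            x = mu + half_mu * mu_y - half_mu * math.sqrt(4.0 * mu_y + mu_y * mu_y)
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
        x = max(x, 1e-300)
    return x


@njit(cache=True)
def _a_coef(n: int, x: float) -> float:
    k = n + 0.5
    if x > _TRUNC:
        return math.pi * k * math.exp(-0.5 * k * k * math.pi**2 * x)
    return math.pow(2.0 / (math.pi * x), 1.5) * math.pi * k * math.exp(-2.0 * k * k / x)


@njit(cache=True)
def _draw_jstar(z: float) -> float:
    """One draw of J*(1, z), z >= 0."""
    fz = _PI2_8 + 0.5 * z * z
    while True:
        if np.random.random() < _mass_texpon(z):
            x = _TRUNC + np.random.exponential(1.0) / fz
        else:
            x = _rtigauss(z)
        s = _a_coef(0, x)
        y = np.random.random() * s
        n = 0
        accepted = False
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    accepted = True
                    break
            else:
                s += _a_coef(n, x)
                if y > s:
                    break
        if accepted:
            return x


@njit(cache=True)
def pg_draws(psi: np.ndarray, seed: int) -> np.ndarray:
    """Vector of PG(1, psi_i) draws, deterministic given ``seed``."""
    np.random.seed(seed)
    out = np.empty(psi.size)
    for i in range(psi.size):
        z = 0.5 * abs(psi[i])
        out[i] = 0.25 * _draw_jstar(z)
    return out


def pg_mean(z: np.ndarray | float) -> np.ndarray | float:
    """E[PG(1, z)] = tanh(z/2) / (2 z); 1/4 at z = 0."""
    z = np.asarray(z, dtype=float)
    out = np.where(z == 0.0, 0.25, np.tanh(z / 2.0) / np.where(z == 0.0, 1.0, 2.0 * z))
    return out if out.ndim else float(out)
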