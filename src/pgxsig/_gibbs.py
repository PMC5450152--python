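"""Numba kernels: exact Polya-Gamma PG(1, z) draws and the Gibbs sweep for
spike-and-slab logistic regression.

The augmentation follows the standard identity for the Bernoulli-logit
likelihood: given auxiliary omega_i ~ PG(1, x_i' beta) the conditional model
is Gaussian in beta, so inclusion indicators can be sampled from exact
conditional marginal likelihoods and coefficients from an exact
multivariate-normal conditional.  PG(1, z) is sampled by Devroye-style
alternating-series rejection from a mixture of a truncated inverse-Gaussian
and an exponential tail (PG(1, z) = J*(1, z/2) / 4).
"""

import math

import numpy as np
from numba import njit

_TRUNC = 0.64  # series crossover point for the J*(1, z) density


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


@njit(cache=True)
def _pigauss_cdf(t, z):
    """CDF at t of an inverse-Gaussian with mean 1/z and shape 1 (z >= 0)."""
    s = 1.0 / math.sqrt(t)
    return _norm_cdf(s * (t * z - 1.0)) + math.exp(2.0 * z) * _norm_cdf(
        -s * (t * z + 1.0)
    )


@njit(cache=True)
def _series_coef(n, x):
    """Coefficient a_n(x) of the alternating series for the J*(1,.) density."""
    h = n + 0.5
    if x > _TRUNC:
        return math.pi * h * math.exp(-h * h * math.pi * math.pi * x / 2.0)
    return (
        math.pow(2.0 / (math.pi * x), 1.5)
        * math.pi
        * h
        * math.exp(-2.0 * h * h / x)
    )


@njit(cache=True)
def _rtigauss(z, t):
    """Inverse-Gaussian(mean 1/z, shape 1) truncated to (0, t)."""
    x = t + 1.0
    if t * z < 1.0:  # mean above the truncation point: rejection from Levy
        accepted = False
        while not accepted:
            while True:
                e1 = np.random.exponential(1.0)
                e2 = np.random.exponential(1.0)
                if e1 * e1 <= 2.0 * e2 / t:
                    break
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            if np.random.random() <= math.exp(-0.5 * z * z * x):
                accepted = True
    else:
        mu = 1.0 / z
        while x > t:
            y = np.random.standard_normal()
            y = y * y
            muy = mu * y
            x = mu + 0.5 * mu * muy - 0.5 * mu * math.sqrt(4.0 * muy + muy * muy)
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
    return x


@njit(cache=True)
def pg_draw(z):
    """One draw from PG(1, z)."""
    z = abs(z) * 0.5
    fz = math.pi * math.pi / 8.0 + z * z / 2.0
    p = (math.pi / (2.0 * fz)) * math.exp(-fz * _TRUNC)
    q = 2.0 * math.exp(-z) * _pigauss_cdf(_TRUNC, z)
    ratio = p / (p + q)
    while True:
        if np.random.random() < ratio:
            x = _TRUNC + np.random.exponential(1.0) / fz
        else:
            x = _rtigauss(z, _TRUNC)
        s = _series_coef(0, x)
        y = np.random.random() * s
        n = 0
        accepted = False
        while True:
            n += 1
            if n % 2 == 1:
                s -= _series_coef(n, x)
                if y <= s:
                    accepted = True
                    break
            else:
                s += _series_coef(n, x)
                if y > s:
                    break
        if accepted:
            return x / 4.0


@njit(cache=True)
def pg_sample(z, seed):
    """Vector of independent PG(1, z_i) draws (test/diagnostic helper)."""
    np.random.seed(seed)
    out = np.empty(z.size)
    for i in range(z.size):
        out[i] = pg_draw(z[i])
    return out


@njit(cache=True)
def _log_marginal(A, b, prior_prec, active):
    """Log marginal of the Gaussianized likelihood for one inclusion
    configuration, up to terms shared by configurations differing in a
    single coordinate."""
    k = active.size
    P = np.empty((k, k))
    bb = np.empty(k)
    half_logdet_prior = 0.0
    for i in range(k):
        ai = active[i]
        for j in range(k):
            P[i, j] = A[ai, active[j]]
        P[i, i] += prior_prec[ai]
        bb[i] = b[ai]
        half_logdet_prior += 0.5 * math.log(prior_prec[ai])
    L = np.linalg.cholesky(P)
    half_logdet_post = 0.0
    for i in range(k):
        half_logdet_post += math.log(L[i, i])
    m = np.linalg.solve(P, bb)
    quad = 0.0
    for i in range(k):
        quad += bb[i] * m[i]
    return half_logdet_prior - half_logdet_post + 0.5 * quad


@njit(cache=True)
def _active_indices(gamma):
    k = 0
    for j in range(gamma.size):
        if gamma[j]:
            k += 1
    out = np.empty(k, dtype=np.int64)
    i = 0
    for j in range(gamma.size):
        if gamma[j]:
            out[i] = j
            i += 1
    return out


@njit(cache=True)
def gibbs_kernel(X, y, prior_incl, prior_prec, n_iter, seed, always_in):
    """Spike-and-slab logistic Gibbs sampler.

    X: (n, p) design with intercept column included; y: 0/1 outcomes;
    prior_incl: per-column prior inclusion probability (ignored where
    always_in); prior_prec: per-column slab precision.  Returns
    (beta_draws, gamma_draws) of shape (n_iter, p); excluded coefficients
    are recorded as exact zeros.
    """
    np.random.seed(seed)
    n, p = X.shape
    XT = np.ascontiguousarray(X.T)
    kappa = np.empty(n)
    for i in range(n):
        kappa[i] = y[i] - 0.5
    b = XT @ kappa if n > 0 else np.zeros(p)

    beta = np.zeros(p)
    gamma = np.zeros(p, dtype=np.bool_)
    for j in range(p):
        gamma[j] = True  # start from the full model
    beta_draws = np.zeros((n_iter, p))
    gamma_draws = np.zeros((n_iter, p), dtype=np.bool_)
    omega = np.empty(n)
    A = np.zeros((p, p))

    for it in range(n_iter):
        # -- Polya-Gamma auxiliaries given beta
        if n > 0:
            psi = X @ beta
            for i in range(n):
                omega[i] = pg_draw(psi[i])
            A = XT @ (X * omega.reshape(n, 1))
        # -- inclusion indicators, one coordinate at a time
        for j in range(p):
            if always_in[j]:
                continue
            gamma[j] = True
            l1 = _log_marginal(A, b, prior_prec, _active_indices(gamma))
            gamma[j] = False
            l0 = _log_marginal(A, b, prior_prec, _active_indices(gamma))
            lo = (l1 - l0) + math.log(prior_incl[j]) - math.log(1.0 - prior_incl[j])
            if lo > 35.0:
                gamma[j] = True
            elif lo < -35.0:
                gamma[j] = False
            else:
                gamma[j] = np.random.random() < 1.0 / (1.0 + math.exp(-lo))
        # -- coefficients for the active set
        active = _active_indices(gamma)
        k = active.size
        P = np.empty((k, k))
        bb = np.empty(k)
        for i in range(k):
            ai = active[i]
            for jj in range(k):
                P[i, jj] = A[ai, active[jj]]
            P[i, i] += prior_prec[ai]
            bb[i] = b[ai]
        L = np.linalg.cholesky(P)
        m = np.linalg.solve(P, bb)
        zdraw = np.random.standard_normal(k)
        w = np.linalg.solve(L.T, zdraw)  # w ~ N(0, P^{-1})
        for j in range(p):
            beta[j] = 0.0
        for i in range(k):
            beta[active[i]] = m[i] + w[i]
        beta_draws[it] = beta
        gamma_draws[it] = gamma
    return beta_draws, gamma_draws
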