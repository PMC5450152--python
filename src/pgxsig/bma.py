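"""Stage II: spike-and-slab Bayesian model averaging for logistic
regression, signature selection, interaction screening and the final refit.

The sampler is a data-augmentation Gibbs scheme with exact Polya-Gamma
auxiliary updates (see :mod:`pgxsig._gibbs`).  Each coefficient other than
the intercept carries a Bernoulli spike with configurable prior inclusion
probability and a zero-mean normal slab with information-scaled variance.

Reported per-coefficient credible intervals are *conditional on inclusion*:
equal-tailed quantiles over the post-burn-in draws in which the coefficient
was in the model.  Exact-zero draws from excluded states are not mixed in.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from pgxsig._gibbs import gibbs_kernel
from pgxsig.datatypes import ConfigError, DataError, SignatureModel

INTERCEPT = "(Intercept)"

RHAT_WARN = 1.1
ESS_WARN = 100.0


@dataclass(frozen=True)
class SpikeSlabConfig:
    n_iterations: int = 50_000
    burn_in_fraction: float = 0.1
    #: expected number of included terms; prior inclusion probability per
    #: term is min(0.5, expected_model_size / n_terms) unless overridden
    expected_model_size: float = 5.0
    prior_inclusion_probability: float | None = None
    #: slab precision is information_weight x (unit Fisher information at
    #: p=1/2), i.e. information_weight * mean(x_j^2) / 4
    information_weight: float = 1.0
    intercept_prior_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations <= 0:
            raise ConfigError("n_iterations must be positive")
        if not (0.0 <= self.burn_in_fraction < 1.0):
            raise ConfigError("burn_in_fraction must be in [0, 1)")
        if self.prior_inclusion_probability is not None and not (
            0.0 < self.prior_inclusion_probability < 1.0
        ):
            raise ConfigError("prior inclusion probability must be in (0, 1)")
        if self.information_weight <= 0:
            raise ConfigError("information_weight must be positive")

    @property
    def burn_in(self) -> int:
        return int(self.n_iterations * self.burn_in_fraction)


@dataclass
class SpikeSlabPosterior:
    terms: list[str]
    beta_draws: np.ndarray   # (draws, terms), zeros where excluded
    gamma_draws: np.ndarray  # (draws, terms) bool
    config: SpikeSlabConfig
    prior_inclusion: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def pip(self) -> pd.Series:
        """Posterior inclusion probability per term."""
        return pd.Series(self.gamma_draws.mean(axis=0), index=self.terms, name="pip")

    def _included(self, j: int) -> np.ndarray:
        return self.beta_draws[self.gamma_draws[:, j], j]

    @property
    def posterior_mean(self) -> pd.Series:
        """Posterior mean of each coefficient conditional on inclusion."""
        out = np.full(len(self.terms), np.nan)
        for j in range(len(self.terms)):
            inc = self._included(j)
            if inc.size:
                out[j] = inc.mean()
        return pd.Series(out, index=self.terms, name="posterior_mean")

    def credible_interval(self, level: float = 0.95) -> pd.DataFrame:
        lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
        rows = np.full((len(self.terms), 2), np.nan)
        for j in range(len(self.terms)):
            inc = self._included(j)
            if inc.size:
                rows[j] = np.quantile(inc, [lo_q, hi_q])
        return pd.DataFrame(rows, index=self.terms, columns=["lower", "upper"])

    def excludes_zero(self, term: str, level: float = 0.95) -> bool:
        ci = self.credible_interval(level).loc[term]
        if not np.isfinite(ci["lower"]):
            return False
        return bool(ci["lower"] > 0 or ci["upper"] < 0)

    def summary(self) -> pd.DataFrame:
        ci = self.credible_interval()
        return pd.DataFrame(
            {
                "pip": self.pip,
                "mean": self.posterior_mean,
                "ci_lower": ci["lower"],
                "ci_upper": ci["upper"],
            }
        )


def fit_spike_slab(
    design: pd.DataFrame,
    outcome: np.ndarray,
    config: SpikeSlabConfig | None = None,
) -> SpikeSlabPosterior:
    """Run the spike-and-slab sampler on a coded design matrix.

    ``design`` holds the coded SNPs (and optional covariates) without an
    intercept; the intercept is always included with a diffuse prior and is
    never subject to selection.  Rows with any missing value are dropped.
    An empty design (zero rows) is accepted and returns draws from the
    prior, which is useful for calibration checks.
    """
    config = config or SpikeSlabConfig()
    y = np.asarray(outcome, dtype=float)
    Xdf = design.astype(float)
    if len(Xdf) != y.size:
        raise DataError("design and outcome lengths differ")
    keep = ~(np.isnan(y) | Xdf.isna().any(axis=1).to_numpy())
    Xdf, y = Xdf.loc[keep], y[keep]
    n = len(Xdf)
    if n > 0:
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise DataError("outcome must be binary 0/1")
        if len(np.unique(y)) < 2:
            raise DataError("outcome must contain both classes")
        degenerate = [c for c in Xdf.columns if Xdf[c].std(ddof=0) == 0.0]
        if degenerate:
            raise DataError(f"degenerate design columns: {degenerate}")

    terms = [INTERCEPT] + list(Xdf.columns)
    p = len(terms)
    X = np.column_stack([np.ones(n), Xdf.to_numpy()]) if n else np.zeros((0, p))

    # slab precisions: unit-information scale per coefficient
    prior_prec = np.empty(p)
    prior_prec[0] = 1.0 / config.intercept_prior_sd**2
    for j in range(1, p):
        msq = float(np.mean(X[:, j] ** 2)) if n else 1.0
        prior_prec[j] = config.information_weight * 0.25 * max(msq, 1e-12)

    if config.prior_inclusion_probability is not None:
        pi = config.prior_inclusion_probability
    else:
        pi = min(0.5, config.expected_model_size / max(p - 1, 1))
    prior_incl = np.full(p, pi)
    always_in = np.zeros(p, dtype=np.bool_)
    always_in[0] = True
    prior_incl[0] = 1.0

    beta_draws, gamma_draws = gibbs_kernel(
        np.ascontiguousarray(X),
        y,
        prior_incl,
        prior_prec,
        config.n_iterations,
        config.seed,
        always_in,
    )
    burn = config.burn_in
    return SpikeSlabPosterior(
        terms=terms,
        beta_draws=beta_draws[burn:],
        gamma_draws=gamma_draws[burn:],
        config=config,
        prior_inclusion=prior_incl,
    )


def select_signature(
    posterior_with_covariates: SpikeSlabPosterior,
    posterior_without_covariates: SpikeSlabPosterior,
    snp_terms: list[str] | None = None,
    pip_min: float = 0.80,
) -> list[str]:
    """SNPs with PIP above ``pip_min`` and a zero-excluding 95% credible
    interval in both fits (with and without baseline covariates)."""
    if snp_terms is None:
        snp_terms = [t for t in posterior_without_covariates.terms if t != INTERCEPT]
    selected = []
    for term in snp_terms:
        ok = True
        for post in (posterior_with_covariates, posterior_without_covariates):
            if term not in post.terms:
                raise DataError(f"term {term!r} absent from posterior")
            if post.pip[term] <= pip_min or not post.excludes_zero(term):
                ok = False
                break
        if ok:
            selected.append(term)
    return selected


def screen_interactions(
    selected: list[str],
    design: pd.DataFrame,
    outcome: np.ndarray,
    config: SpikeSlabConfig | None = None,
) -> pd.Series:
    """PIPs for all pairwise products of the selected coded SNPs.

    The design is augmented with the product terms and refitted; returns
    the interaction-term PIPs (empty for fewer than two selected SNPs).
    """
    if len(selected) < 2:
        return pd.Series(dtype=float, name="pip")
    aug = design.copy()
    inter_terms = []
    for a, b in itertools.combinations(selected, 2):
        name = f"{a}:{b}"
        aug[name] = design[a] * design[b]
        inter_terms.append(name)
    post = fit_spike_slab(aug, outcome, config)
    return post.pip[inter_terms]


def refit_final(
    design: pd.DataFrame,
    outcome: np.ndarray,
    codings: dict[str, str] | None = None,
    level: float = 0.95,
) -> SignatureModel:
    """Plain maximum-likelihood logistic refit of the selected SNPs only.

    Returns the signature model with coefficients, exponentiated odds
    ratios and exponentiated Wald confidence intervals.  Separation is
    flagged on the model rather than raised.
    """
    y = np.asarray(outcome, dtype=float)
    Xdf = design.astype(float)
    keep = ~(np.isnan(y) | Xdf.isna().any(axis=1).to_numpy())
    Xdf, y = Xdf.loc[keep], y[keep]
    if Xdf.shape[1] == 0:
        raise DataError("selected SNP set is empty")
    X = sm.add_constant(Xdf.to_numpy())
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        except Exception:
            separated = True
            res = sm.Logit(y, X).fit(method="bfgs", disp=0, maxiter=500)
    params = np.asarray(res.params, dtype=float)
    if np.any(np.abs(params) > 15.0):
        separated = True
    ci = np.asarray(res.conf_int(alpha=1 - level), dtype=float)
    snp_ids = list(Xdf.columns)
    return SignatureModel(
        snp_ids=snp_ids,
        codings=[(codings or {}).get(s, "additive") for s in snp_ids],
        coefficients=[float(b) for b in params[1:]],
        intercept=float(params[0]),
        coef_ci=[(float(lo), float(hi)) for lo, hi in ci[1:]],
        separated=separated,
        meta={"n": int(len(y)), "level": level},
    )


# ---------------------------------------------------------------------------
# convergence diagnostics


def effective_sample_size(x: np.ndarray) -> float:
    """ESS via Geyer's initial positive sequence of autocorrelations."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        raise DataError("too few draws for ESS")
    v = x.var()
    if v == 0.0:
        return 0.0
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1 :] / n
    rho = acov / acov[0]
    # sum consecutive pairs while positive
    total = 0.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        total += pair
        t += 2
    ess = n / (1.0 + 2.0 * total)
    return float(min(ess, n))


def split_rhat(x: np.ndarray) -> float:
    """Potential scale reduction from the two halves of a single chain."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        raise DataError("too few draws for split-chain statistic")
    half = n // 2
    chains = np.stack([x[:half], x[half : 2 * half]])
    within = chains.var(axis=1, ddof=1).mean()
    if within == 0.0:
        return np.nan
    between = half * chains.mean(axis=1).var(ddof=1)
    var_plus = (half - 1) / half * within + between / half
    return float(np.sqrt(var_plus / within))


def diagnostics(posterior: SpikeSlabPosterior) -> pd.DataFrame:
    """Per-coefficient ESS and split-chain scale reduction with verdicts.

    A term warns when its split-chain statistic exceeds 1.1, its ESS falls
    below 100, or its draws are degenerate (stuck chain).
    """
    rows = []
    for j, term in enumerate(posterior.terms):
        draws = posterior.beta_draws[:, j]
        if draws.size < 4:
            raise DataError("too few draws for diagnostics")
        if posterior.pip.iloc[j] == 0.0:
            # never included: nothing to diagnose
            rows.append(
                {"term": term, "ess": np.nan, "rhat": np.nan, "verdict": "excluded"}
            )
            continue
        ess = effective_sample_size(draws)
        rhat = split_rhat(draws)
        stuck = draws.var() == 0.0
        warn = stuck or ess < ESS_WARN or (np.isfinite(rhat) and rhat > RHAT_WARN)
        rows.append(
            {
                "term": term,
                "ess": ess,
                "rhat": rhat,
                "verdict": "warn" if warn else "pass",
            }
        )
    return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# reference evidence computation for tiny problems (used by tests/oracles)


def enumerate_model_pips(
    design: pd.DataFrame,
    outcome: np.ndarray,
    config: SpikeSlabConfig | None = None,
    grid_sd: float = 7.0,
    grid_points: int = 61,
) -> pd.Series:
    """Exact-by-quadrature PIPs for small problems (p <= 3 predictors).

    Enumerates every inclusion configuration, computes each model's
    evidence by dense-grid integration of the logistic likelihood times the
    normal slab (grid centered on the per-model MAP), and returns the
    evidence-weighted inclusion probabilities.  Serves as the independent
    oracle for the MCMC sampler.
    """
    config = config or SpikeSlabConfig()
    y = np.asarray(outcome, dtype=float)
    Xdf = design.astype(float)
    p_terms = Xdf.shape[1]
    if p_terms > 3:
        raise ConfigError("enumeration oracle limited to 3 predictors")
    n = len(Xdf)
    X = np.column_stack([np.ones(n), Xdf.to_numpy()])

    prior_prec = np.empty(p_terms + 1)
    prior_prec[0] = 1.0 / config.intercept_prior_sd**2
    for j in range(1, p_terms + 1):
        prior_prec[j] = config.information_weight * 0.25 * np.mean(X[:, j] ** 2)
    if config.prior_inclusion_probability is not None:
        pi = config.prior_inclusion_probability
    else:
        pi = min(0.5, config.expected_model_size / p_terms)

    def log_evidence(active: tuple[int, ...]) -> float:
        idx = np.array(active)
        Xa = X[:, idx]
        prec = prior_prec[idx]

        def neg_log_post(beta):
            lp = Xa @ beta
            ll = np.sum(y * lp - np.log1p(np.exp(lp)))
            return -(ll - 0.5 * np.sum(prec * beta**2))

        from scipy.optimize import minimize

        opt = minimize(neg_log_post, np.zeros(idx.size), method="BFGS")
        mode = opt.x
        # curvature-scaled grid around the mode
        pr = 1.0 / (1.0 + np.exp(-(Xa @ mode)))
        H = (Xa * (pr * (1 - pr))[:, None]).T @ Xa + np.diag(prec)
        sds = np.sqrt(np.diag(np.linalg.inv(H)))
        axes = [
            np.linspace(m - grid_sd * s, m + grid_sd * s, grid_points)
            for m, s in zip(mode, sds)
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        B = np.stack([m.ravel() for m in mesh], axis=1)  # (G, k)
        lp = B @ Xa.T  # (G, n)
        loglik = lp @ y - np.log1p(np.exp(lp)).sum(axis=1)
        logprior = -0.5 * np.sum(prec * B**2, axis=1) + 0.5 * np.sum(
            np.log(prec / (2 * np.pi))
        )
        logint = loglik + logprior
        step = np.prod([a[1] - a[0] for a in axes])
        m = logint.max()
        return float(m + np.log(np.exp(logint - m).sum() * step))

    log_weights = {}
    for r in range(p_terms + 1):
        for combo in itertools.combinations(range(1, p_terms + 1), r):
            active = (0,) + combo
            prior = r * np.log(pi) + (p_terms - r) * np.log(1 - pi)
            log_weights[combo] = log_evidence(active) + prior
    lw = np.array(list(log_weights.values()))
    w = np.exp(lw - lw.max())
    w /= w.sum()
    pips = np.zeros(p_terms)
    for weight, combo in zip(w, log_weights):
        for j in combo:
            pips[j - 1] += weight
    return pd.Series(pips, index=list(Xdf.columns), name="pip")
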