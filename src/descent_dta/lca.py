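"""Bayesian two-class latent class analysis for diagnostic test accuracy
without a gold standard.

Each of J binary tests (here: the binarised dynamic-descent result of each
imaging modality) is an imperfect observation of an unobserved binary disease
state. Conditional on the state, tests are independent (readings were blinded
to each other), so the likelihood for patient i with latent class z_i is

    prod_j theta_{j, z_i}^{y_ij} (1 - theta_{j, z_i})^{1 - y_ij}

over the tests j that were observed for i; theta_{j,1} is test j's
sensitivity and 1 - theta_{j,0} its specificity, and the class indicator has
prior pi = P(diseased). With Beta priors on pi and every theta the full
conditionals are conjugate, giving a standard Gibbs sampler:

  1. each z_i from its Bernoulli posterior given (pi, theta) and row i's
     observed entries (missing entries contribute no factor);
  2. pi from Beta(a + n_diseased, b + n_healthy);
  3. theta_{jc} from Beta(a + positives, b + negatives) over patients
     currently in class c with test j observed.

Label switching is resolved per draw by relabelling so the "diseased" class
is the one with the larger mean positivity across tests. Defaults: B(1,1)
priors throughout, 100,000 iterations, burn-in 5,000, thinning 20 (4,750
retained draws).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LCAConfig:
    prior_prevalence: tuple[float, float] = (1.0, 1.0)
    prior_positivity: tuple[float, float] = (1.0, 1.0)
    burn_in: int = 5_000
    iterations: int = 100_000
    thinning: int = 20
    rng_seed: int = 0

    def validate(self) -> None:
        if self.burn_in >= self.iterations:
            raise ConfigurationError("burn_in must be < iterations")
        if self.thinning < 1:
            raise ConfigurationError("thinning must be >= 1")
        for pair in (self.prior_prevalence, self.prior_positivity):
            if pair[0] <= 0 or pair[1] <= 0:
                raise ConfigurationError("Beta prior parameters must be > 0")

    @property
    def n_retained(self) -> int:
        # every thinning-th post-burn-in draw: floor((iterations - burn_in)/thinning)
        return (self.iterations - self.burn_in) // self.thinning


@dataclass
class LCAPosterior:
    """Retained Gibbs draws.

    ``theta`` has shape (draws, tests, 2): positivity probability of each test
    in the healthy (index 0) and diseased (index 1) class. ``prevalence`` has
    shape (draws,).
    """

    test_names: list[str]
    prevalence: np.ndarray
    theta: np.ndarray

    @property
    def n_draws(self) -> int:
        return self.prevalence.size

    @property
    def sensitivity(self) -> np.ndarray:  # (draws, tests)
        return self.theta[:, :, 1]

    @property
    def specificity(self) -> np.ndarray:  # (draws, tests)
        return 1.0 - self.theta[:, :, 0]

    def parameter_draws(self) -> dict[str, np.ndarray]:
        """Named scalar chains, for diagnostics."""
        out = {"prevalence": self.prevalence}
        for j, name in enumerate(self.test_names):
            out[f"sens_{name}"] = self.sensitivity[:, j]
            out[f"spec_{name}"] = self.specificity[:, j]
        return out


def validate_matrix(matrix: pd.DataFrame) -> np.ndarray:
    """Check a patients x tests binary matrix and return a float array
    (1.0 positive / 0.0 negative / NaN missing)."""
    if matrix.shape[1] < 2:
        raise SchemaError("latent class analysis needs >= 2 tests")
    y = matrix.to_numpy(dtype=float)
    observed = ~np.isnan(y)
    if not observed.any(axis=1).all():
        bad = matrix.index[~observed.any(axis=1)].tolist()
        raise SchemaError(f"patients with no observed test result: {bad}")
    vals = y[observed]
    if not np.isin(vals, (0.0, 1.0)).all():
        raise SchemaError("test matrix entries must be 0, 1 or missing")
    for j, name in enumerate(matrix.columns):
        col = y[:, j]
        col = col[~np.isnan(col)]
        if col.size and (col == col[0]).all():
            logger.warning("test %s shows no variation; proceeding", name)
    return y


def gibbs_lca(matrix: pd.DataFrame, config: LCAConfig | None = None) -> LCAPosterior:
    """Run the Gibbs sampler on a patients x tests binary matrix.

    Missing entries (NaN) drop out of every full conditional. The latent
    classes are initialised by thresholding each patient's positive-test
    count at the cohort median. Deterministic given ``config.rng_seed``.
    """
    config = config or LCAConfig()
    config.validate()
    y = validate_matrix(matrix)
    n, n_tests = y.shape
    observed = ~np.isnan(y)
    y0 = np.nan_to_num(y, nan=0.0)

    rng = np.random.default_rng(config.rng_seed)
    a_pi, b_pi = config.prior_prevalence
    a_th, b_th = config.prior_positivity

    pos_count = y0.sum(axis=1)
    z = (pos_count > np.median(pos_count)).astype(int)
    pi = 0.5
    theta = np.full((n_tests, 2), 0.5)

    keep_prev = np.empty(config.n_retained)
    keep_theta = np.empty((config.n_retained, n_tests, 2))
    kept = 0

    for it in range(config.iterations):
        # 1. latent classes: log-odds of diseased vs healthy per patient
        with np.errstate(divide="ignore"):
            log_theta = np.log(theta)
            log_1m = np.log1p(-theta)
        # contribution of observed entries only
        ll = np.zeros((n, 2))
        for c in (0, 1):
            term = y0 * log_theta[:, c] + (1.0 - y0) * log_1m[:, c]
            ll[:, c] = np.where(observed, term, 0.0).sum(axis=1)
        logit = (ll[:, 1] - ll[:, 0]) + (np.log(pi) - np.log1p(-pi))
        p_dis = 1.0 / (1.0 + np.exp(-np.clip(logit, -700, 700)))
        z = (rng.random(n) < p_dis).astype(int)

        # 2. prevalence
        n_dis = int(z.sum())
        pi = rng.beta(a_pi + n_dis, b_pi + n - n_dis)
        pi = min(max(pi, 1e-12), 1 - 1e-12)

        # 3. per-test class-conditional positivity
        for c in (0, 1):
            in_c = z == c
            obs_c = observed[in_c]
            pos = (y0[in_c] * obs_c).sum(axis=0)
            tot = obs_c.sum(axis=0)
            theta[:, c] = rng.beta(a_th + pos, b_th + tot - pos)

        # label identification: diseased class = larger mean positivity
        if theta[:, 1].mean() < theta[:, 0].mean():
            theta = theta[:, ::-1].copy()
            pi = 1.0 - pi
            z = 1 - z

        if it >= config.burn_in and (it - config.burn_in + 1) % config.thinning == 0:
            keep_prev[kept] = pi
            keep_theta[kept] = theta
            kept += 1

    assert kept == config.n_retained
    return LCAPosterior(
        test_names=list(matrix.columns),
        prevalence=keep_prev,
        theta=keep_theta,
    )


def log_likelihood(matrix: pd.DataFrame, pi: float, theta: np.ndarray) -> float:
    """Marginal log-likelihood of the observed matrix at fixed parameters.

    Sums, over patients, the log of the two-class mixture
    ``(1-pi) P(row | healthy) + pi P(row | diseased)`` with missing entries
    contributing no factor. ``theta`` has shape (tests, 2).
    """
    y = validate_matrix(matrix)
    observed = ~np.isnan(y)
    y0 = np.nan_to_num(y, nan=0.0)
    for c, weight in ((0, 1.0 - pi), (1, pi)):
        term = y0 * np.log(theta[:, c]) + (1.0 - y0) * np.log1p(-theta[:, c])
        ll_c = np.where(observed, term, 0.0).sum(axis=1)
        if c == 0:
            acc = np.log(weight) + ll_c
        else:
            acc = np.logaddexp(acc, np.log(weight) + ll_c)
    return float(acc.sum())


# --- derived diagnostic-accuracy metrics -------------------------------------

METRICS = ("sensitivity", "specificity", "auc", "ppv", "npv", "lr_pos", "lr_neg")


def _summarise(draws: np.ndarray) -> dict[str, float]:
    """Posterior mean (over finite draws), median and equal-tailed 95% CrI.

    Percentiles use all draws (they are robust to infinities); infinite draws
    are excluded from the mean and their count logged by the caller.
    """
    finite = draws[np.isfinite(draws)]
    # linear interpolation is undefined against +/-inf; fall back to the
    # nearest order statistic when infinite draws are present
    method = "linear" if finite.size == draws.size else "nearest"
    return {
        "mean": float(finite.mean()) if finite.size else float("inf"),
        "median": float(np.percentile(draws, 50, method=method)),
        "cri_low": float(np.percentile(draws, 2.5, method=method)),
        "cri_high": float(np.percentile(draws, 97.5, method=method)),
    }


def derive_metrics(posterior: LCAPosterior) -> pd.DataFrame:
    """Per-draw diagnostic-accuracy metrics, summarised per test.

    For each retained draw with prevalence pi, sensitivity se and specificity
    sp:

        PPV  = pi se / (pi se + (1 - pi)(1 - sp))
        NPV  = (1 - pi) sp / ((1 - pi) sp + pi (1 - se))
        LR+  = se / (1 - sp)        LR- = (1 - se) / sp
        AUC  = (se + sp) / 2

    Draws with sp = 1 give LR+ = +inf; these are kept for the percentiles but
    excluded from the posterior mean (the exclusion count is logged). Returns
    one row per (test, metric) plus a prevalence row, each with posterior
    mean, median and 95% equal-tailed credibility interval.
    """
    if posterior.n_draws == 0:
        raise ValueError("posterior has no retained draws")
    pi = posterior.prevalence
    rows = []
    for j, name in enumerate(posterior.test_names):
        se = posterior.sensitivity[:, j]
        sp = posterior.specificity[:, j]
        with np.errstate(divide="ignore", invalid="ignore"):
            per_draw = {
                "sensitivity": se,
                "specificity": sp,
                "auc": (se + sp) / 2.0,
                "ppv": pi * se / (pi * se + (1 - pi) * (1 - sp)),
                "npv": (1 - pi) * sp / ((1 - pi) * sp + pi * (1 - se)),
                "lr_pos": se / (1 - sp),
                "lr_neg": (1 - se) / sp,
            }
        for metric, draws in per_draw.items():
            n_inf = int((~np.isfinite(draws)).sum())
            if n_inf:
                logger.info(
                    "%s %s: %d infinite draw(s) excluded from the mean",
                    name, metric, n_inf,
                )
            rows.append({"test": name, "metric": metric, **_summarise(draws)})
    rows.append({"test": "(cohort)", "metric": "prevalence", **_summarise(pi)})
    return pd.DataFrame(rows)


# --- convergence diagnostics --------------------------------------------------


def effective_sample_size(chain: np.ndarray) -> float:
    """ESS from the autocovariance: n / (1 + 2 sum rho_k).

    Autocorrelations are summed with Geyer's initial positive sequence rule
    (stop when the sum of an even/odd lag pair turns non-positive), the usual
    window for MCMC output. A constant chain returns 0.
    """
    x = np.asarray(chain, dtype=float)
    n = x.size
    if n < 4 or np.ptp(x) == 0.0:
        return 0.0
    x = x - x.mean()
    acov = np.correlate(x, x, mode="full")[n - 1 :] / n
    rho = acov / acov[0]
    s = 0.0
    k = 1
    while k + 1 < n:
        pair = rho[k] + rho[k + 1]
        if pair <= 0:
            break
        s += pair
        k += 2
    return float(n / (1.0 + 2.0 * s))


def geweke_z(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence score: z-difference of early vs late segment means,
    with segment variances scaled by each segment's effective sample size."""
    x = np.asarray(chain, dtype=float)
    n = x.size
    a = x[: int(first * n)]
    b = x[int((1 - last) * n) :]
    if np.ptp(x) == 0.0:
        return 0.0
    var_a = a.var(ddof=1) / max(effective_sample_size(a), 1.0)
    var_b = b.var(ddof=1) / max(effective_sample_size(b), 1.0)
    denom = math.sqrt(var_a + var_b)
    if denom == 0.0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def diagnostics(
    posterior: LCAPosterior, ess_floor: float = 400.0, z_limit: float = 3.0
) -> pd.DataFrame:
    """Convergence report: ESS and Geweke z per parameter, with flags."""
    rows = []
    for name, chain in posterior.parameter_draws().items():
        degenerate = np.ptp(chain) == 0.0
        ess = effective_sample_size(chain)
        z = geweke_z(chain)
        flagged = degenerate or ess < ess_floor or abs(z) > z_limit
        rows.append(
            {
                "parameter": name,
                "ess": ess,
                "geweke_z": z,
                "degenerate": degenerate,
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)
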