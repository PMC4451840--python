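"""Randomisation inference, grounding-rate GLMs and population back-calculation.

The inference toolkit mirrors a small-sample movement-ecology workflow:

* two-group randomisation tests (difference of means), enumerated exhaustively
  when the number of distinct group reassignments C(n, n1) is small and
  Monte-Carlo sampled otherwise, with the add-one (b+1)/(m+1) convention;
* one-tailed Monte-Carlo Spearman rank tests (default 9,999 replications);
* the Yates continuity-corrected 2×2 chi-square;
* univariate grouped-binomial logit GLMs ranked by AICc with % deviance
  explained, plus VIF collinearity screening;
* the mark-recovery back-calculation of breeding pairs from annual rescue
  counts, a grounding (affection) rate, and breeding success.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)

EXHAUSTIVE_LIMIT = 200_000
DEFAULT_ITERATIONS = 9_999

GLM_COVARIATES = (
    "distance_to_sea_m",
    "elevation_m",
    "radiance_mean_3km",
    "radiance_max_3km",
    "radiance_at_colony",
)


# ---------------------------------------------------------------------------
# result types


@dataclass(frozen=True)
class PermutationTestResult:
    statistic: float  # mean(x) − mean(y)
    p_value: float
    method: str  # "exhaustive" | "monte_carlo"
    tail: str
    n_arrangements: int | None = None
    n_iterations: int | None = None


@dataclass(frozen=True)
class CorrelationTestResult:
    rho: float
    p_value: float
    n: int
    tail: str
    n_iterations: int


@dataclass(frozen=True)
class GlmFit:
    """One fitted grounding-rate model (grouped binomial, logit link)."""

    covariate: str  # "none" for the intercept-only model
    params: dict  # term -> estimate
    bse: dict  # term -> standard error
    ci95: dict  # term -> (low, high), Wald
    log_likelihood: float
    residual_deviance: float
    null_deviance: float
    k: int
    n: int
    aic: float
    aicc: float
    deviance_explained_pct: float


@dataclass(frozen=True)
class PopulationEstimate:
    rescued: int
    grounding_rate: float
    breeding_success: float
    pairs_raw: float
    pairs: int  # floored to the nearest hundred


# ---------------------------------------------------------------------------
# randomisation tests


def count_arrangements(n: int, n1: int) -> int:
    """Number of distinct two-group reassignments, the exact C(n, n1)."""
    if n < 0 or n1 < 0 or n1 > n:
        raise ValueError("need 0 <= n1 <= n")
    return math.comb(n, n1)


def _tail_count(null_stats, observed, tail, atol):
    null_stats = np.asarray(null_stats, dtype=float)
    if tail == "two_sided":
        return int(np.sum(np.abs(null_stats) >= abs(observed) - atol))
    if tail == "greater":
        return int(np.sum(null_stats >= observed - atol))
    if tail == "less":
        return int(np.sum(null_stats <= observed + atol))
    raise ValueError(f"unknown tail {tail!r}")


def randomisation_test(
    x,
    y,
    tail: str = "two_sided",
    exhaustive_limit: int = EXHAUSTIVE_LIMIT,
    n_iterations: int = DEFAULT_ITERATIONS,
    seed: int | None = None,
) -> PermutationTestResult:
    """Two-group randomisation test on the difference of group means.

    All C(n, n1) group reassignments are enumerated exactly when their count
    is at most ``exhaustive_limit``; otherwise ``n_iterations`` reassignments
    are sampled without replacement within each draw, and the Monte-Carlo
    p-value is (b+1)/(m+1), which includes the observed arrangement and never
    reaches zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    observed = float(x.mean() - y.mean())
    atol = 1e-12 * (1.0 + float(np.abs(pooled).max()))
    if np.ptp(pooled) == 0:
        warnings.warn("pooled data are constant; p = 1", stacklevel=2)
        return PermutationTestResult(observed, 1.0, "exhaustive", tail, n_arrangements=1)

    n, n1 = pooled.size, x.size
    total = count_arrangements(n, n1)
    if total <= exhaustive_limit:
        null_stats = []
        pooled_sum = pooled.sum()
        for idx in combinations(range(n), n1):
            sx = pooled[list(idx)].sum()
            null_stats.append(sx / n1 - (pooled_sum - sx) / (n - n1))
        b = _tail_count(null_stats, observed, tail, atol)
        return PermutationTestResult(observed, b / total, "exhaustive", tail, n_arrangements=total)

    rng = np.random.default_rng(seed)
    perm = np.array([rng.permutation(n)[:n1] for _ in range(n_iterations)])
    sx = pooled[perm].sum(axis=1)
    null_stats = sx / n1 - (pooled.sum() - sx) / (n - n1)
    b = _tail_count(null_stats, observed, tail, atol)
    return PermutationTestResult(
        observed, (b + 1) / (n_iterations + 1), "monte_carlo", tail, n_iterations=n_iterations
    )


def spearman_mc_test(
    u,
    v,
    tail: str = "greater",
    n_iterations: int = DEFAULT_ITERATIONS,
    seed: int | None = None,
) -> CorrelationTestResult:
    """One-tailed Monte-Carlo Spearman rank test of independence.

    rho is computed on average ranks (ties allowed); the null distribution is
    built by permuting ``v`` ``n_iterations`` times; p = (b+1)/(m+1) in the
    stated direction.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.size != v.size or u.size < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    if np.ptp(u) == 0 or np.ptp(v) == 0:
        raise ValueError("constant vector: Spearman rho undefined")
    ru = stats.rankdata(u)
    rv = stats.rankdata(v)
    ru_c = (ru - ru.mean()) / np.sqrt(np.sum((ru - ru.mean()) ** 2))
    rv_c = (rv - rv.mean()) / np.sqrt(np.sum((rv - rv.mean()) ** 2))
    rho = float(ru_c @ rv_c)
    rng = np.random.default_rng(seed)
    null = np.empty(n_iterations)
    for i in range(n_iterations):
        null[i] = ru_c @ rv_c[rng.permutation(v.size)]
    atol = 1e-12
    if tail == "greater":
        b = int(np.sum(null >= rho - atol))
    elif tail == "less":
        b = int(np.sum(null <= rho + atol))
    else:
        raise ValueError("tail must be 'greater' or 'less' (one-tailed test)")
    return CorrelationTestResult(rho, (b + 1) / (n_iterations + 1), int(u.size), tail, n_iterations)


def yates_chi2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Yates continuity-corrected chi-square for the 2×2 table [[a, b], [c, d]].

    The 0.5 correction is clamped at |O − E| so near-proportional tables
    cannot yield a negative statistic; p from chi-square with 1 df.
    """
    obs = np.array([[a, b], [c, d]], dtype=float)
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("all table margins must be positive")
    exp = np.outer(row, col) / obs.sum()
    corr = np.maximum(np.abs(obs - exp) - 0.5, 0.0)
    chi2 = float(np.sum(corr**2 / exp))
    return chi2, float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# grounding-rate GLMs


def _colony_arrays(colonies, covariate):
    succ = np.array([c.n_recovered for c in colonies], dtype=float)
    fail = np.array([c.n_banded - c.n_recovered for c in colonies], dtype=float)
    if covariate == "none":
        exog = np.ones((len(colonies), 1))
        names = ["intercept"]
    else:
        x = np.array([getattr(c, covariate) for c in colonies], dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"covariate {covariate!r} has non-finite values")
        exog = np.column_stack([np.ones(len(colonies)), x])
        names = ["intercept", covariate]
    return np.column_stack([succ, fail]), exog, names


def fit_binomial_logit(colonies, covariate: str = "none") -> GlmFit:
    """Fit one univariate grouped-binomial logit model of the recovery rate.

    The response is the two-column (recovered, not-recovered) matrix per
    colony; the fit is IRLS maximum likelihood.  AICc uses the number of
    colonies as the sample size and counts the intercept in k.
    """
    if len(colonies) < 3:
        raise ValueError("need at least 3 colonies")
    endog, exog, names = _colony_arrays(colonies, covariate)
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    res = model.fit(tol=1e-10, maxiter=200)
    if np.any(np.abs(res.params) > 1e3) or np.any(res.bse > 1e5) or not np.all(np.isfinite(res.bse)):
        raise ValueError(f"complete separation (or unstable fit) for covariate {covariate!r}")
    k = exog.shape[1]
    n = len(colonies)
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n − k − 1 = {n - k - 1} <= 0")
    ll = float(res.llf)
    aic = -2.0 * ll + 2.0 * k
    aicc = aic + 2.0 * k * (k + 1) / (n - k - 1)
    params = dict(zip(names, (float(p) for p in res.params)))
    bse = dict(zip(names, (float(s) for s in res.bse)))
    ci95 = {t: (params[t] - 1.96 * bse[t], params[t] + 1.96 * bse[t]) for t in names}
    null_dev = float(res.null_deviance)
    resid_dev = float(res.deviance)
    if covariate == "none":
        null_dev = resid_dev  # identical by definition; avoid float residue
    return GlmFit(
        covariate=covariate,
        params=params,
        bse=bse,
        ci95=ci95,
        log_likelihood=ll,
        residual_deviance=resid_dev,
        null_deviance=null_dev,
        k=k,
        n=n,
        aic=aic,
        aicc=aicc,
        deviance_explained_pct=100.0 * (null_dev - resid_dev) / null_dev if null_dev > 0 else 0.0,
    )


def rank_models(fits: list[GlmFit]) -> pd.DataFrame:
    """Candidate-model table ordered by AICc with ΔAICc and % deviance explained."""
    if not fits:
        raise ValueError("need at least one fit")
    if len({f.n for f in fits}) != 1:
        raise ValueError("all fits must be on the identical colony set")
    best = min(f.aicc for f in fits)
    rows = []
    for f in sorted(fits, key=lambda f: f.aicc):
        slope = f.covariate if f.covariate != "none" else None
        rows.append(
            {
                "covariate": f.covariate,
                "estimate": f.params[slope] if slope else float("nan"),
                "se": f.bse[slope] if slope else float("nan"),
                "ci_low": f.ci95[slope][0] if slope else float("nan"),
                "ci_high": f.ci95[slope][1] if slope else float("nan"),
                "aicc": f.aicc,
                "delta_aicc": f.aicc - best,
                "deviance_explained_pct": f.deviance_explained_pct,
            }
        )
    return pd.DataFrame(rows)


def vif(colonies, covariates=GLM_COVARIATES) -> dict[str, float]:
    """Variance inflation factors among colony covariates.

    VIF_j = 1/(1 − R²_j) from the OLS regression of covariate j on the others
    (with intercept).  Perfect collinearity yields inf.
    """
    covariates = list(covariates)
    if len(colonies) < len(covariates) + 2:
        raise ValueError("need at least covariates + 2 colonies")
    xmat = np.column_stack([[getattr(c, v) for c in colonies] for v in covariates])
    out = {}
    for j, name in enumerate(covariates):
        yj = xmat[:, j]
        others = np.column_stack([np.ones(len(colonies)), np.delete(xmat, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        if ss_tot == 0:
            out[name] = float("inf")
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


# ---------------------------------------------------------------------------
# recovery rates and population back-calculation


def pooled_recovery_rate(n_recovered: int, n_banded: int) -> float:
    """Recovery (grounding/affection) rate as a fraction."""
    if n_banded <= 0:
        raise ValueError("n_banded must be positive")
    if not 0 <= n_recovered <= n_banded:
        raise ValueError("need 0 <= n_recovered <= n_banded")
    return n_recovered / n_banded


def estimate_population(rescued: int, grounding_rate: float, breeding_success: float) -> PopulationEstimate:
    """Back-calculate breeding pairs from annual rescue counts.

    pairs = rescued / (grounding_rate × breeding_success), floored to the
    nearest hundred (the raw value is also kept).
    """
    if rescued < 0:
        raise ValueError("rescued must be >= 0")
    if not 0 < grounding_rate <= 1 or not 0 < breeding_success <= 1:
        raise ValueError("rate and success must be in (0, 1]")
    raw = rescued / (grounding_rate * breeding_success)
    return PopulationEstimate(
        rescued=rescued,
        grounding_rate=grounding_rate,
        breeding_success=breeding_success,
        pairs_raw=raw,
        pairs=int(raw // 100) * 100,
    )
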