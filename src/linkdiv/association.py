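"""Rank correlations, rank-sum contrasts, and linear models on window records.

The analysis asks whether neutral nucleotide diversity tracks local
recombination rate across the genome, as predicted by selection at linked
sites.  Three complementary statistics are run on the joined per-window
records:

* Spearman's rank correlation between a diversity estimator and the
  recombination rate (and between any other pair of window variables);
* Wilcoxon rank-sum contrasts — diversity in windows in the extreme
  high-rate vs. low-rate percentile classes (two-sided), and diversity in
  windows with vs. without double-strand-break hotspots (one-sided, hotspots
  higher under the alternative);
* ordinary least squares with diversity as the response and recombination
  rate, divergence, CpG count, transcribed proportion, and the
  CpG x transcribed interaction as predictors.

P-value conventions: Spearman uses the exact permutation null for n <= 10
and the t approximation above; the rank-sum test uses exact enumeration for
n1 + n2 <= 12 and a tie- and continuity-corrected normal approximation
otherwise.  No multiple-testing correction is applied; a Bonferroni summary
is logged for transparency.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MODEL_TERMS = ["intercept", "rate", "jc_div", "cpg_count", "tx_prop", "cpg_x_tx"]


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n_windows: int
    x_label: str = "x"
    y_label: str = "y"


@dataclass(frozen=True)
class RankTestResult:
    statistic: float  # Mann-Whitney U for the first group
    p_value: float
    alternative: str
    n1: int
    n2: int


@dataclass(frozen=True)
class ModelFit:
    terms: pd.DataFrame  # index: term; columns: estimate, std_error, p_value
    n: int
    r_squared: float
    response: str = "theta_pi"


def _midranks(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def spearman(x, y, x_label: str = "x", y_label: str = "y") -> CorrelationResult:
    """Spearman's rho with midrank ties.

    rho is the Pearson correlation of the rank vectors.  For n <= 10 the
    two-sided p-value is an exact permutation enumeration of |rho|; above
    that, the t approximation t = rho * sqrt((n - 2) / (1 - rho^2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 paired observations, got {n}")
    rx, ry = _midranks(x), _midranks(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        logger.warning("zero variance in a rank vector; correlation undefined")
        return CorrelationResult(np.nan, np.nan, n, x_label, y_label)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 10:
        p = _spearman_exact_p(rx, ry, rho)
    else:
        rho_c = min(max(rho, -1 + 1e-15), 1 - 1e-15)
        t = rho_c * math.sqrt((n - 2) / (1.0 - rho_c**2))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return CorrelationResult(rho, float(min(p, 1.0)), n, x_label, y_label)


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p: share of permutations with |rho| >= |rho_obs|."""
    n = len(rx)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    target = abs(rho_obs) - 1e-12
    count = total = 0
    perms = itertools.permutations(range(n))
    while True:
        chunk = list(itertools.islice(perms, 200_000))
        if not chunk:
            break
        idx = np.asarray(chunk, dtype=np.int8)
        r = (ryc[idx] @ rxc) / denom
        count += int(np.sum(np.abs(r) >= target))
        total += len(chunk)
    return count / total


def wilcoxon_ranksum(group_a, group_b, alternative: str = "two-sided") -> RankTestResult:
    """Mann-Whitney/Wilcoxon rank-sum test with midrank ties.

    ``alternative='greater'`` tests whether ``group_a`` is stochastically
    larger than ``group_b``.  Exact enumeration of rank assignments is used
    when n1 + n2 <= 12; otherwise the normal approximation with tie
    correction and a 0.5 continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    if alternative not in {"two-sided", "greater", "less"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0

    if n1 + n2 <= 12:
        p = _ranksum_exact_p(ranks, n1, u1, alternative)
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var == 0:
            p = 1.0
        else:
            sd = math.sqrt(var)
            if alternative == "two-sided":
                z = (abs(u1 - mu) - 0.5) / sd
                p = 2.0 * stats.norm.sf(max(z, 0.0))
            elif alternative == "greater":
                z = (u1 - mu - 0.5) / sd
                p = stats.norm.sf(z)
            else:
                z = (u1 - mu + 0.5) / sd
                p = stats.norm.cdf(z)
    return RankTestResult(u1, float(min(p, 1.0)), alternative, n1, n2)


def _ranksum_exact_p(ranks: np.ndarray, n1: int, u_obs: float, alternative: str) -> float:
    """Exact p over all C(n, n1) assignments of the observed (mid)ranks to group a."""
    n = len(ranks)
    offset = n1 * (n1 + 1) / 2.0
    us = np.array([ranks[list(c)].sum() - offset
                   for c in itertools.combinations(range(n), n1)])
    eps = 1e-9
    p_greater = float(np.mean(us >= u_obs - eps))
    p_less = float(np.mean(us <= u_obs + eps))
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2.0 * min(p_greater, p_less))


def build_design(records: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Design matrix [1, rate, jc_div, cpg_count, tx_prop, cpg_count*tx_prop]."""
    x = np.column_stack([
        np.ones(len(records)),
        records["rate"].to_numpy(dtype=float),
        records["jc_div"].to_numpy(dtype=float),
        records["cpg_count"].to_numpy(dtype=float),
        records["tx_prop"].to_numpy(dtype=float),
        records["cpg_count"].to_numpy(dtype=float) * records["tx_prop"].to_numpy(dtype=float),
    ])
    return x, list(MODEL_TERMS)


def fit_linear_model(records: pd.DataFrame, response: str = "theta_pi") -> ModelFit:
    """OLS of a diversity estimator on rate, divergence, CpG count, transcribed
    proportion and the CpG x transcribed interaction (complete cases only)."""
    import statsmodels.api as sm

    needed = ["rate", "jc_div", "cpg_count", "tx_prop", response]
    cc = records.dropna(subset=needed)
    if "eligible" in cc.columns:
        cc = cc[cc["eligible"]]
    x, terms = build_design(cc)
    if len(cc) <= x.shape[1]:
        raise ValueError(f"too few complete-case windows ({len(cc)}) for {x.shape[1]} terms")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name the collinear culprits for the error message
        bad = []
        for j in range(1, x.shape[1]):
            keep = [c for c in range(x.shape[1]) if c != j]
            if np.linalg.matrix_rank(x[:, keep]) == rank:
                bad.append(terms[j])
        raise ValueError(f"rank-deficient design; collinear terms: {bad or 'unknown'}")
    fit = sm.OLS(cc[response].to_numpy(dtype=float), x).fit()
    table = pd.DataFrame({"estimate": fit.params, "std_error": fit.bse,
                          "p_value": fit.pvalues}, index=terms)
    k_tests = x.shape[1] - 1
    logger.info("OLS %s ~ covariates: n=%d R2=%.4g; Bonferroni alpha=0.05/%d=%.3g",
                response, len(cc), fit.rsquared, k_tests, 0.05 / k_tests)
    return ModelFit(terms=table, n=len(cc), r_squared=float(fit.rsquared),
                    response=response)


def percentile_contrast(records: pd.DataFrame, response: str = "theta_pi",
                        class_col: str = "rate_class") -> RankTestResult:
    """Two-sided rank-sum contrast of the response between the high- and
    low-recombination percentile classes."""
    high = records.loc[records[class_col] == "high", response].dropna()
    low = records.loc[records[class_col] == "low", response].dropna()
    if not len(high) or not len(low):
        raise ValueError("both percentile classes must be populated")
    return wilcoxon_ranksum(high, low, alternative="two-sided")


def hotspot_contrast(records: pd.DataFrame, response: str = "theta_pi") -> RankTestResult:
    """One-sided rank-sum contrast: windows containing hotspots are tested for
    higher diversity than windows without."""
    with_hs = records.loc[records["hotspot_presence"].astype(bool), response].dropna()
    without = records.loc[~records["hotspot_presence"].astype(bool), response].dropna()
    if not len(with_hs) or not len(without):
        raise ValueError("need windows both with and without hotspots")
    return wilcoxon_ranksum(with_hs, without, alternative="greater")
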