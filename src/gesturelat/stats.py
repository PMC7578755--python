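"""The cohort-level statistical battery.

Implements the tests the gesture-laterality analysis relies on, with the
conventions spelled out per test:

* Spearman rank correlation (mid-ranks; p via the t approximation on n-2 df,
  exact permutation p available for small n),
* Mann-Whitney U with an exact null distribution (rank-sum count recursion)
  whenever n1*n2 <= 400 and the data are tie-free, otherwise the normal
  approximation with tie correction,
* one-sample and paired t tests,
* the default JZS Bayes factor for a t test (Cauchy prior on the standardised
  effect, scale r; numerical quadrature),
* the 2 (group) x 2 (arm) mixed ANOVA via its exact sum/difference-score
  decomposition (Type III, unweighted means),
* ANCOVA with Type III sums of squares (through an OLS fit),
* a robust median/MAD outlier rule that flags — never silently deletes.

Every result is returned as a :class:`StatResult` that records the options
used (exact vs approximate, tie handling, prior scale), so reports are
self-describing.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import integrate
from scipy import stats as sps

MAX_EXACT_U_PRODUCT = 400
DEFAULT_BF_RSCALE = 0.707
MAD_SCALE = 1.4826  # consistency constant for the normal distribution


class StatError(ValueError):
    """Raised when a test's preconditions are not met (degenerate input)."""


@dataclass
class StatResult:
    """One test's outcome with enough metadata to reproduce it."""

    name: str
    statistic: float
    stat_symbol: str
    df: tuple | float | None
    p: float
    n: tuple | int
    direction: str = ""
    bayes_factor_10: float | None = None
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.p is not None and not (0.0 <= self.p <= 1.0):
            raise StatError(f"p value {self.p} outside [0, 1]")
        if self.bayes_factor_10 is not None and self.bayes_factor_10 <= 0:
            raise StatError("BF10 must be positive")

    def summary(self) -> str:
        df = self.df
        dftxt = f"({df[0]:g}, {df[1]:g})" if isinstance(df, tuple) else (
            f"({df:g})" if df is not None else ""
        )
        txt = f"{self.name}: {self.stat_symbol}{dftxt} = {self.statistic:.4g}, p = {self.p:.4g}"
        if self.bayes_factor_10 is not None:
            txt += f", BF10 = {self.bayes_factor_10:.4g}"
        return txt


# -- ranks and correlation ---------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman(x, y, exact: bool = False) -> StatResult:
    """Spearman rho via Pearson correlation of mid-ranks.

    The default p uses the t approximation with n-2 df; ``exact=True``
    enumerates all permutations (only permitted for n <= 10) and reports the
    two-sided permutation p of |rho|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatError("x and y must be aligned 1-d arrays")
    n = len(x)
    if n < 4:
        raise StatError(f"need n >= 4 pairs, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise StatError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatError("constant input: rho undefined")
    rx, ry = _midranks(x), _midranks(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    opts = {"p_method": "t_approximation", "ties": "midrank"}
    if exact:
        if n > 10:
            raise StatError("exact permutation p limited to n <= 10")
        obs = abs(rho)
        count = total = 0
        rxc = rx - rx.mean()
        denom_x = math.sqrt(float(rxc @ rxc))
        ryc = ry - ry.mean()
        denom_y = math.sqrt(float(ryc @ ryc))
        for perm in itertools.permutations(range(n)):
            r = float(rxc @ ryc[list(perm)]) / (denom_x * denom_y)
            count += abs(r) >= obs - 1e-12
            total += 1
        p = count / total
        opts["p_method"] = "exact_permutation"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2 * sps.t.sf(abs(t), n - 2))
    return StatResult(
        name="spearman", statistic=rho, stat_symbol="rho", df=float(n - 2), p=p,
        n=n, direction="positive" if rho > 0 else "negative", options=opts,
    )


# -- Mann-Whitney U ----------------------------------------------------------

@lru_cache(maxsize=64)
def _u_null_pmf(n1: int, n2: int) -> np.ndarray:
    """Exact null pmf of the first sample's U over 0..n1*n2 (no ties).

    Counts subsets of the pooled ranks 1..N of size n1 by rank sum
    (dp over ranks), then shifts the rank sum to U.
    """
    N = n1 + n2
    max_w = n1 * N - n1 * (n1 - 1) // 2  # sum of the n1 largest ranks
    dp = np.zeros((n1 + 1, max_w + 1))
    dp[0, 0] = 1.0
    for r in range(1, N + 1):
        for k in range(min(n1, r), 0, -1):
            dp[k, r:] += dp[k - 1, : max_w + 1 - r]
    w = dp[n1]
    min_w = n1 * (n1 + 1) // 2
    counts = w[min_w : min_w + n1 * n2 + 1]
    return counts / counts.sum()


def mann_whitney_u(a, b, exact: bool | None = None) -> StatResult:
    """Mann-Whitney U test; the statistic reported is U for the first sample.

    U_a = #{(i, j): a_i > b_j} + 1/2 #{a_i = b_j} (so U_a + U_b = n1*n2).
    The two-sided p doubles the lower tail of min(U_a, U_b): exact from the
    full null distribution when feasible (n1*n2 <= 400) and the pooled data
    are tie-free, otherwise a normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatError("both samples must be non-empty")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise StatError("inputs must be finite")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    w_a = float(ranks[:n1].sum())
    u_a = w_a - n1 * (n1 + 1) / 2.0
    u_b = n1 * n2 - u_a
    u_min = min(u_a, u_b)
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    feasible = n1 * n2 <= MAX_EXACT_U_PRODUCT and not has_ties
    if exact is True and not feasible:
        raise StatError(
            "exact p requires tie-free data and n1*n2 <= "
            f"{MAX_EXACT_U_PRODUCT} (got ties={has_ties}, n1*n2={n1 * n2})"
        )
    use_exact = feasible if exact is None else exact

    if use_exact:
        pmf = _u_null_pmf(n1, n2)
        p = float(min(1.0, 2.0 * pmf[: int(u_min) + 1].sum()))
        method = "exact"
    else:
        N = n1 + n2
        mean_u = n1 * n2 / 2.0
        tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (N * (N - 1)))
        var_u = n1 * n2 / 12.0 * ((N + 1) - tie_term)
        if var_u <= 0:
            raise StatError("zero-variance U (all pooled values identical)")
        z = (u_a - mean_u) / math.sqrt(var_u)
        p = float(2 * sps.norm.sf(abs(z)))
        method = "normal_approximation_tie_corrected"
    return StatResult(
        name="mann_whitney_u", statistic=u_a, stat_symbol="U", df=None, p=p,
        n=(n1, n2),
        direction="first_sample_higher" if u_a > n1 * n2 / 2 else "first_sample_lower",
        options={
            "p_method": method, "u_first": u_a, "u_second": u_b, "u_min": u_min,
            "ties": has_ties,
        },
    )


# -- t tests and the JZS Bayes factor ---------------------------------------

def one_sample_t(
    x, mu0: float = 0.0, bayes: bool = False, r_scale: float = DEFAULT_BF_RSCALE,
    name: str = "one_sample_t",
) -> StatResult:
    """Two-sided one-sample t test of mean == mu0, optionally with BF10."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise StatError("need n >= 2 observations")
    if not np.isfinite(x).all():
        raise StatError("inputs must be finite")
    sd = x.std(ddof=1)
    mean = x.mean()
    opts: dict = {}
    if sd == 0:
        if mean == mu0:
            t, p = 0.0, 1.0
            opts["zero_variance"] = True
        else:
            raise StatError("zero variance with mean != mu0: t undefined")
    else:
        t = float((mean - mu0) / (sd / math.sqrt(n)))
        p = float(2 * sps.t.sf(abs(t), n - 1))
    bf = jzs_bayes_factor(t, n, r_scale) if bayes else None
    if bayes:
        opts["bf_r_scale"] = r_scale
    return StatResult(
        name=name, statistic=t, stat_symbol="t", df=float(n - 1), p=p, n=n,
        direction="above_mu0" if mean > mu0 else "below_mu0",
        bayes_factor_10=bf, options=opts,
    )


def paired_t(a, b, bayes: bool = False, r_scale: float = DEFAULT_BF_RSCALE) -> StatResult:
    """Two-sided paired t test (one-sample t on the pairwise differences)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise StatError("paired samples must align")
    res = one_sample_t(a - b, 0.0, bayes=bayes, r_scale=r_scale, name="paired_t")
    res.direction = "first_higher" if a.mean() > b.mean() else "first_lower"
    return res


def jzs_bayes_factor(t: float, n: int, r_scale: float = DEFAULT_BF_RSCALE) -> float:
    """Default JZS Bayes factor BF10 for a one-sample/paired t statistic.

    The alternative places a Cauchy(0, r) prior on the standardised effect
    size, equivalently g ~ InverseGamma(1/2, r^2/2) on the Zellner-Siow
    g-prior variance. BF10 = M1 / M0 with

        M0 = (1 + t^2/v)^{-(v+1)/2},        v = n - 1
        M1 = \\int_0^inf (1+n g)^{-1/2} (1 + t^2/((1+n g) v))^{-(v+1)/2}
             * (r^2/2)^{1/2} / Gamma(1/2) * g^{-3/2} exp(-r^2/(2g)) dg

    evaluated by adaptive quadrature (relative tolerance 1e-8). BF10 < 1 is
    evidence for the null.
    """
    if not np.isfinite(t):
        raise StatError("t must be finite")
    if n < 2:
        raise StatError("need n >= 2")
    if r_scale <= 0:
        raise StatError("prior scale must be positive")
    v = n - 1
    r2 = r_scale * r_scale
    log_m0 = -(v + 1) / 2.0 * math.log1p(t * t / v)
    prior_const = math.sqrt(r2 / 2.0) / math.gamma(0.5)

    def integrand(g: float) -> float:
        if g <= 0:
            return 0.0
        one_ng = 1.0 + n * g
        log_lik = -0.5 * math.log(one_ng) - (v + 1) / 2.0 * math.log1p(
            t * t / (one_ng * v)
        )
        log_prior = -1.5 * math.log(g) - r2 / (2.0 * g)
        return prior_const * math.exp(log_lik + log_prior - log_m0)

    bf, err = integrate.quad(integrand, 0.0, np.inf, epsrel=1e-8, epsabs=0.0, limit=200)
    if not np.isfinite(bf) or bf <= 0 or (err / bf) > 1e-6:
        raise StatError(f"JZS quadrature did not converge (bf={bf}, err={err})")
    return float(bf)


# -- factorial models --------------------------------------------------------

def _ols_t2(y: np.ndarray, c: np.ndarray):
    """t^2 (= F on 1, N-2 df) for intercept and contrast of y ~ 1 + c."""
    X = np.column_stack([np.ones_like(y), c])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - 2
    if dof <= 0:
        raise StatError("need more than two subjects")
    s2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = beta**2 / (s2 * np.diag(xtx_inv))
    scale = max(1.0, float(np.abs(y).max()))
    if s2 <= (1e-12 * scale) ** 2:
        # saturated fit: a numerically-zero coefficient is a null effect
        t2 = np.where(np.abs(beta) <= 1e-10 * scale, 0.0, np.inf)
    return t2, dof, beta


def mixed_anova_2x2(y_level1, y_level2, group) -> dict[str, StatResult]:
    """2 (between: group) x 2 (within: arm) mixed-model ANOVA.

    ``y_level1``/``y_level2`` hold each participant's value at the two
    within-subject levels. For a two-level within factor the mixed ANOVA
    decomposes exactly into two OLS regressions on an effects-coded group
    contrast: the subject sums (group main effect) and the subject
    differences (within main effect = intercept, interaction = contrast).
    This is the Type III / unweighted-means analysis, each F on (1, N-2) df.
    """
    y1 = np.asarray(y_level1, dtype=float)
    y2 = np.asarray(y_level2, dtype=float)
    g = np.asarray(group)
    if not (y1.shape == y2.shape == g.shape):
        raise StatError("y_level1, y_level2 and group must align")
    if np.isnan(y1).any() or np.isnan(y2).any():
        raise StatError("missing within-level cell")
    levels = list(dict.fromkeys(g.tolist()))
    if len(levels) != 2:
        raise StatError(f"need exactly 2 groups, got {levels}")
    n_per = [(g == lv).sum() for lv in levels]
    if min(n_per) < 2:
        raise StatError("need >= 2 participants per group")
    c = np.where(g == levels[0], 1.0, -1.0)
    s = (y1 + y2) / 2.0
    d = y1 - y2
    t2_s, dof, _ = _ols_t2(s, c)
    t2_d, _, beta_d = _ols_t2(d, c)

    def _res(name: str, f: float, direction: str = "") -> StatResult:
        f = float(f)
        return StatResult(
            name=name, statistic=f, stat_symbol="F", df=(1.0, float(dof)),
            p=float(sps.f.sf(f, 1, dof)), n=tuple(int(v) for v in n_per),
            direction=direction,
            options={"groups": levels, "decomposition": "sum/difference t^2"},
        )

    return {
        "group": _res("mixed_anova_group", t2_s[1]),
        "within": _res(
            "mixed_anova_within", t2_d[0],
            "level1_higher" if beta_d[0] > 0 else "level2_higher",
        ),
        "interaction": _res("mixed_anova_interaction", t2_d[1]),
    }


def ancova(df, y: str, factors: list[str], covariate: str) -> dict[str, StatResult]:
    """ANCOVA: y ~ sum-coded factors + covariate, Type III sums of squares.

    Fit through an OLS linear model; returns one :class:`StatResult` per
    factor and for the covariate, each F on (term df, residual df).
    """
    import pandas as pd
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    data = pd.DataFrame(df).dropna(subset=[y, covariate] + factors)
    for f in factors:
        counts = data[f].value_counts()
        if (counts < 1).any() or len(counts) < 2:
            raise StatError(f"factor {f!r} has an empty level after exclusions")
    terms = " + ".join([f"C({f}, Sum)" for f in factors] + [covariate])
    model = smf.ols(f"{y} ~ {terms}", data=data).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise StatError("design matrix is rank deficient")
    table = anova_lm(model, typ=3)
    resid_df = float(model.df_resid)
    out: dict[str, StatResult] = {}
    for term in factors + [covariate]:
        row_name = f"C({term}, Sum)" if term in factors else term
        row = table.loc[row_name]
        out[term] = StatResult(
            name=f"ancova_{term}", statistic=float(row["F"]), stat_symbol="F",
            df=(float(row["df"]), resid_df), p=float(row["PR(>F)"]),
            n=len(data), options={"ss_type": 3, "coding": "sum"},
        )
    return out


# -- outliers and multiplicity ----------------------------------------------

def outlier_policy(values, rule: str = "mad", k: float = 3.0) -> np.ndarray:
    """Flag outliers for parametric analyses; nonparametric analyses keep all.

    Default rule: |value - median| > k * scaled MAD (MAD * 1.4826). With a
    degenerate MAD of 0 any deviation from the median is flagged. Returns a
    boolean flag array — exclusion is the caller's, logged, decision.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 5:
        raise StatError("outlier rule needs >= 5 values")
    if rule != "mad":
        raise StatError(f"unknown outlier rule {rule!r}")
    med = np.median(v)
    mad = MAD_SCALE * np.median(np.abs(v - med))
    return np.abs(v - med) > k * mad


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up adjusted p values (optional extension column in reports)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = n - rank_from_top  # 1-based rank of this p value
        running = min(running, p[idx] * n / i)
        adj[idx] = running
    return adj
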