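"""Frequentist and Bayesian statistical battery for SST cohort analyses.

Covers the inferential layer around the stop-signal task summaries:

* group-matching checks (Pearson chi-square, one-way ANOVA with partial
  eta squared),
* 2 (stimulus: emotional/neutral, within) x 3 (group, between) mixed
  ANOVA and a generic two-way fully-within repeated-measures ANOVA,
  both with Bonferroni-adjusted post hocs,
* paired t tests,
* default-prior Bayes factors: the JZS t-test Bayes factor (zero-centred
  Cauchy prior on the standardised effect), a default g-prior one-way
  ANOVA Bayes factor, and a correlation Bayes factor under a stretched
  beta prior,
* repeated-measures power via the noncentral F distribution, and
* the SSRT-index regression with a one-shot >2-sigma residual outlier
  pass.

Frequentist fits are delegated to pingouin / statsmodels / scipy; the
Bayes factors are computed here by one-dimensional numerical quadrature
or seeded Monte Carlo over the g-prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

from .errors import ConfigError, ZeroVarianceError

__all__ = [
    "StatResult",
    "BayesResult",
    "PowerSpec",
    "RegressionFit",
    "RegressionResult",
    "mixed_anova_2x3",
    "rm_anova_2x3_within",
    "paired_t",
    "chi2_independence",
    "one_way_anova",
    "jzs_bf_ttest",
    "default_bf_anova",
    "bf_correlation",
    "power_rm_within",
    "solve_n_rm_within",
    "regress_ssrt_index",
    "bonferroni",
]


@dataclass(frozen=True)
class StatResult:
    """One test outcome: statistic, degrees of freedom, p, effect size."""

    name: str
    statistic: float
    df: tuple[float, ...]
    p: float
    eta_p2: float | None = None
    posthoc: pd.DataFrame | None = None


@dataclass(frozen=True)
class BayesResult:
    """A Bayes factor with its prior descriptor.

    ``bf10`` quantifies evidence for the alternative over the null;
    ``bf01`` is its exact reciprocal.  ``mc_error`` is the Monte-Carlo
    standard error when the factor was computed by sampling.
    """

    bf10: float
    prior: str
    mc_error: float | None = None

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a repeated-measures power computation.

    ``f`` is Cohen's effect size f, ``m`` the number of repeated
    measurements, ``rho`` the correlation among them.
    """

    f: float
    alpha: float = 0.01
    n: int = 30
    m: int = 2
    rho: float = 0.5

    def __post_init__(self):
        if self.f < 0:
            raise ConfigError("effect size f must be >= 0")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.m < 2:
            raise ConfigError("need at least 2 measurements")
        if not -1 < self.rho < 1:
            raise ConfigError("rho must be in (-1, 1)")
        if self.n < 2:
            raise ConfigError("n must be >= 2")


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p value: min(1, m * p)."""
    return min(1.0, m * p)


# --------------------------------------------------------------------------
# frequentist tests
# --------------------------------------------------------------------------


def _np2_from_f(f: float, df1: float, df2: float) -> float:
    """partial eta squared from F and its dfs: F*df1 / (F*df1 + df2)."""
    return f * df1 / (f * df1 + df2)


def _check_complete_within(data: pd.DataFrame, subject: str, within: list[str]):
    counts = data.groupby(subject, observed=True)[within[0]].count()
    expected = int(np.prod([data[w].nunique() for w in within]))
    if (counts != expected).any():
        bad = counts.index[counts != expected].tolist()
        raise ValueError(f"subjects missing within-condition cells: {bad}")


def mixed_anova_2x3(
    data: pd.DataFrame,
    dv: str = "value",
    within: str = "condition",
    subject: str = "subject",
    between: str = "group",
    posthoc: bool = False,
) -> dict[str, StatResult]:
    """Mixed-design ANOVA: one within factor (2 levels per subject) and
    one between factor.

    Returns StatResults keyed ``"within"``, ``"between"`` and
    ``"interaction"``, each with partial eta squared.  With
    ``posthoc=True`` a Bonferroni-adjusted pairwise table is attached to
    the within effect.  Long-format input; every subject must have every
    within level.
    """
    import pingouin as pg

    _check_complete_within(data, subject, [within])
    with np.errstate(invalid="ignore", divide="ignore"):
        aov = pg.mixed_anova(data=data, dv=dv, within=within, subject=subject, between=between)
    aov = aov.set_index("Source")
    ph = None
    if posthoc:
        ph = pg.pairwise_tests(
            data=data,
            dv=dv,
            within=within,
            subject=subject,
            between=between,
            padjust="bonf",
        )
    out = {}
    for key, source in (("between", between), ("within", within), ("interaction", "Interaction")):
        row = aov.loc[source]
        f_val, p_val, np2 = float(row["F"]), float(row["p_unc"]), float(row["np2"])
        if not np.isfinite(f_val) and float(row["SS"]) == 0.0:
            # zero effect SS with zero error SS: no effect, by convention F = 0
            f_val, p_val, np2 = 0.0, 1.0, 0.0
        out[key] = StatResult(
            name=f"mixed ANOVA {key} ({source})",
            statistic=f_val,
            df=(float(row["DF1"]), float(row["DF2"])),
            p=p_val,
            eta_p2=np2,
            posthoc=ph if key == "within" else None,
        )
    return out


def rm_anova_2x3_within(
    data: pd.DataFrame,
    dv: str = "value",
    within: tuple[str, str] = ("emotion", "stimulus"),
    subject: str = "subject",
) -> dict[str, StatResult]:
    """Two-way fully repeated-measures ANOVA (both factors within).

    Returns StatResults keyed by each factor name and ``"interaction"``.
    Partial eta squared is recovered from F and its dfs
    (np2 = F*df1/(F*df1 + df2), an identity of the F ratio).
    Uncorrected dfs and p values are reported.
    """
    import pingouin as pg

    _check_complete_within(data, subject, list(within))
    with np.errstate(invalid="ignore", divide="ignore"):
        aov = pg.rm_anova(
            data=data, dv=dv, within=list(within), subject=subject, detailed=True
        ).set_index("Source")
    out = {}
    labels = {within[0]: within[0], within[1]: within[1], f"{within[0]} * {within[1]}": "interaction"}
    for source, key in labels.items():
        row = aov.loc[source]
        f_val, df1, df2 = float(row["F"]), float(row["ddof1"]), float(row["ddof2"])
        p_val = float(row["p_unc"])
        if not np.isfinite(f_val) and float(row["SS"]) == 0.0:
            f_val, p_val = 0.0, 1.0
        out[key] = StatResult(
            name=f"rm ANOVA {key}",
            statistic=f_val,
            df=(df1, df2),
            p=p_val,
            eta_p2=_np2_from_f(f_val, df1, df2),
        )
    return out


def paired_t(x, y) -> StatResult:
    """Two-sided paired t test; df = n - 1.

    Raises :class:`ZeroVarianceError` when the pairwise differences are
    constant (the t statistic is undefined there).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired_t needs two equal-length samples of size >= 2")
    d = x - y
    if np.allclose(d, d[0]):
        raise ZeroVarianceError("pairwise differences have zero variance")
    res = stats.ttest_rel(x, y)
    return StatResult(
        name="paired t",
        statistic=float(res.statistic),
        df=(float(x.size - 1),),
        p=float(res.pvalue),
    )


def chi2_independence(counts) -> StatResult:
    """Pearson chi-square test of independence on an r x c count table
    (no continuity correction); df = (r-1)(c-1)."""
    table = np.asarray(counts, float)
    if table.ndim != 2 or (table < 0).any():
        raise ValueError("counts must be a nonnegative 2-D table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("every row and column margin must be positive")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return StatResult(name="chi-square independence", statistic=float(chi2), df=(float(dof),), p=float(p))


def one_way_anova(values, groups) -> StatResult:
    """One-way between-subjects ANOVA with partial eta squared."""
    import pingouin as pg

    df = pd.DataFrame({"y": np.asarray(values, float), "g": np.asarray(groups)})
    if df["g"].nunique() < 2:
        raise ValueError("one-way ANOVA needs at least two groups")
    if (df.groupby("g")["y"].count() < 2).any():
        raise ValueError("every group needs at least two members")
    aov = pg.anova(data=df, dv="y", between="g", detailed=True)
    row = aov.iloc[0]
    return StatResult(
        name="one-way ANOVA",
        statistic=float(row["F"]),
        df=(float(row["DF"]), float(aov.iloc[1]["DF"])),
        p=float(row["p_unc"]),
        eta_p2=float(row["np2"]),
    )


# --------------------------------------------------------------------------
# Bayes factors
# --------------------------------------------------------------------------


def jzs_bf_ttest(
    t: float, n: int, scale: float = 0.707, design: str = "paired"
) -> BayesResult:
    """JZS default Bayes factor for a one-sample / paired t statistic.

    The alternative places a zero-centred Cauchy prior with width
    ``scale`` on the standardised effect size delta; BF10 is the ratio
    of the marginal likelihood of ``t`` under that prior (noncentral t
    with noncentrality sqrt(n)*delta, integrated by adaptive quadrature)
    to the central-t likelihood under the null.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    if design not in ("paired", "one-sample"):
        raise ValueError("design must be 'paired' or 'one-sample'")
    nu = n - 1
    root_n = np.sqrt(n)

    def integrand(delta):
        return stats.nct.pdf(t, nu, root_n * delta) * stats.cauchy.pdf(delta, 0.0, scale)

    num, err = integrate.quad(integrand, -np.inf, np.inf, limit=200)
    den = stats.t.pdf(t, nu)
    if not np.isfinite(num) or num <= 0 or err > max(num * 1e-4, 1e-12):
        raise ArithmeticError(
            f"JZS quadrature did not converge (value {num:g}, abserr {err:g})"
        )
    return BayesResult(bf10=float(num / den), prior=f"Cauchy(0, {scale}) on delta ({design})")


def _fixed_effect_design(labels: np.ndarray) -> np.ndarray:
    """Sum-to-zero fixed-effect design: indicator matrix projected onto
    the (a-1)-dimensional centred space with an orthonormal basis, so
    the a effects are exchangeable under an iid prior."""
    cats = np.unique(labels)
    z = (labels[:, None] == cats[None, :]).astype(float)
    a = len(cats)
    center = np.eye(a) - np.ones((a, a)) / a
    vals, vecs = np.linalg.eigh(center)
    q = vecs[:, vals > 0.5]  # eigenvalue-1 eigenvectors
    return z @ q


def _g_marginal_log_ratio(y: np.ndarray, x: np.ndarray, g: np.ndarray) -> np.ndarray:
    """log p(y|g)/p(y|g=0) for y = mu*1 + x beta + eps, beta ~ N(0, g s2 I),
    flat prior on mu and Jeffreys on s2, vectorised over the g draws.

    Uses the Woodbury identity through the eigendecomposition of X'X, so
    each draw costs O(p) with p the number of effect columns.
    """
    n, p = x.shape
    xtx = x.T @ x
    d, u = np.linalg.eigh(xtx)  # xtx = u diag(d) u'
    uy = u.T @ (x.T @ y)
    u1 = u.T @ (x.T @ np.ones(n))
    yty = float(y @ y)
    sy = float(y.sum())
    s0 = yty - sy**2 / n
    g = np.asarray(g, float)[:, None]
    denom = d[None, :] + 1.0 / g  # eigenvalues of M = X'X + I/g
    # W^{-1} quadratic forms via  v' W^{-1} w = v'w - (U'X'v)' D^{-1} (U'X'w)
    a = n - ((u1**2)[None, :] / denom).sum(axis=1)
    b = sy - ((u1 * uy)[None, :] / denom).sum(axis=1)
    c = yty - ((uy**2)[None, :] / denom).sum(axis=1)
    s = c - b**2 / a
    logdet_w = np.log(denom).sum(axis=1) + p * np.log(g[:, 0])  # |I + gXX'|
    return (
        -0.5 * logdet_w
        - 0.5 * (np.log(a) - np.log(n))
        - 0.5 * (n - 1) * (np.log(s) - np.log(s0))
    )


def default_bf_anova(
    values,
    groups=None,
    *,
    within: pd.DataFrame | None = None,
    scale_fixed: float = 0.5,
    n_mc: int = 50_000,
    seed: int = 0,
) -> BayesResult:
    """Default g-prior Bayes factor for a single-factor design.

    Between-subjects mode (``values``, ``groups``): the full model adds
    sum-to-zero group effects with an iid N(0, g*sigma^2) prior and
    g ~ InverseGamma(1/2, scale_fixed^2/2) (a Cauchy prior of width
    ``scale_fixed`` on each standardised effect); BF10 against the
    grand-mean-only null is a seeded Monte-Carlo average over g, with
    the Monte-Carlo standard error reported.

    Within-subjects mode (``within``: a subjects x 2 DataFrame/array of
    condition values): subject effects are removed exactly by
    differencing and the same g-prior machinery runs on the one-sample
    problem, with the effective Cauchy width scale_fixed * sqrt(2) (the
    two-level sum-to-zero parametrisation halves the effect variance).
    """
    rng = np.random.default_rng(seed)
    # g ~ InvGamma(1/2, r^2/2)  <=>  1/g ~ Gamma(1/2, rate r^2/2)
    if within is not None:
        arr = np.asarray(within, float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("within mode expects a subjects x 2 array")
        d = arr[:, 0] - arr[:, 1]
        n = d.size
        if n < 2 or np.allclose(d, d[0]):
            raise ZeroVarianceError("within differences have zero variance")
        t = float(d.mean() / (d.std(ddof=1) / np.sqrt(n)))
        nu = n - 1
        r_eff = scale_fixed * np.sqrt(2.0)
        g = 1.0 / rng.gamma(0.5, 2.0 / r_eff**2, n_mc)
        ratio = (1.0 + n * g) ** -0.5 * (
            (1.0 + t**2 / ((1.0 + n * g) * nu)) / (1.0 + t**2 / nu)
        ) ** (-(nu + 1) / 2.0)
        bf = float(ratio.mean())
        se = float(ratio.std(ddof=1) / np.sqrt(n_mc))
        return BayesResult(
            bf10=bf,
            prior=f"g-prior, effective Cauchy width {r_eff:.4g} (within, 2 levels)",
            mc_error=se,
        )
    y = np.asarray(values, float)
    labels = np.asarray(groups)
    if np.unique(labels).size < 2:
        raise ValueError("need at least two groups")
    x = _fixed_effect_design(labels)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), x])) < x.shape[1] + 1:
        raise ValueError("rank-deficient design")
    g = 1.0 / rng.gamma(0.5, 2.0 / scale_fixed**2, n_mc)
    log_ratio = _g_marginal_log_ratio(y, x, g)
    ratio = np.exp(log_ratio)
    bf = float(ratio.mean())
    se = float(ratio.std(ddof=1) / np.sqrt(n_mc))
    return BayesResult(
        bf10=bf,
        prior=f"g-prior on fixed effects, Cauchy width {scale_fixed} (between)",
        mc_error=se,
    )


def _corr_kernel(rho: np.ndarray, r: float, n: int) -> np.ndarray:
    """Reduced likelihood of the sample correlation r given rho (the
    rho-dependent part of the exact sampling density of r)."""
    rho = np.asarray(rho, float)
    return (
        (1.0 - rho**2) ** ((n - 1) / 2.0)
        * (1.0 - rho * r) ** (1.5 - n)
        * special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1.0) / 2.0)
    )


def bf_correlation(x, y, kappa: float = 1.0) -> BayesResult:
    """Bayes factor for a Pearson correlation under a stretched beta
    prior of width ``kappa`` on rho (kappa = 1 is uniform on (-1, 1)).

    BF10 = integral of the exact r-likelihood over the prior, divided by
    the likelihood at rho = 0; one-dimensional adaptive quadrature.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ZeroVarianceError("correlation undefined for constant input")
    n = x.size
    r = float(np.corrcoef(x, y)[0, 1])
    a = 1.0 / kappa

    def prior(rho):
        return ((1.0 + rho) / 2.0) ** (a - 1.0) * ((1.0 - rho) / 2.0) ** (a - 1.0) / (
            2.0 * special.beta(a, a)
        )

    num, err = integrate.quad(lambda rho: _corr_kernel(rho, r, n) * prior(rho), -1, 1, limit=200)
    den = float(_corr_kernel(np.array([0.0]), r, n)[0])
    if not np.isfinite(num) or num <= 0 or err > max(num * 1e-4, 1e-12):
        raise ArithmeticError("correlation BF quadrature did not converge")
    return BayesResult(bf10=float(num / den), prior=f"stretched beta width {kappa} on rho")


# --------------------------------------------------------------------------
# power
# --------------------------------------------------------------------------


def power_rm_within(spec: PowerSpec, convention: str = "gpower") -> float:
    """Achieved power of the within-factor F test in a one-group
    repeated-measures design.

    Power = P(F' > F_crit(alpha; m-1, (n-1)(m-1))) with F' noncentral F
    with noncentrality lambda.  Two conventions for lambda are exposed:

    * ``"gpower"`` (default): lambda = n * m^2 * f^2 / (1 - rho) — the
      effect-size-correction convention of the G*Power within-factors
      module (f'^2 = f^2 * m/(1-rho); lambda = f'^2 * n * m).
    * ``"classical"``: lambda = n * m * f^2 / (1 - rho), the textbook
      noncentrality of the repeated-measures F with effect size defined
      against total variance.  The classical convention yields
      distinctly lower power for the same inputs.
    """
    lam = _lambda(spec, convention)
    df1 = spec.m - 1
    df2 = (spec.n - 1) * (spec.m - 1)
    crit = stats.f.ppf(1.0 - spec.alpha, df1, df2)
    if lam == 0.0:
        return float(spec.alpha)
    return float(1.0 - stats.ncf.cdf(crit, df1, df2, lam))


def _lambda(spec: PowerSpec, convention: str) -> float:
    base = spec.n * spec.m * spec.f**2 / (1.0 - spec.rho)
    if convention == "gpower":
        return base * spec.m
    if convention == "classical":
        return base
    raise ValueError("convention must be 'gpower' or 'classical'")


def solve_n_rm_within(
    target_power: float,
    f: float,
    alpha: float = 0.01,
    m: int = 2,
    rho: float = 0.5,
    convention: str = "gpower",
    n_max: int = 100_000,
) -> int:
    """Smallest n achieving ``target_power`` (power is monotone in n)."""
    if f <= 0:
        raise ValueError("need f > 0 to reach any power above alpha")
    lo, hi = 2, 2
    while power_rm_within(PowerSpec(f, alpha, hi, m, rho), convention) < target_power:
        hi *= 2
        if hi > n_max:
            raise ValueError(f"target power not reached by n = {n_max}")
    while lo < hi:
        mid = (lo + hi) // 2
        if power_rm_within(PowerSpec(f, alpha, mid, m, rho), convention) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return lo


# --------------------------------------------------------------------------
# SSRT-index regression
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RegressionFit:
    """One OLS fit: coefficient table (term, b, se, t, p, ci), R²,
    overall F with dfs, residual sigma."""

    coef: pd.DataFrame
    r2: float
    f: float
    df: tuple[float, float]
    f_p: float
    sigma: float
    n: int


@dataclass(frozen=True)
class RegressionResult:
    """Initial full fit, the one-shot outlier pass, and the refit."""

    initial: RegressionFit
    final: RegressionFit
    removed: tuple = ()


def _fit_ols(y: np.ndarray, x: pd.DataFrame) -> RegressionFit:
    import statsmodels.api as sm

    design = sm.add_constant(x)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("collinear predictors: design matrix is rank deficient")
    res = sm.OLS(y, design).fit()
    ci = res.conf_int(alpha=0.05)
    coef = pd.DataFrame(
        {
            "term": design.columns,
            "b": res.params.to_numpy(),
            "se": res.bse.to_numpy(),
            "t": res.tvalues.to_numpy(),
            "p": res.pvalues.to_numpy(),
            "ci_low": ci[0].to_numpy(),
            "ci_high": ci[1].to_numpy(),
        }
    )
    return RegressionFit(
        coef=coef,
        r2=float(res.rsquared),
        f=float(res.fvalue),
        df=(float(res.df_model), float(res.df_resid)),
        f_p=float(res.f_pvalue),
        sigma=float(np.sqrt(res.mse_resid)),
        n=int(res.nobs),
    )


def _resid(y: np.ndarray, x: pd.DataFrame, fit: RegressionFit) -> np.ndarray:
    import statsmodels.api as sm

    design = sm.add_constant(x).to_numpy()
    return y - design @ fit.coef["b"].to_numpy()


def regress_ssrt_index(
    index,
    predictors: pd.DataFrame,
    sigma_threshold: float = 2.0,
    stepwise: bool = False,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> RegressionResult:
    """OLS of the per-subject SSRT index on the personality predictors,
    with a one-shot standardised-residual outlier pass.

    Fit all predictors, standardise the residuals by the fit's residual
    sigma, drop observations with |residual| > ``sigma_threshold`` sigma,
    and refit once.  The default full-entry model retains every
    predictor; ``stepwise=True`` instead runs a classic forward/backward
    p-threshold selection (enter at ``p_enter``, remove at ``p_remove``)
    on the post-outlier data before the final fit.
    """
    y = np.asarray(index, float)
    x = pd.DataFrame(predictors).reset_index(drop=True)
    if len(y) != len(x):
        raise ValueError("index and predictors disagree in length")
    if len(y) <= x.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    initial = _fit_ols(y, x)
    z = _resid(y, x, initial) / initial.sigma
    keep = np.abs(z) <= sigma_threshold
    removed = tuple(int(i) for i in np.asarray(x.index)[~keep])
    y2, x2 = y[keep], x.loc[keep].reset_index(drop=True)
    if stepwise:
        x2 = x2[_stepwise_select(y2, x2, p_enter, p_remove)]
    final = _fit_ols(y2, x2)
    return RegressionResult(initial=initial, final=final, removed=removed)


def _stepwise_select(
    y: np.ndarray, x: pd.DataFrame, p_enter: float, p_remove: float
) -> list[str]:
    """Classic p-to-enter / p-to-remove stepwise variable selection."""
    selected: list[str] = []
    while True:
        changed = False
        remaining = [c for c in x.columns if c not in selected]
        if remaining:
            pvals = {}
            for c in remaining:
                fit = _fit_ols(y, x[selected + [c]])
                pvals[c] = fit.coef.set_index("term").loc[c, "p"]
            best = min(pvals, key=pvals.get)
            if pvals[best] < p_enter:
                selected.append(best)
                changed = True
        if selected:
            fit = _fit_ols(y, x[selected])
            tab = fit.coef.set_index("term")["p"].drop("const")
            worst = tab.idxmax()
            if tab[worst] > p_remove:
                selected.remove(worst)
                changed = True
        if not changed:
            return selected
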