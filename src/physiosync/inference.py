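"""Study-level statistics.

t-tests with Cohen's d and noncentral-t confidence intervals, JZS Bayes
factors under the default Cauchy(0, 0.707) effect-size prior, Pearson
correlations with Fisher-z intervals, the Hittner/Dunn-Clark z for comparing
two overlapping dependent correlations, group-controlled regression, and the
percentile-bootstrap mediation model

    Y = c X + e_y          (total effect)
    M = a X + e_m          (action path)
    Y = c' X + b M + e'_y  (direct + mediated)

with indirect effect a*b tested by a seeded 5000-resample percentile CI.
Continuous variables are z-scored before fitting so paths are standardized
betas; the binary group dummy X stays 0/1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from .errors import ConfigError

_Z975 = stats.norm.ppf(0.975)


@dataclass
class BFConfig:
    cauchy_scale: float = 0.707

    def __post_init__(self) -> None:
        if not self.cauchy_scale > 0:
            raise ConfigError("cauchy_scale must be positive")


@dataclass
class TTestResult:
    kind: str
    t: float
    df: float
    p: float
    cohens_d: float
    d_ci_low: float
    d_ci_high: float
    bf10: float


@dataclass
class CorrelationResult:
    r: float
    n: int
    p: float
    ci_low: float
    ci_high: float
    bf10: float


@dataclass
class RegressionResult:
    beta: float
    delta_r2: float
    f: float
    df1: int
    df2: int
    p: float


@dataclass
class MediationResult:
    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    boot_ci_low: float
    boot_ci_high: float
    n_boot: int
    seed: int | None
    covariate_effects: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# t tests
# ---------------------------------------------------------------------------

def _nct_cdf(t: float, df: float, ncp: float) -> float:
    """nct.cdf with a Satterthwaite-style normal fallback where scipy
    underflows (very large |t| or |ncp|)."""
    v = stats.nct.cdf(t, df, ncp)
    if np.isnan(v):
        z = (t * (1.0 - 1.0 / (4.0 * df)) - ncp) / np.sqrt(1.0 + t * t / (2.0 * df))
        v = stats.norm.cdf(z)
    return float(v)


def _d_ci_noncentral(t: float, df: float, d_per_ncp: float, conf: float = 0.95):
    """CI for Cohen's d by inverting the noncentral-t distribution of t."""
    alpha = (1.0 - conf) / 2.0
    span = abs(t) + 10.0

    def solve(q: float) -> float:
        f = lambda ncp: _nct_cdf(t, df, ncp) - q
        lo, hi = t - span, t + span
        while f(lo) < 0:   # cdf too small even at the left edge
            lo -= span
        while f(hi) > 0:
            hi += span
        return optimize.brentq(f, lo, hi, xtol=1e-10)

    return solve(1.0 - alpha) * d_per_ncp, solve(alpha) * d_per_ncp


def jzs_bf10(t: float, n1: int, n2: int | None = None, kind: str = "two_sample",
             cfg: BFConfig | None = None) -> float:
    """Jeffreys-Zellner-Siow Bayes factor for a t statistic.

    One-dimensional quadrature of the marginal likelihood under the
    Cauchy(0, scale) prior on the standardized effect size, against the point
    null; relative tolerance 1e-8.
    """
    cfg = cfg or BFConfig()
    if kind == "two_sample":
        if n2 is None:
            raise ConfigError("two_sample BF needs n2")
        if min(n1, n2) < 2:
            raise ConfigError("need n >= 2 per group")
        n_eff = n1 * n2 / (n1 + n2)
        df = n1 + n2 - 2
    elif kind in ("one_sample", "paired"):
        if n1 < 2:
            raise ConfigError("need n >= 2")
        n_eff = float(n1)
        df = n1 - 1
    else:
        raise ConfigError(f"unknown test kind {kind!r}")

    sq = np.sqrt(n_eff)

    def integrand(delta: float) -> float:
        return stats.nct.pdf(t, df, delta * sq) * stats.cauchy.pdf(delta, 0.0, cfg.cauchy_scale)

    center = t / sq
    breaks = sorted({0.0, center})
    pieces = [(-np.inf, breaks[0])] + list(zip(breaks[:-1], breaks[1:])) + [(breaks[-1], np.inf)]
    total = err = 0.0
    for lo, hi in pieces:
        v, e = integrate.quad(integrand, lo, hi, epsrel=1e-8, epsabs=0.0, limit=200)
        total += v
        err += e
    if not np.isfinite(total) or total <= 0 or err > 1e-6 * total:
        raise ConfigError(f"BF quadrature failed (value {total}, error {err})")
    return total / stats.t.pdf(t, df)


def _ttest_result(kind: str, t: float, df: float, d: float, d_per_ncp: float,
                  bf: float) -> TTestResult:
    p = 2.0 * stats.t.sf(abs(t), df)
    lo, hi = _d_ci_noncentral(t, df, d_per_ncp)
    return TTestResult(kind, float(t), float(df), float(p), float(d), lo, hi, bf)


def two_sample_t(mean1: float, sd1: float, n1: int, mean2: float, sd2: float,
                 n2: int, cfg: BFConfig | None = None) -> TTestResult:
    """Pooled-variance two-sample t from summary statistics, with Cohen's d
    (pooled SD), its noncentral-t 95% CI, and the JZS BF10."""
    if min(n1, n2) < 2:
        raise ConfigError("need n >= 2 per group")
    if min(sd1, sd2) <= 0:
        raise ConfigError("standard deviations must be positive")
    df = n1 + n2 - 2
    sp = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df)
    se = sp * np.sqrt(1.0 / n1 + 1.0 / n2)
    t = (mean1 - mean2) / se
    d = (mean1 - mean2) / sp
    bf = jzs_bf10(t, n1, n2, "two_sample", cfg)
    return _ttest_result("two_sample_pooled", t, df, d,
                         np.sqrt(1.0 / n1 + 1.0 / n2), bf)


def two_sample_t_from_raw(x, y, cfg: BFConfig | None = None) -> TTestResult:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return two_sample_t(x.mean(), x.std(ddof=1), x.size,
                        y.mean(), y.std(ddof=1), y.size, cfg)


def one_sample_t_from_raw(x, mu: float = 0.0, kind: str = "one_sample",
                          cfg: BFConfig | None = None) -> TTestResult:
    x = np.asarray(x, float)
    n = x.size
    if n < 2:
        raise ConfigError("need n >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ConfigError("zero variance")
    t = (x.mean() - mu) / (sd / np.sqrt(n))
    d = (x.mean() - mu) / sd
    bf = jzs_bf10(t, n, kind="one_sample", cfg=cfg)
    return _ttest_result(kind, t, n - 1, d, 1.0 / np.sqrt(n), bf)


def paired_t_from_raw(pre, post, cfg: BFConfig | None = None) -> TTestResult:
    """Paired t on post-minus-pre differences."""
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.shape != post.shape:
        raise ConfigError("pre and post must have the same length")
    return one_sample_t_from_raw(post - pre, 0.0, kind="paired", cfg=cfg)


def bonferroni(p: float, k: int) -> float:
    """p * k, capped at 1."""
    if k < 1:
        raise ConfigError("k must be >= 1")
    return min(1.0, p * k)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def pearson(x, y, cfg: BFConfig | None = None) -> CorrelationResult:
    """Pearson r with two-sided p, Fisher-z 95% CI, and a default-prior BF10."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 3 or y.size != n:
        raise ConfigError("pearson needs matched vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ConfigError("zero variance")
    r, p = stats.pearsonr(x, y)
    if n > 3 and abs(r) < 1:
        z = np.arctanh(r)
        h = _Z975 / np.sqrt(n - 3)
        lo, hi = np.tanh(z - h), np.tanh(z + h)
    else:
        lo, hi = -1.0, 1.0
    import pingouin  # standard-step dependency; local import keeps startup fast
    bf = float(pingouin.bayesfactor_pearson(r, n))
    return CorrelationResult(float(r), int(n), float(p), float(lo), float(hi), bf)


def compare_dependent_correlations(r_jk: float, r_jh: float, r_kh: float, n: int):
    """Hittner et al. (2003) modification of Dunn & Clark's z for two
    overlapping dependent correlations sharing variable j.

    Returns (z, two-sided p from the standard normal).
    """
    for name, r in (("r_jk", r_jk), ("r_jh", r_jh), ("r_kh", r_kh)):
        if not abs(r) < 1:
            raise ConfigError(f"{name} must satisfy |r| < 1, got {r}")
    if n < 4:
        raise ConfigError("need n >= 4")
    rbar = (r_jk + r_jh) / 2.0
    cov = (r_kh * (1.0 - 2.0 * rbar**2)
           - 0.5 * rbar**2 * (1.0 - 2.0 * rbar**2 - r_kh**2)) / (1.0 - rbar**2) ** 2
    z = (np.arctanh(r_jk) - np.arctanh(r_jh)) * np.sqrt((n - 3) / (2.0 - 2.0 * cov))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# regression and mediation
# ---------------------------------------------------------------------------

def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ConfigError("zero variance in a continuous variable")
    return (v - v.mean()) / sd


def regression_control(y, x, group) -> RegressionResult:
    """OLS of standardized y on standardized x plus the group dummy; reports
    x's standardized coefficient and its incremental-variance F test over the
    group-only model."""
    import statsmodels.api as sm

    y = _zscore(np.asarray(y, float))
    x = _zscore(np.asarray(x, float))
    g = np.asarray(group, float)
    n = y.size
    if n <= 3 or x.size != n or g.size != n:
        raise ConfigError("regression needs matched vectors with n > 3")
    X_full = sm.add_constant(np.column_stack([x, g]))
    if np.linalg.cond(X_full) > 1e8:
        raise ConfigError("design matrix is ill-conditioned (collinearity)")
    full = sm.OLS(y, X_full).fit()
    red = sm.OLS(y, sm.add_constant(g)).fit()
    delta_r2 = full.rsquared - red.rsquared
    df2 = n - 3
    resid = 1.0 - full.rsquared
    f = np.inf if resid <= 0 else delta_r2 * df2 / resid
    p = float(stats.f.sf(f, 1, df2))
    return RegressionResult(float(full.params[1]), float(delta_r2), float(f), 1, df2, p)


def _fit_paths(x, m, y, cov):
    """OLS fits of the three mediation equations; returns (a, b, c, c', cov effects)."""
    one = np.ones_like(x)
    base = [one, x] if cov is None else [one, x, cov]
    Xc = np.column_stack(base)
    Xm = np.column_stack(base + [m])
    coef_c = np.linalg.lstsq(Xc, y, rcond=None)[0]
    coef_a = np.linalg.lstsq(Xc, m, rcond=None)[0]
    coef_b = np.linalg.lstsq(Xm, y, rcond=None)[0]
    eff = {}
    if cov is not None:
        eff = {"on_mediator": float(coef_a[2]), "on_outcome": float(coef_b[2])}
    return float(coef_a[1]), float(coef_b[-1]), float(coef_c[1]), float(coef_b[1]), eff


def mediate(x, m, y, covariate=None, n_boot: int = 5000, seed: int | None = None,
            ci: str = "percentile") -> MediationResult:
    """Simple mediation (X -> M -> Y) with an optional covariate entered in
    every equation, standardized paths, and a seeded percentile bootstrap CI
    for the indirect effect a*b (paired resampling of complete rows)."""
    x = np.asarray(x, float)
    m = np.asarray(m, float)
    y = np.asarray(y, float)
    n = x.size
    if m.size != n or y.size != n or (covariate is not None and len(covariate) != n):
        raise ConfigError("x, m, y (and covariate) must have equal length")
    keep = np.isfinite(x) & np.isfinite(m) & np.isfinite(y)
    if covariate is not None:
        covariate = np.asarray(covariate, float)
        keep &= np.isfinite(covariate)
    x, m, y = x[keep], m[keep], y[keep]
    cov = covariate[keep] if covariate is not None else None
    n = x.size
    if n < 10:
        raise ConfigError(f"refusing mediation with n = {n} < 10 complete cases")
    if not set(np.unique(x)) <= {0.0, 1.0} or len(np.unique(x)) < 2:
        raise ConfigError("x must be a binary 0/1 dummy with both groups present")
    if ci != "percentile":
        raise ConfigError("only the percentile bootstrap CI is implemented")
    m = _zscore(m)
    y = _zscore(y)
    if cov is not None:
        cov = _zscore(cov)

    a, b, c, c_prime, eff = _fit_paths(x, m, y, cov)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for k in range(n_boot):
        idx = rng.integers(0, n, n)
        xb = x[idx]
        if xb.min() == xb.max():  # degenerate resample: redraw
            while xb.min() == xb.max():
                idx = rng.integers(0, n, n)
                xb = x[idx]
        ab, bb, _, _, _ = _fit_paths(xb, m[idx], y[idx],
                                     cov[idx] if cov is not None else None)
        boot[k] = ab * bb
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return MediationResult(a, b, c, c_prime, a * b, float(lo), float(hi),
                           n_boot, seed, eff)


def mediation_frame_analysis(frame: pd.DataFrame, covariate: str | None = "empathy",
                             n_boot: int = 5000, seed: int | None = None) -> MediationResult:
    """Convenience wrapper: mediate() on a tidy frame with columns
    x (group dummy), m (similarity), y (liking change) and an optional
    covariate column."""
    cov = frame[covariate].to_numpy() if covariate and covariate in frame else None
    return mediate(frame["x"].to_numpy(), frame["m"].to_numpy(),
                   frame["y"].to_numpy(), cov, n_boot=n_boot, seed=seed)
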