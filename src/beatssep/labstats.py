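"""Per-lab statistics: RM-ANOVA, post-hoc paired t-tests, correlations, power.

The one-way repeated-measures ANOVA uses the classical within-subject
decomposition with an unconditional Greenhouse-Geisser correction (the
epsilon is always estimated and applied; no sphericity pre-test).  Effect
size is partial eta squared, SS_cond / (SS_cond + SS_error).

The a priori power computation follows the G*Power "within factors"
parameterization: Cohen's f^2 = eta^2/(1-eta^2), noncentrality
lambda = f^2 (N-1) m epsilon / (1-rho) with m repeated measures and
correlation rho among them, tested against a critical F with
df1 = (m-1) epsilon and df2 = (N-g)(m-1) epsilon for g condition groups.
The noncentrality is scaled by the error degrees of freedom (N-1); the
companion Monte-Carlo routine simulates the matching compound-symmetric
design and recovers the same power, validating the noncentral-F tail
computation end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "TTestResult",
    "PowerParams",
    "gg_epsilon",
    "gg_epsilon_from_cov",
    "rm_anova_oneway",
    "posthoc_paired_t",
    "pearson_matrix",
    "rm_power",
    "min_n_power",
    "mc_rm_power",
]


@dataclass
class AnovaResult:
    F: float
    df1: float  # GG-corrected
    df2: float
    p: float
    partial_eta2: float
    epsilon_gg: float
    df1_uncorrected: int
    df2_uncorrected: int
    p_uncorrected: float
    ss_condition: float
    ss_subject: float
    ss_error: float


@dataclass
class TTestResult:
    pair: tuple
    t: float
    df: int
    p_raw: float
    p_adjusted: float
    cohens_d: float
    undefined: bool = False


@dataclass
class PowerParams:
    eta2: float = 0.06
    alpha: float = 0.05
    n_conditions: int = 3
    n_measures: int = 10
    rho: float = 0.5
    epsilon: float = 1.0

    def validate(self) -> None:
        if not 0 < self.eta2 < 1:
            raise ValueError("eta2 must be in (0, 1)")
        if not 0 < self.rho < 1:
            raise ValueError("rho must be in (0, 1)")
        if not 0 < self.epsilon <= 1:
            raise ValueError("epsilon must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_conditions < 2 or self.n_measures < 2:
            raise ValueError("need at least 2 conditions and 2 measures")


def gg_epsilon_from_cov(s: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon of a condition covariance matrix.

    Exactly 1 for a compound-symmetric matrix; bounded below by 1/(k-1).
    """
    s = np.asarray(s, dtype=float)
    k = s.shape[0]
    sc = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) + s.mean()
    num = np.trace(sc) ** 2
    den = (k - 1) * np.sum(sc ** 2)
    if den <= 0:
        return 1.0
    return float(min(1.0, max(num / den, 1.0 / (k - 1))))


def gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the sample covariance of conditions."""
    data = np.asarray(data, dtype=float)
    return gg_epsilon_from_cov(np.cov(data, rowvar=False))


def rm_anova_oneway(data: np.ndarray) -> AnovaResult:
    """One-way repeated-measures ANOVA on an n_subjects x k_conditions table."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be subjects x conditions")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    if np.isnan(data).any():
        raise ValueError("missing values are not allowed (drop cases upstream)")
    grand = data.mean()
    ss_subject = k * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_cond = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_error = ss_total - ss_subject - ss_cond
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_cond = ss_cond / df1
    ms_error = ss_error / df2
    tiny = 1e-12 * max(ss_total, 1.0)  # guard float residue in exact-tie cases
    if ms_error > tiny:
        F = ms_cond / ms_error
    else:
        F = 0.0 if ss_cond <= tiny else np.inf
    eps = gg_epsilon(data)
    p_gg = float(stats.f.sf(F, df1 * eps, df2 * eps)) if np.isfinite(F) else 0.0
    p_unc = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    denom = ss_cond + ss_error
    return AnovaResult(
        F=float(F),
        df1=df1 * eps,
        df2=df2 * eps,
        p=p_gg,
        partial_eta2=float(ss_cond / denom) if denom > 0 else 0.0,
        epsilon_gg=eps,
        df1_uncorrected=df1,
        df2_uncorrected=df2,
        p_uncorrected=p_unc,
        ss_condition=float(ss_cond),
        ss_subject=float(ss_subject),
        ss_error=float(ss_error),
    )


def posthoc_paired_t(data, pairs, m_comparisons: int = 3) -> list[TTestResult]:
    """Paired t-tests with Bonferroni adjustment (capped at 1).

    ``data`` maps condition name -> paired vector (or is a subjects x k
    array with integer pairs).  Paired Cohen's d = mean(diff)/sd(diff).
    Zero-variance nonzero differences are flagged undefined.
    """
    if isinstance(data, dict):
        get = lambda c: np.asarray(data[c], dtype=float)
    else:
        arr = np.asarray(data, dtype=float)
        get = lambda c: arr[:, c]
    out = []
    for a, b in pairs:
        diff = get(a) - get(b)
        n = len(diff)
        if n < 2:
            raise ValueError("need at least 2 paired observations")
        sd = diff.std(ddof=1)
        mean = diff.mean()
        if sd == 0:
            if mean == 0:
                out.append(TTestResult((a, b), 0.0, n - 1, 1.0, 1.0, 0.0))
            else:
                out.append(TTestResult((a, b), np.nan, n - 1, np.nan, np.nan,
                                       np.nan, undefined=True))
            continue
        t = mean / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(abs(t), n - 1)
        out.append(
            TTestResult((a, b), float(t), n - 1, float(p),
                        float(min(1.0, m_comparisons * p)), float(mean / sd))
        )
    return out


def pearson_matrix(table: pd.DataFrame):
    """Pairwise-deletion Pearson correlation matrix with p-values and n.

    Pairs with fewer than 3 complete cases or a constant column are
    reported as NaN (mirroring the printed per-lab tables, where a lab
    with no variance in a covariate shows a dash).
    """
    cols = list(table.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            x = pd.to_numeric(table[cols[i]], errors="coerce")
            y = pd.to_numeric(table[cols[j]], errors="coerce")
            ok = x.notna() & y.notna()
            n[i, j] = n[j, i] = int(ok.sum())
            if i == j:
                r[i, i] = 1.0
                continue
            if ok.sum() < 3:
                continue
            xs, ys = x[ok].to_numpy(), y[ok].to_numpy()
            if xs.std() == 0 or ys.std() == 0:
                continue
            rr, pp = stats.pearsonr(xs, ys)
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    idx = pd.Index(cols)
    return (pd.DataFrame(r, index=idx, columns=idx),
            pd.DataFrame(p, index=idx, columns=idx),
            pd.DataFrame(n, index=idx, columns=idx))


def _power_dfs(n: int, params: PowerParams):
    m, g, eps = params.n_measures, params.n_conditions, params.epsilon
    df1 = (m - 1) * eps
    df2 = (n - g) * (m - 1) * eps
    return df1, df2


def rm_power(n: int, params: PowerParams) -> float:
    """Power of the repeated-measures F test at per-lab sample size ``n``."""
    params.validate()
    df1, df2 = _power_dfs(n, params)
    if df2 <= 0:
        return 0.0
    f2 = params.eta2 / (1.0 - params.eta2)
    lam = f2 * (n - 1) * params.n_measures * params.epsilon / (1.0 - params.rho)
    f_crit = stats.f.isf(params.alpha, df1, df2)
    return float(stats.ncf.sf(f_crit, df1, df2, lam))


def min_n_power(params: PowerParams, target: float = 0.80,
                n_max: int = 10000) -> int:
    """Smallest n with power >= target (searching upward)."""
    params.validate()
    for n in range(params.n_conditions + 1, n_max + 1):
        if rm_power(n, params) >= target:
            return n
    raise ValueError(f"target power {target} not reachable below n={n_max}")


def mc_rm_power(n: int, params: PowerParams, n_reps: int = 10000,
                rng: np.random.Generator | None = None) -> float:
    """Monte-Carlo power of the matching compound-symmetric design.

    Simulates n subjects x m measures from a multivariate normal with
    compound symmetry (unit variance, correlation rho) and level means
    scaled so the true noncentrality equals the analytic convention's
    lambda at this n, then runs :func:`rm_anova_oneway` on every draw and
    counts rejections of the uncorrected F test (epsilon enters the
    analytic formula as a fixed design constant, 1 under the stated
    parameters).  Agreement with :func:`rm_power` validates both the
    noncentral-F computation and the ANOVA implementation.
    """
    params.validate()
    rng = rng or np.random.default_rng()
    m, rho = params.n_measures, params.rho
    f2 = params.eta2 / (1.0 - params.eta2)
    # sum of squared level effects giving lambda = f2*(n-1)*m*eps/(1-rho)
    ss_tau = f2 * m * params.epsilon * (n - 1) / n
    pattern = np.arange(m) - (m - 1) / 2.0
    pattern /= np.sqrt(np.sum(pattern ** 2))
    mu = np.sqrt(ss_tau) * pattern
    df1, df2 = params.n_measures - 1, (n - 1) * (params.n_measures - 1)
    f_crit = stats.f.isf(params.alpha, df1, df2)
    rejections = 0
    for _ in range(n_reps):
        subj = rng.standard_normal((n, 1))
        noise = rng.standard_normal((n, m))
        y = mu + np.sqrt(rho) * subj + np.sqrt(1.0 - rho) * noise
        res = rm_anova_oneway(y)
        if res.F > f_crit:
            rejections += 1
    return rejections / n_reps
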