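"""Trial-level logistic regression: does neural amplitude predict accuracy?

Each test trial contributes one binary outcome (probe judged correctly or
not) and a predictor set of lab, covariates (music/dance years), imagery
type, probe type (ON vs OFF the imagined beat), the subject's
noise-subtracted amplitude at the imagined-beat frequency and at the
2.4 Hz stimulus frequency.

The fit is maximum likelihood by iteratively reweighted least squares,
with the per-iteration deviance retained.  Subjects enter through
cluster-robust standard errors by default (``subject_encoding='cluster'``)
because full subject dummies are exactly collinear with the lab dummies;
``'dummy'`` mode is available and drops the aliased lab columns after an
explicit rank check.  Every term is reported with a 1-df Wald chi-square,
(coef/SE)^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

CONTINUOUS = ("music_years", "dance_years", "amp_imagery", "amp_stimulus")

__all__ = [
    "probe_is_on_beat",
    "LogisticResult",
    "build_design",
    "fit_logistic",
    "fit_by_imagery",
    "TrialLogistic",
]


def probe_is_on_beat(imagery_type: str, probe_position: str) -> bool:
    """A probe falls ON the imagined beat iff its metrical position matches
    the imagery being performed (binary probe during binary imagery,
    ternary probe during ternary imagery)."""
    if imagery_type not in ("binary", "ternary"):
        raise ValueError(f"unknown imagery type {imagery_type!r}")
    if probe_position not in ("binary", "ternary"):
        raise ValueError(f"unknown probe position {probe_position!r}")
    return imagery_type == probe_position


@dataclass
class LogisticResult:
    terms: pd.DataFrame  # coef, se, wald_chi2, p per design column
    converged: bool
    n_used: int
    n_iter: int
    deviance: float
    deviance_trace: list = field(default_factory=list)
    diagnostic: str = ""
    cluster_robust: bool = False

    def __getitem__(self, term: str) -> pd.Series:
        return self.terms.loc[term]


class AliasedDesignError(ValueError):
    """Raised when the encoded design matrix is rank deficient."""

    def __init__(self, aliased_columns):
        self.aliased_columns = list(aliased_columns)
        super().__init__(
            "design matrix is rank deficient; aliased columns: "
            + ", ".join(self.aliased_columns)
        )


def _dummies(s: pd.Series, prefix: str) -> pd.DataFrame:
    """Dummy-code with the alphabetically first level as reference."""
    levels = sorted(s.astype(str).unique())
    return pd.DataFrame(
        {f"{prefix}[{lv}]": (s.astype(str) == lv).astype(float)
         for lv in levels[1:]},
        index=s.index,
    )


def _aliased(X: np.ndarray, names) -> list:
    """Columns linearly dependent on the others, by sequential projection.

    Lab dummies are tested last so that when subject dummies absorb the lab
    structure, the aliasing is reported on the lab columns (the redundant
    coarser encoding), which is the actionable message.
    """
    order = sorted(range(len(names)),
                   key=lambda i: (names[i].startswith("lab["), i))
    basis: list[np.ndarray] = []
    aliased = []
    norms = np.linalg.norm(X, axis=0)
    tol = (norms.max() if norms.size else 0.0) * max(X.shape) * np.finfo(float).eps
    for i in order:
        col = X[:, i].astype(float)
        for b in basis:
            col = col - (b @ col) * b
        nrm = np.linalg.norm(col)
        if nrm <= tol:
            aliased.append(names[i])
        else:
            basis.append(col / nrm)
    return sorted(aliased, key=names.index)


def build_design(
    records: pd.DataFrame,
    subject_encoding: str = "cluster",
    standardize: bool = False,
    include_imagery: bool = True,
    drop_aliased_lab: bool = False,
):
    """Encode trial records into (X, y, groups).

    Categorical predictors are dummy-coded against the alphabetically
    first level.  ``subject_encoding``:

    * ``'cluster'`` — subjects are not in X; their ids are returned as
      ``groups`` for cluster-robust SEs;
    * ``'dummy'`` — subject dummies enter X (raises
      :class:`AliasedDesignError` naming the aliased columns unless
      ``drop_aliased_lab`` removes the lab dummies they absorb); the
      subject-constant covariates music/dance years are omitted in this
      mode because subject dummies absorb them exactly;
    * ``'omit'`` — neither dummies nor clusters.
    """
    if len(records) == 0:
        raise ValueError("no trial records")
    if subject_encoding not in ("cluster", "dummy", "omit"):
        raise ValueError(f"unknown subject_encoding {subject_encoding!r}")
    parts = [pd.DataFrame({"intercept": np.ones(len(records))},
                          index=records.index)]
    if "lab_id" in records and records["lab_id"].nunique() > 1:
        parts.append(_dummies(records["lab_id"], "lab"))
    subject_constant = ("music_years", "dance_years")
    for col in CONTINUOUS:
        if subject_encoding == "dummy" and col in subject_constant:
            continue
        if col in records:
            x = records[col].astype(float)
            if standardize and x.std(ddof=0) > 0:
                x = (x - x.mean()) / x.std(ddof=0)
            parts.append(x.rename(col).to_frame())
    if include_imagery and "imagery_type" in records \
            and records["imagery_type"].nunique() > 1:
        parts.append(_dummies(records["imagery_type"], "imagery"))
    if "probe_type" in records and records["probe_type"].nunique() > 1:
        parts.append(_dummies(records["probe_type"], "probe"))
    if subject_encoding == "dummy":
        parts.append(_dummies(records["subject_id"].astype(str)
                              + "@" + records["lab_id"].astype(str), "subject"))
    X = pd.concat(parts, axis=1)
    aliased = _aliased(X.to_numpy(), list(X.columns))
    if aliased:
        lab_cols = [c for c in aliased if c.startswith("lab[")]
        if drop_aliased_lab and subject_encoding == "dummy" and lab_cols:
            X = X.drop(columns=lab_cols)
            rest = _aliased(X.to_numpy(), list(X.columns))
            if rest:
                raise AliasedDesignError(rest)
        else:
            raise AliasedDesignError(aliased)
    y = records["accuracy"].astype(float).to_numpy()
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("accuracy must be binary 0/1")
    groups = None
    if subject_encoding == "cluster":
        groups = (records["lab_id"].astype(str) + "@"
                  + records["subject_id"].astype(str)).to_numpy()
    return X, y, groups


def _deviance(y, p):
    eps = 1e-12
    return float(-2.0 * np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


def fit_logistic(
    X,
    y,
    max_iter: int = 100,
    tol: float = 1e-8,
    clusters=None,
) -> LogisticResult:
    """Maximum-likelihood logistic fit by IRLS with Wald tests per term.

    Separation or other non-convergence is reported via
    ``converged=False`` with a diagnostic; coefficients are still returned
    for inspection but carry no silent guarantee.
    """
    names = list(X.columns) if hasattr(X, "columns") else \
        [f"x{i}" for i in range(np.asarray(X).shape[1])]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta = np.zeros(k)
    dev_trace = []
    converged = False
    diagnostic = ""
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        dev_trace.append(_deviance(y, p))
        if np.min(w) < 1e-10:
            diagnostic = (
                "fitted probabilities numerically 0 or 1 "
                "(possible complete separation)"
            )
            break
        z = eta + (y - p) / w
        xtw = X.T * w
        try:
            beta_new = np.linalg.solve(xtw @ X, xtw @ z)
        except np.linalg.LinAlgError:
            diagnostic = "singular weighted normal equations"
            break
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    dev = _deviance(y, p)
    if not converged and not diagnostic:
        diagnostic = f"no convergence in {max_iter} IRLS iterations"
    w = np.clip(p * (1.0 - p), 1e-10, None)
    info = (X.T * w) @ X
    bread = np.linalg.inv(info)
    if clusters is not None:
        clusters = np.asarray(clusters)
        score = X * (y - p)[:, None]
        meat = np.zeros((k, k))
        labels = pd.unique(clusters)
        for g in labels:
            sg = score[clusters == g].sum(axis=0)
            meat += np.outer(sg, sg)
        g_n = len(labels)
        if g_n > 1:
            meat *= g_n / (g_n - 1.0)
        cov = bread @ meat @ bread
    else:
        cov = bread
    se = np.sqrt(np.diag(cov))
    wald = (beta / se) ** 2
    terms = pd.DataFrame(
        {
            "coef": beta,
            "se": se,
            "wald_chi2": wald,
            "p": stats.chi2.sf(wald, df=1),
        },
        index=names,
    )
    return LogisticResult(
        terms=terms, converged=converged, n_used=n, n_iter=len(dev_trace),
        deviance=dev, deviance_trace=dev_trace, diagnostic=diagnostic,
        cluster_robust=clusters is not None,
    )


def fit_by_imagery(records: pd.DataFrame, **design_kwargs) -> dict:
    """The pre-registered model refit within each imagery condition,
    with the imagery-type term removed."""
    out = {}
    for imagery in ("binary", "ternary"):
        sub = records[records["imagery_type"] == imagery]
        if len(sub) == 0:
            raise ValueError(f"no {imagery}-imagery trials")
        X, y, groups = build_design(sub, include_imagery=False, **design_kwargs)
        out[imagery] = fit_logistic(X, y, clusters=groups)
    return out


class TrialLogistic(BaseEstimator):
    """Sklearn-style estimator over :func:`build_design` + :func:`fit_logistic`.

    ``fit`` accepts the tidy trial-record frame; fitted attributes:
    ``coef_`` (Series), ``se_``, ``wald_chi2_``, ``p_values_``,
    ``result_`` (full :class:`LogisticResult`).
    """

    def __init__(self, subject_encoding: str = "cluster",
                 standardize: bool = False, include_imagery: bool = True,
                 max_iter: int = 100, tol: float = 1e-8):
        self.subject_encoding = subject_encoding
        self.standardize = standardize
        self.include_imagery = include_imagery
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, records: pd.DataFrame, y=None):
        X, yy, groups = build_design(
            records, subject_encoding=self.subject_encoding,
            standardize=self.standardize, include_imagery=self.include_imagery,
        )
        self.result_ = fit_logistic(X, yy, max_iter=self.max_iter,
                                    tol=self.tol, clusters=groups)
        self.feature_names_in_ = np.array(X.columns)
        self.coef_ = self.result_.terms["coef"]
        self.se_ = self.result_.terms["se"]
        self.wald_chi2_ = self.result_.terms["wald_chi2"]
        self.p_values_ = self.result_.terms["p"]
        return self

    def predict_proba(self, records: pd.DataFrame) -> np.ndarray:
        X, _, _ = build_design(
            records, subject_encoding="omit" if self.subject_encoding == "cluster"
            else self.subject_encoding,
            standardize=self.standardize, include_imagery=self.include_imagery,
        )
        X = X.reindex(columns=self.coef_.index, fill_value=0.0)
        p1 = 1.0 / (1.0 + np.exp(-(X.to_numpy() @ self.coef_.to_numpy())))
        return np.column_stack([1 - p1, p1])
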