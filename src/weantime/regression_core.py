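"""Regression machinery for the comparative weaning analysis.

Two fitting conventions coexist in this kind of comparative work and both
are provided:

* **Model II (reduced major axis, RMA)** bivariate fits for allometric
  scatterplots, where both variables carry error.  The RMA slope is
  ``sign(r) * sd(y)/sd(x)``, equivalently the geometric mean of the two
  directional OLS slopes.
* **Ordinary least squares ANCOVA** for the multi-predictor model
  ``log10(weaning PC) ~ log10(brain mass) + limb dummy + diet dummy``,
  with per-term partial eta-squared effect sizes, sequential variance
  partitioning, and t-based prediction intervals.

Per-term effect sizes are computed from partial (each-term-last, Type III)
sums of squares by default; sequential (entry-order, Type I) sums of
squares drive the variance partition, which is the only decomposition in
which the per-predictor increments add up to the full-model R².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateFitError, SingularDesignError, ValidationError
from .trait_data import TraitTable

_RANK_TOL = 1e-10


def format_p(p: float) -> str:
    """Reporting convention: values below 1e-4 print as ``<.0001``."""
    return "<.0001" if p < 1e-4 else f"{p:.4f}"


# ----------------------------------------------------------------------
# Model II / reduced major axis
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class RmaFit:
    slope: float
    intercept: float
    r: float
    r_squared: float
    n: int
    p_value: float


def rma_fit(x: Sequence[float], y: Sequence[float]) -> RmaFit:
    """Reduced major axis (Model II) line through (x, y).

    slope = sign(r) * sd(y)/sd(x); intercept through the means; the p-value
    is that of the Pearson correlation test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValidationError(f"need at least 3 points for an RMA fit, got {n}")
    sx = float(np.std(x, ddof=1))
    sy = float(np.std(y, ddof=1))
    if sx <= 0 or sy <= 0:
        raise DegenerateFitError("constant x or y: RMA slope undefined")
    r, p = stats.pearsonr(x, y)
    r = float(r)
    slope = (math.copysign(1.0, r) if r != 0 else 1.0) * sy / sx
    intercept = float(np.mean(y)) - slope * float(np.mean(x))
    return RmaFit(slope=slope, intercept=intercept, r=r, r_squared=r * r,
                  n=n, p_value=float(p))


# ----------------------------------------------------------------------
# OLS / ANCOVA
# ----------------------------------------------------------------------

@dataclass
class RegressionFit:
    """A fitted least-squares model with everything needed downstream.

    ``coefficients`` maps predictor name -> estimate, with the intercept
    under the key ``"intercept"``.  ``partial_eta_squared`` uses partial
    (Type III) sums of squares; ``partial_eta_squared_sequential`` the
    entry-order (Type I) ones.
    """

    coefficients: dict[str, float]
    coefficient_se: dict[str, float]
    coefficient_p_values: dict[str, float]
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    f_p_value: float
    df_model: int
    df_residual: int
    n: int
    residuals: np.ndarray
    resid_std: float
    partial_eta_squared: dict[str, float]
    partial_eta_squared_sequential: dict[str, float]
    term_f: dict[str, float]
    term_f_p_values: dict[str, float]
    response: str
    predictors: list[str]
    # prediction internals
    _xtx_inv: np.ndarray = field(repr=False, default=None)
    _pred_min: np.ndarray = field(repr=False, default=None)
    _pred_max: np.ndarray = field(repr=False, default=None)

    def linear_predictor(self, newpoint: Mapping[str, float]) -> float:
        value = self.coefficients["intercept"]
        for name in self.predictors:
            if name not in newpoint:
                raise ValidationError(f"newpoint is missing predictor {name!r}")
            value += self.coefficients[name] * float(newpoint[name])
        return float(value)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "predictors": list(self.predictors),
            "coefficients": dict(self.coefficients),
            "coefficient_se": dict(self.coefficient_se),
            "coefficient_p_values": dict(self.coefficient_p_values),
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
            "f_statistic": self.f_statistic,
            "f_p_value": self.f_p_value,
            "df_model": self.df_model,
            "df_residual": self.df_residual,
            "n": self.n,
            "resid_std": self.resid_std,
            "partial_eta_squared": dict(self.partial_eta_squared),
            "partial_eta_squared_sequential": dict(self.partial_eta_squared_sequential),
            "term_f": dict(self.term_f),
            "term_f_p_values": dict(self.term_f_p_values),
        }


def _design(df, response: str, predictors: Sequence[str]):
    y = np.asarray(df[response], dtype=float)
    X = np.column_stack([np.ones(len(y))] + [np.asarray(df[p], dtype=float) for p in predictors])
    return X, y


def _sse(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def ols_ancova(
    table: "TraitTable | object",
    response: str,
    continuous: Sequence[str],
    dummies: Sequence[str] = (),
) -> RegressionFit:
    """Least-squares ANCOVA of ``response`` on continuous covariates and 0/1 dummies.

    Raises :class:`SingularDesignError` on a rank-deficient design and
    :class:`ValidationError` if a dummy column is not coded 0/1.
    """
    df = table.to_frame() if isinstance(table, TraitTable) else table
    predictors = list(continuous) + list(dummies)
    n = len(df)
    if n <= len(predictors) + 1:
        raise ValidationError(
            f"need n > p + 1 observations (n={n}, p={len(predictors)})"
        )
    for d in dummies:
        vals = set(np.unique(np.asarray(df[d], dtype=float)))
        if not vals <= {0.0, 1.0}:
            raise ValidationError(f"dummy column {d!r} must be coded 0/1")
    X, y = _design(df, response, predictors)
    p = X.shape[1]
    if np.linalg.matrix_rank(X, tol=_RANK_TOL * max(1.0, float(np.abs(X).max()))) < p:
        raise SingularDesignError("design matrix is rank deficient (collinear predictors)")

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0:
        raise DegenerateFitError("response has zero variance")
    r2 = 1.0 - sse / sst
    df_model = p - 1
    df_resid = n - p
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df_resid
    mse = sse / df_resid
    if sse <= _RANK_TOL * sst:
        f_stat = math.inf
        f_p = 0.0
    else:
        f_stat = (r2 / df_model) / ((1.0 - r2) / df_resid)
        f_p = float(stats.f.sf(f_stat, df_model, df_resid))

    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(mse * np.diag(xtx_inv), 0.0))
    names = ["intercept"] + predictors
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)

    # partial (Type III) sums of squares: drop each term from the full model
    eta_partial: dict[str, float] = {}
    term_f: dict[str, float] = {}
    term_f_p: dict[str, float] = {}
    for j, name in enumerate(predictors):
        keep = [k for k in range(p) if k != j + 1]
        ss_term = _sse(X[:, keep], y) - sse
        eta_partial[name] = ss_term / (ss_term + sse) if (ss_term + sse) > 0 else 0.0
        if mse > 0:
            term_f[name] = ss_term / mse
            term_f_p[name] = float(stats.f.sf(term_f[name], 1, df_resid))
        else:
            term_f[name] = math.inf
            term_f_p[name] = 0.0

    # sequential (Type I, entry order) sums of squares
    eta_seq: dict[str, float] = {}
    prev_sse = sst
    for j, name in enumerate(predictors):
        cur_sse = _sse(X[:, : j + 2], y)
        ss_term = prev_sse - cur_sse
        eta_seq[name] = ss_term / (ss_term + sse) if (ss_term + sse) > 0 else 0.0
        prev_sse = cur_sse

    Xp = X[:, 1:]
    return RegressionFit(
        coefficients=dict(zip(names, map(float, beta))),
        coefficient_se=dict(zip(names, map(float, se))),
        coefficient_p_values=dict(zip(names, map(float, pvals))),
        r_squared=r2,
        adj_r_squared=adj_r2,
        f_statistic=float(f_stat),
        f_p_value=float(f_p),
        df_model=df_model,
        df_residual=df_resid,
        n=n,
        residuals=resid,
        resid_std=math.sqrt(mse),
        partial_eta_squared=eta_partial,
        partial_eta_squared_sequential=eta_seq,
        term_f=term_f,
        term_f_p_values=term_f_p,
        response=response,
        predictors=predictors,
        _xtx_inv=xtx_inv,
        _pred_min=Xp.min(axis=0) if p > 1 else np.empty(0),
        _pred_max=Xp.max(axis=0) if p > 1 else np.empty(0),
    )


# ----------------------------------------------------------------------
# Variance partitioning
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class VariancePartition:
    """Sequential (entry-order) incremental R² contributions, in percent."""

    order: tuple[str, ...]
    increments: tuple[float, ...]
    total: float

    def to_dict(self) -> dict:
        return {
            "order": list(self.order),
            "increments_pct": list(self.increments),
            "total_pct": self.total,
        }


def sequential_partition(
    table: "TraitTable | object", response: str, order: Sequence[str]
) -> VariancePartition:
    """Incremental R² (percent of variance) as predictors enter in the stated order."""
    df = table.to_frame() if isinstance(table, TraitTable) else table
    y = np.asarray(df[response], dtype=float)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0:
        raise DegenerateFitError("response has zero variance")
    increments = []
    prev_r2 = 0.0
    for i in range(1, len(order) + 1):
        X, _ = _design(df, response, list(order[:i]))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise SingularDesignError(
                f"collinear design after adding predictor {order[i - 1]!r}"
            )
        r2 = 1.0 - _sse(X, y) / sst
        increments.append((r2 - prev_r2) * 100.0)
        prev_r2 = r2
    return VariancePartition(order=tuple(order), increments=tuple(increments),
                             total=prev_r2 * 100.0)


# ----------------------------------------------------------------------
# Partial correlation
# ----------------------------------------------------------------------

def partial_correlation(
    x: Sequence[float], y: Sequence[float], control: Sequence[float]
) -> tuple[float, float]:
    """First-order partial correlation of x and y controlling one covariate.

    Computed as the Pearson correlation of the residuals of x|control and
    y|control; p from the t transform on n - 3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(control, dtype=float)
    n = len(x)
    if not (len(y) == len(c) == n):
        raise ValidationError("x, y and control must have equal length")
    if n < 4:
        raise ValidationError("need at least 4 points for a partial correlation")
    Z = np.column_stack([np.ones(n), c])
    if np.std(c) <= 0:
        raise DegenerateFitError("control variable is constant")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    if np.std(rx) <= _RANK_TOL * max(1.0, np.std(x)) or \
       np.std(ry) <= _RANK_TOL * max(1.0, np.std(y)):
        raise DegenerateFitError("a variable is collinear with the control")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 3
    r_clip = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clip * math.sqrt(df / (1.0 - r_clip * r_clip))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return r, p


# ----------------------------------------------------------------------
# Prediction
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class PredictionResult:
    """A point prediction on the log10-days scale with a t prediction interval."""

    point: float
    point_days: float
    interval_low: float
    interval_high: float
    level: float
    extrapolation: bool

    def to_dict(self) -> dict:
        return {
            "point_log10_days": self.point,
            "point_days": self.point_days,
            "interval_low_log10_days": self.interval_low,
            "interval_high_log10_days": self.interval_high,
            "interval_low_days": 10 ** self.interval_low,
            "interval_high_days": 10 ** self.interval_high,
            "level": self.level,
            "extrapolation": self.extrapolation,
        }


def predict_with_interval(
    fit: RegressionFit, newpoint: Mapping[str, float], level: float = 0.90
) -> PredictionResult:
    """Predict a new observation with a t-based prediction interval.

    interval = point +/- t_{1-(1-level)/2, df_resid} * s * sqrt(1 + leverage).
    A new point outside the span of any predictor sets ``extrapolation`` —
    a flag, not an error.
    """
    if not (0.0 < level < 1.0):
        raise ValidationError(f"level must be in (0, 1), got {level}")
    if fit.df_residual <= 0:
        raise ValidationError("fit has no residual degrees of freedom")
    x0 = np.concatenate([[1.0], [float(newpoint[name]) for name in fit.predictors]])
    point = float(x0 @ np.array([fit.coefficients["intercept"]]
                                + [fit.coefficients[p] for p in fit.predictors]))
    leverage = float(x0 @ fit._xtx_inv @ x0)
    s = fit.resid_std
    tcrit = float(stats.t.ppf(1.0 - (1.0 - level) / 2.0, fit.df_residual))
    half = tcrit * s * math.sqrt(1.0 + leverage)
    xp = x0[1:]
    extrap = bool(np.any(xp < fit._pred_min - 1e-12) or np.any(xp > fit._pred_max + 1e-12))
    return PredictionResult(
        point=point,
        point_days=10 ** point,
        interval_low=point - half,
        interval_high=point + half,
        level=level,
        extrapolation=extrap,
    )


def loo_species_prediction(
    table: TraitTable,
    species: str,
    response: str = "log_wean_pc",
    continuous: Sequence[str] = ("log_brain",),
    dummies: Sequence[str] = ("lb_code", "dp_code"),
    level: float = 0.90,
    at: Mapping[str, float] | None = None,
) -> tuple[PredictionResult, RegressionFit]:
    """Leave-one-species-out prediction.

    The model is refitted on all other species and evaluated at the focal
    species' predictor values (or explicit ``at`` overrides).  Returns the
    prediction and the n-1 fit it came from.
    """
    df = table.to_frame()
    match = df["species"] == species
    if not match.any():
        raise ValidationError(f"species {species!r} not present in table")
    rest = table.drop_species(species)
    fit = ols_ancova(rest, response, continuous, dummies)
    row = df[match].iloc[0]
    newpoint = {name: float(row[name]) for name in list(continuous) + list(dummies)}
    if at:
        newpoint.update({k: float(v) for k, v in at.items()})
    return predict_with_interval(fit, newpoint, level=level), fit
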