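"""Old-age dependency ratio (ODR) definition and the curve-regression family.

The ODR is 100 x P65+ / P15-64, a percentage. The prediction model links a
region's ODR (y) to its zonal SUM of nighttime-light DN (x) through one of
eleven classical curve-estimation forms:

    Linear        y = b0 + b1 x
    Logarithmic   y = b0 + b1 ln x
    Inverse       y = b0 + b1 / x
    Quadratic     y = b0 + b1 x + b2 x^2
    Cubic         y = b0 + b1 x + b2 x^2 + b3 x^3
    Compound      y = b0 b1^x
    Power         y = b0 x^b1
    Sigmoid       y = exp(b0 + b1 / x)
    Growth        y = exp(b0 + b1 x)
    Exponential   y = b0 exp(b1 x)
    Logistic      y = 1 / (1/mu + b0 b1^x)

The polynomial-type forms are fitted by ordinary least squares on the
(transformed) x; the intrinsically exponential forms are log-linearised
(OLS on ln y) and their coefficients back-transformed — the behaviour of
classical curve-estimation routines. R^2 is reported on the fitting scale
(so it lies in [0, 1]), with the original-scale R^2 alongside for
transparency. Compound, Growth and Exponential are reparameterisations of
one curve and always share an identical fitting-scale R^2.

The Sigmoid form y = exp(b0 + b1/x) with b1 < 0 is the one selected for
ODR prediction: strictly increasing in brightness with a finite ceiling
exp(b0) — aging saturates as cities brighten.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_NAMES",
    "CurveModelSpec",
    "CurveFitResult",
    "ModelComparisonTable",
    "compute_odr",
    "fit_curve_model",
    "compare_models",
    "predict_curve",
    "predict_sigmoid",
    "recover_sigmoid_from_two_points",
    "filter_large_cities",
]

#: Fixed model-name order; also the tie-break order for model selection.
MODEL_NAMES = (
    "Linear", "Logarithmic", "Inverse", "Quadratic", "Cubic",
    "Compound", "Power", "Sigmoid", "Growth", "Exponential", "Logistic",
)

_N_PARAMS = {name: 2 for name in MODEL_NAMES}
_N_PARAMS["Quadratic"] = 3
_N_PARAMS["Cubic"] = 4

_LOG_MODELS = frozenset({"Compound", "Power", "Sigmoid", "Growth",
                         "Exponential", "Logistic"})
_NEEDS_POSITIVE_X = frozenset({"Logarithmic", "Inverse", "Power", "Sigmoid"})


@dataclass(frozen=True)
class CurveModelSpec:
    """One member of the curve family."""

    name: str
    logistic_mu_mode: str = "mean_x"  # or "fixed_bound"
    logistic_bound: float = None

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}")
        if self.logistic_mu_mode not in ("mean_x", "fixed_bound"):
            raise ValueError("logistic_mu_mode must be mean_x or fixed_bound")

    @property
    def n_params(self) -> int:
        return _N_PARAMS[self.name]

    @property
    def fitting_scale(self) -> str:
        return "log-linearized" if self.name in _LOG_MODELS else "original"


@dataclass
class CurveFitResult:
    """Coefficients and goodness of fit for one curve model."""

    model: CurveModelSpec
    b0: float
    b1: float
    b2: float = None
    b3: float = None
    mu: float = None
    r_squared: float = None       # on the fitting scale
    r_squared_original: float = None
    n_obs: int = 0

    @property
    def coefficients(self):
        return tuple(b for b in (self.b0, self.b1, self.b2, self.b3) if b is not None)


def compute_odr(p65plus, p15to64) -> float:
    """Old-age dependency ratio in percent: 100 * P65+ / P15-64."""
    if p65plus < 0:
        raise ValueError("old-age population must be non-negative")
    if p15to64 <= 0:
        raise ValueError("working-age population must be strictly positive")
    return 100.0 * p65plus / p15to64


# -- fitting ----------------------------------------------------------------


def _design(name, x, mu):
    if name in ("Linear", "Growth"):
        return np.column_stack([np.ones_like(x), x])
    if name in ("Logarithmic", "Power"):
        return np.column_stack([np.ones_like(x), np.log(x)])
    if name in ("Inverse", "Sigmoid"):
        return np.column_stack([np.ones_like(x), 1.0 / x])
    if name == "Quadratic":
        return np.column_stack([np.ones_like(x), x, x**2])
    if name == "Cubic":
        return np.column_stack([np.ones_like(x), x, x**2, x**3])
    if name in ("Compound", "Exponential", "Logistic"):
        return np.column_stack([np.ones_like(x), x])
    raise AssertionError(name)


def _response(spec, x, y):
    """Response on the fitting scale, or raise on domain violations."""
    name = spec.name
    if name not in _LOG_MODELS:
        return np.asarray(y, dtype=float), None
    if name == "Logistic":
        mu = float(np.mean(x)) if spec.logistic_mu_mode == "mean_x" else float(spec.logistic_bound)
        if mu <= 0:
            raise ValueError("logistic mu must be positive")
        inner = 1.0 / y - 1.0 / mu
        bad = np.flatnonzero(inner <= 0)
        if bad.size:
            raise ValueError(
                f"logistic transform undefined (1/y <= 1/mu) at points {bad.tolist()}"
            )
        return np.log(inner), mu
    bad = np.flatnonzero(y <= 0)
    if bad.size:
        raise ValueError(f"nonpositive y for log-linearised model at points {bad.tolist()}")
    return np.log(y), None


def _back_transform(name, beta, mu):
    """Map OLS coefficients on the fitting scale to model parameters."""
    b2 = b3 = None
    if name in ("Linear", "Logarithmic", "Inverse"):
        b0, b1 = beta
    elif name == "Quadratic":
        b0, b1, b2 = beta
    elif name == "Cubic":
        b0, b1, b2, b3 = beta
    elif name in ("Sigmoid", "Growth"):
        b0, b1 = beta              # already the model parameters
    elif name in ("Compound", "Logistic"):
        b0, b1 = math.exp(beta[0]), math.exp(beta[1])
    elif name == "Exponential":
        b0, b1 = math.exp(beta[0]), beta[1]
    elif name == "Power":
        b0, b1 = math.exp(beta[0]), beta[1]
    else:
        raise AssertionError(name)
    return b0, b1, b2, b3


def predict_curve(fit: CurveFitResult, x):
    """Evaluate a fitted curve at brightness x (scalar or array)."""
    x = np.asarray(x, dtype=float)
    name = fit.model.name
    b0, b1, b2, b3 = fit.b0, fit.b1, fit.b2, fit.b3
    if name == "Linear":
        return b0 + b1 * x
    if name == "Logarithmic":
        return b0 + b1 * np.log(x)
    if name == "Inverse":
        return b0 + b1 / x
    if name == "Quadratic":
        return b0 + b1 * x + b2 * x**2
    if name == "Cubic":
        return b0 + b1 * x + b2 * x**2 + b3 * x**3
    if name == "Compound":
        return b0 * b1**x
    if name == "Power":
        return b0 * x**b1
    if name == "Sigmoid":
        return np.exp(b0 + b1 / x)
    if name == "Growth":
        return np.exp(b0 + b1 * x)
    if name == "Exponential":
        return b0 * np.exp(b1 * x)
    if name == "Logistic":
        return 1.0 / (1.0 / fit.mu + b0 * b1**x)
    raise AssertionError(name)


def _r_squared(observed, fitted):
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    ss_res = float(np.sum((observed - fitted) ** 2))
    if ss_tot == 0.0:
        raise ValueError("response is constant; R^2 undefined")
    return 1.0 - ss_res / ss_tot


def fit_curve_model(points, model) -> CurveFitResult:
    """Fit one curve model to (x = SUM of DN, y = ODR %) pairs by OLS.

    ``model`` may be a name or a :class:`CurveModelSpec`. Raises on domain
    violations (nonpositive x for ln/1/x transforms, nonpositive y for
    log-linearised forms) and on rank-deficient designs.
    """
    spec = model if isinstance(model, CurveModelSpec) else CurveModelSpec(model)
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be a sequence of (x, y) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if len(x) < spec.n_params:
        raise ValueError(f"{spec.name} needs at least {spec.n_params} points")
    if spec.name in _NEEDS_POSITIVE_X and np.any(x <= 0):
        raise ValueError(f"{spec.name} requires strictly positive x")

    z, mu = _response(spec, x, y)
    X = _design(spec.name, x, mu)
    # column-scale so polynomial designs at brightness magnitudes (~1e5)
    # keep well-separated singular values
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        raise np.linalg.LinAlgError(f"rank-deficient design for {spec.name}")
    Xs = X / norms
    if np.linalg.matrix_rank(Xs) < X.shape[1]:
        raise np.linalg.LinAlgError(f"rank-deficient design for {spec.name}")
    beta, *_ = np.linalg.lstsq(Xs, z, rcond=None)
    beta = beta / norms
    b0, b1, b2, b3 = _back_transform(spec.name, beta, mu)
    if not all(np.isfinite(b) for b in (b0, b1) if b is not None):
        raise ValueError(f"non-finite coefficients for {spec.name}")

    fit = CurveFitResult(spec, b0, b1, b2, b3, mu=mu, n_obs=len(x))
    fit.r_squared = _r_squared(z, X @ beta)
    fit.r_squared_original = _r_squared(y, np.asarray(predict_curve(fit, x)))
    return fit


# -- model comparison and selection ----------------------------------------


@dataclass
class ModelComparisonTable:
    """Per-year fitting-scale R^2 for every model, with per-model means.

    ``table`` is a DataFrame indexed by model name with one column per year
    label plus a ``Mean`` column (the mean over the year columns that
    fitted; failed cells are NaN and excluded from the mean).
    """

    table: pd.DataFrame
    fits: dict = field(default_factory=dict)

    @property
    def best_model(self) -> str:
        """Model with the highest mean R^2; ties broken by fewer parameters,
        then by fixed model-name order."""
        means = self.table["Mean"]
        best = max(
            means.index,
            key=lambda m: (means[m], -_N_PARAMS[m], -MODEL_NAMES.index(m)),
        )
        return best


def compare_models(series: dict, models=MODEL_NAMES, **spec_kwargs) -> ModelComparisonTable:
    """Fit every model to every year's (x, y) series and tabulate R^2.

    ``series`` maps a year label to a list of (SUM of DN, ODR) pairs. A model
    failing on a year records NaN for that cell (with a warning) and that
    cell is excluded from the model's mean.
    """
    years = list(series.keys())
    grid = pd.DataFrame(index=list(models), columns=years, dtype=float)
    fits = {}
    for name in models:
        for year in years:
            try:
                fit = fit_curve_model(series[year], CurveModelSpec(name, **spec_kwargs))
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning("model %s failed for %s: %s", name, year, exc)
                grid.loc[name, year] = np.nan
                continue
            grid.loc[name, year] = fit.r_squared
            fits[(name, year)] = fit
    grid["Mean"] = grid[years].mean(axis=1, skipna=True)
    return ModelComparisonTable(grid, fits)


# -- the selected Sigmoid model ---------------------------------------------


def predict_sigmoid(fit: CurveFitResult, x):
    """Municipal ODR (%) predicted by a fitted Sigmoid at brightness x."""
    if fit.model.name != "Sigmoid":
        raise ValueError("predict_sigmoid requires a Sigmoid fit")
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("SUM of DN must be strictly positive")
    out = np.exp(fit.b0 + fit.b1 / x)
    return float(out) if out.ndim == 0 else out


def recover_sigmoid_from_two_points(p1, p2) -> CurveFitResult:
    """Exact Sigmoid coefficients through two (SUM of DN, ODR) points.

    Two observations determine exp(b0 + b1/x) exactly:
        b1 = (ln y1 - ln y2) / (1/x1 - 1/x2),  b0 = ln y1 - b1/x1.
    Used to reconstruct a published model from printed prediction pairs.
    """
    (x1, y1), (x2, y2) = p1, p2
    if x1 <= 0 or x2 <= 0 or y1 <= 0 or y2 <= 0:
        raise ValueError("both points need positive x and y")
    if x1 == x2:
        raise ValueError("degenerate input: coincident x")
    b1 = (math.log(y1) - math.log(y2)) / (1.0 / x1 - 1.0 / x2)
    b0 = math.log(y1) - b1 / x1
    return CurveFitResult(CurveModelSpec("Sigmoid"), b0, b1,
                          r_squared=1.0, r_squared_original=1.0, n_obs=2)


def filter_large_cities(records, odr_min=13.71, sum_min=115_762) -> list:
    """Keep the large and medium-sized cities: round(ODR, 2) >= odr_min and
    SUM of DN >= sum_min; returned sorted by ODR descending.

    ``records`` is a sequence of (zone_id, sum_dn, odr) triples. The ODR is
    rounded to two decimals before thresholding, so a city printed at the
    cutoff (e.g. 13.706 -> 13.71) is retained.
    """
    kept = [
        (zid, sum_dn, odr)
        for zid, sum_dn, odr in records
        if round(float(odr), 2) >= odr_min and sum_dn >= sum_min
    ]
    return sorted(kept, key=lambda r: -r[2])
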