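"""Single-substance concentration-response curves.

Inhibition of chlorophyll-a fluorescence is modelled as a fraction of the
control response on a log10 concentration scale.  Two sigmoid families are
supported:

* logistic:  ``E(c) = theta_max / (1 + exp(-(alpha + beta*log10 c)))``
* weibull:   ``E(c) = theta_max * (1 - exp(-exp(alpha + beta*log10 c)))``

with ``theta_max`` in (0, 1] the maximal effect, ``alpha`` the location and
``beta > 0`` the slope.  Both curves rise strictly from 0 (at c = 0, taken as
the limit of the log scale) to ``theta_max``.

Fitting is nonlinear least squares in effect space, seeded from a coarse
parameter grid because sigmoid likelihoods are multimodal; the best family is
picked by AIC.  Fitted curves for a panel of herbicides can be persisted to a
plain-text (YAML) database and read back losslessly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import yaml
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "FAMILIES",
    "ResponseModel",
    "FitResult",
    "DoseResponseCurve",
    "effect_at",
    "ecx",
    "fit_model",
    "select_best",
    "curve_db_write",
    "curve_db_read",
]

FAMILIES = ("logistic", "weibull")

#: responses outside this window are treated as data errors, not clipped
RESPONSE_WINDOW = (-0.1, 1.1)

#: spread below which a dataset is considered flat (no dose dependence)
FLAT_SPREAD = 0.01

CURVE_DB_SCHEMA = "herbtox-curvedb/1"


@dataclass(frozen=True)
class ResponseModel:
    """A fitted sigmoid concentration-response curve for one substance."""

    family: str
    theta_max: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; expected one of {FAMILIES}")
        if not (0.0 < self.theta_max <= 1.0):
            raise ValueError(f"theta_max must be in (0, 1], got {self.theta_max}")
        if not (self.beta > 0.0 and math.isfinite(self.beta)):
            raise ValueError(f"beta must be positive and finite, got {self.beta}")
        if not math.isfinite(self.alpha):
            raise ValueError(f"alpha must be finite, got {self.alpha}")

    def effect(self, concentration):
        return effect_at(self, concentration)

    def ecx(self, x: float) -> float:
        return ecx(self, x)

    @property
    def ec50(self) -> float:
        """Concentration producing a 50% effect (requires theta_max > 0.5)."""
        return ecx(self, 0.5)


@dataclass
class FitResult:
    """Outcome of fitting one family to one concentration-response dataset."""

    model: ResponseModel | None
    rss: float
    aic: float
    n_points: int
    converged: bool


def effect_at(model: ResponseModel, concentration):
    """Predicted inhibition fraction at the given concentration(s) (nmol/L).

    The zero-concentration limit is handled explicitly and returns 0.
    Negative concentrations raise ``ValueError``.
    """
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    out = np.zeros_like(c)
    pos = c > 0
    with np.errstate(divide="ignore"):
        z = model.alpha + model.beta * np.log10(np.where(pos, c, 1.0))
    if model.family == "logistic":
        e = model.theta_max / (1.0 + np.exp(-z))
    else:  # weibull
        e = model.theta_max * (1.0 - np.exp(-np.exp(z)))
    out[pos] = e[pos]
    if np.isscalar(concentration) or np.ndim(concentration) == 0:
        return float(out)
    return out


def ecx(model: ResponseModel, x: float) -> float:
    """Concentration producing effect fraction ``x`` (closed-form inversion).

    Valid for 0 < x < theta_max; outside this the effect level is unreachable.
    """
    if not (0.0 < x < model.theta_max):
        raise ValueError(
            f"effect level x={x} outside attainable range (0, theta_max={model.theta_max})"
        )
    p = x / model.theta_max
    if model.family == "logistic":
        z = math.log(p / (1.0 - p))
    else:  # weibull
        z = math.log(-math.log(1.0 - p))
    return 10.0 ** ((z - model.alpha) / model.beta)


# ---------------------------------------------------------------------------
# fitting


def _validate_points(concentration, response):
    c = np.asarray(concentration, dtype=float).ravel()
    y = np.asarray(response, dtype=float).ravel()
    if c.shape != y.shape:
        raise ValueError("concentration and response must have the same length")
    if not np.all(np.isfinite(c)) or not np.all(np.isfinite(y)):
        raise ValueError("concentration and response must be finite")
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    lo, hi = RESPONSE_WINDOW
    if np.any(y < lo) or np.any(y > hi):
        bad = y[(y < lo) | (y > hi)]
        raise ValueError(
            f"responses outside [{lo}, {hi}] look like data errors: {bad[:5].tolist()}"
        )
    # zero-concentration controls are used only for normalisation upstream
    keep = c > 0
    c, y = c[keep], y[keep]
    if np.unique(c).size < 4:
        raise ValueError("need at least 4 distinct nonzero concentrations to fit")
    return c, y


def _predict(family: str, theta: float, alpha: float, beta: float, logc):
    z = alpha + beta * logc
    if family == "logistic":
        return theta / (1.0 + np.exp(-z))
    return theta * (1.0 - np.exp(-np.exp(z)))


# coarse multistart grid; sigmoid least squares surfaces are multimodal
_GRID_ALPHA = np.linspace(-6.0, 6.0, 25)
_GRID_BETA = (0.5, 1.0, 2.0, 4.0)
_GRID_THETA = (0.6, 0.8, 1.0)


def _grid_seed(family: str, logc, y):
    best = None
    for theta in _GRID_THETA:
        for beta in _GRID_BETA:
            pred = _predict(family, theta, _GRID_ALPHA[:, None], beta, logc[None, :])
            sse = np.sum((pred - y[None, :]) ** 2, axis=1)
            i = int(np.argmin(sse))
            if best is None or sse[i] < best[0]:
                best = (float(sse[i]), theta, float(_GRID_ALPHA[i]), beta)
    _, theta, alpha, beta = best
    return theta, alpha, beta


def _aic(rss: float, n: int, k: int = 4) -> float:
    # k = 3 curve parameters + 1 error variance; rss floored for noiseless fits
    return n * math.log(max(rss, 1e-30) / n) + 2.0 * k


class DoseResponseCurve(RegressorMixin, BaseEstimator):
    """Sigmoid concentration-response regressor for one substance.

    Parameters
    ----------
    family : {"logistic", "weibull"}
        Sigmoid family fitted by nonlinear least squares in effect space.

    Attributes
    ----------
    theta_max_, alpha_, beta_ : float
        Fitted curve parameters.
    rss_ : float
        Residual sum of squares at the optimum.
    aic_ : float
        Information criterion used for family selection.
    converged_ : bool
        False for flat data or optimizer failure; parameters are then unset.
    model_ : ResponseModel
        The fitted curve as a value object (only when converged).
    """

    def __init__(self, family: str = "logistic"):
        self.family = family

    def fit(self, X, y):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be a single concentration column")
            X = X[:, 0]
        c, yy = _validate_points(X, y)
        self.n_points_ = int(c.size)
        self.converged_ = False
        self.rss_ = float("nan")
        self.aic_ = float("nan")
        if float(np.ptp(yy)) <= FLAT_SPREAD:
            # flat data carries no dose information; refuse an arbitrary curve
            return self

        logc = np.log10(c)
        theta0, alpha0, beta0 = _grid_seed(self.family, logc, yy)

        def resid(p):
            return _predict(self.family, p[0], p[1], p[2], logc) - yy

        try:
            sol = least_squares(
                resid,
                x0=[theta0, alpha0, beta0],
                bounds=([1e-6, -50.0, 1e-6], [1.0, 50.0, 50.0]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:
            return self
        if not sol.success or not np.all(np.isfinite(sol.x)):
            return self
        theta, alpha, beta = (float(v) for v in sol.x)
        self.theta_max_, self.alpha_, self.beta_ = theta, alpha, beta
        self.rss_ = float(np.sum(resid(sol.x) ** 2))
        self.aic_ = _aic(self.rss_, self.n_points_)
        self.converged_ = True
        return self

    @property
    def model_(self) -> ResponseModel:
        if not getattr(self, "converged_", False):
            raise AttributeError("fit did not converge; no model available")
        return ResponseModel(self.family, self.theta_max_, self.alpha_, self.beta_)

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return np.asarray(effect_at(self.model_, X), dtype=float)

    def result_(self) -> FitResult:
        if getattr(self, "converged_", False):
            return FitResult(self.model_, self.rss_, self.aic_, self.n_points_, True)
        return FitResult(None, float("nan"), float("nan"),
                         getattr(self, "n_points_", 0), False)


def fit_model(concentration, response, family: str = "logistic") -> FitResult:
    """Fit one sigmoid family; see :class:`DoseResponseCurve`."""
    est = DoseResponseCurve(family=family).fit(np.asarray(concentration), response)
    return est.result_()


def select_best(concentration, response, families=FAMILIES) -> FitResult:
    """Fit every family and return the converged fit with the lowest AIC.

    AIC ties break toward the logistic family (listed first by default).
    Raises ``RuntimeError`` when no family converges.
    """
    fits = [(fam, fit_model(concentration, response, fam)) for fam in families]
    converged = [(fam, f) for fam, f in fits if f.converged]
    if not converged:
        raise RuntimeError(f"no converged fit among families {tuple(families)}")
    best = min(converged, key=lambda t: (t[1].aic, t[0] != "logistic"))
    return best[1]


# ---------------------------------------------------------------------------
# curve database persistence


def curve_db_write(curves: dict[str, FitResult | ResponseModel], path) -> None:
    """Persist fitted curves to a versioned plain-text (YAML) database."""
    records = []
    for name, item in curves.items():
        model = item.model if isinstance(item, FitResult) else item
        if model is None:
            raise ValueError(f"curve for {name!r} has no converged model")
        rec = {
            "herbicide": str(name),
            "family": model.family,
            "theta_max": float(model.theta_max),
            "alpha": float(model.alpha),
            "beta": float(model.beta),
        }
        if isinstance(item, FitResult):
            rec["rss"] = float(item.rss)
            rec["aic"] = float(item.aic)
            rec["n_points"] = int(item.n_points)
        records.append(rec)
    doc = {"schema": CURVE_DB_SCHEMA, "curves": records}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def curve_db_read(path) -> dict[str, FitResult]:
    """Read a curve database written by :func:`curve_db_write`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or doc.get("schema") != CURVE_DB_SCHEMA:
        raise ValueError(f"not a {CURVE_DB_SCHEMA} database: {path}")
    out: dict[str, FitResult] = {}
    for rec in doc.get("curves") or []:
        name = rec["herbicide"]
        if name in out:
            raise ValueError(f"duplicate herbicide {name!r} in curve database")
        family = rec["family"]
        if family not in FAMILIES:
            raise ValueError(f"unknown model family tag {family!r} for {name!r}")
        model = ResponseModel(family, rec["theta_max"], rec["alpha"], rec["beta"])
        out[name] = FitResult(
            model,
            float(rec.get("rss", float("nan"))),
            float(rec.get("aic", float("nan"))),
            int(rec.get("n_points", 0)),
            True,
        )
    return out
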