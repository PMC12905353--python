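"""The three fire-property GLMs.

Burnt area is fitted as a quasi-binomial with a logit link (fractional burnt
area read as a probability of burning); fire size and fire intensity as
quasi-Poisson with a log link after min-max normalisation of the response.
Predictors are z-scored on the training set so the absolute t value
(coefficient / standard error) is unitless and comparable across predictors.
Dispersion is the Pearson chi-square over residual degrees of freedom; point
estimates are identical to the plain binomial/Poisson fits and only the
standard errors scale with the square root of the dispersion.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .predictors import PREDICTORS, PredictorField

RESPONSES = ("BA", "FS", "FI")
_FAMILIES = {"BA": ("quasi-binomial", "logit"),
             "FS": ("quasi-Poisson", "log"),
             "FI": ("quasi-Poisson", "log")}


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; names the collinear columns."""


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the deviance trace."""


@dataclass
class FittedGLM:
    """Fitted coefficients and metadata for one fire-property model.

    ``beta``/``se``/``t_values`` are length 17 (intercept first, then the 16
    predictors in canonical order) on the standardised-predictor scale.
    ``norm_min``/``norm_max`` are the min-max constants used to map FS/FI to
    [0, 1] before fitting (identity for BA).
    """

    response: str
    family: str
    link: str
    beta: np.ndarray
    se: np.ndarray
    dispersion: float
    cov_beta: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray
    norm_min: float = 0.0
    norm_max: float = 1.0
    layout: tuple[str, ...] = PREDICTORS
    # training data kept for partial residuals; not serialised
    _train_Z: np.ndarray | None = field(default=None, repr=False)
    _train_y: np.ndarray | None = field(default=None, repr=False)

    @property
    def t_values(self) -> np.ndarray:
        return self.beta / self.se

    # ------------------------------------------------------------- io
    def to_json(self) -> str:
        doc = {
            "response": self.response, "family": self.family, "link": self.link,
            "beta": self.beta.tolist(), "se": self.se.tolist(),
            "dispersion": self.dispersion, "cov_beta": self.cov_beta.tolist(),
            "x_mean": self.x_mean.tolist(), "x_std": self.x_std.tolist(),
            "norm_min": self.norm_min, "norm_max": self.norm_max,
            "layout": list(self.layout),
        }
        return json.dumps(doc, indent=2)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "FittedGLM":
        doc = json.loads(text)
        return cls(
            response=doc["response"], family=doc["family"], link=doc["link"],
            beta=np.asarray(doc["beta"]), se=np.asarray(doc["se"]),
            dispersion=float(doc["dispersion"]),
            cov_beta=np.asarray(doc["cov_beta"]),
            x_mean=np.asarray(doc["x_mean"]), x_std=np.asarray(doc["x_std"]),
            norm_min=float(doc["norm_min"]), norm_max=float(doc["norm_max"]),
            layout=tuple(doc["layout"]),
        )

    @classmethod
    def load(cls, path) -> "FittedGLM":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _design(X) -> np.ndarray:
    if isinstance(X, PredictorField):
        return X.matrix()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(PREDICTORS):
        raise ValueError(
            f"design must have {len(PREDICTORS)} columns in canonical order "
            f"{list(PREDICTORS)}; got shape {X.shape}")
    return X


def _check_rank(Z: np.ndarray) -> None:
    A = np.column_stack([np.ones(Z.shape[0]), Z])
    r = np.linalg.matrix_rank(A)
    if r < A.shape[1]:
        # identify offending columns via the QR diagonal of the design
        _, rmat = np.linalg.qr(A)
        diag = np.abs(np.diag(rmat))
        tol = diag.max() * max(A.shape) * np.finfo(float).eps
        bad_idx = np.flatnonzero(diag < tol)
        names = ["intercept"] + list(PREDICTORS)
        bad = [names[i] for i in bad_idx] or ["(linear combination)"]
        raise RankDeficiencyError(f"rank-deficient design; collinear columns: {bad}")


def fit_glm(X, y, response: str, mask=None, maxiter: int = 100,
            tol: float = 1e-8) -> FittedGLM:
    """Fit the quasi-binomial (BA) or quasi-Poisson (FS/FI) model.

    ``mask`` selects the training cells (e.g. observed-fire cells for FS/FI).
    FS/FI responses are min-max normalised to [0, 1] before fitting and the
    constants stored on the model.
    """
    if response not in RESPONSES:
        raise ValueError(f"response must be one of {RESPONSES}")
    Xmat = _design(X)
    y = np.asarray(y, dtype=float).ravel()
    if y.size != Xmat.shape[0]:
        raise ValueError("response length does not match design rows")
    if mask is not None:
        mask = np.asarray(mask).ravel().astype(bool)
        Xmat, y = Xmat[mask], y[mask]
    if not np.all(np.isfinite(Xmat)) or not np.all(np.isfinite(y)):
        raise ValueError("missing or non-finite values on included cells")
    n, p = Xmat.shape
    if n < 10 * (p + 1):
        raise ValueError(f"need >= {10 * (p + 1)} cells for {p + 1} parameters; got {n}")

    x_mean = Xmat.mean(axis=0)
    x_std = Xmat.std(axis=0)
    if np.any(x_std == 0):
        bad = [PREDICTORS[i] for i in np.flatnonzero(x_std == 0)]
        raise RankDeficiencyError(f"rank-deficient design; constant columns: {bad}")
    Z = (Xmat - x_mean) / x_std
    _check_rank(Z)

    norm_min, norm_max = 0.0, 1.0
    if response in ("FS", "FI"):
        norm_min, norm_max = float(y.min()), float(y.max())
        if norm_max <= norm_min:
            raise ValueError(f"{response} response is constant; cannot normalise")
        y = (y - norm_min) / (norm_max - norm_min)
        family = sm.families.Poisson()
    else:
        if y.min() < 0 or y.max() > 1:
            raise ValueError("BA response must lie in [0, 1]")
        family = sm.families.Binomial()

    A = np.column_stack([np.ones(n), Z])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # fractional endog triggers DomainWarning
        model = sm.GLM(y, A, family=family)
        res = model.fit(maxiter=maxiter, tol=tol)
    if not getattr(res, "converged", True):
        raise ConvergenceError(
            f"IRLS did not converge in {maxiter} iterations; deviance trace: "
            f"{res.fit_history.get('deviance', [])}")

    # quasi-family: point estimates are the plain-family MLE; the Pearson
    # dispersion rescales the covariance (SE ratio = sqrt(dispersion))
    dispersion = float(res.pearson_chi2 / res.df_resid)
    cov = np.asarray(res.cov_params()) * dispersion
    fam_name, link = _FAMILIES[response]
    return FittedGLM(
        response=response, family=fam_name, link=link,
        beta=np.asarray(res.params), se=np.sqrt(np.diag(cov)),
        dispersion=dispersion, cov_beta=cov,
        x_mean=x_mean, x_std=x_std, norm_min=norm_min, norm_max=norm_max,
        _train_Z=Z, _train_y=y,
    )


def _standardised_design(model: FittedGLM, X) -> np.ndarray:
    Xmat = _design(X)
    return (Xmat - model.x_mean) / model.x_std


def _eta(model: FittedGLM, X) -> np.ndarray:
    Z = _standardised_design(model, X)
    return model.beta[0] + Z @ model.beta[1:]


def _inv_link(model: FittedGLM, eta: np.ndarray) -> np.ndarray:
    return expit(eta) if model.link == "logit" else np.exp(eta)


def predict(model: FittedGLM, X, denormalise: bool = False) -> np.ndarray:
    """Inverse-link(X beta).  For FS/FI, ``denormalise=True`` maps the
    prediction back to physical units with the stored min-max constants."""
    mu = _inv_link(model, _eta(model, X))
    if denormalise and model.response in ("FS", "FI"):
        mu = mu * (model.norm_max - model.norm_min) + model.norm_min
    if isinstance(X, PredictorField):
        mu = mu.reshape(X.grid.shape)
    return mu


def predictive_interval(model: FittedGLM, X, level: float = 0.95,
                        literal: bool = False, denormalise: bool = False
                        ) -> tuple[np.ndarray, np.ndarray]:
    """95% predictive confidence band.

    Default construction: fitted linear predictor +/- z * SE(eta), pushed
    through the inverse link, which keeps burnt-area bounds inside (0, 1).
    ``literal=True`` instead uses the multiplicative reading fitted value
    +/- fitted * z * SE.
    """
    if not (0 < level < 1):
        raise ValueError("confidence level must lie in (0, 1)")
    Z = _standardised_design(model, X)
    A = np.column_stack([np.ones(Z.shape[0]), Z])
    eta = A @ model.beta
    se_eta = np.sqrt(np.einsum("ij,jk,ik->i", A, model.cov_beta, A))
    z = stats.norm.ppf(0.5 + level / 2.0)
    if literal:
        mu = _inv_link(model, eta)
        lower, upper = mu * (1.0 - z * se_eta), mu * (1.0 + z * se_eta)
    else:
        lower = _inv_link(model, eta - z * se_eta)
        upper = _inv_link(model, eta + z * se_eta)
    if denormalise and model.response in ("FS", "FI"):
        rng = model.norm_max - model.norm_min
        lower = lower * rng + model.norm_min
        upper = upper * rng + model.norm_min
    if isinstance(X, PredictorField):
        lower = lower.reshape(X.grid.shape)
        upper = upper.reshape(X.grid.shape)
    return lower, upper


def partial_residuals(model: FittedGLM, predictor: str
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Working residuals plus beta_j * z_j for the training cells; the
    standard diagnostic showing a predictor's effect with the others held
    constant.  Returns (z_j values, partial residuals)."""
    if predictor not in model.layout:
        raise ValueError(f"unknown predictor {predictor!r}")
    if model._train_Z is None:
        raise ValueError("model carries no training data (deserialised?)")
    j = model.layout.index(predictor)
    Z, y = model._train_Z, model._train_y
    eta = model.beta[0] + Z @ model.beta[1:]
    mu = _inv_link(model, eta)
    if model.link == "logit":
        dlink = 1.0 / (mu * (1.0 - mu))
    else:
        dlink = 1.0 / mu
    working = (y - mu) * dlink
    return Z[:, j], working + model.beta[1 + j] * Z[:, j]
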