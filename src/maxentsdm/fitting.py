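"""Maximum-entropy model fitting by infinitely weighted logistic regression.

Presence-background data carry no absences, so the occurrence density is
estimated as the strong-background-weight limit of a weighted logistic
regression (IWLR): presences enter with label 1 and weight 1, and the
background — with all presences appended to it, so that it represents every
condition in the study area — enters with label 0 and a large weight.  In
that limit the slope coefficients converge to the Gibbs-distribution
(maximum-entropy) estimates, and predictions are expressed as the
probability ratio

    PRO_i = N * exp(alpha + sum_k beta_k x_ik)

where ``N`` is the number of background locations, ``alpha`` a normalizing
constant chosen so that the raw output sums to one over the training
background, and ``x`` the matrix of derived variables scaled to [0, 1].
PRO = 1 is the suitability of an average training location.

Presence-absence data are fitted by ordinary (unweighted) logistic
regression instead; the same derived-variable designs are accepted by both
paths.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

__all__ = [
    "MaxentModel",
    "FittingError",
    "ConvergenceError",
    "fit_model",
    "deviance_stats",
    "predict_pro",
    "is_background",
]


class FittingError(ValueError):
    pass


class ConvergenceError(FittingError):
    pass


def is_background(rv) -> np.ndarray:
    """Boolean mask of background rows (response coded as missing)."""
    return np.asarray(pd.isna(np.asarray(rv, dtype=float)))


def _weighted_logistic_irls(X, y, w, tol=1e-8, max_iter=100):
    """Newton/IRLS for the weighted binomial log-likelihood.

    Maximizes  sum_i w_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ]  with
    p = expit(X b).  Step-halving guards each Newton step; convergence is
    declared on the max-norm of the gradient.

    Returns (coef, loglik, converged, grad_norm).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)

    def loglik(b):
        eta = X @ b
        # log p = -log(1+e^-eta), log(1-p) = -log(1+e^eta)
        return float(np.sum(w * (y * -np.logaddexp(0.0, -eta) + (1.0 - y) * -np.logaddexp(0.0, eta))))

    ll = loglik(beta)
    converged = False
    grad_norm = np.inf
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        grad = X.T @ (w * (y - mu))
        grad_norm = float(np.max(np.abs(grad))) if grad.size else 0.0
        if grad_norm < tol:
            converged = True
            break
        wvar = w * mu * (1.0 - mu)
        H = X.T @ (X * wvar[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step-halving: never accept a decrease in the log-likelihood
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = loglik(cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll = loglik(beta)
    return beta, ll, converged, grad_norm


def _binomial_deviance(X, y, w, beta):
    eta = np.asarray(X, dtype=float) @ beta
    ll = np.sum(
        np.asarray(w, float)
        * (np.asarray(y, float) * -np.logaddexp(0.0, -eta) + (1.0 - np.asarray(y, float)) * -np.logaddexp(0.0, eta))
    )
    # saturated log-likelihood is 0 for 0/1 responses
    return float(-2.0 * ll)


class MaxentModel(BaseEstimator):
    """Presence-background maximum-entropy model (or presence-absence GLM).

    Parameters
    ----------
    algorithm : {"maxent", "LR"}
        "maxent" fits by infinitely weighted logistic regression on
        presence-background data (background rows coded as missing response);
        "LR" fits a standard logistic regression on 0/1 responses.
    bg_weight : float
        Weight given to background rows in the IWLR fit.  Any sufficiently
        large value yields the same slope estimates (the infinite-weight
        limit); 100 is comfortably inside that regime.
    tol, max_iter : IRLS stopping rule (max-norm of the score).

    Attributes (after ``fit``)
    --------------------------
    dv_names_ : list of str            design-column names
    beta_ : ndarray                    one coefficient per DV
    alpha_ : float                     maxent normalizer (maxent only)
    intercept_ : float                 LR intercept (LR only)
    n_background_ : int                N of the PRO formula (maxent only)
    deviance_, null_deviance_, dsq_ :  weighted-binomial deviance bookkeeping
    """

    def __init__(self, algorithm="maxent", bg_weight=100.0, tol=1e-8, max_iter=100):
        self.algorithm = algorithm
        self.bg_weight = bg_weight
        self.tol = tol
        self.max_iter = max_iter

    # ------------------------------------------------------------------
    def _design(self, X):
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), list(X.columns)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X, [f"dv{i}" for i in range(X.shape[1])]

    def fit(self, X, y):
        """Fit on a DV design ``X`` and response ``y``.

        ``y`` uses 1 for presence, 0 for absence and NaN for uninformed
        background.  For ``algorithm="maxent"`` presences are appended to the
        background before fitting, per the rationale that the background
        should represent all conditions in the study area.
        """
        Xd, names = self._design(X)
        y = np.asarray(y, dtype=float)
        if Xd.shape[0] != y.shape[0]:
            raise FittingError("X and y have different lengths")
        pres = y == 1.0
        n_pres = int(pres.sum())
        if n_pres < 1:
            raise FittingError("at least one presence row is required")

        if self.algorithm == "maxent":
            bg = is_background(y) | (y == 0.0)
            Xf = np.vstack([Xd[pres], Xd[bg], Xd[pres]])
            yf = np.concatenate([np.ones(n_pres), np.zeros(int(bg.sum()) + n_pres)])
            wf = np.concatenate([np.ones(n_pres), np.full(int(bg.sum()) + n_pres, float(self.bg_weight))])
            self.n_background_ = int(bg.sum()) + n_pres
            bg_design = np.vstack([Xd[bg], Xd[pres]])
        elif self.algorithm == "LR":
            if not np.all(np.isin(y, [0.0, 1.0])):
                raise FittingError("LR requires a 0/1 response (no background rows)")
            Xf, yf, wf = Xd, y, np.ones_like(y)
            self.n_background_ = None
            bg_design = None
        else:
            raise FittingError(f"unknown algorithm {self.algorithm!r}")

        design = np.hstack([np.ones((Xf.shape[0], 1)), Xf])
        coef, ll, converged, gnorm = _weighted_logistic_irls(
            design, yf, wf, tol=self.tol, max_iter=self.max_iter
        )
        if not converged:
            warnings.warn(
                f"IRLS did not reach gradient tolerance {self.tol:g} in "
                f"{self.max_iter} iterations (|grad|={gnorm:.3g}); possible separation",
                RuntimeWarning,
            )
        coef0, _, _, _ = _weighted_logistic_irls(
            np.ones((Xf.shape[0], 1)), yf, wf, tol=self.tol, max_iter=self.max_iter
        )
        self.deviance_ = _binomial_deviance(design, yf, wf, coef)
        self.null_deviance_ = _binomial_deviance(np.ones((Xf.shape[0], 1)), yf, wf, coef0)
        if self.null_deviance_ <= 0:
            raise FittingError("null deviance is zero; D-squared undefined")
        self.dsq_ = max(0.0, 1.0 - self.deviance_ / self.null_deviance_)
        self.dv_names_ = names
        self.beta_ = coef[1:]
        self.converged_ = converged
        if self.algorithm == "maxent":
            # alpha is a normalizing constant, not a free parameter: discard
            # the fitted intercept and renormalize over the background.
            self.intercept_ = None
            lin = bg_design @ self.beta_ if self.beta_.size else np.zeros(bg_design.shape[0])
            m = float(np.max(lin)) if lin.size else 0.0
            self.alpha_ = -(m + float(np.log(np.sum(np.exp(lin - m)))))
        else:
            self.intercept_ = float(coef[0])
            self.alpha_ = None
        return self

    # ------------------------------------------------------------------
    @property
    def m_(self) -> int:
        """Number of DVs in the model."""
        return len(self.beta_)

    def decision_function(self, X):
        Xd, _ = self._design(X)
        if Xd.shape[1] != self.m_:
            raise FittingError(
                f"design has {Xd.shape[1]} columns, model expects {self.m_}"
            )
        return Xd @ self.beta_

    def predict(self, X):
        """PRO values (maxent; range (0, inf)) or probabilities (LR)."""
        lin = self.decision_function(X)
        if self.algorithm == "maxent":
            return self.n_background_ * np.exp(self.alpha_ + lin)
        return expit(self.intercept_ + lin)

    # ------------------------------------------------------------------
    def to_dict(self):
        d = {
            "algorithm": self.algorithm,
            "bg_weight": self.bg_weight,
            "dv_names": list(self.dv_names_),
            "beta": [float(b) for b in self.beta_],
            "alpha": self.alpha_,
            "intercept": self.intercept_,
            "N": self.n_background_,
            "deviance": self.deviance_,
            "null_deviance": self.null_deviance_,
            "Dsq": self.dsq_,
        }
        return d

    @classmethod
    def from_dict(cls, d):
        model = cls(algorithm=d["algorithm"], bg_weight=d.get("bg_weight", 100.0))
        model.dv_names_ = list(d["dv_names"])
        model.beta_ = np.asarray(d["beta"], dtype=float)
        model.alpha_ = d["alpha"]
        model.intercept_ = d["intercept"]
        model.n_background_ = d["N"]
        model.deviance_ = d["deviance"]
        model.null_deviance_ = d["null_deviance"]
        model.dsq_ = d["Dsq"]
        model.converged_ = True
        return model

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
        return path

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ----------------------------------------------------------------------
# thin functional wrappers


def fit_model(dv_matrix, rv, algorithm="maxent", bg_weight=100.0, **kw) -> MaxentModel:
    """Fit a maximum-entropy (IWLR) or logistic-regression model."""
    return MaxentModel(algorithm=algorithm, bg_weight=bg_weight, **kw).fit(dv_matrix, rv)


def deviance_stats(model: MaxentModel):
    """(deviance, null_deviance, Dsq) of a fitted model."""
    return model.deviance_, model.null_deviance_, model.dsq_


def predict_pro(model: MaxentModel, dv_rows):
    """Probability-ratio output (maxent) or probabilities (LR) for DV rows."""
    return model.predict(dv_rows)
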