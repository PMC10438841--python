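"""Penalized-spline additive model for the natural log of annual nitrogen load.

The response model is

    ln Q_TN = beta_0 + sum_j f_j(x_j) + eps,     eps ~ N(0, sigma^2)

where each f_j is either a linear term or a penalized cubic B-spline smooth.
Because the Gaussian model lives on the log scale, Q_TN is conditionally
lognormal and ``exp(linear predictor)`` is the *median* (not the mean) of the
predictive distribution; all back-transformed predictions here are medians.

Smooths use quantile-spaced knots, a second-order difference penalty, a
sum-to-zero constraint for identifiability, and smoothing parameters chosen
by generalized cross-validation (GCV).  Model complexity is measured by the
effective degrees of freedom (EDF), the trace of the influence matrix, and
model comparison uses BIC with the residual-variance scale parameter counted
in the penalty.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import null_space
from scipy.optimize import minimize, minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "TermSpec",
    "LoadGAM",
    "fit_loading_model",
    "gaussian_bic",
    "load_model",
]

#: percentile levels stored with every fitted model (used for covariate pinning)
_PCTL_LEVELS = (1, 2.5, 5, 10, 25, 50, 75, 90, 95, 97.5, 99)


@dataclass(frozen=True)
class TermSpec:
    """One additive term: a covariate and how it enters the linear predictor.

    Parameters
    ----------
    name : str
        Covariate (column) name.
    kind : {"smooth", "linear"}
        Penalized cubic B-spline smooth or an unpenalized straight line.
    basis_size : int
        Number of B-spline basis functions before the identifiability
        constraint (>= 4 for smooths; ignored for linear terms).
    penalty_order : int
        Order of the difference penalty on spline coefficients (2 penalizes
        curvature, leaving straight lines unpenalized).
    """

    name: str
    kind: str = "smooth"
    basis_size: int = 10
    penalty_order: int = 2

    def __post_init__(self) -> None:
        if self.kind not in ("smooth", "linear"):
            raise ValueError(f"unknown term kind {self.kind!r}")
        if self.kind == "smooth" and self.basis_size < 4:
            raise ValueError("smooth terms need basis_size >= 4")


def _quantile_knots(x: np.ndarray, basis_size: int) -> np.ndarray:
    """Cubic B-spline knot vector with interior knots at quantiles of x."""
    n_interior = basis_size - 4
    probs = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
    lo, hi = float(np.min(x)), float(np.max(x))
    interior = np.quantile(x, probs) if n_interior > 0 else np.array([])
    # strictly increasing interior knots; collapse duplicates from ties
    interior = np.unique(np.clip(interior, lo, hi))
    interior = interior[(interior > lo) & (interior < hi)]
    return np.concatenate([[lo] * 4, interior, [hi] * 4])


class _SmoothBasis:
    """Evaluates a cubic B-spline basis with linear extrapolation outside
    the training range (value + first derivative at the boundary), so that
    predictions beyond support degrade gracefully instead of exploding."""

    def __init__(self, knots: np.ndarray):
        self.knots = np.asarray(knots, dtype=float)
        self.size = len(self.knots) - 4
        self._spl = BSpline(self.knots, np.eye(self.size), 3)
        self._dspl = self._spl.derivative()
        self.lo = self.knots[3]
        self.hi = self.knots[-4]

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        xi = np.clip(x, self.lo, self.hi)
        B = self._spl(xi)
        below = x < self.lo
        above = x > self.hi
        if np.any(below):
            B[below] += np.outer(x[below] - self.lo, self._dspl(self.lo))
        if np.any(above):
            B[above] += np.outer(x[above] - self.hi, self._dspl(self.hi))
        return B

    def deriv(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        xi = np.clip(x, self.lo, self.hi)
        return self._dspl(xi)


@dataclass
class _TermBlock:
    """Internal per-term design metadata: column slice plus basis machinery."""

    spec: TermSpec
    sl: slice
    basis: _SmoothBasis | None = None
    constraint: np.ndarray | None = None  # (basis_size, basis_size-1) null-space map
    penalty: np.ndarray | None = None  # constrained penalty block
    center: float = 0.0  # column centering offset for linear terms


def _greville(knots: np.ndarray) -> np.ndarray:
    """Greville abscissae of a cubic B-spline basis (coefficient sites)."""
    k = len(knots) - 4
    return np.array([knots[i + 1 : i + 4].mean() for i in range(k)])


def _difference_penalty(knots: np.ndarray, order: int) -> np.ndarray:
    """Divided-difference penalty on spline coefficients.

    Differences are taken with respect to the Greville sites so that, for
    order 2, the null space is exactly the coefficient vectors representing
    straight lines in x — the lambda -> infinity limit of a penalized smooth
    is then a linear fit even with non-uniform (quantile) knots.
    """
    g = _greville(knots)
    D = np.eye(len(g))
    for _ in range(order):
        D = np.diff(D, axis=0) / np.diff(g)[:, None]
        g = 0.5 * (g[1:] + g[:-1])
    return D.T @ D


class LoadGAM(BaseEstimator, RegressorMixin):
    """Gaussian additive model on ln(load) with penalized B-spline smooths.

    Parameters
    ----------
    terms : sequence of TermSpec
        Additive terms; covariate names must match columns of the design
        frame passed to :meth:`fit`.
    lam : float, sequence of float, or None
        Fixed smoothing parameter(s), one per smooth term.  ``None``
        (default) selects them by minimizing GCV.

    Attributes
    ----------
    coef_ : ndarray
        Coefficients (intercept first).
    lambda_ : dict
        Smoothing parameter per smooth term.
    edf_ : float
        Total effective degrees of freedom (trace of the influence matrix).
    term_edf_ : dict
        Per-term EDF.
    sigma2_ : float
        Residual variance of ln(load), RSS/n.
    bic_ : float
        Bayesian Information Criterion (see :func:`gaussian_bic`).
    percentiles_ : DataFrame
        Training covariate percentiles (levels x covariates).
    """

    def __init__(self, terms=(), lam=None):
        self.terms = terms
        self.lam = lam

    # ------------------------------------------------------------------ design

    def _build_blocks(self, X: pd.DataFrame) -> list[_TermBlock]:
        blocks: list[_TermBlock] = []
        col = 1  # column 0 is the intercept
        for spec in self.terms:
            x = X[spec.name].to_numpy(dtype=float)
            kind = spec.kind
            if kind == "smooth" and np.unique(x).size <= spec.basis_size:
                warnings.warn(
                    f"smooth term {spec.name!r} has too few distinct values; "
                    "degrading to linear",
                    UserWarning,
                )
                kind = "linear"
            if kind == "linear":
                blocks.append(
                    _TermBlock(
                        spec=TermSpec(spec.name, "linear", 1, spec.penalty_order),
                        sl=slice(col, col + 1),
                        center=float(np.mean(x)),
                    )
                )
                col += 1
            else:
                knots = _quantile_knots(x, spec.basis_size)
                basis = _SmoothBasis(knots)
                B = basis(x)
                # sum-to-zero constraint: coefficients restricted to the null
                # space of the column-sum functional, removing the constant
                # direction so the intercept stays identifiable
                Z = null_space(B.sum(axis=0)[None, :])
                S = Z.T @ _difference_penalty(knots, spec.penalty_order) @ Z
                ncol = Z.shape[1]
                blocks.append(
                    _TermBlock(
                        spec=spec,
                        sl=slice(col, col + ncol),
                        basis=basis,
                        constraint=Z,
                        penalty=S,
                    )
                )
                col += ncol
        self._ncol = col
        return blocks

    def _design(self, X: pd.DataFrame) -> np.ndarray:
        n = len(X)
        M = np.empty((n, self._ncol))
        M[:, 0] = 1.0
        for b in self._blocks:
            x = X[b.spec.name].to_numpy(dtype=float)
            if b.basis is None:
                M[:, b.sl] = (x - b.center)[:, None]
            else:
                M[:, b.sl] = b.basis(x) @ b.constraint
        return M

    # -------------------------------------------------------------------- fit

    def fit(self, X: pd.DataFrame, y):
        """Fit to covariates ``X`` and strictly positive loads ``y`` (kg N/yr).

        The response is modeled on the natural-log scale; ``y`` is the raw
        load, logged internally.
        """
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        if y.shape[0] != len(X):
            raise ValueError("X and y lengths differ")
        if np.any(~np.isfinite(y)) or np.any(y <= 0):
            raise ValueError("loads must be finite and strictly positive (log link)")
        missing = [t.name for t in self.terms if t.name not in X.columns]
        if missing:
            raise KeyError(f"missing covariate columns: {missing}")

        self._blocks = self._build_blocks(X)
        M = self._design(X)
        n, p = M.shape
        if n <= p:
            raise ValueError(f"need n > total basis dimension ({n} <= {p})")
        z = np.log(y)

        G = M.T @ M
        g = M.T @ z
        zz = float(z @ z)
        smooth_blocks = [b for b in self._blocks if b.penalty is not None]

        def penalized(lams: np.ndarray):
            A = G.copy()
            for lam, b in zip(lams, smooth_blocks):
                A[b.sl, b.sl] += lam * b.penalty
            Ainv = np.linalg.solve(A, np.eye(p))
            beta = Ainv @ g
            edf = float(np.sum(Ainv * G.T))  # trace(A^{-1} G)
            rss = max(zz - 2.0 * beta @ g + beta @ (G @ beta), 0.0)
            return beta, edf, rss, Ainv

        if smooth_blocks:
            if self.lam is not None:
                lams = np.broadcast_to(
                    np.atleast_1d(np.asarray(self.lam, dtype=float)),
                    (len(smooth_blocks),),
                ).copy()
            else:
                lams = self._select_lambda(penalized, n, len(smooth_blocks))
        else:
            lams = np.array([])

        beta, edf, rss, Ainv = penalized(lams)
        self.coef_ = beta
        self.lambda_ = {
            b.spec.name: float(lam) for lam, b in zip(lams, smooth_blocks)
        }
        self.edf_ = edf
        H_diag_term = {}
        T = Ainv @ G  # influence-matrix trace decomposition by coefficient
        for b in self._blocks:
            H_diag_term[b.spec.name] = float(np.trace(T[b.sl, b.sl]))
        self.term_edf_ = H_diag_term
        self.n_ = n
        self.rss_ = rss
        self.sigma2_ = rss / n
        self.bic_ = gaussian_bic(n, rss, edf)
        self.percentiles_ = pd.DataFrame(
            {
                t.name: np.percentile(X[t.name].to_numpy(dtype=float), _PCTL_LEVELS)
                for t in self.terms
            },
            index=list(_PCTL_LEVELS),
        )
        self.support_ = {
            t.name: (
                float(X[t.name].min()),
                float(X[t.name].max()),
            )
            for t in self.terms
        }
        return self

    @staticmethod
    def _select_lambda(penalized, n: int, k: int) -> np.ndarray:
        def gcv(loglams):
            _, edf, rss, _ = penalized(10.0 ** np.asarray(loglams, dtype=float))
            denom = max(n - edf, 1e-8)
            return n * rss / denom**2

        if k == 1:
            res = minimize_scalar(
                lambda u: gcv([u]), bounds=(-6.0, 9.0), method="bounded",
                options={"xatol": 1e-4},
            )
            return np.array([10.0**res.x])
        res = minimize(
            gcv, x0=np.zeros(k), method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-8, "maxiter": 400},
        )
        return 10.0 ** res.x

    # ---------------------------------------------------------------- predict

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        """Fitted ln(median load) at the supplied covariates."""
        self._check_fitted()
        return self._design(pd.DataFrame(X)) @ self.coef_

    def predict_median(self, X: pd.DataFrame) -> np.ndarray:
        """Median load prediction, exp(linear predictor); strictly positive.

        Points outside the training support are evaluated by linear
        extrapolation of the smooths and raise an extrapolation warning.
        """
        X = pd.DataFrame(X)
        flags = self.extrapolation_flags(X)
        if flags.any():
            warnings.warn(
                f"{int(flags.sum())} evaluation point(s) outside training support",
                UserWarning,
            )
        return np.exp(self.linear_predictor(X))

    def predict(self, X: pd.DataFrame) -> np.ndarray:  # sklearn surface
        return self.predict_median(X)

    def extrapolation_flags(self, X: pd.DataFrame) -> np.ndarray:
        """Boolean mask of rows with any covariate outside training support."""
        self._check_fitted()
        X = pd.DataFrame(X)
        flags = np.zeros(len(X), dtype=bool)
        for t in self.terms:
            lo, hi = self.support_[t.name]
            x = X[t.name].to_numpy(dtype=float)
            flags |= (x < lo) | (x > hi)
        return flags

    def partial_effect(self, name: str, x: np.ndarray) -> np.ndarray:
        """Contribution of one term to the linear predictor (centered)."""
        self._check_fitted()
        for b in self._blocks:
            if b.spec.name == name:
                x = np.asarray(x, dtype=float)
                if b.basis is None:
                    return (x - b.center) * self.coef_[b.sl][0]
                return b.basis(x) @ b.constraint @ self.coef_[b.sl]
        raise KeyError(name)

    def partial_derivative(self, name: str, x: np.ndarray) -> np.ndarray:
        """Analytic d(linear predictor)/dx for one term (B-spline derivative)."""
        self._check_fitted()
        for b in self._blocks:
            if b.spec.name == name:
                x = np.asarray(x, dtype=float)
                if b.basis is None:
                    return np.full(x.shape, self.coef_[b.sl][0])
                return b.basis.deriv(x) @ b.constraint @ self.coef_[b.sl]
        raise KeyError(name)

    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted")

    # ---------------------------------------------------------- serialization

    def to_dict(self) -> dict:
        self._check_fitted()
        blocks = []
        for b in self._blocks:
            blocks.append(
                {
                    "name": b.spec.name,
                    "kind": b.spec.kind,
                    "basis_size": b.spec.basis_size,
                    "penalty_order": b.spec.penalty_order,
                    "knots": None if b.basis is None else b.basis.knots.tolist(),
                    "constraint": None
                    if b.constraint is None
                    else b.constraint.tolist(),
                    "center": b.center,
                }
            )
        return {
            "format": "nitroclim-loadgam-v1",
            "blocks": blocks,
            "coef": self.coef_.tolist(),
            "lambda": self.lambda_,
            "edf": self.edf_,
            "term_edf": self.term_edf_,
            "n": self.n_,
            "rss": self.rss_,
            "sigma2": self.sigma2_,
            "bic": self.bic_,
            "percentile_levels": list(self.percentiles_.index),
            "percentiles": {
                c: self.percentiles_[c].tolist() for c in self.percentiles_.columns
            },
            "support": self.support_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LoadGAM":
        terms = [
            TermSpec(b["name"], b["kind"], b["basis_size"], b["penalty_order"])
            for b in d["blocks"]
        ]
        m = cls(terms=terms)
        blocks = []
        col = 1
        for b in d["blocks"]:
            if b["knots"] is None:
                blocks.append(
                    _TermBlock(
                        spec=TermSpec(b["name"], "linear", 1, b["penalty_order"]),
                        sl=slice(col, col + 1),
                        center=b["center"],
                    )
                )
                col += 1
            else:
                basis = _SmoothBasis(np.asarray(b["knots"]))
                Z = np.asarray(b["constraint"])
                S = Z.T @ _difference_penalty(basis.knots, b["penalty_order"]) @ Z
                blocks.append(
                    _TermBlock(
                        spec=TermSpec(
                            b["name"], "smooth", b["basis_size"], b["penalty_order"]
                        ),
                        sl=slice(col, col + Z.shape[1]),
                        basis=basis,
                        constraint=Z,
                        penalty=S,
                    )
                )
                col += Z.shape[1]
        m._blocks = blocks
        m._ncol = col
        m.coef_ = np.asarray(d["coef"])
        m.lambda_ = dict(d["lambda"])
        m.edf_ = d["edf"]
        m.term_edf_ = dict(d["term_edf"])
        m.n_ = d["n"]
        m.rss_ = d["rss"]
        m.sigma2_ = d["sigma2"]
        m.bic_ = d["bic"]
        m.percentiles_ = pd.DataFrame(
            {c: v for c, v in d["percentiles"].items()},
            index=d["percentile_levels"],
        )
        m.support_ = {k: tuple(v) for k, v in d["support"].items()}
        return m

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def median_covariates(self) -> dict[str, float]:
        """Training medians of every covariate, for pinning."""
        self._check_fitted()
        return {c: float(self.percentiles_.loc[50, c]) for c in self.percentiles_}


def load_model(path) -> LoadGAM:
    with open(path) as fh:
        return LoadGAM.from_dict(json.load(fh))


def gaussian_bic(n: int, rss: float, edf: float) -> float:
    """BIC for the Gaussian log-scale model with sigma^2 profiled out.

    BIC = -2 max log-likelihood + ln(n) * (edf + 1); the +1 counts the
    residual-variance scale parameter alongside the effective degrees of
    freedom of the mean structure.
    """
    sigma2 = max(rss / n, 1e-300)
    neg2ll = n * np.log(2.0 * np.pi * sigma2) + n
    return float(neg2ll + np.log(n) * (edf + 1.0))


def fit_loading_model(
    records: pd.DataFrame, terms, load_col: str = "Q_TN", lam=None
) -> LoadGAM:
    """Fit a :class:`LoadGAM` from a catchment-year table.

    ``records`` must contain ``load_col`` plus every covariate named by
    ``terms``.
    """
    model = LoadGAM(terms=list(terms), lam=lam)
    return model.fit(records, records[load_col].to_numpy(dtype=float))
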