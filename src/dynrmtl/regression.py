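"""Dynamic- and static-effect RMTL regression estimators.

The model links the restricted mean time lost (RMTL) due to the event of
interest during an ``l``-year follow-up to covariates through an identity
link,

    mu_1(l | Z) = E[(l - T(l)) I(eps(l) = 1) | Z] = Z*(l) beta,

where each covariate's effect is a quadratic in the horizon,
``beta_k(l) = beta_k0 + beta_k1 l + beta_k2 l^2``, so the expanded design
``Z*(l)`` carries the products ``z_k``, ``z_k l``, ``z_k l^2`` for the
active terms.  Coefficients solve the IPCW estimating equation summed over
subjects and horizons of the stacked dataset; with the identity link this
is a single weighted least-squares solve.  The covariance is the robust
sandwich ``A^-1 B A^-1`` with the J per-horizon score contributions of each
subject clustered at the subject level, the weights treated as fixed.

``beta_k(l)`` is the *cumulative* between-group difference in life lost up
to ``l`` (negative = protective); its slope ``dbeta_k/dl`` is the
*real-time* effect — the speed at which the difference accumulates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator

from .restriction import StackedDataset, TimeGrid, build_stacked_dataset, select_time_grid

__all__ = [
    "TimeBasis",
    "DynamicRMTLRegression",
    "StaticRMTLRegression",
    "SingularFitError",
    "ExtrapolationWarning",
    "fit_dynamic_rmtl",
    "fit_static_rmtl",
    "expand_design",
]

_TERM_LABELS = ("1", "l", "l^2", "l^3")


class SingularFitError(np.linalg.LinAlgError):
    """Raised when the expanded design is rank deficient."""


class ExtrapolationWarning(UserWarning):
    """Horizon outside the fitted grid range: quadratic extrapolation."""


@dataclass
class TimeBasis:
    """Active-term mask over the polynomial time basis (1, l, l^2, ...).

    Row 0 is the intercept; rows 1..p follow the covariate order.  The
    intercept's constant term is always active.
    """

    mask: np.ndarray  # bool, (p + 1, degree + 1)

    @classmethod
    def full(cls, n_covariates: int, degree: int = 2) -> "TimeBasis":
        return cls(np.ones((n_covariates + 1, degree + 1), dtype=bool))

    @property
    def degree(self) -> int:
        return self.mask.shape[1] - 1

    def active_terms(self):
        """(covariate index, power) pairs in covariate-major order."""
        return [(k, d) for k in range(self.mask.shape[0])
                for d in range(self.mask.shape[1]) if self.mask[k, d]]

    def drop(self, k: int, d: int) -> "TimeBasis":
        m = self.mask.copy()
        m[k, d] = False
        return TimeBasis(m)

    def validate(self) -> None:
        if not self.mask[0].any():
            raise ValueError("intercept must keep at least its constant term")


def expand_design(X1: np.ndarray, l, basis: TimeBasis) -> np.ndarray:
    """Expanded design rows ``z_k l^d`` for the active (k, d) terms.

    ``X1`` includes the leading intercept column; ``l`` is a scalar or a
    per-row vector.  Columns are covariate-major, increasing power.
    """
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    if X1.shape[1] != basis.mask.shape[0]:
        raise ValueError(
            f"design has {X1.shape[1]} columns but basis mask expects "
            f"{basis.mask.shape[0]}")
    l = np.broadcast_to(np.asarray(l, dtype=float), (X1.shape[0],))
    pows = np.vander(l, basis.degree + 1, increasing=True)  # 1, l, l^2, ...
    cols = [X1[:, k] * pows[:, d] for k, d in basis.active_terms()]
    return np.column_stack(cols)


def _parse_survival_y(y):
    """Accept (n, 2) arrays, or DataFrames/record arrays with time+status."""
    if isinstance(y, pd.DataFrame):
        missing = {"time", "status"} - set(y.columns)
        if missing:
            raise ValueError(f"y is missing columns {sorted(missing)}")
        return y["time"].to_numpy(float), y["status"].to_numpy()
    y = np.asarray(y)
    if y.dtype.names:
        return y["time"].astype(float), y["status"]
    if y.ndim != 2 or y.shape[1] != 2:
        raise ValueError("y must be (n, 2) [time, status] or a DataFrame")
    return y[:, 0].astype(float), y[:, 1].astype(np.int64)


class DynamicRMTLRegression(BaseEstimator):
    """IPCW regression for dynamic covariate effects on the RMTL scale.

    Parameters
    ----------
    horizons : array-like, optional
        Explicit horizon grid.  Default: ``n_horizons`` points equally
        spaced between the 10th and 95th percentile of observed
        event-of-interest times (capped at ``tau`` when given).
    n_horizons : int, default 30
        Grid size J when ``horizons`` is not given.  ``n_horizons=1`` with
        ``degree=0`` reduces to the static model.
    tau : float, optional
        Maximum restriction time (years).
    degree : int, default 2
        Polynomial degree of the time basis for every covariate.
    stepwise : bool, default False
        Backward elimination of individual expanded terms by Wald p-value.
    alpha : float, default 0.05
        Removal threshold for ``stepwise``.

    Attributes
    ----------
    coef_ : ndarray of active expanded coefficients (covariate-major).
    coef_matrix_ : (p + 1, degree + 1) matrix, zeros at inactive terms.
    covariance_ : sandwich covariance of ``coef_``.
    basis_ : fitted :class:`TimeBasis`.
    grid_ : fitted :class:`~dynrmtl.restriction.TimeGrid`.
    """

    def __init__(self, horizons=None, n_horizons: int = 30,
                 tau: float | None = None, degree: int = 2,
                 stepwise: bool = False, alpha: float = 0.05):
        self.horizons = horizons
        self.n_horizons = n_horizons
        self.tau = tau
        self.degree = degree
        self.stepwise = stepwise
        self.alpha = alpha

    # ------------------------------------------------------------------ fit

    def fit(self, X, y):
        X, names = self._validate_X(X, reset=True)
        time, status = _parse_survival_y(y)
        if time.shape[0] != X.shape[0]:
            raise ValueError("X and y have different numbers of subjects")
        if self.horizons is not None:
            h = np.asarray(self.horizons, dtype=float)
            grid = TimeGrid(h, self.tau if self.tau is not None else float(h[-1]))
        else:
            grid = select_time_grid(time, status, self.n_horizons, self.tau)
        stacked = build_stacked_dataset(time, status, X, grid,
                                        feature_names=names)
        return self._fit_stacked(stacked)

    def fit_stacked(self, stacked: StackedDataset):
        """Fit directly on a pre-built stacked dataset."""
        self._validate_X(stacked.covariates, reset=True,
                         names=stacked.feature_names)
        return self._fit_stacked(stacked)

    def _fit_stacked(self, stacked: StackedDataset):
        basis = TimeBasis.full(stacked.covariates.shape[1], self.degree)
        beta, V = self._solve(stacked, basis)
        if self.stepwise:
            basis, beta, V = self._backward_stepwise(stacked, basis, beta, V)
        self.basis_ = basis
        self.coef_ = beta
        self.covariance_ = V
        mat = np.zeros_like(basis.mask, dtype=float)
        for b, (k, d) in zip(beta, basis.active_terms()):
            mat[k, d] = b
        self.coef_matrix_ = mat
        self.grid_ = stacked.grid
        self.n_subjects_ = stacked.n_subjects
        self.n_dropped_rows_ = stacked.n_dropped
        return self

    def _solve(self, stacked: StackedDataset, basis: TimeBasis):
        basis.validate()
        X1 = np.column_stack([np.ones(stacked.n_subjects),
                              stacked.covariates])
        rows = X1[stacked.subject]
        Xe = expand_design(rows, stacked.horizon, basis)
        w = stacked.weight
        y = stacked.lost_time
        sw = np.sqrt(w)
        Xw = Xe * sw[:, None]
        yw = y * sw
        q = Xe.shape[1]
        beta, _, rank, sv = np.linalg.lstsq(Xw, yw, rcond=None)
        if rank < q:
            bad = self._collinear_columns(Xw, basis)
            raise SingularFitError(
                f"rank-deficient expanded design (rank {rank} < {q}); "
                f"collinear columns: {bad}")
        V = self._sandwich(stacked, Xe, beta)
        return beta, V

    def _collinear_columns(self, Xw, basis):
        names = self._term_names(basis)
        _, _, piv = linalg.qr(Xw, mode="economic", pivoting=True)
        rank = np.linalg.matrix_rank(Xw)
        return [names[j] for j in sorted(piv[rank:])]

    def _sandwich(self, stacked: StackedDataset, Xe: np.ndarray,
                  beta: np.ndarray) -> np.ndarray:
        w = stacked.weight
        resid = stacked.lost_time - Xe @ beta
        A = Xe.T @ (Xe * w[:, None])
        score = Xe * (w * resid)[:, None]           # per-row psi contribution
        q = Xe.shape[1]
        S = np.zeros((stacked.n_subjects, q))
        np.add.at(S, stacked.subject, score)        # cluster the J blocks
        B = S.T @ S
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise SingularFitError("bread matrix A is singular") from exc
        V = Ainv @ B @ Ainv
        return (V + V.T) / 2.0

    def _backward_stepwise(self, stacked, basis, beta, V):
        while True:
            se = np.sqrt(np.diag(V))
            with np.errstate(divide="ignore", invalid="ignore"):
                p = 2 * stats.norm.sf(np.abs(beta) / se)
            removable = [i for i, (k, d) in enumerate(basis.active_terms())
                         if not (k == 0 and d == 0)]
            if not removable:
                break
            worst = max(removable, key=lambda i: p[i])
            if not np.isfinite(p[worst]) or p[worst] <= self.alpha:
                break
            k, d = basis.active_terms()[worst]
            basis = basis.drop(k, d)
            if not basis.mask.any():
                raise SingularFitError("stepwise removed every term")
            beta, V = self._solve(stacked, basis)
        return basis, beta, V

    # ------------------------------------------------------------ inference

    def _term_names(self, basis: TimeBasis | None = None):
        basis = basis if basis is not None else self.basis_
        names = ["Intercept"] + list(self.feature_names_in_)
        out = []
        for k, d in basis.active_terms():
            lbl = _TERM_LABELS[d]
            out.append(names[k] if d == 0 else f"{names[k]}:{lbl}")
        return out

    def wald_table(self) -> pd.DataFrame:
        """Per-term estimates, robust SEs, z statistics and p-values."""
        self._check_fitted()
        se = np.sqrt(np.diag(self.covariance_))
        z = np.divide(self.coef_, se, out=np.zeros_like(self.coef_),
                      where=se > 0)
        p = 2 * stats.norm.sf(np.abs(z))
        names = ["Intercept"] + list(self.feature_names_in_)
        return pd.DataFrame({
            "variable": [names[k] for k, _ in self.basis_.active_terms()],
            "time_function": [_TERM_LABELS[d]
                              for _, d in self.basis_.active_terms()],
            "coefficient": self.coef_,
            "se": se,
            "z": z,
            "p": p,
        })

    def _covariate_index(self, covariate) -> int:
        names = ["Intercept"] + list(self.feature_names_in_)
        if isinstance(covariate, str):
            try:
                return names.index(covariate)
            except ValueError:
                raise KeyError(f"unknown covariate {covariate!r}; "
                               f"choose from {names}") from None
        return int(covariate)

    def _basis_vector(self, k: int, l: float) -> np.ndarray:
        """Active-coefficient loading vector b(l) for covariate k."""
        b = np.zeros(self.coef_.size)
        for i, (kk, d) in enumerate(self.basis_.active_terms()):
            if kk == k:
                b[i] = l ** d
        return b

    def _check_range(self, l) -> None:
        lo, hi = self.grid_.horizons[0], self.grid_.horizons[-1]
        l = np.atleast_1d(l)
        if np.any(l < lo - 1e-12) or np.any(l > hi + 1e-12):
            warnings.warn(
                f"horizon outside the fitted range [{lo:.4g}, {hi:.4g}]: "
                "quadratic extrapolation", ExtrapolationWarning, stacklevel=3)

    def coefficient_curve(self, covariate, l, level: float = 0.95):
        """Cumulative effect ``beta_k(l)`` with a delta-method pointwise CI.

        Returns ``(estimate, se, lower, upper)``; each is an array if ``l``
        is an array.
        """
        self._check_fitted()
        self._check_range(l)
        k = self._covariate_index(covariate)
        ls = np.atleast_1d(np.asarray(l, dtype=float))
        est = np.empty(ls.size)
        se = np.empty(ls.size)
        for i, li in enumerate(ls):
            b = self._basis_vector(k, li)
            est[i] = b @ self.coef_
            se[i] = np.sqrt(b @ self.covariance_ @ b)
        zq = stats.norm.ppf(0.5 + level / 2)
        lo, hi = est - zq * se, est + zq * se
        if np.isscalar(l) or np.ndim(l) == 0:
            return est[0], se[0], lo[0], hi[0]
        return est, se, lo, hi

    def realtime_effect(self, covariate, l):
        """Signed slope ``dbeta_k/dl`` — the speed of effect accumulation."""
        self._check_fitted()
        self._check_range(l)
        k = self._covariate_index(covariate)
        ls = np.asarray(l, dtype=float)
        row = self.coef_matrix_[k]
        out = np.zeros_like(ls, dtype=float)
        for d in range(1, row.size):
            out = out + d * row[d] * ls ** (d - 1)
        return out if out.ndim else float(out)

    # ----------------------------------------------------------- prediction

    def predict(self, X, l, truncate: bool = False):
        """Predicted RMTL ``mu_1(l | z)`` for each row of ``X``.

        ``l`` may be a scalar (returns shape (n,)) or a vector of horizons
        (returns shape (n, len(l))).  Predictions are reported as-is;
        ``truncate=True`` clips them to ``[0, l]``.
        """
        self._check_fitted()
        X, _ = self._validate_X(X, reset=False)
        self._check_range(l)
        X1 = np.column_stack([np.ones(X.shape[0]), X])
        ls = np.atleast_1d(np.asarray(l, dtype=float))
        out = np.empty((X.shape[0], ls.size))
        for i, li in enumerate(ls):
            out[:, i] = expand_design(X1, li, self.basis_) @ self.coef_
            if truncate:
                out[:, i] = np.clip(out[:, i], 0.0, li)
        if np.isscalar(l) or np.ndim(l) == 0:
            return out[:, 0]
        return out

    # -------------------------------------------------------------- helpers

    def _validate_X(self, X, reset: bool, names=None):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        if reset:
            self.n_features_in_ = X.shape[1]
            self.feature_names_in_ = (list(names) if names is not None
                                      else [f"z{k+1}" for k in range(X.shape[1])])
        else:
            if X.shape[1] != self.n_features_in_:
                raise ValueError(
                    f"X has {X.shape[1]} features; the model was fit with "
                    f"{self.n_features_in_}")
        return X, (list(names) if names is not None else None)

    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise AttributeError("this estimator is not fitted yet")


class StaticRMTLRegression(DynamicRMTLRegression):
    """Static (cumulative-only) RMTL regression at a single restriction time.

    Equivalent to the dynamic model with a one-point grid at ``tau`` and a
    constant-only time basis: each coefficient is the between-group
    difference in mean life lost over ``[0, tau]``.
    """

    def __init__(self, tau: float, stepwise: bool = False, alpha: float = 0.05):
        super().__init__(horizons=None, n_horizons=1, tau=tau, degree=0,
                         stepwise=stepwise, alpha=alpha)
        self.tau = tau

    def get_params(self, deep=True):
        return {"tau": self.tau, "stepwise": self.stepwise,
                "alpha": self.alpha}


def fit_dynamic_rmtl(time, status, covariates, **kwargs) -> DynamicRMTLRegression:
    """Functional wrapper: fit the dynamic model on arrays."""
    y = np.column_stack([np.asarray(time, dtype=float), np.asarray(status)])
    return DynamicRMTLRegression(**kwargs).fit(covariates, y)


def fit_static_rmtl(time, status, covariates, tau: float,
                    **kwargs) -> StaticRMTLRegression:
    """Functional wrapper: fit the static model at restriction time ``tau``."""
    y = np.column_stack([np.asarray(time, dtype=float), np.asarray(status)])
    return StaticRMTLRegression(tau=tau, **kwargs).fit(covariates, y)
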