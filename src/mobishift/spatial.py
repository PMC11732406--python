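"""Regression suite for mobility change: OLS, OLS + distance-to-CBD, spatial lag, spatial error.

Models (y = per-origin lambda_mob, X = z-scored predictors, W = row-
standardized spatial weights):

* ``ols``      y = a + X b + e
* ``ols_cbd``  same with standardized distance to the city centre added
* ``lag``      y = rho W y + a + X b + e            (spatial autoregressive lag)
* ``error``    y = a + X b + u,  u = lam W u + e    (spatial autoregressive error)

The spatial models are fitted by maximum likelihood through the concentrated
log-likelihood in the single spatial parameter; the Jacobian term
log det(I - r W) is computed from the spectrum of W.  W is built as a
k-nearest-neighbour graph on origin centroids, symmetrized by union and
row-standardized, so W = D^-1 A with A symmetric and the spectrum can be
obtained from the similar symmetric matrix D^-1/2 A D^-1/2 (real eigenvalues
in [-1, 1], computed once and cached).  Both spatial likelihoods reduce
exactly to the OLS likelihood at parameter 0.

Estimators follow the scikit-learn protocol (``fit(X, y)``, ``predict``,
``get_params``; fitted attributes carry a trailing underscore) and compose
with sklearn tooling; the module-level ``fit_*`` functions are thin wrappers.
Standard errors for the spatial models come from the observed information
(numerical Hessian of the full log-likelihood at the optimum).  AIC is
2k - 2 loglik with k counting intercept + slopes + error variance
(+ the spatial parameter where present), for every model alike.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.spatial import cKDTree
from scipy.stats import norm
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import CapabilityError, InputError
from .ingest import PartitionSet

_MAX_DENSE_SPECTRUM = 10_000


# ---------------------------------------------------------------------------
# design helpers

def standardize_predictors(table: pd.DataFrame, columns=None):
    """Z-score the given columns in-sample.

    Returns ``(z_table, means, sds)`` so raw-scale coefficients can be
    recovered as beta_raw = beta_z / sd.  Zero-variance columns are an error.
    """
    columns = list(columns) if columns is not None else list(table.columns)
    means = table[columns].mean()
    sds = table[columns].std(ddof=0)
    zero = sds[sds == 0].index.tolist()
    if zero:
        raise InputError(f"zero-variance predictor(s): {zero}")
    z = (table[columns] - means) / sds
    return z, means, sds


def distance_to_cbd(origins: PartitionSet, cbd) -> pd.Series:
    """Euclidean centroid-to-CBD distance (planar km), per origin."""
    cents = origins.centroids()
    return pd.Series(
        np.hypot(cents["x"] - cbd[0], cents["y"] - cbd[1]),
        index=cents.index,
        name="dist_cbd",
    )


# ---------------------------------------------------------------------------
# spatial weights

@dataclass
class SpatialWeights:
    """Row-standardized symmetrized k-NN weights over an ordered unit set."""

    ids: np.ndarray
    W: sp.csr_matrix
    k: int
    scheme: str = "knn_union_row_std"
    _adjacency: sp.csr_matrix | None = field(default=None, repr=False)
    _eigs: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.ids)

    def eigenvalues(self) -> np.ndarray:
        """Spectrum of W (real, in [-1, 1]); computed once, then cached."""
        if self._eigs is None:
            if self.n > _MAX_DENSE_SPECTRUM:
                raise CapabilityError(
                    f"dense spectrum limited to n <= {_MAX_DENSE_SPECTRUM}; got {self.n}"
                )
            A = self._adjacency
            if A is None:
                raise InputError("weights carry no adjacency matrix; rebuild with build_weights")
            d = np.asarray(A.sum(axis=1)).ravel()
            s = 1.0 / np.sqrt(d)
            M = (A.multiply(s[:, None]).multiply(s[None, :])).toarray()
            self._eigs = np.linalg.eigvalsh(M)
        return self._eigs

    def lag_of(self, v: np.ndarray) -> np.ndarray:
        return self.W @ v


def build_weights(origins, k: int = 8) -> SpatialWeights:
    """k-nearest-neighbour weights on centroids, union-symmetrized, row-standardized.

    ``origins`` is a PartitionSet or a frame/array of centroid coordinates
    indexed by unit id.  Distance ties are broken deterministically by id
    order; duplicate centroids resolve the same way with a logged warning.
    """
    if isinstance(origins, PartitionSet):
        cents = origins.centroids()
        ids = origins.ids
        xy = cents.to_numpy()
    else:
        df = pd.DataFrame(origins)
        ids = df.index.to_numpy()
        xy = df.to_numpy(dtype=float)
    n = len(ids)
    if n < k + 1:
        raise InputError(f"need at least k+1 = {k + 1} units, got {n}")
    order = np.argsort(ids.astype(str), kind="stable")  # id order for tie-breaking
    rank_of = np.empty(n, dtype=int)
    rank_of[order] = np.arange(n)

    tree = cKDTree(xy)
    extra = min(n - 1, k + 8)  # headroom so boundary ties can be re-broken by id
    dist, nbr = tree.query(xy, k=extra + 1)
    rows, cols = [], []
    dup_warned = False
    for i in range(n):
        cand = [(round(float(d), 9), rank_of[j], j) for d, j in zip(dist[i], nbr[i]) if j != i]
        if not dup_warned and any(c[0] == 0.0 for c in cand):
            warnings.warn("duplicate centroids: k-NN ties resolved by id order", stacklevel=2)
            dup_warned = True
        cand.sort()
        for _, _, j in cand[:k]:
            rows.append(i)
            cols.append(j)
    A = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    A = A.maximum(A.T)  # union symmetrization
    A.data[:] = 1.0
    deg = np.asarray(A.sum(axis=1)).ravel()
    W = sp.diags(1.0 / deg) @ A
    return SpatialWeights(ids=np.asarray(ids), W=W.tocsr(), k=k, _adjacency=A)


# ---------------------------------------------------------------------------
# results container

@dataclass
class RegressionResult:
    """Coefficients, inference and fit quality for one model."""

    model: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    loglik: float
    aic: float
    n: int
    k: int
    rho_lag: float | None = None
    lambda_err: float | None = None
    units_hash: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "model": self.model,
                "predictor": name,
                "coefficient": self.params[name],
                "se": self.bse[name],
                "p": self.pvalues[name],
            }
            for name in self.params.index
        ]
        df = pd.DataFrame(rows)
        df["rho_lag"] = np.nan if self.rho_lag is None else self.rho_lag
        df["lambda_err"] = np.nan if self.lambda_err is None else self.lambda_err
        df["loglik"] = self.loglik
        df["aic"] = self.aic
        df["n"] = self.n
        return df


def _as_design(X) -> tuple:
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        arr = X.to_numpy(dtype=float)
        units = tuple(X.index)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        names = [f"x{j}" for j in range(arr.shape[1])]
        units = tuple(range(arr.shape[0]))
    return arr, names, hash(units)


def _check_xy(Xa, y):
    y = np.asarray(y, dtype=float).ravel()
    n, p = Xa.shape
    if y.size != n:
        raise InputError(f"X has {n} rows but y has {y.size}")
    if n <= p + 1:
        raise InputError("need n > p + 1 observations")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), Xa])) < p + 1:
        raise InputError("rank-deficient design matrix")
    return y


def _numerical_hessian(f, x0: np.ndarray) -> np.ndarray:
    """Central-difference Hessian, steps scaled to parameter magnitude."""
    x0 = np.asarray(x0, dtype=float)
    m = x0.size
    h = 1e-4 * np.maximum(np.abs(x0), 1e-2)
    H = np.empty((m, m))
    f0 = f(x0)
    for i in range(m):
        ei = np.zeros(m)
        ei[i] = h[i]
        H[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h[i] ** 2
        for j in range(i + 1, m):
            ej = np.zeros(m)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def _wald(params: np.ndarray, cov: np.ndarray, names) -> tuple:
    se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, params / se, np.inf)
    p = 2 * norm.sf(np.abs(zstat))
    return pd.Series(se, index=names), pd.Series(p, index=names)


# ---------------------------------------------------------------------------
# estimators

class OLSRegression(BaseEstimator, RegressorMixin):
    """Ordinary least squares with Gaussian ML log-likelihood and AIC.

    Thin estimator facade over ``statsmodels`` OLS; AIC is recomputed with
    the error variance counted as a free parameter so it is comparable with
    the spatial models below.
    """

    def __init__(self, model_name: str = "ols"):
        self.model_name = model_name

    def fit(self, X, y):
        Xa, names, uhash = _as_design(X)
        y = _check_xy(Xa, y)
        res = sm.OLS(y, sm.add_constant(Xa)).fit()
        all_names = ["intercept"] + names
        k = len(all_names) + 1  # + sigma2
        self.coef_ = res.params[1:].copy()
        self.intercept_ = float(res.params[0])
        self.result_ = RegressionResult(
            model=self.model_name,
            params=pd.Series(res.params, index=all_names),
            bse=pd.Series(res.bse, index=all_names),
            pvalues=pd.Series(res.pvalues, index=all_names),
            loglik=float(res.llf),
            aic=2 * k - 2 * float(res.llf),
            n=int(res.nobs),
            k=k,
            units_hash=uhash,
        )
        return self

    def predict(self, X):
        Xa, _, _ = _as_design(X)
        return self.intercept_ + Xa @ self.coef_


class _SpatialMLBase(BaseEstimator, RegressorMixin):
    """Shared machinery for the lag and error models."""

    def __init__(self, weights: SpatialWeights | None = None):
        self.weights = weights

    def _prepare(self, X, y):
        if self.weights is None:
            raise InputError("spatial model requires a SpatialWeights instance")
        Xa, names, uhash = _as_design(X)
        y = _check_xy(Xa, y)
        if Xa.shape[0] != self.weights.n:
            raise InputError(
                f"weights cover {self.weights.n} units but design has {Xa.shape[0]} rows"
            )
        if isinstance(X, pd.DataFrame) and not np.array_equal(
            X.index.to_numpy(), self.weights.ids
        ):
            raise InputError("design row order does not match the weights' unit order")
        eigs = self.weights.eigenvalues()
        lo = 1.0 / eigs.min() if eigs.min() < 0 else -0.999999
        return Xa, names, uhash, y, eigs, (lo + 1e-8, 1.0 - 1e-8)

    def _optimize(self, negcll, bounds):
        res = minimize_scalar(negcll, bounds=bounds, method="bounded",
                              options={"xatol": 1e-9})
        if not res.success:
            raise InputError(f"spatial ML optimisation failed: {res.message}")
        return float(res.x)

    def predict(self, X):
        Xa, _, _ = _as_design(X)
        return self.intercept_ + Xa @ self.coef_


class SpatialLagRegression(_SpatialMLBase):
    """ML spatial lag model y = rho W y + a + X b + e.

    The likelihood is concentrated in rho: for fixed rho the coefficients
    are the OLS fit of (I - rho W) y on [1 X] and sigma^2 the mean squared
    residual, so the profile reduces to a 1-D search over
    (1/min-eigenvalue, 1) with the log-det taken from the cached spectrum.
    """

    def fit(self, X, y):
        Xa, names, uhash, y, eigs, bounds = self._prepare(X, y)
        n = y.size
        Z = np.column_stack([np.ones(n), Xa])
        Wy = self.weights.lag_of(y)
        # residual-maker applied once to y and Wy
        Q, _ = np.linalg.qr(Z)
        e0 = y - Q @ (Q.T @ y)
        ed = Wy - Q @ (Q.T @ Wy)
        e0e0, e0ed, eded = e0 @ e0, e0 @ ed, ed @ ed

        def concentrated_ll(rho):
            sse = e0e0 - 2 * rho * e0ed + rho * rho * eded
            with np.errstate(invalid="ignore"):
                logdet = np.log1p(-rho * eigs).sum()
            return -n / 2 * (np.log(2 * np.pi * sse / n) + 1) + logdet

        rho = self._optimize(lambda r: -concentrated_ll(r), bounds)
        beta = np.linalg.lstsq(Z, y - rho * Wy, rcond=None)[0]
        resid = y - rho * Wy - Z @ beta
        sigma2 = resid @ resid / n
        ll = float(concentrated_ll(rho))

        all_names = ["intercept"] + names
        WZcols = {"Wy": Wy}

        def negll(theta):
            b, r, s2 = theta[: len(all_names)], theta[-2], theta[-1]
            if s2 <= 0 or not (bounds[0] < r < bounds[1]):
                return np.inf
            u = y - r * WZcols["Wy"] - Z @ b
            return (
                n / 2 * np.log(2 * np.pi * s2)
                - np.log1p(-r * eigs).sum()
                + u @ u / (2 * s2)
            )

        theta = np.concatenate([beta, [rho, sigma2]])
        H = _numerical_hessian(negll, theta)
        cov = _safe_inverse(H)
        se_all, p_all = _wald(theta, cov, all_names + ["rho_lag", "sigma2"])

        k = len(all_names) + 2  # + rho + sigma2
        self.coef_ = beta[1:]
        self.intercept_ = float(beta[0])
        self.rho_ = rho
        self.sigma2_ = float(sigma2)
        self.loglik_ = ll
        self.result_ = RegressionResult(
            model="lag",
            params=pd.Series(np.append(beta, rho), index=all_names + ["rho_lag"]),
            bse=se_all[all_names + ["rho_lag"]],
            pvalues=p_all[all_names + ["rho_lag"]],
            loglik=ll,
            aic=2 * k - 2 * ll,
            n=n,
            k=k,
            rho_lag=rho,
            units_hash=uhash,
        )
        return self


class SpatialErrorRegression(_SpatialMLBase):
    """ML spatial error model y = a + X b + u, u = lam W u + e.

    Concentrated in lam: for fixed lam, beta is the OLS fit of the spatially
    filtered variables (I - lam W) y on (I - lam W) [1 X] (a GLS step) and
    sigma^2 the mean squared filtered residual.
    """

    def fit(self, X, y):
        Xa, names, uhash, y, eigs, bounds = self._prepare(X, y)
        n = y.size
        Z = np.column_stack([np.ones(n), Xa])
        Wy = self.weights.lag_of(y)
        WZ = np.column_stack([self.weights.lag_of(Z[:, j]) for j in range(Z.shape[1])])

        def gls(lam):
            ys = y - lam * Wy
            Zs = Z - lam * WZ
            beta, *_ = np.linalg.lstsq(Zs, ys, rcond=None)
            resid = ys - Zs @ beta
            return beta, resid @ resid / n

        def concentrated_ll(lam):
            _, sigma2 = gls(lam)
            logdet = np.log1p(-lam * eigs).sum()
            return -n / 2 * (np.log(2 * np.pi * sigma2) + 1) + logdet

        lam = self._optimize(lambda r: -concentrated_ll(r), bounds)
        beta, sigma2 = gls(lam)
        ll = float(concentrated_ll(lam))

        all_names = ["intercept"] + names

        def negll(theta):
            b, r, s2 = theta[: len(all_names)], theta[-2], theta[-1]
            if s2 <= 0 or not (bounds[0] < r < bounds[1]):
                return np.inf
            u = (y - r * Wy) - (Z - r * WZ) @ b
            return (
                n / 2 * np.log(2 * np.pi * s2)
                - np.log1p(-r * eigs).sum()
                + u @ u / (2 * s2)
            )

        theta = np.concatenate([beta, [lam, sigma2]])
        H = _numerical_hessian(negll, theta)
        cov = _safe_inverse(H)
        se_all, p_all = _wald(theta, cov, all_names + ["lambda_err", "sigma2"])

        k = len(all_names) + 2
        self.coef_ = beta[1:]
        self.intercept_ = float(beta[0])
        self.lambda_err_ = lam
        self.sigma2_ = float(sigma2)
        self.loglik_ = ll
        self.result_ = RegressionResult(
            model="error",
            params=pd.Series(np.append(beta, lam), index=all_names + ["lambda_err"]),
            bse=se_all[all_names + ["lambda_err"]],
            pvalues=p_all[all_names + ["lambda_err"]],
            loglik=ll,
            aic=2 * k - 2 * ll,
            n=n,
            k=k,
            lambda_err=lam,
            units_hash=uhash,
        )
        return self


def _safe_inverse(H: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


# ---------------------------------------------------------------------------
# functional wrappers and model comparison

def fit_ols(y, X, model_name: str = "ols") -> RegressionResult:
    return OLSRegression(model_name=model_name).fit(X, y).result_


def fit_spatial_lag(y, X, weights: SpatialWeights) -> RegressionResult:
    return SpatialLagRegression(weights=weights).fit(X, y).result_


def fit_spatial_error(y, X, weights: SpatialWeights) -> RegressionResult:
    return SpatialErrorRegression(weights=weights).fit(X, y).result_


def model_comparison(results) -> pd.DataFrame:
    """Log-likelihood / k / AIC / delta-AIC table over models fitted on identical units."""
    results = list(results)
    if not results:
        raise InputError("no results to compare")
    ns = {r.n for r in results}
    hashes = {r.units_hash for r in results}
    if len(ns) > 1 or len(hashes) > 1:
        raise InputError("models were not fitted on the identical unit set")
    df = pd.DataFrame(
        {
            "model": [r.model for r in results],
            "loglik": [r.loglik for r in results],
            "k": [r.k for r in results],
            "aic": [r.aic for r in results],
        }
    )
    df["delta_aic"] = df["aic"] - df["aic"].min()
    return df
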