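"""Multivariate autoregressive (MVAR) model fitting.

An MVAR(p) process models each source as a linear combination of the
p previous samples of all sources:

    x_t = A_1 x_{t-1} + ... + A_p x_{t-p} + e_t,  e_t ~ N(0, Sigma)

The fit is multichannel least squares; multi-trial data are handled by
stacking the per-trial lagged design matrices, so no regression row
crosses a trial boundary.  ``order="auto"`` selects the order that
minimizes an information criterion (BIC by default) over 1..max_order.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator

from .datasets import SourceSeries
from .simulate import companion_spectral_radius

__all__ = ["MVAR", "fit_mvar"]


def _as_trials(X) -> np.ndarray:
    """Coerce input to (n_trials, n_samples, n_sources)."""
    if isinstance(X, SourceSeries):
        d = X.data
        if d.ndim == 2:
            return d.T[None]  # sources x samples -> 1 trial
        return d.transpose(2, 1, 0)
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 2:
        return arr[None]
    if arr.ndim == 3:
        return arr
    raise ValueError("expected samples x sources or trials x samples x sources")


def _design(trials: np.ndarray, p: int):
    """Stacked lagged design. Returns (Z, Y): Z is (n_obs, n_sources*p)
    with lag-1 blocks first, Y is (n_obs, n_sources)."""
    n_trials, n_samp, n_src = trials.shape
    if n_samp <= p:
        raise ValueError(f"trials of {n_samp} samples cannot support order {p}")
    zs, ys = [], []
    for tr in range(n_trials):
        x = trials[tr]
        ys.append(x[p:])
        zs.append(
            np.concatenate([x[p - k : n_samp - k] for k in range(1, p + 1)], axis=1)
        )
    return np.vstack(zs), np.vstack(ys)


class MVAR(BaseEstimator):
    """Least-squares multichannel autoregressive model.

    Parameters
    ----------
    order : int or "auto"
        Model order p, or ``"auto"`` to minimize ``criterion`` over
        ``1..max_order``.
    max_order : int
        Upper bound for automatic order selection.
    criterion : {"bic", "aic"}
        Information criterion used by automatic selection.

    Attributes
    ----------
    coef_ : ndarray of shape (order, n_sources, n_sources)
        ``coef_[k - 1]`` is the lag-k coefficient matrix A_k.
    noise_cov_ : ndarray
        Residual covariance Sigma (ddof = number of regressors).
    order_ : int
        The order actually fitted.
    ic_values_ : dict[int, float]
        Criterion value per candidate order (auto mode only).
    stable_ : bool
        Companion-matrix spectral radius < 1.  An unstable fit is
        flagged with a warning, never silently used.
    """

    def __init__(self, order="auto", max_order: int = 20, criterion: str = "bic"):
        self.order = order
        self.max_order = max_order
        self.criterion = criterion

    def fit(self, X, y=None) -> "MVAR":
        if self.criterion not in ("bic", "aic"):
            raise ValueError("criterion must be 'bic' or 'aic'")
        trials = _as_trials(X)
        n_src = trials.shape[2]
        if self.order == "auto":
            self.ic_values_ = {}
            best_p, best_ic = None, np.inf
            max_p = min(self.max_order, trials.shape[1] - 1)
            for p in range(1, max_p + 1):
                try:
                    _, sigma, n_obs = self._ls_fit(trials, p)
                except np.linalg.LinAlgError:
                    continue
                sign, logdet = np.linalg.slogdet(sigma)
                if sign <= 0:
                    continue
                k = n_src * n_src * p
                penalty = (np.log(n_obs) if self.criterion == "bic" else 2.0)
                ic = logdet + k * penalty / n_obs
                self.ic_values_[p] = float(ic)
                if ic < best_ic:
                    best_p, best_ic = p, ic
            if best_p is None:
                raise ValueError("automatic order selection failed for every order")
            p = best_p
        else:
            p = int(self.order)
            if p < 1:
                raise ValueError("order must be >= 1")
            self.ic_values_ = {}
        n_min = 10 * p * n_src
        n_obs_avail = trials.shape[0] * (trials.shape[1] - p)
        if n_obs_avail < n_min:
            warnings.warn(
                f"only {n_obs_avail} observations for order {p} with {n_src} "
                f"sources (< {n_min}); estimates may be unreliable"
            )
        coef, sigma, _ = self._ls_fit(trials, p)
        self.coef_ = coef
        self.noise_cov_ = sigma
        self.order_ = p
        self.n_sources_ = n_src
        radius = companion_spectral_radius(coef)
        self.stable_ = bool(radius < 1.0)
        if not self.stable_:
            warnings.warn(
                f"fitted MVAR is unstable (companion spectral radius {radius:.3f})"
            )
        return self

    @staticmethod
    def _ls_fit(trials: np.ndarray, p: int):
        Z, Y = _design(trials, p)
        n_obs, n_reg = Z.shape
        rank = np.linalg.matrix_rank(Z)
        if rank < n_reg:
            raise np.linalg.LinAlgError(
                f"rank-deficient regressor matrix (rank {rank} < {n_reg})"
            )
        B, *_ = np.linalg.lstsq(Z, Y, rcond=None)
        resid = Y - Z @ B
        ddof = max(n_obs - n_reg, 1)
        sigma = resid.T @ resid / ddof
        n_src = Y.shape[1]
        coef = np.stack(
            [B[k * n_src : (k + 1) * n_src].T for k in range(p)]
        )
        return coef, sigma, n_obs

    def residuals(self, X) -> np.ndarray:
        trials = _as_trials(X)
        Z, Y = _design(trials, self.order_)
        B = np.concatenate([self.coef_[k].T for k in range(self.order_)], axis=0)
        return Y - Z @ B


def fit_mvar(series, order="auto", max_order: int = 20, criterion: str = "bic") -> MVAR:
    """Functional wrapper around :class:`MVAR`."""
    return MVAR(order=order, max_order=max_order, criterion=criterion).fit(series)
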