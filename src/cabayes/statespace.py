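"""Kalman-Rauch smoothing for nonlinear state-space models.

The state-update workhorse of the variational inversion uses posterior
statistical linearization: the evolution and observation functions are
replaced, frame by frame, with affine maps obtained by cubature (sigma-point)
regression at a reference posterior (the previous sweep's smoothed marginals,
or a self-referencing filter pass on the first sweep).  The affine model is
then smoothed exactly with a forward Kalman filter and a backward
Rauch-Tung-Striebel pass, including the lag-one cross covariances needed by
the free energy.

Statistical linearization is what makes the saturating nonlinearities of the
calcium-imaging models tractable: a point Jacobian of the Boltzmann channel
activation taken at rest is essentially zero and makes a linearized smoother
extrapolate wildly, whereas sigma points spread over the state uncertainty
see the activation rise.  For linear models the regression recovers the model
matrices exactly, so the smoother reproduces the closed-form Kalman-Rauch
solution regardless of the reference.

The lagged forward pass conditions the running belief for frame t on
observations up to frame t+k before advancing, which pulls fast transients
into the first-sweep reference trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["StateSpaceModel", "SmootherResult", "fd_jacobian", "kalman_rauch_lagged"]

_FD_H = 1e-6


@dataclass
class StateSpaceModel:
    """Discrete-time stochastic nonlinear state-space model on the frame grid.

    x_{t+1} = f(x_t, theta) + eta_t,   eta ~ N(0, (alpha * Ups_x)^-1)
    y_t     = g(x_t, phi)   + eps_t,   eps ~ N(0, (sigma * Ups_y)^-1)

    ``f`` and ``g`` broadcast over a leading time axis and take a dict of
    natural-valued parameters.  ``Ups_x`` is the diagonal of the state inverse
    covariance; ``Ups_y`` is scalar (one fluorescence channel).  ``f`` may
    internally take several Euler micro-steps per frame (``micro_steps``).
    """

    f: Callable
    g: Callable
    n_states: int
    state_names: tuple[str, ...]
    Ups_x: np.ndarray
    Ups_y: float
    micro_steps: int = 1
    lag: int = 0
    state_bounds: tuple | None = None  # (lo, hi) guard for reference states
    fd_scales: np.ndarray | None = None  # absolute FD steps for the evolution Jacobian

    def __post_init__(self):
        self.Ups_x = np.asarray(self.Ups_x, dtype=float)
        if np.any(self.Ups_x <= 0) or self.Ups_y <= 0:
            raise ValueError("inverse covariances must be positive")
        if self.micro_steps < 1:
            raise ValueError("micro_steps must be >= 1")

    def clip_states(self, X: np.ndarray) -> np.ndarray:
        if self.state_bounds is None:
            return X
        lo, hi = self.state_bounds
        return np.clip(X, lo, hi)


@dataclass
class SmootherResult:
    means: np.ndarray        # (T, n) smoothed marginal means
    covs: np.ndarray         # (T, n, n)
    lag1: np.ndarray         # (T-1, n, n), Cov(x_t, x_{t+1})
    loglik: float            # innovation log-likelihood of the affine model
    filt_means: np.ndarray = None
    filt_covs: np.ndarray = None


def fd_jacobian(fun, X: np.ndarray, *args, h: float = _FD_H,
                scales=None) -> np.ndarray:
    """Central finite-difference Jacobian of a vectorized map.

    ``X`` is (T, n); returns (T, m, n) where m is the output dimension (n for
    the evolution, 1 for the observation).  Step size is relative per column;
    ``scales`` optionally sets per-column absolute minimum steps, which
    smooths near-discontinuous features (the spike repolarization gate is a
    fraction of a millivolt wide and would otherwise yield huge local slopes).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T, n = X.shape
    f0 = np.asarray(fun(X, *args), dtype=float)
    m = 1 if f0.ndim <= 1 else f0.shape[-1]
    J = np.empty((T, m, n))
    for j in range(n):
        hj = h * np.maximum(np.abs(X[:, j]), 1.0)
        if scales is not None and scales[j] > 0:
            hj = np.maximum(hj, scales[j])
        Xp = X.copy(); Xp[:, j] += hj
        Xm = X.copy(); Xm[:, j] -= hj
        fp = np.asarray(fun(Xp, *args), dtype=float).reshape(T, m)
        fm = np.asarray(fun(Xm, *args), dtype=float).reshape(T, m)
        J[:, :, j] = (fp - fm) / (2.0 * hj)[:, None]
    return J


def _sym(P):
    return 0.5 * (P + P.swapaxes(-1, -2))


def _sqrtm_psd(P: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(P)
    except np.linalg.LinAlgError:
        w, U = np.linalg.eigh(_sym(P))
        return U * np.sqrt(np.maximum(w, 0.0))


def _cubature_points(m: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Third-degree spherical-radial cubature points (2n, equal weights)."""
    n = len(m)
    S = _sqrtm_psd(P) * np.sqrt(n)
    return np.concatenate([m + S.T, m - S.T], axis=0)


def _affine_sigma(fun, args, m, P):
    """Statistically linearized affine approximation of ``fun`` at N(m, P).

    Returns (A, b, Lam): slope, offset and residual covariance such that
    fun(x) ~ A x + b + N(0, Lam) over the reference density.  Exact (Lam = 0)
    for affine ``fun``.
    """
    X = _cubature_points(m, P)
    Y = np.asarray(fun(X, args), dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    ym = Y.mean(axis=0)
    dX = X - m
    dY = Y - ym
    Cxy = dX.T @ dY / X.shape[0]                       # (n, d)
    A = np.linalg.lstsq(P, Cxy, rcond=None)[0].T       # (d, n); 0 along null dirs
    Lam = dY.T @ dY / X.shape[0] - A @ P @ A.T
    w, U = np.linalg.eigh(_sym(Lam))
    Lam = (U * np.maximum(w, 0.0)) @ U.T
    b = ym - A @ m
    return A, b, Lam



def _noise_covs(ssm, exp_alpha, exp_sigma):
    """State/observation noise covariances with a 1e-12 floor (precisions are
    effectively capped at 1e12, the package's 'infinite precision' convention)."""
    Q = np.diag(np.maximum(1.0 / (exp_alpha * ssm.Ups_x), 1e-12))
    R = max(1.0 / (exp_sigma * ssm.Ups_y), 1e-12)
    return Q, R


_VAR_CEIL = 1e8  # state-variance ceiling; keeps roundoff below the noise floor


def _cap_cov(P):
    """Project a (near-)covariance onto the PSD cone with a variance ceiling."""
    P = _sym(P)
    d = np.diag(P)
    if np.all(d >= 0.0) and np.all(d <= _VAR_CEIL) and np.all(np.isfinite(P)):
        return P
    P = np.where(np.isfinite(P), P, 0.0)
    w, U = np.linalg.eigh(P)
    w = np.clip(w, 0.0, _VAR_CEIL)
    return _sym((U * w) @ U.T)


def _solve_gain(P_pred, M):
    """RTS gain J = M P_pred^{-1} computed robustly (lstsq fallback)."""
    try:
        return np.linalg.solve(P_pred.T, M.T).T
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(P_pred.T, M.T, rcond=None)[0].T


def _affine_filter_smoother(Fs, bs, Lams, Gs, cs, ss, y, Q, R, x0_mean, x0_cov):
    """Exact Kalman filter + RTS smoother of a time-varying affine model."""
    T = len(y)
    n = len(x0_mean)
    fm = np.empty((T, n)); fP = np.empty((T, n, n))
    pm = np.empty((T, n)); pP = np.empty((T, n, n))
    m, P = x0_mean, x0_cov
    loglik = 0.0
    I = np.eye(n)
    for t in range(T):
        pm[t], pP[t] = m, P
        S = max(float(Gs[t] @ P @ Gs[t]) + ss[t], 0.0) + R
        v = float(y[t] - (Gs[t] @ m + cs[t]))
        K = (P @ Gs[t]) / S
        m = m + K * v
        # Joseph form: positive semidefinite under cancellation-heavy scales
        IKG = I - np.outer(K, Gs[t])
        P = _sym(IKG @ P @ IKG.T) + np.outer(K, K) * (R + ss[t])
        loglik += -0.5 * (np.log(2.0 * np.pi * S) + v * v / S)
        fm[t], fP[t] = m, P
        if t < T - 1:
            m = Fs[t] @ m + bs[t]
            P = _cap_cov(_sym(Fs[t] @ P @ Fs[t].T + Q + Lams[t]))
    sm = np.empty((T, n)); sP = np.empty((T, n, n))
    C = np.empty((max(T - 1, 0), n, n))
    sm[-1], sP[-1] = fm[-1], fP[-1]
    for t in range(T - 2, -1, -1):
        P_pred = pP[t + 1]
        Jt = _solve_gain(P_pred, fP[t] @ Fs[t].T)
        sm[t] = fm[t] + Jt @ (sm[t + 1] - pm[t + 1])
        sP[t] = _cap_cov(_sym(fP[t] + Jt @ (sP[t + 1] - P_pred) @ Jt.T))
        C[t] = Jt @ sP[t + 1]
    return SmootherResult(sm, sP, C, float(loglik), fm, fP)


def _adf_reference(ssm, y, theta, phi, Q, R, x0_mean, x0_cov, lag):
    """Self-referencing cubature pass building an initial reference posterior.

    Forward cubature Kalman filter (with lagged refinement of the running
    belief when ``lag`` > 0) followed by a statistically linearized RTS pass.
    """
    T = len(y)
    n = ssm.n_states
    fm = np.empty((T, n)); fP = np.empty((T, n, n))
    m, P = x0_mean, x0_cov
    As = np.empty((T - 1, n, n)); bs = np.empty((T - 1, n))
    pm = np.empty((T, n)); pP = np.empty((T, n, n))
    for t in range(T):
        pm[t], pP[t] = m, P
        G, c, s = _affine_sigma(ssm.g, phi, m, P)
        G = G[0]; c = float(c[0]); s = float(s[0, 0])
        S = max(float(G @ P @ G) + s, 0.0) + R
        v = float(y[t] - (G @ m + c))
        K = (P @ G) / S
        m = m + K * v
        IKG = np.eye(n) - np.outer(K, G)
        P = _sym(IKG @ P @ IKG.T) + np.outer(K, K) * (R + s)
        m = ssm.clip_states(m)
        if lag > 0 and t < T - 1:
            m, P = _lag_refine(ssm, m, P, y[t + 1:t + 1 + lag], theta, phi, Q, R)
            m = ssm.clip_states(m)
        fm[t], fP[t] = m, P
        if t < T - 1:
            A, b, Lam = _affine_sigma(ssm.f, theta, m, P)
            As[t], bs[t] = A, b
            m = A @ m + b
            P = _cap_cov(_sym(A @ P @ A.T + Q + Lam))
    sm = np.empty((T, n)); sP = np.empty((T, n, n))
    sm[-1], sP[-1] = fm[-1], fP[-1]
    for t in range(T - 2, -1, -1):
        m_pred = As[t] @ fm[t] + bs[t]
        P_pred = _sym(As[t] @ fP[t] @ As[t].T + Q)
        Jt = _solve_gain(P_pred, fP[t] @ As[t].T)
        sm[t] = fm[t] + Jt @ (sm[t + 1] - m_pred)
        sP[t] = _cap_cov(_sym(fP[t] + Jt @ (sP[t + 1] - P_pred) @ Jt.T))
    return ssm.clip_states(sm), sP


def _lag_refine(ssm, m, P, y_future, theta, phi, Q, R):
    """Condition the current belief on the next ``k`` observations.

    Runs a short cubature filter over the future window while tracking the
    cross covariance between the head state and the running window state.
    """
    mh, Ph = m, P
    mw, Pw = m, P
    Cross = Ph.copy()                  # Cov(head, x_window)
    for y_t in y_future:
        A, b, Lam = _affine_sigma(ssm.f, theta, mw, Pw)
        Cross = Cross @ A.T
        mw = A @ mw + b
        Pw = _cap_cov(_sym(A @ Pw @ A.T + Q + Lam))
        G, c, s = _affine_sigma(ssm.g, phi, mw, Pw)
        G = G[0]; c = float(c[0]); s = float(s[0, 0])
        S = max(float(G @ Pw @ G) + s, 0.0) + R
        v = float(y_t - (G @ mw + c))
        K = (Pw @ G) / S
        mw = mw + K * v
        IKGw = np.eye(len(mw)) - np.outer(K, G)
        Pw = _sym(IKGw @ Pw @ IKGw.T) + np.outer(K, K) * (R + s)
        Kh = (Cross @ G) / S
        mh = mh + Kh * v
        Ph = _sym(Ph - np.outer(Kh, Kh) * S)
        Cross = Cross - np.outer(Kh, K) * S
    return mh, Ph


def kalman_rauch_lagged(ssm: StateSpaceModel, y: np.ndarray, theta: dict, phi: dict,
                        exp_alpha: float, exp_sigma: float,
                        x0_mean: np.ndarray, x0_cov: np.ndarray,
                        lin_points=None, lag: int | None = None) -> SmootherResult:
    """Per-frame state marginals given fixed parameter values.

    ``lin_points`` is the reference posterior for statistical linearization:
    either None (a self-referencing lagged cubature pass builds it) or a
    ``(means, covs)`` pair, typically the previous sweep's smoothed marginals.
    Returns smoothed means, covariances, lag-one cross covariances and the
    innovation log-likelihood of the affine surrogate model.
    """
    y = np.asarray(y, dtype=float).reshape(-1)
    T = len(y)
    n = ssm.n_states
    lag = ssm.lag if lag is None else lag
    Q, R = _noise_covs(ssm, exp_alpha, exp_sigma)
    x0_mean = np.asarray(x0_mean, dtype=float).reshape(n)
    x0_cov = np.asarray(x0_cov, dtype=float).reshape(n, n)

    if lin_points is None:
        ref_m, ref_P = _adf_reference(ssm, y, theta, phi, Q, R, x0_mean, x0_cov, lag)
    else:
        ref_m, ref_P = lin_points
        ref_m = ssm.clip_states(np.asarray(ref_m, dtype=float).reshape(T, n))
        ref_P = np.asarray(ref_P, dtype=float).reshape(T, n, n)

    Fs = np.empty((T - 1, n, n)); bs = np.empty((T - 1, n)); Lams = np.empty((T - 1, n, n))
    Gs = np.empty((T, n)); cs = np.empty(T); ss = np.empty(T)
    for t in range(T):
        G, c, s = _affine_sigma(ssm.g, phi, ref_m[t], ref_P[t])
        Gs[t], cs[t], ss[t] = G[0], float(c[0]), float(s[0, 0])
        if t < T - 1:
            A, b, Lam = _affine_sigma(ssm.f, theta, ref_m[t], ref_P[t])
            Fs[t], bs[t], Lams[t] = A, b, Lam
    return _affine_filter_smoother(Fs, bs, Lams, Gs, cs, ss, y, Q, R, x0_mean, x0_cov)


def map_objective(ssm: StateSpaceModel, y, theta, phi, exp_alpha, exp_sigma,
                  x0_mean, x0_var, X) -> float:
    """Negative log joint density (up to constants) of a state trajectory."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    e = X[1:] - np.asarray(ssm.f(X[:-1], theta), dtype=float)
    r = y - np.asarray(ssm.g(X, phi), dtype=float).reshape(-1)
    J = 0.5 * exp_alpha * float(np.sum((e ** 2) @ ssm.Ups_x))
    J += 0.5 * exp_sigma * ssm.Ups_y * float(np.sum(r ** 2))
    v = np.asarray(x0_var, dtype=float)
    free = v > 0
    d0 = X[0] - np.asarray(x0_mean, dtype=float)
    J += 0.5 * float(np.sum(d0[free] ** 2 / v[free]))
    return J


def linearized_smoother(ssm: StateSpaceModel, y, theta, phi, exp_alpha, exp_sigma,
                        x0_mean, x0_cov, traj) -> SmootherResult:
    """Affine Kalman-Rauch pass linearized (finite differences) at ``traj``.

    At a Gauss-Newton fixed point of the MAP objective the returned means
    coincide with ``traj`` and the covariances are the Laplace covariances.
    """
    y = np.asarray(y, dtype=float).reshape(-1)
    T = len(y)
    n = ssm.n_states
    Q, R = _noise_covs(ssm, exp_alpha, exp_sigma)
    X = np.asarray(traj, dtype=float).reshape(T, n)
    Fj = fd_jacobian(ssm.f, X[:-1], theta, scales=ssm.fd_scales)
    np.clip(Fj, -50.0, 50.0, out=Fj)
    fb = np.asarray(ssm.f(X[:-1], theta), dtype=float)
    bs = fb - np.einsum("tij,tj->ti", Fj, X[:-1])
    Gj = fd_jacobian(ssm.g, X, phi).reshape(T, n)
    np.clip(Gj, -1e6, 1e6, out=Gj)
    gb = np.asarray(ssm.g(X, phi), dtype=float).reshape(-1)
    cs = gb - np.einsum("ti,ti->t", Gj, X)
    Lams = np.zeros((T - 1, n, n))
    ss = np.zeros(T)
    return _affine_filter_smoother(Fj, bs, Lams, Gj, cs, ss, y, Q, R,
                                   np.asarray(x0_mean, dtype=float),
                                   np.asarray(x0_cov, dtype=float))


def map_refine(ssm: StateSpaceModel, y, theta, phi, exp_alpha, exp_sigma,
               x0_mean, x0_cov, x0_var, init_traj, n_iter: int = 8,
               tol: float = 1e-3, freeze: tuple | None = None) -> SmootherResult:
    """Damped Gauss-Newton maximization of the state MAP objective.

    Each iteration solves the smoothing problem of the model linearized at the
    current trajectory (the Gauss-Newton step) and backtracks along the step
    until the exact objective improves.  Returns the Laplace result at the
    final trajectory: means plus covariances and lag-one cross covariances
    from the last linearization.
    """
    X = ssm.clip_states(np.asarray(init_traj, dtype=float).copy())
    if freeze is not None:
        idx, vals = freeze
        X[:, idx] = vals
    obj = map_objective(ssm, y, theta, phi, exp_alpha, exp_sigma, x0_mean, x0_var, X)
    for _ in range(n_iter):
        res = linearized_smoother(ssm, y, theta, phi, exp_alpha, exp_sigma,
                                  x0_mean, x0_cov, X)
        target = ssm.clip_states(res.means)
        if freeze is not None:
            target[:, idx] = vals
        improved = False
        for gamma in (1.0, 0.5, 0.25, 0.125, 0.0625):
            X_new = ssm.clip_states(X + gamma * (target - X))
            if freeze is not None:
                X_new[:, idx] = vals
            obj_new = map_objective(ssm, y, theta, phi, exp_alpha, exp_sigma,
                                    x0_mean, x0_var, X_new)
            if obj_new < obj - 1e-12:
                gain = obj - obj_new
                X, obj = X_new, obj_new
                improved = True
                break
        if not improved or gain < tol:
            break
    # Laplace at the refined mode: covariances from the linearization at X,
    # with the mode itself as the reported mean
    final = linearized_smoother(ssm, y, theta, phi, exp_alpha, exp_sigma,
                                x0_mean, x0_cov, X)
    return SmootherResult(X, final.covs, final.lag1, final.loglik,
                          final.filt_means, final.filt_covs)
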