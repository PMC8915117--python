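"""Unscented Kalman filter.

A general additive-noise UKF with scaled sigma points.  In this package its
job is to smooth the scale-2 wavelet detail coefficient sequence of an ECG
record in place of threshold shrinkage, but the implementation is a generic
state estimator: the state-transition and observation maps are injected
callables, so any nonlinear system with additive Gaussian noise fits.

The unscented transform propagates the state mean and covariance through the
nonlinear maps via 2n+1 deterministically chosen sigma points, avoiding the
linearisation error of the extended Kalman filter.  On a linear-Gaussian
system the filter reproduces the classical Kalman recursion (this equivalence
is the defining sanity check in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["StateSpaceModel", "UKFConfig", "sigma_points", "ukf_run", "random_walk_model"]


@dataclass
class StateSpaceModel:
    """Additive-noise state-space system.

    x_{k+1} = f(x_k) + w,  w ~ N(0, Q)
    y_k     = h(x_k) + v,  v ~ N(0, R)
    """

    f: Callable[[np.ndarray], np.ndarray]
    h: Callable[[np.ndarray], np.ndarray]
    Q: np.ndarray
    R: np.ndarray
    x0: np.ndarray
    P0: np.ndarray

    def __post_init__(self) -> None:
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        self.R = np.atleast_2d(np.asarray(self.R, dtype=float))
        self.x0 = np.atleast_1d(np.asarray(self.x0, dtype=float))
        self.P0 = np.atleast_2d(np.asarray(self.P0, dtype=float))
        for name, m in (("Q", self.Q), ("R", self.R), ("P0", self.P0)):
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
        if np.any(np.linalg.eigvalsh(self.P0) <= 0):
            raise ValueError("P0 must be positive definite")


@dataclass(frozen=True)
class UKFConfig:
    """Scaled sigma-point parameters (canonical literature defaults)."""

    alpha: float = 1e-3
    beta: float = 2.0
    kappa: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


def sigma_points(
    mean: Sequence[float], cov: np.ndarray, config: UKFConfig = UKFConfig()
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled sigma points and their mean/covariance weights.

    Returns ``(points, wm, wc)`` where ``points`` has shape ``(2n+1, n)``.
    The weighted mean of the points equals ``mean`` and their weighted
    covariance equals ``cov`` exactly (the defining property of the
    unscented transform).
    """
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    n = mean.size
    lam = config.alpha**2 * (n + config.kappa) - n
    try:
        sqrt = np.linalg.cholesky((n + lam) * cov)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "covariance not positive definite in sigma-point generation"
        ) from exc
    points = np.empty((2 * n + 1, n))
    points[0] = mean
    for i in range(n):
        points[1 + i] = mean + sqrt[:, i]
        points[1 + n + i] = mean - sqrt[:, i]
    wm = np.full(2 * n + 1, 1.0 / (2 * (n + lam)))
    wc = wm.copy()
    wm[0] = lam / (n + lam)
    wc[0] = lam / (n + lam) + (1 - config.alpha**2 + config.beta)
    return points, wm, wc


def _unscented_moments(
    transformed: np.ndarray, wm: np.ndarray, wc: np.ndarray, noise: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    mean = wm @ transformed
    dev = transformed - mean
    cov = (wc[:, None] * dev).T @ dev + noise
    return mean, cov


def ukf_run(
    observations: Sequence[float] | np.ndarray,
    model: StateSpaceModel,
    config: UKFConfig = UKFConfig(),
) -> np.ndarray:
    """Forward UKF pass; returns one filtered state mean per observation.

    Both the time-update (propagation through ``f``) and the
    measurement-update (propagation through ``h``) use the unscented
    transform.  The state covariance is re-symmetrised after every update to
    keep it numerically PSD.

    Raises
    ------
    FloatingPointError
        If the state or covariance becomes non-finite, reporting the step.
    """
    obs = np.asarray(observations, dtype=float)
    if obs.ndim == 1:
        obs = obs[:, None]
    if len(obs) < 1:
        raise ValueError("need at least one observation")

    x = model.x0.copy()
    P = model.P0.copy()
    out = np.empty((len(obs), x.size))
    for k, y in enumerate(obs):
        # predict
        pts, wm, wc = sigma_points(x, P, config)
        fx = np.array([np.atleast_1d(model.f(p)) for p in pts])
        x_pred, P_pred = _unscented_moments(fx, wm, wc, model.Q)
        # update
        pts, wm, wc = sigma_points(x_pred, P_pred, config)
        hy = np.array([np.atleast_1d(model.h(p)) for p in pts])
        y_pred, S = _unscented_moments(hy, wm, wc, model.R)
        Pxy = (wc[:, None] * (pts - x_pred)).T @ (hy - y_pred)
        K = np.linalg.solve(S.T, Pxy.T).T
        x = x_pred + K @ (y - y_pred)
        P = P_pred - K @ S @ K.T
        P = 0.5 * (P + P.T)
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(P))):
            raise FloatingPointError(f"UKF diverged (non-finite state) at step {k}")
        out[k] = x
    return out


def random_walk_model(
    observations: Sequence[float],
    r: float | None = None,
    q_ratio: float = 0.01,
) -> StateSpaceModel:
    """Scalar random-walk model for a wavelet-coefficient sequence.

    x_{k+1} = x_k + w, y_k = x_k + v: the simplest model whose smoothing
    suppresses oscillatory (powerline-band) content while tracking slow
    coefficient structure.  The observation-noise variance ``r`` defaults to
    the robust wavelet-domain estimate (MAD/0.6745)^2 of the sequence, and
    the process noise is ``q_ratio * r`` — small ``q_ratio`` smooths harder.
    """
    obs = np.asarray(observations, dtype=float)
    if r is None:
        mad = np.median(np.abs(obs - np.median(obs)))
        r = float((mad / 0.6745) ** 2)
        if r == 0.0:
            r = 1e-12
    q = q_ratio * r
    identity = lambda x: x
    return StateSpaceModel(
        f=identity, h=identity, Q=[[q]], R=[[r]], x0=[obs[0]], P0=[[r]]
    )
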