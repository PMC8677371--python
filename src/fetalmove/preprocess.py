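"""Epoch segmentation and Kalman-filter signal recovery.

The raw acceleration stream is cut into non-overlapping 2.56 s epochs and each
epoch is denoised with a Kalman filter — the minimum-variance linear state
estimator.  The state-space model is the scalar *local level* model
(random walk observed in white noise):

    x_k = x_{k-1} + w_{k-1},      w ~ N(0, Q)
    y_k = x_k + v_k,              v ~ N(0, R)

which is the minimal model consistent with recovering a slowly varying
low-amplitude signal from a noisy background.  R is estimated robustly from
the data (median absolute first difference) and Q is tied to it through a
configurable ratio.  The filter itself is implemented for general matrix
parameters; the scalar model takes a fast path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .synthetic import LabeledRecording

__all__ = [
    "Epoch",
    "KalmanParams",
    "KalmanState",
    "NumericalDegeneracyError",
    "segment",
    "estimate_measurement_noise",
    "kalman_filter",
    "preprocess_epoch",
]

EPOCH_SECONDS = 2.56
NOISE_FLOOR = 1e-12


class NumericalDegeneracyError(ArithmeticError):
    """Innovation covariance became singular during filtering."""


@dataclass
class Epoch:
    """A fixed-duration window of samples, optionally labeled.

    ``samples`` is ``(n,)`` for a single channel or ``(n, n_axes)``.
    """

    samples: np.ndarray
    fs: float
    index: int = 0
    label: int | None = None
    degenerate: bool = False

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]


@dataclass
class KalmanParams:
    """State-space matrices for the linear filter.

    Defaults give the scalar local-level model (A = C = 1, B = 0, u = 0).
    Scalars are accepted and promoted to 1x1 matrices.
    """

    A: np.ndarray | float = 1.0
    B: np.ndarray | float = 0.0
    C: np.ndarray | float = 1.0
    Q: np.ndarray | float = 1.0
    R: np.ndarray | float = 1.0
    x0: np.ndarray | float = 0.0
    P0: np.ndarray | float = 1.0
    u: np.ndarray | None = None  # (n_steps, p) control inputs; default zero

    @classmethod
    def local_level(
        cls, R: float, q_ratio: float = 0.1, x0: float = 0.0, P0: float | None = None
    ) -> "KalmanParams":
        """Scalar local-level parameters with Q = q_ratio * R and P0 = R."""
        return cls(A=1.0, B=0.0, C=1.0, Q=q_ratio * R, R=R, x0=x0,
                   P0=R if P0 is None else P0)


@dataclass
class KalmanState:
    """Filter internals after the last step (prior/posterior mean & covariance)."""

    x_prior: np.ndarray
    x_post: np.ndarray
    P_prior: np.ndarray
    P_post: np.ndarray
    K: np.ndarray


def segment(
    recording: "LabeledRecording | np.ndarray",
    epoch_seconds: float = EPOCH_SECONDS,
    fs: float | None = None,
    labels: Sequence[int] | None = None,
) -> list[Epoch]:
    """Cut a recording into non-overlapping consecutive epochs.

    A trailing partial epoch is dropped; the epoch count is
    ``floor(n_samples / round(fs * epoch_seconds))``.  Accepts either a
    :class:`~fetalmove.synthetic.LabeledRecording` or a raw array plus *fs*.
    """
    if hasattr(recording, "samples"):
        samples = np.asarray(recording.samples)
        fs = recording.fs
    else:
        samples = np.asarray(recording)
        if fs is None:
            raise ValueError("fs is required when passing a raw sample array")
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    if epoch_seconds <= 0:
        raise ValueError(f"epoch_seconds must be positive, got {epoch_seconds}")
    samples_per_epoch = int(round(fs * epoch_seconds))
    n_epochs = samples.shape[0] // samples_per_epoch
    epochs = []
    for k in range(n_epochs):
        chunk = samples[k * samples_per_epoch : (k + 1) * samples_per_epoch]
        lab = None if labels is None else int(labels[k])
        epochs.append(Epoch(samples=np.array(chunk), fs=float(fs), index=k, label=lab))
    return epochs


def estimate_measurement_noise(x: np.ndarray) -> float:
    """Robust measurement-noise variance from first differences.

    sigma_hat = median(|diff(x)|) / (0.6745 * sqrt(2)); returns sigma_hat**2,
    floored at 1e-12 so downstream divisions stay defined.  Robust to sparse
    transients (bursts, steps), unlike the raw sample variance.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1-d vector of length >= 3")
    sigma = np.median(np.abs(np.diff(x))) / (0.6745 * np.sqrt(2.0))
    return max(float(sigma) ** 2, NOISE_FLOOR)


def _is_scalar_model(params: KalmanParams) -> bool:
    return all(
        np.isscalar(getattr(params, name)) or np.asarray(getattr(params, name)).size == 1
        for name in ("A", "B", "C", "Q", "R", "x0", "P0")
    )


def _scalar_kalman(y: np.ndarray, params: KalmanParams, collect: bool):
    a = float(np.asarray(params.A).reshape(()))
    b = float(np.asarray(params.B).reshape(()))
    c = float(np.asarray(params.C).reshape(()))
    q = float(np.asarray(params.Q).reshape(()))
    r = float(np.asarray(params.R).reshape(()))
    x = float(np.asarray(params.x0).reshape(()))
    p = float(np.asarray(params.P0).reshape(()))
    u = params.u
    n = len(y)
    out = np.empty(n)
    hist_K = np.empty(n) if collect else None
    hist_P = np.empty(n) if collect else None
    x_pr = x
    p_pr = p
    k_gain = 0.0
    yl = [float(v) for v in y]
    for i in range(n):
        uk = float(np.asarray(u[i]).reshape(())) if u is not None else 0.0
        x_pr = a * x + b * uk
        p_pr = a * p * a + q
        s = c * p_pr * c + r
        if s == 0.0:
            raise NumericalDegeneracyError(
                f"innovation covariance is zero at step {i}"
            )
        k_gain = p_pr * c / s
        x = x_pr + k_gain * (yl[i] - c * x_pr)
        p = (1.0 - k_gain * c) * p_pr
        out[i] = x
        if collect:
            hist_K[i] = k_gain
            hist_P[i] = p
    state = KalmanState(
        x_prior=np.array([x_pr]),
        x_post=np.array([x]),
        P_prior=np.array([[p_pr]]),
        P_post=np.array([[p]]),
        K=np.array([[k_gain]]),
    )
    history = {"K": hist_K, "P_post": hist_P} if collect else None
    return out, state, history


def kalman_filter(
    y: np.ndarray,
    params: KalmanParams,
    return_history: bool = False,
):
    """Run the predict/update recursion over a measurement sequence.

    Predict:  x_prior = A x + B u;     P_prior = A P A' + Q
    Update:   K = P_prior C' (C P_prior C' + R)^{-1}
              x = x_prior + K (y_k - C x_prior);   P = (I - K C) P_prior

    Returns ``(filtered, state)`` where *filtered* holds the posterior state
    estimates (length equals the input length) and *state* the final
    :class:`KalmanState`.  With ``return_history=True`` a third element gives
    per-step gain and posterior covariance, useful for convergence checks.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1 and _is_scalar_model(params):
        out, state, history = _scalar_kalman(y, params, return_history)
        return (out, state, history) if return_history else (out, state)

    A = np.atleast_2d(np.asarray(params.A, dtype=float))
    C = np.atleast_2d(np.asarray(params.C, dtype=float))
    Q = np.atleast_2d(np.asarray(params.Q, dtype=float))
    R = np.atleast_2d(np.asarray(params.R, dtype=float))
    n_state = A.shape[0]
    n_meas = C.shape[0]
    B = np.atleast_2d(np.asarray(params.B, dtype=float))
    if B.shape == (1, 1) and n_state > 1:
        B = np.zeros((n_state, 1))
    x = np.atleast_1d(np.asarray(params.x0, dtype=float)).reshape(n_state)
    P = np.atleast_2d(np.asarray(params.P0, dtype=float))
    Y = y.reshape(len(y), n_meas)
    I = np.eye(n_state)
    out = np.empty((len(Y), n_state))
    hist_K, hist_P = ([], []) if return_history else (None, None)
    x_pr, P_pr, K = x, P, np.zeros((n_state, n_meas))
    for i, yk in enumerate(Y):
        uk = (
            np.atleast_1d(np.asarray(params.u[i], dtype=float))
            if params.u is not None
            else np.zeros(B.shape[1])
        )
        x_pr = A @ x + B @ uk
        P_pr = A @ P @ A.T + Q
        S = C @ P_pr @ C.T + R
        try:
            K = np.linalg.solve(S.T, (P_pr @ C.T).T).T
        except np.linalg.LinAlgError as exc:
            raise NumericalDegeneracyError(
                f"singular innovation covariance at step {i}"
            ) from exc
        x = x_pr + K @ (yk - C @ x_pr)
        P = (I - K @ C) @ P_pr
        out[i] = x
        if return_history:
            hist_K.append(K.copy())
            hist_P.append(P.copy())
    state = KalmanState(x_prior=x_pr, x_post=x, P_prior=P_pr, P_post=P, K=K)
    if return_history:
        return out, state, {"K": np.array(hist_K), "P_post": np.array(hist_P)}
    return out, state


def _filter_channel(x: np.ndarray, q_ratio: float) -> np.ndarray:
    R = estimate_measurement_noise(x)
    params = KalmanParams.local_level(R=R, q_ratio=q_ratio, x0=float(x[0]))
    filtered, _ = kalman_filter(x, params)
    return filtered


def preprocess_epoch(
    epoch: Epoch,
    mode: str = "per_axis_then_magnitude",
    q_ratio: float = 0.1,
) -> Epoch:
    """Denoise one epoch and reduce it to a single analysis channel.

    ``per_axis_then_magnitude`` (default) filters each axis with the scalar
    local-level model — R from :func:`estimate_measurement_noise`, Q =
    ``q_ratio * R`` — then combines the axes into the Euclidean norm.
    ``magnitude_then_filter`` takes the norm first and filters once.  An
    all-zero epoch is returned unchanged with its ``degenerate`` flag set.
    """
    if mode not in ("per_axis_then_magnitude", "magnitude_then_filter"):
        raise ValueError(f"unknown mode: {mode!r}")
    x = np.asarray(epoch.samples, dtype=float)
    if not np.any(x):
        out = x if x.ndim == 1 else np.linalg.norm(x, axis=1)
        return Epoch(out, epoch.fs, epoch.index, epoch.label, degenerate=True)
    if x.ndim == 1:
        filtered = _filter_channel(x, q_ratio)
    elif mode == "per_axis_then_magnitude":
        cols = [_filter_channel(x[:, j], q_ratio) for j in range(x.shape[1])]
        filtered = np.linalg.norm(np.column_stack(cols), axis=1)
    else:
        filtered = _filter_channel(np.linalg.norm(x, axis=1), q_ratio)
    return Epoch(filtered, epoch.fs, epoch.index, epoch.label)
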