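"""Linear time-varying dynamic network models (DNMs).

A DNM is the sequence of state-transition matrices A_1 … A_M obtained by
splitting a multichannel recording into non-overlapping windows of
duration T (125 ms by default) and fitting, within each window, the
one-step linear model

    x(t+1) = A x(t) + e(t)

by least squares. Entry (i, j) of A quantifies how channel j's current
activity drives channel i's next-step activity; the sequence of A's
captures how that influence structure drifts over the recording.

At 250 Hz a 125 ms window holds floor(31.25) = 31 samples, i.e. 30
regression pairs for 19 unknowns per row — barely overdetermined, so a
tiny relative ridge (1e-6 × mean Gram diagonal) is applied by default to
stabilize near-singular windows. ``ridge=0`` reproduces plain least
squares exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateInputError, SingularSystemError
from .io import Recording

#: relative ridge applied when ridge="auto"
AUTO_RIDGE_REL = 1e-6


@dataclass
class DNM:
    """Ordered sequence of per-window state-transition matrices."""

    A_seq: np.ndarray  # n_windows × N × N
    window_len_samples: int
    window_duration_ms: float
    fs: float
    channel_labels: list[str]
    cond_flags: list[str | None]
    valid: np.ndarray  # boolean mask over windows

    @property
    def n_windows(self) -> int:
        return self.A_seq.shape[0]

    @property
    def n_channels(self) -> int:
        return self.A_seq.shape[1]


def window_len_samples(T_ms: float, fs: float) -> int:
    return int(np.floor(T_ms * fs / 1000.0))


def segment_windows(n_samples: int, T_ms: float, fs: float) -> list[range]:
    """Non-overlapping, contiguous half-open sample ranges of one window each.

    The trailing partial window is dropped.
    """
    L = window_len_samples(T_ms, fs)
    if L < 2:
        raise DegenerateInputError(f"window of {L} samples (< 2) at T={T_ms} ms, fs={fs} Hz")
    n_win = n_samples // L
    if n_win < 1:
        raise DegenerateInputError(
            f"recording of {n_samples} samples shorter than one {L}-sample window"
        )
    return [range(k * L, (k + 1) * L) for k in range(n_win)]


def fit_transition_matrix(window_data: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Least-squares one-step transition matrix for a single window.

    Solves argmin_A Σ_t ||x(t+1) − A x(t)||² over the window's L−1
    one-step pairs. With ``ridge > 0`` the term ridge·I is added to the
    Gram matrix X₁X₁ᵀ. Underdetermined ridgeless systems fall back to the
    minimum-norm pseudo-inverse solution.
    """
    W = np.asarray(window_data, dtype=np.float64)
    if W.ndim != 2 or W.shape[1] < 2:
        raise DegenerateInputError("window must be N × L with L >= 2")
    if not np.any(W):
        raise SingularSystemError("all-zero window")
    X1, X2 = W[:, :-1], W[:, 1:]
    if ridge > 0:
        G = X1 @ X1.T + ridge * np.eye(W.shape[0])
        return np.linalg.solve(G, X1 @ X2.T).T
    # plain least squares; lstsq gives the minimum-norm solution when
    # the system is underdetermined (L-1 < N) or rank-deficient
    A_T, *_ = np.linalg.lstsq(X1.T, X2.T, rcond=None)
    return A_T.T


def fit_dnm(rec: Recording, T_ms: float = 125.0, ridge: float | str = "auto") -> DNM:
    """Fit the windowed LTV model over a whole recording.

    ``ridge="auto"`` applies a per-window relative ridge of
    ``1e-6 × mean(diag(Gram))``; a float is used as an absolute ridge and
    0.0 gives plain least squares. Degenerate windows are flagged and
    excluded (via the validity mask) rather than zero-filled.
    """
    windows = segment_windows(rec.n_samples, T_ms, rec.fs)
    L = len(windows[0])
    N = rec.n_channels
    M = len(windows)

    # stack windows: M × N × L
    stacked = rec.data[:, : M * L].reshape(N, M, L).transpose(1, 0, 2)
    X1 = stacked[:, :, :-1]
    X2 = stacked[:, :, 1:]
    G = X1 @ X1.transpose(0, 2, 1)  # M × N × N
    B = X1 @ X2.transpose(0, 2, 1)  # M × N × N  (= X1 X2ᵀ)

    cond_flags: list[str | None] = [None] * M
    valid = np.ones(M, dtype=bool)
    A_seq = np.zeros((M, N, N))

    if ridge == "auto":
        lam = AUTO_RIDGE_REL * np.einsum("mii->m", G) / N
    else:
        lam = np.full(M, float(ridge))

    underdetermined = (L - 1) < N
    for m in range(M):
        if not np.any(stacked[m]):
            cond_flags[m] = "all-zero window"
            valid[m] = False
            continue
        if lam[m] > 0:
            try:
                A_seq[m] = np.linalg.solve(G[m] + lam[m] * np.eye(N), B[m]).T
                continue
            except np.linalg.LinAlgError:
                cond_flags[m] = "singular Gram; pseudo-inverse fallback"
        elif underdetermined:
            cond_flags[m] = "underdetermined (L-1 < N); minimum-norm solution"
        A_T, *_ = np.linalg.lstsq(X1[m].T, X2[m].T, rcond=None)
        A_seq[m] = A_T.T

    if not valid.any():
        raise SingularSystemError("no window could be fitted")
    return DNM(
        A_seq=A_seq,
        window_len_samples=L,
        window_duration_ms=T_ms,
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        cond_flags=cond_flags,
        valid=valid,
    )
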