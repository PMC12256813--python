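"""Sink-index computation from dynamic network models.

For each window's transition matrix A, every channel i gets a (row, column)
norm pair: the row 2-norm measures how strongly the channel is driven by
the network, the column 2-norm how strongly it drives the network. Both
norm vectors are ranked across channels (rank 1 = smallest, rank N =
largest) and normalized by N, giving coordinates (rr_i, cr_i) on the grid
{1/N, …, 1}². The *ideal sink* sits at rr = 1 (most driven), cr = 1/N
(least driving), and the sink index is the additive constant minus the
Euclidean distance from that corner:

    SI_i = c − ‖(rr_i, cr_i) − (1, 1/N)‖₂

With the default c = √2 the attainable range for an N-channel network is
[√2/N, √2] — for N = 19 approximately [0.074, 1.414]. Larger = more
sink-like. Channel × window sink maps are averaged over time and then over
the frontal–temporal (FT) and central–parietal–occipital (CPO) electrode
groups; the FT/CPO ratio of those means is the scalar subject marker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dnm import DNM
from .exceptions import EmptyModelError, ValidationError

#: Default additive constant of the sink-index formula.
DEFAULT_CONSTANT = math.sqrt(2.0)

#: Frontal–temporal electrode group (8 nodes).
FT_CHANNELS = ("Fp1", "Fp2", "F3", "F4", "F7", "F8", "T3", "T4")

#: Central–parietal–occipital electrode group (11 nodes; includes the
#: frontal-midline Fz, following the grouping convention this marker uses).
CPO_CHANNELS = ("O1", "T5", "O2", "T6", "Cz", "Pz", "P3", "Fz", "P4", "C3", "C4")


@dataclass(frozen=True)
class RegionScheme:
    """Disjoint FT/CPO electrode grouping covering the montage."""

    ft_channels: frozenset[str] = frozenset(FT_CHANNELS)
    cpo_channels: frozenset[str] = frozenset(CPO_CHANNELS)

    def __post_init__(self) -> None:
        if self.ft_channels & self.cpo_channels:
            raise ValidationError("FT and CPO groups overlap")

    def check_covers(self, labels) -> None:
        missing = set(labels) - (self.ft_channels | self.cpo_channels)
        if missing:
            raise ValidationError(f"channels not assigned to FT or CPO: {sorted(missing)}")


@dataclass
class SinkMap:
    """Channels × windows sink indices with rank coordinates."""

    si: np.ndarray        # N × M sink indices
    rr_rank: np.ndarray   # N × M normalized row ranks
    cr_rank: np.ndarray   # N × M normalized column ranks
    channel_labels: list[str]
    time_avg_si: np.ndarray  # per-channel mean over valid windows
    valid: np.ndarray        # window validity mask (length M)

    def to_frame(self, window_duration_ms: float | None = None) -> pd.DataFrame:
        cols = range(self.si.shape[1])
        if window_duration_ms is not None:
            cols = [k * window_duration_ms / 1000.0 for k in cols]
        return pd.DataFrame(self.si, index=self.channel_labels, columns=cols)


@dataclass
class SubjectMarker:
    subject_id: str
    si_ft: float
    si_cpo: float
    si_ratio: float
    group: str | None = None


def row_col_norms(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row and column 2-norms of a square matrix (diagonal included)."""
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError(f"expected a square matrix, got shape {A.shape}")
    return np.linalg.norm(A, axis=1), np.linalg.norm(A, axis=0)


def normalized_ranks(values: np.ndarray) -> np.ndarray:
    """Normalized ranks in {1/N, …, 1}; smallest → 1/N, largest → 1.

    Ties are broken by first-occurrence order (stable), so the output is
    always a permutation of {1/N, …, 1}.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 1 or values.size < 2:
        raise ValidationError("need a 1-D vector of length >= 2")
    if not np.all(np.isfinite(values)):
        raise ValidationError("NaN/Inf in values to rank")
    N = values.size
    order = np.argsort(values, kind="stable")
    ranks = np.empty(N)
    ranks[order] = np.arange(1, N + 1)
    return ranks / N


def _ranks_along_channels(norms: np.ndarray) -> np.ndarray:
    """Stable normalized ranks per column of an N × M norm matrix."""
    N, M = norms.shape
    order = np.argsort(norms, axis=0, kind="stable")
    ranks = np.empty((N, M))
    np.put_along_axis(ranks, order, np.arange(1, N + 1)[:, None].repeat(M, axis=1), axis=0)
    return ranks / N


def sink_index_of_matrix(A: np.ndarray, c: float = DEFAULT_CONSTANT) -> np.ndarray:
    """Per-channel sink index of a single transition matrix."""
    row_sizes, col_sizes = row_col_norms(A)
    rr = normalized_ranks(row_sizes)
    cr = normalized_ranks(col_sizes)
    N = A.shape[0]
    return c - np.hypot(rr - 1.0, cr - 1.0 / N)


def si_bounds(N: int, c: float = DEFAULT_CONSTANT) -> tuple[float, float]:
    """Attainable (min, max) sink index for an N-channel network.

    The extremes lie at the corners of the normalized-rank grid: the ideal
    sink (rr=1, cr=1/N) attains c, the ideal source (rr=1/N, cr=1) attains
    c − √2·(1 − 1/N).
    """
    return c - math.sqrt(2.0) * (1.0 - 1.0 / N), c


def sink_map(dnm: DNM, c: float = DEFAULT_CONSTANT) -> SinkMap:
    """Sink indices for every channel and window of a DNM.

    ``time_avg_si`` averages over valid windows only; degenerate windows
    contribute nothing.
    """
    if not dnm.valid.any():
        raise EmptyModelError("DNM has no valid windows")
    A = dnm.A_seq  # M × N × N
    N = dnm.n_channels
    row_norms = np.linalg.norm(A, axis=2).T  # N × M
    col_norms = np.linalg.norm(A, axis=1).T
    rr = _ranks_along_channels(row_norms)
    cr = _ranks_along_channels(col_norms)
    si = c - np.hypot(rr - 1.0, cr - 1.0 / N)
    time_avg = si[:, dnm.valid].mean(axis=1)
    return SinkMap(
        si=si,
        rr_rank=rr,
        cr_rank=cr,
        channel_labels=list(dnm.channel_labels),
        time_avg_si=time_avg,
        valid=dnm.valid.copy(),
    )


def subject_marker(
    smap: SinkMap,
    scheme: RegionScheme | None = None,
    subject_id: str = "",
    group: str | None = None,
) -> SubjectMarker:
    """FT/CPO means of the time-averaged sink index and their ratio."""
    scheme = scheme or RegionScheme()
    scheme.check_covers(smap.channel_labels)
    labels = np.asarray(smap.channel_labels)
    ft_mask = np.isin(labels, list(scheme.ft_channels))
    cpo_mask = np.isin(labels, list(scheme.cpo_channels))
    if not ft_mask.any() or not cpo_mask.any():
        raise ValidationError("region scheme matches no channels in one group")
    si_ft = float(smap.time_avg_si[ft_mask].mean())
    si_cpo = float(smap.time_avg_si[cpo_mask].mean())
    if si_cpo == 0:
        raise ZeroDivisionError("CPO mean sink index is zero")
    return SubjectMarker(subject_id, si_ft, si_cpo, si_ft / si_cpo, group)
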