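"""Cross-recurrence quantification of the LF and HF pupil oscillators.

Both band components are delay-embedded with a common embedding dimension and
time delay, a fixed-amount-of-nearest-neighbours (FAN) cross-recurrence matrix
is built so that the recurrence density is pinned at ``fan_fraction`` per
column, and determinism (DET, % of recurrence points on diagonal lines of
length >= lmin) and the Shannon entropy of the diagonal line-length
distribution (ENT, bits) are computed.

Hyper-parameter estimation follows the pipeline's conventions: the embedding
dimension comes from the flattening point of the normalized log eigenvalue
spectrum of the trajectory-matrix Gram matrix (a symplectic-geometry style
spectrum criterion); the time delay maximizes sample entropy over the
candidate range (0, w / emb_dim] where ``w`` is the (unrounded) Hampel window
width.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import cdist

from .exceptions import (
    DegenerateInputError,
    DomainError,
    UndefinedEntropyError,
)


@dataclass
class EmbeddingSpec:
    """Embedding hyper-parameters shared by the two band components."""

    emb_dim: int
    td: int
    fan_fraction: float = 0.20

    def __post_init__(self) -> None:
        if self.emb_dim < 1 or self.td < 1:
            raise DomainError("emb_dim and td must be >= 1")
        if not 0 < self.fan_fraction < 1:
            raise DomainError("fan_fraction must be in (0, 1)")


@dataclass
class CrossRecurrenceResult:
    """FAN cross-recurrence matrix with its diagonal-line measures."""

    matrix: np.ndarray
    rr: float
    det: float
    ent: float
    line_histogram: dict[int, int]
    lmin: int


def estimate_embedding_dim(series: np.ndarray, max_dim: int = 12,
                           plateau_tol: float = 0.5) -> int:
    """Embedding dimension from the trajectory-matrix eigen-spectrum.

    The series is embedded at the cap dimension (delay 1), the eigenvalues of
    the Gram matrix are normalized and log10-transformed, and the dimension
    returned is one past the last decrement of the log-spectrum larger than
    ``plateau_tol`` (in decades) — i.e. the index at which the spectrum
    flattens into its noise floor. A spectrum with no decrement above the
    tolerance (e.g. white noise) returns ``max_dim``. Deterministic.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 100:
        raise DegenerateInputError("series too short for dimension estimation")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant series has no dynamics")
    X = sliding_window_view(x - x.mean(), max_dim)
    gram = X.T @ X / X.shape[0]
    lam = np.linalg.eigvalsh(gram)[::-1]
    lam = np.maximum(lam, 0.0)
    lam = lam / lam.sum()
    logspec = np.log10(np.maximum(lam, 1e-14))
    decrements = logspec[:-1] - logspec[1:]
    above = np.nonzero(decrements > plateau_tol)[0]
    if above.size == 0:
        return max_dim
    return int(above[-1] + 2)  # one past the last large drop (1-based dims)


def embed(series: np.ndarray, emb_dim: int, td: int) -> np.ndarray:
    """Delay embedding: row i is ``(x_i, x_{i+td}, ..., x_{i+(m-1)td})``."""
    x = np.asarray(series, dtype=float)
    span = (emb_dim - 1) * td
    if x.size <= span:
        raise DegenerateInputError(
            f"series of length {x.size} too short for emb_dim={emb_dim}, "
            f"td={td}")
    idx = np.arange(x.size - span)[:, None] + np.arange(emb_dim)[None, :] * td
    return x[idx]


def sample_entropy(series: np.ndarray, m: int, r_tol: float,
                   lag: int = 1) -> float:
    """Sample entropy ``-ln(A/B)`` with lag-``lag`` template construction.

    ``B`` counts ordered template pairs of length ``m`` within Chebyshev
    tolerance ``r_tol``; ``A`` counts pairs of length ``m + 1``. Both counts
    run over the index set where the longer template exists, so a constant
    series gives ``A == B`` and an entropy of exactly zero. Self-matches are
    excluded.
    """
    x = np.asarray(series, dtype=float)
    if x.size <= (m + 1) * lag:
        raise DegenerateInputError("series too short for sample entropy")

    def count_matches(templates: np.ndarray) -> int:
        n = templates.shape[0]
        total = 0
        # chunked pairwise Chebyshev comparison to bound memory
        chunk = max(1, int(2e7 // max(n, 1)))
        for start in range(0, n, chunk):
            block = templates[start:start + chunk]
            d = np.abs(block[:, None, :] - templates[None, :, :]).max(-1)
            total += int((d <= r_tol).sum()) - block.shape[0]  # no self-match
        return total

    longer = embed(x, m + 1, lag)
    B = count_matches(longer[:, :m])
    if B == 0:
        raise UndefinedEntropyError("no length-m template matches")
    A = count_matches(longer)
    if A == 0:
        raise UndefinedEntropyError("no length-(m+1) template matches")
    return float(-np.log(A / B))


def select_delay(series: np.ndarray, emb_dim: int, w: float = 52.8,
                 r_factor: float = 0.2) -> int:
    """Time delay maximizing sample entropy over ``td in {1..floor(w/m)}``.

    Sample entropy uses ``m = emb_dim`` and tolerance ``r_factor * SD`` of
    the series. Ties break toward the smaller delay; candidates where the
    entropy is undefined are skipped.
    """
    max_td = int(np.floor(w / emb_dim))
    if max_td < 1:
        raise DomainError("w/emb_dim < 1: no candidate delays")
    r_tol = r_factor * float(np.std(series))
    best_td, best_se = None, -np.inf
    for td in range(1, max_td + 1):
        try:
            se = sample_entropy(series, emb_dim, r_tol, lag=td)
        except (UndefinedEntropyError, DegenerateInputError):
            continue
        if se > best_se:
            best_td, best_se = td, se
    if best_td is None:
        raise UndefinedEntropyError("sample entropy undefined for every "
                                    "candidate delay")
    return best_td


def cross_recurrence_matrix(states_a: np.ndarray, states_b: np.ndarray,
                            fan_fraction: float = 0.20) -> np.ndarray:
    """FAN cross-recurrence matrix.

    Entry ``(i, j)`` is True iff state ``a_i`` is among the
    ``k = round(fan_fraction * N')`` nearest (Euclidean) A-states of state
    ``b_j``. Both state sequences are truncated to the common length ``N'``;
    every column then holds exactly ``k`` True entries, which pins the
    recurrence rate at ``fan_fraction`` up to integer rounding. Distance ties
    break toward the smaller row index.
    """
    n = min(len(states_a), len(states_b))
    if n == 0:
        raise DegenerateInputError("empty state sequence")
    A, B = states_a[:n], states_b[:n]
    k = int(round(fan_fraction * n))
    if k < 1:
        raise DomainError("fan_fraction * N' < 1: no neighbours")
    D = cdist(A, B)  # D[i, j] = ||a_i - b_j||
    order = np.argsort(D, axis=0, kind="stable")
    matrix = np.zeros((n, n), dtype=bool)
    cols = np.broadcast_to(np.arange(n), (k, n))
    matrix[order[:k], cols] = True
    return matrix


def diagonal_line_histogram(matrix: np.ndarray, lmin: int = 2) -> dict[int, int]:
    """Counts of maximal diagonal runs of True cells with length >= lmin."""
    m = np.asarray(matrix, dtype=bool)
    counts: Counter[int] = Counter()
    rows, cols = m.shape
    for offset in range(-(rows - 1), cols):
        diag = np.diagonal(m, offset=offset)
        padded = np.concatenate([[0], diag.astype(np.int8), [0]])
        delta = np.diff(padded)
        starts = np.nonzero(delta == 1)[0]
        ends = np.nonzero(delta == -1)[0]
        for length in ends - starts:
            if length >= lmin:
                counts[int(length)] += 1
    return dict(counts)


def rqa_measures(matrix: np.ndarray, line_histogram: dict[int, int],
                 lmin: int = 2) -> tuple[float, float]:
    """Determinism (%) and diagonal-line Shannon entropy (bits).

    DET is the fraction of recurrence points lying on diagonal lines of
    length >= lmin, over all recurrence points; ENT is the base-2 Shannon
    entropy of the normalized line-length histogram.
    """
    total = int(np.asarray(matrix, bool).sum())
    if total == 0:
        raise DegenerateInputError("matrix has no recurrence points")
    on_lines = sum(l * c for l, c in line_histogram.items() if l >= lmin)
    det = 100.0 * on_lines / total
    n_lines = sum(c for l, c in line_histogram.items() if l >= lmin)
    if n_lines == 0:
        ent = 0.0
    else:
        p = np.array([c / n_lines for l, c in line_histogram.items()
                      if l >= lmin])
        ent = float(-(p * np.log2(p)).sum())
    return det, ent


def crqa(lf: np.ndarray, hf: np.ndarray, spec: EmbeddingSpec,
         lmin: int = 2) -> CrossRecurrenceResult:
    """Embed both band series and compute the FAN cross-recurrence measures."""
    states_lf = embed(lf, spec.emb_dim, spec.td)
    states_hf = embed(hf, spec.emb_dim, spec.td)
    matrix = cross_recurrence_matrix(states_lf, states_hf, spec.fan_fraction)
    hist = diagonal_line_histogram(matrix, lmin)
    det, ent = rqa_measures(matrix, hist, lmin)
    rr = matrix.sum() / matrix.size
    return CrossRecurrenceResult(matrix=matrix, rr=float(rr), det=det,
                                 ent=ent, line_histogram=hist, lmin=lmin)
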