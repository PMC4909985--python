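"""Circular binary segmentation of mirrored BAF and candidate filtering.

The change-point search maximizes, over every arc (i, j) of the current
stretch, the two-sample t-statistic between the arc and its (circular)
complement; the split is accepted when its permutation p-value falls below
``alpha``.  Permutations are evaluated in vectorized chunks with early
rejection once the exceedance count makes ``p < alpha`` impossible, so null
stretches are cheap while accepted splits pay the full permutation cost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .probe_model import MosaicXWarning

#: Minimum arc width (probes) considered by the change-point search.
MIN_ARC_WIDTH = 3


@dataclass(frozen=True)
class Segment:
    """A maximal run of informative probes with homogeneous mean mBAF.

    ``start_idx``/``end_idx`` are half-open indices into the informative
    probe series; ``start_bp``/``end_bp`` are the 0-based half-open bp
    bounds spanned by the first and last probe of the segment.
    """

    start_idx: int
    end_idx: int
    start_bp: int
    end_bp: int
    n_probes: int
    mean_mbaf: float
    delta_b: float

    def __post_init__(self) -> None:
        if self.start_idx >= self.end_idx:
            raise ValueError("segment must satisfy start_idx < end_idx")
        if self.n_probes < 1:
            raise ValueError("segment must contain at least one probe")
        if not (0.0 <= self.delta_b <= 0.5):
            raise ValueError("delta_b must lie in [0, 0.5]")

    @property
    def size_bp(self) -> int:
        return self.end_bp - self.start_bp


def _valid_arcs(n: int, min_width: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boundary index pairs (i, j) with min_width <= j-i <= n-min_width."""
    i, j = np.triu_indices(n + 1, k=min_width)
    keep = (j - i) <= n - min_width
    i, j = i[keep], j[keep]
    return i, j, (j - i).astype(float)


def _arc_t2(s: np.ndarray, ss_total, n: int,
            i: np.ndarray, j: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Squared t-statistics of arcs vs complements; works on a batch.

    ``s`` is the zero-prefixed cumulative sum, shape (..., n+1);
    ``ss_total`` the total sum of squares with matching leading shape.
    """
    total = s[..., -1:]
    a = s[..., j] - s[..., i]
    m1 = a / w
    m0 = (total - a) / (n - w)
    # pooled variance from the within-groups sum of squares
    wss = ss_total - w * m1 * m1 - (n - w) * m0 * m0
    var = np.maximum(wss / max(n - 2, 1), 1e-16)
    return (m1 - m0) ** 2 / (var * (1.0 / w + 1.0 / (n - w)))


def _arc_t2_max(x: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Max squared t-statistic over arcs (i, j), and its boundaries.

    Returns ``(t2, i, j)`` comparing ``x[i:j]`` against the rest.
    """
    n = len(x)
    i, j, w = _valid_arcs(n, min_width)
    if i.size == 0:
        return -np.inf, 0, n
    s = np.concatenate(([0.0], np.cumsum(x)))
    t2 = _arc_t2(s, float(np.sum(x * x)), n, i, j, w)
    best = int(np.argmax(t2))
    return float(t2[best]), int(i[best]), int(j[best])


def _arc_t2_max_batch(
    xs: np.ndarray, min_width: int,
    arcs: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Max arc t^2 for each row of ``xs`` (permutation batch)."""
    p, n = xs.shape
    i, j, w = arcs if arcs is not None else _valid_arcs(n, min_width)
    if i.size == 0:
        return np.full(p, -np.inf)
    s = np.concatenate([np.zeros((p, 1)), np.cumsum(xs, axis=1)], axis=1)
    ss_total = np.sum(xs * xs, axis=1)[:, None]
    return _arc_t2(s, ss_total, n, i, j, w).max(axis=1)


def _perm_chunk_size(n: int, budget: int = 4_000_000) -> int:
    return max(1, budget // max(n * n // 2, 1))


def _test_split(
    x: np.ndarray,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
    min_width: int = MIN_ARC_WIDTH,
) -> tuple[int, int] | None:
    """Permutation test of the best arc split; None if not significant."""
    n = len(x)
    if n < 2 * min_width:
        return None
    if np.var(x) < 1e-18:
        return None
    t2_obs, i, j = _arc_t2_max(x, min_width)
    if not np.isfinite(t2_obs):
        return None
    # early rejection: once exceed > alpha * n_perm the p-value cannot
    # drop below alpha, so stop permuting
    reject_at = int(np.floor(alpha * n_perm))
    exceed = 0
    done = 0
    chunk = _perm_chunk_size(n)
    arcs = _valid_arcs(n, min_width)
    while done < n_perm:
        k = min(chunk, n_perm - done)
        perms = rng.permuted(np.broadcast_to(x, (k, n)), axis=1)
        exceed += int(
            np.sum(_arc_t2_max_batch(perms, min_width, arcs) >= t2_obs)
        )
        done += k
        if exceed > reject_at:
            return None
    p = exceed / n_perm
    if p < alpha:
        return i, j
    return None


def cbs_segment(
    values: np.ndarray,
    positions: np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_markers: int = 50,
    seed: int | None = None,
    merge_tol: float = 0.005,
) -> list[Segment]:
    """Segment a mirrored-BAF series into mean-homogeneous pieces.

    Parameters follow common practice for this segmentation family:
    permutation p-threshold ``alpha``, ``n_perm`` label permutations per
    candidate split, stretches shorter than ``min_markers`` are not split
    further, and adjacent segments whose means differ by less than
    ``merge_tol`` are merged.  All randomness derives from ``seed``; each
    stretch draws its permutations from a seed keyed on its boundaries so
    decisions are independent of recursion order.
    """
    values = np.asarray(values, dtype=float)
    positions = np.asarray(positions, dtype=np.int64)
    if len(values) != len(positions):
        raise ValueError("values and positions must have equal length")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite (drop missing probes first)")
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives too coarse a p-resolution")
    if len(values) < min_markers:
        warnings.warn(
            f"only {len(values)} informative probes (< min_markers="
            f"{min_markers}); returning a single segment",
            MosaicXWarning,
            stacklevel=2,
        )
        if len(values) == 0:
            return []
        return [_make_segment(values, positions, 0, len(values))]

    boundaries = {0, len(values)}
    stack = [(0, len(values))]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < min_markers:
            continue
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=0 if seed is None else seed,
                                   spawn_key=(lo, hi))
        )
        split = _test_split(values[lo:hi], alpha, n_perm, rng)
        if split is None:
            continue
        i, j = split
        for b in (lo + i, lo + j):
            if lo < b < hi:
                boundaries.add(b)
        pieces = sorted({lo, lo + i, lo + j, hi})
        for a, b in zip(pieces, pieces[1:]):
            if b - a >= min_markers and (a, b) != (lo, hi):
                stack.append((a, b))

    cuts = sorted(boundaries)
    segs = [(a, b, float(np.mean(values[a:b]))) for a, b in zip(cuts, cuts[1:])]
    # merge adjacent segments with near-identical means
    merged: list[list] = []
    for a, b, m in segs:
        if merged and abs(merged[-1][2] - m) < merge_tol:
            pa, _, pm = merged[-1]
            w1, w2 = merged[-1][1] - pa, b - a
            merged[-1][1] = b
            merged[-1][2] = (pm * w1 + m * w2) / (w1 + w2)
        else:
            merged.append([a, b, m])
    return [_make_segment(values, positions, a, b) for a, b, _ in merged]


def _make_segment(values: np.ndarray, positions: np.ndarray, a: int, b: int) -> Segment:
    mean = float(np.mean(values[a:b]))
    return Segment(
        start_idx=a,
        end_idx=b,
        start_bp=int(positions[a]),
        end_bp=int(positions[b - 1]) + 1,
        n_probes=b - a,
        mean_mbaf=mean,
        delta_b=float(np.clip(mean - 0.5, 0.0, 0.5)),
    )


def filter_segments(
    segments: list[Segment],
    min_size_bp: int = 2_000_000,
    min_delta_b: float = 0.03,
) -> list[Segment]:
    """Keep candidate mosaic segments: >= ``min_size_bp`` long and with a
    het-band deviation of at least ``min_delta_b``.

    The size floor controls the false-positive rate; the deviation floor
    corresponds to a ~6% cell-fraction detection limit for copy-neutral
    events (f = 2 * delta_b).
    """
    return [
        s
        for s in segments
        if s.size_bp >= min_size_bp and s.delta_b >= min_delta_b
    ]
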