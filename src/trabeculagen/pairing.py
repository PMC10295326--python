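"""Slice correspondence between an MDCT stack and a micro-CT stack.

The two modalities image the same specimen with different slice spacings
(about two micro-CT slices per MDCT slice), so building ground-truth image
pairs requires aligning the stacks along the slice axis.  The alignment is
appearance-based:

1. every MDCT slice is upsampled (bicubic) to the micro-CT in-plane grid;
2. SIFT keypoints are detected in each slice and matched across modalities
   with a Lowe ratio test plus mutual-nearest-neighbour filtering;
3. the distance between two slices is the mean Euclidean distance between
   matched keypoint coordinates (a sentinel — the largest finite distance in
   the matrix plus one — where fewer than three matches are found);
4. dynamic time warping through the full distance matrix yields the
   monotone slice-to-slice path, and each micro-CT slice is then paired with
   the MDCT slice the path assigns it, replicating MDCT slices as needed
   (250 MDCT x 2 -> 500 pairs per specimen).
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np
from skimage.feature import SIFT, match_descriptors
from skimage.transform import resize

from .core import VoxelVolume

__all__ = [
    "KeypointSet",
    "PairingResult",
    "detect_keypoints",
    "detect_and_match",
    "image_distance",
    "build_distance_matrix",
    "dtw_align",
    "replicate_and_pair",
    "pair_stacks",
]

MIN_MATCHES = 3


@dataclass
class KeypointSet:
    """SIFT keypoints of one slice in the common (micro-CT) pixel frame."""

    coordinates: np.ndarray  # (n, 2) of (row, col)
    descriptors: np.ndarray  # (n, d)

    def __post_init__(self) -> None:
        if len(self.coordinates) != len(self.descriptors):
            raise ValueError("one descriptor per coordinate required")


@dataclass
class PairingResult:
    distance_matrix: np.ndarray  # (n_mdct, n_micro)
    path: list  # [(i_mdct, j_micro), ...] boundary to boundary
    pairs: list  # [(mdct_index, micro_index)] one per micro slice
    replication_factor: int = 2
    meta: dict | None = None


# ---------------------------------------------------------------------------
# keypoints
# ---------------------------------------------------------------------------

def _as_float_image(img) -> np.ndarray:
    a = np.asarray(img, dtype=np.float64)
    if a.ndim != 2:
        raise ValueError("expected a 2-D slice")
    rng = a.max() - a.min()
    return (a - a.min()) / rng if rng > 0 else a * 0.0


def detect_keypoints(img, upsample_to=None) -> KeypointSet:
    """SIFT keypoints of one slice, optionally after bicubic upsampling to
    the common (micro-CT) grid shape."""
    a = _as_float_image(img)
    if upsample_to is not None and tuple(upsample_to) != a.shape:
        a = resize(a, upsample_to, order=3, anti_aliasing=False)
    det = SIFT()
    try:
        det.detect_and_extract(a)
    except RuntimeError:  # no keypoints found
        return KeypointSet(np.empty((0, 2)), np.empty((0, 128), dtype=np.uint8))
    return KeypointSet(det.keypoints.astype(float), det.descriptors)


def detect_and_match(a, b, ratio: float = 0.75, upsample_a_to=None) -> tuple[np.ndarray, np.ndarray]:
    """Matched keypoint coordinate pairs between two slices.

    ``a`` may be upsampled to ``upsample_a_to`` (the shape of ``b``) first so
    both coordinate sets live on one grid.  Matching is descriptor
    nearest-neighbour with Lowe ratio test and mutual-nearest-neighbour
    (cross-check) filtering.  Returns ``(coords_a, coords_b)``, possibly
    empty.
    """
    ka = a if isinstance(a, KeypointSet) else detect_keypoints(a, upsample_to=upsample_a_to)
    kb = b if isinstance(b, KeypointSet) else detect_keypoints(b)
    if len(ka.coordinates) == 0 or len(kb.coordinates) == 0:
        return np.empty((0, 2)), np.empty((0, 2))
    m = match_descriptors(
        ka.descriptors, kb.descriptors, cross_check=True, max_ratio=ratio
    )
    return ka.coordinates[m[:, 0]], kb.coordinates[m[:, 1]]


def image_distance(a, b, ratio: float = 0.75, upsample_a_to=None) -> float:
    """Mean Euclidean distance between matched keypoint coordinates, or
    ``nan`` if fewer than ``MIN_MATCHES`` matches are found (the caller
    substitutes the sentinel when assembling a distance matrix)."""
    ca, cb = detect_and_match(a, b, ratio=ratio, upsample_a_to=upsample_a_to)
    if len(ca) < MIN_MATCHES:
        return float("nan")
    return float(np.linalg.norm(ca - cb, axis=1).mean())


def build_distance_matrix(mdct_stack, micro_stack, ratio: float = 0.75) -> np.ndarray:
    """All-pairs slice distance matrix (n_mdct x n_micro).

    Keypoints are detected once per slice (MDCT slices upsampled to the
    micro-CT in-plane grid) and matched for every pair.  Unmatched pairs
    receive the sentinel: the largest finite distance in the matrix plus 1.
    """
    mdct = mdct_stack.data if isinstance(mdct_stack, VoxelVolume) else np.asarray(mdct_stack)
    micro = micro_stack.data if isinstance(micro_stack, VoxelVolume) else np.asarray(micro_stack)
    if len(mdct) == 0 or len(micro) == 0:
        raise ValueError("empty stack")
    target = micro.shape[1:]
    kp_mdct = [detect_keypoints(s, upsample_to=target) for s in mdct]
    kp_micro = [detect_keypoints(s) for s in micro]
    d = np.full((len(mdct), len(micro)), np.nan)
    for i, ka in enumerate(kp_mdct):
        for j, kb in enumerate(kp_micro):
            ca, cb = detect_and_match(ka, kb, ratio=ratio)
            if len(ca) >= MIN_MATCHES:
                d[i, j] = np.linalg.norm(ca - cb, axis=1).mean()
    if np.isnan(d).all():
        d[:] = 1.0  # nothing matched anywhere: uninformative flat matrix
    else:
        d[np.isnan(d)] = np.nanmax(d) + 1.0
    return d


# ---------------------------------------------------------------------------
# dynamic time warping
# ---------------------------------------------------------------------------

@numba.njit(cache=True)
def _dtw_table(d):  # pragma: no cover - jitted
    n, m = d.shape
    acc = np.full((n, m), np.inf)
    step = np.zeros((n, m), dtype=np.int8)  # 0 diag, 1 left (0,1), 2 up (1,0)
    acc[0, 0] = d[0, 0]
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + d[0, j]
        step[0, j] = 1
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + d[i, 0]
        step[i, 0] = 2
        for j in range(1, m):
            # tie-break preference: diagonal, then (0,1), then (1,0)
            best = acc[i - 1, j - 1]
            s = 0
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
                s = 1
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
                s = 2
            acc[i, j] = best + d[i, j]
            step[i, j] = s
    return acc, step


def dtw_align(matrix) -> tuple[list, float]:
    """Minimal-cost monotone warping path through a distance matrix.

    Standard dynamic time warping with steps {(1,0), (0,1), (1,1)}; ties are
    broken preferring the diagonal step, then (0,1), then (1,0).  Returns
    ``(path, cost)`` where the path runs from (0,0) to (n-1, m-1).
    """
    d = np.ascontiguousarray(np.asarray(matrix, dtype=np.float64))
    if d.ndim != 2 or d.size == 0:
        raise ValueError("distance matrix must be 2-D and non-empty")
    if not np.isfinite(d).all() or (d < 0).any():
        raise ValueError("distance matrix must be finite and nonnegative")
    acc, step = _dtw_table(d)
    i, j = d.shape[0] - 1, d.shape[1] - 1
    path = [(i, j)]
    while (i, j) != (0, 0):
        s = step[i, j]
        if s == 0 and i > 0 and j > 0:
            i, j = i - 1, j - 1
        elif s == 1 and j > 0:
            j -= 1
        else:
            i -= 1
        path.append((i, j))
    path.reverse()
    return path, float(acc[-1, -1])


def replicate_and_pair(path, n_mdct: int, n_micro: int) -> list[tuple[int, int]]:
    """One (mdct_index, micro_index) pair per micro-CT slice.

    Every micro-CT index appears exactly once; its partner is the MDCT slice
    the warping path assigns it (the first path entry for that micro index),
    so MDCT slices are replicated wherever the path moves faster through the
    micro stack — e.g. 250 MDCT slices yield 500 pairs against 500 micro-CT
    slices.
    """
    first = {}
    for i, j in path:
        if j not in first:
            first[j] = i
    if len(first) != n_micro or max(first) != n_micro - 1:
        raise ValueError("path does not cover all micro-CT slices")
    return [(first[j], j) for j in range(n_micro)]


def pair_stacks(
    mdct_stack=None,
    micro_stack=None,
    distance_matrix=None,
    ratio: float = 0.75,
) -> PairingResult:
    """Full pairing pipeline: distance matrix (unless precomputed), DTW and
    2:1 replication."""
    if distance_matrix is None:
        distance_matrix = build_distance_matrix(mdct_stack, micro_stack, ratio=ratio)
    d = np.asarray(distance_matrix, dtype=float)
    path, cost = dtw_align(d)
    pairs = replicate_and_pair(path, d.shape[0], d.shape[1])
    return PairingResult(
        distance_matrix=d,
        path=path,
        pairs=pairs,
        replication_factor=int(round(d.shape[1] / d.shape[0])) if d.shape[0] else 0,
        meta={"dtw_cost": cost, "lowe_ratio": ratio, "mutual_nn": True},
    )
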