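"""Second-order texture statistics: run-length and co-occurrence features.

Two classical matrix statistics drive the feature vector:

* the gray-level run-length matrix (GLRLM) counts maximal runs of equal
  gray level along a scan direction — many short runs indicate fine
  texture, long runs coarse texture;
* the gray-level co-occurrence matrix (GLCM) is the joint distribution of
  gray-level pairs at a fixed displacement (distance ``d``, angle ``θ``).

Both are computed in the four principal directions (0°, 45°, 90°, 135°)
and every feature is averaged across directions, yielding a 12-dimensional
vector: six run-length emphasis descriptors (SRE, LRE, SRLGE, SRHGE,
LRLGE, LRHGE) and six co-occurrence measures (contrast, entropy, angular
second moment, homogeneity, variance, correlation).

Formula conventions
-------------------
Descriptors that divide by the gray-level index use 1-based indices
(``i = bin + 1``) so low-gray-emphasis terms are defined at bin 0.  The
run-percentage coefficient is ``nr / n_pixels`` (runs per pixel scanned).
Entropy uses the natural logarithm with ``0·log 0 = 0``.  Correlation is
the Pearson form with marginal means/SDs and is defined as 0 when either
marginal is degenerate (constant image).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import graycomatrix

from .image import GrayImage

DIRECTIONS = (0, 45, 90, 135)

#: skimage angle giving the conventional displacement for each direction:
#: 0° → (0, d), 45° → (−d, d), 90° → (−d, 0), 135° → (−d, −d)
_SKIMAGE_ANGLE = {0: 0.0, 45: -np.pi / 4, 90: -np.pi / 2, 135: -3 * np.pi / 4}

RLM_DESCRIPTOR_NAMES = (
    "SRE", "LRE", "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE",
    "GLNU", "RLNU", "RPC",
)
RLM_SELECTED = ("SRE", "LRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE")
GLCM_MEASURE_NAMES = (
    "contrast", "entropy", "angular_second_moment", "homogeneity",
    "variance", "correlation", "maximum_probability",
    "inverse_difference_moment", "cluster_tendency",
)
GLCM_SELECTED = ("contrast", "entropy", "angular_second_moment",
                 "homogeneity", "variance", "correlation")

#: Order of the 12 entries of the texture feature vector.
FEATURE_NAMES = RLM_SELECTED + GLCM_SELECTED


@dataclass(frozen=True)
class RunLengthMatrix:
    """Run counts ``p(i, j)`` (gray level i, run length j) for one direction."""

    counts: np.ndarray        # shape (G, N_max), integer counts
    direction: int            # degrees, one of DIRECTIONS
    n_pixels_scanned: int

    @property
    def nr(self) -> int:
        """Total number of runs."""
        return int(self.counts.sum())


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Normalized joint probabilities of gray-level pairs at one displacement."""

    probs: np.ndarray         # shape (G, G), sums to 1
    distance: int
    angle: int
    symmetric: bool


def _runs_of_line(line: np.ndarray, counts: np.ndarray) -> None:
    """Accumulate maximal-run counts of a 1-D gray-level sequence into counts."""
    n = line.size
    if n == 0:
        return
    # boundaries where the value changes split the line into maximal runs
    change = np.flatnonzero(np.diff(line) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [n]))
    for s, e in zip(starts, ends):
        counts[line[s], e - s - 1] += 1


def compute_glrlm(image: GrayImage, direction: int) -> RunLengthMatrix:
    """Compute the gray-level run-length matrix along one principal direction.

    Every maximal run of equal-valued consecutive pixels along the scan
    direction contributes one count to ``p(gray, length)``.  The run-length
    axis spans the maximum geometrically possible run for the direction
    (image width at 0°, height at 90°, the shorter side on the diagonals).
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    px = image.pixels
    rows, cols = px.shape
    if direction == 0:
        lines = list(px)
        max_len = cols
    elif direction == 90:
        lines = list(px.T)
        max_len = rows
    else:
        # 135°: down-right diagonals; 45°: up-right, i.e. down-right of the
        # left-right mirrored image (runs are direction-reversal invariant)
        diag_src = np.fliplr(px) if direction == 45 else px
        lines = [np.diagonal(diag_src, offset=k)
                 for k in range(-(rows - 1), cols)]
        max_len = min(rows, cols)
    counts = np.zeros((image.gray_levels, max_len), dtype=np.int64)
    for line in lines:
        _runs_of_line(np.ascontiguousarray(line), counts)
    return RunLengthMatrix(counts, direction, n_pixels_scanned=px.size)


def rlm_descriptors(rlm: RunLengthMatrix) -> dict[str, float]:
    """Evaluate all eleven run-length descriptors of one matrix.

    Gray-level index ``i`` and run-length index ``j`` are 1-based inside the
    emphasis formulas; every descriptor carries the ``1/nr`` prefactor.
    """
    nr = rlm.nr
    if nr == 0:
        raise ValueError("empty run-length matrix (nr = 0)")
    p = rlm.counts.astype(float)
    g, n = p.shape
    i = np.arange(1, g + 1, dtype=float)[:, None]
    j = np.arange(1, n + 1, dtype=float)[None, :]
    row_sums = p.sum(axis=1)
    col_sums = p.sum(axis=0)
    return {
        "SRE": float((p / j**2).sum() / nr),
        "LRE": float((p * j**2).sum() / nr),
        "LGRE": float((p / i**2).sum() / nr),
        "HGRE": float((p * i**2).sum() / nr),
        "SRLGE": float((p / (i**2 * j**2)).sum() / nr),
        "SRHGE": float((p * i**2 / j**2).sum() / nr),
        "LRLGE": float((p * j**2 / i**2).sum() / nr),
        "LRHGE": float((p * i**2 * j**2).sum() / nr),
        "GLNU": float((row_sums**2).sum() / nr),
        "RLNU": float((col_sums**2).sum() / nr),
        "RPC": float(nr / rlm.n_pixels_scanned),
    }


def compute_glcm(image: GrayImage, distance: int = 1, angle: int = 0,
                 symmetric: bool = True) -> CooccurrenceMatrix:
    """Compute the normalized co-occurrence matrix at one displacement.

    Counts ordered gray-level pairs at the stated (distance, angle)
    displacement — plus the opposite displacement when ``symmetric`` —
    normalized to sum to 1.
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    if angle not in DIRECTIONS:
        raise ValueError(f"angle must be one of {DIRECTIONS}, got {angle!r}")
    px = image.pixels
    if image.gray_levels > 256:
        raise ValueError("co-occurrence computation requires G <= 256")
    raw = graycomatrix(px.astype(np.uint8), [distance], [_SKIMAGE_ANGLE[angle]],
                       levels=image.gray_levels, symmetric=symmetric,
                       normed=False)[:, :, 0, 0].astype(float)
    total = raw.sum()
    if total == 0:
        raise ValueError("displacement exceeds image extent: no valid pixel pairs")
    return CooccurrenceMatrix(raw / total, distance, angle, symmetric)


def glcm_measures(glcm: CooccurrenceMatrix, idm_exponent: int = 2) -> dict[str, float]:
    """Evaluate the co-occurrence measures of one normalized matrix.

    Returns the six selected measures plus maximum probability, inverse
    difference moment (off-diagonal terms weighted by ``|i−j|^k``) and
    cluster tendency.
    """
    p = glcm.probs
    g = p.shape[0]
    i = np.arange(g, dtype=float)[:, None]
    j = np.arange(g, dtype=float)[None, :]
    pi = p.sum(axis=1)          # marginal over first pixel
    pj = p.sum(axis=0)
    levels = np.arange(g, dtype=float)
    mu_i = float(levels @ pi)
    mu_j = float(levels @ pj)
    var_i = float(((levels - mu_i) ** 2) @ pi)
    var_j = float(((levels - mu_j) ** 2) @ pj)

    nonzero = p[p > 0]
    entropy = float(-(nonzero * np.log(nonzero)).sum())
    contrast = float(((i - j) ** 2 * p).sum())
    asm = float((p**2).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    variance = 0.5 * float((((i - mu_i) ** 2 + (j - mu_j) ** 2) * p).sum())
    cov = float(((i - mu_i) * (j - mu_j) * p).sum())
    sd = np.sqrt(var_i * var_j)
    correlation = cov / sd if sd > 0 else 0.0

    off = np.abs(i - j) > 0
    idm = float((p[off] / (np.abs(i - j)[off] ** idm_exponent)).sum())
    cluster = float((((i - mu_i) + (j - mu_j)) ** 2 * p).sum())
    return {
        "contrast": contrast,
        "entropy": entropy,
        "angular_second_moment": asm,
        "homogeneity": homogeneity,
        "variance": variance,
        "correlation": correlation,
        "maximum_probability": float(p.max()),
        "inverse_difference_moment": idm,
        "cluster_tendency": cluster,
    }


def feature_vector(image: GrayImage, distance: int = 1,
                   symmetric: bool = True) -> dict[str, float]:
    """The 12-dimensional texture feature vector of one image.

    Each feature is the arithmetic mean of its per-direction value over
    0°, 45°, 90° and 135°: the six selected run-length descriptors followed
    by the six selected co-occurrence measures (order: FEATURE_NAMES).
    """
    acc = {name: 0.0 for name in FEATURE_NAMES}
    for direction in DIRECTIONS:
        rlm = rlm_descriptors(compute_glrlm(image, direction))
        glcm = glcm_measures(compute_glcm(image, distance, direction, symmetric))
        for name in RLM_SELECTED:
            acc[name] += rlm[name]
        for name in GLCM_SELECTED:
            acc[name] += glcm[name]
    return {name: value / len(DIRECTIONS) for name, value in acc.items()}
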