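"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain double loops over the matrix or image,
deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import math

import numpy as np

# conventional displacement (drow, dcol) of each principal direction
OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glrlm_loops(px: np.ndarray, gray_levels: int, direction: int) -> np.ndarray:
    """Maximal-run counts by explicit line walking."""
    rows, cols = px.shape
    if direction == 0:
        lines = [[px[r, c] for c in range(cols)] for r in range(rows)]
        max_len = cols
    elif direction == 90:
        lines = [[px[r, c] for r in range(rows)] for c in range(cols)]
        max_len = rows
    elif direction == 45:           # up-right diagonals
        lines = []
        for start_r in range(rows):
            line, r, c = [], start_r, 0
            while r >= 0 and c < cols:
                line.append(px[r, c])
                r, c = r - 1, c + 1
            lines.append(line)
        for start_c in range(1, cols):
            line, r, c = [], rows - 1, start_c
            while r >= 0 and c < cols:
                line.append(px[r, c])
                r, c = r - 1, c + 1
            lines.append(line)
        max_len = min(rows, cols)
    elif direction == 135:          # down-right diagonals
        lines = []
        for start_r in range(rows - 1, -1, -1):
            line, r, c = [], start_r, 0
            while r < rows and c < cols:
                line.append(px[r, c])
                r, c = r + 1, c + 1
            lines.append(line)
        for start_c in range(1, cols):
            line, r, c = [], 0, start_c
            while r < rows and c < cols:
                line.append(px[r, c])
                r, c = r + 1, c + 1
            lines.append(line)
        max_len = min(rows, cols)
    else:
        raise ValueError(direction)
    counts = np.zeros((gray_levels, max_len), dtype=np.int64)
    for line in lines:
        i = 0
        while i < len(line):
            j = i
            while j + 1 < len(line) and line[j + 1] == line[i]:
                j += 1
            counts[line[i], j - i] += 1
            i = j + 1
    return counts


def rlm_descriptors_loops(counts: np.ndarray, n_pixels: int) -> dict[str, float]:
    """All eleven run-length descriptors via explicit double loops, 1-based indices."""
    g, n = counts.shape
    nr = counts.sum()
    out = {k: 0.0 for k in ("SRE", "LRE", "LGRE", "HGRE", "SRLGE",
                            "SRHGE", "LRLGE", "LRHGE")}
    for gi in range(g):
        for rj in range(n):
            p = counts[gi, rj]
            if p == 0:
                continue
            i, j = gi + 1, rj + 1
            out["SRE"] += p / j**2
            out["LRE"] += p * j**2
            out["LGRE"] += p / i**2
            out["HGRE"] += p * i**2
            out["SRLGE"] += p / (i**2 * j**2)
            out["SRHGE"] += p * i**2 / j**2
            out["LRLGE"] += p * j**2 / i**2
            out["LRHGE"] += p * i**2 * j**2
    glnu = sum(sum(counts[gi, rj] for rj in range(n)) ** 2 for gi in range(g))
    rlnu = sum(sum(counts[gi, rj] for gi in range(g)) ** 2 for rj in range(n))
    out["GLNU"] = glnu
    out["RLNU"] = rlnu
    result = {k: v / nr for k, v in out.items()}
    result["RPC"] = nr / n_pixels
    return result


def glcm_loops(px: np.ndarray, gray_levels: int, distance: int, angle: int,
               symmetric: bool) -> np.ndarray:
    """Normalized pair counts by looping over every pixel and offset."""
    rows, cols = px.shape
    dr, dc = OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    counts = np.zeros((gray_levels, gray_levels), dtype=float)
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols:
                counts[px[r, c], px[r2, c2]] += 1
                if symmetric:
                    counts[px[r2, c2], px[r, c]] += 1
    total = counts.sum()
    return counts / total


def glcm_measures_loops(p: np.ndarray, idm_exponent: int = 2) -> dict[str, float]:
    """Co-occurrence measures via explicit double loops."""
    g = p.shape[0]
    mu_i = sum(i * p[i, j] for i in range(g) for j in range(g))
    mu_j = sum(j * p[i, j] for i in range(g) for j in range(g))
    var_i = sum((i - mu_i) ** 2 * p[i, j] for i in range(g) for j in range(g))
    var_j = sum((j - mu_j) ** 2 * p[i, j] for i in range(g) for j in range(g))
    out = {"contrast": 0.0, "entropy": 0.0, "angular_second_moment": 0.0,
           "homogeneity": 0.0, "variance": 0.0, "correlation": 0.0,
           "maximum_probability": 0.0, "inverse_difference_moment": 0.0,
           "cluster_tendency": 0.0}
    cov = 0.0
    for i in range(g):
        for j in range(g):
            q = p[i, j]
            out["contrast"] += (i - j) ** 2 * q
            if q > 0:
                out["entropy"] -= q * math.log(q)
            out["angular_second_moment"] += q * q
            out["homogeneity"] += q / (1 + abs(i - j))
            out["variance"] += 0.5 * ((i - mu_i) ** 2 + (j - mu_j) ** 2) * q
            cov += (i - mu_i) * (j - mu_j) * q
            out["maximum_probability"] = max(out["maximum_probability"], q)
            if i != j:
                out["inverse_difference_moment"] += q / abs(i - j) ** idm_exponent
            out["cluster_tendency"] += ((i - mu_i) + (j - mu_j)) ** 2 * q
    sd = math.sqrt(var_i * var_j)
    out["correlation"] = cov / sd if sd > 0 else 0.0
    return out


def mse_loops(targets: np.ndarray, outputs: np.ndarray) -> float:
    """Mean squared error by per-sample, per-output accumulation."""
    total, count = 0.0, 0
    for t_row, y_row in zip(targets, outputs):
        for t, y in zip(t_row, y_row):
            total += (t - y) ** 2
            count += 1
    return total / count
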