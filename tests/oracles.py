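"""Independent brute-force oracles used by the test suite.

Everything here is written as plain Python loops over pixels, pairs,
runs and zones, straight from the textbook definitions, deliberately
sharing no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np

OFFSETS = {"N": (-1, 0), "S": (1, 0), "E": (0, 1), "W": (0, -1)}


def glcm_pairs(levels: np.ndarray, mask: np.ndarray, direction: str) -> np.ndarray:
    """Exhaustive ordered-pair count matrix, normalized."""
    dr, dc = OFFSETS[direction]
    ng = int(levels[mask].max())
    counts = np.zeros((ng, ng))
    nrow, ncol = levels.shape
    for r in range(nrow):
        for c in range(ncol):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < nrow and 0 <= c2 < ncol and mask[r, c] and mask[r2, c2]:
                counts[levels[r, c] - 1, levels[r2, c2] - 1] += 1
    total = counts.sum()
    return counts / total if total else counts


def glcm_feature_oracle(P: np.ndarray) -> dict[str, float]:
    """Haralick-style descriptor formulas evaluated by explicit loops."""
    ng = P.shape[0]
    px = [sum(P[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(P[i, j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    sd_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng)))
    sd_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng)))
    p_sum: dict[int, float] = {}
    p_diff: dict[int, float] = {}
    out = dict.fromkeys(
        [
            "glcm_asm", "glcm_autocorrelation", "glcm_cluster_prominence",
            "glcm_cluster_shade", "glcm_contrast", "glcm_correlation",
            "glcm_diff_average", "glcm_diff_entropy", "glcm_diff_variance",
            "glcm_entropy", "glcm_idm", "glcm_imc1", "glcm_imc2",
            "glcm_inverse_diff", "glcm_inverse_diff_norm", "glcm_joint_average",
            "glcm_joint_max", "glcm_mcc", "glcm_sum_average", "glcm_sum_entropy",
            "glcm_sum_squares", "glcm_sum_variance",
        ],
        0.0,
    )
    for i in range(ng):
        for j in range(ng):
            p = P[i, j]
            a, b = i + 1, j + 1
            out["glcm_asm"] += p * p
            out["glcm_contrast"] += (a - b) ** 2 * p
            out["glcm_autocorrelation"] += a * b * p
            out["glcm_sum_squares"] += (a - mu_x) ** 2 * p
            out["glcm_idm"] += p / (1 + (a - b) ** 2)
            out["glcm_inverse_diff"] += p / (1 + abs(a - b))
            out["glcm_inverse_diff_norm"] += p / (1 + abs(a - b) / ng)
            out["glcm_joint_average"] += a * p
            out["glcm_cluster_shade"] += (a + b - mu_x - mu_y) ** 3 * p
            out["glcm_cluster_prominence"] += (a + b - mu_x - mu_y) ** 4 * p
            if p > 0:
                out["glcm_entropy"] -= p * math.log2(p)
            p_sum[a + b] = p_sum.get(a + b, 0.0) + p
            p_diff[abs(a - b)] = p_diff.get(abs(a - b), 0.0) + p
    out["glcm_joint_max"] = float(P.max())
    if sd_x > 0 and sd_y > 0:
        out["glcm_correlation"] = (
            out["glcm_autocorrelation"] - mu_x * mu_y
        ) / (sd_x * sd_y)
    sa = sum(k * v for k, v in p_sum.items())
    out["glcm_sum_average"] = sa
    out["glcm_sum_variance"] = sum((k - sa) ** 2 * v for k, v in p_sum.items())
    out["glcm_sum_entropy"] = -sum(v * math.log2(v) for v in p_sum.values() if v > 0)
    da = sum(k * v for k, v in p_diff.items())
    out["glcm_diff_average"] = da
    out["glcm_diff_variance"] = sum((k - da) ** 2 * v for k, v in p_diff.items())
    out["glcm_diff_entropy"] = -sum(v * math.log2(v) for v in p_diff.values() if v > 0)
    hx = -sum(v * math.log2(v) for v in px if v > 0)
    hy = -sum(v * math.log2(v) for v in py if v > 0)
    hxy1 = hxy2 = 0.0
    for i in range(ng):
        for j in range(ng):
            q = px[i] * py[j]
            if q > 0:
                hxy1 -= P[i, j] * math.log2(q)
                hxy2 -= q * math.log2(q)
    denom = max(hx, hy)
    out["glcm_imc1"] = (out["glcm_entropy"] - hxy1) / denom if denom > 0 else 0.0
    out["glcm_imc2"] = math.sqrt(
        max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - out["glcm_entropy"])))
    )
    rows = [i for i in range(ng) if px[i] > 0]
    cols = [j for j in range(ng) if py[j] > 0]
    if len(rows) >= 2 and len(cols) >= 2:
        Q = np.zeros((len(rows), len(rows)))
        for a_idx, i in enumerate(rows):
            for b_idx, j in enumerate(rows):
                Q[a_idx, b_idx] = sum(
                    P[i, k] * P[j, k] / (px[i] * py[k]) for k in cols
                )
        eig = sorted(abs(np.linalg.eigvals(Q)))
        out["glcm_mcc"] = math.sqrt(min(max(eig[-2], 0.0), 1.0))
    return out


def runs_in_direction(
    levels: np.ndarray, mask: np.ndarray, direction: str
) -> list[tuple[int, int]]:
    """All maximal constant-level in-mask runs as (level, length) tuples."""
    if direction in ("N", "S"):
        levels, mask = levels.T, mask.T
    runs = []
    for row_lvl, row_mask in zip(levels, mask):
        lvl, length = None, 0
        for v, m in zip(row_lvl, row_mask):
            if not m:
                if length:
                    runs.append((lvl, length))
                lvl, length = None, 0
            elif v == lvl:
                length += 1
            else:
                if length:
                    runs.append((lvl, length))
                lvl, length = int(v), 1
        if length:
            runs.append((lvl, length))
    return runs


def glrlm_feature_oracle(runs: list[tuple[int, int]], n_pixels: int) -> dict[str, float]:
    nr = len(runs)
    mu_i = sum(i for i, _ in runs) / nr
    mu_j = sum(j for _, j in runs) / nr
    counts: dict[tuple[int, int], int] = {}
    for run in runs:
        counts[run] = counts.get(run, 0) + 1
    gray: dict[int, int] = {}
    length: dict[int, int] = {}
    for i, j in runs:
        gray[i] = gray.get(i, 0) + 1
        length[j] = length.get(j, 0) + 1
    return {
        "glrlm_sre": sum(1 / j**2 for _, j in runs) / nr,
        "glrlm_lre": sum(j**2 for _, j in runs) / nr,
        "glrlm_glnu": sum(v**2 for v in gray.values()) / nr,
        "glrlm_glnu_norm": sum(v**2 for v in gray.values()) / nr**2,
        "glrlm_rlnu": sum(v**2 for v in length.values()) / nr,
        "glrlm_rlnu_norm": sum(v**2 for v in length.values()) / nr**2,
        "glrlm_rp": nr / n_pixels,
        "glrlm_lgre": sum(1 / i**2 for i, _ in runs) / nr,
        "glrlm_hgre": sum(i**2 for i, _ in runs) / nr,
        "glrlm_srlge": sum(1 / (i**2 * j**2) for i, j in runs) / nr,
        "glrlm_srhge": sum(i**2 / j**2 for i, j in runs) / nr,
        "glrlm_lrlge": sum(j**2 / i**2 for i, j in runs) / nr,
        "glrlm_lrhge": sum(i**2 * j**2 for i, j in runs) / nr,
        "glrlm_glv": sum((i - mu_i) ** 2 for i, _ in runs) / nr,
        "glrlm_rlv": sum((j - mu_j) ** 2 for _, j in runs) / nr,
        "glrlm_run_entropy": -sum(
            (v / nr) * math.log2(v / nr) for v in counts.values()
        ),
    }


def flood_fill_zones(levels: np.ndarray, mask: np.ndarray) -> list[tuple[int, int]]:
    """8-connected equal-level zones of masked pixels as (level, size) tuples."""
    nrow, ncol = levels.shape
    seen = np.zeros_like(mask, dtype=bool)
    zones = []
    for r0 in range(nrow):
        for c0 in range(ncol):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            lvl = int(levels[r0, c0])
            stack, size = [(r0, c0)], 0
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        r2, c2 = r + dr, c + dc
                        if (
                            0 <= r2 < nrow
                            and 0 <= c2 < ncol
                            and mask[r2, c2]
                            and not seen[r2, c2]
                            and levels[r2, c2] == lvl
                        ):
                            seen[r2, c2] = True
                            stack.append((r2, c2))
            zones.append((lvl, size))
    return zones


def glszm_feature_oracle(zones: list[tuple[int, int]], n_pixels: int) -> dict[str, float]:
    nz = len(zones)
    mu_i = sum(i for i, _ in zones) / nz
    mu_s = sum(s for _, s in zones) / nz
    counts: dict[tuple[int, int], int] = {}
    for z in zones:
        counts[z] = counts.get(z, 0) + 1
    gray: dict[int, int] = {}
    size: dict[int, int] = {}
    for i, s in zones:
        gray[i] = gray.get(i, 0) + 1
        size[s] = size.get(s, 0) + 1
    return {
        "glszm_sze": sum(1 / s**2 for _, s in zones) / nz,
        "glszm_lze": sum(s**2 for _, s in zones) / nz,
        "glszm_lgze": sum(1 / i**2 for i, _ in zones) / nz,
        "glszm_hgze": sum(i**2 for i, _ in zones) / nz,
        "glszm_szlge": sum(1 / (i**2 * s**2) for i, s in zones) / nz,
        "glszm_szhge": sum(i**2 / s**2 for i, s in zones) / nz,
        "glszm_lzlge": sum(s**2 / i**2 for i, s in zones) / nz,
        "glszm_lzhge": sum(i**2 * s**2 for i, s in zones) / nz,
        "glszm_glnu": sum(v**2 for v in gray.values()) / nz,
        "glszm_glnu_norm": sum(v**2 for v in gray.values()) / nz**2,
        "glszm_zsnu": sum(v**2 for v in size.values()) / nz,
        "glszm_zsnu_norm": sum(v**2 for v in size.values()) / nz**2,
        "glszm_zp": nz / n_pixels,
        "glszm_glzv": sum((i - mu_i) ** 2 for i, _ in zones) / nz,
        "glszm_zsv": sum((s - mu_s) ** 2 for _, s in zones) / nz,
        "glszm_zse": -sum((v / nz) * math.log2(v / nz) for v in counts.values()),
    }


def lbp_code_oracle(image: np.ndarray, mask: np.ndarray) -> list[int]:
    """Brute-force LBP codes of masked pixels with all 8 neighbors masked."""
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]
    nrow, ncol = image.shape
    codes = []
    for r in range(nrow):
        for c in range(ncol):
            if not mask[r, c]:
                continue
            neighbors = []
            ok = True
            for dr, dc in offsets:
                r2, c2 = r + dr, c + dc
                if not (0 <= r2 < nrow and 0 <= c2 < ncol and mask[r2, c2]):
                    ok = False
                    break
                neighbors.append(image[r2, c2])
            if not ok:
                continue
            code = 0
            for bit, v in enumerate(neighbors):
                if v >= image[r, c]:
                    code |= 1 << bit
            codes.append(code)
    return codes


def bh_fdr_oracle(p_values: list[float]) -> list[float]:
    """Adjusted p-values by explicit min-over-suffix of m*p/rank."""
    m = len(p_values)
    order = sorted(range(m), key=lambda k: p_values[k])
    adjusted = [0.0] * m
    for pos, idx in enumerate(order):
        candidates = [
            m * p_values[order[later]] / (later + 1) for later in range(pos, m)
        ]
        adjusted[idx] = min(1.0, min(candidates))
    return adjusted
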