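"""Gray-level co-occurrence, run-length and size-zone descriptors.

All three matrices are built strictly inside the mask: a pixel pair
contributes to the GLCM only when both pixels are masked, runs are
broken at mask boundaries, and zones are connected components of masked
pixels.  GLCM and GLRLM use the four unit offsets N, S, E, W (1-pixel
offset); descriptors are computed per direction and averaged.  GLSZM
zones use 8-connectivity.

Descriptor formulas follow the standard Haralick (GLCM), Galloway /
Chu / Dasarathy-extended (GLRLM) and Thibault (GLSZM) reference
definitions; entropies use log base 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DegenerateROIError
from .feature_names import GLCM, GLRLM, GLSZM
from .quantize import QuantizedROI

#: Unit pixel offsets (row, col) for the four directions.
DIRECTIONS = {"N": (-1, 0), "S": (1, 0), "E": (0, 1), "W": (0, -1)}


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Normalized Ng x Ng joint gray-level pair frequencies for one direction."""

    P: np.ndarray = field(repr=False)
    direction: str
    n_pairs: int


def build_glcm(q: QuantizedROI, direction: str) -> CooccurrenceMatrix:
    """Count ordered level pairs (p, p + d) with both pixels masked; normalize."""
    dr, dc = DIRECTIONS[direction]
    levels, mask = q.levels, q.mask
    nrow, ncol = levels.shape
    r0, r1 = max(0, -dr), min(nrow, nrow - dr)
    c0, c1 = max(0, -dc), min(ncol, ncol - dc)
    a = levels[r0:r1, c0:c1]
    b = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    ai = a[valid] - 1
    bi = b[valid] - 1
    n_pairs = ai.size
    if n_pairs == 0:
        raise DegenerateROIError(f"no valid pixel pair in direction {direction}")
    counts = np.bincount(ai * q.Ng + bi, minlength=q.Ng * q.Ng).reshape(q.Ng, q.Ng)
    return CooccurrenceMatrix(
        P=counts / n_pairs, direction=direction, n_pairs=int(n_pairs)
    )


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _glcm_mcc(P: np.ndarray) -> float:
    # Second-largest eigenvalue of the Q matrix (square-rooted), restricted
    # to occupied rows/columns; rank < 2 -> 0 by convention.
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    rows = np.where(px > 0)[0]
    cols = np.where(py > 0)[0]
    if rows.size < 2 or cols.size < 2:
        return 0.0
    Psub = P[np.ix_(rows, cols)]
    W = Psub / py[cols]  # P(i,k) / py(k)
    Q = (Psub / px[rows, None]) @ W.T
    eig = np.sort(np.abs(np.linalg.eigvals(Q)))
    lam2 = float(eig[-2])
    return float(np.sqrt(min(max(lam2, 0.0), 1.0)))


def glcm_features_from_matrix(P: np.ndarray) -> dict[str, float]:
    """The 22 Haralick-style descriptors of one normalized co-occurrence matrix."""
    Ng = P.shape[0]
    i = np.arange(1, Ng + 1)
    I = i[:, None].astype(float)
    J = i[None, :].astype(float)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    sd_x = float(np.sqrt(np.sum((i - mu_x) ** 2 * px)))
    sd_y = float(np.sqrt(np.sum((i - mu_y) ** 2 * py)))

    # diagonal / cross-diagonal marginals
    k_sum = np.arange(2, 2 * Ng + 1)
    p_sum = np.zeros(k_sum.size)
    k_diff = np.arange(0, Ng)
    p_diff = np.zeros(k_diff.size)
    sums = (I + J).astype(int)
    diffs = np.abs(I - J).astype(int)
    np.add.at(p_sum, (sums - 2).ravel(), P.ravel())
    np.add.at(p_diff, diffs.ravel(), P.ravel())

    asm = float(np.sum(P**2))
    contrast = float(np.sum((I - J) ** 2 * P))
    autocorr = float(np.sum(I * J * P))
    if sd_x > 0 and sd_y > 0:
        correlation = (autocorr - mu_x * mu_y) / (sd_x * sd_y)
    else:
        correlation = 0.0
    sum_sq = float(np.sum((I - mu_x) ** 2 * P))
    idm = float(np.sum(P / (1.0 + (I - J) ** 2)))
    inv_diff = float(np.sum(P / (1.0 + np.abs(I - J))))
    inv_diff_norm = float(np.sum(P / (1.0 + np.abs(I - J) / Ng)))
    sum_avg = float(np.sum(k_sum * p_sum))
    sum_var = float(np.sum((k_sum - sum_avg) ** 2 * p_sum))
    sum_entropy = float(-np.sum(_xlog2(p_sum)))
    entropy = float(-np.sum(_xlog2(P)))
    diff_avg = float(np.sum(k_diff * p_diff))
    diff_var = float(np.sum((k_diff - diff_avg) ** 2 * p_diff))
    diff_entropy = float(-np.sum(_xlog2(p_diff)))

    hx = float(-np.sum(_xlog2(px)))
    hy = float(-np.sum(_xlog2(py)))
    pxpy = px[:, None] * py[None, :]
    log_pxpy = np.zeros_like(pxpy)
    nz = pxpy > 0
    log_pxpy[nz] = np.log2(pxpy[nz])
    hxy1 = float(-np.sum(P * log_pxpy))
    hxy2 = float(-np.sum(pxpy[nz] * log_pxpy[nz]))
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    cluster = I + J - mu_x - mu_y
    out = {
        "glcm_asm": asm,
        "glcm_autocorrelation": autocorr,
        "glcm_cluster_prominence": float(np.sum(cluster**4 * P)),
        "glcm_cluster_shade": float(np.sum(cluster**3 * P)),
        "glcm_contrast": contrast,
        "glcm_correlation": float(correlation),
        "glcm_diff_average": diff_avg,
        "glcm_diff_entropy": diff_entropy,
        "glcm_diff_variance": diff_var,
        "glcm_entropy": entropy,
        "glcm_idm": idm,
        "glcm_imc1": float(imc1),
        "glcm_imc2": imc2,
        "glcm_inverse_diff": inv_diff,
        "glcm_inverse_diff_norm": inv_diff_norm,
        "glcm_joint_average": mu_x,
        "glcm_joint_max": float(P.max()),
        "glcm_mcc": _glcm_mcc(P),
        "glcm_sum_average": sum_avg,
        "glcm_sum_entropy": sum_entropy,
        "glcm_sum_squares": sum_sq,
        "glcm_sum_variance": sum_var,
    }
    assert list(out) == GLCM
    return out


def glcm_features(q: QuantizedROI) -> dict[str, float]:
    """4-direction average of the 22 GLCM descriptors (degenerate directions skipped)."""
    per_direction = []
    for direction in DIRECTIONS:
        try:
            cm = build_glcm(q, direction)
        except DegenerateROIError:
            continue
        per_direction.append(glcm_features_from_matrix(cm.P))
    if not per_direction:
        raise DegenerateROIError("all four GLCM directions are degenerate")
    return {
        name: float(np.mean([d[name] for d in per_direction])) for name in GLCM
    }


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunLengthMatrix:
    """Run counts R[level-1, length-1] for one direction."""

    R: np.ndarray = field(repr=False)
    direction: str
    n_runs: int
    n_pixels: int


def _scan_runs(line_levels: np.ndarray, line_mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal constant-level runs (level, length) of one scan line; runs break at mask gaps."""
    runs: list[tuple[int, int]] = []
    current_level = 0
    current_len = 0
    for lvl, inside in zip(line_levels, line_mask):
        if not inside:
            if current_len:
                runs.append((int(current_level), current_len))
            current_level, current_len = 0, 0
        elif lvl == current_level:
            current_len += 1
        else:
            if current_len:
                runs.append((int(current_level), current_len))
            current_level, current_len = int(lvl), 1
    if current_len:
        runs.append((int(current_level), current_len))
    return runs


def build_glrlm(q: QuantizedROI, direction: str) -> RunLengthMatrix:
    """Decompose in-mask scan lines into maximal constant-level runs."""
    levels, mask = q.levels, q.mask
    if direction in ("N", "S"):
        levels, mask = levels.T, mask.T
    max_len = levels.shape[1]
    R = np.zeros((q.Ng, max_len), dtype=np.int64)
    for row_levels, row_mask in zip(levels, mask):
        for lvl, length in _scan_runs(row_levels, row_mask):
            R[lvl - 1, length - 1] += 1
    return RunLengthMatrix(
        R=R, direction=direction, n_runs=int(R.sum()), n_pixels=q.n_masked
    )


def glrlm_features_from_matrix(R: np.ndarray, n_pixels: int) -> dict[str, float]:
    """The 16 run-length descriptors of one run-count matrix."""
    Nr = float(R.sum())
    Ng, Lmax = R.shape
    i = np.arange(1, Ng + 1, dtype=float)[:, None]
    j = np.arange(1, Lmax + 1, dtype=float)[None, :]
    r = R.astype(float)
    r_g = r.sum(axis=1)  # per gray level
    r_l = r.sum(axis=0)  # per run length
    p = r / Nr
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    nzp = p[p > 0]
    out = {
        "glrlm_glnu": float(np.sum(r_g**2) / Nr),
        "glrlm_glnu_norm": float(np.sum(r_g**2) / Nr**2),
        "glrlm_glv": float(np.sum((i - mu_i) ** 2 * p)),
        "glrlm_hgre": float(np.sum(r * i**2) / Nr),
        "glrlm_lgre": float(np.sum(r / i**2) / Nr),
        "glrlm_lre": float(np.sum(r * j**2) / Nr),
        "glrlm_lrhge": float(np.sum(r * i**2 * j**2) / Nr),
        "glrlm_lrlge": float(np.sum(r * j**2 / i**2) / Nr),
        "glrlm_rlnu": float(np.sum(r_l**2) / Nr),
        "glrlm_rlnu_norm": float(np.sum(r_l**2) / Nr**2),
        "glrlm_rlv": float(np.sum((j - mu_j) ** 2 * p)),
        "glrlm_rp": float(Nr / n_pixels),
        "glrlm_run_entropy": float(-np.sum(nzp * np.log2(nzp))),
        "glrlm_sre": float(np.sum(r / j**2) / Nr),
        "glrlm_srhge": float(np.sum(r * i**2 / j**2) / Nr),
        "glrlm_srlge": float(np.sum(r / (i**2 * j**2)) / Nr),
    }
    assert list(out) == GLRLM
    return out


def glrlm_features(q: QuantizedROI) -> dict[str, float]:
    """4-direction average of the 16 GLRLM descriptors."""
    per_direction = []
    for direction in DIRECTIONS:
        rm = build_glrlm(q, direction)
        per_direction.append(glrlm_features_from_matrix(rm.R, rm.n_pixels))
    return {
        name: float(np.mean([d[name] for d in per_direction])) for name in GLRLM
    }


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

_CONN8 = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class SizeZoneMatrix:
    """Zone counts Z[level-1, size-1]; zones are 8-connected equal-level components."""

    Z: np.ndarray = field(repr=False)
    n_zones: int
    n_pixels: int


def build_glszm(q: QuantizedROI) -> SizeZoneMatrix:
    """Count 8-connected equal-level zones of masked pixels by level and size."""
    n_pixels = q.n_masked
    Z = np.zeros((q.Ng, n_pixels), dtype=np.int64)
    present = np.unique(q.levels[q.mask])
    for lvl in present:
        labeled, n_comp = ndimage.label(q.levels == lvl, structure=_CONN8)
        if n_comp == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        for s in sizes:
            Z[lvl - 1, s - 1] += 1
    return SizeZoneMatrix(Z=Z, n_zones=int(Z.sum()), n_pixels=n_pixels)


def glszm_features_from_matrix(Z: np.ndarray, n_pixels: int) -> dict[str, float]:
    """The 16 size-zone descriptors of one zone-count matrix."""
    Nz = float(Z.sum())
    Ng, Smax = Z.shape
    i = np.arange(1, Ng + 1, dtype=float)[:, None]
    s = np.arange(1, Smax + 1, dtype=float)[None, :]
    z = Z.astype(float)
    z_g = z.sum(axis=1)
    z_s = z.sum(axis=0)
    p = z / Nz
    mu_i = float(np.sum(i * p))
    mu_s = float(np.sum(s * p))
    nzp = p[p > 0]
    out = {
        "glszm_glnu": float(np.sum(z_g**2) / Nz),
        "glszm_glnu_norm": float(np.sum(z_g**2) / Nz**2),
        "glszm_glzv": float(np.sum((i - mu_i) ** 2 * p)),
        "glszm_hgze": float(np.sum(z * i**2) / Nz),
        "glszm_lgze": float(np.sum(z / i**2) / Nz),
        "glszm_lze": float(np.sum(z * s**2) / Nz),
        "glszm_lzhge": float(np.sum(z * i**2 * s**2) / Nz),
        "glszm_lzlge": float(np.sum(z * s**2 / i**2) / Nz),
        "glszm_sze": float(np.sum(z / s**2) / Nz),
        "glszm_szhge": float(np.sum(z * i**2 / s**2) / Nz),
        "glszm_szlge": float(np.sum(z / (i**2 * s**2)) / Nz),
        "glszm_zp": float(Nz / n_pixels),
        "glszm_zse": float(-np.sum(nzp * np.log2(nzp))),
        "glszm_zsnu": float(np.sum(z_s**2) / Nz),
        "glszm_zsnu_norm": float(np.sum(z_s**2) / Nz**2),
        "glszm_zsv": float(np.sum((s - mu_s) ** 2 * p)),
    }
    assert list(out) == GLSZM
    return out


def glszm_features(q: QuantizedROI) -> dict[str, float]:
    """The 16 GLSZM descriptors of one quantized ROI."""
    zm = build_glszm(q)
    return glszm_features_from_matrix(zm.Z, zm.n_pixels)
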