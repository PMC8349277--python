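"""Independent brute-force oracles used by the unit and acceptance suites.

These deliberately use naive enumeration / literal formula transcription and
share no code with the package implementation they check.
"""

from __future__ import annotations

import math

import numpy as np


def otsu_by_exhaustive_search(data: np.ndarray, bins: int) -> float:
    """Maximize between-class variance over every histogram cut by brute force."""
    counts, edges = np.histogram(data, bins=bins, range=(data.min(), data.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_var, best_cut = -1.0, None
    for cut in range(1, bins):  # class 0 = bins [0, cut), class 1 = [cut, bins)
        n0 = counts[:cut].sum()
        n1 = counts[cut:].sum()
        if n0 == 0 or n1 == 0:
            var = 0.0
        else:
            m0 = (counts[:cut] * centers[:cut]).sum() / n0
            m1 = (counts[cut:] * centers[cut:]).sum() / n1
            var = n0 * n1 * (m0 - m1) ** 2
        if var > best_var + 1e-12:
            best_var, best_cut = var, cut
    return float(edges[best_cut])


def glcm_by_pair_enumeration(
    image: np.ndarray,
    mask: np.ndarray,
    distance: int,
    theta: int,
    gray_levels: int,
    symmetric: bool,
) -> np.ndarray:
    """Count co-occurring quantized pairs one pixel at a time."""
    vals = image[mask]
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        q = np.zeros_like(image, dtype=int)
    else:
        q = np.minimum(
            (np.floor((image - lo) / (hi - lo) * gray_levels)).astype(int), gray_levels - 1
        )
    offsets = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
    dr, dc = offsets[theta % 180]
    dr, dc = dr * distance, dc * distance
    counts = np.zeros((gray_levels, gray_levels))
    h, w = image.shape
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                counts[q[r, c], q[r2, c2]] += 1
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def haralick_by_literal_formulas(p: np.ndarray) -> dict[str, float]:
    """The 13 Haralick statistics transcribed as explicit double loops."""
    g = p.shape[0]
    px = [sum(p[i][j] for j in range(g)) for i in range(g)]
    py = [sum(p[i][j] for i in range(g)) for j in range(g)]
    mu_x = sum(i * px[i] for i in range(g))
    mu_y = sum(j * py[j] for j in range(g))
    sd_x = math.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(g)))
    sd_y = math.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(g)))
    p_sum = [0.0] * (2 * g - 1)
    p_diff = [0.0] * g
    for i in range(g):
        for j in range(g):
            p_sum[i + j] += p[i][j]
            p_diff[abs(i - j)] += p[i][j]

    def ent(vals):
        return -sum(v * math.log(v) for v in vals if v > 0)

    out = {}
    out["asm"] = sum(p[i][j] ** 2 for i in range(g) for j in range(g))
    out["contrast"] = sum((i - j) ** 2 * p[i][j] for i in range(g) for j in range(g))
    if sd_x > 0 and sd_y > 0:
        out["correlation"] = (
            sum((i - mu_x) * (j - mu_y) * p[i][j] for i in range(g) for j in range(g))
            / (sd_x * sd_y)
        )
    else:
        out["correlation"] = 0.0
    out["variance"] = sum((i - mu_x) ** 2 * p[i][j] for i in range(g) for j in range(g))
    out["idm"] = sum(p[i][j] / (1 + (i - j) ** 2) for i in range(g) for j in range(g))
    out["sum_average"] = sum(k * p_sum[k] for k in range(2 * g - 1))
    out["sum_variance"] = sum(
        (k - out["sum_average"]) ** 2 * p_sum[k] for k in range(2 * g - 1)
    )
    out["sum_entropy"] = ent(p_sum)
    out["entropy"] = ent([p[i][j] for i in range(g) for j in range(g)])
    mu_d = sum(k * p_diff[k] for k in range(g))
    out["difference_variance"] = sum((k - mu_d) ** 2 * p_diff[k] for k in range(g))
    out["difference_entropy"] = ent(p_diff)
    hxy = out["entropy"]
    hxy1 = -sum(
        p[i][j] * math.log(px[i] * py[j])
        for i in range(g)
        for j in range(g)
        if p[i][j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * math.log(px[i] * py[j])
        for i in range(g)
        for j in range(g)
        if px[i] * py[j] > 0
    )
    hx, hy = ent(px), ent(py)
    out["imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    out["imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    return out


def decision_template_scores_by_frobenius(profile, templates) -> list[float]:
    """score_w = 1 - ||DP - T_w||_F^2 / (L*c), written out elementwise."""
    L = len(profile)
    c = len(profile[0])
    scores = []
    for T in templates:
        d2 = 0.0
        for l in range(L):
            for k in range(c):
                d2 += (profile[l][k] - T[l][k]) ** 2
        scores.append(1.0 - d2 / (L * c))
    return scores


def gabor_energy_by_double_loop(roi, mask, kernel, mean_abs=True) -> float:
    """Mean-subtracted reflect-padded convolution and |.| accumulation,
    written as explicit loops."""
    roi = np.asarray(roi, dtype=float)
    masked_mean = roi[mask].mean()
    centered = roi - masked_mean
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    # edge-repeating reflection, i.e. (d c b a | a b c d)
    padded = np.pad(centered, ((ph, ph), (pw, pw)), mode="symmetric")
    total, count = 0.0, 0
    h, w = roi.shape
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            acc = 0.0
            for dr in range(kh):
                for dc in range(kw):
                    # correlation with the flipped kernel = convolution
                    acc += padded[r + dr, c + dc] * kernel[kh - 1 - dr, kw - 1 - dc]
            total += abs(acc)
            count += 1
    return total / count if mean_abs else total
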