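"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most direct route available —
explicit loops, exhaustive enumeration, from-scratch definitions — so it
shares no code path with the implementation it checks.
"""

from __future__ import annotations

import numpy as np


def brute_force_color_distance(bins_a, bins_b, dialect: str = "squared") -> float:
    """Loop over bins and channels summing squared differences."""
    total = 0.0
    for i in range(len(bins_a)):
        for ch in range(3):
            diff = bins_a[i][ch] - bins_b[i][ch]
            total += diff * diff
    return float(np.sqrt(total)) if dialect == "euclidean" else total


def ess(points: np.ndarray) -> float:
    """Error sum of squares of a point set about its centroid."""
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    return float(np.sum((pts - centroid) ** 2))


def ward_ess_agglomeration(points: np.ndarray):
    """From-scratch Ward agglomeration computed from coordinates.

    At every step, for every candidate cluster pair, recompute the ESS
    increment ESS(a ∪ b) - ESS(a) - ESS(b) from the original points and
    merge the minimum; ties go to the lexicographically smallest pair of
    node ids.  Node ids follow the leaves-then-internal convention.
    Returns merges as (left, right, height, size) with height = 2 x ESS
    increment (the Ward distance of the merged pair).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = len(pts)
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = []
    for m in range(n - 1):
        ids = sorted(clusters)
        best, best_inc = None, np.inf
        for ii, i in enumerate(ids):
            for j in ids[ii + 1:]:
                inc = (ess(pts[clusters[i] + clusters[j]])
                       - ess(pts[clusters[i]]) - ess(pts[clusters[j]]))
                if inc < best_inc:
                    best_inc, best = inc, (i, j)
        i, j = best
        merges.append((i, j, 2.0 * best_inc,
                       len(clusters[i]) + len(clusters[j])))
        clusters[n + m] = clusters.pop(i) + clusters.pop(j)
    return merges


def single_linkage_agglomeration(dist: np.ndarray):
    """Brute-force single linkage: inter-cluster distance is the minimum
    pairwise leaf distance, recomputed from the original matrix each step."""
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = []
    for m in range(n - 1):
        ids = sorted(clusters)
        best, best_d = None, np.inf
        for ii, i in enumerate(ids):
            for j in ids[ii + 1:]:
                d = min(D[a, b] for a in clusters[i] for b in clusters[j])
                if d < best_d:
                    best_d, best = d, (i, j)
        i, j = best
        merges.append((i, j, best_d, len(clusters[i]) + len(clusters[j])))
        clusters[n + m] = clusters.pop(i) + clusters.pop(j)
    return merges


def lca_cophenetic(merges, n: int) -> np.ndarray:
    """Cophenetic distances by explicit lowest-common-ancestor search."""

    def leaves_under(node):
        if node < n:
            return {node}
        li, ri, _, _ = merges[node - n]
        return leaves_under(li) | leaves_under(ri)

    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            # lowest merge whose leaf set contains both
            for m, (li, ri, h, _) in enumerate(merges):
                under = leaves_under(n + m)
                if a in under and b in under:
                    out[a, b] = out[b, a] = h
                    break
    return out


def is_ultrametric(mat: np.ndarray, rtol: float = 1e-9) -> bool:
    """Max over every triple attained at least twice (within tolerance)."""
    M = np.asarray(mat, dtype=float)
    n = M.shape[0]
    tol = rtol * max(1.0, float(M.max()))
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                trip = sorted([M[i, j], M[i, k], M[j, k]])
                if trip[2] - trip[1] > tol:
                    return False
    return True


def cmf_integration_rgb8_1nm(center_nm, width_nm, amplitude, baseline):
    """Direct 1 nm numerical integration oracle for spectrum rendering.

    Linearly interpolates the 10 nm CIE table to a 1 nm grid and integrates
    there; shares only the published data table with the implementation,
    not its integration path.
    """
    from phagesensor.colorimetry import (
        CIE_WAVELENGTHS_NM, CIE_XYZ_CMF, XYZ_TO_LINEAR_SRGB,
    )

    lam = np.arange(380.0, 780.0 + 0.5, 1.0)
    cmf = np.column_stack([
        np.interp(lam, CIE_WAVELENGTHS_NM, CIE_XYZ_CMF[:, c]) for c in range(3)
    ])
    refl = baseline + (amplitude - baseline) * np.exp(
        -4.0 * np.log(2.0) * ((lam - center_nm) / width_nm) ** 2)
    xyz = refl @ cmf / cmf[:, 1].sum()
    linear = np.clip(XYZ_TO_LINEAR_SRGB @ xyz, 0.0, 1.0)
    srgb = np.where(linear <= 0.0031308, 12.92 * linear,
                    1.055 * np.power(linear, 1.0 / 2.4) - 0.055)
    return np.clip(np.round(srgb * 255.0), 0, 255).astype(int)
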