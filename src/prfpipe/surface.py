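"""Surface-map operations: cortical magnification, smoothing, summaries.

The cortical magnification factor (CMF, mm of cortex per degree of visual
field) is estimated locally at each vertex from its one-ring neighbourhood:
the area of the polygon its cortical neighbours span, divided — after
square roots — by the area of the polygon their pRF centres span in visual
space.  Map smoothing is a Gaussian-weighted neighbourhood mean on the flat
patch.  Summary statistics are computed in 1°-wide eccentricity bins with
bootstrap confidence intervals, and maps are compared with a circular
correlation for polar angle plus a Spearman rank correlation for
eccentricity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr

__all__ = [
    "RetinoMesh",
    "neighbor_polygon_area",
    "cmf_map",
    "smooth_map",
    "bin_summarize",
    "circular_corr",
    "compare_maps",
    "DEFAULT_BIN_EDGES",
]

#: Eccentricity band edges: 1° bins from 0.5° to 9.5°.
DEFAULT_BIN_EDGES = np.arange(0.5, 10.0, 1.0)


@dataclass
class RetinoMesh:
    """Triangulated cortical patch with an aligned per-vertex pRF table.

    ``vertices`` holds positions in mm (N × 2 for a flat patch, N × 3
    accepted with smoothing/areas using the first two coordinates);
    ``triangles`` is M × 3 vertex indices.  ``fits`` carries at least
    columns vertex_id, x0, y0 (and typically sigma, r2).
    """

    vertices: np.ndarray
    triangles: np.ndarray
    fits: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] not in (2, 3):
            raise ValueError("vertices must be (N, 2) or (N, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (M, 3)")
        if self.triangles.max(initial=-1) >= len(self.vertices):
            raise ValueError("triangle index out of range")

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    def patch_xy(self) -> np.ndarray:
        """In-patch 2D coordinates (first two columns)."""
        return self.vertices[:, :2]

    def adjacency(self) -> list[set[int]]:
        nbrs: list[set[int]] = [set() for _ in range(self.n_vertices)]
        for a, b, c in self.triangles:
            nbrs[a].update((b, c))
            nbrs[b].update((a, c))
            nbrs[c].update((a, b))
        return nbrs

    def triangle_count_per_vertex(self) -> np.ndarray:
        counts = np.zeros(self.n_vertices, dtype=int)
        for tri in self.triangles:
            counts[tri] += 1
        return counts

    def interior_mask(self) -> np.ndarray:
        """Interior vertices: one-ring closes (triangle count == neighbour count)."""
        nbrs = self.adjacency()
        counts = self.triangle_count_per_vertex()
        return np.array(
            [len(nbrs[v]) >= 3 and counts[v] == len(nbrs[v]) for v in range(self.n_vertices)]
        )

    def ordered_ring(self, v: int) -> np.ndarray:
        """One-ring neighbours of v sorted by angle around v in the patch plane."""
        nbrs = sorted(self.adjacency()[v])
        xy = self.patch_xy()
        d = xy[nbrs] - xy[v]
        order = np.argsort(np.arctan2(d[:, 1], d[:, 0]), kind="stable")
        return np.asarray(nbrs, dtype=int)[order]


def neighbor_polygon_area(points: np.ndarray) -> float:
    """Absolute shoelace area of an ordered 2D polygon; NaN below 3 points."""
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if len(pts) < 3:
        return float("nan")
    x, y = pts[:, 0], pts[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _polygon_signed_consistent(points: np.ndarray) -> bool:
    """True when the polygon's edges wind consistently (no sign flips)."""
    pts = np.asarray(points, dtype=np.float64)
    centre = pts.mean(axis=0)
    d = pts - centre
    cross = d[:, 0] * np.roll(d[:, 1], -1) - d[:, 1] * np.roll(d[:, 0], -1)
    nz = cross[np.abs(cross) > 1e-12]
    return bool(len(nz) == 0 or (np.sign(nz) == np.sign(nz[0])).all())


def cmf_map(mesh: RetinoMesh, fits: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-vertex cortical magnification factor √(cortical area / visual area).

    Both areas come from the polygon of one-ring neighbours — cortical
    positions in the patch plane, pRF centres in visual space — traversed in
    the same (cortical-angle) order.  Boundary vertices, vertices with a
    degenerate neighbour, and zero visual area give NaN.  Vertices whose
    visual polygon winds inconsistently (scatter in the map) are flagged.
    """
    table = fits if fits is not None else mesh.fits
    if table is None:
        raise ValueError("mesh has no pRF table")
    table = table.set_index("vertex_id") if "vertex_id" in table.columns else table
    vx = table["x0"].reindex(range(mesh.n_vertices)).to_numpy()
    vy = table["y0"].reindex(range(mesh.n_vertices)).to_numpy()
    xy = mesh.patch_xy()
    interior = mesh.interior_mask()

    cmf = np.full(mesh.n_vertices, np.nan)
    inconsistent = np.zeros(mesh.n_vertices, dtype=bool)
    for v in range(mesh.n_vertices):
        if not interior[v]:
            continue
        ring = mesh.ordered_ring(v)
        visual = np.column_stack([vx[ring], vy[ring]])
        if not np.isfinite(visual).all():
            continue
        cortical_area = neighbor_polygon_area(xy[ring])
        visual_area = neighbor_polygon_area(visual)
        if not visual_area > 0:
            continue
        cmf[v] = np.sqrt(cortical_area) / np.sqrt(visual_area)
        inconsistent[v] = not _polygon_signed_consistent(visual)
    return pd.DataFrame(
        {
            "vertex_id": np.arange(mesh.n_vertices),
            "cmf": cmf,
            "interior": interior,
            "winding_inconsistent": inconsistent,
        }
    )


def smooth_map(
    mesh: RetinoMesh, values: np.ndarray, fwhm_mm: float
) -> np.ndarray:
    """Gaussian surface smoothing of a per-vertex map on the flat patch.

    Weighted mean with Gaussian weights on within-patch Euclidean distance,
    truncated at 3 SD; NaN (undefined) neighbours drop out with the weights
    renormalised.  fwhm → 0 reduces to the identity.
    """
    if not fwhm_mm >= 0:
        raise ValueError("fwhm_mm must be nonnegative")
    values = np.asarray(values, dtype=np.float64)
    sd = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    if sd == 0:
        return values.copy()
    xy = mesh.patch_xy()
    d = cdist(xy, xy)
    w = np.exp(-(d**2) / (2.0 * sd**2))
    w[d > 3.0 * sd] = 0.0
    valid = np.isfinite(values)
    w = w * valid[None, :]
    norm = w.sum(axis=1)
    out = np.full_like(values, np.nan)
    ok = norm > 0
    out[ok] = (w[ok] @ np.where(valid, values, 0.0)) / norm[ok]
    return out


def bin_summarize(
    eccentricity: np.ndarray,
    values: np.ndarray,
    statistic: str = "mean",
    r_squared: np.ndarray | None = None,
    r2_threshold: float | None = 0.15,
    bin_edges: np.ndarray = DEFAULT_BIN_EDGES,
    n_boot: int = 1000,
    ci_level: float = 0.95,
    rng: np.random.Generator | int | None = 0,
) -> pd.DataFrame:
    """Eccentricity-binned summary with bootstrap confidence intervals.

    Bins are half-open [lo, lo+width) with the final bin closed.  Vertices
    with R² at or below ``r2_threshold`` are excluded (pass None to keep
    all).  The per-bin statistic ("mean" or "median") is bootstrapped with
    ``n_boot`` resamples; the CI is the central ``ci_level`` of the
    bootstrap distribution.  Empty bins are flagged with NaN value/CI.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    rng = np.random.default_rng(rng)
    ecc = np.asarray(eccentricity, dtype=np.float64)
    val = np.asarray(values, dtype=np.float64)
    keep = np.isfinite(ecc) & np.isfinite(val)
    if r_squared is not None and r2_threshold is not None:
        keep &= np.asarray(r_squared, dtype=np.float64) > r2_threshold
    ecc, val = ecc[keep], val[keep]

    stat = np.mean if statistic == "mean" else np.median
    lo_q, hi_q = 100 * (1 - ci_level) / 2, 100 * (1 + ci_level) / 2
    rows = []
    edges = np.asarray(bin_edges, dtype=np.float64)
    for i in range(len(edges) - 1):
        lo, hi = edges[i], edges[i + 1]
        if i == len(edges) - 2:
            sel = (ecc >= lo) & (ecc <= hi)
        else:
            sel = (ecc >= lo) & (ecc < hi)
        v = val[sel]
        if len(v) == 0:
            rows.append(
                dict(bin_lo=lo, bin_hi=hi, statistic=statistic, value=np.nan,
                     ci_low=np.nan, ci_high=np.nan, n=0, empty=True)
            )
            continue
        idx = rng.integers(0, len(v), size=(n_boot, len(v)))
        boots = stat(v[idx], axis=1)
        rows.append(
            dict(
                bin_lo=lo,
                bin_hi=hi,
                statistic=statistic,
                value=float(stat(v)),
                ci_low=float(np.percentile(boots, lo_q)),
                ci_high=float(np.percentile(boots, hi_q)),
                n=int(len(v)),
                empty=False,
            )
        )
    return pd.DataFrame(rows)


def circular_corr(angles_a: np.ndarray, angles_b: np.ndarray) -> float:
    """Fisher–Lee circular correlation between two samples of angles (radians).

    r = Σ_{i<j} sin(a_i−a_j) sin(b_i−b_j) /
        √(Σ_{i<j} sin²(a_i−a_j) · Σ_{i<j} sin²(b_i−b_j))

    Rotation-invariant; returns NaN for fewer than 3 pairs or a degenerate
    (zero-spread) sample.
    """
    a = np.asarray(angles_a, dtype=np.float64)
    b = np.asarray(angles_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("angle arrays must share a shape")
    if a.size < 3:
        return float("nan")
    sa = np.sin(a[:, None] - a[None, :])
    sb = np.sin(b[:, None] - b[None, :])
    num = np.sum(sa * sb)
    den = np.sqrt(np.sum(sa**2) * np.sum(sb**2))
    if den == 0:
        return float("nan")
    return float(num / den)


def compare_maps(
    fit_a: pd.DataFrame, fit_b: pd.DataFrame, r2_threshold: float = 0.10
) -> dict:
    """Map agreement between two fits of the same vertices.

    Restricts to vertices with R² above threshold in BOTH maps, then
    correlates polar angle (circular correlation) and eccentricity
    (Spearman's ρ).  Returns {"polar_r", "ecc_rho", "n_common"}.
    """
    a = fit_a.set_index("vertex_id")
    b = fit_b.set_index("vertex_id")
    common = a.index.intersection(b.index)
    a, b = a.loc[common], b.loc[common]
    sel = (a["r2"] > r2_threshold) & (b["r2"] > r2_threshold)
    a, b = a[sel], b[sel]
    n = int(sel.sum())
    if n < 3:
        return {"polar_r": float("nan"), "ecc_rho": float("nan"), "n_common": n}
    pol_a = np.arctan2(a["y0"], a["x0"]).to_numpy()
    pol_b = np.arctan2(b["y0"], b["x0"]).to_numpy()
    ecc_a = np.hypot(a["x0"], a["y0"]).to_numpy()
    ecc_b = np.hypot(b["x0"], b["y0"]).to_numpy()
    rho = spearmanr(ecc_a, ecc_b).statistic
    return {
        "polar_r": circular_corr(pol_a, pol_b),
        "ecc_rho": float(rho),
        "n_common": n,
    }
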