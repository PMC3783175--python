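"""Molecule segmentation and backbone tracing on AFM height images.

The tracer reproduces the classic single-molecule contour workflow:
threshold the height map, label connected components, skeletonize each
molecule, order the skeleton between its endpoints (or around the ring),
refine every point to the transverse brightness maximum with sub-pixel
accuracy, and resample the centerline at a fixed arc step (default 8 nm,
half the apparent cross-sectional diameter).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from skimage.measure import label as sk_label
from skimage.morphology import skeletonize

from .errors import BranchError, ParameterError, SamplingError, TraceError
from .image import AFMImage

__all__ = [
    "MoleculeRegion",
    "TraceResult",
    "segment_molecules",
    "trace_backbone",
    "measure_contour_length",
    "height_profile",
    "write_traces_csv",
    "read_traces_csv",
]

SQRT2 = float(np.sqrt(2.0))


# =============================================================================
# domain types
# =============================================================================
@dataclass
class MoleculeRegion:
    """A labelled candidate molecule in an image."""

    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    mean_height_nm: float
    area_nm2: float
    class_hint: str  # linear | circular | compact | reject
    molecule_id: int = 0
    crest_height_nm: float = 0.0  # robust (95th pct) height; the "measured height"


@dataclass
class TraceResult:
    """Ordered centerline points (nm) resampled at a fixed arc step."""

    points: np.ndarray
    step_nm: float
    closed: bool
    molecule_id: int = 0
    image_index: int = 0  # which image of an ensemble the trace came from

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if len(self.points) < 4:
            raise TraceError("a trace needs at least 4 points")

    def spacings(self) -> np.ndarray:
        d = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if self.closed:
            d = np.append(d, np.linalg.norm(self.points[0] - self.points[-1]))
        return d


# =============================================================================
# skeleton graph helpers (module-private, shared with topology)
# =============================================================================
def skeleton_graph(skel: np.ndarray) -> nx.Graph:
    """8-connected pixel graph of a skeleton, with redundant diagonals removed.

    Edge weights are Euclidean pixel distances.  When two orthogonal edges
    close a triangle with a diagonal edge, the diagonal is dropped so that
    degree counts reflect the curve topology.
    """
    g = nx.Graph()
    rr, cc = np.nonzero(skel)
    pixels = set(zip(rr.tolist(), cc.tolist()))
    for r, c in pixels:
        g.add_node((r, c))
        for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
            q = (r + dr, c + dc)
            if q in pixels:
                g.add_edge((r, c), q, weight=1.0 if dr * dc == 0 else SQRT2)
    # drop diagonal chords of right-angle triangles
    for u, v in [e for e in g.edges if g.edges[e]["weight"] > 1.0]:
        common = set(g[u]) & set(g[v])
        if any(
            g.edges[u, w]["weight"] == 1.0 and g.edges[v, w]["weight"] == 1.0
            for w in common
        ):
            g.remove_edge(u, v)
    return g


def prune_spurs(g: nx.Graph, min_px: int = 3) -> nx.Graph:
    """Iteratively remove side branches shorter than ``min_px`` pixels."""
    changed = True
    while changed:
        changed = False
        for end in [n for n in g if g.degree(n) == 1]:
            if end not in g:
                continue
            path = [end]
            prev, cur = None, end
            while g.degree(cur) <= 2:
                nbrs = [x for x in g[cur] if x != prev]
                if not nbrs:
                    break
                prev, cur = cur, nbrs[0]
                path.append(cur)
                if g.degree(cur) != 2:
                    break
            if g.degree(cur) >= 3 and len(path) - 1 <= min_px:
                g.remove_nodes_from(path[:-1])
                changed = True
    return g


def graph_length_px(g: nx.Graph) -> float:
    return float(sum(d["weight"] for _, _, d in g.edges(data=True)))


def endpoints_of(g: nx.Graph) -> list[tuple[int, int]]:
    return sorted(n for n in g if g.degree(n) == 1)


def branch_points_of(g: nx.Graph) -> list[tuple[int, int]]:
    return sorted(n for n in g if g.degree(n) >= 3)


def _walk_cycle(g: nx.Graph) -> list[tuple[int, int]]:
    """Ordered node list of a simple cycle graph (all degrees 2)."""
    start = min(g.nodes)
    nbrs = sorted(g[start])
    order = [start, nbrs[0]]
    while True:
        nxt = [x for x in g[order[-1]] if x != order[-2]]
        if not nxt:
            raise TraceError("cycle walk broke off")
        if nxt[0] == start:
            break
        order.append(nxt[0])
    return order


# =============================================================================
# segmentation
# =============================================================================
def _robust_threshold(image: AFMImage) -> float:
    """Half the robust ridge height, floored above the noise level.

    The ridge height is the 90th percentile of pixels clearly above the
    background (5 noise s.d., at least 0.1 nm), so it does not depend on
    how little of the image the molecules cover.
    """
    h = image.heights
    noise_sd = 1.4826 * np.median(np.abs(h - np.median(h)))
    floor = max(5.0 * noise_sd, 0.1)
    candidates = h[h > floor]
    if candidates.size == 0:
        return float(h.max() + 1.0)  # nothing above background
    ridge_est = float(np.percentile(candidates, 90))
    thresh = max(0.5 * ridge_est, floor)
    fg = (h > thresh).mean()
    if fg > 0.25:  # degenerate: fall back to Otsu
        from skimage.filters import threshold_otsu

        thresh = float(threshold_otsu(h))
    return thresh


def segment_molecules(
    image: AFMImage,
    min_len_nm: float = 50.0,
    height_band: tuple[float, float] = (0.2, 1.4),
    compact_height_nm: float = 1.2,
) -> list[MoleculeRegion]:
    """Find candidate molecules and classify them for downstream tracing.

    Thresholds at half the ridge height (Otsu fallback), labels 8-connected
    components, and discards components touching the border or with less
    than ``min_len_nm`` of skeletal length.  Components whose robust crest
    height (95th percentile, the particle's measured height) exceeds
    ``compact_height_nm`` are classed ``compact``; skeletons with
    more than two endpoints (after pruning) or with branch points are
    classed ``reject`` (overlap/branch); zero endpoints means ``circular``,
    two endpoints ``linear``.  An all-background image yields an empty list.
    """
    thresh = _robust_threshold(image)
    fg = image.heights > thresh
    labels = sk_label(fg, connectivity=2)
    regions: list[MoleculeRegion] = []
    mol_id = 0
    for lab in range(1, labels.max() + 1):
        mask = labels == lab
        rr, cc = np.nonzero(mask)
        if (
            rr.min() == 0
            or cc.min() == 0
            or rr.max() == mask.shape[0] - 1
            or cc.max() == mask.shape[1] - 1
        ):
            continue  # border-touching
        skel = skeletonize(mask)
        g = prune_spurs(skeleton_graph(skel))
        if graph_length_px(g) * image.pixel_nm < min_len_nm:
            continue
        mean_h = float(image.heights[mask].mean())
        crest_h = float(np.percentile(image.heights[mask], 95))
        area = float(mask.sum()) * image.pixel_nm**2
        n_ends = len(endpoints_of(g))
        n_branch = len(branch_points_of(g))
        if crest_h > compact_height_nm:
            hint = "compact"
        elif mean_h < height_band[0]:
            hint = "reject"
        elif n_ends == 0 and n_branch == 0 and nx.is_connected(g):
            hint = "circular"
        elif n_ends == 2 and n_branch == 0:
            hint = "linear"
        else:
            hint = "reject"
        regions.append(
            MoleculeRegion(
                mask=mask,
                bbox=(int(rr.min()), int(cc.min()), int(rr.max()), int(cc.max())),
                mean_height_nm=mean_h,
                area_nm2=area,
                class_hint=hint,
                molecule_id=mol_id,
                crest_height_nm=crest_h,
            )
        )
        mol_id += 1
    return regions


# =============================================================================
# backbone tracing
# =============================================================================
def _ordered_skeleton_xy(
    image: AFMImage, region: MoleculeRegion
) -> tuple[np.ndarray, bool]:
    """Ordered skeleton pixel positions (nm) and whether the path is a ring."""
    skel = skeletonize(region.mask)
    g = prune_spurs(skeleton_graph(skel))
    ends = endpoints_of(g)
    if len(ends) == 0:
        if branch_points_of(g):
            raise BranchError("circular skeleton has branch points")
        order = _walk_cycle(g)
        closed = True
    elif len(ends) == 2:
        if branch_points_of(g):
            raise BranchError("skeleton has residual branch points")
        order = nx.shortest_path(g, ends[0], ends[1], weight="weight")
        closed = False
    else:
        raise BranchError(f"skeleton has {len(ends)} endpoints after pruning")
    rc = np.asarray(order, dtype=float)
    xy = image.rc_to_xy(rc)
    if closed:
        # canonical orientation: positive shoelace area in the (x, y) frame,
        # starting from the smallest (row, col) pixel
        x, y = xy[:, 0], xy[:, 1]
        area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        if area < 0:
            xy = xy[::-1]
        start = int(np.lexsort((xy[:, 0], xy[:, 1]))[0])
        xy = np.roll(xy, -start, axis=0)
    return xy, closed


def _refine_subpixel(
    image: AFMImage,
    points: np.ndarray,
    closed: bool,
    halfwidth_nm: float,
    n_samples: int = 7,
    n_iter: int = 2,
) -> np.ndarray:
    """Move each point to the transverse brightness maximum (parabola apex)."""
    pts = points.copy()
    for it in range(n_iter):
        w = halfwidth_nm / (2**it)
        offsets = np.linspace(-w, w, n_samples)
        if closed:
            nxt, prv = np.roll(pts, -1, axis=0), np.roll(pts, 1, axis=0)
        else:
            nxt = np.vstack([pts[1:], pts[-1] + (pts[-1] - pts[-2])])
            prv = np.vstack([pts[0] - (pts[1] - pts[0]), pts[:-1]])
        tang = nxt - prv
        norm = np.linalg.norm(tang, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        tang /= norm
        normal = np.column_stack([-tang[:, 1], tang[:, 0]])
        # sample all points x offsets in one interpolation call
        probe = pts[None, :, :] + offsets[:, None, None] * normal[None, :, :]
        heights = image.sample(probe.reshape(-1, 2)).reshape(n_samples, len(pts))
        # quadratic fit per point: h = a*o^2 + b*o + c
        o = offsets
        design = np.column_stack([o**2, o, np.ones_like(o)])
        coef, *_ = np.linalg.lstsq(design, heights, rcond=None)
        a, b = coef[0], coef[1]
        shift = np.where(a < 0, -b / (2 * np.where(a < 0, a, -1.0)), 0.0)
        shift = np.clip(shift, -w, w)
        pts = pts + shift[:, None] * normal
    return pts


def _smooth(points: np.ndarray, closed: bool, window: int = 3) -> np.ndarray:
    if window <= 1:
        return points
    k = np.ones(window) / window
    if closed:
        pad = window // 2
        ext = np.vstack([points[-pad:], points, points[:pad]])
        sm = np.column_stack(
            [np.convolve(ext[:, 0], k, "valid"), np.convolve(ext[:, 1], k, "valid")]
        )
        return sm
    sm = points.copy()
    half = window // 2
    for i in range(len(points)):
        lo, hi = max(0, i - half), min(len(points), i + half + 1)
        sm[i] = points[lo:hi].mean(axis=0)
    return sm


def _ridge_sigma_nm(image: AFMImage, points: np.ndarray) -> float:
    """Effective transverse Gaussian width of the ridge, from interior profiles.

    Fits a parabola to log-height over the +-6 nm core of the transverse
    profile at several interior points; the median width is returned.
    """
    n = len(points)
    idx = np.unique(np.linspace(n // 4, 3 * n // 4, 7).astype(int))
    offsets = np.linspace(-6.0, 6.0, 9)
    sigmas = []
    for i in idx:
        a, b = points[max(0, i - 1)], points[min(n - 1, i + 1)]
        tang = b - a
        norm = np.linalg.norm(tang)
        if norm == 0:
            continue
        tang /= norm
        normal = np.array([-tang[1], tang[0]])
        prof = image.sample(points[i] + offsets[:, None] * normal[None, :])
        if prof.min() <= 0:
            continue
        coef = np.polyfit(offsets, np.log(prof), 2)
        if coef[0] < 0:
            sigmas.append(np.sqrt(-1.0 / (2 * coef[0])))
    return float(np.median(sigmas)) if sigmas else 4.5


def _extend_open_ends(
    image: AFMImage, points: np.ndarray, probe_nm: float = 20.0, ds: float = 0.25
) -> np.ndarray:
    """Recover ridge length lost to skeleton end erosion.

    The thresholded mask ends where the Gaussian end-cap falls to half the
    crest, a distance ``sigma_eff * sqrt(2 ln 2)`` beyond the true chain
    end, while skeletonization retracts the endpoint inside the cap.  Each
    end is therefore extended along its outward tangent to the measured
    half-crest crossing minus that analytic cap overshoot.
    """
    sigma = _ridge_sigma_nm(image, points)
    overshoot = sigma * np.sqrt(2 * np.log(2.0))
    d_grid = np.arange(0.0, probe_nm, ds)
    pts = points
    for which in (0, -1):
        end = pts[0] if which == 0 else pts[-1]
        inner = pts[1] if which == 0 else pts[-2]
        t_out = end - inner
        norm = np.linalg.norm(t_out)
        if norm == 0:
            continue
        t_out /= norm
        interior = pts[2:6] if which == 0 else pts[-6:-2]
        crest = float(image.sample(interior).mean())
        if crest <= 0:
            continue
        prof = image.sample(end[None, :] + d_grid[:, None] * t_out[None, :])
        below = np.nonzero(prof < 0.5 * crest)[0]
        if len(below) == 0 or below[0] == 0:
            continue
        k = below[0]
        # linear interpolation of the half-crest crossing
        frac = (0.5 * crest - prof[k - 1]) / (prof[k] - prof[k - 1])
        d_half = d_grid[k - 1] + frac * ds
        ext = np.clip(d_half - overshoot, 0.0, probe_nm)
        if ext > ds:
            new_end = end + ext * t_out
            pts = (
                np.vstack([new_end, pts]) if which == 0 else np.vstack([pts, new_end])
            )
    return pts


def _arc_resample(
    points: np.ndarray, step_nm: float, closed: bool
) -> np.ndarray:
    p = points
    if closed:
        p = np.vstack([p, p[:1]])
    d = np.linalg.norm(np.diff(p, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(d)])
    total = s[-1]
    if closed:
        m = max(4, int(round(total / step_nm)))
        t = np.linspace(0.0, total, m, endpoint=False)
    else:
        ks = int(np.floor(total / step_nm + 1e-9))
        t = step_nm * np.arange(ks + 1)
        if total - t[-1] > 1e-6:
            t = np.append(t, total)  # keep the short final segment
    return np.column_stack(
        [np.interp(t, s, p[:, 0]), np.interp(t, s, p[:, 1])]
    )


def trace_backbone(
    image: AFMImage,
    region: MoleculeRegion,
    step_nm: float = 8.0,
    *,
    normal_halfwidth_nm: float = 6.0,
    smooth_window: int = 3,
) -> TraceResult:
    """Extract the ordered, sub-pixel refined centerline of one molecule.

    Pipeline: skeletonize, prune short side branches, order the skeleton
    between its endpoints (rings: start at the smallest (row, col) pixel,
    counter-clockwise), refine each point to the transverse brightness
    apex via a quadratic fit along the local normal, smooth with a short
    moving average, and resample at a uniform arc step.
    """
    if region.class_hint not in ("linear", "circular"):
        raise TraceError(f"cannot trace a region classed {region.class_hint!r}")
    if step_nm <= 0:
        raise ParameterError("step_nm must be > 0")
    xy, closed = _ordered_skeleton_xy(image, region)
    skel_len = np.linalg.norm(np.diff(xy, axis=0), axis=1).sum()
    if closed:
        skel_len += np.linalg.norm(xy[0] - xy[-1])
    if skel_len < 3 * step_nm:
        raise TraceError(
            f"skeletal length {skel_len:.1f} nm below 3 steps of {step_nm} nm"
        )
    refined = _refine_subpixel(image, xy, closed, normal_halfwidth_nm)
    smoothed = _smooth(refined, closed, smooth_window)
    if not closed:
        smoothed = _extend_open_ends(image, smoothed)
    resampled = _arc_resample(smoothed, step_nm, closed)
    return TraceResult(
        points=resampled,
        step_nm=step_nm,
        closed=closed,
        molecule_id=region.molecule_id,
    )


def measure_contour_length(trace: TraceResult) -> float:
    """Contour length in nm: sum of consecutive point distances."""
    return float(trace.spacings().sum())


# =============================================================================
# height profiling
# =============================================================================
def height_profile(
    image: AFMImage,
    trace: TraceResult,
    n_positions: int = 50,
    seed: int = 0,
    *,
    halfwidth_nm: float = 12.0,
    end_exclusion_nm: float = 10.0,
    n_samples: int = 17,
) -> tuple[float, float, np.ndarray]:
    """Apex height above local background at random positions along the trace.

    At ``n_positions`` uniformly drawn arc positions (excluding
    ``end_exclusion_nm`` at each end of open traces) the transverse height
    profile is sampled along the local normal; the apex height above the
    local background (median of the profile tails) is recorded.  Returns
    (mean, sd, samples); deterministic for a fixed seed.
    """
    if n_positions <= 0:
        raise ParameterError("n_positions must be > 0")
    p = trace.points
    if trace.closed:
        p = np.vstack([p, p[:1]])
    d = np.linalg.norm(np.diff(p, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(d)])
    total = s[-1]
    lo, hi = (0.0, total) if trace.closed else (end_exclusion_nm, total - end_exclusion_nm)
    if hi - lo < 1e-9 or (hi - lo) < n_positions * 1e-6:
        raise SamplingError("trace interior too short for height sampling")
    rng = np.random.default_rng(seed)
    pos = rng.uniform(lo, hi, n_positions)
    x = np.interp(pos, s, p[:, 0])
    y = np.interp(pos, s, p[:, 1])
    # tangents from neighboring resampled points
    eps = max(1.0, trace.step_nm / 4)
    xf = np.interp(np.minimum(pos + eps, total), s, p[:, 0])
    yf = np.interp(np.minimum(pos + eps, total), s, p[:, 1])
    xb = np.interp(np.maximum(pos - eps, 0.0), s, p[:, 0])
    yb = np.interp(np.maximum(pos - eps, 0.0), s, p[:, 1])
    tang = np.column_stack([xf - xb, yf - yb])
    norm = np.linalg.norm(tang, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    tang /= norm
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    offsets = np.linspace(-halfwidth_nm, halfwidth_nm, n_samples)
    centers = np.column_stack([x, y])
    probe = centers[None, :, :] + offsets[:, None, None] * normal[None, :, :]
    prof = image.sample(probe.reshape(-1, 2)).reshape(n_samples, n_positions)
    background = np.median(prof[[0, 1, -2, -1], :], axis=0)
    # parabola through the max sample and its neighbors for a sub-sample apex
    imax = np.clip(np.argmax(prof, axis=0), 1, n_samples - 2)
    cols = np.arange(n_positions)
    h0, h1, h2 = prof[imax - 1, cols], prof[imax, cols], prof[imax + 1, cols]
    denom = h0 - 2 * h1 + h2
    apex = np.where(denom < 0, h1 - (h0 - h2) ** 2 / (8 * denom), h1)
    samples = apex - background
    return float(samples.mean()), float(samples.std(ddof=1)), samples


# =============================================================================
# trace I/O
# =============================================================================
def write_traces_csv(traces: list[TraceResult], path: str | Path) -> None:
    rows = []
    for tr in traces:
        for i, (x, y) in enumerate(tr.points):
            rows.append(
                (tr.molecule_id, i, float(x), float(y), tr.step_nm, int(tr.closed))
            )
    pd.DataFrame(
        rows,
        columns=["molecule_id", "point_index", "x_nm", "y_nm", "step_nm", "closed"],
    ).to_csv(path, index=False, float_format="%.6f")


def read_traces_csv(path: str | Path) -> list[TraceResult]:
    df = pd.read_csv(path)
    traces = []
    for mol_id, grp in df.groupby("molecule_id", sort=True):
        grp = grp.sort_values("point_index")
        traces.append(
            TraceResult(
                points=grp[["x_nm", "y_nm"]].to_numpy(),
                step_nm=float(grp["step_nm"].iloc[0]),
                closed=bool(grp["closed"].iloc[0]),
                molecule_id=int(mol_id),
            )
        )
    return traces
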