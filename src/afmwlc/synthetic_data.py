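"""Ground-truth 2D worm-like chains and AFM-like renders of them.

Chains are generated in the plane (the experimental geometry: molecules
equilibrated in 2D on a surface), as equilateral polylines whose turning
angles follow the worm-like-chain (WLC) Gaussian bending statistics
``theta ~ N(0, seg_len / lp)``.  For such an ensemble the tangent-tangent
correlation decays as ``<cos theta(L)> = exp(-L / (2 Lp))``.

Closed (circular plasmid-like) chains are drawn from the same bending
energy restricted to exactly closed, non-self-intersecting rings using a
crankshaft-reflection Metropolis sampler: a random sub-arc is reflected
across the chord joining its endpoints.  The reflection is an isometry, so
segment lengths and ring closure are preserved exactly, and in
tangent-angle coordinates the move is an affine involution with unit
Jacobian, so detailed balance holds for the WLC Boltzmann weight on the
closure manifold.

Rendering emulates AFM imaging: the chain becomes a Gaussian ridge of
given peak height and cross-sectional width, convolved with a Gaussian tip
point-spread, plus optional free-protein background dots and additive
pixel noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from numba import njit
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely.geometry import LineString

from .errors import DiscretizationError, GeometryError, ParameterError
from .image import AFMImage

__all__ = [
    "Polymer2D",
    "RenderParams",
    "ConditionSpec",
    "PlectonemeTruth",
    "sample_wlc_2d",
    "sample_closed_wlc_2d",
    "render_afm",
    "make_condition_ensemble",
    "generate_plectoneme",
    "generate_compact",
    "write_ensemble",
]

#: internal generation step (nm); finer than the 8 nm analysis step so that
#: resampling error in downstream tracing is negligible.
DEFAULT_SEG_NM = 2.0


# =============================================================================
# domain types
# =============================================================================
@dataclass
class Polymer2D:
    """Ground-truth chain: ordered vertices in nm.

    For closed chains the first vertex is repeated as the last one, so
    ``vertices`` has ``n_segments + 1`` rows in both cases.
    """

    vertices: np.ndarray
    closed: bool
    true_lp: float
    true_contour: float
    seed: int
    label: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ParameterError("vertices must be an (N, 2) array")

    @property
    def n_segments(self) -> int:
        return len(self.vertices) - 1

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)

    def contour_length(self) -> float:
        return float(self.segment_lengths().sum())

    def headings(self) -> np.ndarray:
        """Tangent headings (rad) of the segments, in order."""
        d = np.diff(self.vertices, axis=0)
        return np.arctan2(d[:, 1], d[:, 0])

    def turning_angles(self) -> np.ndarray:
        """Signed turning angles between consecutive segments, in (-pi, pi].

        For closed chains this includes the wrap-around angle, so the sum
        is +-2*pi for a simple ring.
        """
        h = self.headings()
        if self.closed:
            th = np.diff(np.concatenate([h, h[:1]]))
        else:
            th = np.diff(h)
        return _wrap_angle(th)

    def validate(self) -> None:
        """Check the container invariants; raise ParameterError on violation."""
        seg = self.segment_lengths()
        if seg.min() <= 0:
            raise ParameterError("degenerate zero-length segment")
        if (seg.max() - seg.min()) / seg.mean() > 1e-9:
            raise ParameterError("segment lengths are not uniform")
        if abs(self.contour_length() - self.true_contour) > 1e-6 * self.true_contour:
            raise ParameterError("contour length inconsistent with true_contour")
        if self.closed:
            if np.linalg.norm(self.vertices[0] - self.vertices[-1]) > 1e-6:
                raise ParameterError("closed chain does not close")
            total_turn = self.turning_angles().sum()
            if abs(abs(total_turn) - 2 * np.pi) > 1e-6:
                raise ParameterError("closed chain turning angles do not sum to +-2*pi")


@dataclass
class RenderParams:
    """Parameters of the AFM-like renderer.

    ridge_sigma_nm is the Gaussian cross-sectional width of the DNA ridge
    before tip broadening; tip_sigma_nm an additional isotropic blur
    emulating the finite tip radius.  Defaults give an apparent molecule
    width (FWHM ~ 7 nm) typical of duplex DNA imaged on mica with a
    sharp tip.
    """

    pixel_nm: float = 2.0
    ridge_height_nm: float = 0.6
    ridge_sigma_nm: float = 2.5
    tip_sigma_nm: float = 1.5
    noise_sd_nm: float = 0.05
    background_particles: int = 0
    image_shape: tuple[int, int] = (512, 512)
    particle_height_nm: float = 1.0
    particle_sigma_nm: float = 2.0

    def __post_init__(self) -> None:
        if self.pixel_nm <= 0 or self.ridge_sigma_nm <= 0:
            raise ParameterError("pixel_nm and ridge_sigma_nm must be > 0")
        if self.tip_sigma_nm < 0 or self.noise_sd_nm < 0:
            raise ParameterError("tip_sigma_nm and noise_sd_nm must be >= 0")
        if not 0.3 <= self.ridge_height_nm <= 3.0:
            raise ParameterError(
                f"ridge_height_nm must lie in [0.3, 3.0] nm, got {self.ridge_height_nm}"
            )
        if self.background_particles < 0:
            raise ParameterError("background_particles must be >= 0")
        if len(self.image_shape) != 2 or min(self.image_shape) < 8:
            raise ParameterError("image_shape must be (rows, cols) with >= 8 pixels")

    @property
    def blurred_peak_nm(self) -> float:
        """Peak height of a long straight ridge after tip convolution.

        1D transverse convolution of two Gaussians: the peak rescales by
        ridge_sigma / sqrt(ridge_sigma^2 + tip_sigma^2).
        """
        s2 = self.ridge_sigma_nm**2 + self.tip_sigma_nm**2
        return self.ridge_height_nm * self.ridge_sigma_nm / np.sqrt(s2)


@dataclass
class ConditionSpec:
    """One experimental condition of the synthetic study."""

    n_molecules: int
    lp_nm: float = 56.0
    contour_nm: float = 328.0
    ridge_height_nm: float = 0.6
    closed: bool = False
    label: str = ""
    render: RenderParams = field(default_factory=RenderParams)
    seg_nm: float = DEFAULT_SEG_NM


@dataclass
class PlectonemeTruth:
    """Branched path set of a plectoneme with its known superhelical axis."""

    paths: list[np.ndarray]
    axis_nm: float
    contour_nm: float
    axis_ratio: float
    seed: int


# =============================================================================
# helpers
# =============================================================================
def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    w = (-a + np.pi) % (2 * np.pi)
    return -(w - np.pi)


def derive_seed(master: int, *stream: int) -> int:
    """Deterministic child seed (< 2**31) from a master seed and stream ids."""
    ss = np.random.SeedSequence([int(master), *[int(s) for s in stream]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _check_wlc_params(seg_len: float, lp: float) -> None:
    if lp <= 0 or seg_len <= 0:
        raise ParameterError(f"lp and seg_len must be > 0 (lp={lp}, seg_len={seg_len})")
    if seg_len > lp / 4:
        raise DiscretizationError(
            f"seg_len={seg_len} nm too coarse for lp={lp} nm; need seg_len <= lp/4"
        )


# =============================================================================
# open chains
# =============================================================================
def sample_wlc_2d(n_segments: int, seg_len: float, lp: float, seed: int) -> Polymer2D:
    """Sample an open 2D worm-like chain.

    Turning angles are i.i.d. zero-mean Gaussians with variance
    ``seg_len / lp``; the initial heading is uniform on the circle.
    Deterministic for a fixed seed.
    """
    if n_segments < 1:
        raise ParameterError("n_segments must be >= 1")
    _check_wlc_params(seg_len, lp)
    rng = np.random.default_rng(seed)
    h0 = rng.uniform(0, 2 * np.pi)
    theta = rng.normal(0.0, np.sqrt(seg_len / lp), n_segments - 1)
    headings = h0 + np.concatenate([[0.0], np.cumsum(theta)])
    steps = seg_len * np.column_stack([np.cos(headings), np.sin(headings)])
    vertices = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return Polymer2D(
        vertices=vertices,
        closed=False,
        true_lp=lp,
        true_contour=n_segments * seg_len,
        seed=seed,
    )


# =============================================================================
# closed chains (crankshaft-reflection Metropolis)
# =============================================================================
@njit(cache=True)
def _turn_at(v: np.ndarray, k: int, n: int) -> float:
    kp = (k + 1) % n
    km = (k - 1) % n
    h1 = np.arctan2(v[kp, 1] - v[k, 1], v[kp, 0] - v[k, 0])
    h0 = np.arctan2(v[k, 1] - v[km, 1], v[k, 0] - v[km, 0])
    t = h1 - h0
    while t > np.pi:
        t -= 2 * np.pi
    while t <= -np.pi:
        t += 2 * np.pi
    return t


@njit(cache=True)
def _reflect_arc(v: np.ndarray, i: int, j: int, n: int) -> None:
    ax, ay = v[i, 0], v[i, 1]
    dx, dy = v[j, 0] - ax, v[j, 1] - ay
    L2 = dx * dx + dy * dy
    if L2 < 1e-24:
        return
    cnt = (j - i) % n
    for q in range(1, cnt):
        k = (i + q) % n
        px, py = v[k, 0] - ax, v[k, 1] - ay
        t = (px * dx + py * dy) / L2
        v[k, 0] = ax + 2 * t * dx - px
        v[k, 1] = ay + 2 * t * dy - py


@njit(cache=True)
def _ring_mcmc_core(
    v: np.ndarray, beta: float, ii: np.ndarray, arc: np.ndarray, us: np.ndarray
) -> int:
    """Metropolis sweep over crankshaft reflections; returns acceptance count.

    Only the two turning angles at the arc junctions change energy: interior
    angles are negated by the reflection, which leaves theta^2 invariant.
    """
    n = v.shape[0]
    nacc = 0
    for m in range(len(ii)):
        i = ii[m]
        j = (i + arc[m]) % n
        old = _turn_at(v, i, n) ** 2 + _turn_at(v, j, n) ** 2
        _reflect_arc(v, i, j, n)
        new = _turn_at(v, i, n) ** 2 + _turn_at(v, j, n) ** 2
        d_e = beta * (new - old)
        if d_e <= 0 or us[m] < np.exp(-d_e):
            nacc += 1
        else:
            _reflect_arc(v, i, j, n)  # involution: reflect back
    return nacc


def _regular_polygon(n: int, seg_len: float) -> np.ndarray:
    radius = seg_len / (2 * np.sin(np.pi / n))
    ang = 2 * np.pi * np.arange(n) / n
    return np.ascontiguousarray(
        radius * np.column_stack([np.cos(ang), np.sin(ang)])
    )


def _is_simple_ring(v: np.ndarray) -> bool:
    return LineString(np.vstack([v, v[:1]])).is_simple


def sample_closed_wlc_2d(
    n_segments: int,
    seg_len: float,
    lp: float,
    seed: int,
    *,
    sweeps: int = 800,
    max_tries: int = 60,
) -> Polymer2D:
    """Sample a closed, non-self-intersecting 2D worm-like chain.

    Starting from a regular ``n_segments``-gon, crankshaft reflections are
    applied under Metropolis acceptance for the WLC bending energy
    ``E = lp/(2 seg_len) * sum theta_i^2``.  Segment lengths and closure are
    preserved exactly by the isometric moves.  Final configurations that
    self-intersect, or whose winding number is not +-1, are rejected and
    resampled with a derived seed (bounded retries); the kept ring is
    oriented counter-clockwise (turning angles summing to +2*pi).

    In the stiff limit (lp -> inf) every move that bends the ring is
    rejected and the regular polygon is returned.
    """
    if n_segments < 16:
        raise ParameterError("n_segments must be >= 16 for a closed chain")
    _check_wlc_params(seg_len, lp)
    beta = lp / (2 * seg_len)
    from .errors import SamplingError

    for attempt in range(max_tries):
        rng = np.random.default_rng(derive_seed(seed, attempt))
        v = _regular_polygon(n_segments, seg_len)
        nmov = sweeps * n_segments
        ii = rng.integers(0, n_segments, nmov)
        arc = rng.integers(2, n_segments - 1, nmov)
        us = rng.random(nmov)
        _ring_mcmc_core(v, beta, ii.astype(np.int64), arc.astype(np.int64), us)
        d = np.diff(np.vstack([v, v[:1]]), axis=0)
        h = np.arctan2(d[:, 1], d[:, 0])
        total_turn = _wrap_angle(np.diff(np.concatenate([h, h[:1]]))).sum()
        if abs(abs(total_turn) - 2 * np.pi) > 1e-6:
            continue  # winding != +-1: necessarily self-intersecting
        if total_turn < 0:  # mirror to the canonical counter-clockwise sense
            v = v * np.array([1.0, -1.0])
        if not _is_simple_ring(v):
            continue
        vertices = np.vstack([v, v[:1]])
        return Polymer2D(
            vertices=vertices,
            closed=True,
            true_lp=lp,
            true_contour=n_segments * seg_len,
            seed=seed,
        )
    raise SamplingError(
        f"no simple closed chain in {max_tries} tries (lp={lp}, n={n_segments})"
    )


# =============================================================================
# rendering
# =============================================================================
def _densify(points: np.ndarray, ds: float) -> np.ndarray:
    """Resample a polyline at arc step <= ds (keeps both ends)."""
    p = np.asarray(points, dtype=float)
    if len(p) == 1:
        return p
    d = np.linalg.norm(np.diff(p, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(d)])
    total = s[-1]
    m = max(2, int(np.ceil(total / ds)) + 1)
    t = np.linspace(0.0, total, m)
    return np.column_stack([np.interp(t, s, p[:, 0]), np.interp(t, s, p[:, 1])])


def _render_paths(
    paths: list[tuple[np.ndarray, float]],
    params: RenderParams,
    seed: int,
    *,
    check_bounds: bool = True,
) -> AFMImage:
    """Render ridge paths (points_nm, peak_height_nm) into a height map."""
    if not paths or any(len(p) == 0 for p, _ in paths):
        raise ParameterError("empty path set cannot be rendered")
    rows, cols = params.image_shape
    width, height = cols * params.pixel_nm, rows * params.pixel_nm
    margin = 3 * params.ridge_sigma_nm
    if check_bounds:
        for p, _ in paths:
            if (
                p[:, 0].min() < margin
                or p[:, 1].min() < margin
                or p[:, 0].max() > width - margin
                or p[:, 1].max() > height - margin
            ):
                raise GeometryError(
                    "polymer does not fit inside the image with a "
                    f"{margin:.1f} nm margin"
                )
    xs = (np.arange(cols) + 0.5) * params.pixel_nm
    ys = (np.arange(rows) + 0.5) * params.pixel_nm
    gx, gy = np.meshgrid(xs, ys)
    pix = np.column_stack([gx.ravel(), gy.ravel()])

    base = np.zeros(rows * cols)
    ds = params.pixel_nm / 4
    for p, peak in paths:
        dense = _densify(p, ds)
        dist, _ = cKDTree(dense).query(pix, k=1)
        np.maximum(base, peak * np.exp(-(dist**2) / (2 * params.ridge_sigma_nm**2)), out=base)
    base = base.reshape(rows, cols)

    rng = np.random.default_rng(seed)
    if params.background_particles:
        px = rng.uniform(margin, width - margin, params.background_particles)
        py = rng.uniform(margin, height - margin, params.background_particles)
        for x0, y0 in zip(px, py):
            r2 = (gx - x0) ** 2 + (gy - y0) ** 2
            dot = params.particle_height_nm * np.exp(
                -r2 / (2 * params.particle_sigma_nm**2)
            )
            np.maximum(base, dot, out=base)

    if params.tip_sigma_nm > 0:
        base = ndimage.gaussian_filter(base, params.tip_sigma_nm / params.pixel_nm)
    if params.noise_sd_nm > 0:
        base = base + rng.normal(0.0, params.noise_sd_nm, base.shape)
    return AFMImage(heights=base, pixel_nm=params.pixel_nm)


def render_afm(polymer: Polymer2D, params: RenderParams, seed: int) -> AFMImage:
    """Render a single chain as an AFM-like height image.

    The chain becomes a Gaussian ridge (peak ``ridge_height_nm``, width
    ``ridge_sigma_nm``, max over the polyline), convolved with the Gaussian
    tip blur, plus optional background protein dots and additive Gaussian
    pixel noise.  Deterministic for a fixed seed.
    """
    if len(polymer.vertices) == 0:
        raise ParameterError("empty polymer")
    return _render_paths(
        [(polymer.vertices, params.ridge_height_nm)], params, seed
    )


# =============================================================================
# ensembles and special morphologies
# =============================================================================
def _center_in_image(points: np.ndarray, params: RenderParams) -> np.ndarray:
    rows, cols = params.image_shape
    center = np.array([cols * params.pixel_nm / 2, rows * params.pixel_nm / 2])
    return points - points.mean(axis=0) + center


def make_condition_ensemble(
    spec: ConditionSpec, seed: int
) -> list[tuple[Polymer2D, AFMImage]]:
    """Generate paired ground truth and images for one condition.

    Per-molecule seeds are derived deterministically from the master seed.
    A molecule whose equilibrated conformation does not fit the image with
    the rendering margin is resampled (bounded retries).
    """
    if spec.n_molecules < 1:
        raise ParameterError("n_molecules must be >= 1")
    params = replace(spec.render, ridge_height_nm=spec.ridge_height_nm)
    n_seg = int(round(spec.contour_nm / spec.seg_nm))
    out: list[tuple[Polymer2D, AFMImage]] = []
    for i in range(spec.n_molecules):
        for attempt in range(20):
            mol_seed = derive_seed(seed, i, attempt)
            if spec.closed:
                poly = sample_closed_wlc_2d(n_seg, spec.seg_nm, spec.lp_nm, mol_seed)
            else:
                poly = sample_wlc_2d(n_seg, spec.seg_nm, spec.lp_nm, mol_seed)
            poly.label = spec.label
            poly.vertices = _center_in_image(poly.vertices, params)
            try:
                img = render_afm(poly, params, derive_seed(seed, i, attempt, 1))
            except GeometryError:
                continue
            out.append((poly, img))
            break
        else:
            raise GeometryError(
                f"molecule {i} never fit the {params.image_shape} image in 20 tries"
            )
    return out


def generate_plectoneme(
    contour_nm: float,
    axis_ratio: float,
    seed: int,
    *,
    params: RenderParams | None = None,
    n_branches: int = 0,
    branch_len_nm: float = 30.0,
) -> tuple[PlectonemeTruth, AFMImage]:
    """Construct a plectonemic (interwound) molecule and its image.

    The superhelical axis is a gently curved path of length
    ``axis_ratio * contour_nm``; the interwound body is rendered with
    doubled ridge height (two unresolved strands).  Optional short branches
    emulate branched plectonemes; their lengths count toward the recorded
    true axis length.
    """
    if not 0.2 <= axis_ratio <= 0.5:
        raise ParameterError(f"axis_ratio must lie in [0.2, 0.5], got {axis_ratio}")
    if contour_nm <= 0:
        raise ParameterError("contour_nm must be > 0")
    params = params or RenderParams()
    rng = np.random.default_rng(seed)

    axis_len = axis_ratio * contour_nm
    n = max(8, int(round(axis_len / 2.0)))
    seg = axis_len / n
    amp = 0.25
    phase = rng.uniform(0, 2 * np.pi)
    s_mid = (np.arange(n) + 0.5) * seg
    headings = rng.uniform(0, 2 * np.pi) + amp * np.sin(
        2 * np.pi * s_mid / axis_len + phase
    )
    steps = seg * np.column_stack([np.cos(headings), np.sin(headings)])
    axis_pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])

    body_height = 2 * params.ridge_height_nm
    paths = [(axis_pts, body_height)]
    total_axis = axis_len
    for _ in range(n_branches):
        t = rng.uniform(0.25, 0.75)
        idx = int(t * n)
        tang = axis_pts[idx + 1] - axis_pts[idx]
        tang = tang / np.linalg.norm(tang)
        ang = np.deg2rad(rng.uniform(40, 70)) * rng.choice([-1, 1])
        c, s = np.cos(ang), np.sin(ang)
        direction = np.array([c * tang[0] - s * tang[1], s * tang[0] + c * tang[1]])
        branch = axis_pts[idx] + np.outer(
            np.linspace(0, branch_len_nm, 16), direction
        )
        paths.append((branch, body_height))
        total_axis += branch_len_nm

    shift = _center_in_image(np.vstack([p for p, _ in paths]), params) - np.vstack(
        [p for p, _ in paths]
    )
    paths = [(p + shift[0], h) for p, h in paths]

    render = replace(params, ridge_height_nm=min(body_height, 3.0))
    img = _render_paths(paths, render, derive_seed(seed, 1))
    truth = PlectonemeTruth(
        paths=[p for p, _ in paths],
        axis_nm=total_axis,
        contour_nm=contour_nm,
        axis_ratio=axis_ratio,
        seed=seed,
    )
    return truth, img


def generate_compact(
    seed: int,
    *,
    params: RenderParams | None = None,
    length_nm: float = 45.0,
    width_nm: float = 17.0,
    height_nm: float = 1.5,
) -> AFMImage:
    """Render a compacted molecule: a filled rounded rectangle.

    Emulates fully condensed DNA-protein particles (rod/toroid collapse),
    used only to exercise the compact-class filter: default dimensions
    45 x 17 nm at 1.5 nm height.
    """
    params = params or RenderParams()
    rng = np.random.default_rng(seed)
    rows, cols = params.image_shape
    width, height = cols * params.pixel_nm, rows * params.pixel_nm
    center = np.array([width / 2, height / 2]) + rng.uniform(-40, 40, 2)
    ang = rng.uniform(0, np.pi)
    half = (length_nm - width_nm) / 2
    direction = np.array([np.cos(ang), np.sin(ang)])
    a, b = center - half * direction, center + half * direction

    xs = (np.arange(cols) + 0.5) * params.pixel_nm
    ys = (np.arange(rows) + 0.5) * params.pixel_nm
    gx, gy = np.meshgrid(xs, ys)
    ab = b - a
    t = np.clip(((gx - a[0]) * ab[0] + (gy - a[1]) * ab[1]) / (ab @ ab), 0, 1)
    dx = gx - (a[0] + t * ab[0])
    dy = gy - (a[1] + t * ab[1])
    dist = np.hypot(dx, dy)
    base = np.where(dist <= width_nm / 2, height_nm, 0.0)

    if params.tip_sigma_nm > 0:
        base = ndimage.gaussian_filter(base, params.tip_sigma_nm / params.pixel_nm)
    if params.noise_sd_nm > 0:
        base = base + rng.normal(0.0, params.noise_sd_nm, base.shape)
    return AFMImage(heights=base, pixel_nm=params.pixel_nm)


# =============================================================================
# on-disk artifacts
# =============================================================================
def write_ensemble(
    out_dir: str | Path,
    pairs: list[tuple[Polymer2D, AFMImage]],
    spec: ConditionSpec,
    seed: int,
) -> dict:
    """Write images (float TIFF + YAML sidecar), ground-truth CSV, manifest JSON."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (poly, img) in enumerate(pairs):
        img.to_tiff(out / "images" / f"mol_{i:03d}.tif")
        for x, y in poly.vertices:
            rows.append((i, float(x), float(y)))
    import pandas as pd

    pd.DataFrame(rows, columns=["molecule_id", "x_nm", "y_nm"]).to_csv(
        out / "ground_truth.csv", index=False, float_format="%.6f"
    )
    manifest = {
        "seed": int(seed),
        "n_molecules": len(pairs),
        "label": spec.label,
        "true_lp_nm": spec.lp_nm,
        "true_contour_nm": pairs[0][0].true_contour,
        "closed": spec.closed,
        "pixel_nm": spec.render.pixel_nm,
        "ridge_height_nm": spec.ridge_height_nm,
        "noise_sd_nm": spec.render.noise_sd_nm,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def load_condition_yaml(path: str | Path) -> ConditionSpec:
    """Read a condition description from YAML (keys as in ConditionSpec)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    render_keys = {k: v for k, v in data.pop("render", {}).items()}
    allowed = {f for f in ConditionSpec.__dataclass_fields__ if f != "render"}
    unknown = set(data) - allowed
    if unknown:
        raise ParameterError(f"unknown condition keys: {sorted(unknown)}")
    spec = ConditionSpec(**data)
    if render_keys:
        spec.render = RenderParams(**render_keys)
    return spec
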