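"""2D and 3D semicircular-canal morphometry.

From a segmented canal volume the module derives the full metric set
used to compare canal geometry across species: the circuit radius R
(root-mean-square of the fitted duct-circuit ellipse semi-axes), the
lumen radius r (from the mean cross-section area), ampulla roundness,
the moment-equivalent ellipsoid with its elongation (a/b) and flatness
(b/c) ratios, the duct centerline and its length, the cross-section area
profile along the duct with stenosis metrics, and the endolymph
displacement sensitivity proxy ``X_max = Cst * R * r**2`` — larger
circuits with wider lumina displace more endolymph per head rotation
and are therefore more sensitive.
"""

from __future__ import annotations

import dataclasses
import warnings

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import EllipseModel
from skimage.morphology import skeletonize

from .io_formats import CanalVolume


class FitError(ValueError):
    pass


class SegmentationError(ValueError):
    pass


class ResolutionError(ValueError):
    pass


class TopologyError(ValueError):
    pass


@dataclasses.dataclass
class EllipseFit2D:
    center: tuple[float, float]  # μm
    semi_major: float  # Ra, μm
    semi_minor: float  # Rb, μm
    orientation: float  # degrees

    def __post_init__(self) -> None:
        if not self.semi_major >= self.semi_minor > 0:
            raise FitError("require semi_major >= semi_minor > 0")


@dataclasses.dataclass
class CrossSectionProfile:
    s_norm: np.ndarray  # normalized arclength, ampulla end at 1
    area: np.ndarray  # μm^2
    cs_mean: float
    cs_min: float
    stenosis_ratio: float  # cs_min / cs_mean, in (0, 1]
    stenosis_position: float  # normalized arclength of the minimum
    has_stenosis: bool


@dataclasses.dataclass
class CanalMorphometry:
    """Full 2D/3D metric set for one specimen's horizontal canal."""

    circuit_radius: float  # R, μm
    lumen_radius: float  # r, μm
    Ra: float  # μm
    Rb: float  # μm
    ellipsoid_a: float  # μm
    ellipsoid_b: float  # μm
    ellipsoid_c: float  # μm
    elongation_ratio: float  # a/b
    flatness_ratio: float  # b/c
    volume: float  # μm^3
    duct_length: float  # μm
    cs_mean: float  # μm^2
    cs_min: float  # μm^2
    stenosis_ratio: float
    stenosis_position: float
    xmax_relative: float  # Cst * R * r^2, Cst = 1


# ---------------------------------------------------------------------------
# 2D metrics


def circuit_radius(Ra: float, Rb: float) -> float:
    """Effective circuit radius: root mean square of the ellipse semi-axes."""
    if Ra <= 0 or Rb <= 0:
        raise ValueError("semi-axes must be positive")
    return float(np.sqrt((Ra**2 + Rb**2) / 2.0))


def fit_ellipse_2d(points: np.ndarray) -> EllipseFit2D:
    """Direct least-squares ellipse fit to 2D boundary points (μm)."""
    pts = np.asarray(points, float).reshape(-1, 2)
    if len(pts) < 6:
        raise FitError("need at least 6 points for an ellipse fit")
    # center the data for numerical conditioning; shift the center back
    mean = pts.mean(axis=0)
    model = EllipseModel.from_estimate(pts - mean)
    if not model:
        raise FitError("degenerate point configuration")
    xc, yc = model.center
    a, b = model.axis_lengths
    theta = model.theta
    if a < b:
        a, b = b, a
        theta += np.pi / 2
    if not np.isfinite([xc, yc, a, b]).all() or b <= 0:
        raise FitError("degenerate point configuration")
    return EllipseFit2D(
        center=(float(xc + mean[0]), float(yc + mean[1])),
        semi_major=float(a),
        semi_minor=float(b),
        orientation=float(np.rad2deg(theta) % 180.0),
    )


def ampulla_shape(points: np.ndarray) -> tuple[float, float, float]:
    """Ampulla major/minor axes and their ratio (1 = perfect circle)."""
    fit = fit_ellipse_2d(points)
    return fit.semi_major, fit.semi_minor, fit.semi_major / fit.semi_minor


# ---------------------------------------------------------------------------
# segmentation


def segment_volume(
    vol: CanalVolume, blur_sigma: float = 4.0, threshold: str | float = "otsu"
) -> CanalVolume:
    """Gaussian blur, threshold, keep the largest connected component.

    ``threshold`` is either a numeric cutoff on the blurred intensities or
    ``"otsu"`` for automatic bimodal thresholding.
    """
    img = ndimage.gaussian_filter(np.asarray(vol.voxels, float), blur_sigma)
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold method {threshold!r}")
        if img.max() <= img.min():
            raise SegmentationError("volume has no contrast")
        thr = threshold_otsu(img)
    else:
        thr = float(threshold)
    mask = img > thr
    if not mask.any():
        raise SegmentationError("empty foreground after thresholding")
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return CanalVolume(mask.astype(np.uint8), vol.voxel_size, is_binary=True)


# ---------------------------------------------------------------------------
# 3D ellipsoid metrics


def fit_ellipsoid_3d(
    binary: CanalVolume, c_mode: str = "moment"
) -> tuple[float, float, float, float, float, float]:
    """Moment-equivalent ellipsoid of the foreground.

    Semi-axes derive from the second moments of the foreground voxel
    cloud (axis = sqrt(5 * eigenvalue), exact for a solid ellipsoid),
    ordered a >= b >= c. Returns ``(a, b, c, elongation, flatness,
    volume)`` with elongation = a/b and flatness = b/c. ``c_mode="zext"``
    instead takes c as half the anatomical z-extent of the foreground
    (the vertical elevation reading of the depth axis).
    """
    mask = np.asarray(binary.voxels) > 0
    idx = np.argwhere(mask)  # (n, 3) in (z, y, x)
    if len(idx) < 10:
        raise ResolutionError("foreground of fewer than 10 voxels")
    dz, dy, dx = binary.voxel_size
    coords = idx[:, ::-1] * np.array([dx, dy, dz])  # world (x, y, z) μm
    cov = np.cov(coords.T)
    evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    a, b, c = np.sqrt(5.0 * np.clip(evals, 0, None))
    if c_mode == "zext":
        zmin, zmax = coords[:, 2].min(), coords[:, 2].max()
        c = (zmax - zmin + dz) / 2.0
    elif c_mode != "moment":
        raise ValueError(f"unknown c_mode {c_mode!r}")
    volume = float(len(idx)) * binary.voxel_volume
    return float(a), float(b), float(c), float(a / b), float(b / c), volume


# ---------------------------------------------------------------------------
# centerline


def _skeleton_graph(skel: np.ndarray, voxel_size) -> nx.Graph:
    dz, dy, dx = voxel_size
    pts = np.argwhere(skel)
    index = {tuple(p): i for i, p in enumerate(pts)}
    g = nx.Graph()
    g.add_nodes_from(range(len(pts)))
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) > (0, 0, 0)
    ]
    for p in pts:
        i0 = index[tuple(p)]
        for off in offsets:
            q = tuple(p + off)
            j0 = index.get(q)
            if j0 is not None:
                w = np.linalg.norm(np.array(off) * [dz, dy, dx])
                g.add_edge(i0, j0, weight=w)
    return g


def _moving_average(path: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(path) < window:
        return path
    kernel = np.ones(window) / window
    out = np.empty_like(path)
    for k in range(path.shape[1]):
        out[:, k] = np.convolve(path[:, k], kernel, mode="same")
    # shrink the endpoints only lightly: re-anchor them on the raw path
    half = window // 2
    out[:half] = path[:half]
    out[-half:] = path[-half:]
    return out


def _extend_to_caps(
    world: np.ndarray, mask: np.ndarray, voxel_size, tube_radius: float
) -> np.ndarray:
    """Extend both path ends to the duct end caps.

    Skeletonization retracts the medial axis roughly one tube radius from
    each end cap. For each end the foreground voxels inside a thin
    cylinder (half the tube radius wide) along the local end tangent are
    projected onto that tangent; the farthest forward projection marks
    the cap. Restricting to the cylinder core keeps the correction from
    drifting off-axis on curved ducts.
    """
    dz, dy, dx = voxel_size
    vox = np.array([dx, dy, dz])
    k = min(10, len(world) - 1)
    prepend, append = None, None
    for side in (0, 1):
        end = world[0] if side == 0 else world[-1]
        ref = world[k] if side == 0 else world[-1 - k]
        tangent = end - ref
        norm = np.linalg.norm(tangent)
        if norm == 0:
            continue
        tangent /= norm
        # local crop around the endpoint
        reach = 2.5 * tube_radius
        lo = np.maximum(((end - reach)[::-1] / vox[::-1]).astype(int), 0)
        hi = np.minimum(
            ((end + reach)[::-1] / vox[::-1]).astype(int) + 2, mask.shape
        )
        sub = mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        idx = np.argwhere(sub)
        if idx.size == 0:
            continue
        pts = (idx + lo + 0.5)[:, ::-1] * vox  # world coordinates, μm
        rel = pts - end
        proj = rel @ tangent
        perp = np.linalg.norm(rel - proj[:, None] * tangent[None, :], axis=1)
        core = (proj > 0) & (proj <= reach) & (perp <= 0.5 * tube_radius)
        if not core.any():
            continue
        cap = end + tangent * proj[core].max()
        if side == 0:
            prepend = cap
        else:
            append = cap
    parts = []
    if prepend is not None:
        parts.append(prepend[None, :])
    parts.append(world)
    if append is not None:
        parts.append(append[None, :])
    return np.concatenate(parts, axis=0)


def extract_centerline(
    binary: CanalVolume, smooth_window: int = 5, extend_ends: bool = True
) -> tuple[np.ndarray, float]:
    """Skeletonize the duct and return its centerline polyline and length.

    The 3D skeleton is reduced to the geodesically longest endpoint-to-
    endpoint path; more than two endpoints (side spurs) raise a topology
    warning but the longest path is still returned; a skeleton without
    endpoints (closed loop) is an error. The path is smoothed with a
    moving average (default window 5 points) and, with ``extend_ends``,
    prolonged along its end tangents to the duct caps (compensating the
    end retraction of the medial axis) before the polyline arc length is
    measured. Returns ``(points_xyz_um, duct_length_um)``.
    """
    mask = np.asarray(binary.voxels) > 0
    if not mask.any():
        raise SegmentationError("empty volume")
    skel = skeletonize(mask)
    g = _skeleton_graph(skel, binary.voxel_size)
    if g.number_of_nodes() == 0:
        raise SegmentationError("skeleton vanished; foreground too thin")
    # largest connected piece of the skeleton
    comp = max(nx.connected_components(g), key=len)
    g = g.subgraph(comp).copy()
    endpoints = [n for n in g.nodes if g.degree(n) == 1]
    if not endpoints:
        raise TopologyError("skeleton forms a closed loop; cannot orient a centerline")
    if len(endpoints) > 2:
        warnings.warn(
            f"skeleton has {len(endpoints)} endpoints; keeping the longest path",
            RuntimeWarning,
            stacklevel=2,
        )
    # geodesically farthest endpoint pair
    best = (None, None, -1.0)
    for i, src in enumerate(endpoints):
        dist = nx.single_source_dijkstra_path_length(g, src, weight="weight")
        for dst in endpoints[i + 1 :]:
            if dist.get(dst, -1) > best[2]:
                best = (src, dst, dist[dst])
    path_nodes = nx.dijkstra_path(g, best[0], best[1], weight="weight")
    pts_zyx = np.argwhere(skel)
    chain = pts_zyx[path_nodes].astype(float)
    dz, dy, dx = binary.voxel_size
    world = chain[:, ::-1] * np.array([dx, dy, dz])  # (x, y, z) μm
    world = _moving_average(world, smooth_window)
    if extend_ends and len(world) > 11:
        r_est = np.sqrt(mask.sum() * binary.voxel_volume / max(
            np.linalg.norm(np.diff(world, axis=0), axis=1).sum(), 1.0) / np.pi)
        world = _extend_to_caps(world, mask, binary.voxel_size, r_est)
    length = float(np.linalg.norm(np.diff(world, axis=0), axis=1).sum())
    return world, length


# ---------------------------------------------------------------------------
# cross-section profile


def _plane_basis(tangents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.tile(np.array([0.0, 0.0, 1.0]), (len(tangents), 1))
    degenerate = np.abs(tangents[:, 2]) > 0.9
    ref[degenerate] = (1.0, 0.0, 0.0)
    u = np.cross(tangents, ref)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(tangents, u)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return u, v


def cross_section_profile(
    binary: CanalVolume,
    centerline: np.ndarray,
    n_samples: int = 200,
    min_area_ratio: float = 0.5,
    stenosis_region: tuple[float, float] = (2.0 / 3.0, 1.0),
) -> CrossSectionProfile:
    """Cross-section area along the duct and stenosis metrics.

    At each centerline sample the foreground is intersected with the
    plane perpendicular to the local tangent; the area is the in-plane
    connected component containing the centerline point, counted on a
    sub-voxel plane grid. The profile is interpolated to ``n_samples``
    equidistant normalized-arclength points and oriented so the wider
    (ampulla) end sits at arclength 1. A stenosis is reported when the
    profile minimum within ``stenosis_region`` falls below the profile
    mean minus one profile SD and under ``min_area_ratio`` of the mean.
    """
    mask = np.asarray(binary.voxels) > 0
    dz, dy, dx = binary.voxel_size
    vox = np.array([dx, dy, dz])
    pts = np.asarray(centerline, float)
    if len(pts) < 5:
        raise ValueError("centerline too short")

    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    length = s[-1]
    step = min(binary.voxel_size)
    # keep half a tube radius clear of the end caps, where a perpendicular
    # plane would only graze the foreground
    r_margin = 0.5 * np.sqrt(
        mask.sum() * binary.voxel_volume / max(length, step) / np.pi
    )
    margin = min(r_margin, 0.2 * length)
    # sample at ~1-voxel arclength steps, then interpolate to the grid
    n_planes = max(int((length - 2 * margin) / step), 8)
    s_planes = np.linspace(margin, length - margin, n_planes)
    centers = np.stack([np.interp(s_planes, s, pts[:, k]) for k in range(3)], axis=1)
    tangents = np.gradient(centers, s_planes, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    u, v = _plane_basis(tangents)

    # plane grid sized from a tube-radius estimate (volume / length)
    r_est = np.sqrt(mask.sum() * binary.voxel_volume / max(length, step) / np.pi)
    extent = max(4.0 * r_est, 10.0 * step)
    h = 0.5 * step  # in-plane sampling pitch, μm
    m = int(np.ceil(extent / h))
    gg = (np.arange(-m, m + 1)) * h
    GU, GV = np.meshgrid(gg, gg, indexing="ij")
    side = 2 * m + 1

    areas = np.empty(n_planes)
    for i in range(n_planes):
        plane = (
            centers[i][None, :]
            + GU.reshape(-1, 1) * u[i][None, :]
            + GV.reshape(-1, 1) * v[i][None, :]
        )
        # world (x, y, z) μm -> fractional voxel indices (z, y, x)
        zyx = (plane[:, ::-1] / vox[::-1][None, :]) - 0.5
        inside = ndimage.map_coordinates(
            mask.astype(np.uint8), zyx.T, order=0, mode="constant", cval=0
        ).reshape(side, side)
        labels, n = ndimage.label(inside)
        if n == 0:
            areas[i] = 0.0
            continue
        center_label = labels[m, m]
        if center_label == 0:
            sizes = ndimage.sum_labels(inside, labels, index=np.arange(1, n + 1))
            center_label = 1 + int(np.argmax(sizes))
        areas[i] = (labels == center_label).sum() * h * h

    s_norm = s_planes / length
    grid = np.linspace(0.0, 1.0, n_samples)
    profile = np.interp(grid, s_norm, areas)
    # orient the ampulla (wider) end at s = 1
    tail_w = int(max(0.1 * n_samples, 2))
    if profile[:tail_w].mean() > profile[-tail_w:].mean():
        profile = profile[::-1]

    cs_mean = float(profile.mean())
    cs_sd = float(profile.std())
    lo, hi = stenosis_region
    region = (grid >= lo) & (grid <= hi)
    cs_min = float(profile.min())
    pos = float(grid[int(np.argmin(profile))])
    region_min = float(profile[region].min()) if region.any() else np.inf
    has_stenosis = bool(
        region_min < cs_mean - cs_sd and region_min / cs_mean < min_area_ratio
    )
    return CrossSectionProfile(
        s_norm=grid,
        area=profile,
        cs_mean=cs_mean,
        cs_min=cs_min,
        stenosis_ratio=cs_min / cs_mean,
        stenosis_position=pos,
        has_stenosis=has_stenosis,
    )


# ---------------------------------------------------------------------------
# sensitivity model


def xmax(R: float, r: float, Cst: float = 1.0) -> float:
    """Relative endolymph displacement sensitivity ``Cst * R * r**2``.

    With the constant factor (endolymph viscosity/density bundle) unknown,
    only relative sensitivities between canals are meaningful; ``Cst``
    defaults to 1.
    """
    if R <= 0 or r <= 0:
        raise ValueError("R and r must be positive")
    return Cst * R * r**2


def xmax_grid(
    r_range: tuple[float, float] = (20.0, 120.0),
    R_range: tuple[float, float] = (300.0, 900.0),
    n: int = 100,
    Cst: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Iso-sensitivity surface over an (r, R) grid for sensitivity maps."""
    r = np.linspace(*r_range, n)
    R = np.linspace(*R_range, n)
    RR, rr = np.meshgrid(R, r, indexing="ij")
    return r, R, Cst * RR * rr**2


# ---------------------------------------------------------------------------
# assembly


def measure_canal(binary: CanalVolume, c_mode: str = "moment") -> CanalMorphometry:
    """Full morphometric chain on a segmented canal volume.

    The circuit ellipse is fitted to the centerline projected onto the
    canal plane (the plane of the two largest moment axes); the lumen
    radius is the mean-equivalent cross-section radius sqrt(cs_mean/pi).
    """
    a, b, c, elong, flat, volume = fit_ellipsoid_3d(binary, c_mode=c_mode)
    centerline, duct_length = extract_centerline(binary)
    profile = cross_section_profile(binary, centerline)

    # project the centerline onto its best-fit plane for the 2D circuit fit
    center = centerline.mean(axis=0)
    _, _, vt = np.linalg.svd(centerline - center, full_matrices=False)
    plane2d = (centerline - center) @ vt[:2].T
    fit = fit_ellipse_2d(plane2d)
    R = circuit_radius(fit.semi_major, fit.semi_minor)
    r = float(np.sqrt(profile.cs_mean / np.pi))
    return CanalMorphometry(
        circuit_radius=R,
        lumen_radius=r,
        Ra=fit.semi_major,
        Rb=fit.semi_minor,
        ellipsoid_a=a,
        ellipsoid_b=b,
        ellipsoid_c=c,
        elongation_ratio=elong,
        flatness_ratio=flat,
        volume=volume,
        duct_length=duct_length,
        cs_mean=profile.cs_mean,
        cs_min=profile.cs_min,
        stenosis_ratio=profile.stenosis_ratio,
        stenosis_position=profile.stenosis_position,
        xmax_relative=xmax(R, r),
    )
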