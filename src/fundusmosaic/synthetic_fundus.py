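"""Synthetic SLO-like fundus pairs with known ground-truth transforms.

The clinical datasets behind SLO mosaicing work are not public, so this
module builds stand-in scenes carrying the features the pipeline relies
on: a recursively bifurcating tree of dark vessels (Gaussian
cross-section) on a brighter textured background with a radial
vignette, a bright elliptical optic disc and a smooth dark macular
region.  Two 768x768 views are cropped from one master scene — one
centered on the fovea, one near the optic nerve head — with a known
similarity or projective perturbation of the ONH view, per-view
contrast (gamma) jitter and independent sensor noise.  The exact
homography relating the two views and a set of matched centerline
points are returned as ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import ProjectiveTransform, warp

from .errors import GenerationError, ParameterError
from .image_io import GrayImage
from .mosaic import overlap_percentage, project_points

log = logging.getLogger(__name__)

VIEW_SIZE = 768


@dataclass
class SyntheticScene:
    """Master scene from which the two views are cropped.

    ``background`` and the per-width centerline masks are kept separately
    so each view can re-render the vessel layer with its own width and
    amplitude jitter (vessel appearance varies between acquisitions while
    the geometry stays fixed).
    """

    canvas: GrayImage
    centerlines: list[np.ndarray]            # per-branch (N, 2) float (x, y)
    disc_center: tuple[float, float]
    fovea_center: tuple[float, float]
    vessel_widths: list[float]               # per-branch tube width, pixels
    background: np.ndarray | None = None
    centerline_masks: dict | None = None     # width bucket -> point mask

    @property
    def n_centerline_points(self) -> int:
        return int(sum(c.shape[0] for c in self.centerlines))


@dataclass
class SyntheticPair:
    """A macula/ONH view pair with exact ground truth."""

    macula_image: GrayImage
    onh_image: GrayImage
    true_homography: np.ndarray              # maps ONH coords -> macula coords
    true_overlap: float
    planted_points_macula: np.ndarray        # (K, 2)
    planted_points_onh: np.ndarray           # (K, 2), matched row-for-row
    transform_kind: str = "similarity"
    seed: int = field(default=0, repr=False)


def _grow_branch(rng: np.random.Generator, start: np.ndarray, angle: float,
                 length: float, width: float, depth: int, size: int,
                 centerlines: list, widths: list) -> None:
    """Random-walk polyline with two children per branch (recursion depth 6)."""
    n = max(int(length), 4)
    pts = np.empty((n, 2))
    pos = start.astype(float).copy()
    for i in range(n):
        angle += rng.normal(0.0, 0.035)
        pos = pos + np.array([np.cos(angle), np.sin(angle)])
        pts[i] = pos
    inside = (pts[:, 0] >= 2) & (pts[:, 0] < size - 2) & (pts[:, 1] >= 2) & (pts[:, 1] < size - 2)
    pts = pts[inside]
    if pts.shape[0] >= 4:
        centerlines.append(pts)
        widths.append(width)
    if depth <= 1 or pts.shape[0] < 4:
        return
    spread = np.deg2rad(22.0 + rng.normal(0.0, 6.0))
    for sign in (-1.0, 1.0):
        _grow_branch(rng, pts[-1], angle + sign * spread * rng.uniform(0.6, 1.2),
                     length * 0.78, max(width * 0.78, 1.5), depth - 1, size,
                     centerlines, widths)


def generate_vessel_tree(seed: int, n_roots: int = 4,
                         image_size: int = 1400) -> SyntheticScene:
    """Build a master scene with a planted vessel tree.

    ``n_roots`` main vessels emanate near the optic disc (arcade-like
    fan), each bifurcating recursively six levels deep.  Degenerate
    parameters are clamped with a warning rather than rejected.
    """
    if n_roots < 1:
        log.warning("n_roots=%d clamped to 1", n_roots)
        n_roots = 1
    if image_size < VIEW_SIZE + 64:
        log.warning("image_size=%d too small for a %d view; clamped to %d",
                    image_size, VIEW_SIZE, VIEW_SIZE + 64)
        image_size = VIEW_SIZE + 64
    rng = np.random.default_rng(seed)
    size = image_size
    disc = np.array([0.64 * size, 0.48 * size]) + rng.uniform(-8, 8, size=2)
    fovea = np.array([0.36 * size, 0.52 * size]) + rng.uniform(-8, 8, size=2)

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    base = 0.56 + 0.05 * ndi.gaussian_filter(rng.standard_normal((size, size)), 30)
    base += 0.025 * ndi.gaussian_filter(rng.standard_normal((size, size)), 2.0)
    r2 = (xx - size / 2) ** 2 + (yy - size / 2) ** 2
    base -= 0.10 * r2 / r2.max()                      # radial vignette
    dqx = (xx - disc[0]) / 52.0
    dqy = (yy - disc[1]) / 42.0
    base += 0.22 * np.exp(-((dqx ** 2 + dqy ** 2) ** 1.5))   # bright optic disc
    fr2 = (xx - fovea[0]) ** 2 + (yy - fovea[1]) ** 2
    base -= 0.13 * np.exp(-fr2 / (2 * 70.0 ** 2))            # dark macula

    centerlines: list[np.ndarray] = []
    widths: list[float] = []
    toward_fovea = np.arctan2(fovea[1] - disc[1], fovea[0] - disc[0])
    # arcade fan: roots leave the disc spread around the disc-fovea axis
    fan = np.linspace(-1.25, 1.25, n_roots) if n_roots > 1 else np.array([0.35])
    for k in range(n_roots):
        a0 = toward_fovea + fan[k] + rng.normal(0.0, 0.12)
        start = disc + rng.uniform(-6, 6, size=2)
        _grow_branch(rng, start, a0, length=110.0, width=5.5, depth=6,
                     size=size, centerlines=centerlines, widths=widths)

    # render tubes: a line of ones blurred with sigma = w/2 has cross-section
    # peak 1/(sqrt(2*pi)*sigma); rescale so each tube darkens by ~depth_amp
    darkness = np.zeros((size, size))
    buckets: dict[float, np.ndarray] = {}
    for pts, w in zip(centerlines, widths):
        key = round(w * 2) / 2
        m = buckets.setdefault(key, np.zeros((size, size)))
        ix = np.clip(np.round(pts[:, 0]).astype(int), 0, size - 1)
        iy = np.clip(np.round(pts[:, 1]).astype(int), 0, size - 1)
        m[iy, ix] = 1.0
    darkness = _render_darkness(buckets)
    canvas = np.clip(base - np.minimum(darkness, 0.30), 0.02, 0.98)
    return SyntheticScene(canvas=GrayImage(canvas),
                          centerlines=centerlines,
                          disc_center=(float(disc[0]), float(disc[1])),
                          fovea_center=(float(fovea[0]), float(fovea[1])),
                          vessel_widths=widths,
                          background=base,
                          centerline_masks=buckets)


def _render_darkness(buckets: dict, width_factor: float = 1.0,
                     amp_factor: float = 1.0) -> np.ndarray:
    darkness = None
    for w, m in buckets.items():
        sigma = max(w * width_factor / 2.0, 0.8)
        depth_amp = amp_factor * (0.16 + 0.012 * w)
        layer = depth_amp * np.sqrt(2 * np.pi) * sigma * ndi.gaussian_filter(m, sigma)
        darkness = layer if darkness is None else darkness + layer
    return darkness if darkness is not None else np.zeros(())


def _translation(t: np.ndarray) -> np.ndarray:
    M = np.eye(3)
    M[0, 2], M[1, 2] = t[0], t[1]
    return M


def _perturbation(kind: str, rng: np.random.Generator) -> np.ndarray:
    """Perturbation of the ONH view about its own image center."""
    c = np.array([(VIEW_SIZE - 1) / 2.0, (VIEW_SIZE - 1) / 2.0])
    if kind == "translation":
        return np.eye(3)
    theta = np.deg2rad(rng.uniform(-5.0, 5.0))
    s = rng.uniform(0.97, 1.03)
    R = np.array([[np.cos(theta), -np.sin(theta), 0],
                  [np.sin(theta), np.cos(theta), 0],
                  [0, 0, 1.0]])
    P = R.copy()
    P[:2, :2] *= s
    if kind == "projective":
        P[2, 0] = rng.uniform(-1.5e-5, 1.5e-5)
        P[2, 1] = rng.uniform(-1.5e-5, 1.5e-5)
    elif kind != "similarity":
        raise ParameterError(f"unknown transform_kind {kind!r}")
    return _translation(c) @ P @ _translation(-c)


def _solve_center_distance(u: np.ndarray, target: float) -> float:
    """Distance between view centers giving the requested footprint overlap
    for a pure translation (closed-form product of the two axis overlaps)."""
    W = float(VIEW_SIZE)

    def overlap(d: float) -> float:
        dx, dy = abs(d * u[0]), abs(d * u[1])
        return max(W - dx, 0.0) * max(W - dy, 0.0) / W ** 2

    lo, hi = 0.0, W / max(abs(u[0]), abs(u[1]))
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if overlap(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def make_pair(scene: SyntheticScene, transform_kind: str = "similarity",
              overlap_target: float = 0.5, contrast_jitter: float = 0.15,
              noise_sd: float = 0.01, speckle_sd: float = 0.005,
              seed: int = 0) -> SyntheticPair:
    """Crop the two 768x768 views and compose the exact ground-truth homography.

    The macula view is an integer-offset crop centered on the fovea; the
    ONH view center sits on the fovea-to-disc axis at the distance that
    yields ``overlap_target``, and is additionally perturbed by the
    requested transform class about its own center.  Per-view gamma
    jitter (log-sd ``contrast_jitter``) and independent Gaussian sensor
    noise are applied after cropping.
    """
    if not (0.2 <= overlap_target <= 0.9):
        raise ParameterError(f"overlap_target must be in [0.2, 0.9], got {overlap_target}")
    rng = np.random.default_rng(seed)
    size = scene.canvas.width
    half = (VIEW_SIZE - 1) / 2.0
    fovea = np.array(scene.fovea_center)
    disc = np.array(scene.disc_center)
    u = disc - fovea
    u = u / np.linalg.norm(u)

    m_off = np.clip(np.round(fovea - half), 0, size - VIEW_SIZE).astype(int)
    d = _solve_center_distance(u, overlap_target)
    o_center = (m_off + half) + d * u
    o_off = np.clip(np.round(o_center - half), 0, size - VIEW_SIZE).astype(int)

    P = _perturbation(transform_kind, rng)
    A = _translation(o_off.astype(float)) @ P          # ONH coords -> master coords
    H = _translation(-m_off.astype(float)) @ A          # ONH coords -> macula coords
    H = H / H[2, 2]

    def view_canvas() -> np.ndarray:
        # per-view vessel rendering: caliber and contrast vary between
        # acquisitions (pulsation, focus, device tone curve), and the
        # caliber variation is local — a smooth random field blends a
        # thin and a thick render so vessel cross-sections differ along
        # their length between the two views
        if scene.background is None or scene.centerline_masks is None:
            return scene.canvas.pixels
        af = float(np.exp(rng.normal(0.0, 0.15)))
        d_thin = _render_darkness(scene.centerline_masks, width_factor=0.7, amp_factor=af)
        d_thick = _render_darkness(scene.centerline_masks, width_factor=1.3, amp_factor=af)
        blend = ndi.gaussian_filter(rng.standard_normal(d_thin.shape), 12.0)
        blend = np.clip(0.5 + 0.5 * blend / (2.0 * blend.std()), 0.0, 1.0)
        dark = blend * d_thin + (1.0 - blend) * d_thick
        amp_field = ndi.gaussian_filter(rng.standard_normal(d_thin.shape), 20.0)
        dark = dark * np.clip(1.0 + 0.3 * amp_field / (2.0 * amp_field.std()), 0.55, 1.45)
        return np.clip(scene.background - np.minimum(dark, 0.30), 0.02, 0.98)

    mac_master = view_canvas()
    onh_master = view_canvas()
    mac = mac_master[m_off[1]:m_off[1] + VIEW_SIZE, m_off[0]:m_off[0] + VIEW_SIZE].copy()
    onh = warp(onh_master, ProjectiveTransform(matrix=A),
               output_shape=(VIEW_SIZE, VIEW_SIZE), order=1, mode="constant", cval=0.0)

    def jitter(img: np.ndarray) -> np.ndarray:
        # per-view acquisition effects, drawn independently for each view:
        # defocus, smooth illumination field, gamma (contrast) and sensor noise
        out = ndi.gaussian_filter(np.clip(img, 0.0, 1.0), float(rng.uniform(0.5, 0.9)))
        illum = ndi.gaussian_filter(rng.standard_normal(img.shape), 150.0)
        scale = float(np.abs(illum).max())
        if scale > 0:
            out = out + 0.04 * illum / scale
        gamma = float(np.exp(rng.normal(0.0, contrast_jitter)))
        out = np.clip(out, 0.0, 1.0) ** gamma
        if speckle_sd > 0:
            # spatially correlated speckle, the dominant SLO noise source
            sp = ndi.gaussian_filter(rng.standard_normal(img.shape), 1.2)
            out = out + speckle_sd * sp / sp.std()
        if noise_sd > 0:
            out = out + rng.normal(0.0, noise_sd, size=img.shape)
        # views are delivered as 8-bit exports; quantize like the device does
        return np.round(np.clip(out, 0.0, 1.0) * 255.0) / 255.0

    mac_img = GrayImage(jitter(mac), center_label="macula")
    onh_img = GrayImage(jitter(onh), center_label="onh")

    achieved = overlap_percentage(H, mac.shape, onh.shape)
    if abs(achieved - overlap_target) > 0.1:
        raise GenerationError(
            f"requested overlap {overlap_target:.2f} unattainable for this scene "
            f"geometry; achieved {achieved:.2f}")

    all_pts = np.vstack(scene.centerlines) if scene.centerlines else np.empty((0, 2))
    p_mac = all_pts - m_off
    Ainv = np.linalg.inv(A)
    p_onh = project_points(Ainv, all_pts) if all_pts.size else all_pts
    margin = 12.0
    lim = VIEW_SIZE - 1 - margin
    keep = ((p_mac[:, 0] >= margin) & (p_mac[:, 0] <= lim)
            & (p_mac[:, 1] >= margin) & (p_mac[:, 1] <= lim)
            & (p_onh[:, 0] >= margin) & (p_onh[:, 0] <= lim)
            & (p_onh[:, 1] >= margin) & (p_onh[:, 1] <= lim))
    p_mac, p_onh = p_mac[keep], p_onh[keep]
    if p_mac.shape[0] > 3000:  # deterministic thinning keeps the pair small
        step = p_mac.shape[0] // 3000 + 1
        p_mac, p_onh = p_mac[::step], p_onh[::step]
    return SyntheticPair(macula_image=mac_img, onh_image=onh_img,
                         true_homography=H, true_overlap=float(achieved),
                         planted_points_macula=p_mac, planted_points_onh=p_onh,
                         transform_kind=transform_kind, seed=seed)


def default_pair(seed: int, transform_kind: str = "similarity",
                 overlap_target: float = 0.5) -> SyntheticPair:
    """One-call generator used by the evaluation harness: scene and pair
    derive their sub-seeds from ``seed`` deterministically."""
    scene = generate_vessel_tree(seed=seed, n_roots=4)
    return make_pair(scene, transform_kind=transform_kind,
                     overlap_target=overlap_target, seed=seed + 10_000)
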