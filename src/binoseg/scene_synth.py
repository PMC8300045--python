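"""Procedural binocular scene synthesis with exact ground truth.

Generates multi-object 3D scenes on a circular ground plane under a
hemispherical textured sky dome, and renders them from a parallel-geometry
stereo camera rig by analytic ray casting.  Every rendered frame carries
pixel-exact per-camera segmentation label maps and normalized depth maps,
which is the point of replacing a general-purpose renderer with an analytic
one: the ground truth is produced by the same visibility computation as the
images themselves.

Conventions (used everywhere in this package):

* World frame: ``z`` is up, the ground plane is ``z = 0``.
* Image frame: row 0 is the top of the image, column 0 the left edge;
  pixel centers sit at half-integer coordinates.
* The left camera is the reference camera for the canonical depth output.
* Depth means distance along the optical axis (z-depth), which is the
  quantity entering the parallel-rig disparity relation ``d = f * B / Z``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

# --------------------------------------------------------------------------
# Module-wide constants (dataset-scale depth normalization; shared between
# scenes so that all depth maps live on a single relative scale).
# --------------------------------------------------------------------------

DEFAULT_NEAR = 0.7   # meters; closest surface mapped to normalized depth 0
DEFAULT_FAR = 12.0   # meters; everything at or beyond maps to depth 1

BACKGROUND_ID = 0    # reserved label for floor + sky

_AMBIENT = 0.45      # diffuse-light shading: ambient term
_DIFFUSE = 0.55      # diffuse-light shading: Lambertian term


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of the scene family to sample from.

    ``n_objects`` objects with pairwise-distinct category ids are strewn
    across a flat disc of radius ``floor_radius`` (meters), enclosed by a
    textured hemispherical dome.  Textures are band-limited power-law
    ("1/f-like") noise with radially averaged power spectrum decaying as
    ``k ** -texture_spectrum_exponent``.
    """

    n_objects: int = 24
    floor_radius: float = 5.2
    category_count: int = 24            # object categories; background is id 0
    object_size_range: tuple[float, float] = (0.3, 0.9)   # diameters, meters
    dome_radius: float = 40.0
    texture_spectrum_exponent: float = 2.0
    rng_seed: int = 0
    appearance_seed: int = 0            # fixes each category's object identity

    def validate(self) -> None:
        if self.n_objects < 0:
            raise ValueError("n_objects must be >= 0")
        if self.category_count < 1:
            raise ValueError("category_count must be >= 1")
        if self.floor_radius <= 0:
            raise ValueError("floor_radius must be > 0")
        if self.dome_radius <= self.floor_radius:
            raise ValueError("dome_radius must exceed floor_radius")
        lo, hi = self.object_size_range
        if not (0 < lo <= hi):
            raise ValueError("object_size_range must satisfy 0 < min <= max")
        if self.n_objects > self.category_count:
            raise ValueError(
                f"cannot place {self.n_objects} objects with pairwise-distinct "
                f"categories drawn from {self.category_count} categories"
            )


@dataclass(frozen=True)
class CameraRig:
    """A parallel-geometry binocular camera pair.

    The two pinhole cameras share their orientation; their optical centers
    are separated by ``baseline`` meters perpendicular to the (common)
    optical axis.  ``focal_length_px`` is the focal length expressed in
    pixels of the target image.
    """

    baseline: float = 0.065
    focal_length_px: float = 260.0
    image_width: int = 224
    image_height: int = 224
    geometry: Literal["parallel"] = "parallel"

    def validate(self) -> None:
        if self.baseline < 0:
            raise ValueError("baseline must be >= 0")
        if self.focal_length_px <= 0:
            raise ValueError("focal_length_px must be > 0")
        if self.image_width < 1 or self.image_height < 1:
            raise ValueError("image dimensions must be positive")
        if self.geometry != "parallel":
            raise ValueError("only parallel viewing geometry is supported")


@dataclass(frozen=True)
class PlacedObject:
    shape: Literal["sphere", "box"]
    category: int                      # 1..category_count
    position: np.ndarray               # (3,) center, meters
    size: float                        # diameter / edge length, meters
    yaw: float                         # box orientation about z, radians
    texture_seed: int
    base_color: np.ndarray             # (3,) RGB in [0,1]

    @property
    def radius(self) -> float:
        """Bounding-sphere radius."""
        if self.shape == "sphere":
            return self.size / 2.0
        return self.size / 2.0 * math.sqrt(3.0)


@dataclass(frozen=True)
class SceneGraph:
    objects: tuple[PlacedObject, ...]
    spec: SceneSpec
    dome_texture_seed: int
    floor_texture_seed: int
    dome_color: np.ndarray
    floor_color: np.ndarray
    light_dir: np.ndarray              # unit vector pointing *toward* the light


@dataclass(frozen=True)
class CameraPose:
    position: np.ndarray               # (3,) cyclopean optical center
    view_dir: np.ndarray               # (3,) unit, points into the scene


@dataclass
class StereoFrame:
    """One binocular sample with full ground truth for both cameras."""

    left_rgb: np.ndarray               # (H, W, 3) float in [0, 1]
    right_rgb: np.ndarray
    left_labels: np.ndarray            # (H, W) int, 0..category_count
    right_labels: np.ndarray
    depth_left: np.ndarray             # (H, W) float in [0, 1], 0 = nearest
    depth_right: np.ndarray

    def validate(self) -> None:
        h, w = self.left_labels.shape
        for name in ("left_rgb", "right_rgb"):
            if getattr(self, name).shape != (h, w, 3):
                raise ValueError(f"{name} has inconsistent shape")
        for name in ("right_labels", "depth_left", "depth_right"):
            if getattr(self, name).shape != (h, w):
                raise ValueError(f"{name} has inconsistent shape")
        for name in ("depth_left", "depth_right"):
            d = getattr(self, name)
            if d.min() < 0.0 or d.max() > 1.0:
                raise ValueError(f"{name} outside [0, 1]")


# --------------------------------------------------------------------------
# Power-law textures
# --------------------------------------------------------------------------


def powerlaw_texture(shape: tuple[int, int], exponent: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Band-limited noise image with a ``k**-exponent`` power spectrum.

    Built in the Fourier domain: white Gaussian noise is shaped with an
    amplitude envelope ``k**(-exponent/2)`` so the radially averaged power
    spectrum decays as ``k**-exponent`` (the "1/f-like" statistics of
    natural images for an exponent near 2).  Output is rescaled to [0, 1].
    """
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    k = np.hypot(fy, fx)
    k[0, 0] = 1.0  # DC untouched
    envelope = k ** (-exponent / 2.0)
    envelope[0, 0] = 0.0
    spectrum = envelope * (rng.standard_normal((h, w))
                           + 1j * rng.standard_normal((h, w)))
    img = np.fft.ifft2(spectrum).real
    lo, hi = img.min(), img.max()
    if hi - lo < 1e-12:
        return np.full(shape, 0.5)
    return (img - lo) / (hi - lo)


def radial_power_slope(img: np.ndarray) -> float:
    """Fit the log-log slope of the radially averaged power spectrum."""
    h, w = img.shape
    f = np.fft.fft2(img - img.mean())
    power = np.abs(f) ** 2
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    k = np.hypot(fy, fx).ravel()
    p = power.ravel()
    # log-spaced annuli between the fundamental and Nyquist
    edges = np.geomspace(1.5 / max(h, w), 0.45, 24)
    centers, means = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        m = (k >= a) & (k < b)
        if m.sum() >= 4:
            centers.append(math.sqrt(a * b))
            means.append(p[m].mean())
    lx = np.log(np.asarray(centers))
    ly = np.log(np.asarray(means))
    slope = np.polyfit(lx, ly, 1)[0]
    return float(slope)


class _Texture:
    """A tileable texture map with bilinear lookup by (u, v) in [0, 1)."""

    def __init__(self, size: int, exponent: float, seed: int):
        self.map = powerlaw_texture((size, size), exponent,
                                    np.random.default_rng(seed))
        self.n = size

    def sample(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        x = np.mod(u, 1.0) * self.n
        y = np.mod(v, 1.0) * self.n
        x0 = np.floor(x).astype(np.intp) % self.n
        y0 = np.floor(y).astype(np.intp) % self.n
        x1 = (x0 + 1) % self.n
        y1 = (y0 + 1) % self.n
        tx = x - np.floor(x)
        ty = y - np.floor(y)
        m = self.map
        return ((1 - ty) * ((1 - tx) * m[y0, x0] + tx * m[y0, x1])
                + ty * ((1 - tx) * m[y1, x0] + tx * m[y1, x1]))


# --------------------------------------------------------------------------
# Scene sampling
# --------------------------------------------------------------------------


def category_appearance(spec: SceneSpec, category: int) -> dict:
    """The fixed visual identity of one object category.

    Each category is a *particular* object — the same shape, size, color
    and surface texture wherever it appears, as for a fixed physical object
    set photographed in many arrangements.  Only placement and orientation
    vary between scenes.  Deterministic in (appearance_seed, category).
    """
    rng = np.random.default_rng((spec.appearance_seed, int(category)))
    return {
        "shape": "sphere" if rng.random() < 0.5 else "box",
        "size": float(rng.uniform(*spec.object_size_range)),
        "base_color": 0.25 + 0.75 * rng.random(3),
        "texture_seed": int(rng.integers(0, 2**31 - 1)),
    }


def sample_scene(spec: SceneSpec, seed: int | None = None) -> SceneGraph:
    """Place ``spec.n_objects`` objects on the floor disc, rejection-sampling
    positions so that no two bounding circles overlap.

    Categories are a random draw *without replacement* from
    ``1..category_count`` — every object in a scene is a distinct category,
    and each category keeps its fixed appearance (see category_appearance).
    Deterministic for a fixed ``seed``.
    """
    spec.validate()
    if seed is None:
        seed = spec.rng_seed
    rng = np.random.default_rng(seed)
    categories = 1 + rng.permutation(spec.category_count)[: spec.n_objects]
    objects: list[PlacedObject] = []
    placed_xy: list[tuple[float, float, float]] = []   # (x, y, footprint r)
    for cat in categories:
        look = category_appearance(spec, cat)
        size = look["size"]
        shape = look["shape"]
        half = size / 2.0
        footprint = half * (math.sqrt(2.0) if shape == "box" else 1.0)
        for _attempt in range(200):
            r = spec.floor_radius * math.sqrt(rng.random())
            theta = rng.uniform(0.0, 2.0 * math.pi)
            x, y = r * math.cos(theta), r * math.sin(theta)
            if math.hypot(x, y) + footprint > spec.floor_radius:
                continue
            if all(math.hypot(x - px, y - py) > footprint + pr
                   for px, py, pr in placed_xy):
                break
        else:
            raise RuntimeError("could not place object without overlap; "
                               "reduce n_objects or object sizes")
        placed_xy.append((x, y, footprint))
        z = half  # rests on the floor
        objects.append(PlacedObject(
            shape=shape,
            category=int(cat),
            position=np.array([x, y, z]),
            size=size,
            yaw=float(rng.uniform(0.0, 2.0 * math.pi)),
            texture_seed=look["texture_seed"],
            base_color=look["base_color"],
        ))
    az = rng.uniform(0.0, 2.0 * math.pi)
    el = rng.uniform(math.radians(35.0), math.radians(75.0))
    light = np.array([math.cos(az) * math.cos(el),
                      math.sin(az) * math.cos(el),
                      math.sin(el)])
    return SceneGraph(
        objects=tuple(objects),
        spec=spec,
        dome_texture_seed=int(rng.integers(0, 2**31 - 1)),
        floor_texture_seed=int(rng.integers(0, 2**31 - 1)),
        dome_color=np.array([0.55, 0.65, 0.85]) * (0.8 + 0.4 * rng.random()),
        floor_color=np.array([0.45, 0.40, 0.30]) * (0.7 + 0.6 * rng.random()),
        light_dir=light,
    )


# --------------------------------------------------------------------------
# Camera walk
# --------------------------------------------------------------------------


def plan_camera_walk(spec: SceneSpec, n_frames: int, seed: int | None = None,
                     camera_height: float = 1.1, look_height: float = 0.35,
                     max_step: float = 0.35) -> list[CameraPose]:
    """A pseudo-random walk around the scene perimeter.

    The cyclopean camera stays on an annulus just outside the floor edge at
    fixed height, advancing by a bounded pseudo-random arc step each frame
    (drifting consistently clockwise or anticlockwise), always looking
    inward at a point on the scene axis.  ``max_step`` bounds the Euclidean
    distance between consecutive camera positions (meters).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if seed is None:
        seed = spec.rng_seed
    rng = np.random.default_rng(seed)
    radius = spec.floor_radius * 1.02
    theta = rng.uniform(0.0, 2.0 * math.pi)
    direction = 1.0 if rng.random() < 0.5 else -1.0
    max_dtheta = max_step / radius
    target = np.array([0.0, 0.0, look_height])
    poses: list[CameraPose] = []
    for _i in range(n_frames):
        pos = np.array([radius * math.cos(theta),
                        radius * math.sin(theta),
                        camera_height])
        view = target - pos
        view = view / np.linalg.norm(view)
        poses.append(CameraPose(position=pos, view_dir=view))
        theta += direction * rng.uniform(0.3, 0.999) * max_dtheta
    return poses


# --------------------------------------------------------------------------
# Ray casting
# --------------------------------------------------------------------------


def _camera_basis(pose: CameraPose):
    f = pose.view_dir / np.linalg.norm(pose.view_dir)
    up = np.array([0.0, 0.0, 1.0])
    r = np.cross(f, up)
    nr = np.linalg.norm(r)
    if nr < 1e-9:
        raise ValueError("degenerate pose: view direction is vertical")
    r = r / nr
    u = np.cross(r, f)
    return f, r, u


def _pixel_rays(rig: CameraRig, f: np.ndarray, r: np.ndarray, u: np.ndarray):
    """Un-normalized ray directions with unit component along the optical
    axis, so the ray parameter *is* z-depth."""
    h, w = rig.image_height, rig.image_width
    cols = (np.arange(w) + 0.5 - w / 2.0) / rig.focal_length_px
    rows = (np.arange(h) + 0.5 - h / 2.0) / rig.focal_length_px
    a = cols[None, :, None]            # horizontal image-plane offset
    b = -rows[:, None, None]           # row 0 is the top of the image
    return f[None, None, :] + a * r[None, None, :] + b * u[None, None, :]


def _intersect_sphere(origin, dirs, center, radius):
    """Smallest positive ray parameter for a sphere, inf where missed."""
    oc = origin - center
    a = np.einsum("hwk,hwk->hw", dirs, dirs)
    b = 2.0 * np.einsum("hwk,k->hw", dirs, oc)
    c = oc @ oc - radius * radius
    disc = b * b - 4 * a * c
    hit = disc >= 0
    sq = np.sqrt(np.where(hit, disc, 0.0))
    t1 = (-b - sq) / (2 * a)
    t2 = (-b + sq) / (2 * a)
    t = np.where(t1 > 1e-6, t1, t2)
    return np.where(hit & (t > 1e-6), t, np.inf)

def _intersect_box(origin, dirs, obj: PlacedObject):
    """Slab intersection with a yaw-rotated cube of edge ``obj.size``."""
    c, s = math.cos(obj.yaw), math.sin(obj.yaw)
    rot = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])  # world->obj
    o = rot @ (origin - obj.position)
    d = np.einsum("ij,hwj->hwi", rot, dirs)
    half = obj.size / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / d
        t0 = (-half - o) * inv
        t1 = (half - o) * inv
    tmin = np.minimum(t0, t1)
    tmax = np.maximum(t0, t1)
    # parallel rays outside a slab never hit it
    parallel_miss = (np.abs(d) < 1e-12) & (np.abs(o) > half)[None, None, :]
    tmin = np.where(np.isnan(tmin) | parallel_miss, -np.inf, tmin)
    tmax = np.where(np.isnan(tmax) | parallel_miss, np.inf, tmax)
    tmax = np.where(parallel_miss.any(axis=2)[..., None], -np.inf, tmax)
    tn = tmin.max(axis=2)
    tf = tmax.min(axis=2)
    t = np.where(tn > 1e-6, tn, tf)
    ok = (tf >= tn) & (t > 1e-6)
    return np.where(ok, t, np.inf)


def _box_normal_and_uv(pts_obj, half):
    """Outward normal (object frame) and a face-atlas (u, v) per point."""
    q = pts_obj / half
    axis = np.argmax(np.abs(q), axis=-1)
    sign = np.sign(np.take_along_axis(q, axis[..., None], -1))[..., 0]
    normal = np.zeros_like(pts_obj)
    np.put_along_axis(normal, axis[..., None], sign[..., None], -1)
    # uv from the two remaining coordinates
    u = np.where(axis == 0, q[..., 1], q[..., 0])
    v = np.where(axis == 2, q[..., 1], q[..., 2])
    u = (u + 1) / 2 + axis          # offset per face so faces differ
    v = (v + 1) / 2 + sign
    return normal, u, v


def render_stereo(scene: SceneGraph, pose: CameraPose, rig: CameraRig,
                  near: float = DEFAULT_NEAR, far: float = DEFAULT_FAR
                  ) -> StereoFrame:
    """Render both cameras of the rig and all ground truth for one pose.

    The two optical centers are offset by ±baseline/2 along the camera's
    right vector; both share the pose's orientation (parallel geometry).
    Visibility is nearest-surface-wins per pixel, and labels and depth come
    from exactly that visibility computation.
    """
    rig.validate()
    f, r, u = _camera_basis(pose)
    half_b = rig.baseline / 2.0
    eyes = {
        "left": pose.position - half_b * r,
        "right": pose.position + half_b * r,
    }
    for name, origin in eyes.items():
        for obj in scene.objects:
            if np.linalg.norm(origin - obj.position) <= obj.radius:
                raise ValueError(
                    f"degenerate pose: {name} camera is inside object "
                    f"category {obj.category}")
    dirs = _pixel_rays(rig, f, r, u)
    out = {}
    for name, origin in eyes.items():
        out[name] = _render_one(scene, origin, dirs, rig, near, far)
    rgb_l, lab_l, dep_l = out["left"]
    rgb_r, lab_r, dep_r = out["right"]
    frame = StereoFrame(left_rgb=rgb_l, right_rgb=rgb_r,
                        left_labels=lab_l, right_labels=lab_r,
                        depth_left=dep_l, depth_right=dep_r)
    frame.validate()
    return frame


def _render_one(scene: SceneGraph, origin, dirs, rig: CameraRig,
                near: float, far: float):
    h, w = rig.image_height, rig.image_width
    spec = scene.spec
    zbuf = np.full((h, w), np.inf)
    labels = np.zeros((h, w), dtype=np.int64)
    # 0 = floor, 1 = dome, 2.. = objects
    surf = np.full((h, w), 1, dtype=np.int64)

    # floor disc (z = 0)
    dz = dirs[..., 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_floor = -origin[2] / dz
    px = origin[0] + t_floor * dirs[..., 0]
    py = origin[1] + t_floor * dirs[..., 1]
    ok = (dz < -1e-12) & (t_floor > 1e-6) & (np.hypot(px, py) <= spec.floor_radius)
    t_floor = np.where(ok, t_floor, np.inf)
    closer = t_floor < zbuf
    zbuf = np.where(closer, t_floor, zbuf)
    surf = np.where(closer, 0, surf)

    # objects
    for i, obj in enumerate(scene.objects):
        if obj.shape == "sphere":
            t = _intersect_sphere(origin, dirs, obj.position, obj.size / 2.0)
        else:
            t = _intersect_box(origin, dirs, obj)
        closer = t < zbuf
        zbuf = np.where(closer, t, zbuf)
        surf = np.where(closer, i + 2, surf)
        labels = np.where(closer, obj.category, labels)
    labels = np.where(surf >= 2, labels, 0)

    # dome distance for shading/texture of remaining pixels (depth clips to 1)
    t_dome = _intersect_sphere(origin, dirs, np.zeros(3), spec.dome_radius)
    zdome = np.where(np.isfinite(t_dome), t_dome, spec.dome_radius)
    zfull = np.where(surf == 1, zdome, zbuf)

    pts = origin[None, None, :] + zfull[..., None] * dirs
    rgb = np.zeros((h, w, 3))
    exp = spec.texture_spectrum_exponent

    # dome shading: textured by view direction (equirectangular), unlit
    dome_mask = surf == 1
    if dome_mask.any():
        tex = _Texture(256, exp, scene.dome_texture_seed)
        d = pts[dome_mask]
        az = np.arctan2(d[:, 1], d[:, 0]) / (2 * math.pi)
        el = np.clip(d[:, 2] / np.maximum(np.linalg.norm(d, axis=1), 1e-9), -1, 1)
        el = np.arcsin(el) / math.pi + 0.5
        val = tex.sample(az * 4.0, el * 4.0)
        rgb[dome_mask] = scene.dome_color * (0.4 + 0.6 * val[:, None])

    light = scene.light_dir
    # floor: texture by world position, lit from above
    floor_mask = surf == 0
    if floor_mask.any():
        tex = _Texture(256, exp, scene.floor_texture_seed)
        p = pts[floor_mask]
        val = tex.sample(p[:, 0] / (2 * spec.floor_radius),
                         p[:, 1] / (2 * spec.floor_radius))
        shade = _AMBIENT + _DIFFUSE * max(light[2], 0.0)
        rgb[floor_mask] = scene.floor_color * shade * (0.4 + 0.6 * val[:, None])

    # objects: texture by object-frame surface coordinates (view-consistent)
    for i, obj in enumerate(scene.objects):
        m = surf == i + 2
        if not m.any():
            continue
        tex = _Texture(128, exp, obj.texture_seed)
        p = pts[m] - obj.position
        if obj.shape == "sphere":
            n = p / np.maximum(np.linalg.norm(p, axis=1, keepdims=True), 1e-9)
            uu = np.arctan2(n[:, 1], n[:, 0]) / (2 * math.pi)
            vv = np.arcsin(np.clip(n[:, 2], -1, 1)) / math.pi + 0.5
            val = tex.sample(uu * 2.0, vv * 2.0)
        else:
            c, s = math.cos(obj.yaw), math.sin(obj.yaw)
            rot = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])
            po = p @ rot.T
            n_obj, uu, vv = _box_normal_and_uv(po, obj.size / 2.0)
            n = n_obj @ rot
            val = tex.sample(uu / 3.0, vv / 3.0)
        lam = np.maximum(n @ light, 0.0)
        shade = _AMBIENT + _DIFFUSE * lam
        rgb[m] = obj.base_color * (shade * (0.4 + 0.6 * val))[:, None]

    rgb = np.clip(rgb, 0.0, 1.0)
    depth = normalize_depth(zfull, near, far)
    return rgb, labels, depth


def normalize_depth(raw_depth: np.ndarray, near: float, far: float
                    ) -> np.ndarray:
    """Affine map of metric z-depth onto [0, 1]; 0 = nearest, 1 = farthest.

    ``near`` and ``far`` are dataset-wide constants so all scenes share one
    relative depth scale; values outside [near, far] are clipped.
    """
    if not (far > near > 0):
        raise ValueError("require far > near > 0")
    return np.clip((raw_depth - near) / (far - near), 0.0, 1.0)


# --------------------------------------------------------------------------
# Dataset generation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitPlan:
    """Scene counts per split and frames per scene."""

    train: int = 40
    val: int = 7
    test: int = 4
    frames_per_scene: int = 50
    test_frames_per_scene: int | None = 25
    # the analyses downstream use 100 test images; with 4 test scenes that
    # means 25 frames per test scene, hence the separate test default

    def frames_for(self, split: str) -> int:
        if split == "test" and self.test_frames_per_scene is not None:
            return self.test_frames_per_scene
        return self.frames_per_scene


def generate_dataset(spec: SceneSpec, rig: CameraRig, plan: SplitPlan,
                     out_dir, seed: int = 0, overwrite: bool = False,
                     near: float = DEFAULT_NEAR, far: float = DEFAULT_FAR,
                     walk_kwargs: dict | None = None):
    """Render a full train/val/test dataset to ``out_dir``.

    Per-scene seeds are spawned deterministically from ``seed`` and are
    disjoint across scenes and splits; regenerating with the same master
    seed reproduces the dataset bit-for-bit.  Returns the manifest dict
    (also written to ``manifest.json``).
    """
    from . import io_cli  # deferred: io_cli imports this module's types

    spec.validate()
    rig.validate()
    walk_kwargs = dict(walk_kwargs or {})
    counts = {"train": plan.train, "val": plan.val, "test": plan.test}
    rng = np.random.default_rng(seed)
    manifest = io_cli.new_manifest(spec, rig, plan, seed, near, far)
    scene_index = 0
    for split, n_scenes in counts.items():
        n_frames = plan.frames_for(split)
        for j in range(n_scenes):
            scene_seed = int(rng.integers(0, 2**31 - 1))
            walk_seed = int(rng.integers(0, 2**31 - 1))
            scene = sample_scene(spec, scene_seed)
            poses = plan_camera_walk(spec, n_frames, walk_seed, **walk_kwargs)
            frames = [render_stereo(scene, pose, rig, near, far)
                      for pose in poses]
            io_cli.write_scene(manifest, out_dir, split, scene_index, frames,
                               scene_seed=scene_seed, walk_seed=walk_seed,
                               overwrite=overwrite)
            scene_index += 1
    io_cli.write_manifest(manifest, out_dir)
    return manifest
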