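"""Synthetic phantoms: CT-like fusiform aneurysm volumes and analytic meshes.

The fusiform phantom is a straight tube with a smooth Gaussian bulge,

    r(z) = r0 + (rmax - r0) * exp(-((z - z0) * dz)^2 / w^2) ,

rendered slice-by-slice as three-tissue images (lumen brighter than wall,
wall brighter than background, additive Gaussian noise) with per-slice
ground-truth outer-wall masks and the exact circular contours.  Intensity
values are synthetic — they only reproduce the contrast *ordering* of
contrast-enhanced CT, not CT physics.

Analytic cylinder and icosphere meshes provide Laplace-law stress oracles
(hoop = pR/h for the cylinder, pR/2h biaxial for the sphere) for validating
the membrane solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .geometry import ContourStack, SurfaceMesh, MM_PER_CM
from .nurbs import SliceContour


@dataclass(frozen=True)
class FusiformSpec:
    """Geometry, grid, and intensity model of the fusiform phantom.

    Radii in cm; grid spacing in mm.  Defaults describe a modest abdominal
    aneurysm: a 2 cm diameter aorta dilating to a 4 cm diameter bulge over a
    ~3 cm half-width, on a CTA-like grid (0.8 mm pixels, 2 mm slices).
    """

    r0: float = 1.0          # baseline (non-aneurysmal) outer radius, cm
    rmax: float = 2.0        # bulge outer radius, cm
    z0: int = 20             # bulge apex slice index
    w: float = 3.0           # bulge Gaussian half-width, cm
    n_slices: int = 40
    grid: int = 128          # in-plane grid, pixels
    pixel_size: float = 0.8  # mm / pixel
    slice_spacing: float = 2.0  # mm
    wall_thickness: float = 0.15  # cm, lumen sits this far inside the wall
    intensities: tuple[float, float, float] = (300.0, 120.0, 20.0)
    noise_sd: float = 10.0
    seed: int = 0
    ring_points: int = 96    # samples per ground-truth contour

    def __post_init__(self) -> None:
        lumen, wall, background = self.intensities
        if not (self.rmax >= self.r0 > 0):
            raise ValueError("need rmax >= r0 > 0")
        if not (lumen > wall > background):
            raise ValueError("intensities must be ordered lumen > wall > "
                             "background")
        if self.n_slices < 1 or self.grid < 8:
            raise ValueError("invalid grid")


def radius_profile(spec: FusiformSpec, z) -> np.ndarray:
    """Outer-wall radius r(z) in cm at slice index ``z`` (scalar or array)."""
    z = np.asarray(z, dtype=float)
    dist_cm = (z - spec.z0) * spec.slice_spacing / MM_PER_CM
    return spec.r0 + (spec.rmax - spec.r0) * np.exp(-(dist_cm / spec.w) ** 2)


def make_volume(spec: FusiformSpec):
    """Render the phantom.

    Returns ``(images, masks, stack)``: float image stack (n, grid, grid),
    uint8 ground-truth outer-wall masks, and the :class:`ContourStack` of
    analytic circles sampled at ``spec.ring_points`` points per slice.
    """
    rng = np.random.default_rng(spec.seed)
    lumen_i, wall_i, background_i = spec.intensities
    n, g = spec.n_slices, spec.grid
    center = (g - 1) / 2.0
    yy, xx = np.mgrid[0:g, 0:g]
    rr_px = np.hypot(xx - center, yy - center)

    images = np.empty((n, g, g), dtype=float)
    masks = np.empty((n, g, g), dtype=np.uint8)
    contours = []
    theta = 2 * np.pi * np.arange(spec.ring_points) / spec.ring_points
    max_r_px = (g / 2.0 - 2) * spec.pixel_size / MM_PER_CM
    for z in range(n):
        r_cm = float(radius_profile(spec, z))
        if r_cm > max_r_px:
            raise ValueError(
                f"phantom radius {r_cm:.2f} cm exceeds grid at slice {z}")
        r_px = r_cm * MM_PER_CM / spec.pixel_size
        lumen_px = max(r_cm - spec.wall_thickness, 0.0) \
            * MM_PER_CM / spec.pixel_size
        outer = rr_px <= r_px
        inner = rr_px <= lumen_px
        img = np.full((g, g), background_i, dtype=float)
        img[outer] = wall_i
        img[inner] = lumen_i
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=img.shape)
        images[z] = img
        masks[z] = outer.astype(np.uint8)
        pts = np.column_stack([center + r_px * np.cos(theta),
                               center + r_px * np.sin(theta)])
        contours.append(SliceContour(points=pts,
                                     pixel_size=spec.pixel_size))
    stack = ContourStack(contours=contours,
                         slice_spacing=spec.slice_spacing,
                         pixel_size=spec.pixel_size)
    return images, masks, stack


def normalize_images(images: np.ndarray) -> np.ndarray:
    """Scale an image stack to [0, 1] for network input."""
    lo, hi = float(images.min()), float(images.max())
    if hi <= lo:
        return np.zeros_like(images, dtype=float)
    return (images - lo) / (hi - lo)


def cylinder_stack(radius_cm: float, length_cm: float, n_slices: int = 25,
                   grid: int = 128, pixel_size: float = 0.8,
                   ring_points: int = 96) -> ContourStack:
    """Contour stack of a straight circular cylinder (Laplace-law oracle
    through the image-space pipeline)."""
    spacing = length_cm * MM_PER_CM / (n_slices - 1)
    center = (grid - 1) / 2.0
    r_px = radius_cm * MM_PER_CM / pixel_size
    theta = 2 * np.pi * np.arange(ring_points) / ring_points
    pts = np.column_stack([center + r_px * np.cos(theta),
                           center + r_px * np.sin(theta)])
    contours = [SliceContour(points=pts.copy(), pixel_size=pixel_size)
                for _ in range(n_slices)]
    return ContourStack(contours=contours, slice_spacing=spacing,
                        pixel_size=pixel_size)


def make_cylinder_mesh(radius: float, length: float, n_theta: int = 48,
                       n_z: int = 25) -> SurfaceMesh:
    """Open circular cylinder of radius/length in cm along +z, with two
    boundary rings; vertices lie exactly on the analytic surface."""
    if radius <= 0 or length <= 0:
        raise ValueError("radius and length must be positive")
    if n_theta < 8 or n_z < 2:
        raise ValueError("need n_theta >= 8 and n_z >= 2")
    theta = 2 * np.pi * np.arange(n_theta) / n_theta
    zs = np.linspace(0.0, length, n_z)
    verts = np.empty((n_z * n_theta, 3))
    for k, z in enumerate(zs):
        sl = slice(k * n_theta, (k + 1) * n_theta)
        verts[sl, 0] = radius * np.cos(theta)
        verts[sl, 1] = radius * np.sin(theta)
        verts[sl, 2] = z
    tris = []
    for k in range(n_z - 1):
        a = k * n_theta + np.arange(n_theta)
        a1 = k * n_theta + (np.arange(n_theta) + 1) % n_theta
        b = a + n_theta
        b1 = a1 + n_theta
        tris.append(np.column_stack([a, a1, b]))
        tris.append(np.column_stack([a1, b1, b]))
    mesh = SurfaceMesh(
        vertices=verts, triangles=np.vstack(tris),
        proximal_ring=np.arange(n_theta),
        distal_ring=np.arange((n_z - 1) * n_theta, n_z * n_theta),
    )
    from .geometry import orient_outward

    return orient_outward(mesh)


def make_sphere_mesh(radius: float, subdivisions: int = 3) -> SurfaceMesh:
    """Closed icosphere of given radius (cm); no boundary rings."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    ico = trimesh.creation.icosphere(subdivisions=subdivisions,
                                     radius=radius)
    return SurfaceMesh(vertices=np.asarray(ico.vertices),
                       triangles=np.asarray(ico.faces))
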