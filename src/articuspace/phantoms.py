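"""Synthetic joint phantoms with analytically known joint-space geometry.

Two articulating bodies — a convex "metacarpal head" and a concave
"phalangeal base" — are voxelized on an isotropic grid, optionally
degraded by Gaussian blur (partial-volume / finite resolution) and
additive Gaussian noise. Because the generating geometry is analytic,
every phantom carries exact ground-truth bone masks and exact gap
statistics, which is what makes the downstream segmentation and
joint-space-width stages testable without patient scans.

Geometries
----------
``parallel_plate``
    Two slabs spanning the full lateral field of view, separated by a
    constant gap along the scan axis. Gap boundaries are aligned to
    voxel boundaries so an integer-voxel gap voxelizes to exactly that
    many gap layers.
``tilted_plate``
    As above but the proximal surface is tilted, giving a linear gap
    gradient across the first lateral axis.
``ball_and_cup``
    Solid sphere (head, distal) articulating with a spherical-shell
    sector (cup, proximal) whose cavity faces the head. An axial center
    offset makes the gap vary over the articulating cap.
``contact_patch``
    Parallel plates with a bony bridge over a fraction of the facing
    area (localized complete loss of joint space, up to full ankylosis).

Voxelization rule: a voxel is bone iff its center lies inside the
analytic solid (center sampling).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .grid import BonePairMask, GridSpec, VolumeImage

__all__ = [
    "OsteophyteSpec",
    "PhantomSpec",
    "GroundTruth",
    "make_phantom",
    "add_contact_patch",
]

GEOMETRIES = ("parallel_plate", "tilted_plate", "ball_and_cup", "contact_patch")

#: Full-width-half-maximum of the default blur kernel, mm — the
#: effective spatial resolution of the emulated scan protocol.
DEFAULT_BLUR_FWHM_MM = 0.130

#: Default additive noise level, in units of the bone/background
#: contrast (bone = 1, background = 0). Chosen conservatively low; the
#: protocol does not prescribe a grayscale noise magnitude.
DEFAULT_NOISE_SD = 0.05


@dataclass(frozen=True)
class OsteophyteSpec:
    """A beak-like marginal bony outgrowth.

    Modeled as a cone attached at the articular rim, pointing outward
    past the joint margin (so it never intrudes into the articular gap,
    matching the marginal hook/beak morphology seen at metacarpal
    heads). Only supported for ``ball_and_cup`` geometry, which is the
    only one with an anatomical rim.
    """

    bone: str = "distal"  # "distal" (head) or "proximal" (cup)
    location_deg: float = 0.0  # azimuth around the rim
    length: float = 1.0  # mm
    base_width: float = 0.6  # mm

    def __post_init__(self) -> None:
        if self.bone not in ("distal", "proximal"):
            raise ValueError("osteophyte bone must be 'distal' or 'proximal'")
        if self.length < 0:
            raise ValueError("osteophyte length must be >= 0")
        if self.length > 0 and not self.base_width > 0:
            raise ValueError("osteophyte base_width must be > 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic joint phantom."""

    geometry: str = "parallel_plate"
    gap: float = 1.0  # mm, nominal joint-space width
    tilt_slope: float = 0.1  # mm gap change per mm lateral (tilted_plate)
    head_radius: float = 2.5  # mm (ball_and_cup)
    cup_radius: float = 3.5  # mm cavity radius (ball_and_cup)
    cup_wall: float = 1.5  # mm shell wall thickness
    cap_angle_deg: float = 70.0  # angular extent of the articulating cap
    center_offset: float = 0.0  # mm, + narrows the gap at the cap pole
    contact_fraction: float = 0.0  # fraction of facing area in bony contact
    plate_thickness: float = 1.5  # mm (plate geometries)
    osteophytes: tuple[OsteophyteSpec, ...] = ()
    blur_fwhm: float = DEFAULT_BLUR_FWHM_MM  # mm; 0 disables
    noise_sd: float = DEFAULT_NOISE_SD  # intensity units; 0 disables
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.gap < 0:
            raise ValueError("gap must be >= 0")
        if not 0.0 <= self.contact_fraction <= 1.0:
            raise ValueError("contact_fraction must lie in [0, 1]")
        if self.blur_fwhm < 0 or self.noise_sd < 0:
            raise ValueError("blur_fwhm and noise_sd must be >= 0")
        if self.geometry == "ball_and_cup" and not self.cup_radius > self.head_radius:
            raise ValueError("invalid ball-and-cup: cup_radius must exceed head_radius")
        object.__setattr__(self, "osteophytes", tuple(self.osteophytes))


@dataclass
class GroundTruth:
    """Analytic gap statistics of a phantom.

    ``jsw_min/mean/max`` summarize the true local gap over the
    articulating surface; ``contact`` is set iff the minimum gap is
    zero. ``gap_field`` maps articulating-surface parameters to the true
    local gap in mm (plates: lateral position; ball-and-cup: polar
    angle).
    """

    jsw_min: float
    jsw_mean: float
    jsw_max: float
    contact: bool
    gap_field: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if not (self.jsw_min <= self.jsw_mean + 1e-12 and self.jsw_mean <= self.jsw_max + 1e-12):
            raise ValueError("ground truth must satisfy min <= mean <= max")
        if self.contact != (self.jsw_min == 0.0):
            raise ValueError("contact flag must hold iff minimum gap is zero")


def add_contact_patch(spec: PhantomSpec, fraction: float) -> PhantomSpec:
    """Return a spec whose phantom has a bony contact patch.

    The stated fraction of the articulating area gets gap zero (the
    bones touch). ``fraction = 0`` returns the spec unchanged;
    ``fraction = 1`` produces a fully ankylotic pair.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if fraction == spec.contact_fraction:
        return spec
    return dataclasses.replace(spec, contact_fraction=fraction)


def _check_fit(condition: bool) -> None:
    if not condition:
        raise ValueError("phantom exceeds grid")


def _plate_solids(spec: PhantomSpec, grid: GridSpec):
    h = grid.voxel_size
    nx, ny, nz = grid.shape
    # Align the gap start to a voxel boundary so integer-voxel gaps
    # voxelize exactly.
    b0 = nz // 2 - int(round(spec.gap / (2 * h)))
    z0 = b0 * h
    z1 = z0 + spec.gap
    t = spec.plate_thickness
    _check_fit(z0 - t >= 2 * h and z1 + t <= (nz - 2) * h)
    X, Y, Z = grid.coordinates()
    cx = nx * h / 2.0

    if spec.geometry == "tilted_plate":
        prox_lo = z1 + spec.tilt_slope * (X - cx)
    else:
        prox_lo = np.full_like(X + Y + 0 * Z, z1)

    distal = (Z >= z0 - t) & (Z < z0)
    proximal = (Z >= prox_lo) & (Z < prox_lo + t)
    distal = np.broadcast_to(distal, grid.shape).copy()
    proximal = np.broadcast_to(proximal, grid.shape).copy()

    frac = spec.contact_fraction
    if frac > 0 and spec.geometry != "tilted_plate":
        area = (nx * h) * (ny * h)
        cy = ny * h / 2.0
        r2 = (X - cx) ** 2 + (Y - cy) ** 2
        in_gap = (Z >= z0) & (Z < z1)
        if frac >= 1.0:
            patch = np.broadcast_to(in_gap, grid.shape)
        else:
            rho2 = frac * area / np.pi
            patch = np.broadcast_to(in_gap & (r2 <= rho2), grid.shape)
        zmid = (z0 + z1) / 2.0
        lower = np.broadcast_to(Z < zmid, grid.shape)
        distal |= patch & lower
        proximal |= patch & ~lower

    # True gap field over the lateral facing area.
    if spec.geometry == "tilted_plate":
        half = nx * h / 2.0
        lo = max(spec.gap - abs(spec.tilt_slope) * half, 0.0)
        hi = spec.gap + abs(spec.tilt_slope) * half
        gt = GroundTruth(lo, spec.gap, hi, contact=(lo == 0.0),
                         gap_field=lambda x: spec.gap + spec.tilt_slope * (np.asarray(x) - cx))
    else:
        g = spec.gap
        if frac > 0:
            mean = (1.0 - frac) * g
            mx = 0.0 if frac >= 1.0 else g
            gt = GroundTruth(0.0, mean, mx, contact=True,
                             gap_field=lambda x: np.full_like(np.asarray(x, dtype=float), g))
        else:
            gt = GroundTruth(g, g, g, contact=(g == 0.0),
                             gap_field=lambda x: np.full_like(np.asarray(x, dtype=float), g))
    return distal, proximal, gt


def _ball_gap(theta: np.ndarray, r_h: float, r_c: float, e: float) -> np.ndarray:
    """Exact radial gap between head surface and cavity surface.

    ``theta`` is the polar angle from the cap pole, measured at the cup
    (cavity) center; the head center sits ``e`` mm above it (positive
    offset pushes the head toward the pole, narrowing the gap there).
    """
    theta = np.asarray(theta, dtype=float)
    s = np.sin(theta)
    c = np.cos(theta)
    inner = np.sqrt(np.maximum(r_h * r_h - e * e * s * s, 0.0)) + e * c
    return r_c - inner


def _ball_solids(spec: PhantomSpec, grid: GridSpec):
    h = grid.voxel_size
    nx, ny, nz = grid.shape
    r_h, r_c, wall = spec.head_radius, spec.cup_radius, spec.cup_wall
    e = spec.center_offset
    cap = np.deg2rad(spec.cap_angle_deg)
    cx, cy = nx * h / 2.0, ny * h / 2.0
    # Head center placed so head + cup + margins fit along z.
    z_head = (nz * h) / 2.0 - (r_c + wall - r_h) / 2.0
    c_head = np.array([cx, cy, z_head])
    c_cup = c_head - np.array([0.0, 0.0, e])
    _check_fit(z_head - r_h >= 2 * h and c_cup[2] + r_c + wall <= nz * h - 2 * h)
    _check_fit(cx - (r_c + wall) >= 2 * h and cy - (r_c + wall) >= 2 * h)

    X, Y, Z = grid.coordinates()
    d_head2 = (X - c_head[0]) ** 2 + (Y - c_head[1]) ** 2 + (Z - c_head[2]) ** 2
    dxc, dyc, dzc = X - c_cup[0], Y - c_cup[1], Z - c_cup[2]
    d_cup = np.sqrt(dxc ** 2 + dyc ** 2 + dzc ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.where(d_cup > 0, dzc / d_cup, 1.0), -1.0, 1.0))

    distal = np.broadcast_to(d_head2 <= r_h * r_h, grid.shape).copy()
    proximal = np.broadcast_to(
        (d_cup >= r_c) & (d_cup <= r_c + wall) & (theta <= cap), grid.shape
    ).copy()

    frac = spec.contact_fraction
    if frac > 0:
        # Solid-angle fraction of the cap fused from the pole outward.
        cos_p = 1.0 - frac * (1.0 - np.cos(cap))
        theta_p = np.arccos(np.clip(cos_p, -1.0, 1.0))
        between = (d_head2 > r_h * r_h) & (d_cup < r_c) & (theta <= theta_p)
        between = np.broadcast_to(between, grid.shape)
        closer_head = np.broadcast_to(
            np.sqrt(d_head2) - r_h <= r_c - d_cup, grid.shape
        )
        distal |= between & closer_head
        proximal |= between & ~closer_head

    for ost in spec.osteophytes:
        cone = _osteophyte_cone(ost, c_head, c_cup, r_h, r_c, wall, cap, X, Y, Z)
        if ost.bone == "distal":
            distal |= cone
        else:
            proximal |= cone

    # Analytic gap over the cap; extrema at pole/edge (monotone in theta).
    base = _ball_gap(np.array([0.0, cap]), r_h, r_c, e)
    lo, hi = float(min(base)), float(max(base))
    thetas = np.linspace(0.0, cap, 2049)
    gvals = _ball_gap(thetas, r_h, r_c, e)
    w = np.sin(thetas)
    mean = float(np.trapezoid(gvals * w, thetas) / np.trapezoid(w, thetas))
    if frac > 0:
        cos_p = 1.0 - frac * (1.0 - np.cos(cap))
        theta_p = np.arccos(np.clip(cos_p, -1.0, 1.0))
        fused = thetas <= theta_p
        gv = np.where(fused, 0.0, gvals)
        mean = float(np.trapezoid(gv * w, thetas) / np.trapezoid(w, thetas))
        hi = 0.0 if frac >= 1.0 else hi
        gt = GroundTruth(0.0, mean, hi, contact=True)
    else:
        gt = GroundTruth(min(lo, mean), mean, max(hi, mean), contact=(lo == 0.0),
                         gap_field=lambda t: _ball_gap(t, r_h, r_c, e))
    return distal, proximal, gt


def _osteophyte_cone(ost, c_head, c_cup, r_h, r_c, wall, cap, X, Y, Z):
    """Voxelize one marginal osteophyte cone."""
    phi = np.deg2rad(ost.location_deg)
    if ost.bone == "distal":
        # Base on the head surface just past the articular margin,
        # pointing radially outward from the head center.
        theta = min(cap + np.deg2rad(15.0), np.pi / 2)
        u = np.array([np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)])
        a = c_head + r_h * u
    else:
        # Base on the cup rim annulus, pointing radially outward in the
        # rim direction.
        u = np.array([np.sin(cap) * np.cos(phi), np.sin(cap) * np.sin(phi), np.cos(cap)])
        a = c_cup + (r_c + wall / 2.0) * u
    if ost.length == 0:
        return np.zeros(np.broadcast_shapes(X.shape, Y.shape, Z.shape), dtype=bool)
    px, py, pz = X - a[0], Y - a[1], Z - a[2]
    t = px * u[0] + py * u[1] + pz * u[2]
    lat2 = (px - t * u[0]) ** 2 + (py - t * u[1]) ** 2 + (pz - t * u[2]) ** 2
    with np.errstate(invalid="ignore"):
        rad = (ost.base_width / 2.0) * (1.0 - t / ost.length)
    cone = (t >= -1e-9) & (t <= ost.length) & (lat2 <= np.maximum(rad, 0.0) ** 2)
    return np.broadcast_to(cone, np.broadcast_shapes(X.shape, Y.shape, Z.shape)).copy()


def make_phantom(
    spec: PhantomSpec, grid: GridSpec
) -> tuple[VolumeImage, BonePairMask, GroundTruth]:
    """Generate one synthetic joint volume with exact ground truth.

    Returns the grayscale volume (bone 1.0, background 0.0, optionally
    blurred and noised), the exact ground-truth bone-pair masks, and the
    analytic gap statistics. With ``blur_fwhm = 0`` and ``noise_sd = 0``
    the volume thresholded at 0.5 reproduces the masks exactly.
    """
    if spec.osteophytes and spec.geometry != "ball_and_cup":
        raise ValueError("osteophytes require ball_and_cup geometry")
    if spec.geometry == "ball_and_cup":
        distal, proximal, gt = _ball_solids(spec, grid)
    else:
        distal, proximal, gt = _plate_solids(spec, grid)

    values = (distal | proximal).astype(np.float64)
    if spec.blur_fwhm > 0:
        sigma = spec.blur_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / grid.voxel_size
        values = ndimage.gaussian_filter(values, sigma=sigma)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)

    masks = BonePairMask(distal=distal, proximal=proximal, grid=grid)
    return VolumeImage(values=values, grid=grid), masks, gt
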