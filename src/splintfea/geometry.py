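"""Parametric dentition geometry: tooth, PDL-shell and splint solids.

The patient CT is replaced by an idealized mandibular arch of axisymmetric
teeth.  Each tooth is a crown frustum (z in [0, crown_height]) stacked on a
tapered root frustum (z in [-root_length, 0]) along the vertical occlusal
axis; the periodontal ligament (PDL) is an equidistant shell of fixed
thickness around the root surface only; the splint is a connected band
following the arch that covers the crowns with zero inner gap (the teeth are
subtracted from the band, so its inner surface coincides with the crown
surfaces).

All solids are implicit: they expose a vectorized inside/outside predicate
and a bounding box, which is what the background-grid mesher and the voxel
phantom consume.  Coordinates are in mm; +z is occlusal (up).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ToothSolid",
    "PdlShell",
    "SplintSolid",
    "DentitionSpec",
    "Dentition",
    "ARCH_ORDER_14",
    "build_tooth_solid",
    "build_pdl_shell",
    "build_splint_solid",
    "build_dentition",
]

#: Left-to-right anatomical order of the 14 mandibular teeth (FDI codes).
ARCH_ORDER_14: tuple[int, ...] = (37, 36, 35, 34, 33, 32, 31, 41, 42, 43, 44, 45, 46, 47)

#: Per-tooth-position default dimensions of the miniature synthetic arch, mm.
#: Keys are the FDI position digit (1 incisor .. 7 second molar); values are
#: (crown_radius, crown_height, root_length).
_DEFAULT_DIMS: Mapping[int, tuple[float, float, float]] = {
    1: (0.55, 1.8, 2.4),
    2: (0.55, 1.8, 2.4),
    3: (0.65, 1.9, 3.0),
    4: (0.75, 1.7, 2.6),
    5: (0.75, 1.7, 2.6),
    6: (0.95, 1.6, 2.8),
    7: (0.95, 1.6, 2.8),
}


def _seg_dist_2d(p: np.ndarray, a: tuple[float, float], b: tuple[float, float]) -> np.ndarray:
    """Distance from 2-D points ``p`` (N,2) to the segment a-b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(p - a, axis=1)
    t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(p - proj, axis=1)


@dataclass(frozen=True)
class ToothSolid:
    """Axisymmetric crown+root solid with a vertical axis through ``center``."""

    fdi: int
    center: tuple[float, float]
    crown_radius: float
    crown_height: float
    root_length: float
    crown_top_radius: float | None = None
    root_radius: float | None = None
    root_tip_radius: float | None = None

    def __post_init__(self) -> None:
        for name in ("crown_radius", "crown_height", "root_length"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive for tooth {self.fdi}")
        if self.crown_top_radius is None:
            # cylindrical crown by default: a tapered crown rasterizes to a
            # staircase whose notches concentrate stress artificially
            object.__setattr__(self, "crown_top_radius", self.crown_radius)
        if self.root_radius is None:
            object.__setattr__(self, "root_radius", 0.85 * self.crown_radius)
        if self.root_tip_radius is None:
            object.__setattr__(self, "root_tip_radius", 0.25 * self.crown_radius)
        if not (0.0 <= self.root_tip_radius < self.root_radius):
            raise ValueError("root must taper: 0 <= tip radius < cervical radius")

    # -- geometry queries --------------------------------------------------

    def _cyl(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        r = np.hypot(pts[:, 0] - self.center[0], pts[:, 1] - self.center[1])
        return r, pts[:, 2]

    def radius_at(self, z: np.ndarray) -> np.ndarray:
        """Piecewise-linear profile radius R(z); 0 outside the solid's span."""
        z = np.asarray(z, dtype=float)
        crown = self.crown_radius + (self.crown_top_radius - self.crown_radius) * (
            z / self.crown_height
        )
        root = self.root_radius + (self.root_tip_radius - self.root_radius) * (
            -z / self.root_length
        )
        R = np.where(z >= 0.0, crown, root)
        return np.where((z >= -self.root_length) & (z <= self.crown_height), R, -1.0)

    def contains(self, pts: np.ndarray) -> np.ndarray:
        r, z = self._cyl(pts)
        return r <= self.radius_at(z)

    def root_surface_distance(self, pts: np.ndarray) -> np.ndarray:
        """Distance (mm) to the root surface: lateral taper plus apex cap.

        Axisymmetry reduces this to a 2-D point-to-polyline distance in the
        (radial, z) half-plane.
        """
        r, z = self._cyl(pts)
        p2 = np.column_stack([r, z])
        lateral = _seg_dist_2d(p2, (self.root_radius, 0.0), (self.root_tip_radius, -self.root_length))
        apex = _seg_dist_2d(p2, (self.root_tip_radius, -self.root_length), (0.0, -self.root_length))
        return np.minimum(lateral, apex)

    @property
    def total_height(self) -> float:
        return self.crown_height + self.root_length

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        rmax = max(self.crown_radius, self.crown_top_radius, self.root_radius)
        cx, cy = self.center
        lo = np.array([cx - rmax, cy - rmax, -self.root_length])
        hi = np.array([cx + rmax, cy + rmax, self.crown_height])
        return lo, hi

    def analytic_volume(self) -> float:
        """Exact volume of the crown frustum plus the root frustum, mm^3."""

        def frustum(h: float, R: float, r: float) -> float:
            return np.pi * h / 3.0 * (R * R + R * r + r * r)

        return frustum(self.crown_height, self.crown_radius, self.crown_top_radius) + frustum(
            self.root_length, self.root_radius, self.root_tip_radius
        )

    def root_lateral_area(self) -> float:
        """Lateral (slant) surface area of the root frustum, mm^2."""
        slant = np.hypot(self.root_length, self.root_radius - self.root_tip_radius)
        return np.pi * (self.root_radius + self.root_tip_radius) * slant


@dataclass(frozen=True)
class PdlShell:
    """Equidistant shell of ``thickness`` mm around the root part of a tooth."""

    tooth: ToothSolid
    thickness: float = 0.25

    def __post_init__(self) -> None:
        if self.thickness <= 0.0:
            raise ValueError("PDL thickness must be positive")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        below_cervix = pts[:, 2] <= 1e-12
        outside = ~self.tooth.contains(pts)
        near = self.tooth.root_surface_distance(pts) <= self.thickness
        return below_cervix & outside & near

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.tooth.bounding_box
        t = self.thickness
        return lo - t, np.array([hi[0] + t, hi[1] + t, 0.0])

    def analytic_volume(self) -> float:
        """First-order thin-shell estimate of the shell volume.

        Lateral area evaluated on the mid-offset surface (the outward offset
        grows the frustum radii by (t/2) * L/slant) plus the apex cap, times
        the thickness.  Good to a few percent for shells thin relative to
        the root radius.
        """
        t = self.tooth
        slant = np.hypot(t.root_length, t.root_radius - t.root_tip_radius)
        delta = 0.5 * self.thickness * t.root_length / slant
        lateral_mid = np.pi * (t.root_radius + t.root_tip_radius + 2 * delta) * slant
        cap = np.pi * t.root_tip_radius**2
        return (lateral_mid + cap) * self.thickness


@dataclass(frozen=True)
class SplintSolid:
    """Connected occlusal splint: an arch-following band minus the teeth.

    The band spans ``z_lo .. z_hi`` vertically and extends ``halfwidth`` mm
    laterally from the arch polyline through the tooth axes.  Because the
    tooth solids are subtracted, the inner splint surface coincides with the
    crown surfaces (no gap), which is how the appliance seats clinically.
    """

    teeth: tuple[ToothSolid, ...]
    thickness: float
    halfwidth: float
    z_lo: float
    z_hi: float

    def __post_init__(self) -> None:
        if len(self.teeth) < 2:
            raise ValueError("a splint needs at least 2 teeth")
        if self.thickness <= 0.0:
            raise ValueError("splint thickness must be positive")

    @property
    def arch_polyline(self) -> np.ndarray:
        return np.array([t.center for t in self.teeth], dtype=float)

    def _band(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        xy = pts[:, :2]
        poly = self.arch_polyline
        d = np.full(len(xy), np.inf)
        for a, b in zip(poly[:-1], poly[1:]):
            d = np.minimum(d, _seg_dist_2d(xy, tuple(a), tuple(b)))
        return (d <= self.halfwidth) & (pts[:, 2] >= self.z_lo) & (pts[:, 2] <= self.z_hi)

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        inside = self._band(pts)
        for tooth in self.teeth:
            inside &= ~tooth.contains(pts)
        return inside

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        poly = self.arch_polyline
        lo = np.array([poly[:, 0].min() - self.halfwidth, poly[:, 1].min() - self.halfwidth, self.z_lo])
        hi = np.array([poly[:, 0].max() + self.halfwidth, poly[:, 1].max() + self.halfwidth, self.z_hi])
        return lo, hi


@dataclass(frozen=True)
class DentitionSpec:
    """Parameters of the synthetic arch standing in for the patient CT."""

    n_teeth: int = 14
    arch_depth_ratio: float = 0.55          # sagittal depth / half-span of the arch
    crown_gap_mm: float = 0.40              # clearance between adjacent crowns
    pdl_thickness_mm: float = 0.25
    splint_thickness_mm: float = 0.40
    dims_by_position: Mapping[int, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_DIMS)
    )
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.n_teeth <= 14:
            raise ValueError("n_teeth must be in 2..14")
        if self.pdl_thickness_mm <= 0 or self.splint_thickness_mm <= 0:
            raise ValueError("thicknesses must be positive")
        for pos, (rc, hc, lr) in self.dims_by_position.items():
            if min(rc, hc, lr) <= 0:
                raise ValueError(f"non-positive tooth dimension for position {pos}")

    @property
    def fdi_codes(self) -> tuple[int, ...]:
        """FDI codes used, centred on the midline for partial arches."""
        n = self.n_teeth
        start = (14 - n) // 2
        return ARCH_ORDER_14[start : start + n]


@dataclass(frozen=True)
class Dentition:
    """A built arch: tooth solids, their PDL shells, optional splint."""

    spec: DentitionSpec
    teeth: tuple[ToothSolid, ...]
    pdl_shells: tuple[PdlShell, ...]
    splint: SplintSolid | None = None

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        boxes = [t.bounding_box for t in self.teeth] + [s.bounding_box for s in self.pdl_shells]
        if self.splint is not None:
            boxes.append(self.splint.bounding_box)
        lo = np.min([b[0] for b in boxes], axis=0)
        hi = np.max([b[1] for b in boxes], axis=0)
        return lo, hi

    def with_splint(self, splint: SplintSolid | None) -> "Dentition":
        return replace(self, splint=splint)


# ---------------------------------------------------------------------------
# builders


def build_tooth_solid(
    fdi: int,
    center: tuple[float, float] = (0.0, 0.0),
    crown_radius: float = 0.75,
    crown_height: float = 1.8,
    root_length: float = 2.6,
    **kwargs,
) -> ToothSolid:
    return ToothSolid(
        fdi=fdi,
        center=center,
        crown_radius=crown_radius,
        crown_height=crown_height,
        root_length=root_length,
        **kwargs,
    )


def build_pdl_shell(tooth: ToothSolid, thickness: float = 0.25) -> PdlShell:
    return PdlShell(tooth=tooth, thickness=thickness)


def _arch_positions(radii: Sequence[float], gap: float, depth_ratio: float) -> np.ndarray:
    """Place tooth axes along a parabolic arch with prescribed crown spacing.

    The arch is y = depth * (1 - (x/halfspan)^2); tooth centres are spaced
    along its arc so adjacent crowns keep ``gap`` mm of clearance.  The
    half-span is solved by bisection so the total arc length matches the sum
    of the required spacings.
    """
    spacings = [radii[i] + radii[i + 1] + gap for i in range(len(radii) - 1)]
    total = float(sum(spacings))
    if len(radii) == 2:
        # trivial arch: two teeth on a straight segment
        return np.array([[-total / 2, 0.0], [total / 2, 0.0]])

    def arc_xy(halfspan: float, n: int = 2048) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        depth = depth_ratio * halfspan
        x = np.linspace(-halfspan, halfspan, n)
        y = depth * (1.0 - (x / halfspan) ** 2)
        s = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(x), np.diff(y)))])
        return x, y, s

    lo, hi = total / 4.0, total
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if arc_xy(mid)[2][-1] < total:
            lo = mid
        else:
            hi = mid
    x, y, s = arc_xy(0.5 * (lo + hi))
    targets = np.concatenate([[0.0], np.cumsum(spacings)])
    cx = np.interp(targets, s, x)
    cy = np.interp(targets, s, y)
    return np.column_stack([cx, cy])


def build_dentition(spec: DentitionSpec, with_splint: bool = False) -> Dentition:
    """Build the synthetic arch (teeth + PDL shells, optionally a splint)."""
    codes = spec.fdi_codes
    dims = [spec.dims_by_position[c % 10] for c in codes]
    radii = [d[0] for d in dims]
    centers = _arch_positions(radii, spec.crown_gap_mm, spec.arch_depth_ratio)

    teeth = tuple(
        ToothSolid(
            fdi=code,
            center=(float(cx), float(cy)),
            crown_radius=rc,
            crown_height=hc,
            root_length=lr,
        )
        for code, (cx, cy), (rc, hc, lr) in zip(codes, centers, dims)
    )

    # PDL shells must not reach a neighbouring tooth
    for a, b in zip(teeth[:-1], teeth[1:]):
        d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
        root_gap = d - a.root_radius - b.root_radius
        if root_gap <= spec.pdl_thickness_mm:
            raise ValueError(
                f"PDL thickness {spec.pdl_thickness_mm} mm exceeds the "
                f"{root_gap:.3f} mm root gap between teeth {a.fdi} and {b.fdi}"
            )

    shells = tuple(PdlShell(t, spec.pdl_thickness_mm) for t in teeth)
    splint = build_splint_solid(list(teeth), spec.splint_thickness_mm) if with_splint else None
    return Dentition(spec=spec, teeth=teeth, pdl_shells=shells, splint=splint)


def build_splint_solid(teeth: Sequence[ToothSolid], thickness: float) -> SplintSolid:
    """Build the splint band over a sequence of (arch-ordered) crowns."""
    if len(teeth) < 2:
        raise ValueError("a splint needs at least 2 teeth")
    halfwidth = max(t.crown_radius for t in teeth) + thickness
    z_hi = max(t.crown_height for t in teeth) + thickness
    z_lo = 0.45 * min(t.crown_height for t in teeth)
    return SplintSolid(
        teeth=tuple(teeth), thickness=thickness, halfwidth=halfwidth, z_lo=z_lo, z_hi=z_hi
    )
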