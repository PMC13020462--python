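"""Parametric synthetic thorax: torso, lungs, heart, ribs, airways, fluid.

The anatomy is a simplified stand-in for a CT-segmented thorax, built from
implicit solids so that every region query is a vectorized point test:

* torso: vertical elliptic cylinder (semi-axes ``a``, ``b``, height ``H``),
  auto-scaled so pi*a*b*H hits the target thorax volume (default 23.4 L);
* lungs: vertically truncated ellipsoids, one per side, auto-scaled so their
  realized volume (after carving heart and bronchi) hits the target total
  inflated-lung volume (default 4.84 L);
* heart: an ellipsoid centred left of the midline; where it overlaps the lung
  solids it takes precedence, emulating the cardiac notch;
* ribs: 12 pairs of thin elliptical-arc bars on a shell just inside the torso
  surface, interrupted at sternum and spine;
* airways: trachea plus two main bronchi whose lumina are excluded from the
  conductive domain (inner surfaces electrically insulating);
* fluid: dependent pooling in a lower lobe, ``lung AND {z < cut_height}``,
  with the cut height found by bisection against a tabulated volume profile.

Coordinates are SI: z vertical (toward the head), +y anterior, +x toward the
patient's left.  Electrode patches live on the anterior surface and are
addressed in the unrolled surface metric ``(w, z)`` where ``w`` is arc length
along the anterior ellipse arc, measured from the midline, positive toward
the patient's right.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Literal

import numpy as np

__all__ = [
    "GeometryError",
    "ThoraxParams",
    "FluidSpec",
    "ElectrodeArray",
    "ThoraxGeometry",
    "build_geometry",
    "carve_fluid_region",
    "place_electrode_array",
    "REGION_LABELS",
    "LABEL_NAMES",
    "AIRWAY_LUMEN",
]

Side = Literal["left", "right"]

# integer element labels; AIRWAY_LUMEN marks excluded (non-conductive) cells
REGION_LABELS = {
    "soft_tissue": 0,
    "lung_left": 1,
    "lung_right": 2,
    "heart": 3,
    "rib": 4,
    "fluid": 5,
}
LABEL_NAMES = {v: k for k, v in REGION_LABELS.items()}
AIRWAY_LUMEN = -1

# corner angles (degrees) of the four structured-mesh blocks on the torso
# ellipse; the anterior face spans [30, 150] and carries the electrodes
CORNER_ANGLES_DEG = (30.0, 150.0, 210.0, 330.0)

DEFAULT_CORNERS = {"A": "TL", "B": "BL", "C": "TR", "D": "BR"}

_QUAD_N = (96, 96, 160)  # lung volume quadrature grid (x, y, z)


class GeometryError(ValueError):
    """Raised when a requested geometry is infeasible; names the constraint."""


@dataclass(frozen=True)
class ThoraxParams:
    """Parametric description of the synthetic thorax (all lengths in m)."""

    # chest-like proportions: wide and shallow (transverse/AP ratio ~1.45),
    # 38 cm segment height; realizes 23.4 L exactly after auto-scaling
    torso_semi_axis_x: float = 0.169
    torso_semi_axis_y: float = 0.117
    torso_height: float = 0.38
    # lung ellipsoid template, shared by both sides before volume scaling;
    # the base plane cuts just below the equator, giving a wide
    # diaphragm-side base and a tapering apex (truncated half-ellipsoid)
    lung_semi_axes: tuple[float, float, float] = (0.055, 0.080, 0.20)
    lung_center_abs_x: float = 0.090
    lung_center_y: float = 0.004
    # cardiac impression: the heart displaces the left lung posteriorly,
    # so left lower-lobe fluid lies deeper beneath the chest surface than
    # right - the anatomical source of the left/right sensitivity contrast
    lung_left_posterior_offset: float = 0.012
    lung_center_z: float = 0.16
    lung_base_height: float = 0.105
    lung_volume_fraction_right: float = 0.53
    # heart: ~0.73 L ellipsoid, predominantly left of the midline, resting
    # low against the anterior chest wall (cardiac notch).  Left lower-lobe
    # fluid is therefore retrocardiac - displaced posteriorly, away from
    # the left electrode array - which is what makes left-side measurements
    # less sensitive to fluid than right-side ones
    heart_center: tuple[float, float, float] = (0.052, 0.038, 0.160)
    heart_semi_axes: tuple[float, float, float] = (0.055, 0.046, 0.064)
    ribs_enabled: bool = True
    rib_count_pairs: int = 12
    rib_cross_section_radius: float = 0.004
    rib_shell_scale: float = 0.90
    rib_z_range: tuple[float, float] = (0.125, 0.340)
    airways_enabled: bool = True
    trachea_radius: float = 0.008
    trachea_xy: tuple[float, float] = (0.0, -0.020)
    carina_height: float = 0.245
    bronchus_radius: float = 0.0065
    bronchus_end: tuple[float, float, float] = (0.070, -0.008, 0.190)
    target_thorax_volume: float = 23.4e-3
    target_lung_volume_total: float = 4.84e-3

    def validate(self) -> None:
        for name in ("torso_semi_axis_x", "torso_semi_axis_y", "torso_height",
                     "rib_cross_section_radius", "trachea_radius",
                     "bronchus_radius", "target_thorax_volume",
                     "target_lung_volume_total"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if any(s <= 0 for s in self.lung_semi_axes + self.heart_semi_axes):
            raise GeometryError("semi-axes must be positive")
        if not 0.0 < self.lung_volume_fraction_right < 1.0:
            raise GeometryError("lung_volume_fraction_right must be in (0, 1)")
        if self.rib_count_pairs < 0:
            raise GeometryError("rib_count_pairs must be non-negative")


@dataclass(frozen=True)
class FluidSpec:
    """Dependent fluid pooling in one lower lobe."""

    side: Side
    target_volume: float
    realized_volume: float | None = None
    cut_height: float | None = None


@dataclass(frozen=True)
class ElectrodeArray:
    """Tetrapolar square array on the anterior surface.

    ``centers`` maps each label A..D to its (w, z) surface coordinates.
    """

    side: Side
    vertical_offset: float
    separation: float
    diameter: float
    corner_assignment: tuple[tuple[str, str], ...]
    centers: tuple[tuple[str, float, float], ...]

    def center_of(self, label: str) -> tuple[float, float]:
        for lab, w, z in self.centers:
            if lab == label:
                return (w, z)
        raise KeyError(label)


@dataclass(frozen=True)
class _Lung:
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    base_height: float


def _truncated_ellipsoid_volume(semi: tuple[float, float, float],
                                cz: float, z_lo: float) -> float:
    """Volume of an ellipsoid clipped to z >= z_lo (closed form)."""
    la, lb, lc = semi
    t0 = max(-1.0, min(1.0, (z_lo - cz) / lc))
    f = lambda t: t - t**3 / 3.0
    return math.pi * la * lb * lc * (f(1.0) - f(t0))


class ThoraxGeometry:
    """Immutable solid model with labelled implicit regions."""

    def __init__(self, params: ThoraxParams, torso_ab: tuple[float, float],
                 lungs: dict[Side, _Lung],
                 fluid: dict[Side, FluidSpec] | None = None,
                 electrode_array: ElectrodeArray | None = None):
        self.params = params
        self.torso_a, self.torso_b = torso_ab
        self.height = params.torso_height
        self.lungs = lungs
        self.fluid = dict(fluid or {})
        self.electrode_array = electrode_array
        self._arc_cache: tuple[np.ndarray, np.ndarray] | None = None
        self._lung_sample_cache: dict[Side, tuple[float, np.ndarray]] = {}

    # ---------------------------------------------------------------- solids
    def torso_volume(self) -> float:
        """Analytic pi*a*b*H of the elliptic-cylinder torso."""
        return math.pi * self.torso_a * self.torso_b * self.height

    def heart_volume(self) -> float:
        a, b, c = self.params.heart_semi_axes
        return 4.0 / 3.0 * math.pi * a * b * c

    def lung_base_height(self, side: Side) -> float:
        return self.lungs[side].base_height

    def _in_ellipsoid(self, pts, center, semi) -> np.ndarray:
        d = (pts - np.asarray(center)) / np.asarray(semi)
        return np.einsum("ij,ij->i", d, d) <= 1.0

    def _in_lung_solid(self, pts: np.ndarray, side: Side) -> np.ndarray:
        lung = self.lungs[side]
        return self._in_ellipsoid(pts, lung.center, lung.semi_axes) & (
            pts[:, 2] >= lung.base_height
        )

    def _in_heart(self, pts: np.ndarray) -> np.ndarray:
        p = self.params
        return self._in_ellipsoid(pts, p.heart_center, p.heart_semi_axes)

    def _in_airway_lumen(self, pts: np.ndarray) -> np.ndarray:
        p = self.params
        if not p.airways_enabled:
            return np.zeros(len(pts), dtype=bool)
        tx, ty = p.trachea_xy
        mask = ((pts[:, 2] >= p.carina_height)
                & ((pts[:, 0] - tx) ** 2 + (pts[:, 1] - ty) ** 2
                   <= p.trachea_radius**2))
        carina = np.array([tx, ty, p.carina_height])
        ex, ey, ez = p.bronchus_end
        for sgn in (+1.0, -1.0):
            end = np.array([sgn * ex, ey, ez])
            mask |= _near_segment(pts, carina, end, p.bronchus_radius)
        return mask

    def _in_rib(self, pts: np.ndarray) -> np.ndarray:
        p = self.params
        if not p.ribs_enabled or p.rib_count_pairs == 0:
            return np.zeros(len(pts), dtype=bool)
        sa = p.rib_shell_scale * self.torso_a
        sb = p.rib_shell_scale * self.torso_b
        r = p.rib_cross_section_radius
        z_lo, z_hi = p.rib_z_range
        n = p.rib_count_pairs
        # cheap prefilters: distance to the nearest rib plane (levels are
        # equispaced) and to the shell ring, before any trigonometry
        if n > 1:
            step = (z_hi - z_lo) / (n - 1)
            k = np.clip(np.round((pts[:, 2] - z_lo) / step), 0, n - 1)
            dz = np.abs(pts[:, 2] - (z_lo + k * step))
        else:
            dz = np.abs(pts[:, 2] - z_lo)
        rr = np.sqrt((pts[:, 0] / sa) ** 2 + (pts[:, 1] / sb) ** 2)
        cand = (dz <= r) & (np.abs(rr - 1.0) * min(sa, sb) <= 1.5 * r)
        mask = np.zeros(len(pts), dtype=bool)
        if not cand.any():
            return mask
        sub = pts[cand]
        phi = np.arctan2(sub[:, 1] / sb, sub[:, 0] / sa)
        near = np.column_stack([sa * np.cos(phi), sb * np.sin(phi)])
        dp2 = np.sum((sub[:, :2] - near) ** 2, axis=1)
        hit = dp2 + dz[cand] ** 2 <= r**2
        # interruptions at the sternum (anterior) and spine (posterior)
        deg = np.degrees(phi)
        hit &= np.abs(_angdiff(deg, 90.0)) > 18.0
        hit &= np.abs(_angdiff(deg, 270.0)) > 12.0
        mask[np.nonzero(cand)[0]] = hit
        return mask

    def inside_torso(self, pts: np.ndarray) -> np.ndarray:
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        return ((x / self.torso_a) ** 2 + (y / self.torso_b) ** 2 <= 1.0) & (
            (z >= 0.0) & (z <= self.height)
        )

    def inside_domain(self, pts: np.ndarray) -> np.ndarray:
        """Conductive domain: torso minus airway lumina."""
        return self.inside_torso(pts) & ~self._in_airway_lumen(pts)

    def label_points(self, pts: np.ndarray) -> np.ndarray:
        """Region label per point (points assumed inside the torso).

        Precedence: airway lumen (excluded) > heart > fluid > lung > rib >
        soft tissue; precedence is what keeps the regions disjoint.
        """
        pts = np.asarray(pts, dtype=float)
        out = np.full(len(pts), REGION_LABELS["soft_tissue"], dtype=np.int32)
        rib = self._in_rib(pts)
        out[rib] = REGION_LABELS["rib"]
        for side in ("left", "right"):
            in_lung = self._in_lung_solid(pts, side)
            out[in_lung] = REGION_LABELS[f"lung_{side}"]
            spec = self.fluid.get(side)
            if spec is not None and spec.cut_height is not None:
                out[in_lung & (pts[:, 2] < spec.cut_height)] = (
                    REGION_LABELS["fluid"])
        heart = self._in_heart(pts)
        out[heart] = REGION_LABELS["heart"]
        out[self._in_airway_lumen(pts)] = AIRWAY_LUMEN
        return out

    # -------------------------------------------------- lung volume sampling
    def _lung_samples(self, side: Side) -> tuple[np.ndarray, np.ndarray]:
        """Piecewise-linear cumulative volume profile V(z) for one lung.

        Midpoint-rule quadrature of the lung solid minus heart and airway
        lumen on a deterministic grid; per-slab counts are spread linearly
        across each slab so the profile is continuous in the cut height.
        Returns (slab edge heights, cumulative volume at those edges).
        """
        if side in self._lung_sample_cache:
            return self._lung_sample_cache[side]
        lung = self.lungs[side]
        la, lb, lc = lung.semi_axes
        cx, cy, cz = lung.center
        nx, ny, nz = _QUAD_N
        xs = cx + la * _midpoints(nx)
        ys = cy + lb * _midpoints(ny)
        z_lo = max(lung.base_height, cz - lc)
        dz = (cz + lc - z_lo) / nz
        zs = z_lo + dz * (np.arange(nz) + 0.5)
        cell = (xs[1] - xs[0]) * (ys[1] - ys[0]) * dz
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        keep = self._in_lung_solid(pts, side)
        keep &= ~self._in_heart(pts)
        keep &= ~self._in_airway_lumen(pts)
        counts = np.bincount(
            np.round((pts[keep, 2] - zs[0]) / dz).astype(int), minlength=nz)
        edges = np.concatenate([[z_lo], z_lo + dz * (np.arange(nz) + 1.0)])
        cum = np.concatenate([[0.0], np.cumsum(counts) * cell])
        self._lung_sample_cache[side] = (edges, cum)
        return edges, cum

    def lung_volume(self, side: Side) -> float:
        """Realized lung volume (heart and bronchi carved out), in m^3."""
        _, cum = self._lung_samples(side)
        return float(cum[-1])

    def lung_volume_total(self) -> float:
        return self.lung_volume("left") + self.lung_volume("right")

    def lung_volume_below(self, side: Side, cut_height: float) -> float:
        edges, cum = self._lung_samples(side)
        return float(np.interp(cut_height, edges, cum))

    # --------------------------------------------------- anterior arc tables
    def _arc_tables(self) -> tuple[np.ndarray, np.ndarray]:
        if self._arc_cache is None:
            phi0, phi1 = np.radians(CORNER_ANGLES_DEG[0]), np.radians(
                CORNER_ANGLES_DEG[1])
            phi = np.linspace(phi0, phi1, 4001)
            speed = np.hypot(self.torso_a * np.sin(phi),
                             self.torso_b * np.cos(phi))
            s = np.concatenate([[0.0], np.cumsum(
                0.5 * (speed[1:] + speed[:-1]) * np.diff(phi))])
            s_mid = np.interp(math.pi / 2.0, phi, s)
            # w increases with phi: positive toward the patient's right
            self._arc_cache = (phi, s - s_mid)
        return self._arc_cache

    def anterior_halfwidth(self) -> float:
        """Arc length from midline to the anterior-face edge (min of sides)."""
        _, w = self._arc_tables()
        return min(-w[0], w[-1])

    def w_of_phi(self, phi: np.ndarray | float) -> np.ndarray | float:
        phis, ws = self._arc_tables()
        return np.interp(phi, phis, ws)

    def phi_of_w(self, w: np.ndarray | float) -> np.ndarray | float:
        phis, ws = self._arc_tables()
        return np.interp(w, ws, phis)

    def surface_point(self, w: float, z: float) -> np.ndarray:
        phi = float(self.phi_of_w(w))
        return np.array([self.torso_a * math.cos(phi),
                         self.torso_b * math.sin(phi), z])

    def w_of_xy(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        phi = np.arctan2(y / self.torso_b, x / self.torso_a)
        return self.w_of_phi(phi)

    def array_center_w(self, side: Side) -> float:
        """Arc coordinate of the chest point in front of the lung centre."""
        cx = self.lungs[side].center[0]
        phi = math.acos(max(-1.0, min(1.0, cx / self.torso_a)))
        return float(self.w_of_phi(phi))

    # ------------------------------------------------------------- metadata
    def describe(self) -> dict:
        d = {
            "torso_a": self.torso_a,
            "torso_b": self.torso_b,
            "height": self.height,
            "lungs": {s: {"center": list(l.center),
                          "semi_axes": list(l.semi_axes),
                          "base_height": l.base_height}
                      for s, l in self.lungs.items()},
            "fluid": {s: {"target_volume": f.target_volume,
                          "realized_volume": f.realized_volume,
                          "cut_height": f.cut_height}
                      for s, f in self.fluid.items()},
        }
        if self.electrode_array is not None:
            ea = self.electrode_array
            d["electrodes"] = {
                "side": ea.side, "vertical_offset": ea.vertical_offset,
                "separation": ea.separation, "diameter": ea.diameter,
                "corner_assignment": dict(ea.corner_assignment),
            }
        return d

    def _copy(self, **kw) -> "ThoraxGeometry":
        g = ThoraxGeometry(self.params, (self.torso_a, self.torso_b),
                           self.lungs,
                           kw.get("fluid", self.fluid),
                           kw.get("electrode_array", self.electrode_array))
        g._lung_sample_cache = self._lung_sample_cache
        g._arc_cache = self._arc_cache
        return g


def _midpoints(n: int) -> np.ndarray:
    return -1.0 + 2.0 * (np.arange(n) + 0.5) / n


def _near_segment(pts, p0, p1, radius) -> np.ndarray:
    lo = np.minimum(p0, p1) - radius
    hi = np.maximum(p0, p1) + radius
    cand = np.all((pts >= lo) & (pts <= hi), axis=1)
    out = np.zeros(len(pts), dtype=bool)
    if not cand.any():
        return out
    sub = pts[cand]
    d = p1 - p0
    t = np.clip((sub - p0) @ d / (d @ d), 0.0, 1.0)
    proj = p0 + t[:, None] * d
    out[np.nonzero(cand)[0]] = np.sum((sub - proj) ** 2, axis=1) <= radius**2
    return out


def _angdiff(deg, ref) -> np.ndarray:
    return (np.asarray(deg) - ref + 180.0) % 360.0 - 180.0


# ---------------------------------------------------------------- operations

@lru_cache(maxsize=8)
def build_geometry(params: ThoraxParams | None = None) -> ThoraxGeometry:
    """Build the solid model, auto-scaling torso and lungs to target volumes.

    The torso semi-axes are rescaled (aspect preserved) so pi*a*b*H equals the
    target thorax volume exactly; the lung in-plane semi-axes are rescaled by
    a secant iteration so the realized total lung volume (after carving heart
    and bronchi) matches the target within far less than the +-2% contract.
    """
    params = params or ThoraxParams()
    params.validate()
    # torso scaling: exact by construction
    ratio = params.torso_semi_axis_x / params.torso_semi_axis_y
    ab = params.target_thorax_volume / (math.pi * params.torso_height)
    a = math.sqrt(ab * ratio)
    b = math.sqrt(ab / ratio)

    la, lb, lc0 = params.lung_semi_axes
    frac = {"right": params.lung_volume_fraction_right,
            "left": 1.0 - params.lung_volume_fraction_right}

    def lc_for_volume(la_s: float, lb_s: float, target: float) -> float:
        # vertical semi-axis realizing the target truncated volume; keeping
        # the in-plane footprint common to both sides makes the two pooling
        # columns geometrically alike, so left/right differences in the
        # fluid response reflect the heart, not the column height
        lo, hi = 0.045, 0.40
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            v = _truncated_ellipsoid_volume(
                (la_s, lb_s, mid), params.lung_center_z,
                params.lung_base_height)
            if v < target:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def make(tgt: dict[str, float], fp: dict[str, float]) -> ThoraxGeometry:
        lungs = {}
        for s in ("left", "right"):
            la_s, lb_s = la * fp[s], lb * fp[s]
            lc_s = lc_for_volume(la_s, lb_s, tgt[s])
            sgn = +1.0 if s == "left" else -1.0
            cy = params.lung_center_y - (
                params.lung_left_posterior_offset if s == "left" else 0.0)
            lungs[s] = _Lung(
                center=(sgn * params.lung_center_abs_x, cy,
                        params.lung_center_z),
                semi_axes=(la_s, lb_s, lc_s),
                base_height=params.lung_base_height)
        return ThoraxGeometry(params, (a, b), lungs)

    def fit_volumes(fp: dict[str, float]) -> ThoraxGeometry:
        # fixed point on the per-side analytic targets: inflate each lung's
        # vertical extent until the realized volume (after carving heart
        # and bronchi) matches its share of the total target
        tgt = {s: frac[s] * v_target for s in ("left", "right")}
        geom = make(tgt, fp)
        for _ in range(8):
            err = {s: geom.lung_volume(s) - frac[s] * v_target
                   for s in ("left", "right")}
            if abs(sum(err.values())) < 1e-3 * v_target:
                break
            tgt = {s: tgt[s] - err[s] for s in ("left", "right")}
            geom = make(tgt, fp)
        return geom

    v_target = params.target_lung_volume_total
    geom = fit_volumes({"left": 1.0, "right": 1.0})
    _validate_geometry(geom)
    return geom


def _validate_geometry(geom: ThoraxGeometry) -> None:
    p = geom.params
    u = np.linspace(0, math.pi, 48)
    v = np.linspace(0, 2 * math.pi, 96, endpoint=False)
    U, V = np.meshgrid(u, v, indexing="ij")
    for side, lung in geom.lungs.items():
        la, lb, lc = lung.semi_axes
        cx, cy, cz = lung.center
        x = cx + la * np.sin(U) * np.cos(V)
        y = cy + lb * np.sin(U) * np.sin(V)
        z = cz + lc * np.cos(U)
        keep = z >= lung.base_height
        r2 = (x / geom.torso_a) ** 2 + (y / geom.torso_b) ** 2
        if np.any(r2[keep] >= 1.0) or np.any(z[keep] >= geom.height) \
                or lung.base_height <= 0.0:
            raise GeometryError(
                f"lung_{side} protrudes from the torso envelope")
    medial = {s: abs(l.center[0]) - l.semi_axes[0]
              for s, l in geom.lungs.items()}
    if min(medial.values()) < 0.0:
        raise GeometryError("lungs overlap across the midline")
    hx = p.heart_center[0]
    if not (-abs(geom.lungs["right"].center[0]) < hx
            < abs(geom.lungs["left"].center[0])):
        raise GeometryError("heart centre is not between the lung centres")
    hz_top = p.heart_center[2] + p.heart_semi_axes[2]
    if hz_top >= geom.height or p.heart_center[2] - p.heart_semi_axes[2] <= 0:
        raise GeometryError("heart protrudes from the torso envelope")
    vt = geom.torso_volume()
    if abs(vt - p.target_thorax_volume) > 0.02 * p.target_thorax_volume:
        raise GeometryError("torso volume misses its target by more than 2%")
    vl = geom.lung_volume_total()
    if abs(vl - p.target_lung_volume_total) > 0.02 * p.target_lung_volume_total:
        raise GeometryError("lung volume misses its target by more than 2%")


def carve_fluid_region(geom: ThoraxGeometry, spec: FluidSpec,
                       max_iter: int = 60) -> ThoraxGeometry:
    """Designate ``lung AND {z < cut_height}`` as fluid on one side.

    The cut height is found by bisection on the tabulated volume-below-height
    profile of that lung; the realized volume lands within 1% of the target
    (typically much closer).  A zero target returns the geometry unchanged.
    """
    if spec.target_volume < 0:
        raise GeometryError("fluid target_volume must be non-negative")
    if spec.target_volume == 0:
        return geom
    v_lung = geom.lung_volume(spec.side)
    if spec.target_volume > 0.9 * v_lung:
        raise GeometryError(
            f"fluid target {spec.target_volume * 1e3:.0f} mL exceeds 90% of "
            f"the {spec.side} lung volume ({v_lung * 1e3:.0f} mL)")
    lung = geom.lungs[spec.side]
    lo = lung.base_height
    hi = lung.center[2] + lung.semi_axes[2]
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if geom.lung_volume_below(spec.side, mid) < spec.target_volume:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-6:
            break
    cut = 0.5 * (lo + hi)
    realized = geom.lung_volume_below(spec.side, cut)
    if abs(realized - spec.target_volume) > 0.01 * spec.target_volume:
        raise GeometryError("fluid bisection failed to reach 1% of target")
    done = replace(spec, realized_volume=realized, cut_height=cut)
    fluid = dict(geom.fluid)
    fluid[spec.side] = done
    return geom._copy(fluid=fluid)


def place_electrode_array(
    geom: ThoraxGeometry,
    side: Side,
    vertical_offset: float = 0.0,
    separation: float = 0.08,
    diameter: float = 0.01,
    corner_assignment: dict[str, str] | None = None,
) -> ThoraxGeometry:
    """Place the tetrapolar square array on the anterior chest surface.

    Centers form a square of side ``separation`` in the unrolled (w, z)
    metric, centred in front of the chosen lung; at ``vertical_offset = 0``
    the bottom electrode row is level with that lung's lower margin.
    """
    corners = dict(DEFAULT_CORNERS if corner_assignment is None
                   else corner_assignment)
    if sorted(corners) != ["A", "B", "C", "D"] or \
            sorted(corners.values()) != ["BL", "BR", "TL", "TR"]:
        raise GeometryError(
            "corner_assignment must map A..D onto TL, BL, TR, BR")
    if separation <= 0 or diameter <= 0:
        raise GeometryError("separation and diameter must be positive")
    r = 0.5 * diameter
    w_c = geom.array_center_w(side)
    z0 = geom.lung_base_height(side) + vertical_offset
    # L/R in corner names refer to smaller/larger w respectively
    pos = {"BL": (w_c - separation / 2, z0),
           "BR": (w_c + separation / 2, z0),
           "TL": (w_c - separation / 2, z0 + separation),
           "TR": (w_c + separation / 2, z0 + separation)}
    w_max = geom.anterior_halfwidth()
    for corner, (w, z) in pos.items():
        if abs(w) + r > w_max:
            raise GeometryError(
                f"electrode {corner} at w={w:.3f} m falls off the anterior "
                f"surface (half-width {w_max:.3f} m)")
        if not (r <= z <= geom.height - r):
            raise GeometryError(
                f"electrode {corner} at z={z:.3f} m falls off the torso")
    centers = tuple((lab, *pos[corners[lab]]) for lab in "ABCD")
    arr = ElectrodeArray(side=side, vertical_offset=vertical_offset,
                         separation=separation, diameter=diameter,
                         corner_assignment=tuple(sorted(corners.items())),
                         centers=centers)
    return geom._copy(electrode_array=arr)
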