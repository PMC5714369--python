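"""Cylindrical diode-array geometry: spiral layout, annular phantom, ray paths.

Coordinate conventions (documented constants, used everywhere in this package):

* Fixed right-handed frame with ``x`` toward patient left (RL axis), ``y``
  anterior (AP axis), ``z`` superior (SI axis, the detector-cylinder axis).
* Gantry angle 0 deg means the beam enters from anterior; the unit vector from
  isocenter toward the source is ``(sin g, cos g, 0)`` for gantry angle ``g``.
* The spiral's angular origin (``angle = 0``) is at anterior (+y); the angle
  increases with positive rotation about +z.

All lengths are centimetres, all densities g/cc.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np
import yaml

__all__ = [
    "DiodeArrayLayout",
    "PhantomModel",
    "Ray",
    "LayoutConfigError",
    "build_layout",
    "entrance_exit_masks",
    "unwrap_index",
    "radiological_path",
    "radiological_depths",
    "export_layout",
    "import_layout",
    "export_phantom_config",
    "import_phantom_config",
]

#: spacing commensurability tolerance: the effective per-diode arc spacing
#: (circumference / per-revolution count) may deviate from the requested
#: spacing by at most this much.
SPACING_TOLERANCE_CM = 1e-3


class LayoutConfigError(ValueError):
    """Raised when layout parameters are geometrically inconsistent."""


@dataclass(frozen=True)
class DiodeArrayLayout:
    """Diode positions along a single spiral on a cylinder.

    ``angle``/``z`` are per-diode arrays ordered by the spiral parameter
    (diode index 0 first).  ``spacing`` is the *effective* arc length between
    consecutive diodes (circumference / diodes-per-revolution), which may
    differ from a requested nominal spacing by up to ``SPACING_TOLERANCE_CM``.
    """

    angle: np.ndarray            # radians, per diode
    z: np.ndarray                # cm along the cylinder axis, per diode
    radius: float                # cm, shared by all diodes
    pitch: float                 # cm of axial advance per revolution
    spacing: float               # cm arc length between consecutive diodes
    n_per_revolution: int
    n_revolutions: int

    @property
    def n_diodes(self) -> int:
        return self.angle.size

    @property
    def diode_index(self) -> np.ndarray:
        return np.arange(self.n_diodes)

    @property
    def axial_length(self) -> float:
        """Axial extent: pitch x number of revolutions."""
        return self.pitch * self.n_revolutions

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) cartesian diode positions in the fixed frame."""
        x = -self.radius * np.sin(self.angle)
        y = self.radius * np.cos(self.angle)
        return np.column_stack([x, y, self.z])

    @property
    def outward_normals(self) -> np.ndarray:
        """(n, 3) unit radial outward normals at each diode."""
        n = self.positions.copy()
        n[:, 2] = 0.0
        return n / np.linalg.norm(n[:, :2], axis=1, keepdims=True)


@dataclass(frozen=True)
class PhantomModel:
    """Annular acrylic phantom with an optional central plug.

    The cavity (inside ``inner_diameter``) is air unless ``plug_present``;
    outside the outer cylinder is air as well (``exterior_density``).
    """

    outer_diameter: float = 26.59
    inner_diameter: float = 15.0
    shell_density: float = 1.17
    plug_present: bool = False
    plug_density: float = 1.17
    cavity_density: float = 0.0012   # air; the source text is silent on this
    exterior_density: float = 0.0012

    def __post_init__(self):
        if not 0 < self.inner_diameter < self.outer_diameter:
            raise ValueError("require 0 < inner_diameter < outer_diameter")

    @property
    def cavity_fill_density(self) -> float:
        return self.plug_density if self.plug_present else self.cavity_density

    def with_plug(self, present: bool) -> "PhantomModel":
        return replace(self, plug_present=present)


@dataclass(frozen=True)
class Ray:
    """A ray anchored at the radiation source."""

    source_point: np.ndarray
    direction: np.ndarray
    source_axis_distance: float = 100.0

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError(f"direction must be unit norm, got |d| = {n}")
        object.__setattr__(self, "direction", d)
        object.__setattr__(
            self, "source_point", np.asarray(self.source_point, dtype=float)
        )


def build_layout(
    pitch: float = 1.0,
    spacing: float = 1.0,
    diameter: float = 21.0,
    axial_length: float = 21.0,
    angle_origin: float = 0.0,
) -> DiodeArrayLayout:
    """Place diodes along a spiral of the given pitch on a cylinder.

    The per-revolution diode count is ``round(pi * diameter / spacing)``; the
    requested spacing must be commensurate with the circumference, i.e. the
    effective spacing (circumference / count) must agree with the request
    within ``SPACING_TOLERANCE_CM``.  Total count = per-revolution count x
    (axial_length / pitch).  The array is centred axially on z = 0.

    Parameters are all in cm and must be positive.  ``angle_origin`` rotates
    the whole spiral (radians); it does not change any count.
    """
    for name, v in [("pitch", pitch), ("spacing", spacing),
                    ("diameter", diameter), ("axial_length", axial_length)]:
        if not v > 0:
            raise LayoutConfigError(f"{name} must be > 0, got {v}")
    circumference = np.pi * diameter
    n_col = int(round(circumference / spacing))
    if n_col < 1:
        raise LayoutConfigError("spacing exceeds the cylinder circumference")
    effective = circumference / n_col
    residual = abs(effective - spacing)
    if residual > SPACING_TOLERANCE_CM:
        raise LayoutConfigError(
            f"spacing {spacing} cm is not commensurate with circumference "
            f"{circumference:.4f} cm: effective spacing {effective:.6f} cm "
            f"deviates by {residual:.6f} cm (> {SPACING_TOLERANCE_CM} cm)"
        )
    n_rev_f = axial_length / pitch
    n_rev = int(round(n_rev_f))
    if n_rev < 1 or abs(n_rev_f - n_rev) > 1e-9:
        raise LayoutConfigError(
            f"axial_length/pitch = {n_rev_f} must be a positive integer "
            "number of revolutions"
        )
    k = np.arange(n_col * n_rev)
    angle = angle_origin + 2.0 * np.pi * k / n_col
    z = -axial_length / 2.0 + pitch * k / n_col
    return DiodeArrayLayout(
        angle=angle,
        z=z,
        radius=diameter / 2.0,
        pitch=pitch,
        spacing=effective,
        n_per_revolution=n_col,
        n_revolutions=n_rev,
    )


def source_direction(gantry_angle_deg: float) -> np.ndarray:
    """Unit vector from isocenter toward the source for a gantry angle."""
    g = np.deg2rad(gantry_angle_deg)
    return np.array([np.sin(g), np.cos(g), 0.0])


def entrance_exit_masks(
    layout: DiodeArrayLayout, gantry_angle: float
) -> tuple[np.ndarray, np.ndarray]:
    """Partition the diodes into the source-facing and far half-cylinders.

    A diode is *entrance* when its position has a nonnegative component along
    the isocenter->source direction; diodes exactly on the dividing plane are
    assigned to entrance (documented tie-break).  Every diode lands in
    exactly one of the two returned boolean masks.
    """
    if not 0 <= gantry_angle < 360:
        raise ValueError("gantry_angle must lie in [0, 360)")
    s = source_direction(gantry_angle)
    proj = layout.positions @ s
    # tolerance absorbs float noise in trig terms; real off-plane projections
    # are O(radius x sin(angular step)) >> 1e-9 cm
    entrance = proj >= -1e-9
    return entrance, ~entrance


def unwrap_index(layout: DiodeArrayLayout) -> dict[int, tuple[int, int]]:
    """Map each diode index to an (axial row, angular column) grid cell.

    Rows are revolutions (row 0 most inferior), columns are positions within
    a revolution (column 0 at the spiral's angular origin, anterior by
    default).  The mapping is a bijection onto the full
    ``n_revolutions x n_per_revolution`` grid.
    """
    n_col = layout.n_per_revolution
    return {int(k): (k // n_col, k % n_col) for k in range(layout.n_diodes)}


def unwrap_shape(layout: DiodeArrayLayout) -> tuple[int, int]:
    return layout.n_revolutions, layout.n_per_revolution


def unwrap_values(layout: DiodeArrayLayout, per_diode: np.ndarray) -> np.ndarray:
    """Arrange a per-diode vector onto the (rows x columns) unwrap grid."""
    per_diode = np.asarray(per_diode)
    if per_diode.shape[0] != layout.n_diodes:
        raise ValueError("per-diode vector length does not match the layout")
    return per_diode.reshape(layout.n_revolutions, layout.n_per_revolution)


def _cylinder_crossings(source_xy, delta_xy, radius):
    """Parameters t of |source_xy + t*delta_xy| = radius (vectorised).

    Returns (t1, t2) arrays with NaN where there is no crossing.
    """
    a = np.sum(delta_xy * delta_xy, axis=-1)
    b = 2.0 * np.sum(source_xy * delta_xy, axis=-1)
    c = np.sum(source_xy * source_xy, axis=-1) - radius * radius
    disc = b * b - 4.0 * a * c
    with np.errstate(invalid="ignore", divide="ignore"):
        sq = np.sqrt(np.where(disc >= 0, disc, np.nan))
        t1 = (-b - sq) / (2.0 * a)
        t2 = (-b + sq) / (2.0 * a)
    bad = ~np.isfinite(t1)
    t1 = np.where(bad, np.nan, t1)
    t2 = np.where(bad, np.nan, t2)
    return t1, t2


def radiological_depths(
    phantom: PhantomModel, source: np.ndarray, points: np.ndarray
) -> np.ndarray:
    """Water-equivalent path length from ``source`` to each of ``points``.

    Analytic: the segment is split at its crossings with the inner and outer
    phantom cylinders (axis = z) and each piece is weighted by the density of
    the region it traverses (shell / cavity-or-plug / exterior air).
    Vectorised over the trailing point dimension; shape (n, 3) -> (n,).
    """
    source = np.asarray(source, dtype=float)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    delta = points - source
    length = np.linalg.norm(delta, axis=1)
    s_xy = np.broadcast_to(source[:2], (points.shape[0], 2))
    d_xy = delta[:, :2]

    r_in = phantom.inner_diameter / 2.0
    r_out = phantom.outer_diameter / 2.0
    ti1, ti2 = _cylinder_crossings(s_xy, d_xy, r_in)
    to1, to2 = _cylinder_crossings(s_xy, d_xy, r_out)

    # Breakpoints of the parameter t in [0, 1]; invalid crossings collapse to 0.
    brk = np.stack([
        np.zeros_like(length), np.ones_like(length),
        np.nan_to_num(np.clip(ti1, 0.0, 1.0)),
        np.nan_to_num(np.clip(ti2, 0.0, 1.0)),
        np.nan_to_num(np.clip(to1, 0.0, 1.0)),
        np.nan_to_num(np.clip(to2, 0.0, 1.0)),
    ], axis=1)
    brk.sort(axis=1)
    mid = 0.5 * (brk[:, 1:] + brk[:, :-1])
    seg = (brk[:, 1:] - brk[:, :-1]) * length[:, None]

    mid_xy = s_xy[:, None, :] + mid[..., None] * d_xy[:, None, :]
    r_mid = np.linalg.norm(mid_xy, axis=2)
    density = np.where(
        r_mid < r_in,
        phantom.cavity_fill_density,
        np.where(r_mid < r_out, phantom.shell_density, phantom.exterior_density),
    )
    return np.sum(seg * density, axis=1)


def radiological_path(
    phantom: PhantomModel,
    ray: Ray,
    from_point: np.ndarray,
    to_point: np.ndarray,
    on_ray_tol: float = 1e-6,
) -> float:
    """Water-equivalent length of the segment [from_point, to_point].

    Both points must lie on ``ray`` (within ``on_ray_tol`` cm of its line);
    the result is symmetric in endpoint order and additive over sub-segments.
    """
    from_point = np.asarray(from_point, dtype=float)
    to_point = np.asarray(to_point, dtype=float)
    for p in (from_point, to_point):
        v = p - ray.source_point
        off = np.linalg.norm(v - (v @ ray.direction) * ray.direction)
        if off > on_ray_tol:
            raise ValueError(
                f"point {p} is {off:.2e} cm off the ray line (tol {on_ray_tol})"
            )
    return float(radiological_depths(phantom, from_point, to_point[None, :])[0])


# ---------------------------------------------------------------------------
# plain-text export / import

_LAYOUT_HEADER = "# arcqa diode layout v1"


def export_layout(layout: DiodeArrayLayout, path) -> None:
    """Write the layout as a plain-text table: index, x, y, z, angle."""
    pos = layout.positions
    with open(path, "w") as fh:
        fh.write(_LAYOUT_HEADER + "\n")
        fh.write(f"# radius_cm: {layout.radius!r}\n")
        fh.write(f"# pitch_cm: {layout.pitch!r}\n")
        fh.write(f"# spacing_cm: {layout.spacing!r}\n")
        fh.write(f"# n_per_revolution: {layout.n_per_revolution}\n")
        fh.write(f"# n_revolutions: {layout.n_revolutions}\n")
        fh.write("# columns: index x_cm y_cm z_cm angle_rad\n")
        for k in range(layout.n_diodes):
            fh.write(
                f"{k}\t{float(pos[k, 0])!r}\t{float(pos[k, 1])!r}"
                f"\t{float(pos[k, 2])!r}\t{float(layout.angle[k])!r}\n"
            )


def import_layout(path) -> DiodeArrayLayout:
    meta = {}
    rows = []
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _LAYOUT_HEADER:
            raise ValueError(f"not an arcqa layout file: {path}")
        for line in fh:
            if line.startswith("#"):
                if ":" in line:
                    key, _, val = line[1:].partition(":")
                    meta[key.strip()] = val.strip()
                continue
            rows.append(line.split())
    arr = np.array(rows, dtype=float)
    order = np.argsort(arr[:, 0])
    arr = arr[order]
    return DiodeArrayLayout(
        angle=arr[:, 4],
        z=arr[:, 3],
        radius=float(meta["radius_cm"]),
        pitch=float(meta["pitch_cm"]),
        spacing=float(meta["spacing_cm"]),
        n_per_revolution=int(meta["n_per_revolution"]),
        n_revolutions=int(meta["n_revolutions"]),
    )


def export_phantom_config(phantom: PhantomModel, path=None) -> str:
    doc = {
        "outer_diameter_cm": phantom.outer_diameter,
        "inner_diameter_cm": phantom.inner_diameter,
        "shell_density_gcc": phantom.shell_density,
        "plug_present": phantom.plug_present,
        "plug_density_gcc": phantom.plug_density,
        "cavity_density_gcc": phantom.cavity_density,
        "exterior_density_gcc": phantom.exterior_density,
    }
    text = yaml.safe_dump(doc, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def import_phantom_config(source) -> PhantomModel:
    if hasattr(source, "read") or isinstance(source, io.IOBase):
        doc = yaml.safe_load(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    return PhantomModel(
        outer_diameter=float(doc["outer_diameter_cm"]),
        inner_diameter=float(doc["inner_diameter_cm"]),
        shell_density=float(doc["shell_density_gcc"]),
        plug_present=bool(doc["plug_present"]),
        plug_density=float(doc["plug_density_gcc"]),
        cavity_density=float(doc["cavity_density_gcc"]),
        exterior_density=float(doc.get("exterior_density_gcc", 0.0012)),
    )
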