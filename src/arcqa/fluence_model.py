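"""Control-point -> subfield decomposition and MLC-aware fluence rendering.

A beam with N control points yields N-1 subfields.  Each subfield carries the
meterset fraction delivered between its two bounding control points and the
midpoint of their apertures (the interpolant between bounding states is not
prescribed anywhere authoritative; the unbiased midpoint is used and
documented).  Fluence maps are relative (open field = 1) on an
isocenter-plane grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rt_io import Beam, DEFAULT_LEAF_BOUNDARIES, N_LEAF_PAIRS

__all__ = [
    "Subfield",
    "MLCModel",
    "FluenceMap",
    "decompose_subfields",
    "render_fluence",
    "accumulate_fluence",
    "circular_midpoint",
]


def circular_midpoint(a: float, b: float) -> float:
    """Midpoint of two angles along the shortest arc, in [0, 360)."""
    diff = (b - a + 180.0) % 360.0 - 180.0
    return (a + diff / 2.0) % 360.0


@dataclass
class Subfield:
    """Static-aperture stand-in for the delivery between two control points."""

    jaw_positions: np.ndarray            # (x1, x2, y1, y2) cm
    mlc_positions: np.ndarray            # (2, 60) cm
    meterset: float                      # MU
    gantry_span: tuple[float, float]     # degrees (start, end)
    representative_gantry: float         # degrees, circular midpoint
    collimator_angle: float = 0.0
    couch_angle: float = 0.0

    def __post_init__(self):
        if self.meterset < 0:
            raise ValueError("subfield meterset must be >= 0")


@dataclass(frozen=True)
class MLCModel:
    """Dosimetric MLC description used as a fluence modifier.

    ``transmission`` is the relative fluence under a leaf; the rounded leaf
    end is modelled as a dosimetric gap (each tip retracted by
    ``rounded_leaf_end_offset``); tongue-and-groove is a strip of width
    ``tongue_and_groove_width`` rendered at transmission on the open side of
    an inter-leaf boundary wherever adjacent leaf tips differ.
    """

    leaf_boundaries: np.ndarray = field(
        default_factory=lambda: DEFAULT_LEAF_BOUNDARIES.copy())
    transmission: float = 0.015
    rounded_leaf_end_offset: float = 0.1
    tongue_and_groove_width: float = 0.05

    def __post_init__(self):
        b = np.asarray(self.leaf_boundaries, dtype=float)
        object.__setattr__(self, "leaf_boundaries", b)
        if b.size != N_LEAF_PAIRS + 1:
            raise ValueError(f"need {N_LEAF_PAIRS + 1} leaf boundaries")
        if np.any(np.diff(b) <= 0):
            raise ValueError("leaf boundaries must be increasing")
        if not 0 <= self.transmission < 1:
            raise ValueError("transmission must lie in [0, 1)")
        if self.rounded_leaf_end_offset < 0 or self.tongue_and_groove_width < 0:
            raise ValueError("offsets must be >= 0")


@dataclass
class FluenceMap:
    """Relative fluence on an isocenter-plane grid.

    ``values[i, j]`` is the fluence at ``(x0 + j*spacing, y0 + i*spacing)``
    in the beam's-eye-view plane.  ``field_size`` is the equivalent-square
    side of the jaw aperture, used by the dose engine.
    """

    values: np.ndarray
    spacing: float
    x0: float
    y0: float
    meterset: float
    field_size: float = 10.0

    @property
    def xs(self) -> np.ndarray:
        return self.x0 + np.arange(self.values.shape[1]) * self.spacing

    @property
    def ys(self) -> np.ndarray:
        return self.y0 + np.arange(self.values.shape[0]) * self.spacing

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Bilinear fluence at beam's-eye-view coordinates; 0 outside."""
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            (self.ys, self.xs), self.values, method="linear",
            bounds_error=False, fill_value=0.0)
        pts = np.column_stack([np.ravel(y), np.ravel(x)])
        return interp(pts).reshape(np.shape(x))

    def export(self, path) -> None:
        """Plain-text export with a small header (for inspection/plotting)."""
        with open(path, "w") as fh:
            fh.write("# arcqa fluence map v1\n")
            fh.write(f"# spacing_cm: {self.spacing!r}\n")
            fh.write(f"# x0_cm: {self.x0!r}\n")
            fh.write(f"# y0_cm: {self.y0!r}\n")
            fh.write(f"# meterset_mu: {self.meterset!r}\n")
            fh.write(f"# field_size_cm: {self.field_size!r}\n")
            np.savetxt(fh, self.values, fmt="%.8g")


def equivalent_square(jaws: np.ndarray) -> float:
    """Equivalent-square side 2ab/(a+b) of the jaw-defined rectangle."""
    a = max(jaws[1] - jaws[0], 1e-6)
    b = max(jaws[3] - jaws[2], 1e-6)
    return 2.0 * a * b / (a + b)


def decompose_subfields(beam: Beam) -> list[Subfield]:
    """Split an arc beam into N-1 MU-weighted static subfields.

    Subfield meterset = (delta cumulative weight) x beam MU; the aperture is
    the midpoint of the bounding control points' leaf and jaw positions; the
    representative gantry angle is the circular (shortest-arc) midpoint.
    Metersets sum to the beam meterset by construction.
    """
    cps = beam.control_points
    if len(cps) < 2:
        raise ValueError("need at least 2 control points")
    out = []
    for a, b in zip(cps[:-1], cps[1:]):
        out.append(Subfield(
            jaw_positions=0.5 * (a.jaw_positions + b.jaw_positions),
            mlc_positions=0.5 * (a.mlc_positions + b.mlc_positions),
            meterset=(b.cumulative_weight - a.cumulative_weight) * beam.meterset,
            gantry_span=(a.gantry_angle, b.gantry_angle),
            representative_gantry=circular_midpoint(a.gantry_angle,
                                                    b.gantry_angle),
            collimator_angle=circular_midpoint(a.collimator_angle,
                                               b.collimator_angle),
            couch_angle=circular_midpoint(a.couch_angle, b.couch_angle),
        ))
    return out


def _grid_axes(jaws: np.ndarray, spacing: float, margin: float = 1.0):
    x_lo, x_hi = jaws[0] - margin, jaws[1] + margin
    y_lo, y_hi = jaws[2] - margin, jaws[3] + margin
    nx = int(np.ceil((x_hi - x_lo) / spacing)) + 1
    ny = int(np.ceil((y_hi - y_lo) / spacing)) + 1
    xs = x_lo + (np.arange(nx) + 0.5) * spacing
    ys = y_lo + (np.arange(ny) + 0.5) * spacing
    return xs, ys


def render_fluence(
    subfield: Subfield,
    mlc: MLCModel | None = None,
    grid_spacing: float = 0.1,
    grid_axes: tuple[np.ndarray, np.ndarray] | None = None,
) -> FluenceMap:
    """Rasterise a subfield aperture into a relative fluence map.

    Open region = 1; under-leaf = transmission; leaf tips are retracted by
    the rounded-leaf-end offset before rasterisation; tongue-and-groove
    strips at inter-leaf boundaries with differing tips are set to
    transmission; everything outside the jaws = 0.  Pixels are classified by
    their centre (half-open [lo, hi) intervals).
    """
    if grid_spacing <= 0:
        raise ValueError("grid spacing must be > 0")
    mlc = mlc or MLCModel()
    jaws = subfield.jaw_positions
    if grid_axes is None:
        xs, ys = _grid_axes(jaws, grid_spacing)
    else:
        xs, ys = grid_axes
    values = np.zeros((ys.size, xs.size))

    off = mlc.rounded_leaf_end_offset
    bank_a = subfield.mlc_positions[0] - off
    bank_b = subfield.mlc_positions[1] + off
    bounds = mlc.leaf_boundaries

    # per-leaf open masks along x (half-open intervals, centre sampling)
    open_x = [(xs >= bank_a[i]) & (xs < bank_b[i]) for i in range(N_LEAF_PAIRS)]
    inside_y = (ys >= jaws[2]) & (ys < jaws[3])
    inside_x = (xs >= jaws[0]) & (xs < jaws[1])

    for i in range(N_LEAF_PAIRS):
        rows = (ys >= bounds[i]) & (ys < bounds[i + 1])
        if not np.any(rows):
            continue
        row_vals = np.where(open_x[i], 1.0, mlc.transmission)
        values[rows, :] = row_vals[None, :]

    # tongue-and-groove: strip of width w on the open side of each boundary
    w = mlc.tongue_and_groove_width
    if w > 0:
        for i in range(N_LEAF_PAIRS - 1):
            b_y = bounds[i + 1]
            only_lower = open_x[i] & ~open_x[i + 1]
            only_upper = open_x[i + 1] & ~open_x[i]
            if np.any(only_lower):
                rows = (ys >= b_y - w) & (ys < b_y)
                values[np.ix_(rows, only_lower)] = mlc.transmission
            if np.any(only_upper):
                rows = (ys >= b_y) & (ys < b_y + w)
                values[np.ix_(rows, only_upper)] = mlc.transmission

    values[~inside_y, :] = 0.0
    values[:, ~inside_x] = 0.0
    return FluenceMap(
        values=values,
        spacing=grid_spacing,
        x0=float(xs[0]),
        y0=float(ys[0]),
        meterset=subfield.meterset,
        field_size=equivalent_square(jaws),
    )


def accumulate_fluence(
    subfields: list[Subfield],
    mlc: MLCModel | None = None,
    angular_bin: float = 360.0,
    grid_spacing: float = 0.1,
) -> list[tuple[float, FluenceMap]]:
    """Group subfields by gantry bin and meterset-average their fluences.

    Returns (representative gantry, composite FluenceMap) per nonempty bin;
    the composite's values are the meterset-weighted mean of the members'
    (staying relative), its meterset is the member sum, so total meterset is
    conserved.  The representative gantry is the meterset-weighted circular
    mean of the members.
    """
    if angular_bin <= 0:
        raise ValueError("angular_bin must be > 0")
    if not subfields:
        return []
    mlc = mlc or MLCModel()

    # one shared grid so maps within (and across) bins are summable
    all_jaws = np.array([sf.jaw_positions for sf in subfields])
    union_jaws = np.array([all_jaws[:, 0].min(), all_jaws[:, 1].max(),
                           all_jaws[:, 2].min(), all_jaws[:, 3].max()])
    axes = _grid_axes(union_jaws, grid_spacing)

    bins: dict[int, list[tuple[Subfield, FluenceMap]]] = {}
    for sf in subfields:
        key = int(sf.representative_gantry // angular_bin)
        fm = render_fluence(sf, mlc, grid_spacing, grid_axes=axes)
        bins.setdefault(key, []).append((sf, fm))

    out = []
    for key in sorted(bins):
        members = bins[key]
        total_mu = sum(sf.meterset for sf, _ in members)
        if total_mu > 0:
            values = sum(sf.meterset * fm.values for sf, fm in members) / total_mu
            sin_sum = sum(sf.meterset *
                          np.sin(np.deg2rad(sf.representative_gantry))
                          for sf, _ in members)
            cos_sum = sum(sf.meterset *
                          np.cos(np.deg2rad(sf.representative_gantry))
                          for sf, _ in members)
            rep = float(np.rad2deg(np.arctan2(sin_sum, cos_sum)) % 360.0)
        else:
            values = members[0][1].values * 0.0
            rep = members[0][0].representative_gantry
        proto = members[0][1]
        fs = sum(sf.meterset * fm.field_size for sf, fm in members) / total_mu \
            if total_mu > 0 else proto.field_size
        out.append((rep, FluenceMap(
            values=values, spacing=proto.spacing, x0=proto.x0, y0=proto.y0,
            meterset=total_mu, field_size=fs)))
    return out
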