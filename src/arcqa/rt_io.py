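"""Radiotherapy object I/O: DICOM-RT Plan, DICOM-RT Dose, CT-number density ramp.

Internal units are cm and Gy (QA reports convert to cGy); DICOM files store
mm and scaled integer dose per the standard semantics.  Grids are restricted
to axis-aligned orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _dicom
from ._dicom import Dataset, DicomError, deterministic_uid

__all__ = [
    "ControlPoint",
    "Beam",
    "ArcPlan",
    "DoseGrid",
    "DensityRamp",
    "PlanParseError",
    "read_plan",
    "write_plan",
    "read_dose",
    "write_dose",
    "hu_to_density",
    "default_density_ramp",
]

RTPLAN_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"
RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"

N_LEAF_PAIRS = 60

#: Millennium-style 120-leaf boundary layout: 10 outer 1 cm pairs, 40 central
#: 0.5 cm pairs, 10 outer 1 cm pairs, spanning -20..+20 cm (config-overridable).
DEFAULT_LEAF_BOUNDARIES = np.concatenate([
    -20.0 + np.arange(11) * 1.0,            # -20 .. -10
    -10.0 + np.arange(1, 41) * 0.5,         # -9.5 .. 10
    10.0 + np.arange(1, 11) * 1.0,          # 11 .. 20
])


class PlanParseError(DicomError):
    pass


@dataclass
class ControlPoint:
    """One sampled delivery state of an arc beam.

    ``jaw_positions`` is (x1, x2, y1, y2) in cm at isocenter scale;
    ``mlc_positions`` is a (2, 60) array, bank A (row 0, left/negative side)
    and bank B (row 1), with A <= B per pair.
    """

    gantry_angle: float
    collimator_angle: float
    couch_angle: float
    jaw_positions: np.ndarray
    mlc_positions: np.ndarray
    cumulative_weight: float

    def __post_init__(self):
        self.jaw_positions = np.asarray(self.jaw_positions, dtype=float)
        self.mlc_positions = np.asarray(self.mlc_positions, dtype=float)
        if self.jaw_positions.shape != (4,):
            raise ValueError("jaw_positions must be (x1, x2, y1, y2)")
        if self.mlc_positions.shape != (2, N_LEAF_PAIRS):
            raise ValueError(f"mlc_positions must be (2, {N_LEAF_PAIRS})")
        if np.any(self.mlc_positions[0] > self.mlc_positions[1] + 1e-9):
            raise ValueError("bank-A leaf positions must not exceed bank B")


@dataclass
class Beam:
    control_points: list[ControlPoint]
    meterset: float                       # MU
    energy: str = "6X"
    leaf_boundaries: np.ndarray = field(
        default_factory=lambda: DEFAULT_LEAF_BOUNDARIES.copy())
    name: str = "ARC"

    def __post_init__(self):
        if len(self.control_points) < 2:
            raise ValueError("a beam needs at least 2 control points")
        w = np.array([cp.cumulative_weight for cp in self.control_points])
        if abs(w[0]) > 1e-9 or abs(w[-1] - 1.0) > 1e-9:
            raise ValueError("cumulative weights must start at 0 and end at 1")
        if np.any(np.diff(w) < -1e-12):
            raise ValueError("cumulative weights must be nondecreasing")


@dataclass
class ArcPlan:
    beams: list[Beam]
    label: str = "arcqa plan"

    def __post_init__(self):
        if not self.beams:
            raise ValueError("plan has no beams")


@dataclass
class DoseGrid:
    """Absolute dose (Gy) on a rectilinear, axis-aligned grid.

    ``values`` has shape (nz, ny, nx); ``origin`` is the centre of voxel
    [0, 0, 0] in cm; ``spacing`` is (dx, dy, dz) in cm.
    """

    values: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray
    axes: tuple[str, str, str] = ("x", "y", "z")

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be 3D (nz, ny, nx)")
        if np.any(self.values < 0):
            raise ValueError("dose values must be nonnegative")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive on all axes")

    def coordinates(self):
        """Axis coordinate vectors (xs, ys, zs) in cm."""
        nz, ny, nx = self.values.shape
        xs = self.origin[0] + np.arange(nx) * self.spacing[0]
        ys = self.origin[1] + np.arange(ny) * self.spacing[1]
        zs = self.origin[2] + np.arange(nz) * self.spacing[2]
        return xs, ys, zs

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear dose at (n, 3) cartesian points; errors if outside."""
        from scipy.interpolate import RegularGridInterpolator

        xs, ys, zs = self.coordinates()
        interp = RegularGridInterpolator(
            (zs, ys, xs), self.values, method="linear", bounds_error=True)
        points = np.atleast_2d(points)
        try:
            return interp(points[:, ::-1])
        except ValueError as exc:
            lo = np.array([xs[0], ys[0], zs[0]])
            hi = np.array([xs[-1], ys[-1], zs[-1]])
            outside = np.nonzero(
                np.any((points < lo) | (points > hi), axis=1))[0]
            raise ValueError(
                f"points outside dose grid (indices {outside.tolist()})"
            ) from exc


@dataclass
class DensityRamp:
    """Piecewise-linear CT number -> physical density conversion."""

    knots: list[tuple[float, float]]

    def __post_init__(self):
        if len(self.knots) < 2:
            raise ValueError("ramp needs at least 2 knots")
        ct = np.array([k[0] for k in self.knots], dtype=float)
        rho = np.array([k[1] for k in self.knots], dtype=float)
        if np.any(np.diff(ct) <= 0):
            raise ValueError("CT numbers must be strictly increasing")
        if np.any(rho < 0):
            raise ValueError("densities must be nonnegative")
        self._ct, self._rho = ct, rho

    @classmethod
    def from_text(cls, path) -> "DensityRamp":
        arr = np.loadtxt(path, ndmin=2)
        return cls([(float(a), float(b)) for a, b in arr])

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# CT_number density_gcc\n")
            for ct, rho in self.knots:
                fh.write(f"{ct!r} {rho!r}\n")


def default_density_ramp() -> DensityRamp:
    """Stand-in ramp (air -> water -> acrylic-like); the scanner-specific
    curve is a required config input in any real deployment."""
    return DensityRamp([(-1000.0, 0.0012), (0.0, 1.0), (250.0, 1.17)])


def hu_to_density(ramp: DensityRamp, ct_number) -> np.ndarray | float:
    """Linear interpolation between ramp knots, clamped at the ends."""
    out = np.interp(np.asarray(ct_number, dtype=float), ramp._ct, ramp._rho)
    return float(out) if np.isscalar(ct_number) else out


# ---------------------------------------------------------------------------
# DICOM-RT Plan

def _ds(value, decimals: int = 6) -> str:
    """Format a number as a DICOM decimal string (<= 16 chars)."""
    text = f"{float(value):.{decimals}f}".rstrip("0").rstrip(".")
    if text in ("-0", ""):
        text = "0"
    if len(text) > 16:
        text = f"{float(value):.8g}"
    return text


def _angle_for_dicom(angle: float) -> float:
    return float(np.mod(angle, 360.0))


def _energy_to_mv(energy: str) -> float:
    digits = "".join(ch for ch in energy if (ch.isdigit() or ch == "."))
    return float(digits) if digits else 6.0


def write_plan(plan: ArcPlan, path) -> None:
    """Serialise an ArcPlan as a DICOM-RT Plan (explicit VR little endian)."""
    ds = Dataset()
    uid = deterministic_uid("rtplan", plan.label, len(plan.beams),
                            *(f"{b.meterset:.6f}" for b in plan.beams))
    ds.add(0x0008, 0x0016, "UI", RTPLAN_SOP_CLASS)
    ds.add(0x0008, 0x0018, "UI", uid)
    ds.add(0x0008, 0x0060, "CS", "RTPLAN")
    ds.add(0x0010, 0x0010, "PN", "arcqa^phantom")
    ds.add(0x0010, 0x0020, "LO", "ARCQA000")
    ds.add(0x300A, 0x0002, "SH", plan.label[:16])

    ref_beams = []
    for i, beam in enumerate(plan.beams, start=1):
        rb = Dataset()
        rb.add(0x300A, 0x0086, "DS", _ds(beam.meterset, 8))
        rb.add(0x300C, 0x0006, "IS", str(i))
        ref_beams.append(rb)
    fg = Dataset()
    fg.add(0x300A, 0x0071, "IS", "1")
    fg.add(0x300A, 0x0078, "IS", "1")
    fg.add(0x300C, 0x0004, "SQ", ref_beams)
    ds.add(0x300A, 0x0070, "SQ", [fg])

    beam_items = []
    for i, beam in enumerate(plan.beams, start=1):
        b = Dataset()
        b.add(0x300A, 0x00C0, "IS", str(i))
        b.add(0x300A, 0x00C2, "LO", beam.name)
        b.add(0x300A, 0x00C4, "CS", "DYNAMIC")
        b.add(0x300A, 0x00C6, "CS", "PHOTON")
        b.add(0x300A, 0x010E, "DS", "1")
        b.add(0x300A, 0x0110, "IS", str(len(beam.control_points)))

        bld = []
        for dev, n_pairs in (("ASYMX", 1), ("ASYMY", 1), ("MLCX", N_LEAF_PAIRS)):
            d = Dataset()
            d.add(0x300A, 0x00B8, "CS", dev)
            d.add(0x300A, 0x00BC, "IS", str(n_pairs))
            if dev == "MLCX":
                d.add(0x300A, 0x00BE, "DS",
                      [_ds(v * 10.0, 4) for v in beam.leaf_boundaries])
            bld.append(d)
        b.add(0x300A, 0x00B6, "SQ", bld)

        cps = []
        for j, cp in enumerate(beam.control_points):
            c = Dataset()
            c.add(0x300A, 0x0112, "IS", str(j))
            c.add(0x300A, 0x0134, "DS", _ds(cp.cumulative_weight, 9))
            c.add(0x300A, 0x011E, "DS", _ds(_angle_for_dicom(cp.gantry_angle)))
            c.add(0x300A, 0x011F, "CS", "NONE")
            c.add(0x300A, 0x0120, "DS",
                  _ds(_angle_for_dicom(cp.collimator_angle)))
            c.add(0x300A, 0x0122, "DS", _ds(_angle_for_dicom(cp.couch_angle)))
            if j == 0:
                c.add(0x300A, 0x0114, "DS", _ds(_energy_to_mv(beam.energy)))
            jaws_x = [_ds(cp.jaw_positions[0] * 10.0, 4),
                      _ds(cp.jaw_positions[1] * 10.0, 4)]
            jaws_y = [_ds(cp.jaw_positions[2] * 10.0, 4),
                      _ds(cp.jaw_positions[3] * 10.0, 4)]
            mlc = [_ds(v * 10.0, 4) for v in cp.mlc_positions.ravel()]
            bldp = []
            for dev, vals in (("ASYMX", jaws_x), ("ASYMY", jaws_y),
                              ("MLCX", mlc)):
                d = Dataset()
                d.add(0x300A, 0x00B8, "CS", dev)
                d.add(0x300A, 0x011C, "DS", vals)
                bldp.append(d)
            c.add(0x300A, 0x011A, "SQ", bldp)
            cps.append(c)
        b.add(0x300A, 0x0111, "SQ", cps)
        beam_items.append(b)
    ds.add(0x300A, 0x00B0, "SQ", beam_items)
    _dicom.write_file(path, ds, RTPLAN_SOP_CLASS, uid)


def _as_float_list(value) -> list[float]:
    if isinstance(value, (list, tuple)):
        return [float(v) for v in value]
    return [float(value)]


def read_plan(path) -> ArcPlan:
    ds = _dicom.read_file(path)
    if ds.get_value((0x0008, 0x0016)) != RTPLAN_SOP_CLASS:
        raise PlanParseError(f"{path}: not an RT Plan object")
    metersets = {}
    for fg in ds.get_value((0x300A, 0x0070), []):
        for rb in fg.get_value((0x300C, 0x0004), []):
            metersets[int(rb.require((0x300C, 0x0006), "ReferencedBeamNumber"))] = \
                float(rb.require((0x300A, 0x0086), "BeamMeterset"))

    beams = []
    for b in ds.require((0x300A, 0x00B0), "BeamSequence"):
        number = int(b.require((0x300A, 0x00C0), "BeamNumber"))
        name = str(b.get_value((0x300A, 0x00C2), "ARC"))
        boundaries = None
        for d in b.get_value((0x300A, 0x00B6), []):
            if d.get_value((0x300A, 0x00B8)) == "MLCX":
                boundaries = np.array(
                    _as_float_list(d.require((0x300A, 0x00BE),
                                             "LeafPositionBoundaries"))) / 10.0
        if boundaries is None:
            raise PlanParseError(
                f"beam {number}: no MLCX beam-limiting device sequence")

        cps_raw = b.require((0x300A, 0x0111), "ControlPointSequence")
        energy_mv = None
        state = {"gantry": 0.0, "coll": 0.0, "couch": 0.0,
                 "jaws": None, "mlc": None}
        cps = []
        prev_w = -np.inf
        for j, c in enumerate(cps_raw):
            w = float(c.require((0x300A, 0x0134), "CumulativeMetersetWeight"))
            if w < prev_w - 1e-12:
                raise PlanParseError(
                    f"beam {number} control point {j}: cumulative weight "
                    f"{w} decreases")
            prev_w = w
            if (0x300A, 0x0114) in c:
                energy_mv = float(c.get_value((0x300A, 0x0114)))
            for tag, key in (((0x300A, 0x011E), "gantry"),
                             ((0x300A, 0x0120), "coll"),
                             ((0x300A, 0x0122), "couch")):
                if tag in c:
                    state[key] = float(c.get_value(tag))
            for d in c.get_value((0x300A, 0x011A), []):
                dev = d.get_value((0x300A, 0x00B8))
                vals = np.array(_as_float_list(
                    d.require((0x300A, 0x011C), "LeafJawPositions"))) / 10.0
                if dev == "ASYMX":
                    jaws = state["jaws"] if state["jaws"] is not None \
                        else np.zeros(4)
                    state["jaws"] = np.array(
                        [vals[0], vals[1], jaws[2], jaws[3]])
                elif dev == "ASYMY":
                    jaws = state["jaws"] if state["jaws"] is not None \
                        else np.zeros(4)
                    state["jaws"] = np.array(
                        [jaws[0], jaws[1], vals[0], vals[1]])
                elif dev == "MLCX":
                    if vals.size != 2 * N_LEAF_PAIRS:
                        raise PlanParseError(
                            f"beam {number} control point {j}: MLCX has "
                            f"{vals.size} values, expected {2 * N_LEAF_PAIRS}")
                    state["mlc"] = vals.reshape(2, N_LEAF_PAIRS)
            if state["mlc"] is None:
                raise PlanParseError(
                    f"beam {number} control point {j}: no MLC positions")
            if state["jaws"] is None:
                raise PlanParseError(
                    f"beam {number} control point {j}: no jaw positions")
            cps.append(ControlPoint(
                gantry_angle=state["gantry"],
                collimator_angle=state["coll"],
                couch_angle=state["couch"],
                jaw_positions=state["jaws"].copy(),
                mlc_positions=state["mlc"].copy(),
                cumulative_weight=w,
            ))
        energy_label = f"{energy_mv:g}X" if energy_mv is not None else "6X"
        beams.append(Beam(
            control_points=cps,
            meterset=metersets.get(number, 0.0),
            energy=energy_label,
            leaf_boundaries=boundaries,
            name=name,
        ))
    label = str(ds.get_value((0x300A, 0x0002), "arcqa plan"))
    return ArcPlan(beams=beams, label=label)


# ---------------------------------------------------------------------------
# DICOM-RT Dose

def write_dose(grid: DoseGrid, path) -> None:
    """Serialise a DoseGrid as DICOM-RT Dose (32-bit scaled integers, mm)."""
    nz, ny, nx = grid.values.shape
    vmax = float(grid.values.max())
    # decimal power-of-ten scaling: short, exactly re-parseable, and exact
    # for decimal-valued doses; quantization step <= 10 * vmax / 2^32
    k = int(np.ceil(np.log10(vmax / (2**32 - 1)))) if vmax > 0 else 0
    scaling = float(f"1e{k}")
    stored = np.clip(np.round(grid.values / scaling), 0, 2**32 - 1) \
        .astype(np.uint32)

    ds = Dataset()
    uid = deterministic_uid("rtdose", nx, ny, nz, f"{vmax:.9e}")
    ds.add(0x0008, 0x0016, "UI", RTDOSE_SOP_CLASS)
    ds.add(0x0008, 0x0018, "UI", uid)
    ds.add(0x0008, 0x0060, "CS", "RTDOSE")
    ds.add(0x0010, 0x0010, "PN", "arcqa^phantom")
    ds.add(0x0010, 0x0020, "LO", "ARCQA000")
    ds.add(0x0028, 0x0002, "US", 1)
    ds.add(0x0028, 0x0004, "CS", "MONOCHROME2")
    ds.add(0x0028, 0x0008, "IS", str(nz))
    ds.add(0x0028, 0x0010, "US", ny)
    ds.add(0x0028, 0x0011, "US", nx)
    ds.add(0x0028, 0x0100, "US", 32)
    ds.add(0x0028, 0x0101, "US", 32)
    ds.add(0x0028, 0x0102, "US", 31)
    ds.add(0x0028, 0x0103, "US", 0)
    # PixelSpacing is (row spacing, column spacing) = (dy, dx), in mm
    ds.add(0x0028, 0x0030, "DS", [_ds(grid.spacing[1] * 10.0, 6),
                                  _ds(grid.spacing[0] * 10.0, 6)])
    ds.add(0x0020, 0x0032, "DS", [_ds(grid.origin[0] * 10.0, 6),
                                  _ds(grid.origin[1] * 10.0, 6),
                                  _ds(grid.origin[2] * 10.0, 6)])
    ds.add(0x0020, 0x0037, "DS", ["1", "0", "0", "0", "1", "0"])
    ds.add(0x3004, 0x0002, "CS", "GY")
    ds.add(0x3004, 0x0004, "CS", "PHYSICAL")
    ds.add(0x3004, 0x000A, "CS", "PLAN")
    ds.add(0x3004, 0x000C, "DS",
           [_ds(i * grid.spacing[2] * 10.0, 6) for i in range(nz)])
    ds.add(0x3004, 0x000E, "DS", f"1e{k}")
    ds.add(0x7FE0, 0x0010, "OW", stored.astype("<u4").tobytes())
    _dicom.write_file(path, ds, RTDOSE_SOP_CLASS, uid)


def read_dose(path) -> DoseGrid:
    ds = _dicom.read_file(path)
    if ds.get_value((0x0008, 0x0016)) != RTDOSE_SOP_CLASS:
        raise DicomError(f"{path}: not an RT Dose object")
    nz = int(ds.require((0x0028, 0x0008), "NumberOfFrames"))
    ny = int(ds.require((0x0028, 0x0010), "Rows"))
    nx = int(ds.require((0x0028, 0x0011), "Columns"))
    offsets = np.array(_as_float_list(
        ds.require((0x3004, 0x000C), "GridFrameOffsetVector"))) / 10.0
    if offsets.size != nz:
        raise DicomError("GridFrameOffsetVector length mismatch")
    if nz > 1:
        dz_all = np.diff(offsets)
        if np.any(dz_all <= 0) or np.ptp(dz_all) > 1e-6:
            raise DicomError("nonuniform frame offsets are not supported")
        dz = float(dz_all[0])
    else:
        dz = 1.0
    orient = _as_float_list(ds.require((0x0020, 0x0037),
                                       "ImageOrientationPatient"))
    if not np.allclose(orient, [1, 0, 0, 0, 1, 0], atol=1e-9):
        raise DicomError("only axis-aligned dose grids are supported")
    spacing_mm = _as_float_list(ds.require((0x0028, 0x0030), "PixelSpacing"))
    dy, dx = spacing_mm[0] / 10.0, spacing_mm[1] / 10.0
    origin = np.array(_as_float_list(
        ds.require((0x0020, 0x0032), "ImagePositionPatient"))) / 10.0
    scaling = float(ds.require((0x3004, 0x000E), "DoseGridScaling"))
    raw = ds.require((0x7FE0, 0x0010), "PixelData")
    stored = np.frombuffer(raw[: nx * ny * nz * 4], dtype="<u4")
    values = (stored.astype(float) * scaling).reshape(nz, ny, nx)
    return DoseGrid(values=values, origin=origin,
                    spacing=np.array([dx, dy, dz]))
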