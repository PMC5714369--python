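"""Desk-scale dose engine and perturbation generators.

Stands in for linac + measurement + full transport: primary-ray dose with an
analytic (or tabulated) depth-dose curve, water-equivalent path lengths
through the annular phantom, and inverse-square correction.  Also provides
the diode angular-response model, rigid setup misalignments, multiplicative
measurement noise, and the synthetic DICOM-RT fixture generator.

Point doses are cGy (calibration default 1 cGy/MU at dmax, 10x10 cm^2,
100 cm SSD); assembled :class:`~arcqa.rt_io.DoseGrid` objects are Gy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .detector_geometry import (
    DiodeArrayLayout,
    PhantomModel,
    build_layout,
    entrance_exit_masks,
    radiological_depths,
)
from .fluence_model import FluenceMap, MLCModel, accumulate_fluence, \
    decompose_subfields
from .rt_io import (
    ArcPlan,
    Beam,
    ControlPoint,
    DEFAULT_LEAF_BOUNDARIES,
    DoseGrid,
    N_LEAF_PAIRS,
    write_dose,
    write_plan,
)

__all__ = [
    "BeamModel",
    "AngularResponse",
    "RigidTransform",
    "Projection",
    "beam_axes",
    "compute_point_doses",
    "compute_dose_grid",
    "diode_dose_from_center",
    "virtual_diode_readings",
    "apply_misalignment",
    "generate_arc_plan",
    "make_fixtures",
    "plan_projections",
    "write_readings",
    "read_readings",
]

#: per-energy (dmax cm, effective attenuation coefficient 1/cm) for the
#: analytic depth-dose stand-in (measured tables may be supplied instead)
ENERGY_DEFAULTS = {"6X": (1.5, 0.0466), "10X": (2.5, 0.0398)}


@dataclass(frozen=True)
class BeamModel:
    """Depth-dose + calibration model of the treatment beam.

    Analytic default: linear buildup from ``surface_ratio`` at depth 0 to
    1.0 at ``dmax``, then exponential falloff ``exp(-mu (d - dmax))``.  A
    tabulated curve ``tmr_table = (depths, values)`` overrides the analytic
    form.  ``calibration`` is dose per MU at dmax for a 10x10 cm^2 field at
    100 cm SSD (cGy/MU).
    """

    energy: str = "6X"
    dmax: float = 1.5
    mu_attenuation: float = 0.0466
    surface_ratio: float = 0.5
    calibration: float = 1.0            # cGy/MU
    source_axis_distance: float = 100.0
    tmr_table: tuple[np.ndarray, np.ndarray] | None = None
    attenuation_enabled: bool = True

    @classmethod
    def for_energy(cls, energy: str, **kwargs) -> "BeamModel":
        dmax, mu = ENERGY_DEFAULTS.get(energy, ENERGY_DEFAULTS["6X"])
        return cls(energy=energy, dmax=dmax, mu_attenuation=mu, **kwargs)

    @classmethod
    def no_attenuation(cls, **kwargs) -> "BeamModel":
        """Depth-independent beam (TMR = 1): isolates the inverse-square law."""
        return cls(attenuation_enabled=False, **kwargs)

    def tmr(self, depth, field_size: float = 10.0):
        """Tissue-maximum-ratio at water-equivalent depth (cm).

        The analytic stand-in carries no field-size dependence; the argument
        is accepted so tabulated models may use it.
        """
        depth = np.asarray(depth, dtype=float)
        if not self.attenuation_enabled:
            return np.ones_like(depth)
        if self.tmr_table is not None:
            d_knots, v_knots = self.tmr_table
            return np.interp(depth, d_knots, v_knots)
        d = np.clip(depth, 0.0, None)
        buildup = self.surface_ratio + (1.0 - self.surface_ratio) * d / self.dmax
        falloff = np.exp(-self.mu_attenuation * (d - self.dmax))
        return np.where(d < self.dmax, buildup, falloff)


@dataclass(frozen=True)
class AngularResponse:
    """Diode response vs beam incidence: a raised-cosine lobe.

    ``factor = 1 - amplitude * (1 - |cos(angle)|)`` where ``angle`` is
    between the beam direction and the diode outward normal; 1 at normal
    incidence, deviating by at most ``amplitude``.  ``correction_enabled``
    models the vendor's automatic correction (division by the same factor,
    which with a matching model recovers the unperturbed reading exactly).
    """

    amplitude: float = 0.08
    enabled: bool = True
    correction_enabled: bool = False

    def __post_init__(self):
        if not 0 <= self.amplitude < 1:
            raise ValueError("amplitude must lie in [0, 1)")

    def factor(self, cos_incidence) -> np.ndarray:
        c = np.abs(np.asarray(cos_incidence, dtype=float))
        return 1.0 - self.amplitude * (1.0 - c)


@dataclass(frozen=True)
class RigidTransform:
    """Rigid setup misalignment: translation + rotation about one axis.

    ``translation`` is (AP, RL, SI) in cm; rotation is degrees in
    (-180, 180] about the detector-cylinder axis (``axis="cylinder"``, the
    default) or the vertical axis (``axis="vertical"``, couch-yaw-like).
    """

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: float = 0.0
    axis: str = "cylinder"

    def __post_init__(self):
        if not -180.0 < self.rotation_deg <= 180.0:
            raise ValueError("rotation must lie in (-180, 180] degrees")
        if self.axis not in ("cylinder", "vertical"):
            raise ValueError("axis must be 'cylinder' or 'vertical'")

    @property
    def translation_xyz(self) -> np.ndarray:
        ap, rl, si = self.translation
        return np.array([rl, ap, si])      # frame: x=RL, y=AP, z=SI

    @property
    def rotation_matrix(self) -> np.ndarray:
        t = np.deg2rad(self.rotation_deg)
        c, s = np.cos(t), np.sin(t)
        if self.axis == "cylinder":        # about z
            return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Rotate about the isocenter, then translate."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.rotation_matrix.T + self.translation_xyz
        return out if np.asarray(points).ndim == 2 else out[0]

    def apply_vector(self, v: np.ndarray) -> np.ndarray:
        return np.asarray(v, dtype=float) @ self.rotation_matrix.T

    def inverse(self) -> "RigidTransform":
        r_inv = self.rotation_matrix.T
        t_inv = -(r_inv @ self.translation_xyz)
        rl, ap, si = t_inv[0], t_inv[1], t_inv[2]
        rot = -self.rotation_deg
        if rot <= -180.0:
            rot += 360.0
        return RigidTransform(translation=(float(ap), float(rl), float(si)),
                              rotation_deg=rot, axis=self.axis)

    @property
    def is_identity(self) -> bool:
        return (self.rotation_deg == 0.0
                and all(t == 0.0 for t in self.translation))


def apply_misalignment(transform: RigidTransform, geometry) -> np.ndarray:
    """Rigidly move detector/phantom geometry (point sets).

    Accepts a :class:`DiodeArrayLayout` (returns its transformed (n, 3)
    positions) or any (n, 3) point array.
    """
    if isinstance(geometry, DiodeArrayLayout):
        return transform.apply(geometry.positions)
    return transform.apply(np.asarray(geometry, dtype=float))


# ---------------------------------------------------------------------------
# beam geometry

@dataclass
class Projection:
    """One static fluence projection of a delivery."""

    fluence: FluenceMap
    gantry_angle: float
    couch_angle: float = 0.0
    collimator_angle: float = 0.0


def beam_axes(gantry_deg: float, couch_deg: float = 0.0,
              sad: float = 100.0,
              setup_transform: RigidTransform | None = None):
    """Source position and beam's-eye-view basis in the phantom frame.

    Returns ``(u, v, w, source)``: ``w`` points from source toward the
    isocenter, ``u``/``v`` span the isocenter plane (``v`` along SI for a
    coplanar beam).  A setup misalignment of the phantom is equivalently
    applied as the *inverse* transform of the beam.
    """
    g = np.deg2rad(gantry_deg)
    s0 = np.array([np.sin(g), np.cos(g), 0.0])
    u0 = np.array([np.cos(g), -np.sin(g), 0.0])
    v0 = np.array([0.0, 0.0, 1.0])
    c = np.deg2rad(couch_deg)
    ry = np.array([[np.cos(c), 0.0, np.sin(c)],
                   [0.0, 1.0, 0.0],
                   [-np.sin(c), 0.0, np.cos(c)]])
    s_dir, u, v = ry @ s0, ry @ u0, ry @ v0
    source = sad * s_dir
    w = -s_dir
    if setup_transform is not None and not setup_transform.is_identity:
        inv = setup_transform.inverse()
        source = inv.apply(source)
        u, v, w = inv.apply_vector(u), inv.apply_vector(v), inv.apply_vector(w)
    return u, v, w, source


def compute_point_doses(
    points: np.ndarray,
    projections: list[Projection],
    beam: BeamModel,
    phantom: PhantomModel,
    angular: AngularResponse | None = None,
    normals: np.ndarray | None = None,
    setup_transform: RigidTransform | None = None,
) -> np.ndarray:
    """Primary-ray dose (cGy) at cartesian points, summed over projections.

    Per projection and point: meterset x calibration x fluence at the ray's
    isocenter-plane coordinates x TMR(effective depth) x (SAD / source
    distance)^2.  When ``angular`` is enabled (and ``normals`` given), each
    contribution is additionally scaled by the diode response factor for its
    incidence angle, divided back out when correction is enabled.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    sad = beam.source_axis_distance
    dose = np.zeros(points.shape[0])
    for proj in projections:
        if proj.fluence.meterset == 0:
            continue
        u, v, w, src = beam_axes(proj.gantry_angle, proj.couch_angle, sad,
                                 setup_transform)
        q = points - src
        qw = q @ w
        valid = qw > 1e-9
        qw_safe = np.where(valid, qw, 1.0)
        bx = (q @ u) * sad / qw_safe
        by = (q @ v) * sad / qw_safe
        if proj.collimator_angle:
            t = np.deg2rad(proj.collimator_angle)
            bx, by = (bx * np.cos(t) + by * np.sin(t),
                      -bx * np.sin(t) + by * np.cos(t))
        f = proj.fluence.sample(bx, by)
        f[~valid] = 0.0
        if not np.any(f):
            continue
        deff = radiological_depths(phantom, src, points)
        dist2 = np.sum(q * q, axis=1)
        contrib = (proj.fluence.meterset * beam.calibration * f
                   * beam.tmr(deff, proj.fluence.field_size)
                   * sad * sad / dist2)
        if angular is not None and angular.enabled and normals is not None:
            dirs = q / np.sqrt(dist2)[:, None]
            fac = angular.factor(np.sum(dirs * normals, axis=1))
            contrib = contrib * fac
            if angular.correction_enabled:
                contrib = contrib / fac
        dose += contrib
    return dose


def compute_dose_grid(
    projections: list[Projection],
    beam: BeamModel,
    phantom: PhantomModel,
    grid_spacing: float = 1.0,
    grid_extent: tuple[float, float, float] = (28.0, 28.0, 24.0),
    grid_center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    setup_transform: RigidTransform | None = None,
) -> DoseGrid:
    """Deterministic 3D dose grid (Gy) from fluence projections."""
    ex, ey, ez = grid_extent
    cx, cy, cz = grid_center
    nx = int(round(ex / grid_spacing)) + 1
    ny = int(round(ey / grid_spacing)) + 1
    nz = int(round(ez / grid_spacing)) + 1
    xs = cx - ex / 2.0 + np.arange(nx) * grid_spacing
    ys = cy - ey / 2.0 + np.arange(ny) * grid_spacing
    zs = cz - ez / 2.0 + np.arange(nz) * grid_spacing
    zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    cgy = compute_point_doses(pts, projections, beam, phantom,
                              setup_transform=setup_transform)
    return DoseGrid(
        values=(cgy / 100.0).reshape(nz, ny, nx),
        origin=np.array([xs[0], ys[0], zs[0]]),
        spacing=np.array([grid_spacing] * 3),
    )


@dataclass
class DiodeDoseResult:
    """Expected diode doses derived from a central-axis dose."""

    dose: np.ndarray            # cGy; NaN where the diode is outside the beam
    in_beam: np.ndarray         # boolean per diode
    entrance: np.ndarray        # boolean per diode (source-facing half)
    exit: np.ndarray


def diode_dose_from_center(
    center_dose: float,
    beam: BeamModel,
    phantom: PhantomModel,
    layout: DiodeArrayLayout,
    gantry_angle: float,
    field_size: float = 10.0,
    couch_angle: float = 0.0,
) -> DiodeDoseResult:
    """Propagate an isocenter dose to the diodes (calibration math).

    ``D_diode = D_center x TMR(d_diode) / TMR(d_center) x (SAD/r_diode)^2``
    with water-equivalent depths from the analytic path integral and
    ``r_diode`` the source-to-diode distance.  Diodes whose ray falls outside
    the square field are flagged, not computed.
    """
    sad = beam.source_axis_distance
    u, v, w, src = beam_axes(gantry_angle, couch_angle, sad)
    pts = layout.positions
    q = pts - src
    qw = q @ w
    bx = (q @ u) * sad / qw
    by = (q @ v) * sad / qw
    in_beam = (np.abs(bx) <= field_size / 2.0) & \
              (np.abs(by) <= field_size / 2.0) & (qw > 0)
    d_diode = radiological_depths(phantom, src, pts)
    d_center = radiological_depths(phantom, src,
                                   np.zeros((1, 3)))[0]
    r = np.linalg.norm(q, axis=1)
    factor = (beam.tmr(d_diode, field_size)
              / beam.tmr(np.array(d_center), field_size)) * (sad / r) ** 2
    dose = np.where(in_beam, center_dose * factor, np.nan)
    ent, ext = entrance_exit_masks(layout, gantry_angle % 360.0)
    return DiodeDoseResult(dose=dose, in_beam=in_beam, entrance=ent, exit=ext)


def virtual_diode_readings(
    dose,
    layout: DiodeArrayLayout,
    source: np.ndarray | None = None,
    angular: AngularResponse | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    positions: np.ndarray | None = None,
) -> np.ndarray:
    """Simulated diode readings (cGy).

    ``dose`` is either a :class:`DoseGrid` (trilinear interpolation at the
    diode positions, Gy -> cGy) or a per-diode cGy array from the ray engine.
    The angular response multiplies the reading when enabled and is divided
    back out when its correction flag is set (a matching correction model
    recovers the unperturbed reading exactly).  Noise is multiplicative
    gaussian; any nonzero ``noise_sd`` requires an explicit ``seed``.
    """
    pos = layout.positions if positions is None else np.asarray(positions)
    if isinstance(dose, DoseGrid):
        readings = dose.interpolate(pos) * 100.0
    else:
        readings = np.asarray(dose, dtype=float).copy()
        if readings.shape[0] != pos.shape[0]:
            raise ValueError("per-diode dose length does not match layout")
    if angular is not None and angular.enabled and source is not None:
        dirs = pos - np.asarray(source, dtype=float)
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        normals = layout.outward_normals
        fac = angular.factor(np.sum(dirs * normals, axis=1))
        readings = readings * fac
        if angular.correction_enabled:
            readings = readings / fac
    if noise_sd:
        if seed is None:
            raise ValueError("noise requires an explicit seed")
        rng = np.random.default_rng(seed)
        readings = readings * (1.0 + noise_sd * rng.standard_normal(
            readings.shape[0]))
    return readings


# ---------------------------------------------------------------------------
# synthetic plan / fixture generation

def _aperture_banks(pattern: str, field_size: float, frac: float,
                    rng: np.random.Generator | None):
    """Bank A/B leaf positions for one control point of a pattern."""
    bounds = DEFAULT_LEAF_BOUNDARIES
    centers = 0.5 * (bounds[:-1] + bounds[1:])
    half = field_size / 2.0
    bank_a = np.zeros(N_LEAF_PAIRS)
    bank_b = np.zeros(N_LEAF_PAIRS)
    open_leaves = (bounds[1:] > -half + 1e-9) & (bounds[:-1] < half - 1e-9)
    if pattern == "open":
        bank_a[open_leaves] = -half
        bank_b[open_leaves] = half
    elif pattern == "wedge":
        # staggered tips: lateral wedge, varies with leaf position
        rel = (centers[open_leaves] + half) / field_size  # 0..1 over the field
        bank_a[open_leaves] = -half
        bank_b[open_leaves] = -half + field_size * (0.3 + 0.7 * rel)
    elif pattern == "multiseg":
        if rng is None:
            raise ValueError("multiseg pattern requires a seeded rng")
        rel = (centers[open_leaves] + half) / field_size
        drift = 0.35 * half * np.sin(2.0 * np.pi * (frac + rel)
                                     + rng.uniform(0, 2 * np.pi))
        gap = half * rng.uniform(0.4, 1.0)
        c = np.clip(drift, -half + gap / 2.0, half - gap / 2.0)
        bank_a[open_leaves] = np.clip(c - gap / 2.0, -half, half)
        bank_b[open_leaves] = np.clip(c + gap / 2.0, -half, half)
    else:
        raise ValueError(f"unknown modulation pattern: {pattern!r}")
    return bank_a, bank_b


def generate_arc_plan(
    pattern: str = "open",
    n_control_points: int = 177,
    energy: str = "6X",
    mu: float = 100.0,
    field_size: float = 10.0,
    gantry_start: float = 180.0,
    gantry_span: float = 359.0,
    couch_angle: float = 0.0,
    collimator_angle: float = 0.0,
    seed: int | None = None,
    label: str = "arcqa synthetic arc",
) -> ArcPlan:
    """Synthesise a single-beam VMAT arc with equally spaced control points.

    Cumulative meterset weights are uniform (0 ... 1); the aperture pattern
    is ``open`` (static square), ``wedge`` (staggered leaf tips) or
    ``multiseg`` (seeded per-control-point sliding segments).
    """
    if n_control_points < 2:
        raise ValueError("need at least 2 control points")
    rng = np.random.default_rng(seed) if seed is not None else None
    half = field_size / 2.0
    cps = []
    for i in range(n_control_points):
        frac = i / (n_control_points - 1)
        bank_a, bank_b = _aperture_banks(pattern, field_size, frac, rng)
        cps.append(ControlPoint(
            gantry_angle=(gantry_start + gantry_span * frac) % 360.0,
            collimator_angle=collimator_angle,
            couch_angle=couch_angle,
            jaw_positions=np.array([-half, half, -half, half]),
            mlc_positions=np.vstack([bank_a, bank_b]),
            cumulative_weight=frac,
        ))
    beam = Beam(control_points=cps, meterset=mu, energy=energy)
    return ArcPlan(beams=[beam], label=label)


def plan_projections(
    plan: ArcPlan,
    mlc: MLCModel | None = None,
    angular_bin: float = 15.0,
    fluence_spacing: float = 0.25,
) -> list[Projection]:
    """Decompose every beam of a plan into binned fluence projections."""
    projections = []
    for beam in plan.beams:
        subfields = decompose_subfields(beam)
        for rep_gantry, fm in accumulate_fluence(
                subfields, mlc, angular_bin, fluence_spacing):
            projections.append(Projection(
                fluence=fm,
                gantry_angle=rep_gantry,
                couch_angle=subfields[0].couch_angle,
                collimator_angle=subfields[0].collimator_angle,
            ))
    return projections


def write_readings(path, readings: np.ndarray,
                   chamber_cgy: float | None = None,
                   seed: int | None = None) -> None:
    """Plain-text readings table: diode index, reading in cGy."""
    with open(path, "w") as fh:
        fh.write("# arcqa diode readings v1\n")
        fh.write("# units: cGy\n")
        if chamber_cgy is not None:
            fh.write(f"# chamber_cgy: {chamber_cgy!r}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        fh.write("# columns: diode_index reading_cgy\n")
        for i, r in enumerate(readings):
            fh.write(f"{i}\t{float(r)!r}\n")


def read_readings(path) -> tuple[np.ndarray, float | None]:
    """Read a readings table; returns (per-diode cGy, chamber cGy or None)."""
    chamber = None
    idx, vals = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if line[1:].strip().startswith("chamber_cgy:"):
                    chamber = float(line.split(":", 1)[1])
                continue
            parts = line.split()
            if parts:
                idx.append(int(parts[0]))
                vals.append(float(parts[1]))
    readings = np.full(max(idx) + 1 if idx else 0, np.nan)
    readings[np.array(idx, dtype=int)] = vals
    return readings, chamber


DEFAULT_FIXTURE_SPEC = {
    "pattern": "open",
    "n_control_points": 177,
    "energy": "6X",
    "mu": 100.0,
    "field_size": 10.0,
    "gantry_start": 180.0,
    "gantry_span": 359.0,
    "angular_bin": 15.0,
    "fluence_spacing": 0.25,
    "grid_spacing": 1.0,
    "grid_extent": (28.0, 28.0, 24.0),
    "noise_sd": 0.0,
    "plug_present": False,
}


def make_fixtures(spec: dict | None, seed: int, out_dir) -> dict[str, Path]:
    """Generate a consistent (plan, dose, readings) fixture triple on disk.

    The plan is a synthetic arc per ``spec``; the dose grid is the ray
    engine's result for that plan; the readings are the grid interpolated at
    the diode positions (optionally noise-perturbed with the given seed).
    All outputs parse back through :mod:`arcqa.rt_io` /
    :func:`read_readings`, and identical (spec, seed) produce byte-identical
    files.
    """
    cfg = dict(DEFAULT_FIXTURE_SPEC)
    cfg.update(spec or {})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    plan = generate_arc_plan(
        pattern=cfg["pattern"],
        n_control_points=int(cfg["n_control_points"]),
        energy=cfg["energy"],
        mu=float(cfg["mu"]),
        field_size=float(cfg["field_size"]),
        gantry_start=float(cfg["gantry_start"]),
        gantry_span=float(cfg["gantry_span"]),
        seed=seed,
        label=f"arcqa fixture {cfg['pattern']} seed {seed}",
    )
    beam_model = BeamModel.for_energy(cfg["energy"])
    phantom = PhantomModel(plug_present=bool(cfg["plug_present"]))
    layout = build_layout()
    projections = plan_projections(
        plan, angular_bin=float(cfg["angular_bin"]),
        fluence_spacing=float(cfg["fluence_spacing"]))
    grid = compute_dose_grid(
        projections, beam_model, phantom,
        grid_spacing=float(cfg["grid_spacing"]),
        grid_extent=tuple(cfg["grid_extent"]))
    readings = virtual_diode_readings(
        grid, layout, noise_sd=float(cfg["noise_sd"]),
        seed=seed if cfg["noise_sd"] else None)

    from .qa_pipeline import ChamberProbe, central_dose  # avoid import cycle
    chamber = central_dose(grid, ChamberProbe())

    paths = {
        "plan": out_dir / "plan.dcm",
        "dose": out_dir / "dose.dcm",
        "readings": out_dir / "readings.tsv",
    }
    write_plan(plan, paths["plan"])
    write_dose(grid, paths["dose"])
    write_readings(paths["readings"], readings, chamber_cgy=chamber, seed=seed)
    return paths
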