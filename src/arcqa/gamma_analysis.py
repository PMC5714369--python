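"""Gamma-index comparison of 2D dose distributions.

For every reference point above the low-dose threshold,

    gamma(r) = min over r' of sqrt( |r - r'|^2 / dta^2
                                    + (D_eval(r') - D_ref(r))^2 / dD^2 )

is minimised over the evaluated distribution upsampled to a step of at most
dta/10, searching a neighbourhood of radius 3 x dta that is automatically
expanded whenever a farther point could still improve the minimum (so the
result equals the exhaustive search).  Cylindrical (unwrapped) maps measure
column distance along the cylinder surface across the 0/360 degree seam.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import interp1d

__all__ = [
    "GammaCriteria",
    "GammaResult",
    "GammaError",
    "DoseMap2D",
    "CylindricalDoseMap",
    "gamma_map",
    "criteria_sweep",
    "unwrapped_gamma",
]


class GammaError(ValueError):
    pass


@dataclass(frozen=True)
class GammaCriteria:
    """%dose / DTA acceptance criteria with a low-dose analysis threshold."""

    dose_tolerance: float = 3.0        # % of the normalization dose
    dta_mm: float = 3.0
    low_dose_threshold: float = 10.0   # % of the normalization dose
    normalization: str = "global"      # 'global' (max of reference) | 'local'
    search_radius_factor: float = 3.0
    upsample_factor: float = 10.0      # evaluated step = dta / this

    def __post_init__(self):
        if self.dose_tolerance <= 0 or self.dta_mm <= 0:
            raise ValueError("dose tolerance and DTA must be > 0")
        if not 0 <= self.low_dose_threshold < 100:
            raise ValueError("low-dose threshold must lie in [0, 100)")
        if self.normalization not in ("global", "local"):
            raise ValueError("normalization must be 'global' or 'local'")

    @property
    def dta_cm(self) -> float:
        return self.dta_mm / 10.0

    def label(self) -> str:
        return f"{self.dose_tolerance:g}%/{self.dta_mm:g}mm"


@dataclass
class GammaResult:
    """Per-point gamma values and the derived passing rate."""

    gamma: np.ndarray           # NaN below the low-dose threshold
    pass_mask: np.ndarray       # True where gamma <= 1 (False below threshold)
    n_evaluated: int
    criteria: GammaCriteria

    @property
    def passing_rate(self) -> float:
        """Percentage of evaluated points with gamma <= 1."""
        return 100.0 * int(self.pass_mask.sum()) / self.n_evaluated


@dataclass
class DoseMap2D:
    """A 2D dose distribution on a regular (row x column) grid, cm spacing."""

    values: np.ndarray
    row_spacing: float
    col_spacing: float
    wrap_cols: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D")
        if self.row_spacing <= 0 or self.col_spacing <= 0:
            raise ValueError("spacings must be > 0")

    @property
    def col_period(self) -> float:
        return self.values.shape[1] * self.col_spacing

    def grids_match(self, other: "DoseMap2D") -> bool:
        return (self.values.shape == other.values.shape
                and np.isclose(self.row_spacing, other.row_spacing)
                and np.isclose(self.col_spacing, other.col_spacing)
                and self.wrap_cols == other.wrap_cols)


@dataclass
class CylindricalDoseMap(DoseMap2D):
    """Unwrapped (axial x angular) peripheral dose at the detector radius."""

    wrap_cols: bool = True
    entrance_mask: np.ndarray | None = None
    exit_mask: np.ndarray | None = None

    @classmethod
    def from_readings(cls, layout, per_diode: np.ndarray,
                      gantry_angle: float | None = None) -> "CylindricalDoseMap":
        """Arrange per-diode values onto the layout's unwrap grid.

        Row spacing is the spiral pitch; column spacing is the arc length
        between angular bins.  Optional entrance/exit masks for one beam
        angle are unwrapped alongside.
        """
        from .detector_geometry import entrance_exit_masks, unwrap_values

        values = unwrap_values(layout, per_diode)
        ent = ext = None
        if gantry_angle is not None:
            e, x = entrance_exit_masks(layout, gantry_angle)
            ent = unwrap_values(layout, e)
            ext = unwrap_values(layout, x)
        return cls(values=values, row_spacing=layout.pitch,
                   col_spacing=layout.spacing, wrap_cols=True,
                   entrance_mask=ent, exit_mask=ext)


def _fine_axis(extent: float, max_step: float) -> np.ndarray:
    """Uniform samples over [0, extent] with step <= max_step, inclusive."""
    n = max(int(np.ceil(extent / max_step)), 1)
    return np.linspace(0.0, extent, n + 1)


def build_fine_grid(evaluated: DoseMap2D, criteria: GammaCriteria):
    """Upsample the evaluated map (step <= dta/10) via separable linear
    interpolation; wrapped maps are padded by half a period on each side so
    every across-the-seam candidate is present.

    Returns (fine_values, fine_row_coords, fine_col_coords); column
    coordinates of a wrapped map start below zero.  Exposed so that tests
    can run an exhaustive search over the identical candidate set.
    """
    vals = evaluated.values
    nr, nc = vals.shape
    dy, dx = evaluated.row_spacing, evaluated.col_spacing
    h = criteria.dta_cm / criteria.upsample_factor

    if evaluated.wrap_cols:
        m = (nc + 1) // 2
        idx = (np.arange(-m, nc + m)) % nc
        vals = vals[:, idx]
        col0 = -m * dx
    else:
        col0 = 0.0
    ncx = vals.shape[1]

    rows = np.arange(nr) * dy
    cols = col0 + np.arange(ncx) * dx
    fine_rows = _fine_axis(rows[-1], h) if nr > 1 else rows.copy()
    fine_cols = col0 + (_fine_axis(cols[-1] - col0, h)
                        if ncx > 1 else np.array([0.0]))
    part = interp1d(rows, vals, axis=0, assume_sorted=True)(fine_rows) \
        if nr > 1 else np.repeat(vals, 1, axis=0)
    fine = interp1d(cols, part, axis=1, assume_sorted=True)(fine_cols) \
        if ncx > 1 else part
    return fine, fine_rows, fine_cols


def _gamma_core(reference: DoseMap2D, evaluated: DoseMap2D,
                criteria: GammaCriteria) -> GammaResult:
    if not reference.grids_match(evaluated):
        raise GammaError("reference and evaluated maps are on different grids")
    ref = reference.values
    norm = float(np.nanmax(ref))
    if norm <= 0:
        raise GammaError("no evaluable points (reference maximum is 0)")
    threshold = criteria.low_dose_threshold / 100.0 * norm
    evaluable = np.isfinite(ref) & (ref >= threshold)
    if not np.any(evaluable):
        raise GammaError("no evaluable points above the low-dose threshold")

    fine, frows, fcols = build_fine_grid(evaluated, criteria)
    dta = criteria.dta_cm
    dy, dx = reference.row_spacing, reference.col_spacing
    hy = frows[1] - frows[0] if frows.size > 1 else 1.0
    hx = fcols[1] - fcols[0] if fcols.size > 1 else 1.0

    gamma = np.full(ref.shape, np.nan)
    r0 = criteria.search_radius_factor * dta
    ii, jj = np.nonzero(evaluable)
    for i, j in zip(ii, jj):
        yr, xr = i * dy, j * dx
        d_ref = ref[i, j]
        if criteria.normalization == "global":
            dd_tol = criteria.dose_tolerance / 100.0 * norm
        else:
            dd_tol = criteria.dose_tolerance / 100.0 * d_ref
        radius = r0
        while True:
            lo_r = max(int(np.floor((yr - radius) / hy)), 0)
            hi_r = min(int(np.ceil((yr + radius) / hy)), frows.size - 1)
            lo_c = max(int(np.floor((xr - radius - fcols[0]) / hx)), 0)
            hi_c = min(int(np.ceil((xr + radius - fcols[0]) / hx)),
                       fcols.size - 1)
            d2r = (frows[lo_r:hi_r + 1] - yr) ** 2
            d2c = (fcols[lo_c:hi_c + 1] - xr) ** 2
            window = fine[lo_r:hi_r + 1, lo_c:hi_c + 1]
            g2 = (d2r[:, None] + d2c[None, :]) / (dta * dta) \
                + (window - d_ref) ** 2 / (dd_tol * dd_tol)
            g_min = float(np.sqrt(g2.min()))
            whole = (lo_r == 0 and hi_r == frows.size - 1
                     and lo_c == 0 and hi_c == fcols.size - 1)
            if g_min <= radius / dta or whole:
                break
            radius *= 2.0    # a farther point could still beat the minimum
        gamma[i, j] = g_min

    pass_mask = np.zeros(ref.shape, dtype=bool)
    pass_mask[evaluable] = gamma[evaluable] <= 1.0
    return GammaResult(gamma=gamma, pass_mask=pass_mask,
                       n_evaluated=int(evaluable.sum()), criteria=criteria)


def gamma_map(reference: DoseMap2D, evaluated: DoseMap2D,
              criteria: GammaCriteria) -> GammaResult:
    """Gamma index of ``evaluated`` against ``reference`` on a planar grid."""
    return _gamma_core(reference, evaluated, criteria)


def unwrapped_gamma(reference: CylindricalDoseMap,
                    evaluated: CylindricalDoseMap,
                    criteria: GammaCriteria) -> GammaResult:
    """Gamma on unwrapped cylinder maps with angular wrap-around.

    Column distance across the 0/360 seam is measured along the cylinder
    surface (arc length), never through the seam discontinuity.
    """
    if not (reference.wrap_cols and evaluated.wrap_cols):
        raise GammaError("unwrapped_gamma requires wrapped cylindrical maps")
    return _gamma_core(reference, evaluated, criteria)


def criteria_sweep(reference: DoseMap2D, evaluated: DoseMap2D,
                   dose_tolerances: list[float], dta_list_mm: list[float],
                   low_dose_threshold: float = 10.0,
                   normalization: str = "global") -> pd.DataFrame:
    """Passing-rate table over a grid of (%dose, DTA) criteria.

    Rows are dose tolerances (%), columns DTA (mm); rates are percentages.
    Rates are nondecreasing along both loosening directions.
    """
    if not dose_tolerances or not dta_list_mm:
        raise ValueError("criteria lists must be nonempty")
    table = pd.DataFrame(
        index=pd.Index(dose_tolerances, name="dose_pct"),
        columns=pd.Index(dta_list_mm, name="dta_mm"), dtype=float)
    for tol in dose_tolerances:
        for dta in dta_list_mm:
            crit = GammaCriteria(dose_tolerance=tol, dta_mm=dta,
                                 low_dose_threshold=low_dose_threshold,
                                 normalization=normalization)
            table.loc[tol, dta] = _gamma_core(reference, evaluated,
                                              crit).passing_rate
    return table
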