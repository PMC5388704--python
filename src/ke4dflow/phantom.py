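"""Synthetic 4D flow phantoms with known ground truth.

Every downstream stage of the measurement chain (eddy-current correction,
phase unwrapping, temporal reconstruction, KE quantification, cohort
statistics) is testable against these generators without patient data:

* analytic phantoms (uniform flow, Poiseuille pipe) whose kinetic energy
  has a closed form;
* a parameterized single-ventricle phantom whose ROI-summed KE follows a
  prescribed two-peak cycle template (systolic-dominant, diastolic-dominant
  or diastolic-plateau pattern) — the velocities are a fixed spatial jet
  profile rescaled per phase, not a flow-physics solution, because the
  pipeline under test is a measurement chain and KE-level ground truth is
  what its tests need;
* corruption injectors that apply the acquisition artifacts the
  preprocessing stage must undo (static first-order eddy-current velocity
  offsets, venc aliasing wraps, Gaussian velocity noise);
* a cohort simulator drawing per-subject peak KE/SV from stated group
  distributions, emulating a single-ventricle (Fontan) group versus
  healthy controls.

Default acquisition settings mirror a pediatric/adult 4D PC-MRI protocol:
venc 100 cm/s, 2–3 mm isotropic voxels, ~20 acquired phases later
reconstructed to 40.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import GeometryError, FlowError
from .io import (
    BLOOD_DENSITY_G_CM3,
    FlowMetadata,
    LABEL_CODES,
    MaskSeries,
    VelocityField4D,
    uniform_phase_times,
)
from .kinetic_energy import ke_volume_mj

logger = logging.getLogger(__name__)


@dataclass
class PhantomTruth:
    """Ground truth attached to a synthetic dataset.

    ``true_ke_curve`` is the ROI-summed KE per phase in mJ;
    ``eddy_plane`` holds the injected per-component first-order velocity
    offset (offset cm/s; gradients cm/s per mm along x, y, z);
    ``wrap_sites`` lists (phase, x, y, z, component) indices where venc
    aliasing was injected.
    """

    true_ke_curve: np.ndarray
    true_volume_curve: Optional[np.ndarray] = None  # ml per phase
    eddy_plane: Optional[np.ndarray] = None  # (3, 4)
    wrap_sites: list = dc_field(default_factory=list)
    noise_sigma: float = 0.0
    continuum_ke_mj: Optional[float] = None
    extras: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.true_ke_curve = np.asarray(self.true_ke_curve, dtype=np.float64)
        if np.any(self.true_ke_curve < 0):
            raise FlowError("true KE curve cannot be negative")


def _check_unit(direction: Sequence[float]) -> np.ndarray:
    d = np.asarray(direction, dtype=np.float64)
    if d.shape != (3,) or abs(np.linalg.norm(d) - 1.0) > 1e-6:
        raise FlowError(f"direction must be a unit 3-vector, got {direction}")
    return d


def _metadata(subject_id: str, spacing, n_phases: int, rr: float,
              venc: float, **kw) -> FlowMetadata:
    return FlowMetadata(subject_id=subject_id, venc=venc,
                        voxel_spacing=tuple(spacing),
                        n_phases_acquired=n_phases,
                        rr_interval=rr, **kw)


def make_uniform_phantom(speed: float, direction: Sequence[float] = (0.0, 0.0, 1.0),
                         grid: Sequence[int] = (20, 20, 20),
                         spacing: Sequence[float] = (2.0, 2.0, 2.0),
                         n_phases: int = 20, *,
                         rr_interval: float = 1000.0, venc: float = 100.0,
                         roi_shape: Optional[Sequence[int]] = None,
                         roi_label: str = "ventricle",
                         subject_id: str = "uniform_phantom"
                         ) -> tuple[VelocityField4D, MaskSeries, PhantomTruth]:
    """Constant plug flow inside a centered box ROI, zero outside.

    The true KE per phase is the closed form ½·ρ·V_roi·v² (in mJ) with
    V_roi the ROI voxel count times the voxel volume.
    """
    if speed < 0:
        raise FlowError("speed must be nonnegative")
    d = _check_unit(direction)
    grid = tuple(int(g) for g in grid)
    if any(g < 1 for g in grid):
        raise GeometryError("grid must be nonempty")
    if roi_shape is None:
        roi_shape = tuple(max(1, g // 2) for g in grid)
    roi_shape = tuple(int(r) for r in roi_shape)
    if any(r > g for r, g in zip(roi_shape, grid)):
        raise GeometryError(f"ROI {roi_shape} exceeds grid {grid}")

    roi = np.zeros(grid, dtype=bool)
    sl = tuple(slice((g - r) // 2, (g - r) // 2 + r) for g, r in zip(grid, roi_shape))
    roi[sl] = True

    values = np.zeros((n_phases,) + grid + (3,))
    values[:, roi, :] = speed * d
    meta = _metadata(subject_id, spacing, n_phases, rr_interval, venc)
    fld = VelocityField4D(values=values,
                         phase_times=uniform_phase_times(n_phases, rr_interval),
                         metadata=meta)
    labels = np.where(roi, LABEL_CODES[roi_label], 0).astype(np.int16)
    masks = MaskSeries(labels=np.broadcast_to(labels, (n_phases,) + grid).copy())

    n_roi = int(roi.sum())
    ke = ke_volume_mj(n_roi * speed**2, meta.voxel_volume_mm3, meta.blood_density)
    vol_ml = n_roi * meta.voxel_volume_mm3 / 1000.0
    truth = PhantomTruth(true_ke_curve=np.full(n_phases, ke),
                         true_volume_curve=np.full(n_phases, vol_ml),
                         continuum_ke_mj=ke)
    return fld, masks, truth


def make_poiseuille_vessel(radius: float, length: float, v_max: float,
                           grid: Optional[Sequence[int]] = None,
                           spacing: Sequence[float] = (1.0, 1.0, 1.0),
                           n_phases: int = 4, *,
                           rr_interval: float = 1000.0, venc: float = 100.0,
                           roi_label: str = "ivc_tunnel",
                           subject_id: str = "poiseuille_phantom"
                           ) -> tuple[VelocityField4D, MaskSeries, PhantomTruth]:
    """Steady Poiseuille (parabolic) flow in a cylinder along z.

    Axial velocity v(r) = v_max (1 − r²/R²).  The continuum KE is
    ½·ρ·(v_max²/3)·πR²L (∫v² dA = v_max²·A/3 for a parabola); the
    discretized voxel sum converges to it as spacing shrinks.  Both are
    attached to the truth object.

    radius and length in mm, v_max in cm/s.
    """
    sx, sy, sz = (float(s) for s in spacing)
    if radius < 2.0 * max(sx, sy):
        raise GeometryError(
            f"radius {radius} mm not resolvable at in-plane spacing "
            f"({sx}, {sy}) mm (need radius >= 2x spacing)"
        )
    if grid is None:
        nxy = int(math.ceil(2.0 * radius / sx)) + 4
        nz = int(math.ceil(length / sz)) + 2
        grid = (nxy, nxy, nz)
    grid = tuple(int(g) for g in grid)
    nx, ny, nz = grid
    if 2.0 * radius > nx * sx or 2.0 * radius > ny * sy or length > nz * sz:
        raise GeometryError(
            f"cylinder (R={radius} mm, L={length} mm) exceeds grid "
            f"{grid} at spacing {spacing} mm"
        )

    # voxel-center coordinates, cylinder centered in the grid
    x = (np.arange(nx) + 0.5) * sx - nx * sx / 2.0
    y = (np.arange(ny) + 0.5) * sy - ny * sy / 2.0
    z = (np.arange(nz) + 0.5) * sz - nz * sz / 2.0
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    r_sq = X**2 + Y**2
    inside = (r_sq < radius**2) & (np.abs(Z) < length / 2.0)

    vz = np.where(inside, v_max * (1.0 - r_sq / radius**2), 0.0)
    values = np.zeros((n_phases,) + grid + (3,))
    values[:, ..., 2] = vz
    meta = _metadata(subject_id, spacing, n_phases, rr_interval, venc)
    fld = VelocityField4D(values=values,
                         phase_times=uniform_phase_times(n_phases, rr_interval),
                         metadata=meta)
    labels = np.where(inside, LABEL_CODES[roi_label], 0).astype(np.int16)
    masks = MaskSeries(labels=np.broadcast_to(labels, (n_phases,) + grid).copy())

    disc_ke = ke_volume_mj(float(np.sum(vz[inside] ** 2)),
                           meta.voxel_volume_mm3, meta.blood_density)
    # analytic volume πR²L with mean squared axial velocity v_max²/3
    continuum = 0.5 * meta.blood_density * (v_max**2 / 3.0) \
        * math.pi * radius**2 * length * 1e-7
    vol_ml = float(inside.sum()) * meta.voxel_volume_mm3 / 1000.0
    truth = PhantomTruth(true_ke_curve=np.full(n_phases, disc_ke),
                         true_volume_curve=np.full(n_phases, vol_ml),
                         continuum_ke_mj=continuum,
                         extras={"radius_mm": radius, "length_mm": length,
                                 "analytic_area_cm2": math.pi * radius**2 / 100.0})
    return fld, masks, truth


# ---------------------------------------------------------------------------
# Single-ventricle phantom
# ---------------------------------------------------------------------------

VENTRICLE_PATTERNS = ("systolic_dominant", "diastolic_dominant", "plateau")

#: default peak KE/SV (mJ/ml) per pattern: right-ventricular-morphology
#: patients show a systolic-dominant pattern, short-outflow left-ventricular
#: morphology a diastolic-dominant one; the plateau pattern accompanies
#: significant aortopulmonary collateral flow.
_DEFAULT_PATTERN_PEAKS = {
    "systolic_dominant": (0.043, 0.025),
    "diastolic_dominant": (0.022, 0.033),
    "plateau": (0.036, 0.028),
}


@dataclass
class VolumeCurveParams:
    """Parameters of the periodic ventricular volume curve.

    The curve starts at end-diastole (maximum volume), falls smoothly to
    end-systole at ``systole_frac`` of the cycle, then refills; it has a
    single minimum, as required by the systole/diastole split.
    """

    edv_ml: float = 150.0
    esv_ml: float = 90.0
    systole_frac: float = 0.38

    def __post_init__(self) -> None:
        if not (self.edv_ml > self.esv_ml > 0):
            raise FlowError("need EDV > ESV > 0")
        if not 0.1 < self.systole_frac < 0.9:
            raise FlowError("systole_frac must lie well inside the cycle")

    @property
    def sv_ml(self) -> float:
        return self.edv_ml - self.esv_ml

    def curve(self, n_phases: int) -> np.ndarray:
        """Target volume (ml) at each of ``n_phases`` uniform cycle samples."""
        i_es = max(1, int(round(self.systole_frac * n_phases)))
        v = np.empty(n_phases)
        for i in range(n_phases):
            if i <= i_es:
                x = i / i_es
                v[i] = self.edv_ml - self.sv_ml * 0.5 * (1 - math.cos(math.pi * x))
            else:
                x = (i - i_es) / (n_phases - i_es)
                # early rapid filling, then slower late filling
                v[i] = self.esv_ml + self.sv_ml * 0.5 * (1 - math.cos(math.pi * x**0.75))
        return v


def _gaussian_bump(n: int, center: int, sigma: float) -> np.ndarray:
    i = np.arange(n)
    # cyclic distance so bumps near the wrap behave periodically
    d = np.minimum(np.abs(i - center), n - np.abs(i - center))
    return np.exp(-0.5 * (d / sigma) ** 2)


def ke_cycle_template(n_phases: int, pattern: str, peak_sys_mj: float,
                      peak_dia_mj: float, systole_frac: float = 0.38, *,
                      atrial_peak_frac: float = 0.0,
                      baseline_frac: float = 0.03) -> np.ndarray:
    """Two-peak KE cycle template (mJ per phase).

    One systolic peak (ejection) at mid-systole and one diastolic peak
    (early filling) are always present; ``atrial_peak_frac`` > 0 adds a
    distinct late-diastolic (atrial contraction) bump of that fraction of
    the diastolic peak.  The ``plateau`` pattern instead holds mid-diastolic
    KE within a few percent of the early-diastolic peak through most of
    diastole.  Bump centers sit exactly on sample indices so the sampled
    maxima equal the nominal peak values.
    """
    if pattern not in VENTRICLE_PATTERNS:
        raise FlowError(f"unknown pattern {pattern!r}; choose from {VENTRICLE_PATTERNS}")
    n = int(n_phases)
    i_es = max(2, int(round(systole_frac * n)))
    m = n - i_es  # diastole length in samples
    i_sys = i_es // 2
    i_e = i_es + max(1, int(round(0.25 * m)))
    i_a = i_es + min(m - 2, int(round(0.85 * m)))
    sigma = max(1.0, 0.07 * n)

    ke = peak_sys_mj * _gaussian_bump(n, i_sys, sigma)
    if pattern == "plateau":
        # ramp to the early-diastolic peak, hold within 3% through late
        # diastole, then decay toward the cycle wrap
        plate = np.zeros(n)
        hold_end = i_es + int(round(0.85 * m))
        for i in range(i_es, n):
            if i < i_e:
                x = (i - i_es) / max(1, i_e - i_es)
                plate[i] = peak_dia_mj * 0.5 * (1 - math.cos(math.pi * x))
            elif i == i_e:
                plate[i] = peak_dia_mj
            elif i <= hold_end:
                plate[i] = 0.97 * peak_dia_mj
            else:
                x = (i - hold_end) / max(1, n - hold_end)
                plate[i] = 0.97 * peak_dia_mj * 0.5 * (1 + math.cos(math.pi * x))
        ke = np.maximum(ke, plate)
    else:
        ke = ke + peak_dia_mj * _gaussian_bump(n, i_e, sigma)
        if atrial_peak_frac > 0:
            ke = ke + atrial_peak_frac * peak_dia_mj * _gaussian_bump(
                n, i_a, max(1.0, 0.05 * n))

    baseline = baseline_frac * max(peak_sys_mj, peak_dia_mj)
    return np.maximum(ke, baseline)


def _ellipsoid_mask(grid: tuple[int, int, int], spacing: tuple[float, float, float],
                    semi_axes_mm: tuple[float, float, float]) -> np.ndarray:
    nx, ny, nz = grid
    sx, sy, sz = spacing
    a, b, c = semi_axes_mm
    x = (np.arange(nx) + 0.5) * sx - nx * sx / 2.0
    y = (np.arange(ny) + 0.5) * sy - ny * sy / 2.0
    z = (np.arange(nz) + 0.5) * sz - nz * sz / 2.0
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    return (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0


#: long-axis / short-axis ratio of the ellipsoidal ventricle model
_ELONGATION = 1.2


def make_ventricle_phantom(pattern: str = "systolic_dominant",
                           volume_curve_params: Optional[VolumeCurveParams] = None,
                           grid: Sequence[int] = (32, 32, 32),
                           spacing: Sequence[float] = (3.0, 3.0, 3.0),
                           n_phases: int = 20, seed: int = 0, *,
                           peak_sys_mj: Optional[float] = None,
                           peak_dia_mj: Optional[float] = None,
                           atrial_peak_frac: float = 0.0,
                           noise_sigma: float = 0.0,
                           rr_interval: float = 1000.0, venc: float = 100.0,
                           subject_id: str = "ventricle_phantom",
                           **metadata_kw,
                           ) -> tuple[VelocityField4D, MaskSeries, PhantomTruth]:
    """Ellipsoidal single-ventricle phantom realizing a prescribed KE cycle.

    A per-phase ellipsoid (scaled isotropically to follow the volume curve)
    carries an axial jet profile — Gaussian in distance from the long axis,
    directed out of the ventricle during systole and into it during
    diastole — rescaled each phase so the ROI-summed KE equals the
    requested cycle template exactly.  Peak KE defaults are the pattern's
    typical peak KE/SV (mJ/ml) times the realized stroke volume.
    """
    if n_phases < 10:
        raise FlowError("ventricle phantom needs n_phases >= 10")
    if pattern not in VENTRICLE_PATTERNS:
        raise FlowError(f"unknown pattern {pattern!r}; choose from {VENTRICLE_PATTERNS}")
    params = volume_curve_params or VolumeCurveParams()
    grid = tuple(int(g) for g in grid)
    spacing = tuple(float(s) for s in spacing)
    meta = _metadata(subject_id, spacing, n_phases, rr_interval, venc,
                     **metadata_kw)

    target_vol = params.curve(n_phases)  # ml
    # end-diastolic ellipsoid semi-axes from the maximum volume
    a0 = (3.0 * params.edv_ml * 1000.0 / (4.0 * math.pi * _ELONGATION)) ** (1.0 / 3.0)
    c0 = _ELONGATION * a0
    half_extent = tuple(0.5 * g * s for g, s in zip(grid, spacing))
    if a0 > half_extent[0] - spacing[0] or a0 > half_extent[1] - spacing[1] \
            or c0 > half_extent[2] - spacing[2]:
        raise GeometryError(
            f"end-diastolic ellipsoid (a={a0:.1f} mm, c={c0:.1f} mm) does not "
            f"fit grid {grid} at spacing {spacing} mm"
        )

    masks_arr = np.zeros((n_phases,) + grid, dtype=np.int16)
    roi_list = []
    actual_vol = np.empty(n_phases)
    voxvol = meta.voxel_volume_mm3
    for p in range(n_phases):
        s = (target_vol[p] / params.edv_ml) ** (1.0 / 3.0)
        roi = _ellipsoid_mask(grid, spacing, (s * a0, s * a0, s * c0))
        roi_list.append(roi)
        masks_arr[p][roi] = LABEL_CODES["ventricle"]
        actual_vol[p] = roi.sum() * voxvol / 1000.0

    # realized stroke volume from the voxelized (measurable) volume curve
    sv = float(actual_vol.max() - actual_vol.min())
    if peak_sys_mj is None or peak_dia_mj is None:
        ps, pd = _DEFAULT_PATTERN_PEAKS[pattern]
        peak_sys_mj = peak_sys_mj if peak_sys_mj is not None else ps * sv
        peak_dia_mj = peak_dia_mj if peak_dia_mj is not None else pd * sv

    template = ke_cycle_template(n_phases, pattern, peak_sys_mj, peak_dia_mj,
                                 params.systole_frac,
                                 atrial_peak_frac=atrial_peak_frac)

    # two spatially disjoint axial jet lobes — outflow (systole, +z) in the
    # x>0 half, inflow (diastole, -z) in the x<0 half — Gaussian in distance
    # from each lobe axis.  The kinetic energy handed from the outflow to
    # the inflow lobe fades smoothly around end-systole so that per-voxel
    # velocity steps between phases stay well below venc (temporal
    # unwrapping relies on that continuity).
    nx, ny, nz = grid
    sx, sy, sz = spacing
    x = (np.arange(nx) + 0.5) * sx - nx * sx / 2.0
    y = (np.arange(ny) + 0.5) * sy - ny * sy / 2.0
    X, Y = np.meshgrid(x, y, indexing="ij")
    jet_sigma = 0.35 * a0
    lobe_off = 0.4 * a0
    out_profile = np.where(
        X > 0, np.exp(-0.5 * ((X - lobe_off) ** 2 + Y**2) / jet_sigma**2), 0.0)
    in_profile = np.where(
        X <= 0, np.exp(-0.5 * ((X + lobe_off) ** 2 + Y**2) / jet_sigma**2), 0.0)
    out_profile = np.broadcast_to(out_profile[..., None], grid)
    in_profile = np.broadcast_to(in_profile[..., None], grid)

    # velocities live on the full end-diastolic support at every phase so
    # each voxel's time series is continuous even as the contracting ROI
    # sheds boundary voxels; KE truth only ever sums over the per-phase ROI
    support = roi_list[int(np.argmax(actual_vol))]

    i_es = max(1, int(round(params.systole_frac * n_phases)))
    values = np.zeros((n_phases,) + grid + (3,))
    for p in range(n_phases):
        roi = roi_list[p]
        # outflow-lobe KE share: 1 in systole, 0 in diastole, cosine ramp
        xw = np.clip((p - (i_es - 2)) / 4.0, 0.0, 1.0)
        w = 0.5 * (1.0 + math.cos(math.pi * xw))
        vz = np.zeros(grid)
        for share, profile, direction in ((w, out_profile, 1.0),
                                          ((1.0 - w), in_profile, -1.0)):
            if share <= 0:
                continue
            unit_ke = ke_volume_mj(float(np.sum(profile[roi] ** 2)), voxvol,
                                   meta.blood_density)
            if unit_ke > 0:
                scale = math.sqrt(share * template[p] / unit_ke)
                vz += np.where(support, direction * scale * profile, 0.0)
        values[p, ..., 2] = vz

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sigma, size=values.shape)

    fld = VelocityField4D(values=values,
                         phase_times=uniform_phase_times(n_phases, rr_interval),
                         metadata=meta)
    masks = MaskSeries(labels=masks_arr)
    truth = PhantomTruth(true_ke_curve=template, true_volume_curve=actual_vol,
                         noise_sigma=noise_sigma,
                         extras={"pattern": pattern, "sv_ml": sv,
                                 "peak_sys_mj": float(peak_sys_mj),
                                 "peak_dia_mj": float(peak_dia_mj),
                                 "end_systole_idx": i_es})
    return fld, masks, truth


# ---------------------------------------------------------------------------
# Corruption injectors
# ---------------------------------------------------------------------------

def _plane_values(plane: np.ndarray, grid: tuple[int, int, int],
                  spacing: tuple[float, float, float]) -> np.ndarray:
    """Evaluate per-component first-order polynomials on the voxel grid.

    ``plane`` is (3, 4): per component an offset (cm/s) and gradients
    (cm/s per mm) along x, y, z; coordinates are voxel index times spacing.
    Returns (x, y, z, 3).
    """
    nx, ny, nz = grid
    sx, sy, sz = spacing
    X, Y, Z = np.meshgrid(np.arange(nx) * sx, np.arange(ny) * sy,
                          np.arange(nz) * sz, indexing="ij")
    out = np.empty(grid + (3,))
    for c in range(3):
        c0, gx, gy, gz = plane[c]
        out[..., c] = c0 + gx * X + gy * Y + gz * Z
    return out


def inject_eddy_offset(fld: VelocityField4D, plane: np.ndarray,
                       truth: Optional[PhantomTruth] = None) -> VelocityField4D:
    """Add a static spatial first-order velocity offset to every phase.

    This is the inverse of the eddy-current compensation step: scanner eddy
    currents superimpose a spatially smooth, time-independent velocity
    offset that a first-order polynomial fit to stationary tissue removes.
    """
    plane = np.asarray(plane, dtype=np.float64)
    if plane.shape != (3, 4):
        raise FlowError(f"plane must be (3, 4) coefficients, got {plane.shape}")
    offs = _plane_values(plane, fld.grid_shape, fld.metadata.voxel_spacing)
    out = fld.copy()
    out.values = out.values + offs[None, ...]
    if truth is not None:
        truth.eddy_plane = plane.copy()
    return out


def wrap_to_venc(values: np.ndarray, venc: float) -> np.ndarray:
    """Map velocities into [−venc, venc) by the aliasing congruence
    v ↦ v − 2·venc·k, exactly as the phase signal wraps on the scanner.

    Values already inside the range pass through bit-exactly.
    """
    v = np.asarray(values, dtype=np.float64)
    outside = (v >= venc) | (v < -venc)
    return np.where(outside, np.mod(v + venc, 2.0 * venc) - venc, v)


def inject_aliasing(fld: VelocityField4D,
                    truth: Optional[PhantomTruth] = None) -> VelocityField4D:
    """Wrap every velocity component beyond ±venc, as aliasing does.

    Idempotent on its own output (which lies within [−venc, venc)); the
    injected wrap sites are recorded in the truth object when given.
    """
    venc = fld.metadata.venc
    out = fld.copy()
    wrapped = wrap_to_venc(out.values, venc)
    sites = np.argwhere(wrapped != out.values)
    out.values = wrapped
    if truth is not None:
        truth.wrap_sites = [tuple(s) for s in sites]
    return out


def inject_noise(fld: VelocityField4D, sigma: float, seed: int,
                 truth: Optional[PhantomTruth] = None) -> VelocityField4D:
    """Add i.i.d. Gaussian velocity noise (cm/s) to every component."""
    out = fld.copy()
    rng = np.random.default_rng(seed)
    out.values = out.values + rng.normal(0.0, sigma, size=out.values.shape)
    if truth is not None:
        truth.noise_sigma = sigma
    return out


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class GroupParams:
    """Distribution parameters for one subject group.

    Peak KE/SV in mJ/ml, EDVI in ml/m², EF in %, BSA in m², heart-rate
    range in beats/min, aortopulmonary-collateral (APC) flow fraction in %
    of stroke volume.  ``morphology_mix`` maps ventricular morphology to
    its probability.
    """

    peak_sys_ke_sv: tuple[float, float]
    peak_dia_ke_sv: tuple[float, float]
    edvi: tuple[float, float] = (100.0, 15.0)
    ef: tuple[float, float] = (55.0, 5.0)
    bsa: tuple[float, float] = (1.8, 0.2)
    hr_range: tuple[float, float] = (55.0, 90.0)
    morphology_mix: dict = dc_field(default_factory=lambda: {"left": 1.0})
    apc_fraction: tuple[float, float] = (0.0, 0.0)


#: group parameters mirroring the published single-ventricle cohort:
#: Fontan patients with left-ventricular morphology vs the left ventricle
#: of healthy controls (peak systolic / diastolic KE/SV 0.022±0.004 /
#: 0.033±0.007 vs 0.048±0.012 / 0.058±0.010 mJ/ml).
FONTAN_LV = GroupParams(
    peak_sys_ke_sv=(0.022, 0.004), peak_dia_ke_sv=(0.033, 0.007),
    edvi=(102.0, 42.0), ef=(43.0, 6.0), bsa=(1.1, 0.35),
    hr_range=(70.0, 110.0), morphology_mix={"left": 1.0},
    apc_fraction=(26.0, 12.0),
)
FONTAN_RV = GroupParams(
    peak_sys_ke_sv=(0.043, 0.018), peak_dia_ke_sv=(0.025, 0.012),
    edvi=(87.0, 20.0), ef=(39.0, 7.0), bsa=(1.1, 0.35),
    hr_range=(70.0, 110.0), morphology_mix={"right": 1.0},
    apc_fraction=(26.0, 12.0),
)
CONTROL_LV = GroupParams(
    peak_sys_ke_sv=(0.048, 0.012), peak_dia_ke_sv=(0.058, 0.010),
    edvi=(101.0, 11.0), ef=(57.0, 5.0), bsa=(1.9, 0.2),
    hr_range=(55.0, 75.0), morphology_mix={"left": 1.0},
    apc_fraction=(0.0, 0.0),
)
CONTROL_RV = GroupParams(
    peak_sys_ke_sv=(0.074, 0.014), peak_dia_ke_sv=(0.034, 0.007),
    edvi=(96.0, 17.0), ef=(59.0, 6.0), bsa=(1.9, 0.2),
    hr_range=(55.0, 75.0), morphology_mix={"right": 1.0},
    apc_fraction=(0.0, 0.0),
)


@dataclass
class CohortSpec:
    """Specification of a two-group simulated cohort."""

    n_per_group: int = 10
    groups: dict = dc_field(default_factory=lambda: {
        "fontan": FONTAN_LV, "control": CONTROL_LV})
    seed: int = 0
    noise_sigma: float = 1.0  # cm/s, ~1% of venc
    inject_corruptions: bool = True
    grid: tuple[int, int, int] = (36, 36, 36)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_phases_acquired: int = 20
    venc: float = 100.0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise FlowError("n_per_group must be >= 1")
        for name, g in self.groups.items():
            for mean, sd in (g.peak_sys_ke_sv, g.peak_dia_ke_sv):
                if sd < 0:
                    raise FlowError(f"group {name}: SD must be >= 0")
            if not (0 <= g.apc_fraction[0] <= 100):
                raise FlowError(f"group {name}: APC fraction mean outside [0, 100]")


@dataclass
class SubjectSample:
    """One simulated subject: data, masks, ground truth, metadata."""

    field: VelocityField4D
    masks: MaskSeries
    truth: PhantomTruth
    metadata: FlowMetadata


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float = math.inf, what: str = "") -> float:
    """Draw N(mean, sd) redrawing (up to 100x) into [lo, hi]; clips after."""
    if sd == 0:
        return min(max(mean, lo), hi)
    for _ in range(100):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return v
    logger.info("truncated infeasible draw for %s to bounds [%s, %s]", what, lo, hi)
    return min(max(mean, lo), hi)


def simulate_cohort(spec: CohortSpec) -> list[SubjectSample]:
    """Simulate a two-group cohort of single-ventricle phantoms.

    Per-subject peak systolic/diastolic KE/SV are drawn from the group
    distributions and realized exactly by the ventricle phantom (the truth
    curve's sampled peaks over the realized stroke volume equal the draws).
    With ``inject_corruptions`` the stored field additionally carries an
    eddy-current plane, venc aliasing (where speeds exceed venc) and
    Gaussian velocity noise, so the full measurement chain is exercised.
    Deterministic under ``spec.seed``.
    """
    root = np.random.SeedSequence(spec.seed)
    subjects: list[SubjectSample] = []
    group_seeds = dict(zip(sorted(spec.groups), root.spawn(len(spec.groups))))

    # largest end-diastolic ellipsoid the grid can hold, with one-voxel margin
    half = min(0.5 * g * s - s for g, s in zip(spec.grid, spec.spacing))
    edv_cap = 0.95 * (4.0 / 3.0) * math.pi * (half**3 / _ELONGATION**2) / 1000.0

    for group in sorted(spec.groups):
        params: GroupParams = spec.groups[group]
        subj_seeds = group_seeds[group].spawn(spec.n_per_group)
        for i in range(spec.n_per_group):
            rng = np.random.default_rng(subj_seeds[i])
            sid = f"{group}_{i:03d}"

            sys_ke_sv = _truncated_normal(rng, *params.peak_sys_ke_sv, lo=1e-4,
                                          what=f"{sid} systolic KE/SV")
            dia_ke_sv = _truncated_normal(rng, *params.peak_dia_ke_sv, lo=1e-4,
                                          what=f"{sid} diastolic KE/SV")
            bsa = _truncated_normal(rng, *params.bsa, lo=0.4, hi=2.3,
                                    what=f"{sid} BSA")
            edvi = _truncated_normal(rng, *params.edvi, lo=40.0,
                                     hi=edv_cap / bsa if bsa > 0 else 200.0,
                                     what=f"{sid} EDVI")
            ef = _truncated_normal(rng, *params.ef, lo=15.0, hi=75.0,
                                   what=f"{sid} EF")
            hr = float(rng.uniform(*params.hr_range))
            rr = 60000.0 / hr
            apc = _truncated_normal(rng, *params.apc_fraction, lo=0.0, hi=100.0,
                                    what=f"{sid} APC fraction")
            morphs, probs = zip(*sorted(params.morphology_mix.items()))
            morph = str(rng.choice(morphs, p=np.asarray(probs) / sum(probs)))

            edv = edvi * bsa
            esv = edv * (1.0 - ef / 100.0)
            vparams = VolumeCurveParams(edv_ml=edv, esv_ml=esv)

            if apc > 25.0:
                pattern = "plateau"
            elif dia_ke_sv > sys_ke_sv:
                pattern = "diastolic_dominant"
            else:
                pattern = "systolic_dominant"

            # build once to learn the realized (voxelized) stroke volume,
            # then set the KE peaks so peak-KE / realized-SV equals the draw
            _, masks_probe, truth_probe = make_ventricle_phantom(
                pattern, vparams, spec.grid, spec.spacing,
                spec.n_phases_acquired, seed=0,
                peak_sys_mj=1.0, peak_dia_mj=1.0)
            sv = truth_probe.extras["sv_ml"]

            fld, masks, truth = make_ventricle_phantom(
                pattern, vparams, spec.grid, spec.spacing,
                spec.n_phases_acquired, seed=int(rng.integers(2**31)),
                peak_sys_mj=sys_ke_sv * sv, peak_dia_mj=dia_ke_sv * sv,
                rr_interval=rr, venc=spec.venc, subject_id=sid,
                group_label=group if group in ("fontan", "control") else "fontan",
                ventricular_morphology=morph, bsa=bsa)
            truth.extras.update({
                "peak_sys_ke_sv": sys_ke_sv, "peak_dia_ke_sv": dia_ke_sv,
                "apc_fraction": apc, "edv_ml": edv, "esv_ml": esv, "ef": ef,
            })

            if spec.inject_corruptions:
                plane = np.concatenate(
                    [rng.normal(0.0, 2.0, size=(3, 1)),
                     rng.normal(0.0, 0.03, size=(3, 3))], axis=1)
                fld = inject_eddy_offset(fld, plane, truth)
                fld = inject_noise(fld, spec.noise_sigma,
                                   seed=int(rng.integers(2**31)), truth=truth)
                fld = inject_aliasing(fld, truth)

            subjects.append(SubjectSample(field=fld, masks=masks, truth=truth,
                                          metadata=fld.metadata))
    return subjects
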