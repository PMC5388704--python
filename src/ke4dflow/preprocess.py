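"""Corrections applied to raw 4D phase-contrast velocity fields.

The processing order is fixed: temporal phase unwrapping first (so the
eddy fit sees wrap-free statics), then first-order-polynomial eddy-current
compensation fitted to stationary tissue, then temporal reconstruction to
the analysis phase count.  A clean field passes through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Optional

import numpy as np

from .errors import DegenerateDataError
from .io import FlowMetadata, VelocityField4D, uniform_phase_times

#: static-tissue selection defaults, as fractions of venc
DEFAULT_SD_FRAC = 0.05
DEFAULT_MEAN_FRAC = 0.10


@dataclass
class StaticTissueMask:
    """Phase-independent boolean mask of stationary-tissue voxels."""

    member: np.ndarray  # (x, y, z) bool
    sd_threshold: float  # cm/s
    mean_threshold: float  # cm/s

    @property
    def n_voxels(self) -> int:
        return int(self.member.sum())


def detect_static_tissue(fld: VelocityField4D,
                         sd_threshold: Optional[float] = None,
                         mean_threshold: Optional[float] = None) -> StaticTissueMask:
    """Select stationary-tissue voxels for the eddy-current fit.

    A voxel is static iff the temporal standard deviation of every velocity
    component is below ``sd_threshold`` and the magnitude of its temporal
    mean velocity is below ``mean_threshold`` (both cm/s; defaults scale
    with venc: 5% and 10% respectively).  Static tissue may still carry the
    eddy-current offset — that is exactly what the fit removes.
    """
    venc = fld.metadata.venc
    if sd_threshold is None:
        sd_threshold = DEFAULT_SD_FRAC * venc
    if mean_threshold is None:
        mean_threshold = DEFAULT_MEAN_FRAC * venc
    sd = fld.values.std(axis=0)  # (x,y,z,3)
    mean = fld.values.mean(axis=0)
    mean_speed = np.linalg.norm(mean, axis=-1)
    member = np.all(sd < sd_threshold, axis=-1) & (mean_speed < mean_threshold)
    if not member.any():
        raise DegenerateDataError(
            f"no static-tissue voxels at sd_threshold={sd_threshold} cm/s, "
            f"mean_threshold={mean_threshold} cm/s; relax the thresholds"
        )
    return StaticTissueMask(member=member, sd_threshold=float(sd_threshold),
                            mean_threshold=float(mean_threshold))


@dataclass
class EddyFit:
    """Fitted first-order eddy-current velocity offset.

    ``coefficients`` is (3, 4): per component an offset (cm/s) and spatial
    gradients (cm/s per mm along x, y, z), so fits are spacing-invariant.
    """

    coefficients: np.ndarray
    residual_rms: np.ndarray  # per component, cm/s over static voxels
    n_static: int


def _design_matrix(member: np.ndarray, spacing) -> np.ndarray:
    idx = np.argwhere(member).astype(np.float64)
    coords = idx * np.asarray(spacing)[None, :]  # mm
    return np.column_stack([np.ones(len(coords)), coords])


def correct_eddy_currents(fld: VelocityField4D, static: StaticTissueMask
                          ) -> tuple[VelocityField4D, EddyFit]:
    """Fit and subtract the first-order eddy-current plane.

    Per component, a least-squares fit of offset + linear spatial terms to
    the time-averaged velocity over static voxels; the fitted plane is then
    subtracted from every phase.  Exact (to numerical precision) when the
    static-tissue velocities truly are first-order polynomials.
    """
    member = static.member
    n = int(member.sum())
    if n < 4:
        raise DegenerateDataError(
            f"eddy fit needs >= 4 static voxels, got {n}")
    A = _design_matrix(member, fld.metadata.voxel_spacing)
    if np.linalg.matrix_rank(A) < 4:
        raise DegenerateDataError(
            "static-tissue voxels are coplanar/degenerate: first-order fit "
            "is rank-deficient"
        )
    mean_v = fld.values.mean(axis=0)[member]  # (n, 3)
    coef, *_ = np.linalg.lstsq(A, mean_v, rcond=None)  # (4, 3)
    coefficients = coef.T  # (3, 4)
    resid = mean_v - A @ coef
    residual_rms = np.sqrt(np.mean(resid**2, axis=0))

    nx, ny, nz = fld.grid_shape
    sx, sy, sz = fld.metadata.voxel_spacing
    X, Y, Z = np.meshgrid(np.arange(nx) * sx, np.arange(ny) * sy,
                          np.arange(nz) * sz, indexing="ij")
    plane = np.empty(fld.grid_shape + (3,))
    for c in range(3):
        c0, gx, gy, gz = coefficients[c]
        plane[..., c] = c0 + gx * X + gy * Y + gz * Z

    out = fld.copy()
    out.values = out.values - plane[None, ...]
    return out, EddyFit(coefficients=coefficients, residual_rms=residual_rms,
                        n_static=n)


@dataclass
class WrapReport:
    """Sites changed by temporal phase unwrapping."""

    sites: np.ndarray  # (k, 5) indices (phase, x, y, z, comp)

    @property
    def n_corrected(self) -> int:
        return int(self.sites.shape[0])


def unwrap_velocity(fld: VelocityField4D) -> tuple[VelocityField4D, WrapReport]:
    """Temporal phase unwrapping of venc aliasing, per voxel per component.

    Walking the phases in time order from phase 0 (trusted unwrapped),
    whenever the step to the next phase exceeds venc in magnitude a
    multiple of 2·venc is added to minimize the step — the temporal-
    continuity criterion.  Output values may legitimately exceed venc.
    Never changes a value by anything other than an integer multiple of
    2·venc.
    """
    venc = fld.metadata.venc
    out = fld.copy()
    out.values = np.unwrap(out.values, axis=0, period=2.0 * venc)
    sites = np.argwhere(out.values != fld.values)
    return out, WrapReport(sites=sites)


def reconstruct_phases(fld: VelocityField4D, n_out: int) -> VelocityField4D:
    """Resample the cycle to ``n_out`` uniform phases by periodic linear
    interpolation in normalized cycle time.

    The cycle is treated as periodic over the RR interval (the sample after
    the last phase is phase 0 again).  With ``n_out`` equal to the input
    phase count on aligned sample times this is the identity.
    """
    if n_out < 2:
        raise DegenerateDataError("need n_out >= 2 reconstructed phases")
    rr = fld.metadata.rr_interval
    t_in = fld.phase_times
    t_out = uniform_phase_times(n_out, rr)

    t_ext = np.append(t_in, t_in[0] + rr)
    v_ext = np.concatenate([fld.values, fld.values[:1]], axis=0)
    idx = np.clip(np.searchsorted(t_ext, t_out, side="right") - 1, 0,
                  len(t_in) - 1)
    w = (t_out - t_ext[idx]) / (t_ext[idx + 1] - t_ext[idx])
    w = w.reshape((-1,) + (1,) * (fld.values.ndim - 1))
    values = (1.0 - w) * v_ext[idx] + w * v_ext[idx + 1]

    meta = replace(fld.metadata, n_phases_reconstructed=n_out)
    return VelocityField4D(values=values, phase_times=t_out, metadata=meta)


def resample_mask_series(masks, phase_times: np.ndarray, rr_interval: float,
                         n_out: int):
    """Resample per-phase label masks to ``n_out`` uniform phases.

    Labels are categorical, so nearest-neighbor in cyclic normalized time
    is used (no interpolation between contours).
    """
    from .io import MaskSeries  # local import to avoid a cycle
    t_in = np.asarray(phase_times, dtype=np.float64)
    t_out = uniform_phase_times(n_out, rr_interval)
    # cyclic nearest: distance modulo RR
    d = np.abs(t_out[:, None] - t_in[None, :])
    d = np.minimum(d, rr_interval - d)
    nearest = np.argmin(d, axis=1)
    return MaskSeries(labels=masks.labels[nearest])


@dataclass
class PreprocessReport:
    """What the preprocessing chain did to one study."""

    eddy_fit: Optional[EddyFit]
    n_wraps_corrected: int
    n_static_voxels: int
    n_phases_out: int
    thresholds: dict = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "eddy_coefficients": (self.eddy_fit.coefficients.tolist()
                                  if self.eddy_fit else None),
            "eddy_residual_rms": (self.eddy_fit.residual_rms.tolist()
                                  if self.eddy_fit else None),
            "n_wraps_corrected": self.n_wraps_corrected,
            "n_static_voxels": self.n_static_voxels,
            "n_phases_out": self.n_phases_out,
            "thresholds": self.thresholds,
        }


def preprocess_field(fld: VelocityField4D, *, n_phases_out: Optional[int] = None,
                     sd_threshold: Optional[float] = None,
                     mean_threshold: Optional[float] = None,
                     do_unwrap: bool = True, do_eddy: bool = True
                     ) -> tuple[VelocityField4D, PreprocessReport]:
    """Full preprocessing: unwrap → eddy-correct → reconstruct phases.

    ``n_phases_out`` defaults to the metadata's reconstructed phase count
    (40 by convention).  On a field that is already clean the chain is the
    identity to numerical precision.
    """
    if n_phases_out is None:
        n_phases_out = fld.metadata.n_phases_reconstructed
    n_wraps = 0
    if do_unwrap:
        fld, report = unwrap_velocity(fld)
        n_wraps = report.n_corrected
    eddy_fit = None
    n_static = 0
    if do_eddy:
        static = detect_static_tissue(fld, sd_threshold, mean_threshold)
        n_static = static.n_voxels
        fld, eddy_fit = correct_eddy_currents(fld, static)
    out = reconstruct_phases(fld, n_phases_out)
    thresholds = {"sd_threshold": sd_threshold, "mean_threshold": mean_threshold}
    return out, PreprocessReport(eddy_fit=eddy_fit, n_wraps_corrected=n_wraps,
                                 n_static_voxels=n_static,
                                 n_phases_out=n_phases_out,
                                 thresholds=thresholds)
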