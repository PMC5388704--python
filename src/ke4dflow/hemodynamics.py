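"""Ventricular volumes, global hemodynamics and collateral-flow quantities.

Volumes come from per-phase segmentation masks (voxel count × voxel
volume); effective stroke volume from through-plane flow in the ascending
aorta; aortopulmonary-collateral (APC) flow from the difference between
aortic (or pulmonary venous) and caval flow volumes, with the >25%-of-SV
significance rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import AnalysisError, DegenerateDataError
from .io import MaskSeries

logger = logging.getLogger(__name__)


@dataclass
class VolumeCurve:
    """Ventricular volume per phase and the global indices derived from it.

    EDV/ESV are the maximal/minimal volumes over the cycle, SV = EDV − ESV,
    EF = 100·SV/EDV; indexed variants divide by BSA.
    """

    volume_per_phase: np.ndarray  # ml
    edv: float
    esv: float
    sv: float
    ef: float  # %
    edvi: Optional[float] = None  # ml/m^2
    esvi: Optional[float] = None


def volume_curve(masks: MaskSeries, spacing, bsa: Optional[float] = None,
                 region: str = "ventricle") -> VolumeCurve:
    """Ventricular volume curve from per-phase label masks.

    ``spacing`` is the voxel spacing triplet in mm; volumes in ml.
    """
    member = masks.region_mask(region)
    counts = member.reshape(member.shape[0], -1).sum(axis=1)
    if np.any(counts == 0):
        empty = np.nonzero(counts == 0)[0].tolist()
        raise AnalysisError(f"region {region!r} empty in phases {empty}")
    voxvol = float(np.prod(np.asarray(spacing, dtype=np.float64)))
    vol = counts * voxvol / 1000.0  # mm^3 -> ml
    edv = float(vol.max())
    esv = float(vol.min())
    sv = edv - esv
    ef = 100.0 * sv / edv
    edvi = esvi = None
    if bsa is not None:
        if not bsa > 0:
            raise AnalysisError(f"BSA must be positive, got {bsa}")
        edvi = edv / bsa
        esvi = esv / bsa
    return VolumeCurve(volume_per_phase=vol, edv=edv, esv=esv, sv=sv, ef=ef,
                       edvi=edvi, esvi=esvi)


@dataclass
class FlowCurve:
    """Volumetric flow (ml/s) through a plane ROI and its per-beat integral."""

    flow_per_phase: np.ndarray  # ml/s
    net_forward_volume: float  # ml per beat (effective SV when aortic)


def plane_flow(velocity_series: np.ndarray, roi: np.ndarray, pixel_area: float,
               phase_times: np.ndarray, rr_interval: float, *,
               sign: Optional[int] = None) -> FlowCurve:
    """Through-plane flow from a 2-D velocity time series.

    Parameters
    ----------
    velocity_series : (n_phases, ny, nx) through-plane velocities, cm/s.
    roi : (ny, nx) boolean plane ROI (vessel lumen).
    pixel_area : mm².
    sign : +1 or −1; the caller must declare which velocity sign is the
        forward direction — there is no safe default.

    Flow per phase is Σ(pixel velocity × pixel area); the net forward
    volume is the time integral over the closed cycle (trapezoidal, with
    the periodic wrap sample included).
    """
    if sign not in (+1, -1):
        raise AnalysisError(
            "sign convention unset: pass sign=+1 or sign=-1 to declare the "
            "positive through-plane direction"
        )
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise AnalysisError("empty plane ROI")
    v = np.asarray(velocity_series, dtype=np.float64)
    if v.ndim != 3 or v.shape[1:] != roi.shape:
        raise AnalysisError(
            f"velocity series {v.shape} does not match ROI {roi.shape}")
    # cm/s * mm^2 = 10 mm^3/s = 0.01 ml/s
    flow = sign * 0.01 * pixel_area * v[:, roi].sum(axis=1)
    t = np.asarray(phase_times, dtype=np.float64)
    t_ext = np.append(t, t[0] + rr_interval)
    f_ext = np.append(flow, flow[0])
    net = float(np.trapezoid(f_ext, t_ext) / 1000.0)  # ml/s * ms -> ml
    return FlowCurve(flow_per_phase=flow, net_forward_volume=net)


def cardiac_indices(sv: float, heart_rate: float, bsa: float
                    ) -> tuple[float, float]:
    """Cardiac output (l/min) and cardiac index (l/min/m²)."""
    for name, val in (("sv", sv), ("heart_rate", heart_rate), ("bsa", bsa)):
        if not val > 0:
            raise AnalysisError(f"{name} must be positive, got {val}")
    co = sv * heart_rate / 1000.0
    return co, co / bsa


@dataclass
class APCResult:
    """Aortopulmonary-collateral flow estimate.

    APC volume is the reference flow volume (aortic SV, or total pulmonary
    venous return when aortic flow is unavailable) minus the caval venous
    volume; the fraction is relative to that same reference.  Flow is
    hemodynamically significant when the fraction strictly exceeds the
    threshold (default 25% of SV).
    """

    apc_volume: float  # ml/beat
    apc_fraction: float  # % of reference SV
    method: str  # aortic_minus_caval | pulmonary_minus_caval
    significant: bool
    threshold: float


def apc_flow(caval_volume: float, aortic_sv: Optional[float] = None,
             pulmonary_venous_volume: Optional[float] = None,
             threshold: float = 25.0) -> APCResult:
    """Quantify APC flow by aortic−caval or pulmonary−caval subtraction.

    Exactly one reference (aortic SV or pulmonary venous volume) selects
    the method.  Small negative estimates — possible under measurement
    noise — are floored at zero with a warning.
    """
    provided = [x is not None for x in (aortic_sv, pulmonary_venous_volume)]
    if sum(provided) != 1:
        raise AnalysisError(
            "provide exactly one of aortic_sv / pulmonary_venous_volume "
            "to select the APC method"
        )
    if aortic_sv is not None:
        reference, method = aortic_sv, "aortic_minus_caval"
    else:
        reference, method = pulmonary_venous_volume, "pulmonary_minus_caval"
    if not reference > 0:
        raise AnalysisError(f"reference volume must be positive, got {reference}")
    apc = reference - caval_volume
    if apc < 0:
        warnings.warn(
            f"negative APC estimate {apc:.2f} ml floored at 0 "
            f"(caval {caval_volume} > reference {reference})"
        )
        apc = 0.0
    fraction = 100.0 * apc / reference
    return APCResult(apc_volume=apc, apc_fraction=fraction, method=method,
                     significant=fraction > threshold, threshold=threshold)


def cross_sectional_area(mask: np.ndarray, spacing, axis: int = 2) -> float:
    """Lumen cross-sectional area (cm²) of a vessel label mask.

    For a 2-D mask: pixel count × pixel area.  For a 3-D mask the area is
    the mean over nonempty slices perpendicular to ``axis`` (the vessel
    axis), which for a straight phantom vessel is the slice pixel count ×
    pixel area.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise DegenerateDataError("empty vessel label")
    spacing = np.asarray(spacing, dtype=np.float64)
    if m.ndim == 2:
        pixel_area = float(spacing[0] * spacing[1])
        return m.sum() * pixel_area / 100.0  # mm^2 -> cm^2
    if m.ndim != 3:
        raise AnalysisError(f"mask must be 2-D or 3-D, got {m.ndim}-D")
    in_plane = [i for i in range(3) if i != axis]
    pixel_area = float(spacing[in_plane[0]] * spacing[in_plane[1]])
    counts = m.sum(axis=tuple(in_plane))
    counts = counts[counts > 0]
    return float(counts.mean()) * pixel_area / 100.0


def vessel_segment_volume(masks: MaskSeries, spacing, region: str) -> float:
    """Time-averaged vessel-segment volume (ml) — the denominator used when
    indexing vessel KE to the volume of the vessel part."""
    member = masks.region_mask(region)
    counts = member.reshape(member.shape[0], -1).sum(axis=1)
    if np.all(counts == 0):
        raise DegenerateDataError(f"region {region!r} empty in all phases")
    voxvol = float(np.prod(np.asarray(spacing, dtype=np.float64)))
    return float(counts.mean()) * voxvol / 1000.0
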