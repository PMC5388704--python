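"""Data model and on-disk format for 4D phase-contrast flow studies.

A study is stored as three NIfTI scalar volumes (one per velocity component,
each ``(nx, ny, nz, n_phases)``) plus a JSON sidecar of acquisition metadata.
Masks are NIfTI integer label volumes with a JSON label dictionary.  In
memory, velocities live in a single ``(n_phases, nx, ny, nz, 3)`` float64
array in cm/s — the velocity-encoding (venc) convention of the scanner —
and are converted to SI only inside the kinetic-energy computation.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np

from .errors import (
    DimensionMismatchError,
    FlowError,
    LabelVocabularyError,
    MetadataError,
)

logger = logging.getLogger(__name__)

#: Region vocabulary for mask label volumes.
LABEL_CODES = {
    "background": 0,
    "ventricle": 1,
    "svc": 2,
    "ivc_tunnel": 3,
    "lpa": 4,
    "rpa": 5,
    "aorta_plane": 6,
}
CODE_LABELS = {v: k for k, v in LABEL_CODES.items()}

#: Exact sidecar key set of the on-disk dialect.
SIDECAR_KEYS = (
    "subject_id",
    "group_label",
    "ventricular_morphology",
    "venc_cm_s",
    "voxel_spacing_mm",
    "n_phases_acquired",
    "n_phases_reconstructed",
    "rr_interval_ms",
    "heart_rate_bpm",
    "bsa_m2",
    "blood_density_g_cm3",
)

GROUP_LABELS = ("fontan", "control")
MORPHOLOGIES = ("left", "right", "left_long_outflow")

#: Density of blood used for the voxel mass, g/cm^3.
BLOOD_DENSITY_G_CM3 = 1.05


@dataclass
class FlowMetadata:
    """Acquisition and subject metadata for one 4D flow study.

    venc is the velocity-encoding limit in cm/s; velocities beyond ±venc
    alias (wrap) in the phase signal.  ``rr_interval`` and ``heart_rate``
    must be mutually consistent (60000/HR = RR within 1%).
    """

    subject_id: str
    group_label: str = "fontan"
    ventricular_morphology: str = "left"
    venc: float = 100.0
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_phases_acquired: int = 20
    n_phases_reconstructed: int = 40
    rr_interval: float = 1000.0
    heart_rate: Optional[float] = None
    bsa: Optional[float] = None
    blood_density: float = BLOOD_DENSITY_G_CM3

    def __post_init__(self) -> None:
        if self.heart_rate is None:
            self.heart_rate = 60000.0 / self.rr_interval
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        self.validate()

    def validate(self) -> None:
        if not self.venc > 0:
            raise MetadataError(f"venc must be positive, got {self.venc}")
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise MetadataError(
                f"voxel_spacing must be 3 positive lengths (mm), got {self.voxel_spacing}"
            )
        if self.n_phases_acquired < 2:
            raise MetadataError("n_phases_acquired must be >= 2")
        if not self.rr_interval > 0:
            raise MetadataError("rr_interval must be positive")
        if not self.blood_density > 0:
            raise MetadataError("blood_density must be positive")
        if self.group_label not in GROUP_LABELS:
            raise MetadataError(
                f"group_label must be one of {GROUP_LABELS}, got {self.group_label!r}"
            )
        if self.ventricular_morphology not in MORPHOLOGIES:
            raise MetadataError(
                f"ventricular_morphology must be one of {MORPHOLOGIES}, "
                f"got {self.ventricular_morphology!r}"
            )
        implied_rr = 60000.0 / self.heart_rate
        if abs(implied_rr - self.rr_interval) > 0.01 * self.rr_interval:
            raise MetadataError(
                f"heart_rate {self.heart_rate} bpm implies RR {implied_rr:.1f} ms, "
                f"inconsistent with rr_interval {self.rr_interval} ms (>1%)"
            )

    @property
    def voxel_volume_mm3(self) -> float:
        """Physical volume of one voxel (product of spacings), mm^3."""
        sx, sy, sz = self.voxel_spacing
        return sx * sy * sz

    def to_sidecar_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "group_label": self.group_label,
            "ventricular_morphology": self.ventricular_morphology,
            "venc_cm_s": self.venc,
            "voxel_spacing_mm": list(self.voxel_spacing),
            "n_phases_acquired": self.n_phases_acquired,
            "n_phases_reconstructed": self.n_phases_reconstructed,
            "rr_interval_ms": self.rr_interval,
            "heart_rate_bpm": self.heart_rate,
            "bsa_m2": self.bsa,
            "blood_density_g_cm3": self.blood_density,
        }

    @classmethod
    def from_sidecar_dict(cls, d: dict) -> "FlowMetadata":
        if "venc_cm_s" not in d or d["venc_cm_s"] is None:
            raise MetadataError(
                "sidecar is missing 'venc_cm_s'; the velocity-encoding limit "
                "must be stated explicitly (no silent default on load)"
            )
        required = ("subject_id", "voxel_spacing_mm", "rr_interval_ms")
        missing = [k for k in required if k not in d or d[k] is None]
        if missing:
            raise MetadataError(f"sidecar is missing required keys: {missing}")
        return cls(
            subject_id=d["subject_id"],
            group_label=d.get("group_label", "fontan"),
            ventricular_morphology=d.get("ventricular_morphology", "left"),
            venc=float(d["venc_cm_s"]),
            voxel_spacing=tuple(d["voxel_spacing_mm"]),
            n_phases_acquired=int(d.get("n_phases_acquired", 2) or 2),
            n_phases_reconstructed=int(d.get("n_phases_reconstructed", 40) or 40),
            rr_interval=float(d["rr_interval_ms"]),
            heart_rate=d.get("heart_rate_bpm"),
            bsa=d.get("bsa_m2"),
            blood_density=float(d.get("blood_density_g_cm3") or BLOOD_DENSITY_G_CM3),
        )


def uniform_phase_times(n_phases: int, rr_interval: float) -> np.ndarray:
    """Uniform per-phase time offsets (ms) spanning exactly one RR interval.

    The first sample is at 0 and the implicit next sample after the last
    lands exactly on the RR interval (retrospective-gating convention).
    """
    return np.arange(n_phases) * (rr_interval / n_phases)


@dataclass
class VelocityField4D:
    """Per-voxel 3-component blood velocity over one cardiac cycle.

    ``values`` has axes (phase, x, y, z, component), in cm/s.
    """

    values: np.ndarray
    phase_times: np.ndarray
    metadata: FlowMetadata

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.phase_times = np.asarray(self.phase_times, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.values.ndim != 5 or self.values.shape[-1] != 3:
            raise DimensionMismatchError(
                f"velocity array must be (phase, x, y, z, 3), got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise FlowError(f"non-finite velocity at (phase,x,y,z,comp)={tuple(int(i) for i in bad)}")
        n = self.values.shape[0]
        if self.phase_times.shape != (n,):
            raise DimensionMismatchError(
                f"phase_times length {self.phase_times.shape} does not match "
                f"{n} phases"
            )
        if self.phase_times[0] != 0.0:
            raise MetadataError("phase_times must start at 0")
        if np.any(np.diff(self.phase_times) <= 0):
            raise MetadataError("phase_times must be strictly increasing")
        if self.phase_times[-1] >= self.metadata.rr_interval:
            raise MetadataError(
                f"last phase time {self.phase_times[-1]} ms must be below the "
                f"RR interval {self.metadata.rr_interval} ms"
            )

    @property
    def n_phases(self) -> int:
        return self.values.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape[1:4]

    def copy(self) -> "VelocityField4D":
        return VelocityField4D(
            values=self.values.copy(),
            phase_times=self.phase_times.copy(),
            metadata=replace(self.metadata),
        )


@dataclass
class MaskSeries:
    """Per-phase voxel labels for the ventricle and Fontan-pathway vessels.

    ``labels`` has axes (phase, x, y, z) with codes from :data:`LABEL_CODES`;
    the geometry must match the velocity field it indexes.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 4:
            raise DimensionMismatchError(
                f"mask labels must be (phase, x, y, z), got shape {self.labels.shape}"
            )
        self.validate_vocabulary()

    def validate_vocabulary(self) -> None:
        codes = set(np.unique(self.labels).tolist())
        unknown = sorted(codes - set(CODE_LABELS))
        if unknown:
            raise LabelVocabularyError(
                f"unknown label codes {unknown}; known codes are "
                f"{sorted(CODE_LABELS)} ({LABEL_CODES})"
            )

    def region_mask(self, region: str) -> np.ndarray:
        """Boolean (phase, x, y, z) membership of the named region."""
        if region not in LABEL_CODES:
            raise LabelVocabularyError(
                f"unknown region {region!r}; known regions: {sorted(LABEL_CODES)}"
            )
        return self.labels == LABEL_CODES[region]

    def check_matches(self, fld: VelocityField4D) -> None:
        if self.labels.shape != fld.values.shape[:4]:
            raise DimensionMismatchError(
                f"mask shape {self.labels.shape} does not match velocity grid "
                f"{fld.values.shape[:4]}"
            )


_COMPONENT_NAMES = ("vx", "vy", "vz")
_AXIS_NAMES = ("x", "y", "z")


def _affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def load_flow_study(volume_paths: Sequence[os.PathLike | str],
                    sidecar_path: os.PathLike | str) -> VelocityField4D:
    """Assemble a :class:`VelocityField4D` from component volumes + sidecar.

    ``volume_paths`` are the x, y, z component NIfTI files in that order,
    each ``(nx, ny, nz, n_phases)``.  Phase times are taken from the sidecar
    when present, otherwise reconstructed uniformly over the RR interval.
    """
    if len(volume_paths) != 3:
        raise DimensionMismatchError(
            f"expected 3 component volumes (x, y, z), got {len(volume_paths)}"
        )
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    meta = FlowMetadata.from_sidecar_dict(sidecar)

    comps = []
    shapes = []
    for p in volume_paths:
        img = nib.load(str(p))
        arr = np.asarray(img.dataobj, dtype=np.float64)
        if arr.ndim != 4:
            raise DimensionMismatchError(
                f"{p}: expected a 4-D volume (x, y, z, phase), got {arr.ndim}-D"
            )
        comps.append(arr)
        shapes.append(arr.shape)
    ref = shapes[0]
    for p, shp in zip(volume_paths[1:], shapes[1:]):
        if shp != ref:
            bad_axes = [
                _AXIS_NAMES[i] if i < 3 else "phase"
                for i in range(4)
                if shp[i] != ref[i]
            ]
            raise DimensionMismatchError(
                f"component volumes disagree along axis/axes {bad_axes}: "
                f"{ref} vs {shp} ({p})"
            )

    # (x,y,z,phase) per component -> (phase,x,y,z,3)
    values = np.stack([np.moveaxis(c, 3, 0) for c in comps], axis=-1)
    times = sidecar.get("phase_times_ms")
    if times is None:
        times = uniform_phase_times(values.shape[0], meta.rr_interval)
    return VelocityField4D(values=values, phase_times=np.asarray(times, float),
                           metadata=meta)


def save_flow_study(fld: VelocityField4D, out_dir: os.PathLike | str) -> dict:
    """Write a field as three component NIfTIs + JSON sidecar.

    Round-trips bit-exactly through :func:`load_flow_study`.  Refuses fields
    containing non-finite values (reporting the first offending voxel).
    Returns the mapping of written roles to paths.
    """
    if str(out_dir) == "":
        raise IOError("output directory path is empty")
    if not np.all(np.isfinite(fld.values)):
        bad = np.argwhere(~np.isfinite(fld.values))[0]
        raise FlowError(
            f"refusing to save field with non-finite velocity at "
            f"(phase,x,y,z,comp)={tuple(int(i) for i in bad)}"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(fld.metadata.voxel_spacing)
    written = {}
    for ci, name in enumerate(_COMPONENT_NAMES):
        arr = np.moveaxis(fld.values[..., ci], 0, 3)  # -> (x,y,z,phase)
        img = nib.Nifti1Image(arr.astype(np.float64), aff)
        path = out / f"{name}.nii"
        nib.save(img, str(path))
        written[name] = str(path)
    sidecar = fld.metadata.to_sidecar_dict()
    sidecar["phase_times_ms"] = fld.phase_times.tolist()
    sidecar_path = out / "flow_sidecar.json"
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
    written["sidecar"] = str(sidecar_path)
    return written


def component_paths(study_dir: os.PathLike | str) -> tuple[list, str]:
    """Paths of the component volumes and sidecar inside a study directory."""
    d = Path(study_dir)
    return [str(d / f"{n}.nii") for n in _COMPONENT_NAMES], str(d / "flow_sidecar.json")


def load_study_dir(study_dir: os.PathLike | str) -> VelocityField4D:
    vols, sidecar = component_paths(study_dir)
    return load_flow_study(vols, sidecar)


def save_mask_series(masks: MaskSeries, out_dir: os.PathLike | str,
                     spacing: Sequence[float] = (1.0, 1.0, 1.0)) -> dict:
    """Write masks as an integer label NIfTI plus a JSON label dictionary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arr = np.moveaxis(masks.labels.astype(np.int16), 0, 3)
    img = nib.Nifti1Image(arr, _affine(spacing))
    label_path = out / "masks.nii"
    nib.save(img, str(label_path))
    dict_path = out / "mask_labels.json"
    with open(dict_path, "w") as fh:
        json.dump(LABEL_CODES, fh, indent=2, sort_keys=True)
    return {"labels": str(label_path), "label_dict": str(dict_path)}


def load_mask_series(path: os.PathLike | str, fld: VelocityField4D) -> MaskSeries:
    """Load a label volume aligned to ``fld``.

    A single-phase mask (3-D, or 4-D with one phase) is broadcast to all
    phases with a logged notice — cine-derived contours are often supplied
    time-averaged.
    """
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    if arr.ndim == 3:
        arr = arr[..., None]
    if arr.ndim != 4:
        raise DimensionMismatchError(
            f"mask volume must be 3-D or 4-D, got {arr.ndim}-D"
        )
    labels = np.moveaxis(arr, 3, 0)  # -> (phase,x,y,z)
    n_phases = fld.n_phases
    if labels.shape[0] == 1 and n_phases > 1:
        logger.info(
            "single-phase mask broadcast to %d phases of the velocity field",
            n_phases,
        )
        labels = np.broadcast_to(labels, (n_phases,) + labels.shape[1:]).copy()
    masks = MaskSeries(labels=labels.astype(np.int16))
    masks.check_matches(fld)
    return masks
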