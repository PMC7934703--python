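"""Split multi-subject ("mouse hotel") DICOM series into per-subject series.

A multi-mouse acquisition images several animals in one field of view; for
one-to-one queries against clinical data each animal needs its own series.
The split is purely geometric: the stored pixel matrix is tiled into equal
in-plane regions (optionally also into equal slice slabs along the bore),
each region is cropped out, and the patient-space position of each derived
slice is shifted to the source location of the region's first voxel —
pixel spacing and orientation cosines are never touched, so derived voxels
keep exactly their original patient coordinates.

Identity and provenance are rewritten on every derived slice: fresh
UUID-derived UIDs (SOP instance per slice, study/series per subject slot),
new patient name/ID rendered from a naming template, and back-references to
the source (derivation description, derivation image sequence, and the
source patient group identification sequence holding the original name/ID).
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from pydicom.dataset import Dataset
from pydicom.tag import Tag

from .core import UidGenerator, validate_uid

__all__ = [
    "VolumeGeometry",
    "GridPlan",
    "SplitRegion",
    "SubjectSeries",
    "SplitResult",
    "SeriesVolume",
    "SplitError",
    "compute_regions",
    "shift_position",
    "split_series",
    "rewrite_identity",
    "label_orientation",
    "TABLE1_TAGS",
    "GEOMETRY_TAGS",
]

logger = logging.getLogger(__name__)

#: Identity/provenance attributes rewritten on every derived slice.
TABLE1_TAGS: tuple[Tag, ...] = tuple(
    Tag(t)
    for t in (
        0x00080018,  # SOPInstanceUID
        0x00082111,  # DerivationDescription
        0x00089124,  # DerivationImageSequence
        0x00100010,  # PatientName
        0x00100020,  # PatientID
        0x00100026,  # SourcePatientGroupIdentificationSequence
        0x0020000D,  # StudyInstanceUID
        0x0020000E,  # SeriesInstanceUID
        0x00200011,  # SeriesNumber
        0x00880140,  # StorageMediaFileSetUID
    )
)

#: Additionally-changed attributes implied by cropping.
GEOMETRY_TAGS: tuple[Tag, ...] = tuple(
    Tag(t)
    for t in (
        0x00080008,  # ImageType (first value -> DERIVED)
        0x00280010,  # Rows
        0x00280011,  # Columns
        0x00200032,  # ImagePositionPatient
        0x7FE00010,  # PixelData
    )
)


class SplitError(ValueError):
    """A split that cannot be performed (bad plan or inconsistent series)."""


def _default_series_number_rule(original: int, slot: int) -> int:
    return original * 100 + slot


@dataclass(frozen=True)
class VolumeGeometry:
    """Shared geometry of a single-frame series.

    ``orientation`` holds the six direction cosines: indices 0-2 are the row
    direction u (increasing column index), 3-5 the column direction v
    (increasing row index).  ``pixel_spacing`` is (row spacing, column
    spacing) in mm.  ``positions`` is one patient-space 3-vector per slice.
    """

    rows: int
    cols: int
    pixel_spacing: tuple[float, float]
    orientation: tuple[float, ...]
    positions: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")
        u, v = self.u, self.v
        if abs(np.linalg.norm(u) - 1) > 1e-4 or abs(np.linalg.norm(v) - 1) > 1e-4:
            raise ValueError("orientation cosines are not unit-length")
        if abs(float(np.dot(u, v))) > 1e-4:
            raise ValueError("row and column directions are not orthogonal")

    @property
    def u(self) -> np.ndarray:
        return np.asarray(self.orientation[:3], dtype=float)

    @property
    def v(self) -> np.ndarray:
        return np.asarray(self.orientation[3:], dtype=float)

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.u, self.v)

    def voxel_to_patient(self, slice_index: int, r: float, c: float) -> np.ndarray:
        """Full slice-to-patient affine: position + c·Δc·u + r·Δr·v."""
        pos = np.asarray(self.positions[slice_index], dtype=float)
        dr, dc = self.pixel_spacing
        return pos + c * dc * self.u + r * dr * self.v


@dataclass
class GridPlan:
    """How to tile the field of view into subject slots.

    Slots are numbered row-major from the top-left of the stored pixel
    matrix, starting at 1.  With ``n_stacks > 1`` the slice stack is also
    partitioned into equal contiguous runs along the bore and slot numbering
    becomes stack-major (all in-plane cells of stack 1, then stack 2, ...).
    ``occupied`` lists the slots actually holding an animal; ``None`` means
    all of them.
    """

    n_rows: int = 1
    n_cols: int = 1
    n_stacks: int = 1
    occupied: frozenset[int] | None = None
    naming_template: str = "{orig_id}_{slot}"
    name_template: str = "{orig_name}_{slot}"
    series_number_rule: Callable[[int, int], int] = _default_series_number_rule

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1 or self.n_stacks < 1:
            raise ValueError("grid dimensions must be >= 1")
        n = self.n_slots
        if self.occupied is None:
            self.occupied = frozenset(range(1, n + 1))
        else:
            self.occupied = frozenset(int(s) for s in self.occupied)
            if not self.occupied or min(self.occupied) < 1 or max(self.occupied) > n:
                raise ValueError(f"occupied slots must be within 1..{n} and non-empty")

    @property
    def n_slots(self) -> int:
        return self.n_rows * self.n_cols * self.n_stacks

    def cell_of(self, slot: int) -> tuple[int, int, int]:
        """(stack, grid-row, grid-col) of a 1-based slot, all 0-based."""
        k = slot - 1
        per_stack = self.n_rows * self.n_cols
        stack, cell = divmod(k, per_stack)
        i, j = divmod(cell, self.n_cols)
        return stack, i, j

    @classmethod
    def from_json(cls, payload: dict) -> "GridPlan":
        kwargs: dict = {}
        for key in ("n_rows", "n_cols", "n_stacks"):
            if key in payload:
                kwargs[key] = int(payload[key])
        if payload.get("occupied"):
            kwargs["occupied"] = frozenset(int(s) for s in payload["occupied"])
        for key in ("naming_template", "name_template"):
            if key in payload:
                kwargs[key] = str(payload[key])
        rule = payload.get("series_number_rule")
        if rule is not None:
            mult = int(rule.get("multiplier", 100))
            kwargs["series_number_rule"] = lambda orig, slot, _m=mult: orig * _m + slot
        return cls(**kwargs)


@dataclass(frozen=True)
class SplitRegion:
    """An in-plane pixel sub-rectangle assigned to one subject slot."""

    slot_index: int
    r0: int
    c0: int
    region_rows: int
    region_cols: int


@dataclass
class SubjectSeries:
    """One subject's derived series plus its provenance."""

    slot_index: int
    datasets: list[Dataset]
    patient_name: str
    patient_id: str
    study_uid: str
    series_uid: str
    region: SplitRegion
    slice_range: tuple[int, int]
    sop_map: dict[str, str] = field(default_factory=dict)  # derived -> source


@dataclass
class SplitResult:
    """All derived subject series from one split invocation."""

    subjects: dict[int, SubjectSeries]
    source_patient_name: str
    source_patient_id: str
    source_uids: frozenset[str]

    def manifest(self) -> dict[str, str]:
        """Derived SOPInstanceUID → source SOPInstanceUID, all subjects."""
        out: dict[str, str] = {}
        for subject in self.subjects.values():
            out.update(subject.sop_map)
        return out


class SeriesVolume:
    """An ordered stack of single-frame slices with shared series identity.

    Slices are sorted by their projection onto the slice normal (tie-broken
    by instance number).  Construction verifies that rows, columns,
    orientation and pixel spacing agree across slices; heterogeneous stacks
    are rejected.
    """

    def __init__(self, datasets: Sequence[Dataset]):
        if not datasets:
            raise SplitError("empty series")
        for ds in datasets:
            if int(getattr(ds, "NumberOfFrames", 1) or 1) > 1:
                raise SplitError(
                    "multi-frame (enhanced) objects are not supported; "
                    "split classic single-frame series"
                )
        ref = datasets[0]
        key = (
            int(ref.Rows),
            int(ref.Columns),
            tuple(str(x) for x in ref.ImageOrientationPatient),
            tuple(str(x) for x in ref.PixelSpacing),
        )
        for ds in datasets[1:]:
            other = (
                int(ds.Rows),
                int(ds.Columns),
                tuple(str(x) for x in ds.ImageOrientationPatient),
                tuple(str(x) for x in ds.PixelSpacing),
            )
            if other != key:
                raise SplitError("heterogeneous geometry across slices")
        iop = np.asarray([float(x) for x in ref.ImageOrientationPatient])
        normal = np.cross(iop[:3], iop[3:])

        def sort_key(ds: Dataset) -> tuple[float, int]:
            pos = np.asarray([float(x) for x in ds.ImagePositionPatient])
            return (float(np.dot(pos, normal)), int(getattr(ds, "InstanceNumber", 0) or 0))

        self.datasets: list[Dataset] = sorted(datasets, key=sort_key)

    def __len__(self) -> int:
        return len(self.datasets)

    @property
    def geometry(self) -> VolumeGeometry:
        ref = self.datasets[0]
        return VolumeGeometry(
            rows=int(ref.Rows),
            cols=int(ref.Columns),
            pixel_spacing=(float(ref.PixelSpacing[0]), float(ref.PixelSpacing[1])),
            orientation=tuple(float(x) for x in ref.ImageOrientationPatient),
            positions=tuple(
                tuple(float(x) for x in ds.ImagePositionPatient) for ds in self.datasets
            ),
        )

    def pixel_stack(self) -> np.ndarray:
        """(n_slices, rows, cols) array of the stored pixel data."""
        return np.stack([ds.pixel_array for ds in self.datasets])

    def all_uids(self) -> frozenset[str]:
        uids: set[str] = set()
        for ds in self.datasets:
            uids.add(str(ds.SOPInstanceUID))
            uids.add(str(ds.StudyInstanceUID))
            uids.add(str(ds.SeriesInstanceUID))
            if "StorageMediaFileSetUID" in ds:
                uids.add(str(ds.StorageMediaFileSetUID))
        return frozenset(uids)


def compute_regions(rows: int, cols: int, plan: GridPlan) -> list[SplitRegion]:
    """Equal-size in-plane regions for the plan's occupied slots.

    Each region is floor(rows/n_rows) × floor(cols/n_cols); remainder pixels
    at the high-index edges belong to no region (a warning is logged when
    the matrix does not divide evenly).
    """
    if plan.n_rows > rows or plan.n_cols > cols:
        raise SplitError(
            f"grid {plan.n_rows}x{plan.n_cols} larger than pixel matrix {rows}x{cols}"
        )
    region_rows = rows // plan.n_rows
    region_cols = cols // plan.n_cols
    if rows % plan.n_rows or cols % plan.n_cols:
        logger.warning(
            "matrix %dx%d does not divide evenly into %dx%d grid; dropping %d row(s) "
            "and %d column(s) at the high-index edges",
            rows, cols, plan.n_rows, plan.n_cols, rows % plan.n_rows, cols % plan.n_cols,
        )
    regions = []
    for slot in sorted(plan.occupied):
        _, i, j = plan.cell_of(slot)
        regions.append(
            SplitRegion(
                slot_index=slot,
                r0=i * region_rows,
                c0=j * region_cols,
                region_rows=region_rows,
                region_cols=region_cols,
            )
        )
    # distinct in-plane cells must be disjoint by construction
    seen = {}
    for reg in regions:
        stack = plan.cell_of(reg.slot_index)[0]
        cell_key = (stack, reg.r0, reg.c0)
        if cell_key in seen:
            raise SplitError(f"slots {seen[cell_key]} and {reg.slot_index} share a cell")
        seen[cell_key] = reg.slot_index
    return regions


def shift_position(
    position: Sequence[float], geometry: VolumeGeometry, r0: int, c0: int
) -> np.ndarray:
    """Patient-space location of the source voxel at (r0, c0).

    position + c0·Δc·u + r0·Δr·v — the new ImagePositionPatient of a slice
    cropped at pixel offset (r0, c0).  Pixel spacing is untouched.
    """
    dr, dc = geometry.pixel_spacing
    return np.asarray(position, dtype=float) + c0 * dc * geometry.u + r0 * dr * geometry.v


def label_orientation(orientation: Sequence[float]) -> str:
    """Radiological orientation label from the slice normal.

    The principal axis of n = u × v decides: z → trans-axial, y → coronal,
    x → sagittal; ties break in that priority order.
    """
    iop = np.asarray([float(x) for x in orientation])
    n = np.cross(iop[:3], iop[3:])
    mags = np.abs(n)
    if float(mags.max()) < 1e-8:
        raise ValueError("degenerate orientation: zero slice normal")
    for axis, name in ((2, "trans-axial"), (1, "coronal"), (0, "sagittal")):
        if mags[axis] >= mags.max() - 1e-12:
            return name
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class Provenance:
    """Source identity carried into every derived slice."""

    orig_name: str
    orig_id: str
    sop_class_uid: str
    sop_instance_uid: str


def _render_template(template: str, **values: object) -> str:
    try:
        return template.format(**values)
    except (KeyError, IndexError) as exc:
        raise SplitError(f"naming template {template!r}: unknown placeholder {exc}") from exc


def rewrite_identity(
    elements: Dataset,
    slot: int,
    plan: GridPlan,
    provenance: Provenance,
    uid_source: UidGenerator,
    study_uid: str,
    series_uid: str,
) -> Dataset:
    """Rewrite identity and provenance attributes on one derived slice.

    Mutates and returns ``elements``: fresh SOP instance UID, derivation
    description and image sequence referencing the source instance, new
    patient name/ID from the plan's templates, the source patient group
    identification sequence holding the original name and ID, the slot's
    study/series UIDs, the derived series number, a fresh file-set UID when
    the source carried one, and ImageType first value DERIVED.
    """
    ctx = {"orig_name": provenance.orig_name, "orig_id": provenance.orig_id, "slot": slot}
    new_name = _render_template(plan.name_template, **ctx)
    new_id = _render_template(plan.naming_template, **ctx)

    elements.SOPInstanceUID = uid_source()
    elements.DerivationDescription = (
        f"Split of multi-subject acquisition: slot {slot} of "
        f"{plan.n_rows}x{plan.n_cols}"
        + (f"x{plan.n_stacks}" if plan.n_stacks > 1 else "")
        + f" grid; derived from SOPInstanceUID {provenance.sop_instance_uid}"
    )
    src_ref = Dataset()
    src_ref.ReferencedSOPClassUID = provenance.sop_class_uid
    src_ref.ReferencedSOPInstanceUID = provenance.sop_instance_uid
    deriv_item = Dataset()
    deriv_item.SourceImageSequence = [src_ref]
    elements.DerivationImageSequence = [deriv_item]

    elements.PatientName = new_name
    elements.PatientID = new_id
    group_item = Dataset()
    group_item.PatientName = provenance.orig_name
    group_item.PatientID = provenance.orig_id
    elements.SourcePatientGroupIdentificationSequence = [group_item]

    elements.StudyInstanceUID = study_uid
    elements.SeriesInstanceUID = series_uid
    orig_series_number = int(getattr(elements, "SeriesNumber", 0) or 0)
    elements.SeriesNumber = plan.series_number_rule(orig_series_number, slot)
    if "StorageMediaFileSetUID" in elements:
        elements.StorageMediaFileSetUID = uid_source()

    image_type = list(getattr(elements, "ImageType", []) or [])
    if image_type:
        image_type[0] = "DERIVED"
    else:
        image_type = ["DERIVED", "SECONDARY"]
    elements.ImageType = image_type
    return elements


def split_series(
    volume: SeriesVolume,
    plan: GridPlan,
    uid_source: UidGenerator,
    study_uids: dict[int, str] | None = None,
) -> SplitResult:
    """Split one multi-subject series into per-slot derived series.

    Every slice is cropped to its slot's region; Rows/Columns and the
    patient-space position are updated; pixel spacing and orientation are
    copied unchanged; identity and provenance are rewritten per slice.  All
    other source elements are copied verbatim.

    ``study_uids`` lets a caller splitting several series of one study reuse
    the same derived study UID per slot, keeping a subject's multi-series
    session a single study.
    """
    geometry = volume.geometry
    regions = {r.slot_index: r for r in compute_regions(geometry.rows, geometry.cols, plan)}

    n_slices = len(volume)
    if plan.n_stacks > n_slices:
        raise SplitError(f"{plan.n_stacks} stacks requested but only {n_slices} slice(s)")
    slab_len = n_slices // plan.n_stacks
    if n_slices % plan.n_stacks:
        logger.warning(
            "%d slice(s) do not divide into %d stack(s); dropping %d at the high end",
            n_slices, plan.n_stacks, n_slices % plan.n_stacks,
        )

    ref = volume.datasets[0]
    orig_name = str(getattr(ref, "PatientName", ""))
    orig_id = str(getattr(ref, "PatientID", ""))

    study_uids = dict(study_uids or {})
    subjects: dict[int, SubjectSeries] = {}
    for slot in sorted(plan.occupied):
        region = regions[slot]
        stack = plan.cell_of(slot)[0]
        lo, hi = stack * slab_len, (stack + 1) * slab_len
        if slot not in study_uids:
            study_uids[slot] = uid_source()
        study_uid = study_uids[slot]
        series_uid = uid_source()

        derived_slices: list[Dataset] = []
        sop_map: dict[str, str] = {}
        patient_name = patient_id = ""
        for src in volume.datasets[lo:hi]:
            derived = copy.deepcopy(src)
            arr = src.pixel_array
            crop = np.ascontiguousarray(
                arr[region.r0 : region.r0 + region.region_rows,
                    region.c0 : region.c0 + region.region_cols]
            )
            derived.Rows = region.region_rows
            derived.Columns = region.region_cols
            derived.PixelData = crop.tobytes()
            new_pos = shift_position(
                [float(x) for x in src.ImagePositionPatient], geometry,
                region.r0, region.c0,
            )
            derived.ImagePositionPatient = [f"{x:.10g}" for x in new_pos]
            provenance = Provenance(
                orig_name=orig_name,
                orig_id=orig_id,
                sop_class_uid=str(src.SOPClassUID),
                sop_instance_uid=str(src.SOPInstanceUID),
            )
            rewrite_identity(
                derived, slot, plan, provenance, uid_source, study_uid, series_uid
            )
            ok, reason = validate_uid(str(derived.SOPInstanceUID))
            if not ok:
                raise SplitError(f"minted invalid UID: {reason}")
            sop_map[str(derived.SOPInstanceUID)] = str(src.SOPInstanceUID)
            patient_name = str(derived.PatientName)
            patient_id = str(derived.PatientID)
            derived_slices.append(derived)

        subjects[slot] = SubjectSeries(
            slot_index=slot,
            datasets=derived_slices,
            patient_name=patient_name,
            patient_id=patient_id,
            study_uid=study_uid,
            series_uid=series_uid,
            region=region,
            slice_range=(lo, hi),
            sop_map=sop_map,
        )

    return SplitResult(
        subjects=subjects,
        source_patient_name=orig_name,
        source_patient_id=orig_id,
        source_uids=volume.all_uids(),
    )
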