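"""Synthetic fixtures: phantom multi-mouse series and tracking sheets.

Everything the toolkit consumes can be generated offline with known ground
truth.  The phantom generator builds a classic single-frame MR series whose
pixel data holds one ellipsoidal "mouse" blob per occupied grid cell on a
zero background (optionally with seeded Gaussian noise); the sheet generator
writes tab-delimited tracking sheets whose every term resolves through the
shipped lexicon, so the full sheet→SR pipeline runs without external data.

Both generators are deterministic under their seed.
"""

from __future__ import annotations

import csv
import datetime as _dt
import io
import math
import random
from dataclasses import dataclass, field

import numpy as np
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import UID, ExplicitVRLittleEndian

from .acquisition import DEFAULT_COLUMN_MAP, DEFAULT_OBSERVER, SubjectRecord
from .core import UidGenerator, encode_dicom_date
from .splitter import GridPlan, SeriesVolume, compute_regions

__all__ = [
    "PhantomSpec",
    "BlobSpec",
    "make_phantom_volume",
    "make_tracking_sheet",
    "worked_example_record",
    "ORIENTATION_PRESETS",
]

MR_IMAGE_STORAGE = UID("1.2.840.10008.5.1.4.1.1.4")


def _rotated_axial(yaw_deg: float, tilt_deg: float) -> tuple[float, ...]:
    """Axial orientation rotated about z (yaw) then x (tilt); stays orthonormal."""
    cy, sy = math.cos(math.radians(yaw_deg)), math.sin(math.radians(yaw_deg))
    ct, st = math.cos(math.radians(tilt_deg)), math.sin(math.radians(tilt_deg))
    rz = np.array([[cy, -sy, 0], [sy, cy, 0], [0, 0, 1]])
    rx = np.array([[1, 0, 0], [0, ct, -st], [0, st, ct]])
    rot = rx @ rz
    u = rot @ np.array([1.0, 0.0, 0.0])
    v = rot @ np.array([0.0, 1.0, 0.0])
    return tuple(float(x) for x in u) + tuple(float(x) for x in v)


ORIENTATION_PRESETS: dict[str, tuple[float, ...]] = {
    "axial": (1, 0, 0, 0, 1, 0),
    "coronal": (1, 0, 0, 0, 0, -1),
    "sagittal": (0, 1, 0, 0, 0, -1),
    "oblique": _rotated_axial(30.0, 20.0),
}


@dataclass(frozen=True)
class BlobSpec:
    """One ellipsoidal blob, positioned relative to its grid cell.

    ``centroid`` is (slice, row, col) as fractions of (n_slices, cell rows,
    cell cols); ``radii`` is (slices, rows, cols) in voxels.
    """

    centroid: tuple[float, float, float] = (0.5, 0.5, 0.5)
    radii: tuple[float, float, float] = (3.0, 8.0, 8.0)
    intensity: int = 1000


@dataclass
class PhantomSpec:
    """Parameters of a phantom multi-mouse acquisition."""

    n_rows: int = 2
    n_cols: int = 2
    matrix: tuple[int, int] = (128, 128)
    n_slices: int = 10
    pixel_spacing: tuple[float, float] = (0.5, 0.5)
    slice_spacing: float = 1.0
    orientation: str = "axial"
    origin: tuple[float, float, float] = (-30.0, -30.0, 0.0)
    blobs: dict[int, BlobSpec] = field(default_factory=dict)
    noise_sigma: float = 0.0
    modality: str = "MR"
    patient_name: str = "MM_CAGE1"
    patient_id: str = "MM001"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATION_PRESETS:
            raise ValueError(f"unknown orientation preset {self.orientation!r}")
        if not self.blobs:
            n = self.n_rows * self.n_cols
            self.blobs = {
                slot: BlobSpec(intensity=1000 + 200 * slot) for slot in range(1, n + 1)
            }
        intensities = [b.intensity for b in self.blobs.values()]
        if len(set(intensities)) != len(intensities):
            raise ValueError("blob intensities must be pairwise distinct")


def make_phantom_volume(
    spec: PhantomSpec,
) -> tuple[SeriesVolume, list[dict]]:
    """Generate a phantom series and its ground-truth table.

    Returns the series volume and one ground-truth row per blob:
    ``{"slot", "centroid_patient", "centroid_index", "intensity",
    "voxel_count"}``.  Blobs must lie strictly inside their grid cells;
    violations raise ``ValueError``.
    """
    rows, cols = spec.matrix
    plan = GridPlan(n_rows=spec.n_rows, n_cols=spec.n_cols,
                    occupied=frozenset(spec.blobs))
    regions = {r.slot_index: r for r in compute_regions(rows, cols, plan)}
    orient = ORIENTATION_PRESETS[spec.orientation]
    u = np.asarray(orient[:3])
    v = np.asarray(orient[3:])
    normal = np.cross(u, v)
    dr, dc = spec.pixel_spacing
    origin = np.asarray(spec.origin, dtype=float)

    volume = np.zeros((spec.n_slices, rows, cols), dtype=np.float64)
    sidx = np.arange(spec.n_slices)[:, None, None]
    ridx = np.arange(rows)[None, :, None]
    cidx = np.arange(cols)[None, None, :]

    truth: list[dict] = []
    for slot, blob in sorted(spec.blobs.items()):
        region = regions[slot]
        s_c = blob.centroid[0] * spec.n_slices
        r_c = region.r0 + blob.centroid[1] * region.region_rows
        c_c = region.c0 + blob.centroid[2] * region.region_cols
        rs, rr, rc = blob.radii
        if not (region.r0 + rr < r_c < region.r0 + region.region_rows - rr):
            raise ValueError(f"blob {slot} not strictly inside its cell (rows)")
        if not (region.c0 + rc < c_c < region.c0 + region.region_cols - rc):
            raise ValueError(f"blob {slot} not strictly inside its cell (cols)")
        inside = (
            ((sidx - s_c) / rs) ** 2 + ((ridx - r_c) / rr) ** 2 + ((cidx - c_c) / rc) ** 2
        ) <= 1.0
        volume[inside] = blob.intensity
        centroid_patient = (
            origin + c_c * dc * u + r_c * dr * v + s_c * spec.slice_spacing * normal
        )
        truth.append(
            {
                "slot": slot,
                "centroid_index": (float(s_c), float(r_c), float(c_c)),
                "centroid_patient": tuple(float(x) for x in centroid_patient),
                "intensity": blob.intensity,
                "voxel_count": int(inside.sum()),
            }
        )

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        volume = volume + rng.normal(0.0, spec.noise_sigma, volume.shape)
    volume = np.clip(np.rint(volume), 0, 65535).astype(np.uint16)

    uids = UidGenerator(spec.seed)
    study_uid = uids()
    series_uid = uids()
    frame_uid = uids()
    fileset_uid = uids()
    datasets: list[Dataset] = []
    for i in range(spec.n_slices):
        ds = Dataset()
        meta = FileMetaDataset()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        ds.SOPClassUID = MR_IMAGE_STORAGE
        ds.SOPInstanceUID = uids()
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.StorageMediaFileSetUID = fileset_uid
        ds.Modality = spec.modality
        ds.PatientName = spec.patient_name
        ds.PatientID = spec.patient_id
        ds.PatientBirthDate = ""
        ds.PatientSex = ""
        ds.StudyDate = "20190904"
        ds.StudyTime = "120000"
        ds.StudyID = "1"
        ds.AccessionNumber = ""
        ds.ReferringPhysicianName = ""
        ds.SeriesNumber = 1
        ds.InstanceNumber = i + 1
        ds.ImageType = ["ORIGINAL", "PRIMARY"]
        ds.ImageOrientationPatient = [f"{x:.10g}" for x in orient]
        pos = origin + i * spec.slice_spacing * normal
        ds.ImagePositionPatient = [f"{x:.10g}" for x in pos]
        ds.PixelSpacing = [f"{dr:.10g}", f"{dc:.10g}"]
        ds.SliceThickness = f"{spec.slice_spacing:.10g}"
        ds.Rows = rows
        ds.Columns = cols
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = volume[i].tobytes()
        datasets.append(ds)

    return SeriesVolume(datasets), truth


_LATERALITY_CHOICES = ("Right", "Left", None)


def make_tracking_sheet(
    n_subjects: int, seed: int = 0
) -> tuple[str, list[SubjectRecord]]:
    """Generate a tab-delimited tracking sheet plus its ground-truth records.

    Every term is drawn from the shipped lexicon, so each row is guaranteed
    to build into a valid acquisition-context SR; dates are consistent
    (implant ≤ excision).  Deterministic under ``seed``.
    """
    rng = random.Random(seed)
    headers = list(DEFAULT_COLUMN_MAP.values())
    field_for = {v: k for k, v in DEFAULT_COLUMN_MAP.items()}

    records: list[SubjectRecord] = []
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(headers)
    for i in range(n_subjects):
        implant = _dt.date(2019, 1, 1) + _dt.timedelta(days=rng.randrange(0, 300))
        excision = (
            implant + _dt.timedelta(days=rng.randrange(7, 90))
            if rng.random() < 0.8 else None
        )
        specimen = f"{rng.randrange(100000, 999999)}-{rng.randrange(100, 999)}-T"
        record = SubjectRecord(
            subject_id=f"PDX-{i + 1:03d}",
            subject_name=f"Mouse^{i + 1:03d}",
            observer_name=DEFAULT_OBSERVER,
            species_term="Mus musculus",
            strain_description="NOD.Cg-Prkdc<scid> Il2rg<tm1Wjl>/SzJ",
            strain_nomenclature="MGI_2013",
            graft_term="Melanoma",
            tissue_of_origin_term="Skin",
            taxon_of_origin_term="Homo sapiens",
            specimen_id=specimen,
            implant_date=implant,
            excision_date=excision,
            route_term="Subcutaneous",
            site_term="Flank",
            laterality_term=rng.choice(_LATERALITY_CHOICES),
        )
        records.append(record)
        row = []
        for header in headers:
            value = getattr(record, field_for[header])
            if isinstance(value, _dt.date):
                row.append(encode_dicom_date(value))
            elif value is None:
                row.append("")
            else:
                row.append(str(value))
        writer.writerow(row)
    return buf.getvalue(), records


def worked_example_record() -> SubjectRecord:
    """The melanoma patient-derived-xenograft subject used throughout the docs.

    Human melanoma fragment (specimen 425362-245-T) implanted subcutaneously
    in the right flank of an NSG mouse on 2019-07-22 and excised 2019-09-04.
    """
    return SubjectRecord(
        subject_id="PDX-425362",
        subject_name="Mouse^425362",
        observer_name=DEFAULT_OBSERVER,
        species_term="Mus musculus",
        strain_description="NOD.Cg-Prkdc<scid> Il2rg<tm1Wjl>/SzJ",
        strain_nomenclature="MGI_2013",
        graft_term="Melanoma",
        tissue_of_origin_term="Skin",
        taxon_of_origin_term="Homo sapiens",
        specimen_id="425362-245-T",
        implant_date=_dt.date(2019, 7, 22),
        excision_date=_dt.date(2019, 9, 4),
        route_term="Subcutaneous",
        site_term="Flank",
        laterality_term="Right",
    )
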