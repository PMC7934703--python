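"""Native conformance checks for SR documents and split outputs.

Two audiences: :func:`validate_sr` checks an acquisition-context SR against
the template-8101 subtree this toolkit produces (root container and template
identity, observation context, exogenous-substance structure, completeness of
every coded item, UID validity, and the animal patient-module attributes);
:func:`validate_split` audits a split result against the splitter's
contract (UID freshness, untouched spacing/orientation, the patient-space
geometry oracle, attribute conservation, provenance resolvability, and pixel
conservation).

Each check has a stable ``rule_id`` so individual rules can be triggered and
asserted independently.  Unknown extra SR content items are warnings, not
errors — the full template is wider than the subtree produced here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from pydicom.dataset import Dataset
from pydicom.tag import Tag

from . import acquisition as acq
from .core import validate_uid
from .splitter import (
    GEOMETRY_TAGS,
    TABLE1_TAGS,
    SeriesVolume,
    SplitResult,
    VolumeGeometry,
)

__all__ = [
    "Finding",
    "ValidationReport",
    "validate_sr",
    "validate_split",
    "SR_RULES",
    "SPLIT_RULES",
]

SR_RULES = {
    "SR_ROOT": "root content item is a CONTAINER with the acquisition-context concept",
    "SR_TEMPLATE": "root carries content template DCMR/8101",
    "SR_LANGUAGE": "language concept modifier present and CODE-typed",
    "SR_COUNTRY": "country-of-language concept modifier present and CODE-typed",
    "SR_OBSERVER": "person-observer PNAME present in the observation context",
    "SR_GRAFT": "exogenous-substance container has a CODE tumor-graft child",
    "SR_CODE_COMPLETE": "every CODE item carries code value, scheme and meaning",
    "SR_UID": "every UID element is a valid DICOM UID",
    "SR_PATIENT_ANIMAL": "animal patient-module attributes present (orientation type, species)",
    "SR_RELATIONSHIP": "content-item relationships drawn from the allowed set",
    "SR_UNKNOWN_ITEM": "content item outside the produced template subtree (warning)",
}

SPLIT_RULES = {
    "SPLIT_UID_FRESH": "derived UIDs are fresh, valid and duplicate-free",
    "SPLIT_SPACING": "pixel spacing and orientation cosines identical to the source",
    "SPLIT_GEOMETRY": "derived voxel patient coordinates equal their source pre-image",
    "SPLIT_ATTRS": "attribute changes confined to the identity/geometry tag set",
    "SPLIT_PROVENANCE": "derivation references and original name/ID resolvable",
    "SPLIT_PIXELS": "derived pixel arrays equal the source restricted to their regions",
}

GEOMETRY_TOL_MM = 1e-6


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    rule_id: str
    path: str
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not any(f.severity == "error" for f in self.findings)

    @property
    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    def add(self, severity: str, rule_id: str, path: str, message: str) -> None:
        self.findings.append(Finding(severity, rule_id, path, message))

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "findings": [
                {
                    "severity": f.severity,
                    "rule_id": f.rule_id,
                    "path": f.path,
                    "message": f.message,
                }
                for f in self.findings
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def _concept_key(concept) -> tuple[str, str]:
    return (concept.code_value, concept.scheme)


_KNOWN_CONCEPT_KEYS = {
    _concept_key(c)
    for c in (
        acq.ROOT_CONCEPT,
        acq.LANGUAGE_CONCEPT,
        acq.COUNTRY_CONCEPT,
        acq.OBSERVER_CONCEPT,
        acq.EXOGENOUS_CONCEPT,
        acq.TUMOR_GRAFT_CONCEPT,
        acq.DATE_STARTED_CONCEPT,
        acq.DATE_ENDED_CONCEPT,
        acq.BRAND_NAME_CONCEPT,
        acq.ROUTE_CONCEPT,
        acq.SITE_CONCEPT,
        acq.LATERALITY_CONCEPT,
        acq.TISSUE_CONCEPT,
        acq.TAXON_CONCEPT,
    )
}


def _raw_concept_name(item: Dataset) -> tuple[str, str]:
    """(code value, scheme) of a content item's concept name; tolerant of gaps."""
    seq = getattr(item, "ConceptNameCodeSequence", None)
    if not seq:
        return ("", "")
    return (str(getattr(seq[0], "CodeValue", "")),
            str(getattr(seq[0], "CodingSchemeDesignator", "")))


def _find_item(item: Dataset, key: tuple[str, str]) -> Dataset | None:
    if _raw_concept_name(item) == key:
        return item
    for child in getattr(item, "ContentSequence", []) or []:
        found = _find_item(child, key)
        if found is not None:
            return found
    return None


def validate_sr(dataset: Dataset) -> ValidationReport:
    """Check an SR dataset against the produced template-8101 subtree.

    The walk operates on the raw content items (not the typed tree), so a
    structurally defective document — a code item missing its scheme, an
    out-of-set relationship — still yields a report rather than a parse
    failure.  Raises ``ValueError`` only when the dataset carries no SR
    content at all.
    """
    if "ValueType" not in dataset or "ConceptNameCodeSequence" not in dataset:
        raise ValueError("dataset carries no SR content tree")
    report = ValidationReport()

    root_key = _raw_concept_name(dataset)
    if str(dataset.ValueType) != "CONTAINER" or root_key != _concept_key(acq.ROOT_CONCEPT):
        report.add(
            "error", "SR_ROOT", "1",
            f"root is {dataset.ValueType} {root_key}, expected CONTAINER "
            f"{_concept_key(acq.ROOT_CONCEPT)}",
        )
    tpl_seq = getattr(dataset, "ContentTemplateSequence", None)
    tpl_id = str(getattr(tpl_seq[0], "TemplateIdentifier", "")) if tpl_seq else ""
    tpl_res = str(getattr(tpl_seq[0], "MappingResource", "")) if tpl_seq else ""
    if tpl_id != acq.TEMPLATE_ID or tpl_res != acq.MAPPING_RESOURCE:
        report.add(
            "error", "SR_TEMPLATE", "1",
            f"root template is ({tpl_res},{tpl_id}), expected "
            f"({acq.MAPPING_RESOURCE},{acq.TEMPLATE_ID})",
        )

    for rule_id, concept, value_type, what in (
        ("SR_LANGUAGE", acq.LANGUAGE_CONCEPT, "CODE", "language concept modifier"),
        ("SR_COUNTRY", acq.COUNTRY_CONCEPT, "CODE", "country-of-language concept modifier"),
        ("SR_OBSERVER", acq.OBSERVER_CONCEPT, "PNAME", "person-observer name"),
    ):
        item = _find_item(dataset, _concept_key(concept))
        if item is None or str(getattr(item, "ValueType", "")) != value_type:
            report.add("error", rule_id, "1",
                       f"{what} missing or not {value_type}-typed")

    exo = _find_item(dataset, _concept_key(acq.EXOGENOUS_CONCEPT))
    if exo is not None:
        graft = _find_item(exo, _concept_key(acq.TUMOR_GRAFT_CONCEPT))
        if graft is None or str(getattr(graft, "ValueType", "")) != "CODE":
            report.add("error", "SR_GRAFT", "1",
                       "exogenous-substance container lacks a CODE tumor-graft child")

    def walk(item: Dataset, path: str, is_root: bool) -> None:
        if not is_root:
            rel = str(getattr(item, "RelationshipType", ""))
            if rel not in acq.ALLOWED_RELATIONSHIPS:
                report.add("error", "SR_RELATIONSHIP", path,
                           f"relationship {rel!r} not in allowed set")
        if str(getattr(item, "ValueType", "")) == "CODE":
            seq = getattr(item, "ConceptCodeSequence", None)
            code = seq[0] if seq else None
            if (
                code is None
                or not str(getattr(code, "CodeValue", ""))
                or not str(getattr(code, "CodingSchemeDesignator", ""))
                or not str(getattr(code, "CodeMeaning", ""))
            ):
                report.add("error", "SR_CODE_COMPLETE", path,
                           "CODE item missing code value, scheme or meaning")
        key = _raw_concept_name(item)
        if key not in _KNOWN_CONCEPT_KEYS:
            report.add("warning", "SR_UNKNOWN_ITEM", path,
                       f"content item {key} outside the produced subtree")
        for i, child in enumerate(getattr(item, "ContentSequence", []) or [], start=1):
            walk(child, f"{path}.{i}", is_root=False)

    walk(dataset, "1", is_root=True)

    for elem in dataset.iterall():
        if elem.VR == "UI" and elem.value:
            values = elem.value if isinstance(elem.value, (list, tuple)) else [elem.value]
            for v in values:
                ok, reason = validate_uid(str(v))
                if not ok:
                    report.add("error", "SR_UID", str(elem.tag),
                               f"invalid UID {v!r}: {reason}")

    if str(getattr(dataset, "AnatomicalOrientationType", "")) != "QUADRUPED":
        report.add("error", "SR_PATIENT_ANIMAL", "(0010,2210)",
                   "anatomical orientation type missing or not QUADRUPED")
    if not str(getattr(dataset, "PatientSpeciesDescription", "")):
        report.add("error", "SR_PATIENT_ANIMAL", "(0010,2201)",
                   "patient species description missing")
    if not getattr(dataset, "PatientSpeciesCodeSequence", None):
        report.add("error", "SR_PATIENT_ANIMAL", "(0010,2202)",
                   "patient species code sequence missing")
    return report


_ALLOWED_CHANGED = set(TABLE1_TAGS) | set(GEOMETRY_TAGS)


def _elements_differ(a: Dataset, b: Dataset, tag: Tag) -> bool:
    in_a, in_b = tag in a, tag in b
    if in_a != in_b:
        return True
    if not in_a:
        return False
    return a[tag] != b[tag]


def validate_split(source: SeriesVolume, result: SplitResult) -> ValidationReport:
    """Audit a split result against the splitter contract.

    Raises ``ValueError`` when the pairing is inconsistent (e.g. the result
    references slices the source does not contain).
    """
    report = ValidationReport()
    src_geom = source.geometry
    src_stack = source.pixel_stack()
    src_by_sop = {str(ds.SOPInstanceUID): i for i, ds in enumerate(source.datasets)}

    # --- UID freshness -----------------------------------------------------
    fresh: list[tuple[str, str]] = []
    for subject in result.subjects.values():
        fresh.append((subject.study_uid, f"slot {subject.slot_index} study"))
        fresh.append((subject.series_uid, f"slot {subject.slot_index} series"))
        for ds in subject.datasets:
            fresh.append((str(ds.SOPInstanceUID), f"slot {subject.slot_index} instance"))
            if "StorageMediaFileSetUID" in ds:
                fresh.append(
                    (str(ds.StorageMediaFileSetUID), f"slot {subject.slot_index} fileset")
                )
    seen: dict[str, str] = {}
    for uid, where in fresh:
        ok, reason = validate_uid(uid)
        if not ok:
            report.add("error", "SPLIT_UID_FRESH", where, f"invalid UID {uid!r}: {reason}")
        if uid in result.source_uids:
            report.add("error", "SPLIT_UID_FRESH", where,
                       f"derived UID {uid!r} collides with a source UID")
        if uid in seen and seen[uid] != where and "study" not in where and "series" not in where:
            report.add("error", "SPLIT_UID_FRESH", where, f"duplicate derived UID {uid!r}")
        seen.setdefault(uid, where)
    # instance-level UIDs must be pairwise distinct
    instance_uids = [u for u, w in fresh if "instance" in w]
    if len(set(instance_uids)) != len(instance_uids):
        report.add("error", "SPLIT_UID_FRESH", "result",
                   "derived SOP instance UIDs are not pairwise distinct")

    for subject in result.subjects.values():
        region = subject.region
        lo, hi = subject.slice_range
        if hi > len(source.datasets):
            raise ValueError("result references slices beyond the source volume")
        for j, ds in enumerate(subject.datasets):
            where = f"slot {subject.slot_index} slice {j}"
            src_ds = source.datasets[lo + j]

            # --- spacing / orientation identity ---------------------------
            if list(map(str, ds.PixelSpacing)) != list(map(str, src_ds.PixelSpacing)):
                report.add("error", "SPLIT_SPACING", where,
                           "pixel spacing differs from source")
            if list(map(str, ds.ImageOrientationPatient)) != list(
                map(str, src_ds.ImageOrientationPatient)
            ):
                report.add("error", "SPLIT_SPACING", where,
                           "orientation cosines differ from source")

            # --- geometry oracle ------------------------------------------
            der_geom = VolumeGeometry(
                rows=int(ds.Rows),
                cols=int(ds.Columns),
                pixel_spacing=(float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1])),
                orientation=tuple(float(x) for x in ds.ImageOrientationPatient),
                positions=(tuple(float(x) for x in ds.ImagePositionPatient),),
            )
            probes = [
                (0, 0),
                (0, der_geom.cols - 1),
                (der_geom.rows - 1, 0),
                (der_geom.rows - 1, der_geom.cols - 1),
                ((der_geom.rows - 1) // 2, (der_geom.cols - 1) // 2),
            ]
            src_slice_geom = VolumeGeometry(
                rows=src_geom.rows,
                cols=src_geom.cols,
                pixel_spacing=src_geom.pixel_spacing,
                orientation=src_geom.orientation,
                positions=(tuple(float(x) for x in src_ds.ImagePositionPatient),),
            )
            for r, c in probes:
                derived_pt = der_geom.voxel_to_patient(0, r, c)
                source_pt = src_slice_geom.voxel_to_patient(0, r + region.r0, c + region.c0)
                err = float(np.max(np.abs(derived_pt - source_pt)))
                if err > GEOMETRY_TOL_MM:
                    report.add("error", "SPLIT_GEOMETRY", where,
                               f"voxel ({r},{c}) patient coordinate off by {err:.3g} mm")
                    break

            # --- attribute conservation -----------------------------------
            tags = {e.tag for e in src_ds} | {e.tag for e in ds}
            for tag in sorted(tags):
                if tag in _ALLOWED_CHANGED:
                    continue
                if _elements_differ(src_ds, ds, tag):
                    report.add("error", "SPLIT_ATTRS", where,
                               f"unexpected change at {tag}")

            # --- provenance -----------------------------------------------
            deriv = getattr(ds, "DerivationImageSequence", None)
            ref_ok = False
            if deriv:
                try:
                    ref = deriv[0].SourceImageSequence[0]
                    ref_uid = str(ref.ReferencedSOPInstanceUID)
                    ref_ok = (
                        ref_uid in src_by_sop
                        and str(ref.ReferencedSOPClassUID) == str(src_ds.SOPClassUID)
                        and ref_uid == str(src_ds.SOPInstanceUID)
                    )
                except (AttributeError, IndexError):
                    ref_ok = False
            if not ref_ok:
                report.add("error", "SPLIT_PROVENANCE", where,
                           "derivation image sequence does not resolve to the source slice")
            group = getattr(ds, "SourcePatientGroupIdentificationSequence", None)
            if not group or (
                str(group[0].PatientName) != result.source_patient_name
                or str(group[0].PatientID) != result.source_patient_id
            ):
                report.add("error", "SPLIT_PROVENANCE", where,
                           "source patient group item does not hold the original name/ID")
            if not str(getattr(ds, "DerivationDescription", "")):
                report.add("error", "SPLIT_PROVENANCE", where,
                           "derivation description missing")

        # --- pixel conservation -------------------------------------------
        derived_px = np.stack([d.pixel_array for d in subject.datasets])
        src_crop = src_stack[
            lo:hi,
            region.r0 : region.r0 + region.region_rows,
            region.c0 : region.c0 + region.region_cols,
        ]
        if derived_px.shape != src_crop.shape or not np.array_equal(derived_px, src_crop):
            report.add("error", "SPLIT_PIXELS", f"slot {subject.slot_index}",
                       "derived pixels differ from the source region")

    return report
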