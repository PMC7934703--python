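"""Acquisition-context structured reports for small-animal imaging.

Turns one row of an animal-tracking sheet into a DICOM Pre-clinical Small
Animal Image Acquisition Context SR (template 8101 of the DCMR mapping
resource): free-text sheet terms are resolved to coded concepts through a
lexicon, assembled into the template's content tree (observation context plus
the exogenous-substance subtree: tumor graft, implant/excision dates, specimen
brand name, route, site with laterality, tissue and taxon of origin), and
serialized as a Part 10 SR object together with the augmented patient module
(quadruped orientation, species and strain codes).

The inverse — recovering a :class:`SubjectRecord` from an SR — is provided so
the whole pipeline is round-trip testable.
"""

from __future__ import annotations

import csv
import datetime as _dt
import io
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, TextIO

from pydicom.dataset import Dataset
from pydicom.uid import UID

from .core import (
    CodedConcept,
    UidGenerator,
    encode_dicom_date,
    parse_sheet_date,
)

__all__ = [
    "SubjectRecord",
    "SrNode",
    "Lexicon",
    "LexiconError",
    "SheetError",
    "DEFAULT_COLUMN_MAP",
    "DEFAULT_LANGUAGE",
    "DEFAULT_COUNTRY",
    "DEFAULT_OBSERVER",
    "parse_tracking_sheet",
    "lookup_code",
    "build_acquisition_context_tree",
    "build_patient_module",
    "sr_tree_to_dataset",
    "dataset_to_tree",
    "extract_record_from_sr",
]

ACQUISITION_CONTEXT_SR_STORAGE = UID("1.2.840.10008.5.1.4.1.1.88.71")
TEMPLATE_ID = "8101"
MAPPING_RESOURCE = "DCMR"

# Concept names of the template subtree this toolkit produces.
ROOT_CONCEPT = CodedConcept("127001", "DCM", "Preclinical Small Animal Imaging Acquisition Context")
LANGUAGE_CONCEPT = CodedConcept("121049", "DCM", "Language of Content Item and Descendants")
COUNTRY_CONCEPT = CodedConcept("121046", "DCM", "Country of Language")
OBSERVER_CONCEPT = CodedConcept("121008", "DCM", "Person Observer Name")
EXOGENOUS_CONCEPT = CodedConcept("127400", "DCM", "Exogenous substance")
TUMOR_GRAFT_CONCEPT = CodedConcept("127460", "DCM", "Tumor Graft")
DATE_STARTED_CONCEPT = CodedConcept("111526", "DCM", "DateTime Started")
DATE_ENDED_CONCEPT = CodedConcept("111527", "DCM", "DateTime Ended")
BRAND_NAME_CONCEPT = CodedConcept("111529", "DCM", "Brand Name")
ROUTE_CONCEPT = CodedConcept("410675002", "SCT", "Route of administration")
SITE_CONCEPT = CodedConcept("272737002", "SCT", "Site of")
LATERALITY_CONCEPT = CodedConcept("272741003", "SCT", "Laterality")
TISSUE_CONCEPT = CodedConcept("127401", "DCM", "Tissue of origin")
TAXON_CONCEPT = CodedConcept("127402", "DCM", "Taxonomic rank of origin")

DEFAULT_LANGUAGE = CodedConcept("eng", "RFC5646", "English")
DEFAULT_COUNTRY = CodedConcept("US", "ISO3166_1", "United States")
DEFAULT_OBSERVER = "SAIP^Imager"

ALLOWED_RELATIONSHIPS = {"CONTAINS", "HAS CONCEPT MOD", "HAS OBS CONTEXT", "HAS PROPERTIES"}
ALLOWED_VALUE_TYPES = {"CONTAINER", "CODE", "TEXT", "DATETIME", "PNAME"}


class LexiconError(KeyError):
    """An unknown term or category — coded output must never be guessed."""


class SheetError(ValueError):
    """A malformed tracking sheet (missing column, bad cell)."""


@dataclass
class SubjectRecord:
    """One tracking-sheet row, normalized into named fields."""

    subject_id: str
    subject_name: str = ""
    observer_name: str = ""
    species_term: str = ""
    strain_description: str = ""
    strain_nomenclature: str = ""
    strain_code: CodedConcept | None = None
    graft_term: str = ""
    tissue_of_origin_term: str = ""
    taxon_of_origin_term: str = ""
    specimen_id: str = ""
    implant_date: _dt.date | None = None
    excision_date: _dt.date | None = None
    route_term: str = ""
    site_term: str = ""
    laterality_term: str | None = None

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")
        if (
            self.implant_date is not None
            and self.excision_date is not None
            and self.implant_date > self.excision_date
        ):
            raise ValueError(
                f"implant date {self.implant_date} is after excision date {self.excision_date}"
            )


@dataclass
class SrNode:
    """One SR content item: typed value, concept name, children.

    ``relationship`` is ``None`` only for the document root, which must be a
    SEPARATE CONTAINER carrying template id "8101".
    """

    value_type: str
    concept_name: CodedConcept
    relationship: str | None = None
    value: object = None
    continuity: str | None = None
    template_id: str | None = None
    children: list["SrNode"] = field(default_factory=list)

    def walk(self) -> Iterable["SrNode"]:
        yield self
        for child in self.children:
            yield from child.walk()

    def find(self, concept: CodedConcept) -> "SrNode | None":
        for node in self.walk():
            if node.concept_name == concept:
                return node
        return None


def _normalize_term(term: str) -> str:
    return " ".join(term.split()).casefold()


class Lexicon:
    """Category → (normalized term → coded concept) mapping.

    Lookups are case- and whitespace-insensitive.  Reverse lookups return the
    canonical (first-registered) spelling of a concept's term, which makes
    build→extract round trips exact for sheets written with canonical terms.
    """

    def __init__(self, categories: dict[str, dict[str, CodedConcept]], version: str = ""):
        self.version = version
        self._forward: dict[str, dict[str, CodedConcept]] = {}
        self._canonical: dict[str, dict[tuple[str, str], str]] = {}
        for category, terms in categories.items():
            self._forward[category] = {}
            self._canonical[category] = {}
            for term, concept in terms.items():
                self.add(category, term, concept)

    def add(self, category: str, term: str, concept: CodedConcept) -> None:
        fwd = self._forward.setdefault(category, {})
        rev = self._canonical.setdefault(category, {})
        fwd[_normalize_term(term)] = concept
        rev.setdefault((concept.code_value, concept.scheme), term)

    @property
    def categories(self) -> list[str]:
        return list(self._forward)

    def lookup(self, term: str, category: str) -> CodedConcept:
        if category not in self._forward:
            raise LexiconError(f"unknown lexicon category: {category!r}")
        concept = self._forward[category].get(_normalize_term(term))
        if concept is None:
            raise LexiconError(f"unknown term {term!r} in category {category!r}")
        return concept

    def lookup_optional(self, term: str, category: str) -> CodedConcept | None:
        try:
            return self.lookup(term, category)
        except LexiconError:
            return None

    def term_for(self, concept: CodedConcept, category: str) -> str:
        """Canonical term for a concept (reverse lookup)."""
        rev = self._canonical.get(category, {})
        term = rev.get((concept.code_value, concept.scheme))
        if term is None:
            raise LexiconError(
                f"no term for ({concept.code_value},{concept.scheme}) in category {category!r}"
            )
        return term

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "Lexicon":
        if isinstance(source, (str, Path)):
            with open(source, encoding="utf-8") as fh:
                payload = json.load(fh)
        else:
            payload = source
        categories = {
            cat: {
                term: CodedConcept(code_value=triple[0], scheme=triple[1], meaning=triple[2])
                for term, triple in terms.items()
            }
            for cat, terms in payload["categories"].items()
        }
        return cls(categories, version=payload.get("version", ""))

    @classmethod
    def default(cls) -> "Lexicon":
        """The shipped lexicon (every concept used by the worked example)."""
        text = resources.files("mousehotel.data").joinpath("lexicon.json").read_text("utf-8")
        return cls.from_json(json.loads(text))


def lookup_code(term: str, category: str, lexicon: Lexicon) -> CodedConcept:
    """Resolve a free-text sheet term to its coded concept."""
    return lexicon.lookup(term, category)


DEFAULT_COLUMN_MAP: dict[str, str] = {
    "subject_id": "Animal ID",
    "subject_name": "Animal Name",
    "observer_name": "Observer",
    "species_term": "Species",
    "strain_description": "Strain",
    "strain_nomenclature": "Strain Nomenclature",
    "graft_term": "Graft",
    "tissue_of_origin_term": "Tissue of Origin",
    "taxon_of_origin_term": "Taxon of Origin",
    "specimen_id": "Specimen ID",
    "implant_date": "Implant Date",
    "excision_date": "Excision Date",
    "route_term": "Route",
    "site_term": "Site",
    "laterality_term": "Laterality",
}

_MANDATORY_FIELDS = (
    "subject_id",
    "species_term",
    "graft_term",
    "tissue_of_origin_term",
    "taxon_of_origin_term",
    "specimen_id",
    "implant_date",
    "route_term",
    "site_term",
)
_OPTIONAL_FIELDS = (
    "subject_name",
    "observer_name",
    "strain_description",
    "strain_nomenclature",
    "excision_date",
    "laterality_term",
)
_DATE_FIELDS = ("implant_date", "excision_date")


def parse_tracking_sheet(
    stream: TextIO | str | Path,
    column_map: dict[str, str] | None = None,
) -> list[SubjectRecord]:
    """Parse a tab-delimited tracking sheet into subject records.

    The first row is a header; ``column_map`` binds record fields to header
    names (defaults to :data:`DEFAULT_COLUMN_MAP`).  Mandatory columns must be
    present; optional ones (excision date, laterality, strain, observer) may
    be absent or empty.  Row order is preserved.
    """
    column_map = dict(column_map or DEFAULT_COLUMN_MAP)
    if isinstance(stream, (str, Path)) and "\t" not in str(stream) and "\n" not in str(stream):
        fh: TextIO = open(stream, encoding="utf-8", newline="")
        close = True
    elif isinstance(stream, str):
        fh = io.StringIO(stream)
        close = False
    else:
        fh = stream  # type: ignore[assignment]
        close = False
    try:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SheetError("sheet has no header row")
        header = [h.strip() for h in header]
        index: dict[str, int] = {}
        for fld in _MANDATORY_FIELDS:
            col = column_map.get(fld)
            if col is None or col not in header:
                raise SheetError(f"missing mandatory column for field {fld!r}"
                                 + (f" (header {col!r})" if col else ""))
            index[fld] = header.index(col)
        for fld in _OPTIONAL_FIELDS:
            col = column_map.get(fld)
            if col is not None and col in header:
                index[fld] = header.index(col)

        records: list[SubjectRecord] = []
        for row_no, row in enumerate(reader, start=2):
            if not any(cell.strip() for cell in row):
                continue
            kwargs: dict[str, object] = {}
            for fld, col_idx in index.items():
                cell = row[col_idx].strip() if col_idx < len(row) else ""
                if fld in _DATE_FIELDS:
                    if not cell:
                        kwargs[fld] = None
                        continue
                    try:
                        kwargs[fld] = parse_sheet_date(cell)
                    except ValueError as exc:
                        raise SheetError(
                            f"row {row_no}, column {header[col_idx]!r}: {exc}"
                        ) from exc
                elif fld == "laterality_term":
                    kwargs[fld] = cell or None
                else:
                    kwargs[fld] = cell
            records.append(SubjectRecord(**kwargs))  # type: ignore[arg-type]
        return records
    finally:
        if close:
            fh.close()


def build_acquisition_context_tree(
    record: SubjectRecord,
    lexicon: Lexicon,
    language: CodedConcept = DEFAULT_LANGUAGE,
    country: CodedConcept = DEFAULT_COUNTRY,
    observer_name: str | None = None,
) -> SrNode:
    """Build the template-8101 content tree for one subject.

    The tree covers the observation context (language, country, person
    observer) and the exogenous-substance container with the tumor graft and
    its properties.  Every coded slot is resolved through the lexicon; an
    unresolvable term raises :class:`LexiconError` rather than emitting
    free text into a coded slot.
    """
    for fld in ("graft_term", "route_term", "site_term", "tissue_of_origin_term",
                "taxon_of_origin_term", "specimen_id"):
        if not getattr(record, fld):
            raise ValueError(f"record field {fld!r} is required to build the tree")
    if record.implant_date is None:
        raise ValueError("record field 'implant_date' is required to build the tree")

    observer = observer_name or record.observer_name or DEFAULT_OBSERVER

    graft = SrNode(
        "CODE", TUMOR_GRAFT_CONCEPT, "CONTAINS",
        value=lexicon.lookup(record.graft_term, "tumor_graft"),
    )
    graft.children.append(
        SrNode("DATETIME", DATE_STARTED_CONCEPT, "HAS PROPERTIES",
               value=encode_dicom_date(record.implant_date))
    )
    if record.excision_date is not None:
        graft.children.append(
            SrNode("DATETIME", DATE_ENDED_CONCEPT, "HAS PROPERTIES",
                   value=encode_dicom_date(record.excision_date))
        )
    graft.children.append(
        SrNode("TEXT", BRAND_NAME_CONCEPT, "HAS PROPERTIES", value=record.specimen_id)
    )
    graft.children.append(
        SrNode("CODE", ROUTE_CONCEPT, "HAS PROPERTIES",
               value=lexicon.lookup(record.route_term, "route"))
    )
    site = SrNode("CODE", SITE_CONCEPT, "HAS PROPERTIES",
                  value=lexicon.lookup(record.site_term, "site"))
    if record.laterality_term:
        site.children.append(
            SrNode("CODE", LATERALITY_CONCEPT, "HAS CONCEPT MOD",
                   value=lexicon.lookup(record.laterality_term, "laterality"))
        )
    graft.children.append(site)
    graft.children.append(
        SrNode("CODE", TISSUE_CONCEPT, "HAS PROPERTIES",
               value=lexicon.lookup(record.tissue_of_origin_term, "tissue"))
    )
    graft.children.append(
        SrNode("CODE", TAXON_CONCEPT, "HAS PROPERTIES",
               value=lexicon.lookup(record.taxon_of_origin_term, "taxon"))
    )

    exogenous = SrNode("CONTAINER", EXOGENOUS_CONCEPT, "CONTAINS",
                       continuity="SEPARATE", children=[graft])

    language_node = SrNode("CODE", LANGUAGE_CONCEPT, "HAS CONCEPT MOD", value=language)
    language_node.children.append(
        SrNode("CODE", COUNTRY_CONCEPT, "HAS CONCEPT MOD", value=country)
    )

    return SrNode(
        "CONTAINER",
        ROOT_CONCEPT,
        relationship=None,
        continuity="SEPARATE",
        template_id=TEMPLATE_ID,
        children=[
            language_node,
            SrNode("PNAME", OBSERVER_CONCEPT, "HAS OBS CONTEXT", value=observer),
            exogenous,
        ],
    )


def build_patient_module(record: SubjectRecord, lexicon: Lexicon) -> Dataset:
    """Augmented patient module for a research animal.

    Writes the quadruped anatomical-orientation type, the species description
    and code sequence, and the strain description/nomenclature with the strain
    code sequence when a code is known.
    """
    species = lexicon.lookup(record.species_term, "species")
    ds = Dataset()
    ds.PatientName = record.subject_name or record.subject_id
    ds.PatientID = record.subject_id
    ds.PatientBirthDate = ""
    ds.PatientSex = ""
    ds.AnatomicalOrientationType = "QUADRUPED"
    ds.PatientSpeciesDescription = record.species_term
    ds.PatientSpeciesCodeSequence = [species.to_item()]
    if record.strain_description:
        ds.StrainDescription = record.strain_description
        ds.StrainNomenclature = record.strain_nomenclature
        strain = record.strain_code or lexicon.lookup_optional(
            record.strain_description, "strain"
        )
        if strain is not None:
            ds.StrainCodeSequence = [strain.to_item()]
    return ds


class TreeError(ValueError):
    """An SR content tree violating the node invariants; names the node path."""


def _check_tree(node: SrNode, path: str, is_root: bool) -> None:
    if node.value_type not in ALLOWED_VALUE_TYPES:
        raise TreeError(f"{path}: unknown value type {node.value_type!r}")
    if is_root:
        if node.relationship is not None:
            raise TreeError(f"{path}: root must have no relationship")
        if node.value_type != "CONTAINER":
            raise TreeError(f"{path}: root must be a CONTAINER")
        if node.template_id != TEMPLATE_ID:
            raise TreeError(f"{path}: root template id must be {TEMPLATE_ID!r}")
    else:
        if node.relationship not in ALLOWED_RELATIONSHIPS:
            raise TreeError(f"{path}: relationship {node.relationship!r} not allowed")
    if node.value_type == "CONTAINER":
        if node.value is not None:
            raise TreeError(f"{path}: CONTAINER must carry no value")
        if node.continuity != "SEPARATE":
            raise TreeError(f"{path}: CONTAINER continuity must be SEPARATE")
    elif node.value_type == "CODE":
        if not isinstance(node.value, CodedConcept):
            raise TreeError(f"{path}: CODE node value must be a coded concept")
    elif node.value is None or not isinstance(node.value, str) or not node.value:
        raise TreeError(f"{path}: {node.value_type} node needs a string value")
    for i, child in enumerate(node.children, start=1):
        _check_tree(child, f"{path}.{i}", is_root=False)


def _node_to_item(node: SrNode, is_root: bool) -> Dataset:
    item = Dataset()
    if not is_root:
        item.RelationshipType = node.relationship
    item.ValueType = node.value_type
    item.ConceptNameCodeSequence = [node.concept_name.to_item()]
    if node.value_type == "CONTAINER":
        item.ContinuityOfContent = node.continuity
        if node.template_id:
            tpl = Dataset()
            tpl.MappingResource = MAPPING_RESOURCE
            tpl.TemplateIdentifier = node.template_id
            item.ContentTemplateSequence = [tpl]
    elif node.value_type == "CODE":
        item.ConceptCodeSequence = [node.value.to_item()]  # type: ignore[union-attr]
    elif node.value_type == "TEXT":
        item.TextValue = node.value
    elif node.value_type == "DATETIME":
        item.DateTime = node.value
    elif node.value_type == "PNAME":
        item.PersonName = node.value
    if node.children:
        item.ContentSequence = [_node_to_item(c, is_root=False) for c in node.children]
    return item


def sr_tree_to_dataset(
    tree: SrNode,
    patient: Dataset,
    uid_source: UidGenerator,
    content_datetime: tuple[str, str] | None = None,
) -> Dataset:
    """Serialize a content tree plus patient module as a complete SR object.

    Fresh study/series/SOP instance UIDs are drawn from ``uid_source``.
    ``content_datetime`` is a ``(DA, TM)`` pair; by default the DateTime
    Started node's date (the implant date) at 000000 is used, so identical
    inputs with an identically seeded generator yield byte-identical files.
    """
    _check_tree(tree, path="1", is_root=True)

    if content_datetime is None:
        started = tree.find(DATE_STARTED_CONCEPT)
        content_datetime = (str(started.value) if started else "19000101", "000000")

    ds = Dataset()
    for elem in patient.iterall():
        ds.add(elem)
    ds.SOPClassUID = ACQUISITION_CONTEXT_SR_STORAGE
    ds.SOPInstanceUID = uid_source()
    ds.StudyInstanceUID = uid_source()
    ds.SeriesInstanceUID = uid_source()
    ds.Modality = "SR"
    ds.SeriesNumber = 1
    ds.InstanceNumber = 1
    ds.StudyID = ""
    ds.AccessionNumber = ""
    ds.ReferringPhysicianName = ""
    ds.StudyDate, ds.StudyTime = content_datetime
    ds.ContentDate, ds.ContentTime = content_datetime
    ds.Manufacturer = "mousehotel"
    ds.CompletionFlag = "COMPLETE"
    ds.VerificationFlag = "UNVERIFIED"

    # splice the root content item's elements into the top-level dataset
    root = _node_to_item(tree, is_root=True)
    for elem in root:
        ds.add(elem)
    return ds


def _item_to_node(item: Dataset, is_root: bool, path: str) -> SrNode:
    concept = CodedConcept.from_item(item.ConceptNameCodeSequence[0])
    vt = str(item.ValueType)
    value: object = None
    continuity = None
    template_id = None
    if vt == "CONTAINER":
        continuity = str(getattr(item, "ContinuityOfContent", "")) or None
        tpl_seq = getattr(item, "ContentTemplateSequence", None)
        if tpl_seq:
            template_id = str(tpl_seq[0].TemplateIdentifier)
    elif vt == "CODE":
        value = CodedConcept.from_item(item.ConceptCodeSequence[0])
    elif vt == "TEXT":
        value = str(item.TextValue)
    elif vt == "DATETIME":
        value = str(item.DateTime)
    elif vt == "PNAME":
        value = str(item.PersonName)
    node = SrNode(
        value_type=vt,
        concept_name=concept,
        relationship=None if is_root else str(item.RelationshipType),
        value=value,
        continuity=continuity,
        template_id=template_id,
    )
    for i, child in enumerate(getattr(item, "ContentSequence", []) or [], start=1):
        node.children.append(_item_to_node(child, is_root=False, path=f"{path}.{i}"))
    return node


def dataset_to_tree(dataset: Dataset) -> SrNode:
    """Recover the content tree from a serialized SR dataset."""
    if "ValueType" not in dataset or "ConceptNameCodeSequence" not in dataset:
        raise TreeError("dataset carries no SR content")
    return _item_to_node(dataset, is_root=True, path="1")


def extract_record_from_sr(dataset: Dataset, lexicon: Lexicon) -> SubjectRecord:
    """Recover a :class:`SubjectRecord` from a template-8101 SR.

    The lexicon is used in reverse: each coded value maps back to its
    canonical term.  Rejects documents whose root template is not 8101 or
    that lack the exogenous-substance container.
    """
    tree = dataset_to_tree(dataset)
    if tree.template_id != TEMPLATE_ID or tree.concept_name != ROOT_CONCEPT:
        raise TreeError(
            f"root is not a template-{TEMPLATE_ID} acquisition context "
            f"(template {tree.template_id!r})"
        )
    exo = tree.find(EXOGENOUS_CONCEPT)
    if exo is None:
        raise TreeError("missing exogenous-substance container")
    graft = exo.find(TUMOR_GRAFT_CONCEPT)
    if graft is None:
        raise TreeError("missing tumor-graft content item")

    def code_term(parent: SrNode, concept: CodedConcept, category: str) -> str:
        node = parent.find(concept)
        if node is None:
            return ""
        return lexicon.term_for(node.value, category)  # type: ignore[arg-type]

    observer = tree.find(OBSERVER_CONCEPT)
    started = graft.find(DATE_STARTED_CONCEPT)
    ended = graft.find(DATE_ENDED_CONCEPT)
    brand = graft.find(BRAND_NAME_CONCEPT)
    site = graft.find(SITE_CONCEPT)
    laterality = site.find(LATERALITY_CONCEPT) if site is not None else None

    species_term = ""
    strain_description = str(getattr(dataset, "StrainDescription", ""))
    strain_nomenclature = str(getattr(dataset, "StrainNomenclature", ""))
    strain_code = None
    species_seq = getattr(dataset, "PatientSpeciesCodeSequence", None)
    if species_seq:
        species_term = lexicon.term_for(CodedConcept.from_item(species_seq[0]), "species")
    strain_seq = getattr(dataset, "StrainCodeSequence", None)
    if strain_seq:
        strain_code = CodedConcept.from_item(strain_seq[0])

    return SubjectRecord(
        subject_id=str(getattr(dataset, "PatientID", "")) or "UNKNOWN",
        subject_name=str(getattr(dataset, "PatientName", "")),
        observer_name=str(observer.value) if observer else "",
        species_term=species_term,
        strain_description=strain_description,
        strain_nomenclature=strain_nomenclature,
        strain_code=strain_code,
        graft_term=lexicon.term_for(graft.value, "tumor_graft"),  # type: ignore[arg-type]
        tissue_of_origin_term=code_term(graft, TISSUE_CONCEPT, "tissue"),
        taxon_of_origin_term=code_term(graft, TAXON_CONCEPT, "taxon"),
        specimen_id=str(brand.value) if brand else "",
        implant_date=_dt.datetime.strptime(str(started.value), "%Y%m%d").date()
        if started else None,
        excision_date=_dt.datetime.strptime(str(ended.value), "%Y%m%d").date()
        if ended else None,
        route_term=code_term(graft, ROUTE_CONCEPT, "route"),
        site_term=code_term(graft, SITE_CONCEPT, "site"),
        laterality_term=lexicon.term_for(laterality.value, "laterality")  # type: ignore[arg-type]
        if laterality is not None else None,
    )
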