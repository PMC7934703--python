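"""Foundation primitives shared by the whole toolkit.

Coded concepts (the code-value / scheme / meaning triples all structured-report
content and coded patient attributes are made of), UID minting and validation
under the ``2.25.<decimal UUID>`` OID policy, and DICOM DA-format date
encoding.  Everything here is deterministic given an injected random source,
so every downstream artifact (SR files, split series) can be reproduced
byte-for-byte from a seed.
"""

from __future__ import annotations

import datetime as _dt
import random
import re
import uuid
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian

__all__ = [
    "CodedConcept",
    "UidGenerator",
    "oid_from_uuid_int",
    "generate_oid",
    "validate_uid",
    "encode_dicom_date",
    "parse_sheet_date",
    "read_part10",
    "write_part10",
]

#: Maximum length of a DICOM UI value (VR limit).
UID_MAX_LEN = 64

#: Maximum length of a ``2.25.`` + decimal-UUID OID: 5 + 39 digits of 2**128-1.
OID_MAX_LEN = 44

_UID_RE = re.compile(r"^[0-9]+(\.[0-9]+)*$")


@dataclass(frozen=True)
class CodedConcept:
    """A (code value, coding scheme designator, code meaning) triple.

    Equality and hashing use only ``(code_value, scheme)``; the meaning is
    display text and two systems may render it differently.
    """

    code_value: str
    scheme: str
    meaning: str = field(compare=False)

    def __post_init__(self) -> None:
        if not self.code_value:
            raise ValueError("code_value must be non-empty")
        if not self.scheme:
            raise ValueError("coding scheme designator must be non-empty")

    def to_item(self) -> Dataset:
        """Encode as one item of a DICOM code sequence."""
        item = Dataset()
        item.CodeValue = self.code_value
        item.CodingSchemeDesignator = self.scheme
        item.CodeMeaning = self.meaning
        return item

    @classmethod
    def from_item(cls, item: Dataset) -> "CodedConcept":
        return cls(
            code_value=str(item.CodeValue),
            scheme=str(item.CodingSchemeDesignator),
            meaning=str(getattr(item, "CodeMeaning", "")),
        )


def oid_from_uuid_int(value: int) -> str:
    """OID for a 128-bit UUID integer: ``"2.25."`` + base-10 encoding.

    Exposed separately from :func:`generate_oid` so deterministic encodings
    (including edge values) can be exercised directly.
    """
    if not 0 <= value < 1 << 128:
        raise ValueError("UUID integer out of 128-bit range")
    return f"2.25.{value:d}"


class UidGenerator:
    """Seedable source of UUID-derived DICOM UIDs.

    Draws 128 random bits per UID, forces the version-4 / RFC 4122 variant
    bits, and encodes the result as an OID.  With a fixed seed the sequence
    of UIDs is fully reproducible.
    """

    def __init__(self, seed: int | None = None):
        self._rng = random.Random(seed)

    def __call__(self) -> str:
        u = uuid.UUID(int=self._rng.getrandbits(128), version=4)
        return oid_from_uuid_int(u.int)

    def __iter__(self) -> Iterator[str]:
        while True:
            yield self()


def generate_oid(rng: random.Random | UidGenerator | None = None) -> str:
    """Mint one fresh UID under the ``2.25.`` OID policy.

    ``rng`` may be a :class:`UidGenerator`, a ``random.Random`` (128 bits are
    drawn from it), or ``None`` for an unseeded draw.
    """
    if isinstance(rng, UidGenerator):
        return rng()
    if rng is None:
        u = uuid.uuid4()
    else:
        u = uuid.UUID(int=rng.getrandbits(128), version=4)
    return oid_from_uuid_int(u.int)


def validate_uid(candidate: str) -> tuple[bool, str]:
    """Check a string against the DICOM UI / OID rules.

    Returns ``(ok, reason)``; ``reason`` is empty when valid and names the
    violated rule otherwise.  Never raises.
    """
    if not isinstance(candidate, str) or not candidate:
        return False, "empty or non-string UID"
    if len(candidate) > UID_MAX_LEN:
        return False, f"UID longer than {UID_MAX_LEN} characters"
    if not _UID_RE.match(candidate):
        return False, "UID must be dot-separated non-empty numeric components"
    for comp in candidate.split("."):
        if len(comp) > 1 and comp[0] == "0":
            return False, f"component {comp!r} has a leading zero"
    return True, ""


def encode_dicom_date(date: _dt.date) -> str:
    """Encode a calendar date as an 8-character DICOM DA string (YYYYMMDD)."""
    if not isinstance(date, _dt.date):
        raise TypeError(f"expected datetime.date, got {type(date).__name__}")
    return f"{date.year:04d}{date.month:02d}{date.day:02d}"


_ISO_RE = re.compile(r"^(\d{4})-(\d{1,2})-(\d{1,2})$")
_MDY_RE = re.compile(r"^(\d{1,2})/(\d{1,2})/(\d{4})$")
_DA_RE = re.compile(r"^(\d{4})(\d{2})(\d{2})$")


def parse_sheet_date(text: str) -> _dt.date:
    """Parse a tracking-sheet date cell.

    Accepts ISO 8601 (``2019-07-22``), the US spreadsheet dialect
    (``7/22/2019``), and already-encoded DA strings (``20190722``).
    """
    text = text.strip()
    for pat, order in ((_ISO_RE, (0, 1, 2)), (_MDY_RE, (2, 0, 1)), (_DA_RE, (0, 1, 2))):
        m = pat.match(text)
        if m:
            g = m.groups()
            y, mo, d = (int(g[i]) for i in order)
            return _dt.date(y, mo, d)  # raises ValueError on impossible dates
    raise ValueError(f"unparseable date: {text!r}")


def read_part10(path: str | Path) -> Dataset:
    """Read a DICOM Part 10 file."""
    return pydicom.dcmread(str(path))


def write_part10(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset as Part 10 with explicit VR little endian.

    Builds file meta from the dataset's SOP class/instance and enforces the
    64-character UI limit on every UID element before writing.
    """
    for elem in dataset.iterall():
        if elem.VR == "UI":
            values = elem.value if isinstance(elem.value, (list, tuple)) else [elem.value]
            for v in values:
                if v is not None and len(str(v)) > UID_MAX_LEN:
                    raise ValueError(
                        f"UI element {elem.tag} exceeds {UID_MAX_LEN} characters: {v!r}"
                    )
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = dataset.SOPClassUID
    meta.MediaStorageSOPInstanceUID = dataset.SOPInstanceUID
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    dataset.file_meta = meta
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dataset.save_as(str(path), enforce_file_format=True, little_endian=True, implicit_vr=False)
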