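# Methods

## Scope and model

The toolkit implements two curation operations around multi-subject
("mouse hotel") small-animal imaging, plus the validators and synthetic
fixtures needed to exercise them offline.

**Acquisition-context SR.** Each subject's experimental context is encoded
as a DICOM structured report conforming to the Pre-clinical Small Animal
Image Acquisition Context template (template identifier 8101, mapping
resource DCMR). Only the subtree needed for graft-bearing subjects is
produced: the observation context (language, country, person observer) and
the exogenous-substance container holding the tumor graft with its
properties — implant and excision dates, specimen identifier (in the Brand
Name slot), administration route, implantation site with optional
laterality modifier, tissue of origin and taxon of origin. The template
also defines branches for anesthesia, housing and biosafety; these are
accepted by the validator when present in third-party documents (as
warnings, never errors) but are not generated, because their encodings are
not fixed by the use case this toolkit serves. Date-valued items are
encoded date-only (8-character `YYYYMMDD`), matching how tracking sheets
record them.

Every coded slot is filled through a lexicon mapping normalized free-text
terms (case- and whitespace-insensitive) to (code value, scheme designator,
code meaning) triples. The shipped lexicon covers the concepts the toolkit's
reference workflow uses — melanoma graft, subcutaneous route, flank,
right/left laterality, skin, *Homo sapiens*, *Mus musculus*, and the NOD
scid gamma strain under the MGI_2013 nomenclature — and is user-extensible
via JSON. An unknown term is a hard error: silently emitting uncoded text
into a coded slot would defeat the interoperability purpose of the SR.

The augmented patient module records what a scanner console cannot:
Anatomical Orientation Type `QUADRUPED`, the species description and code
sequence, and the strain description, nomenclature and code sequence. A
strain without a lexicon code keeps its description and nomenclature but
omits the code sequence.

**Splitting.** A multi-subject series is tiled into `n_rows × n_cols` equal
in-plane regions of `floor(rows/n_rows) × floor(cols/n_cols)` pixels;
remainder pixels at the high-index edges belong to no region and are
dropped with a logged warning (equal region sizes are kept literal; an
unequal last region would silently give one subject a different field of
view). Slots are numbered row-major from the top-left of the stored pixel
matrix, 1-based; an `occupied` set lets callers skip empty bore positions.
An optional `n_stacks` axis additionally partitions the slice stack into
equal contiguous runs along the bore for sequentially arranged animals;
the default is in-plane only.

Geometry is updated by pure translation. With row-direction cosines `u`,
column-direction cosines `v`, pixel spacing (Δr, Δc) and a crop offset
(r₀, c₀), each derived slice's position becomes
`IPP + c₀·Δc·u + r₀·Δr·v` — the source location of the region's first
voxel — while pixel spacing and orientation are copied bit-identically.
This makes the derived voxel-to-patient affine agree with the source affine
at every voxel, which the validator and tests check to 1e-6 mm. The frame
of reference UID is intentionally retained: derived coordinates remain
expressed in the source frame, preserving cross-subject spatial
relationships.

Identity rewriting touches exactly: SOP instance UID, derivation
description, derivation image sequence (one source-image reference carrying
the original SOP class and instance UIDs; no derivation code sequence is
invented), patient name and ID (rendered from templates
`{orig_name}_{slot}` / `{orig_id}_{slot}` by default — site conventions
vary, so both are configurable), the source patient group identification
sequence (one item with the original name and ID), study and series
instance UIDs, series number (default rule `original·100 + slot`), and the
storage-media file-set UID when the source carried one. Rows, Columns,
image position and the first ImageType value (`DERIVED`) change as a
consequence of cropping. Everything else is copied verbatim, and the
attribute-conservation audit enforces that the diff is confined to this
set. One fresh study UID is minted per (source study, slot) and shared
across all series of that slot split in one invocation, so a subject's
multi-sequence session remains a single study. Enhanced multi-frame
objects are rejected with a clear error; the pipeline addresses classic
single-frame series.

**UIDs.** All minted identifiers are `2.25.` followed by the decimal
encoding of a random version-4 UUID (the X.667 OID form), at most 44
characters. The generator is seedable: identical inputs and seed produce
byte-identical SR files and split output, which is what makes batch runs
reproducible and auditable. UID validity (numeric dot-separated components,
no leading zeros, ≤ 64 characters) is enforced both at minting and on
Part 10 write.

## Parameters that matter

| Parameter | Default | Why |
|---|---|---|
| grid `n_rows × n_cols` | 2 × 2 | the common four-mouse cradle layout |
| `occupied` | all slots | empty bore positions are skipped by listing slots |
| naming templates | `{orig_id}_{slot}`, `{orig_name}_{slot}` | deliberately simple; site conventions are unpublished, so no claim of matching any particular site |
| series number rule | `orig·100 + slot` | keeps derived numbers sortable under the original |
| language / country | eng (RFC5646) / US (ISO3166_1) | overridable per site |
| SR completion / verification | COMPLETE / UNVERIFIED | least-claim defaults for machine-generated documents |
| geometry tolerance | 1e-6 mm | far below any voxel size; catches logic errors, not float noise |

## Synthetic fixtures

The phantom generator emulates only what the splitter contract needs: a
classic single-frame MR series (type-1 image-module attributes, uint16
pixels) with one axis-aligned ellipsoidal blob of distinct intensity per
occupied grid cell, optional seeded Gaussian noise, and four orientation
presets (axial, coronal, sagittal, and an oblique produced by rotating the
axial frame 30° about z and 20° about x). Ground truth records each blob's
slot, index-space and patient-space centroid, intensity and voxel count.
It does not emulate mouse anatomy, coil or noise physics, intensity
inhomogeneity, or scanner-specific private attributes — so passing tests
demonstrate geometric and structural correctness of the split, not
robustness to vendor quirks in real headers. Test problem sizes (64×64
matrices, 4 slices, 20-phantom batches) were chosen to exercise every
orientation preset and every code path at comfortably interactive runtimes;
the operations are linear in voxel count and carry over unchanged to
clinical-size matrices.

The sheet generator draws every term from the shipped lexicon (guaranteeing
buildability), generates consistent implant/excision dates (excision absent
in ~20% of rows, exercising the optional-field paths), and varies laterality
across right/left/absent. It emulates column layout and value dialects, not
the messiness of real spreadsheets (merged cells, stray notes, locale
formats beyond ISO 8601 / M/D/YYYY / `YYYYMMDD`).

## Numerical and design choices

- Region arithmetic is integer floor division; no resampling, rotation or
  interpolation anywhere — the split is exact cropping by construction.
- Orientation labelling takes the principal axis of the slice normal
  `n = u × v` with ties broken trans-axial → coronal → sagittal.
- SR content date/time defaults to the implant date at 000000 rather than
  the wall clock, keeping builds deterministic; callers can override.
- The SR validator walks raw content items rather than the typed tree, so a
  structurally defective document (e.g. a code missing its scheme) yields a
  finding with a content-item path instead of a parse failure. Unknown
  additional content items are warnings: the full template is wider than
  the produced subtree, and strictness there would be guesswork.
- Record extraction from an SR uses the lexicon in reverse (concept →
  canonical term), so round trips are exact for sheets written with
  canonical spellings; a sheet using an alias (e.g. lowercase) round-trips
  to the canonical spelling, which is the intended normalization.
- UID equality of a re-used seed: feeding the same seed to a fixture
  generator and to the splitter replays the same UUID stream, so the
  splitter's freshness audit treats it as a collision. Distinct seeds per
  role are the supported pattern; the CLI derives all UIDs of one run from
  one `--seed`, which is safe because fixture generation and splitting are
  separate invocations.

## Known limitations

- Only the paper-exercised template subtree is generated; anesthesia,
  housing and biosafety branches are out of scope.
- No automatic animal detection: regions are user-specified, as in the
  interactive workflow this replaces.
- Compressed transfer syntaxes are not transcoded; inputs are expected in
  (or convertible to) explicit VR little endian, which is also the only
  output transfer syntax.
- The validators check what this toolkit writes, not full IOD conformance;
  they are not a general-purpose DICOM verifier.
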