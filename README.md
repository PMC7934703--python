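# mousehotel

Pre-clinical small-animal DICOM curation: acquisition-context structured
reports and multi-mouse image splitting.

## The problem

Small-animal imaging labs track their animals — strain, tumor graft, implant
and excision dates, injection route and site — in spreadsheets, while the
scanners emit DICOM with almost none of that context. And because scanners
image several mice at once ("mouse hotels") for throughput, a stored series
often contains four animals sharing one patient record and one set of UIDs,
which makes one-to-one queries against clinical archives impossible.

`mousehotel` closes both gaps:

1. **Acquisition-context SR builder** — converts each row of a tab-delimited
   tracking sheet into a DICOM Pre-clinical Small Animal Image Acquisition
   Context structured report (template 8101 of the DCMR mapping resource).
   Free-text terms are resolved to coded concepts (SNOMED CT, DICOM-defined
   DCM codes, Mouse Genome Informatics strain codes) through a shipped,
   user-extensible lexicon; unknown terms are hard errors, never silent
   free-text leaks into coded slots. The augmented patient module carries
   Anatomical Orientation Type `QUADRUPED`, the species code sequence
   (e.g. *Mus musculus* → SCT 447612001) and the strain code sequence
   (e.g. NOD scid gamma → MGI 3577020).

2. **Multi-mouse splitter** — tiles a multi-subject series into equal
   in-plane regions (optionally equal slice slabs along the bore), crops each
   region into its own series, and updates the patient-space geometry. With
   row direction `u`, column direction `v` (the six orientation cosines) and
   pixel spacing (Δr, Δc), a slice cropped at pixel offset (r₀, c₀) gets

   ```
   IPP' = IPP + c₀·Δc·u + r₀·Δr·v
   ```

   so every derived voxel keeps exactly its original patient coordinate —
   pixel spacing and orientation are never touched. Each subject gets fresh
   UIDs minted as `2.25.<decimal uuid4>` OIDs, a templated patient name/ID,
   and provenance back to the source: a derivation description, a derivation
   image sequence referencing the original SOP instance, and the source
   patient group identification sequence holding the original name and ID.

Native validators audit both artifacts, and a fixture module generates
phantom multi-mouse series and synthetic tracking sheets with known ground
truth, so the whole pipeline is testable offline.

## Worked example

```python
from mousehotel import (
    Lexicon, UidGenerator, build_acquisition_context_tree,
    build_patient_module, sr_tree_to_dataset, validate_sr,
    worked_example_record,
)

lexicon = Lexicon.default()
record = worked_example_record()   # melanoma PDX, implanted 2019-07-22
tree = build_acquisition_context_tree(record, lexicon)
for node in tree.walk():
    name = node.concept_name
    value = node.value
    if hasattr(value, "code_value"):
        value = f"({value.code_value},{value.scheme},{value.meaning})"
    print(f"{node.relationship or 'ROOT'}: {node.value_type}: "
          f"({name.code_value},{name.scheme}) = {value}")

sr = sr_tree_to_dataset(tree, build_patient_module(record, lexicon),
                        UidGenerator(seed=1))
print("valid:", validate_sr(sr).passed)
```

prints the full content tree of the acquisition-context document:

```
ROOT: CONTAINER: (127001,DCM) = None
HAS CONCEPT MOD: CODE: (121049,DCM) = (eng,RFC5646,English)
HAS CONCEPT MOD: CODE: (121046,DCM) = (US,ISO3166_1,United States)
HAS OBS CONTEXT: PNAME: (121008,DCM) = SAIP^Imager
CONTAINS: CONTAINER: (127400,DCM) = None
CONTAINS: CODE: (127460,DCM) = (2092003,SCT,Melanoma)
HAS PROPERTIES: DATETIME: (111526,DCM) = 20190722
HAS PROPERTIES: DATETIME: (111527,DCM) = 20190904
HAS PROPERTIES: TEXT: (111529,DCM) = 425362-245-T
HAS PROPERTIES: CODE: (410675002,SCT) = (34206005,SCT,Subcutaneous route)
HAS PROPERTIES: CODE: (272737002,SCT) = (58602004,SCT,Flank)
HAS CONCEPT MOD: CODE: (272741003,SCT) = (24028007,SCT,Right)
HAS PROPERTIES: CODE: (127401,DCM) = (39937001,SCT,Skin)
HAS PROPERTIES: CODE: (127402,DCM) = (337915000,SCT,Homo sapiens)
valid: True
```

— the exogenous-substance subtree records a human melanoma graft (specimen
425362-245-T) implanted subcutaneously in the right flank, with skin as the
tissue of origin and *Homo sapiens* as the taxon of origin.

Splitting a four-mouse phantom from the shell:

```sh
mousehotel fixtures-phantom --out series/ --seed 5
echo '{"n_rows": 2, "n_cols": 2}' > plan.json
mousehotel split --in series/ --out split/ --plan plan.json --seed 9
# -> wrote 40 slice(s) across 4 subject(s) to split
mousehotel validate-split --in series/ --out split/
# -> {"passed": true, "findings": []}   (exit code 0)
```

Each subject directory (`MM001_1` … `MM001_4`) holds one derived series;
`split_map.json` maps every derived SOP instance UID back to its source.
Re-running with the same seed reproduces byte-identical output.

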