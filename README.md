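# icd2iss

Automated trauma-severity scoring from German routine diagnosis data:
**ICD-10-GM → ICD-10-CM → AIS → ISS**, plus the statistical machinery to
validate automatic scores against a manual gold standard.

## The problem

The Injury Severity Score (ISS) grades overall anatomic trauma severity.
The body is divided into six regions (head/neck, face, thorax, abdomen,
extremities incl. pelvic girdle, external); each injury receives an
Abbreviated Injury Scale (AIS) severity 1–6, and

```
ISS = a² + b² + c²
```

where *a, b, c* are the highest AIS values of the three most severely
injured regions (range 0–75; ISS ≥ 16 defines severe polytrauma). Manual
AIS coding is the gold standard but slow and needs trained coders. US
hospitals can score ICD-10-CM discharge codes automatically through
GEM-based crosswalk tables, but German hospitals code in ICD-10-GM, a
six-character billing format those tools cannot read.

`icd2iss` closes that gap for registry and epidemiology work:

1. **Re-coding** (`gm_to_cm`) — GM codes are mapped onto CM stems via a
   reviewed substitution table (e.g. GM `S22.03`, fracture of the 5th/6th
   thoracic vertebra, becomes CM `S22.05`), "!"-suffixed GM secondary
   detail codes (e.g. the `S06.7-!` unconsciousness family) are folded into
   the CM *seventh character* via a policy table, and every code is padded
   to the canonical eight-character form with encounter character `A`.
2. **Scoring** (`ais_iss`) — canonical CM codes are resolved through a
   GEM-style longest-prefix lookup table to (AIS severity, body region);
   multi-valued candidate sets are resolved by **GEMmax** (highest) or
   **GEMmin** (lowest); per-region maxima give the ISS and its group
   (1: 0–8, 2: 9–15, 3: 16–24, 4: 25–40, 5: 41–49, 6: 50–75).
3. **Validation** (`agreement_stats`) — paired manual/automatic scores are
   compared with the two one-sided tests (TOST) procedure at equivalence
   bounds ±3 ISS points together with a Wilcoxon signed-rank NHST
   (equivalence requires a significant TOST *and* a non-significant NHST),
   linearly weighted Cohen's kappa on the 6×6 group cross-tabulation,
   per-group absolute-difference summaries, Bonferroni correction, and a
   TOST power/sample-size routine for paired designs.
4. **Synthesis** (`synthetic`) — fixture crosswalk/AIS tables covering the
   worked examples, a generator for cohorts with known ground-truth
   profiles, and a paired-score generator with a calibrated disagreement
   model, so everything is testable without patient data.

All crosswalk, policy, and AIS tables are **pluggable TSV files**; the
shipped fixtures cover the documented examples, and full review tables are
drop-in replacements.

## Worked example

```bash
icd2iss simulate --n 200 --seed 7 --out cohort.csv
icd2iss convert  --in cohort.csv --out cm.csv
icd2iss score    --in cm.csv --mode gemmax --out scored.csv
icd2iss simulate --paired --n 640 --seed 1 --out pairs.csv
icd2iss compare  --in pairs.csv --out report.json
# stderr: n=640 kappa=0.47 (moderate) overall equivalent=True
```

Each command writes a `*.manifest.json` with option values and table
checksums so runs can be reproduced exactly.

The same pipeline in Python, on the subdural-haematoma example:

```python
import pandas as pd
from icd2iss import gm_to_cm, ais_iss, synthetic
from icd2iss.icd_codes import parse_gm

rules, pol = synthetic.default_rules(), synthetic.default_policies()
dmap, ais = synthetic.default_detail_map(), synthetic.default_ais_table()

codes = [parse_gm("S06.5"), parse_gm("S06.73!")]   # SDH + "LOC > 24 h, no return"
injuries, ann = gm_to_cm.collect_details(codes, dmap)
cm = gm_to_cm.to_cm(injuries[0], ann, rules, pol).cm
print(cm.canonical)                                # S06.5X6A
frame = pd.DataFrame({"patient_id": ["p"], "cm_code": [cm.canonical]})
print(ais_iss.score_cohort(frame, ais).iloc[0][["ais_head_neck", "iss"]])
# ais_head_neck 5, iss 25   (without the detail code: AIS 4, ISS 16)
```

A subdural haematoma maps to AIS 4 by default; the German detail code for
unconsciousness beyond 24 hours without return selects the CM seventh
character `6`, whose table row carries AIS 5 — so the ISS rises from 16
to 25.

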