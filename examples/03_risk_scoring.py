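"""Clinical-genomic (Spratt) risk labeling of lesions and patients.

NCCN group (0-3) and Decipher category (0-2) are summed into a six-tier
score and collapsed to three tiers; a lesion is low risk iff (NCCN low
and Decipher low/intermediate) or (NCCN low-or-intermediate and Decipher
low).  A patient is low risk only when all lesions are.
"""

import itertools

from radiorisk.io import ClinicalRecord
from radiorisk.risk import (
    DecipherCategory,
    NccnGroup,
    lesion_labels,
    patient_label,
    spratt_labels,
)

rec = ClinicalRecord(age=64, psa=6.2, prostate_volume=38.0, dre=0,
                     pirads=4, t_stage="T1c", grade_group=1)
lab = lesion_labels(rec, decipher_score=0.52)
print(f"example lesion: NCCN={lab.nccn_group.name}, "
      f"Decipher={lab.decipher_category.name}, numeric={lab.spratt_numeric}, "
      f"tier={lab.three_tier.name}, low_risk={lab.low_risk}")

print("\nfull 12-cell (NCCN x Decipher) map (numeric / tier / low?):")
for nccn in NccnGroup:
    row = []
    for dec in DecipherCategory:
        cell = spratt_labels(nccn, dec)
        row.append(f"{cell.spratt_numeric}/{cell.three_tier.name[:3]}"
                   f"{'*' if cell.low_risk else ' '}")
    print(f"  NCCN {int(nccn)}: " + "  ".join(row))
print("  (* = low risk)")

lesions = [lesion_labels(rec, 0.2), lesion_labels(rec, 0.7)]
patient = patient_label(lesions)
print(f"\npatient with lesions {[l.three_tier.name for l in lesions]} "
      f"-> {patient.three_tier.name} (worst lesion dominates)")
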