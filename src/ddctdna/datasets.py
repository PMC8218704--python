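"""Bundled reference inputs from a published pediatric HGG/DMG liquid-biopsy
feasibility study.

The study assayed 43 biofluid samples (27 plasma, 6 serum, 9 CSF, 1 cystic
fluid) from 32 patients by droplet digital PCR and tabulated the 16 samples
with detectable ctDNA: droplet counts, printed VAFs (count-ratio, percent, 3
decimals) and per-allele cfDNA concentrations (ng/mL). The limit-of-detection
validation compared two H3F3A_K27M assays (neat fractional abundances 79.3%
and 79.1%), both detectable down to the 1:100 dilution of the
1:10–1:10,000 series.

These are small printed tables, bundled so analyses and tests run without any
external download.
"""

from __future__ import annotations

import pandas as pd

from .io_formats import SampleRecord

#: assayed samples per biofluid in the feasibility cohort
COHORT_SIZES = {"plasma": 27, "serum": 6, "csf": 9, "cyst": 1}

_DETECTED = [
    # patient_id, assay_id, sample_type, volume_ml, vaf_pct, n_mut, n_wt, cfdna_mut, cfdna_wt
    ("013-T", "H3F3A-K27M", "plasma", 2.7, 2.451, 10, 398, 0.028, 1.131),
    ("045-T", "TP53-R282W", "csf", 5.0, 49.343, 3945, 4050, 271.913, 279.585),
    ("045-T", "TP53-R282W", "plasma", 5.0, 0.118, 3, 2540, 0.021, 18.313),
    ("054-T", "H3F3A-G34R", "plasma", 5.0, 0.468, 2, 425, 0.007, 1.561),
    ("106-T", "IDH1-R132H", "plasma", 3.5, 0.335, 11, 3272, 0.029, 8.844),
    ("120-T", "H3F3A-G34R", "plasma", 3.0, 1.143, 2, 173, 0.005, 0.422),
    ("131-T", "H3F3A-K27M", "cyst", 38.5, 42.680, 10944, 14698, 367.594, 541.671),
    ("131-T", "H3F3A-K27M", "plasma", 2.0, 0.850, 3, 350, 0.009, 1.048),
    ("15-3381", "H3F3A-K27M", "csf", 1.0, 3.646, 7, 185, 0.044, 1.177),
    ("16120B", "PIK3CA-E542K", "serum", 2.0, 0.072, 7, 9674, 0.291, 472.795),
    ("ICR-B134", "H3F3A-K27M", "serum", 1.3, 0.390, 2, 511, 0.015, 3.934),
    ("ICR-B276", "PIK3CA-H1047R", "plasma", 2.0, 0.116, 2, 1727, 0.006, 5.098),
    ("ICR-CXJ-026", "TP53-C238Y", "csf", 2.5, 2.073, 4, 189, 0.013, 0.633),
    ("ICR-CXJ-028", "ACVR1-G328V", "csf", 1.8, 35.737, 446, 802, 1.472, 2.662),
    ("I-16-3200", "H3F3A-K27M", "csf", 0.7, 0.051, 3, 5916, 0.071, 159.274),
    ("I-16-855", "H3F3A-K27M", "csf", 1.5, 1.149, 9, 774, 0.054, 4.703),
]

_COLUMNS = [
    "patient_id", "assay_id", "sample_type", "volume_ml",
    "vaf_pct", "mutant_droplets", "wildtype_droplets",
    "cfdna_mut_ng_ml", "cfdna_wt_ng_ml",
]

#: limit-of-detection validation of the two H3F3A_K27M assays:
#: neat fractional abundance and the deepest dilution factor with >= 2
#: mutant droplets (the 1:1000 and 1:10,000 points were not detectable)
LOD_VALIDATION = {
    "H3F3A-K27M-commercial": {"neat_af": 0.793, "deepest_detectable_factor": 100},
    "H3F3A-K27M-custom": {"neat_af": 0.791, "deepest_detectable_factor": 100},
}

#: dilution factors of the serial-dilution LoD design
LOD_DILUTION_FACTORS = (10, 100, 1000, 10000)


def detected_samples() -> pd.DataFrame:
    """The 16 detected ctDNA samples as a DataFrame (one row per sample)."""
    return pd.DataFrame(_DETECTED, columns=_COLUMNS)


def detected_sample_records() -> list[tuple[tuple[int, int], SampleRecord]]:
    """Detected samples as ((n_mut, n_wt), SampleRecord) pairs for the pipeline."""
    pairs = []
    for row in _DETECTED:
        pid, assay, stype, vol, _vaf, n_mut, n_wt, _cm, _cw = row
        pairs.append(
            (
                (n_mut, n_wt),
                SampleRecord(
                    patient_id=pid, sample_type=stype, assay_id=assay, biofluid_volume_ml=vol
                ),
            )
        )
    return pairs
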