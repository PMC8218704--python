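"""Quantify a single liquid-biopsy well from its droplet tallies.

A CSF well with 15,000 accepted droplets, 3,945 mutant-positive and 4,050
wild-type-positive, extracted from 5 mL of CSF with a 20 µL PCR loaded with
10 of 50 µL of eluate.
"""

from ddctdna import ReactionSetup, SampleRecord, WellCounts, run_sample

setup = ReactionSetup(v_pcr=20.0, v_elu=50.0, v_dna_pcr=10.0)
sample = SampleRecord(
    patient_id="045-T", sample_type="csf", assay_id="TP53-R282W", biofluid_volume_ml=5.0
)
counts = WellCounts(n_total=15000, n_mut=3945, n_wt=4050, n_double=1060)

result = run_sample(counts, setup, sample)

print(f"sample            : {result.sample_id} ({result.sample_type}, {result.assay_id})")
print(f"VAF (count ratio) : {100 * result.af:.3f} %")
print(f"C_MUT             : {result.c_mut:.1f} copies/uL PCR mix")
print(f"C_MUT_ori         : {result.c_mut_ori:.0f} copies/mL CSF")
print(f"cfDNA (mut/wt)    : {result.ccfdna_mut:.3f} / {result.ccfdna_wt:.3f} ng/mL")
print(f"positive (>=2 mutant droplets): {result.positive}")
# The VAF is the mutant share of all template-bearing droplets; the ng/mL
# figures convert back-calculated copies/mL to mass via 0.003 ng per haploid
# genome. A sample is called ctDNA-positive at two or more mutant droplets.
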