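"""Filter raw fusion-panel candidates through the six-rule rejection chain."""

from ddctdna.fusion import (
    Breakpoint,
    CaptureSet,
    FilterResources,
    FusionCandidate,
    filter_candidates,
)

resources = FilterResources(
    capture_set=CaptureSet([("chr12", 11_800_000, 12_050_000),
                            ("chr15", 87_900_000, 88_100_000)]),
    blocklist_positions=frozenset({("chr12", 12_000_000)}),
    blocklist_gene_pairs=frozenset({frozenset({"FGFR3", "TACC3"})}),
)

candidates = [
    FusionCandidate("ETV6", "NTRK3", Breakpoint("chr12", 11_869_969),
                    Breakpoint("chr15", 88_010_000), 23, 23, homology_length=5),
    FusionCandidate("ETV6", "ETV6", Breakpoint("chr12", 11_870_000),
                    Breakpoint("chr12", 11_900_000), 8, 8),
    FusionCandidate("BRAF", "MET", Breakpoint("chr7", 100), Breakpoint("chr7", 999),
                    12, 12),
    FusionCandidate("ETV6", "NTRK3", Breakpoint("chr12", 11_869_969),
                    Breakpoint("chr15", 88_010_000), 2, 23, homology_length=15),
]

retained, rejected = filter_candidates(candidates, resources)
for cand in retained:
    print(f"RETAIN {cand.gene5}:{cand.gene3} "
          f"(reads {cand.supporting_reads_gene5}/{cand.supporting_reads_gene3})")
for rej in rejected:
    print(f"REJECT {rej.candidate.gene5}:{rej.candidate.gene3} -> "
          f"{', '.join(rej.failed_rules)}")
# The well-supported in-capture ETV6:NTRK3 junction survives; the intragenic,
# off-panel and under-supported/high-homology candidates are rejected with the
# rule(s) that fired.
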