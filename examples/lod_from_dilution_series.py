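"""Limit of detection from a serial-dilution experiment.

Mutant DNA with a neat fractional abundance of 79.3% is diluted 1:10 to
1:10,000 into constant wild-type background and run in duplicate; a point is
detectable at >= 2 pooled mutant droplets.
"""

from ddctdna import DilutionPoint, compute_lod, summarize_lod_panel

series = [
    DilutionPoint(10, (131, 132)),
    DilutionPoint(100, (13, 13)),
    DilutionPoint(1000, (1, 0)),     # a single stray droplet: not detectable
    DilutionPoint(10000, (0, 0)),
]

result = compute_lod(neat_af=0.793, series=series)
print(f"deepest detectable dilution : 1:{result.lowest_detectable_factor:g}")
print(f"limit of detection          : {100 * result.lod:.3f} %")

# Pool several assays' LoDs into a panel summary (range and median):
panel = summarize_lod_panel([0.00041, 0.00203, 0.00793, 0.00993])
print(f"panel LoD range {100 * panel.min:.3f}-{100 * panel.max:.3f} %, "
      f"median {100 * panel.median:.3f} %")
# The LoD is the neat abundance divided by the deepest dilution that still
# shows mutant signal — here 79.3% / 100 = 0.793%.
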