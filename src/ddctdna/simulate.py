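"""Synthetic droplet-level and cohort-level data generation.

The simulator emulates the physical process a droplet reader observes:

* a known DNA mass (default 5 ng) is converted to haploid genome copies using
  0.003 ng per haploid genome (~1667 copies), split into mutant and wild-type
  template copies by the designed allele fraction;
* copies partition at random into ~15,000 nanoliter droplets — per-droplet
  occupancies are independent Poisson draws with mean copies/n_droplets
  (default), or an exact multinomial scatter that conserves totals;
* each droplet's two fluorescence amplitudes are drawn from its channel's
  positive cluster when it holds at least one template of that allele, else
  from the negative cluster; optional "rain" (intermediate amplitudes) and
  per-droplet false positives probe classifier robustness.

Every ground truth (template counts, per-droplet occupancies and labels) is
returned alongside the amplitude table so downstream stages can be scored
exactly. Randomness is reproducible: a master seed spawns per-well child
streams through numpy's SeedSequence, so replicates differ but runs repeat.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import WellCounts
from .errors import ValidationError
from .io_formats import AmplitudeTable, SampleRecord
from .lod import DilutionPoint


@dataclass(frozen=True)
class ChannelClusters:
    """Amplitude cluster parameters for one fluorescence channel."""

    neg_mean: float = 1000.0
    neg_sd: float = 150.0
    pos_mean: float = 8000.0
    pos_sd: float = 300.0

    def __post_init__(self) -> None:
        if self.neg_sd <= 0 or self.pos_sd <= 0:
            raise ValidationError("cluster SDs must be positive")
        if self.neg_mean < 0 or self.pos_mean <= self.neg_mean:
            raise ValidationError("positive cluster mean must exceed negative cluster mean")


@dataclass(frozen=True)
class SimulationDesign:
    """Study conditions for one simulated well.

    Defaults mirror the assay-validation design: ~15,000 droplets of 0.85 nL,
    5 ng DNA input (≈1667 haploid copies at 0.003 ng/genome), and cleanly
    separated amplitude clusters; rain and false positives are off by default.
    """

    n_droplets: int = 15000
    droplet_volume_nl: float = 0.85
    dna_input_ng: float = 5.0
    true_vaf: float = 0.01
    genome_mass_ng: float = 0.003
    ch1: ChannelClusters = field(default_factory=ChannelClusters)
    ch2: ChannelClusters = field(default_factory=ChannelClusters)
    rain_fraction: float = 0.0
    false_positive_rate: float = 0.0
    partitioning: str = "poisson"  # or "multinomial"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_droplets <= 0:
            raise ValidationError("n_droplets must be positive")
        if not (0.0 <= self.true_vaf <= 1.0):
            raise ValidationError("true_vaf must lie in [0, 1]")
        if self.dna_input_ng < 0 or self.genome_mass_ng <= 0:
            raise ValidationError("dna_input_ng >= 0 and genome_mass_ng > 0 required")
        for name in ("rain_fraction", "false_positive_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.partitioning not in ("poisson", "multinomial"):
            raise ValidationError("partitioning must be 'poisson' or 'multinomial'")

    def template_copies(self) -> tuple[int, int]:
        """(mutant, wild-type) template copies implied by mass, genome size and VAF."""
        total = self.dna_input_ng / self.genome_mass_ng
        mut = round(total * self.true_vaf)
        wt = round(total) - mut
        return int(mut), int(wt)


@dataclass
class SimulatedWell:
    """One simulated well with full ground truth."""

    table: AmplitudeTable
    labels: np.ndarray                 # 'empty' | 'mut' | 'wt' | 'double', pre-noise
    mut_occupancy: np.ndarray          # template copies per droplet, mutant allele
    wt_occupancy: np.ndarray
    n_mut_templates: int
    n_wt_templates: int
    partitioning: str

    def true_counts(self) -> WellCounts:
        """Ground-truth WellCounts from template occupancies (channel totals include doubles)."""
        mut = self.mut_occupancy >= 1
        wt = self.wt_occupancy >= 1
        return WellCounts(
            n_total=len(self.table),
            n_mut=int(mut.sum()),
            n_wt=int(wt.sum()),
            n_double=int((mut & wt).sum()),
        )


def _partition(copies: int, n: int, mode: str, rng: np.random.Generator) -> np.ndarray:
    if mode == "multinomial":
        return rng.multinomial(copies, np.full(n, 1.0 / n))
    return rng.poisson(copies / n, size=n)


def _amplitudes(
    occupied: np.ndarray, clusters: ChannelClusters, design: SimulationDesign,
    rng: np.random.Generator,
) -> np.ndarray:
    n = occupied.size
    amps = np.where(
        occupied,
        rng.normal(clusters.pos_mean, clusters.pos_sd, size=n),
        rng.normal(clusters.neg_mean, clusters.neg_sd, size=n),
    )
    if design.false_positive_rate > 0:
        flip = ~occupied & (rng.random(n) < design.false_positive_rate)
        amps[flip] = rng.normal(clusters.pos_mean, clusters.pos_sd, size=int(flip.sum()))
    if design.rain_fraction > 0:
        rain = rng.random(n) < design.rain_fraction
        amps[rain] = rng.uniform(clusters.neg_mean, clusters.pos_mean, size=int(rain.sum()))
    return np.clip(amps, 0.0, None)


def _simulate_from_copies(
    design: SimulationDesign,
    mut_copies: int,
    wt_copies: int,
    rng: np.random.Generator,
    well_id: str = "sim",
) -> SimulatedWell:
    n = design.n_droplets
    mut_occ = _partition(mut_copies, n, design.partitioning, rng)
    wt_occ = _partition(wt_copies, n, design.partitioning, rng)
    labels = np.full(n, "empty", dtype="U6")
    m, w = mut_occ >= 1, wt_occ >= 1
    labels[m & ~w] = "mut"
    labels[~m & w] = "wt"
    labels[m & w] = "double"
    table = AmplitudeTable(
        well_id=well_id,
        ch1=_amplitudes(m, design.ch1, design, rng),
        ch2=_amplitudes(w, design.ch2, design, rng),
    )
    return SimulatedWell(
        table=table,
        labels=labels,
        mut_occupancy=mut_occ,
        wt_occupancy=wt_occ,
        n_mut_templates=int(mut_occ.sum()) if design.partitioning == "poisson" else mut_copies,
        n_wt_templates=int(wt_occ.sum()) if design.partitioning == "poisson" else wt_copies,
        partitioning=design.partitioning,
    )


def simulate_well(
    design: SimulationDesign, rng: np.random.Generator | None = None, well_id: str = "sim"
) -> SimulatedWell:
    """Simulate one well under the given design, fully reproducible from its seed."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(design.seed))
    mut, wt = design.template_copies()
    return _simulate_from_copies(design, mut, wt, rng, well_id=well_id)


def simulate_dilution_series(
    neat_design: SimulationDesign,
    factors: Sequence[float] = (10, 100, 1000, 10000),
    replicates: int = 2,
    include_neat: bool = False,
) -> list[DilutionPoint]:
    """Simulate a serial dilution of mutant DNA into constant wild-type background.

    Mutant template copies are scaled by 1/factor; wild-type copies are held
    constant (the dilution design keeps the wild-type concentration fixed).
    Each point runs ``replicates`` wells with distinct child seeds spawned
    from the neat design's master seed. Droplet counts in the returned points
    are ground-truth occupancy counts (channel totals, doubles included).
    """
    if list(factors) != sorted(factors) or any(f < 1 for f in factors):
        raise ValidationError("factors must be sorted ascending and >= 1")
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    all_factors = ([1.0] if include_neat else []) + [float(f) for f in factors]
    mut_neat, wt_neat = neat_design.template_copies()
    children = np.random.SeedSequence(neat_design.seed).spawn(len(all_factors) * replicates)
    points = []
    for i, factor in enumerate(all_factors):
        mut_counts, wt_counts = [], []
        for r in range(replicates):
            rng = np.random.default_rng(children[i * replicates + r])
            well = _simulate_from_copies(
                neat_design, round(mut_neat / factor), wt_neat, rng,
                well_id=f"dil{factor:g}-r{r}",
            )
            counts = well.true_counts()
            mut_counts.append(counts.n_mut)
            wt_counts.append(counts.n_wt)
        points.append(
            DilutionPoint(
                dilution_factor=factor,
                mutant_counts=tuple(mut_counts),
                wt_counts=tuple(wt_counts),
            )
        )
    return points


@dataclass(frozen=True)
class FluidSpec:
    """Cohort-generator settings for one biofluid."""

    n_samples: int
    positivity: float                 # probability a sample carries detectable ctDNA
    median_vaf: float = 0.01          # median VAF of positive samples (log-normal)
    vaf_log_sd: float = 1.0           # SD of ln(VAF) for positive samples
    volume_mean_ml: float = 3.0
    volume_sd_ml: float = 1.0
    dna_input_ng: float = 5.0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValidationError("n_samples must be positive")
        if not (0.0 <= self.positivity <= 1.0):
            raise ValidationError("positivity must lie in [0, 1]")


def default_cohort_spec() -> dict[str, FluidSpec]:
    """Biofluid mix mirroring the feasibility cohort: 27 plasma, 6 serum, 9 CSF, 1 cyst.

    Positivity parameters equal the observed per-fluid detection fractions
    (7/27, 2/6, 6/9, 1/1); volumes match the reported per-fluid means/SDs.
    CSF-class fluids carry higher VAFs than blood-derived fluids.
    """
    return {
        "plasma": FluidSpec(27, 7 / 27, median_vaf=0.008, volume_mean_ml=3.14, volume_sd_ml=1.2),
        "serum": FluidSpec(6, 2 / 6, median_vaf=0.002, volume_mean_ml=2.0, volume_sd_ml=0.4),
        "csf": FluidSpec(9, 6 / 9, median_vaf=0.15, vaf_log_sd=1.5,
                         volume_mean_ml=1.74, volume_sd_ml=1.5),
        "cyst": FluidSpec(1, 1.0, median_vaf=0.4, volume_mean_ml=35.0, volume_sd_ml=1.0),
    }


def simulate_cohort(
    fluid_specs: Mapping[str, FluidSpec] | None = None,
    seed: int = 0,
    base_design: SimulationDesign | None = None,
) -> tuple[list[SampleRecord], dict[str, WellCounts], pd.DataFrame]:
    """Simulate a liquid-biopsy cohort with known per-sample truth.

    Each sample draws a zero-inflated true VAF (zero with probability
    1 − positivity, else log-normal around the fluid's median), then a well is
    simulated at that VAF and tallied by ground-truth occupancy. Returns
    (sample sheet records, per-sample WellCounts keyed by sample id, truth
    table with the drawn VAFs and template counts).
    """
    specs = fluid_specs if fluid_specs is not None else default_cohort_spec()
    base = base_design if base_design is not None else SimulationDesign()
    master = np.random.SeedSequence(seed)
    samples: list[SampleRecord] = []
    counts: dict[str, WellCounts] = {}
    truth_rows = []
    for fluid in sorted(specs):
        spec = specs[fluid]
        children = master.spawn(spec.n_samples)
        for i in range(spec.n_samples):
            rng = np.random.default_rng(children[i])
            sample_id = f"{fluid}-{i:03d}"
            is_positive = rng.random() < spec.positivity
            vaf = 0.0
            if is_positive:
                vaf = float(
                    np.clip(rng.lognormal(np.log(spec.median_vaf), spec.vaf_log_sd), 1e-4, 0.6)
                )
            volume = float(max(0.1, rng.normal(spec.volume_mean_ml, spec.volume_sd_ml)))
            design = replace(
                base, true_vaf=vaf, dna_input_ng=spec.dna_input_ng, seed=base.seed
            )
            well = _simulate_from_copies(design, *design.template_copies(), rng, well_id=sample_id)
            wc = well.true_counts()
            samples.append(
                SampleRecord(
                    patient_id=sample_id,
                    sample_type=fluid,
                    assay_id="sim-assay",
                    biofluid_volume_ml=volume,
                )
            )
            counts[sample_id] = wc
            truth_rows.append(
                {
                    "sample_id": sample_id,
                    "sample_type": fluid,
                    "true_vaf": vaf,
                    "carries_ctdna": is_positive,
                    "mut_templates": well.n_mut_templates,
                    "wt_templates": well.n_wt_templates,
                    "n_mut_droplets": wc.n_mut,
                    "n_wt_droplets": wc.n_wt,
                }
            )
    return samples, counts, pd.DataFrame(truth_rows)
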