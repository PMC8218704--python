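"""Concentration, allele-fraction, biofluid back-calculation and call rules.

The quantitative chain for one well:

1. Poisson inversion turns positive-droplet counts into copies/µL of PCR mix:
   with positive fraction p and droplet volume v (nL),

       λ = −ln(1 − p)            mean template copies per droplet
       C = λ / (v · 10⁻³)        copies per µL

2. The mutant allele fraction is

       AF = C_MUT / (C_MUT + C_WT)

   which in the dilute limit equals the raw droplet-count quotient
   n_mut / (n_mut + n_wt); both modes are provided (``count_ratio`` is the
   default because reported VAF tables are count quotients).

3. Back-calculation to the original biofluid (copies/mL):

       C_ori = (V_PCR · C · V_ELU) / (V_DNA-PCR · V_SAMPLE)

   where V_PCR is the final PCR-mix volume (µL), V_ELU the extraction eluate
   volume (µL), V_DNA-PCR the eluate volume loaded into the mix (µL) and
   V_SAMPLE the biofluid volume extracted (mL).

4. cfDNA mass concentration (ng/mL) uses the mass of one haploid human
   genome, 0.003 ng:  C_cfDNA ≈ 0.003 · (C_MUT_ori + C_WT_ori).

Call rules: a sample is ctDNA-positive when it shows at least two
mutant-positive droplets; a copy-number target is amplified when its
target/reference concentration ratio exceeds 4-fold (strictly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import SaturationError, UndefinedFractionError, ValidationError
from .io_formats import ReactionSetup

#: minimum mutant-positive droplets for a positive ctDNA call
POSITIVITY_THRESHOLD = 2
#: target/reference concentration ratio above which a CNV call is "amplified"
AMPLIFICATION_FOLD = 4.0
#: mass of one haploid human genome (ng)
HAPLOID_GENOME_MASS_NG = 0.003


@dataclass
class QuantResult:
    """Quantification output for one sample/well.

    Fields that cannot be computed from the available inputs (e.g. copies/µL
    without a total droplet count, or biofluid concentrations without a
    reaction setup) are ``None`` — never imputed zeros.
    """

    n_mut: int
    n_wt: int
    af: float | None
    positive: bool
    af_mode: str = "count_ratio"
    c_mut: float | None = None            # copies/µL PCR mix
    c_wt: float | None = None
    c_mut_ori: float | None = None        # copies/mL biofluid
    c_wt_ori: float | None = None
    ccfdna_mut: float | None = None       # ng/mL biofluid, mutant allele
    ccfdna_wt: float | None = None
    ccfdna: float | None = None           # ng/mL biofluid, total
    sample_id: str | None = None
    assay_id: str | None = None
    sample_type: str | None = None

    @property
    def mutant_droplets(self) -> int:
        return self.n_mut

    def __post_init__(self) -> None:
        if self.af is not None and not (0.0 <= self.af <= 1.0):
            raise ValidationError("allele fraction must lie in [0, 1]")
        for name in ("c_mut", "c_wt", "c_mut_ori", "c_wt_ori", "ccfdna_mut", "ccfdna_wt", "ccfdna"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be non-negative")


@dataclass(frozen=True)
class CNVResult:
    """Copy-number ratio call: fold = target / reference, amplified iff fold > 4."""

    c_target: float
    c_reference: float
    fold: float
    amplified: bool


def poisson_concentration(n_positive: int, n_total: int, droplet_volume_nl: float = 0.85) -> float:
    """Copies/µL of PCR mix from positive-droplet counts by Poisson inversion.

    Raises
    ------
    SaturationError
        If every droplet is positive (occupancy unbounded).
    ValidationError
        If ``n_total`` is zero or counts are inconsistent.
    """
    if n_total <= 0:
        raise ValidationError("n_total must be positive")
    if not 0 <= n_positive <= n_total:
        raise ValidationError("n_positive must lie in [0, n_total]")
    if n_positive == n_total:
        raise SaturationError(
            f"all {n_total} droplets positive: concentration is unbounded"
        )
    if droplet_volume_nl <= 0:
        raise ValidationError("droplet_volume_nl must be positive")
    lam = -math.log1p(-n_positive / n_total)
    return lam / (droplet_volume_nl * 1e-3)


def allele_fraction(
    n_mut: int,
    n_wt: int,
    n_total: int | None = None,
    mode: str = "count_ratio",
    droplet_volume_nl: float = 0.85,
) -> float:
    """Mutant allele fraction from channel-positive droplet counts.

    ``count_ratio`` returns n_mut / (n_mut + n_wt) — the convention used when
    printing VAF tables. ``poisson`` corrects each channel for multiple
    occupancy first (λ_mut / (λ_mut + λ_wt)) and requires ``n_total``; the two
    agree closely below ~5% channel occupancy.
    """
    if n_mut < 0 or n_wt < 0:
        raise ValidationError("droplet counts must be non-negative")
    if n_mut + n_wt == 0:
        raise UndefinedFractionError("allele fraction undefined: no positive droplets")
    if mode == "count_ratio":
        return n_mut / (n_mut + n_wt)
    if mode == "poisson":
        if n_total is None:
            raise ValidationError("poisson mode requires n_total")
        c_mut = poisson_concentration(n_mut, n_total, droplet_volume_nl)
        c_wt = poisson_concentration(n_wt, n_total, droplet_volume_nl)
        if c_mut + c_wt == 0:
            raise UndefinedFractionError("allele fraction undefined: zero occupancy")
        return c_mut / (c_mut + c_wt)
    raise ValidationError(f"unknown allele-fraction mode {mode!r}")


def back_calculate_original(
    c: float, setup: ReactionSetup, v_sample_ml: float | None = None
) -> float:
    """Copies/mL of the original biofluid from copies/µL of PCR mix.

    ``v_sample_ml`` overrides ``setup.v_sample`` (the sample sheet usually
    carries the per-sample biofluid volume).
    """
    if c < 0:
        raise ValidationError("concentration must be non-negative")
    v_sample = v_sample_ml if v_sample_ml is not None else setup.v_sample
    if v_sample is None or v_sample <= 0:
        raise ValidationError("a positive biofluid volume (mL) is required")
    return (setup.v_pcr * c * setup.v_elu) / (setup.v_dna_pcr * v_sample)


def cfdna_mass_concentration(
    c_mut_ori: float, c_wt_ori: float, genome_mass_ng: float = HAPLOID_GENOME_MASS_NG
) -> float:
    """Total cfDNA mass concentration (ng/mL): genome mass × summed allele copies/mL."""
    if c_mut_ori < 0 or c_wt_ori < 0:
        raise ValidationError("allele concentrations must be non-negative")
    return genome_mass_ng * (c_mut_ori + c_wt_ori)


def call_positivity(mutant_droplets: int, threshold: int = POSITIVITY_THRESHOLD) -> bool:
    """True iff the well shows at least ``threshold`` mutant-positive droplets."""
    if mutant_droplets < 0:
        raise ValidationError("mutant_droplets must be non-negative")
    return mutant_droplets >= threshold


def cnv_fold(c_target: float, c_reference: float, fold_threshold: float = AMPLIFICATION_FOLD) -> CNVResult:
    """Target/reference concentration ratio; amplified iff strictly above threshold."""
    if c_reference <= 0:
        raise ValidationError("reference concentration must be positive")
    if c_target < 0:
        raise ValidationError("target concentration must be non-negative")
    fold = c_target / c_reference
    return CNVResult(
        c_target=c_target, c_reference=c_reference, fold=fold, amplified=fold > fold_threshold
    )
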