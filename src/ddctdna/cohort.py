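"""Per-sample quantification over a cohort, positivity summaries, longitudinal series."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import WellCounts
from .errors import UndefinedFractionError, ValidationError
from .io_formats import ReactionSetup, SampleRecord
from .quantify import (
    QuantResult,
    allele_fraction,
    back_calculate_original,
    call_positivity,
    cfdna_mass_concentration,
    poisson_concentration,
)


def run_sample(
    counts: WellCounts | tuple[int, int],
    setup: ReactionSetup | None,
    sample: SampleRecord | None = None,
    af_mode: str = "count_ratio",
) -> QuantResult:
    """Quantify one sample from its droplet tallies.

    Chains allele fraction → Poisson concentrations → biofluid
    back-calculation → cfDNA mass concentration → positivity call. Inputs
    that are unavailable (no total droplet count, no reaction setup, no
    biofluid volume) leave the dependent fields ``None`` rather than zero:
    with bare ``(n_mut, n_wt)`` tuples only the count-ratio VAF and the
    positivity call are computed.
    """
    if isinstance(counts, WellCounts):
        n_mut, n_wt, n_total = counts.n_mut, counts.n_wt, counts.n_total
    else:
        n_mut, n_wt = int(counts[0]), int(counts[1])
        n_total = None
    sample_id = sample.patient_id if sample else None
    try:
        af = allele_fraction(n_mut, n_wt, n_total=n_total, mode=af_mode,
                             droplet_volume_nl=setup.droplet_volume_nl if setup else 0.85)
    except UndefinedFractionError as exc:
        raise UndefinedFractionError(
            f"sample {sample_id or '<unnamed>'}: {exc}"
        ) from exc
    result = QuantResult(
        n_mut=n_mut,
        n_wt=n_wt,
        af=af,
        positive=call_positivity(n_mut),
        af_mode=af_mode,
        sample_id=sample_id,
        assay_id=sample.assay_id if sample else None,
        sample_type=sample.sample_type if sample else None,
    )
    if n_total is None or setup is None:
        return result
    v_sample = sample.biofluid_volume_ml if sample else setup.v_sample
    result.c_mut = poisson_concentration(n_mut, n_total, setup.droplet_volume_nl)
    result.c_wt = poisson_concentration(n_wt, n_total, setup.droplet_volume_nl)
    if v_sample is not None:
        result.c_mut_ori = back_calculate_original(result.c_mut, setup, v_sample)
        result.c_wt_ori = back_calculate_original(result.c_wt, setup, v_sample)
        result.ccfdna_mut = setup.genome_mass_ng * result.c_mut_ori
        result.ccfdna_wt = setup.genome_mass_ng * result.c_wt_ori
        result.ccfdna = cfdna_mass_concentration(
            result.c_mut_ori, result.c_wt_ori, setup.genome_mass_ng
        )
    return result


def round_half_up_percent(fraction: float) -> int:
    """Integer percent with exact half-up rounding (0.265 -> 27)."""
    return int(math.floor(fraction * 100.0 + 0.5))


@dataclass(frozen=True)
class FluidSummary:
    n_assayed: int
    n_positive: int
    positivity: float
    positivity_pct: int
    volume_mean: float | None = None
    volume_sd: float | None = None
    volume_median: float | None = None
    ccfdna_mean: float | None = None
    ccfdna_sd: float | None = None
    ccfdna_median: float | None = None


@dataclass
class CohortSummary:
    """Per-biofluid positivity tallies plus descriptive statistics."""

    fluids: dict[str, FluidSummary]
    total_assayed: int
    total_positive: int

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for fluid in sorted(self.fluids):
            s = self.fluids[fluid]
            rows.append({"sample_type": fluid, **s.__dict__})
        return pd.DataFrame(rows)


def _stats(values: list[float]) -> tuple[float | None, float | None, float | None]:
    if not values:
        return None, None, None
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd, float(np.median(arr))


def summarize_cohort(
    results: Sequence[tuple[QuantResult, SampleRecord]],
    cohort_totals: Mapping[str, int] | None = None,
) -> CohortSummary:
    """Per-fluid positivity and descriptive statistics over joined results.

    ``cohort_totals`` supplies the assayed denominator per fluid when the
    result list covers only detected samples (a published summary table lists
    only positives); fluids present in the totals but absent from the results
    contribute zero positives. Every result must be joined to a sample record.
    """
    per_fluid: dict[str, dict] = {}
    for item in results:
        try:
            result, sample = item
        except (TypeError, ValueError):
            raise ValidationError("each result must be joined to a sample record")
        if sample is None:
            raise ValidationError(f"unjoined result (sample_id={result.sample_id!r})")
        bucket = per_fluid.setdefault(
            sample.sample_type, {"n": 0, "pos": 0, "volumes": [], "ccfdna": []}
        )
        bucket["n"] += 1
        bucket["pos"] += int(result.positive)
        bucket["volumes"].append(sample.biofluid_volume_ml)
        if result.ccfdna is not None:
            bucket["ccfdna"].append(result.ccfdna)
    if cohort_totals:
        for fluid, n in cohort_totals.items():
            bucket = per_fluid.setdefault(fluid, {"n": 0, "pos": 0, "volumes": [], "ccfdna": []})
            if bucket["pos"] > n:
                raise ValidationError(
                    f"{fluid}: {bucket['pos']} positives exceed cohort total {n}"
                )
            bucket["n"] = n
    fluids = {}
    for fluid, b in per_fluid.items():
        vol_mean, vol_sd, vol_med = _stats(b["volumes"])
        cf_mean, cf_sd, cf_med = _stats(b["ccfdna"])
        positivity = b["pos"] / b["n"] if b["n"] else 0.0
        fluids[fluid] = FluidSummary(
            n_assayed=b["n"],
            n_positive=b["pos"],
            positivity=positivity,
            positivity_pct=round_half_up_percent(positivity),
            volume_mean=vol_mean, volume_sd=vol_sd, volume_median=vol_med,
            ccfdna_mean=cf_mean, ccfdna_sd=cf_sd, ccfdna_median=cf_med,
        )
    return CohortSummary(
        fluids=fluids,
        total_assayed=sum(s.n_assayed for s in fluids.values()),
        total_positive=sum(s.n_positive for s in fluids.values()),
    )


@dataclass(frozen=True)
class LongitudinalObservation:
    """One time-point of one patient's cfDNA trajectory."""

    patient_id: str
    time_point: str
    days: float
    ccfdna_ng_ml: float | None
    event: str | None = None  # e.g. "resection", "progression"


@dataclass
class LongitudinalSeries:
    patient_id: str
    points: list[LongitudinalObservation] = field(default_factory=list)


def build_longitudinal(
    observations: Iterable[LongitudinalObservation],
) -> dict[str, LongitudinalSeries]:
    """Group observations per patient, sorted by days from randomization.

    Missing time-points are permitted; duplicate (patient, time_point) labels
    or non-increasing times raise :class:`ValidationError` naming the
    collision.
    """
    series: dict[str, LongitudinalSeries] = {}
    for obs in observations:
        series.setdefault(obs.patient_id, LongitudinalSeries(obs.patient_id)).points.append(obs)
    for patient, s in series.items():
        labels = [p.time_point for p in s.points]
        dupes = {t for t in labels if labels.count(t) > 1}
        if dupes:
            raise ValidationError(f"patient {patient}: duplicate time-points {sorted(dupes)}")
        s.points.sort(key=lambda p: p.days)
        days = [p.days for p in s.points]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValidationError(f"patient {patient}: time must be strictly increasing")
    return series


def longitudinal_frame(series: Mapping[str, LongitudinalSeries]) -> pd.DataFrame:
    """Tidy table (one row per patient × time-point) for plotting."""
    rows = []
    for patient in sorted(series):
        for p in series[patient].points:
            rows.append(
                {
                    "patient_id": patient,
                    "time_point": p.time_point,
                    "days": p.days,
                    "ccfdna_ng_ml": p.ccfdna_ng_ml,
                    "event": p.event,
                }
            )
    return pd.DataFrame(
        rows, columns=["patient_id", "time_point", "days", "ccfdna_ng_ml", "event"]
    )
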