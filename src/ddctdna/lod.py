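"""Limit of detection from a serial-dilution experiment.

An assay's LoD is estimated by serially diluting mutant DNA into a constant
background of wild-type DNA (1:10, 1:100, 1:1000, 1:10,000), running each
dilution in duplicate, and finding the deepest dilution that still yields a
detectable mutant signal (at least two mutant-positive droplets). The LoD is
then

    LoD = neat fractional abundance / deepest detectable dilution factor

so a neat 79.3% VAF detectable down to 1:100 gives an LoD of 0.793%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .errors import NoDetectionError, ValidationError


@dataclass(frozen=True)
class DilutionPoint:
    """Replicate droplet counts at one dilution factor (1 = neat)."""

    dilution_factor: float
    mutant_counts: tuple[int, ...]
    wt_counts: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mutant_counts", tuple(int(c) for c in self.mutant_counts))
        if self.wt_counts is not None:
            object.__setattr__(self, "wt_counts", tuple(int(c) for c in self.wt_counts))
        if self.dilution_factor < 1:
            raise ValidationError("dilution_factor must be >= 1")
        if not self.mutant_counts:
            raise ValidationError("at least one replicate is required")
        if any(c < 0 for c in self.mutant_counts):
            raise ValidationError("droplet counts must be non-negative")


@dataclass(frozen=True)
class LoDResult:
    """Limit of detection: lod = neat_af / lowest_detectable_factor (fractions)."""

    neat_af: float
    lowest_detectable_factor: float
    lod: float


class LodPanelSummary(NamedTuple):
    min: float
    max: float
    median: float


def _detectable(point: DilutionPoint, threshold: int, rule: str) -> bool:
    if rule == "pooled":
        return sum(point.mutant_counts) >= threshold
    if rule == "any":
        return any(c >= threshold for c in point.mutant_counts)
    raise ValidationError(f"unknown replicate_rule {rule!r}")


def compute_lod(
    neat_af: float,
    series: Sequence[DilutionPoint],
    detect_threshold: int = 2,
    replicate_rule: str = "pooled",
) -> LoDResult:
    """Apply the serial-dilution LoD rule.

    A dilution point is detectable when its mutant droplets — summed across
    replicates under ``replicate_rule="pooled"`` (default), or in at least one
    replicate under ``"any"`` — reach ``detect_threshold``. The LoD is the neat
    fractional abundance divided by the LARGEST detectable dilution factor.

    Raises
    ------
    NoDetectionError
        If no point in the series (including a neat point, if present) is
        detectable.
    """
    if not series:
        raise ValidationError("series must be non-empty")
    if not (0 < neat_af <= 1):
        raise ValidationError("neat_af must lie in (0, 1]")
    detectable = [p.dilution_factor for p in series if _detectable(p, detect_threshold, replicate_rule)]
    if not detectable:
        raise NoDetectionError(
            f"no dilution point reached {detect_threshold} mutant droplets"
        )
    factor = max(detectable)
    return LoDResult(neat_af=neat_af, lowest_detectable_factor=factor, lod=neat_af / factor)


def summarize_lod_panel(lods: Sequence[LoDResult | float]) -> LodPanelSummary:
    """Range and median of a panel of assay LoDs (accepts results or bare fractions)."""
    values = [x.lod if isinstance(x, LoDResult) else float(x) for x in lods]
    if not values:
        raise ValidationError("empty LoD panel")
    return LodPanelSummary(
        min=float(np.min(values)), max=float(np.max(values)), median=float(np.median(values))
    )
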