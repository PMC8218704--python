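"""Droplet classification from two-channel fluorescence amplitudes.

A duplex ddPCR well reads every droplet on two channels: channel 1 carries the
mutant-specific probe (FAM), channel 2 the wild-type probe (VIC/HEX). A droplet
is called positive on a channel when its amplitude strictly exceeds that
channel's cutoff; ties at the cutoff classify as negative. Channel totals
include double positives, which is what the downstream Poisson formulas
consume.

The default classifier is a deterministic k-sigma threshold derived from the
negative (no-template) control: cutoff = mean + k·SD per channel, k = 5 by
default. Instrument vendors ship proprietary cluster-based callers; a
threshold rule is reproducible and testable against simulated ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io_formats import AmplitudeTable

#: per-droplet class labels used throughout the package
LABELS = ("empty", "mut", "wt", "double")


@dataclass(frozen=True)
class ClassificationThresholds:
    """Per-channel amplitude cutoffs.

    ``method`` records provenance ("fixed" or "control-derived");
    ``separation_warning`` is set when a control-derived cutoff did not fall
    below the positive-control cluster mean.
    """

    ch1_cutoff: float
    ch2_cutoff: float
    method: str = "fixed"
    separation_warning: bool = False

    def __post_init__(self) -> None:
        for name, v in (("ch1_cutoff", self.ch1_cutoff), ("ch2_cutoff", self.ch2_cutoff)):
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be strictly positive and finite")


@dataclass(frozen=True)
class WellCounts:
    """Classified droplet tallies for one well.

    ``n_mut`` and ``n_wt`` are channel totals and therefore each INCLUDE the
    double positives.
    """

    n_total: int
    n_mut: int
    n_wt: int
    n_double: int

    def __post_init__(self) -> None:
        if min(self.n_total, self.n_mut, self.n_wt, self.n_double) < 0:
            raise ValidationError("droplet tallies must be non-negative")
        if self.n_double > min(self.n_mut, self.n_wt):
            raise ValidationError("n_double cannot exceed either channel total")
        if max(self.n_mut, self.n_wt) > self.n_total:
            raise ValidationError("channel totals cannot exceed n_total")
        if self.n_mut + self.n_wt - self.n_double > self.n_total:
            raise ValidationError("positive droplets cannot exceed n_total")

    @property
    def n_empty(self) -> int:
        return self.n_total - (self.n_mut + self.n_wt - self.n_double)


def classify_labels(table: AmplitudeTable, thresholds: ClassificationThresholds) -> np.ndarray:
    """Per-droplet labels ('empty' | 'mut' | 'wt' | 'double'), strict-inequality rule."""
    mut = table.ch1 > thresholds.ch1_cutoff
    wt = table.ch2 > thresholds.ch2_cutoff
    labels = np.full(len(table), "empty", dtype="U6")
    labels[mut & ~wt] = "mut"
    labels[~mut & wt] = "wt"
    labels[mut & wt] = "double"
    return labels


def classify_droplets(table: AmplitudeTable, thresholds: ClassificationThresholds) -> WellCounts:
    """Tally a well's droplets into mutant / wild-type / double / empty classes."""
    mut = table.ch1 > thresholds.ch1_cutoff
    wt = table.ch2 > thresholds.ch2_cutoff
    return WellCounts(
        n_total=len(table),
        n_mut=int(np.count_nonzero(mut)),
        n_wt=int(np.count_nonzero(wt)),
        n_double=int(np.count_nonzero(mut & wt)),
    )


def estimate_thresholds(
    negative_control: AmplitudeTable,
    positive_control: AmplitudeTable,
    k: float = 5.0,
) -> ClassificationThresholds:
    """Derive per-channel cutoffs from a no-template control: mean + k·SD.

    The positive control is used only as a sanity check: if a cutoff does not
    fall below the positive-control cluster mean on its channel, the result
    carries ``separation_warning=True``.

    Raises
    ------
    ValidationError
        If the negative control has fewer than 50 droplets or zero variance
        on a channel (degenerate control).
    """
    if len(negative_control) < 50:
        raise ValidationError("negative control must contain at least 50 droplets")
    cutoffs = []
    warning = False
    for neg, pos in (
        (negative_control.ch1, positive_control.ch1),
        (negative_control.ch2, positive_control.ch2),
    ):
        sd = float(np.std(neg, ddof=1))
        if sd == 0.0:
            raise ValidationError("degenerate negative control: zero amplitude variance")
        cutoff = float(np.mean(neg)) + k * sd
        if len(positive_control) and cutoff >= float(np.mean(pos)):
            warning = True
        cutoffs.append(cutoff)
    return ClassificationThresholds(
        ch1_cutoff=cutoffs[0],
        ch2_cutoff=cutoffs[1],
        method="control-derived",
        separation_warning=warning,
    )
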