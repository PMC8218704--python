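"""Post-filtering of structural-variant fusion candidates from a capture panel.

SV callers emit a generous candidate list; on a hybridization-capture fusion
panel most raw junctions are artifacts. Each candidate is screened against six
rejection rules:

* ``min_reads`` — fewer than ``min_reads`` (default 3, i.e. "more than 2")
  reads covering either partner gene;
* ``outside_capture`` — BOTH breakpoints fall outside the capture intervals
  (one targeted end suffices to keep a candidate, as capture designs bait one
  side of a junction);
* ``blocklist_position`` — either breakpoint lies within ``bp_tolerance``
  (default 10 bp) of a known false-positive position;
* ``blocklist_pair`` — the unordered gene pair is a known false-positive pair;
* ``intragenic`` — both partners are the same gene;
* ``homology`` — junction flanking homology longer than ``max_homology``
  (default 10 bp), the signature of alignment ambiguity.

Coordinates: BED files are half-open 0-based on disk; candidate breakpoints
are 1-based inclusive. Conversion happens in exactly two helpers below.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .errors import FormatError, ValidationError

RULE_TAGS = (
    "min_reads",
    "outside_capture",
    "blocklist_position",
    "blocklist_pair",
    "intragenic",
    "homology",
)


def bed_to_position(start_0based: int) -> int:
    """First 1-based position covered by a half-open BED interval start."""
    return start_0based + 1


def position_to_bed(pos_1based: int) -> int:
    """0-based offset of a 1-based position (for capture-interval lookups)."""
    return pos_1based - 1


@dataclass(frozen=True)
class Breakpoint:
    contig: str
    position: int  # 1-based inclusive

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError("breakpoint positions are 1-based (>= 1)")


@dataclass
class FusionCandidate:
    """One putative fusion junction between a 5' and a 3' partner gene."""

    gene5: str
    gene3: str
    breakpoint5: Breakpoint
    breakpoint3: Breakpoint
    supporting_reads_gene5: int
    supporting_reads_gene3: int
    homology_length: int = 0
    passed_filters: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.supporting_reads_gene5, self.supporting_reads_gene3) < 0:
            raise ValidationError("read counts must be non-negative")
        if self.homology_length < 0:
            raise ValidationError("homology_length must be non-negative")


class CaptureSet:
    """Merged genomic intervals targeted by the capture panel (0-based, half-open)."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]]):
        self._trees: dict[str, IntervalTree] = {}
        for contig, start, end in intervals:
            if start >= end:
                raise ValidationError(f"malformed interval {contig}:{start}-{end}")
            self._trees.setdefault(contig, IntervalTree()).addi(start, end)
        for tree in self._trees.values():
            tree.merge_overlaps(strict=False)

    def contains(self, contig: str, pos_1based: int) -> bool:
        """Membership of a breakpoint position; contigs absent from the set are outside.

        The half-open convention is applied to the position value itself, so a
        position equal to an interval's BED end is outside.
        """
        tree = self._trees.get(contig)
        if tree is None:
            return False
        return tree.overlaps_point(pos_1based)

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for contig in sorted(self._trees):
            for iv in sorted(self._trees[contig]):
                out.append((contig, iv.begin, iv.end))
        return out


@dataclass
class FilterResources:
    """Capture set and blocklists consumed by the candidate filter.

    Blocklists are site-specific resources supplied by the user; empty
    blocklists are valid.
    """

    capture_set: CaptureSet
    blocklist_positions: frozenset[tuple[str, int]] = frozenset()
    blocklist_gene_pairs: frozenset[frozenset[str]] = frozenset()


@dataclass(frozen=True)
class FilterRejection:
    candidate: FusionCandidate
    first_failed: str
    failed_rules: tuple[str, ...]


def load_capture_bed(path: str | Path) -> CaptureSet:
    """Load a BED3+ capture file into merged intervals.

    Raises :class:`FormatError` with a line number on malformed lines.
    """
    intervals = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}: line {lineno}: expected >= 3 BED columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise FormatError(f"{path}: line {lineno}: non-integer coordinates")
        if start < 0 or start >= end:
            raise FormatError(f"{path}: line {lineno}: invalid interval {start}-{end}")
        intervals.append((fields[0], start, end))
    return CaptureSet(intervals)


def load_blocklist_positions(path: str | Path) -> frozenset[tuple[str, int]]:
    """TSV of (contig, 1-based position) false-positive breakpoints."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=["contig", "position"])
    return frozenset((str(c), int(p)) for c, p in zip(df["contig"], df["position"]))


def load_blocklist_pairs(path: str | Path) -> frozenset[frozenset[str]]:
    """TSV of unordered false-positive gene pairs (two columns)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=["gene_a", "gene_b"])
    return frozenset(frozenset((str(a), str(b))) for a, b in zip(df["gene_a"], df["gene_b"]))


def read_candidates(path: str | Path) -> list[FusionCandidate]:
    """Read BEDPE-like candidates (chrom1 start1 end1 chrom2 start2 end2 gene5
    gene3 reads5 reads3 homology); breakpoints taken as the 1-based position of
    each interval's start."""
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
            "gene5", "gene3", "reads5", "reads3", "homology"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols)
    out = []
    for _, row in df.iterrows():
        out.append(
            FusionCandidate(
                gene5=str(row["gene5"]),
                gene3=str(row["gene3"]),
                breakpoint5=Breakpoint(str(row["chrom1"]), bed_to_position(int(row["start1"]))),
                breakpoint3=Breakpoint(str(row["chrom2"]), bed_to_position(int(row["start2"]))),
                supporting_reads_gene5=int(row["reads5"]),
                supporting_reads_gene3=int(row["reads3"]),
                homology_length=int(row["homology"]),
            )
        )
    return out


def _near_blocklisted(
    bp: Breakpoint, positions: frozenset[tuple[str, int]], tol: int
) -> bool:
    return any(c == bp.contig and abs(p - bp.position) <= tol for c, p in positions)


def _failed_rules(
    cand: FusionCandidate,
    resources: FilterResources,
    min_reads: int,
    max_homology: int,
    bp_tolerance: int,
) -> tuple[str, ...]:
    failed = []
    if min(cand.supporting_reads_gene5, cand.supporting_reads_gene3) < min_reads:
        failed.append("min_reads")
    in5 = resources.capture_set.contains(cand.breakpoint5.contig, cand.breakpoint5.position)
    in3 = resources.capture_set.contains(cand.breakpoint3.contig, cand.breakpoint3.position)
    if not in5 and not in3:
        failed.append("outside_capture")
    if _near_blocklisted(cand.breakpoint5, resources.blocklist_positions, bp_tolerance) or \
            _near_blocklisted(cand.breakpoint3, resources.blocklist_positions, bp_tolerance):
        failed.append("blocklist_position")
    if frozenset((cand.gene5, cand.gene3)) in resources.blocklist_gene_pairs:
        failed.append("blocklist_pair")
    if cand.gene5 == cand.gene3:
        failed.append("intragenic")
    if cand.homology_length > max_homology:
        failed.append("homology")
    return tuple(failed)


def filter_candidates(
    candidates: Sequence[FusionCandidate],
    resources: FilterResources,
    min_reads: int = 3,
    max_homology: int = 10,
    bp_tolerance: int = 10,
) -> tuple[list[FusionCandidate], list[FilterRejection]]:
    """Apply the six-rule rejection chain to every candidate.

    Returns (retained, rejections). Retained candidates carry the full rule
    pass-list in ``passed_filters``; each rejection names its first failing
    rule and all failing rules. Input candidates are not mutated.
    """
    retained, rejected = [], []
    for cand in candidates:
        failed = _failed_rules(cand, resources, min_reads, max_homology, bp_tolerance)
        if failed:
            rejected.append(FilterRejection(cand, first_failed=failed[0], failed_rules=failed))
        else:
            retained.append(replace(cand, passed_filters=list(RULE_TAGS)))
    return retained, rejected
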