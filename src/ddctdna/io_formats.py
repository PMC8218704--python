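"""Readers and writers for every external table the pipeline touches.

Dialects (documented conventions, configurable where noted):

* droplet amplitude tables — comma-separated, UTF-8, header row with columns
  ``"Ch1 Amplitude"`` / ``"Ch2 Amplitude"`` (instrument-export style) and an
  optional ``"Cluster"`` label column; alternative headers via ``column_map``.
* sample sheets and result tables — tab-separated (sample labels may contain
  commas).
* reaction setup — TOML.

Serialization precision: percent allele fractions and ng/mL concentrations are
written with 3 decimals, matching the precision such results are reported at.
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

VALID_SAMPLE_TYPES = ("plasma", "serum", "csf", "cyst")

DEFAULT_AMPLITUDE_COLUMNS = {
    "ch1": "Ch1 Amplitude",
    "ch2": "Ch2 Amplitude",
    "cluster": "Cluster",
}


@dataclass
class AmplitudeTable:
    """Two-channel fluorescence amplitudes for the accepted droplets of one well.

    Channel 1 carries the mutant-specific (FAM) probe signal, channel 2 the
    wild-type (VIC/HEX) signal. One row per accepted droplet, order preserved.
    """

    well_id: str
    ch1: np.ndarray
    ch2: np.ndarray
    cluster: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ch1 = np.asarray(self.ch1, dtype=float)
        self.ch2 = np.asarray(self.ch2, dtype=float)
        if self.ch1.shape != self.ch2.shape or self.ch1.ndim != 1:
            raise ValidationError("ch1 and ch2 must be 1-D arrays of equal length")
        for name, arr in (("ch1", self.ch1), ("ch2", self.ch2)):
            if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr < 0)):
                raise ValidationError(f"{name} amplitudes must be finite and non-negative")
        if self.cluster is not None:
            self.cluster = np.asarray(self.cluster)
            if self.cluster.shape != self.ch1.shape:
                raise ValidationError("cluster labels must match droplet count")

    def __len__(self) -> int:
        return int(self.ch1.size)


@dataclass(frozen=True)
class SampleRecord:
    """One row of a sample sheet."""

    patient_id: str
    sample_type: str
    assay_id: str
    biofluid_volume_ml: float
    time_point: str | None = None

    def __post_init__(self) -> None:
        if self.sample_type not in VALID_SAMPLE_TYPES:
            raise ValidationError(
                f"unknown sample_type {self.sample_type!r}; allowed: {VALID_SAMPLE_TYPES}"
            )
        if not (self.biofluid_volume_ml > 0):
            raise ValidationError("biofluid_volume_ml must be > 0")


@dataclass(frozen=True)
class ReactionSetup:
    """Volumes and constants of one ddPCR reaction setup.

    Parameters
    ----------
    v_pcr : float
        Final PCR mix volume (µL).
    v_elu : float
        cfDNA elution volume from extraction (µL).
    v_dna_pcr : float
        Volume of eluate loaded into the PCR mix (µL); at most ``v_elu``.
    v_sample : float, optional
        Biofluid volume used for extraction (mL); may instead be supplied
        per sample at back-calculation time.
    droplet_volume_nl : float
        Droplet volume (nL); 0.85 nL is the common instrument figure.
    genome_mass_ng : float
        Mass of one haploid human genome (ng); 0.003 ng by convention.
    """

    v_pcr: float
    v_elu: float
    v_dna_pcr: float
    v_sample: float | None = None
    droplet_volume_nl: float = 0.85
    genome_mass_ng: float = 0.003

    def __post_init__(self) -> None:
        for name in ("v_pcr", "v_elu", "v_dna_pcr", "droplet_volume_nl", "genome_mass_ng"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be a finite positive number")
        if self.v_dna_pcr > self.v_elu:
            raise ValidationError("v_dna_pcr cannot exceed v_elu")
        if self.v_sample is not None and not (self.v_sample > 0):
            raise ValidationError("v_sample must be > 0 when given")


def _resolve_columns(df: pd.DataFrame, column_map: Mapping[str, str] | None, path: Path):
    cols = dict(DEFAULT_AMPLITUDE_COLUMNS)
    if column_map:
        cols.update(column_map)
    for key in ("ch1", "ch2"):
        if cols[key] not in df.columns:
            raise FormatError(f"{path}: missing amplitude column {cols[key]!r}")
    return cols


def read_amplitude_table(
    path: str | Path,
    well_id: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> AmplitudeTable:
    """Read a droplet amplitude CSV; one row per accepted droplet.

    Raises :class:`FormatError` if an amplitude column is missing or a value
    is non-numeric (the message names the offending line).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: no header row")
    cols = _resolve_columns(df, column_map, path)
    channels = {}
    for key in ("ch1", "ch2"):
        raw = df[cols[key]]
        numeric = pd.to_numeric(raw, errors="coerce")
        bad = numeric.isna() & raw.notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise FormatError(
                f"{path}: non-numeric amplitude {raw[bad.idxmax()]!r} "
                f"in column {cols[key]!r}, line {line}"
            )
        if numeric.isna().any():
            line = int(numeric.isna().idxmax()) + 2
            raise FormatError(f"{path}: empty amplitude in column {cols[key]!r}, line {line}")
        channels[key] = numeric.to_numpy(dtype=float)
    cluster = df[cols["cluster"]].to_numpy() if cols["cluster"] in df.columns else None
    return AmplitudeTable(
        well_id=well_id or path.stem, ch1=channels["ch1"], ch2=channels["ch2"], cluster=cluster
    )


def write_amplitude_table(table: AmplitudeTable, path: str | Path) -> None:
    """Write an amplitude table in the same CSV dialect ``read_amplitude_table`` reads."""
    data = {
        DEFAULT_AMPLITUDE_COLUMNS["ch1"]: table.ch1,
        DEFAULT_AMPLITUDE_COLUMNS["ch2"]: table.ch2,
    }
    if table.cluster is not None:
        data[DEFAULT_AMPLITUDE_COLUMNS["cluster"]] = table.cluster
    pd.DataFrame(data).to_csv(path, index=False)


_SHEET_COLUMNS = ("patient_id", "assay_id", "sample_type", "biofluid_volume_ml")


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    """Read a tab-separated sample sheet into validated records.

    Required columns: patient_id, assay_id, sample_type, biofluid_volume_ml;
    optional: time_point. sample_type is matched case-insensitively against
    ``VALID_SAMPLE_TYPES``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in _SHEET_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing sample sheet column {col!r}")
    records = []
    for idx, row in df.iterrows():
        stype = str(row["sample_type"]).strip().lower()
        try:
            volume = float(row["biofluid_volume_ml"])
        except (TypeError, ValueError):
            raise ValidationError(
                f"{path}: non-numeric biofluid_volume_ml {row['biofluid_volume_ml']!r} "
                f"for sample {row['patient_id']!r}"
            )
        tp = row.get("time_point")
        records.append(
            SampleRecord(
                patient_id=str(row["patient_id"]),
                sample_type=stype,
                assay_id=str(row["assay_id"]),
                biofluid_volume_ml=volume,
                time_point=None if tp is None or pd.isna(tp) else str(tp),
            )
        )
    return records


def write_sample_sheet(records: Sequence[SampleRecord], path: str | Path) -> None:
    rows = [dataclasses.asdict(r) for r in records]
    pd.DataFrame(rows, columns=_SHEET_COLUMNS + ("time_point",)).to_csv(
        path, sep="\t", index=False
    )


# Result tables ---------------------------------------------------------------

RESULT_COLUMNS = (
    "sample_id",
    "assay_id",
    "sample_type",
    "vaf_pct",
    "mutant_droplets",
    "wildtype_droplets",
    "cfdna_mut_ng_ml",
    "cfdna_wt_ng_ml",
    "positive",
)


def _fmt(value: float | None, decimals: int = 3) -> str:
    return "" if value is None else f"{value:.{decimals}f}"


def write_results(results: Sequence, path: str | Path) -> None:
    """Write quantification results as a TSV with a fixed column order.

    Percent VAFs and ng/mL concentrations are serialized with 3 decimals;
    absent fields are written as empty cells, never as zeros.
    """
    lines = ["\t".join(RESULT_COLUMNS)]
    for r in results:
        lines.append(
            "\t".join(
                [
                    r.sample_id or "",
                    r.assay_id or "",
                    r.sample_type or "",
                    _fmt(None if r.af is None else 100.0 * r.af),
                    str(r.n_mut),
                    str(r.n_wt),
                    _fmt(r.ccfdna_mut),
                    _fmt(r.ccfdna_wt),
                    str(bool(r.positive)),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results TSV (round-trip counterpart of :func:`write_results`)."""
    return pd.read_csv(path, sep="\t")


def read_reaction_setup(path: str | Path) -> ReactionSetup:
    """Load a :class:`ReactionSetup` from a TOML file.

    Keys: v_pcr, v_elu, v_dna_pcr and optionally v_sample, droplet_volume_nl,
    genome_mass_ng.
    """
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    allowed = {f.name for f in dataclasses.fields(ReactionSetup)}
    unknown = set(data) - allowed
    if unknown:
        raise FormatError(f"{path}: unknown reaction setup keys {sorted(unknown)}")
    try:
        return ReactionSetup(**data)
    except TypeError as exc:
        raise FormatError(f"{path}: {exc}")


def read_dilution_series(path: str | Path):
    """Read a serial-dilution TSV (factor, replicate_id, mutant_droplets, wt_droplets).

    Returns a list of :class:`ddctdna.lod.DilutionPoint`, sorted by factor.
    """
    from .lod import DilutionPoint

    df = pd.read_csv(path, sep="\t")
    for col in ("factor", "mutant_droplets"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing dilution series column {col!r}")
    points = []
    for factor, group in df.groupby("factor"):
        wt = group["wt_droplets"].astype(int).tolist() if "wt_droplets" in df.columns else None
        points.append(
            DilutionPoint(
                dilution_factor=float(factor),
                mutant_counts=group["mutant_droplets"].astype(int).tolist(),
                wt_counts=wt,
            )
        )
    return sorted(points, key=lambda p: p.dilution_factor)
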