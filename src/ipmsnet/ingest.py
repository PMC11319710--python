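"""Reading protein-level abundance reports and applying database-refinement filters.

An IP-MS experiment produces one protein report per study: one row per
protein with identification confidence metrics (posterior error probability,
q-value, number of unique peptides) and one MS1 abundance column per sample.
This module parses such reports against a sample design sheet and applies the
quality filters that define the candidate protein set:

* PEP strictly below a threshold (default 0.01),
* q-value at most a threshold (default 0, i.e. q must be exactly zero),
* at least a minimum number of unique peptides (default 2),
* total abundance summed over all samples at least a floor (default 9e6).

Missing abundance cells are represented as *absent*, never as zero: an empty
cell means the protein was not quantified in that sample, and all downstream
statistics (fold changes, correlations, keratin fractions) exclude absent
values rather than imputing them.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, SchemaError, ValidationError

#: Columns every protein report must contain, in canonical order, before the
#: per-sample abundance columns.
REPORT_COLUMNS = (
    "accession",
    "gene",
    "description",
    "mw_kda",
    "pep",
    "q_value",
    "unique_peptides",
    "modifications",
)

VALID_CONDITIONS = ("ip", "control")


@dataclass(frozen=True)
class Sample:
    """One sample of the design: its id, condition and originating cell line."""

    sample_id: str
    condition: str  # "ip" or "control"
    cell_line: str


@dataclass(frozen=True)
class SampleDesign:
    """Ordered collection of samples with IP/control labels.

    The design must contain at least one IP and one control sample for the
    enrichment stage to be meaningful, and sample ids must be unique.
    """

    samples: tuple[Sample, ...]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("sample_ids must be unique in a SampleDesign")
        for s in self.samples:
            if s.condition not in VALID_CONDITIONS:
                raise ValidationError(
                    f"sample {s.sample_id!r}: condition must be one of {VALID_CONDITIONS},"
                    f" got {s.condition!r}"
                )
        if not self.ip_ids or not self.control_ids:
            raise ValidationError(
                "SampleDesign needs at least one 'ip' and one 'control' sample"
            )

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(s.sample_id for s in self.samples)

    @property
    def ip_ids(self) -> tuple[str, ...]:
        return tuple(s.sample_id for s in self.samples if s.condition == "ip")

    @property
    def control_ids(self) -> tuple[str, ...]:
        return tuple(s.sample_id for s in self.samples if s.condition == "control")

    @property
    def cell_lines(self) -> tuple[str, ...]:
        seen: list[str] = []
        for s in self.samples:
            if s.cell_line not in seen:
                seen.append(s.cell_line)
        return tuple(seen)

    def samples_for_line(self, cell_line: str) -> tuple[str, ...]:
        return tuple(s.sample_id for s in self.samples if s.cell_line == cell_line)

    @classmethod
    def from_csv(cls, path) -> "SampleDesign":
        """Read a sample sheet with columns sample_id, condition, cell_line."""
        frame = pd.read_csv(path, dtype=str)
        for col in ("sample_id", "condition", "cell_line"):
            if col not in frame.columns:
                raise SchemaError(f"sample sheet is missing required column {col!r}")
        samples = tuple(
            Sample(row.sample_id, row.condition, row.cell_line)
            for row in frame.itertuples()
        )
        return cls(samples)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(["sample_id", "condition", "cell_line"])
            for s in self.samples:
                writer.writerow([s.sample_id, s.condition, s.cell_line])


@dataclass
class ProteinRecord:
    """One protein's identity, QC metrics and per-sample abundances.

    ``abundance`` maps sample id to a positive MS1 abundance; samples where
    the protein was not quantified are simply absent from the mapping.
    """

    accession: str
    gene: str
    description: str
    mw_kda: float
    pep: float
    q_value: float
    unique_peptides: int
    modifications: str = ""
    abundance: dict[str, float] = field(default_factory=dict)

    def present_in(self, sample_ids: Iterable[str]) -> bool:
        return any(sid in self.abundance for sid in sample_ids)

    def total_abundance(self) -> float:
        """Sum of present abundances; absent cells are excluded, not zeroed."""
        return float(sum(self.abundance.values()))

    def values_for(self, sample_ids: Sequence[str]) -> list[float]:
        return [self.abundance[s] for s in sample_ids if s in self.abundance]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the database-refinement step.

    Inequality directions follow the reporting convention of Proteome
    Discoverer-style candidate screens: PEP strictly below ``pep_max``,
    q-value at most ``q_max`` (with the default 0 this demands a perfect q),
    unique peptides and the summed-abundance floor inclusive.
    """

    pep_max: float = 0.01
    q_max: float = 0.0
    min_unique_peptides: int = 2
    min_total_abundance: float = 9e6

    def __post_init__(self) -> None:
        for name in ("pep_max", "q_max", "min_unique_peptides", "min_total_abundance"):
            if getattr(self, name) < 0:
                raise ConfigError(f"FilterConfig.{name} must be >= 0")


#: Reject reasons, in the order the clauses are evaluated.
REJECT_REASONS = ("pep", "q_value", "unique_peptides", "total_abundance")


def read_report(path, design: SampleDesign) -> list[ProteinRecord]:
    """Parse a protein report CSV/TSV into records.

    The delimiter is auto-detected. The header must contain every column in
    :data:`REPORT_COLUMNS` plus one abundance column per sample id in
    ``design``. Empty abundance cells become absent entries (missing is never
    coerced to zero). Duplicate accessions and negative abundances are
    rejected.
    """
    with open(path) as handle:
        header_line = handle.readline()
    sep = "\t" if "\t" in header_line else ","
    # round_trip parsing so written abundances are recovered bit-exactly
    frame = pd.read_csv(
        path, sep=sep, dtype={"accession": str}, float_precision="round_trip"
    )
    required = list(REPORT_COLUMNS) + list(design.sample_ids)
    for col in required:
        if col not in frame.columns:
            raise SchemaError(f"report is missing required column {col!r}")

    if frame["accession"].duplicated().any():
        dupes = frame.loc[frame["accession"].duplicated(), "accession"].tolist()
        raise ValidationError(f"duplicate accession(s) in report: {sorted(set(dupes))}")

    records: list[ProteinRecord] = []
    for row in frame.itertuples(index=False):
        abundance: dict[str, float] = {}
        for sid in design.sample_ids:
            value = getattr(row, sid)
            if pd.isna(value) or value == "":
                continue
            value = float(value)
            if value < 0:
                raise ValidationError(
                    f"negative abundance for {row.accession} in sample {sid}"
                )
            abundance[sid] = value
        records.append(
            ProteinRecord(
                accession=str(row.accession),
                gene="" if pd.isna(row.gene) else str(row.gene),
                description="" if pd.isna(row.description) else str(row.description),
                mw_kda=float(row.mw_kda),
                pep=float(row.pep),
                q_value=float(row.q_value),
                unique_peptides=int(row.unique_peptides),
                modifications=""
                if pd.isna(row.modifications)
                else str(row.modifications),
                abundance=abundance,
            )
        )
    return records


def first_failing_clause(record: ProteinRecord, config: FilterConfig) -> str | None:
    """Return the first filter clause the record fails, or None if it passes.

    Clauses are evaluated in a fixed order (PEP, q-value, unique peptides,
    summed abundance) so that the reported rejection reason is deterministic.
    """
    if not record.pep < config.pep_max:
        return "pep"
    if not record.q_value <= config.q_max:
        return "q_value"
    if not record.unique_peptides >= config.min_unique_peptides:
        return "unique_peptides"
    if not record.total_abundance() >= config.min_total_abundance:
        return "total_abundance"
    return None


def apply_filters(
    records: Sequence[ProteinRecord], config: FilterConfig | None = None
) -> tuple[list[ProteinRecord], list[tuple[ProteinRecord, str]]]:
    """Partition records into (kept, rejected-with-reason).

    ``kept + [r for r, _ in rejected]`` is always a permutation of the input.
    """
    config = config or FilterConfig()
    kept: list[ProteinRecord] = []
    rejected: list[tuple[ProteinRecord, str]] = []
    for record in records:
        reason = first_failing_clause(record, config)
        if reason is None:
            kept.append(record)
        else:
            rejected.append((record, reason))
    return kept, rejected


def candidate_counts(
    kept: Sequence[ProteinRecord],
    design: SampleDesign,
    lines: Sequence[str] | None = None,
) -> dict[str, int]:
    """Count kept proteins with a present abundance in each cell line's samples.

    A protein contributes to a line's count if it is quantified in at least
    one of that line's samples. ``lines`` defaults to every cell line in the
    design; requesting a line not in the design is an error.
    """
    if lines is None:
        lines = design.cell_lines
    known = set(design.cell_lines)
    counts: dict[str, int] = {}
    for line in lines:
        if line not in known:
            raise ValidationError(f"unknown cell line {line!r} (not in sample design)")
        sample_ids = design.samples_for_line(line)
        counts[line] = sum(1 for rec in kept if rec.present_in(sample_ids))
    return counts


def records_to_frame(
    records: Sequence[ProteinRecord],
    design: SampleDesign,
    reject_reasons: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Render records back into report-table layout (absent cells become NaN)."""
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "accession": rec.accession,
            "gene": rec.gene,
            "description": rec.description,
            "mw_kda": rec.mw_kda,
            "pep": rec.pep,
            "q_value": rec.q_value,
            "unique_peptides": rec.unique_peptides,
            "modifications": rec.modifications,
        }
        for sid in design.sample_ids:
            row[sid] = rec.abundance.get(sid, float("nan"))
        if reject_reasons is not None:
            row["reject_reason"] = reject_reasons.get(rec.accession, "")
        rows.append(row)
    columns = list(REPORT_COLUMNS) + list(design.sample_ids)
    if reject_reasons is not None:
        columns.append("reject_reason")
    return pd.DataFrame(rows, columns=columns)
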