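"""Keratin mass fractions and keratin-composition percentages.

The keratin mass fraction of a sample is the summed abundance of keratin
(bait-class) proteins divided by the summed abundance of all proteins
quantified in that sample. The per-sample fraction vector doubles as the
reference against which every candidate protein is correlated ("correlation
with keratin content"); an absolute-abundance variant of the vector is
available since either reading is defensible.

Missing values are excluded from both numerator and denominator, consistent
with the ingest convention that an absent cell is not a zero.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .ingest import ProteinRecord, SampleDesign

__all__ = [
    "KeratinConfig",
    "keratin_fraction",
    "keratin_fractions",
    "keratin_vector",
    "keratin_composition",
]


@dataclass(frozen=True)
class KeratinConfig:
    """How keratin (bait-class) proteins are recognized.

    A record counts as keratin when its accession is in ``accessions`` or its
    gene symbol matches one of the (case-insensitive, shell-style)
    ``gene_patterns``. The default pattern captures the conventional Krt*
    symbols. ``bait_id`` optionally names the bait keratin's accession.
    """

    gene_patterns: tuple[str, ...] = ("Krt*",)
    accessions: frozenset[str] = frozenset()
    bait_id: str | None = None

    def __post_init__(self) -> None:
        if not self.gene_patterns and not self.accessions:
            raise ConfigError(
                "KeratinConfig requires gene_patterns or accessions to be non-empty"
            )

    def is_keratin(self, record: ProteinRecord) -> bool:
        if record.accession in self.accessions:
            return True
        gene = (record.gene or "").lower()
        return any(fnmatch.fnmatch(gene, pat.lower()) for pat in self.gene_patterns)


def keratin_fraction(
    records: Sequence[ProteinRecord],
    sample_id: str,
    config: KeratinConfig | None = None,
) -> float | None:
    """Keratin fraction of one sample's total quantified abundance, in [0, 1].

    Returns ``None`` (not evaluable) when no protein is quantified in the
    sample at all; returns 0.0 when proteins are present but none is keratin.
    """
    config = config or KeratinConfig()
    total = 0.0
    keratin_sum = 0.0
    any_present = False
    for record in records:
        value = record.abundance.get(sample_id)
        if value is None:
            continue
        any_present = True
        total += value
        if config.is_keratin(record):
            keratin_sum += value
    if not any_present or total == 0:
        return None
    return keratin_sum / total


def keratin_fractions(
    records: Sequence[ProteinRecord],
    design: SampleDesign,
    config: KeratinConfig | None = None,
) -> dict[str, float | None]:
    """Per-sample keratin mass fractions, in design order."""
    return {
        sid: keratin_fraction(records, sid, config) for sid in design.sample_ids
    }


def keratin_vector(
    records: Sequence[ProteinRecord],
    design: SampleDesign,
    config: KeratinConfig | None = None,
    mode: str = "fraction",
) -> np.ndarray:
    """Reference keratin vector for correlation analysis, in design order.

    ``mode="fraction"`` gives the per-sample keratin mass fraction;
    ``mode="absolute"`` the per-sample summed keratin abundance. Samples with
    nothing quantified yield NaN.
    """
    if mode not in ("fraction", "absolute"):
        raise ConfigError(f"keratin vector mode must be 'fraction' or 'absolute', got {mode!r}")
    config = config or KeratinConfig()
    values = []
    for sid in design.sample_ids:
        if mode == "fraction":
            frac = keratin_fraction(records, sid, config)
            values.append(np.nan if frac is None else frac)
        else:
            present = [
                rec.abundance[sid]
                for rec in records
                if config.is_keratin(rec) and sid in rec.abundance
            ]
            values.append(float(np.sum(present)) if present else np.nan)
    return np.asarray(values, dtype=float)


def keratin_composition(
    records: Sequence[ProteinRecord],
    config: KeratinConfig | None = None,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, float] | None:
    """Percent of total keratin abundance (summed over all samples) per group.

    ``groups`` maps a group name to the gene symbols (shell-style patterns
    allowed) it covers; keratins matching no group are pooled under
    ``"other"`` so that the reported percentages always sum to 100 up to
    rounding. With ``groups=None`` each keratin gene is its own group.
    Returns ``None`` when no keratin abundance is present at all.
    """
    config = config or KeratinConfig()
    totals: dict[str, float] = {}
    for record in records:
        if not config.is_keratin(record):
            continue
        label = record.gene or record.accession
        totals[label] = totals.get(label, 0.0) + record.total_abundance()
    grand_total = sum(totals.values())
    if grand_total == 0:
        return None

    if groups is None:
        return {gene: 100.0 * value / grand_total for gene, value in totals.items()}

    composition = {name: 0.0 for name in groups}
    other = 0.0
    for gene, value in totals.items():
        for name, patterns in groups.items():
            if any(fnmatch.fnmatch(gene.lower(), str(p).lower()) for p in patterns):
                composition[name] += 100.0 * value / grand_total
                break
        else:
            other += 100.0 * value / grand_total
    if other > 0:
        composition["other"] = composition.get("other", 0.0) + other
    return composition
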