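"""Pairwise Pearson correlation with explicit missing-value validation.

Correlations between protein abundance profiles are computed on
pairwise-complete observations: for a pair of proteins only the samples in
which *both* are quantified enter the calculation. A pair is valid only when
at least ``min_pairs`` (default 5) such complete observations exist — with a
six-sample design this means a protein missing from two samples can never
yield a defined coefficient, and every one of its pairs is excluded rather
than silently computed on too few points. Excluded pairs are counted, and
``n_excluded + n_computed == n(n-1)/2`` holds for every run.

Both the signed Pearson r and the coefficient of determination CD = r^2 are
carried on each entry, because downstream module extraction interprets the
sign (cooperating modules are positively, antagonistic modules negatively
correlated) while CD is the primary association strength.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .ingest import ProteinRecord, SampleDesign

__all__ = [
    "CorrelationConfig",
    "CorrelationEntry",
    "PearsonResult",
    "pearson",
    "pair_universe",
    "correlation_table",
    "keratin_correlations",
    "entries_to_frame",
    "correlation_matrix",
]

INSUFFICIENT_PAIRS = "insufficient_pairs"
ZERO_VARIANCE = "zero_variance"


@dataclass(frozen=True)
class CorrelationConfig:
    """Validation rules for the correlation stage.

    ``min_pairs`` is the minimum number of both-present observations for a
    pair to be computed. ``min_present`` controls the analysis universe: a
    protein enters pairwise analysis only if quantified in at least that many
    samples (default ``n_samples - 1``, i.e. at most one missing sample).
    ``log_transform`` correlates log10 abundances instead of raw values.
    """

    min_pairs: int = 5
    min_present: int | None = None
    log_transform: bool = False
    keratin_vector_mode: str = "fraction"

    def __post_init__(self) -> None:
        if self.min_pairs < 2:
            raise ConfigError("CorrelationConfig.min_pairs must be >= 2")
        if self.min_present is not None and self.min_present < 0:
            raise ConfigError("CorrelationConfig.min_present must be >= 0")
        if self.keratin_vector_mode not in ("fraction", "absolute"):
            raise ConfigError(
                "CorrelationConfig.keratin_vector_mode must be 'fraction' or 'absolute'"
            )


@dataclass(frozen=True)
class PearsonResult:
    """Pearson r and CD on the complete positions of two vectors."""

    r: float | None
    cd: float | None
    n_complete: int
    excluded_reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.excluded_reason is None


@dataclass(frozen=True)
class CorrelationEntry:
    """A validated (or excluded) unordered protein pair."""

    a: str
    b: str
    r: float | None
    cd: float | None
    n_complete: int
    excluded_reason: str | None = None

    @property
    def pair(self) -> tuple[str, str]:
        return (self.a, self.b)

    @property
    def defined(self) -> bool:
        return self.excluded_reason is None


def pearson(
    x: Sequence[float], y: Sequence[float], min_pairs: int = 2
) -> PearsonResult:
    """Pearson r (and CD = r^2) on the both-present positions of x and y.

    NaN marks a missing value. Pairs with fewer than ``min_pairs`` complete
    positions are flagged ``insufficient_pairs``; a constant sub-vector is
    flagged ``zero_variance``. Neither condition raises: degenerate proteins
    must not abort a pipeline run.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("pearson requires equal-length vectors")
    mask = ~(np.isnan(x) | np.isnan(y))
    n_complete = int(mask.sum())
    if n_complete < max(2, min_pairs):
        return PearsonResult(None, None, n_complete, INSUFFICIENT_PAIRS)
    xs, ys = x[mask], y[mask]
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return PearsonResult(None, None, n_complete, ZERO_VARIANCE)
    r = float(stats.pearsonr(xs, ys).statistic)
    r = max(-1.0, min(1.0, r))
    return PearsonResult(r, r * r, n_complete)


def _profile(record: ProteinRecord, design: SampleDesign, log_transform: bool) -> np.ndarray:
    values = np.array(
        [record.abundance.get(sid, np.nan) for sid in design.sample_ids], dtype=float
    )
    if log_transform:
        with np.errstate(divide="ignore"):
            values = np.log10(values)
    return values


def pair_universe(
    kept_records: Sequence[ProteinRecord],
    design: SampleDesign,
    config: CorrelationConfig | None = None,
) -> tuple[list[ProteinRecord], list[tuple[str, str]], int]:
    """Form the analysis universe and its unordered pair list.

    The universe holds QC-passing proteins quantified in at least
    ``min_present`` samples (default: all but one). Returns the universe
    records, the n(n-1)/2 unordered accession pairs in sorted order, and the
    pair count.
    """
    config = config or CorrelationConfig()
    min_present = (
        config.min_present
        if config.min_present is not None
        else len(design.sample_ids) - 1
    )
    universe = [
        rec for rec in kept_records if len(rec.abundance) >= min_present
    ]
    universe.sort(key=lambda rec: rec.accession)
    accs = [rec.accession for rec in universe]
    pairs = list(combinations(accs, 2))
    n_total = len(accs) * (len(accs) - 1) // 2
    return universe, pairs, n_total


def correlation_table(
    kept_records: Sequence[ProteinRecord],
    design: SampleDesign,
    config: CorrelationConfig | None = None,
) -> tuple[list[CorrelationEntry], int]:
    """All pairwise correlations over the analysis universe.

    Each unordered pair appears exactly once; pairs failing the
    completeness/variance rules carry an exclusion flag instead of a
    coefficient. Returns ``(entries, n_excluded)``.
    """
    config = config or CorrelationConfig()
    universe, pairs, _ = pair_universe(kept_records, design, config)
    profiles = {
        rec.accession: _profile(rec, design, config.log_transform) for rec in universe
    }
    entries: list[CorrelationEntry] = []
    n_excluded = 0
    for a, b in pairs:
        result = pearson(profiles[a], profiles[b], min_pairs=config.min_pairs)
        if not result.defined:
            n_excluded += 1
        entries.append(
            CorrelationEntry(
                a, b, result.r, result.cd, result.n_complete, result.excluded_reason
            )
        )
    return entries, n_excluded


def keratin_correlations(
    kept_records: Sequence[ProteinRecord],
    keratin_vec: np.ndarray,
    design: SampleDesign,
    config: CorrelationConfig | None = None,
) -> dict[str, PearsonResult]:
    """Each protein's Pearson r / CD against the keratin reference vector.

    The same missing-value rules apply: samples where the protein is absent
    (or the keratin vector undefined) are dropped, and fewer than
    ``min_pairs`` remaining observations exclude the protein.
    """
    config = config or CorrelationConfig()
    keratin_vec = np.asarray(keratin_vec, dtype=float)
    if keratin_vec.shape != (len(design.sample_ids),):
        raise ValueError("keratin vector length must match the number of samples")
    out: dict[str, PearsonResult] = {}
    for rec in kept_records:
        profile = _profile(rec, design, config.log_transform)
        out[rec.accession] = pearson(profile, keratin_vec, min_pairs=config.min_pairs)
    return out


def entries_to_frame(entries: Sequence[CorrelationEntry]) -> pd.DataFrame:
    """Long-format table (protein_a, protein_b, n_complete, r, cd, excluded_reason)."""
    return pd.DataFrame(
        {
            "protein_a": [e.a for e in entries],
            "protein_b": [e.b for e in entries],
            "n_complete": [e.n_complete for e in entries],
            "r": [e.r for e in entries],
            "cd": [e.cd for e in entries],
            "excluded_reason": [e.excluded_reason or "" for e in entries],
        }
    )


def correlation_matrix(
    entries: Sequence[CorrelationEntry], order: Sequence[str]
) -> pd.DataFrame:
    """Square signed-r matrix over ``order`` (heatmap layout; diagonal 1)."""
    index = list(order)
    matrix = pd.DataFrame(np.nan, index=index, columns=index)
    for acc in index:
        matrix.loc[acc, acc] = 1.0
    wanted = set(index)
    for e in entries:
        if e.defined and e.a in wanted and e.b in wanted:
            matrix.loc[e.a, e.b] = e.r
            matrix.loc[e.b, e.a] = e.r
    return matrix
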