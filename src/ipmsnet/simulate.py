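"""Seeded simulation of IP-MS protein reports with planted statistical structure.

The generator emulates the data layout of a small co-immunoprecipitation
study: a handful of samples (by default four antibody-capture samples, one
per cell line, plus two no-antibody controls), lognormal MS1 abundances
spanning several orders of magnitude, and the structures the downstream
stages are meant to detect:

* a *core module* of proteins whose abundances are pairwise proportional
  across samples (a shared latent per-sample intensity, per-protein scale
  factors, multiplicative lognormal noise) — these have near-perfect
  coefficients of determination;
* an *antagonist module* built on the latent vector reflected about its
  mid-range, so every antagonist is negatively correlated with every core
  member (exactly r = -1 in the noise-free limit) while antagonists are
  positively correlated with one another; the first antagonist serves as the
  module anchor;
* *capture-enriched* proteins whose IP-sample abundances are a configurable
  factor above their control level before noise;
* *keratin* rows whose per-sample totals are set so that the keratin mass
  fraction of each sample hits a configured target exactly (when nothing is
  missing) — these provide the reference vector for keratin-correlation
  analysis;
* independent *background* proteins with their own per-sample lognormal
  variation;
* missing cells from two mechanisms: missing-completely-at-random (a flat
  per-cell rate) and missing-not-at-random left-censoring (a logistic
  dropout probability that grows as log10 abundance falls);
* QC metadata (PEP, q-value, unique-peptide count) with a configured
  fraction of background rows given failing metrics, one failing clause per
  row.

All randomness flows through a single :class:`numpy.random.Generator` seeded
from ``SimConfig.seed`` (PCG64 bit generator), so an identical configuration
produces byte-identical fixture files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .ingest import REPORT_COLUMNS, Sample, SampleDesign

__all__ = ["SimConfig", "GroundTruth", "generate", "write_fixture", "read_truth"]

#: Cell-line labels used for IP samples, in order.
DEFAULT_CELL_LINES = ("4C9", "2C1", "1000W", "BP3")

#: Default per-sample keratin mass-fraction targets (four IP lines in the
#: order above, then the two no-antibody controls).
DEFAULT_KERATIN_TARGETS = (0.3474, 0.4903, 0.5540, 0.6243, 0.5464, 0.3468)

#: Keratin gene symbols and their share of total keratin abundance. The two
#: dominant basal-cell keratins (Krt14 type I, Krt5 type II) carry ~67%, the
#: bait pair Krt17/Krt6a ~21%, differentiation keratins a few percent.
DEFAULT_KERATIN_WEIGHTS = (
    ("Krt14", 0.40),
    ("Krt5", 0.27),
    ("Krt17", 0.11),
    ("Krt6a", 0.10),
    ("Krt8", 0.08),
    ("Krt4", 0.03),
    ("Krt10", 0.01),
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Noise parameters are standard deviations of multiplicative lognormal
    noise in natural-log space; ``mnar_midpoint`` is on the log10 abundance
    scale. ``mnar_steepness = 0`` disables abundance-dependent dropout
    entirely (and ``mcar_rate = 0`` disables the random mechanism), so a
    fully observed report can be requested.
    """

    n_samples: int = 6
    n_ip: int = 4
    n_background: int = 12
    n_enriched: int = 8
    core_size: int = 5
    n_antagonists: int = 3
    core_noise_sigma: float = 0.1
    background_sigma: float = 0.25
    latent_sigma: float = 0.9
    capture_factor: float = 4.0
    base_log10_mean: float = 7.5
    base_log10_sd: float = 0.6
    keratin_fraction_targets: tuple[float, ...] | None = DEFAULT_KERATIN_TARGETS
    mnar_steepness: float = 3.0
    mnar_midpoint: float = 4.5
    mcar_rate: float = 0.01
    qc_fail_fraction: float = 0.1
    seed: int = 0
    cell_lines: tuple[str, ...] = DEFAULT_CELL_LINES

    def __post_init__(self) -> None:
        counts = (
            "n_samples",
            "n_ip",
            "n_background",
            "n_enriched",
            "core_size",
            "n_antagonists",
        )
        for name in counts:
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 0:
                raise ConfigError(f"SimConfig.{name} must be a non-negative integer")
        if self.n_ip >= self.n_samples:
            raise ConfigError("SimConfig.n_ip must be < n_samples")
        if self.n_ip < 1 or self.n_samples - self.n_ip < 1:
            raise ConfigError("SimConfig.n_ip must leave >=1 IP and >=1 control sample")
        for name in ("mcar_rate", "qc_fail_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"SimConfig.{name} must lie in [0, 1]")
        if self.capture_factor <= 0:
            raise ConfigError("SimConfig.capture_factor must be > 0")
        for name in ("core_noise_sigma", "background_sigma", "latent_sigma",
                     "mnar_steepness", "base_log10_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"SimConfig.{name} must be >= 0")
        if self.keratin_fraction_targets is not None:
            targets = self.keratin_fraction_targets
            if len(targets) != self.n_samples:
                raise ConfigError(
                    "SimConfig.keratin_fraction_targets must have one entry per sample"
                )
            if any(not 0.0 <= t < 1.0 for t in targets):
                raise ConfigError(
                    "SimConfig.keratin_fraction_targets entries must lie in [0, 1)"
                )

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            value = getattr(self, f.name)
            out[f.name] = list(value) if isinstance(value, tuple) else value
        out["rng"] = "numpy.random.Generator(PCG64)"
        return out


@dataclass
class GroundTruth:
    """Planted labels the generator emits alongside the report (test oracle)."""

    core_members: set[str] = field(default_factory=set)
    antagonist_members: set[str] = field(default_factory=set)
    anchor: str | None = None
    enriched_members: set[str] = field(default_factory=set)
    qc_failing: set[str] = field(default_factory=set)
    missing_cells: set[tuple[str, str]] = field(default_factory=set)

    def to_json_dict(self) -> dict:
        return {
            "core_members": sorted(self.core_members),
            "antagonist_members": sorted(self.antagonist_members),
            "anchor": self.anchor,
            "enriched_members": sorted(self.enriched_members),
            "qc_failing": sorted(self.qc_failing),
            "missing_cells": sorted(list(cell) for cell in self.missing_cells),
        }


def _make_design(config: SimConfig) -> SampleDesign:
    samples = []
    for i in range(config.n_ip):
        line = (
            config.cell_lines[i]
            if i < len(config.cell_lines)
            else f"LINE{i + 1}"
        )
        samples.append(Sample(f"ip_{line}", "ip", line))
    for j in range(config.n_samples - config.n_ip):
        samples.append(Sample(f"ctrl_{j + 1}", "control", "pool"))
    return SampleDesign(tuple(samples))


def generate(config: SimConfig) -> tuple[pd.DataFrame, SampleDesign, GroundTruth]:
    """Generate (report, design, truth) for the configured synthetic study.

    The report is a DataFrame in the external report layout (identity and QC
    columns, then one abundance column per sample id; missing cells are NaN).
    """
    rng = np.random.default_rng(config.seed)
    design = _make_design(config)
    n_s = config.n_samples
    is_ip = np.array([s.condition == "ip" for s in design.samples])
    truth = GroundTruth()

    names: list[tuple[str, str, str]] = []  # (accession, gene, description)
    profiles: list[np.ndarray] = []

    def lognoise(sigma: float, size) -> np.ndarray:
        return np.exp(rng.normal(0.0, sigma, size)) if sigma > 0 else np.ones(size)

    def base_scale(size: int) -> np.ndarray:
        return 10.0 ** rng.normal(config.base_log10_mean, config.base_log10_sd, size)

    # Shared latent per-sample intensity for the planted modules: standard
    # normal quantiles scaled by latent_sigma and shuffled, then
    # exponentiated. The dynamic range of the module profile is thereby
    # fixed by latent_sigma while its orientation across samples is random,
    # so a planted module is always detectable at the configured noise level.
    # Identifiability constraint: orientations nearly collinear with the
    # IP/control capture indicator are rejected — a module profile that
    # coincides with the capture pattern would be indistinguishable from
    # capture enrichment, which the recovery oracles must keep separate.
    quantiles = stats.norm.ppf((np.arange(n_s) + 0.5) / n_s)
    indicator = is_ip.astype(float)
    for _ in range(1000):
        latent = np.exp(config.latent_sigma * rng.permutation(quantiles))
        collinearity = abs(float(np.corrcoef(latent, indicator)[0, 1]))
        if collinearity <= 0.45 or config.latent_sigma == 0:
            break
    reflected = latent.max() + latent.min() - latent  # r = -1 with latent

    core_scales = base_scale(config.core_size)
    for i in range(config.core_size):
        acc = f"CORE{i + 1:02d}"
        names.append((acc, f"Core{i + 1}", "planted core-module protein"))
        profiles.append(core_scales[i] * latent * lognoise(config.core_noise_sigma, n_s))
        truth.core_members.add(acc)

    antagonist_scales = base_scale(config.n_antagonists)
    for i in range(config.n_antagonists):
        acc = f"ANTA{i + 1:02d}"
        names.append((acc, f"Anta{i + 1}", "planted antagonist-module protein"))
        profiles.append(
            antagonist_scales[i] * reflected * lognoise(config.core_noise_sigma, n_s)
        )
        truth.antagonist_members.add(acc)
        if i == 0:
            truth.anchor = acc

    # Enriched proteins carry their own independent per-sample biological
    # variation (background_sigma) on top of the capture factor and the
    # measurement noise, so enrichment does not by itself make two proteins
    # into a co-abundance module.
    enriched_scales = base_scale(config.n_enriched)
    capture = np.where(is_ip, config.capture_factor, 1.0)
    for i in range(config.n_enriched):
        acc = f"ENRI{i + 1:03d}"
        names.append((acc, f"Enri{i + 1}", "planted capture-enriched protein"))
        profiles.append(
            enriched_scales[i]
            * capture
            * lognoise(config.background_sigma, n_s)
            * lognoise(config.core_noise_sigma, n_s)
        )
        truth.enriched_members.add(acc)

    background_scales = base_scale(config.n_background)
    background_accs = []
    for i in range(config.n_background):
        acc = f"BACK{i + 1:03d}"
        names.append((acc, f"Back{i + 1}", "independent background protein"))
        profiles.append(background_scales[i] * lognoise(config.background_sigma, n_s))
        background_accs.append(acc)

    # Keratin rows: per-sample keratin total K_s chosen so that
    # K_s / (K_s + T_s) equals the target fraction, with T_s the non-keratin
    # total in sample s; split across keratin genes by fixed weights. No noise
    # is applied so realized fractions equal the targets when nothing is missing.
    if config.keratin_fraction_targets is not None and profiles:
        targets = np.asarray(config.keratin_fraction_targets, dtype=float)
        non_keratin_total = np.sum(profiles, axis=0)
        keratin_total = targets / (1.0 - targets) * non_keratin_total
        for gene, weight in DEFAULT_KERATIN_WEIGHTS:
            acc = gene.upper()
            names.append((acc, gene, f"keratin ({gene}), bait-class protein"))
            profiles.append(weight * keratin_total)

    n_proteins = len(names)
    if n_proteins == 0:
        report = pd.DataFrame(columns=list(REPORT_COLUMNS) + list(design.sample_ids))
        return report, design, truth

    matrix = np.vstack(profiles)

    # QC metadata: clean metrics everywhere, then failing clauses for a
    # configured fraction of background rows (one clause per failing row so
    # each filter is exercised).
    mw = np.round(rng.uniform(10.0, 300.0, n_proteins), 1)
    pep = rng.uniform(0.0, 0.009, n_proteins)
    q_value = np.zeros(n_proteins)
    unique_peptides = rng.integers(2, 31, n_proteins)

    n_fail = int(round(config.qc_fail_fraction * len(background_accs)))
    accs = [acc for acc, _, _ in names]
    index_of = {acc: i for i, acc in enumerate(accs)}
    if n_fail > 0:
        failing = rng.choice(len(background_accs), size=n_fail, replace=False)
        modes = rng.integers(0, 3, n_fail)
        for pos, mode in zip(np.sort(failing), modes):
            idx = index_of[background_accs[pos]]
            if mode == 0:
                pep[idx] = rng.uniform(0.02, 0.5)
            elif mode == 1:
                q_value[idx] = rng.uniform(0.001, 0.05)
            else:
                unique_peptides[idx] = 1
            truth.qc_failing.add(accs[idx])

    # Missingness: MCAR and MNAR draws are independent; a cell is missing if
    # either mechanism fires. Steepness 0 switches MNAR off.
    mcar_mask = rng.random((n_proteins, n_s)) < config.mcar_rate
    if config.mnar_steepness > 0:
        with np.errstate(divide="ignore"):
            log10_ab = np.log10(np.where(matrix > 0, matrix, np.nan))
        p_mnar = 1.0 / (
            1.0 + np.exp(-config.mnar_steepness * (config.mnar_midpoint - log10_ab))
        )
        p_mnar = np.nan_to_num(p_mnar, nan=1.0)
        mnar_mask = rng.random((n_proteins, n_s)) < p_mnar
    else:
        mnar_mask = np.zeros((n_proteins, n_s), dtype=bool)
    missing = mcar_mask | mnar_mask

    values = matrix.astype(float)
    for i in range(n_proteins):
        for j, sid in enumerate(design.sample_ids):
            if missing[i, j]:
                values[i, j] = np.nan
                truth.missing_cells.add((accs[i], sid))

    report = pd.DataFrame(
        {
            "accession": accs,
            "gene": [g for _, g, _ in names],
            "description": [d for _, _, d in names],
            "mw_kda": mw,
            "pep": pep,
            "q_value": q_value,
            "unique_peptides": unique_peptides,
            "modifications": [""] * n_proteins,
        }
    )
    for j, sid in enumerate(design.sample_ids):
        report[sid] = values[:, j]
    return report, design, truth


def write_fixture(
    report: pd.DataFrame,
    design: SampleDesign,
    truth: GroundTruth,
    prefix,
) -> dict[str, Path]:
    """Write report CSV, sample-sheet CSV and truth JSON under a path prefix.

    Missing abundances are written as empty cells. Returns the mapping of
    artifact name to path. The files round-trip losslessly through
    :func:`ipmsnet.ingest.read_report` / :meth:`SampleDesign.from_csv` /
    :func:`read_truth`.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "report": prefix.with_name(prefix.name + "_report.csv"),
        "samples": prefix.with_name(prefix.name + "_samples.csv"),
        "truth": prefix.with_name(prefix.name + "_truth.json"),
    }
    report.to_csv(paths["report"], index=False)
    design.to_csv(paths["samples"])
    with open(paths["truth"], "w") as handle:
        json.dump(truth.to_json_dict(), handle, indent=2, sort_keys=True)
        handle.write("\n")
    return paths


def read_truth(path) -> GroundTruth:
    """Re-read a truth JSON written by :func:`write_fixture`."""
    with open(path) as handle:
        data = json.load(handle)
    return GroundTruth(
        core_members=set(data["core_members"]),
        antagonist_members=set(data["antagonist_members"]),
        anchor=data.get("anchor"),
        enriched_members=set(data["enriched_members"]),
        qc_failing=set(data["qc_failing"]),
        missing_cells={(acc, sid) for acc, sid in data["missing_cells"]},
    )
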