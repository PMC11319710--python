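"""End-to-end orchestration: ingest -> QC -> enrichment -> keratin -> correlation -> network.

A single :class:`PipelineConfig` (serializable to/from YAML, unknown keys
rejected) drives a full run. Every stage writes its table under the output
directory and contributes counts to a machine-readable run manifest, so all
thresholds and stage sizes of a run are auditable. Reruns with identical
config and inputs produce an identical manifest hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import networkx
import numpy
import pandas
import scipy
import yaml

from . import __version__
from .correlate import (
    CorrelationConfig,
    correlation_table,
    entries_to_frame,
    pair_universe,
)
from .enrich import enrichment_table
from .errors import ConfigError, ValidationError
from .ingest import (
    FilterConfig,
    SampleDesign,
    apply_filters,
    candidate_counts,
    read_report,
    records_to_frame,
)
from .keratin import KeratinConfig, keratin_composition, keratin_fractions, keratin_vector
from .network import (
    classify_and_count,
    cores_to_json_dict,
    find_antagonists,
    find_cores,
    load_class_annotation,
    write_graph_outputs,
)
from .simulate import SimConfig, generate, write_fixture

logger = logging.getLogger("ipmsnet")
if not logger.handlers:  # stage-tagged lines to stderr
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    logger.addHandler(handler)
logger.setLevel(logging.INFO)


@dataclass(frozen=True)
class NetworkConfig:
    """Module-extraction parameters for the network stage."""

    tau_core: float = 0.75
    min_size: int = 3
    min_degree: int = 2
    mode: str = "component"
    anchor: str | None = None
    reference_module: tuple[str, ...] | None = None
    strict_undefined: bool = False


@dataclass(frozen=True)
class PipelineConfig:
    """Paths, per-stage settings and the simulation seed for one run."""

    report: str | None = None
    samples: str | None = None
    annotation: str | None = None
    out_dir: str = "ipmsnet_out"
    filters: FilterConfig = field(default_factory=FilterConfig)
    fold_threshold: float = 2.0
    enrich_stat: str = "mean"
    require_significance: bool = False
    alpha: float = 0.05
    correlation: CorrelationConfig = field(default_factory=CorrelationConfig)
    keratin: KeratinConfig = field(default_factory=KeratinConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    seed: int = 0

    _NESTED = {
        "filters": FilterConfig,
        "correlation": CorrelationConfig,
        "keratin": KeratinConfig,
        "network": NetworkConfig,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls) if not f.name.startswith("_")}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config key(s): {sorted(unknown)}")
        kwargs = dict(data)
        for name, sub_cls in cls._NESTED.items():
            if name in kwargs and isinstance(kwargs[name], dict):
                sub_known = {f.name for f in fields(sub_cls)}
                sub_unknown = set(kwargs[name]) - sub_known
                if sub_unknown:
                    raise ConfigError(
                        f"unknown key(s) in {name!r} config: {sorted(sub_unknown)}"
                    )
                sub = dict(kwargs[name])
                for key, value in sub.items():
                    if isinstance(value, list):
                        sub[key] = tuple(value)
                kwargs[name] = sub_cls(**sub)
        if "keratin" in kwargs and isinstance(kwargs["keratin"], KeratinConfig):
            pass
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        def convert(obj):
            if isinstance(obj, (list, tuple, set, frozenset)):
                return sorted(convert(v) for v in obj) if isinstance(obj, (set, frozenset)) else [convert(v) for v in obj]
            if isinstance(obj, dict):
                return {k: convert(v) for k, v in obj.items()}
            return obj

        return convert(asdict(self))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def _versions() -> dict[str, str]:
    return {
        "ipmsnet": __version__,
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "scipy": scipy.version.version,
        "networkx": networkx.__version__,
        "rng": "numpy.random.Generator(PCG64)",
    }


def simulate(sim_config: SimConfig, out_prefix) -> dict:
    """Generate a synthetic study and write its fixture files."""
    report, design, truth = generate(sim_config)
    paths = write_fixture(report, design, truth, out_prefix)
    logger.info("simulate: %d proteins, %d samples -> %s",
                len(report), len(design.samples), paths["report"])
    return {name: str(path) for name, path in paths.items()}


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written to disk)."""
    if config.report is None or config.samples is None:
        raise ConfigError("run_all requires 'report' and 'samples' paths")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- ingest & QC -------------------------------------------------------
    design = SampleDesign.from_csv(config.samples)
    records = read_report(config.report, design)
    kept, rejected = apply_filters(records, config.filters)
    logger.info("ingest_qc: parsed %d, kept %d, rejected %d",
                len(records), len(kept), len(rejected))
    records_to_frame(kept, design, reject_reasons={}).to_csv(
        out_dir / "kept.csv", index=False
    )
    records_to_frame(
        [rec for rec, _ in rejected],
        design,
        reject_reasons={rec.accession: reason for rec, reason in rejected},
    ).to_csv(out_dir / "rejected.csv", index=False)
    counts = candidate_counts(kept, design)
    with open(out_dir / "candidate_counts.json", "w") as fh:
        json.dump(counts, fh, indent=2, sort_keys=True)

    # --- enrichment --------------------------------------------------------
    enrichment = enrichment_table(
        kept,
        design,
        fold_threshold=config.fold_threshold,
        alpha=config.alpha,
        stat=config.enrich_stat,
        require_significance=config.require_significance,
    )
    enriched_flags = {e.accession: bool(e.enriched) for e in enrichment}
    n_enriched = sum(1 for e in enrichment if e.enriched)
    logger.info("enrichment: %d/%d proteins enriched (fold >= %g)",
                n_enriched, len(enrichment), config.fold_threshold)
    pandas.DataFrame(
        {
            "accession": [e.accession for e in enrichment],
            "fold_change": [e.fold_change for e in enrichment],
            "u_statistic": [e.u_statistic for e in enrichment],
            "p_value": [e.p_value for e in enrichment],
            "enriched": [e.enriched for e in enrichment],
            "control_absent": [e.control_absent for e in enrichment],
            "evaluable": [e.evaluable for e in enrichment],
            "n_ip_present": [e.n_ip_present for e in enrichment],
            "n_control_present": [e.n_control_present for e in enrichment],
        }
    ).to_csv(out_dir / "enrichment.csv", index=False)

    # --- keratin metrics ---------------------------------------------------
    fractions = keratin_fractions(kept, design, config.keratin)
    composition = keratin_composition(kept, config.keratin)
    with open(out_dir / "keratin.json", "w") as fh:
        json.dump(
            {"fractions": fractions, "composition": composition},
            fh, indent=2, sort_keys=True,
        )
    kvec = keratin_vector(
        kept, design, config.keratin, mode=config.correlation.keratin_vector_mode
    )

    # --- correlation -------------------------------------------------------
    # Bait-class (keratin) rows are the reference for keratin-content
    # correlation, not interactor candidates: they are excluded from the
    # pairwise universe and enter through the keratin vector instead.
    candidates = [rec for rec in kept if not config.keratin.is_keratin(rec)]
    universe, _, n_pairs_total = pair_universe(candidates, design, config.correlation)
    entries, n_excluded = correlation_table(candidates, design, config.correlation)
    logger.info("correlation: universe %d -> %d pairs (%d excluded)",
                len(universe), n_pairs_total, n_excluded)
    entries_to_frame(entries).to_csv(out_dir / "correlations.csv", index=False)
    from .correlate import keratin_correlations as _keratin_correlations

    kcorr = _keratin_correlations(universe, kvec, design, config.correlation)
    pandas.DataFrame(
        {
            "accession": list(kcorr),
            "r": [res.r for res in kcorr.values()],
            "cd": [res.cd for res in kcorr.values()],
            "n_complete": [res.n_complete for res in kcorr.values()],
            "excluded_reason": [res.excluded_reason or "" for res in kcorr.values()],
        }
    ).to_csv(out_dir / "keratin_correlations.csv", index=False)

    # --- network -----------------------------------------------------------
    net = config.network
    cores = find_cores(
        entries,
        tau_core=net.tau_core,
        min_size=net.min_size,
        min_degree=net.min_degree,
        mode=net.mode,
    )
    antagonists = None
    if net.anchor is not None:
        reference = (
            list(net.reference_module)
            if net.reference_module
            else (list(cores[0].members) if cores else None)
        )
        if reference:
            antagonists = find_antagonists(
                entries, net.anchor, reference, strict_undefined=net.strict_undefined
            )
    logger.info("network: %d core(s)%s", len(cores),
                f", antagonists around {net.anchor}" if antagonists else "")
    with open(out_dir / "modules.json", "w") as fh:
        json.dump(cores_to_json_dict(cores, antagonists), fh, indent=2, sort_keys=True)
    write_graph_outputs(
        entries, net.tau_core, out_dir / "edges.csv", out_dir / "network.graphml"
    )

    venn = None
    if config.annotation is not None:
        annotation = load_class_annotation(config.annotation)
        report_counts = classify_and_count(
            [rec.accession for rec in universe], annotation, enriched_flags
        )
        venn = {
            name: {
                "n": s.n,
                "primary_class_counts": s.primary_class_counts,
                "venn_regions": s.venn_regions,
                "cross_linkers": list(s.cross_linkers),
            }
            for name, s in report_counts.strata.items()
        }
        with open(out_dir / "venn_counts.json", "w") as fh:
            json.dump(venn, fh, indent=2, sort_keys=True)

    # --- manifest ----------------------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "versions": _versions(),
        "stage_counts": {
            "n_parsed": len(records),
            "n_kept": len(kept),
            "n_rejected": len(rejected),
            "candidate_counts": counts,
            "n_enriched": n_enriched,
            "n_universe": len(universe),
            "n_pairs_total": n_pairs_total,
            "n_pairs_computed": n_pairs_total - n_excluded,
            "n_pairs_excluded": n_excluded,
            "n_cores": len(cores),
            "core_sizes": [len(c.members) for c in cores],
            "n_antagonists": len(antagonists.members) if antagonists else 0,
        },
    }
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def validate_manifest_conservation(manifest: dict) -> None:
    """Check the conservation laws a manifest must satisfy; raise if violated."""
    sc = manifest["stage_counts"]
    if sc["n_kept"] + sc["n_rejected"] != sc["n_parsed"]:
        raise ValidationError("manifest violates kept + rejected = parsed")
    n = sc["n_universe"]
    if sc["n_pairs_total"] != n * (n - 1) // 2:
        raise ValidationError("manifest violates pairs = n(n-1)/2")
    if sc["n_pairs_computed"] + sc["n_pairs_excluded"] != sc["n_pairs_total"]:
        raise ValidationError("manifest violates computed + excluded = total pairs")
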