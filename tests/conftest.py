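"""Shared fixtures: synthetic datasets round-tripped through the ingest layer."""

from __future__ import annotations

import pytest

from ipmsnet.ingest import SampleDesign, read_report
from ipmsnet.simulate import SimConfig, generate, write_fixture


def load_dataset(config: SimConfig, tmp_path):
    """Generate a dataset, write it to disk and re-read it through ingest."""
    report, design, truth = generate(config)
    paths = write_fixture(report, design, truth, tmp_path / f"sim{config.seed}")
    design_read = SampleDesign.from_csv(paths["samples"])
    records = read_report(paths["report"], design_read)
    return records, design_read, truth


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """Default-config synthetic study (seed 0) as ingested records."""
    tmp = tmp_path_factory.mktemp("default_dataset")
    return load_dataset(SimConfig(seed=0), tmp)


@pytest.fixture(scope="session")
def clean_dataset(tmp_path_factory):
    """Fully observed, QC-clean dataset (no missingness, no failing rows)."""
    tmp = tmp_path_factory.mktemp("clean_dataset")
    config = SimConfig(
        seed=7, mcar_rate=0.0, mnar_steepness=0.0, qc_fail_fraction=0.0
    )
    return load_dataset(config, tmp)
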