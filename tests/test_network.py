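"""Core extraction, antagonist rule and class/Venn accounting."""

from __future__ import annotations

import random

import numpy as np
import pytest

from ipmsnet.correlate import CorrelationEntry, correlation_table
from ipmsnet.errors import ValidationError
from ipmsnet.network import (
    ClassAnnotation,
    classify_and_count,
    find_antagonists,
    find_cores,
    load_enriched_reference_annotation,
)
from ipmsnet.simulate import SimConfig
from ipmsnet.ingest import apply_filters
from ipmsnet.keratin import KeratinConfig
from conftest import load_dataset


def entry(a, b, r, n=6):
    return CorrelationEntry(min(a, b), max(a, b), r, r * r, n)


def excluded(a, b):
    return CorrelationEntry(min(a, b), max(a, b), None, None, 3, "insufficient_pairs")


class TestFindCores:
    def test_planted_module_recovered_exactly_without_noise_competition(self, tmp_path):
        config = SimConfig(
            seed=2, core_noise_sigma=0.05, n_background=0, n_enriched=0,
            keratin_fraction_targets=None, mcar_rate=0.0, mnar_steepness=0.0,
            qc_fail_fraction=0.0,
        )
        records, design, truth = load_dataset(config, tmp_path)
        entries, _ = correlation_table(records, design)
        cores = find_cores(entries, tau_core=0.75)
        memberships = [set(c.members) for c in cores]
        assert truth.core_members in memberships
        assert truth.antagonist_members in memberships

    def test_no_edges_above_threshold_gives_empty(self):
        entries = [entry("A", "B", 0.5), entry("B", "C", -0.9)]
        assert find_cores(entries, tau_core=0.75) == []

    def test_fully_proportional_universe_single_core(self):
        names = [f"P{i}" for i in range(6)]
        entries = [
            entry(a, b, 1.0) for i, a in enumerate(names) for b in names[i + 1 :]
        ]
        cores = find_cores(entries, tau_core=0.75)
        assert len(cores) == 1
        assert set(cores[0].members) == set(names)

    def test_negative_r_edges_never_used(self):
        # perfect anticorrelation has cd = 1 but must not create an edge
        entries = [
            entry("A", "B", -1.0), entry("B", "C", -1.0), entry("A", "C", 1.0),
        ]
        cores = find_cores(entries, tau_core=0.75, min_size=2, min_degree=0)
        assert len(cores) == 1 and set(cores[0].members) == {"A", "C"}

    def test_min_degree_prunes_single_edge_attachments(self):
        triangle = [entry("A", "B", 0.95), entry("B", "C", 0.95), entry("A", "C", 0.95)]
        pendant = [entry("C", "X", 0.95)]
        cores = find_cores(triangle + pendant, tau_core=0.75, min_degree=2)
        assert len(cores) == 1
        assert set(cores[0].members) == {"A", "B", "C"}
        # disabling the pruning restores plain connected components
        cores_all = find_cores(triangle + pendant, tau_core=0.75, min_degree=0)
        assert set(cores_all[0].members) == {"A", "B", "C", "X"}

    def test_members_ranked_by_degree(self):
        entries = [
            entry("HUB", "A", 0.9), entry("HUB", "B", 0.9), entry("HUB", "C", 0.9),
            entry("A", "B", 0.9), entry("A", "C", 0.9), entry("B", "C", 0.9),
            entry("C", "D", 0.9), entry("B", "D", 0.9),
        ]
        (core,) = find_cores(entries, tau_core=0.75)
        degrees = core.degrees
        assert list(core.members) == sorted(
            core.members, key=lambda m: (-degrees[m], m)
        )

    def test_raising_tau_never_grows_cores(self):
        rng = np.random.default_rng(0)
        names = [f"P{i}" for i in range(12)]
        entries = [
            entry(a, b, float(rng.uniform(-1, 1)))
            for i, a in enumerate(names)
            for b in names[i + 1 :]
        ]
        previous_members = None
        for tau in (0.3, 0.5, 0.7, 0.9):
            cores = find_cores(entries, tau_core=tau, min_size=2, min_degree=0)
            members = set().union(*(c.member_set for c in cores)) if cores else set()
            if previous_members is not None:
                assert members <= previous_members
            previous_members = members


class TestFindAntagonists:
    def test_planted_antagonists_recovered(self, tmp_path):
        config = SimConfig(
            seed=3, mcar_rate=0.0, mnar_steepness=0.0, qc_fail_fraction=0.0
        )
        records, design, truth = load_dataset(config, tmp_path)
        entries, _ = correlation_table(records, design)
        module = find_antagonists(entries, truth.anchor, sorted(truth.core_members))
        assert truth.antagonist_members <= set(module.members)
        assert not (set(module.members) & truth.core_members)
        assert module.anchor_qualifies

    def test_single_positive_reference_coefficient_disqualifies(self):
        entries = [
            entry("X", "ANCHOR", 0.9),
            entry("X", "R1", -0.8),
            entry("X", "R2", 0.1),  # positive with one reference member
            entry("ANCHOR", "R1", -0.9),
            entry("ANCHOR", "R2", -0.9),
        ]
        module = find_antagonists(entries, "ANCHOR", ["R1", "R2"])
        assert "X" not in module.members
        assert "ANCHOR" in module.members  # anchor negative with all references

    def test_undefined_coefficients_tolerated_by_default(self):
        entries = [
            entry("X", "ANCHOR", 0.9),
            entry("X", "R1", -0.8),
            excluded("X", "R2"),
            entry("ANCHOR", "R1", -0.9),
            entry("ANCHOR", "R2", -0.9),
        ]
        tolerant = find_antagonists(entries, "ANCHOR", ["R1", "R2"])
        assert "X" in tolerant.members
        strict = find_antagonists(
            entries, "ANCHOR", ["R1", "R2"], strict_undefined=True
        )
        assert "X" not in strict.members

    def test_reference_order_invariance(self):
        entries = [
            entry("X", "ANCHOR", 0.9),
            entry("X", "R1", -0.8),
            entry("X", "R2", -0.7),
            entry("ANCHOR", "R1", -0.9),
            entry("ANCHOR", "R2", -0.9),
        ]
        reference = ["R1", "R2"]
        baseline = find_antagonists(entries, "ANCHOR", reference)
        for _ in range(5):
            random.shuffle(reference)
            assert (
                find_antagonists(entries, "ANCHOR", reference).members
                == baseline.members
            )

    def test_empty_reference_module_rejected(self):
        with pytest.raises(ValidationError, match="reference"):
            find_antagonists([], "ANCHOR", [])


@pytest.fixture(scope="module")
def reference():
    return load_enriched_reference_annotation()


class TestClassification:
    def test_reference_annotation_counts(self, reference):
        universe = sorted(reference.classes)
        report = classify_and_count(
            universe, reference, {acc: True for acc in universe}
        )
        counts = report.enriched.primary_class_counts
        assert counts["actin"] == 29
        assert counts["microtubule"] == 6
        assert counts["keratin_other"] == 38
        assert len(report.enriched.cross_linkers) == 6

    def test_venn_regions_disjoint_and_conserved(self, reference):
        universe = sorted(reference.classes)
        report = classify_and_count(
            universe, reference, {acc: True for acc in universe}
        )
        regions = report.enriched.venn_regions
        assert sum(regions.values()) == len(universe)
        # a dual-class protein sits in the intersection region only once
        assert regions["actin+microtubule"] == 5
        assert regions["actin+keratin_other"] == 1

    def test_strata_split(self, reference):
        universe = sorted(reference.classes)
        flags = {acc: i % 2 == 0 for i, acc in enumerate(universe)}
        report = classify_and_count(universe, reference, flags)
        assert report.enriched.n + report.not_enriched.n == len(universe)

    def test_unannotated_accession_counts_as_none(self, reference):
        report = classify_and_count(["UNKNOWN1"], reference, {})
        assert report.not_enriched.primary_class_counts["none"] == 1
        assert report.not_enriched.venn_regions == {"none": 1}

    def test_unknown_class_label_rejected(self):
        with pytest.raises(ValidationError, match="unknown class"):
            ClassAnnotation({"P1": ("mystery",)})


class TestRecoveryProperty:
    def test_core_f1_and_antagonist_recall_over_seeds(self, tmp_path):
        """Planted-structure recovery at default config over 20 seeds."""
        keratin_config = KeratinConfig()
        f1s, recalls = [], []
        for seed in range(20):
            records, design, truth = load_dataset(SimConfig(seed=seed), tmp_path)
            kept, _ = apply_filters(records)
            candidates = [r for r in kept if not keratin_config.is_keratin(r)]
            entries, _ = correlation_table(candidates, design)
            cores = find_cores(entries)
            best = 0.0
            for core in cores:
                inter = len(core.member_set & truth.core_members)
                precision = inter / len(core.members)
                recall = inter / len(truth.core_members)
                if precision + recall:
                    best = max(best, 2 * precision * recall / (precision + recall))
            f1s.append(best)
            module = find_antagonists(
                entries, truth.anchor, sorted(truth.core_members)
            )
            recalls.append(
                len(set(module.members) & truth.antagonist_members)
                / len(truth.antagonist_members)
            )
        assert float(np.mean(f1s)) >= 0.9
        assert float(np.mean(recalls)) >= 0.9
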