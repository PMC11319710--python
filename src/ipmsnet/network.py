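"""Module extraction from the correlation table.

Two kinds of modules are extracted from the sign structure of the pairwise
correlation table:

* **Cores** (cooperating modules): connected components of the graph whose
  edges are pairs with positive r and CD at or above ``tau_core``. By
  default each component is then reduced to its 2-core — every member must
  be supported by at least two qualifying edges. With only a handful of
  samples a single high correlation arises by chance a few percent of the
  time, so one edge is weak evidence of membership; requiring two
  independent supporting edges (the "connectedness" of a member within the
  module) keeps chance attachments out. Maximal-clique extraction is
  available as an alternative mode.

* **Antagonist modules**: given an anchor protein and a reference core, the
  antagonist set holds every protein positively correlated with the anchor
  and negatively correlated with *all* reference members for which a
  coefficient is defined. Undefined (excluded) coefficients do not
  disqualify by default — the missing-value rules legitimately leave some
  pairs undetermined — but a strict mode treats them as disqualifying.

Class annotation (actin / microtubule / keratin-or-other / none) is a user
input, not a database lookup; proteins carrying two or more cytoskeletal
classes are reported as candidate cross-linkers, and counts of every Venn
region are returned for enriched and non-enriched strata separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .correlate import CorrelationEntry
from .errors import ValidationError

__all__ = [
    "ClassAnnotation",
    "Core",
    "AntagonistModule",
    "ClassCountReport",
    "build_correlation_graph",
    "find_cores",
    "find_antagonists",
    "classify_and_count",
    "load_class_annotation",
    "load_enriched_reference_annotation",
]

VALID_CLASSES = ("actin", "microtubule", "keratin_other", "none")
CYTOSKELETAL_CLASSES = frozenset({"actin", "microtubule", "keratin_other"})


@dataclass(frozen=True)
class ClassAnnotation:
    """Accession -> ordered class tuple (primary class first).

    The first class is the protein's primary assignment (the table it was
    reported in); any further classes mark additional cytoskeletal elements
    the protein is known to associate with. Order matters only for
    primary-class counting; region and cross-linker logic use the set.
    """

    classes: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for acc, labels in self.classes.items():
            if not labels:
                raise ValidationError(f"annotation for {acc!r} has no classes")
            for label in labels:
                if label not in VALID_CLASSES:
                    raise ValidationError(
                        f"unknown class label {label!r} for {acc!r};"
                        f" valid labels: {VALID_CLASSES}"
                    )

    def get(self, accession: str) -> tuple[str, ...]:
        return self.classes.get(accession, ("none",))

    def __contains__(self, accession: str) -> bool:
        return accession in self.classes


def load_class_annotation(source) -> ClassAnnotation:
    """Read an annotation CSV with columns accession, classes (semicolon-separated)."""
    frame = pd.read_csv(source, dtype=str)
    if "accession" not in frame.columns or "classes" not in frame.columns:
        raise ValidationError(
            "class annotation CSV needs 'accession' and 'classes' columns"
        )
    mapping = {
        row.accession: tuple(part.strip() for part in row.classes.split(";") if part.strip())
        for row in frame.itertuples()
    }
    return ClassAnnotation(mapping)


def load_enriched_reference_annotation() -> ClassAnnotation:
    """Packaged class annotation of the rat basal-airway Krt17 IP candidate set.

    Covers the antibody-enriched candidates: 29 actin-associated, 6
    microtubule-associated and 38 keratin/membrane/junction-associated
    proteins, six of which carry two cytoskeletal classes (candidate
    cross-linkers).
    """
    with resources.files("ipmsnet.data").joinpath("enriched_classes.csv").open() as fh:
        return load_class_annotation(fh)


@dataclass
class Core:
    """A cooperating module: members ranked by degree, with supporting edges."""

    name: str
    members: tuple[str, ...]  # ranked by degree (desc), ties alphabetical
    degrees: dict[str, int]
    edges: tuple[tuple[str, str, float, float], ...]  # (a, b, r, cd)

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)


@dataclass
class AntagonistModule:
    """An antagonist set with the sign pattern justifying each member."""

    anchor: str
    members: tuple[str, ...]
    #: member -> {reference accession -> r or None (undefined)}
    sign_patterns: dict[str, dict[str, float | None]] = field(default_factory=dict)
    anchor_qualifies: bool = False


def build_correlation_graph(
    entries: Sequence[CorrelationEntry], tau_core: float
) -> nx.Graph:
    """Graph of positively correlated pairs with CD >= tau_core."""
    graph = nx.Graph()
    for e in entries:
        if e.defined and e.r > 0 and e.cd >= tau_core:
            graph.add_edge(e.a, e.b, r=e.r, cd=e.cd)
    return graph


def find_cores(
    entries: Sequence[CorrelationEntry],
    tau_core: float = 0.75,
    min_size: int = 3,
    min_degree: int = 2,
    mode: str = "component",
) -> list[Core]:
    """Extract cooperating modules from the thresholded positive-r graph.

    ``mode="component"`` takes connected components and (for
    ``min_degree > 0``) reduces each to its ``min_degree``-core, dropping
    members hanging on a single edge; ``mode="clique"`` returns maximal
    cliques instead. Modules smaller than ``min_size`` are discarded. Cores
    are named core_1, core_2, ... in decreasing size order.
    """
    if mode not in ("component", "clique"):
        raise ValidationError(f"find_cores mode must be 'component' or 'clique', got {mode!r}")
    graph = build_correlation_graph(entries, tau_core)
    if mode == "clique":
        groups: list[set[str]] = [set(c) for c in nx.find_cliques(graph)]
    else:
        pruned = nx.k_core(graph, k=min_degree) if min_degree > 0 else graph
        groups = [set(c) for c in nx.connected_components(pruned)]
    groups = [g for g in groups if len(g) >= min_size]
    groups.sort(key=lambda g: (-len(g), min(g)))

    cores: list[Core] = []
    for i, group in enumerate(groups, start=1):
        sub = graph.subgraph(group)
        degrees = {node: int(sub.degree(node)) for node in group}
        ranked = tuple(sorted(group, key=lambda n: (-degrees[n], n)))
        edges = tuple(
            sorted(
                (min(a, b), max(a, b), data["r"], data["cd"])
                for a, b, data in sub.edges(data=True)
            )
        )
        cores.append(Core(f"core_{i}", ranked, degrees, edges))
    return cores


def _r_lookup(entries: Sequence[CorrelationEntry]) -> dict[tuple[str, str], float | None]:
    lookup: dict[tuple[str, str], float | None] = {}
    for e in entries:
        value = e.r if e.defined else None
        lookup[(e.a, e.b)] = value
        lookup[(e.b, e.a)] = value
    return lookup


def find_antagonists(
    entries: Sequence[CorrelationEntry],
    anchor: str,
    reference_module: Iterable[str],
    strict_undefined: bool = False,
) -> AntagonistModule:
    """Proteins positively tied to ``anchor`` and negatively to the reference.

    A candidate qualifies when r(candidate, anchor) is defined and > 0 and
    r(candidate, m) < 0 for every reference member m with a defined
    coefficient (all of them must be defined under ``strict_undefined``).
    The anchor itself is included iff its own r with every defined reference
    member is negative. The result is invariant to reference ordering.
    """
    reference = sorted(set(reference_module))
    if not reference:
        raise ValidationError("find_antagonists requires a non-empty reference module")
    lookup = _r_lookup(entries)
    universe = sorted({acc for e in entries for acc in (e.a, e.b)})

    def negative_with_all_reference(acc: str) -> tuple[bool, dict[str, float | None]]:
        pattern: dict[str, float | None] = {}
        ok = True
        for m in reference:
            if m == acc:
                continue
            r = lookup.get((acc, m))
            pattern[m] = r
            if r is None:
                if strict_undefined:
                    ok = False
            elif r >= 0:
                ok = False
        return ok, pattern

    members: list[str] = []
    sign_patterns: dict[str, dict[str, float | None]] = {}

    anchor_ok, anchor_pattern = negative_with_all_reference(anchor)
    if anchor_ok:
        members.append(anchor)
        sign_patterns[anchor] = anchor_pattern

    for acc in universe:
        if acc == anchor or acc in reference:
            continue
        r_anchor = lookup.get((acc, anchor))
        if r_anchor is None or r_anchor <= 0:
            continue
        ok, pattern = negative_with_all_reference(acc)
        if ok:
            pattern["__anchor__"] = r_anchor
            members.append(acc)
            sign_patterns[acc] = pattern

    return AntagonistModule(
        anchor=anchor,
        members=tuple(members),
        sign_patterns=sign_patterns,
        anchor_qualifies=anchor_ok,
    )


@dataclass
class StratumCounts:
    """Class accounting within one enrichment stratum."""

    n: int
    primary_class_counts: dict[str, int]
    venn_regions: dict[str, int]  # "actin+microtubule" style keys, disjoint
    cross_linkers: tuple[str, ...]


@dataclass
class ClassCountReport:
    strata: dict[str, StratumCounts]

    @property
    def enriched(self) -> StratumCounts:
        return self.strata["enriched"]

    @property
    def not_enriched(self) -> StratumCounts:
        return self.strata["not_enriched"]


def classify_and_count(
    universe: Sequence[str],
    annotation: ClassAnnotation,
    enriched_flags: Mapping[str, bool],
) -> ClassCountReport:
    """Per-class, per-Venn-region and cross-linker accounting.

    ``universe`` lists the accessions under analysis; unannotated accessions
    count as class "none". Within each stratum (enriched / not enriched):

    * ``primary_class_counts`` counts each protein once under its primary
      (first-listed) class,
    * ``venn_regions`` counts each protein once in the region given by its
      full class set (region counts are disjoint and sum to the stratum
      size),
    * ``cross_linkers`` lists proteins annotated with two or more
      cytoskeletal classes.
    """
    strata: dict[str, dict] = {
        "enriched": {"accs": []},
        "not_enriched": {"accs": []},
    }
    for acc in universe:
        stratum = "enriched" if enriched_flags.get(acc, False) else "not_enriched"
        strata[stratum]["accs"].append(acc)

    out: dict[str, StratumCounts] = {}
    for name, data in strata.items():
        accs = data["accs"]
        primary = {label: 0 for label in VALID_CLASSES}
        regions: dict[str, int] = {}
        linkers: list[str] = []
        for acc in accs:
            labels = annotation.get(acc)
            primary[labels[0]] += 1
            region = "+".join(sorted(set(labels)))
            regions[region] = regions.get(region, 0) + 1
            if len(set(labels) & CYTOSKELETAL_CLASSES) >= 2:
                linkers.append(acc)
        out[name] = StratumCounts(
            n=len(accs),
            primary_class_counts=primary,
            venn_regions=regions,
            cross_linkers=tuple(sorted(linkers)),
        )
    return ClassCountReport(strata=out)


def cores_to_json_dict(cores: Sequence[Core], antagonists: AntagonistModule | None) -> dict:
    """Serializable summary of extracted modules."""
    payload: dict = {
        "cores": [
            {
                "name": c.name,
                "members": list(c.members),
                "degrees": c.degrees,
                "edges": [list(e) for e in c.edges],
            }
            for c in cores
        ]
    }
    if antagonists is not None:
        payload["antagonists"] = {
            "anchor": antagonists.anchor,
            "anchor_qualifies": antagonists.anchor_qualifies,
            "members": list(antagonists.members),
            "sign_patterns": antagonists.sign_patterns,
        }
    return payload


def write_graph_outputs(
    entries: Sequence[CorrelationEntry], tau_core: float, edge_csv, graphml_path
) -> None:
    """Emit the thresholded graph as an edge-list CSV and GraphML."""
    graph = build_correlation_graph(entries, tau_core)
    rows = [
        {"protein_a": a, "protein_b": b, "r": d["r"], "cd": d["cd"]}
        for a, b, d in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["protein_a", "protein_b", "r", "cd"]).to_csv(
        edge_csv, index=False
    )
    nx.write_graphml(graph, graphml_path)
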