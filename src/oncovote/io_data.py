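"""File formats and the core network data model.

A protein–protein interaction (PPI) network is an undirected graph over
opaque, case-sensitive protein identifiers.  A subset of the nodes carries a
"cancer" label (tumour-associated proteins); every edge then falls into one
of three classes:

* ``CC`` — both endpoints are cancer proteins,
* ``CX`` — exactly one endpoint is a cancer protein,
* ``XX`` — neither endpoint is.

Input formats are deliberately minimal and text-only:

* edge list: TSV/whitespace, two identifier columns, ``#`` comments;
* domain annotations: TSV, (protein, domain accession) per row, repeated
  rows increment multiplicity;
* label / test lists: one identifier per line;
* feature table: TSV with header ``protein_a protein_b ddi dfs_c dfs_x cld
  class``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .exceptions import EmptyNetworkError, ParseError

logger = logging.getLogger(__name__)

Edge = tuple[str, str]

#: the three edge classes: cancer-cancer, cancer-other, other-other
EDGE_CLASSES = ("CC", "CX", "XX")

FEATURE_COLUMNS = ("ddi", "dfs_c", "dfs_x", "cld")

FEATURE_TABLE_COLUMNS = ("protein_a", "protein_b", *FEATURE_COLUMNS, "class")


def canonical_edge(a: str, b: str) -> Edge:
    """Return the unordered edge (a, b) in canonical (sorted) orientation."""
    return (a, b) if a <= b else (b, a)


@dataclass
class ProteinNetwork:
    """Undirected PPI network with per-node cancer labels.

    Backed by a :class:`networkx.Graph`; ``cancer_set`` is the subset of
    nodes labelled as cancer proteins.  Self-interactions (homodimers) are
    retained and can be listed via :attr:`self_loops`.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    cancer_set: set[str] = field(default_factory=set)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[Edge]:
        return {canonical_edge(a, b) for a, b in self.graph.edges}

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def self_loops(self) -> set[Edge]:
        return {(a, a) for a, _ in nx.selfloop_edges(self.graph)}

    def add_edge(self, a: str, b: str) -> None:
        self.graph.add_edge(a, b)

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def neighbors(self, protein: str) -> set[str]:
        if protein not in self.graph:
            return set()
        return set(self.graph.neighbors(protein))

    def is_cancer(self, protein: str) -> bool:
        return protein in self.cancer_set

    def edge_class(self, edge: Edge) -> str:
        a, b = edge
        n_cancer = int(a in self.cancer_set) + int(b in self.cancer_set)
        return ("XX", "CX", "CC")[n_cancer]

    def copy(self) -> "ProteinNetwork":
        return ProteinNetwork(graph=self.graph.copy(), cancer_set=set(self.cancer_set))


@dataclass
class DomainAnnotationMap:
    """Per-protein multiset of domain types.

    ``assignments[p]`` is a :class:`collections.Counter` over domain
    accessions; its total count is the number of domain instances |S(p)|
    used by the interaction-model weights.  Proteins absent from the map are
    treated as domainless.
    """

    assignments: dict[str, Counter] = field(default_factory=dict)
    domain_universe: set[str] = field(default_factory=set)

    def domains_of(self, protein: str) -> Counter:
        return self.assignments.get(protein, Counter())

    def n_instances(self, protein: str) -> int:
        """Number of domain instances on ``protein`` (multiset cardinality)."""
        return sum(self.domains_of(protein).values())

    def has_domains(self, protein: str) -> bool:
        return self.n_instances(protein) > 0


def _identifier_columns(line: str) -> list[str]:
    # accept tab- or whitespace-separated columns
    if "\t" in line:
        return [c.strip() for c in line.split("\t")]
    return line.split()


def read_edge_list(path, exclusion_path=None) -> ProteinNetwork:
    """Parse a two-column edge list into a :class:`ProteinNetwork`.

    Lines beginning with ``#`` are comments; duplicate edges (in either
    orientation) collapse to one.  Edges listed in ``exclusion_path`` (same
    format) are removed — a generic stand-in for homology-based edge
    filtering.  Labels are not attached here.
    """
    net = ProteinNetwork()
    n_lines = 0
    for lineno, cols in _iter_pair_lines(path):
        n_lines += 1
        if len(cols) < 2 or not cols[0] or not cols[1]:
            raise ParseError(path, lineno, "expected two identifier columns")
        net.add_edge(cols[0], cols[1])
    if net.n_edges == 0:
        raise EmptyNetworkError(f"no edges parsed from {path}")
    n_before = net.n_edges
    if exclusion_path is not None:
        excluded = set()
        for lineno, cols in _iter_pair_lines(exclusion_path):
            if len(cols) < 2:
                raise ParseError(exclusion_path, lineno, "expected two identifier columns")
            excluded.add(canonical_edge(cols[0], cols[1]))
        for a, b in excluded:
            if net.has_edge(a, b):
                net.graph.remove_edge(a, b)
        net.graph.remove_nodes_from(list(nx.isolates(net.graph)))
    logger.info(
        "read %d lines -> %d unique edges (%d removed by exclusion list)",
        n_lines, net.n_edges, n_before - net.n_edges,
    )
    if net.self_loops:
        logger.info("network contains %d self-interactions", len(net.self_loops))
    return net


def _iter_pair_lines(path):
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, _identifier_columns(line)


def read_domain_annotations(path) -> DomainAnnotationMap:
    """Parse a (protein, domain) TSV into a :class:`DomainAnnotationMap`.

    Repeated (protein, domain) rows increment the domain's multiplicity on
    that protein.
    """
    annotations = DomainAnnotationMap()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = _identifier_columns(line)
            if len(cols) < 2 or not cols[0] or not cols[1]:
                raise ParseError(path, lineno, "expected (protein, domain) columns")
            protein, domain = cols[0], cols[1]
            annotations.assignments.setdefault(protein, Counter())[domain] += 1
            annotations.domain_universe.add(domain)
    return annotations


def read_protein_list(path) -> list[str]:
    """Read a one-identifier-per-line list (labels or test proteins)."""
    out: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            out.append(line.split()[0])
    return out


def attach_labels(net: ProteinNetwork, cancer_path) -> ProteinNetwork:
    """Attach cancer labels from a one-per-line identifier list.

    Identifiers absent from the network are counted and logged, never an
    error (label lists routinely cover proteins outside the interactome).
    The edge set is untouched.
    """
    listed = read_protein_list(cancer_path)
    nodes = net.nodes
    matched = {p for p in listed if p in nodes}
    unmatched = len(set(listed)) - len(matched)
    net.cancer_set = matched
    logger.info(
        "attached %d cancer labels (%d listed identifiers not in network)",
        len(matched), unmatched,
    )
    return net


def write_feature_table(features: pd.DataFrame | Iterable, path) -> None:
    """Write per-edge feature vectors as TSV.

    Accepts the feature :class:`pandas.DataFrame` produced by the dataset
    builder (or any iterable of row dicts with the same keys).  Values
    round-trip losslessly at 12 significant digits.
    """
    if not isinstance(features, pd.DataFrame):
        features = pd.DataFrame(list(features))
    if features.empty:
        raise ValueError("refusing to write an empty feature table")
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")
    out = features.loc[:, list(FEATURE_TABLE_COLUMNS)]
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str})
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(path, 1, f"feature table is missing columns: {missing}")
    return df


def network_from_edges(edges: Iterable[tuple[str, str]],
                       cancer: Iterable[str] = ()) -> ProteinNetwork:
    """Build a network directly from in-memory edge pairs (test/synthetic use)."""
    net = ProteinNetwork()
    for a, b in edges:
        net.add_edge(a, b)
    net.cancer_set = {p for p in cancer if p in net.graph}
    return net


def annotations_from_mapping(mapping: Mapping[str, Iterable[str]]) -> DomainAnnotationMap:
    """Build an annotation map from ``{protein: iterable of domains}``."""
    ann = DomainAnnotationMap()
    for protein, domains in mapping.items():
        counter = Counter(domains)
        if counter:
            ann.assignments[protein] = counter
            ann.domain_universe.update(counter)
    return ann


def write_edge_list(net: ProteinNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# protein_a\tprotein_b\n")
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")


def write_domain_annotations(ann: DomainAnnotationMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# protein\tdomain\n")
        for protein in sorted(ann.assignments):
            for domain in sorted(ann.assignments[protein].elements()):
                fh.write(f"{protein}\t{domain}\n")


def write_protein_list(proteins: Iterable[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in sorted(set(proteins)):
            fh.write(f"{p}\n")
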