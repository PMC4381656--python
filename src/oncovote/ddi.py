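"""One-to-one domain–domain interaction (DDI) model.

For an interacting protein pair (P_i, P_j) carrying M and N domain
instances, each of the M·N ordered domain pairs receives mass 1/(M·N), so
every annotated edge contributes exactly unit mass.  Accumulating over a
set of edges gives the observed pair matrix I_{α,β}.  A null ensemble is
built by permuting the global multiset of domain-assignment instances
across proteins while preserving each protein's assignment count; the
ensemble mean ⟨I^rand⟩ over B randomizations normalises the observed mass
into the ratio R_{α,β} = I_{α,β} / ⟨I^rand⟩_{α,β}.  Pairs with R > 1 occur
more often than chance and are treated as preferred DDIs; the per-edge DDI
score sums the R values (strictly) above 1 over the edge's distinct domain
pairs.

Mass is accumulated on *unordered* domain-pair keys: a physical domain
contact is symmetric, and an ordered bookkeeping would double-count pairs
in the per-edge score.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np

from .exceptions import DomainlessProteinError, EmptySelectionError, ProvenanceError
from .io_data import DomainAnnotationMap, Edge, ProteinNetwork

logger = logging.getLogger(__name__)

DomainPair = tuple[str, str]

#: default number of null randomizations; the ratio estimates stabilise by
#: a few tens of draws, and 40 is the documented default
DEFAULT_N_RANDOMIZATIONS = 40
DEFAULT_RANDOMIZATION_SEED = 20150317


def domain_pair(alpha: str, beta: str) -> DomainPair:
    """Canonical unordered domain-pair key."""
    return (alpha, beta) if alpha <= beta else (beta, alpha)


@dataclass
class RandomizationPlan:
    """How the null ensemble is drawn.

    ``floor`` is the substitute null mean used when a pair has observed
    mass but never appears in any randomization; ``None`` selects the
    data-driven floor 1/(B · max_e M_e N_e) — the smallest mean a pair
    could attain by appearing once, with minimal weight, in one draw.
    """

    n_randomizations: int = DEFAULT_N_RANDOMIZATIONS
    seed: int = DEFAULT_RANDOMIZATION_SEED
    floor: float | None = None

    def __post_init__(self):
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be >= 1")


@dataclass
class DomainPairMatrix:
    """Sparse unordered domain-pair → nonnegative mass map.

    ``mode`` records what the mass means: raw accumulated mass
    (``observed``), ensemble-average mass (``null_mean``) or the
    observed/null ratio (``ratio``).  ``subset`` and ``max_mn`` carry
    provenance so ratios are only formed between matrices built from the
    same edge selection.
    """

    mass: dict[DomainPair, float] = field(default_factory=dict)
    mode: str = "observed"
    subset: str = "CC"
    n_randomizations: int | None = None
    n_edges: int = 0
    max_mn: int = 0

    def __getitem__(self, pair: DomainPair) -> float:
        return self.mass.get(domain_pair(*pair), 0.0)

    def total_mass(self) -> float:
        return sum(self.mass.values())

    def to_frame(self):
        import pandas as pd

        rows = [
            {"domain_a": a, "domain_b": b, "mass": m}
            for (a, b), m in sorted(self.mass.items())
        ]
        return pd.DataFrame(rows, columns=["domain_a", "domain_b", "mass"])


def domain_pairs_of_edge(annotations: DomainAnnotationMap, edge: Edge) -> set[DomainPair]:
    """Distinct unordered domain pairs {α, β} with α ∈ S(P_i), β ∈ S(P_j).

    For a self-interaction both sides use the protein's own domain set.
    Raises :class:`DomainlessProteinError` if either endpoint has no
    annotated domains.
    """
    a, b = edge
    s_a, s_b = annotations.domains_of(a), annotations.domains_of(b)
    if not s_a or not s_b:
        missing = a if not s_a else b
        raise DomainlessProteinError(f"protein {missing!r} has no domain annotations")
    return {domain_pair(x, y) for x in s_a for y in s_b}


def _edge_selector(net: ProteinNetwork, edge_subset: str | Callable[[Edge], bool]):
    if callable(edge_subset):
        return edge_subset
    if edge_subset == "all":
        return lambda e: True
    if edge_subset in ("CC", "CX", "XX"):
        return lambda e: net.edge_class(e) == edge_subset
    raise ValueError(f"unknown edge subset {edge_subset!r}")


def _accumulate(matrix: DomainPairMatrix, annotations: DomainAnnotationMap,
                edges: Iterable[Edge]) -> None:
    """Add each edge's 1/(M·N)-weighted ordered contributions onto unordered keys."""
    for a, b in edges:
        s_a, s_b = annotations.domains_of(a), annotations.domains_of(b)
        m, n = sum(s_a.values()), sum(s_b.values())
        w = 1.0 / (m * n)
        matrix.max_mn = max(matrix.max_mn, m * n)
        for alpha, mult_a in s_a.items():
            for beta, mult_b in s_b.items():
                key = domain_pair(alpha, beta)
                matrix.mass[key] = matrix.mass.get(key, 0.0) + mult_a * mult_b * w
        matrix.n_edges += 1


def select_annotated_edges(net: ProteinNetwork, annotations: DomainAnnotationMap,
                           edge_subset: str | Callable[[Edge], bool] = "CC",
                           ) -> tuple[list[Edge], int]:
    """Edges in the subset with both endpoints annotated, plus skip count."""
    selector = _edge_selector(net, edge_subset)
    selected = [e for e in sorted(net.edges) if selector(e)]
    if not selected:
        raise EmptySelectionError(f"edge subset {edge_subset!r} selected no edges")
    usable = [e for e in selected
              if annotations.has_domains(e[0]) and annotations.has_domains(e[1])]
    return usable, len(selected) - len(usable)


def interaction_matrix(net: ProteinNetwork, annotations: DomainAnnotationMap,
                       edge_subset: str | Callable[[Edge], bool] = "CC",
                       ) -> DomainPairMatrix:
    """Observed domain-pair mass I_{α,β} over the selected edges.

    The default selection is cancer–cancer edges: the DDI rules are derived
    from the cancerous part of the interactome.  Edges with a domainless
    endpoint are skipped with a logged count.
    """
    usable, n_skipped = select_annotated_edges(net, annotations, edge_subset)
    subset_name = edge_subset if isinstance(edge_subset, str) else "custom"
    matrix = DomainPairMatrix(mode="observed", subset=subset_name)
    _accumulate(matrix, annotations, usable)
    if n_skipped:
        logger.info("interaction_matrix: skipped %d edges with domainless endpoints",
                    n_skipped)
    return matrix


def randomize_annotations(annotations: DomainAnnotationMap,
                          seed: int) -> DomainAnnotationMap:
    """Permute domain-assignment instances across proteins.

    The global multiset of domain instances is shuffled and re-dealt so that
    every protein keeps exactly its original number of assignments.
    Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    proteins = sorted(annotations.assignments)
    pool = [d for p in proteins for d in sorted(annotations.assignments[p].elements())]
    pool = list(rng.permutation(pool))
    out = DomainAnnotationMap(domain_universe=set(annotations.domain_universe))
    i = 0
    for p in proteins:
        k = annotations.n_instances(p)
        out.assignments[p] = Counter(pool[i:i + k])
        i += k
    return out


def null_mean_matrix(net: ProteinNetwork, annotations: DomainAnnotationMap,
                     edge_subset: str | Callable[[Edge], bool] = "CC",
                     plan: RandomizationPlan | None = None) -> DomainPairMatrix:
    """Ensemble average ⟨I_{α,β}^rand⟩ over B annotation randomizations."""
    plan = plan or RandomizationPlan()
    rng = np.random.default_rng(plan.seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=plan.n_randomizations)
    subset_name = edge_subset if isinstance(edge_subset, str) else "custom"
    acc = DomainPairMatrix(mode="null_mean", subset=subset_name,
                           n_randomizations=plan.n_randomizations)
    b = plan.n_randomizations
    for s in child_seeds:
        draw = interaction_matrix(net, randomize_annotations(annotations, int(s)),
                                  edge_subset)
        acc.max_mn = max(acc.max_mn, draw.max_mn)
        acc.n_edges = draw.n_edges
        for key, mass in draw.mass.items():
            acc.mass[key] = acc.mass.get(key, 0.0) + mass / b
    return acc


def ratio_matrix(observed: DomainPairMatrix, null_mean: DomainPairMatrix,
                 floor: float | None = None) -> DomainPairMatrix:
    """Ratio R_{α,β} = I_{α,β} / ⟨I^rand⟩_{α,β} on the observed support.

    Pairs never observed get R = 0.  When the null mean is exactly zero for
    an observed pair, it is floored at ``floor`` (default
    1/(B · max_e M_e N_e)) so that R stays finite and monotone in evidence.
    """
    if observed.mode != "observed" or null_mean.mode != "null_mean":
        raise ProvenanceError("ratio_matrix needs an observed and a null_mean matrix")
    if observed.subset != null_mean.subset:
        raise ProvenanceError(
            f"edge-subset mismatch: observed={observed.subset!r} "
            f"null={null_mean.subset!r}")
    if floor is None:
        b = null_mean.n_randomizations or 1
        floor = 1.0 / (b * max(observed.max_mn, 1))
    out = DomainPairMatrix(mode="ratio", subset=observed.subset,
                           n_randomizations=null_mean.n_randomizations,
                           n_edges=observed.n_edges, max_mn=observed.max_mn)
    for key, obs in observed.mass.items():
        if obs <= 0.0:
            continue
        null = null_mean.mass.get(key, 0.0)
        out.mass[key] = obs / (null if null > 0.0 else floor)
    return out


def edge_ddi_score(ratio: DomainPairMatrix, annotations: DomainAnnotationMap,
                   edge: Edge) -> float:
    """Per-edge DDI score: sum of ratio values strictly above 1.

    The sum runs over the edge's *distinct* unordered domain pairs; an edge
    whose pairs all sit at or below 1 scores 0.  Orientation-invariant.
    """
    if ratio.mode != "ratio":
        raise ProvenanceError("edge_ddi_score needs a ratio-mode matrix")
    total = 0.0
    for pair in domain_pairs_of_edge(annotations, edge):
        r = ratio.mass.get(pair, 0.0)
        if r > 1.0:
            total += r
    return total


def export_ratio_table(observed: DomainPairMatrix, null_mean: DomainPairMatrix,
                       ratio: DomainPairMatrix, path) -> None:
    """TSV export (domain_a, domain_b, observed_mass, null_mean, ratio)."""
    keys = sorted(set(observed.mass) | set(null_mean.mass))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("domain_a\tdomain_b\tobserved_mass\tnull_mean\tratio\n")
        for a, b in keys:
            fh.write(f"{a}\t{b}\t{observed[(a, b)]:.12g}\t"
                     f"{null_mean[(a, b)]:.12g}\t{ratio[(a, b)]:.12g}\n")
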