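"""Lift edge-level CC predictions to protein-level cancer calls.

A candidate protein is first treated as noncancer (X).  Its incident edges
to *known* cancer proteins are, by construction, CX edges; each is scored
with the trained edge classifier panel.  Edges the panel re-classifies as
CC are evidence that the candidate itself is a cancer protein: under the
``any`` rule one positive edge suffices, under ``majority`` more than half
of the tested edges must be positive.  Candidates with no testable edges
are unclassifiable and excluded from hit counting but kept in the hit-ratio
denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .bench import TrainedPanel
from .dataset import edge_feature_row
from .ddi import DomainPairMatrix
from .features import DomainFrequencyTable
from .io_data import DomainAnnotationMap, ProteinNetwork

logger = logging.getLogger(__name__)


@dataclass
class ProteinPrediction:
    protein: str
    n_edges_tested: int
    n_edges_positive: int
    call: str  # cancer | noncancer | unclassifiable


@dataclass
class HitReport:
    """Hit statistics over an all-positive independent protein list."""

    hit_number: int
    hit_ratio: float
    n_listed: int
    n_unclassifiable: int

    def as_dict(self) -> dict:
        return {"hit_number": self.hit_number, "hit_ratio": self.hit_ratio,
                "n_listed": self.n_listed,
                "n_unclassifiable": self.n_unclassifiable}


def _call(n_tested: int, n_positive: int, rule: str) -> str:
    if n_tested == 0:
        return "unclassifiable"
    if rule == "any":
        return "cancer" if n_positive >= 1 else "noncancer"
    if rule == "majority":
        return "cancer" if 2 * n_positive > n_tested else "noncancer"
    raise ValueError(f"unknown aggregation rule {rule!r}")


def predict_proteins(net: ProteinNetwork, annotations: DomainAnnotationMap,
                     ratio: DomainPairMatrix, table: DomainFrequencyTable,
                     panel: TrainedPanel, test_proteins: Iterable[str],
                     rule: str = "any", vote_mode: str = "majority",
                     panel_subset: Sequence[str] | None = None,
                     partners: str = "cancer") -> list[ProteinPrediction]:
    """Classify each test protein from its incident edges.

    ``partners`` selects which incident edges are tested: ``"cancer"``
    (default — only edges to known cancer proteins, the CX construction)
    or ``"all"``.  ``vote_mode``/``panel_subset`` choose how the panel
    combines its member classifiers per edge.
    """
    predictions: list[ProteinPrediction] = []
    pending: list[tuple[int, str, int]] = []  # (row offset, protein, n_edges)
    rows: list[dict] = []
    for protein in test_proteins:
        if protein not in net.graph:
            predictions.append(ProteinPrediction(protein, 0, 0, "unclassifiable"))
            continue
        neighbours = net.neighbors(protein) - {protein}
        if partners == "cancer":
            neighbours = {p for p in neighbours if net.is_cancer(p)}
        elif partners != "all":
            raise ValueError(f"unknown partners mode {partners!r}")
        if not neighbours:
            predictions.append(ProteinPrediction(protein, 0, 0, "unclassifiable"))
            continue
        pending.append((len(rows), protein, len(neighbours)))
        for partner in sorted(neighbours):
            rows.append(edge_feature_row(net, annotations, ratio, table,
                                         (protein, partner), label="CX"))
    if rows:
        frame = pd.DataFrame(rows)
        votes = panel.vote(frame, mode=vote_mode, subset=panel_subset)
    for offset, protein, n_edges in pending:
        n_pos = int(votes[offset:offset + n_edges].sum())
        predictions.append(ProteinPrediction(protein, n_edges, n_pos,
                                             _call(n_edges, n_pos, rule)))
    return predictions


def hit_ratio(predictions: Sequence[ProteinPrediction]) -> HitReport:
    """Hit number and ratio over an all-positive list.

    Every prediction corresponds to a listed (true cancer) protein, so a
    ``cancer`` call is a true positive hit.  Unclassifiable proteins count
    in the denominator and are reported separately.
    """
    if not predictions:
        raise ValueError("hit_ratio needs a nonempty prediction list")
    hits = sum(1 for p in predictions if p.call == "cancer")
    n_unc = sum(1 for p in predictions if p.call == "unclassifiable")
    return HitReport(hit_number=hits, hit_ratio=hits / len(predictions),
                     n_listed=len(predictions), n_unclassifiable=n_unc)


def filter_test_list(test_proteins: Iterable[str], net: ProteinNetwork,
                     annotations: DomainAnnotationMap,
                     training_labels: Iterable[str] = (),
                     ) -> tuple[list[str], dict]:
    """Generic candidate-list filter chain for independent case studies.

    Removes (1) proteins already carrying a training cancer label, then
    (2) proteins lacking PPI or domain data.  Returns the surviving list
    and the removal bookkeeping.
    """
    listed = list(dict.fromkeys(test_proteins))
    labels = set(training_labels)
    after_labels = [p for p in listed if p not in labels]
    survivors = [p for p in after_labels
                 if p in net.graph and annotations.has_domains(p)]
    stats = {"n_listed": len(listed),
             "n_removed_training": len(listed) - len(after_labels),
             "n_removed_missing_data": len(after_labels) - len(survivors),
             "n_survivors": len(survivors)}
    logger.info("filter_test_list: %s", stats)
    return survivors, stats
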