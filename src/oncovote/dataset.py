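"""Edge labelling, feature-matrix assembly and balanced sampling.

Cancer–cancer (CC) edges form the positive class; the negative class pools
the remaining CX and XX edges (optionally XX only).  Because the positive
class is a small minority of the interactome, training uses a balanced
1:1 sample: all positives are kept and an equal number of negatives is
drawn uniformly without replacement.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ddi as _ddi
from .exceptions import SizeError
from .features import (DomainFrequencyTable, cld_score, dfs_scores)
from .io_data import (FEATURE_COLUMNS, DomainAnnotationMap, Edge,
                      ProteinNetwork, read_feature_table, write_feature_table)

logger = logging.getLogger(__name__)

POSITIVE_CLASS = "CC"


def label_edges(net: ProteinNetwork) -> dict[Edge, str]:
    """Classify every edge as CC, CX or XX from its endpoints' labels."""
    return {edge: net.edge_class(edge) for edge in net.edges}


@dataclass
class LabeledDataset:
    """Per-edge feature rows plus sampling provenance.

    ``frame`` has columns (protein_a, protein_b, ddi, dfs_c, dfs_x, cld,
    class); ``provenance`` records seeds and class counts so a dataset can
    be reproduced from its sidecar.
    """

    frame: pd.DataFrame
    positive_class: str = POSITIVE_CLASS
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def class_counts(self) -> dict[str, int]:
        return self.frame["class"].value_counts().to_dict()

    def X(self) -> np.ndarray:
        """Feature matrix (n_edges × 4), column order ddi, dfs_c, dfs_x, cld."""
        return self.frame.loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=float)

    def y(self) -> np.ndarray:
        """Binary labels: 1 for the positive (CC) class."""
        return (self.frame["class"] == self.positive_class).to_numpy(dtype=int)

    def save(self, table_path, sidecar_path=None) -> None:
        write_feature_table(self.frame, table_path)
        if sidecar_path is not None:
            with open(sidecar_path, "w", encoding="utf-8") as fh:
                json.dump({"positive_class": self.positive_class,
                           "provenance": self.provenance,
                           "class_counts": {k: int(v) for k, v
                                            in self.class_counts.items()}},
                          fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, table_path, sidecar_path=None) -> "LabeledDataset":
        frame = read_feature_table(table_path)
        positive, provenance = POSITIVE_CLASS, {}
        if sidecar_path is not None:
            with open(sidecar_path, "r", encoding="utf-8") as fh:
                meta = json.load(fh)
            positive = meta.get("positive_class", POSITIVE_CLASS)
            provenance = meta.get("provenance", {})
        return cls(frame=frame, positive_class=positive, provenance=provenance)


def edge_feature_row(net: ProteinNetwork, annotations: DomainAnnotationMap,
                     ratio: _ddi.DomainPairMatrix, table: DomainFrequencyTable,
                     edge: Edge, label: str | None = None) -> dict:
    """One feature row for an edge; DDI falls back to 0 for domainless endpoints."""
    a, b = edge
    if annotations.has_domains(a) and annotations.has_domains(b):
        ddi_score = _ddi.edge_ddi_score(ratio, annotations, edge)
    else:
        ddi_score = 0.0
    dfs_c, dfs_x = dfs_scores(table, annotations, edge)
    return {
        "protein_a": a, "protein_b": b,
        "ddi": ddi_score, "dfs_c": dfs_c, "dfs_x": dfs_x,
        "cld": cld_score(net, edge),
        "class": net.edge_class(edge) if label is None else label,
    }


def build_feature_matrix(net: ProteinNetwork, annotations: DomainAnnotationMap,
                         ratio: _ddi.DomainPairMatrix,
                         table: DomainFrequencyTable,
                         require_domains: bool = True) -> LabeledDataset:
    """Assemble the per-edge feature table for every (computable) edge.

    Edges with a domainless endpoint are skipped (with a logged count) when
    ``require_domains`` is set — mirroring the exclusion of proteins lacking
    domain data — otherwise they are retained with DDI = DFS = 0.
    """
    rows, skipped = [], 0
    for edge in sorted(net.edges):
        a, b = edge
        if require_domains and not (annotations.has_domains(a)
                                    and annotations.has_domains(b)):
            skipped += 1
            continue
        rows.append(edge_feature_row(net, annotations, ratio, table, edge))
    if skipped:
        logger.info("build_feature_matrix: skipped %d edges lacking domain data",
                    skipped)
    frame = pd.DataFrame(rows, columns=["protein_a", "protein_b",
                                        *FEATURE_COLUMNS, "class"])
    counts = frame["class"].value_counts().to_dict() if len(frame) else {}
    return LabeledDataset(frame=frame,
                          provenance={"n_edges": len(frame),
                                      "n_skipped_domainless": skipped,
                                      "class_counts": {k: int(v)
                                                       for k, v in counts.items()}})


def balanced_sample(ds: LabeledDataset, seed: int,
                    negatives: str = "pooled") -> LabeledDataset:
    """Draw a 1:1 positive:negative training sample.

    All positive (CC) rows are kept; an equal number of negative rows is
    drawn uniformly without replacement.  ``negatives`` is ``"pooled"``
    (CX ∪ XX, the default) or ``"XX"`` for the ablation restricting the
    negative class to noncancer–noncancer edges.
    """
    is_pos = ds.frame["class"] == ds.positive_class
    pos = ds.frame[is_pos]
    if negatives == "pooled":
        neg = ds.frame[~is_pos]
    elif negatives == "XX":
        neg = ds.frame[ds.frame["class"] == "XX"]
    else:
        raise ValueError(f"unknown negatives mode {negatives!r}")
    if len(pos) == 0 or len(neg) == 0:
        raise SizeError("balanced_sample needs both classes nonempty")
    if len(neg) < len(pos):
        raise SizeError(
            f"only {len(neg)} negatives available for {len(pos)} positives")
    rng = np.random.default_rng(seed)
    idx = rng.choice(neg.index.to_numpy(), size=len(pos), replace=False)
    frame = pd.concat([pos, neg.loc[np.sort(idx)]], ignore_index=True)
    counts = frame["class"].value_counts().to_dict()
    return LabeledDataset(
        frame=frame, positive_class=ds.positive_class,
        provenance={**ds.provenance, "balanced_seed": int(seed),
                    "negatives_mode": negatives,
                    "class_counts": {k: int(v) for k, v in counts.items()}})
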