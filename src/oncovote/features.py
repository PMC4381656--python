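"""Weighted domain-frequency scores, cancer linker degree, normalization.

Three of the four per-edge features live here:

* ``DFS_C`` / ``DFS_X`` — for each domain instance on either endpoint, add
  the domain's occurrence count among cancer (C(α)) or noncancer (X(α))
  proteins, then divide by the constant m + n (number of domain types seen
  in cancer plus noncancer proteins).  High DFS_C marks edges whose domains
  are common cargo of cancer proteins.
* ``CLD`` — the cancer linker degree of an edge: the fraction of the two
  endpoints' distinct external neighbours that are cancer proteins.  An
  edge with CLD near 1 sits inside a cancer-dense neighbourhood.

Min–max normalization (x − min)/(max − min) puts the four features on a
common [0, 1] scale; parameters are fitted on training rows and applied
with clamping to held-out rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .exceptions import DegenerateTableError
from .io_data import (FEATURE_COLUMNS, DomainAnnotationMap, Edge,
                      ProteinNetwork)


@dataclass
class DomainFrequencyTable:
    """Occurrence counts of each domain in cancer vs noncancer proteins.

    ``m`` and ``n`` are the numbers of domain *types* occurring in cancer
    and noncancer proteins; their sum is the DFS denominator.  Counts are
    over domain instances, so a domain repeated within one protein counts
    each time.
    """

    cancer_count: dict[str, int] = field(default_factory=dict)
    noncancer_count: dict[str, int] = field(default_factory=dict)

    @property
    def m(self) -> int:
        return sum(1 for v in self.cancer_count.values() if v > 0)

    @property
    def n(self) -> int:
        return sum(1 for v in self.noncancer_count.values() if v > 0)

    def to_frame(self) -> pd.DataFrame:
        domains = sorted(set(self.cancer_count) | set(self.noncancer_count))
        return pd.DataFrame({
            "domain": domains,
            "cancer_count": [self.cancer_count.get(d, 0) for d in domains],
            "noncancer_count": [self.noncancer_count.get(d, 0) for d in domains],
        })


def build_frequency_table(net: ProteinNetwork,
                          annotations: DomainAnnotationMap) -> DomainFrequencyTable:
    """Count domain occurrences across cancer and noncancer proteins.

    Every node of the labelled network contributes its domain multiset to
    the cancer or the noncancer side according to its label.
    """
    table = DomainFrequencyTable()
    for protein in net.nodes:
        target = table.cancer_count if net.is_cancer(protein) else table.noncancer_count
        for domain, mult in annotations.domains_of(protein).items():
            target[domain] = target.get(domain, 0) + mult
    return table


def dfs_scores(table: DomainFrequencyTable, annotations: DomainAnnotationMap,
               edge: Edge) -> tuple[float, float]:
    """Weighted domain-frequency scores (DFS_C, DFS_X) of an edge.

    Each domain instance on either endpoint contributes its global
    occurrence count; the sum is scaled by the constant 1/(m + n).
    Unannotated endpoints and unknown domains contribute 0.
    """
    denom = table.m + table.n
    if denom == 0:
        raise DegenerateTableError("frequency table has no occupied domain types")
    c_sum = x_sum = 0
    for protein in edge:
        for domain, mult in annotations.domains_of(protein).items():
            c_sum += mult * table.cancer_count.get(domain, 0)
            x_sum += mult * table.noncancer_count.get(domain, 0)
    return c_sum / denom, x_sum / denom


def cld_score(net: ProteinNetwork, edge: Edge) -> float:
    """Cancer linker degree n^C / (n^C + n^X) of an edge.

    Neighbours are the distinct proteins adjacent to either endpoint,
    excluding the endpoints themselves (a shared neighbour counts once).
    A pair with no external neighbours scores 0 — the conservative, least
    cancer-like value.
    """
    a, b = edge
    neighbours = (net.neighbors(a) | net.neighbors(b)) - {a, b}
    if not neighbours:
        return 0.0
    n_cancer = sum(1 for p in neighbours if net.is_cancer(p))
    return n_cancer / len(neighbours)


@dataclass
class NormalizationParams:
    """Per-feature min–max parameters for the [0, 1] rescaling.

    Degenerate features (max == min) map identically to 0.  With ``clamp``
    set, transformed values are clipped into [0, 1] — the intended behaviour
    when parameters fitted on training data are applied to held-out rows.
    """

    minima: dict[str, float] = field(default_factory=dict)
    maxima: dict[str, float] = field(default_factory=dict)
    clamp: bool = True

    def transform_value(self, feature: str, x: float) -> float:
        lo, hi = self.minima[feature], self.maxima[feature]
        if hi == lo:
            return 0.0
        y = (x - lo) / (hi - lo)
        if self.clamp:
            y = min(1.0, max(0.0, y))
        return y

    def to_frame(self) -> pd.DataFrame:
        feats = sorted(self.minima)
        return pd.DataFrame({"feature": feats,
                             "min": [self.minima[f] for f in feats],
                             "max": [self.maxima[f] for f in feats]})


def fit_normalizer(features: pd.DataFrame, columns=FEATURE_COLUMNS,
                   clamp: bool = True) -> NormalizationParams:
    """Fit per-feature min/max over a feature table."""
    if len(features) == 0:
        raise ValueError("cannot fit a normalizer on an empty collection")
    params = NormalizationParams(clamp=clamp)
    for col in columns:
        series = features[col].astype(float)
        params.minima[col] = float(series.min())
        params.maxima[col] = float(series.max())
    return params


def apply_normalizer(params: NormalizationParams,
                     features: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of ``features`` with each fitted column rescaled."""
    out = features.copy()
    for col in params.minima:
        out[col] = [params.transform_value(col, x) for x in out[col].astype(float)]
    return out
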