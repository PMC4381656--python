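"""Synthetic labelled PPI networks with domain annotations.

The generator reproduces the two statistical structures the prediction
method exploits, with controllable strength:

* **domain propensity** — domain types are partitioned into cancer-only,
  shared and noncancer-only pools; cancer proteins draw their domains with
  the cancer-enriched pool upweighted by an odds multiplier
  (``enrichment``), noncancer proteins mirror this for the noncancer pool.
  ``enrichment = 1`` makes domain content independent of the label.
* **assortative wiring** — edges are drawn independently per endpoint-class
  pair (class-conditional Erdős–Rényi) with probabilities ``p_cc``,
  ``p_cx``, ``p_xx``; ``p_cc > p_cx`` concentrates cancer proteins'
  neighbourhoods on other cancer proteins, the signal the linker-degree
  feature reads.

Domain popularity within each pool follows a Zipf (1/rank) law, matching
the heavy-tailed family-size distribution of real domain databases; counts
per protein are Poisson (minimum 1) and sampled with replacement, so
within-protein multiplicity occurs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from . import ddi as _ddi
from .dataset import LabeledDataset, balanced_sample, build_feature_matrix
from .exceptions import ConfigError
from .features import build_frequency_table
from .io_data import (DomainAnnotationMap, ProteinNetwork,
                      annotations_from_mapping, network_from_edges,
                      write_domain_annotations, write_edge_list,
                      write_protein_list)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic interactome.

    The defaults are the strong-signal benchmark: 300 cancer / 1200
    noncancer proteins, 400 domain types, fourfold pool enrichment and a
    fivefold cancer-cancer wiring excess.
    """

    n_cancer: int = 300
    n_noncancer: int = 1200
    n_domains: int = 400
    frac_cancer_only_domains: float = 0.10
    frac_shared_domains: float = 0.21
    enrichment: float = 4.0
    mean_domains_per_protein: float = 3.0
    zipf_exponent: float = 1.0
    p_cc: float = 0.02
    p_cx: float = 0.004
    p_xx: float = 0.004
    seed: int = 0

    def validate(self) -> None:
        if self.n_cancer < 0 or self.n_noncancer < 0:
            raise ConfigError("protein counts must be nonnegative")
        if self.n_domains < 1:
            raise ConfigError("need at least one domain type")
        for p in (self.p_cc, self.p_cx, self.p_xx):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("edge probabilities must lie in [0, 1]")
        fracs = (self.frac_cancer_only_domains, self.frac_shared_domains)
        if any(not 0.0 <= f <= 1.0 for f in fracs) or sum(fracs) > 1.0:
            raise ConfigError("pool fractions must be in [0, 1] and sum <= 1")
        if self.enrichment < 1.0:
            raise ConfigError("enrichment must be >= 1")
        if self.mean_domains_per_protein <= 0:
            raise ConfigError("mean_domains_per_protein must be positive")


def strong_signal_config(seed: int = 0) -> GeneratorConfig:
    """The default benchmark conditions (clearly separable classes)."""
    return GeneratorConfig(seed=seed)


def null_config(seed: int = 0) -> GeneratorConfig:
    """Label-independent conditions for calibration checks.

    ``enrichment = 1`` and equal wiring probabilities make every feature
    uninformative in the population.  The sizes are chosen so the two
    residual finite-sample couplings of the *method itself* stay far below
    the calibration tolerances: many proteins (per-node neighbourhood
    effects shared across an endpoint's edges dominate the variance of a
    rank AUC, which scales like 1/sqrt(n_cancer)), and a small, heavily
    reused domain universe (domain pairs seen on only one or two
    cancer–cancer edges would otherwise ratio-score their own training
    edges).  Roughly 2800 cancer–cancer edges among ~25k edges result.
    """
    return GeneratorConfig(n_cancer=3000, n_noncancer=6000, n_domains=8,
                           frac_cancer_only_domains=0.125,
                           frac_shared_domains=0.25,
                           enrichment=1.0, p_cc=6.2e-4, p_cx=6.2e-4,
                           p_xx=6.2e-4, seed=seed)


def _sample_pairs(rng, nodes_a, nodes_b, p, within: bool):
    """Distinct unordered cross-pairs (or within-set pairs) at rate p."""
    if within:
        n = len(nodes_a)
        n_pairs = n * (n - 1) // 2
    else:
        n_pairs = len(nodes_a) * len(nodes_b)
    if n_pairs == 0 or p == 0.0:
        return []
    k = rng.binomial(n_pairs, p)
    if k == 0:
        return []
    chosen = rng.choice(n_pairs, size=k, replace=False)
    edges = []
    if within:
        # unrank the flat index into an upper-triangular (i < j) pair
        idx_a = np.triu_indices(len(nodes_a), k=1)
        for flat in chosen:
            i, j = idx_a[0][flat], idx_a[1][flat]
            edges.append((nodes_a[i], nodes_a[j]))
    else:
        nb = len(nodes_b)
        for flat in chosen:
            edges.append((nodes_a[flat // nb], nodes_b[flat % nb]))
    return edges


def generate(config: GeneratorConfig,
             ) -> tuple[ProteinNetwork, DomainAnnotationMap, list[str]]:
    """Draw one (network, annotations, cancer-label list) triple.

    Deterministic under ``config.seed``.  Every protein gets at least one
    domain; proteins that end up without any edge are dropped from the
    network but keep their annotations (they simply never contribute).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    width = max(4, len(str(max(config.n_cancer, config.n_noncancer))))
    cancer = [f"C{i:0{width}d}" for i in range(config.n_cancer)]
    noncancer = [f"X{i:0{width}d}" for i in range(config.n_noncancer)]
    domains = [f"D{i:04d}" for i in range(config.n_domains)]

    n_conly = int(round(config.frac_cancer_only_domains * config.n_domains))
    n_shared = int(round(config.frac_shared_domains * config.n_domains))
    pool_of = np.array(["cancer"] * n_conly + ["shared"] * n_shared
                       + ["noncancer"] * (config.n_domains - n_conly - n_shared))

    base = 1.0 / np.arange(1, config.n_domains + 1) ** config.zipf_exponent
    base = rng.permutation(base)  # decouple popularity rank from pool membership

    def weights(is_cancer: bool) -> np.ndarray:
        w = base.copy()
        if is_cancer:
            w[pool_of == "cancer"] *= config.enrichment
            w[pool_of == "noncancer"] /= config.enrichment
        else:
            w[pool_of == "noncancer"] *= config.enrichment
            w[pool_of == "cancer"] /= config.enrichment
        return w / w.sum()

    w_cancer, w_noncancer = weights(True), weights(False)
    assignments: dict[str, list[str]] = {}
    for names, w in ((cancer, w_cancer), (noncancer, w_noncancer)):
        for p in names:
            k = max(1, int(rng.poisson(config.mean_domains_per_protein)))
            assignments[p] = [domains[i]
                              for i in rng.choice(config.n_domains, size=k, p=w)]
    annotations = annotations_from_mapping(assignments)

    edges = []
    edges += _sample_pairs(rng, cancer, cancer, config.p_cc, within=True)
    edges += _sample_pairs(rng, cancer, noncancer, config.p_cx, within=False)
    edges += _sample_pairs(rng, noncancer, noncancer, config.p_xx, within=True)
    net = network_from_edges(edges, cancer=cancer)
    logger.info("generated network: %d nodes, %d edges (%d cancer labels)",
                len(net.nodes), net.n_edges, len(net.cancer_set))
    return net, annotations, cancer


def write_inputs(config: GeneratorConfig, edges_path, domains_path,
                 cancer_path) -> None:
    """Emit the three pipeline input files for a generated interactome."""
    net, annotations, cancer = generate(config)
    write_edge_list(net, edges_path)
    write_domain_annotations(annotations, domains_path)
    write_protein_list(cancer, cancer_path)


def run_feature_pipeline(net: ProteinNetwork, annotations: DomainAnnotationMap,
                         plan: _ddi.RandomizationPlan | None = None,
                         edge_subset: str = "CC"):
    """Observed/null/ratio matrices plus the frequency table for one network."""
    plan = plan or _ddi.RandomizationPlan()
    observed = _ddi.interaction_matrix(net, annotations, edge_subset)
    null = _ddi.null_mean_matrix(net, annotations, edge_subset, plan)
    ratio = _ddi.ratio_matrix(observed, null)
    table = build_frequency_table(net, annotations)
    return observed, null, ratio, table


def make_benchmark(config: GeneratorConfig, balanced: bool = True,
                   plan: _ddi.RandomizationPlan | None = None,
                   ) -> tuple[LabeledDataset, dict]:
    """Full pipeline on a generated network: features plus balanced sample.

    Returns the dataset and a context dict carrying the network,
    annotations, ratio matrix and frequency table, so downstream stages
    (panel training, protein inference) reuse the same artifacts.
    """
    net, annotations, cancer = generate(config)
    plan = plan or _ddi.RandomizationPlan(seed=config.seed + 1)
    observed, null, ratio, table = run_feature_pipeline(net, annotations, plan)
    full = build_feature_matrix(net, annotations, ratio, table)
    ds = balanced_sample(full, seed=config.seed + 2) if balanced else full
    ds.provenance.update({"generator_seed": config.seed,
                          "n_randomizations": plan.n_randomizations})
    context = {"net": net, "annotations": annotations, "cancer": cancer,
               "observed": observed, "null": null, "ratio": ratio,
               "table": table, "full_dataset": full}
    return ds, context


def with_seed(config: GeneratorConfig, seed: int) -> GeneratorConfig:
    return replace(config, seed=seed)


def benchmark_study(config: GeneratorConfig, holdout_frac: float = 0.2,
                    folds: int = 10, panel_size: int = 5) -> dict:
    """One full benchmark study: features, bench CV, voting, hold-out hits.

    A fraction of the cancer proteins is hidden from the training labels
    (they enter the pipeline as apparent noncancer proteins) and used as an
    independent all-positive test list, mimicking an external cancer-gene
    resource.  The hold-out list is predicted with the strict consensus of
    the top ``panel_size`` classifiers by F1 (the case-study recipe) and,
    for comparison, with the same panel's majority vote; both use the
    ``any`` edge-aggregation rule.

    Returns a dict with the dataset, CV result, per-feature AUCs, the
    top-``panel_size`` majority-vote report and the two hit reports.
    """
    from . import bench as _bench
    from . import inference as _inference
    from .bench import TrainedPanel

    net, annotations, _ = generate(config)
    rng = np.random.default_rng(config.seed + 7)
    n_held = int(round(holdout_frac * len(net.cancer_set)))
    held = sorted(rng.choice(sorted(net.cancer_set), size=n_held,
                             replace=False)) if n_held else []
    net.cancer_set -= set(held)
    plan = _ddi.RandomizationPlan(seed=config.seed + 1)
    _, _, ratio, table = run_feature_pipeline(net, annotations, plan)
    full = build_feature_matrix(net, annotations, ratio, table)
    ds = balanced_sample(full, seed=config.seed + 2)
    result = _bench.run_cv(ds, folds=folds, seed=config.seed + 3)
    panel = TrainedPanel.fit(ds, seed=config.seed + 3)
    top = _bench.top_k_subset(result.reports, panel_size)
    vote = _bench.vote_report(result, top)
    hits = {}
    if held:
        for vote_mode in ("strict", "majority"):
            preds = _inference.predict_proteins(
                net, annotations, ratio, table, panel, held,
                rule="any", vote_mode=vote_mode, panel_subset=top)
            hits[vote_mode] = _inference.hit_ratio(preds)
    return {"net": net, "annotations": annotations, "ratio": ratio,
            "table": table, "full_dataset": full, "dataset": ds,
            "cv": result, "panel": panel, "panel_subset": top,
            "vote_report": vote, "feature_auc": _bench.feature_auc(full),
            "held_out": held, "hit_reports": hits}
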