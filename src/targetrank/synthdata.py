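"""Seeded synthetic-data generators for every input kind the framework reads.

The generators plant a controllable druggability signal so the whole pipeline
can be exercised and validated offline: informative continuous features carry
an additive mean shift of ``effect`` standard-deviation units for positive
genes, binary flags carry a label-dependent odds tilt proportional to the
same effect, and the interaction graph gives seed-seed gene pairs an
``assortativity_boost``-fold higher edge probability, emulating the empirical
tendency of druggable genes to interact with other druggable genes. With
``effect = 0`` and ``assortativity_boost = 1`` every generated signal is null.
Missingness is completely at random (MCAR).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import (
    CHANNELS_DEFAULT,
    GeneFeatureTable,
    InputError,
    InteractionGraph,
    LabelSet,
    substream,
    write_class_map,
    write_edge_list,
    write_feature_table,
    write_gene_list,
)

logger = logging.getLogger("targetrank")


@dataclass
class SynthSpec:
    """Parameters of the planted-signal generators.

    ``effect`` is the mean shift (in sd units) of informative features for
    positive genes; ``missing_frac`` is either a single MCAR fraction or a
    per-feature-class mapping; ``assortativity_boost`` multiplies the
    seed-seed edge probability of the interaction graph.
    """

    n_genes: int = 1000
    n_pos: int = 100
    n_informative: int = 10
    n_noise: int = 40
    n_binary: int = 5
    effect: float = 3.0
    missing_frac: float | dict = 0.1
    mean_degree: float = 6.0
    assortativity_boost: float = 5.0
    n_types: int = 12
    n_pathways: int = 30
    n_domains: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos >= self.n_genes:
            raise InputError("n_pos must be smaller than n_genes")
        if self.effect < 0:
            raise InputError("effect must be non-negative")
        fracs = (
            self.missing_frac.values()
            if isinstance(self.missing_frac, dict)
            else [self.missing_frac]
        )
        if any(not (0 <= f < 1) for f in fracs):
            raise InputError("missing_frac must lie in [0, 1)")

    @property
    def gene_ids(self) -> list:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    def missing_frac_for(self, feature_class: str) -> float:
        if isinstance(self.missing_frac, dict):
            return float(self.missing_frac.get(feature_class, 0.0))
        return float(self.missing_frac)


def gen_labels(spec: SynthSpec) -> LabelSet:
    """Uniformly sampled positive set of size n_pos."""
    rng = substream(spec.seed, "labels")
    chosen = rng.choice(spec.n_genes, size=spec.n_pos, replace=False)
    genes = frozenset(spec.gene_ids[i] for i in chosen)
    return LabelSet("synthetic_positives", genes)


def gen_feature_matrix(spec: SynthSpec, labels: LabelSet) -> GeneFeatureTable:
    """Continuous informative + noise features and tilted binary flags.

    Informative features ~ Normal(effect * 1[positive], 1); noise ~ N(0, 1);
    binary flags ~ Bernoulli with the positive-class odds multiplied by
    exp(effect / 2), so effect = 0 makes them uninformative too.
    """
    genes = spec.gene_ids
    if not labels.genes <= set(genes):
        raise InputError("labels outside the gene universe")
    rng = substream(spec.seed, "features")
    is_pos = np.array([g in labels for g in genes], dtype=float)
    cols, classes = {}, {}
    for j in range(spec.n_informative):
        cols[f"informative_{j}"] = rng.normal(0, 1, spec.n_genes) + spec.effect * is_pos
        classes[f"informative_{j}"] = "continuous_global"
    for j in range(spec.n_noise):
        cols[f"noise_{j}"] = rng.normal(0, 1, spec.n_genes)
        classes[f"noise_{j}"] = "continuous_global"
    base_p = 0.2
    odds = base_p / (1 - base_p) * math.exp(spec.effect / 2.0)
    pos_p = odds / (1 + odds)
    for j in range(spec.n_binary):
        p = np.where(is_pos > 0, pos_p, base_p)
        cols[f"flag_{j}"] = (rng.random(spec.n_genes) < p).astype(float)
        classes[f"flag_{j}"] = "binary_flag"
    df = pd.DataFrame(cols, index=pd.Index(genes, name="Gene_Name"))
    for c in df.columns:
        frac = spec.missing_frac_for(classes[c])
        if frac > 0:
            mask = rng.random(spec.n_genes) < frac
            df.loc[mask, c] = np.nan
    return GeneFeatureTable(df, classes)


def gen_ppi_graph(spec: SynthSpec, labels: LabelSet) -> InteractionGraph:
    """Random graph at the requested mean degree with boosted seed-seed edges.

    A G(n, p) background (p = mean_degree / (n-1)) is overlaid with extra
    edges among seed genes drawn at p * (assortativity_boost - 1), so the
    seed-seed edge probability is approximately boost-fold the background.
    Channels are assigned uniformly at random.
    """
    if spec.mean_degree < 1:
        raise InputError("mean_degree must be >= 1")
    rng = substream(spec.seed, "graph")
    genes = spec.gene_ids
    n = spec.n_genes
    p = spec.mean_degree / (n - 1)
    g = nx.fast_gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
    mapping = dict(enumerate(genes))
    g = nx.relabel_nodes(g, mapping)
    boost = spec.assortativity_boost
    if boost > 1:
        p_extra = min(1.0, p * (boost - 1))
        seeds_sorted = sorted(labels.genes)
        extra = nx.fast_gnp_random_graph(
            len(seeds_sorted), p_extra, seed=int(rng.integers(2**31 - 1))
        )
        for i, j in extra.edges():
            g.add_edge(seeds_sorted[i], seeds_sorted[j])
    rows = []
    for a, b in g.edges():
        channel = CHANNELS_DEFAULT[int(rng.integers(len(CHANNELS_DEFAULT)))]
        rows.append((a, b, channel, float(rng.random())))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "channel", "confidence"])
    return InteractionGraph(df)


def gen_annotation_tables(
    spec: SynthSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Zipf-skewed annotation tables: (interaction-type counts, pathway
    memberships, domain memberships).

    Type rates and pathway sizes follow a 1/rank law so the percentile-based
    featurization thresholds have non-trivial behaviour.
    """
    rng = substream(spec.seed, "annotations")
    genes = pd.Index(spec.gene_ids, name="Gene_Name")
    n = spec.n_genes

    rates = 3.0 / np.arange(1, spec.n_types + 1)
    counts = pd.DataFrame(
        {f"type_{t}": rng.poisson(rates[t], n) for t in range(spec.n_types)},
        index=genes,
    )

    sizes = np.maximum(2, (0.5 * n / np.arange(1, spec.n_pathways + 1)).astype(int))
    pathways = {}
    for t in range(spec.n_pathways):
        members = rng.choice(n, size=int(sizes[t]), replace=False)
        col = np.zeros(n, dtype=bool)
        col[members] = True
        pathways[f"pw_{t}"] = col
    pathway_df = pd.DataFrame(pathways, index=genes)

    probs = 0.15 / np.sqrt(np.arange(1, spec.n_domains + 1))
    domains = pd.DataFrame(
        {f"dom_{t}": rng.random(n) < probs[t] for t in range(spec.n_domains)},
        index=genes,
    )
    return counts, pathway_df, domains


def write_synth_inputs(spec: SynthSpec, outdir) -> dict:
    """Generate and write all four input kinds; returns the file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = gen_labels(spec)
    table = gen_feature_matrix(spec, labels)
    graph = gen_ppi_graph(spec, labels)
    counts, pathways, domains = gen_annotation_tables(spec)
    paths = {
        "features": outdir / "features.tsv",
        "class_map": outdir / "feature_classes.csv",
        "labels": outdir / "labels.txt",
        "edges": outdir / "edges.tsv",
        "interaction_types": outdir / "interaction_types.csv",
        "pathways": outdir / "pathways.csv",
        "domains": outdir / "domains.csv",
    }
    write_feature_table(table, paths["features"])
    write_class_map(table.feature_class, paths["class_map"])
    write_gene_list(labels, paths["labels"])
    write_edge_list(graph, paths["edges"])
    counts.to_csv(paths["interaction_types"])
    pathways.astype(int).to_csv(paths["pathways"])
    domains.astype(int).to_csv(paths["domains"])
    return {k: str(v) for k, v in paths.items()}
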