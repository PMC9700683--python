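"""Structured feature engineering from interaction graphs and categorical
annotation tables.

For every gene the direct (distance-1) and indirect (distance-2) seed-overlap
ratios are computed: the fraction of genes at exactly that shortest-path
distance that belong to the positive seed set. The distance-2 shell is exactly
distance 2 (it excludes the gene itself and its direct neighbours), and a
seed gene's own label never contributes to its own ratios, so the feature
cannot leak the training label. A harmonic-mean summary combines the two
ratios with zero-annihilation.

Categorical annotation tables (interaction-type counts, pathway memberships,
domain memberships) are turned into features with percentile-based frequency
filters: only sufficiently frequent types/pathways become individual columns,
the long tail is aggregated.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import GeneFeatureTable, InputError, InteractionGraph, LabelSet

logger = logging.getLogger("targetrank")


def _as_nx(graph) -> nx.Graph:
    if isinstance(graph, InteractionGraph):
        return graph.to_networkx()
    return graph


def _as_seed_set(seeds) -> frozenset:
    if isinstance(seeds, LabelSet):
        return seeds.genes
    return frozenset(seeds)


def seed_overlap_ratio(
    graph, seeds, hops: int, genes: Sequence | None = None
) -> pd.Series:
    """Fraction of a gene's exact-distance-``hops`` neighbours that are seeds.

    Genes with an empty distance-``hops`` shell (including genes absent from
    the graph) get ratio 0.
    """
    if hops not in (1, 2):
        raise InputError("hops must be 1 or 2")
    g = _as_nx(graph)
    seed_set = _as_seed_set(seeds)
    if genes is None:
        genes = sorted(g.nodes())
    if not (seed_set & set(g.nodes())):
        logger.warning("seed set is disjoint from the graph; all ratios are 0")
    out = {}
    for gene in genes:
        if gene not in g:
            out[gene] = 0.0
            continue
        shell1 = set(g.neighbors(gene))
        if hops == 1:
            shell = shell1
        else:
            shell = set()
            for nb in shell1:
                shell.update(g.neighbors(nb))
            shell -= shell1
            shell.discard(gene)
        out[gene] = len(shell & seed_set) / len(shell) if shell else 0.0
    return pd.Series(out, name=f"seed_overlap_r{hops}")


def hmean_overlap(r1, r2):
    """Harmonic mean of the two hop ratios, 0 whenever either ratio is 0."""
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if np.any((r1 < 0) | (r1 > 1) | (r2 < 0) | (r2 > 1)):
        raise InputError("overlap ratios must lie in [0, 1]")
    total = r1 + r2
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(total > 0, 2.0 * r1 * r2 / np.where(total > 0, total, 1.0), 0.0)
    return h if h.ndim else float(h)


def overlap_feature_table(
    graph: InteractionGraph,
    seeds,
    channels: Iterable[str] | None = None,
    genes: Sequence | None = None,
) -> GeneFeatureTable:
    """Per-channel r1/r2/hmean seed-overlap features as a mergeable table.

    With ``channels=None`` a single feature triple is computed over all edges;
    otherwise one triple per listed channel (edges filtered on the tag).
    """
    if genes is None:
        genes = sorted(graph.nodes())
    blocks = {}
    tags: list = [None] if channels is None else list(channels)
    for tag in tags:
        g = graph.to_networkx(channel=tag)
        prefix = "all" if tag is None else tag
        r1 = seed_overlap_ratio(g, seeds, 1, genes=genes)
        r2 = seed_overlap_ratio(g, seeds, 2, genes=genes)
        blocks[f"{prefix}_seed_overlap_r1"] = r1
        blocks[f"{prefix}_seed_overlap_r2"] = r2
        blocks[f"{prefix}_seed_overlap_hmean"] = pd.Series(
            hmean_overlap(r1.to_numpy(), r2.to_numpy()), index=r1.index
        )
    df = pd.DataFrame(blocks, index=pd.Index(genes, name="Gene_Name"))
    return GeneFeatureTable(df, {c: "network" for c in df.columns})


def featurize_interaction_types(
    counts: pd.DataFrame, percentile: float = 50
) -> GeneFeatureTable:
    """Count features for frequent interaction types.

    Type frequency = total count across genes. Types at or above the given
    percentile of the frequency distribution (linear interpolation) keep an
    individual count column; the rest are aggregated into ``other_types``.
    A per-gene ``unique_interactions`` column counts distinct nonzero types.
    """
    if counts.shape[1] == 0 or counts.shape[0] == 0:
        raise InputError("empty interaction-type count table")
    if (counts.to_numpy() < 0).any():
        raise InputError("interaction-type counts must be non-negative")
    freq = counts.sum(axis=0)
    cut = float(np.percentile(freq.to_numpy(dtype=float), percentile))
    kept = [t for t in counts.columns if freq[t] >= cut]
    rest = [t for t in counts.columns if t not in set(kept)]
    df = counts[kept].astype(float).copy()
    df.columns = [f"ixn_type_{t}" for t in kept]
    df["other_types"] = counts[rest].sum(axis=1).astype(float) if rest else 0.0
    df["unique_interactions"] = (counts > 0).sum(axis=1).astype(float)
    df.index.name = counts.index.name or "Gene_Name"
    return GeneFeatureTable(df, {c: "subset_signal" for c in df.columns})


def featurize_pathways(
    membership: pd.DataFrame, percentile: float = 90
) -> GeneFeatureTable:
    """Boolean flag per large pathway, plus a count of remaining memberships.

    Pathways whose size (number of member genes) is at or above the given
    percentile of the size distribution become individual 0/1 columns; the
    rest contribute to a per-gene membership count.
    """
    memb = membership.astype(bool)
    sizes = memb.sum(axis=0)
    if memb.shape[1] == 0:
        df = pd.DataFrame(index=memb.index)
        df["other_pathways_count"] = 0.0
        return GeneFeatureTable(df, {"other_pathways_count": "subset_signal"})
    cut = float(np.percentile(sizes.to_numpy(dtype=float), percentile))
    kept = [p for p in memb.columns if sizes[p] >= cut]
    rest = [p for p in memb.columns if p not in set(kept)]
    df = memb[kept].astype(float).copy()
    df.columns = [f"pathway_{p}" for p in kept]
    df["other_pathways_count"] = (
        memb[rest].sum(axis=1).astype(float) if rest else 0.0
    )
    df.index.name = membership.index.name or "Gene_Name"
    classes = {c: "binary_flag" for c in df.columns}
    classes["other_pathways_count"] = "subset_signal"
    return GeneFeatureTable(df, classes)


def featurize_domains(membership: pd.DataFrame) -> GeneFeatureTable:
    """One unfiltered 0/1 flag per protein domain/family/superfamily."""
    memb = membership.astype(bool).astype(float)
    memb.columns = [f"domain_{d}" for d in membership.columns]
    memb.index.name = membership.index.name or "Gene_Name"
    return GeneFeatureTable(memb, {c: "binary_flag" for c in memb.columns})


def merge_feature_tables(*tables: GeneFeatureTable) -> GeneFeatureTable:
    """Column-wise merge of feature tables sharing one gene universe."""
    base = tables[0].values.index
    for t in tables[1:]:
        if not base.equals(t.values.index):
            raise InputError("feature tables disagree on the gene universe")
    df = pd.concat([t.values for t in tables], axis=1)
    classes = {}
    for t in tables:
        classes.update(t.feature_class)
    return GeneFeatureTable(df, classes)
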