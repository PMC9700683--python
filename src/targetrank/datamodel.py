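"""Core domain types, file readers/writers, run configuration and seeded RNG streams.

The central containers are deliberately thin wrappers around pandas/networkx
objects: a :class:`GeneFeatureTable` is a genes x features DataFrame with an
explicit per-feature class tag (which drives imputation policy), a
:class:`LabelSet` is a named set of positive ("seed") gene symbols, and an
:class:`InteractionGraph` is an undirected gene graph with optional evidence
channels. Gene identifiers are opaque, case-sensitive strings; no symbol
normalisation is attempted.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("targetrank")

FEATURE_CLASSES = ("binary_flag", "subset_signal", "continuous_global", "network")

#: tokens (case-insensitive) treated as a missing cell in delimited input
MISSING_TOKENS = frozenset({"", "na", "nan"})

GB_DEFAULTS: dict = {
    "n_estimators": 200,
    "learning_rate": 0.1,
    "max_depth": 5,
    "max_features": "sqrt",
    "min_samples_leaf": 4,
    "min_samples_split": 5,
}

#: pre-tuning gradient-boosting values the tuned ones replaced
GB_INHERITED: dict = {
    "n_estimators": 500,
    "learning_rate": 0.1,
    "max_depth": 20,
    "max_features": "sqrt",
    "min_samples_leaf": 4,
    "min_samples_split": 5,
}


class InputError(ValueError):
    """Malformed or inconsistent user input."""


def substream(seed: int, name: str, *extra: int) -> np.random.Generator:
    """Named, independent RNG substream derived from a single run seed.

    All randomness in the package flows through this helper so a run is
    bit-reproducible from ``RunConfig.seed`` alone.
    """
    key = [int(seed), zlib.crc32(name.encode("utf-8"))] + [int(e) for e in extra]
    return np.random.default_rng(np.random.SeedSequence(key))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneFeatureTable:
    """Genes x features matrix with NaN as the missing marker.

    ``values`` is indexed by gene identifier with one column per feature;
    ``feature_class`` tags every feature with one of :data:`FEATURE_CLASSES`.
    """

    values: pd.DataFrame
    feature_class: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise InputError(f"duplicate gene identifier: {dup!r}")
        cols = self.values.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise InputError(f"duplicate feature name: {dup!r}")
        # booleans stored as 0/1; everything else must be numeric
        vals = self.values
        for c in cols:
            if vals[c].dtype == bool:
                vals[c] = vals[c].astype(float)
            elif not pd.api.types.is_numeric_dtype(vals[c]):
                raise InputError(f"feature {c!r} holds non-numeric values")
        self.values = vals.astype(float)
        for c in cols:
            cls = self.feature_class.setdefault(c, "continuous_global")
            if cls not in FEATURE_CLASSES:
                raise InputError(f"unknown feature class {cls!r} for {c!r}")
        # drop stale class entries for features not present
        self.feature_class = {c: self.feature_class[c] for c in cols}

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_names(self) -> list:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def select_features(self, names: Sequence[str]) -> "GeneFeatureTable":
        return GeneFeatureTable(
            self.values[list(names)].copy(),
            {n: self.feature_class[n] for n in names},
        )

    def copy(self) -> "GeneFeatureTable":
        return GeneFeatureTable(self.values.copy(), dict(self.feature_class))


@dataclass(frozen=True)
class LabelSet:
    """Named positive (seed) gene set; every other gene is unlabelled."""

    name: str
    genes: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise InputError(f"label set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, g) -> bool:
        return g in self.genes


CHANNELS_DEFAULT = ("experimental", "inferred", "physical", "protein")


@dataclass
class InteractionGraph:
    """Undirected gene graph with optional per-edge channel tag and confidence.

    Edges are stored unordered (A-B == B-A), without self-loops, and
    deduplicated within each channel.
    """

    edges: pd.DataFrame  # columns: gene_a, gene_b, channel, confidence

    def __post_init__(self) -> None:
        df = self.edges.copy()
        for col, default in (("channel", None), ("confidence", np.nan)):
            if col not in df.columns:
                df[col] = default
        df = df[["gene_a", "gene_b", "channel", "confidence"]]
        loops = df["gene_a"] == df["gene_b"]
        if loops.any():
            logger.warning("dropping %d self-loop edge(s)", int(loops.sum()))
            df = df[~loops]
        a = df["gene_a"].astype(str).to_numpy()
        b = df["gene_b"].astype(str).to_numpy()
        swap = a > b
        df = df.assign(gene_a=np.where(swap, b, a), gene_b=np.where(swap, a, b))
        df = df.drop_duplicates(subset=["gene_a", "gene_b", "channel"])
        self.edges = df.reset_index(drop=True)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def channels(self) -> list:
        ch = self.edges["channel"].dropna().unique().tolist()
        return sorted(ch)

    def nodes(self) -> set:
        return set(self.edges["gene_a"]) | set(self.edges["gene_b"])

    def to_networkx(self, channel: str | None = None) -> nx.Graph:
        """Simple undirected graph, optionally restricted to one channel."""
        df = self.edges
        if channel is not None:
            df = df[df["channel"] == channel]
        g = nx.Graph()
        g.add_nodes_from(self.nodes())
        g.add_edges_from(zip(df["gene_a"], df["gene_b"]))
        return g


@dataclass
class ScoreTable:
    """Per-gene mean out-of-bag probability with prediction count and percentile."""

    table: pd.DataFrame  # columns: gene, score, n_oob, percentile

    def __post_init__(self) -> None:
        required = {"gene", "score", "n_oob"}
        missing = required - set(self.table.columns)
        if missing:
            raise InputError(f"score table missing columns: {sorted(missing)}")
        if "percentile" not in self.table.columns:
            self.table["percentile"] = np.nan
        t = self.table
        if (t["n_oob"] < 0).any():
            raise InputError("negative n_oob count")
        defined = t["n_oob"] > 0
        s = t.loc[defined, "score"]
        if ((s < 0) | (s > 1)).any():
            raise InputError("scores must lie in [0, 1]")

    @property
    def genes(self) -> list:
        return list(self.table["gene"])

    def score_of(self, gene) -> float:
        row = self.table[self.table["gene"] == gene]
        return float(row["score"].iloc[0])


@dataclass
class ClassifierSpec:
    """Name + hyperparameter map for a registry classifier."""

    name: str = "gradient_boosting"
    hyperparameters: dict = field(default_factory=dict)


@dataclass
class RunConfig:
    """Run-level parameters for the stochastic PU ensemble.

    L -- number of stochastic iterations; k -- CV folds; rho -- balancing
    ratio of unlabelled to positive genes per partition.
    """

    L: int = 10
    k: int = 10
    rho: float = 1.5
    seed: int = 0
    correlation_threshold: float = 0.8
    missing_data_thres: float = 0.99
    classifier_spec: ClassifierSpec = field(default_factory=ClassifierSpec)

    def __post_init__(self) -> None:
        if self.L < 1:
            raise InputError("L must be a positive integer")
        if self.k < 2:
            raise InputError("k must be >= 2")
        if self.rho <= 0:
            raise InputError("rho must be positive")
        for name in ("correlation_threshold", "missing_data_thres"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise InputError(f"{name} must lie in (0, 1]")
        if isinstance(self.classifier_spec, dict):
            self.classifier_spec = ClassifierSpec(**self.classifier_spec)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_feature_table(path, class_map: Mapping[str, str] | None = None) -> GeneFeatureTable:
    """Read a delimited gene x feature table (first column = gene identifiers).

    Missing cells are empty or "NA"/"NaN" (case-insensitive). Any other
    non-numeric cell is a hard error naming the offending row and column.
    """
    path = Path(path)
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    seen: set = set()
    for name in header[1:]:
        if name in seen:
            raise InputError(f"{path}: duplicate feature name {name!r}")
        seen.add(name)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise InputError(f"{path}: expected gene column plus >=1 feature column")
    gene_col = raw.columns[0]
    genes = raw[gene_col]
    dup = genes[genes.duplicated()]
    if len(dup):
        raise InputError(f"{path}: duplicate gene row {dup.iloc[0]!r}")
    data = raw.drop(columns=[gene_col])
    out = {}
    for col in data.columns:
        cells = data[col].str.strip()
        is_missing = cells.str.lower().isin(MISSING_TOKENS)
        lowered = cells.str.lower()
        cells = cells.mask(lowered == "true", "1").mask(lowered == "false", "0")
        probe = pd.to_numeric(cells.mask(is_missing), errors="coerce")
        bad = probe.isna() & ~is_missing
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise InputError(
                f"{path}: non-numeric cell {data[col].iloc[row]!r} "
                f"at gene {genes.iloc[row]!r}, feature {col!r}"
            )
        # python float() parsing is exact to the ulp, unlike to_numeric's
        out[col] = cells.mask(is_missing).astype(float)
    values = pd.DataFrame(out)
    values.index = pd.Index(genes, name=gene_col)
    return GeneFeatureTable(values, dict(class_map or {}))


def write_feature_table(table: GeneFeatureTable, path) -> None:
    path = Path(path)
    df = table.values.copy()
    df.index.name = df.index.name or "Gene_Name"
    df.to_csv(path, sep=_sep_for(path), na_rep="")


def read_gene_list(path, name: str | None = None) -> LabelSet:
    """Plain-text gene list, one symbol per line; repeats collapse to a set."""
    path = Path(path)
    genes = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not genes:
        raise InputError(f"{path}: empty gene list")
    return LabelSet(name or path.stem, frozenset(genes))


def write_gene_list(labels: LabelSet, path) -> None:
    Path(path).write_text("\n".join(sorted(labels.genes)) + "\n")


def read_edge_list(path) -> InteractionGraph:
    """TSV edge list: geneA, geneB [, channel [, confidence]]. No header."""
    path = Path(path)
    rows = []
    for i, ln in enumerate(path.read_text().splitlines()):
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) < 2:
            raise InputError(f"{path}:{i + 1}: edge row needs >= 2 columns")
        a, b = parts[0].strip(), parts[1].strip()
        channel = parts[2].strip() if len(parts) > 2 and parts[2].strip() else None
        conf = float(parts[3]) if len(parts) > 3 and parts[3].strip() else np.nan
        rows.append((a, b, channel, conf))
    if not rows:
        raise InputError(f"{path}: empty edge list")
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "channel", "confidence"])
    return InteractionGraph(df)


def write_edge_list(graph: InteractionGraph, path) -> None:
    df = graph.edges.copy()
    df["channel"] = df["channel"].fillna("")
    df["confidence"] = df["confidence"].map(
        lambda v: "" if pd.isna(v) else repr(float(v))
    )
    df.to_csv(path, sep="\t", header=False, index=False)


SCORE_COLUMNS = ["Gene_Name", "druggability_score", "n_oob", "percentile"]


def write_scores(scores: ScoreTable, path) -> None:
    """Scores CSV with header Gene_Name, druggability_score, n_oob, percentile."""
    df = scores.table.rename(
        columns={"gene": "Gene_Name", "score": "druggability_score"}
    )[SCORE_COLUMNS]
    df = df.copy()
    df["druggability_score"] = df["druggability_score"].round(6)
    df["percentile"] = df["percentile"].round(6)
    df.to_csv(path, index=False)


def read_scores(path) -> ScoreTable:
    df = pd.read_csv(path)
    df = df.rename(columns={"Gene_Name": "gene", "druggability_score": "score"})
    return ScoreTable(df)


def read_class_map(path) -> dict:
    """Two-column CSV (feature, class) mapping features to feature classes."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise InputError(f"{path}: class map needs feature and class columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_class_map(feature_class: Mapping[str, str], path) -> None:
    pd.DataFrame(
        {"feature": list(feature_class), "class": list(feature_class.values())}
    ).to_csv(path, index=False)


def read_config(path) -> RunConfig:
    """YAML key:value file mirroring RunConfig fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise InputError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
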