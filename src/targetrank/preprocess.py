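"""Automated feature pre-processing: sparsity filter, correlation pruning,
class-aware imputation and standardization.

The pipeline order is fixed (drop_sparse -> prune_correlated -> impute ->
standardize) and the composed operation is idempotent on its own output. The
gene universe is never altered; only feature columns change, and the returned
report fully accounts for every column dropped, imputed or rescaled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .datamodel import GeneFeatureTable, InputError, RunConfig

logger = logging.getLogger("targetrank")


@dataclass
class PreprocessReport:
    dropped_correlated: list = field(default_factory=list)  # (kept, dropped, r)
    dropped_sparse: list = field(default_factory=list)      # (feature, missing_frac)
    imputed: dict = field(default_factory=dict)             # feature -> (policy, fill)
    standardized: dict = field(default_factory=dict)        # feature -> (mean, sd)

    def merge(self, other: "PreprocessReport") -> "PreprocessReport":
        return PreprocessReport(
            self.dropped_correlated + other.dropped_correlated,
            self.dropped_sparse + other.dropped_sparse,
            {**self.imputed, **other.imputed},
            {**self.standardized, **other.standardized},
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kept, dropped, r in self.dropped_correlated:
            rows.append(("dropped_correlated", dropped, f"kept={kept}", r))
        for feat, frac in self.dropped_sparse:
            rows.append(("dropped_sparse", feat, "missing_fraction", frac))
        for feat, (policy, fill) in self.imputed.items():
            rows.append(("imputed", feat, policy, fill))
        for feat, (mean, sd) in self.standardized.items():
            rows.append(("standardized", feat, f"mean={mean!r}", sd))
        return pd.DataFrame(rows, columns=["step", "feature", "detail", "value"])


def drop_sparse(
    table: GeneFeatureTable, missing_data_thres: float = 0.99
) -> tuple[GeneFeatureTable, PreprocessReport]:
    """Drop features whose missing fraction exceeds the threshold.

    The default of 0.99 keeps even very sparse features, provided at least
    1% of genes have an observed value.
    """
    if not (0 < missing_data_thres <= 1):
        raise InputError("missing_data_thres must lie in (0, 1]")
    frac = table.values.isna().mean()
    drop = frac.index[frac > missing_data_thres]
    report = PreprocessReport(
        dropped_sparse=[(f, float(frac[f])) for f in drop]
    )
    if len(drop):
        logger.info("drop_sparse: removing %d feature(s)", len(drop))
    keep = [f for f in table.feature_names if f not in set(drop)]
    return table.select_features(keep), report


def prune_correlated(
    table: GeneFeatureTable, threshold: float = 0.8
) -> tuple[GeneFeatureTable, PreprocessReport]:
    """Remove one member of every feature pair with |Pearson r| above threshold.

    Correlations are computed pairwise over cells where both features are
    observed; a feature with fewer than 3 jointly observed values against
    every other feature is excluded from testing (and retained). Features are
    scanned in column order and the earlier column of a flagged pair is kept.
    """
    if table.values.shape[1] < 1:
        raise InputError("feature table has no features")
    corr = table.values.corr(method="pearson", min_periods=3)
    untestable = [
        f for f in table.feature_names
        if corr.loc[f].drop(f).isna().all()
    ]
    if untestable:
        logger.info(
            "prune_correlated: %d feature(s) lack >=3 jointly observed values "
            "with every other feature and are retained untested", len(untestable)
        )
    kept: list = []
    report = PreprocessReport()
    for f in table.feature_names:
        partner = None
        for k in kept:
            r = corr.loc[k, f]
            if pd.notna(r) and abs(r) > threshold:
                partner = (k, float(r))
                break
        if partner is None:
            kept.append(f)
        else:
            report.dropped_correlated.append((partner[0], f, partner[1]))
    return table.select_features(kept), report


def impute(table: GeneFeatureTable) -> tuple[GeneFeatureTable, PreprocessReport]:
    """Fill missing cells: zero for binary flags, subset signals and network
    features; the feature's observed median for continuous_global features."""
    values = table.values.copy()
    report = PreprocessReport()
    for f in table.feature_names:
        col = values[f]
        n_missing = int(col.isna().sum())
        if n_missing == 0:
            continue
        cls = table.feature_class[f]
        if cls == "continuous_global":
            observed = col.dropna()
            if observed.empty:
                raise InputError(
                    f"continuous feature {f!r} has no observed values; "
                    "it should have been removed by drop_sparse"
                )
            fill = float(observed.median())
            policy = "median"
        else:
            fill, policy = 0.0, "zero"
        values[f] = col.fillna(fill)
        report.imputed[f] = (policy, fill)
    return GeneFeatureTable(values, dict(table.feature_class)), report


def standardize(table: GeneFeatureTable) -> tuple[GeneFeatureTable, PreprocessReport]:
    """Rescale every feature to zero mean and unit variance (population
    moments); constant features map to all-zeros."""
    if table.n_missing:
        raise InputError("standardize requires a fully imputed table")
    values = table.values.copy()
    report = PreprocessReport()
    for f in table.feature_names:
        col = values[f].to_numpy(dtype=float)
        mean = float(col.mean())
        sd = float(col.std(ddof=0))
        if sd == 0.0:
            values[f] = 0.0
        else:
            values[f] = (col - mean) / sd
        report.standardized[f] = (mean, sd)
    return GeneFeatureTable(values, dict(table.feature_class)), report


def run_preprocess(
    table: GeneFeatureTable, config: RunConfig | None = None
) -> tuple[GeneFeatureTable, PreprocessReport]:
    """Full pipeline in fixed order: drop_sparse -> prune_correlated ->
    impute -> standardize."""
    config = config or RunConfig()
    t, rep1 = drop_sparse(table, config.missing_data_thres)
    t, rep2 = prune_correlated(t, config.correlation_threshold)
    t, rep3 = impute(t)
    t, rep4 = standardize(t)
    return t, rep1.merge(rep2).merge(rep3).merge(rep4)
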