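"""Shadow-feature selection (Boruta) with binomial hit classification.

Each iteration appends a "shadow" copy of the feature matrix — every column
independently permuted, destroying any association with the labels — fits a
random forest on the augmented matrix, and records a *hit* for every original
feature whose importance strictly exceeds the most important shadow feature.
After R iterations, a feature's hit count is compared against Binomial(R, 1/2):
features above the 95th-percentile bound are Confirmed, below the
5th-percentile bound Rejected, and everything between is Tentative.

Unlike the classic sequential variant, all features stay in play for all R
iterations and are classified once at the end; the terminal binomial rule is
identical, the mid-run removal of already-rejected features is not performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.ensemble import RandomForestClassifier

from .datamodel import GeneFeatureTable, InputError

logger = logging.getLogger("targetrank")

CONFIRMED, TENTATIVE, REJECTED = "Confirmed", "Tentative", "Rejected"


@dataclass
class BorutaResult:
    features: list
    hits: np.ndarray                 # per feature, in [0, R]
    status: list                     # Confirmed / Tentative / Rejected
    importances: np.ndarray          # R x n_features, per-iteration importances
    shadow_max: np.ndarray           # per iteration, max shadow importance
    shadow_mean: np.ndarray          # per iteration, mean shadow importance
    R: int

    @property
    def mean_importance(self) -> np.ndarray:
        return self.importances.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.features,
                "hits": self.hits,
                "status": self.status,
                "mean_importance": self.mean_importance,
            }
        )


def binomial_bounds(R: int, p: float = 0.5) -> tuple[int, int]:
    """(rejected_bound, confirmed_bound) for Binomial(R, p).

    confirmed_bound = smallest q with CDF >= 0.95 (Confirmed iff hits > q);
    rejected_bound = largest q with CDF <= 0.05 (Rejected iff hits < q).
    """
    upper = int(binom.ppf(0.95, R, p))
    lower = int(binom.ppf(0.05, R, p))
    if binom.cdf(lower, R, p) > 0.05:
        lower -= 1
    return lower, upper


def status_from_hits(hits: int, R: int) -> str:
    """Terminal Boruta status from the hit count alone (pure function)."""
    lower, upper = binomial_bounds(R)
    if hits > upper:
        return CONFIRMED
    if hits < lower:
        return REJECTED
    return TENTATIVE


def make_shadows(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shadow matrix: each column independently permuted, so every shadow
    keeps its source column's marginal distribution but loses any association
    with the labels."""
    n = X.shape[0]
    return np.column_stack([X[rng.permutation(n), j] for j in range(X.shape[1])])


def boruta_select(
    X,
    y,
    R: int = 40,
    rng: np.random.Generator | None = None,
    n_estimators: int = 100,
    importance: str = "impurity",
) -> BorutaResult:
    """Run R shadow-feature iterations and classify every feature.

    ``importance`` selects the forest importance measure; only the
    impurity-based measure is currently registered.
    """
    if importance != "impurity":
        raise InputError(f"unknown importance measure {importance!r}")
    if isinstance(X, GeneFeatureTable):
        X = X.values
    X = pd.DataFrame(X)
    y = np.asarray(y)
    if X.shape[1] == 0:
        raise InputError("no features to select from")
    if set(np.unique(y)) - {0, 1} or len(np.unique(y)) != 2:
        raise InputError("labels must be binary 0/1 with both classes present")
    if R < 10:
        raise InputError("R must be >= 10 for a meaningful binomial bound")
    rng = rng or np.random.default_rng()

    n, f = X.shape
    Xv = X.to_numpy(dtype=float)
    hits = np.zeros(f, dtype=int)
    importances = np.empty((R, f))
    shadow_max = np.empty(R)
    shadow_mean = np.empty(R)
    for r in range(R):
        shadows = make_shadows(Xv, rng)
        augmented = np.hstack([Xv, shadows])
        forest = RandomForestClassifier(
            n_estimators=n_estimators,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(augmented, y)
        imp = forest.feature_importances_
        orig, shad = imp[:f], imp[f:]
        s_prime = shad.max()
        hits += orig > s_prime
        importances[r] = orig
        shadow_max[r] = s_prime
        shadow_mean[r] = shad.mean()

    status = [status_from_hits(int(h), R) for h in hits]
    return BorutaResult(
        features=list(X.columns),
        hits=hits,
        status=status,
        importances=importances,
        shadow_max=shadow_max,
        shadow_mean=shadow_mean,
        R=R,
    )


def importance_zscores(result: BorutaResult) -> pd.Series:
    """Rank features by z = (mean importance - mean shadow importance) / sd.

    The sd is taken over the feature's per-iteration importances; a zero sd
    yields a +inf sentinel ranked first.
    """
    mean_imp = result.importances.mean(axis=0)
    sd = result.importances.std(axis=0, ddof=1)
    baseline = result.shadow_mean.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (mean_imp - baseline) / sd
    z = np.where(sd == 0, np.inf, z)
    if np.isinf(z).any():
        logger.warning("%d feature(s) with zero importance variance", int(np.isinf(z).sum()))
    series = pd.Series(z, index=result.features, name="z")
    return series.sort_values(ascending=False)
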