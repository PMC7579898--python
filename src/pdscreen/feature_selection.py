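"""Maximum-relevance minimum-redundancy (mRMR) feature ranking.

Features are ranked by greedy forward selection: the first feature
maximizes the mutual information I(feature; label); each subsequent pick
maximizes the MID (difference) criterion

    score(f) = I(f; y) - mean_{s in S} I(f; s)

over the already-selected set S. Mutual information is estimated on
equal-frequency (quantile) discretized features with min(10, ceil(sqrt(n)))
bins, which makes the ranking invariant to strictly monotone transforms of
any single feature and to row order. Ties are broken by higher relevance,
then by canonical (column) order, so the ranking is fully deterministic.

Gender-stratified runs ("male" / "female") reproduce the protocol of
ranking the dysphonia features separately per gender; rows with unknown
gender participate only in the pooled ("both") run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score

from .errors import DegenerateLabelError, ParameterError
from .io_formats import LabeledFeatureTable

STRATA = ("both", "male", "female")


@dataclass
class FeatureRanking:
    """Ordered mRMR selection: rank 1 is the first feature chosen."""

    names: list[str]          # in selection order
    relevance: np.ndarray     # I(feature; label), same order
    redundancy: np.ndarray    # mean MI with previously selected, same order
    stratum: str

    def __len__(self) -> int:
        return len(self.names)

    @property
    def ranks(self) -> dict[str, int]:
        return {name: i + 1 for i, name in enumerate(self.names)}

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "name": self.names,
            "rank": np.arange(1, len(self.names) + 1),
            "relevance": self.relevance,
            "redundancy": self.redundancy,
        })


def quantile_discretize(col: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency discretization; constant columns map to one bin."""
    col = np.asarray(col, float)
    edges = np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, col, side="right")


def _n_bins(n_rows: int) -> int:
    return int(min(10, np.ceil(np.sqrt(n_rows))))


def mrmr_rank(table: LabeledFeatureTable, stratum: str = "both",
              ) -> FeatureRanking:
    """Rank all features of a labelled table by greedy mRMR (MID form)."""
    if stratum not in STRATA:
        raise ParameterError(f"stratum must be one of {STRATA}, got {stratum!r}")
    if stratum != "both":
        mask = (table.gender == stratum).to_numpy()
        table = table.subset(mask)
    X = table.features.to_numpy(dtype=float)
    y = table.status.to_numpy()
    names = table.feature_names
    n, p = X.shape
    if p < 2:
        raise ParameterError(f"need >= 2 features, got {p}")
    if len(np.unique(y)) < 2:
        raise DegenerateLabelError(
            f"stratum {stratum!r} holds a single class; cannot rank")
    if not np.all(np.isfinite(X)):
        raise ParameterError("feature table contains missing/non-finite values")
    bins = _n_bins(n)
    D = np.column_stack([quantile_discretize(X[:, j], bins) for j in range(p)])
    relevance = np.array([mutual_info_score(y, D[:, j]) for j in range(p)])
    pair_mi = np.full((p, p), np.nan)

    def mi(a: int, b: int) -> float:
        if np.isnan(pair_mi[a, b]):
            v = mutual_info_score(D[:, a], D[:, b])
            pair_mi[a, b] = pair_mi[b, a] = v
        return pair_mi[a, b]

    selected: list[int] = []
    red_out: list[float] = []
    remaining = list(range(p))
    while remaining:
        best_j, best_key, best_red = None, None, 0.0
        for j in remaining:
            red = (np.mean([mi(j, s) for s in selected]) if selected else 0.0)
            score = relevance[j] - red
            # tie-breaks: higher relevance, then canonical column order
            key = (round(score, 12), round(relevance[j], 12), -j)
            if best_key is None or key > best_key:
                best_j, best_key, best_red = j, key, red
        selected.append(best_j)
        red_out.append(best_red)
        remaining.remove(best_j)
    return FeatureRanking(
        [names[j] for j in selected],
        relevance[selected],
        np.asarray(red_out),
        stratum,
    )


def select_top_k(ranking: FeatureRanking, k: int) -> list[str]:
    """First k feature names in rank order."""
    if not 1 <= k <= len(ranking):
        raise ParameterError(f"k must be 1..{len(ranking)}, got {k}")
    return ranking.names[:k]
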