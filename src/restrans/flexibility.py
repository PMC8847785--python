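"""Per-ASV flexibility scores: partitioning residents from transients.

For each ASV, every unordered sample pair in which the ASV is present in
at least one member is scored 1 if it is present in both, 0 if in exactly
one (the per-ASV binary Sorensen sharing; double-absence pairs carry no
information about the taxon and are excluded). Averaging over
same-population pairs gives ``s_within``, over different-population pairs
``s_between``, and the flexibility score is the sharing ratio

    FS = s_within / s_between.

FS > 1 means the ASV is restricted to particular host populations
(resident), FS < 1 that it is shared across populations more often than
within them (transient), FS = 1 that it is population-blind (neutral).
``s_between = 0`` with ``s_within > 0`` gives FS = +inf: a perfectly
population-restricted taxon.

An alternative ``mode="dissimilarity"`` scores the literal ratio of
within- to between-population per-ASV dissimilarity,
``(1 - s_within) / (1 - s_between)``; its orientation is inverted
(resident <=> score < 1) and it is not the default because the resident /
transient reading above is only satisfied by the sharing ratio.

All pair counts are computed in closed form from per-population presence
counts: with ``K_p`` = number of samples of population ``p`` containing
the ASV and ``n_p`` the population size,

    both-present within   = sum_p C(K_p, 2)
    eligible within       = sum_p [C(K_p, 2) + K_p (n_p - K_p)]
    both-present between  = (S^2 - sum_p K_p^2) / 2,     S = sum_p K_p
    eligible between      = both-present between
                            + sum_p K_p (N - n_p - (S - K_p))

which makes the scores exact and O(populations x ASVs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import (
    DegenerateDesignError,
    EmptyResultError,
    ParameterError,
)
from .filters import PrevalenceFilter
from .io import validate_asv_table


@dataclass
class TailSelection:
    fraction: float
    top_asvs: List[str]
    bottom_asvs: List[str]


def _population_presence_counts(
    table: pd.DataFrame, populations: pd.Series
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-population presence counts K (pops x ASVs) and sizes n_p."""
    presence = (table.to_numpy() > 0)
    pop = populations.loc[table.index].to_numpy()
    labels = np.unique(pop)
    K = np.stack([presence[pop == p].sum(axis=0) for p in labels]).astype(np.int64)
    n_p = np.array([(pop == p).sum() for p in labels], dtype=np.int64)
    return K, n_p


def _sharing_components(K: np.ndarray, n_p: np.ndarray):
    """Vectorised within/between sharing from population presence counts."""
    S = K.sum(axis=0)
    N = n_p.sum()
    within_both = (K * (K - 1) // 2).sum(axis=0)
    within_elig = within_both + (K * (n_p[:, None] - K)).sum(axis=0)
    between_both = (S * S - (K * K).sum(axis=0)) // 2
    between_elig = between_both + (
        K * ((N - n_p[:, None]) - (S[None, :] - K))
    ).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        s_within = np.where(within_elig > 0, within_both / np.maximum(within_elig, 1), np.nan)
        s_between = np.where(between_elig > 0, between_both / np.maximum(between_elig, 1), np.nan)
    return s_within, s_between, within_elig, between_elig


def per_asv_sharing(
    table: pd.DataFrame, meta: pd.DataFrame, asv: str
) -> Tuple[float, float, int, int]:
    """(s_within, s_between, n_within_pairs, n_between_pairs) for one ASV.

    Pair counts are the numbers of eligible pairs (ASV present in at least
    one member) in each comparison class.
    """
    table = validate_asv_table(table)
    if asv not in table.columns:
        raise ParameterError(f"unknown ASV {asv!r}")
    if (table[asv] > 0).sum() < 1:
        raise ParameterError(f"ASV {asv!r} is absent from every sample")
    pops = meta.loc[table.index, "population"]
    if pops.nunique() < 2:
        raise DegenerateDesignError("sharing needs at least 2 populations")
    K, n_p = _population_presence_counts(table[[asv]], pops)
    s_w, s_b, we, be = _sharing_components(K, n_p)
    return float(s_w[0]), float(s_b[0]), int(we[0]), int(be[0])


class FlexibilityScorer(BaseEstimator):
    """Estimator computing per-ASV flexibility scores and residency calls.

    Parameters
    ----------
    min_prevalence : float, default 0.01
        ASVs present in at most this fraction of samples are dropped
        before scoring (strictly-greater-than rule).
    smoothing : float, default 0
        Pseudo-pair smoothing: FS = (s_within + smoothing) /
        (s_between + smoothing). Zero keeps the plain ratio and permits
        FS = +inf.
    mode : {"sharing", "dissimilarity"}
        Score orientation (see module docstring).

    Call ``fit(X, y)`` with ``X`` a samples x ASVs count frame and ``y``
    per-sample population labels (aligned sequence or Series indexed by
    sample).

    Attributes
    ----------
    scores_ : pandas.DataFrame
        One row per scored ASV: s_within, s_between, fs, n_within_pairs,
        n_between_pairs, residency, prevalence.
    n_undefined_ : int
        ASVs with no eligible pair in one class (flagged ``undefined``).
    n_infinite_ : int
        ASVs with an infinite score.
    """

    def __init__(self, min_prevalence: float = 0.01, smoothing: float = 0.0,
                 mode: str = "sharing"):
        self.min_prevalence = min_prevalence
        self.smoothing = smoothing
        self.mode = mode

    def fit(self, X: pd.DataFrame, y=None):
        if self.mode not in ("sharing", "dissimilarity"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        if self.smoothing < 0:
            raise ParameterError("smoothing must be non-negative")
        X = validate_asv_table(X)
        if y is None:
            raise ParameterError("population labels (y) are required")
        pops = (y.loc[X.index] if isinstance(y, pd.Series)
                else pd.Series(list(y), index=X.index)).astype(str)
        if pops.nunique() < 2:
            raise DegenerateDesignError(
                "flexibility scores need at least 2 populations"
            )
        if self.min_prevalence > 0:
            X = PrevalenceFilter(min_fraction=self.min_prevalence).fit(X).transform(X)
        else:
            keep = (X > 0).any(axis=0)
            if not keep.any():
                raise EmptyResultError("no ASV present in any sample")
            X = X.loc[:, keep]

        K, n_p = _population_presence_counts(X, pops)
        s_w, s_b, we, be = _sharing_components(K, n_p)
        prevalence = (X > 0).mean(axis=0).to_numpy()

        defined = (we > 0) & (be > 0)
        eps = self.smoothing
        with np.errstate(divide="ignore", invalid="ignore"):
            if self.mode == "sharing":
                num, den = s_w + eps, s_b + eps
            else:
                num, den = (1.0 - s_w) + eps, (1.0 - s_b) + eps
            fs = np.where(den > 0, num / den, np.where(num > 0, np.inf, np.nan))
        fs = np.where(defined, fs, np.nan)
        undefined = ~defined | ~(np.isfinite(fs) | np.isinf(fs))

        if self.mode == "sharing":
            resident = fs > 1
            transient = fs < 1
        else:  # dissimilarity ratio: orientation inverted
            resident = fs < 1
            transient = fs > 1
        residency = np.where(
            undefined, "undefined",
            np.where(resident, "resident", np.where(transient, "transient", "neutral")),
        )
        self.scores_ = pd.DataFrame(
            {
                "s_within": s_w,
                "s_between": s_b,
                "fs": fs,
                "n_within_pairs": we,
                "n_between_pairs": be,
                "residency": residency,
                "prevalence": prevalence,
            },
            index=pd.Index(X.columns, name="asv_id"),
        )
        self.n_undefined_ = int(undefined.sum())
        self.n_infinite_ = int(np.isinf(fs).sum())
        self.populations_ = pops
        return self

    def predict(self, X=None) -> pd.Series:
        """Residency call per scored ASV (resident/transient/neutral)."""
        return self.scores_["residency"]


def flexibility_scores(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    min_prevalence: float = 0.01,
    smoothing: float = 0.0,
    mode: str = "sharing",
) -> pd.DataFrame:
    """Per-ASV flexibility table (thin wrapper over FlexibilityScorer)."""
    scorer = FlexibilityScorer(
        min_prevalence=min_prevalence, smoothing=smoothing, mode=mode
    )
    scorer.fit(table, meta.loc[table.index, "population"])
    return scorer.scores_


def select_tails(fs_table: pd.DataFrame, fraction: float = 0.01) -> TailSelection:
    """Top and bottom FS tails, ``ceil(fraction * n)`` ASVs per side.

    +inf ranks above every finite score; ties at the boundary are broken
    by higher prevalence, then lexicographic ASV id. ASVs with undefined
    scores are not rankable and are skipped.
    """
    if not (0 < fraction < 0.5):
        raise ParameterError("tail fraction must lie in (0, 0.5)")
    rankable = fs_table[fs_table["fs"].notna()]
    if rankable.empty:
        raise EmptyResultError("no rankable flexibility scores")
    n = len(rankable)
    size = ceil(fraction * n)
    frame = rankable.reset_index()
    id_col = frame.columns[0]
    top = frame.sort_values(
        ["fs", "prevalence", id_col], ascending=[False, False, True]
    )[id_col].head(size).tolist()
    bottom = frame.sort_values(
        ["fs", "prevalence", id_col], ascending=[True, False, True]
    )[id_col].head(size).tolist()
    return TailSelection(fraction=fraction, top_asvs=top, bottom_asvs=bottom)


def order_level_summary(fs_table: pd.DataFrame, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """FS distribution summaries per taxonomic order.

    ASVs lacking an order label are grouped under ``unclassified``. Rows:
    one per order with n, min, quartiles, max and the fraction of ASVs
    with FS > 1 (infinite scores count as > 1; undefined scores are
    excluded).
    """
    scored = fs_table[fs_table["fs"].notna()]
    overlap = scored.index.intersection(taxonomy.index)
    if "order" not in taxonomy.columns:
        raise ParameterError("taxonomy table lacks an 'order' column")
    if overlap.empty:
        raise EmptyResultError("taxonomy covers no scored ASV")
    order = taxonomy["order"].reindex(scored.index)
    order = order.fillna("unclassified").replace("", "unclassified")
    rows = []
    for name, block in scored.groupby(order, sort=True):
        fs = block["fs"].to_numpy()
        finite = fs[np.isfinite(fs)]
        rows.append(
            {
                "order": name,
                "n": len(fs),
                "min": float(np.min(fs)),
                "q1": float(np.quantile(finite, 0.25)) if finite.size else np.inf,
                "median": float(np.quantile(finite, 0.5)) if finite.size else np.inf,
                "q3": float(np.quantile(finite, 0.75)) if finite.size else np.inf,
                "max": float(np.max(fs)),
                "fraction_fs_above_1": float(np.mean(fs > 1)),
            }
        )
    return pd.DataFrame(rows).set_index("order")
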