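"""Sorensen-Dice beta diversity and pairwise comparison extraction.

The Sorensen-Dice dissimilarity between two samples is computed on
presence/absence: with ``a`` = ASVs present in both, ``b``/``c`` = ASVs
unique to either sample,

    D = 1 - 2a / (2a + b + c)

Two samples sharing nothing (but each non-empty) are at distance 1; a
sample with no observed taxa has an undefined distance and is an error.
A quantitative variant (1 - 2*sum(min)/sum(x+y), i.e. abundance-weighted
Bray-Curtis complement-of-similarity) is available but non-default, since
the binary form is what the named index means.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import EmptySelectionError, UndefinedDistanceError, ValidationError
from .io import validate_asv_table


class SorensenDice(BaseEstimator, TransformerMixin):
    """Transformer mapping a samples x ASVs count frame to a distance matrix.

    Parameters
    ----------
    binary : bool, default True
        Use presence/absence (the Sorensen-Dice index proper). ``False``
        selects the quantitative (abundance-weighted) variant.
    """

    def __init__(self, binary: bool = True):
        self.binary = binary

    def fit(self, X: pd.DataFrame, y=None):
        X = validate_asv_table(X)
        empty = X.index[(X.sum(axis=1) == 0)].tolist()
        if empty:
            raise UndefinedDistanceError(
                f"samples with no observed taxa have undefined Sorensen-Dice "
                f"distance: {empty}"
            )
        self.sample_ids_ = X.index.tolist()
        return self

    def transform(self, X: pd.DataFrame) -> DistanceMatrix:
        X = validate_asv_table(X)
        empty = X.index[(X.sum(axis=1) == 0)].tolist()
        if empty:
            raise UndefinedDistanceError(
                f"samples with no observed taxa: {empty}"
            )
        if self.binary:
            presence = (X.to_numpy() > 0)
            condensed = pdist(presence, metric="dice")
        else:
            condensed = pdist(X.to_numpy().astype(float), metric="braycurtis")
        square = squareform(condensed, checks=False)
        np.fill_diagonal(square, 0.0)
        return DistanceMatrix(square, ids=[str(i) for i in X.index])


def sorensen_dice_matrix(table: pd.DataFrame, binary: bool = True) -> DistanceMatrix:
    """Pairwise Sorensen-Dice dissimilarity matrix of an ASV table."""
    est = SorensenDice(binary=binary)
    return est.fit(table).transform(table)


def _resolve_mask(meta: pd.DataFrame, selector) -> pd.Series:
    """Turn a predicate (callable, boolean Series, or pandas query string)
    into a boolean mask over ``meta``'s index."""
    if selector is None:
        return pd.Series(True, index=meta.index)
    if callable(selector):
        mask = selector(meta)
    elif isinstance(selector, str):
        mask = meta.eval(selector)
    else:
        mask = pd.Series(selector, index=meta.index)
    mask = pd.Series(mask, index=meta.index).astype(bool)
    return mask


def pairwise_comparisons(
    dist: DistanceMatrix,
    meta: pd.DataFrame,
    set_a_filter=None,
    set_b_filter=None,
) -> pd.DataFrame:
    """Extract labelled unordered sample pairs crossing two selections.

    Every unordered pair with one member matching ``set_a_filter`` and the
    other matching ``set_b_filter`` appears exactly once; self-pairs are
    excluded. Pairs are classed ``within_population`` / ``between_population``
    by population equality. The ``timepoint`` column carries the
    common-garden member's timepoint when exactly one member is a garden
    sample (the divergence-regression time axis), else NaN.

    Returns a long-format frame with columns
    ``sample_a, sample_b, dissimilarity, comparison_class, population_a,
    population_b, timepoint``.
    """
    ids = list(dist.ids)
    missing = [s for s in ids if s not in meta.index]
    if missing:
        raise ValidationError(f"samples in distance matrix missing from metadata: {missing}")
    meta = meta.loc[ids]
    mask_a = _resolve_mask(meta, set_a_filter)
    mask_b = _resolve_mask(meta, set_b_filter)
    idx_a = np.flatnonzero(mask_a.to_numpy())
    idx_b = np.flatnonzero(mask_b.to_numpy())
    if idx_a.size == 0 or idx_b.size == 0:
        raise EmptySelectionError("a pair selection matched no samples")

    data = dist.data
    pop = meta["population"].to_numpy()
    source = meta["source"].to_numpy()
    tp = meta["timepoint"].to_numpy(dtype=float)

    seen = set()
    rows = []
    for i in idx_a:
        for j in idx_b:
            if i == j:
                continue
            key = (i, j) if i < j else (j, i)
            if key in seen:
                continue
            seen.add(key)
            a, b = key
            garden_a = source[a] == "common_garden"
            garden_b = source[b] == "common_garden"
            if garden_a != garden_b:
                t = tp[a] if garden_a else tp[b]
            else:
                t = np.nan
            rows.append(
                (
                    ids[a],
                    ids[b],
                    data[a, b],
                    "within_population" if pop[a] == pop[b] else "between_population",
                    pop[a],
                    pop[b],
                    t,
                )
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "sample_a",
            "sample_b",
            "dissimilarity",
            "comparison_class",
            "population_a",
            "population_b",
            "timepoint",
        ],
    )
    return frame.sort_values(["sample_a", "sample_b"], ignore_index=True)
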