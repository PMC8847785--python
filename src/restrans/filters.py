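"""Sample-depth and ASV-prevalence filters.

Both filters are scikit-learn style transformers over a samples x ASVs count
frame, so they compose with :class:`sklearn.pipeline.Pipeline`; the
module-level functions are thin wrappers kept for scripting convenience.

The pipeline applies :class:`DepthFilter` before :class:`PrevalenceFilter`
(prevalence is evaluated on the depth-filtered sample set).
"""

from __future__ import annotations

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import EmptyResultError, ParameterError
from .io import validate_asv_table


class DepthFilter(BaseEstimator, TransformerMixin):
    """Drop samples whose total read count is below ``min_reads``.

    The boundary follows a strict "less than" rule: a sample with exactly
    ``min_reads`` reads is retained.

    Attributes
    ----------
    kept_samples_ : list of str
        Samples retained by the last ``fit``.
    removed_samples_ : list of str
        Samples removed (reported for the run log).
    """

    def __init__(self, min_reads: int = 1000):
        self.min_reads = min_reads

    def fit(self, X: pd.DataFrame, y=None):
        if not (isinstance(self.min_reads, (int,)) and self.min_reads > 0):
            raise ParameterError("min_reads must be a positive integer")
        X = validate_asv_table(X)
        depth = X.sum(axis=1)
        keep = depth >= self.min_reads
        self.kept_samples_ = X.index[keep].tolist()
        self.removed_samples_ = X.index[~keep].tolist()
        if not self.kept_samples_:
            raise EmptyResultError(
                f"all samples have fewer than {self.min_reads} reads"
            )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = validate_asv_table(X)
        keep = [s for s in X.index if s in set(self.kept_samples_)]
        return X.loc[keep]


class PrevalenceFilter(BaseEstimator, TransformerMixin):
    """Drop ASVs present (count > 0) in at most ``min_fraction`` of samples.

    "Present in more than 1% of the samples" is read strictly: an ASV whose
    presence fraction equals the threshold is removed.

    Attributes
    ----------
    kept_asvs_ : list of str
    removed_asvs_ : list of str
    prevalence_ : pandas.Series
        Presence fraction per ASV measured on the fitted samples.
    """

    def __init__(self, min_fraction: float = 0.01):
        self.min_fraction = min_fraction

    def fit(self, X: pd.DataFrame, y=None):
        if not (0 <= self.min_fraction < 1):
            raise ParameterError("min_fraction must satisfy 0 <= f < 1")
        X = validate_asv_table(X)
        self.prevalence_ = (X > 0).mean(axis=0)
        keep = self.prevalence_ > self.min_fraction
        self.kept_asvs_ = X.columns[keep].tolist()
        self.removed_asvs_ = X.columns[~keep].tolist()
        if not self.kept_asvs_:
            raise EmptyResultError(
                f"no ASV is present in more than {self.min_fraction:.2%} of samples"
            )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = validate_asv_table(X)
        keep = [a for a in X.columns if a in set(self.kept_asvs_)]
        return X[keep]


def filter_sample_depth(table: pd.DataFrame, min_reads: int = 1000) -> pd.DataFrame:
    """Retain samples with total count >= ``min_reads`` (ASV set unchanged)."""
    f = DepthFilter(min_reads=min_reads).fit(table)
    return f.transform(table)


def filter_prevalence(table: pd.DataFrame, min_fraction: float = 0.01) -> pd.DataFrame:
    """Retain ASVs present in strictly more than ``min_fraction`` of samples."""
    f = PrevalenceFilter(min_fraction=min_fraction).fit(table)
    return f.transform(table)
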