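"""Normalization stages: spike-in scaling, QC-flag filtering, quantile normalization.

The estimator classes follow the scikit-learn transformer contract and operate
on ``(n_samples, n_features)`` arrays — one row per array sample, one column
per probe. The module-level functions wrap them for the pipeline's
probes-x-samples DataFrame orientation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .datatypes import PRESENT_FLAGS, NormalizedChannels, RawArrayDataset


class NormalizationError(ValueError):
    """Spike-in controls missing or unusable in some sample/channel."""


class SpikeInNormalizer(TransformerMixin, BaseEstimator):
    """Scale each array sample by its spike-in controls, on the log2 scale.

    For every row (sample) the transform returns
    ``log2(X) - mean(log2(X[:, spikein_mask]))`` so that, per sample, the mean
    log2 intensity over the spike-in probes becomes 0. Equivalently, on the
    linear scale each sample is divided by the geometric mean of its spike-in
    intensities.

    Parameters
    ----------
    spikein_mask : boolean array of shape (n_features,)
        True for spike-in control probes. At least one True entry required.
    """

    def __init__(self, spikein_mask=None):
        self.spikein_mask = spikein_mask

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        mask = np.asarray(self.spikein_mask, dtype=bool)
        if mask.ndim != 1 or mask.shape[0] != X.shape[1]:
            raise ValueError("spikein_mask must be 1-D with one entry per feature")
        if not mask.any():
            raise NormalizationError("no spike-in probes in mask")
        self.spikein_mask_ = mask
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "spikein_mask_")
        X = check_array(X, dtype=float)
        if np.any(X <= 0):
            raise NormalizationError("raw intensities must be strictly positive")
        spikes = X[:, self.spikein_mask_]
        if not np.all(np.isfinite(spikes)) or np.any(spikes <= 0):
            raise NormalizationError("spike-in intensity missing or non-positive")
        log2x = np.log2(X)
        scale = np.log2(spikes).mean(axis=1, keepdims=True)
        return log2x - scale


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Force every sample's intensity distribution onto a common reference.

    ``fit`` computes the reference distribution as the mean of the sorted
    per-sample vectors; ``transform`` replaces each sample's values by the
    reference values at their (average, for ties) ranks, with linear
    interpolation at half-integer ranks. ``fit_transform`` on a single matrix
    is therefore the classic sorted-mean-substitution quantile normalization
    used by limma, and the operation is idempotent.
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if X.shape[0] < 2:
            warnings.warn(
                "quantile normalization with a single sample is the identity",
                UserWarning, stacklevel=2,
            )
        self.reference_ = np.sort(X, axis=1).mean(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.reference_.shape[0]:
            raise ValueError("feature count differs from the fitted reference")
        out = np.empty_like(X, dtype=float)
        positions = np.arange(self.reference_.shape[0], dtype=float)
        for i in range(X.shape[0]):
            ranks = rankdata(X[i], method="average") - 1.0
            out[i] = np.interp(ranks, positions, self.reference_)
        return out


def filter_by_flags(flags: pd.DataFrame, min_present: int = 1) -> pd.Series:
    """Keep probes flagged Present or Marginal in at least ``min_present`` samples.

    This is the "All Targets Value" screen: a probe survives when at least
    ``min_present`` of the loaded samples (both groups pooled) call it P or M.
    """
    if min_present < 1:
        raise ValueError("min_present must be >= 1")
    n_present = flags.isin(PRESENT_FLAGS).sum(axis=1)
    return n_present >= min_present


def spikein_normalize(
    raw: RawArrayDataset, shared_spike_mean: bool = False
) -> NormalizedChannels:
    """Spike-in-normalize both channels of a dataset; drop the spike-in rows.

    By default each channel is normalized against its own spike-in log2 mean;
    ``shared_spike_mean=True`` subtracts the mean over both channels' spike-in
    intensities from both channels instead.
    """
    spike = raw.is_spikein
    if not spike.any():
        raise NormalizationError("dataset contains no spike-in probes")
    mask = spike.to_numpy()
    norm = SpikeInNormalizer(spikein_mask=mask)

    ip_t = raw.ip_raw.to_numpy(dtype=float).T  # samples x probes
    sup_t = raw.sup_raw.to_numpy(dtype=float).T
    if shared_spike_mean:
        if np.any(ip_t <= 0) or np.any(sup_t <= 0):
            raise NormalizationError("raw intensities must be strictly positive")
        both = np.concatenate([ip_t[:, mask], sup_t[:, mask]], axis=1)
        if np.any(~np.isfinite(both)) or np.any(both <= 0):
            raise NormalizationError("spike-in intensity missing or non-positive")
        scale = np.log2(both).mean(axis=1, keepdims=True)
        ip_n, sup_n = np.log2(ip_t) - scale, np.log2(sup_t) - scale
    else:
        ip_n = norm.fit(ip_t).transform(ip_t)
        sup_n = norm.fit(sup_t).transform(sup_t)

    keep = ~mask
    index = raw.probes.index[keep]
    cols = raw.samples.index
    return NormalizedChannels(
        ip_norm=pd.DataFrame(ip_n.T[keep], index=index, columns=cols),
        sup_norm=pd.DataFrame(sup_n.T[keep], index=index, columns=cols),
    )


def quantile_normalize(matrix: pd.DataFrame | np.ndarray):
    """Quantile-normalize a probes-x-samples matrix across its columns."""
    values = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if values.shape[1] < 2:
        warnings.warn("single-column matrix returned unchanged", UserWarning, stacklevel=2)
        return matrix.copy() if isinstance(matrix, pd.DataFrame) else values.copy()
    qn = QuantileNormalizer()
    out = qn.fit_transform(values.T).T
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out
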