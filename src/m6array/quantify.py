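"""From raw two-channel intensities to methylation level, m6A quantity, expression.

Stage order: spike-in normalization -> quantile normalization of the total
(IP+Sup) expression matrix -> QC flag screening -> per-probe statistics.

Definitions (all on spike-in-normalized intensities):

* methylation level (% Modified) = IP / (IP + Sup), a within-sample ratio
  in [0, 1];
* m6A quantity = the linear-scale normalized IP (Cy5) intensity;
* RNA expression level = the linear-scale total IP + Sup.

Quantile normalization rescales each probe/sample's total abundance; the same
per-cell factor is applied to the m6A quantity so the elementwise identity
``expression * meth_level == m6a_quantity`` is preserved, while the
methylation level — a ratio within a sample — is left untouched.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import MethylationProfile, RawArrayDataset
from .normalize import filter_by_flags, quantile_normalize, spikein_normalize

#: linear-intensity floor below which a (probe, sample) total is treated as missing
INTENSITY_FLOOR = 2.0 ** -20


def percent_modified(ip_linear, sup_linear, floor: float = INTENSITY_FLOOR):
    """% Modified = IP / (IP + Sup) on linear-scale intensities.

    Cells whose total intensity ``ip + sup`` does not exceed ``floor`` are
    returned as NaN (missing), not zero. Accepts scalars, arrays or
    DataFrames; negative intensities are rejected.
    """
    ip = np.asarray(ip_linear, dtype=float)
    sup = np.asarray(sup_linear, dtype=float)
    if np.any(ip < 0) or np.any(sup < 0):
        raise ValueError("channel intensities must be non-negative")
    total = ip + sup
    with np.errstate(divide="ignore", invalid="ignore"):
        level = np.where(total > floor, ip / np.where(total > 0, total, np.nan), np.nan)
    if isinstance(ip_linear, pd.DataFrame):
        return pd.DataFrame(level, index=ip_linear.index, columns=ip_linear.columns)
    if level.ndim == 0:
        return float(level)
    return level


def quantify(
    raw: RawArrayDataset,
    min_present: int = 1,
    shared_spike_mean: bool = False,
    quantile_norm: bool = True,
    floor: float = INTENSITY_FLOOR,
) -> MethylationProfile:
    """Run the full quantification chain on a raw dataset.

    Returns a :class:`MethylationProfile` restricted to probes passing the
    "All Targets Value" flag screen (P or M in at least ``min_present``
    samples); spike-in probes are consumed by normalization and never appear
    in the profile. ``quantile_norm=False`` skips the between-sample quantile
    step, leaving the spike-in-normalized quantities untouched — useful when
    the mostly-unchanged-probes assumption behind quantile normalization does
    not hold, since the step otherwise compresses true group differences.
    """
    channels = spikein_normalize(raw, shared_spike_mean=shared_spike_mean)

    ip_lin = np.exp2(channels.ip_norm)
    sup_lin = np.exp2(channels.sup_norm)
    total = ip_lin + sup_lin

    # quantile normalization runs on the full expression matrix, before the
    # flag screen, so the reference distribution reflects the whole array
    expression = quantile_normalize(total) if quantile_norm else total
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = expression / total
    meth_level = percent_modified(ip_lin, sup_lin, floor=floor)
    m6a_quantity = ip_lin * scale

    flags = raw.flags.loc[channels.ip_norm.index]
    kept = filter_by_flags(flags, min_present=min_present)
    channels.kept_probes = kept
    keep_idx = kept[kept].index

    return MethylationProfile(
        meth_level=meth_level.loc[keep_idx],
        m6a_quantity=m6a_quantity.loc[keep_idx],
        expression=expression.loc[keep_idx],
        kept_probes=kept,
        probes=raw.probes.loc[keep_idx],
        samples=raw.samples.copy(),
    )
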