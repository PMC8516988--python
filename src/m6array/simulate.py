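"""Synthetic two-color epitranscriptomic array generator with planted truth.

Emulates an 8 x 60 K-style two-channel m6A array at toy scale: each probe
carries a lognormal total-RNA abundance split between an IP (methylated,
Cy5) and a Sup (unmethylated, Cy3) channel according to a per-probe baseline
methylation level, with spike-in control probes, P/M/A QC flags, two groups
of samples (patients T, controls N) and planted differential-methylation and
differential-expression effects in group T. The returned ground truth flags
exactly the probes that received an effect, so every downstream stage can be
checked against known answers.

Generative model, per probe i and sample j (all on the log2 scale):

    ip[i,j]  = a_i + log2(m_i')      + delta_expr(i,j) + delta_meth(i,j) + dye + noise
    sup[i,j] = a_i + log2(1 - m_i')  + delta_expr(i,j)                   + dye + noise

where ``a_i ~ Normal(baseline_log2_mean, baseline_log2_sd)`` is the total
abundance, ``m_i ~ Uniform(meth_baseline_low, meth_baseline_high)`` the
baseline methylation level, ``delta_meth = meth_effect_log2`` on the IP
channel of affected probes in group T, ``delta_expr = expr_effect_log2`` on
both channels of affected probes in group T, and the noise terms are iid
``Normal(0, noise_log2_sd)``. With zero noise and no effects the % Modified
statistic recovered downstream equals ``m_i`` exactly.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from .datatypes import RawArrayDataset


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Study-condition knobs for the array simulator.

    Defaults emulate the study design — two groups of 5 arrays each — with
    probe counts reduced to a testable scale. Noise magnitudes are not
    reported for the real arrays; the defaults below are the package's
    choice of a realistic two-color array regime.
    """

    n_probes: int = 200
    n_spikeins: int = 8
    n_T: int = 5
    n_N: int = 5
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 2.0
    noise_log2_sd: float = 0.5
    frac_diff_meth: float = 0.1
    meth_effect_log2: float = -3.0
    frac_diff_expr: float = 0.1
    expr_effect_log2: float = -1.0
    flag_absent_rate: float = 0.05
    flag_marginal_rate: float = 0.1
    meth_baseline_low: float = 0.2
    meth_baseline_high: float = 0.8
    spike_log2_level: float = 10.0
    dye_effect_log2_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not isinstance(value, (int, float)) or not math.isfinite(value):
                raise ConfigurationError(f"{f.name} must be finite, got {value!r}")
        for name in ("frac_diff_meth", "frac_diff_expr", "flag_absent_rate",
                     "flag_marginal_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_probes", "n_spikeins", "n_T", "n_N"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ConfigurationError(f"{name} must be a non-negative integer")
        for name in ("baseline_log2_sd", "noise_log2_sd", "dye_effect_log2_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not 0.0 < self.meth_baseline_low <= self.meth_baseline_high < 1.0:
            raise ConfigurationError(
                "need 0 < meth_baseline_low <= meth_baseline_high < 1"
            )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted per-probe effects; covers every non-spike-in probe once.

    ``table`` is indexed by probe_id with columns ``is_diff_meth`` and
    ``is_diff_expr`` in {-1, 0, +1} (sign of the planted log2 shift) and
    ``true_meth_level_T`` / ``true_meth_level_N``, the noiseless % Modified
    each group would show.
    """

    table: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def diff_meth_probes(self) -> pd.Index:
        return self.table.index[self.table["is_diff_meth"] != 0]

    @property
    def diff_expr_probes(self) -> pd.Index:
        return self.table.index[self.table["is_diff_expr"] != 0]


def _shifted_level(m: np.ndarray, log2_shift: float) -> np.ndarray:
    """% Modified after multiplying the IP channel by 2**log2_shift."""
    g = 2.0 ** log2_shift
    return m * g / (m * g + (1.0 - m))


def generate_dataset(config: SimulationConfig) -> tuple[RawArrayDataset, GroundTruth]:
    """Simulate one dataset; deterministic (bit-identical) for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, k = int(config.n_probes), int(config.n_spikeins)
    n_samples = int(config.n_T) + int(config.n_N)
    if n < 1 or n_samples < 2:
        raise ConfigurationError("need at least one probe and two samples")

    probe_ids = [f"P{i:06d}" for i in range(n)]
    spike_ids = [f"SPIKE{i:02d}" for i in range(k)]
    rna_types = rng.choice(
        ["mRNA", "lncRNA", "pri-miRNA", "pre-miRNA", "snoRNA"],
        size=n, p=[0.70, 0.15, 0.05, 0.05, 0.05],
    )
    chroms = rng.choice([f"chr{c}" for c in list(range(1, 23)) + ["X"]], size=n)
    starts = rng.integers(1, 200_000_000, size=n)
    lengths = rng.integers(100, 200_000, size=n)
    strands = rng.choice(["+", "-"], size=n)

    probes = pd.DataFrame(
        {
            "gene_symbol": [f"GENE{i:05d}" for i in range(n)] + spike_ids,
            "rna_type": list(rna_types) + ["spike-in"] * k,
            "chrom": list(chroms) + ["chrS"] * k,
            "start": list(starts) + [1] * k,
            "end": list(starts + lengths) + [100] * k,
            "strand": list(strands) + ["+"] * k,
        },
        index=pd.Index(probe_ids + spike_ids, name="probe_id"),
    )

    sample_ids = [f"T{i + 1}" for i in range(config.n_T)] + [
        f"N{i + 1}" for i in range(config.n_N)
    ]
    samples = pd.DataFrame(
        {"group": ["T"] * config.n_T + ["N"] * config.n_N},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    in_t = (samples["group"] == "T").to_numpy()

    abundance = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    base_meth = rng.uniform(config.meth_baseline_low, config.meth_baseline_high, size=n)

    n_dm = int(round(config.frac_diff_meth * n))
    n_de = int(round(config.frac_diff_expr * n))
    dm_idx = rng.choice(n, size=n_dm, replace=False)
    de_idx = rng.choice(n, size=n_de, replace=False)
    meth_dir = np.zeros(n, dtype=int)
    meth_dir[dm_idx] = int(np.sign(config.meth_effect_log2)) or 1
    expr_dir = np.zeros(n, dtype=int)
    expr_dir[de_idx] = int(np.sign(config.expr_effect_log2)) or 1

    meth_shift = np.zeros(n)
    meth_shift[dm_idx] = config.meth_effect_log2
    expr_shift = np.zeros(n)
    expr_shift[de_idx] = config.expr_effect_log2

    # log2 means, probes x samples; planted shifts act only in group T
    t_mask = in_t[np.newaxis, :].astype(float)
    log_ip = (
        abundance[:, None]
        + np.log2(base_meth)[:, None]
        + expr_shift[:, None] * t_mask
        + meth_shift[:, None] * t_mask
    )
    log_sup = (
        abundance[:, None]
        + np.log2(1.0 - base_meth)[:, None]
        + expr_shift[:, None] * t_mask
    )
    spike_ip = np.full((k, n_samples), config.spike_log2_level)
    spike_sup = np.full((k, n_samples), config.spike_log2_level)

    log_ip = np.vstack([log_ip, spike_ip])
    log_sup = np.vstack([log_sup, spike_sup])

    if config.dye_effect_log2_sd > 0:
        dye_ip = rng.normal(0.0, config.dye_effect_log2_sd, size=n_samples)
        dye_sup = rng.normal(0.0, config.dye_effect_log2_sd, size=n_samples)
        log_ip = log_ip + dye_ip[None, :]
        log_sup = log_sup + dye_sup[None, :]

    if config.noise_log2_sd > 0:
        log_ip = log_ip + rng.normal(0.0, config.noise_log2_sd, size=log_ip.shape)
        log_sup = log_sup + rng.normal(0.0, config.noise_log2_sd, size=log_sup.shape)

    ip_raw = pd.DataFrame(np.exp2(log_ip), index=probes.index, columns=samples.index)
    sup_raw = pd.DataFrame(np.exp2(log_sup), index=probes.index, columns=samples.index)

    u = rng.random(size=(n, n_samples))
    flag_arr = np.where(
        u < config.flag_absent_rate, "A",
        np.where(u < config.flag_absent_rate
                 + (1 - config.flag_absent_rate) * config.flag_marginal_rate, "M", "P"),
    )
    flags = pd.DataFrame(
        np.vstack([flag_arr, np.full((k, n_samples), "P")]),
        index=probes.index, columns=samples.index,
    )

    truth = pd.DataFrame(
        {
            "is_diff_meth": meth_dir,
            "is_diff_expr": expr_dir,
            "true_meth_level_N": base_meth,
            "true_meth_level_T": np.where(
                meth_dir != 0, _shifted_level(base_meth, config.meth_effect_log2),
                base_meth,
            ),
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )

    dataset = RawArrayDataset(
        probes=probes, samples=samples, ip_raw=ip_raw, sup_raw=sup_raw, flags=flags
    )
    return dataset, GroundTruth(table=truth, config=config)


def write_truth(truth: GroundTruth, path) -> None:
    truth.table.to_csv(path, sep="\t", index_label="probe_id")
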