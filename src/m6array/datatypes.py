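"""Core in-memory containers for two-color MeRIP array analysis.

The pipeline moves through three representations:

``RawArrayDataset``
    per-probe, per-sample raw Cy5 (IP, immunoprecipitated / methylated) and
    Cy3 (Sup, supernatant / unmethylated) intensities plus P/M/A QC flags.
``NormalizedChannels``
    log2-scale spike-in-normalized IP and Sup matrices.
``MethylationProfile``
    the three derived per-probe quantities: methylation level
    (% Modified = IP/(IP+Sup), in [0, 1]), m6A quantity (normalized IP on the
    linear scale) and RNA expression level (IP + Sup, linear scale).

All matrices are pandas DataFrames with probe ids as the index and sample ids
as columns; annotations and the sample sheet are DataFrames indexed by
probe id / sample id.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RNA_TYPES = ("mRNA", "lncRNA", "pri-miRNA", "pre-miRNA", "snoRNA", "spike-in", "other")
SPIKEIN_TYPE = "spike-in"
GROUPS = ("T", "N")
FLAGS = ("P", "M", "A")
PRESENT_FLAGS = frozenset({"P", "M"})

REGULATION_LABELS = ("Hyper-up", "Hyper-down", "Hypo-up", "Hypo-down", "ns")


class FormatError(ValueError):
    """Malformed input table (names the offending row/column where possible)."""


# loci are printed like "chr15:80,253,234-80,263,511:-"; accept comma grouping,
# ASCII hyphen or en-dash, and an optional space before the strand sign
_LOCUS_RE = re.compile(
    r"^(?P<chrom>[^:]+):(?P<start>[\d,]+)[–-](?P<end>[\d,]+):\s*(?P<strand>[+-])$"
)


@dataclass(frozen=True)
class Locus:
    """1-based, fully closed genomic interval. Carried as annotation only."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"locus start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise FormatError(f"invalid strand {self.strand!r}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"

    @classmethod
    def parse(cls, text: str) -> "Locus":
        m = _LOCUS_RE.match(text.strip().replace("−", "-"))
        if m is None:
            raise FormatError(f"cannot parse locus {text!r}")
        return cls(
            chrom=m.group("chrom"),
            start=int(m.group("start").replace(",", "")),
            end=int(m.group("end").replace(",", "")),
            strand=m.group("strand"),
        )


@dataclass
class RawArrayDataset:
    """Raw two-channel array data plus annotation, sample sheet and QC flags.

    Attributes
    ----------
    probes : DataFrame indexed by probe_id with columns
        ``gene_symbol, rna_type, chrom, start, end, strand``.
    samples : DataFrame indexed by sample_id with column ``group`` in {T, N}.
    ip_raw, sup_raw : probes x samples matrices of strictly positive linear
        intensities (Cy5 and Cy3 channels).
    flags : probes x samples matrix of {P, M, A} QC calls.
    """

    probes: pd.DataFrame
    samples: pd.DataFrame
    ip_raw: pd.DataFrame
    sup_raw: pd.DataFrame
    flags: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.probes.index.has_duplicates:
            dups = self.probes.index[self.probes.index.duplicated()].tolist()
            raise FormatError(f"duplicate probe_id(s): {dups[:5]}")
        pidx, sidx = self.probes.index, self.samples.index
        for name, mat in (("ip_raw", self.ip_raw), ("sup_raw", self.sup_raw),
                          ("flags", self.flags)):
            if not (mat.index.equals(pidx) and mat.columns.equals(sidx)):
                raise FormatError(
                    f"{name} dimensions/labels do not match probes x samples"
                )
        groups = set(self.samples["group"].unique())
        if groups != set(GROUPS):
            raise FormatError(
                f"sample sheet must contain both groups {GROUPS}, found {sorted(groups)}"
            )
        for name, mat in (("ip_raw", self.ip_raw), ("sup_raw", self.sup_raw)):
            vals = mat.to_numpy(dtype=float)
            bad = ~(np.isfinite(vals) & (vals > 0))
            if bad.any():
                i, j = map(int, np.argwhere(bad)[0])
                raise FormatError(
                    f"non-positive or non-finite raw intensity in {name} at "
                    f"probe {mat.index[i]!r}, sample {mat.columns[j]!r}"
                )
        badflag = ~self.flags.isin(FLAGS)
        if badflag.to_numpy().any():
            i, j = map(int, np.argwhere(badflag.to_numpy())[0])
            raise FormatError(
                f"invalid QC flag {self.flags.iat[i, j]!r} at probe "
                f"{self.flags.index[i]!r}, sample {self.flags.columns[j]!r}"
            )

    @property
    def is_spikein(self) -> pd.Series:
        return self.probes["rna_type"] == SPIKEIN_TYPE

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def group_samples(self, group: str) -> list[str]:
        return self.samples.index[self.samples["group"] == group].tolist()


@dataclass
class NormalizedChannels:
    """Spike-in-normalized log2 IP/Sup matrices (spike-in rows removed)."""

    ip_norm: pd.DataFrame
    sup_norm: pd.DataFrame
    kept_probes: pd.Series = field(default=None)  # set by the flag filter

    def __post_init__(self) -> None:
        if not self.ip_norm.index.equals(self.sup_norm.index):
            raise FormatError("ip_norm and sup_norm probe indices differ")
        if not self.ip_norm.columns.equals(self.sup_norm.columns):
            raise FormatError("ip_norm and sup_norm sample columns differ")


@dataclass
class MethylationProfile:
    """Per-probe methylation level, m6A quantity and expression level.

    ``meth_level`` is the % Modified statistic IP/(IP+Sup) in [0, 1];
    ``m6a_quantity`` the linear-scale normalized IP; ``expression`` the
    linear-scale total (IP + Sup) after quantile normalization. The identity
    ``expression * meth_level == m6a_quantity`` holds elementwise.
    Rows are the probes kept by the QC flag filter.
    """

    meth_level: pd.DataFrame
    m6a_quantity: pd.DataFrame
    expression: pd.DataFrame
    kept_probes: pd.Series
    probes: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        idx, cols = self.meth_level.index, self.meth_level.columns
        for mat in (self.m6a_quantity, self.expression):
            if not (mat.index.equals(idx) and mat.columns.equals(cols)):
                raise FormatError("profile matrices have inconsistent labels")
        lv = self.meth_level.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any((lv < 0) | (lv > 1)):
                raise FormatError("methylation level outside [0, 1]")

    def group_samples(self, group: str) -> list[str]:
        return self.samples.index[self.samples["group"] == group].tolist()
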