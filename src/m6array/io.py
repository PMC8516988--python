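"""Tab-delimited readers/writers for array data, result tables and GMT sets.

File dialect
------------
* ``intensities.tsv`` — column ``probe_id`` then, per sample ``S``, three
  columns ``S_IP``, ``S_Sup`` and ``S_flag`` (raw linear intensities, P/M/A).
* ``annotation.tsv`` — ``probe_id, gene_symbol, rna_type, locus`` with the
  locus serialized as ``chr:start-end:strand`` (1-based closed; comma
  grouping and en-dashes are accepted on input, never written).
* ``samples.tsv`` — ``sample_id, group`` with group in {T, N}.
* differential tables mirror the published layout: gene name, regulation
  class, log2 fold changes for m6A and gene expression (GE), linear
  methylation-ratio fold change, p-values and locus.
* GMT — standard ``name<TAB>description<TAB>member...`` lines.

Numeric fields are written with ``repr``-level precision so that
read(write(x)) round-trips bit-exactly on identifiers/flags and to full
precision on floats.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    FLAGS,
    GROUPS,
    RNA_TYPES,
    FormatError,
    Locus,
    RawArrayDataset,
)

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["gene_symbol", "rna_type", "chrom", "start", "end", "strand"]

DIFFERENTIAL_COLUMNS = [
    "probe_id",
    "gene_symbol",
    "rna_type",
    "regulation",
    "fc_m6a_log2",
    "fc_ge_log2",
    "fc_meth_ratio",
    "p_m6a",
    "p_ge",
    "p_meth",
    "locus",
]


def write_dataset(dataset: RawArrayDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a dataset as intensities.tsv / annotation.tsv / samples.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "intensities": outdir / "intensities.tsv",
        "annotation": outdir / "annotation.tsv",
        "samples": outdir / "samples.tsv",
    }

    wide = pd.DataFrame(index=dataset.probes.index)
    for sid in dataset.samples.index:
        wide[f"{sid}_IP"] = dataset.ip_raw[sid].map(_fmt_float)
        wide[f"{sid}_Sup"] = dataset.sup_raw[sid].map(_fmt_float)
        wide[f"{sid}_flag"] = dataset.flags[sid]
    wide.to_csv(paths["intensities"], sep="\t", index_label="probe_id")

    ann = pd.DataFrame(index=dataset.probes.index)
    ann["gene_symbol"] = dataset.probes["gene_symbol"]
    ann["rna_type"] = dataset.probes["rna_type"]
    ann["locus"] = [
        str(Locus(r.chrom, int(r.start), int(r.end), r.strand))
        for r in dataset.probes.itertuples()
    ]
    ann.to_csv(paths["annotation"], sep="\t", index_label="probe_id")

    dataset.samples.to_csv(paths["samples"], sep="\t", index_label="sample_id")
    return paths


def read_dataset(
    intensity_path: str | Path,
    annotation_path: str | Path,
    sample_sheet_path: str | Path,
) -> RawArrayDataset:
    """Read intensity/annotation/sample-sheet files into a validated dataset.

    Probes present in the intensity table but missing from the annotation are
    kept with ``rna_type='other'`` and a logged warning. Dimension mismatches,
    duplicate probe ids and non-positive intensities raise :class:`FormatError`
    naming the offending row/column.
    """
    samples = pd.read_csv(sample_sheet_path, sep="\t", index_col="sample_id")
    if "group" not in samples.columns:
        raise FormatError(f"{sample_sheet_path}: missing 'group' column")
    samples["group"] = samples["group"].astype(str)
    bad_groups = set(samples["group"]) - set(GROUPS)
    if bad_groups:
        raise FormatError(f"{sample_sheet_path}: unknown group label(s) {bad_groups}")

    wide = pd.read_csv(intensity_path, sep="\t", index_col="probe_id",
                       float_precision="round_trip")
    if wide.index.has_duplicates:
        dups = wide.index[wide.index.duplicated()].tolist()
        raise FormatError(f"{intensity_path}: duplicate probe_id(s) {dups[:5]}")

    ip, sup, flags = {}, {}, {}
    for sid in samples.index:
        for suffix, store in (("IP", ip), ("Sup", sup), ("flag", flags)):
            col = f"{sid}_{suffix}"
            if col not in wide.columns:
                raise FormatError(f"{intensity_path}: missing column {col!r}")
            store[sid] = wide[col]
    ip_raw = pd.DataFrame(ip).astype(float)
    sup_raw = pd.DataFrame(sup).astype(float)
    flag_df = pd.DataFrame(flags).astype(str)
    for mat in (ip_raw, sup_raw, flag_df):
        mat.columns = samples.index

    ann_raw = pd.read_csv(annotation_path, sep="\t", index_col="probe_id")
    probes = pd.DataFrame(index=wide.index, columns=ANNOTATION_COLUMNS)
    missing = wide.index.difference(ann_raw.index)
    if len(missing) > 0:
        logger.warning(
            "%d probe(s) in %s lack annotation; assigning rna_type='other'",
            len(missing), intensity_path,
        )
    known = wide.index.intersection(ann_raw.index)
    probes.loc[known, "gene_symbol"] = ann_raw.loc[known, "gene_symbol"]
    probes.loc[known, "rna_type"] = ann_raw.loc[known, "rna_type"]
    loci = [Locus.parse(s) for s in ann_raw.loc[known, "locus"]]
    probes.loc[known, "chrom"] = [l.chrom for l in loci]
    probes.loc[known, "start"] = [l.start for l in loci]
    probes.loc[known, "end"] = [l.end for l in loci]
    probes.loc[known, "strand"] = [l.strand for l in loci]
    probes.loc[missing, "gene_symbol"] = list(missing)
    probes.loc[missing, "rna_type"] = "other"
    probes.loc[missing, ["chrom", "start", "end", "strand"]] = ["chrUn", 1, 1, "+"]
    probes["start"] = probes["start"].astype(int)
    probes["end"] = probes["end"].astype(int)

    unknown_types = set(probes["rna_type"]) - set(RNA_TYPES)
    if unknown_types:
        raise FormatError(f"{annotation_path}: unknown rna_type(s) {unknown_types}")

    return RawArrayDataset(
        probes=probes, samples=samples, ip_raw=ip_raw, sup_raw=sup_raw, flags=flag_df
    )


def write_differential_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a differential table in the published column layout.

    The ``regulation`` labels are written exactly as classified
    (e.g. ``Hypo-down``); the locus is serialized as ``chr:start-end:strand``.
    Raises :class:`FormatError` on an empty table.
    """
    if len(table) == 0:
        raise FormatError("refusing to write an empty differential table")
    out = table.reset_index() if table.index.name == "probe_id" else table.copy()
    missing = [c for c in DIFFERENTIAL_COLUMNS if c not in out.columns]
    if missing:
        raise FormatError(f"differential table missing column(s) {missing}")
    out = out[DIFFERENTIAL_COLUMNS].copy()
    for col in ("fc_m6a_log2", "fc_ge_log2", "fc_meth_ratio", "p_m6a", "p_ge", "p_meth"):
        out[col] = out[col].map(_fmt_float)
    path = Path(path)
    out.to_csv(path, sep="\t", index=False)
    return path


def read_differential_table(path: str | Path) -> pd.DataFrame:
    """Read back a differential table written by :func:`write_differential_table`."""
    table = pd.read_csv(path, sep="\t", dtype={"locus": str},
                        float_precision="round_trip")
    missing = [c for c in DIFFERENTIAL_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return table.set_index("probe_id")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file into ``{set name: member set}`` (members deduplicated).

    Lines with fewer than three tab-separated fields raise
    :class:`FormatError` with the line number.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member ({len(fields)} field(s) found)"
                )
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = {m for m in fields[2:] if m}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name in sets:
            desc = (descriptions or {}).get(name, "na")
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")
    return path


def write_matrix(matrix: pd.DataFrame, path: str | Path, index_label: str = "probe_id") -> Path:
    path = Path(path)
    matrix.map(_fmt_float).to_csv(path, sep="\t", index_label=index_label)
    return path


def read_matrix(path: str | Path, index_col: str = "probe_id") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col,
                       float_precision="round_trip")


def _fmt_float(x) -> str:
    if isinstance(x, str):
        return x
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    return repr(float(x))
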