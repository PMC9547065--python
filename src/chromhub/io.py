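"""Readers and writers for the plain-text formats the pipeline exchanges.

BED/BEDPE/bedGraph are 0-based half-open; variant TSVs are 1-based on disk
and converted to 0-based positions on read (and back on write). Writers
prepend a ``#chromhub vN`` provenance line by default; readers skip ``#``
comment lines, so round-trips are lossless. Pass ``header=False`` for
strict-format consumers.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GenomeBuild, GenomicInterval, GeneRecord, Loop, SignalTrack

PROVENANCE = "#chromhub v0.1.0"


class FormatError(ValueError):
    """Malformed input file; message carries the path and line number."""


def _lines(path) -> list[tuple[int, str]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track "):
                continue
            out.append((lineno, line))
    return out


def _parse_interval(path, lineno, fields, build: GenomeBuild | None) -> GenomicInterval:
    if len(fields) < 3:
        raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated fields")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
    if build is not None and chrom not in build:
        raise FormatError(f"{path}:{lineno}: chromosome {chrom!r} not in build")
    name = fields[3] if len(fields) > 3 and fields[3] != "." else None
    score = None
    if len(fields) > 4 and fields[4] != ".":
        try:
            score = float(fields[4])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
    try:
        iv = GenomicInterval(chrom, start, end, name=name, score=score)
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: {exc}") from exc
    if build is not None:
        try:
            build.validate(iv)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return iv


def read_bed(path, build: GenomeBuild | None = None) -> list[GenomicInterval]:
    """Read BED3+ into intervals, preserving input order."""
    return [_parse_interval(path, ln, line.split("\t"), build) for ln, line in _lines(path)]


def write_bed(path, intervals: Sequence[GenomicInterval], header: bool = True) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(PROVENANCE + "\n")
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                fields.append(_fmt_num(iv.score))
            fh.write("\t".join(fields) + "\n")


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def read_bedpe(path, build: GenomeBuild | None = None, strict_cis: bool = True) -> list[Loop]:
    """Read BEDPE loops; column 7 = name (ignored), column 8 = q-value.

    Feet are canonicalized on construction. Trans records raise under
    ``strict_cis`` (the default) naming the offending line.
    """
    loops = []
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise FormatError(f"{path}:{lineno}: expected >=6 BEDPE fields")
        a = _parse_interval(path, lineno, fields[0:3], build)
        b = _parse_interval(path, lineno, fields[3:6], build)
        if a.chrom != b.chrom:
            if strict_cis:
                raise FormatError(f"{path}:{lineno}: trans pair {a} / {b}")
            continue
        qvalue = None
        if len(fields) > 7 and fields[7] != ".":
            try:
                qvalue = float(fields[7])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric q-value") from exc
        try:
            loops.append(Loop(a, b, qvalue=qvalue))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return loops


def write_bedpe(path, loops: Sequence[Loop], header: bool = True) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(PROVENANCE + "\n")
        for i, lp in enumerate(loops):
            a, b = lp.footA, lp.footB
            fields = [a.chrom, str(a.start), str(a.end), b.chrom, str(b.start), str(b.end),
                      f"loop_{i}", _fmt_num(lp.qvalue) if lp.qvalue is not None else "."]
            fh.write("\t".join(fields) + "\n")


def read_bedgraph(path, build: GenomeBuild, bin_size: int) -> SignalTrack:
    """Read a bedGraph into a binned SignalTrack (per-bp rate per bin).

    Records must align to the track's bin grid (the writer's own output
    always does); misaligned records are distributed proportionally.
    """
    track = SignalTrack(build, bin_size)
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise FormatError(f"{path}:{lineno}: expected 4 bedGraph fields")
        iv = _parse_interval(path, lineno, fields[0:3], build)
        try:
            value = float(fields[3])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric value") from exc
        arr = track.values[iv.chrom]
        first, last = iv.start // bin_size, (iv.end - 1) // bin_size
        for b in range(first, last + 1):
            lo = max(iv.start, b * bin_size)
            hi = min(iv.end, (b + 1) * bin_size, build[iv.chrom])
            width = min((b + 1) * bin_size, build[iv.chrom]) - b * bin_size
            arr[b] += value * (hi - lo) / width
    return track


def write_bedgraph(path, track: SignalTrack, header: bool = True) -> None:
    """Write a SignalTrack as bedGraph, one record per non-zero run of bins."""
    with open(path, "w") as fh:
        if header:
            fh.write(PROVENANCE + "\n")
        bs = track.bin_size
        for chrom, arr in track.values.items():
            chrom_len = track.build[chrom]
            run_start, run_val = None, None
            for i, v in enumerate(arr):
                if run_val is not None and v == run_val:
                    continue
                if run_val is not None and run_val != 0:
                    fh.write(f"{chrom}\t{run_start * bs}\t{min(i * bs, chrom_len)}\t{_fmt_num(run_val)}\n")
                run_start, run_val = i, v
            if run_val is not None and run_val != 0:
                fh.write(f"{chrom}\t{run_start * bs}\t{chrom_len}\t{_fmt_num(run_val)}\n")


# ---------------------------------------------------------------------------
# Gene / variant tables (TSV with header)
# ---------------------------------------------------------------------------

def read_genes(path, build: GenomeBuild | None = None) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    genes = []
    for row in df.itertuples(index=False):
        body = GenomicInterval(row.chrom, int(row.start), int(row.end))
        if build is not None:
            build.validate(body)
        labels = []
        if hasattr(row, "set_labels") and isinstance(row.set_labels, str) and row.set_labels:
            labels = row.set_labels.split(",")
        expr = float(row.expression) if hasattr(row, "expression") and not pd.isna(row.expression) else None
        tss = int(row.tss) if hasattr(row, "tss") and not pd.isna(row.tss) else None
        genes.append(GeneRecord(
            gene_id=str(row.gene_id), symbol=str(getattr(row, "symbol", row.gene_id)),
            strand=str(row.strand), body=body, tss=tss, expression=expr, set_labels=labels,
        ))
    return genes


def write_genes(path, genes: Sequence[GeneRecord]) -> None:
    rows = [{
        "gene_id": g.gene_id, "symbol": g.symbol, "chrom": g.chrom,
        "start": g.body.start, "end": g.body.end, "strand": g.strand,
        "tss": g.tss, "expression": g.expression,
        "set_labels": ",".join(g.set_labels),
    } for g in genes]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_eqtls(path, build: GenomeBuild | None = None) -> pd.DataFrame:
    """eQTL TSV (variant_id, chrom, pos 1-based, egene_id[, tags]) -> DataFrame.

    The returned ``pos`` column is 0-based.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"variant_id": str, "egene_id": str})
    df["pos"] = df["pos"].astype(int) - 1
    if "tags" not in df.columns:
        df["tags"] = ""
    df["tags"] = df["tags"].fillna("")
    if build is not None:
        for row in df.itertuples():
            if row.chrom not in build or not (0 <= row.pos < build[row.chrom]):
                raise FormatError(f"{path}: variant {row.variant_id} outside build")
    return df


def write_eqtls(path, df: pd.DataFrame) -> None:
    out = df.copy()
    out["pos"] = out["pos"].astype(int) + 1
    out.to_csv(path, sep="\t", index=False)


def read_lead_variants(path, build: GenomeBuild | None = None) -> pd.DataFrame:
    """Lead-variant TSV (rsid, chrom, pos 1-based, locus, disease); pos -> 0-based."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"rsid": str, "locus": str, "disease": str})
    df["pos"] = df["pos"].astype(int) - 1
    if build is not None:
        for row in df.itertuples():
            if row.chrom not in build or not (0 <= row.pos < build[row.chrom]):
                raise FormatError(f"{path}: variant {row.rsid} outside build")
    if df.groupby("disease")["rsid"].apply(lambda s: s.duplicated().any()).any():
        raise FormatError(f"{path}: duplicate rsid within a disease")
    return df


def read_ld_variants(path, build: GenomeBuild | None = None) -> pd.DataFrame:
    """LD-variant TSV (rsid, chrom, pos 1-based, lead_rsid, r2, maf); pos -> 0-based."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"rsid": str, "lead_rsid": str})
    df["pos"] = df["pos"].astype(int) - 1
    if build is not None:
        for row in df.itertuples():
            if row.chrom not in build or not (0 <= row.pos < build[row.chrom]):
                raise FormatError(f"{path}: variant {row.rsid} outside build")
    return df


def write_variants(path, df: pd.DataFrame) -> None:
    out = df.copy()
    out["pos"] = out["pos"].astype(int) + 1
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Contact matrices (triplet text)
# ---------------------------------------------------------------------------

def read_matrix_triplet(path, chrom: str, bin_size: int, n_bins: int) -> np.ndarray:
    """Read a symmetric matrix from 3-column (bin_i, bin_j, count) text."""
    data = np.loadtxt(path, dtype=float, ndmin=2, comments="#")
    mat = np.zeros((n_bins, n_bins))
    if data.size:
        i = data[:, 0].astype(int)
        j = data[:, 1].astype(int)
        if (i < 0).any() or (i >= n_bins).any() or (j < 0).any() or (j >= n_bins).any():
            raise FormatError(f"{path}: bin index outside [0, {n_bins})")
        mat[i, j] = data[:, 2]
        mat[j, i] = data[:, 2]
    return mat


def write_matrix_triplet(path, matrix: np.ndarray, header: bool = True) -> None:
    """Write the upper triangle (incl. diagonal) of a symmetric matrix."""
    iu, ju = np.nonzero(np.triu(matrix))
    with open(path, "w") as fh:
        if header:
            fh.write(PROVENANCE + "\n")
        np.savetxt(fh, np.column_stack([iu, ju, matrix[iu, ju]]), fmt="%d\t%d\t%g")
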