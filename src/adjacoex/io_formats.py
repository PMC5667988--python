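"""Readers and writers for the standard formats the pipeline touches.

Formats: 6-column BED and GFF3 gene annotation, UCSC ``cytoBand.txt``
band tables, TSV expression/copy-number matrices with a header row of
sample ids, GMT / two-column-TSV regulator target sets, SEG segment
tables and FASTA sequence.

Coordinates are normalised at this boundary: BED is already 0-based
half-open; GFF3 (1-based inclusive) is converted on read and back on
write. Everything downstream sees only the internal convention.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    CytobandMap,
    GeneAnnotation,
    GeneRecord,
    GenomicInterval,
    OmicsMatrix,
    ParseError,
    RegulatorSetCollection,
    ValidationError,
)

__all__ = [
    "read_gene_annotation",
    "write_gene_annotation",
    "read_cytoband_map",
    "write_cytoband_map",
    "read_matrix",
    "write_matrix",
    "read_regulator_sets",
    "write_regulator_sets_gmt",
    "read_fasta",
    "write_fasta",
    "read_seg",
    "segments_to_matrix",
    "assign_cytobands",
]


# ---------------------------------------------------------------- annotation


def _read_bed(path: Path) -> list[GeneRecord]:
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"{path}:{lineno}: expected >=6 BED columns, got {len(fields)}"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                iv = GenomicInterval(chrom, int(start), int(end), strand)
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            records.append(GeneRecord(gene_id=name, symbol=name, interval=iv))
    return records


def _read_gff3(path: Path) -> list[GeneRecord]:
    records = []
    for feat in gffutils.DataIterator(str(path)):
        if feat.featuretype != "gene":
            continue
        attrs = feat.attributes
        gene_id = (attrs.get("ID") or attrs.get("gene_id") or [feat.id])[0]
        symbol = (attrs.get("Name") or attrs.get("gene_name") or [gene_id])[0]
        # GFF3 is 1-based inclusive; internal convention is 0-based half-open.
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand or ".")
        records.append(GeneRecord(gene_id=gene_id, symbol=symbol, interval=iv))
    return records


def read_gene_annotation(path: str | Path, format: str = "bed") -> GeneAnnotation:
    """Read gene records from BED (0-based half-open) or GFF3 (converted).

    Records come back sorted by (chrom, start); duplicate gene ids raise
    a :class:`ValidationError`.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "bed":
        return GeneAnnotation(_read_bed(path))
    if fmt == "gff3":
        return GeneAnnotation(_read_gff3(path))
    raise ValueError(f"unknown annotation format {format!r}")


def write_gene_annotation(
    annotation: GeneAnnotation, path: str | Path, format: str = "bed"
) -> None:
    path = Path(path)
    fmt = format.lower()
    with open(path, "w") as fh:
        for rec in annotation:
            iv = rec.interval
            if fmt == "bed":
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.gene_id}\t0\t{iv.strand}\n"
                )
            elif fmt == "gff3":
                fh.write(
                    f"{iv.chrom}\t.\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                    f"ID={rec.gene_id};Name={rec.symbol}\n"
                )
            else:
                raise ValueError(f"unknown annotation format {format!r}")


# ------------------------------------------------------------------ cytobands


def read_cytoband_map(path: str | Path) -> CytobandMap:
    """Read a UCSC ``cytoBand.txt``-layout table (chrom, start, end, name, stain).

    Band names are composed as ``<chrom-without-chr><name>`` so that
    ``chr20  q11.21`` becomes ``20q11.21``.
    """
    path = Path(path)
    bands = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(
                    f"{path}:{lineno}: expected >=4 cytoband columns, got {len(fields)}"
                )
            chrom, start, end, name = fields[:4]
            full = chrom.removeprefix("chr") + name
            try:
                bands.append((full, GenomicInterval(chrom, int(start), int(end))))
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return CytobandMap(bands)


def write_cytoband_map(bands: CytobandMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, iv in bands:
            short = name.removeprefix(iv.chrom.removeprefix("chr"))
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{short}\tgneg\n")


# ------------------------------------------------------------------- matrices


def read_matrix(path: str | Path) -> OmicsMatrix:
    """Read a TSV matrix: header row of sample ids, first column row ids.

    Empty cells become NaN (the explicit missing sentinel); ragged rows
    and non-numeric cells are parse errors, duplicated row ids are
    validation errors.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    width = len(lines[0].split("\t"))
    for lineno, line in enumerate(lines[1:], start=2):
        n = len(line.split("\t"))
        if n != width:
            raise ParseError(
                f"{path}:{lineno}: ragged row ({n} fields, header has {width})"
            )
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df = df.replace("", float("nan"))
    try:
        # astype(float) parses via strtod and round-trips %.17g output exactly
        df = df.astype(float)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: non-numeric cell: {exc}") from exc
    df.index = df.index.astype(str)
    df.index.name = None
    return OmicsMatrix(df)


def write_matrix(matrix: OmicsMatrix, path: str | Path, id_label: str = "id") -> None:
    df = matrix.data.copy()
    df.index.name = id_label
    # repr-level float formatting keeps the write/read round trip bit-exact
    df.to_csv(path, sep="\t", float_format="%.17g")


# ------------------------------------------------------------- regulator sets


def read_regulator_sets(
    path: str | Path, format: str = "gmt", source: str = "default"
) -> RegulatorSetCollection:
    """Read regulator -> target-gene sets from GMT or two-column TSV.

    GMT: one set per line (``name <tab> description <tab> member...``).
    TSV2COL: ``regulator <tab> target`` rows; duplicates collapse.
    Every entry is tagged with ``source`` so the same regulator from
    different evidence sources stays distinct.
    """
    path = Path(path)
    fmt = format.lower()
    coll = RegulatorSetCollection()
    if fmt == "gmt":
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ParseError(
                        f"{path}:{lineno}: GMT line needs name, description "
                        f"and >=1 member"
                    )
                name, _desc, *members = fields
                members = [m for m in members if m]
                if not members:
                    raise ValidationError(f"{path}:{lineno}: empty member list")
                coll.add(name, source, members)
    elif fmt == "tsv2col":
        pairs: dict[str, set[str]] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ParseError(
                        f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                    )
                pairs.setdefault(fields[0], set()).add(fields[1])
        for reg, members in pairs.items():
            coll.add(reg, source, members)
    else:
        raise ValueError(f"unknown regulator-set format {format!r}")
    return coll


def write_regulator_sets_gmt(
    sets: RegulatorSetCollection, path: str | Path, source: str | None = None
) -> None:
    with open(path, "w") as fh:
        for (reg, src), members in sorted(sets):
            if source is not None and src != source:
                continue
            fh.write(f"{reg}\t{src}\t" + "\t".join(sorted(members)) + "\n")


# --------------------------------------------------------------------- fasta


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ----------------------------------------------------------------------- SEG


SEG_COLUMNS = ["sample", "chrom", "start", "end", "value"]


def read_seg(path: str | Path) -> pd.DataFrame:
    """Read a SEG table (sample, chrom, start, end, value; header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 5:
        raise ParseError(f"{path}: SEG needs 5 columns, got {df.shape[1]}")
    # tolerate a header row
    first = df.iloc[0]
    if not first.iloc[2].lstrip("-").isdigit():
        df = df.iloc[1:]
    df = df.iloc[:, :5].copy()
    df.columns = SEG_COLUMNS
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["value"] = df["value"].astype(float)
    return df.reset_index(drop=True)


def segments_to_matrix(
    segments: pd.DataFrame, annotation: GeneAnnotation, baseline: float = 2.0
) -> OmicsMatrix:
    """Project SEG segments onto genes: each gene takes the value of the
    segment covering its start coordinate, else ``baseline``."""
    samples = sorted(segments["sample"].unique())
    gene_ids = annotation.gene_ids()
    data = pd.DataFrame(baseline, index=gene_ids, columns=samples, dtype=float)
    for sample, sub in segments.groupby("sample"):
        for _, seg in sub.iterrows():
            for rec in annotation:
                iv = rec.interval
                if iv.chrom == seg["chrom"] and seg["start"] <= iv.start < seg["end"]:
                    data.loc[rec.gene_id, sample] = seg["value"]
    return OmicsMatrix(data)


# ------------------------------------------------------------------ cytoband


def assign_cytobands(annotation: GeneAnnotation, bands: CytobandMap) -> GeneAnnotation:
    """Label every gene with the band covering its start coordinate.

    A gene straddling a band boundary gets the band of its start — the
    documented convention. An uncovered start is a validation error
    naming the gene.
    """
    labels: dict[str, str] = {}
    for rec in annotation:
        band = bands.band_at(rec.interval.chrom, rec.interval.start)
        if band is None:
            raise ValidationError(
                f"gene {rec.gene_id} at {rec.interval.chrom}:{rec.interval.start} "
                f"not covered by any cytoband"
            )
        labels[rec.gene_id] = band
    return annotation.with_cytobands(labels)
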