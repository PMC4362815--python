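"""Readers and writers for the plain-text formats used across the toolkit.

BED is tab-separated, 0-based half-open.  BED6 column order is
(chrom, start, end, name, score, strand); an optional 7th column carries
an absolute summit coordinate.  Missing name/score are written as ``.``.
"""

from __future__ import annotations

import os
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    ChromSizes,
    GeneModel,
    GenomicInterval,
    RegionCountMatrix,
    RegionSet,
    SampleInfo,
    ValidationError,
)

__all__ = [
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_genes",
    "write_genes",
    "read_count_matrix",
    "write_count_matrix",
    "read_fasta",
    "write_fasta",
]


class BedParseError(ValueError):
    pass


def _parse_float(tok: str) -> Optional[float]:
    return None if tok in (".", "") else float(tok)


def read_bed(path: str, genome: Optional[ChromSizes] = None, name: str = "") -> RegionSet:
    """Read BED3/BED6(+summit) into a sorted :class:`RegionSet`.

    Unknown chromosomes (when ``genome`` is given) and inverted
    coordinates are rejected; malformed lines raise
    :class:`BedParseError` naming the line number.
    """
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            toks = line.split("\t")
            if len(toks) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                chrom = toks[0]
                start, end = int(toks[1]), int(toks[2])
                iv_name = toks[3] if len(toks) > 3 and toks[3] != "." else None
                score = _parse_float(toks[4]) if len(toks) > 4 else None
                strand = toks[5] if len(toks) > 5 and toks[5] != "." else "."
                summit = (
                    int(toks[6]) if len(toks) > 6 and toks[6] != "." else None
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            try:
                intervals.append(
                    GenomicInterval(
                        chrom, start, end,
                        strand=strand, score=score, summit=summit, name=iv_name,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return RegionSet(
        intervals, name=name or os.path.basename(path), genome=genome
    )


def _fmt_score(score: Optional[float]) -> str:
    if score is None:
        return "."
    if float(score).is_integer() and abs(score) < 1e15:
        return str(int(score))
    return repr(float(score))


def write_bed(regions: RegionSet, path: str, columns: int = 6) -> None:
    """Write BED3, BED6, or BED6+summit (``columns`` in {3, 6, 7})."""
    if columns not in (3, 6, 7):
        raise ValueError("columns must be 3, 6 or 7")
    with open(path, "w") as fh:
        for iv in regions:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if columns >= 6:
                fields += [iv.name or ".", _fmt_score(iv.score), iv.strand]
            if columns == 7:
                fields.append("." if iv.summit is None else str(iv.summit))
            fh.write("\t".join(fields) + "\n")


def read_chrom_sizes(path: str) -> ChromSizes:
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            toks = line.split("\t")
            if len(toks) != 2:
                raise BedParseError(f"{path}:{lineno}: expected 2 columns")
            sizes[toks[0]] = int(toks[1])
    return ChromSizes(sizes)


def write_chrom_sizes(genome: ChromSizes, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.items():
            fh.write(f"{chrom}\t{length}\n")


def _blocks_to_str(blocks: List[Tuple[int, int]], idx: int) -> str:
    return ",".join(str(b[idx]) for b in blocks) + ("," if blocks else "")


def read_genes(path: str) -> List[GeneModel]:
    """Read a refFlat-like gene TSV.

    Columns: gene_id, chrom, strand, txStart, txEnd, exonStarts,
    exonEnds (comma-separated block lists).  txStart < txEnd always;
    strand determines which boundary is the TSS.
    """
    genes: List[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            toks = line.split("\t")
            if len(toks) < 7:
                raise BedParseError(f"{path}:{lineno}: expected 7 columns")
            gene_id, chrom, strand = toks[0], toks[1], toks[2]
            tx_start, tx_end = int(toks[3]), int(toks[4])
            starts = [int(x) for x in toks[5].split(",") if x]
            ends = [int(x) for x in toks[6].split(",") if x]
            if len(starts) != len(ends):
                raise BedParseError(f"{path}:{lineno}: exon block length mismatch")
            exons = list(zip(starts, ends))
            if strand == "+":
                tss, tts = tx_start, tx_end
            else:
                tss, tts = tx_end, tx_start
            genes.append(GeneModel(gene_id, chrom, strand, tss, tts, exons))
    return genes


def write_genes(genes: List[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            lo, hi = g.span
            fh.write(
                "\t".join(
                    [
                        g.gene_id,
                        g.chrom,
                        g.strand,
                        str(lo),
                        str(hi),
                        _blocks_to_str(g.exons, 0),
                        _blocks_to_str(g.exons, 1),
                    ]
                )
                + "\n"
            )


def write_count_matrix(
    matrix: RegionCountMatrix, counts_path: str, samples_path: str
) -> None:
    """Write counts TSV (region_id + one column per sample) and the
    sidecar sample-metadata TSV."""
    region_ids = [
        iv.name or f"{iv.chrom}:{iv.start}-{iv.end}" for iv in matrix.regions
    ]
    df = pd.DataFrame(
        matrix.counts,
        index=pd.Index(region_ids, name="region_id"),
        columns=[s.sample_id for s in matrix.samples],
    )
    df.to_csv(counts_path, sep="\t")
    meta = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "assay": s.assay,
                "time_point": s.time_point,
                "replicate": s.replicate,
                "library_size": s.library_size,
            }
            for s in matrix.samples
        ]
    )
    meta.to_csv(samples_path, sep="\t", index=False)


def read_count_matrix(
    counts_path: str, samples_path: str, regions: RegionSet
) -> RegionCountMatrix:
    df = pd.read_csv(counts_path, sep="\t", index_col="region_id")
    meta = pd.read_csv(samples_path, sep="\t", dtype={"time_point": str})
    if len(df) != len(regions):
        raise ValidationError(
            f"count matrix has {len(df)} rows but region set has {len(regions)}"
        )
    samples = []
    by_id = {row.sample_id: row for row in meta.itertuples()}
    for sid in df.columns:
        if sid not in by_id:
            raise ValidationError(f"sample {sid} missing from metadata")
        row = by_id[sid]
        samples.append(
            SampleInfo(
                sample_id=sid,
                assay=str(row.assay),
                time_point=str(row.time_point),
                replicate=int(row.replicate),
                library_size=int(row.library_size),
            )
        )
    return RegionCountMatrix(regions, samples, df.to_numpy())


def read_fasta(path: str) -> Dict[str, str]:
    """Read a FASTA file into a dict of upper-cased sequences."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")
    }


def write_fasta(sequences: Mapping[str, str], path: str, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
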