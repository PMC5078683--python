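"""Readers and writers for the pipeline's interchange formats.

Coordinates are 0-based half-open everywhere inside the package; the
single place 1-based inclusive coordinates appear is at the GFF3
boundary, where the conversion happens exactly once per direction.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome_context import AnnotationSet
from .pipeline import ConservedMarker
from .primer_design import PrimerPair
from .repeat_finder import SSRLocus, canonicalize_motif

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "read_bed",
    "read_te_annotation",
    "loci_to_frame",
    "write_loci_tsv",
    "read_loci_tsv",
    "write_loci_gff3",
    "primer_table",
    "write_primer_tsv",
    "read_primer_tsv",
    "write_markers_tsv",
    "read_score_matrix",
]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Multi-record FASTA as an ordered mapping seq_id -> residues."""
    genome = {rec.id: str(rec.seq) for rec in SeqIO.parse(os.fspath(path), "fasta")}
    if not genome:
        raise ValueError(f"no FASTA records in {path}")
    return genome


def write_fasta(genome: Mapping[str, str], path: str | os.PathLike, width: int = 60):
    records = [
        SeqRecord(Seq(seq), id=seq_id, description="") for seq_id, seq in genome.items()
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def read_gff3(path: str | os.PathLike) -> AnnotationSet:
    """Gene models (gene/mRNA/exon/CDS/UTR) from a GFF3 file.

    GFF3 is 1-based inclusive; intervals become 0-based half-open here.
    Five- and three-prime UTR features are pooled into one UTR track.
    """
    db = gffutils.create_db(
        os.fspath(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    ann = AnnotationSet()
    utr_types = {
        "five_prime_UTR",
        "three_prime_UTR",
        "5'UTR",
        "3'UTR",
        "UTR",
        "five_prime_utr",
        "three_prime_utr",
    }
    for feat in db.all_features():
        start, end = feat.start - 1, feat.end  # the one conversion point
        if feat.featuretype == "gene":
            ann.add_gene(feat.seqid, start, end)
        elif feat.featuretype == "CDS":
            ann.add_cds(feat.seqid, start, end)
        elif feat.featuretype in utr_types:
            ann.add_utr(feat.seqid, start, end)
    return ann


def read_bed(path: str | os.PathLike) -> list[tuple[str, int, int]]:
    """Minimal BED reader (first three columns); BED is already 0-based."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start")
            intervals.append((fields[0], start, end))
    return intervals


def read_te_annotation(path: str | os.PathLike) -> list[tuple[str, int, int]]:
    """Transposable-element intervals from BED or GFF3 (by extension)."""
    name = os.fspath(path)
    if name.endswith((".gff", ".gff3")):
        intervals = []
        with open(name) as handle:
            for lineno, line in enumerate(handle, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 5:
                    raise ValueError(f"{name}:{lineno}: expected >= 5 GFF columns")
                intervals.append((fields[0], int(fields[3]) - 1, int(fields[4])))
        return intervals
    return read_bed(name)


_LOCUS_COLUMNS = ["seq_id", "start", "end", "unit", "motif_class", "repeat_count",
                  "length"]


def loci_to_frame(loci: Sequence[SSRLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            [l.seq_id, l.start, l.end, l.unit, l.motif_class, l.repeat_count,
             l.total_length]
            for l in loci
        ],
        columns=_LOCUS_COLUMNS,
    )


def write_loci_tsv(loci: Sequence[SSRLocus], path: str | os.PathLike) -> None:
    loci_to_frame(loci).to_csv(path, sep="\t", index=False)


def read_loci_tsv(path: str | os.PathLike) -> list[SSRLocus]:
    df = pd.read_csv(path, sep="\t", dtype={"seq_id": str, "unit": str})
    return [
        SSRLocus(
            seq_id=row.seq_id,
            start=int(row.start),
            end=int(row.end),
            unit=row.unit,
            repeat_count=int(row.repeat_count),
            motif_class=canonicalize_motif(row.unit),
        )
        for row in df.itertuples()
    ]


def write_loci_gff3(loci: Sequence[SSRLocus], path: str | os.PathLike) -> None:
    """Loci as GFF3 ``microsatellite`` features (1-based inclusive)."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for i, l in enumerate(loci):
            attrs = f"ID=ssr{i};unit={l.unit};repeat_count={l.repeat_count}"
            handle.write(
                f"{l.seq_id}\tpalmsat\tmicrosatellite\t{l.start + 1}\t{l.end}\t"
                f".\t+\t.\t{attrs}\n"
            )


_PRIMER_COLUMNS = [
    "marker_id", "forward_seq", "reverse_seq", "forward_tm", "reverse_tm",
    "forward_gc", "reverse_gc", "expected_product_size", "forward_start",
    "reverse_end", "locus_seq_id", "locus_start", "locus_end", "locus_unit",
    "locus_repeat_count",
]


def primer_table(pairs: Sequence[PrimerPair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        l = p.source_locus
        rows.append(
            [p.marker_id, p.forward_seq, p.reverse_seq, round(p.forward_tm, 2),
             round(p.reverse_tm, 2), round(p.forward_gc, 2), round(p.reverse_gc, 2),
             p.expected_product_size, p.forward_start, p.reverse_end, l.seq_id,
             l.start, l.end, l.unit, l.repeat_count]
        )
    return pd.DataFrame(rows, columns=_PRIMER_COLUMNS)


def write_primer_tsv(pairs: Sequence[PrimerPair], path: str | os.PathLike) -> None:
    primer_table(pairs).to_csv(path, sep="\t", index=False)


def read_primer_tsv(path: str | os.PathLike) -> list[PrimerPair]:
    df = pd.read_csv(path, sep="\t", dtype={"locus_seq_id": str})
    pairs = []
    for row in df.itertuples():
        locus = SSRLocus(
            seq_id=row.locus_seq_id,
            start=int(row.locus_start),
            end=int(row.locus_end),
            unit=row.locus_unit,
            repeat_count=int(row.locus_repeat_count),
            motif_class=canonicalize_motif(row.locus_unit),
        )
        pairs.append(
            PrimerPair(
                marker_id=str(row.marker_id),
                forward_seq=row.forward_seq,
                reverse_seq=row.reverse_seq,
                forward_tm=float(row.forward_tm),
                reverse_tm=float(row.reverse_tm),
                forward_gc=float(row.forward_gc),
                reverse_gc=float(row.reverse_gc),
                forward_start=int(row.forward_start),
                reverse_end=int(row.reverse_end),
                source_locus=locus,
            )
        )
    return pairs


def write_markers_tsv(markers: Sequence[ConservedMarker], path) -> None:
    rows = []
    for m in markers:
        p = m.primer_pair
        l = p.source_locus
        rows.append(
            {
                "marker_id": m.marker_id,
                "forward_seq": p.forward_seq,
                "reverse_seq": p.reverse_seq,
                "motif": l.motif_class,
                "repeat_count": l.repeat_count,
                "expected_product_size": p.expected_product_size,
                "n_products_a": m.n_products_a,
                "copy_class_a": m.copy_class_a,
                "n_products_b": m.n_products_b,
                "copy_class_b": m.copy_class_b,
                "best_b_size_deviation": m.best_b_size_deviation,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_score_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Marker x species 0/1 amplification matrix (first column = marker id)."""
    return pd.read_csv(path, sep="\t", index_col=0)
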