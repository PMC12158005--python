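"""Readers and writers for the external formats the pipeline touches.

Coordinates are 0-based half-open everywhere inside the package and are
converted to 1-based inclusive only when a GFF3 line is emitted or parsed.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .seqs import normalize

log = logging.getLogger("phasnet")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into (id, sequence) pairs.

    Sequences are uppercased with U normalized to T; record order is
    preserved and duplicate ids are a format error.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, normalize(str(rec.seq), context=f"record {rec.id}")))
    if not records:
        warnings.warn(f"empty FASTA file {path}", stacklevel=2)
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path):
    """Yield (id, sequence, quality string) from a Phred+33 FASTQ file."""
    n = 0
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            n += 1
            yield rec.id, str(rec.seq).upper().replace("U", "T"), "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ near record {n + 1} in {path}: {exc}") from exc


def write_fastq(reads: list[tuple[str, str]], path: str | Path, quality: str = "I") -> None:
    """Write (id, sequence) reads with a constant Phred+33 quality character."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality * len(seq)}\n")


# ---------------------------------------------------------------------------
# GFF3

_GFF_HEADER = "##gff-version 3"


def write_gff3(loci, path: str | Path, source: str = "phasnet") -> None:
    """Write MIR / PHAS loci as GFF3.

    Loci expose ``chrom``, 0-based half-open ``start``/``end``, ``strand``,
    a ``gff_type`` and a ``gff_attributes()`` mapping; emission converts to
    the 1-based inclusive GFF3 convention.
    """
    with open(path, "w") as fh:
        fh.write(_GFF_HEADER + "\n")
        for locus in loci:
            if locus.start >= locus.end:
                raise ValueError(f"locus {locus.locus_id}: start >= end")
            attrs = {"ID": locus.locus_id, **locus.gff_attributes()}
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
            score = attrs.get("score", ".")
            fh.write(
                f"{locus.chrom}\t{source}\t{locus.gff_type}\t{locus.start + 1}\t"
                f"{locus.end}\t{score}\t{locus.strand}\t.\t{attr_s}\n"
            )


def read_gff3(path: str | Path) -> list[dict]:
    """Parse a GFF3 file back to records with 0-based half-open coordinates."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    out = []
    for feat in db.all_features(order_by=("seqid", "start")):
        out.append(
            {
                "seqid": feat.seqid,
                "type": feat.featuretype,
                "start": feat.start - 1,
                "end": feat.end,
                "strand": feat.strand,
                "attributes": {k: v[0] if len(v) == 1 else v for k, v in feat.attributes.items()},
            }
        )
    return out


# ---------------------------------------------------------------------------
# Count tables

def read_count_table(path: str | Path, manifest: list) -> pd.DataFrame:
    """Read a TSV count table (rows = features, columns = library ids).

    Columns must exactly match the manifest's libraries; missing cells and
    negative counts are errors rather than silently filled.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    lib_ids = [m.library_id for m in manifest]
    unknown = [c for c in df.columns if c not in lib_ids]
    if unknown:
        raise ValueError(f"unknown library column(s) {unknown} not in manifest")
    missing = [l for l in lib_ids if l not in df.columns]
    if missing:
        raise ValueError(f"manifest libraries missing from table: {missing}")
    if df.isna().any().any():
        raise ValueError("missing cells in count table (no silent zero-fill)")
    if (df.to_numpy() < 0).any():
        raise ValueError("negative counts in count table")
    return df[lib_ids].astype(int)


def write_count_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# tag / hit tables (pipeline intermediates)

def write_tags(tags, path: str | Path, lib_ids: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("tag_id\tsequence\t" + "\t".join(lib_ids) + "\n")
        for t in tags:
            counts = "\t".join(str(t.counts.get(l, 0)) for l in lib_ids)
            fh.write(f"{t.tag_id}\t{t.sequence}\t{counts}\n")


def read_tags(path: str | Path):
    from .preprocess import SequenceTag

    tags = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        lib_ids = header[2:]
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            counts = {
                lib: int(c) for lib, c in zip(lib_ids, fields[2:]) if int(c) > 0
            }
            tags.append(SequenceTag(fields[0], fields[1], counts))
    return tags


def write_hits(hits, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tag_id\tchrom\tstart\tstrand\tmismatches\tlength\n")
        for h in hits:
            fh.write(f"{h.tag_id}\t{h.chrom}\t{h.start}\t{h.strand}\t{h.mismatches}\t{h.length}\n")


def read_hits(path: str | Path):
    from .preprocess import GenomeHit

    hits = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            tag_id, chrom, start, strand, mm, length = line.rstrip("\n").split("\t")
            hits.append(GenomeHit(tag_id, chrom, int(start), strand, int(mm), int(length)))
    return hits
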