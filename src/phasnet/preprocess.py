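"""Read cleaning, tag collapsing, blacklist filtering and genome alignment.

Small-RNA reads are trimmed of their 3' adapter, length/quality filtered,
collapsed to unique sequence tags with per-library counts, purged of
structural-ncRNA contaminants and aligned end-to-end (ungapped, Hamming
distance) to the genome with up to two mismatches, reporting *all* hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .config import RunConfig
from .seqs import encode, revcomp

log = logging.getLogger("phasnet")

ADAPTER_SEED_LEN = 8


@dataclass
class SequenceTag:
    """A collapsed unique sRNA read with per-library counts."""

    tag_id: str
    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.sequence)


class GenomeHit(NamedTuple):
    tag_id: str
    chrom: str
    start: int  # 0-based leftmost genomic offset
    strand: str  # '+' or '-'
    mismatches: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


def clean_reads(
    reads: Iterable[str | tuple],
    adapter: str | None,
    min_len: int = 18,
    max_len: int | None = None,
) -> list[str]:
    """Adapter-trim and filter a stream of reads, returning kept sequences.

    The 3' adapter is cut at the first exact match of its first
    ``ADAPTER_SEED_LEN`` nucleotides; reads shorter than ``min_len`` (or
    longer than ``max_len``, if given) after trimming, and reads containing
    N, are discarded.
    """
    seed = (adapter or "")[:ADAPTER_SEED_LEN]
    kept: list[str] = []
    n_in = n_short = n_long = n_with_n = 0
    for item in reads:
        seq = item if isinstance(item, str) else item[1]
        n_in += 1
        if seed:
            pos = seq.find(seed)
            if pos >= 0:
                seq = seq[:pos]
        if "N" in seq:
            n_with_n += 1
            continue
        if len(seq) < min_len:
            n_short += 1
            continue
        if max_len is not None and len(seq) > max_len:
            n_long += 1
            continue
        kept.append(seq)
    log.info(
        "clean_reads: %d in, %d kept, %d short, %d long, %d with N",
        n_in, len(kept), n_short, n_long, n_with_n,
    )
    return kept


def collapse_reads(reads_per_library: dict[str, Iterable[str]]) -> list[SequenceTag]:
    """Merge redundant sequences into unique tags with per-library counts.

    Total read count per library is conserved; tag ids are assigned in
    canonical (sequence-sorted) order so the result is input-order invariant.
    """
    counts: dict[str, dict[str, int]] = {}
    for lib_id, reads in reads_per_library.items():
        for seq in reads:
            per_lib = counts.setdefault(seq, {})
            per_lib[lib_id] = per_lib.get(lib_id, 0) + 1
    tags = [
        SequenceTag(f"tag{i + 1:06d}", seq, counts[seq])
        for i, seq in enumerate(sorted(counts))
    ]
    log.info("collapse_reads: %d unique tags from %d libraries", len(tags), len(reads_per_library))
    return tags


def filter_blacklist(tags: list[SequenceTag], blacklist: list[tuple[str, str]]) -> list[SequenceTag]:
    """Drop tags matching any blacklist sequence as an exact substring
    (either strand); mismatched near-hits are retained."""
    if not blacklist:
        log.warning("filter_blacklist: empty blacklist, returning tags unchanged")
        return list(tags)
    refs = [seq for _, seq in blacklist]
    kept: list[SequenceTag] = []
    removed = 0
    for tag in tags:
        fwd, rev = tag.sequence, revcomp(tag.sequence)
        if any(fwd in ref or rev in ref for ref in refs):
            removed += 1
        else:
            kept.append(tag)
    log.info("filter_blacklist: removed %d/%d tags", removed, len(tags))
    return kept


def align_tags(
    tags: list[SequenceTag],
    genome: dict[str, str],
    max_mismatches: int = 2,
) -> list[GenomeHit]:
    """Report all end-to-end ungapped hits with <= max_mismatches on both strands.

    Equivalent to a brute-force Hamming scan over every genome window; the
    result is canonically ordered by (chrom, start, strand, tag).
    """
    chrom_codes = {c: encode(s) for c, s in genome.items()}
    hits: list[GenomeHit] = []
    # cache sliding windows per (chrom, length)
    windows: dict[tuple[str, int], np.ndarray] = {}
    for tag in tags:
        L = len(tag.sequence)
        queries = (("+", encode(tag.sequence)), ("-", encode(revcomp(tag.sequence))))
        for chrom, codes in chrom_codes.items():
            if L > codes.size:
                continue
            wv = windows.get((chrom, L))
            if wv is None:
                wv = sliding_window_view(codes, L)
                windows[(chrom, L)] = wv
            for strand, q in queries:
                mm = np.count_nonzero(wv != q[None, :], axis=1)
                for start in np.nonzero(mm <= max_mismatches)[0]:
                    hits.append(
                        GenomeHit(tag.tag_id, chrom, int(start), strand, int(mm[start]), L)
                    )
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand, h.tag_id))
    log.info("align_tags: %d hits for %d tags", len(hits), len(tags))
    return hits


def filter_multimap(hits: list[GenomeHit], max_hits: int = 20) -> list[GenomeHit]:
    """Remove every hit of tags placed at more than ``max_hits`` genomic
    positions (strictly more; a tag with exactly ``max_hits`` hits is kept)."""
    n_per_tag: dict[str, int] = {}
    for h in hits:
        n_per_tag[h.tag_id] = n_per_tag.get(h.tag_id, 0) + 1
    kept = [h for h in hits if n_per_tag[h.tag_id] <= max_hits]
    log.info("filter_multimap: kept %d/%d hits", len(kept), len(hits))
    return kept


def run_preprocess(
    fastq_per_library: dict[str, str],
    genome: dict[str, str],
    blacklist: list[tuple[str, str]],
    adapter: str | None,
    config: RunConfig,
) -> tuple[list[SequenceTag], list[GenomeHit]]:
    """Full preprocessing stage: clean, collapse, blacklist-filter, align."""
    from .io import read_fastq

    cleaned = {
        lib: clean_reads(read_fastq(path), adapter, config.min_read_len, config.max_read_len)
        for lib, path in fastq_per_library.items()
    }
    tags = collapse_reads(cleaned)
    tags = filter_blacklist(tags, blacklist)
    hits = align_tags(tags, genome, config.max_mismatches)
    if config.multimap_filter_phas:
        hits = filter_multimap(hits, config.max_genome_hits)
    return tags, hits
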