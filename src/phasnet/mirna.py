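"""MIR locus calling from aligned tag stacks.

A MIR locus is accepted when a candidate tag cluster yields a mature/star
duplex with hairpin-compatible spacing (5-300 nt between the two reads),
a 20-22 nt mature, and when mature + star reads (with +/-1 nt isomiR
tolerance) carry at least 75% of the locus abundance. Duplex validity is
assessed by direct mature:star complementarity (Watson-Crick + G:U) under
the canonical 2-nt 3' overhang register, with at most 5 unpaired mature
positions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .config import RunConfig
from .preprocess import GenomeHit, SequenceTag
from .seqs import can_pair

log = logging.getLogger("phasnet")


@dataclass
class Candidate:
    chrom: str
    strand: str
    hits: list[GenomeHit]

    @property
    def start(self) -> int:
        return min(h.start for h in self.hits)

    @property
    def end(self) -> int:
        return max(h.end for h in self.hits)


@dataclass
class DuplexCall:
    mature_hit: GenomeHit | None
    star_hit: GenomeHit | None
    mature_seq: str = ""
    star_seq: str = ""
    valid: bool = False
    unpaired: int | None = None
    reason: str = ""


@dataclass
class MirLocus:
    locus_id: str
    chrom: str
    strand: str
    start: int
    end: int
    mature: str
    mature_offset: int
    star: str
    star_offset: int
    family: str | None
    novel: bool
    duplex_fraction: float
    probably_flag: bool = False

    gff_type = "miRNA_primary_transcript"

    def gff_attributes(self) -> dict:
        return {
            "Name": self.family or "unnamed",
            "mature": self.mature,
            "star": self.star,
            "duplex_fraction": f"{self.duplex_fraction:.4f}",
            "novel": str(self.novel).lower(),
            "probably": str(self.probably_flag).lower(),
        }


def cluster_candidate_loci(hits: list[GenomeHit], max_gap: int = 200) -> list[Candidate]:
    """Group hits into maximal same-strand clusters where consecutive tag
    starts are at most ``max_gap`` apart."""
    by_key: dict[tuple[str, str], list[GenomeHit]] = {}
    for h in hits:
        by_key.setdefault((h.chrom, h.strand), []).append(h)
    out: list[Candidate] = []
    for (chrom, strand), group in sorted(by_key.items()):
        group.sort(key=lambda h: (h.start, h.tag_id))
        current: list[GenomeHit] = []
        for h in group:
            if current and h.start - current[-1].start > max_gap:
                out.append(Candidate(chrom, strand, current))
                current = []
            current.append(h)
        if current:
            out.append(Candidate(chrom, strand, current))
    return out


def duplex_unpaired(mature: str, star: str) -> int:
    """Unpaired mature positions when mature i pairs star (K-3-i).

    This is the duplex register produced by Dicer's 2-nt 3' overhangs:
    the last two bases of each strand hang off the duplex.
    """
    K = len(star)
    unpaired = 0
    for i, base in enumerate(mature):
        j = K - 3 - i
        if j < 0 or j >= K or not can_pair(base, star[j]):
            unpaired += 1
    return unpaired


def evaluate_duplex(
    candidate: Candidate,
    tags_by_id: dict[str, SequenceTag],
    config: RunConfig | None = None,
) -> DuplexCall:
    """Pick the mature (most abundant legal-length tag) and its star partner.

    Valid iff mature length is 20-22 nt, the inner gap between mature and
    star intervals is 5-300 nt, and the duplex leaves at most 5 mature
    positions unpaired.
    """
    cfg = config or RunConfig()
    lo, hi = cfg.mature_len
    legal = [h for h in candidate.hits if lo <= h.length <= hi]
    if not legal:
        return DuplexCall(None, None, reason="no tag of legal mature length")
    mature_hit = max(legal, key=lambda h: (tags_by_id[h.tag_id].total, -h.start, h.tag_id))
    mature_seq = tags_by_id[mature_hit.tag_id].sequence
    smin, smax = cfg.star_spacing
    best: tuple | None = None
    for h in candidate.hits:
        if h.tag_id == mature_hit.tag_id and h.start == mature_hit.start:
            continue
        # inner gap between the two genomic intervals (loop length)
        if h.start >= mature_hit.end:
            gap = h.start - mature_hit.end
        elif mature_hit.start >= h.end:
            gap = mature_hit.start - h.end
        else:
            continue  # overlapping reads cannot be a duplex pair
        if not smin <= gap <= smax:
            continue
        star_seq = tags_by_id[h.tag_id].sequence
        unpaired = duplex_unpaired(mature_seq, star_seq)
        if unpaired > cfg.max_unpaired_duplex:
            continue
        key = (unpaired, -tags_by_id[h.tag_id].total, h.start, h.tag_id)
        if best is None or key < best[0]:
            best = (key, h, star_seq, unpaired)
    if best is None:
        return DuplexCall(
            mature_hit, None, mature_seq, reason="no star with legal spacing and pairing"
        )
    _, star_hit, star_seq, unpaired = best
    return DuplexCall(mature_hit, star_hit, mature_seq, star_seq, True, unpaired)


def _isomir_match(hit: GenomeHit, anchor: GenomeHit, tol: int) -> bool:
    return abs(hit.start - anchor.start) <= tol and abs(hit.end - anchor.end) <= tol


def call_mir_locus(
    candidate: Candidate,
    duplex: DuplexCall,
    tags_by_id: dict[str, SequenceTag],
    config: RunConfig | None = None,
) -> MirLocus | None:
    """Accept the candidate iff mature+star (with isomiR tolerance) carry at
    least the configured fraction (default 75%) of the locus abundance.

    The MIR locus is the hairpin precursor — the interval from the
    outermost mature/star boundary to the other — so only reads
    overlapping that span count toward the total; unrelated reads in the
    surrounding cluster do not dilute the fraction.
    """
    cfg = config or RunConfig()
    if not duplex.valid:
        return None
    lo = min(duplex.mature_hit.start, duplex.star_hit.start)
    hi = max(duplex.mature_hit.end, duplex.star_hit.end)
    locus_hits = [h for h in candidate.hits if h.start < hi and lo < h.end]
    total = sum(tags_by_id[h.tag_id].total for h in locus_hits)
    if total == 0:
        return None
    tol = cfg.isomir_tolerance
    duplex_abund = sum(
        tags_by_id[h.tag_id].total
        for h in locus_hits
        if _isomir_match(h, duplex.mature_hit, tol) or _isomir_match(h, duplex.star_hit, tol)
    )
    fraction = duplex_abund / total
    if fraction < cfg.duplex_fraction:
        return None
    return MirLocus(
        locus_id="",  # assigned after naming
        chrom=candidate.chrom,
        strand=candidate.strand,
        start=lo,
        end=hi,
        mature=duplex.mature_seq,
        mature_offset=duplex.mature_hit.start,
        star=duplex.star_seq,
        star_offset=duplex.star_hit.start,
        family=None,
        novel=True,
        duplex_fraction=fraction,
    )


def _family_of(ref_id: str) -> str:
    """miR159a -> miR159 (strip species prefix and trailing variant letters)."""
    m = re.search(r"(miR\d+)", ref_id, flags=re.IGNORECASE)
    return m.group(1) if m else ref_id


def _min_mismatches(a: str, b: str) -> int:
    """Best ungapped overlap mismatch count for sequences of length diff <= 1."""
    if len(a) > len(b):
        a, b = b, a
    best = len(a)
    for off in range(len(b) - len(a) + 1):
        mm = sum(1 for x, y in zip(a, b[off : off + len(a)]) if x != y)
        # overhanging bases of the longer sequence count as differences
        best = min(best, mm + (len(b) - len(a)))
    return best


def assign_name(
    mature: str,
    known_reference: list[tuple[str, str]],
    max_mismatches: int = 2,
) -> tuple[str | None, bool]:
    """Name by homology: best reference with <= 2 mismatches and length
    within +/-1; returns (family, novel). Novel names are assigned later in
    genomic order by :func:`name_loci`."""
    best: tuple[int, str] | None = None
    for ref_id, ref_seq in known_reference:
        if abs(len(ref_seq) - len(mature)) > 1:
            continue
        mm = _min_mismatches(mature, ref_seq)
        if mm > max_mismatches:
            continue
        if best is None or (mm, ref_id) < best:
            best = (mm, ref_id)
    if best is None:
        return None, True
    return _family_of(best[1]), False


def name_loci(loci: list[MirLocus], known_reference: list[tuple[str, str]]) -> list[MirLocus]:
    """Assign families and locus ids; novel loci become miRN1, miRN2, ... in
    genomic order. Pure in (sequence set, reference): input order irrelevant."""
    ordered = sorted(loci, key=lambda l: (l.chrom, l.start, l.strand))
    novel_k = 0
    family_counts: dict[str, int] = {}
    for locus in ordered:
        family, novel = assign_name(locus.mature, known_reference)
        if novel:
            novel_k += 1
            family = f"miRN{novel_k}"
        locus.family = family
        locus.novel = novel
        family_counts[family] = family_counts.get(family, 0) + 1
        suffix = f"-{family_counts[family]}" if family_counts[family] > 1 else ""
        locus.locus_id = f"{family}{suffix}"
    return ordered


def flag_probably(
    locus: MirLocus,
    rp10m_row: "pd.Series | dict[str, float]",
    min_rp10m: float = 10.0,
    mode: str = "all",
) -> bool:
    """Low-abundance flag: RP10M < threshold in every library (``all``,
    default) or in at least one library (``any``)."""
    values = list(rp10m_row.values()) if isinstance(rp10m_row, dict) else list(rp10m_row)
    if mode == "all":
        return all(v < min_rp10m for v in values)
    if mode == "any":
        return any(v < min_rp10m for v in values)
    raise ValueError(f"unknown probably mode {mode!r}")


def call_mir_loci(
    hits: list[GenomeHit],
    tags: list[SequenceTag],
    known_reference: list[tuple[str, str]],
    config: RunConfig | None = None,
) -> list[MirLocus]:
    """Full MIR stage: cluster, duplex-evaluate, abundance-filter, name."""
    cfg = config or RunConfig()
    tags_by_id = {t.tag_id: t for t in tags}
    loci: list[MirLocus] = []
    for cand in cluster_candidate_loci(hits, cfg.candidate_gap):
        duplex = evaluate_duplex(cand, tags_by_id, cfg)
        locus = call_mir_locus(cand, duplex, tags_by_id, cfg)
        if locus is not None:
            loci.append(locus)
    loci = name_loci(loci, known_reference)
    log.info("call_mir_loci: %d loci accepted", len(loci))
    return loci


def mir_table(loci: list[MirLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus_id": l.locus_id,
                "chrom": l.chrom,
                "strand": l.strand,
                "start": l.start,
                "end": l.end,
                "mature": l.mature,
                "star": l.star,
                "family": l.family,
                "novel": l.novel,
                "duplex_fraction": l.duplex_fraction,
                "probably": l.probably_flag,
            }
            for l in loci
        ]
    )
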