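"""PHAS locus detection by phase-register statistics over sliding windows.

phasiRNAs are diced from a double-stranded precursor in exact increments of
21 or 24 nt downstream of a trigger cleavage site, so their 5' ends fall on
a periodic grid (a *register*, the residue class mod period). A window is
scored by how improbably many of its occupied 5'-end positions sit on one
register (hypergeometric tail) and by an abundance-weighted phasing score;
significant windows sharing a register merge into loci, which must then
pass the dominant-length, phased-abundance and minimum-length filters.

Phase coordinate convention: a read's phase coordinate is its 5'-end
genomic position on the plus strand, and the 5'-end position + 2 on the
minus strand (the Dicer 2-nt 3' overhang offset). Only reads whose length
equals the period define occupied positions.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .config import RunConfig
from .preprocess import GenomeHit, SequenceTag

log = logging.getLogger("phasnet")


@dataclass
class PhaseWindowStats:
    """Occupancy statistics of one window at one register.

    N: eligible 5'-end positions in the window; m: in-register among N;
    n: occupied positions; k: occupied in-register positions; P/U: summed
    abundances of in-register / out-of-register reads.
    """

    window: tuple[int, int]
    period: int
    register: int
    N: int
    m: int
    n: int
    k: int
    P: float
    U: float

    def __post_init__(self) -> None:
        if self.k > min(self.n, self.m):
            raise ValueError("inconsistent stats: k > min(n, m)")
        if self.n > self.N:
            raise ValueError("inconsistent stats: n > N")


@dataclass
class PhasLocus:
    locus_id: str
    chrom: str
    start: int
    end: int
    period: int
    register: int
    p_value: float
    phasing_score: float
    phased_fraction: float
    dominant_length: int
    # ranked (sequence, phase position, abundance, strand)
    phasirnas: list[tuple[str, int, float, str]] = field(default_factory=list)
    stats: PhaseWindowStats | None = None

    strand = "+"  # loci aggregate both strands; reported on plus
    gff_type = "siRNA_locus"

    def gff_attributes(self) -> dict:
        return {
            "period": str(self.period),
            "register": str(self.register),
            "score": f"{self.phasing_score:.3f}",
            "p_value": f"{self.p_value:.3e}",
            "phased_fraction": f"{self.phased_fraction:.4f}",
            "dominant_length": str(self.dominant_length),
        }


def phase_coordinate(hit: GenomeHit) -> int:
    """5'-end position (+ strand) or 5'-end + 2 (- strand)."""
    if hit.strand == "+":
        return hit.start
    return hit.start + hit.length + 1  # (start + length - 1) + 2


@dataclass
class _Read:
    pc: int
    strand: str
    length: int
    abundance: float
    start: int
    end: int
    sequence: str
    tag_id: str


def _reads_from_hits(hits: list[GenomeHit], tags_by_id: dict[str, SequenceTag]) -> list[_Read]:
    reads = []
    for h in hits:
        t = tags_by_id[h.tag_id]
        reads.append(
            _Read(phase_coordinate(h), h.strand, h.length, t.total, h.start, h.end, t.sequence, h.tag_id)
        )
    return reads


def enumerate_phase_stats(
    reads: list,
    period: int,
    register: int,
    window: tuple[int, int],
    position_model: str = "all",
) -> PhaseWindowStats:
    """Direct enumeration of the occupancy statistics of one window.

    ``reads`` are (phase_coord, strand, length, abundance) tuples or
    :class:`_Read` objects. Under the default ``all`` position model every
    nucleotide of the window on both strands is an eligible 5'-end position
    (N = 2 x window length, m = 2 x cycles); under ``grid`` the strands are
    merged into a single phase-coordinate axis (N = window length,
    m = cycles).
    """
    w0, w1 = window
    wlen = w1 - w0
    if wlen % period != 0:
        raise ValueError("window length must be a multiple of the period")
    cycles = wlen // period
    if position_model == "all":
        N, m = 2 * wlen, 2 * cycles
    elif position_model == "grid":
        N, m = wlen, cycles
    else:
        raise ValueError(f"unknown position model {position_model!r}")

    occupied: set = set()
    P = U = 0.0
    for r in reads:
        if isinstance(r, tuple):
            pc, strand, length, abundance = r[:4]
        else:
            pc, strand, length, abundance = r.pc, r.strand, r.length, r.abundance
        if not w0 <= pc < w1:
            continue
        in_register = (pc - register) % period == 0
        if length == period:
            occupied.add((strand, pc) if position_model == "all" else pc)
            if in_register:
                P += abundance
            else:
                U += abundance
        else:
            U += abundance
    n = len(occupied)
    if position_model == "all":
        k = sum(1 for s, pc in occupied if (pc - register) % period == 0)
    else:
        k = sum(1 for pc in occupied if (pc - register) % period == 0)
    return PhaseWindowStats((w0, w1), period, register, N, m, n, k, P, U)


def phasing_pvalue(stats: PhaseWindowStats) -> float:
    """Exact hypergeometric upper tail P(X >= k).

    Population N positions of which m are in-register; n occupied positions
    are the draws and k the in-register successes. Integer arithmetic keeps
    the tail sum exact before the final division.
    """
    N, m, n, k = stats.N, stats.m, stats.n, stats.k
    if k == 0:
        return 1.0
    if k > min(n, m):
        raise ValueError("k > min(n, m)")
    numer = sum(math.comb(m, x) * math.comb(N - m, n - x) for x in range(k, min(n, m) + 1))
    return numer / math.comb(N, n)


def phasing_score(stats: PhaseWindowStats) -> float:
    """ln[(1 + 10 P / (1 + U))^(k-2)] for k >= 3, else 0.

    Monotone increasing in P and k, decreasing in U; requires at least
    three occupied cycles before any score accrues.
    """
    if stats.k < 3:
        return 0.0
    return (stats.k - 2) * math.log1p(10.0 * stats.P / (1.0 + stats.U))


def _window_best_register(
    wreads: list[_Read], period: int, window: tuple[int, int], model: str
) -> PhaseWindowStats | None:
    """Stats at the register maximizing k (ties: larger P, smaller register).

    At fixed window, N, m and n are register-independent, so the
    hypergeometric tail is monotone in k and the max-k register is the
    minimum-p register; this avoids 21 separate tail sums per window.
    """
    wlen = window[1] - window[0]
    cycles = wlen // period
    N, m = (2 * wlen, 2 * cycles) if model == "all" else (wlen, cycles)
    occupied: set = set()
    k = [0] * period
    P = [0.0] * period
    total = 0.0
    for r in wreads:
        total += r.abundance
        if r.length != period:
            continue
        key = (r.strand, r.pc) if model == "all" else r.pc
        reg = r.pc % period
        P[reg] += r.abundance
        if key not in occupied:
            occupied.add(key)
            k[reg] += 1
    n = len(occupied)
    if n == 0:
        return None
    best = max(range(period), key=lambda reg: (k[reg], P[reg], -reg))
    return PhaseWindowStats(
        window, period, best, N, m, n, k[best], P[best], total - P[best]
    )


def scan_phas(
    hits: list[GenomeHit],
    tags: list[SequenceTag],
    period: int,
    config: RunConfig | None = None,
) -> list[PhasLocus]:
    """Sliding-window scan for loci of the given period (21 or 24).

    Windows of ``cycles`` x period nt slide by one period; windows passing
    p < 0.001 and score > 10 at their best register merge (when overlapping
    or bookended with an equal register) into loci, which are accepted iff
    the locus exceeds 100 bp, its phased fraction exceeds 30% and its
    abundance-dominant read length equals the period. The reported locus
    score is the maximum over its constituent windows.
    """
    cfg = config or RunConfig()
    tags_by_id = {t.tag_id: t for t in tags}
    wlen = cfg.phas_cycles * period
    by_chrom: dict[str, list[GenomeHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.chrom, []).append(h)

    loci: list[PhasLocus] = []
    for chrom in sorted(by_chrom):
        reads = _reads_from_hits(by_chrom[chrom], tags_by_id)
        if not reads:
            continue
        reads.sort(key=lambda r: r.pc)
        pcs = [r.pc for r in reads]
        lo = (min(pcs) // period) * period
        hi = max(pcs)
        retained: list[tuple[int, int, float, float]] = []  # (w0, register, p, score)
        w0 = max(0, lo - wlen + period)
        while w0 <= hi:
            i = bisect.bisect_left(pcs, w0)
            j = bisect.bisect_left(pcs, w0 + wlen)
            wreads = reads[i:j]
            st = (
                _window_best_register(wreads, period, (w0, w0 + wlen), cfg.position_model)
                if wreads
                else None
            )
            if st is not None and st.k >= 3:  # k < 3 scores 0, cannot pass
                p = phasing_pvalue(st)
                sc = phasing_score(st)
                if p < cfg.phas_pmax and sc > cfg.phas_min_score:
                    retained.append((w0, st.register, p, sc))
            w0 += period
        # merge overlapping/bookended retained windows sharing a register
        groups: list[list[tuple[int, int, float, float]]] = []
        for win in retained:
            if (
                groups
                and win[1] == groups[-1][-1][1]
                and win[0] - groups[-1][-1][0] <= wlen
            ):
                groups[-1].append(win)
            else:
                groups.append([win])
        for gi, group in enumerate(groups):
            locus = _build_locus(chrom, group, reads, period, wlen, cfg)
            if locus is not None:
                loci.append(locus)
    # locus ids in genomic order
    loci.sort(key=lambda l: (l.chrom, l.start))
    for i, locus in enumerate(loci, start=1):
        locus.locus_id = f"PHAS{period}-{i}"
    log.info("scan_phas(period=%d): %d loci", period, len(loci))
    return loci


def _build_locus(chrom, group, reads, period, wlen, cfg) -> PhasLocus | None:
    register = group[0][1]
    span0, span1 = group[0][0], group[-1][0] + wlen
    in_range = [r for r in reads if span0 <= r.pc < span1]
    phased = [r for r in in_range if r.length == period and (r.pc - register) % period == 0]
    if not phased:
        return None
    start = min(r.start for r in phased)
    end = max(r.end for r in phased)
    if end - start <= cfg.phas_min_len:
        return None
    P = sum(r.abundance for r in phased)
    U = sum(r.abundance for r in in_range) - P
    frac = P / (P + U) if P + U > 0 else 0.0
    if frac <= cfg.phas_min_phased_frac:
        return None
    length_weight: dict[int, float] = {}
    for r in in_range:
        length_weight[r.length] = length_weight.get(r.length, 0.0) + r.abundance
    dominant = max(sorted(length_weight), key=lambda L: length_weight[L])
    if dominant != period:
        return None
    p_value = min(w[2] for w in group)
    score = max(w[3] for w in group)
    # collapse phased reads to species at a (strand, position)
    species: dict[tuple[str, int], list] = {}
    for r in phased:
        key = (r.strand, r.pc)
        rec = species.setdefault(key, [r.sequence, r.pc, 0.0, r.strand])
        rec[2] += r.abundance
    phasirnas = [tuple(v) for v in species.values()]
    phasirnas.sort(key=lambda x: (-x[2], x[1], x[3]))
    locus = PhasLocus(
        locus_id="",
        chrom=chrom,
        start=start,
        end=end,
        period=period,
        register=register % period,
        p_value=p_value,
        phasing_score=score,
        phased_fraction=frac,
        dominant_length=dominant,
        phasirnas=phasirnas,
    )
    return locus


def top_phasirnas(locus: PhasLocus, top_n: int = 30) -> list[tuple[str, int, float, str]]:
    """The most abundant in-register phasiRNA species (ties broken by lower
    coordinate), at most ``top_n``."""
    ranked = sorted(locus.phasirnas, key=lambda x: (-x[2], x[1], x[3]))
    return ranked[:top_n]


def phas_table(loci: list[PhasLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus_id": l.locus_id,
                "chrom": l.chrom,
                "start": l.start,
                "end": l.end,
                "period": l.period,
                "register": l.register,
                "p_value": l.p_value,
                "phasing_score": l.phasing_score,
                "phased_fraction": l.phased_fraction,
                "dominant_length": l.dominant_length,
                "n_phasirnas": len(l.phasirnas),
            }
            for l in loci
        ]
    )
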