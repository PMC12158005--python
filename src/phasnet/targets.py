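"""sRNA-target complementarity scoring and trigger-miRNA assignment.

The engine scores antiparallel sRNA:site duplexes with the additive
plant-miRNA penalty convention (mismatch 1.0, G:U wobble 0.5, gapped
position 2.0, everything doubled at sRNA positions 2-13 counted from the
5' end) and a scale-free duplex-stability ratio (duplex energy over the
energy of the sRNA's perfect complement, with pair energies GC -3, AU -2,
G:U -1). Target interactions are accepted when the penalty score is below
7 and the energy ratio above 0.65; trigger assignments to PHAS loci use a
penalty of at most 5 within the flanked locus window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .config import RunConfig
from .seqs import encode, revcomp

log = logging.getLogger("phasnet")

# penalty and pair-energy lookup by (srna code, site code); code 4 = N
PAIR_PENALTY = np.ones((5, 5), dtype=float)
PAIR_ENERGY = np.zeros((5, 5), dtype=float)
for _a, _b, _pen, _e in [
    (0, 3, 0.0, -2.0),  # A:T
    (3, 0, 0.0, -2.0),  # T:A
    (1, 2, 0.0, -3.0),  # C:G
    (2, 1, 0.0, -3.0),  # G:C
    (2, 3, 0.5, -1.0),  # G:U wobble
    (3, 2, 0.5, -1.0),  # U:G wobble
]:
    PAIR_PENALTY[_a, _b] = _pen
    PAIR_ENERGY[_a, _b] = _e

GAP_PENALTY = 2.0
CORE_START, CORE_END = 2, 13  # 1-based sRNA positions with doubled penalties
CLEAVAGE_POSITION = 10  # cleavage opposite sRNA positions 10-11


def _weights(L: int) -> np.ndarray:
    w = np.ones(L)
    w[CORE_START - 1 : CORE_END] = 2.0
    return w


@dataclass
class DuplexAlignment:
    """One antiparallel sRNA:site alignment.

    ``pairing`` has one symbol per sRNA position 5'->3': '|' Watson-Crick,
    'o' G:U, 'x' mismatch, '-' bulged (unpaired) sRNA base. A target bulge
    is recorded in ``gap`` as ("target_bulge", srna_pos) where srna_pos is
    the 1-based sRNA position 3' of the bulged site base.
    """

    srna: str
    site: str
    site_start: int
    site_end: int
    pairing: str
    gap: tuple[str, int] | None = None
    transcript_id: str | None = None

    def site_position_of(self, srna_pos: int) -> int:
        """Transcript coordinate paired with the given 1-based sRNA position."""
        i = srna_pos - 1
        L = len(self.srna)
        if self.gap is None:
            return self.site_start + (L - 1 - i)
        kind, g = self.gap
        if kind == "srna_bulge":
            g0 = g - 1
            if i == g0:
                raise ValueError("bulged sRNA position has no site partner")
            idx = (L - 2 - i) if i < g0 else (L - 1 - i)
            return self.site_start + idx
        # target bulge before 1-based position g
        idx = (L - i) if i < g - 1 else (L - 1 - i)
        return self.site_start + idx

    @property
    def cleavage_position(self) -> int:
        """Site coordinate opposite sRNA position 10 (position 11 when 10
        itself is the bulged base)."""
        try:
            return self.site_position_of(CLEAVAGE_POSITION)
        except ValueError:
            return self.site_position_of(CLEAVAGE_POSITION + 1)


def _pairing_symbols(srna_codes: np.ndarray, site_codes_aligned: np.ndarray) -> str:
    out = []
    for a, b in zip(srna_codes, site_codes_aligned):
        if b == 255:
            out.append("-")
        elif PAIR_PENALTY[a, b] == 0.0:
            out.append("|")
        elif PAIR_PENALTY[a, b] == 0.5:
            out.append("o")
        else:
            out.append("x")
    return "".join(out)


def allen_score(duplex: DuplexAlignment) -> float:
    """Additive penalty: mismatch 1, G:U 0.5, gapped position 2; doubled at
    sRNA positions 2-13. A perfect complement scores 0."""
    L = len(duplex.srna)
    w = _weights(L)
    score = 0.0
    for i, sym in enumerate(duplex.pairing):
        if sym == "x":
            score += 1.0 * w[i]
        elif sym == "o":
            score += 0.5 * w[i]
        elif sym == "-":
            score += GAP_PENALTY * w[i]
    if duplex.gap is not None and duplex.gap[0] == "target_bulge":
        pos = min(max(duplex.gap[1], 1), L)
        score += GAP_PENALTY * w[pos - 1]
    return score


def mfe_ratio(duplex: DuplexAlignment) -> float:
    """Duplex energy over the sRNA's perfect-complement energy, in [0, 1].

    Pair energies: GC -3, AU -2, G:U -1; mismatches and gaps contribute 0.
    """
    srna_codes = encode(duplex.srna)
    if np.all(srna_codes == 4):
        raise ValueError("sRNA of all-N has no defined perfect-complement energy")
    e_perfect = float(np.where(np.isin(srna_codes, (1, 2)), -3.0, -2.0)[srna_codes != 4].sum())
    site_codes = encode(duplex.site)
    e = 0.0
    for i, sym in enumerate(duplex.pairing):
        if sym in "|o":
            j = duplex.site_position_of(i + 1) - duplex.site_start
            e += PAIR_ENERGY[srna_codes[i], site_codes[j]]
    ratio = e / e_perfect
    return float(min(1.0, max(0.0, ratio)))


def _ungapped_scan(srna_codes, tx_codes):
    """(unweighted, weighted) penalty per offset for all ungapped alignments."""
    L = srna_codes.size
    wv = sliding_window_view(tx_codes, L)[:, ::-1]  # column i pairs sRNA position i
    pen = PAIR_PENALTY[srna_codes[None, :], wv]
    w = _weights(L)
    return pen.sum(axis=1), (pen * w).sum(axis=1)


def find_candidate_sites(
    srna: str,
    transcript: str,
    max_equiv: float = 7.0,
    include_gaps: bool = True,
    transcript_id: str | None = None,
) -> list[DuplexAlignment]:
    """All antiparallel alignments (exhaustive ungapped scan plus every
    single-gap variant) whose unweighted penalty sum is <= ``max_equiv``.

    The unweighted sum is a lower bound on the position-weighted score, so
    no alignment acceptable at the configured thresholds is missed.
    Deterministic order: by site start, ungapped before gapped variants.
    """
    L = len(srna)
    if len(transcript) < L:
        return []
    s = encode(srna)
    t = encode(transcript)
    w = _weights(L)
    found: list[tuple[int, int, DuplexAlignment]] = []

    unw, _ = _ungapped_scan(s, t)
    for j in np.nonzero(unw <= max_equiv)[0]:
        site = transcript[j : j + L]
        aligned = encode(site)[::-1]
        found.append(
            (int(j), 0, DuplexAlignment(srna, site, int(j), int(j + L), _pairing_symbols(s, aligned), None, transcript_id))
        )

    if include_gaps and L >= 3:
        # sRNA bulge: sRNA position g (0-based, interior) unpaired; site length L-1
        for g in range(1, L - 1):
            reduced = np.concatenate([s[:g], s[g + 1 :]])
            unw_g, _ = _ungapped_scan(reduced, t)
            gap_cost = GAP_PENALTY
            for j in np.nonzero(unw_g + gap_cost <= max_equiv)[0]:
                site = transcript[j : j + L - 1]
                aligned = np.full(L, 255, dtype=np.int64)
                rev = encode(site)[::-1]
                aligned[:g] = rev[:g]
                aligned[g + 1 :] = rev[g:]
                found.append(
                    (int(j), 1 + g, DuplexAlignment(srna, site, int(j), int(j + L - 1), _pairing_symbols(s, aligned), ("srna_bulge", g + 1), transcript_id))
                )
        # target bulge: one extra site base unpaired between sRNA g-1 and g (1-based g)
        if len(transcript) >= L + 1:
            wv = sliding_window_view(t, L + 1)[:, ::-1]  # reversed L+1 windows
            for g in range(1, L):
                aligned_all = np.concatenate([wv[:, : g - 1], wv[:, g:]], axis=1)
                pen = PAIR_PENALTY[s[None, :], aligned_all].sum(axis=1)
                for j in np.nonzero(pen + GAP_PENALTY <= max_equiv)[0]:
                    site = transcript[j : j + L + 1]
                    found.append(
                        (int(j), 100 + g, DuplexAlignment(srna, site, int(j), int(j + L + 1), _pairing_symbols(s, aligned_all[j]), ("target_bulge", g), transcript_id))
                    )
    found.sort(key=lambda x: (x[0], x[1]))
    return [d for _, _, d in found]


@dataclass
class TargetInteraction:
    srna_id: str
    srna_class: str  # "miRNA" or "phasiRNA"
    transcript_id: str
    site_start: int
    site_end: int
    allen_score: float
    mfe_ratio: float
    cleavage_position: int
    accepted: bool
    pairing: str


def predict_targets(
    srnas: list[tuple[str, str, str]],
    transcripts: list[tuple[str, str]],
    config: RunConfig | None = None,
) -> list[TargetInteraction]:
    """Best site per sRNA x transcript; accepted iff Allen score < 7 (strict)
    and MFE ratio > 0.65 (strict).

    ``srnas`` are (id, class, sequence) with class "miRNA" or "phasiRNA".
    """
    cfg = config or RunConfig()
    out: list[TargetInteraction] = []
    for srna_id, srna_class, seq in srnas:
        for tx_id, tx_seq in transcripts:
            sites = find_candidate_sites(seq, tx_seq, max_equiv=cfg.allen_max, transcript_id=tx_id)
            if not sites:
                continue
            best = min(
                enumerate(sites), key=lambda x: (allen_score(x[1]), x[1].site_start, x[0])
            )[1]
            score = allen_score(best)
            ratio = mfe_ratio(best)
            out.append(
                TargetInteraction(
                    srna_id,
                    srna_class,
                    tx_id,
                    best.site_start,
                    best.site_end,
                    score,
                    ratio,
                    best.cleavage_position,
                    score < cfg.allen_max and ratio > cfg.mfe_ratio_min,
                    best.pairing,
                )
            )
    return out


@dataclass
class TriggerAssignment:
    mirna_id: str
    phas_id: str
    penalty: float
    strand: str  # strand of the PHAS precursor the trigger binds
    site_start: int  # genomic coordinate of the site (plus-strand coords)
    cleavage: int  # genomic coordinate of the predicted cleavage 5' end
    in_register: bool


def identify_triggers(
    mir_loci,
    phas_loci,
    genome: dict[str, str],
    config: RunConfig | None = None,
) -> list[TriggerAssignment]:
    """Assign trigger miRNAs to PHAS loci by best-duplex penalty within the
    flanked locus window (locus span plus 400 bp of added flank, 200 nt per
    side), on either strand; reported iff penalty <= 5 (inclusive).

    The predicted cleavage is the site base opposite sRNA positions 10-11;
    ``in_register`` tests whether that coordinate's phase coordinate falls
    on the locus register.
    """
    cfg = config or RunConfig()
    flank = cfg.trigger_window // 2
    out: list[TriggerAssignment] = []
    for phas in phas_loci:
        chrom_seq = genome[phas.chrom]
        ws = max(0, phas.start - flank)
        we = min(len(chrom_seq), phas.end + flank)
        window = chrom_seq[ws:we]
        window_rc = revcomp(window)
        for mir in mir_loci:
            best: tuple | None = None
            for strand, seq in (("+", window), ("-", window_rc)):
                sites = find_candidate_sites(
                    mir.mature, seq, max_equiv=cfg.trigger_max_penalty, include_gaps=True
                )
                for k, d in enumerate(sites):
                    score = allen_score(d)
                    key = (score, 0 if strand == "+" else 1, d.site_start, k)
                    if best is None or key < best[0]:
                        best = (key, strand, d, score)
            if best is None:
                continue
            _, strand, d, penalty = best
            if penalty > cfg.trigger_max_penalty:
                continue
            cleave_local = d.cleavage_position
            if strand == "+":
                cleavage = ws + cleave_local
                site_start = ws + d.site_start
                pc = cleavage
            else:
                cleavage = we - 1 - cleave_local
                site_start = we - d.site_end
                pc = cleavage + 2  # minus-strand phase-coordinate offset
            in_register = (pc - phas.register) % phas.period == 0
            out.append(
                TriggerAssignment(
                    mir.locus_id, phas.locus_id, penalty, strand, site_start, cleavage, in_register
                )
            )
    log.info("identify_triggers: %d assignments", len(out))
    return out
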