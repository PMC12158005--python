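"""Degradome (PARE) validation of predicted cleavage sites.

Degradome reads are the 5' ends of 3' cleavage fragments, so a genuine
sRNA-guided slicing event produces a read pileup at the cleavage position.
Each candidate position is ranked against the rest of its transcript's
signal with the five-category convention of degradome analysis (0 = unique
maximum ... 4 = single read); an interaction is validated when its site
falls in categories 0-3 with an alignment penalty of at most 6 and at
least one read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median

import numpy as np

from .config import RunConfig
from .targets import TargetInteraction

log = logging.getLogger("phasnet")


@dataclass
class DegradomeProfile:
    """Per-position 5'-end read density of one transcript.

    ``density`` holds fractional weights (multi-mapping reads contribute
    1/t at each of their t placements); ``rounded`` is the integer view.
    """

    transcript_id: str
    density: np.ndarray

    @property
    def rounded(self) -> np.ndarray:
        return np.rint(self.density).astype(int)


def map_degradome(
    reads: list[str],
    transcripts: list[tuple[str, str]],
) -> tuple[dict[str, DegradomeProfile], int]:
    """Assign each read's 5' end to its exact-match transcript position(s).

    A read matching t positions (across all transcripts) adds 1/t weight at
    each; reads matching nowhere increment the unmapped counter.
    """
    profiles = {
        tx_id: DegradomeProfile(tx_id, np.zeros(len(seq))) for tx_id, seq in transcripts
    }
    seqs = dict(transcripts)
    unmapped = 0
    for read in reads:
        placements: list[tuple[str, int]] = []
        for tx_id, seq in seqs.items():
            start = seq.find(read)
            while start >= 0:
                placements.append((tx_id, start))
                start = seq.find(read, start + 1)
        if not placements:
            unmapped += 1
            continue
        w = 1.0 / len(placements)
        for tx_id, pos in placements:
            profiles[tx_id].density[pos] += w
    log.info("map_degradome: %d reads, %d unmapped", len(reads), unmapped)
    return profiles, unmapped


def categorize_site(profile: DegradomeProfile | np.ndarray | list, position: int) -> int:
    """Category 0-4 of one occupied position.

    With r the signal at the position, M the maximum and med the median
    over occupied positions of the transcript: 4 if r <= 1 (a single
    read); 0 if r > 1 and r is the unique maximum; 1 if r > 1 equals a
    shared maximum; 2 if med < r < M; 3 if 1 < r <= med.
    """
    density = profile.density if isinstance(profile, DegradomeProfile) else profile
    vals = [float(v) for v in density]
    r = vals[position]
    if r <= 0:
        raise ValueError("no degradome signal at the queried position")
    occupied = [v for v in vals if v > 0]
    if r <= 1:
        return 4
    M = max(occupied)
    if r == M:
        return 0 if occupied.count(M) == 1 else 1
    med = median(occupied)
    if r > med:
        return 2
    return 3


@dataclass
class DegradomeSite:
    srna_id: str
    srna_class: str
    transcript_id: str
    position: int
    reads: float
    category: int | None
    penalty: float
    validated: bool


def validate_interactions(
    interactions: list[TargetInteraction],
    profiles: dict[str, DegradomeProfile],
    config: RunConfig | None = None,
) -> list[DegradomeSite]:
    """Check each interaction's predicted cleavage position against the
    degradome pileup (best signal within +/-1 nt); validated iff category
    <= 3, penalty <= 6 and at least one read."""
    cfg = config or RunConfig()
    out: list[DegradomeSite] = []
    for inter in interactions:
        profile = profiles.get(inter.transcript_id)
        if profile is None:
            out.append(
                DegradomeSite(
                    inter.srna_id, inter.srna_class, inter.transcript_id,
                    inter.cleavage_position, 0.0, None, inter.allen_score, False,
                )
            )
            continue
        n = profile.density.size
        candidates = [
            p
            for p in range(
                inter.cleavage_position - cfg.degradome_slop,
                inter.cleavage_position + cfg.degradome_slop + 1,
            )
            if 0 <= p < n
        ]
        best = max(candidates, key=lambda p: (profile.density[p], -p), default=None)
        reads = float(profile.density[best]) if best is not None else 0.0
        if best is None or reads <= 0:
            out.append(
                DegradomeSite(
                    inter.srna_id, inter.srna_class, inter.transcript_id,
                    inter.cleavage_position, 0.0, None, inter.allen_score, False,
                )
            )
            continue
        category = categorize_site(profile, best)
        validated = (
            category <= cfg.degradome_max_category
            and inter.allen_score <= cfg.degradome_max_penalty
            and reads >= 1
        )
        out.append(
            DegradomeSite(
                inter.srna_id, inter.srna_class, inter.transcript_id,
                best, reads, category, inter.allen_score, validated,
            )
        )
    log.info(
        "validate_interactions: %d/%d validated",
        sum(s.validated for s in out), len(out),
    )
    return out
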