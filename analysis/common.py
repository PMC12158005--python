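"""Shared configuration for the numbered analysis drivers.

All drivers operate on one full-scale synthetic study (SEED below),
reading and writing the same locations: bulky intermediates (FASTQ,
tag/hit tables) under scratch/, final tables under results/.
"""

from pathlib import Path

from phasnet.config import RunConfig
from phasnet.simulate import SimParams, SyntheticDataset

SEED = 1
ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"
SIMDATA = SCRATCH / "simdata"


def get_dataset() -> SyntheticDataset:
    """The study dataset; reconstruction from SEED is deterministic."""
    return SyntheticDataset(SimParams(), SEED)


def get_config() -> RunConfig:
    return RunConfig(random_seed=SEED)


def ensure_dirs() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)


def load_loci(cfg: RunConfig):
    """Re-derive locus calls from the saved tag/hit tables (fast and
    deterministic, so downstream drivers need no pickled state)."""
    from phasnet.io import read_fasta, read_hits, read_tags
    from phasnet.mirna import call_mir_loci
    from phasnet.phasing import scan_phas
    from phasnet.pipeline import _dedupe_mir_loci

    tags = read_tags(SCRATCH / "tags.tsv")
    hits = read_hits(SCRATCH / "hits.tsv")
    known = read_fasta(SIMDATA / "known_mirnas.fa")
    mir_loci = _dedupe_mir_loci(call_mir_loci(hits, tags, known, cfg))
    phas_loci = scan_phas(hits, tags, 21, cfg) + scan_phas(hits, tags, 24, cfg)
    return tags, hits, mir_loci, phas_loci
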