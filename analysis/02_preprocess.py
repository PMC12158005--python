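#!/usr/bin/env python
"""Clean, collapse, blacklist-filter and align the sRNA libraries.

Reads the FASTQ files from 01, applies the standard small-RNA cleanup
(3' adapter trim, length 18-34, drop N), collapses to unique tags,
removes structural-ncRNA contaminants and aligns everything to the
genome (ungapped, <= 2 mismatches, all hits, <= 20 placements).
Tag and hit tables go to scratch/; stage counts to results/.
"""

import json

from common import RESULTS, SCRATCH, SIMDATA, ensure_dirs, get_config, get_dataset
from phasnet.io import read_fasta, read_fastq, write_hits, write_tags
from phasnet.preprocess import (
    align_tags,
    clean_reads,
    collapse_reads,
    filter_blacklist,
    filter_multimap,
)


def main() -> None:
    ensure_dirs()
    ds = get_dataset()
    cfg = get_config()

    cleaned = {}
    raw_total = 0
    for m in ds.manifest:
        reads = list(read_fastq(SIMDATA / f"{m.library_id}.fastq"))
        raw_total += len(reads)
        cleaned[m.library_id] = clean_reads(
            reads, ds.params.adapter, cfg.min_read_len, cfg.max_read_len
        )
    tags = collapse_reads(cleaned)
    n_before_blacklist = len(tags)
    tags = filter_blacklist(tags, read_fasta(SIMDATA / "blacklist.fa"))
    genome = {name: seq for name, seq in read_fasta(SIMDATA / "genome.fa")}
    hits = align_tags(tags, genome, cfg.max_mismatches)
    hits_kept = filter_multimap(hits, cfg.max_genome_hits)

    lib_ids = [m.library_id for m in ds.manifest]
    write_tags(tags, SCRATCH / "tags.tsv", lib_ids)
    write_hits(hits_kept, SCRATCH / "hits.tsv")

    summary = {
        "raw_reads": raw_total,
        "clean_reads": sum(len(v) for v in cleaned.values()),
        "unique_tags": n_before_blacklist,
        "tags_after_blacklist": len(tags),
        "genome_hits": len(hits),
        "hits_after_multimap_filter": len(hits_kept),
    }
    (RESULTS / "02_preprocess_summary.json").write_text(json.dumps(summary, indent=1) + "\n")
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
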