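#!/usr/bin/env python
"""Annotate MIR and PHAS loci from the aligned tag stacks.

MIR loci must satisfy the hairpin duplex rules (mature 20-22 nt, star
spacing 5-300 nt, mature+star >= 75% of locus reads); PHAS loci the
four phasing rules (dominant length = period, phased abundance > 30%,
length > 100 bp, p < 0.001 with score > 10). Emits GFF3 + TSV tables.
"""

from common import RESULTS, SCRATCH, SIMDATA, ensure_dirs, get_config, get_dataset
from phasnet.io import read_fasta, read_hits, read_tags, write_fasta, write_gff3
from phasnet.mirna import call_mir_loci, mir_table
from phasnet.phasing import phas_table, scan_phas, top_phasirnas
from phasnet.pipeline import _dedupe_mir_loci


def main() -> None:
    ensure_dirs()
    cfg = get_config()
    tags = read_tags(SCRATCH / "tags.tsv")
    hits = read_hits(SCRATCH / "hits.tsv")
    known = read_fasta(SIMDATA / "known_mirnas.fa")

    mir_loci = _dedupe_mir_loci(call_mir_loci(hits, tags, known, cfg))
    phas_loci = scan_phas(hits, tags, 21, cfg) + scan_phas(hits, tags, 24, cfg)

    write_gff3(mir_loci, RESULTS / "03_mir_loci.gff3")
    mir_table(mir_loci).to_csv(RESULTS / "03_mir_loci.tsv", sep="\t", index=False)
    write_gff3(phas_loci, RESULTS / "03_phas_loci.gff3")
    phas_table(phas_loci).to_csv(RESULTS / "03_phas_loci.tsv", sep="\t", index=False)
    phasirna_records = [
        (f"{locus.locus_id}|p{i}", seq)
        for locus in phas_loci
        for i, (seq, _, _, _) in enumerate(top_phasirnas(locus, cfg.top_n_phasirna))
    ]
    write_fasta(phasirna_records, RESULTS / "03_top_phasirnas.fa")

    known_n = sum(1 for l in mir_loci if not l.novel)
    print(
        f"called {len(mir_loci)} MIR loci ({known_n} known, {len(mir_loci) - known_n} novel), "
        f"{sum(1 for l in phas_loci if l.period == 21)} x 21-nt and "
        f"{sum(1 for l in phas_loci if l.period == 24)} x 24-nt PHAS loci"
    )


if __name__ == "__main__":
    main()
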