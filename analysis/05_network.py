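#!/usr/bin/env python
"""Differential expression and the miRNA-PHAS-mRNA regulatory network.

Quantifies called loci as RP10M, contrasts reproductive vs vegetative
libraries (miRNA |log2FC| >= 2, PHAS >= 1, mRNA > 1; FDR <= 0.05),
joins trigger and target tables into regulatory triples classified as
Model 1 (miRNA-only) or Model 2 (miRNA + phasiRNA), and exports the
edge table with r > 0.7-filtered trigger edges.
"""

import pandas as pd

from common import RESULTS, SIMDATA, ensure_dirs, get_config, get_dataset, load_loci
from phasnet.config import LibraryManifest
from phasnet.io import read_count_table, read_fasta
from phasnet.network import assemble_network, differential, normalize_rp10m, zscore_rows
from phasnet.phasing import top_phasirnas
from phasnet.pipeline import _feature_counts
from phasnet.targets import identify_triggers, predict_targets


def main() -> None:
    ensure_dirs()
    ds = get_dataset()  # manifest + mRNA counts come from the study design
    cfg = get_config()
    tags, hits, mir_loci, phas_loci = load_loci(cfg)
    genome = dict(read_fasta(SIMDATA / "genome.fa"))
    transcripts = read_fasta(SIMDATA / "transcripts.fa")
    lib_ids = [m.library_id for m in ds.manifest]

    tags_by_seq = {t.sequence: t for t in tags}
    mir_counts = _feature_counts([(l.locus_id, [l.mature]) for l in mir_loci], tags_by_seq, lib_ids)
    phas_counts = _feature_counts(
        [(l.locus_id, [p[0] for p in l.phasirnas]) for l in phas_loci], tags_by_seq, lib_ids
    )
    mrna_counts = read_count_table(SIMDATA / "mrna_counts.tsv", ds.manifest)

    de_mirna = differential(mir_counts, ds.manifest, "miRNA", cfg)
    de_phas = differential(phas_counts, ds.manifest, "PHAS", cfg)
    mrna_manifest = [
        LibraryManifest(m.library_id, m.tissue, total_clean_reads=int(mrna_counts[m.library_id].sum()))
        for m in ds.manifest
    ]
    de_mrna = differential(mrna_counts, mrna_manifest, "mRNA", cfg)
    de_mirna.to_csv(RESULTS / "05_de_mirna.tsv", sep="\t")
    de_phas.to_csv(RESULTS / "05_de_phas.tsv", sep="\t")
    de_mrna.to_csv(RESULTS / "05_de_mrna.tsv", sep="\t")

    srna_expr = normalize_rp10m(
        pd.concat([mir_counts, phas_counts]),
        {m.library_id: m.total_clean_reads for m in ds.manifest},
    )
    zscore_rows(srna_expr.log2).to_csv(RESULTS / "05_srna_expression_zscores.tsv", sep="\t")

    triggers = identify_triggers(mir_loci, phas_loci, genome, cfg)
    mirna_targets = predict_targets([(l.locus_id, "miRNA", l.mature) for l in mir_loci], transcripts, cfg)
    phasi_targets = predict_targets(
        [
            (f"{l.locus_id}|p{i}", "phasiRNA", seq)
            for l in phas_loci
            for i, (seq, _, _, _) in enumerate(top_phasirnas(l, cfg.top_n_phasirna))
        ],
        transcripts,
        cfg,
    )
    phasi_pairs = sorted(
        {(t.srna_id.split("|")[0], t.transcript_id) for t in phasi_targets if t.accepted}
    )
    triples, edges = assemble_network(
        triggers, mirna_targets, phasi_pairs, de_mirna, de_phas, de_mrna, srna_expr, cfg
    )
    triples.to_csv(RESULTS / "05_triples.tsv", sep="\t", index=False)
    edges.to_csv(RESULTS / "05_edges.tsv", sep="\t", index=False)

    print(
        f"{len(triples)} regulatory triples: "
        f"{int((triples.model == 1).sum())} Model 1, {int((triples.model == 2).sum())} Model 2; "
        f"{len(edges)} network edges"
    )


if __name__ == "__main__":
    main()
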