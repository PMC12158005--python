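#!/usr/bin/env python
"""Assign trigger miRNAs, predict sRNA targets and validate them against
the degradome.

Triggers: best duplex penalty <= 5 within the flanked PHAS window, with
the predicted cleavage checked against the locus register. Targets:
Allen score < 7 and MFE ratio > 0.65 on the best site per pair.
Validation: degradome category <= 3 with penalty <= 6 at the predicted
cleavage position (+/- 1 nt).
"""

import pandas as pd

from common import RESULTS, SIMDATA, ensure_dirs, get_config, load_loci
from phasnet.degradome import map_degradome, validate_interactions
from phasnet.io import read_fasta, read_fastq
from phasnet.phasing import top_phasirnas
from phasnet.targets import identify_triggers, predict_targets


def main() -> None:
    ensure_dirs()
    cfg = get_config()
    tags, hits, mir_loci, phas_loci = load_loci(cfg)
    genome = dict(read_fasta(SIMDATA / "genome.fa"))
    transcripts = read_fasta(SIMDATA / "transcripts.fa")

    triggers = identify_triggers(mir_loci, phas_loci, genome, cfg)
    pd.DataFrame(
        [
            {
                "mirna_id": t.mirna_id, "phas_id": t.phas_id, "penalty": t.penalty,
                "strand": t.strand, "site_start": t.site_start,
                "cleavage": t.cleavage, "in_register": t.in_register,
            }
            for t in triggers
        ]
    ).to_csv(RESULTS / "04_triggers.tsv", sep="\t", index=False)

    srnas = [(l.locus_id, "miRNA", l.mature) for l in mir_loci] + [
        (f"{l.locus_id}|p{i}", "phasiRNA", seq)
        for l in phas_loci
        for i, (seq, _, _, _) in enumerate(top_phasirnas(l, cfg.top_n_phasirna))
    ]
    interactions = predict_targets(srnas, transcripts, cfg)
    pd.DataFrame(
        [
            {
                "srna_id": x.srna_id, "class": x.srna_class, "transcript_id": x.transcript_id,
                "site_start": x.site_start, "site_end": x.site_end,
                "allen_score": x.allen_score, "mfe_ratio": x.mfe_ratio,
                "cleavage": x.cleavage_position, "accepted": x.accepted, "pairing": x.pairing,
            }
            for x in interactions
        ]
    ).to_csv(RESULTS / "04_targets.tsv", sep="\t", index=False)

    deg_reads = [seq for _, seq, _ in read_fastq(SIMDATA / "degradome.fastq")]
    profiles, unmapped = map_degradome(deg_reads, transcripts)
    accepted = [x for x in interactions if x.accepted]
    sites = validate_interactions(accepted, profiles, cfg)
    pd.DataFrame(
        [
            {
                "srna_id": s.srna_id, "class": s.srna_class, "transcript_id": s.transcript_id,
                "position": s.position, "reads": s.reads, "category": s.category,
                "penalty": s.penalty, "validated": s.validated,
            }
            for s in sites
        ]
    ).to_csv(RESULTS / "04_validated_sites.tsv", sep="\t", index=False)

    print(
        f"{len(triggers)} trigger assignments "
        f"({sum(t.in_register for t in triggers)} in-register); "
        f"{len(accepted)}/{len(interactions)} interactions accepted; "
        f"{sum(s.validated for s in sites)} degradome-validated "
        f"({unmapped} degradome reads unmapped)"
    )


if __name__ == "__main__":
    main()
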