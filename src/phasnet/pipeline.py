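"""End-to-end orchestration: tags -> loci -> triggers/targets -> network.

Runs every stage of the analysis on a synthetic dataset (or on externally
prepared tags/hits) and returns all intermediate tables, so drivers, tests
and the acceptance script share one code path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .config import LibraryManifest, RunConfig
from .degradome import DegradomeSite, map_degradome, validate_interactions
from .mirna import MirLocus, call_mir_loci, flag_probably
from .network import ExpressionMatrix, assemble_network, differential, normalize_rp10m
from .phasing import PhasLocus, scan_phas, top_phasirnas
from .preprocess import (
    GenomeHit,
    SequenceTag,
    align_tags,
    clean_reads,
    collapse_reads,
    filter_blacklist,
    filter_multimap,
)
from .simulate import SyntheticDataset
from .targets import TargetInteraction, TriggerAssignment, identify_triggers, predict_targets

log = logging.getLogger("phasnet")


@dataclass
class PipelineResult:
    tags: list[SequenceTag]
    hits: list[GenomeHit]
    mir_loci: list[MirLocus]
    phas_loci: list[PhasLocus]
    triggers: list[TriggerAssignment]
    mirna_targets: list[TargetInteraction]
    phasirna_targets: list[TargetInteraction]
    validated: list[DegradomeSite]
    de_mirna: pd.DataFrame
    de_phas: pd.DataFrame
    de_mrna: pd.DataFrame
    triples: pd.DataFrame
    edges: pd.DataFrame
    expr: ExpressionMatrix


def _dedupe_mir_loci(loci: list[MirLocus]) -> list[MirLocus]:
    """A hairpin is annotated once: the mature and star reads of a genuine
    hairpin also co-align on the opposite strand, so overlapping calls
    sharing a mature sequence collapse to the more abundant (plus-strand
    preferred) one."""
    kept: list[MirLocus] = []
    for locus in sorted(loci, key=lambda l: (l.chrom, l.start, 0 if l.strand == "+" else 1)):
        dup = next(
            (
                k
                for k in kept
                if k.chrom == locus.chrom
                and k.start < locus.end
                and locus.start < k.end
                and {k.mature, k.star} & {locus.mature, locus.star}
            ),
            None,
        )
        if dup is None:
            kept.append(locus)
    return kept


def _feature_counts(
    rows: list[tuple[str, list[str]]],
    tags_by_seq: dict[str, SequenceTag],
    lib_ids: list[str],
) -> pd.DataFrame:
    """Per-library counts for features defined by sets of tag sequences."""
    data = []
    for feature_id, seqs in rows:
        counts = {lib: 0 for lib in lib_ids}
        for seq in seqs:
            tag = tags_by_seq.get(seq)
            if tag is None:
                continue
            for lib, c in tag.counts.items():
                counts[lib] += c
        data.append(pd.Series(counts, name=feature_id))
    if not data:
        return pd.DataFrame(columns=lib_ids)
    return pd.DataFrame(data)[lib_ids]


def run_pipeline(
    dataset: SyntheticDataset,
    config: RunConfig | None = None,
    from_fastq_dir: str | None = None,
) -> PipelineResult:
    """Run every stage on a synthetic dataset.

    With ``from_fastq_dir`` the run starts from the emitted FASTQ files
    (exercising cleaning and collapsing); otherwise tags are built directly
    from the simulated species counts.
    """
    cfg = config or RunConfig()
    genome = dataset.genome
    manifest = dataset.manifest
    lib_ids = [m.library_id for m in manifest]

    if from_fastq_dir is not None:
        from .io import read_fastq

        cleaned = {
            m.library_id: clean_reads(
                read_fastq(f"{from_fastq_dir}/{m.library_id}.fastq"),
                dataset.params.adapter,
                cfg.min_read_len,
                cfg.max_read_len,
            )
            for m in manifest
        }
        tags = collapse_reads(cleaned)
    else:
        tags = dataset.to_tags()
    tags = filter_blacklist(tags, dataset.blacklist)

    hits_all = align_tags(tags, genome, cfg.max_mismatches)
    hits_mir = filter_multimap(hits_all, cfg.max_genome_hits)
    hits_phas = hits_mir if cfg.multimap_filter_phas else hits_all

    known_ref = dataset.known_mirna_reference()
    mir_loci = call_mir_loci(hits_mir, tags, known_ref, cfg)
    mir_loci = _dedupe_mir_loci(mir_loci)

    phas_loci = scan_phas(hits_phas, tags, 21, cfg) + scan_phas(hits_phas, tags, 24, cfg)

    tags_by_seq = {t.sequence: t for t in tags}
    mir_counts = _feature_counts(
        [(l.locus_id, [l.mature]) for l in mir_loci], tags_by_seq, lib_ids
    )
    phas_counts = _feature_counts(
        [(l.locus_id, [p[0] for p in l.phasirnas]) for l in phas_loci], tags_by_seq, lib_ids
    )

    srna_expr = normalize_rp10m(
        pd.concat([mir_counts, phas_counts]) if len(phas_counts) else mir_counts,
        {m.library_id: m.total_clean_reads for m in manifest},
    )
    for locus in mir_loci:
        locus.probably_flag = flag_probably(
            locus, srna_expr.rp10m.loc[locus.locus_id].to_dict(),
            min_rp10m=cfg.min_rp10m, mode=cfg.probably_mode,
        )

    triggers = identify_triggers(mir_loci, phas_loci, genome, cfg)

    transcripts = dataset.transcripts
    mirna_targets = predict_targets(
        [(l.locus_id, "miRNA", l.mature) for l in mir_loci], transcripts, cfg
    )
    phasi_srnas = []
    for locus in phas_loci:
        for i, (seq, pos, abund, strand) in enumerate(top_phasirnas(locus, cfg.top_n_phasirna)):
            phasi_srnas.append((f"{locus.locus_id}|p{i}", "phasiRNA", seq))
    phasirna_targets = predict_targets(phasi_srnas, transcripts, cfg)

    deg_profiles, _ = map_degradome(dataset.simulate_degradome(), transcripts)
    accepted = [t for t in mirna_targets + phasirna_targets if t.accepted]
    validated = validate_interactions(accepted, deg_profiles, cfg)

    de_mirna = differential(mir_counts, manifest, "miRNA", cfg)
    de_phas = differential(phas_counts, manifest, "PHAS", cfg)
    mrna_manifest = [
        LibraryManifest(m.library_id, m.tissue, total_clean_reads=int(dataset.mrna_counts[m.library_id].sum()))
        for m in manifest
    ]
    de_mrna = differential(dataset.mrna_counts, mrna_manifest, "mRNA", cfg)

    phasi_pairs = sorted(
        {
            (t.srna_id.split("|")[0], t.transcript_id)
            for t in phasirna_targets
            if t.accepted
        }
    )
    triples, edges = assemble_network(
        triggers, mirna_targets, phasi_pairs, de_mirna, de_phas, de_mrna, srna_expr, cfg
    )

    return PipelineResult(
        tags, hits_phas, mir_loci, phas_loci, triggers, mirna_targets,
        phasirna_targets, validated, de_mirna, de_phas, de_mrna, triples, edges, srna_expr,
    )
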