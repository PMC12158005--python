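"""Planted-truth recovery metrics for synthetic pipeline runs.

Given a synthetic dataset and a pipeline result, these helpers match
called loci back to planted elements by coordinate overlap and measure
recall/precision, trigger recovery, degradome validation (including the
false-validation rate on decoy interactions) and differential-expression
recovery of the planted fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import LibraryManifest, RunConfig
from .degradome import validate_interactions
from .network import differential
from .pipeline import PipelineResult
from .simulate import SimParams, SyntheticDataset
from .targets import TargetInteraction


def _overlaps(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 < b1 and b0 < a1


def match_mir_loci(dataset: SyntheticDataset, result: PipelineResult) -> dict[str, str | None]:
    """Called MIR locus id -> planted hairpin name (None if no overlap)."""
    out = {}
    for locus in result.mir_loci:
        hit = next(
            (
                mt.name
                for mt in dataset.truth.mirs
                if mt.chrom == locus.chrom and _overlaps(locus.start, locus.end, mt.start, mt.end)
            ),
            None,
        )
        out[locus.locus_id] = hit
    return out


def match_phas_loci(dataset: SyntheticDataset, result: PipelineResult) -> dict[str, str | None]:
    out = {}
    for locus in result.phas_loci:
        hit = next(
            (
                pt.name
                for pt in dataset.truth.phas
                if pt.chrom == locus.chrom
                and pt.period == locus.period
                and _overlaps(locus.start, locus.end, pt.start - pt.period - 2, pt.end)
            ),
            None,
        )
        out[locus.locus_id] = hit
    return out


@dataclass
class RecoveryMetrics:
    n_mir_truth: int
    n_mir_called: int
    mir_recovered: int
    mir_false: int
    n_phas_truth: int
    n_phas_called: int
    phas_recovered: int
    phas_false: int
    trigger_pairs_truth: int
    trigger_pairs_recovered: int  # recovered with in_register = True
    decoy_trigger_assignments: int
    cleaved_truth: int
    cleaved_validated: int
    decoy_sites_tested: int
    decoy_sites_validated: int
    de_planted: int
    de_recovered: int
    model2_triples: list[tuple[str, str, str]]
    model1_triples: int

    @property
    def mir_recall(self) -> float:
        return self.mir_recovered / self.n_mir_truth if self.n_mir_truth else 1.0

    @property
    def mir_precision(self) -> float:
        return 1.0 - self.mir_false / self.n_mir_called if self.n_mir_called else 1.0

    @property
    def phas_recall(self) -> float:
        return self.phas_recovered / self.n_phas_truth if self.n_phas_truth else 1.0

    @property
    def phas_precision(self) -> float:
        return 1.0 - self.phas_false / self.n_phas_called if self.n_phas_called else 1.0


def evaluate_run(
    dataset: SyntheticDataset,
    result: PipelineResult,
    config: RunConfig | None = None,
    decoy_seed: int = 0,
    n_decoy_sites: int = 40,
) -> RecoveryMetrics:
    cfg = config or RunConfig()
    truth = dataset.truth
    mir_map = match_mir_loci(dataset, result)
    phas_map = match_phas_loci(dataset, result)

    mir_recovered = len({v for v in mir_map.values() if v is not None})
    mir_false = sum(1 for v in mir_map.values() if v is None)
    phas_recovered = len({v for v in phas_map.values() if v is not None})
    phas_false = sum(1 for v in phas_map.values() if v is None)

    # trigger recovery: planted (mir, phas) pairs found with in-register cleavage
    truth_pairs = {(pt.trigger, pt.name) for pt in truth.phas if pt.trigger is not None}
    called_pairs = {
        (mir_map.get(t.mirna_id), phas_map.get(t.phas_id))
        for t in result.triggers
        if t.in_register
    }
    pairs_recovered = len(truth_pairs & called_pairs)
    decoy_names = {pt.name for pt in truth.phas if pt.trigger is None}
    decoy_assignments = sum(
        1 for t in result.triggers if phas_map.get(t.phas_id) in decoy_names
    )

    # degradome: every planted cleaved interaction validates
    cleaved = [t for t in truth.targets if t.cleavable]
    validated_positions = {
        (site.transcript_id, site.position)
        for site in result.validated
        if site.validated
    }
    cleaved_validated = sum(
        1
        for t in cleaved
        if any(
            (t.transcript_id, p) in validated_positions
            for p in range(t.cleavage_pos - 1, t.cleavage_pos + 2)
        )
    )

    # decoy validation rate: random sites on transcripts without planted peaks
    from .degradome import map_degradome

    rng = np.random.default_rng([decoy_seed, 0xDEC0])
    cleaved_tx = {t.transcript_id for t in cleaved}
    decoy_tx = [tx for tx in dataset.transcripts if tx[0] not in cleaved_tx]
    profiles, _ = map_degradome(dataset.simulate_degradome(), dataset.transcripts)
    decoys: list[TargetInteraction] = []
    for i in range(n_decoy_sites):
        tx_id, seq = decoy_tx[int(rng.integers(0, len(decoy_tx)))]
        pos = int(rng.integers(5, len(seq) - 5))
        decoys.append(
            TargetInteraction(f"decoy{i}", "miRNA", tx_id, pos - 11, pos + 10, 3.0, 0.9, pos, True, "")
        )
    decoy_sites = validate_interactions(decoys, profiles, cfg)
    decoy_validated = sum(1 for s in decoy_sites if s.validated)

    # differential expression recovery of the planted +/-4 fold changes
    truth_by_name = {mt.name: mt for mt in truth.mirs}
    de_planted = de_recovered = 0
    for locus_id, truth_name in mir_map.items():
        if truth_name is None:
            continue
        fc = truth.mir_fc[truth_name]
        if abs(fc) >= 2:
            de_planted += 1
            if locus_id in result.de_mirna.index and bool(result.de_mirna.loc[locus_id, "passes"]):
                de_recovered += 1
    for tx_id, fc in truth.transcript_fc.items():
        if abs(fc) >= 2:
            de_planted += 1
            if tx_id in result.de_mrna.index and bool(result.de_mrna.loc[tx_id, "passes"]):
                de_recovered += 1

    model2 = []
    model1 = 0
    for _, row in result.triples.iterrows():
        if row.model == 2:
            model2.append(
                (
                    mir_map.get(row.mirna_id),
                    phas_map.get(row.phas_id) if row.phas_id else None,
                    row.mrna_id,
                )
            )
        elif row.model == 1:
            model1 += 1

    return RecoveryMetrics(
        n_mir_truth=len(truth.mirs),
        n_mir_called=len(result.mir_loci),
        mir_recovered=mir_recovered,
        mir_false=mir_false,
        n_phas_truth=len(truth.phas),
        n_phas_called=len(result.phas_loci),
        phas_recovered=phas_recovered,
        phas_false=phas_false,
        trigger_pairs_truth=len(truth_pairs),
        trigger_pairs_recovered=pairs_recovered,
        decoy_trigger_assignments=decoy_assignments,
        cleaved_truth=len(cleaved),
        cleaved_validated=cleaved_validated,
        decoy_sites_tested=len(decoy_sites),
        decoy_sites_validated=decoy_validated,
        de_planted=de_planted,
        de_recovered=de_recovered,
        model2_triples=model2,
        model1_triples=model1,
    )


def run_and_evaluate(seed: int, params: SimParams | None = None, config: RunConfig | None = None):
    """Convenience wrapper: simulate, run the pipeline, measure recovery."""
    from .pipeline import run_pipeline

    ds = SyntheticDataset(params or SimParams.small(), seed)
    res = run_pipeline(ds, config)
    return ds, res, evaluate_run(ds, res, config, decoy_seed=seed)


def fold_change_recovery(
    seed: int,
    n_pairs: int = 25,
    base_mean: float = 100.0,
    log2fc: float = 4.0,
    dispersion: float = 0.1,
    n_per_group: int = 4,
    config: RunConfig | None = None,
) -> float:
    """Fraction of planted +/-4 log2FC miRNA/mRNA pairs passing the
    differential-expression thresholds under negative-binomial counts."""
    cfg = config or RunConfig()
    rng = np.random.default_rng([seed, 0xFC])
    lib_ids = [f"rep{i}" for i in range(n_per_group)] + [f"veg{i}" for i in range(n_per_group)]
    tissues = ["ovule"] * n_per_group + ["leaf"] * n_per_group
    nb_n = 1.0 / dispersion

    def nb(mean, size):
        return rng.negative_binomial(nb_n, nb_n / (nb_n + mean), size=size)

    rows = {}
    for i in range(n_pairs):
        fc_mi = log2fc if i % 2 == 0 else -log2fc
        rep_mean = base_mean * 2 ** (fc_mi / 2)
        veg_mean = base_mean * 2 ** (-fc_mi / 2)
        rows[f"mi{i}"] = np.concatenate([nb(rep_mean, n_per_group), nb(veg_mean, n_per_group)])
        rows[f"mrna{i}"] = np.concatenate([nb(veg_mean, n_per_group), nb(rep_mean, n_per_group)])
    # background features so the library totals are not dominated by the planted set
    for i in range(4 * n_pairs):
        rows[f"bg{i}"] = nb(base_mean, 2 * n_per_group)
    raw = pd.DataFrame(rows).T
    raw.columns = lib_ids
    totals = raw.sum(axis=0)
    manifest = [
        LibraryManifest(lib, tis, total_clean_reads=int(totals[lib]))
        for lib, tis in zip(lib_ids, tissues)
    ]
    mi_rows = raw.loc[[f"mi{i}" for i in range(n_pairs)]]
    mrna_rows = raw.loc[[f"mrna{i}" for i in range(n_pairs)]]
    de_mi = differential(pd.concat([mi_rows, raw.loc[[f"bg{i}" for i in range(4 * n_pairs)]]]),
                         manifest, "miRNA", cfg)
    de_mrna = differential(pd.concat([mrna_rows, raw.loc[[f"bg{i}" for i in range(4 * n_pairs)]]]),
                           manifest, "mRNA", cfg)
    passed = 0
    for i in range(n_pairs):
        ok_mi = f"mi{i}" in de_mi.index and bool(de_mi.loc[f"mi{i}", "passes"])
        ok_mrna = f"mrna{i}" in de_mrna.index and bool(de_mrna.loc[f"mrna{i}", "passes"])
        if ok_mi and ok_mrna:
            passed += 1
    return passed / n_pairs
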