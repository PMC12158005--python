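"""Expression normalization, differential expression and network assembly.

Abundances are normalized to reads per ten million (RP10M). The
reproductive-vs-vegetative contrast uses a pooled exact binomial test with
Benjamini-Hochberg FDR control and the class-specific fold-change
thresholds (|log2FC| >= 2 for miRNAs, >= 1 for PHAS loci, > 1 for mRNAs,
FDR <= 0.05). Regulatory triples (miRNA, PHAS locus, mRNA) are classified
into Model 1 (miRNA-only repression: the PHAS locus is either not
co-regulated or not differentially expressed) or Model 2 (concordant
miRNA + phasiRNA regulation) by sign/magnitude inequalities on the three
log2 fold changes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import LibraryManifest, RunConfig

log = logging.getLogger("phasnet")

RP10M_SCALE = 1e7


@dataclass
class ExpressionMatrix:
    """Raw counts with RP10M and log2(RP10M+1) views (features x libraries)."""

    raw: pd.DataFrame
    library_totals: pd.Series

    def __post_init__(self) -> None:
        if (self.library_totals <= 0).any():
            raise ValueError("library totals must be positive")
        missing = [c for c in self.raw.columns if c not in self.library_totals.index]
        if missing:
            raise ValueError(f"no library total for column(s) {missing}")

    @property
    def rp10m(self) -> pd.DataFrame:
        return self.raw * RP10M_SCALE / self.library_totals[self.raw.columns]

    @property
    def log2(self) -> pd.DataFrame:
        return np.log2(self.rp10m + 1.0)


def normalize_rp10m(raw: pd.DataFrame, library_totals: pd.Series | dict) -> ExpressionMatrix:
    """RP10M[f, l] = raw[f, l] * 1e7 / total[l]."""
    totals = pd.Series(library_totals, dtype=float)
    return ExpressionMatrix(raw, totals)


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise standardization to mean 0, sample (ddof=1) sd 1.

    Constant rows map to all-zero with a warning.
    """
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant row(s) mapped to zero", stacklevel=2)
    sd[sd == 0] = 1.0
    return pd.DataFrame((values - mean) / sd, index=matrix.index, columns=matrix.columns)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up BH adjusted p-values: q_(i) = min_{j>=i} p_(j) * n / j."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


_CLASS_FC_THRESHOLD = {"miRNA": "mirna_fc", "PHAS": "phas_fc", "mRNA": "mrna_fc"}


def differential(
    raw: pd.DataFrame,
    manifest: list[LibraryManifest],
    feature_class: str,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Reproductive-vs-vegetative differential expression.

    Features must show RP10M > 10 in at least one library to be tested.
    log2FC = log2((mean RP10M_rep + 0.5) / (mean RP10M_veg + 0.5)); the
    p-value is a two-sided exact binomial test of the pooled reproductive
    count against the pooled library-size proportion; FDR is
    Benjamini-Hochberg. ``passes`` applies the class thresholds
    (miRNA/PHAS: |log2FC| >= threshold; mRNA: strict >) with FDR <= 0.05.
    """
    cfg = config or RunConfig()
    libs = {m.library_id: m for m in manifest}
    missing = [c for c in raw.columns if c not in libs]
    if missing:
        raise ValueError(f"libraries missing from manifest: {missing}")
    rep_cols = [c for c in raw.columns if libs[c].group == "reproductive"]
    veg_cols = [c for c in raw.columns if libs[c].group == "vegetative"]
    if not rep_cols or not veg_cols:
        raise ValueError("both tissue groups must be represented")
    totals = pd.Series({c: libs[c].total_clean_reads for c in raw.columns}, dtype=float)
    if totals[rep_cols].sum() <= 0 or totals[veg_cols].sum() <= 0:
        raise ValueError("a group has all-zero library totals")
    expr = normalize_rp10m(raw, totals)
    rp10m = expr.rp10m

    tested = rp10m.gt(cfg.min_rp10m).any(axis=1)
    sub = raw.loc[tested]
    mean_rep = rp10m.loc[tested, rep_cols].mean(axis=1)
    mean_veg = rp10m.loc[tested, veg_cols].mean(axis=1)
    log2fc = np.log2((mean_rep + 0.5) / (mean_veg + 0.5))

    p_rep = totals[rep_cols].sum() / totals.sum()
    pvals = []
    for _, row in sub.iterrows():
        x = int(row[rep_cols].sum())
        ntot = x + int(row[veg_cols].sum())
        pvals.append(1.0 if ntot == 0 else sps.binomtest(x, ntot, p_rep).pvalue)
    pvals = np.array(pvals)
    fdr = benjamini_hochberg(pvals) if len(pvals) else np.array([])

    threshold = getattr(cfg, _CLASS_FC_THRESHOLD[feature_class])
    if feature_class == "mRNA":
        fc_ok = np.abs(log2fc.to_numpy()) > threshold
    else:
        fc_ok = np.abs(log2fc.to_numpy()) >= threshold
    result = pd.DataFrame(
        {
            "feature_id": sub.index,
            "class": feature_class,
            "log2fc": log2fc.to_numpy(),
            "p": pvals,
            "fdr": fdr,
            "passes": fc_ok & (fdr <= cfg.fdr),
        }
    ).set_index("feature_id")
    log.info(
        "differential(%s): %d tested, %d pass", feature_class, len(result), int(result.passes.sum())
    )
    return result


def classify_triple(
    log2fc_mi: float,
    log2fc_phas: float | None,
    log2fc_mrna: float,
) -> int:
    """Model label for a (miRNA, PHAS, mRNA) fold-change triple.

    Shared requirement S: log2FC_mi x log2FC_mrna < 0 and |log2FC_mi| > 1
    and |log2FC_mrna| > 1 (miRNA-mediated downregulation). Model 1: S and
    (mi x phas < 0 or |phas| < 1) — the PHAS locus is not concordantly
    regulated. Model 2: S and mi x phas > 0 and |phas| > 1. A missing PHAS
    fold change makes the Model-1 clause vacuously true. Returns 1, 2 or 0
    (no model); all inequalities strict.
    """
    s = (log2fc_mi * log2fc_mrna < 0) and abs(log2fc_mi) > 1 and abs(log2fc_mrna) > 1
    if not s:
        return 0
    if log2fc_phas is None:
        return 1
    if log2fc_mi * log2fc_phas < 0 or abs(log2fc_phas) < 1:
        return 1
    if log2fc_mi * log2fc_phas > 0 and abs(log2fc_phas) > 1:
        return 2
    return 0


def correlation_edges(
    expr: ExpressionMatrix,
    pairs: list[tuple[str, str]],
    r_min: float = 0.7,
    method: str = "pearson",
) -> list[tuple[str, str, float]]:
    """Keep pairs with correlation r > r_min (strict) on log2(RP10M+1)
    profiles across all libraries; constant profiles are dropped with a
    warning."""
    logm = expr.log2
    kept: list[tuple[str, str, float]] = []
    for a, b in pairs:
        if a not in logm.index or b not in logm.index:
            raise ValueError(f"pair ({a}, {b}) references unknown feature(s)")
        x = logm.loc[a].to_numpy()
        y = logm.loc[b].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(f"constant profile in pair ({a}, {b}); dropped", stacklevel=2)
            continue
        if method == "pearson":
            r = float(np.corrcoef(x, y)[0, 1])
        elif method == "spearman":
            r = float(sps.spearmanr(x, y).statistic)
        else:
            raise ValueError(f"unknown correlation method {method!r}")
        if r > r_min:
            kept.append((a, b, r))
    return kept


@dataclass
class RegulatoryTriple:
    mirna_id: str
    phas_id: str | None
    mrna_id: str
    log2fc_mi: float
    log2fc_phas: float | None
    log2fc_mrna: float
    r: float | None
    model: int  # 1, 2 or 0


def assemble_network(
    triggers,
    mirna_targets,
    phasirna_targets: list[tuple[str, str]],
    de_mirna: pd.DataFrame,
    de_phas: pd.DataFrame,
    de_mrna: pd.DataFrame,
    expr: ExpressionMatrix | None = None,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join trigger and target tables into classified regulatory triples.

    Triples are (miRNA, PHAS, mRNA) where the miRNA triggers the PHAS locus
    and either the miRNA targets the mRNA or one of the locus's phasiRNAs
    does (``phasirna_targets`` maps PHAS locus id -> mRNA id); miRNAs with
    no trigger contribute (miRNA, none, mRNA) rows. Fold changes are mapped
    on and :func:`classify_triple` applied. The edge table carries
    miRNA->mRNA edges (negative regulation) and miRNA->PHAS trigger edges,
    the latter filtered by expression correlation r > 0.7 when an
    expression matrix is supplied.
    """
    cfg = config or RunConfig()
    fc_mi = de_mirna["log2fc"].to_dict()
    fc_phas = de_phas["log2fc"].to_dict()
    fc_mrna = de_mrna["log2fc"].to_dict()

    triggers_by_mirna: dict[str, list] = {}
    for t in triggers:
        triggers_by_mirna.setdefault(t.mirna_id, []).append(t)

    dangling: list[str] = []
    rows: list[RegulatoryTriple] = []
    seen: set[tuple] = set()

    def lookup(table: dict, key: str, kind: str) -> float | None:
        if key not in table:
            dangling.append(f"{kind}:{key}")
            return None
        return table[key]

    mirna_of_phas = {t.phas_id: t.mirna_id for t in triggers}
    candidate_triples: list[tuple[str, str | None, str]] = []
    for inter in mirna_targets:
        if not inter.accepted:
            continue
        trig = triggers_by_mirna.get(inter.srna_id)
        if trig:
            for t in trig:
                candidate_triples.append((inter.srna_id, t.phas_id, inter.transcript_id))
        else:
            candidate_triples.append((inter.srna_id, None, inter.transcript_id))
    for phas_id, mrna_id in phasirna_targets:
        mi = mirna_of_phas.get(phas_id)
        if mi is None:
            continue  # trigger-less locus: no triple can be formed
        candidate_triples.append((mi, phas_id, mrna_id))

    for mi, phas, mrna in candidate_triples:
        key = (mi, phas, mrna)
        if key in seen:
            continue
        seen.add(key)
        fmi = lookup(fc_mi, mi, "miRNA")
        fmrna = lookup(fc_mrna, mrna, "mRNA")
        fphas = lookup(fc_phas, phas, "PHAS") if phas is not None else None
        if dangling:
            continue
        model = classify_triple(fmi, fphas, fmrna)
        rows.append(RegulatoryTriple(mi, phas, mrna, fmi, fphas, fmrna, None, model))
    if dangling:
        raise ValueError(f"dangling feature ids in network assembly: {sorted(set(dangling))}")

    triples = pd.DataFrame(
        [
            {
                "mirna_id": t.mirna_id,
                "phas_id": t.phas_id if t.phas_id is not None else "",
                "mrna_id": t.mrna_id,
                "log2fc_mi": t.log2fc_mi,
                "log2fc_phas": t.log2fc_phas if t.log2fc_phas is not None else np.nan,
                "log2fc_mrna": t.log2fc_mrna,
                "model": t.model,
            }
            for t in rows
        ]
    )

    edges: list[dict] = []
    for inter in mirna_targets:
        if inter.accepted:
            edges.append(
                {
                    "source": inter.srna_id,
                    "target": inter.transcript_id,
                    "edge_type": "miRNA->mRNA",
                    "sign": "negative",
                    "r": np.nan,
                }
            )
    trigger_pairs = sorted({(t.mirna_id, t.phas_id) for t in triggers})
    if expr is not None:
        present = [
            (a, b) for a, b in trigger_pairs if a in expr.raw.index and b in expr.raw.index
        ]
        kept = correlation_edges(expr, present, cfg.r_min, cfg.correlation_method)
        for a, b, r in kept:
            edges.append(
                {"source": a, "target": b, "edge_type": "miRNA->PHAS", "sign": "positive", "r": r}
            )
    else:
        for a, b in trigger_pairs:
            edges.append(
                {"source": a, "target": b, "edge_type": "miRNA->PHAS", "sign": "positive", "r": np.nan}
            )
    edge_df = pd.DataFrame(edges, columns=["source", "target", "edge_type", "sign", "r"])
    log.info(
        "assemble_network: %d triples (%d model 1, %d model 2), %d edges",
        len(triples),
        int((triples.model == 1).sum()) if len(triples) else 0,
        int((triples.model == 2).sum()) if len(triples) else 0,
        len(edge_df),
    )
    return triples, edge_df
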