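"""Synthetic dataset generator with machine-readable planted ground truth.

The generator emulates the statistical structure of a multi-tissue plant
small-RNA study: a random genome carrying planted MIR hairpins (mature +
loop + star with the 2-nt 3' overhang duplex register), 21-/24-nt phased
loci whose register is set by a planted trigger-complementary site,
transcripts bearing target sites of known penalty, degradome 5'-end
pileups peaked at cleavage positions, and negative-binomially dispersed
per-library counts encoding planted reproductive-vs-vegetative fold
changes. Every planted element is recorded in a JSON-serializable truth
table so downstream recovery is measurable without any external data.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import LibraryManifest, RunConfig
from .seqs import random_seq, revcomp

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


# ---------------------------------------------------------------------------
# parameters

@dataclass
class SimParams:
    """Generator defaults: the study conditions every test runs under."""

    genome_length: int = 50_000
    gc: float = 0.42
    chrom: str = "chr1"
    # MIR loci
    n_mir: int = 6
    n_known_mir: int = 3
    mature_len: int = 21
    mir_loop: int = 60
    mature_mean: float = 300.0
    star_mean: float = 60.0
    hairpin_other_mean: float = 8.0
    # PHAS loci (one 21-nt locus is left trigger-less as a decoy)
    n_phas21: int = 6
    n_phas24: int = 2
    phas_cycles: int = 12
    phasirna_mean: float = 60.0
    minus_strand_fraction: float = 0.4
    offregister_mean: float = 6.0
    # transcripts / mRNA expression
    n_transcripts: int = 12
    transcript_length: int = 800
    mrna_mean: float = 300.0
    # background: a modest pool of recurrent degradation-product species
    # (collapsed background tags recur across libraries in real data)
    n_noise_species: int = 400
    noise_mean: float = 30.0
    noise_len_range: tuple[int, int] = (18, 26)
    n_contaminant_species: int = 20
    contaminant_mean: float = 5.0
    # counts / libraries
    dispersion: float = 0.1
    n_rep_libraries: int = 4
    n_veg_libraries: int = 4
    # degradome
    degradome_peak: int = 30
    degradome_background: int = 300
    degradome_read_len: int = 25
    # reads
    read_length: int = 50
    adapter: str = DEFAULT_ADAPTER

    @classmethod
    def small(cls) -> "SimParams":
        """Reduced problem size for repeated multi-seed recovery runs."""
        return cls(
            genome_length=14_000,
            n_mir=4,
            n_known_mir=1,
            n_phas21=2,
            n_phas24=1,
            n_transcripts=8,
            transcript_length=600,
            n_noise_species=60,
            noise_mean=15.0,
            n_contaminant_species=8,
            mature_mean=150.0,
            star_mean=30.0,
            phasirna_mean=40.0,
            n_rep_libraries=3,
            n_veg_libraries=3,
            degradome_background=150,
        )


# ---------------------------------------------------------------------------
# truth records

@dataclass
class MirTruth:
    name: str
    chrom: str
    start: int
    end: int
    mature: str
    mature_start: int
    star: str
    star_start: int
    known: bool
    ref_name: str | None
    log2fc: float


@dataclass
class PhasTruth:
    name: str
    chrom: str
    start: int  # first in-register position (the planted cleavage site)
    end: int
    period: int
    cycles: int
    register: int
    trigger: str | None  # MirTruth.name
    log2fc: float


@dataclass
class TargetTruth:
    srna_kind: str  # "miRNA" or "phasiRNA"
    srna_name: str  # MirTruth.name or "<phas>:cycle<j>"
    srna_seq: str
    transcript_id: str
    site_start: int
    cleavage_pos: int
    cleavable: bool


@dataclass
class TruthTable:
    seed: int
    params: SimParams
    mirs: list[MirTruth] = field(default_factory=list)
    phas: list[PhasTruth] = field(default_factory=list)
    targets: list[TargetTruth] = field(default_factory=list)
    mir_fc: dict[str, float] = field(default_factory=dict)
    phas_fc: dict[str, float] = field(default_factory=dict)
    transcript_fc: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["params"]["noise_len_range"] = list(self.params.noise_len_range)
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TruthTable":
        d = json.loads(text)
        params = d.pop("params")
        params["noise_len_range"] = tuple(params["noise_len_range"])
        return cls(
            seed=d["seed"],
            params=SimParams(**params),
            mirs=[MirTruth(**m) for m in d["mirs"]],
            phas=[PhasTruth(**p) for p in d["phas"]],
            targets=[TargetTruth(**t) for t in d["targets"]],
            mir_fc=d["mir_fc"],
            phas_fc=d["phas_fc"],
            transcript_fc=d["transcript_fc"],
        )


# ---------------------------------------------------------------------------
# genome construction primitives

class GenomeBuilder:
    """Mutable genome with overlap-checked planting."""

    def __init__(self, length: int, gc: float, rng: np.random.Generator, chrom: str = "chr1"):
        if length <= 0:
            raise ValueError("genome length must be positive")
        self.chrom = chrom
        self.seq = list(random_seq(rng, length, gc))
        self.occupied: list[tuple[int, int]] = []

    def __len__(self) -> int:
        return len(self.seq)

    def _claim(self, start: int, end: int) -> None:
        if start < 0 or end > len(self.seq):
            raise ValueError("planted element outside genome bounds")
        for s, e in self.occupied:
            if start < e and s < end:
                raise ValueError(f"planted elements overlap: [{start},{end}) vs [{s},{e})")
        self.occupied.append((start, end))

    def write(self, start: int, fragment: str) -> None:
        self.seq[start : start + len(fragment)] = list(fragment)

    def slice(self, start: int, end: int) -> str:
        return "".join(self.seq[start:end])

    def as_fasta(self) -> dict[str, str]:
        return {self.chrom: "".join(self.seq)}


def make_genome(length: int, gc: float, seed: int, chrom: str = "chr1") -> dict[str, str]:
    """I.i.d. background genome, deterministic per seed."""
    rng = np.random.default_rng(seed)
    return GenomeBuilder(length, gc, rng, chrom).as_fasta()


def make_star(mature: str, rng: np.random.Generator) -> str:
    """Star strand pairing the mature under the 2-nt 3' overhang register:
    star[j] complements mature[K-3-j], with two free 3' bases."""
    core = revcomp(mature[:-2])
    tail = random_seq(rng, 2, 0.5)
    return core + tail


def plant_mir(
    builder: GenomeBuilder,
    position: int,
    mature: str,
    star_gap: int,
    rng: np.random.Generator,
    arm: str = "5p",
    name: str = "MIR",
) -> MirTruth:
    """Insert mature + loop + star so the duplex criteria hold by construction.

    ``star_gap`` is the loop length between the two reads and must lie in
    the legal 5-300 nt spacing window.
    """
    if not 5 <= star_gap <= 300:
        raise ValueError(f"star gap {star_gap} outside the legal 5-300 nt spacing")
    if arm not in ("5p", "3p"):
        raise ValueError("arm must be '5p' or '3p'")
    star = make_star(mature, rng)
    L, K = len(mature), len(star)
    total = L + star_gap + K
    builder._claim(position, position + total)
    loop = random_seq(rng, star_gap, 0.5)
    if arm == "5p":
        builder.write(position, mature + loop + star)
        mature_start = position
        star_start = position + L + star_gap
    else:
        builder.write(position, star + loop + mature)
        star_start = position
        mature_start = position + K + star_gap
    return MirTruth(
        name, builder.chrom, position, position + total,
        mature, mature_start, star, star_start, False, None, 0.0,
    )


def plant_phas(
    builder: GenomeBuilder,
    cleavage: int,
    period: int,
    cycles: int,
    trigger_mature: str | None,
    name: str = "PHAS",
) -> PhasTruth:
    """Plant a phased locus whose register is set by the trigger cleavage.

    When a trigger is given, its perfect-complement site is written so that
    the base opposite sRNA positions 10-11 is ``cleavage``, i.e. register 0
    of the phased run begins exactly at the cleavage coordinate.
    """
    if cycles < 3:
        raise ValueError("cycles must be >= 3")
    end = cleavage + cycles * period
    L = len(trigger_mature) if trigger_mature else 0
    start_claim = cleavage - (L - 10) - 1 if trigger_mature else cleavage
    builder._claim(max(0, start_claim - period - 1), end)
    if trigger_mature:
        site = revcomp(trigger_mature)
        site_start = cleavage - (L - 10)  # cleavage = site_start + L - 10
        builder.write(site_start, site)
    return PhasTruth(
        name, builder.chrom, cleavage, end, period, cycles,
        cleavage % period, None, 0.0,
    )


# ---------------------------------------------------------------------------
# the orchestrated dataset

@dataclass
class Species:
    """One distinct sRNA sequence with a per-group expected abundance."""

    sequence: str
    mean: float
    log2fc: float
    kind: str  # mature/star/hairpin/phasirna/offregister/noise/contaminant
    feature: str | None = None  # owning truth feature name


class SyntheticDataset:
    """A complete synthetic study: genome, libraries, transcripts,
    degradome and truth."""

    def __init__(self, params: SimParams, seed: int):
        self.params = params
        self.seed = int(seed)
        self.rng = np.random.default_rng([self.seed, 0xBEE5])
        self.truth = TruthTable(seed=self.seed, params=params)
        self.manifest: list[LibraryManifest] = []
        self.species: list[Species] = []
        self._build()

    # -- construction ------------------------------------------------------

    def _layout(self, sizes: list[int], margin: int = 700) -> list[int]:
        """Sequential element placement with randomized spacing."""
        p = self.params
        total = sum(sizes) + margin * (len(sizes) + 1)
        if total > p.genome_length:
            raise ValueError(
                f"genome of {p.genome_length} bp too small for {len(sizes)} elements"
            )
        slack = p.genome_length - total
        gaps = self.rng.multinomial(slack, [1 / (len(sizes) + 1)] * (len(sizes) + 1))
        positions = []
        cursor = margin + int(gaps[0])
        for size, extra in zip(sizes, gaps[1:]):
            positions.append(cursor)
            cursor += size + margin + int(extra)
        return positions

    def _build(self) -> None:
        p, rng = self.params, self.rng
        self.builder = GenomeBuilder(p.genome_length, p.gc, rng, p.chrom)

        mir_size = p.mature_len * 2 + p.mir_loop
        phas_sizes = [40 + p.phas_cycles * 21] * p.n_phas21 + [40 + p.phas_cycles * 24] * p.n_phas24
        layout = self._layout([mir_size] * p.n_mir + phas_sizes)
        mir_pos = layout[: p.n_mir]
        phas_pos = layout[p.n_mir :]

        known_names = ["miR390a", "miR159a", "miR167a", "miR396a", "miR482a", "miR171a"]
        mir_fcs = self._mir_fold_changes()
        for i, pos in enumerate(mir_pos):
            mature = random_seq(rng, p.mature_len, 0.5)
            mt = plant_mir(self.builder, pos, mature, p.mir_loop, rng, name=f"mir{i}")
            if i < p.n_known_mir:
                mt.known = True
                mt.ref_name = known_names[i % len(known_names)]
            mt.log2fc = mir_fcs[i]
            self.truth.mirs.append(mt)
            self.truth.mir_fc[mt.name] = mt.log2fc

        phas_fcs = self._phas_fold_changes()
        trigger_of = self._trigger_plan()
        for j, pos in enumerate(phas_pos):
            period = 21 if j < p.n_phas21 else 24
            trig_idx = trigger_of[j]
            trig_seq = self.truth.mirs[trig_idx].mature if trig_idx is not None else None
            cleavage = pos + 30  # leave room for the trigger site upstream
            pt = plant_phas(
                self.builder, cleavage, period, p.phas_cycles, trig_seq, name=f"phas{j}"
            )
            pt.trigger = self.truth.mirs[trig_idx].name if trig_idx is not None else None
            pt.log2fc = phas_fcs[j]
            self.truth.phas.append(pt)
            self.truth.phas_fc[pt.name] = pt.log2fc

        self._build_transcripts()
        self._build_species()
        self._build_blacklist()  # adds contaminant species; must precede counts
        self._build_manifest_and_counts()
        self._build_mrna_counts()

    def _mir_fold_changes(self) -> list[float]:
        # mir0: Model-2 trigger; mir1: Model-1 (discordant PHAS); mir2:
        # Model-1 (no trigger); the rest are not differentially expressed.
        fcs = [0.0] * self.params.n_mir
        for i in range(min(3, self.params.n_mir)):
            fcs[i] = 4.0
        return fcs

    def _phas_fold_changes(self) -> list[float]:
        fcs = [0.0] * (self.params.n_phas21 + self.params.n_phas24)
        fcs[0] = 2.0  # concordant with its +4 trigger -> Model 2
        if len(fcs) > 1:
            fcs[1] = -2.0  # discordant -> Model 1
        return fcs

    def _trigger_plan(self) -> list[int | None]:
        """PHAS index -> MIR index.

        The last 21-nt locus is a trigger-less decoy and mir2 (the
        trigger-free Model-1 miRNA) is never used. 24-nt loci draw their
        triggers from the non-differentially-expressed miRNAs where
        possible, so the trigger's own reads (which map onto the cleavage
        site) do not dominate the locus's 24-nt length profile.
        """
        p = self.params
        fcs = self._mir_fold_changes()
        n_phas = p.n_phas21 + p.n_phas24
        allowed = [i for i in range(p.n_mir) if i != 2]
        flat = [i for i in allowed if fcs[i] == 0.0] or allowed
        plan: list[int | None] = []
        for j in range(n_phas):
            if j == p.n_phas21 - 1:
                plan.append(None)  # decoy
            elif j == 0:
                plan.append(0)
            elif j == 1 and p.n_mir > 1:
                plan.append(1)
            elif j >= p.n_phas21:
                plan.append(flat[j % len(flat)])
            else:
                plan.append(allowed[j % len(allowed)])
        return plan

    def phasirna_seq(self, phas: PhasTruth, cycle: int, strand: str = "+") -> str:
        """Sequence of the in-register phasiRNA of the given cycle."""
        c = phas.start + cycle * phas.period
        if strand == "+":
            return self.builder.slice(c, c + phas.period)
        start = c - phas.period - 1
        return revcomp(self.builder.slice(start, start + phas.period))

    def _build_transcripts(self) -> None:
        p, rng = self.params, self.rng
        self.transcripts: list[tuple[str, str]] = []
        fc_by_tx: dict[str, float] = {}
        for t in range(p.n_transcripts):
            tx_id = f"tx{t:02d}"
            self.transcripts.append((tx_id, random_seq(rng, p.transcript_length, 0.45)))
            fc_by_tx[tx_id] = 0.0

        def plant_site(tx_index: int, srna_seq: str, srna_kind: str, srna_name: str, cleavable: bool):
            tx_id, seq = self.transcripts[tx_index]
            L = len(srna_seq)
            pos = int(rng.integers(60, len(seq) - L - 60))
            site = revcomp(srna_seq)
            new_seq = seq[:pos] + site + seq[pos + L :]
            self.transcripts[tx_index] = (tx_id, new_seq)
            self.truth.targets.append(
                TargetTruth(srna_kind, srna_name, srna_seq, tx_id, pos, pos + L - 10, cleavable)
            )

        # tx0: CHS-like, targeted by a phasiRNA of phas0 (the Model-2 route)
        phas0 = self.truth.phas[0]
        phasi_seq = self.phasirna_seq(phas0, 2)
        plant_site(0, phasi_seq, "phasiRNA", f"{phas0.name}:cycle2", cleavable=True)
        fc_by_tx["tx00"] = -4.0
        # tx1: targeted by mir1 (Model 1 via discordant PHAS)
        if p.n_mir > 1:
            plant_site(1, self.truth.mirs[1].mature, "miRNA", self.truth.mirs[1].name, True)
            fc_by_tx["tx01"] = -4.0
        # tx2: targeted by mir2 (Model 1, no trigger)
        if p.n_mir > 2:
            plant_site(2, self.truth.mirs[2].mature, "miRNA", self.truth.mirs[2].name, True)
            fc_by_tx["tx02"] = -4.0
        self.truth.transcript_fc = fc_by_tx

    def _build_species(self) -> None:
        p, rng = self.params, self.rng
        species = self.species
        for mt in self.truth.mirs:
            species.append(Species(mt.mature, p.mature_mean, mt.log2fc, "mature", mt.name))
            species.append(Species(mt.star, p.star_mean, mt.log2fc, "star", mt.name))
            # low-abundance loop fragments keep the 75% duplex rule honest
            loop_mid = mt.mature_start + len(mt.mature) + 10
            for off in (0, 12):
                frag = self.builder.slice(loop_mid + off, loop_mid + off + 21)
                species.append(Species(frag, p.hairpin_other_mean, mt.log2fc, "hairpin", mt.name))
        for pt in self.truth.phas:
            plus_mean = p.phasirna_mean * (1 - p.minus_strand_fraction)
            minus_mean = p.phasirna_mean * p.minus_strand_fraction
            for j in range(pt.cycles):
                species.append(
                    Species(self.phasirna_seq(pt, j, "+"), plus_mean, pt.log2fc, "phasirna", pt.name)
                )
                if j >= 1:
                    species.append(
                        Species(self.phasirna_seq(pt, j, "-"), minus_mean, pt.log2fc, "phasirna", pt.name)
                    )
            off_start = pt.start + 7
            species.append(
                Species(
                    self.builder.slice(off_start, off_start + pt.period),
                    p.offregister_mean, pt.log2fc, "offregister", pt.name,
                )
            )
        glen = len(self.builder)
        for _ in range(p.n_noise_species):
            L = int(rng.integers(p.noise_len_range[0], p.noise_len_range[1] + 1))
            pos = int(rng.integers(0, glen - L))
            seq = self.builder.slice(pos, pos + L)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            species.append(Species(seq, p.noise_mean, 0.0, "noise"))

    def _build_blacklist(self) -> None:
        """rRNA/tRNA-like contaminant references plus matching read species."""
        p, rng = self.params, self.rng
        self.blacklist = [
            (f"rRNA_{i}", random_seq(rng, 120, 0.55)) for i in range(3)
        ] + [(f"tRNA_{i}", random_seq(rng, 80, 0.5)) for i in range(2)]
        for _ in range(p.n_contaminant_species):
            ref = self.blacklist[int(rng.integers(0, len(self.blacklist)))][1]
            L = int(rng.integers(18, 25))
            pos = int(rng.integers(0, len(ref) - L))
            self.species.append(Species(ref[pos : pos + L], p.contaminant_mean, 0.0, "contaminant"))

    def _group_mean(self, sp: Species, group: str) -> float:
        factor = 2.0 ** (sp.log2fc / 2) if group == "reproductive" else 2.0 ** (-sp.log2fc / 2)
        return sp.mean * factor

    def _nb(self, mean: float, size: int) -> np.ndarray:
        if mean <= 0:
            return np.zeros(size, dtype=int)
        n = 1.0 / self.params.dispersion
        return self.rng.negative_binomial(n, n / (n + mean), size=size)

    def _build_manifest_and_counts(self) -> None:
        p = self.params
        rep_tissues = ["ovule", "embryo", "FB", "MB", "OS", "MS"]
        veg_tissues = ["leaf", "cambium"]
        libs = [
            (f"rep_{rep_tissues[i % len(rep_tissues)]}_{i + 1}", rep_tissues[i % len(rep_tissues)])
            for i in range(p.n_rep_libraries)
        ] + [
            (f"veg_{veg_tissues[i % len(veg_tissues)]}_{i + 1}", veg_tissues[i % len(veg_tissues)])
            for i in range(p.n_veg_libraries)
        ]
        lib_ids = [l[0] for l in libs]
        counts = np.zeros((len(self.species), len(libs)), dtype=int)
        for si, sp in enumerate(self.species):
            for gi, (lib_id, tissue) in enumerate(libs):
                group = "reproductive" if lib_id.startswith("rep") else "vegetative"
                counts[si, gi] = self._nb(self._group_mean(sp, group), 1)[0]
        # every species needs at least one read somewhere to exist at all
        empty = counts.sum(axis=1) == 0
        counts[empty, 0] += 1
        self.species_counts = pd.DataFrame(
            counts, columns=lib_ids, index=[f"sp{i}" for i in range(len(self.species))]
        )
        totals = self.species_counts.sum(axis=0)
        self.manifest = [
            LibraryManifest(lib_id, tissue, total_clean_reads=max(1, int(totals[lib_id])))
            for lib_id, tissue in libs
        ]

    def _build_mrna_counts(self) -> None:
        p = self.params
        lib_ids = [m.library_id for m in self.manifest]
        rows = []
        for tx_id, _ in self.transcripts:
            fc = self.truth.transcript_fc[tx_id]
            row = []
            for m in self.manifest:
                factor = 2.0 ** (fc / 2) if m.group == "reproductive" else 2.0 ** (-fc / 2)
                row.append(int(self._nb(p.mrna_mean * factor, 1)[0]))
            rows.append(row)
        self.mrna_counts = pd.DataFrame(rows, index=[t[0] for t in self.transcripts], columns=lib_ids)
        self.mrna_counts += 1  # transcripts are never entirely unexpressed

    # -- outputs -----------------------------------------------------------

    @property
    def genome(self) -> dict[str, str]:
        return self.builder.as_fasta()

    def known_mirna_reference(self) -> list[tuple[str, str]]:
        return [(mt.ref_name, mt.mature) for mt in self.truth.mirs if mt.known]

    def to_tags(self):
        """Collapsed tags straight from the species counts (the fast path
        bypassing FASTQ emission)."""
        from .preprocess import collapse_reads

        reads_per_lib: dict[str, list[str]] = {m.library_id: [] for m in self.manifest}
        for si, sp in enumerate(self.species):
            row = self.species_counts.iloc[si]
            for lib_id in reads_per_lib:
                reads_per_lib[lib_id].extend([sp.sequence] * int(row[lib_id]))
        return collapse_reads(reads_per_lib)

    def library_reads(self, lib_id: str) -> list[str]:
        """Full-length sequencer reads (insert + 3' adapter, padded to the
        read length) for one library."""
        p = self.params
        reads = []
        for si, sp in enumerate(self.species):
            n = int(self.species_counts.iloc[si][lib_id])
            if n:
                raw = (sp.sequence + p.adapter + "A" * p.read_length)[: p.read_length]
                reads.extend([raw] * n)
        return reads

    def simulate_degradome(self) -> list[str]:
        """Degradome reads: peaks at planted cleavage sites over a uniform
        background of single reads."""
        p, rng = self.params, self.rng
        seqs = dict(self.transcripts)
        reads: list[str] = []
        for tt in self.truth.targets:
            if not tt.cleavable:
                continue
            seq = seqs[tt.transcript_id]
            frag = seq[tt.cleavage_pos : tt.cleavage_pos + p.degradome_read_len]
            if len(frag) >= 18:
                reads.extend([frag] * p.degradome_peak)
        for _ in range(p.degradome_background):
            tx_id, seq = self.transcripts[int(rng.integers(0, len(self.transcripts)))]
            pos = int(rng.integers(0, len(seq) - p.degradome_read_len))
            reads.append(seq[pos : pos + p.degradome_read_len])
        return reads

    def write_all(self, outdir: str | Path) -> dict[str, Path]:
        """Emit genome, transcripts, reference, blacklist, FASTQ libraries,
        degradome, manifest, count tables and the truth table."""
        from .config import write_manifest
        from .io import write_count_table, write_fasta, write_fastq

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        write_fasta([(self.params.chrom, self.genome[self.params.chrom])], out / "genome.fa")
        write_fasta(self.transcripts, out / "transcripts.fa")
        write_fasta(self.known_mirna_reference(), out / "known_mirnas.fa")
        write_fasta(self.blacklist, out / "blacklist.fa")
        for m in self.manifest:
            reads = self.library_reads(m.library_id)
            write_fastq(
                [(f"{m.library_id}_r{i}", s) for i, s in enumerate(reads)],
                out / f"{m.library_id}.fastq",
            )
        write_fastq(
            [(f"deg_r{i}", s) for i, s in enumerate(self.simulate_degradome())],
            out / "degradome.fastq",
        )
        write_manifest(self.manifest, out / "manifest.tsv")
        write_count_table(self.species_counts, out / "srna_species_counts.tsv")
        write_count_table(self.mrna_counts, out / "mrna_counts.tsv")
        (out / "truth.json").write_text(self.truth.to_json())
        paths = {p.stem: p for p in out.iterdir()}
        return paths


def simulate_libraries(dataset: SyntheticDataset) -> dict[str, list[str]]:
    """Per-library raw reads (adapter-bearing), keyed by library id."""
    return {m.library_id: dataset.library_reads(m.library_id) for m in dataset.manifest}
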