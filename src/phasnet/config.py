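"""Run configuration and library manifests.

Every numeric cut-off of the pipeline lives in :class:`RunConfig` with its
published default; operations read thresholds from the config rather than
hard-coding them, so the cut-offs are data, not code.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

#: Fixed tissue -> group assignment used for the reproductive-vs-vegetative
#: contrast (FB/OS = female/ovulate flower structures, MB/MS = male).
TISSUE_GROUPS = {
    "ovule": "reproductive",
    "embryo": "reproductive",
    "FB": "reproductive",
    "OS": "reproductive",
    "MB": "reproductive",
    "MS": "reproductive",
    "leaf": "vegetative",
    "cambium": "vegetative",
}


@dataclass(frozen=True)
class LibraryManifest:
    """One sequencing library: id, tissue, source path and clean-read total."""

    library_id: str
    tissue: str
    path: str = ""
    total_clean_reads: int = 1

    def __post_init__(self) -> None:
        if self.tissue not in TISSUE_GROUPS:
            raise ValueError(
                f"unknown tissue {self.tissue!r}; expected one of {sorted(TISSUE_GROUPS)}"
            )
        if self.total_clean_reads <= 0:
            raise ValueError("total_clean_reads must be positive")

    @property
    def group(self) -> str:
        return TISSUE_GROUPS[self.tissue]


def read_manifest(path: str | Path) -> list[LibraryManifest]:
    """Read a tab-separated manifest (library_id, tissue, path, total_clean_reads)."""
    out: list[LibraryManifest] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "library_id":  # header
                continue
            lib_id, tissue = fields[0], fields[1]
            p = fields[2] if len(fields) > 2 else ""
            total = int(fields[3]) if len(fields) > 3 else 1
            if lib_id in seen:
                raise ValueError(f"duplicate library_id {lib_id!r} in manifest")
            seen.add(lib_id)
            out.append(LibraryManifest(lib_id, tissue, p, total))
    return out


def write_manifest(libs: list[LibraryManifest], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("library_id\ttissue\tpath\ttotal_clean_reads\n")
        for lib in libs:
            fh.write(f"{lib.library_id}\t{lib.tissue}\t{lib.path}\t{lib.total_clean_reads}\n")


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline (published defaults).

    Lengths are nucleotides, abundances are read counts or RP10M, and the
    fold-change thresholds are on log2 scale.
    """

    # read cleaning / alignment
    min_read_len: int = 18
    max_read_len: int = 34
    max_mismatches: int = 2
    max_genome_hits: int = 20
    # MIR locus criteria
    duplex_fraction: float = 0.75
    mature_len: tuple[int, int] = (20, 22)
    star_spacing: tuple[int, int] = (5, 300)
    max_unpaired_duplex: int = 5
    isomir_tolerance: int = 1
    candidate_gap: int = 200
    min_rp10m: float = 10.0
    probably_mode: str = "all"  # "all": flag iff RP10M<10 in every library
    # PHAS locus criteria
    phas_min_len: int = 100
    phas_pmax: float = 0.001
    phas_min_score: float = 10.0
    phas_min_phased_frac: float = 0.30
    phas_cycles: int = 11
    position_model: str = "all"  # "all" or "grid" (strand-merged)
    multimap_filter_phas: bool = True  # apply the <=20-hit filter before PHAS scan too
    # trigger identification
    trigger_window: int = 400  # total added flank (split across both sides)
    trigger_max_penalty: float = 5.0
    # target prediction
    allen_max: float = 7.0
    mfe_ratio_min: float = 0.65
    top_n_phasirna: int = 30
    # degradome validation
    degradome_max_category: int = 3
    degradome_max_penalty: float = 6.0
    degradome_slop: int = 1
    # differential expression / network
    mirna_fc: float = 2.0
    phas_fc: float = 1.0
    mrna_fc: float = 1.0
    fdr: float = 0.05
    r_min: float = 0.7
    correlation_method: str = "pearson"
    random_seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mature_len"] = list(self.mature_len)
        d["star_spacing"] = list(self.star_spacing)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        if "mature_len" in kwargs:
            kwargs["mature_len"] = tuple(kwargs["mature_len"])
        if "star_spacing" in kwargs:
            kwargs["star_spacing"] = tuple(kwargs["star_spacing"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
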