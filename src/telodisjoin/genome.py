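"""Toy two-species reference genomes and coordinate/feature bookkeeping.

The target genome is a small fission-yeast-like assembly whose chromosome
ends carry, from the tip inward, a telomeric repeat array, a series of
sub-telomeric element (STE) blocks, and then randomly placed genes; the
spike-in genome is a single chromosome carrying one control locus. All
coordinates are 0-based, half-open (BED convention).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FEATURE_CLASSES",
    "FeatureRecord",
    "GenomeModel",
    "TelomereRegion",
    "TelomerePair",
    "GenomeConfig",
    "build_toy_genome",
    "enumerate_telomere_pairs",
    "telomere_mask",
    "write_fasta",
    "read_fasta",
    "write_bed",
    "read_bed",
    "write_chrom_sizes",
    "read_chrom_sizes",
]

COORDINATE_CONVENTION = "0-based, half-open"

FEATURE_CLASSES = frozenset(
    {
        "telomere_repeat",
        "STE",
        "gene",
        "centromere",
        "control_locus",
        "taz1_island",
        "qpcr_amplicon",
    }
)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass(frozen=True)
class FeatureRecord:
    """One annotated interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    feature_class: str
    name: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.name or self.feature_class}: start >= end")
        if self.start < 0:
            raise ValueError("negative start")
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TelomereRegion:
    """Distal window at one chromosome end.

    Orientation contract: downstream consumers index the region so that
    offset 0 is the repeat-proximal (outermost) position/bin.
    """

    chrom: str
    side: str  # "left" | "right"
    start: int
    end: int
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"bad side {self.side!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, str]:
        return (self.chrom, self.side)


@dataclass(frozen=True)
class TelomerePair:
    region_a: TelomereRegion
    region_b: TelomereRegion
    pair_class: str  # "intra" | "inter"


@dataclass
class GenomeModel:
    """Chromosome table plus feature annotations for one species."""

    species_id: str  # "target" | "spikein"
    chromosomes: list[tuple[str, int]]
    features: list[FeatureRecord] = field(default_factory=list)
    sequences: dict[str, str] | None = None
    coordinate_convention: str = COORDINATE_CONVENTION

    # -- lookups ---------------------------------------------------------
    def chromosome_length(self, name: str) -> int:
        for chrom, length in self.chromosomes:
            if chrom == name:
                return length
        raise KeyError(name)

    @property
    def chromosome_names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def features_of_class(self, feature_class: str) -> list[FeatureRecord]:
        return [f for f in self.features if f.feature_class == feature_class]

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.species_id not in ("target", "spikein"):
            raise ValueError(f"bad species_id {self.species_id!r}")
        lengths = dict(self.chromosomes)
        if len(lengths) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"{name}: non-positive length")
        end_slots: set[tuple[str, str]] = set()
        for f in self.features:
            if f.chrom not in lengths:
                raise ValueError(f"feature {f.name!r} on unknown chromosome {f.chrom}")
            if f.end > lengths[f.chrom]:
                raise ValueError(f"feature {f.name!r} exceeds chromosome bounds")
            if f.feature_class == "telomere_repeat":
                if f.start == 0:
                    slot = (f.chrom, "left")
                elif f.end == lengths[f.chrom]:
                    slot = (f.chrom, "right")
                else:
                    raise ValueError(
                        f"telomere_repeat {f.name!r} does not touch a chromosome end"
                    )
                if slot in end_slots:
                    raise ValueError(f"duplicate telomere_repeat at {slot}")
                end_slots.add(slot)
        if self.species_id == "spikein":
            n_ctrl = len(self.features_of_class("control_locus"))
            if n_ctrl != 1:
                raise ValueError(
                    f"spike-in genome must have exactly one control_locus, got {n_ctrl}"
                )
        if self.sequences is not None:
            for name, length in self.chromosomes:
                if len(self.sequences.get(name, "")) != length:
                    raise ValueError(f"{name}: sequence length != declared length")

    # -- telomere geometry ------------------------------------------------
    def telomere_regions(self, extent: int = 150_000) -> list[TelomereRegion]:
        """Both end regions of every chromosome, left then right."""
        regions = []
        for name, length in self.chromosomes:
            span = min(extent, length)
            truncated = span < extent
            regions.append(TelomereRegion(name, "left", 0, span, truncated))
            regions.append(
                TelomereRegion(name, "right", length - span, length, truncated)
            )
        return regions


def enumerate_telomere_pairs(
    genome: GenomeModel, extent: int = 150_000
) -> list[TelomerePair]:
    """All unordered pairs of distinct chromosome-end regions.

    ``pair_class`` is ``"intra"`` iff both ends belong to the same
    chromosome; self-pairs are excluded by construction.
    """
    if not genome.chromosomes:
        raise ValueError("genome has no chromosomes")
    regions = genome.telomere_regions(extent)
    pairs = []
    for a, b in itertools.combinations(regions, 2):
        pair_class = "intra" if a.chrom == b.chrom else "inter"
        pairs.append(TelomerePair(a, b, pair_class))
    return pairs


def telomere_mask(
    genome: GenomeModel,
    boundaries: Mapping[tuple[str, str], int],
) -> dict[str, np.ndarray]:
    """Per-base exclusion masks from per-end quantification boundaries.

    ``boundaries`` maps ``(chromosome, side)`` to a 0-based boundary
    coordinate; every position distal to the boundary (toward the
    chromosome end) is flagged True (excluded from quantification). A
    right-end boundary ``b`` masks ``[b, L)``; a left-end boundary masks
    ``[0, b)``.
    """
    masks = {
        name: np.zeros(length, dtype=bool) for name, length in genome.chromosomes
    }
    for (chrom, side), boundary in boundaries.items():
        length = genome.chromosome_length(chrom)
        if not (0 <= boundary <= length):
            raise ValueError(
                f"boundary {boundary} outside chromosome {chrom} (length {length})"
            )
        if side == "left":
            masks[chrom][:boundary] = True
        elif side == "right":
            masks[chrom][boundary:] = True
        else:
            raise ValueError(f"bad side {side!r}")
    return masks


# ---------------------------------------------------------------------------
# toy genome builder
# ---------------------------------------------------------------------------


@dataclass
class GenomeConfig:
    """Layout parameters for the toy two-species reference."""

    chromosome_lengths: tuple[int, ...] = (300_000, 300_000, 300_000)
    chromosome_names: tuple[str, ...] | None = None
    telomere_length: int = 6_000
    repeat_unit: str = "GGTTACA"  # degenerate fission-yeast-like default
    ste_blocks: tuple[tuple[str, int], ...] = (
        ("STE1", 8_000),
        ("STE2", 5_000),
        ("STE3", 4_000),
    )
    genes_per_chromosome: int = 40
    gene_length: int = 1_500
    centromere_length: int = 10_000
    taz1_islands_per_chromosome: int = 2
    taz1_island_length: int = 500
    spikein_length: int = 200_000
    control_locus_start: int = 99_000
    control_locus_length: int = 2_000
    seed: int = 0

    def names(self) -> tuple[str, ...]:
        if self.chromosome_names is not None:
            if len(self.chromosome_names) != len(self.chromosome_lengths):
                raise ValueError("chromosome_names/lengths size mismatch")
            return self.chromosome_names
        return tuple(f"chr{i + 1}" for i in range(len(self.chromosome_lengths)))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _repeat_array(unit: str, length: int) -> str:
    reps = -(-length // len(unit))
    return (unit * reps)[:length]


def _reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _place_intervals(
    rng: np.random.Generator,
    gaps: list[tuple[int, int]],
    n: int,
    length: int,
    max_tries: int = 20_000,
) -> list[tuple[int, int]]:
    """Randomly place n non-overlapping intervals of fixed length in gaps."""
    placed: list[tuple[int, int]] = []
    gaps = [(s, e) for s, e in gaps if e - s >= length]
    if not gaps:
        raise ValueError("no room to place features")
    widths = np.array([e - s - length + 1 for s, e in gaps], dtype=float)
    for _ in range(max_tries):
        if len(placed) == n:
            break
        gi = rng.choice(len(gaps), p=widths / widths.sum())
        start = int(rng.integers(gaps[gi][0], gaps[gi][1] - length + 1))
        end = start + length
        if all(end <= s or start >= e for s, e in placed):
            placed.append((start, end))
    if len(placed) != n:
        raise ValueError(f"could only place {len(placed)}/{n} intervals")
    return sorted(placed)


def build_toy_genome(config: GenomeConfig | None = None) -> tuple[GenomeModel, GenomeModel]:
    """Deterministically build the (target, spike-in) genome pair.

    Each target chromosome end carries, outermost first, the telomeric
    repeat array then the STE blocks in their configured order; genes and
    taz1 islands are placed randomly (seeded) in the remaining interior,
    avoiding the centromere placed at the chromosome midpoint.
    """
    cfg = config or GenomeConfig()
    rng = np.random.default_rng(cfg.seed)
    names = cfg.names()

    ste_total = sum(length for _, length in cfg.ste_blocks)
    features: list[FeatureRecord] = []
    sequences: dict[str, str] = {}

    for name, chrom_len in zip(names, cfg.chromosome_lengths):
        if cfg.telomere_length > chrom_len // 2:
            raise ValueError(
                f"{name}: telomere array longer than half the chromosome"
            )
        end_block = cfg.telomere_length + ste_total
        cen_start = chrom_len // 2 - cfg.centromere_length // 2
        cen_end = cen_start + cfg.centromere_length
        if cen_start < end_block or cen_end > chrom_len - end_block:
            raise ValueError(f"{name}: overlapping mandatory features")

        # telomere repeat arrays at both ends
        features.append(
            FeatureRecord(name, 0, cfg.telomere_length, "telomere_repeat", f"{name}_telL")
        )
        features.append(
            FeatureRecord(
                name,
                chrom_len - cfg.telomere_length,
                chrom_len,
                "telomere_repeat",
                f"{name}_telR",
            )
        )
        # STE blocks immediately inside the repeat arrays, outermost first
        left_cursor = cfg.telomere_length
        right_cursor = chrom_len - cfg.telomere_length
        for ste_name, ste_len in cfg.ste_blocks:
            features.append(
                FeatureRecord(
                    name, left_cursor, left_cursor + ste_len, "STE", f"{name}_{ste_name}_L"
                )
            )
            features.append(
                FeatureRecord(
                    name,
                    right_cursor - ste_len,
                    right_cursor,
                    "STE",
                    f"{name}_{ste_name}_R",
                )
            )
            left_cursor += ste_len
            right_cursor -= ste_len
        features.append(
            FeatureRecord(name, cen_start, cen_end, "centromere", f"{name}_cen")
        )

        # random non-overlapping genes + taz1 islands in the interior
        gaps = [(left_cursor, cen_start), (cen_end, right_cursor)]
        intervals = _place_intervals(
            rng,
            gaps,
            cfg.genes_per_chromosome + cfg.taz1_islands_per_chromosome,
            cfg.gene_length,
        )
        island_idx = set(
            rng.choice(
                len(intervals), size=cfg.taz1_islands_per_chromosome, replace=False
            ).tolist()
        ) if cfg.taz1_islands_per_chromosome else set()
        gene_no = island_no = 0
        for i, (start, end) in enumerate(intervals):
            if i in island_idx:
                island_no += 1
                mid = (start + end) // 2
                features.append(
                    FeatureRecord(
                        name,
                        mid,
                        mid + cfg.taz1_island_length,
                        "taz1_island",
                        f"{name}_isl{island_no}",
                    )
                )
            else:
                gene_no += 1
                strand = "+" if rng.random() < 0.5 else "-"
                features.append(
                    FeatureRecord(
                        name, start, end, "gene", f"{name}_gene{gene_no}", strand
                    )
                )

        # sequence: random background with tandem repeat arrays at the tips
        seq = list(_random_sequence(rng, chrom_len))
        right_rep = _repeat_array(cfg.repeat_unit, cfg.telomere_length)
        seq[chrom_len - cfg.telomere_length :] = right_rep
        seq[: cfg.telomere_length] = _reverse_complement(right_rep)
        sequences[name] = "".join(seq)

    target = GenomeModel(
        species_id="target",
        chromosomes=list(zip(names, cfg.chromosome_lengths)),
        features=sorted(features, key=lambda f: (f.chrom, f.start)),
        sequences=sequences,
    )
    target.validate()

    spike_name = "spike1"
    if not (0 <= cfg.control_locus_start
            and cfg.control_locus_start + cfg.control_locus_length <= cfg.spikein_length):
        raise ValueError("control locus outside spike-in chromosome")
    spikein = GenomeModel(
        species_id="spikein",
        chromosomes=[(spike_name, cfg.spikein_length)],
        features=[
            FeatureRecord(
                spike_name,
                cfg.control_locus_start,
                cfg.control_locus_start + cfg.control_locus_length,
                "control_locus",
                "control",
            )
        ],
        sequences={spike_name: _random_sequence(rng, cfg.spikein_length)},
    )
    spikein.validate()
    return target, spikein


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_fasta(genome: GenomeModel, path: str | Path) -> None:
    if genome.sequences is None:
        raise ValueError("genome carries no sequences")
    records = [
        SeqRecord(Seq(genome.sequences[name]), id=name, description="")
        for name, _ in genome.chromosomes
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(features: Iterable[FeatureRecord], path: str | Path) -> None:
    """BED6; the name column is ``feature_class|name``."""
    with open(path, "w") as handle:
        for f in features:
            handle.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{f.feature_class}|{f.name}\t0\t{f.strand}\n"
            )


def read_bed(path: str | Path) -> list[FeatureRecord]:
    features = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, _score, strand = line.split("\t")[:6]
            feature_class, _, label = name.partition("|")
            features.append(
                FeatureRecord(chrom, int(start), int(end), feature_class, label, strand)
            )
    return features


def write_chrom_sizes(genome: GenomeModel, path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, length in genome.chromosomes:
            handle.write(f"{name}\t{length}\n")


def read_chrom_sizes(path: str | Path) -> list[tuple[str, int]]:
    out = []
    with open(path) as handle:
        for line in handle:
            if line.strip():
                name, length = line.split()[:2]
                out.append((name, int(length)))
    return out
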