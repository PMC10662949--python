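"""Synthetic data generators with known planted parameters.

Three simulators stand in for deposited raw data: two-species ChIP fragment
sets with planted fold-enrichment profiles, Rabl-configured Hi-C contact
matrices with power-law distance decay plus telomere/centromere clustering
gains, and mitotic cells as 3D point sets. All three are bit-reproducible
under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .foci import CellRecord
from .genome import GenomeModel
from .hic import ContactMatrix

__all__ = [
    "EnrichmentProfile",
    "HiCSimParams",
    "MitoticSimParams",
    "ChipSimulation",
    "simulate_chip",
    "simulate_hic",
    "simulate_mitotic_cells",
    "wildtype_hic_params",
    "cut14_hic_params",
    "wildtype_chip_profile",
    "taz1_chip_profile",
    "write_fragments_bed",
    "read_fragments_bed",
]


# ---------------------------------------------------------------------------
# ChIP
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentProfile:
    """Planted per-feature-class fold enrichments and library parameters.

    The ``background`` multiplier is the unit reference (must be 1);
    feature classes absent from ``multipliers`` behave as background.
    ``ip_efficiency`` scales the amount of immunoprecipitated material, and
    with it the emitted IP fragment count, uniformly across both species.
    """

    multipliers: dict[str, float] = field(
        default_factory=lambda: {
            "telomere_repeat": 8.0,
            "STE": 2.0,
            "gene": 6.0,
            "background": 1.0,
        }
    )
    fragment_length: int = 300
    depth_ip: int = 200_000
    depth_total: int = 200_000
    ip_efficiency: float = 1.0
    spikein_control_multiplier: float = 4.0

    def validate(self) -> None:
        if any(v <= 0 for v in self.multipliers.values()):
            raise ValueError("all multipliers must be > 0")
        if self.multipliers.get("background", 1.0) != 1.0:
            raise ValueError("background multiplier is the unit reference (1.0)")
        if self.depth_ip <= 0 or self.depth_total <= 0:
            raise ValueError("depths must be > 0")
        if self.fragment_length < 1:
            raise ValueError("fragment_length must be >= 1")
        if self.ip_efficiency <= 0:
            raise ValueError("ip_efficiency must be > 0")
        if self.spikein_control_multiplier <= 0:
            raise ValueError("spikein_control_multiplier must be > 0")


@dataclass
class ChipSimulation:
    """Fragment sets for {IP, Total} x {target, spikein}."""

    fragments: dict[tuple[str, str], pd.DataFrame]  # (fraction, species) -> BED-like
    profile: EnrichmentProfile
    mixing_ratio: float
    seed: int | None

    def counts(self) -> dict[tuple[str, str], int]:
        return {k: len(v) for k, v in self.fragments.items()}


def _enrichment_weights(
    genome: GenomeModel, profile: EnrichmentProfile
) -> dict[str, np.ndarray]:
    """Per-base IP sampling weight (background = 1) for one species."""
    weights = {}
    for name, length in genome.chromosomes:
        weights[name] = np.ones(length)
    for f in genome.features:
        if genome.species_id == "spikein":
            mult = (
                profile.spikein_control_multiplier
                if f.feature_class == "control_locus"
                else 1.0
            )
        else:
            mult = profile.multipliers.get(f.feature_class, 1.0)
        if mult != 1.0:
            weights[f.chrom][f.start : f.end] *= mult
    return weights


def _start_weights(weights: np.ndarray, frag_len: int) -> np.ndarray:
    """Weight of each valid fragment start = weight at the fragment midpoint."""
    length = weights.size
    if length <= frag_len:
        return np.empty(0)
    mid = frag_len // 2
    return weights[mid : mid + (length - frag_len + 1)]


def _sample_starts(
    rng: np.random.Generator, start_weights: list[np.ndarray], n: int
) -> list[np.ndarray]:
    """Draw n fragment starts across chromosomes, weighted per position."""
    sizes = [w.size for w in start_weights]
    concat = np.concatenate(start_weights) if sizes else np.empty(0)
    if concat.size == 0 or concat.sum() <= 0:
        raise ValueError("no valid fragment start positions")
    cdf = np.cumsum(concat)
    u = rng.random(n) * cdf[-1]
    idx = np.searchsorted(cdf, u, side="right")
    out, offset = [], 0
    for size in sizes:
        sel = idx[(idx >= offset) & (idx < offset + size)] - offset
        out.append(np.sort(sel))
        offset += size
    return out


def _fragments_frame(
    genome: GenomeModel, starts_per_chrom: list[np.ndarray], frag_len: int
) -> pd.DataFrame:
    frames = []
    for (name, _length), starts in zip(genome.chromosomes, starts_per_chrom):
        frames.append(
            pd.DataFrame(
                {"chrom": name, "start": starts, "end": starts + frag_len}
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_chip(
    target: GenomeModel,
    spikein: GenomeModel,
    profile: EnrichmentProfile | None = None,
    mixing_ratio: float = 5.0,
    seed: int | None = None,
) -> ChipSimulation:
    """Simulate two-species ChIP fragment sets.

    Total fragments are drawn uniformly over each genome, with the species
    split proportional to ``mixing_ratio x genome size``. IP fragments are
    drawn with probability proportional to the local planted enrichment
    (the spike-in is enriched only at its control locus), with the species
    split proportional to ``mixing_ratio x total enrichment weight``. The
    emitted IP fragment count is ``round(depth_ip * ip_efficiency)``.
    """
    profile = profile or EnrichmentProfile()
    profile.validate()
    if mixing_ratio <= 0:
        raise ValueError("mixing_ratio must be > 0")
    for genome in (target, spikein):
        if not genome.chromosomes or genome.total_length == 0:
            raise ValueError(f"empty genome: {genome.species_id}")
    rng = np.random.default_rng(seed)
    frag_len = profile.fragment_length

    mixing = {"target": mixing_ratio, "spikein": 1.0}
    genomes = {"target": target, "spikein": spikein}
    ip_weights = {
        sp: [
            _start_weights(_enrichment_weights(g, profile)[name], frag_len)
            for name, _ in g.chromosomes
        ]
        for sp, g in genomes.items()
    }
    uniform_weights = {
        sp: [np.ones_like(w) for w in ip_weights[sp]] for sp in genomes
    }

    fragments: dict[tuple[str, str], pd.DataFrame] = {}

    # Total: species split by mixing x genome length, uniform within species
    p_total = np.array([mixing[sp] * genomes[sp].total_length for sp in ("target", "spikein")], dtype=float)
    n_total = rng.multinomial(profile.depth_total, p_total / p_total.sum())
    # IP: species split by mixing x summed enrichment weight
    w_sums = np.array(
        [sum(float(w.sum()) for w in ip_weights[sp]) for sp in ("target", "spikein")]
    )
    n_ip_emitted = int(round(profile.depth_ip * profile.ip_efficiency))
    p_ip = np.array(
        [mixing[sp] * ws for sp, ws in zip(("target", "spikein"), w_sums)]
    )
    n_ip = rng.multinomial(n_ip_emitted, p_ip / p_ip.sum())

    for i, sp in enumerate(("target", "spikein")):
        starts = _sample_starts(rng, uniform_weights[sp], int(n_total[i]))
        fragments[("Total", sp)] = _fragments_frame(genomes[sp], starts, frag_len)
        starts = _sample_starts(rng, ip_weights[sp], int(n_ip[i]))
        fragments[("IP", sp)] = _fragments_frame(genomes[sp], starts, frag_len)

    return ChipSimulation(fragments, profile, mixing_ratio, seed)


def wildtype_chip_profile(**overrides) -> EnrichmentProfile:
    return replace(EnrichmentProfile(), **overrides)


def taz1_chip_profile(**overrides) -> EnrichmentProfile:
    """Telomere-repeat multiplier halved relative to the wild-type-like
    profile (sub-telomeric occupancy also dampened)."""
    profile = EnrichmentProfile()
    profile.multipliers = dict(profile.multipliers)
    profile.multipliers["telomere_repeat"] /= 2.0
    profile.multipliers["STE"] = max(1.0, profile.multipliers["STE"] / 2.0)
    return replace(profile, **overrides)


def write_fragments_bed(frame: pd.DataFrame, path: str | Path, name: str = "frag") -> None:
    with open(path, "w") as handle:
        for i, row in enumerate(frame.itertuples(index=False)):
            handle.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}{i}\t0\t.\n")


def read_fragments_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            rows.append((parts[0], int(parts[1]), int(parts[2])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# Hi-C
# ---------------------------------------------------------------------------


@dataclass
class HiCSimParams:
    """Expected-contact model: power-law decay within chromosomes, constant
    inter-chromosomal level, and multiplicative clustering gains that decay
    exponentially with distance from the chromosome end (telomeres) or the
    centromere midpoint (centromeres)."""

    resolution: int = 5_000
    decay_exponent: float = -1.0
    telomere_gain_intra: float = 4.0
    telomere_gain_inter: float = 2.0
    centromere_gain: float = 3.0
    telomere_region_bp: int = 150_000
    centromere_region_bp: int = 150_000
    gain_decay_bp: float = 30_000.0
    inter_level: float = 0.05
    read_pairs: int = 2_000_000
    noise: str = "multinomial"  # multinomial | poisson | none

    def validate(self) -> None:
        if self.decay_exponent >= 0:
            raise ValueError("decay_exponent must be < 0")
        for g in (
            self.telomere_gain_intra,
            self.telomere_gain_inter,
            self.centromere_gain,
        ):
            if g < 1:
                raise ValueError("gains must be >= 1")
        if self.read_pairs <= 0:
            raise ValueError("read_pairs must be > 0")
        if self.noise not in ("multinomial", "poisson", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.resolution < 1 or self.inter_level <= 0 or self.gain_decay_bp <= 0:
            raise ValueError("invalid resolution/inter_level/gain_decay_bp")


def wildtype_hic_params(**overrides) -> HiCSimParams:
    """Wild-type-like preset: telomere clustering with the intra gain above
    the inter gain, so intra-chromosomal end contacts dominate."""
    return replace(
        HiCSimParams(
            decay_exponent=-1.2,
            telomere_gain_intra=5.0,
            telomere_gain_inter=2.0,
            centromere_gain=3.0,
            read_pairs=10_000_000,
        ),
        **overrides,
    )


def cut14_hic_params(**overrides) -> HiCSimParams:
    """Condensin-mutant-like preset: arm-range contacts reduced (steeper
    decay) and telomere clustering gains increased; centromere gain kept
    equal to wild-type. Preset values are free parameters, not ground
    truth."""
    return replace(
        HiCSimParams(
            decay_exponent=-1.6,
            telomere_gain_intra=16.0,
            telomere_gain_inter=6.0,
            centromere_gain=3.0,
            read_pairs=10_000_000,
        ),
        **overrides,
    )


def _expected_matrix(genome: GenomeModel, params: HiCSimParams) -> tuple[np.ndarray, list[int], tuple[str, ...]]:
    res = params.resolution
    bins_per_chrom = [-(-length // res) for _, length in genome.chromosomes]
    partial = tuple(
        name for (name, length) in genome.chromosomes if length % res != 0
    )
    n = sum(bins_per_chrom)
    cidx = np.concatenate(
        [np.full(nb, i) for i, nb in enumerate(bins_per_chrom)]
    )
    local = np.concatenate([np.arange(nb) for nb in bins_per_chrom])
    centers = (local + 0.5) * res

    same = cidx[:, None] == cidx[None, :]
    d_bins = np.abs(local[:, None] - local[None, :])
    with np.errstate(divide="ignore"):
        decay = np.maximum(d_bins, 1).astype(float) ** params.decay_exponent
    expected = np.where(same, decay, params.inter_level)

    # telomere clustering: bins inside an end region carry an exponential
    # proximity term; pairs of bins at *different* ends multiply expectation
    lengths = {name: length for name, length in genome.chromosomes}
    chrom_len = np.array([lengths[name] for name, _ in genome.chromosomes])[cidx]
    d_left = centers
    d_right = chrom_len - centers
    in_left = d_left <= params.telomere_region_bp
    in_right = d_right <= params.telomere_region_bp
    # assign each bin to its nearest end; -1 = not in any end region
    end_id = np.full(n, -1)
    end_d = np.full(n, np.inf)
    use_left = in_left & (d_left <= d_right)
    use_right = in_right & ~use_left
    end_id[use_left] = 2 * cidx[use_left]
    end_d[use_left] = d_left[use_left]
    end_id[use_right] = 2 * cidx[use_right] + 1
    end_d[use_right] = d_right[use_right]

    prox = np.where(end_id >= 0, np.exp(-end_d / params.gain_decay_bp), 0.0)
    tel_pair = (end_id[:, None] >= 0) & (end_id[None, :] >= 0) & (
        end_id[:, None] != end_id[None, :]
    )
    pair_prox = prox[:, None] * prox[None, :]
    gain = np.where(same, params.telomere_gain_intra, params.telomere_gain_inter)
    expected *= np.where(tel_pair, 1.0 + (gain - 1.0) * pair_prox, 1.0)

    # centromere clustering between chromosomes
    cen_mid = {}
    for cen in genome.features_of_class("centromere"):
        cen_mid[cen.chrom] = (cen.start + cen.end) / 2.0
    if cen_mid and params.centromere_gain > 1.0:
        mids = np.array(
            [cen_mid.get(name, np.nan) for name, _ in genome.chromosomes]
        )[cidx]
        d_cen = np.abs(centers - mids)
        in_cen = d_cen <= params.centromere_region_bp / 2.0
        cprox = np.where(in_cen, np.exp(-d_cen / params.gain_decay_bp), 0.0)
        cen_pair = in_cen[:, None] & in_cen[None, :] & ~same
        cpair_prox = cprox[:, None] * cprox[None, :]
        expected *= np.where(
            cen_pair, 1.0 + (params.centromere_gain - 1.0) * cpair_prox, 1.0
        )

    return expected, bins_per_chrom, partial


def simulate_hic(
    genome: GenomeModel,
    params: HiCSimParams | None = None,
    seed: int | None = None,
    condition: str | None = None,
) -> ContactMatrix:
    """Simulate a symmetric raw contact matrix.

    The configured read-pair budget is distributed over the upper triangle
    (diagonal included): multinomially (conserving the budget exactly), as
    independent Poisson counts, or noise-free (the scaled expectation).
    """
    params = params or HiCSimParams()
    params.validate()
    expected, _bins, partial = _expected_matrix(genome, params)
    n = expected.shape[0]
    iu = np.triu_indices(n)
    upper = expected[iu]
    scale = params.read_pairs / upper.sum()
    rng = np.random.default_rng(seed)

    if params.noise == "multinomial":
        counts = rng.multinomial(params.read_pairs, upper / upper.sum()).astype(float)
    elif params.noise == "poisson":
        counts = rng.poisson(upper * scale).astype(float)
    else:
        counts = upper * scale

    matrix = np.zeros((n, n))
    matrix[iu] = counts
    matrix = matrix + matrix.T - np.diag(np.diag(matrix))
    return ContactMatrix(
        params.resolution,
        list(genome.chromosomes),
        matrix,
        state="raw",
        condition=condition,
        partial_bins=partial,
    )


# ---------------------------------------------------------------------------
# mitotic cells
# ---------------------------------------------------------------------------


@dataclass
class MitoticSimParams:
    """Point-set model of mitotic cells.

    Stage mixture orders (interphase, metaphase, anaphase). In anaphase
    each of the 2C telomere loci carries two sister copies that split with
    ``disjunction_prob`` (split pair: one point near each pole; unsplit
    pair: a single point). Emitted points keep a minimum spacing of
    ``min_spacing`` so that ground-truth counts are recoverable by a
    merge-radius smaller than the spacing.
    """

    n_cells: int = 100
    stage_mix: tuple[float, float, float] = (0.2, 0.3, 0.5)
    disjunction_prob: float = 0.9
    decluster_completeness: float = 1.0
    min_spacing: float = 1.0
    nuclear_radius: float = 1.5
    spb_distance: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "interphase": (0.2, 0.8),
            "metaphase": (1.5, 4.0),
            "anaphase": (6.0, 9.0),
        }
    )
    interphase_clusters: tuple[int, int] = (1, 3)

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not math.isclose(sum(self.stage_mix), 1.0, rel_tol=1e-9):
            raise ValueError("stage_mix must sum to 1")
        if any(p < 0 for p in self.stage_mix):
            raise ValueError("stage_mix proportions must be >= 0")
        for p in (self.disjunction_prob, self.decluster_completeness):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.min_spacing < 0:
            raise ValueError("min_spacing must be >= 0")


def _spaced_points(
    rng: np.random.Generator,
    n: int,
    low: np.ndarray,
    high: np.ndarray,
    min_spacing: float,
    existing: np.ndarray | None = None,
    max_tries: int = 5_000,
) -> np.ndarray:
    """Sequential rejection sampling of n points with a minimum pairwise
    spacing inside a box, also respecting spacing to existing points; the
    box is grown if placement stalls."""
    low = np.asarray(low, dtype=float)
    high = np.asarray(high, dtype=float)
    for _expansion in range(8):
        points: list[np.ndarray] = []
        tries = 0
        while len(points) < n and tries < max_tries:
            tries += 1
            cand = low + rng.random(3) * (high - low)
            pool = points if existing is None else points + list(existing)
            if all(np.linalg.norm(cand - p) >= min_spacing for p in pool):
                points.append(cand)
        if len(points) == n:
            return np.array(points).reshape(n, 3)
        center = (low + high) / 2.0
        low = center + (low - center) * 1.5
        high = center + (high - center) * 1.5
    raise RuntimeError(f"could not place {n} points with spacing {min_spacing}")


def simulate_mitotic_cells(
    genome: GenomeModel,
    params: MitoticSimParams | None = None,
    seed: int | None = None,
    condition: str | None = None,
) -> list[CellRecord]:
    """Simulate cells as SPB pairs plus ground-truth telomere focus points.

    Interphase: telomeres clustered into 1-3 peripheral points. Metaphase:
    up to 2C points, sisters co-located; each locus resolves its own point
    with probability ``decluster_completeness``, the remainder collapsing
    onto a residual cluster. Anaphase: up to 4C points, each sister pair
    split with ``disjunction_prob``.
    """
    params = params or MitoticSimParams()
    params.validate()
    n_chrom = len(genome.chromosomes)
    if n_chrom < 1:
        raise ValueError("genome has no chromosomes")
    rng = np.random.default_rng(seed)
    r = params.nuclear_radius
    cells: list[CellRecord] = []
    stage_names = ("interphase", "metaphase", "anaphase")

    for i in range(params.n_cells):
        stage = stage_names[rng.choice(3, p=params.stage_mix)]
        lo, hi = params.spb_distance[stage]
        d = lo + rng.random() * (hi - lo)
        jitter = rng.normal(0.0, 0.05, size=(2, 3))
        spb = np.array([[-d / 2, 0, 0], [d / 2, 0, 0]]) + jitter

        if stage == "interphase":
            k = int(rng.integers(params.interphase_clusters[0],
                                 params.interphase_clusters[1] + 1))
            pts = _spaced_points(
                rng, k, [-r, -r, -r], [r, r, r], params.min_spacing
            )
        elif stage == "metaphase":
            declustered = rng.random(2 * n_chrom) < params.decluster_completeness
            k = int(declustered.sum()) + (1 if (~declustered).any() else 0)
            pts = _spaced_points(
                rng, k, [-1.0, -r, -r], [1.0, r, r], params.min_spacing
            )
        else:  # anaphase
            split = rng.random(2 * n_chrom) < params.disjunction_prob
            n_left = int(split.sum())  # one point per split pair at each pole
            n_right = n_left
            # unsplit sister pairs travel together to one pole
            for _ in range(int((~split).sum())):
                if rng.random() < 0.5:
                    n_left += 1
                else:
                    n_right += 1
            half_w = max(1.2, 0.35 * params.min_spacing * max(n_left, n_right) ** (1 / 3) * 2)
            left = _spaced_points(
                rng,
                n_left,
                [-d / 2 - half_w, -r, -r],
                [-d / 2 + half_w, r, r],
                params.min_spacing,
            )
            right = _spaced_points(
                rng,
                n_right,
                [d / 2 - half_w, -r, -r],
                [d / 2 + half_w, r, r],
                params.min_spacing,
                existing=left,
            )
            pts = np.vstack([left, right])

        cells.append(
            CellRecord(
                cell_id=f"cell{i:04d}",
                spb=spb,
                telomeres=pts,
                condition=condition,
                stage_truth=stage,
                true_focus_count=pts.shape[0],
            )
        )
    return cells
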