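"""Spike-in calibrated ChIP quantification.

Coverage tracks are per-base (or per-bin) fragment-overlap counts. The
calibration factor alpha equalizes IP and Total on the spike-in species
(alpha = spike-in Total count / spike-in IP count), so the per-base target
ratio R(b) = (alpha * IP(b) + pseudocount) / (Total(b) + pseudocount) is
reported on a scale where spike-in occupancy is 1 and coverage biases
shared by IP and Total cancel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import FeatureRecord, GenomeModel
from .stats import replicate_summary

__all__ = [
    "CoverageTrack",
    "RatioTrack",
    "QPCRRecord",
    "MetageneProfile",
    "coverage_from_fragments",
    "calibration_factor",
    "calibrated_ratio",
    "uncalibrated_ratio",
    "qpcr_normalize",
    "metagene_profile",
    "region_mean",
    "telomere_fold",
    "bin_mask",
    "write_bedgraph",
    "read_bedgraph",
]

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_TOTAL_FLOOR = 5.0


@dataclass
class CoverageTrack:
    """Per-base or per-bin fragment-overlap counts for one fraction of one
    species."""

    species: str
    fraction: str  # "IP" | "Total"
    bin_size: int
    data: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.fraction not in ("IP", "Total"):
            raise ValueError(f"bad fraction {self.fraction!r}")
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        for name, arr in self.data.items():
            if np.any(arr < 0):
                raise ValueError(f"{name}: negative counts")

    @property
    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    def same_geometry(self, other: "CoverageTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and set(self.data) == set(other.data)
            and all(self.data[k].shape == other.data[k].shape for k in self.data)
        )


@dataclass
class RatioTrack:
    """Calibrated IP/Total occupancy; NaN marks masked positions."""

    data: dict[str, np.ndarray]
    bin_size: int
    pseudocount: float
    calibration_factor: float
    masked_positions: int = 0

    def unmasked_values(self) -> np.ndarray:
        return np.concatenate(
            [arr[~np.isnan(arr)] for arr in self.data.values()]
        )


@dataclass(frozen=True)
class QPCRRecord:
    locus: str
    percent_ip: float
    control_percent_ip: float
    condition: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.percent_ip < 0 or self.control_percent_ip < 0:
            raise ValueError("percentages must be >= 0")


@dataclass
class MetageneProfile:
    mean: np.ndarray
    sd: np.ndarray
    n_genes: int
    body_bins: int
    flank_bins: int


def _n_bins(length: int, bin_size: int) -> int:
    return -(-length // bin_size)


def coverage_from_fragments(
    fragments: pd.DataFrame,
    genome: GenomeModel,
    bin_size: int = 1,
    species: str | None = None,
    fraction: str = "Total",
) -> CoverageTrack:
    """Fragment-overlap counts per position (or bin).

    A bin counts every fragment overlapping it (not fragment midpoints).
    Fragments outside the chromosome bounds are rejected with the offending
    record identified.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    lengths = dict(genome.chromosomes)
    data = {
        name: np.zeros(_n_bins(length, bin_size), dtype=np.int64)
        for name, length in genome.chromosomes
    }
    for chrom, grp in fragments.groupby("chrom", sort=False):
        if chrom not in lengths:
            bad = grp.iloc[0]
            raise ValueError(
                f"fragment on unknown chromosome: {bad.chrom}:{bad.start}-{bad.end}"
            )
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        bad = (starts < 0) | (ends > lengths[chrom]) | (starts >= ends)
        if bad.any():
            row = grp[bad].iloc[0]
            raise ValueError(
                f"fragment outside chromosome bounds: {row.chrom}:{row.start}-{row.end}"
            )
        first_bin = starts // bin_size
        last_bin = (ends - 1) // bin_size
        diff = np.zeros(data[chrom].size + 1, dtype=np.int64)
        np.add.at(diff, first_bin, 1)
        np.add.at(diff, last_bin + 1, -1)
        data[chrom] += np.cumsum(diff[:-1])
    return CoverageTrack(
        species=species or genome.species_id,
        fraction=fraction,
        bin_size=bin_size,
        data=data,
    )


def calibration_factor(ip_spike: CoverageTrack, total_spike: CoverageTrack) -> float:
    """alpha = spike-in Total read count / spike-in IP read count.

    Multiplying the target IP track by alpha equalizes IP and Total on the
    spike-in, putting target ratios on a scale where spike-in occupancy
    is 1.
    """
    if ip_spike.fraction != "IP" or total_spike.fraction != "Total":
        raise ValueError("expected an (IP, Total) pair of spike-in tracks")
    if ip_spike.species != total_spike.species:
        raise ValueError("spike-in tracks are from different species")
    ip_total = ip_spike.total
    if ip_total == 0:
        raise ValueError("calibration failed: zero spike-in IP counts")
    if total_spike.total == 0:
        raise ValueError("calibration failed: zero spike-in Total counts")
    return total_spike.total / ip_total


def calibrated_ratio(
    ip_target: CoverageTrack,
    total_target: CoverageTrack,
    alpha: float = 1.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    mask: Mapping[str, np.ndarray] | None = None,
    total_floor: float = DEFAULT_TOTAL_FLOOR,
) -> RatioTrack:
    """Per-position calibrated ratio R = (alpha*IP + pc) / (Total + pc).

    Positions under ``mask`` or with Total coverage below ``total_floor``
    are reported as missing (NaN), never as zero.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if not ip_target.same_geometry(total_target):
        raise ValueError("IP and Total tracks have mismatched geometries")
    data = {}
    n_masked = 0
    for chrom, ip in ip_target.data.items():
        tot = total_target.data[chrom].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = (alpha * ip + pseudocount) / (tot + pseudocount)
        low = tot < total_floor
        ratio[low] = np.nan
        if mask is not None and chrom in mask:
            chrom_mask = np.asarray(mask[chrom], dtype=bool)
            if ip_target.bin_size > 1:
                chrom_mask = bin_mask(chrom_mask, ip_target.bin_size)
            if chrom_mask.shape != ratio.shape:
                raise ValueError(f"{chrom}: mask geometry mismatch")
            ratio[chrom_mask] = np.nan
        n_masked += int(np.isnan(ratio).sum())
        data[chrom] = ratio
    logger.info(
        "calibrated_ratio: alpha=%.6g pseudocount=%g floor=%g masked=%d",
        alpha, pseudocount, total_floor, n_masked,
    )
    return RatioTrack(
        data=data,
        bin_size=ip_target.bin_size,
        pseudocount=pseudocount,
        calibration_factor=alpha,
        masked_positions=n_masked,
    )


def uncalibrated_ratio(
    ip_target: CoverageTrack,
    total_target: CoverageTrack,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    mask: Mapping[str, np.ndarray] | None = None,
    total_floor: float = DEFAULT_TOTAL_FLOOR,
) -> RatioTrack:
    """Plain IP/Total ratio (alpha = 1); the calibration-free baseline."""
    return calibrated_ratio(
        ip_target, total_target, 1.0, pseudocount, mask, total_floor
    )


def bin_mask(mask: np.ndarray, bin_size: int) -> np.ndarray:
    """Collapse a per-base mask to bins; a bin is masked if any base is."""
    n = _n_bins(mask.size, bin_size)
    padded = np.zeros(n * bin_size, dtype=bool)
    padded[: mask.size] = mask
    return padded.reshape(n, bin_size).any(axis=1)


# ---------------------------------------------------------------------------
# qPCR-style normalization
# ---------------------------------------------------------------------------


def qpcr_normalize(
    records: Sequence[QPCRRecord],
) -> tuple[pd.DataFrame, list[QPCRRecord]]:
    """Normalize percent-IP values to the spike-in control locus.

    normalized = percent_ip(locus) / percent_ip(control), per replicate;
    replicate mean and n-1 sample SD are reported per (locus, condition).
    Records with a zero or absent control are excluded and returned.
    """
    rows, excluded = [], []
    for rec in records:
        if rec.control_percent_ip <= 0:
            excluded.append(rec)
            continue
        rows.append(
            {
                "locus": rec.locus,
                "condition": rec.condition,
                "replicate": rec.replicate,
                "normalized": rec.percent_ip / rec.control_percent_ip,
            }
        )
    if excluded:
        logger.warning("qpcr_normalize: %d record(s) excluded (no control)", len(excluded))
    if not rows:
        raise ValueError("no usable qPCR records")
    frame = pd.DataFrame(rows)
    out = []
    for (locus, condition), grp in frame.groupby(["locus", "condition"], sort=False):
        summary = replicate_summary(grp["normalized"])
        out.append(
            {
                "locus": locus,
                "condition": condition,
                "mean": summary.mean,
                "sd": summary.sd,
                "n": summary.n,
                "single_replicate": summary.single_replicate,
            }
        )
    return pd.DataFrame(out), excluded


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------


def _gene_profile(
    values: np.ndarray,
    gene: FeatureRecord,
    body_bins: int,
    flank_bp: int,
    flank_bins: int,
) -> np.ndarray:
    """One gene's binned profile, oriented so the TSS is leftmost.

    Positions are assigned to bins by floor division in a strand-aware
    relative coordinate, so a minus-strand gene is the exact mirror of a
    plus-strand gene over the same span. Flank positions beyond the
    chromosome edge contribute missing values.
    """
    length = values.size
    n_out = 2 * flank_bins + body_bins
    sums = np.zeros(n_out)
    counts = np.zeros(n_out, dtype=np.int64)
    gene_len = gene.end - gene.start
    minus = gene.strand == "-"

    def accumulate(pos: np.ndarray, bins: np.ndarray) -> None:
        keep = (pos >= 0) & (pos < length)
        pos, bins = pos[keep], bins[keep]
        vals = values[pos]
        good = ~np.isnan(vals)
        np.add.at(sums, bins[good], vals[good])
        np.add.at(counts, bins[good], 1)

    # body
    body_pos = np.arange(gene.start, gene.end)
    q = (gene.end - 1 - body_pos) if minus else (body_pos - gene.start)
    accumulate(body_pos, flank_bins + (q * body_bins) // gene_len)
    if flank_bins and flank_bp:
        # upstream flank (before the TSS)
        if minus:
            up_pos = np.arange(gene.end, gene.end + flank_bp)
            u = gene.end + flank_bp - 1 - up_pos
        else:
            up_pos = np.arange(gene.start - flank_bp, gene.start)
            u = up_pos - (gene.start - flank_bp)
        accumulate(up_pos, (u * flank_bins) // flank_bp)
        # downstream flank (after the TES)
        if minus:
            dn_pos = np.arange(gene.start - flank_bp, gene.start)
            u = gene.start - 1 - dn_pos
        else:
            dn_pos = np.arange(gene.end, gene.end + flank_bp)
            u = dn_pos - gene.end
        accumulate(dn_pos, flank_bins + body_bins + (u * flank_bins) // flank_bp)

    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def metagene_profile(
    track: RatioTrack,
    genes: Sequence[FeatureRecord],
    body_bins: int = 60,
    flank_bp: int = 500,
    flank_bins: int = 10,
) -> MetageneProfile:
    """Mean profile over genes: rescaled body plus fixed-width flanks.

    Each gene body is rescaled to ``body_bins`` equal segments; flanks of
    ``flank_bp`` are split into ``flank_bins``; minus-strand genes are
    reversed so the TSS is always leftmost. Masked (NaN) positions never
    contribute. Requires per-base tracks.
    """
    if not genes:
        raise ValueError("need at least one gene")
    if track.bin_size != 1:
        raise ValueError("metagene profiles require a per-base track")
    if body_bins < 1 or flank_bins < 0 or flank_bp < 0:
        raise ValueError("invalid binning parameters")
    profiles = []
    for gene in genes:
        if gene.chrom not in track.data:
            raise ValueError(f"gene {gene.name!r} on unknown chromosome")
        profiles.append(
            _gene_profile(track.data[gene.chrom], gene, body_bins, flank_bp, flank_bins)
        )
    stack = np.vstack(profiles)
    import warnings as _warnings

    with _warnings.catch_warnings():
        # bins with no covered position in any gene are legitimately all-NaN
        _warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1) if len(profiles) > 1 else np.zeros_like(mean)
    return MetageneProfile(
        mean=mean, sd=sd, n_genes=len(genes), body_bins=body_bins, flank_bins=flank_bins
    )


# ---------------------------------------------------------------------------
# region summaries
# ---------------------------------------------------------------------------


def region_mean(
    track: RatioTrack, intervals: Iterable[tuple[str, int, int]]
) -> float:
    """Mean of unmasked track values over base-pair intervals."""
    chunks = []
    for chrom, start, end in intervals:
        arr = track.data[chrom]
        if track.bin_size == 1:
            chunk = arr[start:end]
        else:
            chunk = arr[start // track.bin_size : -(-end // track.bin_size)]
        chunks.append(chunk)
    values = np.concatenate(chunks)
    if np.all(np.isnan(values)):
        return float("nan")
    return float(np.nanmean(values))


def telomere_fold(
    track: RatioTrack,
    genome: GenomeModel,
    trim_bp: int = 150,
    background_pad_bp: int = 300,
) -> float:
    """Recovered telomere enrichment: mean ratio over telomere repeat
    arrays (edges trimmed by ``trim_bp`` to avoid fragment-length smearing)
    divided by the mean over featureless background (features padded by
    ``background_pad_bp``)."""
    tel = []
    for f in genome.features_of_class("telomere_repeat"):
        start, end = f.start + trim_bp, f.end - trim_bp
        if start < end:
            tel.append((f.chrom, start, end))
    if not tel:
        raise ValueError("genome has no telomere_repeat features")
    tel_mean = region_mean(track, tel)

    covered = {
        name: np.zeros(length, dtype=bool) for name, length in genome.chromosomes
    }
    for f in genome.features:
        lo = max(0, f.start - background_pad_bp)
        hi = min(genome.chromosome_length(f.chrom), f.end + background_pad_bp)
        covered[f.chrom][lo:hi] = True
    bg_values = []
    for chrom, mask in covered.items():
        arr = track.data[chrom]
        if track.bin_size != 1:
            mask = bin_mask(mask, track.bin_size)
        bg_values.append(arr[~mask])
    bg = np.concatenate(bg_values)
    bg_mean = float(np.nanmean(bg))
    return tel_mean / bg_mean


# ---------------------------------------------------------------------------
# bedGraph I/O (missing positions omitted, per bedGraph convention)
# ---------------------------------------------------------------------------


def _iter_runs(values: np.ndarray):
    """Yield (start, end, value) runs of equal, non-missing values."""
    n = values.size
    if n == 0:
        return
    change = np.empty(n, dtype=bool)
    change[0] = True
    a, b = values[1:], values[:-1]
    change[1:] = ~((a == b) | (np.isnan(a) & np.isnan(b)))
    starts = np.flatnonzero(change)
    ends = np.append(starts[1:], n)
    for s, e in zip(starts, ends):
        v = values[s]
        if not np.isnan(v):
            yield int(s), int(e), float(v)


def write_bedgraph(
    track: CoverageTrack | RatioTrack, path: str | Path, name: str = "track"
) -> None:
    bin_size = track.bin_size
    with open(path, "w") as handle:
        handle.write(f'track type=bedGraph name="{name}"\n')
        for chrom in track.data:
            values = np.asarray(track.data[chrom], dtype=float)
            for s, e, v in _iter_runs(values):
                handle.write(
                    f"{chrom}\t{s * bin_size}\t{e * bin_size}\t{v:.6g}\n"
                )


def read_bedgraph(
    path: str | Path, genome: GenomeModel, bin_size: int = 1
) -> dict[str, np.ndarray]:
    """Read a bedGraph into per-chromosome arrays (missing = NaN)."""
    data = {
        name: np.full(_n_bins(length, bin_size), np.nan)
        for name, length in genome.chromosomes
    }
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            data[chrom][int(start) // bin_size : int(end) // bin_size] = float(value)
    return data
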