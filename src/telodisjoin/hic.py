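"""Hi-C contact-matrix quantification.

Square-root vanilla-coverage normalization, observed/expected, distance
decay curves, differential log2 maps, and chromosome-end pair aggregation:
for every pair of telomere regions the end-region submatrix is extracted
with the repeat-proximal corner at index (0, 0), a fixed window slides over
it, and the collected frames (raw and rank-quantized) are aggregated per
pair class and compared between conditions with a Mann-Whitney test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from . import stats
from .genome import GenomeModel, TelomerePair, TelomereRegion, enumerate_telomere_pairs

__all__ = [
    "ContactMatrix",
    "PairSubmatrixStack",
    "ComparisonResult",
    "vc_sqrt_normalize",
    "observed_over_expected",
    "distance_decay_curve",
    "fit_decay_exponent",
    "differential_map",
    "rank_quantize",
    "telomere_aggregate",
    "centromere_aggregate",
    "compare_conditions",
    "write_matrix_tsv",
    "read_matrix_tsv",
]

_SYM_RTOL = 1e-8
_SYM_ATOL = 1e-10

DEFAULT_ALPHA = 0.001  # per-comparison significance threshold
DEFAULT_CORNER = 5  # focus-block edge for the per-window test summaries


@dataclass
class ContactMatrix:
    """Symmetric binned contact matrix with chromosome bookkeeping.

    ``matrix`` holds floats with NaN marking masked entries; ``state`` is
    one of raw | vc_sqrt | observed_expected | log2_ratio. The bin count
    per chromosome is ``ceil(length / resolution)``; chromosomes whose
    length is not a multiple of the resolution end in a flagged partial
    bin.
    """

    resolution: int
    chromosomes: list[tuple[str, int]]
    matrix: np.ndarray
    state: str = "raw"
    condition: str | None = None
    partial_bins: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.n_bins
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.matrix.shape} != expected ({n}, {n})"
            )

    # -- geometry ---------------------------------------------------------
    @property
    def bins_per_chrom(self) -> list[int]:
        return [-(-length // self.resolution) for _, length in self.chromosomes]

    @property
    def n_bins(self) -> int:
        return sum(self.bins_per_chrom)

    @property
    def chrom_slices(self) -> dict[str, slice]:
        out, offset = {}, 0
        for (name, _), nb in zip(self.chromosomes, self.bins_per_chrom):
            out[name] = slice(offset, offset + nb)
            offset += nb
        return out

    @property
    def bin_chrom_ids(self) -> np.ndarray:
        ids = np.empty(self.n_bins, dtype=int)
        for i, (name, _) in enumerate(self.chromosomes):
            ids[self.chrom_slices[name]] = i
        return ids

    def intra_mask(self) -> np.ndarray:
        ids = self.bin_chrom_ids
        return ids[:, None] == ids[None, :]

    def same_geometry(self, other: "ContactMatrix") -> bool:
        return (
            self.resolution == other.resolution
            and self.chromosomes == other.chromosomes
        )

    def check_symmetric(self) -> None:
        m = self.matrix
        nan_a, nan_b = np.isnan(m), np.isnan(m.T)
        if not np.array_equal(nan_a, nan_b):
            raise ValueError("mask is not symmetric")
        ok = np.allclose(
            np.nan_to_num(m), np.nan_to_num(m.T), rtol=_SYM_RTOL, atol=_SYM_ATOL
        )
        if not ok:
            raise ValueError("matrix is not symmetric within tolerance")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def vc_sqrt_normalize(m: ContactMatrix) -> ContactMatrix:
    """Square-root vanilla-coverage normalization.

    ``M'(i,j) = M(i,j) / sqrt(r_i * r_j)`` with ``r_k`` the marginal sum of
    row k; rows with zero marginal are masked (NaN), not divided.
    """
    if m.state != "raw":
        raise ValueError(f"expected a raw matrix, got state {m.state!r}")
    m.check_symmetric()
    if np.nanmin(m.matrix) < 0:
        raise ValueError("raw matrix has negative entries")
    r = np.nansum(m.matrix, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = m.matrix / np.sqrt(np.outer(r, r))
    out[r == 0, :] = np.nan
    out[:, r == 0] = np.nan
    return ContactMatrix(
        m.resolution, list(m.chromosomes), out, "vc_sqrt", m.condition, m.partial_bins
    )


def observed_over_expected(
    m: ContactMatrix, per_pair_inter: bool = False
) -> ContactMatrix:
    """Divide by the distance-matched expectation.

    expected(d) is the mean of unmasked intra-chromosomal entries at bin
    distance d, pooled across chromosomes; inter-chromosomal entries are
    divided by the pooled mean of all unmasked inter entries (or by a
    per-chromosome-pair mean with ``per_pair_inter``).
    """
    out = np.full_like(m.matrix, np.nan)
    slices = m.chrom_slices
    max_nb = max(m.bins_per_chrom)

    # pooled per-diagonal expectation
    sums = np.zeros(max_nb)
    counts = np.zeros(max_nb)
    for name in slices:
        block = m.matrix[slices[name], slices[name]]
        nb = block.shape[0]
        d = np.abs(np.subtract.outer(np.arange(nb), np.arange(nb)))
        valid = ~np.isnan(block)
        sums += np.bincount(d[valid], weights=block[valid], minlength=max_nb)[:max_nb]
        counts += np.bincount(d[valid], minlength=max_nb)[:max_nb]
    with np.errstate(invalid="ignore"):
        expected = sums / counts  # NaN where a distance class is empty

    for name in slices:
        block = m.matrix[slices[name], slices[name]]
        nb = block.shape[0]
        d = np.abs(np.subtract.outer(np.arange(nb), np.arange(nb)))
        with np.errstate(invalid="ignore", divide="ignore"):
            out[slices[name], slices[name]] = block / expected[d]

    inter = ~m.intra_mask()
    if per_pair_inter:
        names = list(slices)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                blk = m.matrix[slices[a], slices[b]]
                mean = np.nanmean(blk) if np.any(~np.isnan(blk)) else np.nan
                with np.errstate(invalid="ignore", divide="ignore"):
                    out[slices[a], slices[b]] = blk / mean
                    out[slices[b], slices[a]] = m.matrix[slices[b], slices[a]] / mean
    else:
        vals = m.matrix[inter]
        mean = np.nanmean(vals) if np.any(~np.isnan(vals)) else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            out[inter] = m.matrix[inter] / mean

    return ContactMatrix(
        m.resolution,
        list(m.chromosomes),
        out,
        "observed_expected",
        m.condition,
        m.partial_bins,
    )


def distance_decay_curve(
    m: ContactMatrix, n_log_bins: int | None = None, min_distance_bins: int = 1
):
    """Median contact value per genomic distance, scaled to sum to 1.

    Distances are pooled over chromosomes. With ``n_log_bins`` the
    per-diagonal distances are grouped into log-spaced bins; otherwise one
    point per diagonal. Empty bins are omitted.
    """
    import pandas as pd

    slices = m.chrom_slices
    per_d: dict[int, list[np.ndarray]] = {}
    for name in slices:
        block = m.matrix[slices[name], slices[name]]
        nb = block.shape[0]
        for d in range(min_distance_bins, nb):
            vals = np.diagonal(block, offset=d)
            vals = vals[~np.isnan(vals)]
            if vals.size:
                per_d.setdefault(d, []).append(vals)

    distances = np.array(sorted(per_d), dtype=float)
    if distances.size == 0:
        raise ValueError("no unmasked intra-chromosomal entries")
    medians = np.array(
        [np.median(np.concatenate(per_d[int(d)])) for d in distances]
    )
    dist_bp = distances * m.resolution

    if n_log_bins is not None:
        edges = np.geomspace(dist_bp.min(), dist_bp.max() * (1 + 1e-12), n_log_bins + 1)
        idx = np.clip(np.digitize(dist_bp, edges) - 1, 0, n_log_bins - 1)
        rows = []
        for b in range(n_log_bins):
            sel = idx == b
            if not sel.any():
                continue  # empty distance bin omitted
            pooled = np.concatenate(
                [v for d in distances[sel] for v in per_d[int(d)]]
            )
            rows.append(
                (float(np.exp(np.mean(np.log(dist_bp[sel])))), float(np.median(pooled)))
            )
        dist_bp = np.array([r[0] for r in rows])
        medians = np.array([r[1] for r in rows])

    total = medians.sum()
    probability = medians / total if total > 0 else medians
    return pd.DataFrame(
        {"distance_bp": dist_bp, "median": medians, "probability": probability}
    )


def fit_decay_exponent(curve, min_bp: float | None = None, max_bp: float | None = None) -> float:
    """Log-log slope of the median decay curve over an optional bp range."""
    sel = curve["median"] > 0
    if min_bp is not None:
        sel &= curve["distance_bp"] >= min_bp
    if max_bp is not None:
        sel &= curve["distance_bp"] <= max_bp
    x = np.log(curve.loc[sel, "distance_bp"].to_numpy())
    y = np.log(curve.loc[sel, "median"].to_numpy())
    if x.size < 2:
        raise ValueError("not enough points to fit a slope")
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def differential_map(
    a: ContactMatrix, b: ContactMatrix, eps: float | None = None
) -> ContactMatrix:
    """Element-wise log2((a + eps) / (b + eps)); a is the perturbed
    condition, b the control. ``eps`` defaults to the smallest positive
    unmasked value of the control. Entries masked in either input stay
    masked."""
    if not a.same_geometry(b):
        raise ValueError("matrices have different geometry")
    if a.state != b.state:
        raise ValueError("matrices have different normalization states")
    if eps is None:
        positive = b.matrix[np.nan_to_num(b.matrix) > 0]
        if positive.size == 0:
            raise ValueError("control matrix has no positive entries; pass eps")
        eps = float(positive.min())
    if eps < 0:
        raise ValueError("eps must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2((a.matrix + eps) / (b.matrix + eps))
    out[np.isnan(a.matrix) | np.isnan(b.matrix)] = np.nan
    label = f"{a.condition}/{b.condition}" if a.condition and b.condition else None
    return ContactMatrix(
        a.resolution, list(a.chromosomes), out, "log2_ratio", label, a.partial_bins
    )


# ---------------------------------------------------------------------------
# rank quantization and pair aggregation
# ---------------------------------------------------------------------------


def rank_quantize(window: np.ndarray) -> np.ndarray:
    """Replace each cell by ``(rank - 1) / (n - 1)`` with average ties.

    ``n`` is the number of non-missing cells; missing (NaN) cells stay
    missing. Any strictly monotone transform of the input yields identical
    output. An all-missing window maps to an all-missing output; a window
    with a single non-missing cell maps that cell to 0.5.
    """
    window = np.asarray(window, dtype=float)
    if window.size < 2:
        raise ValueError("window must have at least 2 cells")
    flat = window.ravel()
    valid = ~np.isnan(flat)
    out = np.full(flat.shape, np.nan)
    n = int(valid.sum())
    if n == 1:
        out[valid] = 0.5
    elif n > 1:
        ranks = rankdata(flat[valid], method="average")
        out[valid] = (ranks - 1.0) / (n - 1.0)
    return out.reshape(window.shape)


@dataclass
class PairSubmatrixStack:
    """Sliding-window frames collected over the region pairs of one class.

    ``focus`` names where the planted/biological signal concentrates in
    the oriented frames: ``"corner"`` (index (0, 0); telomere pairs, whose
    regions put the repeat-proximal bin first) or ``"center"`` (centromere
    pairs, whose regions are centred on the centromere midpoint).
    """

    pair_class: str
    windows: np.ndarray  # (n_frames, w, w) raw values
    quantized: np.ndarray  # (n_frames, w, w) rank-quantized per frame
    n_pairs: int
    window_size: int
    step: int
    pairs: list[tuple[tuple[str, str], tuple[str, str]]] = field(default_factory=list)
    focus: str = "corner"

    def __post_init__(self) -> None:
        if self.windows.shape != self.quantized.shape:
            raise ValueError("raw/quantized frame stacks differ in shape")
        if self.focus not in ("corner", "center"):
            raise ValueError(f"bad focus {self.focus!r}")

    @property
    def n_frames(self) -> int:
        return self.windows.shape[0]

    def aggregate(self) -> np.ndarray:
        """Element-wise mean over raw frames."""
        return np.nanmean(self.windows, axis=0)

    def aggregate_quantized(self) -> np.ndarray:
        return np.nanmean(self.quantized, axis=0)

    def window_means(self) -> np.ndarray:
        """Per-frame mean of raw values (reported, but not the default test
        summary: observed/expected re-centres each diagonal, so a localized
        gain raises the focus block while depressing the rest of the frame,
        leaving the frame mean nearly unchanged)."""
        return np.nanmean(self.windows, axis=(1, 2))

    def _block(self, frames: np.ndarray, size: int) -> np.ndarray:
        if not (1 <= size <= self.window_size):
            raise ValueError("summary block exceeds window")
        if self.focus == "corner":
            return frames[:, :size, :size]
        lo = (self.window_size - size) // 2
        return frames[:, lo : lo + size, lo : lo + size]

    def block_means(self, variant: str = "raw", size: int = DEFAULT_CORNER) -> np.ndarray:
        """Per-frame mean over the focus block (raw or quantized values).

        These are the per-window summaries fed to the condition test. The
        quantized variant is scale-free (within-window ranks are invariant
        under any common scaling of a frame); the frame-wide mean of a
        quantized window would be identically 0.5 and carry no signal.
        """
        if variant == "raw":
            return np.nanmean(self._block(self.windows, size), axis=(1, 2))
        if variant == "quantized":
            return np.nanmean(self._block(self.quantized, size), axis=(1, 2))
        raise ValueError(f"unknown variant {variant!r}")

    def score(self, size: int = DEFAULT_CORNER) -> float:
        """Aggregate score of the class: mean raw focus-block value."""
        return float(np.nanmean(self.block_means("raw", size)))


def _region_bin_indices(region: TelomereRegion, m: ContactMatrix) -> np.ndarray | None:
    """Global bin indices of an end region, repeat-proximal bin first.

    Returns None when the region does not hold an integer number of full
    bins on its chromosome (truncated region shorter than requested).
    """
    if region.length % m.resolution != 0:
        return None
    k = region.length // m.resolution
    sl = m.chrom_slices[region.chrom]
    nb = sl.stop - sl.start
    if k > nb:
        return None
    if region.side == "left":
        return np.arange(sl.start, sl.start + k)
    return np.arange(sl.stop - 1, sl.stop - 1 - k, -1)


def _sliding_frames(sub: np.ndarray, window: int, step: int) -> np.ndarray:
    k0, k1 = sub.shape
    placements = [
        sub[r : r + window, c : c + window]
        for r in range(0, k0 - window + 1, step)
        for c in range(0, k1 - window + 1, step)
    ]
    return np.stack(placements)


def _build_stacks(
    pair_list: Sequence[tuple[str, np.ndarray, np.ndarray, tuple, tuple]],
    m: ContactMatrix,
    window: int,
    step: int,
    focus: str = "corner",
) -> dict[str, PairSubmatrixStack]:
    by_class: dict[str, dict] = {}
    for pair_class, bins_a, bins_b, key_a, key_b in pair_list:
        sub = m.matrix[np.ix_(bins_a, bins_b)]
        if pair_class == "intra" and key_a[0] == key_b[0]:
            # an unordered pair of ends of one chromosome has no canonical
            # row/column assignment; symmetrize so aggregates are invariant
            # under reversing the chromosome's stored orientation
            sub = (sub + sub.T) / 2.0
        frames = _sliding_frames(sub, window, step)
        entry = by_class.setdefault(
            pair_class, {"frames": [], "pairs": [], "n_pairs": 0}
        )
        entry["frames"].append(frames)
        entry["pairs"].append((key_a, key_b))
        entry["n_pairs"] += 1

    stacks = {}
    for pair_class, entry in by_class.items():
        windows = np.concatenate(entry["frames"], axis=0)
        quantized = np.stack([rank_quantize(w) for w in windows])
        stacks[pair_class] = PairSubmatrixStack(
            pair_class=pair_class,
            windows=windows,
            quantized=quantized,
            n_pairs=entry["n_pairs"],
            window_size=window,
            step=step,
            pairs=entry["pairs"],
            focus=focus,
        )
    return stacks


def telomere_aggregate(
    m: ContactMatrix,
    genome: GenomeModel,
    region_bp: int = 150_000,
    window: int = 21,
    step: int = 1,
) -> tuple[dict[str, PairSubmatrixStack], list[TelomerePair]]:
    """Aggregate end-region submatrices over all telomere pairs.

    For every unordered pair of chromosome-end regions (``region_bp``
    distal window, binned at the matrix resolution, oriented so the
    repeat-proximal bin is index 0) the end-region x end-region submatrix
    is extracted and a ``window x window`` frame slides over it at the
    given step. Frames are pooled per pair class (intra/inter) with both
    raw and rank-quantized variants retained. Pairs whose regions are
    truncated below the window size are excluded and returned.
    """
    if region_bp % m.resolution != 0:
        raise ValueError("region_bp must be a multiple of the resolution")
    k = region_bp // m.resolution
    if k < window:
        raise ValueError("end region smaller than the sliding window")

    pairs = enumerate_telomere_pairs(genome, extent=region_bp)
    usable, excluded = [], []
    for pair in pairs:
        bins_a = _region_bin_indices(pair.region_a, m)
        bins_b = _region_bin_indices(pair.region_b, m)
        if bins_a is None or bins_b is None or bins_a.size < window or bins_b.size < window:
            excluded.append(pair)
            continue
        usable.append(
            (pair.pair_class, bins_a, bins_b, pair.region_a.key, pair.region_b.key)
        )
    stacks = _build_stacks(usable, m, window, step)
    return stacks, excluded


def centromere_aggregate(
    m: ContactMatrix,
    genome: GenomeModel,
    region_bp: int = 150_000,
    window: int = 21,
    step: int = 1,
) -> PairSubmatrixStack:
    """Aggregate over inter-chromosomal centromere-region pairs.

    Regions of ``region_bp`` are centered on each centromere midpoint (one
    per chromosome); used as the no-change control alongside the telomere
    aggregation.
    """
    if region_bp % m.resolution != 0:
        raise ValueError("region_bp must be a multiple of the resolution")
    k = region_bp // m.resolution
    if k < window:
        raise ValueError("region smaller than the sliding window")

    regions = []
    for cen in genome.features_of_class("centromere"):
        sl = m.chrom_slices[cen.chrom]
        mid_bin = sl.start + ((cen.start + cen.end) // 2) // m.resolution
        start = mid_bin - k // 2
        if start < sl.start or start + k > sl.stop:
            raise ValueError(f"centromere region exceeds chromosome {cen.chrom}")
        regions.append(((cen.chrom, "cen"), np.arange(start, start + k)))
    if len(regions) < 2:
        raise ValueError("need at least two centromeres")

    import itertools as _it

    pair_list = [
        ("cen", bins_a, bins_b, key_a, key_b)
        for (key_a, bins_a), (key_b, bins_b) in _it.combinations(regions, 2)
    ]
    return _build_stacks(pair_list, m, window, step, focus="center")["cen"]


@dataclass(frozen=True)
class ComparisonResult:
    """Condition comparison of one pair class, both test variants."""

    pair_class: str
    score_a: float
    score_b: float
    raw_test: stats.TestResult
    quantized_test: stats.TestResult
    alpha: float

    @property
    def significant_raw(self) -> bool:
        return self.raw_test.p_value < self.alpha

    @property
    def significant_quantized(self) -> bool:
        return self.quantized_test.p_value < self.alpha


def compare_conditions(
    stack_a: PairSubmatrixStack,
    stack_b: PairSubmatrixStack,
    alpha: float = DEFAULT_ALPHA,
    block: int = DEFAULT_CORNER,
    method: str = "auto",
) -> ComparisonResult:
    """Two-sided Mann-Whitney between two conditions of one pair class.

    Both variants test per-window summaries over the focus block (the
    repeat-proximal corner for telomere pairs, the centre for centromere
    pairs): raw observed/expected values for the non-quantized variant and
    rank-quantized values for the quantized variant. The quantized variant
    is insensitive to any common rescaling of a frame, so it is the robust
    choice for "no change" decisions under global normalization shifts.
    """
    if stack_a.pair_class != stack_b.pair_class:
        raise ValueError("pair classes differ")
    if stack_a.window_size != stack_b.window_size or stack_a.focus != stack_b.focus:
        raise ValueError("window geometries differ")
    raw_a = stack_a.block_means("raw", block)
    raw_b = stack_b.block_means("raw", block)
    raw_a, raw_b = raw_a[~np.isnan(raw_a)], raw_b[~np.isnan(raw_b)]
    if raw_a.size < 2 or raw_b.size < 2:
        raise ValueError("fewer than 2 windows in a condition")
    q_a = stack_a.block_means("quantized", block)
    q_b = stack_b.block_means("quantized", block)
    q_a, q_b = q_a[~np.isnan(q_a)], q_b[~np.isnan(q_b)]

    raw_test = stats.mann_whitney(raw_a, raw_b, method=method)
    quant_test = stats.mann_whitney(q_a, q_b, method=method)
    return ComparisonResult(
        pair_class=stack_a.pair_class,
        score_a=float(np.mean(raw_a)),
        score_b=float(np.mean(raw_b)),
        raw_test=raw_test,
        quantized_test=quant_test,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# dense TSV I/O
# ---------------------------------------------------------------------------


def write_matrix_tsv(m: ContactMatrix, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write(f"# resolution\t{m.resolution}\n")
        handle.write(f"# state\t{m.state}\n")
        handle.write(f"# condition\t{m.condition or ''}\n")
        handle.write(f"# partial_bins\t{','.join(m.partial_bins)}\n")
        for name, length in m.chromosomes:
            handle.write(f"# chrom\t{name}\t{length}\n")
        np.savetxt(handle, m.matrix, delimiter="\t", fmt="%.10g")


def read_matrix_tsv(path: str | Path) -> ContactMatrix:
    resolution = None
    state = "raw"
    condition: str | None = None
    partial: tuple[str, ...] = ()
    chromosomes: list[tuple[str, int]] = []
    data_start = 0
    with open(path) as handle:
        lines = handle.readlines()
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            data_start = i
            break
        parts = line[1:].strip().split("\t")
        if parts[0] == "resolution":
            resolution = int(parts[1])
        elif parts[0] == "state":
            state = parts[1]
        elif parts[0] == "condition":
            condition = parts[1] or None
        elif parts[0] == "partial_bins":
            partial = tuple(p for p in parts[1].split(",") if p) if len(parts) > 1 else ()
        elif parts[0] == "chrom":
            chromosomes.append((parts[1], int(parts[2])))
    if resolution is None or not chromosomes:
        raise ValueError(f"{path}: missing matrix header")
    matrix = np.loadtxt(lines[data_start:], delimiter="\t", ndmin=2)
    return ContactMatrix(resolution, chromosomes, matrix, state, condition, partial)
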