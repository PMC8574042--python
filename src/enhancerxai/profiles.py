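"""Region-anchored signal profiles, winsorized heatmap matrices,
transcription directionality, observed/expected enrichment, genomic
feature overlap, and TAD-border proximity."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .calling import EnhancerRegion
from .io import GeneModel
from .linkage import promoter_intervals
from .tracks import GenomeBins

DEFAULT_FLANK = 5000
DEFAULT_WINDOW = 500
DEFAULT_OFFSET = 500
DEFAULT_TAD_DISTANCE = 2000

BIDIRECTIONAL = "bidirectional"
POSITIVE = "positive"
NEGATIVE = "negative"
NON_TRANSCRIBED = "non_transcribed"

# genomic feature categories, highest precedence first
CATEGORY_PRECEDENCE = (
    "promoter",
    "utr5",
    "utr3",
    "exon",
    "first_intron",
    "other_intron",
    "intergenic",
)


@dataclass
class ProfileMatrix:
    region_ids: list[str]
    offsets: np.ndarray  # bp offsets relative to region centers
    values: np.ndarray  # (n_regions, n_offsets); NaN where off-chromosome
    mode: str | None = None  # None = raw; "unsigned"/"signed" after rescale


@dataclass
class DirectionalityRecord:
    region_id: str
    score: float
    label: str
    plus_signal: float
    minus_signal: float


@dataclass
class EnrichmentRecord:
    group: str
    category: str
    observed: float
    expected: float
    log2_ratio: float


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


def profile_matrix(
    track: np.ndarray,
    regions: list[EnhancerRegion],
    bins: GenomeBins,
    flank: int = DEFAULT_FLANK,
) -> ProfileMatrix:
    """Sample the per-bin track at fixed offsets around each region's
    midpoint (span +/- ``flank``); rows are sorted by region size
    descending so the largest region is on top."""
    if not regions:
        raise ValueError("no regions to profile")
    track = np.asarray(track, dtype=float)
    if len(track) != bins.n_bins:
        raise ValueError("track not aligned to the bin grid")
    w = bins.width
    n_side = flank // w
    offsets = (np.arange(2 * n_side + 1) - n_side) * w
    order = sorted(
        range(len(regions)),
        key=lambda i: (-(regions[i].end - regions[i].start), regions[i].chrom, regions[i].start),
    )
    values = np.full((len(regions), len(offsets)), np.nan)
    ids = []
    for row, i in enumerate(order):
        region = regions[i]
        ids.append(region.region_id)
        center = (region.start + region.end) // 2
        size = bins.sizes[region.chrom]
        off = bins.offsets[region.chrom]
        pos = center + offsets
        ok = (pos >= 0) & (pos < size)
        idx = off + pos[ok] // w
        values[row, ok] = track[idx]
    return ProfileMatrix(ids, offsets, values)


def winsorize_rescale(
    matrix: ProfileMatrix, mode: str = "unsigned", q: float = 0.95
) -> ProfileMatrix:
    """Winsorize and rescale a raw profile matrix.

    unsigned: negatives -> 0, cap at the ``q`` quantile of positive
    entries, rescale to [0, 1].  signed: positive and negative entries
    are capped (at the ``q`` quantile of their magnitudes) and rescaled
    separately to [0, 1] and [-1, 0].
    """
    if mode not in ("unsigned", "signed"):
        raise ValueError(f"unknown mode {mode!r}")
    v = matrix.values.copy()
    finite = np.isfinite(v)
    pos = finite & (v > 0)
    neg = finite & (v < 0)
    if not pos.any() and not neg.any():
        warnings.warn("all-zero matrix left unchanged by winsorize_rescale")
        return ProfileMatrix(list(matrix.region_ids), matrix.offsets.copy(), v, mode)
    # the "higher" order statistic keeps the transform exactly idempotent:
    # after rescaling, the q-quantile of the capped entries is exactly 1
    if mode == "unsigned":
        v[finite & (v < 0)] = 0.0
        if pos.any():
            cap = float(np.quantile(v[pos], q, method="higher"))
            if cap > 0:
                v[finite] = np.minimum(v[finite], cap) / cap
    else:
        if pos.any():
            cap = float(np.quantile(v[pos], q, method="higher"))
            if cap > 0:
                v[pos] = np.minimum(v[pos], cap) / cap
        if neg.any():
            cap = float(np.quantile(-v[neg], q, method="higher"))
            if cap > 0:
                v[neg] = np.maximum(v[neg], -cap) / cap
    return ProfileMatrix(list(matrix.region_ids), matrix.offsets.copy(), v, mode)


# ---------------------------------------------------------------------------
# transcription directionality
# ---------------------------------------------------------------------------


def directionality_score(
    plus: np.ndarray,
    minus: np.ndarray,
    region: EnhancerRegion,
    bins: GenomeBins,
    window: int = DEFAULT_WINDOW,
    offset: int = DEFAULT_OFFSET,
    pseudocount: float = 1.0,
    transcription_floor: float = 1.0,
) -> DirectionalityRecord | None:
    """log10 ratio of plus- over minus-strand nascent signal in the two
    ``window``-bp flanks placed ``offset`` bp outside the region borders.

    Both strands are summed over the same two windows, which makes the
    score exactly antisymmetric under a plus/minus swap.  Scores within
    [-0.5, 0.5] are bidirectional; regions whose total flank signal is
    below ``transcription_floor`` are non_transcribed.  Returns ``None``
    when a flank falls off the chromosome.
    """
    w = bins.width
    size = bins.sizes[region.chrom]
    off = bins.offsets[region.chrom]
    left_lo = region.start - offset - window
    left_hi = region.start - offset
    right_lo = region.end + offset
    right_hi = region.end + offset + window
    if left_lo < 0 or right_hi > size:
        return None

    def window_sum(track, lo, hi):
        i0 = off + lo // w
        i1 = off + -(-hi // w)
        return float(np.abs(track[i0:i1]).sum())

    p = window_sum(plus, left_lo, left_hi) + window_sum(plus, right_lo, right_hi)
    n = window_sum(minus, left_lo, left_hi) + window_sum(minus, right_lo, right_hi)
    score = float(np.log10((p + pseudocount) / (n + pseudocount)))
    if p + n < transcription_floor:
        label = NON_TRANSCRIBED
    elif -0.5 <= score <= 0.5:
        label = BIDIRECTIONAL
    elif score > 0.5:
        label = POSITIVE
    else:
        label = NEGATIVE
    return DirectionalityRecord(region.region_id, score, label, p, n)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def obs_exp_signal_enrichment(
    track: np.ndarray,
    regions: list[EnhancerRegion],
    bins: GenomeBins,
    group: str = "regions",
    expected_floor: float = 1e-9,
) -> EnrichmentRecord:
    """log2 of (mean track value over bins inside the regions) over
    (mean over the whole genome)."""
    if not regions:
        raise ValueError("empty region group")
    track = np.asarray(track, dtype=float)
    mask = np.zeros(bins.n_bins, dtype=bool)
    for region in regions:
        lo, hi = bins.bin_span(region.chrom, region.start, region.end)
        mask[lo:hi] = True
    observed = float(track[mask].mean())
    expected = float(track.mean())
    ratio = np.log2(max(observed, expected_floor) / max(expected, expected_floor))
    return EnrichmentRecord(group, "signal", observed, expected, float(ratio))


def annotation_category_map(
    genes: list[GeneModel], bins: GenomeBins
) -> dict[str, np.ndarray]:
    """Per-chromosome, per-base category codes (index into
    :data:`CATEGORY_PRECEDENCE`).  Bases in several categories get the
    highest-precedence one (promoter > 5'UTR > 3'UTR > exon > first
    intron > other intron > intergenic)."""
    code = {cat: i for i, cat in enumerate(CATEGORY_PRECEDENCE)}
    maps = {
        chrom: np.full(bins.sizes[chrom], code["intergenic"], dtype=np.int8)
        for chrom in bins.chrom_order
    }
    promoters = promoter_intervals(genes)

    def paint(chrom, start, end, cat):
        if chrom not in maps:
            return
        arr = maps[chrom]
        start = max(0, int(start))
        end = min(len(arr), int(end))
        if end > start:
            arr[start:end] = code[cat]

    # paint lowest precedence first so higher categories overwrite
    for g in genes:
        for iv in g.other_introns():
            paint(g.chrom, iv[0], iv[1], "other_intron")
    for g in genes:
        fi = g.first_intron()
        if fi is not None:
            paint(g.chrom, fi[0], fi[1], "first_intron")
    for g in genes:
        for s, e in g.exons:
            paint(g.chrom, s, e, "exon")
    for g in genes:
        if g.utr3 is not None:
            paint(g.chrom, g.utr3[0], g.utr3[1], "utr3")
        if g.utr5 is not None:
            paint(g.chrom, g.utr5[0], g.utr5[1], "utr5")
    for chrom, start, end, *_ in promoters.itertuples(index=False):
        paint(chrom, start, end, "promoter")
    return maps


def feature_overlap_enrichment(
    regions: list[EnhancerRegion],
    category_map: dict[str, np.ndarray],
    group: str = "regions",
    expected_floor: float = 1e-9,
) -> list[EnrichmentRecord]:
    """Per category: observed = fraction of region bases in the category;
    expected = genome-wide base fraction; report log2(obs/exp)."""
    n_cat = len(CATEGORY_PRECEDENCE)
    genome_counts = np.zeros(n_cat, dtype=np.int64)
    for arr in category_map.values():
        genome_counts += np.bincount(arr, minlength=n_cat)
    region_counts = np.zeros(n_cat, dtype=np.int64)
    for region in regions:
        arr = category_map[region.chrom]
        seg = arr[max(0, region.start) : min(len(arr), region.end)]
        region_counts += np.bincount(seg, minlength=n_cat)
    total_region = region_counts.sum()
    total_genome = genome_counts.sum()
    if total_region == 0:
        raise ValueError("regions cover zero bases")
    records = []
    for i, cat in enumerate(CATEGORY_PRECEDENCE):
        observed = region_counts[i] / total_region
        expected = genome_counts[i] / total_genome
        ratio = np.log2(
            max(observed, expected_floor) / max(expected, expected_floor)
        )
        records.append(EnrichmentRecord(group, cat, observed, expected, float(ratio)))
    return records


def tad_proximity(
    regions: list[EnhancerRegion],
    borders: pd.DataFrame,
    distance: int = DEFAULT_TAD_DISTANCE,
) -> dict[str, bool]:
    """True when a TAD border (position or interval) lies within
    ``distance`` bp of the region (gap distance, 0 when overlapping)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in zip(borders["chrom"], borders["start"], borders["end"]):
        by_chrom.setdefault(chrom, []).append((int(start), int(max(end, start + 1))))
    out = {}
    for region in regions:
        flag = False
        for b_start, b_end in by_chrom.get(region.chrom, ()):
            if region.start < b_end and b_start < region.end:
                gap = 0
            elif b_start >= region.end:
                gap = b_start - region.end
            else:
                gap = region.start - b_end
            if gap <= distance:
                flag = True
                break
        out[region.region_id] = flag
    return out


def body_percentile_score(
    track: np.ndarray,
    region: EnhancerRegion,
    bins: GenomeBins,
    percentile: float = 95.0,
) -> float:
    """Percentile (linear interpolation between order statistics) of the
    track values across the region's bins."""
    lo, hi = bins.bin_span(region.chrom, region.start, region.end)
    if hi <= lo:
        raise ValueError(f"region {region.region_id} spans no bins")
    return float(np.percentile(np.asarray(track, float)[lo:hi], percentile))


def compare_groups(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two score groups."""
    res = mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def enrichment_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": [r.group for r in records],
            "category": [r.category for r in records],
            "observed": [r.observed for r in records],
            "expected": [r.expected for r in records],
            "log2_ratio": [r.log2_ratio for r in records],
        }
    )


def directionality_frame(records: list[DirectionalityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region": [r.region_id for r in records],
            "score": [r.score for r in records],
            "class": [r.label for r in records],
            "plus_signal": [r.plus_signal for r in records],
            "minus_signal": [r.minus_signal for r in records],
        }
    )
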