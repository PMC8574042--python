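"""Turn per-bin enhancer probabilities into called regions.

Candidate regions are maximal runs of bins at or above the probability
threshold (default 0.8).  Neighbouring candidates within the merge gap
(default 100 bp) are merged when the combined mean probability over
their member bins is strictly above the threshold; merging iterates to a
fixpoint.  Regions are then classed by size (fragment / enhancer /
super_enhancer) and, against a reference set, by origin (common /
putative / reference_only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracks import GenomeBins

FRAGMENT = "fragment"
ENHANCER_SIZE = "enhancer"
SUPER_ENHANCER = "super_enhancer"

COMMON = "common"
PUTATIVE = "putative"
REFERENCE_ONLY = "reference_only"


@dataclass
class CallingConfig:
    threshold: float = 0.8
    merge_gap: int = 100
    fragment_max: int = 50  # regions shorter than this are fragments
    super_min: int = 1000  # regions longer than this are super-enhancers

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be inside (0, 1)")
        if self.merge_gap < 0:
            raise ValueError("merge gap must be >= 0")
        if self.fragment_max >= self.super_min:
            raise ValueError("fragment boundary must be below super-enhancer size")


@dataclass
class EnhancerRegion:
    chrom: str
    start: int
    end: int
    mean_probability: float
    size_class: str | None = None
    origin: str | None = None
    bin_spans: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("region end must exceed start")

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def call_candidate_regions(
    probabilities: np.ndarray,
    bins: GenomeBins,
    config: CallingConfig | None = None,
) -> list[EnhancerRegion]:
    """Maximal runs of contiguous bins with probability >= threshold
    ("0.8 or higher": the boundary value is included)."""
    config = config or CallingConfig()
    probabilities = np.asarray(probabilities, dtype=float)
    if len(probabilities) != bins.n_bins:
        raise ValueError(
            f"{len(probabilities)} probabilities for {bins.n_bins} bins"
        )
    regions: list[EnhancerRegion] = []
    chrom_idx, starts, ends = bins.coordinates()
    above = probabilities >= config.threshold
    i = 0
    n = bins.n_bins
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i + 1
        while j < n and above[j] and chrom_idx[j] == chrom_idx[i]:
            j += 1
        regions.append(
            EnhancerRegion(
                chrom=bins.chrom_order[chrom_idx[i]],
                start=int(starts[i]),
                end=int(ends[j - 1]),
                mean_probability=float(probabilities[i:j].mean()),
                bin_spans=[(i, j)],
            )
        )
        i = j
    return regions


def _member_mean(spans: list[tuple[int, int]], probabilities: np.ndarray) -> float:
    total = 0.0
    count = 0
    for lo, hi in spans:
        total += float(probabilities[lo:hi].sum())
        count += hi - lo
    return total / count


def merge_regions(
    candidates: list[EnhancerRegion],
    probabilities: np.ndarray,
    config: CallingConfig | None = None,
) -> list[EnhancerRegion]:
    """Merge neighbouring candidates within the gap limit when the mean
    probability over both regions' member bins is strictly above the
    threshold.  Gap bins are spanned by the merged region but excluded
    from its mean.  The scan restarts after every merge, so the result is
    a fixpoint (re-running changes nothing)."""
    config = config or CallingConfig()
    probabilities = np.asarray(probabilities, dtype=float)
    regions = list(candidates)
    if any(
        regions[i + 1].start < regions[i].start
        for i in range(len(regions) - 1)
        if regions[i + 1].chrom == regions[i].chrom
    ):
        warnings.warn("candidates were not sorted; sorting by coordinate")
        regions.sort(key=lambda r: (r.chrom, r.start))
    changed = True
    while changed:
        changed = False
        for i in range(len(regions) - 1):
            a, b = regions[i], regions[i + 1]
            if a.chrom != b.chrom:
                continue
            gap = b.start - a.end
            if gap > config.merge_gap:
                continue
            spans = a.bin_spans + b.bin_spans
            mean = _member_mean(spans, probabilities)
            if mean > config.threshold:
                regions[i : i + 2] = [
                    EnhancerRegion(
                        chrom=a.chrom,
                        start=a.start,
                        end=b.end,
                        mean_probability=mean,
                        bin_spans=spans,
                    )
                ]
                changed = True
                break
    return regions


def classify_size(
    region: EnhancerRegion, config: CallingConfig | None = None
) -> str:
    """< fragment_max bp: fragment; above super_min bp: super_enhancer;
    in between: enhancer."""
    config = config or CallingConfig()
    if region.size < config.fragment_max:
        cls = FRAGMENT
    elif region.size > config.super_min:
        cls = SUPER_ENHANCER
    else:
        cls = ENHANCER_SIZE
    region.size_class = cls
    return cls


def call_regions(
    probabilities: np.ndarray,
    bins: GenomeBins,
    config: CallingConfig | None = None,
    drop_fragments: bool = True,
) -> list[EnhancerRegion]:
    """Full calling: threshold -> merge -> size classification.  Fragments
    (regions shorter than 50 bp, likely signal noise) are dropped from
    downstream analyses by default."""
    config = config or CallingConfig()
    regions = merge_regions(
        call_candidate_regions(probabilities, bins, config), probabilities, config
    )
    for region in regions:
        classify_size(region, config)
    if drop_fragments:
        regions = [r for r in regions if r.size_class != FRAGMENT]
    return regions


def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    return a_start < b_end and b_start < a_end


def compare_to_reference(
    predicted: list[EnhancerRegion],
    reference: pd.DataFrame,
) -> tuple[list[EnhancerRegion], pd.DataFrame, dict[str, int]]:
    """Origin-classify predictions against a reference region set
    (>= 1 bp overlap -> common, else putative); reference regions with no
    predicted overlap are returned as reference_only."""
    ref_by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for k, (chrom, start, end) in enumerate(
        zip(reference["chrom"], reference["start"], reference["end"])
    ):
        ref_by_chrom.setdefault(chrom, []).append((int(start), int(end), k))
    ref_hit = np.zeros(len(reference), dtype=bool)
    for region in predicted:
        region.origin = PUTATIVE
        for start, end, k in ref_by_chrom.get(region.chrom, ()):
            if _overlaps(region.start, region.end, start, end):
                region.origin = COMMON
                ref_hit[k] = True
    ref_only = reference.loc[~ref_hit].reset_index(drop=True)
    summary = {
        COMMON: sum(r.origin == COMMON for r in predicted),
        PUTATIVE: sum(r.origin == PUTATIVE for r in predicted),
        REFERENCE_ONLY: int((~ref_hit).sum()),
    }
    return predicted, ref_only, summary


def regions_to_frame(regions: list[EnhancerRegion]) -> pd.DataFrame:
    """BED6-style frame: name = origin class (or size class), score =
    1000 * mean probability."""
    rows = [
        (
            r.chrom,
            r.start,
            r.end,
            r.origin or r.size_class or ".",
            round(1000 * r.mean_probability),
            ".",
        )
        for r in regions
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


def regions_from_frame(df: pd.DataFrame) -> list[EnhancerRegion]:
    regions = []
    for _, row in df.iterrows():
        region = EnhancerRegion(
            chrom=row["chrom"],
            start=int(row["start"]),
            end=int(row["end"]),
            mean_probability=float(row.get("score", 0.0)) / 1000.0,
        )
        name = row.get("name", ".")
        if name in (COMMON, PUTATIVE):
            region.origin = name
        regions.append(region)
    return regions
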