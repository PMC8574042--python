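"""Genome tiling, signal/label track construction, and the labeled bin dataset.

Coordinates are 0-based half-open throughout.  A genome is tiled into
fixed-width bins (default 10 bp; the last bin of each chromosome may be
shorter), continuous interval+value records are aggregated into per-bin
values, features are min-max normalized to [0, 1], and reporter-assay
peaks become binary bin labels.  A :class:`BinDataset` bundles the
feature matrix with labels and round-trips through a TSV + JSON sidecar.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_BIN_WIDTH = 10
DEFAULT_PEAK_WIDTH = 400


# ---------------------------------------------------------------------------
# bins
# ---------------------------------------------------------------------------


@dataclass
class GenomeBins:
    """Fixed-width tiling of a genome; bins partition each chromosome."""

    chrom_order: list[str]
    sizes: dict[str, int]
    width: int

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("bin width must be >= 1")
        if not self.chrom_order:
            raise ValueError("empty genome: no chromosomes to tile")
        for chrom in self.chrom_order:
            if self.sizes[chrom] <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive size")
        self.n_per_chrom = {
            c: -(-self.sizes[c] // self.width) for c in self.chrom_order
        }
        offsets, total = {}, 0
        for c in self.chrom_order:
            offsets[c] = total
            total += self.n_per_chrom[c]
        self.offsets = offsets
        self.n_bins = total

    def coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-bin (chrom index, start, end) arrays."""
        chrom_idx = np.empty(self.n_bins, dtype=np.int32)
        starts = np.empty(self.n_bins, dtype=np.int64)
        ends = np.empty(self.n_bins, dtype=np.int64)
        for i, chrom in enumerate(self.chrom_order):
            off = self.offsets[chrom]
            n = self.n_per_chrom[chrom]
            chrom_idx[off : off + n] = i
            s = np.arange(n, dtype=np.int64) * self.width
            starts[off : off + n] = s
            ends[off : off + n] = np.minimum(s + self.width, self.sizes[chrom])
        return chrom_idx, starts, ends

    def bin_span(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Global half-open bin-index range overlapping [start, end)."""
        off = self.offsets[chrom]
        n = self.n_per_chrom[chrom]
        lo = max(0, start // self.width)
        hi = min(n, -(-end // self.width))
        return off + lo, off + max(lo, hi)

    def widths(self) -> np.ndarray:
        _, s, e = self.coordinates()
        return (e - s).astype(np.int64)


def tile_genome(
    chrom_sizes: Mapping[str, int],
    width: int = DEFAULT_BIN_WIDTH,
    exclude: Iterable[str] = (),
) -> GenomeBins:
    """Tile each chromosome into ``ceil(length/width)`` bins; chromosomes in
    ``exclude`` (e.g. sex chromosomes) are dropped entirely."""
    exclude = list(exclude)
    unknown = [c for c in exclude if c not in chrom_sizes]
    if unknown:
        warnings.warn(f"excluded chromosomes not in genome: {unknown}")
    order = [c for c in chrom_sizes if c not in exclude]
    if not order:
        raise ValueError("empty genome after exclusions")
    return GenomeBins(order, {c: int(chrom_sizes[c]) for c in order}, int(width))


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------


@dataclass
class SignalTrack:
    mark: str
    values: np.ndarray
    normalized: bool = False
    norm_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class LabelTrack:
    values: np.ndarray  # boolean, True = enhancer

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)


def map_signal_to_bins(
    records: pd.DataFrame,
    bins: GenomeBins,
    mark: str = "signal",
    aggregator: str = "weighted_mean",
) -> SignalTrack:
    """Aggregate interval+value records (columns chrom/start/end/value)
    into one value per bin.

    The default aggregator is the coverage-weighted mean of overlapping
    record values; ``"max"`` takes the maximum overlapping value.  Bins
    with no record are 0.  Intervals are clipped to chromosome bounds;
    records on unknown chromosomes are skipped with a warning.
    """
    if aggregator not in ("weighted_mean", "max"):
        raise ValueError(f"unknown aggregator {aggregator!r}")
    wsum = np.zeros(bins.n_bins)
    cov = np.zeros(bins.n_bins)
    vmax = np.full(bins.n_bins, -np.inf)
    touched = np.zeros(bins.n_bins, dtype=bool)
    w = bins.width
    skipped = set()
    for row_i, (chrom, start, end, value) in enumerate(
        zip(records["chrom"], records["start"], records["end"], records["value"])
    ):
        if not np.isfinite(value):
            raise ValueError(f"record {row_i}: non-finite value {value!r}")
        if end <= start:
            raise ValueError(f"record {row_i}: empty interval [{start}, {end})")
        if chrom not in bins.offsets:
            skipped.add(chrom)
            continue
        size = bins.sizes[chrom]
        start = max(0, int(start))
        end = min(size, int(end))
        if end <= start:
            continue
        off = bins.offsets[chrom]
        gs = off + start // w
        ge = off + (end - 1) // w
        if aggregator == "max":
            vmax[gs : ge + 1] = np.maximum(vmax[gs : ge + 1], value)
            touched[gs : ge + 1] = True
            continue
        if gs == ge:
            ov = end - start
            wsum[gs] += value * ov
            cov[gs] += ov
        else:
            first = (start // w + 1) * w - start
            last = end - ((end - 1) // w) * w
            wsum[gs] += value * first
            cov[gs] += first
            wsum[ge] += value * last
            cov[ge] += last
            if ge > gs + 1:
                wsum[gs + 1 : ge] += value * w
                cov[gs + 1 : ge] += w
    if skipped:
        warnings.warn(f"records on unknown chromosomes skipped: {sorted(skipped)}")
    if aggregator == "max":
        values = np.where(touched, vmax, 0.0)
    else:
        values = np.divide(wsum, cov, out=np.zeros(bins.n_bins), where=cov > 0)
    return SignalTrack(mark, values)


def minmax_normalize(track: SignalTrack) -> SignalTrack:
    """Min-max normalize to [0, 1]; a constant track maps to all zeros."""
    if track.normalized:
        raise ValueError(f"track {track.mark!r} already normalized")
    v = track.values
    if np.any(~np.isfinite(v)):
        raise ValueError(f"track {track.mark!r} contains non-finite values")
    lo, hi = float(v.min()), float(v.max())
    if hi > lo:
        out = (v - lo) / (hi - lo)
    else:
        out = np.zeros_like(v)
    return SignalTrack(track.mark, out, normalized=True, norm_bounds=(lo, hi))


# ---------------------------------------------------------------------------
# peaks and labels
# ---------------------------------------------------------------------------


def expand_peaks(
    peaks: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    target_width: int = DEFAULT_PEAK_WIDTH,
) -> pd.DataFrame:
    """Replace each peak by a ``target_width`` interval centered on its
    midpoint (peaks already wider are kept); clip to chromosome bounds and
    merge overlapping results."""
    rows = []
    for chrom, start, end in zip(peaks["chrom"], peaks["start"], peaks["end"]):
        if chrom not in chrom_sizes:
            raise ValueError(f"peak on unknown chromosome {chrom!r}")
        size = chrom_sizes[chrom]
        if start < 0 or end > size or end <= start:
            raise ValueError(f"peak [{start}, {end}) off chromosome {chrom!r}")
        width = end - start
        if width < target_width:
            mid = (start + end) // 2
            start = mid - target_width // 2
            end = start + target_width
            start = max(0, start)
            end = min(size, end)
        rows.append((chrom, start, end))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return merge_intervals(df)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or book-ended intervals per chromosome."""
    if df.empty:
        return df.copy()
    out = []
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values(["start", "end"])
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def label_bins(bins: GenomeBins, regions: pd.DataFrame) -> LabelTrack:
    """A bin is labeled enhancer iff it overlaps any region by >= 1 bp."""
    labels = np.zeros(bins.n_bins, dtype=bool)
    if len(regions):
        for chrom, start, end in zip(
            regions["chrom"], regions["start"], regions["end"]
        ):
            if chrom not in bins.offsets:
                continue
            lo, hi = bins.bin_span(chrom, int(start), int(end))
            labels[lo:hi] = True
    return LabelTrack(labels)


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------


@dataclass
class BinDataset:
    """Per-bin feature matrix plus labels.

    ``chrom_codes`` indexes into ``chrom_order``; ``X`` has one column per
    mark in ``feature_order``; ``y`` is the boolean enhancer label.
    """

    chrom_order: list[str]
    chrom_codes: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    X: np.ndarray
    y: np.ndarray
    feature_order: list[str]
    bin_width: int
    norm_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.starts)
        if not (
            len(self.chrom_codes) == len(self.ends) == n
            and self.X.shape == (n, len(self.feature_order))
            and len(self.y) == n
        ):
            raise ValueError("dataset arrays are inconsistent")

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    def features(self, i: int) -> dict[str, float]:
        return {m: float(self.X[i, j]) for j, m in enumerate(self.feature_order)}

    def subset(self, idx: np.ndarray) -> "BinDataset":
        return BinDataset(
            self.chrom_order,
            self.chrom_codes[idx],
            self.starts[idx],
            self.ends[idx],
            self.X[idx],
            self.y[idx],
            list(self.feature_order),
            self.bin_width,
            dict(self.norm_bounds),
        )

    # -- persistence --------------------------------------------------------

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(
            {
                "chrom": [self.chrom_order[c] for c in self.chrom_codes],
                "start": self.starts,
                "end": self.ends,
            }
        )
        for j, mark in enumerate(self.feature_order):
            df[mark] = self.X[:, j]
        df["label"] = self.y.astype(int)
        df.to_csv(outdir / "dataset.tsv", sep="\t", index=False, float_format="%.6g")
        sidecar = {
            "bin_width": self.bin_width,
            "chrom_order": self.chrom_order,
            "feature_order": self.feature_order,
            "norm_bounds": {m: list(b) for m, b in self.norm_bounds.items()},
        }
        with open(outdir / "dataset.json", "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, outdir) -> "BinDataset":
        outdir = Path(outdir)
        with open(outdir / "dataset.json") as fh:
            sidecar = json.load(fh)
        df = pd.read_csv(outdir / "dataset.tsv", sep="\t")
        order = sidecar["chrom_order"]
        code = {c: i for i, c in enumerate(order)}
        return cls(
            order,
            np.array([code[c] for c in df["chrom"]], dtype=np.int32),
            df["start"].to_numpy(np.int64),
            df["end"].to_numpy(np.int64),
            df[sidecar["feature_order"]].to_numpy(float),
            df["label"].to_numpy(bool),
            list(sidecar["feature_order"]),
            int(sidecar["bin_width"]),
            {m: tuple(b) for m, b in sidecar["norm_bounds"].items()},
        )


def build_dataset(
    bins: GenomeBins,
    tracks: Mapping[str, SignalTrack],
    labels: LabelTrack,
    feature_order: Sequence[str] | None = None,
) -> BinDataset:
    """Assemble a :class:`BinDataset` from aligned tracks on one bin grid."""
    order = list(feature_order) if feature_order is not None else list(tracks)
    for mark in order:
        if len(tracks[mark].values) != bins.n_bins:
            raise ValueError(f"track {mark!r} not aligned to bin grid")
    if len(labels.values) != bins.n_bins:
        raise ValueError("label track not aligned to bin grid")
    chrom_idx, starts, ends = bins.coordinates()
    X = np.column_stack([tracks[m].values for m in order])
    bounds = {
        m: tracks[m].norm_bounds for m in order if tracks[m].norm_bounds is not None
    }
    return BinDataset(
        list(bins.chrom_order),
        chrom_idx,
        starts,
        ends,
        X,
        labels.values.copy(),
        order,
        bins.width,
        bounds,
    )


def sample_training_set(
    dataset: BinDataset,
    n: int = 1_000_000,
    test_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[BinDataset, BinDataset]:
    """Stratified sample of ``n`` bins (without replacement) preserving the
    genome-wide enhancer:non-enhancer ratio, split into disjoint
    train/test sets that each preserve the ratio as well."""
    if n > dataset.n_bins:
        raise ValueError(f"cannot sample {n} bins from {dataset.n_bins}")
    if not 0.0 <= test_fraction < 1.0:
        raise ValueError("test_fraction must be in [0, 1)")
    y = dataset.y
    n_pos_total = int(y.sum())
    if n_pos_total == 0 or n_pos_total == len(y):
        raise ValueError("both classes must be present genome-wide")
    rng = np.random.default_rng(seed)
    n_pos = int(round(n * n_pos_total / len(y)))
    n_pos = min(max(n_pos, 1), n_pos_total, n - 1)
    n_neg = n - n_pos
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    pos_take = rng.choice(pos_idx, size=n_pos, replace=False)
    neg_take = rng.choice(neg_idx, size=n_neg, replace=False)
    n_test = int(round(n * test_fraction))
    n_test_pos = int(round(n_test * n_pos / n))
    n_test_neg = n_test - n_test_pos
    test_idx = np.concatenate([pos_take[:n_test_pos], neg_take[:n_test_neg]])
    train_idx = np.concatenate([pos_take[n_test_pos:], neg_take[n_test_neg:]])
    train_idx.sort()
    test_idx.sort()
    return dataset.subset(train_idx), dataset.subset(test_idx)
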