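"""Synthetic genomes with planted fuzzy-rule structure.

The generator plants ground-truth enhancer intervals and a small rule
base; inside a true enhancer the marks named by one planted enhancer
rule are drawn so that the rule fires strongly (all antecedent
memberships >= 0.8 before noise), while background bins are resampled
until no planted enhancer rule fires strongly.  Annotations, 3D
contacts, expression tables, and stranded nascent transcription with a
controllable strand asymmetry complete the inputs the downstream
pipeline expects.  Every output is a pure function of the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as exio
from .fuzzy import (
    ENHANCER,
    FuzzyRule,
    RuleBase,
    default_partition,
    strong_interval,
    weak_interval,
)
from .io import GeneModel
from .tracks import GenomeBins, tile_genome

STRONG_LEVEL = 0.8
WEAK_FIRING = 0.2  # max upper firing a planted rule may reach on background


@dataclass
class ContactModel:
    p_contact_given_enhancer: float = 0.7
    p_contact_background: float = 0.1
    bin_size: int = 1000
    score_range: tuple[float, float] = (2.0, 6.0)

    def __post_init__(self) -> None:
        for p in (self.p_contact_given_enhancer, self.p_contact_background):
            if not 0.0 <= p <= 1.0:
                raise ValueError("contact probabilities must be in [0, 1]")
        if self.score_range[0] <= 1.0:
            raise ValueError("planted contact scores must exceed 1 (obs/exp)")


@dataclass
class ExpressionModel:
    linked_log_mean: float = 2.0
    linked_log_sd: float = 1.0
    unlinked_zero_fraction: float = 0.5
    unlinked_log_mean: float = -1.0
    unlinked_log_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.unlinked_zero_fraction <= 1.0:
            raise ValueError("zero-inflation fraction must be in [0, 1]")


@dataclass
class TranscriptionModel:
    signal_level: float = 10.0
    asymmetry: float = 1.0  # plus:minus ratio at enhancer flanks
    window: int = 500
    offset: int = 500
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.asymmetry <= 0:
            raise ValueError("asymmetry must be positive")


@dataclass
class SyntheticConfig:
    chrom_sizes: dict[str, int] = field(default_factory=lambda: {"chr2L": 1_000_000})
    n_marks: int = 8
    bin_width: int = 10
    planted_rules: RuleBase | None = None
    enhancer_density: float = 10.0  # regions per Mb
    enhancer_width_range: tuple[int, int] = (200, 1000)
    noise_sd: float = 0.05
    label_noise_rate: float = 0.0
    genes_per_mb: float = 20.0
    contact_model: ContactModel = field(default_factory=ContactModel)
    expression_model: ExpressionModel = field(default_factory=ExpressionModel)
    transcription_model: TranscriptionModel = field(default_factory=TranscriptionModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_marks < 2:
            raise ValueError("need at least two marks")
        lo, hi = self.enhancer_width_range
        if lo <= 0 or hi < lo:
            raise ValueError("enhancer widths must be positive and ordered")
        if not 0.0 <= self.label_noise_rate <= 1.0:
            raise ValueError("label_noise_rate must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for size in self.chrom_sizes.values():
            if size <= 0:
                raise ValueError("chromosome sizes must be positive")

    @property
    def marks(self) -> list[str]:
        return [f"mark{i + 1:02d}" for i in range(self.n_marks)]

    def rules(self) -> RuleBase:
        if self.planted_rules is None:
            self.planted_rules = default_planted_rulebase(self.marks)
        return self.planted_rules

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: dict) -> "SyntheticConfig":
        raw = dict(raw)
        if "contact_model" in raw:
            raw["contact_model"] = ContactModel(**raw["contact_model"])
        if "expression_model" in raw:
            raw["expression_model"] = ExpressionModel(**raw["expression_model"])
        if "transcription_model" in raw:
            raw["transcription_model"] = TranscriptionModel(
                **raw["transcription_model"]
            )
        if "enhancer_width_range" in raw:
            raw["enhancer_width_range"] = tuple(raw["enhancer_width_range"])
        return cls(**raw)


@dataclass
class GroundTruth:
    true_enhancers: pd.DataFrame  # chrom/start/end
    planted_rules: RuleBase
    gene_links: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "true_enhancers": self.true_enhancers.to_dict(orient="records"),
            "planted_rules": self.planted_rules.to_dict(),
            "gene_links": self.gene_links,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            pd.DataFrame(
                payload["true_enhancers"], columns=["chrom", "start", "end"]
            ),
            RuleBase.from_dict(payload["planted_rules"]),
            payload.get("gene_links", {}),
        )


def default_planted_rulebase(marks: list[str]) -> RuleBase:
    """Two enhancer rules over the first four marks plus matching
    non-enhancer rules, on the canonical quartile partitions."""
    if len(marks) < 4:
        raise ValueError("default planted rules need at least four marks")
    partitions = {m: default_partition(m) for m in marks}
    rules = [
        FuzzyRule(((marks[0], "high"), (marks[1], "high")), ENHANCER, 1.0),
        FuzzyRule(((marks[2], "high"), (marks[3], "high")), ENHANCER, 1.0),
        FuzzyRule(((marks[0], "low"),), "non_enhancer", 1.0),
        FuzzyRule(((marks[2], "low"),), "non_enhancer", 1.0),
    ]
    return RuleBase(rules, partitions)


# ---------------------------------------------------------------------------
# enhancer placement
# ---------------------------------------------------------------------------


def _place_enhancers(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    lo_w, hi_w = config.enhancer_width_range
    for chrom, size in config.chrom_sizes.items():
        n = int(round(size / 1e6 * config.enhancer_density))
        placed: list[tuple[int, int]] = []
        attempts = 0
        while len(placed) < n:
            attempts += 1
            if attempts > 1000 * max(n, 1):
                raise RuntimeError(
                    f"cannot place {n} non-overlapping enhancers on {chrom}; "
                    f"density infeasible"
                )
            width = int(rng.integers(lo_w, hi_w + 1))
            if width >= size:
                raise RuntimeError(f"chromosome {chrom} shorter than one enhancer")
            start = int(rng.integers(0, size - width))
            end = start + width
            if all(e <= start or s >= end for s, e in placed):
                placed.append((start, end))
        placed.sort()
        rows.extend((chrom, s, e) for s, e in placed)
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# signal tracks
# ---------------------------------------------------------------------------


def generate_tracks(
    config: SyntheticConfig,
) -> tuple[dict[str, np.ndarray], pd.DataFrame, GroundTruth, np.ndarray, GenomeBins]:
    """Generate per-mark per-bin signals, true enhancer intervals, the
    ground truth, and the (possibly label-noised) bin labels."""
    rng = np.random.default_rng(config.seed)
    rules = config.rules()
    bins = tile_genome(config.chrom_sizes, config.bin_width)
    enhancers = _place_enhancers(config, rng)
    marks = config.marks
    enh_rules = [r for r in rules.rules if r.consequent == ENHANCER]
    if not enh_rules:
        raise ValueError("planted rule base has no enhancer rule")

    n = bins.n_bins
    X = rng.uniform(0.0, 1.0, size=(n, len(marks)))
    col = {m: i for i, m in enumerate(marks)}

    labels = np.zeros(n, dtype=bool)
    enh_bin_rule: list[tuple[int, int, FuzzyRule]] = []
    for k, (chrom, start, end) in enumerate(
        zip(enhancers["chrom"], enhancers["start"], enhancers["end"])
    ):
        lo, hi = bins.bin_span(chrom, int(start), int(end))
        labels[lo:hi] = True
        enh_bin_rule.append((lo, hi, enh_rules[k % len(enh_rules)]))

    # background: resample marks until no planted enhancer rule fires strongly
    bg = ~labels
    for _ in range(20):
        offenders = np.zeros(n, dtype=bool)
        worst_rule = np.full(n, -1, dtype=np.int32)
        for ri, rule in enumerate(enh_rules):
            f_up = None
            for mark, lab in rule.antecedents:
                up = rules.partitions[mark].sets[lab].upper(X[:, col[mark]])
                f_up = up if f_up is None else np.minimum(f_up, up)
            strong = bg & (f_up >= WEAK_FIRING)
            offenders |= strong
            worst_rule[strong & (worst_rule < 0)] = ri
        if not offenders.any():
            break
        idx = np.flatnonzero(offenders)
        for i in idx:
            rule = enh_rules[worst_rule[i]]
            mark, lab = rule.antecedents[int(rng.integers(len(rule.antecedents)))]
            w_lo, w_hi = weak_interval(rules.partitions[mark].sets[lab], 0.2)
            X[i, col[mark]] = rng.uniform(w_lo, w_hi)
    else:
        raise RuntimeError("could not sample planted-rule-free background")

    # enhancer bins: make the assigned rule fire strongly
    for lo, hi, rule in enh_bin_rule:
        for mark, lab in rule.antecedents:
            s_lo, s_hi = strong_interval(
                rules.partitions[mark].sets[lab], STRONG_LEVEL
            )
            X[lo:hi, col[mark]] = rng.uniform(s_lo, s_hi, size=hi - lo)

    if config.noise_sd > 0:
        X = np.clip(X + rng.normal(0.0, config.noise_sd, size=X.shape), 0.0, 1.0)

    y = labels.copy()
    if config.label_noise_rate > 0:
        flip = rng.random(n) < config.label_noise_rate
        y = y ^ flip

    truth = GroundTruth(enhancers, rules)
    tracks = {m: X[:, col[m]].copy() for m in marks}
    return tracks, enhancers, truth, y, bins


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def generate_annotation(config: SyntheticConfig) -> list[GeneModel]:
    """Non-overlapping gene models with exon/intron/UTR structure, placed
    on an even grid with seeded jitter.  Promoters (250 bp upstream of
    the TSS) always stay on-chromosome."""
    rng = np.random.default_rng(config.seed + 1)
    genes: list[GeneModel] = []
    margin = 300  # room for the promoter on either end
    for chrom, size in config.chrom_sizes.items():
        n = int(round(size / 1e6 * config.genes_per_mb))
        if n == 0:
            continue
        slot = (size - 2 * margin) // n
        if slot < 1200:
            raise ValueError(
                f"chromosome {chrom} too short for {n} genes (slot {slot} bp)"
            )
        for k in range(n):
            slot_start = margin + k * slot
            length = int(rng.integers(1000, min(6000, slot - 100) + 1))
            start = slot_start + int(rng.integers(0, slot - length))
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"{chrom}_g{k + 1:04d}"
            n_exons = int(rng.integers(2, 4))
            cuts = np.sort(rng.integers(1, length, size=2 * (n_exons - 1)))
            bounds = [0, *cuts.tolist(), length]
            exons = []
            for e in range(n_exons):
                s = start + bounds[2 * e]
                t = start + bounds[2 * e + 1]
                if t <= s:
                    t = s + 1
                exons.append((s, min(t, end)))
            exons[0] = (start, exons[0][1])
            exons[-1] = (exons[-1][0], end)
            utr_len5 = min(200, exons[0][1] - exons[0][0] - 1) if strand == "+" else min(
                200, exons[-1][1] - exons[-1][0] - 1
            )
            utr_len3 = min(150, exons[-1][1] - exons[-1][0] - 1) if strand == "+" else min(
                150, exons[0][1] - exons[0][0] - 1
            )
            if strand == "+":
                utr5 = (start, start + max(utr_len5, 1))
                utr3 = (end - max(utr_len3, 1), end)
            else:
                utr5 = (end - max(utr_len5, 1), end)
                utr3 = (start, start + max(utr_len3, 1))
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    exons=exons,
                    utr5=utr5,
                    utr3=utr3,
                )
            )
    if not genes:
        raise ValueError("no genes generated; chromosomes too short")
    return genes


# ---------------------------------------------------------------------------
# contacts and expression
# ---------------------------------------------------------------------------


def generate_contacts(
    config: SyntheticConfig,
    true_enhancers: pd.DataFrame,
    genes: list[GeneModel],
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Enhancer-promoter contact records (probability
    ``p_contact_given_enhancer`` per enhancer) plus background
    window-promoter records (``p_contact_background`` per gene), all with
    observed/expected scores above 1."""
    rng = np.random.default_rng(config.seed + 2)
    cm = config.contact_model
    from .linkage import promoter_intervals

    promoters = promoter_intervals(genes)
    by_chrom = {c: sub.reset_index(drop=True) for c, sub in promoters.groupby("chrom")}
    rows = []
    gene_links: dict[str, list[str]] = {}
    for chrom, start, end in zip(
        true_enhancers["chrom"], true_enhancers["start"], true_enhancers["end"]
    ):
        if rng.random() >= cm.p_contact_given_enhancer:
            continue
        sub = by_chrom.get(chrom)
        if sub is None or not len(sub):
            continue
        pick = sub.iloc[int(rng.integers(len(sub)))]
        score = float(rng.uniform(*cm.score_range))
        rows.append(
            (
                chrom,
                int(start),
                int(end),
                pick["chrom"],
                int(pick["start"]),
                int(pick["end"]),
                score,
            )
        )
        region_id = f"{chrom}:{int(start)}-{int(end)}"
        gene_links.setdefault(region_id, []).append(str(pick["gene_id"]))
    # background: random windows contacting promoters
    enh_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in zip(
        true_enhancers["chrom"], true_enhancers["start"], true_enhancers["end"]
    ):
        enh_by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    for g in genes:
        if rng.random() >= cm.p_contact_background:
            continue
        size = config.chrom_sizes[g.chrom]
        for _ in range(50):
            w_start = int(rng.integers(0, max(1, size - cm.bin_size)))
            w_end = w_start + cm.bin_size
            if all(
                e <= w_start or s >= w_end
                for s, e in enh_by_chrom.get(g.chrom, ())
            ):
                break
        else:
            continue
        prom = promoter_intervals([g]).iloc[0]
        score = float(rng.uniform(*cm.score_range))
        rows.append(
            (
                g.chrom,
                w_start,
                w_end,
                prom["chrom"],
                int(prom["start"]),
                int(prom["end"]),
                score,
            )
        )
    contacts = pd.DataFrame(rows, columns=exio.CONTACT_COLUMNS)
    return contacts, gene_links


def generate_expression(
    config: SyntheticConfig,
    genes: list[GeneModel],
    gene_links: dict[str, list[str]],
) -> dict[str, float]:
    """FPKM per gene: lognormal for enhancer-linked genes, zero-inflated
    lognormal for the rest."""
    rng = np.random.default_rng(config.seed + 3)
    em = config.expression_model
    linked = {g for gs in gene_links.values() for g in gs}
    fpkm = {}
    for g in genes:
        if g.gene_id in linked:
            fpkm[g.gene_id] = float(
                rng.lognormal(em.linked_log_mean, em.linked_log_sd)
            )
        elif rng.random() < em.unlinked_zero_fraction:
            fpkm[g.gene_id] = 0.0
        else:
            fpkm[g.gene_id] = float(
                rng.lognormal(em.unlinked_log_mean, em.unlinked_log_sd)
            )
    return fpkm


# ---------------------------------------------------------------------------
# stranded transcription
# ---------------------------------------------------------------------------


def generate_stranded_transcription(
    config: SyntheticConfig,
    true_enhancers: pd.DataFrame,
    bins: GenomeBins,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin plus- and minus-strand nascent signal at enhancer flanks.

    Each enhancer gets plus-strand signal downstream of its right border
    and minus-strand signal (stored negative) upstream of its left
    border, with plus:minus level ratio ``asymmetry``.  ``asymmetry=1``
    gives a directionality score of exactly 0; ``asymmetry=a`` gives
    log10(a) in the noise-free limit.
    """
    rng = np.random.default_rng(config.seed + 4)
    tm = config.transcription_model
    plus = np.zeros(bins.n_bins)
    minus = np.zeros(bins.n_bins)
    w = bins.width
    for chrom, start, end in zip(
        true_enhancers["chrom"], true_enhancers["start"], true_enhancers["end"]
    ):
        size = bins.sizes[chrom]
        off = bins.offsets[chrom]
        right_lo = int(end) + tm.offset
        right_hi = right_lo + tm.window
        left_hi = int(start) - tm.offset
        left_lo = left_hi - tm.window
        p_level = tm.signal_level
        m_level = tm.signal_level / tm.asymmetry
        if right_hi <= size:
            plus[off + right_lo // w : off + right_hi // w] = p_level
        if left_lo >= 0:
            minus[off + left_lo // w : off + left_hi // w] = -m_level
    if tm.noise_sd > 0:
        plus = np.maximum(plus + rng.normal(0, tm.noise_sd, bins.n_bins), 0.0)
        minus = np.minimum(minus + rng.normal(0, tm.noise_sd, bins.n_bins), 0.0)
    return plus, minus


# ---------------------------------------------------------------------------
# full simulation to disk
# ---------------------------------------------------------------------------


def simulate_to_dir(config: SyntheticConfig, outdir) -> dict[str, str]:
    """Run every generator and write the standard-format files the
    pipeline ingests.  Returns a manifest of written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tracks, enhancers, truth, y, bins = generate_tracks(config)
    genes = generate_annotation(config)
    contacts, gene_links = generate_contacts(config, enhancers, genes)
    truth.gene_links = gene_links
    fpkm = generate_expression(config, genes, gene_links)
    plus, minus = generate_stranded_transcription(config, enhancers, bins)

    chrom_idx, starts, ends = bins.coordinates()
    paths: dict[str, str] = {}

    exio.write_chrom_sizes(config.chrom_sizes, outdir / "chrom.sizes")
    paths["chrom_sizes"] = str(outdir / "chrom.sizes")

    track_dir = outdir / "tracks"
    track_dir.mkdir(exist_ok=True)
    for mark, values in tracks.items():
        df = exio.values_to_bedgraph(
            bins.chrom_order, chrom_idx, starts, ends, np.round(values, 6)
        )
        exio.write_bedgraph(df, track_dir / f"{mark}.bedGraph")
        paths[f"track:{mark}"] = str(track_dir / f"{mark}.bedGraph")

    exio.write_bed(enhancers.assign(name="true_enhancer"), outdir / "true_enhancers.bed")
    paths["true_enhancers"] = str(outdir / "true_enhancers.bed")

    # label track as BED intervals of enhancer-labeled bins (after noise)
    label_df = exio.values_to_bedgraph(
        bins.chrom_order, chrom_idx, starts, ends, y.astype(float)
    )
    exio.write_bedgraph(
        label_df.loc[label_df["value"] > 0], outdir / "labels.bedGraph"
    )
    paths["labels"] = str(outdir / "labels.bedGraph")

    exio.write_gff3(genes, outdir / "annotation.gff3")
    paths["annotation"] = str(outdir / "annotation.gff3")

    exio.write_contacts(contacts, outdir / "contacts.tsv")
    paths["contacts"] = str(outdir / "contacts.tsv")

    exio.write_fpkm(fpkm, outdir / "fpkm.tsv")
    paths["fpkm"] = str(outdir / "fpkm.tsv")

    for name, values in (("plus", plus), ("minus", minus)):
        df = exio.values_to_bedgraph(
            bins.chrom_order, chrom_idx, starts, ends, np.round(values, 6)
        )
        exio.write_bedgraph(df, outdir / f"nascent_{name}.bedGraph")
        paths[f"nascent_{name}"] = str(outdir / f"nascent_{name}.bedGraph")

    truth.to_json(outdir / "ground_truth.json")
    paths["ground_truth"] = str(outdir / "ground_truth.json")
    return paths
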