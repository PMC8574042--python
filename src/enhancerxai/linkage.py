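"""Classify enhancer regions by promoter proximity and 3D contacts, and
attach expression of the linked genes.

A region is *proximal* to a promoter when the gap between them is at
most 5 kb (0 when overlapping).  A region *contacts* a promoter when
region and promoter fall in the two anchors of one enriched contact
record (>= 1 bp overlap with each anchor).  Categories follow the
distance/contact combinations: ``proximal`` (within 5 kb and also
contacting distal promoters), ``proximal_only`` (within 5 kb, no distal
contacts), ``distal_only`` (further than 5 kb from every promoter but
contacting at least one), and ``neither``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import EnhancerRegion
from .io import GeneModel

PROXIMAL = "proximal"
DISTAL_ONLY = "distal_only"
PROXIMAL_ONLY = "proximal_only"
NEITHER = "neither"
CATEGORIES = (PROXIMAL, DISTAL_ONLY, PROXIMAL_ONLY, NEITHER)

DEFAULT_PROXIMAL_DISTANCE = 5000
DEFAULT_RATIO_THRESHOLD = 2.0
DEFAULT_FPKM_THRESHOLD = 1.0
PROMOTER_WIDTH = 250


@dataclass
class PromoterLinkage:
    region_id: str
    category: str
    contacted_genes: list[str] = field(default_factory=list)
    proximal_genes: list[str] = field(default_factory=list)
    max_fpkm: float = float("nan")
    expressed: bool = False


def promoter_intervals(genes: list[GeneModel]) -> pd.DataFrame:
    """250 bp immediately upstream of each TSS, strand-aware, clipped to
    the chromosome start (gene end bounds are the caller's concern)."""
    rows = []
    for g in genes:
        if g.strand not in ("+", "-"):
            raise ValueError(f"gene {g.gene_id}: strand must be + or -")
        if g.strand == "+":
            tss = g.start
            start, end = max(0, tss - PROMOTER_WIDTH), tss
        else:
            tss = g.end
            start, end = tss, tss + PROMOTER_WIDTH
        if end <= start:
            raise ValueError(f"gene {g.gene_id}: empty promoter interval")
        rows.append((g.chrom, start, end, g.gene_id, g.strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "strand"])


def flag_enriched_contacts(
    contacts: pd.DataFrame, ratio_threshold: float = DEFAULT_RATIO_THRESHOLD
) -> pd.DataFrame:
    """Mark records whose observed/expected ratio is >= the threshold."""
    scores = contacts["score"].to_numpy(float)
    if np.any(scores <= 0):
        raise ValueError("observed/expected ratios must be positive")
    out = contacts.copy()
    out["enriched"] = scores >= ratio_threshold
    return out


def _gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """bp between two half-open intervals; 0 when they overlap."""
    if a_start < b_end and b_start < a_end:
        return 0
    return b_start - a_end if b_start >= a_end else a_start - b_end


def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    return a_start < b_end and b_start < a_end


def link_enhancers_to_promoters(
    regions: list[EnhancerRegion],
    promoters: pd.DataFrame,
    contacts: pd.DataFrame,
    proximal_distance: int = DEFAULT_PROXIMAL_DISTANCE,
) -> list[PromoterLinkage]:
    """Categorize every region by distance to promoters and enriched 3D
    contacts with them; ``contacts`` must carry the ``enriched`` flag."""
    if "enriched" not in contacts.columns:
        raise ValueError("contacts must be flagged first (flag_enriched_contacts)")
    enr = contacts.loc[contacts["enriched"]]
    prom_by_chrom: dict[str, pd.DataFrame] = {
        chrom: sub for chrom, sub in promoters.groupby("chrom", sort=False)
    }
    linkages = []
    for region in regions:
        sub = prom_by_chrom.get(region.chrom)
        gaps: dict[str, int] = {}
        if sub is not None:
            for start, end, gene_id in zip(sub["start"], sub["end"], sub["gene_id"]):
                g = _gap(region.start, region.end, int(start), int(end))
                if gene_id not in gaps or g < gaps[gene_id]:
                    gaps[gene_id] = g
        proximal_genes = sorted(g for g, d in gaps.items() if d <= proximal_distance)
        contacted: set[str] = set()
        for _, rec in enr.iterrows():
            for ra, pa in (("1", "2"), ("2", "1")):
                if rec[f"chrom{ra}"] != region.chrom:
                    continue
                if not _overlaps(
                    region.start, region.end, rec[f"start{ra}"], rec[f"end{ra}"]
                ):
                    continue
                psub = prom_by_chrom.get(rec[f"chrom{pa}"])
                if psub is None:
                    continue
                hit = psub.loc[
                    (psub["start"] < rec[f"end{pa}"])
                    & (rec[f"start{pa}"] < psub["end"])
                ]
                contacted.update(hit["gene_id"])
        has_distal_contact = any(
            gaps.get(g, proximal_distance + 1) > proximal_distance for g in contacted
        )
        if proximal_genes:
            category = PROXIMAL if has_distal_contact else PROXIMAL_ONLY
        elif contacted:
            category = DISTAL_ONLY
        else:
            category = NEITHER
        linkages.append(
            PromoterLinkage(
                region_id=region.region_id,
                category=category,
                contacted_genes=sorted(contacted),
                proximal_genes=proximal_genes,
            )
        )
    return linkages


def linked_expression(
    linkages: list[PromoterLinkage],
    fpkm: dict[str, float],
    threshold: float = DEFAULT_FPKM_THRESHOLD,
) -> list[PromoterLinkage]:
    """Attach the maximum FPKM over the genes a region is linked to
    (contacted promoters plus, for proximal categories, promoters within
    the proximal distance).  ``neither`` regions stay missing (NaN)."""
    for lk in linkages:
        genes = set(lk.contacted_genes)
        if lk.category in (PROXIMAL, PROXIMAL_ONLY):
            genes.update(lk.proximal_genes)
        if lk.category == NEITHER or not genes:
            lk.max_fpkm = float("nan")
            lk.expressed = False
            continue
        missing = [g for g in genes if g not in fpkm]
        if missing:
            raise KeyError(f"expression missing for genes: {missing}")
        lk.max_fpkm = max(fpkm[g] for g in genes)
        lk.expressed = lk.max_fpkm > threshold
    return linkages


def enhancer_enhancer_contacts(
    regions: list[EnhancerRegion], contacts: pd.DataFrame
) -> dict[str, int]:
    """Per region, the number of distinct *other* regions sharing an
    enriched contact record (self-contacts excluded)."""
    if "enriched" not in contacts.columns:
        raise ValueError("contacts must be flagged first (flag_enriched_contacts)")
    enr = contacts.loc[contacts["enriched"]]
    partners: dict[str, set[str]] = {r.region_id: set() for r in regions}
    for _, rec in enr.iterrows():
        in_a1 = [
            r
            for r in regions
            if r.chrom == rec["chrom1"]
            and _overlaps(r.start, r.end, rec["start1"], rec["end1"])
        ]
        in_a2 = [
            r
            for r in regions
            if r.chrom == rec["chrom2"]
            and _overlaps(r.start, r.end, rec["start2"], rec["end2"])
        ]
        for ra in in_a1:
            for rb in in_a2:
                if ra.region_id != rb.region_id:
                    partners[ra.region_id].add(rb.region_id)
                    partners[rb.region_id].add(ra.region_id)
    return {rid: len(s) for rid, s in partners.items()}


def linkage_frame(linkages: list[PromoterLinkage]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region": [lk.region_id for lk in linkages],
            "category": [lk.category for lk in linkages],
            "n_contacted_genes": [len(lk.contacted_genes) for lk in linkages],
            "contacted_genes": [",".join(lk.contacted_genes) for lk in linkages],
            "max_fpkm": [lk.max_fpkm for lk in linkages],
            "expressed": [int(lk.expressed) for lk in linkages],
        }
    )
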