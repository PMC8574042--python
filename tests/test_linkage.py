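import math

import numpy as np
import pandas as pd
import pytest

from enhancerxai.calling import EnhancerRegion
from enhancerxai.io import GeneModel
from enhancerxai.linkage import (
    CATEGORIES,
    DISTAL_ONLY,
    NEITHER,
    PROXIMAL,
    PROXIMAL_ONLY,
    PromoterLinkage,
    enhancer_enhancer_contacts,
    flag_enriched_contacts,
    link_enhancers_to_promoters,
    linked_expression,
    promoter_intervals,
)

CONTACT_COLS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "score"]


def gene(gene_id, chrom, start, end, strand="+"):
    return GeneModel(gene_id, chrom, start, end, strand, exons=[(start, end)])


def contacts_df(*rows, enriched=True):
    df = pd.DataFrame(rows, columns=CONTACT_COLS)
    if enriched:
        df = flag_enriched_contacts(df, 2.0)
    return df


class TestPromoterIntervals:
    def test_plus_strand(self):
        promoters = promoter_intervals([gene("g1", "A", 1000, 2000, "+")])
        assert promoters.iloc[0][["start", "end"]].tolist() == [750, 1000]

    def test_minus_strand_mirror(self):
        promoters = promoter_intervals([gene("g1", "A", 0, 1000, "-")])
        assert promoters.iloc[0][["start", "end"]].tolist() == [1000, 1250]

    def test_clip_at_chromosome_start(self):
        promoters = promoter_intervals([gene("g1", "A", 100, 900, "+")])
        assert promoters.iloc[0][["start", "end"]].tolist() == [0, 100]

    def test_bad_strand(self):
        with pytest.raises(ValueError, match="strand"):
            promoter_intervals([gene("g1", "A", 100, 900, ".")])


class TestEnrichedContacts:
    def test_threshold_flags(self):
        df = contacts_df(
            ("A", 0, 1000, "A", 5000, 6000, 3.0),
            ("A", 0, 1000, "A", 8000, 9000, 1.0),
            enriched=False,
        )
        flagged = flag_enriched_contacts(df, 2.0)
        assert flagged["enriched"].tolist() == [True, False]

    def test_ratio_one_never_enriched_above_one(self):
        df = contacts_df(("A", 0, 10, "A", 50, 60, 1.0), enriched=False)
        assert not flag_enriched_contacts(df, 1.1)["enriched"].any()

    def test_filter_oracle_on_random_records(self):
        rng = np.random.default_rng(0)
        rows = [
            ("A", 0, 10, "A", 50, 60, float(rng.uniform(0.1, 5.0))) for _ in range(100)
        ]
        df = pd.DataFrame(rows, columns=CONTACT_COLS)
        flagged = flag_enriched_contacts(df, 2.0)
        for _, rec in flagged.iterrows():
            assert rec["enriched"] == (rec["score"] >= 2.0)

    def test_non_positive_ratio_rejected(self):
        df = pd.DataFrame([("A", 0, 10, "A", 50, 60, 0.0)], columns=CONTACT_COLS)
        with pytest.raises(ValueError, match="positive"):
            flag_enriched_contacts(df)


class TestLinkCategories:
    GENES = [gene("near", "A", 53_000, 60_000, "+"), gene("far", "A", 100_000, 110_000, "+")]

    def promoters(self):
        return promoter_intervals(self.GENES)  # near: [52750,53000), far: [99750,100000)

    def test_proximal_with_distal_contact(self):
        region = EnhancerRegion("A", 49_000, 50_000, 0.9)  # 2750 bp from `near`
        contacts = contacts_df(("A", 49_000, 50_000, "A", 99_700, 100_000, 3.0))
        lk = link_enhancers_to_promoters([region], self.promoters(), contacts)[0]
        assert lk.category == PROXIMAL
        assert lk.contacted_genes == ["far"]

    def test_proximal_only_without_distal_contact(self):
        region = EnhancerRegion("A", 49_000, 50_000, 0.9)
        contacts = contacts_df(("A", 0, 10, "A", 20, 30, 3.0))
        lk = link_enhancers_to_promoters([region], self.promoters(), contacts)[0]
        assert lk.category == PROXIMAL_ONLY

    def test_distal_only(self):
        region = EnhancerRegion("A", 10_000, 11_000, 0.9)  # > 5 kb from both
        contacts = contacts_df(("A", 10_000, 11_000, "A", 99_800, 100_000, 4.0))
        lk = link_enhancers_to_promoters([region], self.promoters(), contacts)[0]
        assert lk.category == DISTAL_ONLY
        assert lk.contacted_genes == ["far"]

    def test_neither(self):
        region = EnhancerRegion("A", 10_000, 11_000, 0.9)
        contacts = contacts_df(("A", 0, 10, "A", 20, 30, 3.0))
        lk = link_enhancers_to_promoters([region], self.promoters(), contacts)[0]
        assert lk.category == NEITHER

    def test_unflagged_contacts_rejected(self):
        region = EnhancerRegion("A", 0, 100, 0.9)
        df = pd.DataFrame([("A", 0, 10, "A", 20, 30, 3.0)], columns=CONTACT_COLS)
        with pytest.raises(ValueError, match="flagged"):
            link_enhancers_to_promoters([region], self.promoters(), df)

    def _random_case(self, seed, n_regions=60):
        rng = np.random.default_rng(seed)
        genes = [
            gene(f"g{i}", "A", s, s + 2000, "+")
            for i, s in enumerate(sorted(rng.choice(np.arange(5_000, 495_000, 4000), 25, replace=False)))
        ]
        promoters = promoter_intervals(genes)
        regions = [
            EnhancerRegion("A", s, s + int(rng.integers(100, 900)), 0.9)
            for s in rng.integers(0, 490_000, n_regions)
        ]
        rows = []
        for _ in range(80):
            region = regions[int(rng.integers(len(regions)))]
            g = genes[int(rng.integers(len(genes)))]
            prom = promoter_intervals([g]).iloc[0]
            rows.append(
                (
                    "A",
                    region.start,
                    region.end,
                    "A",
                    int(prom["start"]),
                    int(prom["end"]),
                    float(rng.uniform(0.5, 5.0)),
                )
            )
        contacts = flag_enriched_contacts(pd.DataFrame(rows, columns=CONTACT_COLS), 2.0)
        return genes, promoters, regions, contacts

    def test_exhaustive_distance_contact_oracle(self):
        genes, promoters, regions, contacts = self._random_case(seed=1, n_regions=60)
        linkages = link_enhancers_to_promoters(regions, promoters, contacts, 5000)

        def interval_gap(a, b, c, d):
            if a < d and c < b:
                return 0
            return c - b if c >= b else a - d

        prom_iv = {
            row["gene_id"]: (row["start"], row["end"]) for _, row in promoters.iterrows()
        }
        for region, lk in zip(regions, linkages):
            gaps = {
                gid: interval_gap(region.start, region.end, s, e)
                for gid, (s, e) in prom_iv.items()
            }
            contacted = set()
            for _, rec in contacts.iterrows():
                if not rec["enriched"]:
                    continue
                for a, b in ((("start1", "end1"), ("start2", "end2")),
                             (("start2", "end2"), ("start1", "end1"))):
                    if region.start < rec[a[1]] and rec[a[0]] < region.end:
                        for gid, (s, e) in prom_iv.items():
                            if s < rec[b[1]] and rec[b[0]] < e:
                                contacted.add(gid)
            prox = any(g <= 5000 for g in gaps.values())
            distal_contact = any(gaps[g] > 5000 for g in contacted)
            if prox and distal_contact:
                expected = PROXIMAL
            elif prox:
                expected = PROXIMAL_ONLY
            elif contacted:
                expected = DISTAL_ONLY
            else:
                expected = NEITHER
            assert lk.category == expected
            assert sorted(contacted) == lk.contacted_genes

    def test_category_partition(self):
        _, promoters, regions, contacts = self._random_case(seed=2)
        linkages = link_enhancers_to_promoters(regions, promoters, contacts)
        for lk in linkages:
            assert lk.category in CATEGORIES

    def test_raising_distance_moves_toward_proximal(self):
        _, promoters, regions, contacts = self._random_case(seed=3)
        near = link_enhancers_to_promoters(regions, promoters, contacts, 5000)
        far = link_enhancers_to_promoters(regions, promoters, contacts, 50_000)
        rank = {NEITHER: 0, DISTAL_ONLY: 0, PROXIMAL_ONLY: 1, PROXIMAL: 1}
        for a, b in zip(near, far):
            assert rank[b.category] >= rank[a.category]


class TestLinkedExpression:
    def test_maximum_over_contacted_genes(self):
        lk = PromoterLinkage("r", DISTAL_ONLY, contacted_genes=["a", "b"])
        linked_expression([lk], {"a": 2.0, "b": 7.5})
        assert lk.max_fpkm == 7.5
        assert lk.expressed

    def test_zero_fpkm_not_expressed(self):
        lk = PromoterLinkage("r", DISTAL_ONLY, contacted_genes=["a"])
        linked_expression([lk], {"a": 0.0})
        assert lk.max_fpkm == 0.0
        assert not lk.expressed

    def test_neither_is_missing(self):
        lk = PromoterLinkage("r", NEITHER)
        linked_expression([lk], {})
        assert math.isnan(lk.max_fpkm)
        assert not lk.expressed

    def test_proximal_uses_nearby_genes_too(self):
        lk = PromoterLinkage(
            "r", PROXIMAL, contacted_genes=["far"], proximal_genes=["near"]
        )
        linked_expression([lk], {"far": 1.5, "near": 9.0})
        assert lk.max_fpkm == 9.0

    def test_missing_gene_expression_raises(self):
        lk = PromoterLinkage("r", DISTAL_ONLY, contacted_genes=["a"])
        with pytest.raises(KeyError, match="a"):
            linked_expression([lk], {})


class TestEnhancerEnhancerContacts:
    def test_pair_counts_one_each(self):
        regions = [
            EnhancerRegion("A", 0, 1000, 0.9),
            EnhancerRegion("A", 50_000, 51_000, 0.9),
        ]
        contacts = contacts_df(("A", 0, 1000, "A", 50_000, 51_000, 3.0))
        counts = enhancer_enhancer_contacts(regions, contacts)
        assert counts == {"A:0-1000": 1, "A:50000-51000": 1}

    def test_no_contacts_all_zero(self):
        regions = [EnhancerRegion("A", 0, 1000, 0.9)]
        contacts = contacts_df(("A", 5000, 6000, "A", 9000, 9500, 3.0))
        counts = enhancer_enhancer_contacts(regions, contacts)
        assert counts == {"A:0-1000": 0}

    def test_all_pairs_oracle(self):
        rng = np.random.default_rng(4)
        regions = [
            EnhancerRegion("A", s, s + 500, 0.9)
            for s in sorted(rng.choice(np.arange(0, 95_000, 1000), 40, replace=False))
        ]
        rows = []
        for _ in range(60):
            a = regions[int(rng.integers(len(regions)))]
            b = regions[int(rng.integers(len(regions)))]
            rows.append(("A", a.start, a.end, "A", b.start, b.end, float(rng.uniform(1, 5))))
        contacts = flag_enriched_contacts(pd.DataFrame(rows, columns=CONTACT_COLS), 2.0)
        counts = enhancer_enhancer_contacts(regions, contacts)
        for r in regions:
            partners = set()
            for _, rec in contacts.iterrows():
                if not rec["enriched"]:
                    continue
                hit1 = r.start < rec["end1"] and rec["start1"] < r.end
                hit2 = r.start < rec["end2"] and rec["start2"] < r.end
                for other in regions:
                    if other.region_id == r.region_id:
                        continue
                    o1 = other.start < rec["end1"] and rec["start1"] < other.end
                    o2 = other.start < rec["end2"] and rec["start2"] < other.end
                    if (hit1 and o2) or (hit2 and o1):
                        partners.add(other.region_id)
            assert counts[r.region_id] == len(partners)


class TestPlantedRecovery:
    def test_planted_links_recovered_without_background(self):
        from enhancerxai.synth import ContactModel, SyntheticConfig, generate_annotation, generate_contacts, generate_tracks

        config = SyntheticConfig(
            chrom_sizes={"chrA": 500_000},
            enhancer_density=30.0,
            noise_sd=0.0,
            label_noise_rate=0.0,
            contact_model=ContactModel(
                p_contact_given_enhancer=1.0, p_contact_background=0.0
            ),
            seed=9,
        )
        _, enhancers, _, _, _ = generate_tracks(config)
        genes = generate_annotation(config)
        contacts, gene_links = generate_contacts(config, enhancers, genes)
        flagged = flag_enriched_contacts(contacts, 2.0)
        regions = [
            EnhancerRegion(row["chrom"], int(row["start"]), int(row["end"]), 1.0)
            for _, row in enhancers.iterrows()
        ]
        linkages = link_enhancers_to_promoters(
            regions, promoter_intervals(genes), flagged
        )
        for lk in linkages:
            planted = set(gene_links[lk.region_id])
            assert planted <= set(lk.contacted_genes)
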