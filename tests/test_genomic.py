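"""Long-operon calling and focal-gene proximity classification."""

import numpy as np
import pytest

from oracles import brute_force_operons

from metamorphscan.genomic_context import (
    GeneRecord,
    OperonCriteria,
    ProximityCategory,
    analyze_neighborhood,
    classify_proximity,
    find_long_operons,
    read_gene_table,
    write_gene_table,
)
from metamorphscan.synthetic import (
    NeighborhoodRecipe,
    PlantedOperon,
    simulate_gene_neighborhood,
)

CRIT = OperonCriteria()


def _genes(*spec):
    """spec items: (id, start, end, strand)"""
    return [GeneRecord(*s) for s in spec]


class TestFindLongOperons:
    def test_three_gene_operon(self):
        genes = _genes(
            ("a", 1000, 2999, "+"), ("b", 3050, 5049, "+"), ("c", 5100, 7099, "+")
        )
        ops = find_long_operons(genes, CRIT)
        assert len(ops) == 1
        assert ops[0].gene_ids == ["a", "b", "c"]
        assert ops[0].span_length == 6100

    def test_large_gap_splits_run(self):
        genes = _genes(
            ("a", 1000, 2999, "+"), ("b", 3250, 5249, "+"), ("c", 5300, 7299, "+")
        )
        # middle gap 250 bp: run splits, neither half exceeds 5,000 bp
        assert find_long_operons(genes, CRIT) == []

    def test_opposite_strand_breaks_run(self):
        genes = _genes(
            ("a", 1000, 2999, "+"), ("b", 3050, 5049, "-"), ("c", 5100, 7099, "+")
        )
        assert find_long_operons(genes, CRIT) == []

    def test_span_boundary_is_strict(self):
        # two genes spanning exactly 5,000 bp are rejected
        genes = _genes(("a", 1, 2400, "+"), ("b", 2501, 5000, "+"))
        assert (genes[1].end - genes[0].start + 1) == 5000
        assert find_long_operons(genes, CRIT) == []
        genes2 = _genes(("a", 1, 2400, "+"), ("b", 2501, 5001, "+"))
        assert len(find_long_operons(genes2, CRIT)) == 1

    def test_unsorted_input_rejected(self):
        genes = _genes(("b", 3050, 5049, "+"), ("a", 1000, 2999, "+"))
        with pytest.raises(ValueError, match="sorted"):
            find_long_operons(genes, CRIT)

    def test_matches_window_enumeration_oracle(self):
        """Called operons equal brute-force window enumeration on 500
        random gene tables."""
        rng = np.random.default_rng(11)
        for _ in range(500):
            n = int(rng.integers(2, 31))
            genes = []
            pos = int(rng.integers(1, 1000))
            for i in range(n):
                length = int(rng.integers(100, 4001))
                genes.append(
                    GeneRecord(
                        f"g{i}",
                        pos,
                        pos + length - 1,
                        "+" if rng.random() < 0.5 else "-",
                    )
                )
                pos += length + int(rng.integers(0, 400))
            got = [tuple(op.gene_ids) for op in find_long_operons(genes, CRIT)]
            assert got == brute_force_operons(genes, CRIT)

    def test_called_operons_are_disjoint(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            n = int(rng.integers(4, 25))
            genes = []
            pos = 1
            for i in range(n):
                length = int(rng.integers(500, 3500))
                genes.append(
                    GeneRecord(
                        f"g{i}", pos, pos + length - 1,
                        "+" if rng.random() < 0.7 else "-",
                    )
                )
                pos += length + int(rng.integers(0, 300))
            ops = find_long_operons(genes, CRIT)
            seen = set()
            for op in ops:
                assert not (seen & set(op.gene_ids))
                seen |= set(op.gene_ids)


class TestClassifyProximity:
    def _operon_plus(self, first_start=1400):
        genes = _genes(
            ("a", first_start, first_start + 1999, "+"),
            ("b", first_start + 2050, first_start + 4049, "+"),
            ("c", first_start + 4100, first_start + 6099, "+"),
        )
        return find_long_operons(genes, CRIT)[0]

    def test_near_same_direction(self):
        focal = GeneRecord("f", 1, 900, "+")
        res = classify_proximity(focal, self._operon_plus(1400), CRIT)
        assert res.category == ProximityCategory.NEAR_SAME_DIRECTION
        assert res.distance == 500

    def test_distant_beyond_cutoff(self):
        focal = GeneRecord("f", 1, 900, "-")
        res = classify_proximity(focal, self._operon_plus(2200), CRIT)
        assert res.category == ProximityCategory.DISTANT
        assert res.distance == 1300

    def test_inside_operon(self):
        op = self._operon_plus(1400)
        focal = GeneRecord("f", 2000, 2500, "+")
        res = classify_proximity(focal, op, CRIT)
        assert res.category == ProximityCategory.INSIDE
        assert res.distance is None

    def test_near_opposite_direction_minus_operon(self):
        genes = _genes(
            ("a", 1000, 3799, "-"), ("b", 3850, 6849, "-"), ("c", 6900, 9800, "-")
        )
        op = find_long_operons(genes, CRIT)[0]
        focal = GeneRecord("f", 10000, 10700, "+")
        res = classify_proximity(focal, op, CRIT)
        assert res.category == ProximityCategory.NEAR_OPPOSITE_DIRECTION
        assert res.distance == 200

    def test_translation_invariant(self):
        op = self._operon_plus(1400)
        focal = GeneRecord("f", 1, 900, "+")
        base = classify_proximity(focal, op, CRIT)
        shift = 50_000
        genes = _genes(
            ("a", 1400 + shift, 3399 + shift, "+"),
            ("b", 3450 + shift, 5449 + shift, "+"),
            ("c", 5500 + shift, 7499 + shift, "+"),
        )
        op2 = find_long_operons(genes, CRIT)[0]
        focal2 = GeneRecord("f", 1 + shift, 900 + shift, "+")
        moved = classify_proximity(focal2, op2, CRIT)
        assert moved.category == base.category
        assert moved.distance == base.distance


class TestAnalyzeNeighborhood:
    def test_planted_adjacent_operon(self):
        genes, focal, truth = simulate_gene_neighborhood(
            NeighborhoodRecipe(10, PlantedOperon(offset=500), seed=1)
        )
        rep = analyze_neighborhood(genes, "focal", CRIT)
        assert rep.best_proximity.category == ProximityCategory.NEAR_SAME_DIRECTION
        assert rep.best_proximity.distance == 500

    def test_no_qualifying_run(self):
        genes, focal, truth = simulate_gene_neighborhood(
            NeighborhoodRecipe(12, None, seed=2)
        )
        rep = analyze_neighborhood(genes, "focal", CRIT)
        assert rep.operons == []
        assert rep.best_proximity.category == ProximityCategory.DISTANT
        assert rep.best_proximity.operon is None

    def test_focal_inside(self):
        genes, focal, truth = simulate_gene_neighborhood(
            NeighborhoodRecipe(8, PlantedOperon(focal_inside=True), seed=3)
        )
        rep = analyze_neighborhood(genes, "focal", CRIT)
        assert rep.best_proximity.category == ProximityCategory.INSIDE

    def test_missing_focal_rejected(self):
        genes, _, _ = simulate_gene_neighborhood(NeighborhoodRecipe(4, None, seed=4))
        with pytest.raises(ValueError, match="focal"):
            analyze_neighborhood(genes, "nope", CRIT)

    def test_lps_keyword_flag(self):
        genes = _genes(
            ("a", 1000, 2999, "+"), ("b", 3050, 5049, "+"), ("c", 5100, 7099, "+")
        )
        genes[1] = GeneRecord(
            "b", 3050, 5049, "+", product="lipopolysaccharide biosynthesis protein"
        )
        genes.append(GeneRecord("focal", 8000, 8600, "+"))
        rep = analyze_neighborhood(genes, "focal", CRIT)
        assert list(rep.flags.values()) == [True]


class TestGeneTableIO:
    def test_tsv_round_trip(self, tmp_path):
        genes = _genes(("a", 10, 20, "+"), ("b", 30, 40, "-")) + [
            GeneRecord("c", 50, 60, "+", product="LPS export protein")
        ]
        p = tmp_path / "genes.tsv"
        write_gene_table(genes, p)
        back = read_gene_table(p)
        assert back == genes

    def test_gff3(self, tmp_path):
        text = (
            "##gff-version 3\n"
            "chr1\t.\tgene\t100\t400\t.\t+\t.\tID=geneA;product=widget\n"
            "chr1\t.\tgene\t500\t900\t.\t-\t.\tID=geneB\n"
            "chr1\t.\texon\t100\t200\t.\t+\t.\tID=exon1\n"
        )
        p = tmp_path / "n.gff3"
        p.write_text(text)
        genes = read_gene_table(p)
        assert [g.gene_id for g in genes] == ["geneA", "geneB"]
        assert genes[0].product == "widget"
        assert genes[1].strand == "-"


def test_gene_record_validation():
    with pytest.raises(ValueError):
        GeneRecord("x", 10, 5, "+")
    with pytest.raises(ValueError):
        GeneRecord("x", 1, 5, "?")
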