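"""Microsynteny: pairing, tandem collapsing, blocks, quality, ratios."""

import numpy as np
import pytest

from bacpool import simdata, synteny
from bacpool.seqio import GeneModel
from bacpool.synteny import (
    HomologPair,
    collapse_tandem,
    find_blocks,
    pair_homologs,
    quality,
    ratio_stats,
)


def mk_gene(gid, start, te=False, protein=100, n_exons=1, exon_len=300, intron_len=100):
    exons = []
    pos = start
    for _ in range(n_exons):
        exons.append((pos, pos + exon_len))
        pos += exon_len + intron_len
    return GeneModel(gid, "r", "+", exons, te_flag=te,
                     protein_length=0 if te else protein)


def mk_side(prefix, n, te_at=(), start=0, spacing=1000, **kw):
    return [
        mk_gene(f"{prefix}{i}", start + i * spacing, te=(i in te_at), **kw)
        for i in range(n)
    ]


def cross_rows(pairs, ident=90.0, ev=1e-80):
    return [(a, b, ident, ev) for a, b in pairs]


class TestPairHomologs:
    def test_single_pair(self):
        ga, gb = mk_side("a", 1), mk_side("b", 1)
        pairs = pair_homologs(ga, gb, cross_rows([("a0", "b0")]))
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("a0", "b0")]

    def test_reciprocity_required(self):
        ga, gb = mk_side("a", 2), mk_side("b", 1)
        # a0's best is b0, but b0's best is a1
        table = [("a0", "b0", 90.0, 1e-60), ("a1", "b0", 95.0, 1e-90)]
        pairs = pair_homologs(ga, gb, table)
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("a1", "b0")]

    def test_te_and_cutoff_exclusion(self):
        ga = mk_side("a", 2, te_at={1})
        gb = mk_side("b", 2)
        table = [("a1", "b0", 99.0, 1e-200),   # TE: excluded
                 ("a0", "b1", 90.0, 1e-10)]    # fails e-value cut
        assert pair_homologs(ga, gb, table) == []

    def test_truth_recovery_on_simulated_pair(self, gene_only_genome):
        ra, rb, table = simdata.make_synteny_pair(gene_only_genome, 5, 1.3, 0.13, 9)
        pairs = pair_homologs(ra.genes, rb.genes, table)
        truth = {(a, b) for a, b, _, _ in table if "_dup" not in a and b.startswith("g")}
        assert {(p.gene_a, p.gene_b) for p in pairs} == truth
        mean_ident = np.mean([p.identity for p in pairs])
        assert 82.0 <= mean_ident <= 92.0  # ~13% coding divergence


class TestCollapseTandem:
    def test_mutually_homologous_run_collapses(self):
        genes = mk_side("a", 4)
        table = cross_rows([("a0", "a1"), ("a1", "a2")], ev=1e-100)
        coll = collapse_tandem(genes, table, paired_ids={"a1"})
        assert [c.representative for c in coll] == ["a1", "a3"]
        assert coll[0].array_size == 3

    def test_non_homologous_neighbours_unchanged(self):
        genes = mk_side("a", 3)
        coll = collapse_tandem(genes, [])
        assert [c.representative for c in coll] == ["a0", "a1", "a2"]
        assert all(c.array_size == 1 for c in coll)

    def test_planted_tandem_array_recovered(self, gene_only_genome):
        ra, rb, table = simdata.make_synteny_pair(
            gene_only_genome, 0, 1.0, 0.0, 1, tandem_dups=1, tandem_copies=4
        )
        a_genes = sorted((g for g in ra.genes if not g.te_flag), key=lambda g: g.start)
        n_truth = len([g for g in rb.genes if not g.te_flag])
        assert len(a_genes) == n_truth + 3
        pairs = pair_homologs(ra.genes, rb.genes, table)
        coll = collapse_tandem(a_genes, table, {p.gene_a for p in pairs})
        assert len(coll) == n_truth


class TestFindBlocks:
    def oracle_runs(self, genes_a, genes_b, pairs, max_gap=3):
        """Brute-force chain enumeration: sort pairs along A; a block break
        occurs when consecutive pairs are separated by more than max_gap
        unpaired genes on either side; runs of >= 2 pairs survive."""
        order_a = [g.id for g in sorted(genes_a, key=lambda g: g.start) if not g.te_flag]
        order_b = [g.id for g in sorted(genes_b, key=lambda g: g.start) if not g.te_flag]
        paired_a = {p.gene_a for p in pairs}
        paired_b = {p.gene_b for p in pairs}

        def gap(order, paired, x, y):
            i, j = sorted((order.index(x), order.index(y)))
            return sum(1 for g in order[i + 1 : j] if g not in paired)

        chain = sorted(pairs, key=lambda p: order_a.index(p.gene_a))
        runs, cur = [], [chain[0]]
        for prev, nxt in zip(chain, chain[1:]):
            if (gap(order_a, paired_a, prev.gene_a, nxt.gene_a) <= max_gap
                    and gap(order_b, paired_b, prev.gene_b, nxt.gene_b) <= max_gap):
                cur.append(nxt)
            else:
                runs.append(cur)
                cur = [nxt]
        runs.append(cur)
        return [
            [(p.gene_a, p.gene_b) for p in r] for r in runs if len(r) >= 2
        ]

    def test_all_paired_single_block(self):
        ga, gb = mk_side("a", 5), mk_side("b", 5)
        pairs = pair_homologs(ga, gb, cross_rows([(f"a{i}", f"b{i}") for i in range(5)]))
        blocks = find_blocks(ga, gb, pairs)
        assert len(blocks) == 1
        assert blocks[0].n_pairs == 5 and blocks[0].quality == 100.0

    def test_long_unpaired_stretch_splits_blocks(self):
        ga, gb = mk_side("a", 14), mk_side("b", 14)
        paired = [0, 1, 12, 13]  # clusters separated by 10 unpaired genes
        pairs = pair_homologs(ga, gb, cross_rows([(f"a{i}", f"b{i}") for i in paired]))
        blocks = find_blocks(ga, gb, pairs)
        assert len(blocks) == 2
        assert all(b.n_pairs == 2 for b in blocks)

    def test_local_inversion_stays_one_block(self):
        ga, gb = mk_side("a", 4), mk_side("b", 4)
        mapping = [("a0", "b0"), ("a1", "b2"), ("a2", "b1"), ("a3", "b3")]
        pairs = pair_homologs(ga, gb, cross_rows(mapping))
        blocks = find_blocks(ga, gb, pairs)
        assert len(blocks) == 1 and blocks[0].n_pairs == 4

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = int(rng.integers(4, 13)), int(rng.integers(4, 13))
        ga, gb = mk_side("a", na), mk_side("b", nb)
        k = int(rng.integers(2, min(na, nb) + 1))
        ia = sorted(rng.choice(na, size=k, replace=False).tolist())
        ib = rng.permutation(sorted(rng.choice(nb, size=k, replace=False).tolist())).tolist()
        mapping = [(f"a{i}", f"b{j}") for i, j in zip(ia, ib)]
        pairs = pair_homologs(ga, gb, cross_rows(mapping))
        if not pairs:
            return
        got = [[(p.gene_a, p.gene_b) for p in b.pairs] for b in find_blocks(ga, gb, pairs)]
        assert got == self.oracle_runs(ga, gb, pairs)


class TestQuality:
    def test_direct_formula(self):
        assert quality(4, 4, 5, 5) == 80.0
        assert quality(5, 5, 5, 5) == 100.0

    def test_hand_constructed_te_and_tandem_case(self):
        # region A: 6 genes incl. 1 TE and a 2-copy tandem -> 4 countable
        ga = mk_side("a", 6, te_at={5})
        gb = mk_side("b", 4)
        table = cross_rows([("a0", "b0"), ("a1", "b1"), ("a2", "b2")]) + [
            ("a3", "a4", 95.0, 1e-100)  # tandem array a3/a4
        ]
        pairs = pair_homologs(ga, gb, table)
        assert synteny.region_quality(ga, gb, pairs, table) == 75.0

    def test_monotonicity_in_unpaired_genes(self):
        base = quality(3, 3, 4, 4)
        assert quality(3, 3, 5, 4) < base        # extra unpaired gene lowers
        assert quality(3, 3, 4, 4) == base       # extra TE never enters counts

    def test_empty_block_rejected(self):
        with pytest.raises(ValueError):
            quality(0, 0, 0, 0)

    def test_relabeling_and_shift_invariance(self):
        ga1, gb1 = mk_side("a", 5), mk_side("b", 5)
        ga2 = mk_side("x", 5, start=50_000)
        gb2 = mk_side("y", 5, start=90_000)
        m1 = cross_rows([(f"a{i}", f"b{i}") for i in range(4)])
        m2 = cross_rows([(f"x{i}", f"y{i}") for i in range(4)])
        q1 = find_blocks(ga1, gb1, pair_homologs(ga1, gb1, m1))[0].quality
        q2 = find_blocks(ga2, gb2, pair_homologs(ga2, gb2, m2))[0].quality
        assert q1 == q2

    def test_lossless_simulated_pair_scores_100(self, gene_only_genome):
        ra, rb, table = simdata.make_synteny_pair(gene_only_genome, 10, 1.3, 0.1, 4)
        pairs = pair_homologs(ra.genes, rb.genes, table)
        blocks = find_blocks(ra.genes, rb.genes, pairs, table)
        assert len(blocks) == 1
        assert blocks[0].quality == 100.0

    def test_gene_deletion_matches_formula(self, gene_only_genome):
        ra, rb, table = simdata.make_synteny_pair(gene_only_genome, 0, 1.0, 0.0, 1)
        n = len(rb.genes)
        k = 2  # drop two genes from side A along with their truth rows
        dropped = {g.id for g in ra.genes[:k]}
        genes_a = [g for g in ra.genes if g.id not in dropped]
        table = [row for row in table if row[0] not in dropped]
        pairs = pair_homologs(genes_a, rb.genes, table)
        expected = round(100.0 * ((n - k) + (n - k)) / ((n - k) + n), 1)
        assert synteny.region_quality(genes_a, rb.genes, pairs, table) == expected


class TestRatioStats:
    def test_identical_models(self):
        ga = mk_side("a", 3, n_exons=3)
        gb = mk_side("b", 3, n_exons=3)
        pairs = [HomologPair(f"a{i}", f"b{i}", 100.0, 1e-100) for i in range(3)]
        rs = ratio_stats(pairs, ga, gb)
        assert (rs.protein_length_ratio, rs.exon_count_ratio, rs.mean_intron_ratio) == (
            1.0, 1.0, 1.0,
        )

    def test_protein_ratio_arithmetic(self):
        ga = [mk_gene("a0", 0, protein=480)]
        gb = [mk_gene("b0", 0, protein=500)]
        rs = ratio_stats([HomologPair("a0", "b0", 90.0, 1e-60)], ga, gb)
        assert rs.protein_length_ratio == 0.96

    def test_intron_scale_recovered(self, gene_only_genome):
        ra, rb, table = simdata.make_synteny_pair(gene_only_genome, 0, 1.3, 0.1, 7)
        pairs = pair_homologs(ra.genes, rb.genes, table)
        rs = ratio_stats(pairs, ra.genes, rb.genes)
        assert abs(rs.mean_intron_ratio - 1.3) <= 0.1

    def test_missing_structure_skipped_with_warning(self):
        ga = [mk_gene("a0", 0)]
        gb = []
        with pytest.warns(UserWarning, match="skipped"):
            rs = ratio_stats([HomologPair("a0", "b0", 90.0, 1e-60)], ga, gb)
        assert rs.n_pairs_used == 0
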