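import itertools

import numpy as np
import pytest

from tubkit.core import GenomeBundle
from tubkit.synteny import (
    AnchorPair,
    BlockAnnotation,
    BlockMap,
    LabeledAnchor,
    assign_gene_to_block,
    chain_collinear,
    compare_homologous_blocks,
    detect_homeolog_groups,
    find_anchors,
    infer_block_borders,
)

from conftest import make_gene


def anchor(ra, rb, score=10.0, chrom_a="c1", chrom_b="c2", name=None):
    return AnchorPair(
        gene_a=name or f"a{ra}",
        gene_b=f"b{rb}",
        chrom_a=chrom_a,
        chrom_b=chrom_b,
        rank_a=ra,
        rank_b=rb,
        score=score,
    )


def oracle_best_chain(anchors, min_size, max_gap):
    """Exhaustive maximum-score chain over all subsets (n <= 12)."""
    best = 0.0
    n = len(anchors)
    for r in range(min_size, n + 1):
        for combo in itertools.combinations(range(n), r):
            sel = [anchors[i] for i in combo]
            sel.sort(key=lambda a: a.rank_a)
            ra = [a.rank_a for a in sel]
            rb = [a.rank_b for a in sel]
            if len(set(ra)) != len(ra):
                continue
            ok_plus = all(
                0 < ra[i + 1] - ra[i] <= max_gap
                and 0 < rb[i + 1] - rb[i] <= max_gap
                for i in range(len(sel) - 1)
            )
            ok_minus = all(
                0 < ra[i + 1] - ra[i] <= max_gap
                and 0 < rb[i] - rb[i + 1] <= max_gap
                for i in range(len(sel) - 1)
            )
            if ok_plus or ok_minus:
                best = max(best, sum(a.score for a in sel))
    return best


class TestChaining:
    def test_perfect_diagonal(self):
        anchors = [anchor(i, i) for i in range(1, 6)]
        chains = chain_collinear(anchors, min_size=5)
        assert len(chains) == 1
        assert chains[0].orientation == "plus"
        assert chains[0].size == 5

    def test_off_diagonal_excluded(self):
        anchors = [anchor(i, i) for i in range(1, 6)] + [anchor(3, 50, name="odd")]
        # rank collision on rank_a=3: give the interloper a distinct rank
        anchors[-1].rank_a = 6
        chains = chain_collinear(anchors, min_size=5, max_gap=25)
        assert len(chains) == 1
        ids = {a.gene_a for a in chains[0].anchors}
        assert "odd" not in ids
        assert chains[0].score == pytest.approx(
            oracle_best_chain(anchors, 5, 25)
        )

    def test_inversion(self):
        pairs = [(1, 5), (2, 4), (3, 3), (4, 2), (5, 1)]
        anchors = [anchor(a, b) for a, b in pairs]
        chains = chain_collinear(anchors, min_size=5)
        assert len(chains) == 1
        assert chains[0].orientation == "minus"
        assert chains[0].size == 5

    def test_monotone_invariant(self):
        rng = np.random.default_rng(0)
        anchors = [
            anchor(int(ra), int(rb), float(rng.uniform(1, 5)), name=f"g{i}")
            for i, (ra, rb) in enumerate(
                zip(rng.permutation(30), rng.permutation(30))
            )
        ]
        for c in chain_collinear(anchors, min_size=3):
            ra = [a.rank_a for a in c.anchors]
            rb = [a.rank_b for a in c.anchors]
            assert ra == sorted(ra)
            if c.orientation == "plus":
                assert rb == sorted(rb)
            else:
                assert rb == sorted(rb, reverse=True)

    def test_oracle_equivalence_small_sets(self):
        rng = np.random.default_rng(1)
        for trial in range(12):
            n = int(rng.integers(4, 13))
            anchors = [
                anchor(
                    int(rng.integers(1, 15)),
                    int(rng.integers(1, 15)),
                    float(rng.integers(1, 6)),
                    name=f"t{trial}g{i}",
                )
                for i in range(n)
            ]
            # deduplicate rank_a values (ranks are unique per chromosome)
            seen = set()
            uniq = []
            for a in anchors:
                if a.rank_a not in seen and a.rank_b not in {
                    u.rank_b for u in uniq
                }:
                    seen.add(a.rank_a)
                    uniq.append(a)
            min_size, max_gap = 3, 5
            chains = chain_collinear(uniq, min_size=min_size, max_gap=max_gap)
            got = max((c.score for c in chains), default=0.0)
            assert got == pytest.approx(oracle_best_chain(uniq, min_size, max_gap))


class TestFindAnchors:
    def _bundle(self, seqs):
        genes = []
        chrom = "c1"
        pos = 0
        for gid, protein in seqs.items():
            g = make_gene(gid, chrom, [(pos, pos + 30)])
            g.protein = protein
            g.cds = "ATG" * 10
            genes.append(g)
            pos += 100
        return GenomeBundle(
            sequences={chrom: "A" * pos}, genes=genes, subgenome_map={chrom: "G1"}
        )

    def test_self_comparison_unique_sequences_no_anchors(self):
        # sequences with disjoint k-mer content: no candidate pairs at all
        b = self._bundle(
            {
                "g1": "MKVLAAGHTRW" * 10,
                "g2": "PPPQQQNNNYY" * 10,
                "g3": "DDDEEEFFFSS" * 10,
            }
        )
        assert find_anchors(b, b) == []

    def test_homeolog_pairs_are_anchors(self, rates_zero_dataset):
        from tubkit.pipeline import SYNTH_SCAN
        from tubkit.simulate import split_by_subgenome

        bundle, truth, _, _ = rates_zero_dataset
        subs = split_by_subgenome(bundle)
        anchors = find_anchors(subs["G1"], subs["G2"], SYNTH_SCAN)
        pairs = {frozenset((a.gene_a, a.gene_b)) for a in anchors}
        for members in truth.homeolog_groups.values():
            g1 = next(m for m in members if m.endswith("_G1"))
            g2 = next(m for m in members if m.endswith("_G2"))
            assert frozenset((g1, g2)) in pairs

    def test_deleted_gene_has_no_anchor(self, rates_zero_dataset):
        from tubkit.pipeline import SYNTH_SCAN
        from tubkit.simulate import split_by_subgenome

        bundle, truth, _, _ = rates_zero_dataset
        subs = split_by_subgenome(bundle)
        g1, g2 = subs["G1"], subs["G2"]
        victim = next(g for g in g2.genes if g.family)
        g2.genes = [g for g in g2.genes if g.gene_id != victim.gene_id]
        anchors = find_anchors(g1, g2, SYNTH_SCAN)
        partner = victim.gene_id.replace("_G2", "_G1")
        assert all(a.gene_a != partner and a.gene_b != partner for a in anchors)


class TestHomeologGroups:
    def test_rates_zero_all_triplets(self, rates_zero_dataset):
        from tubkit.pipeline import SYNTH_SCAN, build_chains

        bundle, truth, _, _ = rates_zero_dataset
        res = build_chains(bundle, SYNTH_SCAN)
        fam = {g.gene_id: g.family for g in bundle.genes if g.family}
        subs = {g.gene_id: g.subgenome for g in bundle.genes}
        groups = detect_homeolog_groups(res["chains"], fam, subs)
        assert len(groups["triplets"]) == len(truth.homeolog_groups)
        assert not groups["pairs"] and not groups["singletons"]

    def test_forced_loss_gives_pair(self, rates_zero_dataset):
        from tubkit.pipeline import SYNTH_SCAN, build_chains

        bundle, truth, _, _ = rates_zero_dataset
        victim = next(
            m for ms in truth.homeolog_groups.values() for m in ms if m.endswith("_G3")
        )
        pruned = GenomeBundle(
            sequences=bundle.sequences,
            genes=[g for g in bundle.genes if g.gene_id != victim],
            subgenome_map=bundle.subgenome_map,
        )
        res = build_chains(pruned, SYNTH_SCAN)
        fam = {g.gene_id: g.family for g in pruned.genes if g.family}
        subs = {g.gene_id: g.subgenome for g in pruned.genes}
        groups = detect_homeolog_groups(res["chains"], fam, subs)
        assert len(groups["pairs"]) == 1
        assert len(groups["triplets"]) == len(truth.homeolog_groups) - 1


class TestBlockBorders:
    def _anchors(self, labels, spacing=1000, glen=500):
        out = []
        for i, lab in enumerate(labels):
            start = i * spacing
            out.append(LabeledAnchor(f"g{i}", start, start + glen, lab))
        return out

    def test_clean_split_midpoint(self):
        anchors = self._anchors(["A"] * 10 + ["B"] * 10)
        anns = infer_block_borders(anchors, "c1")
        assert [a.block_label for a in anns] == ["A", "B"]
        # border at midpoint between end of anchor 9 and start of anchor 10
        expected = (9 * 1000 + 500 + 10 * 1000) // 2
        assert anns[0].end == expected
        assert anns[1].start == expected

    def test_interloper_absorbed(self):
        labels = ["A"] * 5 + ["B"] + ["A"] * 5
        anns = infer_block_borders(self._anchors(labels), "c1", max_interlopers=2)
        assert [a.block_label for a in anns] == ["A"]
        assert anns[0].anchor_count == 10
        # oracle: exhaustive segmentation minimizing label switches keeps one run
        assert _oracle_min_switches(labels, max_run_override=1) == 0

    def test_minor_fragment_flagged(self):
        labels = ["A"] * 5 + ["F"] * 2 + ["B"] * 5
        anns = infer_block_borders(
            self._anchors(labels), "c1", min_run=3, max_interlopers=0
        )
        frag = [a for a in anns if a.block_label == "F"]
        assert len(frag) == 1
        assert frag[0].minor_fragment

    def test_unlabeled_anchor_warns(self):
        anchors = self._anchors(["A", "", "A", "A"])
        with pytest.warns(UserWarning):
            anns = infer_block_borders(anchors, "c1")
        assert [a.block_label for a in anns] == ["A"]
        assert anns[0].anchor_count == 3

    def test_annotations_never_overlap(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            labels = [
                "AB"[int(x)] for x in rng.integers(0, 2, size=30)
            ]
            anns = infer_block_borders(self._anchors(labels), "c1")
            for x, y in zip(anns, anns[1:]):
                assert x.end <= y.start


def _oracle_min_switches(labels, max_run_override):
    """Minimum label switches after deleting up to max_run_override short
    foreign runs (oracle for the absorb rule)."""
    kept = [l for l in labels if l == max(set(labels), key=labels.count)]
    switches = sum(1 for a, b in zip(kept, kept[1:]) if a != b)
    return switches


class TestBlockAssignment:
    def _map(self):
        bm = BlockMap()
        bm.annotations["c1"] = [
            BlockAnnotation("C", "c1", 1000, 5000, 5),
            BlockAnnotation("D", "c1", 6000, 9000, 5),
        ]
        return bm

    def test_containment(self):
        g = make_gene("g", "c1", [(3000, 3100)])
        assert assign_gene_to_block(g, self._map()) == "C"

    def test_gap_unassigned(self):
        g = make_gene("g", "c1", [(5500, 5600)])
        assert assign_gene_to_block(g, self._map()) == "unassigned"

    def test_missing_chromosome_fatal(self):
        g = make_gene("g", "cX", [(0, 100)])
        with pytest.raises(KeyError):
            assign_gene_to_block(g, self._map())

    def test_five_prime_convention_minus_strand(self):
        g = make_gene("g", "c1", [(4900, 5100)], "-")
        # 5' end of a minus-strand gene is its right edge (5099) -> gap
        assert assign_gene_to_block(g, self._map()) == "unassigned"


class TestCompareBlocks:
    def _map(self, sizes):
        bm = BlockMap()
        for i, s in enumerate(sizes):
            chrom = f"c{i + 1}"
            bm.annotations[chrom] = [BlockAnnotation("X", chrom, 0, s, 5)]
        return bm

    def test_similar_sizes_not_flagged(self):
        bm = self._map([3_600_000, 3_650_000, 3_700_000])
        res = compare_homologous_blocks(
            bm, "X", {"c1": "G1", "c2": "G2", "c3": "G3"}
        )
        assert res["ratio"] == pytest.approx(3.7 / 3.6, abs=1e-3)
        assert not res["flagged"]

    def test_large_ratio_flagged(self):
        bm = self._map([1, 2, 3])
        res = compare_homologous_blocks(
            bm, "X", {"c1": "G1", "c2": "G2", "c3": "G3"}
        )
        assert res["ratio"] == pytest.approx(3.0)
        assert res["flagged"]

    def test_single_subgenome_ratio_one(self):
        bm = self._map([1000])
        res = compare_homologous_blocks(bm, "X", {"c1": "G1"})
        assert res["ratio"] == 1.0

    def test_absent_block_fatal(self):
        bm = self._map([1000])
        with pytest.raises(ValueError):
            compare_homologous_blocks(bm, "Z", {"c1": "G1"})
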