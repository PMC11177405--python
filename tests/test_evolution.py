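import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq

from tubkit.evolution import (
    DistanceMatrix,
    SENSE_CODONS,
    align_pair,
    align_proteins,
    assign_class_by_clade,
    codon_align,
    codon_pair_differences,
    kaks_summary,
    ng86_kaks,
    nj_tree,
    protein_distance,
    synonymous_sites,
)

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}


def oracle_syn_sites(codon):
    """Independent enumeration of synonymous site fractions."""
    aa = str(Seq(codon).translate())
    total = 0.0
    for pos in range(3):
        alts = [
            codon[:pos] + b + codon[pos + 1 :]
            for b in BASES
            if b != codon[pos]
        ]
        alts = [a for a in alts if a not in STOPS]
        if not alts:
            continue
        syn = sum(1 for a in alts if str(Seq(a).translate()) == aa)
        total += syn / len(alts)
    return total


class TestNG86Sites:
    def test_all_sense_codons_match_oracle(self):
        for codon in SENSE_CODONS:
            assert synonymous_sites(codon) == pytest.approx(oracle_syn_sites(codon))

    def test_worked_examples(self):
        assert synonymous_sites("GGG") == pytest.approx(1.0)
        assert synonymous_sites("TTT") == pytest.approx(1 / 3)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            synonymous_sites("TAA")


class TestCodonPairDiffs:
    def test_identical(self):
        assert codon_pair_differences("ATG", "ATG") == (0.0, 0.0)

    def test_single_synonymous(self):
        # GGA -> GGG is synonymous (Gly)
        assert codon_pair_differences("GGA", "GGG") == (1.0, 0.0)

    def test_single_nonsynonymous(self):
        assert codon_pair_differences("ATG", "ACG") == (0.0, 1.0)

    def test_double_path_average(self):
        # TTT(F) <-> TTA(L) at pos3 and CTT(L) path combinations
        sd, nd = codon_pair_differences("TTT", "CTA")
        # paths: TTT->CTT(non)->CTA(syn) ; TTT->TTA(non)->CTA(syn)
        assert sd + nd == pytest.approx(2.0)
        assert sd == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        sense = list(SENSE_CODONS)
        for _ in range(50):
            c1, c2 = rng.choice(sense, 2)
            assert codon_pair_differences(c1, c2) == codon_pair_differences(c2, c1)


class TestNg86KaKs:
    def test_identical_cds(self):
        pairs = [("ATG", "ATG"), ("GGG", "GGG"), ("TTT", "TTT")]
        r = ng86_kaks(pairs)
        assert r.Ka == 0.0 and r.Ks == 0.0
        assert r.undefined_ratio

    def test_sites_sum_to_three_per_codon(self):
        rng = np.random.default_rng(1)
        sense = list(SENSE_CODONS)
        pairs = [tuple(rng.choice(sense, 2)) for _ in range(100)]
        r = ng86_kaks(pairs)
        assert r.S_sites + r.N_sites == pytest.approx(3 * len(pairs))

    def test_single_nonsyn_change_gives_zero_ks(self):
        pairs = [("GCT", "GCT")] * 29 + [("ATG", "ACG")]
        r = ng86_kaks(pairs)
        assert r.Ks == 0.0
        assert r.Ka > 0.0

    def test_symmetry_in_argument_order(self):
        rng = np.random.default_rng(2)
        sense = list(SENSE_CODONS)
        pairs = [tuple(rng.choice(sense, 2)) for _ in range(15)]
        pairs += [(c, c) for c in rng.choice(sense, 60)]
        r1 = ng86_kaks(pairs)
        r2 = ng86_kaks([(b, a) for a, b in pairs])
        assert r1.Ka == pytest.approx(r2.Ka)
        assert r1.Ks == pytest.approx(r2.Ks)

    def test_empty_fatal(self):
        with pytest.raises(ValueError):
            ng86_kaks([])


class TestCodonAlign:
    def test_gap_free(self):
        cds = "ATGGCTGCTGAA"
        pairs = codon_align(cds, cds)
        assert len(pairs) == 4

    def test_terminal_stop_trimmed(self):
        pairs = codon_align("ATGGCTTAA", "ATGGCTTAA")
        assert len(pairs) == 2

    def test_gap_columns_dropped(self):
        a = "ATG" + "GCT" * 8
        b = "ATG" + "GCT" * 2 + "GCT" * 4  # 2 fewer residues
        pairs = codon_align(a, b)
        assert len(pairs) == 7  # 9 vs 7 -> 7 retained columns

    def test_internal_stop_fatal(self):
        with pytest.raises(ValueError, match="stop"):
            codon_align("ATGTAAGCT", "ATGGCTGCT")

    def test_alignment_mismatch_fatal(self):
        with pytest.raises(ValueError):
            codon_align("ATGGCT", "ATGGCT", ("MAX", "MAX"))


class TestProteinDistance:
    def test_identical_rows(self):
        dm = protein_distance({"a": "MKV", "b": "MKV"})
        assert dm.get("a", "b") == 0.0

    def test_p_distance_value(self):
        a = "A" * 450
        b = "C" * 10 + "A" * 440
        dm = protein_distance({"a": a, "b": b})
        assert dm.get("a", "b") == pytest.approx(10 / 450, abs=1e-6)

    def test_poisson_saturated_undefined(self):
        dm = protein_distance({"a": "AAAA", "b": "CCCC"}, model="poisson")
        assert math.isnan(dm.get("a", "b"))

    def test_no_comparable_sites(self):
        with pytest.raises(ValueError, match="a.*b|b.*a"):
            protein_distance({"a": "AA--", "b": "--CC"})


class TestNJ:
    def test_three_taxa(self):
        dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float))
        t = nj_tree(dm)
        sp = t.splits()
        assert sp[frozenset({"A"})] == pytest.approx(1.0)
        assert sp[frozenset({"B"})] == pytest.approx(1.0)
        assert sp[frozenset({"C"})] == pytest.approx(2.0)

    def test_worked_four_taxon_example(self):
        taxa = ["A", "B", "C", "D"]
        m = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        t = nj_tree(DistanceMatrix(taxa, m))
        sp = t.splits()
        assert sp[frozenset({"A"})] == pytest.approx(1.0)
        assert sp[frozenset({"B"})] == pytest.approx(2.0)
        assert sp[frozenset({"C"})] == pytest.approx(3.0)
        assert sp[frozenset({"D"})] == pytest.approx(4.0)
        assert sp[frozenset({"A", "B"})] == pytest.approx(1.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        taxa = list("ABCDEF")
        tree = _random_additive(rng, taxa)
        dm = _tree_distances(tree, taxa)
        t1 = nj_tree(DistanceMatrix(taxa, dm))
        perm = ["D", "A", "F", "B", "E", "C"]
        idx = [taxa.index(p) for p in perm]
        t2 = nj_tree(DistanceMatrix(perm, dm[np.ix_(idx, idx)]))
        s1 = {k: round(v, 9) for k, v in t1.splits().items()}
        s2 = {k: round(v, 9) for k, v in t2.splits().items()}
        assert s1 == s2

    def test_asymmetric_fatal(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], float))


def _random_additive(rng, taxa):
    """Random unrooted binary tree with positive branch lengths, as an
    adjacency dict (independent oracle helper)."""
    nodes = list(taxa)
    adj = {}
    counter = [0]

    def join(a, b):
        counter[0] += 1
        new = f"I{counter[0]}"
        adj.setdefault(new, {})
        for x in (a, b):
            bl = float(rng.uniform(0.5, 5.0))
            adj.setdefault(x, {})[new] = bl
            adj[new][x] = bl
        return new

    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[i], nodes[j]
        new = join(a, b)
        nodes = [n for n in nodes if n not in (a, b)] + [new]
    center = "ROOT"
    adj[center] = {}
    for x in nodes:
        bl = float(rng.uniform(0.5, 5.0))
        adj.setdefault(x, {})[center] = bl
        adj[center][x] = bl
    return adj


def _tree_distances(adj, taxa):
    import collections

    n = len(taxa)
    out = np.zeros((n, n))
    for i, a in enumerate(taxa):
        dist = {a: 0.0}
        dq = collections.deque([a])
        while dq:
            u = dq.popleft()
            for v, bl in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + bl
                    dq.append(v)
        for j, b in enumerate(taxa):
            out[i, j] = dist[b]
    return out


def _tree_splits(adj, taxa):
    """Ground-truth splits of the random tree (smaller side canonical)."""
    all_set = frozenset(taxa)
    splits = {}
    seen = set()
    for u in adj:
        for v, bl in adj[u].items():
            if (v, u) in seen or (u, v) in seen:
                continue
            seen.add((u, v))
            # leaves on v's side when edge u-v removed
            stack, side, visited = [v], set(), {u, v}
            while stack:
                x = stack.pop()
                if x in taxa:
                    side.add(x)
                for w in adj[x]:
                    if w not in visited:
                        visited.add(w)
                        stack.append(w)
            side = frozenset(side)
            other = all_set - side
            if not side or not other:
                continue
            key = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
            splits[key] = splits.get(key, 0.0) + bl
    return splits


class TestNJAdditiveRecovery:
    def test_exact_recovery_sample(self):
        taxa = list("ABCDEFGH")
        for seed in range(10):
            rng = np.random.default_rng(seed)
            adj = _random_additive(rng, taxa)
            dm = DistanceMatrix(taxa, _tree_distances(adj, taxa))
            t = nj_tree(dm)
            expected = _tree_splits(adj, taxa)
            got = t.splits()
            assert set(got) == set(expected), f"topology mismatch seed {seed}"
            for k in expected:
                assert got[k] == pytest.approx(expected[k], abs=1e-9)


class TestCladeAssignment:
    def _tree(self, seqs):
        dm = protein_distance(align_proteins(seqs))
        return nj_tree(dm)

    def test_pure_clade(self):
        seqs = {
            "q": "MKVLAAGHTRW" * 5,
            "r1": "MKVLAAGHTRW" * 5,
            "r2": "MKVLAAGHTKW" * 5,
            "s1": "MPPPQQQNNNW" * 5,
            "s2": "MPPPQQQNNNY" * 5,
        }
        tree = self._tree(seqs)
        labels = {"r1": "II", "r2": "II", "s1": "I", "s2": "I"}
        assert assign_class_by_clade(tree, labels, "q") == "II"

    def test_mixed_clade_ambiguous(self):
        # r1/r2 are twins; q sits outside their two-leaf clade, so the
        # smallest labeled clade containing q mixes both labels
        seqs = {
            "q": "MKVLAAGHTKY" + "MKVLAAGHTRW" * 4,
            "r1": "MKVLAAGHTRW" * 5,
            "r2": "MKVLAAGHTRW" * 5,
            "out1": "MPPPQQQNNNW" * 5,
            "out2": "MPPPQQQNNNY" * 5,
        }
        tree = self._tree(seqs)
        labels = {"r1": "TUA3", "r2": "TUA5", "out1": "X", "out2": "X"}
        assert assign_class_by_clade(tree, labels, "q") == "ambiguous"

    def test_query_missing_fatal(self):
        seqs = {"a": "MKV" * 20, "b": "MRV" * 20, "c": "MPV" * 20}
        tree = self._tree(seqs)
        with pytest.raises(ValueError):
            assign_class_by_clade(tree, {"a": "x"}, "zzz")

    def test_simulated_classes_recovered(self, sim_default):
        bundle, truth, _, ancestor = sim_default
        refs = {p.isotype: p for p in ancestor.family_genes()}
        ref_class = {
            f"ref_{p.isotype}": f"{p.family}-{p.cls}"
            for p in ancestor.family_genes()
        }
        from tubkit.pipeline import ancestor_queries

        queries = ancestor_queries(ancestor)
        pseudo = set(truth.pseudogenes)
        seqs = {f"ref_{iso}": prot for iso, prot in queries.items()}
        correct = total = 0
        for g in bundle.genes:
            if not g.family or g.gene_id in pseudo:
                continue
            tree = self._tree({**seqs, "q": g.protein})
            label = assign_class_by_clade(tree, ref_class, "q")
            part = refs[truth.gene_isotype[g.gene_id]]
            total += 1
            correct += label == f"{part.family}-{part.cls}"
        assert correct == total


class TestKaksSummary:
    def test_basic(self):
        r1 = ng86_kaks([("GCT", "GCA")] * 10 + [("ATG", "ATG")] * 90)
        r2 = ng86_kaks([("ATG", "ACG")] + [("GCT", "GCA")] * 5 + [("AAA", "AAA")] * 94)
        df = kaks_summary({"grp": ["p1", "p2"], "empty": []}, {"p1": r1, "p2": r2})
        row = df[df.group == "grp"].iloc[0]
        assert row.n_pairs == 2
        assert row.ka_max == pytest.approx(max(r1.Ka, r2.Ka))
        empty = df[df.group == "empty"].iloc[0]
        assert empty.n_pairs == 0


class TestAlignment:
    def test_align_pair_identity(self):
        a = "MKTAYIAKQRQISFVKSHFSRQ"
        ra, rb = align_pair(a, a)
        assert ra == rb == a

    def test_align_pair_gap(self):
        a = "MKTAYIAKQRQISFVKSHFSRQ"
        b = a[:8] + a[12:]
        ra, rb = align_pair(a, b)
        assert ra.replace("-", "") == a
        assert rb.replace("-", "") == b
        assert rb.count("-") == 4

    def test_msa_equal_width(self):
        seqs = {"a": "MKTAYIAKQRQISFVK", "b": "MKTAYIAKQISFVK", "c": "MKTAYIAKQRQISFVR"}
        aln = align_proteins(seqs)
        widths = {len(v) for v in aln.values()}
        assert len(widths) == 1
        for k, s in aln.items():
            assert s.replace("-", "") == seqs[k]
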