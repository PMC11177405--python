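"""Distance phylogenetics and molecular-evolution rates.

Implements Nei–Gojobori (1986) site counting with Jukes–Cantor correction,
neighbor-joining tree inference with deterministic tie-breaking, codon
alignment threading, and a small progressive protein aligner.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "DistanceMatrix",
    "NJTree",
    "KaKsResult",
    "synonymous_sites",
    "codon_pair_differences",
    "ng86_kaks",
    "codon_align",
    "protein_distance",
    "nj_tree",
    "assign_class_by_clade",
    "align_pair",
    "align_proteins",
    "kaks_summary",
]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


def _codon_table() -> dict[str, str]:
    table = {}
    for c in ("".join(t) for t in itertools.product(_BASES, repeat=3)):
        table[c] = str(Seq(c).translate())
    return table


CODON_TO_AA = _codon_table()
SENSE_CODONS = sorted(c for c in CODON_TO_AA if c not in _STOPS)


# ---------------------------------------------------------------------------
# NG86 site and difference counting
# ---------------------------------------------------------------------------

def synonymous_sites(codon: str) -> float:
    """Synonymous site count of a sense codon.

    Each position contributes the fraction of its non-stop single-nucleotide
    neighbors that are synonymous; stop-creating neighbors are excluded from
    numerator and denominator so the codon always carries 3 sites in total.
    """
    codon = codon.upper()
    if codon in _STOPS or codon not in CODON_TO_AA:
        raise ValueError(f"not a sense codon: {codon}")
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in _STOPS:
                continue
            valid += 1
            if CODON_TO_AA[alt] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s


_SYN_SITES = {c: synonymous_sites(c) for c in SENSE_CODONS}


def _single_step_class(c1: str, c2: str) -> str:
    return "syn" if CODON_TO_AA[c1] == CODON_TO_AA[c2] else "non"


def codon_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons.

    Multi-nucleotide differences are averaged with equal weight over all
    orderings of single steps; paths passing through a stop codon are
    excluded (falling back to all paths if every path hits a stop).
    """
    c1, c2 = c1.upper(), c2.upper()
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                hit_stop = True
            if _single_step_class(cur, nxt) == "syn":
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, hit_stop))
    valid = [(s, n) for s, n, stop in paths if not stop]
    if not valid:
        valid = [(s, n) for s, n, _ in paths]
    sd = sum(v[0] for v in valid) / len(valid)
    nd = sum(v[1] for v in valid) / len(valid)
    return sd, nd


_PAIR_DIFFS: dict[tuple[str, str], tuple[float, float]] = {}


def _pair_diffs_cached(c1: str, c2: str) -> tuple[float, float]:
    key = (c1, c2)
    hit = _PAIR_DIFFS.get(key)
    if hit is None:
        hit = codon_pair_differences(c1, c2)
        _PAIR_DIFFS[key] = hit
        _PAIR_DIFFS[(c2, c1)] = hit[::-1] if False else hit  # symmetric
    return hit


def _jc_correct(p: float) -> tuple[float, bool]:
    """Jukes–Cantor corrected distance; flag True when undefined (p >= 3/4)."""
    if p >= 0.75:
        return math.nan, True
    if p == 0.0:
        return 0.0, False
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p), False


@dataclass
class KaKsResult:
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ks: float
    Ka: float
    ratio: float
    flags: list[str] = field(default_factory=list)

    @property
    def undefined_ratio(self) -> bool:
        return "undefined_ratio" in self.flags


def ng86_kaks(codon_pairs: Sequence[tuple[str, str]]) -> KaKsResult:
    """Nei–Gojobori Ka/Ks over aligned codon pairs (see ``codon_align``)."""
    if not codon_pairs:
        raise ValueError("empty codon alignment")
    S = N = Sd = Nd = 0.0
    for c1, c2 in codon_pairs:
        c1, c2 = c1.upper(), c2.upper()
        s1, s2 = _SYN_SITES[c1], _SYN_SITES[c2]
        S += 0.5 * (s1 + s2)
        N += 0.5 * ((3.0 - s1) + (3.0 - s2))
        sd, nd = _pair_diffs_cached(c1, c2)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    flags = []
    Ks, ks_undef = _jc_correct(ps)
    Ka, ka_undef = _jc_correct(pn)
    if ks_undef:
        flags.append("Ks_undefined")
    if ka_undef:
        flags.append("Ka_undefined")
    if ks_undef or ka_undef or Ks == 0.0:
        ratio = math.nan
        flags.append("undefined_ratio")
    else:
        ratio = Ka / Ks
    return KaKsResult(S, N, Sd, Nd, ps, pn, Ks, Ka, ratio, flags)


# ---------------------------------------------------------------------------
# Pairwise and progressive protein alignment
# ---------------------------------------------------------------------------

def _aligner(mode: str = "global") -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def align_pair(a: str, b: str) -> tuple[str, str]:
    """Global protein alignment of two sequences (BLOSUM62, affine gaps)."""
    aln = _aligner().align(a, b)[0]
    rows = str(aln).splitlines()
    # biotite-style text parsing is fragile; reconstruct from coordinates
    coords = aln.coordinates
    ra, rb = [], []
    for k in range(coords.shape[1] - 1):
        a0, a1 = coords[0, k], coords[0, k + 1]
        b0, b1 = coords[1, k], coords[1, k + 1]
        if a1 > a0 and b1 > b0:
            ra.append(a[a0:a1])
            rb.append(b[b0:b1])
        elif a1 > a0:
            ra.append(a[a0:a1])
            rb.append("-" * (a1 - a0))
        else:
            ra.append("-" * (b1 - b0))
            rb.append(b[b0:b1])
    return "".join(ra), "".join(rb)


def percent_identity(a: str, b: str) -> float:
    """Percent identity over aligned positions of a global alignment."""
    ra, rb = align_pair(a, b)
    matches = sum(1 for x, y in zip(ra, rb) if x == y and x != "-")
    aligned = sum(1 for x, y in zip(ra, rb))
    return 100.0 * matches / aligned if aligned else 0.0


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / len(ka | kb)


def align_proteins(seqs: Mapping[str, str]) -> dict[str, str]:
    """Simple center-star progressive multiple alignment.

    The center sequence is the one with smallest total k-mer distance to
    the rest; every sequence is aligned pairwise to the center and merged
    on center coordinates (once a gap, always a gap).  A deliberate,
    documented stand-in for a full progressive aligner.
    """
    names = list(seqs)
    if len(names) == 1:
        return dict(seqs)
    total = {
        n: sum(_kmer_distance(seqs[n], seqs[m]) for m in names if m != n)
        for n in names
    }
    center = min(names, key=lambda n: (total[n], n))
    center_seq = seqs[center]

    # per-sequence alignment against the center
    pair_alns = {}
    for n in names:
        if n == center:
            continue
        rc, rn = align_pair(center_seq, seqs[n])
        pair_alns[n] = (rc, rn)

    # merged center coordinate system: insertions relative to the center
    # are tracked per center-position
    ins_after = [0] * (len(center_seq) + 1)  # insertions before position i
    parsed = {}
    for n, (rc, rn) in pair_alns.items():
        cols = []  # (center_pos or None, residue of n)
        cpos = 0
        run = 0
        for x, y in zip(rc, rn):
            if x == "-":
                run += 1
                cols.append((None, y))
            else:
                ins_after[cpos] = max(ins_after[cpos], run)
                run = 0
                cols.append((cpos, y))
                cpos += 1
        ins_after[cpos] = max(ins_after[cpos], run)
        parsed[n] = cols

    def render_center() -> str:
        out = []
        for i, ch in enumerate(center_seq):
            out.append("-" * ins_after[i])
            out.append(ch)
        out.append("-" * ins_after[len(center_seq)])
        return "".join(out)

    result = {center: render_center()}
    for n in names:
        if n == center:
            continue
        cols = parsed[n]
        out = []
        # walk the center positions, interleaving insertions
        pending: dict[int, list[str]] = {}
        per_pos: dict[int, str] = {}
        cpos = 0
        buffer: list[str] = []
        for ref, res in cols:
            if ref is None:
                buffer.append(res)
            else:
                pending[ref] = buffer
                per_pos[ref] = res
                buffer = []
        tail = buffer
        for i in range(len(center_seq)):
            ins = pending.get(i, [])
            out.append("".join(ins).rjust(ins_after[i], "-"))
            out.append(per_pos.get(i, "-"))
        out.append("".join(tail).ljust(ins_after[len(center_seq)], "-"))
        result[n] = "".join(out)

    width = len(result[center])
    for n, s in result.items():
        assert len(s) == width, f"ragged alignment for {n}"
    return result


# ---------------------------------------------------------------------------
# Codon alignment
# ---------------------------------------------------------------------------

def codon_align(
    cds_a: str,
    cds_b: str,
    protein_alignment: tuple[str, str] | None = None,
) -> list[tuple[str, str]]:
    """Thread two CDSs through their protein alignment into codon columns.

    Columns with a gap in either row are dropped; a stop codon in a
    retained column is a fatal error.  Terminal stop codons on either CDS
    are trimmed before threading.
    """

    def prep(cds: str) -> tuple[str, str]:
        if len(cds) % 3 != 0:
            raise ValueError(f"CDS length {len(cds)} not a multiple of 3")
        if cds[-3:].upper() in _STOPS:
            cds = cds[:-3]
        aa = str(Seq(cds).translate())
        if "*" in aa:
            raise ValueError(f"internal stop at codon {aa.index('*') + 1}")
        return cds, aa

    cds_a, prot_a = prep(cds_a)
    cds_b, prot_b = prep(cds_b)
    if protein_alignment is None:
        protein_alignment = align_pair(prot_a, prot_b)
    ra, rb = protein_alignment
    if ra.replace("-", "") != prot_a or rb.replace("-", "") != prot_b:
        raise ValueError("protein alignment does not match CDS translations")
    pairs = []
    ia = ib = 0
    for x, y in zip(ra, rb):
        ca = cds_a[3 * ia : 3 * ia + 3] if x != "-" else None
        cb = cds_b[3 * ib : 3 * ib + 3] if y != "-" else None
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
        if ca is None or cb is None:
            continue
        if ca.upper() in _STOPS or cb.upper() in _STOPS:
            raise ValueError(f"stop codon in retained column ({ca}/{cb})")
        pairs.append((ca, cb))
    return pairs


# ---------------------------------------------------------------------------
# Distance matrices and neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix diagonal not zero")
        self.matrix = m

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.taxa.index(a), self.taxa.index(b)])


def protein_distance(
    alignment: Mapping[str, str], model: str = "p_distance"
) -> DistanceMatrix:
    """Pairwise distances over an alignment with pairwise gap deletion."""
    names = list(alignment)
    rows = [alignment[n] for n in names]
    width = {len(r) for r in rows}
    if len(width) != 1:
        raise ValueError("alignment rows have unequal length")
    n = len(names)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp = mis = 0
            for x, y in zip(rows[i], rows[j]):
                if x == "-" or y == "-":
                    continue
                comp += 1
                if x != y:
                    mis += 1
            if comp == 0:
                raise ValueError(
                    f"no comparable sites between {names[i]} and {names[j]}"
                )
            p = mis / comp
            if model == "p_distance":
                d = p
            elif model == "poisson":
                d = math.nan if p >= 1.0 else -math.log(1.0 - p)
            else:
                raise ValueError(f"unknown model {model!r}")
            m[i, j] = m[j, i] = d
    return DistanceMatrix(names, m)


@dataclass
class NJNode:
    label: str | None = None
    children: list[tuple["NJNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.label]
        out = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class NJTree:
    """Unrooted tree held at an internal trifurcation (or a 2-leaf edge)."""

    root: NJNode
    notes: list[str] = field(default_factory=list)

    def leaves(self) -> list[str]:
        return self.root.leaves()

    # -- topology utilities -------------------------------------------------
    def edges(self) -> list[tuple[frozenset, float]]:
        """All edges as (leaf set on the child side, branch length)."""
        out = []

        def walk(node: NJNode) -> None:
            for child, bl in node.children:
                out.append((frozenset(child.leaves()), bl))
                walk(child)

        walk(self.root)
        return out

    def splits(self) -> dict[frozenset, float]:
        """Canonical unrooted splits -> branch length (smaller side kept)."""
        all_leaves = frozenset(self.leaves())
        result = {}
        for side, bl in self.edges():
            other = all_leaves - side
            key = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
            result[key] = result.get(key, 0.0) + bl
        return result

    def newick(self) -> str:
        def fmt(node: NJNode) -> str:
            if node.is_leaf():
                return node.label
            inner = ",".join(f"{fmt(c)}:{bl:.6f}" for c, bl in node.children)
            return f"({inner})"

        return fmt(self.root) + ";"


def nj_tree(dm: DistanceMatrix) -> NJTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties on the Q criterion are broken by the lexicographically smallest
    (sorted) label pair.  Negative branch estimates are clamped to zero
    and noted.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes: dict[str, NJNode] = {t: NJNode(label=t) for t in dm.taxa}
    d: dict[tuple[str, str], float] = {}
    for i, a in enumerate(dm.taxa):
        for j, b in enumerate(dm.taxa):
            d[(a, b)] = float(dm.matrix[i, j])
    active = sorted(dm.taxa)
    notes: list[str] = []
    next_id = 0

    def clamp(x: float) -> float:
        if x < 0:
            notes.append(f"negative branch {x:.6g} clamped to 0")
            return 0.0
        return x

    while len(active) > 3:
        r = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(active, 2):
            q = (len(active) - 2) * d[(a, b)] - r[a] - r[b]
            key = (q, min(a, b), max(a, b))
            if best is None or key < best:
                best = key
        _, a, b = best
        m = len(active)
        bl_a = 0.5 * d[(a, b)] + (r[a] - r[b]) / (2 * (m - 2))
        bl_b = d[(a, b)] - bl_a
        new = NJNode(children=[(nodes[a], clamp(bl_a)), (nodes[b], clamp(bl_b))])
        new_name = f"__nj{next_id}"
        next_id += 1
        nodes[new_name] = new
        for c in active:
            if c in (a, b):
                continue
            d[(new_name, c)] = d[(c, new_name)] = 0.5 * (
                d[(a, c)] + d[(b, c)] - d[(a, b)]
            )
        d[(new_name, new_name)] = 0.0
        active = sorted(set(active) - {a, b} | {new_name})

    a, b, c = active
    bl_a = 0.5 * (d[(a, b)] + d[(a, c)] - d[(b, c)])
    bl_b = 0.5 * (d[(a, b)] + d[(b, c)] - d[(a, c)])
    bl_c = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
    root = NJNode(
        children=[
            (nodes[a], clamp(bl_a)),
            (nodes[b], clamp(bl_b)),
            (nodes[c], clamp(bl_c)),
        ]
    )
    return NJTree(root=root, notes=notes)


# ---------------------------------------------------------------------------
# Clade labeling
# ---------------------------------------------------------------------------

def _midpoint_root(tree: NJTree) -> NJNode:
    """Re-root at the midpoint of the longest leaf-to-leaf path.

    Works on an adjacency representation of the unrooted tree; returns a
    rooted binary NJNode.
    """
    # build adjacency
    adj: dict[int, list[tuple[int, float]]] = {}
    labels: dict[int, str] = {}
    counter = itertools.count()
    idx: dict[id, int] = {}

    def node_id(node: NJNode) -> int:
        key = id(node)
        if key not in idx:
            idx[key] = next(counter)
            if node.is_leaf():
                labels[idx[key]] = node.label
        return idx[key]

    def walk(node: NJNode) -> None:
        u = node_id(node)
        adj.setdefault(u, [])
        for child, bl in node.children:
            v = node_id(child)
            adj.setdefault(v, [])
            adj[u].append((v, bl))
            adj[v].append((u, bl))
            walk(child)

    walk(tree.root)

    def farthest(start: int) -> tuple[int, float, dict[int, tuple[int, float]]]:
        dist = {start: 0.0}
        prev: dict[int, tuple[int, float]] = {}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, bl in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + bl
                    prev[v] = (u, bl)
                    stack.append(v)
        leaf_nodes = [u for u in dist if u in labels]
        far = max(leaf_nodes, key=lambda u: (dist[u], labels[u]))
        return far, dist[far], prev

    some_leaf = min(labels, key=lambda u: labels[u])
    end1, _, _ = farthest(some_leaf)
    end2, diameter, prev = farthest(end1)
    # path end2 -> end1
    path = [end2]
    while path[-1] != end1:
        u, _ = prev[path[-1]]
        path.append(u)
    # locate midpoint edge along path
    target = diameter / 2.0
    acc = 0.0
    edge = None
    for u, v in zip(path, path[1:]):
        bl = next(b for w, b in adj[u] if w == v)
        if acc + bl >= target or (u, v) == (path[-2], path[-1]):
            edge = (u, v, bl, target - acc)
            break
        acc += bl
    u, v, bl, off = edge
    off = min(max(off, 0.0), bl)

    def build(node: int, parent: int) -> NJNode:
        kids = [(w, b) for w, b in adj[node] if w != parent]
        if not kids and node in labels:
            return NJNode(label=labels[node])
        return NJNode(children=[(build(w, node), b) for w, b in kids])

    left = build(u, v)
    right = build(v, u)
    return NJNode(children=[(left, off), (right, bl - off)])


def assign_class_by_clade(
    tree: NJTree,
    reference_labels: Mapping[str, str],
    query: str,
    outgroup: str | None = None,
) -> str:
    """Label the query by the smallest uniformly-labeled clade containing it.

    The unrooted tree is midpoint rooted (or rooted on ``outgroup`` when
    supplied); walking up from the query, the first clade whose reference
    members all share one label gives that label; a clade mixing labels at
    every level yields ``"ambiguous"``.
    """
    if query not in tree.leaves():
        raise ValueError(f"query {query!r} not in tree")
    if outgroup is not None:
        rooted = _root_on_leaf(tree, outgroup)
    else:
        rooted = _midpoint_root(tree)

    # collect path of clades from query leaf to root
    path: list[NJNode] = []

    def find(node: NJNode, trail: list[NJNode]) -> bool:
        trail.append(node)
        if node.is_leaf():
            if node.label == query:
                path.extend(trail)
                return True
            trail.pop()
            return False
        for child, _ in node.children:
            if find(child, trail):
                return True
        trail.pop()
        return False

    find(rooted, [])
    for node in reversed(path[:-1]):  # smallest containing clade first
        labels = {
            reference_labels[leaf]
            for leaf in node.leaves()
            if leaf in reference_labels
        }
        if len(labels) == 1:
            return labels.pop()
        if len(labels) > 1:
            return "ambiguous"
    return "ambiguous"


def _root_on_leaf(tree: NJTree, leaf: str) -> NJNode:
    if leaf not in tree.leaves():
        raise ValueError(f"outgroup {leaf!r} not in tree")
    # reuse midpoint machinery by rebuilding adjacency rooted at the leaf edge
    mid = _midpoint_root(tree)  # gives us a rooted binary topology

    # re-root: find the leaf and hang the tree from its incident edge
    def reroot(node: NJNode, parent_chain: list[tuple[NJNode, float]]) -> NJNode | None:
        if node.is_leaf() and node.label == leaf:
            # build the "rest of tree" by unwinding the chain
            rest = _detach(parent_chain)
            return NJNode(children=[(node, 0.0), (rest, parent_chain[-1][1])])
        for child, bl in node.children:
            r = reroot(child, parent_chain + [(node, bl)])
            if r is not None:
                return r
        return None

    def _detach(chain: list[tuple[NJNode, float]]) -> NJNode:
        # flatten: everything except the path to the outgroup leaf
        node, _ = chain[-1]
        others = [
            (c, bl)
            for c, bl in node.children
            if not (c.is_leaf() and c.label == leaf)
        ]
        if len(chain) == 1:
            if len(others) == 1:
                return others[0][0]
            return NJNode(children=others)
        upper = _detach(chain[:-1])
        return NJNode(children=others + [(upper, chain[-1][1])])

    r = reroot(mid, [])
    if r is None:  # pragma: no cover - leaf existence checked above
        raise RuntimeError("failed to re-root")
    return r


# ---------------------------------------------------------------------------
# Group summaries
# ---------------------------------------------------------------------------

def kaks_summary(
    groups: Mapping[str, Sequence[str]],
    results: Mapping[str, KaKsResult],
    ka_bound: float = 0.04,
    ks_bound: float = 0.2,
):
    """Per-group Ka/Ks statistics with declared-bound exceedance flags."""
    import pandas as pd

    rows = []
    for group, pair_ids in groups.items():
        vals = [results[p] for p in pair_ids if p in results]
        if not vals:
            rows.append(
                {
                    "group": group,
                    "n_pairs": 0,
                    "ka_mean": math.nan,
                    "ka_max": math.nan,
                    "ks_mean": math.nan,
                    "ks_max": math.nan,
                    "ratio_max": math.nan,
                    "ka_exceed": 0,
                    "ks_exceed": 0,
                }
            )
            continue
        kas = [v.Ka for v in vals if not math.isnan(v.Ka)]
        kss = [v.Ks for v in vals if not math.isnan(v.Ks)]
        ratios = [v.ratio for v in vals if not math.isnan(v.ratio)]
        rows.append(
            {
                "group": group,
                "n_pairs": len(vals),
                "ka_mean": float(np.mean(kas)) if kas else math.nan,
                "ka_max": max(kas) if kas else math.nan,
                "ks_mean": float(np.mean(kss)) if kss else math.nan,
                "ks_max": max(kss) if kss else math.nan,
                "ratio_max": max(ratios) if ratios else math.nan,
                "ka_exceed": sum(1 for k in kas if k >= ka_bound),
                "ks_exceed": sum(1 for k in kss if k >= ks_bound),
            }
        )
    return pd.DataFrame(rows)
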