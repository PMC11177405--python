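"""Anchor detection, collinear chaining, homeolog groups and block maps.

Chaining follows the MCScanX idea: dynamic programming over rank pairs
with bounded rank gaps, greedy extraction of the best chain, repeat.
Block borders are placed at midpoints of inter-run gaps; short runs are
kept but flagged as minor fragments.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .core import GenomeBundle, GeneRecord
from .mining import ScanParams, sw_score

__all__ = [
    "AnchorPair",
    "CollinearChain",
    "BlockAnnotation",
    "BlockMap",
    "find_anchors",
    "chain_collinear",
    "detect_homeolog_groups",
    "infer_block_borders",
    "assign_gene_to_block",
    "compare_homologous_blocks",
]


@dataclass
class AnchorPair:
    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    rank_a: int
    rank_b: int
    score: float
    block_label: str | None = None
    ak_chrom: str | None = None
    pos_a: tuple[int, int] | None = None  # genomic extent (start, end)
    pos_b: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("anchor cannot pair a gene with itself")


@dataclass
class CollinearChain:
    anchors: list[AnchorPair]
    chrom_a: str
    chrom_b: str
    orientation: str  # "plus" | "minus"
    score: float

    @property
    def size(self) -> int:
        return len(self.anchors)


@dataclass
class BlockAnnotation:
    block_label: str
    chrom: str
    start: int
    end: int
    anchor_count: int
    minor_fragment: bool = False
    ak_chrom: str | None = None


@dataclass
class BlockMap:
    """Per-chromosome ordered block annotations plus explicit gaps."""

    annotations: dict[str, list[BlockAnnotation]] = field(default_factory=dict)

    def blocks_on(self, chrom: str) -> list[BlockAnnotation]:
        return self.annotations.get(chrom, [])

    def gaps_on(self, chrom: str, chrom_len: int | None = None) -> list[tuple[int, int]]:
        anns = self.blocks_on(chrom)
        gaps = []
        prev_end = 0
        for a in anns:
            if a.start > prev_end:
                gaps.append((prev_end, a.start))
            prev_end = a.end
        if chrom_len is not None and chrom_len > prev_end:
            gaps.append((prev_end, chrom_len))
        return gaps

    def all_blocks(self) -> list[BlockAnnotation]:
        return [a for anns in self.annotations.values() for a in anns]


# ---------------------------------------------------------------------------
# Anchors (reciprocal best hits)
# ---------------------------------------------------------------------------

def _gene_ranks(bundle: GenomeBundle) -> dict[str, tuple[str, int]]:
    """gene id -> (chrom, rank in gene order on that chromosome)."""
    out = {}
    for chrom in bundle.sequences:
        for rank, g in enumerate(bundle.genes_on(chrom)):
            out[g.gene_id] = (chrom, rank)
    return out


def _kmer_set(seq: str, k: int = 4) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def find_anchors(
    bundle_a: GenomeBundle,
    bundle_b: GenomeBundle,
    params: ScanParams | None = None,
    n_candidates: int = 3,
) -> list[AnchorPair]:
    """Reciprocal best hits between the proteomes of two bundles.

    Candidate pairs are pre-filtered by shared-k-mer counts (a seeding
    heuristic) and scored with full Smith–Waterman; a pair is an anchor
    when each member is the other's best-scoring hit.  Self-comparison is
    allowed (self-pairs excluded).
    """
    params = params or ScanParams()
    genes_a = [g for g in bundle_a.genes if g.protein]
    genes_b = [g for g in bundle_b.genes if g.protein]
    ranks_a = _gene_ranks(bundle_a)
    ranks_b = _gene_ranks(bundle_b)
    kmers_b = {g.gene_id: _kmer_set(g.protein) for g in genes_b}
    kmers_a = {g.gene_id: _kmer_set(g.protein) for g in genes_a}
    prot_a = {g.gene_id: g.protein for g in genes_a}
    prot_b = {g.gene_id: g.protein for g in genes_b}
    self_mode = bundle_a is bundle_b

    def best_hits(
        src_ids: Sequence[str],
        src_prot: Mapping[str, str],
        src_kmers: Mapping[str, set],
        dst_prot: Mapping[str, str],
        dst_kmers: Mapping[str, set],
    ) -> dict[str, tuple[str, float]]:
        out = {}
        for gid in src_ids:
            ks = src_kmers[gid]
            cands = sorted(
                (tid for tid in dst_prot if tid != gid),
                key=lambda tid: (-len(ks & dst_kmers[tid]), tid),
            )[:n_candidates]
            best = None
            for tid in cands:
                if not ks & dst_kmers[tid]:
                    continue
                s = sw_score(src_prot[gid], dst_prot[tid], params)
                if best is None or s > best[1] or (s == best[1] and tid < best[0]):
                    best = (tid, s)
            if best is not None:
                out[gid] = best
        return out

    fwd = best_hits([g.gene_id for g in genes_a], prot_a, kmers_a, prot_b, kmers_b)
    rev = best_hits([g.gene_id for g in genes_b], prot_b, kmers_b, prot_a, kmers_a)

    anchors = []
    gene_a_map = {g.gene_id: g for g in genes_a}
    gene_b_map = {g.gene_id: g for g in genes_b}
    for ga, (gb, score) in sorted(fwd.items()):
        back = rev.get(gb)
        if back is None or back[0] != ga:
            continue
        if self_mode and gb < ga:
            continue  # emit each unordered pair once
        ca, ra = ranks_a[ga]
        cb, rb = ranks_b[gb]
        rec_a, rec_b = gene_a_map[ga], gene_b_map[gb]
        anchors.append(
            AnchorPair(
                gene_a=ga,
                gene_b=gb,
                chrom_a=ca,
                chrom_b=cb,
                rank_a=ra,
                rank_b=rb,
                score=score,
                pos_a=(rec_a.locus.start, rec_a.locus.end),
                pos_b=(rec_b.locus.start, rec_b.locus.end),
            )
        )
    return anchors


# ---------------------------------------------------------------------------
# Collinear chaining
# ---------------------------------------------------------------------------

def _best_chain(
    anchors: list[AnchorPair], orientation: str, max_gap: int
) -> tuple[list[int], float]:
    """Best-scoring monotone chain (indices into anchors) via DP."""
    order = sorted(
        range(len(anchors)),
        key=lambda i: (anchors[i].rank_a, anchors[i].rank_b, anchors[i].gene_a),
    )
    n = len(order)
    dp = [anchors[order[i]].score for i in range(n)]
    back = [-1] * n
    for i in range(n):
        ai = anchors[order[i]]
        for j in range(i):
            aj = anchors[order[j]]
            da = ai.rank_a - aj.rank_a
            if da <= 0 or da > max_gap:
                continue
            db = ai.rank_b - aj.rank_b
            if orientation == "plus":
                if db <= 0 or db > max_gap:
                    continue
            else:
                if db >= 0 or -db > max_gap:
                    continue
            cand = dp[j] + ai.score
            if cand > dp[i] + 1e-12:
                dp[i] = cand
                back[i] = j
    if not n:
        return [], 0.0
    best_i = max(range(n), key=lambda i: (dp[i], -anchors[order[i]].rank_a))
    chain = []
    i = best_i
    while i != -1:
        chain.append(order[i])
        i = back[i]
    chain.reverse()
    return chain, dp[best_i]


def chain_collinear(
    anchors: Sequence[AnchorPair], min_size: int = 5, max_gap: int = 25
) -> list[CollinearChain]:
    """Greedy extraction of maximal-scoring collinear chains per chrom pair."""
    by_pair: dict[tuple[str, str], list[AnchorPair]] = defaultdict(list)
    for a in anchors:
        by_pair[(a.chrom_a, a.chrom_b)].append(a)

    chains = []
    for (ca, cb) in sorted(by_pair):
        pool = list(by_pair[(ca, cb)])
        while pool:
            best = None
            for orient in ("plus", "minus"):
                idxs, score = _best_chain(pool, orient, max_gap)
                if len(idxs) >= min_size and (
                    best is None
                    or score > best[2]
                    or (score == best[2] and orient == "plus")
                ):
                    best = (orient, idxs, score)
            if best is None:
                break
            orient, idxs, score = best
            members = [pool[i] for i in idxs]
            chains.append(
                CollinearChain(
                    anchors=members,
                    chrom_a=ca,
                    chrom_b=cb,
                    orientation=orient,
                    score=score,
                )
            )
            taken = set(idxs)
            pool = [a for i, a in enumerate(pool) if i not in taken]
    chains.sort(key=lambda c: (-c.score, c.chrom_a, c.chrom_b))
    return chains


# ---------------------------------------------------------------------------
# Homeolog groups
# ---------------------------------------------------------------------------

def detect_homeolog_groups(
    chains: Sequence[CollinearChain],
    family_genes: Mapping[str, str],
    gene_subgenome: Mapping[str, str],
) -> dict:
    """Merge family genes connected by chain-supported anchors.

    ``family_genes`` maps gene id -> family label; ``gene_subgenome`` maps
    gene id -> subgenome.  Returns triplets (span all three subgenomes),
    pairs, singletons, and the conflict log.
    """
    parent: dict[str, str] = {g: g for g in family_genes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    edge_score: dict[frozenset, float] = {}
    for chain in chains:
        for a in chain.anchors:
            if a.gene_a in family_genes and a.gene_b in family_genes:
                key = frozenset((a.gene_a, a.gene_b))
                edge_score[key] = max(edge_score.get(key, 0.0), chain.score)

    conflicts = []
    for key in sorted(edge_score, key=lambda k: (-edge_score[k], tuple(sorted(k)))):
        a, b = sorted(key)
        if gene_subgenome.get(a) == gene_subgenome.get(b):
            conflicts.append((a, b, "same-subgenome anchor ignored"))
            continue
        union(a, b)

    groups: dict[str, list[str]] = defaultdict(list)
    for g in family_genes:
        groups[find(g)].append(g)

    triplets, pairs, singletons = [], [], []
    for members in groups.values():
        members.sort()
        subs = {gene_subgenome.get(m) for m in members}
        if len(members) >= 3 and subs >= {"G1", "G2", "G3"}:
            triplets.append(members)
        elif len(members) == 2:
            pairs.append(members)
        elif len(members) == 1:
            singletons.append(members[0])
        else:
            pairs.append(members)  # 3+ members not spanning all subgenomes
    triplets.sort()
    pairs.sort()
    singletons.sort()
    return {
        "triplets": triplets,
        "pairs": pairs,
        "singletons": singletons,
        "conflicts": conflicts,
    }


# ---------------------------------------------------------------------------
# Block border inference
# ---------------------------------------------------------------------------

@dataclass
class LabeledAnchor:
    gene_id: str
    start: int
    end: int
    label: str
    ak_chrom: str | None = None


def infer_block_borders(
    anchors: Sequence[LabeledAnchor],
    chrom: str,
    min_run: int = 3,
    max_interlopers: int = 2,
) -> list[BlockAnnotation]:
    """Segment a chromosome's labeled anchors into block annotations.

    Maximal runs of one label absorb up to ``max_interlopers`` contiguous
    foreign anchors; borders sit at midpoints of inter-run gaps; runs
    shorter than ``min_run`` are flagged ``minor_fragment``.
    """
    labeled = []
    for a in sorted(anchors, key=lambda a: (a.start, a.gene_id)):
        if not a.label:
            warnings.warn(f"unlabeled anchor {a.gene_id} ignored", stacklevel=2)
            continue
        labeled.append(a)
    if not labeled:
        return []

    runs: list[list[LabeledAnchor]] = []
    for a in labeled:
        if runs and runs[-1][-1].label == a.label:
            runs[-1].append(a)
        else:
            runs.append([a])

    # absorb short foreign runs sandwiched between runs of one label
    changed = True
    while changed:
        changed = False
        for i in range(1, len(runs) - 1):
            prev_r, cur, next_r = runs[i - 1], runs[i], runs[i + 1]
            if (
                prev_r[-1].label == next_r[0].label
                and cur[0].label != prev_r[-1].label
                and len(cur) <= max_interlopers
                and len(cur) < len(prev_r) + len(next_r)
            ):
                merged = prev_r + next_r  # interlopers logged, not annotated
                runs[i - 1 : i + 2] = [merged]
                changed = True
                break

    annotations = []
    for i, run in enumerate(runs):
        start = run[0].start
        end = run[-1].end
        if i > 0:
            gap_mid = (runs[i - 1][-1].end + run[0].start) // 2
            start = gap_mid
        if i < len(runs) - 1:
            gap_mid = (run[-1].end + runs[i + 1][0].start) // 2
            end = gap_mid
        annotations.append(
            BlockAnnotation(
                block_label=run[0].label,
                chrom=chrom,
                start=start,
                end=end,
                anchor_count=len(run),
                minor_fragment=len(run) < min_run,
                ak_chrom=run[0].ak_chrom,
            )
        )
    return annotations


def assign_gene_to_block(gene: GeneRecord, block_map: BlockMap) -> str:
    """Block label containing the gene's 5' coordinate, or ``unassigned``."""
    chrom = gene.locus.chrom
    if chrom not in block_map.annotations:
        raise KeyError(f"chromosome {chrom} absent from block map")
    pos = gene.five_prime()
    for ann in block_map.blocks_on(chrom):
        if ann.start <= pos < ann.end:
            return ann.block_label
    return "unassigned"


def compare_homologous_blocks(
    block_map: BlockMap,
    block_label: str,
    chrom_subgenome: Mapping[str, str],
    ratio_threshold: float = 1.5,
) -> dict:
    """Per-subgenome sizes of one ancestral block and the max/min ratio."""
    sizes: dict[str, int] = {}
    for chrom, anns in block_map.annotations.items():
        sub = chrom_subgenome.get(chrom, "unplaced")
        for a in anns:
            if a.block_label == block_label:
                sizes[sub] = sizes.get(sub, 0) + (a.end - a.start)
    if not sizes:
        raise ValueError(f"block {block_label!r} absent from map")
    if len(sizes) == 1:
        ratio = 1.0
    else:
        ratio = max(sizes.values()) / min(sizes.values())
    return {
        "block": block_label,
        "sizes_bp": dict(sorted(sizes.items())),
        "ratio": ratio,
        "flagged": ratio > ratio_threshold,
    }


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

def anchors_to_tsv(anchors: Sequence[AnchorPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tchrom_a\tchrom_b\trank_a\trank_b\tscore\tblock\n")
        for a in anchors:
            fh.write(
                f"{a.gene_a}\t{a.gene_b}\t{a.chrom_a}\t{a.chrom_b}\t"
                f"{a.rank_a}\t{a.rank_b}\t{a.score:.1f}\t{a.block_label or '.'}\n"
            )


def block_map_to_tsv(block_map: BlockMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tblock\tak_chrom\tn_anchors\tminor\n")
        for chrom in sorted(block_map.annotations):
            for a in block_map.blocks_on(chrom):
                fh.write(
                    f"{chrom}\t{a.start}\t{a.end}\t{a.block_label}\t"
                    f"{a.ak_chrom or '.'}\t{a.anchor_count}\t"
                    f"{int(a.minor_fragment)}\n"
                )
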