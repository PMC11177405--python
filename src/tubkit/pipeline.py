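"""Stage orchestration: mining -> synteny -> blocks -> classification,
plus ground-truth recovery scoring on synthetic datasets."""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .core import GenomeBundle
from .homology import Evidence, classify_relation
from .mining import ScanParams, filter_hits, scan_proteome
from .simulate import (
    AncestralGenome,
    GroundTruth,
    SimulationConfig,
    simulate_dataset,
    split_by_subgenome,
)
from .synteny import (
    BlockMap,
    LabeledAnchor,
    assign_gene_to_block,
    chain_collinear,
    detect_homeolog_groups,
    find_anchors,
    infer_block_borders,
)

__all__ = [
    "ancestor_queries",
    "mine_family_genes",
    "build_chains",
    "build_block_map",
    "run_recovery",
]

#: scan parameters scaled to the synthetic family (short test proteins)
SYNTH_SCAN = ScanParams(min_hit_len=80, min_coverage=0.5)


def ancestor_queries(ancestor: AncestralGenome) -> dict[str, str]:
    """Reference isotype proteins from the ancestral family genes."""
    out = {}
    for part in ancestor.family_genes():
        cds = part.cds
        if cds[-3:] in ("TAA", "TAG", "TGA"):
            cds = cds[:-3]
        out[part.isotype] = str(Seq(cds).translate())
    return out


def mine_family_genes(
    bundle: GenomeBundle,
    queries: Mapping[str, str],
    params: ScanParams | None = None,
) -> dict:
    """Scan the annotated proteome and filter hits; returns mined gene ids
    with the full hit/discard evidence."""
    params = params or ScanParams()
    targets = {g.gene_id: g.protein for g in bundle.genes if g.protein}
    hits = scan_proteome(queries, targets, params)
    kept, discarded = filter_hits(hits, params)
    return {
        "mined": sorted({h.target_id for h in kept}),
        "hits": hits,
        "kept": kept,
        "discarded": discarded,
    }


def build_chains(
    bundle: GenomeBundle,
    params: ScanParams | None = None,
    min_size: int = 5,
    max_gap: int = 25,
) -> dict:
    """Anchors + collinear chains between every subgenome pair."""
    subs = split_by_subgenome(bundle)
    names = sorted(subs)
    anchors_by_pair = {}
    chains = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = find_anchors(subs[names[i]], subs[names[j]], params)
            anchors_by_pair[(names[i], names[j])] = a
            chains.extend(chain_collinear(a, min_size=min_size, max_gap=max_gap))
    return {"anchors": anchors_by_pair, "chains": chains}


def build_block_map(
    bundle: GenomeBundle, truth: GroundTruth, min_run: int = 3, max_interlopers: int = 2
) -> BlockMap:
    """Infer block borders from truth-labeled filler anchors per chromosome."""
    block_by_chrom = {
        chrom: rows for chrom, rows in truth.block_map.items()
    }
    bm = BlockMap()
    for chrom in sorted(bundle.sequences):
        rows = block_by_chrom.get(chrom, [])
        anchors = []
        for g in bundle.genes_on(chrom):
            if g.family:
                continue
            label = ""
            for s, e, blk, _ in rows:
                if s <= g.locus.start < e:
                    label = blk
                    break
            if label:
                anchors.append(
                    LabeledAnchor(g.gene_id, g.locus.start, g.locus.end, label)
                )
        bm.annotations[chrom] = infer_block_borders(
            anchors, chrom, min_run=min_run, max_interlopers=max_interlopers
        )
    return bm


# ---------------------------------------------------------------------------
# Recovery scoring against ground truth
# ---------------------------------------------------------------------------

def _chain_anchor_pairs(chains) -> set[frozenset]:
    out = set()
    for c in chains:
        for a in c.anchors:
            out.add(frozenset((a.gene_a, a.gene_b)))
    return out


def run_recovery(
    config: SimulationConfig, scan_params: ScanParams | None = None
) -> dict:
    """Simulate one dataset and score pipeline recovery against truth."""
    scan_params = scan_params or SYNTH_SCAN
    bundle, truth, matrix, ancestor = simulate_dataset(config)

    # --- mining -----------------------------------------------------------
    queries = ancestor_queries(ancestor)
    mined = mine_family_genes(bundle, queries, scan_params)["mined"]
    true_family = {g.gene_id for g in bundle.genes if g.family}
    mined_set = set(mined)
    tp = len(mined_set & true_family)
    mining_precision = tp / len(mined_set) if mined_set else 0.0
    mining_recall = tp / len(true_family) if true_family else 1.0

    # --- synteny + homeolog groups ---------------------------------------
    syn = build_chains(bundle, scan_params)
    gene_sub = {g.gene_id: g.subgenome for g in bundle.genes}
    family_map = {g: truth.gene_family.get(g, "fam") for g in mined}
    groups = detect_homeolog_groups(syn["chains"], family_map, gene_sub)
    predicted_triplets = {frozenset(t) for t in groups["triplets"]}
    true_triplets = {
        frozenset(m)
        for m in truth.homeolog_groups.values()
        if len(m) == 3
        and {truth.gene_subgenome[x] for x in m} == {"G1", "G2", "G3"}
    }
    t_tp = len(predicted_triplets & true_triplets)
    triplet_precision = (
        t_tp / len(predicted_triplets) if predicted_triplets else 1.0
    )
    triplet_recall = t_tp / len(true_triplets) if true_triplets else 1.0

    # --- block borders and gene allocation --------------------------------
    block_map = build_block_map(bundle, truth)
    borders_ok = True
    for chrom, rows in truth.block_map.items():
        anns = block_map.blocks_on(chrom)
        labels_truth = [r[2] for r in rows]
        labels_inferred = [a.block_label for a in anns]
        if labels_truth != labels_inferred:
            borders_ok = False
            continue
        for k in range(len(rows) - 1):
            prev_end = rows[k][1]
            next_start = rows[k + 1][0]
            boundary = anns[k].end
            if not (prev_end <= boundary <= next_start):
                borders_ok = False

    assign_ok = assign_total = 0
    fam_genes = [g for g in bundle.genes if g.family]
    for g in fam_genes:
        assign_total += 1
        if assign_gene_to_block(g, block_map) == truth.gene_block.get(g.gene_id):
            assign_ok += 1
    block_assign_accuracy = assign_ok / assign_total if assign_total else 1.0

    # --- relation classification ------------------------------------------
    chain_pairs = _chain_anchor_pairs(syn["chains"])
    pseudo = set(truth.pseudogenes)
    by_id = {g.gene_id: g for g in bundle.genes}

    def evidence_for(a: str, b: str, use_true_blocks: bool) -> Evidence:
        ga, gb = by_id[a], by_id[b]
        if use_true_blocks:
            blk_a = truth.gene_block.get(a)
            blk_b = truth.gene_block.get(b)
        else:
            blk_a = assign_gene_to_block(ga, block_map)
            blk_b = assign_gene_to_block(gb, block_map)
        dist = None
        if ga.locus.chrom == gb.locus.chrom:
            dist = max(gb.locus.start - ga.locus.end, ga.locus.start - gb.locus.end, 0)
        return Evidence(
            subgenomes=(ga.subgenome, gb.subgenome),
            chain_support=frozenset((a, b)) in chain_pairs,
            block_match=blk_a == blk_b,
            clade_agreement=True,
            distance_bp=dist,
            same_chromosome=ga.locus.chrom == gb.locus.chrom,
            any_pseudogene=a in pseudo or b in pseudo,
            block_labels=(blk_a or "", blk_b or ""),
        )

    evaluated = correct = 0
    dup_eval = dup_correct = 0
    for members in truth.homeolog_groups.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                if truth.gene_subgenome[a] == truth.gene_subgenome[b]:
                    continue
                call = classify_relation([a, b], evidence_for(a, b, False))
                expected = (
                    "disrupted_homeolog"
                    if (a in pseudo or b in pseudo)
                    else "homeolog"
                )
                evaluated += 1
                correct += call.relation == expected
    for dup, orig in truth.tandem_pairs:
        call = classify_relation([dup, orig], evidence_for(dup, orig, True))
        evaluated += 1
        dup_eval += 1
        ok = call.relation == "tandem_paralog"
        correct += ok
        dup_correct += ok
    for dup, orig in truth.transposed_pairs:
        call = classify_relation([dup, orig], evidence_for(dup, orig, True))
        evaluated += 1
        dup_eval += 1
        ok = call.relation == "transposed_paralog"
        correct += ok
        dup_correct += ok

    return {
        "mining_precision": mining_precision,
        "mining_recall": mining_recall,
        "triplet_precision": triplet_precision,
        "triplet_recall": triplet_recall,
        "n_true_triplets": len(true_triplets),
        "borders_ok": borders_ok,
        "block_assign_accuracy": block_assign_accuracy,
        "relation_accuracy": correct / evaluated if evaluated else 1.0,
        "n_relations": evaluated,
        "dup_relation_accuracy": dup_correct / dup_eval if dup_eval else 1.0,
        "n_dup_relations": dup_eval,
        "bundle": bundle,
        "truth": truth,
        "matrix": matrix,
        "ancestor": ancestor,
        "groups": groups,
        "block_map": block_map,
    }
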