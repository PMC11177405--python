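"""Synthetic allohexaploid generator with full ground truth.

Builds an ancestral genome of block-structured chromosomes carrying a
multi-isotype gene family plus filler genes, evolves three diverged
subgenome copies under a codon-acceptance mutation model with direct
omega (Ka/Ks) control, merges them into an allohexaploid with
post-polyploidy events (loss, pseudogenization, tandem and transposed
duplication), and simulates tissue expression with subgenome bias and
salt-stress down-regulation.  Every event is logged so downstream
recovery can be scored exactly.

All randomness flows from integer seeds through ``numpy.random.Generator``
(PCG64), giving byte-identical output across platforms.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomeBundle, GeneRecord, GenomicInterval, write_genome_bundle
from .evolution import CODON_TO_AA, SENSE_CODONS, _STOPS
from .expression import DEV_CONDITIONS, ExpressionMatrix, write_expression

__all__ = [
    "FamilyGeneSpec",
    "SimulationConfig",
    "GroundTruth",
    "AncestralGenome",
    "simulate_ancestor",
    "evolve_subgenome",
    "evolve_cds",
    "assemble_allohexaploid",
    "simulate_expression",
    "simulate_dataset",
    "write_dataset",
    "split_by_subgenome",
]

_BASES = "ACGT"
_CODONS_BY_AA: dict[str, list[str]] = {}
for _c in SENSE_CODONS:
    _CODONS_BY_AA.setdefault(CODON_TO_AA[_c], []).append(_c)


@dataclass(frozen=True)
class FamilyGeneSpec:
    family: str
    cls: str
    isotype: str
    exon_count: int
    codon_length: int
    twin_of: str | None = None  # isotype whose CDS is copied verbatim


DEFAULT_FAMILY_SPEC = (
    FamilyGeneSpec("TUA", "I", "TUA2", 4, 150),
    FamilyGeneSpec("TUA", "I", "TUA6", 4, 150),
    FamilyGeneSpec("TUA", "II", "TUA1", 5, 150),
    FamilyGeneSpec("TUA", "II", "TUA3", 5, 150),
    FamilyGeneSpec("TUB", "I", "TUB6", 3, 149),
    FamilyGeneSpec("TUB", "II", "TUB7", 3, 149),
    FamilyGeneSpec("TUG", "1", "TUG1", 10, 158),
    FamilyGeneSpec("TUG", "2", "TUG2", 10, 158),
)


@dataclass
class SimulationConfig:
    seed: int = 1
    n_ancestral_chroms: int = 3
    blocks_per_chrom: int = 3
    genes_per_block: int = 30
    family_spec: tuple[FamilyGeneSpec, ...] = DEFAULT_FAMILY_SPEC
    divergence: tuple[float, float, float] = (0.06, 0.08, 0.04)
    omega: float = 0.05
    loss_rate: float = 0.02
    pseudogenize_rate: float = 0.05
    tandem_dup_rate: float = 0.01
    transpose_rate: float = 0.01
    # expression model
    expr_location: float = float(np.log(50.0))
    expr_scale: float = 0.4
    expr_noise_sigma: float = 0.1
    subgenome_bias: tuple[float, float, float] = (1.0, 1.0, 1.0)
    salt_fc: float = 2.0
    salt_isotypes: tuple[str, ...] = ("TUB7",)
    pseudogene_leakage: float = 0.005

    def __post_init__(self) -> None:
        for r in (
            self.loss_rate,
            self.pseudogenize_rate,
            self.tandem_dup_rate,
            self.transpose_rate,
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError("event rates must be in [0, 1]")
        if any(t <= 0 for t in self.divergence):
            raise ValueError("divergence times must be > 0")
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if any(b <= 0 for b in self.subgenome_bias):
            raise ValueError("bias multipliers must be positive")
        for spec in self.family_spec:
            if spec.exon_count < 1:
                raise ValueError(f"exon_count < 1 for {spec.isotype}")


# ---------------------------------------------------------------------------
# Internal genome-parts representation
# ---------------------------------------------------------------------------

@dataclass
class GenePart:
    gene_id: str  # ancestral id; subgenome suffix added at assembly
    strand: str
    exon_seqs: list[str]  # transcription order; concatenation = CDS
    intron_seqs: list[str]
    family: str | None = None
    cls: str | None = None
    isotype: str | None = None
    block: str = ""
    origin: str = "ancestral"  # ancestral | tandem_dup | transpose

    @property
    def cds(self) -> str:
        return "".join(self.exon_seqs)

    def clone(self, new_id: str, origin: str) -> "GenePart":
        c = copy.deepcopy(self)
        c.gene_id = new_id
        c.origin = origin
        return c


@dataclass
class AncestralGenome:
    """Chromosomes as ordered elements: ("spacer", seq) | ("gene", GenePart)."""

    chroms: dict[str, list] = field(default_factory=dict)
    block_of_gene: dict[str, str] = field(default_factory=dict)
    ak_of_block: dict[str, str] = field(default_factory=dict)
    config: SimulationConfig | None = None

    def genes(self) -> list[GenePart]:
        return [el[1] for els in self.chroms.values() for el in els if el[0] == "gene"]

    def family_genes(self) -> list[GenePart]:
        return [g for g in self.genes() if g.family]

    def to_bundle(self, subgenome_map: Mapping[str, str] | None = None) -> GenomeBundle:
        bundle, _ = _linearize({k: (k, v) for k, v in self.chroms.items()},
                               subgenome_map or {}, self.block_of_gene)
        return bundle


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(
        [c for c in SENSE_CODONS if c != "ATG"], size=n_codons - 1
    )
    return "ATG" + "".join(body)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, size=n)])


def _diverge_protein(
    rng: np.random.Generator, cds: str, p_aa: float
) -> str:
    """Replace ~p_aa of codons (after the start codon) by codons of a
    different amino acid; used to fan isotypes out of a family founder."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for i in range(1, len(codons)):
        if rng.random() < p_aa:
            aa = CODON_TO_AA[codons[i]]
            other_aa = rng.choice([a for a in _CODONS_BY_AA if a != aa])
            codons[i] = rng.choice(_CODONS_BY_AA[other_aa])
    return "".join(codons)


def _split_exons(
    rng: np.random.Generator, cds: str, exon_count: int, min_exon: int = 30
) -> list[str]:
    n = len(cds)
    if exon_count == 1:
        return [cds]
    if n < exon_count * min_exon:
        raise ValueError("CDS too short for requested exon count")
    while True:
        cuts = np.sort(rng.integers(min_exon, n - min_exon + 1, size=exon_count - 1))
        bounds = [0, *cuts.tolist(), n]
        lens = np.diff(bounds)
        if (lens >= min_exon).all():
            return [cds[a:b] for a, b in zip(bounds[:-1], bounds[1:])]


def simulate_ancestor(config: SimulationConfig) -> AncestralGenome:
    """Build the ancestral genome: labeled blocks of filler genes with
    family genes at deterministic mid-block slots."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    total_blocks = config.n_ancestral_chroms * config.blocks_per_chrom
    letters = string.ascii_uppercase
    if total_blocks > len(letters):
        raise ValueError("too many blocks for single-letter labels")

    # family founder/class/isotype coding sequences
    founders: dict[str, str] = {}
    class_cds: dict[tuple[str, str], str] = {}
    iso_cds: dict[str, str] = {}
    for spec in config.family_spec:
        if spec.family not in founders:
            founders[spec.family] = _random_cds(rng, spec.codon_length)
        key = (spec.family, spec.cls)
        if key not in class_cds:
            class_cds[key] = _diverge_protein(rng, founders[spec.family], 0.10)
    for spec in config.family_spec:
        if spec.twin_of:
            continue
        iso_cds[spec.isotype] = _diverge_protein(
            rng, class_cds[(spec.family, spec.cls)], 0.08
        )
    for spec in config.family_spec:
        if spec.twin_of:
            iso_cds[spec.isotype] = iso_cds[spec.twin_of]

    genome = AncestralGenome(config=config)
    block_idx = 0
    filler_counter = 0
    fam_slot = config.genes_per_block // 2
    family_by_block = {
        i % total_blocks: spec for i, spec in enumerate(config.family_spec)
    }

    for ci in range(config.n_ancestral_chroms):
        chrom = f"chr{ci + 1}"
        elements: list = [("spacer", _random_dna(rng, int(rng.integers(100, 400))))]
        for bi in range(config.blocks_per_chrom):
            label = letters[block_idx]
            genome.ak_of_block[label] = f"AK{ci + 1}"
            spec = family_by_block.get(block_idx)
            for si in range(config.genes_per_block):
                if spec is not None and si == fam_slot:
                    gid = f"anc_{spec.isotype}"
                    cds = iso_cds[spec.isotype] + ("TAA", "TAG", "TGA")[
                        int(rng.integers(0, 3))
                    ]
                    exons = _split_exons(rng, cds, spec.exon_count)
                    part = GenePart(
                        gene_id=gid,
                        strand="+" if rng.random() < 0.5 else "-",
                        exon_seqs=exons,
                        intron_seqs=[
                            _random_dna(rng, int(rng.integers(60, 200)))
                            for _ in range(len(exons) - 1)
                        ],
                        family=spec.family,
                        cls=spec.cls,
                        isotype=spec.isotype,
                        block=label,
                    )
                else:
                    filler_counter += 1
                    gid = f"anc_g{filler_counter:04d}"
                    n_codons = int(rng.integers(80, 121))
                    cds = _random_cds(rng, n_codons) + ("TAA", "TAG", "TGA")[
                        int(rng.integers(0, 3))
                    ]
                    n_ex = int(rng.integers(1, 5))
                    exons = _split_exons(rng, cds, n_ex)
                    part = GenePart(
                        gene_id=gid,
                        strand="+" if rng.random() < 0.5 else "-",
                        exon_seqs=exons,
                        intron_seqs=[
                            _random_dna(rng, int(rng.integers(60, 200)))
                            for _ in range(len(exons) - 1)
                        ],
                        block=label,
                    )
                genome.block_of_gene[part.gene_id] = label
                elements.append(("gene", part))
                elements.append(
                    ("spacer", _random_dna(rng, int(rng.integers(100, 400))))
                )
            block_idx += 1
        genome.chroms[chrom] = elements
    return genome


# ---------------------------------------------------------------------------
# Codon-acceptance evolution
# ---------------------------------------------------------------------------

def evolve_cds(
    cds: str, t: float, omega: float, rng: np.random.Generator
) -> str:
    """Mutate a CDS under the codon-acceptance model.

    Single-nucleotide changes are proposed at expected rate ``t`` per site;
    synonymous proposals are always accepted, nonsynonymous with
    probability ``omega``, and proposals creating stop codons are
    rejected.  The first and last codons are frozen (start/stop).
    """
    if t == 0:
        return cds
    seq = list(cds)
    L = len(seq)
    n_prop = rng.poisson(t * L)
    for _ in range(n_prop):
        site = int(rng.integers(0, L))
        ci = site // 3
        if ci == 0 or ci == L // 3 - 1:
            continue  # protect start and terminal codon
        old = seq[site]
        new = _BASES[int(rng.integers(0, 4))]
        if new == old:
            continue
        start = ci * 3
        codon_old = "".join(seq[start : start + 3])
        codon_new = (
            codon_old[: site - start] + new + codon_old[site - start + 1 :]
        )
        if codon_new in _STOPS:
            continue
        if CODON_TO_AA[codon_old] != CODON_TO_AA[codon_new]:
            if rng.random() >= omega:
                continue
        seq[site] = new
    return "".join(seq)


def _mutate_neutral(seq: str, t: float, rng: np.random.Generator) -> str:
    if t == 0 or not seq:
        return seq
    s = list(seq)
    for _ in range(rng.poisson(t * len(s))):
        site = int(rng.integers(0, len(s)))
        s[site] = _BASES[int(rng.integers(0, 4))]
    return "".join(s)


def evolve_subgenome(
    ancestor: AncestralGenome, t: float, omega: float, seed: int
) -> AncestralGenome:
    """Diverged copy of the ancestor: coding sequence under the codon
    acceptance model, introns/spacers neutrally."""
    if t < 0:
        raise ValueError("t must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    out = AncestralGenome(
        block_of_gene=dict(ancestor.block_of_gene),
        ak_of_block=dict(ancestor.ak_of_block),
        config=ancestor.config,
    )
    for chrom, elements in ancestor.chroms.items():
        new_elements = []
        for kind, payload in elements:
            if kind == "spacer":
                new_elements.append(("spacer", _mutate_neutral(payload, t, rng)))
                continue
            part = copy.deepcopy(payload)
            new_cds = evolve_cds(part.cds, t, omega, rng)
            offset = 0
            new_exons = []
            for ex in part.exon_seqs:
                new_exons.append(new_cds[offset : offset + len(ex)])
                offset += len(ex)
            part.exon_seqs = new_exons
            part.intron_seqs = [
                _mutate_neutral(i, t, rng) for i in part.intron_seqs
            ]
            new_elements.append(("gene", part))
        out.chroms[chrom] = new_elements
    return out


# ---------------------------------------------------------------------------
# Assembly with post-polyploidy events
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    homeolog_groups: dict[str, list[str]] = field(default_factory=dict)
    tandem_pairs: list[tuple[str, str]] = field(default_factory=list)
    transposed_pairs: list[tuple[str, str]] = field(default_factory=list)
    pseudogenes: list[str] = field(default_factory=list)
    events: list[dict] = field(default_factory=list)
    block_map: dict[str, list[tuple[int, int, str, str]]] = field(default_factory=dict)
    gene_block: dict[str, str] = field(default_factory=dict)
    gene_subgenome: dict[str, str] = field(default_factory=dict)
    gene_isotype: dict[str, str] = field(default_factory=dict)
    gene_family: dict[str, str] = field(default_factory=dict)
    contributions: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["tandem_pairs"] = [tuple(p) for p in d["tandem_pairs"]]
        d["transposed_pairs"] = [tuple(p) for p in d["transposed_pairs"]]
        d["block_map"] = {
            k: [tuple(x) for x in v] for k, v in d["block_map"].items()
        }
        return cls(**d)


def _linearize(
    chrom_specs: Mapping[str, tuple[str, list]],
    subgenome_map: Mapping[str, str],
    block_of_gene: Mapping[str, str],
) -> tuple[GenomeBundle, dict]:
    """Turn element lists into sequences + GeneRecords with coordinates.

    Returns (bundle, info) where info carries per-gene extents and per-block
    truth intervals keyed by output chromosome name.
    """
    sequences: dict[str, str] = {}
    genes: list[GeneRecord] = []
    block_extents: dict[str, dict[str, list[int]]] = {}
    for out_chrom in sorted(chrom_specs):
        _, elements = chrom_specs[out_chrom]
        pieces: list[str] = []
        pos = 0
        extents = block_extents.setdefault(out_chrom, {})
        for kind, payload in elements:
            if kind == "spacer":
                pieces.append(payload)
                pos += len(payload)
                continue
            part: GenePart = payload
            tx_pieces = []
            for i, ex in enumerate(part.exon_seqs):
                tx_pieces.append(ex)
                if i < len(part.intron_seqs):
                    tx_pieces.append(part.intron_seqs[i])
            gseq = "".join(tx_pieces)
            glen = len(gseq)
            # transcript offsets of exons
            tx_offsets = []
            off = 0
            for i, ex in enumerate(part.exon_seqs):
                tx_offsets.append((off, off + len(ex)))
                off += len(ex)
                if i < len(part.intron_seqs):
                    off += len(part.intron_seqs[i])
            if part.strand == "+":
                chrom_piece = gseq
                exon_ivs = [
                    GenomicInterval(out_chrom, pos + a, pos + b, "+")
                    for a, b in tx_offsets
                ]
            else:
                chrom_piece = _revcomp(gseq)
                exon_ivs = [
                    GenomicInterval(out_chrom, pos + glen - b, pos + glen - a, "-")
                    for a, b in tx_offsets
                ]
            pieces.append(chrom_piece)
            locus = GenomicInterval(out_chrom, pos, pos + glen, part.strand)
            rec = GeneRecord(
                gene_id=part.gene_id,
                locus=locus,
                exons=sorted(exon_ivs, key=lambda e: e.start),
                family=part.family,
                isotype=part.isotype,
                cls=part.cls,
                subgenome=subgenome_map.get(out_chrom, "unplaced"),
            )
            genes.append(rec)
            blk = part.block or block_of_gene.get(part.gene_id, "")
            if blk:
                ext = extents.setdefault(blk, [pos, pos + glen])
                ext[0] = min(ext[0], pos)
                ext[1] = max(ext[1], pos + glen)
            pos += glen
        sequences[out_chrom] = "".join(pieces)

    bundle = GenomeBundle(
        sequences=sequences, genes=genes, subgenome_map=dict(subgenome_map)
    )
    for g in bundle.genes:
        from .core import extract_cds_and_protein

        cds, protein, _ = extract_cds_and_protein(g, bundle)
        g.cds, g.protein = cds, protein
    return bundle, {"block_extents": block_extents}


def _revcomp(seq: str) -> str:
    comp = str.maketrans("ACGT", "TGCA")
    return seq.translate(comp)[::-1]


def assemble_allohexaploid(
    subgenomes: Mapping[str, AncestralGenome],
    config: SimulationConfig,
    seed: int,
) -> tuple[GenomeBundle, GroundTruth]:
    """Merge three diverged subgenome copies, applying post-polyploidy
    events to family genes and recording everything in the ground truth."""
    if sorted(subgenomes) != ["G1", "G2", "G3"]:
        raise ValueError("expected subgenomes G1, G2, G3")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    truth = GroundTruth()

    rates = (
        config.loss_rate,
        config.pseudogenize_rate,
        config.tandem_dup_rate,
        config.transpose_rate,
    )
    cum = np.cumsum(rates)

    chrom_specs: dict[str, tuple[str, list]] = {}
    subgenome_map: dict[str, str] = {}
    block_of_gene: dict[str, str] = {}

    # per-subgenome element lists with renamed gene ids
    per_sub_elements: dict[str, dict[str, list]] = {}
    for sub in ("G1", "G2", "G3"):
        anc = subgenomes[sub]
        chroms = {}
        for chrom, elements in anc.chroms.items():
            out_chrom = f"{sub}_{chrom}"
            subgenome_map[out_chrom] = sub
            new_els = []
            for kind, payload in elements:
                if kind == "spacer":
                    new_els.append((kind, payload))
                else:
                    part = copy.deepcopy(payload)
                    anc_id = part.gene_id
                    part.gene_id = f"{anc_id}_{sub}"
                    block_of_gene[part.gene_id] = part.block
                    new_els.append(("gene", part))
            chroms[out_chrom] = new_els
        per_sub_elements[sub] = chroms

    # ground-truth bookkeeping for every emitted family gene
    anc_of = {}  # emitted id -> ancestral id

    def register(part: GenePart, sub: str, anc_id: str) -> None:
        anc_of[part.gene_id] = anc_id
        truth.gene_subgenome[part.gene_id] = sub
        truth.gene_isotype[part.gene_id] = part.isotype or ""
        truth.gene_family[part.gene_id] = part.family or ""

    def _index_of(elements: list, part: GenePart) -> int:
        return next(
            k for k, (kind, p) in enumerate(elements) if kind == "gene" and p is part
        )

    # two phases per subgenome: draw one event per ancestral family gene on a
    # snapshot, then apply, so insertions can never re-trigger the draw
    for sub in ("G1", "G2", "G3"):
        chroms = per_sub_elements[sub]
        fam_parts = [
            (out_chrom, payload)
            for out_chrom in sorted(chroms)
            for kind, payload in chroms[out_chrom]
            if kind == "gene" and payload.family
        ]
        for out_chrom, part in fam_parts:
            anc_id = part.gene_id.rsplit("_", 1)[0]
            u = rng.random()
            event = None
            for name, bound in zip(
                ("loss", "pseudogenize", "tandem_dup", "transpose"), cum
            ):
                if u < bound:
                    event = name
                    break
            if event == "loss":
                elements = chroms[out_chrom]
                del elements[_index_of(elements, part)]
                truth.events.append(
                    {"type": "loss", "subgenome": sub, "gene": part.gene_id}
                )
                continue
            register(part, sub, anc_id)
            if event == "pseudogenize":
                detail = _pseudogenize(part, rng)
                truth.pseudogenes.append(part.gene_id)
                truth.events.append(
                    {
                        "type": "pseudogenize",
                        "subgenome": sub,
                        "gene": part.gene_id,
                        "detail": detail,
                    }
                )
            elif event == "tandem_dup":
                dup = part.clone(f"{part.gene_id}_td", "tandem_dup")
                block_of_gene[dup.gene_id] = part.block
                register(dup, sub, anc_id)
                elements = chroms[out_chrom]
                i = _index_of(elements, part)
                # insert after the original's spacer: same block, close by
                elements.insert(min(i + 2, len(elements)), ("gene", dup))
                elements.insert(
                    min(i + 2, len(elements)),
                    ("spacer", _random_dna(rng, int(rng.integers(100, 400)))),
                )
                truth.tandem_pairs.append((dup.gene_id, part.gene_id))
                truth.events.append(
                    {
                        "type": "tandem_dup",
                        "subgenome": sub,
                        "gene": part.gene_id,
                        "copy": dup.gene_id,
                    }
                )
            elif event == "transpose":
                dup = part.clone(f"{part.gene_id}_tp", "transpose")
                target = _pick_other_block(chroms, part.block, rng)
                if target is not None:
                    t_chrom, t_idx, t_block = target
                    dup.block = t_block
                    block_of_gene[dup.gene_id] = t_block
                    register(dup, sub, anc_id)
                    chroms[t_chrom].insert(t_idx, ("gene", dup))
                    chroms[t_chrom].insert(
                        t_idx,
                        ("spacer", _random_dna(rng, int(rng.integers(100, 400)))),
                    )
                    truth.transposed_pairs.append((dup.gene_id, part.gene_id))
                    truth.events.append(
                        {
                            "type": "transpose",
                            "subgenome": sub,
                            "gene": part.gene_id,
                            "copy": dup.gene_id,
                            "to_block": t_block,
                        }
                    )
        chrom_specs.update({c: (c, els) for c, els in chroms.items()})

    # homeolog groups over surviving ancestral-origin family genes
    groups: dict[str, list[str]] = {}
    for gid, anc_id in anc_of.items():
        if gid.endswith("_td") or gid.endswith("_tp"):
            continue
        groups.setdefault(anc_id, []).append(gid)
    truth.homeolog_groups = {k: sorted(v) for k, v in sorted(groups.items())}

    bundle, info = _linearize(chrom_specs, subgenome_map, block_of_gene)
    for chrom, extents in info["block_extents"].items():
        anc0 = subgenomes["G1"]
        rows = sorted(
            (start, end, blk, anc0.ak_of_block.get(blk, ""))
            for blk, (start, end) in extents.items()
        )
        truth.block_map[chrom] = rows
    for g in bundle.genes:
        if g.family:
            truth.gene_block[g.gene_id] = block_of_gene.get(g.gene_id, "")
    return bundle, truth


def _pseudogenize(part: GenePart, rng: np.random.Generator) -> str:
    """Premature stop, or a frameshifting internal-exon deletion when one
    is available in the last 40% of the CDS."""
    cds = part.cds
    n_codons = len(cds) // 3
    # exon-deletion candidates: internal exons past 60% of CDS whose length
    # is not a multiple of 3 (guaranteed frameshift)
    offsets = []
    off = 0
    for ex in part.exon_seqs:
        offsets.append(off)
        off += len(ex)
    candidates = [
        i
        for i in range(1, len(part.exon_seqs) - 1)
        if offsets[i] >= 0.6 * len(cds) and len(part.exon_seqs[i]) % 3 != 0
    ]
    if candidates and rng.random() < 0.5:
        i = int(rng.choice(candidates))
        del part.exon_seqs[i]
        del part.intron_seqs[i - 1]
        return f"exon_deletion:{i}"
    ci = int(rng.integers(int(0.65 * n_codons), int(0.9 * n_codons)))
    stop = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
    new_cds = cds[: ci * 3] + stop + cds[ci * 3 + 3 :]
    off = 0
    new_exons = []
    for ex in part.exon_seqs:
        new_exons.append(new_cds[off : off + len(ex)])
        off += len(ex)
    part.exon_seqs = new_exons
    return f"premature_stop:{ci}"


def _pick_other_block(
    chroms: Mapping[str, list], source_block: str, rng: np.random.Generator
):
    """(chrom, element index, block label) of an insertion point in a
    different block of the same subgenome."""
    options = []
    for chrom in sorted(chroms):
        for idx, (kind, payload) in enumerate(chroms[chrom]):
            if kind == "gene" and payload.block != source_block:
                options.append((chrom, idx, payload.block))
    if not options:
        return None
    return options[int(rng.integers(0, len(options)))]


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

SALT_ORGANS = ("root", "shoot")


def simulate_expression(
    truth: GroundTruth, config: SimulationConfig, seed: int
) -> ExpressionMatrix:
    """Tissue expression with subgenome bias plus salt-stress columns.

    Functional family genes draw log-normal abundances around a shared
    per-lineage tissue profile, scaled by their subgenome's bias;
    pseudogenes leak a small fraction; salt-designated isotypes are
    divided by ``salt_fc`` under stress and no gene is ever up-regulated.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    bias = dict(zip(("G1", "G2", "G3"), config.subgenome_bias))
    genes = sorted(truth.gene_subgenome)
    pseudo = set(truth.pseudogenes)

    lineages = sorted({truth.gene_isotype[g] for g in genes})
    base: dict[str, dict[str, float]] = {}
    for iso in lineages:
        base[iso] = {
            cond: float(
                rng.lognormal(mean=config.expr_location, sigma=config.expr_scale)
            )
            for cond in DEV_CONDITIONS
        }
        for organ in SALT_ORGANS:
            base[iso][organ] = float(
                rng.lognormal(mean=config.expr_location, sigma=config.expr_scale)
            )

    cols = list(DEV_CONDITIONS) + [
        f"{o}_{arm}" for o in SALT_ORGANS for arm in ("ctrl", "salt")
    ]
    data = {}
    for g in genes:
        iso = truth.gene_isotype[g]
        sub = truth.gene_subgenome[g]
        leak = config.pseudogene_leakage if g in pseudo else 1.0
        row = {}
        for cond in DEV_CONDITIONS:
            noise = float(rng.lognormal(mean=0.0, sigma=config.expr_noise_sigma))
            row[cond] = base[iso][cond] * bias[sub] * noise * leak
        for organ in SALT_ORGANS:
            noise = float(rng.lognormal(mean=0.0, sigma=config.expr_noise_sigma))
            ctrl = base[iso][organ] * bias[sub] * noise * leak
            if iso in config.salt_isotypes:
                stress = ctrl / config.salt_fc
            else:
                stress = ctrl * float(rng.uniform(0.9, 1.0))
            row[f"{organ}_ctrl"] = ctrl
            row[f"{organ}_salt"] = stress
        data[g] = row

    df = pd.DataFrame.from_dict(data, orient="index").loc[genes, cols]
    matrix = ExpressionMatrix(df)

    functional = [g for g in genes if g not in pseudo]
    contrib: dict[str, dict[str, float]] = {}
    for cond in cols:
        sums = {s: 0.0 for s in ("G1", "G2", "G3")}
        for g in functional:
            sums[truth.gene_subgenome[g]] += df.at[g, cond]
        total = sum(sums.values())
        contrib[cond] = {
            s: (100.0 * v / total if total > 0 else float("nan"))
            for s, v in sums.items()
        }
    truth.contributions = contrib
    return matrix


# ---------------------------------------------------------------------------
# Orchestration and file interfaces
# ---------------------------------------------------------------------------

def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GenomeBundle, GroundTruth, ExpressionMatrix, AncestralGenome]:
    """End-to-end simulation from one seed: ancestor, three subgenomes,
    assembly with events, expression."""
    ancestor = simulate_ancestor(config)
    subs = {}
    for i, sub in enumerate(("G1", "G2", "G3")):
        subs[sub] = evolve_subgenome(
            ancestor,
            config.divergence[i],
            config.omega,
            seed=config.seed * 1000 + i + 1,
        )
    bundle, truth = assemble_allohexaploid(subs, config, seed=config.seed)
    matrix = simulate_expression(truth, config, seed=config.seed)
    return bundle, truth, matrix, ancestor


def write_dataset(
    outdir: str | Path,
    bundle: GenomeBundle,
    truth: GroundTruth,
    matrix: ExpressionMatrix,
    ancestor: AncestralGenome | None = None,
) -> dict[str, Path]:
    """Emit FASTA + GFF3 + subgenome TSV + labeled anchors TSV +
    expression TSV + truth JSON (all plain text)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "genome.fa",
        "gff3": out / "genes.gff3",
        "subgenomes": out / "subgenomes.tsv",
        "anchors": out / "labeled_anchors.tsv",
        "expression": out / "expression.tsv",
        "truth": out / "truth.json",
    }
    write_genome_bundle(bundle, paths["fasta"], paths["gff3"], paths["subgenomes"])
    write_expression(matrix, paths["expression"])
    truth.to_json(paths["truth"])
    block_by_chrom = {
        chrom: {blk: (s, e) for s, e, blk, _ in rows}
        for chrom, rows in truth.block_map.items()
    }
    with open(paths["anchors"], "w") as fh:
        fh.write("chrom\tgene_id\tstart\tend\tblock\n")
        for chrom in sorted(bundle.sequences):
            blocks = block_by_chrom.get(chrom, {})
            for g in bundle.genes_on(chrom):
                if g.family:
                    continue  # filler genes carry the block signal
                label = ""
                for blk, (s, e) in blocks.items():
                    if s <= g.locus.start < e:
                        label = blk
                        break
                fh.write(
                    f"{chrom}\t{g.gene_id}\t{g.locus.start}\t{g.locus.end}\t{label}\n"
                )
    return paths


def split_by_subgenome(bundle: GenomeBundle) -> dict[str, GenomeBundle]:
    """Per-subgenome sub-bundles (chromosome subsets of the same genome)."""
    out = {}
    for sub in sorted(set(bundle.subgenome_map.values())):
        chroms = {c for c, s in bundle.subgenome_map.items() if s == sub}
        out[sub] = GenomeBundle(
            sequences={c: bundle.sequences[c] for c in chroms},
            genes=[g for g in bundle.genes if g.locus.chrom in chroms],
            subgenome_map={c: sub for c in chroms},
        )
    return out
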