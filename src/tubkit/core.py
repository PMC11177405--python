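"""Genome/gene-model data types, standard-format I/O and structure utilities.

Coordinates are 0-based half-open in memory and 1-based inclusive in GFF3
files on disk.  Exons are CDS-bearing (UTRs are out of scope), so for a
functional gene the exon concatenation *is* the coding sequence.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

__all__ = [
    "GenomicInterval",
    "GeneRecord",
    "GenomeBundle",
    "ExonIntronStructure",
    "GenomeFormatError",
    "read_genome_bundle",
    "write_genome_bundle",
    "extract_cds_and_protein",
    "derive_structure",
    "validate_family_structure",
    "diagnose_pseudogene",
    "read_inventory",
]

SUBGENOMES = ("G1", "G2", "G3")
UNPLACED = "unplaced"

#: exon-count expectations per family/class label
DEFAULT_STRUCTURE_EXPECTATIONS = {
    ("TUA", "I"): 4,
    ("TUA", "II"): 5,
    ("TUB", None): 3,
    ("TUG", None): 10,
}


class GenomeFormatError(ValueError):
    """Raised on malformed or inconsistent genome inputs."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeFormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise GenomeFormatError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class GeneRecord:
    gene_id: str
    locus: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    name: str | None = None
    family: str | None = None
    isotype: str | None = None
    cls: str | None = None
    subgenome: str = UNPLACED
    status: str = "functional"
    cds: str | None = None
    protein: str | None = None
    attributes: dict = field(default_factory=dict)

    @property
    def strand(self) -> str:
        return self.locus.strand

    @property
    def length(self) -> int:
        return len(self.locus)

    def five_prime(self) -> int:
        """5'-end genomic coordinate (gene placement convention)."""
        return self.locus.start if self.strand == "+" else self.locus.end - 1

    def exons_in_transcription_order(self) -> list[GenomicInterval]:
        exs = sorted(self.exons, key=lambda e: e.start)
        return exs if self.strand == "+" else exs[::-1]


@dataclass
class GenomeBundle:
    sequences: dict[str, str]
    genes: list[GeneRecord]
    subgenome_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.locus.chrom not in self.sequences:
                raise GenomeFormatError(
                    f"gene {g.gene_id} placed on unknown chromosome {g.locus.chrom}"
                )

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def subgenome_of(self, chrom: str) -> str:
        return self.subgenome_map.get(chrom, UNPLACED)

    def genes_on(self, chrom: str) -> list[GeneRecord]:
        return sorted(
            (g for g in self.genes if g.locus.chrom == chrom),
            key=lambda g: (g.locus.start, g.gene_id),
        )


@dataclass
class ExonIntronStructure:
    exon_lengths: list[int]
    intron_lengths: list[int]

    @property
    def exon_count(self) -> int:
        return len(self.exon_lengths)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    current: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                if name in seqs:
                    raise GenomeFormatError(f"duplicate FASTA record {name}")
                current = seqs.setdefault(name, [])
            else:
                if current is None:
                    raise GenomeFormatError("FASTA sequence before header")
                current.append(line.strip().upper())
    return {k: "".join(v) for k, v in seqs.items()}


def _write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_genome_bundle(
    fasta_path: str | Path,
    gff3_path: str | Path,
    subgenome_table: str | Path | Mapping[str, str] | None = None,
) -> GenomeBundle:
    """Load a genome bundle from FASTA + GFF3 (+ optional chrom->subgenome TSV).

    Gene models are assembled from ``gene`` and child ``exon``/``CDS``
    features (``mRNA`` lines are accepted and ignored for coordinates).
    """
    sequences = _read_fasta(fasta_path)

    sub_map: dict[str, str] = {}
    if subgenome_table is not None:
        if isinstance(subgenome_table, Mapping):
            sub_map = dict(subgenome_table)
        else:
            with open(subgenome_table) as fh:
                for line in fh:
                    line = line.strip()
                    if not line or line.startswith("#"):
                        continue
                    chrom, sub = line.split("\t")[:2]
                    sub_map[chrom] = sub

    genes: dict[str, GeneRecord] = {}
    mrna_parent: dict[str, str] = {}
    with open(gff3_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise GenomeFormatError(f"malformed GFF3 line: {line!r}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype not in ("gene", "mRNA", "exon", "CDS"):
                continue
            if chrom not in sequences:
                raise GenomeFormatError(
                    f"GFF3 feature on unknown chromosome {chrom}: {attrs}"
                )
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            a = _parse_gff_attributes(attrs)
            if ftype == "gene":
                gid = a.get("ID")
                if gid is None:
                    raise GenomeFormatError(f"gene feature without ID: {line!r}")
                genes[gid] = GeneRecord(
                    gene_id=gid,
                    locus=iv,
                    name=a.get("Name"),
                    family=a.get("family"),
                    isotype=a.get("isotype"),
                    cls=a.get("tub_class"),
                    subgenome=sub_map.get(chrom, UNPLACED),
                    attributes=a,
                )
            elif ftype == "mRNA":
                mid, parent = a.get("ID"), a.get("Parent")
                if mid and parent:
                    mrna_parent[mid] = parent
            elif ftype in ("exon", "CDS"):
                # CDS-bearing exon model: exon and CDS features are synonymous
                # here; keep whichever appears (deduplicated by coordinates).
                parent = a.get("Parent")
                gid = mrna_parent.get(parent, parent)
                if gid not in genes:
                    raise GenomeFormatError(
                        f"{ftype} feature with unknown parent {parent!r}"
                    )
                gene = genes[gid]
                if chrom != gene.locus.chrom:
                    raise GenomeFormatError(
                        f"{ftype} {a.get('ID', parent)} on chromosome {chrom} "
                        f"but gene {gid} is on {gene.locus.chrom}"
                    )
                if iv.start < gene.locus.start or iv.end > gene.locus.end:
                    raise GenomeFormatError(
                        f"{ftype} {a.get('ID', '?')} outside span of gene {gid}"
                    )
                if iv not in gene.exons:
                    gene.exons.append(iv)

    records = []
    for g in genes.values():
        g.exons.sort(key=lambda e: e.start)
        for a, b in zip(g.exons, g.exons[1:]):
            if b.start < a.end:
                raise GenomeFormatError(f"overlapping exons in gene {g.gene_id}")
        records.append(g)
    records.sort(key=lambda g: (g.locus.chrom, g.locus.start, g.gene_id))

    bundle = GenomeBundle(sequences=sequences, genes=records, subgenome_map=sub_map)
    for g in bundle.genes:
        if g.exons:
            cds, protein, _ = extract_cds_and_protein(g, bundle)
            g.cds, g.protein = cds, protein
    return bundle


def write_genome_bundle(
    bundle: GenomeBundle,
    fasta_path: str | Path,
    gff3_path: str | Path,
    subgenome_path: str | Path | None = None,
) -> None:
    _write_fasta(bundle.sequences, fasta_path)
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(bundle.genes, key=lambda g: (g.locus.chrom, g.locus.start, g.gene_id)):
            attrs = [f"ID={g.gene_id}"]
            if g.name:
                attrs.append(f"Name={g.name}")
            if g.family:
                attrs.append(f"family={g.family}")
            if g.isotype:
                attrs.append(f"isotype={g.isotype}")
            if g.cls:
                attrs.append(f"tub_class={g.cls}")
            fh.write(
                "\t".join(
                    [
                        g.locus.chrom,
                        "tubkit",
                        "gene",
                        str(g.locus.start + 1),
                        str(g.locus.end),
                        ".",
                        g.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                "\t".join(
                    [
                        g.locus.chrom,
                        "tubkit",
                        "mRNA",
                        str(g.locus.start + 1),
                        str(g.locus.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={mrna_id};Parent={g.gene_id}",
                    ]
                )
                + "\n"
            )
            for i, ex in enumerate(sorted(g.exons, key=lambda e: e.start), 1):
                fh.write(
                    "\t".join(
                        [
                            g.locus.chrom,
                            "tubkit",
                            "exon",
                            str(ex.start + 1),
                            str(ex.end),
                            ".",
                            g.strand,
                            ".",
                            f"ID={g.gene_id}.exon{i};Parent={mrna_id}",
                        ]
                    )
                    + "\n"
                )
    if subgenome_path is not None:
        with open(subgenome_path, "w") as fh:
            for chrom, sub in bundle.subgenome_map.items():
                fh.write(f"{chrom}\t{sub}\n")


# ---------------------------------------------------------------------------
# Sequence extraction and structure
# ---------------------------------------------------------------------------

def extract_cds_and_protein(
    gene: GeneRecord, bundle: GenomeBundle
) -> tuple[str, str, bool]:
    """Return (cds, protein, premature_stop) for a gene.

    The CDS is the exon concatenation in transcription order (reverse
    complemented for minus-strand genes); translation uses the standard
    genetic code and stops at the first stop codon.
    """
    chrom_seq = bundle.sequences.get(gene.locus.chrom)
    if chrom_seq is None:
        raise GenomeFormatError(f"unknown chromosome {gene.locus.chrom}")
    parts = []
    for ex in sorted(gene.exons, key=lambda e: e.start):
        if ex.end > len(chrom_seq):
            raise GenomeFormatError(
                f"exon {ex.start}-{ex.end} of {gene.gene_id} beyond end of "
                f"{gene.locus.chrom} (len {len(chrom_seq)})"
            )
        parts.append(chrom_seq[ex.start : ex.end])
    cds = "".join(parts)
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    n_codons = len(cds) // 3
    aa = str(Seq(cds[: n_codons * 3]).translate())
    stop_idx = aa.find("*")
    premature = False
    if stop_idx == -1:
        protein = aa
    else:
        protein = aa[:stop_idx]
        premature = stop_idx < n_codons - 1
    return cds, protein, premature


def derive_structure(gene: GeneRecord) -> ExonIntronStructure:
    """Exon/intron lengths in transcription order."""
    if not gene.exons:
        raise GenomeFormatError(f"gene {gene.gene_id} has no exons")
    exs = sorted(gene.exons, key=lambda e: e.start)
    for a, b in zip(exs, exs[1:]):
        if b.start < a.end:
            raise GenomeFormatError(f"overlapping exons in gene {gene.gene_id}")
    exon_lengths = [len(e) for e in exs]
    intron_lengths = [b.start - a.end for a, b in zip(exs, exs[1:])]
    if gene.strand == "-":
        exon_lengths.reverse()
        intron_lengths.reverse()
    return ExonIntronStructure(exon_lengths, intron_lengths)


def _expected_exons(family: str, cls: str | None, expectations) -> int | None:
    if (family, cls) in expectations:
        return expectations[(family, cls)]
    if (family, None) in expectations:
        return expectations[(family, None)]
    return None


def validate_family_structure(
    genes: Iterable[GeneRecord],
    expectations: Mapping[tuple[str, str | None], int] | None = None,
) -> dict:
    """Check per-gene exon counts against family/class expectations.

    Returns ``{"passed": [...], "exceptions": [(gene_id, observed, expected)],
    "skipped": [...]}``.
    """
    if expectations is None:
        expectations = DEFAULT_STRUCTURE_EXPECTATIONS
    passed, exceptions, skipped = [], [], []
    for g in genes:
        if not g.family:
            skipped.append(g.gene_id)
            continue
        expected = _expected_exons(g.family, g.cls, expectations)
        if expected is None:
            skipped.append(g.gene_id)
            continue
        observed = len(g.exons)
        if observed == expected:
            passed.append(g.gene_id)
        else:
            exceptions.append((g.gene_id, observed, expected))
    return {"passed": passed, "exceptions": exceptions, "skipped": skipped}


def diagnose_pseudogene(
    gene: GeneRecord,
    reference_protein: str,
    min_len_frac: float = 0.6,
    bundle: GenomeBundle | None = None,
) -> tuple[str, list[str]]:
    """Classify a gene as functional/pseudogene with the triggered reasons.

    Rules: premature internal stop, frameshift (CDS length not a multiple
    of 3), or translated product shorter than ``min_len_frac`` of the
    functional reference.
    """
    if gene.cds is not None:
        cds = gene.cds
        if bundle is not None:
            cds, protein, premature = extract_cds_and_protein(gene, bundle)
        else:
            n_codons = len(cds) // 3
            aa = str(Seq(cds[: n_codons * 3]).translate())
            stop = aa.find("*")
            premature = stop != -1 and stop < n_codons - 1
            protein = aa if stop == -1 else aa[:stop]
    elif bundle is not None:
        cds, protein, premature = extract_cds_and_protein(gene, bundle)
    else:
        raise GenomeFormatError(f"gene {gene.gene_id} has no CDS")
    if not cds:
        raise GenomeFormatError(f"gene {gene.gene_id} has empty CDS")

    reasons = []
    if premature:
        reasons.append("premature_stop")
    if len(cds) % 3 != 0:
        reasons.append("frameshift")
    if len(protein) < min_len_frac * len(reference_protein):
        reasons.append("short_product")
    status = "pseudogene" if reasons else "functional"
    return status, reasons


# ---------------------------------------------------------------------------
# Reference inventory fixture reader
# ---------------------------------------------------------------------------

def read_inventory(path: str | Path):
    """Read a gene-inventory TSV (name, gene id, lengths, family metadata).

    Used for the packaged reference inventory of *Camelina sativa* tubulins.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"ncbi_gene_id": "string"})
    required = {"name", "family", "status"}
    missing = required - set(df.columns)
    if missing:
        raise GenomeFormatError(f"inventory missing columns: {sorted(missing)}")
    return df
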