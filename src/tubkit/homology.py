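"""Relation classification and isotype resolution.

Cross-references phylogenetic clades, collinear-chain support, block
allocation and genomic-context similarity into a single relation label
per evaluated gene pair/triple, plus context-based isotype calls for
near-identical paralogous lineages.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core import GenomeBundle, GeneRecord

__all__ = [
    "ContextProfile",
    "Evidence",
    "HomologyCall",
    "build_orthogroups",
    "context_profile",
    "context_similarity",
    "classify_relation",
    "resolve_isotype",
    "detect_missing_orthologs",
    "name_genes",
]

RELATIONS = (
    "homeolog",
    "ortholog",
    "tandem_paralog",
    "transposed_paralog",
    "homeoparalog",
    "disrupted_homeolog",
)


@dataclass
class ContextProfile:
    gene_id: str
    flank_orthogroups: list[str]  # ordered, focal gene excluded
    truncated: bool = False


@dataclass
class Evidence:
    subgenomes: tuple[str, ...] = ()
    chain_support: bool = False
    block_match: bool = False
    clade_agreement: bool = False
    context_jaccard: float = 0.0
    distance_bp: int | None = None
    same_chromosome: bool = False
    cross_species: bool = False
    any_pseudogene: bool = False
    isotype_lineages_differ: bool = False
    block_labels: tuple[str, ...] = ()


@dataclass
class HomologyCall:
    genes: tuple[str, ...]
    relation: str
    evidence: Evidence
    low_confidence: bool = False
    conflict: bool = False


# ---------------------------------------------------------------------------
# Orthogroups and genomic context
# ---------------------------------------------------------------------------

def build_orthogroups(anchor_lists: Iterable[Sequence]) -> dict[str, str]:
    """Single-linkage clustering over RBH anchor pairs -> gene_id -> og id.

    A deliberate simplification of full orthology inference; anchors from
    any number of bundle comparisons may be pooled.
    """
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for anchors in anchor_lists:
        for a in anchors:
            union(a.gene_a, a.gene_b)

    clusters: dict[str, list[str]] = defaultdict(list)
    for g in parent:
        clusters[find(g)].append(g)
    out = {}
    for i, root in enumerate(sorted(clusters), 1):
        og = f"OG{i:05d}"
        for g in clusters[root]:
            out[g] = og
    return out


def context_profile(
    gene: GeneRecord,
    bundle: GenomeBundle,
    orthogroups: Mapping[str, str],
    window: int = 10,
) -> ContextProfile:
    """Ordered flanking orthogroups within +/- window genes of the focal gene."""
    if window <= 0:
        raise ValueError("window must be > 0")
    neighbors = bundle.genes_on(gene.locus.chrom)
    idx = next(
        (i for i, g in enumerate(neighbors) if g.gene_id == gene.gene_id), None
    )
    if idx is None:
        raise KeyError(f"{gene.gene_id} not on {gene.locus.chrom}")
    lo, hi = max(0, idx - window), min(len(neighbors), idx + window + 1)
    truncated = lo == 0 and idx < window or hi == len(neighbors)
    flank = [
        orthogroups[g.gene_id]
        for i, g in enumerate(neighbors[lo:hi], start=lo)
        if i != idx and g.gene_id in orthogroups
    ]
    return ContextProfile(gene.gene_id, flank, truncated=truncated)


def _lcs_len(a: Sequence[str], b: Sequence[str]) -> int:
    m, n = len(a), len(b)
    dp = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m):
        for j in range(n):
            dp[i + 1][j + 1] = (
                dp[i][j] + 1 if a[i] == b[j] else max(dp[i][j + 1], dp[i + 1][j])
            )
    return dp[m][n]


def context_similarity(
    profile_a: ContextProfile, profile_b: ContextProfile
) -> tuple[float, float]:
    """(jaccard over flank orthogroups, order agreement of the shared ones)."""
    sa, sb = set(profile_a.flank_orthogroups), set(profile_b.flank_orthogroups)
    union = sa | sb
    shared = sa & sb
    jaccard = len(shared) / len(union) if union else 0.0
    if not shared:
        return jaccard, 0.0
    fa = [g for g in profile_a.flank_orthogroups if g in shared]
    fb = [g for g in profile_b.flank_orthogroups if g in shared]
    order = _lcs_len(fa, fb) / max(len(fa), len(fb))
    return jaccard, order


# ---------------------------------------------------------------------------
# Relation classification
# ---------------------------------------------------------------------------

def classify_relation(
    genes: Sequence[str],
    evidence: Evidence,
    tandem_max_bp: int = 1_000_000,
    context_min: float = 0.3,
) -> HomologyCall:
    """Apply the ordered relation rules to a gene pair/triple.

    Rule order (earliest match wins): cross-subgenome homeology, tandem
    paralogy, transposed paralogy, homeoparalogy, cross-species orthology;
    anything else is labeled by context similarity with a low-confidence
    flag.
    """
    ev = evidence
    distinct_subs = len(set(ev.subgenomes)) > 1
    same_sub = len(set(ev.subgenomes)) == 1 and bool(ev.subgenomes)
    conflict = ev.chain_support and not ev.clade_agreement and ev.clade_agreement is not None

    relation = None
    low_conf = False
    if not ev.cross_species and distinct_subs and ev.chain_support and ev.block_match:
        relation = "disrupted_homeolog" if ev.any_pseudogene else "homeolog"
    elif same_sub and ev.block_match and (
        ev.distance_bp is not None and ev.distance_bp <= tandem_max_bp
    ):
        relation = "tandem_paralog"
    elif same_sub and not ev.block_match:
        relation = "transposed_paralog"
    elif not ev.cross_species and distinct_subs and ev.isotype_lineages_differ:
        relation = "homeoparalog"
    elif ev.cross_species and ev.chain_support and ev.block_match:
        relation = "ortholog"
    else:
        low_conf = True
        if ev.cross_species:
            relation = "ortholog" if ev.context_jaccard >= context_min else "homeoparalog"
        elif distinct_subs:
            relation = "homeolog" if ev.context_jaccard >= context_min else "homeoparalog"
        elif same_sub:
            relation = (
                "tandem_paralog"
                if ev.block_match or ev.context_jaccard >= context_min
                else "transposed_paralog"
            )
        else:
            relation = "homeoparalog"
    return HomologyCall(
        genes=tuple(genes),
        relation=relation,
        evidence=ev,
        low_confidence=low_conf,
        conflict=conflict,
    )


# ---------------------------------------------------------------------------
# Isotype resolution
# ---------------------------------------------------------------------------

def resolve_isotype(
    gene_id: str,
    clade_label: str,
    reference_isotypes: Mapping[str, str],
    context_scores: Mapping[str, float] | None = None,
    block_matches: Mapping[str, bool] | None = None,
    context_min: float = 0.3,
) -> tuple[str, str]:
    """(isotype, evidence source) for one gene.

    ``reference_isotypes`` maps clade/reference labels to isotype names.
    When the clade uniquely names an isotype the call is by clade;
    otherwise the reference locus with the best context similarity wins,
    requiring a block match when available.  Permutation-invariant in
    reference order (ties sorted lexicographically -> unresolved).
    """
    if clade_label != "ambiguous" and clade_label in set(reference_isotypes.values()):
        return clade_label, "clade"
    if context_scores is None:
        return "unresolved", "no_context"
    eligible = {}
    for ref, score in context_scores.items():
        if score < context_min:
            continue
        if block_matches is not None and not block_matches.get(ref, False):
            continue
        eligible[ref] = score
    if not eligible:
        return "unresolved", "no_reference_above_context_min"
    best = max(eligible.values())
    winners = sorted(r for r, s in eligible.items() if s == best)
    if len(winners) > 1:
        return "unresolved", f"context_tie:{','.join(winners)}"
    iso = reference_isotypes.get(winners[0], winners[0])
    return iso, "context"


def detect_missing_orthologs(
    species_tables: Mapping[str, Mapping[str, str]]
) -> dict:
    """Presence matrix isotype x species; flags isotypes absent in exactly
    one species.

    ``species_tables``: species -> {isotype: status} where status is
    ``present``/``pseudogene`` (missing keys mean absent).
    """
    if len(species_tables) < 2:
        raise ValueError("need at least two species")
    species = sorted(species_tables)
    isotypes = sorted({iso for t in species_tables.values() for iso in t})
    matrix = {
        iso: {
            sp: species_tables[sp].get(iso, "absent") for sp in species
        }
        for iso in isotypes
    }
    flags = []
    for iso in isotypes:
        absent_in = [sp for sp in species if matrix[iso][sp] == "absent"]
        if len(absent_in) == 1:
            flags.append((iso, absent_in[0]))
    return {"matrix": matrix, "flags": flags}


# ---------------------------------------------------------------------------
# Naming
# ---------------------------------------------------------------------------

_SUBGENOME_LETTER = {"G1": "A", "G2": "B", "G3": "C"}


def name_genes(
    gene_info: Sequence[tuple[str, str, str, str, bool]],
    prefix: str = "",
) -> dict[str, str]:
    """Standardized names <prefix><family><isotype>[p]-<A|B|C|Un>.

    ``gene_info`` rows: (gene_id, family, isotype, subgenome, is_pseudogene).
    Pseudogenes get a "p" suffix on the isotype; unplaced genes get "Un".
    Collisions get an index suffix with a warning.
    """
    import warnings

    names: dict[str, str] = {}
    used: dict[str, int] = {}
    for gene_id, family, isotype, subgenome, is_pseudo in gene_info:
        iso = isotype or "?"
        iso_num = iso[len(family):] if iso.startswith(family) else iso
        letter = _SUBGENOME_LETTER.get(subgenome, "Un")
        base = f"{prefix}{family}{iso_num}{'p' if is_pseudo else ''}-{letter}"
        if base in used:
            used[base] += 1
            name = f"{base}.{used[base]}"
            warnings.warn(f"name collision for {base}; using {name}", stacklevel=2)
        else:
            used[base] = 1
            name = base
        names[gene_id] = name
    return names
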