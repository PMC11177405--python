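"""Gene-family mining: local alignment search, hit filtering, motif scan.

A full Smith–Waterman with affine gaps replaces heuristic seeded search —
desk-scale proteomes make the exact DP affordable.  E-values follow the
Karlin–Altschul form K*m*n*exp(-lambda*S) with configurable constants
(defaults: published gapped BLOSUM62/11/1 values); they are approximate
and used only for thresholding.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

__all__ = [
    "ScanParams",
    "SimilarityHit",
    "MotifModel",
    "smith_waterman",
    "scan_proteome",
    "filter_hits",
    "build_motif_models",
    "motif_scan",
    "save_motif_models",
    "load_motif_models",
]

_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}
_X_INDEX = _AA_INDEX["X"]


def _blosum62_matrix() -> np.ndarray:
    """24x24 BLOSUM62 as float, with X scoring 0 against everything."""
    bl = substitution_matrices.load("BLOSUM62")
    m = np.zeros((len(_ALPHABET), len(_ALPHABET)), dtype=np.float64)
    for i, a in enumerate(_ALPHABET):
        for j, b in enumerate(_ALPHABET):
            m[i, j] = bl[a][b]
    m[_X_INDEX, :] = 0.0
    m[:, _X_INDEX] = 0.0
    return m


_MATRICES = {"BLOSUM62": _blosum62_matrix()}


@dataclass
class ScanParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    evalue_max: float = 1e-5
    word_len: int = 3  # config echo of the BLAST-style setting; unused by DP
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    min_coverage: float = 0.5
    min_hit_len: int = 100

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be > 0")

    def score_matrix(self) -> np.ndarray:
        try:
            return _MATRICES[self.matrix]
        except KeyError:
            raise ValueError(f"unknown matrix {self.matrix!r}") from None


@dataclass
class SimilarityHit:
    query_id: str
    target_id: str
    raw_score: float
    bit_score: float
    evalue: float
    identity_frac: float
    query_coverage: float
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    aln_len: int


def encode_protein(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.int64)
    unknown = []
    for i, ch in enumerate(seq.upper()):
        idx = _AA_INDEX.get(ch)
        if idx is None:
            unknown.append(ch)
            idx = _X_INDEX
        out[i] = idx
    if unknown:
        warnings.warn(
            f"unknown residue(s) {sorted(set(unknown))} treated as X",
            stacklevel=2,
        )
    return out


# ---------------------------------------------------------------------------
# Smith-Waterman kernel (numba-accelerated when available)
# ---------------------------------------------------------------------------

def _sw_matrices_py(a, b, score, gap_open, gap_extend):
    n, m = len(a), len(b)
    NEG = -1e30
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    best = 0.0
    bi = bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open - gap_extend, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open - gap_extend, F[i - 1, j] - gap_extend)
            diag = H[i - 1, j - 1] + score[a[i - 1], b[j - 1]]
            h = max(0.0, diag, E[i, j], F[i, j])
            H[i, j] = h
            if h > best:
                best, bi, bj = h, i, j
    return H, E, F, best, bi, bj


try:  # numba speeds the kernel ~100x; the pure-Python path stays correct
    from numba import njit

    _sw_matrices = njit(cache=False)(_sw_matrices_py)
except Exception:  # pragma: no cover - numba is expected to be present
    _sw_matrices = _sw_matrices_py


def smith_waterman(
    a: str,
    b: str,
    params: ScanParams | None = None,
    query_id: str = "query",
    target_id: str = "target",
    search_space: tuple[int, int] | None = None,
) -> SimilarityHit:
    """Optimal local alignment of two proteins under affine gap costs.

    A gap of length k costs ``gap_open + k * gap_extend``.  Identity and
    coverage are computed on the traceback of the optimal alignment.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    params = params or ScanParams()
    ea, eb = encode_protein(a), encode_protein(b)
    score = params.score_matrix()
    go, ge = float(params.gap_open), float(params.gap_extend)
    H, E, F, best, bi, bj = _sw_matrices(ea, eb, score, go, ge)

    # traceback
    matches = 0
    cols = 0
    i, j = bi, bj
    state = "H"
    end_i, end_j = bi, bj
    while i > 0 and j > 0:
        if state == "H":
            h = H[i, j]
            if h == 0.0:
                break
            if h == H[i - 1, j - 1] + score[ea[i - 1], eb[j - 1]]:
                cols += 1
                if ea[i - 1] == eb[j - 1] and ea[i - 1] != _X_INDEX:
                    matches += 1
                i, j = i - 1, j - 1
            elif h == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            cols += 1
            if E[i, j] == H[i, j - 1] - go - ge:
                state = "H"
            j -= 1
        else:  # F
            cols += 1
            if F[i, j] == H[i - 1, j] - go - ge:
                state = "H"
            i -= 1
    start_i, start_j = i, j

    m, n = search_space if search_space else (len(a), len(b))
    raw = float(best)
    lam, K = params.karlin_lambda, params.karlin_k
    evalue = K * m * n * math.exp(-lam * raw)
    bit = (lam * raw - math.log(K)) / math.log(2.0)
    q_aligned = end_i - start_i
    return SimilarityHit(
        query_id=query_id,
        target_id=target_id,
        raw_score=raw,
        bit_score=bit,
        evalue=evalue,
        identity_frac=(matches / cols) if cols else 0.0,
        query_coverage=q_aligned / len(a),
        query_span=(start_i, end_i),
        target_span=(start_j, end_j),
        aln_len=cols,
    )


def sw_score(a: str, b: str, params: ScanParams | None = None) -> float:
    """Raw Smith–Waterman score only (no traceback)."""
    params = params or ScanParams()
    _, _, _, best, _, _ = _sw_matrices(
        encode_protein(a),
        encode_protein(b),
        params.score_matrix(),
        float(params.gap_open),
        float(params.gap_extend),
    )
    return float(best)


def scan_proteome(
    queries: Mapping[str, str],
    targets: Mapping[str, str],
    params: ScanParams | None = None,
) -> list[SimilarityHit]:
    """All-vs-all local search; best query per target, E-value thresholded.

    Each target is reported at most once (its best-scoring query); hits
    with E-value above ``params.evalue_max`` are dropped.  Results sorted
    by E-value then ids for determinism.
    """
    if not queries:
        raise ValueError("need at least one query")
    params = params or ScanParams()
    hits = []
    for tid in sorted(targets):
        tseq = targets[tid]
        if not tseq:
            continue
        best_hit = None
        for qid in sorted(queries):
            hit = smith_waterman(
                queries[qid], tseq, params, query_id=qid, target_id=tid
            )
            if best_hit is None or hit.raw_score > best_hit.raw_score:
                best_hit = hit
        if best_hit is not None and best_hit.evalue <= params.evalue_max:
            hits.append(best_hit)
    hits.sort(key=lambda h: (h.evalue, h.query_id, h.target_id))
    return hits


def filter_hits(
    hits: Iterable[SimilarityHit], params: ScanParams | None = None
) -> tuple[list[SimilarityHit], list[tuple[SimilarityHit, str]]]:
    """Drop short and low-coverage hits; keep a reasoned discard log."""
    params = params or ScanParams()
    kept, discarded = [], []
    for h in hits:
        if h.aln_len < params.min_hit_len:
            discarded.append((h, "short"))
        elif h.query_coverage < params.min_coverage:
            discarded.append((h, "coverage"))
        else:
            kept.append(h)
    return kept, discarded


def hits_to_tsv(hits: Sequence[SimilarityHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "query_id\ttarget_id\tidentity\taln_len\tq_start\tq_end\t"
            "t_start\tt_end\tevalue\tbit_score\n"
        )
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.target_id}\t{h.identity_frac:.4f}\t"
                f"{h.aln_len}\t{h.query_span[0]}\t{h.query_span[1]}\t"
                f"{h.target_span[0]}\t{h.target_span[1]}\t"
                f"{h.evalue:.3e}\t{h.bit_score:.1f}\n"
            )


# ---------------------------------------------------------------------------
# Conserved-motif scan
# ---------------------------------------------------------------------------

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA20_INDEX = {a: i for i, a in enumerate(_AA20)}


@dataclass
class MotifModel:
    motif_id: str
    pwm: np.ndarray  # length x 20 probabilities
    threshold: float

    @property
    def length(self) -> int:
        return self.pwm.shape[0]

    def log_odds(self) -> np.ndarray:
        bg = 1.0 / 20.0
        return np.log2(self.pwm / bg)

    def best_hit(self, seq: str) -> tuple[float, int]:
        """(best score, position) of the motif along the sequence."""
        lo = self.log_odds()
        L = self.length
        if len(seq) < L:
            return -math.inf, -1
        best, pos = -math.inf, -1
        for i in range(len(seq) - L + 1):
            s = 0.0
            for k in range(L):
                j = _AA20_INDEX.get(seq[i + k])
                s += lo[k, j] if j is not None else 0.0
            if s > best:
                best, pos = s, i
        return best, pos


def build_motif_models(
    proteins: Mapping[str, str],
    n_motifs: int = 11,
    width: int = 10,
    threshold_frac: float = 0.6,
) -> list[MotifModel]:
    """Derive fixed motifs from a reference family protein set.

    The references are multiple-aligned; ``n_motifs`` evenly spaced
    ungapped windows of ``width`` columns become position weight matrices
    (0.5 pseudocounts).  Each motif's threshold is ``threshold_frac`` times
    the minimum training-member score, so every training member passes.
    """
    from .evolution import align_proteins

    if len(proteins) < 1:
        raise ValueError("need reference proteins")
    aln = align_proteins(proteins) if len(proteins) > 1 else dict(proteins)
    rows = list(aln.values())
    ncol = len(rows[0])
    # keep columns without gaps so windows are ungapped in every member
    solid = [c for c in range(ncol) if all(r[c] != "-" for r in rows)]
    if len(solid) < width:
        raise ValueError("reference alignment too gappy for motif windows")
    starts = np.linspace(0, len(solid) - width, n_motifs).astype(int)
    models = []
    for mi, s in enumerate(starts):
        cols = solid[s : s + width]
        pwm = np.full((width, 20), 0.5)
        for r in rows:
            for k, c in enumerate(cols):
                j = _AA20_INDEX.get(r[c])
                if j is not None:
                    pwm[k, j] += 1.0
        pwm /= pwm.sum(axis=1, keepdims=True)
        model = MotifModel(motif_id=f"m{mi + 1}", pwm=pwm, threshold=0.0)
        train_scores = [model.best_hit(p.replace("-", ""))[0] for p in rows]
        lo = min(train_scores)
        model.threshold = threshold_frac * lo if lo > 0 else lo - 1.0
        models.append(model)
    return models


def motif_scan(
    protein: str,
    models: Sequence[MotifModel],
    min_motifs: int = 8,
) -> tuple[list[tuple[str, float, int]], bool]:
    """Scan a protein with motif models; family-like iff >= min_motifs hit
    above threshold at order-consistent positions."""
    if not models:
        raise ValueError("no motif models supplied")
    shortest = min(m.length for m in models)
    if len(protein) < shortest:
        warnings.warn("protein shorter than shortest motif", stacklevel=2)
        return [], False
    hits = []
    for m in models:
        score, pos = m.best_hit(protein)
        if score >= m.threshold:
            hits.append((m.motif_id, score, pos))
    # longest order-consistent subset (positions non-decreasing in model order)
    positions = [h[2] for h in hits]
    best_chain = _longest_nondecreasing(positions)
    return hits, best_chain >= min_motifs


def _longest_nondecreasing(xs: Sequence[int]) -> int:
    if not xs:
        return 0
    tails: list[int] = []
    import bisect

    for x in xs:
        i = bisect.bisect_right(tails, x)
        if i == len(tails):
            tails.append(x)
        else:
            tails[i] = x
    return len(tails)


def save_motif_models(models: Sequence[MotifModel], path: str | Path) -> None:
    payload = [
        {
            "motif_id": m.motif_id,
            "pwm": m.pwm.tolist(),
            "threshold": m.threshold,
            "alphabet": _AA20,
        }
        for m in models
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def load_motif_models(path: str | Path) -> list[MotifModel]:
    payload = json.loads(Path(path).read_text())
    return [
        MotifModel(
            motif_id=d["motif_id"],
            pwm=np.asarray(d["pwm"], dtype=float),
            threshold=float(d["threshold"]),
        )
        for d in payload
    ]
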