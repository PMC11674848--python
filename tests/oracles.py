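"""Independent oracle implementations used by the unit and acceptance suites.

Each oracle recomputes a quantity by a different route than the package
(brute force, enumeration, closed form or a reference library) and must stay
independent of the code paths it checks.
"""

from __future__ import annotations

import math
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np


# --- BH step-up (statsmodels is the reference route) -------------------------

def bh_oracle(p_values: Sequence[float]) -> List[float]:
    from statsmodels.stats.multitest import multipletests

    if len(p_values) == 0:
        return []
    return list(multipletests(p_values, method="fdr_bh")[1])


# --- class codes by per-base membership arrays --------------------------------

def class_code_oracle(transcript, reference) -> str:
    """Literal per-base re-derivation of the i/o/u/x rules."""
    span = transcript.span
    ref_txs = [
        t for t in reference.transcripts.values()
        if t.seq_id == span.seq_id and t.span.start < span.end and span.start < t.span.end
    ]
    if not ref_txs:
        return "u"
    # i: all bases inside one reference transcript's intron
    for t in ref_txs:
        for intron in t.introns():
            if all(intron.start <= b < intron.end for b in (span.start, span.end - 1)):
                return "i"
    # x: all exon bases inside the exonic space of one reference gene
    genes = {t.gene_id for t in ref_txs}
    for gene in genes:
        exon_bases = set()
        for t in reference.transcripts.values():
            if t.gene_id == gene and t.seq_id == span.seq_id:
                for e in t.exons:
                    exon_bases.update(range(e.start, e.end))
        query_bases = set()
        for e in transcript.exons:
            query_bases.update(range(e.start, e.end))
        if query_bases <= exon_bases:
            return "x"
    return "o"


# --- ssGSEA by direct summation ----------------------------------------------

def ssgsea_oracle(expression: Mapping[str, float], gene_set: Sequence[str],
                  exponent: float = 0.25) -> float:
    ids = sorted(expression, key=lambda g: (-expression[g], g))
    n = len(ids)
    members = set(gene_set)
    weights = [(n - pos) ** exponent for pos in range(n)]
    w_in_total = sum(w for g, w in zip(ids, weights) if g in members)
    n_out = sum(1 for g in ids if g not in members)
    total = 0.0
    cum_in = cum_out = 0.0
    cw_all = 0.0
    w_all_total = sum(weights)
    null = 0.0
    for pos, g in enumerate(ids):
        if g in members:
            cum_in += weights[pos]
        else:
            cum_out += 1
        cw_all += weights[pos]
        total += cum_in / w_in_total - cum_out / n_out
        null += cw_all / w_all_total - (pos + 1) / n
    return total / n - null / n


# --- hypergeometric tail by enumeration ---------------------------------------

def hypergeom_tail_oracle(k: int, N: int, K: int, n: int) -> float:
    total = math.comb(N, n)
    return sum(
        math.comb(K, x) * math.comb(N - K, n - x)
        for x in range(k, min(K, n) + 1)
    ) / total


# --- OLS by explicit normal equations ----------------------------------------

def ols_oracle(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, float]:
    """(betas, R^2) from (X'X)^-1 X'y on centered data."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    beta = np.linalg.inv(Xc.T @ Xc) @ Xc.T @ yc
    resid = yc - Xc @ beta
    r2 = 1.0 - float(resid @ resid) / float(yc @ yc)
    return beta, r2


# --- duplex energy by exhaustive window scan -----------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def duplex_oracle(lnc: str, target: str, table: Mapping[str, float]) -> float:
    """Try every (offset, window) ungapped antiparallel alignment explicitly."""
    if len(lnc) < 12 or len(target) < 12:
        return 0.0
    lnc = lnc.upper()
    rt = target.upper()[::-1]  # walk target 3'->5' alongside the lncRNA
    best = 0.0
    for shift in range(-(len(rt) - 1), len(lnc)):
        run = 0
        energy = 0.0
        for i in range(max(0, shift), min(len(lnc), shift + len(rt))):
            j = i - shift
            a, b = lnc[i], rt[j]
            if a in _COMP and _COMP[a] == b:
                if run > 0:
                    energy += table.get(lnc[i - 1:i + 1], 0.0)
                run += 1
                if run >= 2 and energy < best:
                    best = energy
            else:
                run = 0
                energy = 0.0
    return best


def complement_window_oracle(lnc: str, target: str, min_len: int = 12) -> bool:
    """True iff lnc contains the exact reverse complement of some
    ``min_len``-nt window of target (brute-force window scan)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for i in range(len(target) - min_len + 1):
        w = target[i:i + min_len]
        rc = "".join(comp[b] for b in reversed(w))
        if rc in lnc:
            return True
    return False


# --- Smith–Waterman affine-gap DP ---------------------------------------------

def sw_oracle(a: str, b: str, open_cost: int = 11, extend_cost: int = 1) -> int:
    """Independent affine-gap local-alignment DP (gap of length L costs
    open + (L-1)*extend), BLOSUM62."""
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    NEG = -10 ** 9
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (deletion from b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_cost, E[i][j - 1] - extend_cost)
            F[i][j] = max(H[i - 1][j] - open_cost, F[i - 1][j] - extend_cost)
            s = blosum[a[i - 1]][b[j - 1]]
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


# --- longest ORF by exhaustive scan -------------------------------------------

def longest_orf_oracle(seq: str) -> Optional[Tuple[int, int]]:
    stops = {"TAA", "TAG", "TGA"}
    seq = seq.upper()
    candidates = []
    for start in range(len(seq) - 2):
        if seq[start:start + 3] != "ATG":
            continue
        for end in range(start + 3, len(seq) - 2, 3):
            if seq[end:end + 3] in stops:
                candidates.append((start, end + 3))
                break
    if not candidates:
        return None
    return max(candidates, key=lambda c: (c[1] - c[0], -c[0]))


# --- fickett by direct table lookup -------------------------------------------

def fickett_oracle(seq: str) -> float:
    from adtrx._tables import (
        FICKETT_CONTENT_EDGES,
        FICKETT_CONTENT_PROB,
        FICKETT_CONTENT_WEIGHT,
        FICKETT_POSITION_EDGES,
        FICKETT_POSITION_PROB,
        FICKETT_POSITION_WEIGHT,
    )

    seq = seq.upper()
    score = 0.0
    for base in "ACGT":
        counts = [sum(1 for k in range(f, len(seq), 3) if seq[k] == base) for f in range(3)]
        pos_val = max(counts) / (min(counts) + 1)
        content = sum(1 for ch in seq if ch == base) / len(seq)
        pos_prob = FICKETT_POSITION_PROB[base][-1]
        for idx, edge in enumerate(FICKETT_POSITION_EDGES):
            if pos_val >= edge:
                pos_prob = FICKETT_POSITION_PROB[base][idx]
                break
        con_prob = FICKETT_CONTENT_PROB[base][-1]
        for idx, edge in enumerate(FICKETT_CONTENT_EDGES):
            if content >= edge:
                con_prob = FICKETT_CONTENT_PROB[base][idx]
                break
        score += pos_prob * FICKETT_POSITION_WEIGHT[base]
        score += con_prob * FICKETT_CONTENT_WEIGHT[base]
    return score


# --- random catalogs ----------------------------------------------------------

def random_catalog(rng: np.random.Generator, n_transcripts: int = 10,
                   seq_len: int = 20000, n_seqs: int = 2):
    """Random multi-exon catalog for round-trip and index property tests."""
    from adtrx.io_formats import AnnotationCatalog, GenomicInterval, TranscriptModel

    catalog = AnnotationCatalog()
    for i in range(n_transcripts):
        seq_id = f"chr{rng.integers(1, n_seqs + 1)}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 5))
        pos = int(rng.integers(0, seq_len))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(50, 300))
            exons.append(GenomicInterval(seq_id, pos, pos + length, strand))
            pos += length + int(rng.integers(50, 500))
        catalog.add(
            TranscriptModel(
                transcript_id=f"T{i:03d}",
                gene_id=f"G{i // 2:03d}",
                exons=tuple(exons),
                biotype_label="test" if rng.random() < 0.5 else None,
            )
        )
    return catalog
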