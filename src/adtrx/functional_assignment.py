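"""Unique functional re-annotation of transcripts against a protein database.

Each transcript's longest-ORF peptide is searched against the supplied
protein FASTA by Smith–Waterman local alignment (BLOSUM62, affine gaps);
"closest homolog" is the highest-scoring protein.  The assignment is made
globally greedy over all (transcript, protein) scores, each protein usable
at most once — the resulting transcript -> protein map is injective, so no
two splicing variants ever receive the same function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .lncrna_discovery import find_longest_orf

MIN_SCORE = 40
GAP_OPEN = 11  # cost of the first gapped residue; length-L gap costs 11 + (L-1)
GAP_EXTEND = 1

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_VALID_RESIDUES = set(str(_BLOSUM62.alphabet))
_CODON_TABLE = standard_dna_table.forward_table
_STOPS = set(standard_dna_table.stop_codons)


@dataclass(frozen=True)
class AlignmentScore:
    transcript_id: str
    protein_id: str
    score: int
    aligned_fraction: float


@dataclass
class AssignmentResult:
    assignments: Dict[str, str]  # transcript -> protein; injective by construction
    unassigned: List[str]
    scores_used: List[AlignmentScore] = field(default_factory=list)


def translate_longest_orf(transcript_seq: str) -> Optional[str]:
    """Peptide of the longest ORF (stop excluded); codons containing N
    translate as X; ``None`` when the transcript has no ORF."""
    orf = find_longest_orf(transcript_seq)
    if orf is None:
        return None
    start, end, _frame = orf
    cds = transcript_seq.upper()[start:end - 3]  # strip the stop codon
    peptide = []
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3]
        peptide.append(_CODON_TABLE.get(codon, "X"))
    return "".join(peptide)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def local_align_score(
    peptide: str, protein: str, transcript_id: str = "", protein_id: str = ""
) -> AlignmentScore:
    """Smith–Waterman local alignment score (BLOSUM62, affine gaps).

    ``aligned_fraction`` is the fraction of peptide residues inside the
    best local alignment.
    """
    if not peptide or not protein:
        raise ValueError("empty sequence")
    for seq, label in ((peptide, "peptide"), (protein, "protein")):
        bad = set(seq) - _VALID_RESIDUES
        if bad:
            raise ValueError(f"invalid {label} residues: {sorted(bad)}")
    aligner = _make_aligner()
    alignments = aligner.align(peptide, protein)
    try:
        best = alignments[0]
    except IndexError:
        return AlignmentScore(transcript_id, protein_id, 0, 0.0)
    score = int(best.score)
    if score <= 0:
        return AlignmentScore(transcript_id, protein_id, 0, 0.0)
    aligned_residues = sum(end - start for start, end in best.aligned[0])
    return AlignmentScore(
        transcript_id, protein_id, score, aligned_residues / len(peptide)
    )


def score_all_pairs(
    peptides: Mapping[str, str],
    proteins: Mapping[str, str],
    min_score: int = MIN_SCORE,
) -> List[AlignmentScore]:
    """All transcript x protein alignment scores at or above ``min_score``."""
    out = []
    for tid, pep in peptides.items():
        if not pep:
            continue
        for pid, prot in proteins.items():
            s = local_align_score(pep, prot, tid, pid)
            if s.score >= min_score:
                out.append(s)
    return out


def unique_assign(
    scores: Iterable[AlignmentScore],
    min_score: int = MIN_SCORE,
    method: str = "greedy",
) -> AssignmentResult:
    """Injective transcript -> protein assignment from alignment scores.

    ``greedy`` (default): repeatedly take the highest-scoring remaining pair
    with both sides free; ties break lexicographically by (transcript_id,
    protein_id).  Independent of input order.  ``optimal`` solves the
    maximum-weight assignment (Hungarian) instead, for comparison.
    """
    usable = [s for s in scores if s.score >= min_score]
    transcripts = sorted({s.transcript_id for s in usable})
    if method == "optimal":
        assignments = _optimal_assign(usable)
    elif method == "greedy":
        ordered = sorted(usable, key=lambda s: (-s.score, s.transcript_id, s.protein_id))
        assignments = {}
        taken_proteins = set()
        for s in ordered:
            if s.transcript_id in assignments or s.protein_id in taken_proteins:
                continue
            assignments[s.transcript_id] = s.protein_id
            taken_proteins.add(s.protein_id)
    else:
        raise ValueError(f"unknown method {method!r}")
    unassigned = [t for t in transcripts if t not in assignments]
    return AssignmentResult(
        assignments=assignments, unassigned=unassigned, scores_used=list(usable)
    )


def _optimal_assign(usable: Sequence[AlignmentScore]) -> Dict[str, str]:
    import numpy as np
    from scipy.optimize import linear_sum_assignment

    transcripts = sorted({s.transcript_id for s in usable})
    proteins = sorted({s.protein_id for s in usable})
    cost = np.zeros((len(transcripts), len(proteins)))
    t_idx = {t: i for i, t in enumerate(transcripts)}
    p_idx = {p: i for i, p in enumerate(proteins)}
    for s in usable:
        cost[t_idx[s.transcript_id], p_idx[s.protein_id]] = -s.score
    rows, cols = linear_sum_assignment(cost)
    return {
        transcripts[r]: proteins[c]
        for r, c in zip(rows, cols)
        if cost[r, c] < 0
    }


def annotate_transcripts(
    transcript_seqs: Mapping[str, str],
    proteins: Mapping[str, str],
    min_score: int = MIN_SCORE,
    method: str = "greedy",
) -> AssignmentResult:
    """End-to-end re-annotation: translate, align, uniquely assign."""
    peptides = {}
    for tid, seq in transcript_seqs.items():
        pep = translate_longest_orf(seq)
        if pep:
            peptides[tid] = pep
    scores = score_all_pairs(peptides, proteins, min_score)
    result = unique_assign(scores, min_score, method)
    no_orf = [t for t in transcript_seqs if t not in peptides]
    result.unassigned = sorted(set(result.unassigned) | set(no_orf))
    return result
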