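"""LncRNA identification, classification and read-region accounting.

The discovery procedure is two-step.  Step 1 filters assembled transcripts to
candidates (spliced length >= 200 nt, >= 2 exons, both inclusive) and scores
each candidate's protein-coding potential with five independent in-house
scorers; a transcript is called a lncRNA only when *all five* scorers vote
noncoding (unanimous-vote consensus).  Step 2 places each novel lncRNA
relative to a reference annotation: a class code in {i, o, u, x} and a
category in {intergenic, antisense, intronic}.

The five scorers stand in for the five external coding-potential tools the
field normally runs (CNCI/CPAT/CPC/CPPred/PLEK); the consensus rule — the
actual computation of interest — is preserved exactly.  Scorer thresholds are
calibrated on a labeled training split (see :meth:`ScorerSet.calibrate`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import _tables
from .io_formats import AnnotationCatalog, GenomicInterval, TranscriptModel

MIN_LENGTH = 200
MIN_EXONS = 2
STOP_CODONS = ("TAA", "TAG", "TGA")
SCORER_NAMES = ("fickett", "hexamer", "orf_coverage", "orf_length", "gc_content")

NO_ORF_SENTINEL = -math.inf  # hexamer score of a transcript with no ORF


# --- candidate filter -------------------------------------------------------

def filter_candidates(catalog: AnnotationCatalog) -> List[str]:
    """Transcripts with spliced length >= 200 nt and >= 2 exons (inclusive)."""
    return [
        tid
        for tid, t in catalog.transcripts.items()
        if t.length() >= MIN_LENGTH and len(t.exons) >= MIN_EXONS
    ]


# --- ORF finding ------------------------------------------------------------

def find_longest_orf(sequence: str) -> Optional[Tuple[int, int, int]]:
    """Longest ATG..stop ORF on the sense strand.

    Returns ``(start, end, frame)`` with ``end`` exclusive of nothing — the
    ORF includes its stop codon, so ``end - start`` is a multiple of 3.
    Ties are broken toward the 5'-most start.  ``None`` if no ORF exists.
    """
    seq = sequence.upper()
    best: Optional[Tuple[int, int, int]] = None
    for frame in range(3):
        start: Optional[int] = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos:pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in STOP_CODONS:
                end = pos + 3
                if (
                    best is None
                    or end - start > best[1] - best[0]
                    or (end - start == best[1] - best[0] and start < best[0])
                ):
                    best = (start, end, frame)
                start = None
    return best


# --- the five coding-potential scorers --------------------------------------

def _fickett_position_value(seq: str, base: str) -> float:
    counts = [seq[frame::3].count(base) for frame in range(3)]
    return max(counts) / (min(counts) + 1)


def _fickett_lookup(value: float, edges: Sequence[float], probs: Sequence[float]) -> float:
    for edge, prob in zip(edges, probs):
        if value >= edge:
            return prob
    return probs[-1]


def fickett_score(sequence: str) -> float:
    """Fickett TESTCODE statistic (position asymmetry + base composition).

    Eight table lookups (position and content value per base), each weighted
    by the base's discriminative power; higher means more coding-like.
    """
    seq = sequence.upper()
    if len(seq) < MIN_LENGTH:
        raise ValueError(f"fickett_score needs >= {MIN_LENGTH} nt, got {len(seq)}")
    score = 0.0
    denom = len(seq)
    for base in "ACGT":
        pos_val = _fickett_position_value(seq, base)
        content = seq.count(base) / denom
        score += (
            _fickett_lookup(
                pos_val, _tables.FICKETT_POSITION_EDGES, _tables.FICKETT_POSITION_PROB[base]
            )
            * _tables.FICKETT_POSITION_WEIGHT[base]
        )
        score += (
            _fickett_lookup(
                content, _tables.FICKETT_CONTENT_EDGES, _tables.FICKETT_CONTENT_PROB[base]
            )
            * _tables.FICKETT_CONTENT_WEIGHT[base]
        )
    return score


def _inframe_hexamers(orf_seq: str) -> Iterable[str]:
    for pos in range(0, len(orf_seq) - 5, 3):
        yield orf_seq[pos:pos + 6]


def train_hexamer_tables(
    coding_seqs: Iterable[str], noncoding_seqs: Iterable[str]
) -> Tuple[Dict[str, float], Dict[str, float]]:
    """Estimate in-frame hexamer frequency tables with add-one smoothing.

    Coding sequences are read in frame 0 (supply CDS sequences); noncoding
    sequences contribute frame-0 hexamers of the raw transcript.
    """
    def table(seqs: Iterable[str]) -> Dict[str, float]:
        counts: Dict[str, int] = {}
        for seq in seqs:
            for hexamer in _inframe_hexamers(seq.upper()):
                if set(hexamer) <= set("ACGT"):
                    counts[hexamer] = counts.get(hexamer, 0) + 1
        total = sum(counts.values()) + 4096
        bases = "ACGT"
        out = {}
        for i in range(4096):
            h = "".join(bases[(i // 4 ** k) % 4] for k in range(5, -1, -1))
            out[h] = (counts.get(h, 0) + 1) / total
        return out

    return table(coding_seqs), table(noncoding_seqs)


def hexamer_score(
    sequence: str,
    coding_table: Mapping[str, float],
    noncoding_table: Mapping[str, float],
) -> float:
    """Log-likelihood ratio of in-frame hexamers over the longest ORF.

    Positive favors coding.  A transcript without any ORF gets ``-inf``
    (documented sentinel: no reading frame at all is maximal evidence
    against coding potential).
    """
    orf = find_longest_orf(sequence)
    if orf is None:
        return NO_ORF_SENTINEL
    start, end, _frame = orf
    orf_seq = sequence.upper()[start:end]
    score = 0.0
    for hexamer in _inframe_hexamers(orf_seq):
        if hexamer in coding_table and hexamer in noncoding_table:
            score += math.log(coding_table[hexamer] / noncoding_table[hexamer])
    return score


def orf_coverage_score(transcript_length: int, orf_length: int) -> float:
    """Fraction of the transcript covered by its longest ORF, in [0, 1]."""
    if orf_length > transcript_length:
        raise ValueError("ORF cannot be longer than its transcript")
    if transcript_length <= 0:
        raise ValueError("transcript length must be positive")
    return orf_length / transcript_length


def orf_length_score(sequence: str) -> float:
    orf = find_longest_orf(sequence)
    return 0.0 if orf is None else float(orf[1] - orf[0])


def gc_content_score(sequence: str) -> float:
    """Composition stand-in scorer: G+C fraction of the transcript."""
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


# --- votes and consensus ----------------------------------------------------

@dataclass(frozen=True)
class CodingPotentialVote:
    transcript_id: str
    scorer_name: str
    score: float
    verdict: str  # "coding" | "noncoding"


@dataclass(frozen=True)
class ClassCode:
    transcript_id: str
    code: str  # i | o | u | x
    evidence: Tuple[str, ...]  # reference transcript ids overlapped


@dataclass
class LncRNARecord:
    transcript_id: str
    category: str  # intergenic | antisense | intronic
    class_code: ClassCode
    votes: List[CodingPotentialVote]


def consensus_vote(votes: Sequence[CodingPotentialVote]) -> str:
    """Unanimous-vote consensus: lncRNA iff all five verdicts are noncoding."""
    if len(votes) != 5:
        raise ValueError(f"consensus requires exactly 5 votes, got {len(votes)}")
    if all(v.verdict == "noncoding" for v in votes):
        return "lncRNA"
    return "not-lncRNA"


class ScorerSet:
    """The five bundled scorers with calibrated coding/noncoding thresholds.

    A scorer votes "coding" when its score strictly exceeds its threshold.
    :meth:`calibrate` sets every threshold to a high quantile (default 1.0,
    the maximum) of the noncoding training scores: under the unanimous-vote
    rule a single scorer's false coding-vote loses a lncRNA, so each scorer
    is calibrated to never flag a training noncoding transcript, and vetoing
    coding transcripts is left to the scorers with real separation (ORF
    length and hexamer bias separate cleanly on ORF-bearing sequence).
    """

    def __init__(
        self,
        coding_table: Mapping[str, float],
        noncoding_table: Mapping[str, float],
        thresholds: Mapping[str, float],
    ):
        self.coding_table = dict(coding_table)
        self.noncoding_table = dict(noncoding_table)
        self.thresholds = dict(thresholds)
        missing = set(SCORER_NAMES) - set(self.thresholds)
        if missing:
            raise ValueError(f"missing thresholds for {sorted(missing)}")

    def scores(self, sequence: str) -> Dict[str, float]:
        orf = find_longest_orf(sequence)
        orf_len = 0 if orf is None else orf[1] - orf[0]
        return {
            "fickett": fickett_score(sequence),
            "hexamer": hexamer_score(sequence, self.coding_table, self.noncoding_table),
            "orf_coverage": orf_coverage_score(len(sequence), orf_len),
            "orf_length": float(orf_len),
            "gc_content": gc_content_score(sequence),
        }

    def votes(self, transcript_id: str, sequence: str) -> List[CodingPotentialVote]:
        out = []
        for name, score in self.scores(sequence).items():
            verdict = "coding" if score > self.thresholds[name] else "noncoding"
            out.append(CodingPotentialVote(transcript_id, name, score, verdict))
        return out

    @classmethod
    def calibrate(
        cls,
        coding_cds_seqs: Sequence[str],
        coding_tx_seqs: Sequence[str],
        noncoding_tx_seqs: Sequence[str],
        specificity: float = 1.0,
    ) -> "ScorerSet":
        """Train hexamer tables and set per-scorer thresholds.

        ``coding_cds_seqs`` train the coding hexamer table (in-frame CDS);
        ``coding_tx_seqs`` / ``noncoding_tx_seqs`` are full transcript
        sequences of the labeled training split.  The threshold of each
        scorer is the ``specificity`` quantile of its noncoding scores.
        """
        coding_table, noncoding_table = train_hexamer_tables(
            coding_cds_seqs, noncoding_tx_seqs
        )
        prototype = cls(coding_table, noncoding_table, dict.fromkeys(SCORER_NAMES, 0.0))
        nc_scores = {name: [] for name in SCORER_NAMES}
        for seq in noncoding_tx_seqs:
            for name, score in prototype.scores(seq).items():
                if math.isfinite(score):
                    nc_scores[name].append(score)
        thresholds = {
            name: float(np.quantile(vals, specificity)) if vals else 0.0
            for name, vals in nc_scores.items()
        }
        return cls(coding_table, noncoding_table, thresholds)


# --- class codes and categories ---------------------------------------------

def _exon_union_by_gene(reference: AnnotationCatalog, seq_id: str) -> Dict[str, List[Tuple[int, int]]]:
    out: Dict[str, List[Tuple[int, int]]] = {}
    for gene, tids in reference.genes.items():
        merged: List[Tuple[int, int]] = []
        for tid in tids:
            t = reference.transcripts[tid]
            if t.seq_id != seq_id:
                continue
            merged.extend((e.start, e.end) for e in t.exons)
        if merged:
            merged.sort()
            fused = [list(merged[0])]
            for s, e in merged[1:]:
                if s <= fused[-1][1]:
                    fused[-1][1] = max(fused[-1][1], e)
                else:
                    fused.append([s, e])
            out[gene] = [tuple(x) for x in fused]
    return out


def _bases_covered(intervals: Sequence[Tuple[int, int]], start: int, end: int) -> bool:
    """True iff [start, end) is fully covered by the sorted merged intervals."""
    for s, e in intervals:
        if s <= start and end <= e:
            return True
    return False


def assign_class_code(transcript: TranscriptModel, reference: AnnotationCatalog) -> ClassCode:
    """Locational class code of a novel transcript against a reference.

    * ``i`` — every transcript base lies within one reference transcript's intron
    * ``u`` — no overlap with any reference transcript span (intergenic)
    * ``x`` — every exon base falls in the exonic space of one reference gene
    * ``o`` — any other (partial) overlap
    """
    span = transcript.span
    hits = reference.overlapping(span.seq_id, span.start, span.end)
    if not hits:
        return ClassCode(transcript.transcript_id, "u", ())

    for tid in hits:
        for intron in reference.transcripts[tid].introns():
            if intron.start <= span.start and span.end <= intron.end:
                return ClassCode(transcript.transcript_id, "i", (tid,))

    exon_space = _exon_union_by_gene(reference, span.seq_id)
    hit_genes = {reference.transcripts[tid].gene_id for tid in hits}
    for gene in sorted(hit_genes):
        intervals = exon_space.get(gene, [])
        if intervals and all(
            _bases_covered(intervals, e.start, e.end) for e in transcript.exons
        ):
            evidence = tuple(
                tid for tid in hits if reference.transcripts[tid].gene_id == gene
            )
            return ClassCode(transcript.transcript_id, "x", evidence)

    return ClassCode(transcript.transcript_id, "o", tuple(hits))


def categorize_lncrna(
    transcript: TranscriptModel,
    class_code: ClassCode,
    reference: AnnotationCatalog,
) -> str:
    """Category in {antisense, intronic, intergenic}.

    Precedence antisense > intronic > intergenic: any opposite-strand overlap
    with a reference transcript wins; class code ``i`` on the same strand is
    intronic; class code ``u`` is intergenic.  A transcript matching none of
    the three (e.g. same-strand partial overlap) defaults to intergenic with
    a warning.
    """
    span = transcript.span
    strand = transcript.oriented_strand()
    for tid in reference.overlapping(span.seq_id, span.start, span.end):
        ref = reference.transcripts[tid]
        if ref.oriented_strand() != strand:
            return "antisense"
    if class_code.code == "i":
        return "intronic"
    if class_code.code == "u":
        return "intergenic"
    warnings.warn(
        f"{transcript.transcript_id}: class {class_code.code!r} on the sense "
        "strand matches no lncRNA category; defaulting to intergenic",
        stacklevel=2,
    )
    return "intergenic"


# --- read-region distribution ------------------------------------------------

UPSTREAM_WINDOW = 10_000
REGION_ORDER = ("CDS", "three_prime_utr", "intron", "upstream")


def _region_intervals(reference: AnnotationCatalog) -> Dict[str, Dict[str, List[Tuple[int, int]]]]:
    regions: Dict[str, Dict[str, List[Tuple[int, int]]]] = {
        r: {} for r in REGION_ORDER
    }

    def push(region: str, seq_id: str, start: int, end: int) -> None:
        if start < end:
            regions[region].setdefault(seq_id, []).append((start, end))

    for t in reference.transcripts.values():
        seq_id = t.seq_id
        strand = t.oriented_strand()
        for intron in t.introns():
            push("intron", seq_id, intron.start, intron.end)
        if strand == "+":
            push("upstream", seq_id, max(0, t.span.start - UPSTREAM_WINDOW), t.span.start)
        else:
            push("upstream", seq_id, t.span.end, t.span.end + UPSTREAM_WINDOW)
        if not t.cds:
            continue
        for c in t.cds:
            push("CDS", seq_id, c.start, c.end)
        cds_start = min(c.start for c in t.cds)
        cds_end = max(c.end for c in t.cds)
        for e in t.exons:
            if strand == "+":
                push("three_prime_utr", seq_id, max(e.start, cds_end), e.end)
            else:
                push("three_prime_utr", seq_id, e.start, min(e.end, cds_start))
    return regions


def region_read_distribution(
    read_intervals: Sequence[GenomicInterval], reference: AnnotationCatalog
) -> Dict[str, float]:
    """Fraction of reads per genomic region, precedence CDS > 3'UTR > intron >
    upstream-10kb.  Reads overlapping none of the four regions are dropped;
    fractions are over assigned reads and sum to 1."""
    regions = _region_intervals(reference)
    counts = dict.fromkeys(REGION_ORDER, 0)
    for read in read_intervals:
        for region in REGION_ORDER:
            ivs = regions[region].get(read.seq_id, ())
            if any(s < read.end and read.start < e for s, e in ivs):
                counts[region] += 1
                break
    assigned = sum(counts.values())
    if assigned == 0:
        return dict.fromkeys(REGION_ORDER, 0.0)
    return {region: counts[region] / assigned for region in REGION_ORDER}


# --- the full discovery pipeline ---------------------------------------------

def identify_lncrnas(
    assembled: AnnotationCatalog,
    reference: AnnotationCatalog,
    genome: Mapping[str, str],
    scorers: ScorerSet,
) -> List[LncRNARecord]:
    """Run the two-step procedure over an assembled catalog.

    Candidates (length/exon filter) are scored by the five scorers; unanimous
    noncoding votes make a lncRNA, which is then classified against the
    reference (class code + category).  Transcripts whose id already exists
    in the reference are treated as known and classified but keep their
    reference placement (class code computed all the same for reporting).
    """
    records: List[LncRNARecord] = []
    for tid in filter_candidates(assembled):
        t = assembled.transcripts[tid]
        seq = t.spliced_sequence(genome)
        votes = scorers.votes(tid, seq)
        if consensus_vote(votes) != "lncRNA":
            continue
        code = assign_class_code(t, reference)
        category = categorize_lncrna(t, code, reference)
        records.append(
            LncRNARecord(transcript_id=tid, category=category, class_code=code, votes=votes)
        )
    return records
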