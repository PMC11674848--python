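"""Alternative-splicing event detection, PSI and group testing.

Events come from pairwise comparison of transcript models within a gene and
fall into the five canonical types: SE (skipped exon), A5SS/A3SS
(alternative 5'/3' splice site), MXE (mutually exclusive exons) and RI
(retained intron).  Percent Spliced In (PSI) for an event is the
length-normalized fraction of junction evidence supporting the inclusion
form:  psi = (I/l_I) / (I/l_I + S/l_S), where l_I and l_S count the
junctions supporting each form (2 vs 1 for SE, 2 vs 2 for MXE, 1 vs 1
otherwise).  Group comparison uses a two-sided rank-sum test on per-sample
PSI; an event is kept when p < 0.05 and |dPSI| > 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from scipy import stats

from .io_formats import AnnotationCatalog, TranscriptModel

EVENT_TYPES = ("SE", "A5SS", "A3SS", "MXE", "RI")

# junction-support sizes (inclusion form, skipping form) per event type
FORM_LENGTHS: Dict[str, Tuple[int, int]] = {
    "SE": (2, 1),
    "A5SS": (1, 1),
    "A3SS": (1, 1),
    "MXE": (2, 2),
    "RI": (1, 1),
}


@dataclass(frozen=True)
class SpliceEvent:
    event_id: str
    gene_id: str
    type: str
    inclusion_form: Tuple[int, ...]  # coordinates defining the inclusion variant
    skipping_form: Tuple[int, ...]
    transcripts: Tuple[str, str]  # the transcript pair the event was derived from

    @property
    def inclusion_len(self) -> int:
        return FORM_LENGTHS[self.type][0]

    @property
    def skipping_len(self) -> int:
        return FORM_LENGTHS[self.type][1]


@dataclass(frozen=True)
class PsiRecord:
    event_id: str
    sample_id: str
    inclusion_count: int
    skipping_count: int
    psi: Optional[float]
    group: str


@dataclass(frozen=True)
class EventTestResult:
    event_id: str
    delta_psi: float  # mean PSI(group A) - mean PSI(group B)
    p_value: float
    kept: bool


# --- detection ---------------------------------------------------------------

def _intron_pairs(t: TranscriptModel) -> List[Tuple[int, int]]:
    return [(a.end, b.start) for a, b in zip(t.exons, t.exons[1:]) if a.end < b.start]


def _pair_events(x: TranscriptModel, y: TranscriptModel) -> List[Tuple[str, Tuple[int, ...], Tuple[int, ...], Tuple[int, ...]]]:
    """All events between one transcript pair.

    Returns tuples ``(type, key, inclusion_form, skipping_form)`` where the
    inclusion isoform is ``x`` for SE/RI/MXE conventions below.
    """
    out = []
    ix, iy = _intron_pairs(x), _intron_pairs(y)
    set_iy = set(iy)
    strand = x.oriented_strand()

    # SE: x carries internal exon e with flanking introns (a, e.start) and
    # (e.end, b); y has the single intron (a, b).
    for j in range(1, len(x.exons) - 1):
        e = x.exons[j]
        a = x.exons[j - 1].end
        b = x.exons[j + 1].start
        if (a, e.start) in ix and (e.end, b) in ix and (a, b) in set_iy:
            key = (a, e.start, e.end, b)
            out.append(("SE", key, key, (a, b)))

    # RI: y's exon [s, t] equals x's consecutive exons [s, a], [b, t] fused.
    for j in range(len(x.exons) - 1):
        ea, eb = x.exons[j], x.exons[j + 1]
        if ea.end >= eb.start:
            continue
        for ey in y.exons:
            if ey.start == ea.start and ey.end == eb.end:
                key = (ea.start, ea.end, eb.start, eb.end)
                # inclusion form = intron retained (single exon), per rMATS
                out.append(("RI", key, (ea.start, eb.end), key))

    # A5SS / A3SS: introns sharing exactly one boundary; the exons adjacent
    # to the differing boundary must share their outer boundary (otherwise
    # the difference is a skipped exon, handled above).
    for (a1, b1) in ix:
        for (a2, b2) in iy:
            if b1 == b2 and a1 != a2:
                ex = next(e for e in x.exons if e.end == a1)
                ey = next(e for e in y.exons if e.end == a2)
                if ex.start == ey.start:
                    etype = "A5SS" if strand == "+" else "A3SS"
                    lo, hi = min(a1, a2), max(a1, a2)
                    out.append(
                        (etype, (lo, hi, b1), (hi, b1), (lo, b1))
                    )
            if a1 == a2 and b1 != b2:
                ex = next(e for e in x.exons if e.start == b1)
                ey = next(e for e in y.exons if e.start == b2)
                if ex.end == ey.end:
                    etype = "A3SS" if strand == "+" else "A5SS"
                    lo, hi = min(b1, b2), max(b1, b2)
                    out.append(
                        (etype, (a1, lo, hi), (a1, lo), (a1, hi))
                    )

    # MXE: x has middle exon m1 between shared flanks (b, g); y has a
    # disjoint middle exon m2 between the same flanks.
    for j in range(1, len(x.exons) - 1):
        m1 = x.exons[j]
        b = x.exons[j - 1].end
        g = x.exons[j + 1].start
        if (b, m1.start) not in ix or (m1.end, g) not in ix:
            continue
        for k in range(1, len(y.exons) - 1):
            m2 = y.exons[k]
            bb = y.exons[k - 1].end
            gg = y.exons[k + 1].start
            if bb != b or gg != g:
                continue
            if (b, m2.start) not in set_iy or (m2.end, g) not in set_iy:
                continue
            if m1.end <= m2.start:  # disjoint, m1 upstream: report once per pair
                key = (b, m1.start, m1.end, m2.start, m2.end, g)
                out.append(("MXE", key, (b, m1.start, m1.end, g), (b, m2.start, m2.end, g)))
    return out


def detect_events(catalog: AnnotationCatalog) -> List[SpliceEvent]:
    """Detect SE/A5SS/A3SS/MXE/RI events by pairwise transcript comparison
    within each gene, deduplicated by (gene, type, coordinates)."""
    events: Dict[Tuple[str, str, Tuple[int, ...]], SpliceEvent] = {}
    for gene, tids in catalog.genes.items():
        for i, ta in enumerate(tids):
            for tb in tids[i + 1:]:
                x, y = catalog.transcripts[ta], catalog.transcripts[tb]
                if x.seq_id != y.seq_id or x.oriented_strand() != y.oriented_strand():
                    continue
                for first, second in ((x, y), (y, x)):
                    for etype, key, inc, skp in _pair_events(first, second):
                        dedup = (gene, etype, key)
                        if dedup in events:
                            continue
                        event_id = f"{etype}:{gene}:" + "-".join(map(str, key))
                        events[dedup] = SpliceEvent(
                            event_id=event_id,
                            gene_id=gene,
                            type=etype,
                            inclusion_form=inc,
                            skipping_form=skp,
                            transcripts=(first.transcript_id, second.transcript_id),
                        )
    return sorted(events.values(), key=lambda e: e.event_id)


# --- PSI ---------------------------------------------------------------------

def compute_psi(
    inclusion: int, skipping: int, inclusion_len: int = 1, skipping_len: int = 1
) -> Optional[float]:
    """Length-normalized Percent Spliced In; ``None`` when no evidence."""
    if inclusion < 0 or skipping < 0:
        raise ValueError("junction counts must be non-negative")
    if inclusion_len < 1 or skipping_len < 1:
        raise ValueError("form lengths must be >= 1")
    num = inclusion / inclusion_len
    den = num + skipping / skipping_len
    if den == 0:
        return None
    return num / den


def psi_records(
    junction_counts: Sequence[Mapping],
    groups: Mapping[str, str],
    form_lengths: Optional[Mapping[str, Tuple[int, int]]] = None,
) -> List[PsiRecord]:
    """Build PsiRecords from rows with event_id/sample_id/inclusion/skipping.

    ``form_lengths`` maps event_id -> (l_I, l_S); unlisted events use (1, 1).
    """
    out = []
    for row in junction_counts:
        eid, sid = row["event_id"], row["sample_id"]
        inc, skp = int(row["inclusion_count"]), int(row["skipping_count"])
        l_i, l_s = (form_lengths or {}).get(eid, (1, 1))
        out.append(
            PsiRecord(
                event_id=eid,
                sample_id=sid,
                inclusion_count=inc,
                skipping_count=skp,
                psi=compute_psi(inc, skp, l_i, l_s),
                group=groups[sid],
            )
        )
    return out


# --- group testing -----------------------------------------------------------

def event_kept(
    p_value: float,
    delta_psi: float,
    p_threshold: float = 0.05,
    dpsi_threshold: float = 0.05,
    direction: str = "retain",
) -> bool:
    """The event-level decision rule: p strictly below threshold and |dPSI|
    strictly above it (``direction="remove"`` inverts the dPSI gate)."""
    if direction not in ("retain", "remove"):
        raise ValueError("direction must be 'retain' or 'remove'")
    passes_dpsi = abs(delta_psi) > dpsi_threshold
    if direction == "remove":
        passes_dpsi = not passes_dpsi
    return bool(p_value < p_threshold and passes_dpsi)


def test_events(
    records: Sequence[PsiRecord],
    group_a: str,
    group_b: str,
    p_threshold: float = 0.05,
    dpsi_threshold: float = 0.05,
    direction: str = "retain",
) -> List[EventTestResult]:
    """Rank-sum test of per-sample PSI between two groups.

    dPSI = mean(PSI in group_a) - mean(PSI in group_b).  With the default
    ``direction="retain"`` an event is kept iff p < p_threshold and
    |dPSI| > dpsi_threshold; ``direction="remove"`` inverts the dPSI gate.
    Events with fewer than two defined PSI values in either group are
    skipped with a warning.
    """
    if direction not in ("retain", "remove"):
        raise ValueError("direction must be 'retain' or 'remove'")
    by_event: Dict[str, Dict[str, List[float]]] = {}
    for r in records:
        if r.group not in (group_a, group_b) or r.psi is None:
            continue
        by_event.setdefault(r.event_id, {group_a: [], group_b: []})[r.group].append(r.psi)

    results = []
    for eid in sorted(by_event):
        a = by_event[eid][group_a]
        b = by_event[eid][group_b]
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"event {eid}: <2 defined PSI values per group; skipped")
            continue
        delta = sum(a) / len(a) - sum(b) / len(b)
        if all(v == a[0] for v in a) and all(v == a[0] for v in b):
            p = 1.0  # identical constant PSI in both groups
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        results.append(
            EventTestResult(
                event_id=eid,
                delta_psi=delta,
                p_value=p,
                kept=event_kept(p, delta, p_threshold, dpsi_threshold, direction),
            )
        )
    return results


def count_genes_with_events(
    kept_events: Sequence[SpliceEvent],
) -> Dict[str, Tuple[int, int]]:
    """Per-type (and "total") event and gene counts; a gene counts once per type."""
    counts: Dict[str, Tuple[int, set]] = {}
    for e in kept_events:
        n, genes = counts.get(e.type, (0, set()))
        counts[e.type] = (n + 1, genes | {e.gene_id})
    out = {etype: (n, len(genes)) for etype, (n, genes) in counts.items()}
    out["total"] = (
        sum(n for n, _ in out.values()),
        len({e.gene_id for e in kept_events}),
    )
    return out
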