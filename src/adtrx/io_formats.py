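"""Standard-format I/O and the shared coordinate conventions.

All genomic coordinates inside the package are 0-based, half-open, on a
named sequence with an explicit strand.  GTF files (1-based, inclusive)
are converted exactly once, in :func:`read_gtf` / :func:`write_gtf`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

STRANDS = ("+", "-", ".")
GROUP_LABELS = ("normal", "MCI", "AD")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GtfParseError(ValueError):
    """Raised on a malformed GTF line; the message names the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Stranded half-open interval ``[start, end)`` on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start <= other.start
            and other.end <= self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Distance in bp between two intervals on the same sequence (0 if
        they overlap or abut)."""
        if self.seq_id != other.seq_id:
            raise ValueError("intervals on different sequences have no distance")
        return max(0, other.start - self.end, self.start - other.end)


@dataclass
class TranscriptModel:
    """A stranded, exon-structured transcript: the atom of the catalog."""

    transcript_id: str
    gene_id: str
    exons: Tuple[GenomicInterval, ...]
    cds: Optional[Tuple[GenomicInterval, ...]] = None
    biotype_label: Optional[str] = None

    def __post_init__(self):
        self.exons = tuple(sorted(self.exons, key=lambda e: e.start))
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        seqs = {e.seq_id for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(seqs) != 1 or len(strands) != 1:
            raise ValueError(f"{self.transcript_id}: exons on mixed seq/strand")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if self.cds is not None:
            self.cds = tuple(sorted(self.cds, key=lambda c: c.start))

    @property
    def seq_id(self) -> str:
        return self.exons[0].seq_id

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.seq_id, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    def introns(self) -> List[GenomicInterval]:
        return [
            GenomicInterval(self.seq_id, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if a.end < b.start
        ]

    def oriented_strand(self) -> str:
        """Strand used for orientation-dependent rules ('.' maps to '+')."""
        if self.strand == ".":
            warnings.warn(
                f"{self.transcript_id}: unstranded transcript treated as '+'",
                stacklevel=2,
            )
            return "+"
        return self.strand

    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        """Mature (spliced) transcript sequence, 5'->3'."""
        chrom = genome[self.seq_id]
        seq = "".join(chrom[e.start:e.end] for e in self.exons)
        if self.oriented_strand() == "-":
            seq = reverse_complement(seq)
        return seq


class AnnotationCatalog:
    """Transcript catalog with gene grouping and a per-sequence span index."""

    def __init__(self, transcripts: Iterable[TranscriptModel] = ()):
        self.transcripts: Dict[str, TranscriptModel] = {}
        self.genes: Dict[str, List[str]] = {}
        self._index: Optional[Dict[str, tuple]] = None
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self.transcripts:
            raise ValueError(f"duplicate transcript_id {t.transcript_id!r}")
        self.transcripts[t.transcript_id] = t
        self.genes.setdefault(t.gene_id, []).append(t.transcript_id)
        self._index = None

    def __len__(self) -> int:
        return len(self.transcripts)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    def _build_index(self) -> Dict[str, tuple]:
        by_seq: Dict[str, list] = {}
        for t in self.transcripts.values():
            by_seq.setdefault(t.seq_id, []).append(t)
        index = {}
        for seq_id, ts in by_seq.items():
            ts.sort(key=lambda t: t.span.start)
            starts = np.array([t.span.start for t in ts])
            ends = np.array([t.span.end for t in ts])
            ids = [t.transcript_id for t in ts]
            index[seq_id] = (starts, ends, ids)
        return index

    def overlapping(self, seq_id: str, start: int, end: int) -> List[str]:
        """Transcript ids whose genomic span overlaps ``[start, end)``."""
        if self._index is None:
            self._index = self._build_index()
        entry = self._index.get(seq_id)
        if entry is None:
            return []
        starts, ends, ids = entry
        hit = np.flatnonzero((starts < end) & (ends > start))
        return [ids[i] for i in hit]

    def subset(self, transcript_ids: Iterable[str]) -> "AnnotationCatalog":
        return AnnotationCatalog(self.transcripts[i] for i in transcript_ids)


# --- GTF --------------------------------------------------------------------

def _format_attributes(t: TranscriptModel) -> str:
    parts = [f'gene_id "{t.gene_id}"', f'transcript_id "{t.transcript_id}"']
    if t.biotype_label is not None:
        parts.append(f'biotype "{t.biotype_label}"')
    return "; ".join(parts) + ";"


def _parse_attributes(raw: str, lineno: int) -> Dict[str, str]:
    attrs = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            raise GtfParseError(f"line {lineno}: malformed attribute {chunk!r}")
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str) -> AnnotationCatalog:
    """Parse a GTF file into an :class:`AnnotationCatalog`.

    GTF's 1-based inclusive coordinates become 0-based half-open here.
    Only ``exon`` and ``CDS`` features contribute geometry; other feature
    types are ignored (their attributes may still carry the biotype).
    """
    exons: Dict[str, List[GenomicInterval]] = {}
    cds: Dict[str, List[GenomicInterval]] = {}
    gene_of: Dict[str, str] = {}
    biotype_of: Dict[str, str] = {}
    order: List[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            seq_id, _src, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
            if strand not in STRANDS:
                raise GtfParseError(f"line {lineno}: invalid strand {strand!r}")
            attrs = _parse_attributes(attr_s, lineno)
            tid = attrs.get("transcript_id")
            if feature in ("exon", "CDS") and tid is None:
                raise GtfParseError(f"line {lineno}: {feature} without transcript_id")
            if tid is None:
                continue
            if "gene_id" in attrs:
                gene_of.setdefault(tid, attrs["gene_id"])
            for key in ("biotype", "transcript_biotype", "gene_biotype"):
                if key in attrs:
                    biotype_of.setdefault(tid, attrs[key])
                    break
            interval = GenomicInterval(seq_id, start1 - 1, end1, strand)
            if feature == "exon":
                if tid not in exons:
                    order.append(tid)
                exons.setdefault(tid, []).append(interval)
            elif feature == "CDS":
                cds.setdefault(tid, []).append(interval)

    catalog = AnnotationCatalog()
    for tid in order:
        gene = gene_of.get(tid)
        if gene is None:
            raise GtfParseError(f"transcript {tid!r} has no gene_id attribute")
        catalog.add(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene,
                exons=tuple(exons[tid]),
                cds=tuple(cds[tid]) if tid in cds else None,
                biotype_label=biotype_of.get(tid),
            )
        )
    return catalog


def write_gtf(catalog: AnnotationCatalog, path: str) -> None:
    """Write a catalog as GTF; ``read_gtf(write_gtf(c))`` reproduces ``c``."""
    with open(path, "w") as fh:
        fh.write("##format: gtf\n")
        for tid in catalog.transcripts:
            t = catalog.transcripts[tid]
            attrs = _format_attributes(t)
            span = t.span
            rows = [("transcript", span)]
            rows += [("exon", e) for e in t.exons]
            if t.cds:
                rows += [("CDS", c) for c in t.cds]
            for feature, iv in rows:
                fh.write(
                    "\t".join(
                        (
                            iv.seq_id,
                            "adtrx",
                            feature,
                            str(iv.start + 1),
                            str(iv.end),
                            ".",
                            iv.strand,
                            ".",
                            attrs,
                        )
                    )
                    + "\n"
                )


# --- FASTA ------------------------------------------------------------------

def read_fasta(path: str) -> Dict[str, str]:
    """Read FASTA into an ordered ``{id: SEQUENCE}`` map (upper-cased)."""
    out: Dict[str, str] = {}
    for record in SeqIO.parse(path, "fasta"):
        if record.id in out:
            raise ValueError(f"duplicate FASTA id {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for FASTA id {record.id!r}")
        out[record.id] = seq
    return out


def write_fasta(sequences: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# --- expression matrices ----------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Transcripts x samples abundance table with a unit tag and group labels."""

    values: pd.DataFrame  # rows: transcript ids, columns: sample ids
    unit: str  # "TPM" or "counts"
    groups: Dict[str, str] = field(default_factory=dict)  # sample -> group label

    def __post_init__(self):
        if self.unit not in ("TPM", "counts"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate transcript ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        for sample in self.values.columns:
            if sample not in self.groups:
                raise ValueError(f"sample {sample!r} missing from groups map")

    @property
    def transcript_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> List[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def row(self, transcript_id: str) -> pd.Series:
        return self.values.loc[transcript_id]


def read_matrix(path: str, unit: str, groups: Mapping[str, str]) -> ExpressionMatrix:
    """Read a TSV matrix (first column transcript ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().to_numpy().any():
        raise ValueError(f"{path}: ragged rows or missing values")
    return ExpressionMatrix(values=df.astype(float), unit=unit, groups=dict(groups))


def write_matrix(matrix: ExpressionMatrix, path: str) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="transcript_id")


# --- gene sets (GMT) --------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene/transcript-id sets (GMT membership lists)."""

    sets: Dict[str, List[str]]

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __iter__(self):
        return iter(self.sets.items())

    def __len__(self):
        return len(self.sets)

    def __getitem__(self, name: str) -> List[str]:
        return self.sets[name]


def read_gmt(path: str) -> GeneSetCollection:
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path} line {lineno}: GMT needs name, description, >=1 member"
                )
            sets[fields[0]] = [m for m in fields[2:] if m]
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na"] + list(members)) + "\n")


def read_groups(path: str) -> Dict[str, str]:
    """Two-column TSV ``sample<TAB>group`` -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"])
    return dict(zip(df["sample"].astype(str), df["group"].astype(str)))


def write_groups(groups: Mapping[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")
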