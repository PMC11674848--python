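"""Self-contained synthetic toy study with serialized ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, at a scale that runs in seconds:

* a single-chromosome genome carrying multi-exon protein-coding genes whose
  ORFs use a GC-biased codon table (so coding sequence has a learnable
  hexamer/composition signature), and planted lncRNAs with unbiased
  sequence, deliberately placed to realize each locational class code
  (i / o / u / x) and category (intergenic / antisense / intronic);
* gene pairs of isoforms realizing each of the five splicing event types,
  with the alternative region confined to the 3'UTR so both isoforms stay
  genuinely protein-coding;
* negative-binomial counts with log-normal baseline means, planted
  group fold changes (differential transcripts) and latent-factor
  co-expression linking planted regulator lncRNAs to their pathway's genes;
* binomial junction inclusion/skipping counts with group-shifted PSI for
  planted events;
* a protein database of per-gene translations at 5% substitution plus
  shuffled decoys.

Everything is deterministic under the config seed; ground truth is
serializable to JSON so downstream evaluation reads it rather than
regenerating it.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._tables import CODON_WEIGHTS
from .io_formats import (
    AnnotationCatalog,
    ExpressionMatrix,
    GeneSetCollection,
    GenomicInterval,
    TranscriptModel,
    reverse_complement,
    write_fasta,
    write_gmt,
    write_groups,
    write_gtf,
    write_matrix,
)

CHROM = "chr1"
_STOP_CODONS = ("TAA", "TAG", "TGA")
_CODONS = sorted(CODON_WEIGHTS)
_CODON_P = np.array([CODON_WEIGHTS[c] for c in _CODONS])
_CODON_P = _CODON_P / _CODON_P.sum()
_AA = "ACDEFGHIKLMNPQRSTVWY"

EVENT_TYPES = ("SE", "A5SS", "A3SS", "MXE", "RI")

# junction-support sizes by event type (inclusion form, skipping form)
_FORM_LENGTHS = {"SE": (2, 1), "A5SS": (1, 1), "A3SS": (1, 1), "MXE": (2, 2), "RI": (1, 1), "null": (1, 1)}


@dataclass
class SimConfig:
    """Knobs of the stated synthetic world (defaults = the toy study)."""

    seed: int = 0
    n_genes: int = 60
    n_lncrna: int = 30
    n_samples_per_group: int = 30
    nb_dispersion: float = 0.1
    planted_fc: float = 2.0
    frac_det: float = 0.1
    n_pathways: int = 10
    regulator_strength: float = 0.8
    n_cis_pairs: int = 4
    n_trans_pairs: int = 4
    psi_shift: float = 0.3
    n_event_genes_per_type: int = 2
    n_null_events: int = 60
    junction_depth: float = 50.0
    protein_substitution_rate: float = 0.05
    n_decoys: int = 20

    def validate(self) -> None:
        positive = (
            "n_genes", "n_lncrna", "n_samples_per_group", "n_pathways",
            "n_event_genes_per_type",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("frac_det",):
            if not (0 < getattr(self, name) < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if not (0 <= self.psi_shift < 1):
            raise ValueError("psi_shift must lie in [0, 1)")
        if self.nb_dispersion <= 0 or self.planted_fc <= 0:
            raise ValueError("nb_dispersion and planted_fc must be positive")
        if min(self.n_cis_pairs, self.n_trans_pairs, self.n_null_events, self.n_decoys) < 0:
            raise ValueError("pair/decoy counts must be non-negative")


@dataclass
class GroundTruth:
    true_lncrna_ids: List[str] = field(default_factory=list)
    true_class_codes: Dict[str, str] = field(default_factory=dict)
    true_categories: Dict[str, str] = field(default_factory=dict)
    true_det_ids: Dict[str, List[str]] = field(default_factory=dict)
    true_regulator_pairs: List[dict] = field(default_factory=list)
    true_events: List[dict] = field(default_factory=list)
    true_trans_windows: List[dict] = field(default_factory=list)
    true_protein_of: Dict[str, str] = field(default_factory=dict)
    coding_transcript_ids: List[str] = field(default_factory=list)
    pathway_sets: Dict[str, List[str]] = field(default_factory=dict)  # gene ids

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# --- low-level helpers -------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    codons = rng.choice(len(_CODONS), size=n_codons, p=_CODON_P)
    stop = _STOP_CODONS[rng.integers(0, 3)]
    return "ATG" + "".join(_CODONS[i] for i in codons) + stop


def _partition(rng: np.random.Generator, total: int, parts: int, minimum: int) -> List[int]:
    extra = total - parts * minimum
    if extra < 0:
        raise ValueError("genome too small to place requested features")
    add = rng.multinomial(extra, [1.0 / parts] * parts)
    return [minimum + int(a) for a in add]


def _map_to_genomic(
    exons: Sequence[Tuple[int, int]], lo: int, hi: int
) -> List[Tuple[int, int]]:
    """Map the mRNA interval [lo, hi) through exon blocks to genomic pieces."""
    out = []
    offset = 0
    for s, e in exons:
        length = e - s
        a, b = max(lo, offset), min(hi, offset + length)
        if a < b:
            out.append((s + a - offset, s + b - offset))
        offset += length
    return out


@dataclass
class _GeneBuild:
    gene_id: str
    isoforms: List[TranscriptModel]
    orf_seq: str
    orf_genomic: List[Tuple[int, int]]  # where to write the ORF
    end: int  # genomic end of the gene span
    u5: int = 0  # 5'UTR length (ORF offset in the mature transcript)


def _build_regular_gene(
    rng: np.random.Generator, gene_id: str, start: int, role: Optional[str]
) -> _GeneBuild:
    u5 = int(rng.integers(30, 61))
    orf_len = 3 * int(rng.integers(100, 181)) + 6
    if role == "x_host":
        utr3, tail = 340, [150, 160]
    elif role == "o_host":
        utr3, tail = 300, [250]
    else:
        utr3, tail = int(rng.integers(80, 181)), []
    mrna_len = u5 + orf_len + utr3
    head = mrna_len - sum(tail)
    exon_lens = _partition(rng, head, int(rng.integers(2, 4)), 110) + tail
    intron_lens = [int(rng.integers(250, 601)) for _ in range(len(exon_lens) - 1)]
    if role == "i_host":
        intron_lens[0] = 1700

    exons = []
    pos = start
    for i, elen in enumerate(exon_lens):
        exons.append((pos, pos + elen))
        pos += elen + (intron_lens[i] if i < len(intron_lens) else 0)
    orf = _random_orf(rng, (orf_len - 6) // 3)
    cds_genomic = _map_to_genomic(exons, u5, u5 + orf_len)
    tx = TranscriptModel(
        transcript_id=f"{gene_id}.T1",
        gene_id=gene_id,
        exons=tuple(GenomicInterval(CHROM, s, e, "+") for s, e in exons),
        cds=tuple(GenomicInterval(CHROM, s, e, "+") for s, e in cds_genomic),
        biotype_label="protein_coding",
    )
    return _GeneBuild(gene_id, [tx], orf, cds_genomic, exons[-1][1], u5)


def _build_event_gene(
    rng: np.random.Generator, gene_id: str, start: int, etype: str
) -> _GeneBuild:
    u5 = int(rng.integers(30, 61))
    orf_len = 3 * int(rng.integers(100, 161)) + 6
    L1 = u5 + orf_len + 50  # exon 1 holds the whole ORF plus a bit of 3'UTR
    g = start
    e1 = (g, g + L1)
    b = g + L1

    def tx(tid_suffix: str, exons: Sequence[Tuple[int, int]], with_cds: bool) -> TranscriptModel:
        return TranscriptModel(
            transcript_id=f"{gene_id}.{tid_suffix}",
            gene_id=gene_id,
            exons=tuple(GenomicInterval(CHROM, s, e, "+") for s, e in exons),
            cds=(
                (GenomicInterval(CHROM, g + u5, g + u5 + orf_len, "+"),)
                if with_cds
                else None
            ),
            biotype_label="protein_coding",
        )

    if etype == "SE":
        e2 = (b + 300, b + 420)
        e3 = (b + 720, b + 870)
        iso = [tx("T1", [e1, e2, e3], True), tx("T2", [e1, e3], False)]
        end = e3[1]
    elif etype == "A5SS":
        e1x = (g, b + 60)
        e2 = (b + 400, b + 550)
        iso = [tx("T1", [e1, e2], True), tx("T2", [e1x, e2], False)]
        end = e2[1]
    elif etype == "A3SS":
        e2a = (b + 300, b + 520)
        e2b = (b + 360, b + 520)
        iso = [tx("T1", [e1, e2a], True), tx("T2", [e1, e2b], False)]
        end = e2a[1]
    elif etype == "MXE":
        m1 = (b + 300, b + 420)
        m2 = (b + 600, b + 720)
        e4 = (b + 900, b + 1050)
        iso = [tx("T1", [e1, m1, e4], True), tx("T2", [e1, m2, e4], False)]
        end = e4[1]
    elif etype == "RI":
        e2 = (b + 300, b + 450)
        e3 = (b + 750, b + 900)
        e23 = (b + 300, b + 900)
        iso = [tx("T1", [e1, e2, e3], True), tx("T2", [e1, e23], False)]
        end = e3[1]
    else:
        raise ValueError(f"unknown event type {etype!r}")

    orf = _random_orf(rng, (orf_len - 6) // 3)
    return _GeneBuild(gene_id, iso, orf, [(g + u5, g + u5 + orf_len)], end, u5)


# --- annotation --------------------------------------------------------------

def simulate_annotation(
    config: SimConfig,
) -> Tuple[Dict[str, str], AnnotationCatalog, GroundTruth]:
    """Generate genome, transcript catalog and the locational ground truth."""
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    truth = GroundTruth()

    n_event = config.n_event_genes_per_type * len(EVENT_TYPES)
    if config.n_genes <= n_event:
        raise ValueError("genome too small: n_genes must exceed the event genes")

    # lncRNA class plan: cycle u, i, o, x
    classes = [("u", "i", "o", "x")[i % 4] for i in range(config.n_lncrna)]
    n_u = classes.count("u")
    n_i, n_o, n_x = classes.count("i"), classes.count("o"), classes.count("x")
    if config.n_cis_pairs + config.n_trans_pairs > n_u:
        raise ValueError(
            "genome too small: not enough intergenic lncRNAs for the requested "
            "cis/trans regulator pairs"
        )

    n_regular = config.n_genes - n_event
    if config.n_cis_pairs + config.n_trans_pairs + n_i + n_x + n_o > n_regular:
        raise ValueError("genome too small: not enough coding genes for host roles")

    # roles for regular genes (after the cis/trans target genes)
    roles: List[Optional[str]] = [None] * n_regular
    cursor_role = config.n_cis_pairs + config.n_trans_pairs
    for count, role in ((n_i, "i_host"), (n_x, "x_host"), (n_o, "o_host")):
        for _ in range(count):
            roles[cursor_role] = role
            cursor_role += 1

    # --- lay out genes left to right ---
    builds: List[_GeneBuild] = []
    gap_after: List[Tuple[int, int]] = []  # gap interval after gene i
    pos = 2000
    event_plan = [
        (etype, rep)
        for etype in EVENT_TYPES
        for rep in range(config.n_event_genes_per_type)
    ]
    regular_ids: List[str] = []
    for gi in range(config.n_genes):
        gene_id = f"G{gi + 1:04d}"
        if gi < n_event:
            etype, _rep = event_plan[gi]
            build = _build_event_gene(rng, gene_id, pos, etype)
            truth.true_events.append(
                {
                    "event_id": f"{etype}:{gene_id}",
                    "gene_id": gene_id,
                    "type": etype,
                    "delta_psi": config.psi_shift,
                }
            )
        else:
            build = _build_regular_gene(rng, gene_id, pos, roles[gi - n_event])
            regular_ids.append(gene_id)
        builds.append(build)
        gap = int(rng.integers(3000, 6001))
        gap_after.append((build.end, build.end + gap))
        pos = build.end + gap
    genome_len = pos + 2000

    # pathway membership: round-robin over regular genes
    pathways: Dict[str, List[str]] = {
        f"PW{p + 1:02d}": regular_ids[p::config.n_pathways]
        for p in range(config.n_pathways)
    }
    truth.pathway_sets = {k: v for k, v in pathways.items() if len(v) >= 2}

    # --- genome background + coding ORFs ---
    bases = np.array(list("ACGT"))
    genome_arr = bases[rng.integers(0, 4, size=genome_len)]

    def write_orf(build: _GeneBuild) -> None:
        offset = 0
        for s, e in build.orf_genomic:
            genome_arr[s:e] = list(build.orf_seq[offset:offset + (e - s)])
            offset += e - s

    for build in builds:
        write_orf(build)

    # guarantee the annotated ORF is the transcript's longest (as in real
    # coding genes, where shifted frames are stop-rich); redraw ORFs whose
    # GC-biased sequence happens to contain a longer spurious frame
    from .lncrna_discovery import find_longest_orf

    for build in builds:
        t1 = build.isoforms[0]
        orf_len = len(build.orf_seq)
        for _attempt in range(40):
            spliced = "".join(
                "".join(genome_arr[e.start:e.end]) for e in t1.exons
            )
            found = find_longest_orf(spliced)
            if found and found[1] == build.u5 + orf_len and found[0] <= build.u5:
                break
            build.orf_seq = _random_orf(rng, (orf_len - 6) // 3)
            write_orf(build)
        else:
            raise ValueError(f"could not plant a dominant ORF for {build.gene_id}")

    catalog = AnnotationCatalog()
    for build in builds:
        for t in build.isoforms:
            catalog.add(t)
            truth.coding_transcript_ids.append(t.transcript_id)

    # --- place lncRNAs ---
    gene_index = {b.gene_id: i for i, b in enumerate(builds)}
    host_cycle = {
        "i": [n_event + i for i, r in enumerate(roles) if r == "i_host"],
        "o": [n_event + i for i, r in enumerate(roles) if r == "o_host"],
        "x": [n_event + i for i, r in enumerate(roles) if r == "x_host"],
    }
    used_gaps: set = set()
    u_specs: List[Tuple[int, str]] = []  # (lncRNA index, mode) for gap placement
    u_seen = 0
    for li, cls in enumerate(classes):
        if cls != "u":
            continue
        if u_seen < config.n_cis_pairs:
            u_specs.append((li, "cis"))
        elif u_seen < config.n_cis_pairs + config.n_trans_pairs:
            u_specs.append((li, "trans"))
        else:
            u_specs.append((li, "plain"))
        u_seen += 1

    # pre-assign gaps for the u-type lncRNAs
    gap_of_u: Dict[int, int] = {}
    trans_rank = 0
    plain_gaps = iter(range(n_event, config.n_genes))
    n_cis_seen = 0
    for li, mode in u_specs:
        if mode == "cis":
            gidx = gene_index[regular_ids[n_cis_seen]]
            n_cis_seen += 1
        elif mode == "trans":
            gidx = config.n_genes - 1 - trans_rank
            trans_rank += 1
        else:
            gidx = next(g for g in plain_gaps if g not in used_gaps)
        if gidx in used_gaps:
            raise ValueError("genome too small: gap collision while placing lncRNAs")
        used_gaps.add(gidx)
        gap_of_u[li] = gidx

    lnc_transcripts: List[TranscriptModel] = []
    trans_specs: List[Tuple[str, str]] = []  # (lncrna transcript id, target transcript id)
    regulator_specs: List[dict] = []
    host_ptr = {"i": 0, "o": 0, "x": 0}
    u_mode = dict(u_specs)
    n_trans_seen = 0
    n_cis_seen = 0

    for li, cls in enumerate(classes):
        lnc_gene = f"LNC{li + 1:04d}"
        tid = f"{lnc_gene}.T1"
        if cls == "u":
            gidx = gap_of_u[li]
            gs, ge = gap_after[gidx]
            anchor = gs + 800
            n_ex = int(rng.integers(2, 4))
            exon_lens = [int(rng.integers(120, 221)) for _ in range(n_ex)]
            intron_lens = [int(rng.integers(150, 351)) for _ in range(n_ex - 1)]
            if anchor + sum(exon_lens) + sum(intron_lens) > ge - 400:
                raise ValueError("genome too small: lncRNA does not fit its gap")
            exons = []
            p = anchor
            for i, elen in enumerate(exon_lens):
                exons.append(GenomicInterval(CHROM, p, p + elen, "+"))
                p += elen + (intron_lens[i] if i < n_ex - 1 else 0)
            strand = "+"
            category = "intergenic"
            mode = u_mode[li]
            if mode == "cis":
                target_gene = regular_ids[n_cis_seen]
                set_name = f"PW{n_cis_seen + 1:02d}"
                n_cis_seen += 1
                regulator_specs.append(
                    {
                        "lncrna_id": tid,
                        "set_name": set_name,
                        "mode": "cis",
                        "target_id": f"{target_gene}.T1",
                    }
                )
            elif mode == "trans":
                target_gene = regular_ids[config.n_cis_pairs + n_trans_seen]
                set_name = f"PW{config.n_cis_pairs + n_trans_seen + 1:02d}"
                n_trans_seen += 1
                regulator_specs.append(
                    {
                        "lncrna_id": tid,
                        "set_name": set_name,
                        "mode": "trans",
                        "target_id": f"{target_gene}.T1",
                    }
                )
                trans_specs.append((tid, f"{target_gene}.T1"))
        elif cls == "i":
            gidx = host_cycle["i"][host_ptr["i"]]
            host_ptr["i"] += 1
            host = builds[gidx].isoforms[0]
            intron = host.introns()[0]
            l1, l2 = int(rng.integers(120, 201)), int(rng.integers(120, 201))
            gap = int(rng.integers(200, 401))
            s = intron.start + 100
            if s + l1 + gap + l2 > intron.end - 100:
                raise ValueError("genome too small: host intron cannot hold lncRNA")
            exons = [
                GenomicInterval(CHROM, s, s + l1, "+"),
                GenomicInterval(CHROM, s + l1 + gap, s + l1 + gap + l2, "+"),
            ]
            strand, category = "+", "intronic"
        elif cls == "o":
            gidx = host_cycle["o"][host_ptr["o"]]
            host_ptr["o"] += 1
            host = builds[gidx].isoforms[0]
            ge_end = host.exons[-1].end
            exons = [
                GenomicInterval(CHROM, ge_end - 120, ge_end + 40, "-"),
                GenomicInterval(CHROM, ge_end + 240, ge_end + 400, "-"),
            ]
            strand, category = "-", "antisense"
        else:  # x
            gidx = host_cycle["x"][host_ptr["x"]]
            host_ptr["x"] += 1
            host = builds[gidx].isoforms[0]
            ea, eb = host.exons[-2], host.exons[-1]
            exons = [
                GenomicInterval(CHROM, ea.start + 15, ea.start + 135, "-"),
                GenomicInterval(CHROM, eb.start + 20, eb.start + 140, "-"),
            ]
            strand, category = "-", "antisense"

        lnc = TranscriptModel(
            transcript_id=tid,
            gene_id=lnc_gene,
            exons=tuple(exons),
            biotype_label="lncRNA",
        )
        lnc_transcripts.append(lnc)
        truth.true_lncrna_ids.append(tid)
        truth.true_class_codes[tid] = cls
        truth.true_categories[tid] = category

    # --- embed trans complementarity windows ---
    for lnc_tid, target_tid in trans_specs:
        target = catalog.transcripts[target_tid]
        lnc = next(t for t in lnc_transcripts if t.transcript_id == lnc_tid)
        if lnc.span.gap_to(target.span) <= 100_000:
            raise ValueError(
                "genome too small: planted trans target falls inside the cis window"
            )
        cds_start = target.cds[0].start if target.cds else target.exons[0].start
        window = "".join(genome_arr[cds_start + 9:cds_start + 34])  # 25 nt of ORF
        e0 = lnc.exons[0]
        emb = reverse_complement(window)
        genome_arr[e0.start + 20:e0.start + 20 + len(emb)] = list(emb)
        truth.true_trans_windows.append(
            {"lncrna_id": lnc_tid, "target_id": target_tid, "length": len(emb)}
        )
    genome = {CHROM: "".join(genome_arr)}

    for lnc in lnc_transcripts:
        catalog.add(lnc)
    truth.true_regulator_pairs = regulator_specs
    return genome, catalog, truth


def reference_catalog(catalog: AnnotationCatalog, truth: GroundTruth) -> AnnotationCatalog:
    """The reference annotation: the catalog without the planted lncRNAs."""
    keep = [tid for tid in catalog.transcripts if tid not in set(truth.true_lncrna_ids)]
    return catalog.subset(keep)


# --- expression --------------------------------------------------------------

def sample_table(config: SimConfig) -> Tuple[List[str], Dict[str, str]]:
    samples, groups = [], {}
    for group in ("normal", "MCI", "AD"):
        for i in range(config.n_samples_per_group):
            sid = f"{group}_{i + 1:02d}"
            samples.append(sid)
            groups[sid] = group
    return samples, groups


def simulate_expression(
    catalog: AnnotationCatalog, truth: GroundTruth, config: SimConfig
) -> Tuple[ExpressionMatrix, ExpressionMatrix]:
    """Counts (negative binomial) and TPM matrices with planted structure."""
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    samples, groups = sample_table(config)
    tids = list(catalog.transcripts)
    n_t, n_s = len(tids), len(samples)
    t_idx = {t: i for i, t in enumerate(tids)}

    base = np.exp(rng.normal(np.log(150.0), 1.0, size=n_t))

    # transcripts carrying a latent regulator factor (computed before the DET
    # draw: factor-loaded transcripts have inflated variance, so planting fold
    # changes on them would make the differential truth unrecoverable by design)
    gene_tx: Dict[str, List[str]] = {}
    for tid, t in catalog.transcripts.items():
        gene_tx.setdefault(t.gene_id, []).append(tid)
    loaded_ids: set = set()
    for pair in truth.true_regulator_pairs:
        loaded_ids.add(pair["lncrna_id"])
        for gene in truth.pathway_sets[pair["set_name"]]:
            loaded_ids.update(gene_tx[gene])

    # planted fold changes, drawn from factor-free transcripts
    n_det = max(1, round(config.frac_det * n_t))
    eligible = [i for i, tid in enumerate(tids) if tid not in loaded_ids]
    if len(eligible) < n_det:
        raise ValueError("not enough factor-free transcripts to plant DETs")
    det_ids = [tids[i] for i in rng.choice(eligible, size=n_det, replace=False)]
    third = max(1, n_det // 3)
    mci_only, ad_only, both = det_ids[:third], det_ids[third:2 * third], det_ids[2 * third:]
    truth.true_det_ids = {
        "MCI": sorted(mci_only + both),
        "AD": sorted(ad_only + both),
        "case": sorted(det_ids),
    }
    log_fc = np.zeros((n_t, n_s))
    group_arr = np.array([groups[s] for s in samples])
    for tid in mci_only + both:
        log_fc[t_idx[tid], group_arr == "MCI"] += np.log(config.planted_fc)
    for tid in ad_only + both:
        log_fc[t_idx[tid], group_arr == "AD"] += np.log(config.planted_fc)
    # latent-factor co-expression for planted regulator pairs
    for pair in truth.true_regulator_pairs:
        f = rng.normal(0.0, 1.0, size=n_s)
        loaded = [pair["lncrna_id"]]
        for gene in truth.pathway_sets[pair["set_name"]]:
            loaded.extend(gene_tx[gene])
        for tid in loaded:
            log_fc[t_idx[tid]] += config.regulator_strength * f

    mu = base[:, None] * np.exp(log_fc)
    r = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu)).astype(float)

    lengths = np.array([catalog.transcripts[t].length() for t in tids], dtype=float)
    rate = counts / lengths[:, None]
    tpm = rate / rate.sum(axis=0, keepdims=True) * 1e6

    counts_df = pd.DataFrame(counts, index=tids, columns=samples)
    tpm_df = pd.DataFrame(tpm, index=tids, columns=samples)
    return (
        ExpressionMatrix(values=counts_df, unit="counts", groups=groups),
        ExpressionMatrix(values=tpm_df, unit="TPM", groups=groups),
    )


# --- junction counts ---------------------------------------------------------

def simulate_junction_counts(truth: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """Long-format inclusion/skipping junction counts per event and sample.

    Planted events (from the truth) shift PSI by ``psi_shift`` in the MCI and
    AD groups; ``n_null_events`` additional events have identical PSI in all
    groups.  A zero-depth sample yields 0/0 counts (PSI undefined downstream).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 3])
    samples, groups = sample_table(config)

    events = [
        (e["event_id"], e["type"], config.psi_shift) for e in truth.true_events
    ]
    events += [(f"null_{i + 1:03d}", "null", 0.0) for i in range(config.n_null_events)]

    rows = []
    for event_id, etype, shift in events:
        l_i, l_s = _FORM_LENGTHS[etype]
        psi0 = float(rng.uniform(0.35, 0.65))
        for sid in samples:
            psi = psi0 if groups[sid] == "normal" else min(psi0 + shift, 0.98)
            total = int(rng.poisson(config.junction_depth))
            pr = psi * l_i / (psi * l_i + (1 - psi) * l_s)
            inc = int(rng.binomial(total, pr)) if total > 0 else 0
            rows.append(
                {
                    "event_id": event_id,
                    "sample_id": sid,
                    "inclusion_count": inc,
                    "skipping_count": total - inc,
                    "inclusion_len": l_i,
                    "skipping_len": l_s,
                }
            )
    return pd.DataFrame(rows)


# --- protein database --------------------------------------------------------

def cds_sequence(transcript: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Spliced CDS sequence of a coding transcript (forward-strand genes)."""
    if not transcript.cds:
        raise ValueError(f"{transcript.transcript_id} has no CDS")
    chrom = genome[transcript.seq_id]
    seq = "".join(chrom[c.start:c.end] for c in transcript.cds)
    if transcript.oriented_strand() == "-":
        seq = reverse_complement(seq)
    return seq


_CODON_AA = None


def _translate(cds: str) -> str:
    global _CODON_AA
    if _CODON_AA is None:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_AA = dict(standard_dna_table.forward_table)
    return "".join(
        _CODON_AA.get(cds[i:i + 3], "X") for i in range(0, len(cds) - 3 + 1, 3)
        if cds[i:i + 3] not in _STOP_CODONS
    )


def simulate_protein_db(
    catalog: AnnotationCatalog,
    genome: Mapping[str, str],
    truth: GroundTruth,
    config: SimConfig,
) -> Dict[str, str]:
    """One protein per coding gene (CDS translation with point substitutions)
    plus shuffled decoys; records the transcript -> protein truth map."""
    config.validate()
    rng = np.random.default_rng([config.seed, 4])
    proteins: Dict[str, str] = {}
    reals: List[str] = []
    for tid, t in catalog.transcripts.items():
        if not t.cds:
            continue
        pep = list(_translate(cds_sequence(t, genome)))
        for i in range(len(pep)):
            if rng.random() < config.protein_substitution_rate:
                choices = _AA.replace(pep[i], "")
                pep[i] = choices[rng.integers(0, len(choices))]
        pid = f"P_{tid}"
        proteins[pid] = "".join(pep)
        reals.append(pid)
        truth.true_protein_of[tid] = pid
    for i in range(config.n_decoys):
        src = proteins[reals[int(rng.integers(0, len(reals)))]]
        shuffled = "".join(np.array(list(src))[rng.permutation(len(src))])
        proteins[f"DECOY_{i + 1:03d}"] = shuffled
    return proteins


# --- orchestration -----------------------------------------------------------

@dataclass
class SimulatedStudy:
    config: SimConfig
    genome: Dict[str, str]
    catalog: AnnotationCatalog
    truth: GroundTruth
    counts: ExpressionMatrix
    tpm: ExpressionMatrix
    junctions: pd.DataFrame
    proteins: Dict[str, str]
    pathways: GeneSetCollection
    groups: Dict[str, str]


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Run the full generator: annotation, expression, junctions, proteins."""
    genome, catalog, truth = simulate_annotation(config)
    counts, tpm = simulate_expression(catalog, truth, config)
    junctions = simulate_junction_counts(truth, config)
    proteins = simulate_protein_db(catalog, genome, truth, config)
    _samples, groups = sample_table(config)
    return SimulatedStudy(
        config=config,
        genome=genome,
        catalog=catalog,
        truth=truth,
        counts=counts,
        tpm=tpm,
        junctions=junctions,
        proteins=proteins,
        pathways=GeneSetCollection(sets=dict(truth.pathway_sets)),
        groups=groups,
    )


def write_study(study: SimulatedStudy, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    write_fasta(study.genome, os.path.join(outdir, "genome.fa"))
    write_gtf(study.catalog, os.path.join(outdir, "annotation.gtf"))
    write_matrix(study.counts, os.path.join(outdir, "counts.tsv"))
    write_matrix(study.tpm, os.path.join(outdir, "tpm.tsv"))
    study.junctions.to_csv(os.path.join(outdir, "junctions.tsv"), sep="\t", index=False)
    write_fasta(study.proteins, os.path.join(outdir, "proteins.fa"))
    write_gmt(study.pathways, os.path.join(outdir, "pathways.gmt"))
    write_groups(study.groups, os.path.join(outdir, "groups.tsv"))
    study.truth.to_json(os.path.join(outdir, "truth.json"))


def training_sequences(
    study: SimulatedStudy,
) -> Tuple[List[str], List[str], List[str]]:
    """(CDS seqs, coding transcript seqs, lncRNA transcript seqs) for scorer
    calibration on a training-split study."""
    cds_seqs, coding_tx, noncoding_tx = [], [], []
    lnc = set(study.truth.true_lncrna_ids)
    for tid, t in study.catalog.transcripts.items():
        seq = t.spliced_sequence(study.genome)
        if tid in lnc:
            noncoding_tx.append(seq)
        else:
            coding_tx.append(seq)
            if t.cds:
                cds_seqs.append(cds_sequence(t, study.genome))
    return cds_seqs, coding_tx, noncoding_tx
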