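"""LncRNA -> pathway regulator inference.

The chain: for each pathway (gene set), principal components of its member
genes' expression are computed and the smallest number of PCs explaining at
least 60% of the variance is retained; each lncRNA's expression is regressed
(OLS) on those PCs; a lncRNA is called a regulator of the pathway when the
fit is strong (R^2 >= threshold, BH-adjusted F-test p < 0.05) *and* the
lncRNA has at least one predicted cis or trans target gene inside the
pathway.  Cis targets are co-expressed genes within 100 kb (inclusive, gap
distance between spans, strand-agnostic); trans targets are distant genes
with a hybridization energy below -10 kcal/mol (strict) from an ungapped
nearest-neighbor duplex scan, again co-expressed.  Co-expression means
Spearman |r| > 0 with BH-adjusted p < 0.05, one BH family per evidence type.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from ._tables import NN_STACK
from .expression_stats import bh_adjust
from .io_formats import (
    AnnotationCatalog,
    ExpressionMatrix,
    TranscriptModel,
    reverse_complement,
)

CIS_WINDOW = 100_000
ENERGY_CUTOFF = -10.0
R2_THRESHOLD = 0.6
VAR_THRESHOLD = 0.60
_EPS = 1e-12


# --- pathway principal components -------------------------------------------

@dataclass
class PathwayPCs:
    set_name: str
    component_vectors: np.ndarray  # samples x k PC scores
    explained_fractions: List[float]  # all components, non-increasing
    k: int
    sample_ids: List[str] = field(default_factory=list)


def select_k(explained_fractions: Sequence[float], var_threshold: float = VAR_THRESHOLD) -> int:
    """Smallest k with cumulative explained fraction >= threshold (inclusive)."""
    cum = 0.0
    for k, frac in enumerate(explained_fractions, start=1):
        cum += frac
        if cum >= var_threshold - _EPS:
            return k
    return len(explained_fractions)


def compute_pathway_pcs(
    matrix: ExpressionMatrix,
    gene_set: Sequence[str],
    var_threshold: float = VAR_THRESHOLD,
    scale: bool = True,
    set_name: str = "",
) -> PathwayPCs:
    """PCA over samples of the set genes' expression rows.

    Genes are centered and (by default) unit-scaled, i.e. correlation-matrix
    PCA, so no single high-variance transcript dominates the components.
    Zero-variance genes are dropped with a warning.
    """
    present = [g for g in gene_set if g in matrix.values.index]
    if len(present) < 2:
        raise ValueError(
            f"gene set {set_name!r}: needs >= 2 genes present in the matrix"
        )
    X = matrix.values.loc[present].to_numpy(dtype=float).T  # samples x genes
    if X.shape[0] < 3:
        raise ValueError("PCA needs >= 3 samples")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"gene set {set_name!r}: dropping {int((~keep).sum())} zero-variance genes"
        )
        X, sd = X[:, keep], sd[keep]
        if X.shape[1] < 2:
            raise ValueError(f"gene set {set_name!r}: <2 non-constant genes")
    X = X - X.mean(axis=0)
    if scale:
        X = X / sd
    U, S, _Vt = np.linalg.svd(X, full_matrices=False)
    var = S ** 2
    fractions = (var / var.sum()).tolist()
    k = select_k(fractions, var_threshold)
    scores = U[:, :k] * S[:k]
    return PathwayPCs(
        set_name=set_name,
        component_vectors=scores,
        explained_fractions=fractions,
        k=k,
        sample_ids=matrix.sample_ids,
    )


# --- regression --------------------------------------------------------------

@dataclass
class RegressionFit:
    lncrna_id: str
    set_name: str
    betas: List[float]
    beta0: float  # |beta0| is a diagnostic; centering drives it to 0
    r_squared: float
    p_value: float  # overall F-test
    p_adj: float = math.nan


def fit_pc_regression(
    lncrna_expr: Sequence[float],
    pcs: PathwayPCs,
    lncrna_id: str = "",
) -> RegressionFit:
    """OLS of the (centered) lncRNA expression on the retained PCs.

    Response and predictors are mean-centered, which makes the intercept
    exactly zero; beta0 reports the residual offset as a diagnostic.  The
    p-value is the overall F-test of the k-predictor fit.
    """
    y = np.asarray(lncrna_expr, dtype=float)
    X = np.asarray(pcs.component_vectors, dtype=float)
    n, k = X.shape
    if y.shape[0] != n:
        raise ValueError("sample mismatch between expression vector and PCs")
    if n <= k + 1:
        raise ValueError("need n > k + 1 samples for the F-test")
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    if np.linalg.matrix_rank(Xc) < k:
        raise ValueError(f"rank-deficient PC matrix for set {pcs.set_name!r}")
    beta, _res, _rank, _sv = np.linalg.lstsq(Xc, yc, rcond=None)
    fitted = Xc @ beta
    rss = float(np.sum((yc - fitted) ** 2))
    tss = float(np.sum(yc ** 2))
    if tss == 0:
        raise ValueError("constant lncRNA expression vector")
    r2 = 1.0 - rss / tss
    df_num, df_den = k, n - k - 1
    if rss <= _EPS * tss:
        p = 0.0
    else:
        f_stat = (r2 / df_num) / ((1.0 - r2) / df_den)
        p = float(stats.f.sf(f_stat, df_num, df_den))
    return RegressionFit(
        lncrna_id=lncrna_id,
        set_name=pcs.set_name,
        betas=beta.tolist(),
        beta0=float(np.mean(yc - fitted)),
        r_squared=r2,
        p_value=p,
    )


def fit_all_regressions(
    matrix: ExpressionMatrix,
    lncrna_ids: Sequence[str],
    pathway_pcs: Sequence[PathwayPCs],
) -> List[RegressionFit]:
    """Every (lncRNA, pathway) fit, BH-adjusted as one pooled family."""
    fits = []
    for pcs in pathway_pcs:
        for lid in lncrna_ids:
            fits.append(
                fit_pc_regression(matrix.values.loc[lid].to_numpy(), pcs, lncrna_id=lid)
            )
    for fit, adj in zip(fits, bh_adjust([f.p_value for f in fits])):
        fit.p_adj = adj
    return fits


# --- co-expression -----------------------------------------------------------

def spearman_coexpression(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Tie-aware Spearman correlation with a two-sided p-value.

    Constant input yields (nan, nan) with a warning; callers drop such pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ValueError("vectors must have equal length >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant vector: Spearman correlation undefined")
        return math.nan, math.nan
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


# --- cis targets -------------------------------------------------------------

@dataclass
class CisCandidate:
    lncrna_id: str
    target_id: str
    distance_bp: int
    spearman_r: float
    p_value: float
    p_adj: float = math.nan
    kept: bool = False


def cis_window_targets(
    lncrna: TranscriptModel,
    catalog: AnnotationCatalog,
    window: int = CIS_WINDOW,
) -> List[Tuple[str, int]]:
    """(transcript_id, gap distance) of other-gene transcripts within the
    window of the lncRNA span (inclusive; 0 means overlap)."""
    span = lncrna.span
    out = []
    # +1 keeps the query half-open while the gap rule itself is inclusive
    for tid in catalog.overlapping(span.seq_id, max(0, span.start - window), span.end + window + 1):
        t = catalog.transcripts[tid]
        if t.gene_id == lncrna.gene_id:
            continue
        d = span.gap_to(t.span)
        if d <= window:
            out.append((tid, d))
    return out


def predict_cis_targets(
    lncrna_ids: Sequence[str],
    catalog: AnnotationCatalog,
    matrix: ExpressionMatrix,
    window: int = CIS_WINDOW,
    alpha: float = 0.05,
) -> List[CisCandidate]:
    """Cis candidates for a batch of lncRNAs, one pooled BH family.

    A candidate is kept iff its gap distance is <= window (inclusive),
    |r| > 0 and BH-adjusted Spearman p < alpha.
    """
    candidates: List[CisCandidate] = []
    for lid in lncrna_ids:
        lnc = catalog.transcripts[lid]
        expr_l = matrix.values.loc[lid].to_numpy()
        for tid, dist in cis_window_targets(lnc, catalog, window):
            if tid not in matrix.values.index:
                continue
            r, p = spearman_coexpression(expr_l, matrix.values.loc[tid].to_numpy())
            if math.isnan(r):
                continue
            candidates.append(CisCandidate(lid, tid, dist, r, p))
    for cand, adj in zip(candidates, bh_adjust([c.p_value for c in candidates])):
        cand.p_adj = adj
        cand.kept = bool(adj < alpha and abs(cand.spearman_r) > 0)
    return candidates


# --- duplex energy -----------------------------------------------------------

@dataclass
class DuplexHit:
    lncrna_id: str
    target_id: str
    best_window: Tuple[int, int]  # [start, end) on the lncRNA
    energy: float  # kcal/mol; 0 means no duplex found


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_CODE.get(b, 4) for b in seq.upper()], dtype=np.int8)


def _scan_duplex(l_codes, comp_t, step):
    """Walk every anti-diagonal of the pairing matrix; return the
    minimum-energy complementary run as (energy, lnc_start, lnc_end)."""
    n_l, n_t = len(l_codes), len(comp_t)
    best = 0.0
    bs = be = 0
    for c in range(n_l + n_t - 1):
        i0 = c - n_t + 1
        if i0 < 0:
            i0 = 0
        i1 = c if c < n_l - 1 else n_l - 1
        run_len = 0
        energy = 0.0
        for i in range(i0, i1 + 1):
            j = c - i
            if l_codes[i] < 4 and comp_t[j] < 4 and l_codes[i] == comp_t[j]:
                if run_len > 0:
                    energy += step[i - 1]
                run_len += 1
                if run_len >= 2 and energy < best:
                    best = energy
                    bs = i - run_len + 1
                    be = i + 1
            else:
                run_len = 0
                energy = 0.0
    return best, bs, be


try:  # pragma: no cover - exercised when numba is installed
    from numba import njit

    _scan_duplex_fast = njit(cache=False)(_scan_duplex)
except ImportError:  # pragma: no cover
    _scan_duplex_fast = _scan_duplex


def duplex_energy(
    lncrna_seq: str,
    target_seq: str,
    table: Mapping[str, float] = NN_STACK,
    lncrna_id: str = "",
    target_id: str = "",
) -> DuplexHit:
    """Minimum-energy ungapped antiparallel duplex between two sequences.

    Every Watson–Crick-paired run (lncRNA base vs complement of target base,
    antiparallel; N never pairs) accumulates nearest-neighbor stacking
    energies from the 16-entry table; a mismatch terminates the run.  The
    hit with the lowest (most stable) energy is returned; sequences shorter
    than 12 nt, or pairs with no complementary run of >= 2 bases, return
    energy 0.
    """
    if len(lncrna_seq) < 12 or len(target_seq) < 12:
        return DuplexHit(lncrna_id, target_id, (0, 0), 0.0)
    l = _encode(lncrna_seq)
    t = _encode(target_seq)
    comp_t = np.where(t < 4, 3 - t, np.int8(4)).astype(np.int8)

    lup = lncrna_seq.upper()
    step = np.zeros(len(l), dtype=np.float64)  # step[i] = stack energy of l[i:i+2]
    for i in range(len(l) - 1):
        step[i] = table.get(lup[i:i + 2], 0.0)

    energy, bs, be = _scan_duplex_fast(l, comp_t, step)
    if energy >= 0.0:
        return DuplexHit(lncrna_id, target_id, (0, 0), 0.0)
    return DuplexHit(lncrna_id, target_id, (int(bs), int(be)), float(energy))


# --- trans targets -----------------------------------------------------------

@dataclass
class TransCandidate:
    lncrna_id: str
    target_id: str
    hit: DuplexHit
    spearman_r: float
    p_value: float
    p_adj: float = math.nan
    kept: bool = False


def predict_trans_targets(
    lncrna_ids: Sequence[str],
    catalog: AnnotationCatalog,
    genome: Mapping[str, str],
    matrix: ExpressionMatrix,
    energy_cutoff: float = ENERGY_CUTOFF,
    window: int = CIS_WINDOW,
    alpha: float = 0.05,
) -> List[TransCandidate]:
    """Trans candidates: duplex energy strictly below the cutoff plus
    co-expression; genes inside the cis window are excluded from trans
    testing.  One pooled BH family across all tested trans pairs."""
    seq_cache: Dict[str, str] = {}

    def seq_of(tid: str) -> str:
        if tid not in seq_cache:
            seq_cache[tid] = catalog.transcripts[tid].spliced_sequence(genome)
        return seq_cache[tid]

    candidates: List[TransCandidate] = []
    for lid in lncrna_ids:
        lnc = catalog.transcripts[lid]
        cis_ids = {tid for tid, _ in cis_window_targets(lnc, catalog, window)}
        expr_l = matrix.values.loc[lid].to_numpy()
        lseq = seq_of(lid)
        for tid, t in catalog.transcripts.items():
            if (
                tid == lid
                or t.gene_id == lnc.gene_id
                or tid in cis_ids
                or tid not in matrix.values.index
            ):
                continue
            hit = duplex_energy(lseq, seq_of(tid), lncrna_id=lid, target_id=tid)
            if hit.energy >= energy_cutoff:  # strict: energy must be < cutoff
                continue
            r, p = spearman_coexpression(expr_l, matrix.values.loc[tid].to_numpy())
            if math.isnan(r):
                continue
            candidates.append(TransCandidate(lid, tid, hit, r, p))
    for cand, adj in zip(candidates, bh_adjust([c.p_value for c in candidates])):
        cand.p_adj = adj
        cand.kept = bool(adj < alpha and abs(cand.spearman_r) > 0)
    return candidates


# --- regulator calls ---------------------------------------------------------

@dataclass
class RegulatorCall:
    lncrna_id: str
    set_name: str
    fit: RegressionFit
    supporting_targets: List[Tuple[str, str, float, float]]  # (target, mode, r, p_adj)
    called: bool


def call_pathway_regulators(
    fits: Sequence[RegressionFit],
    cis: Sequence[CisCandidate],
    trans: Sequence[TransCandidate],
    sets: Mapping[str, Sequence[str]],
    gene_of: Mapping[str, str],
    r2_threshold: float = R2_THRESHOLD,
    alpha: float = 0.05,
) -> List[RegulatorCall]:
    """Combine regression and target evidence into per-(lncRNA, pathway) calls.

    ``gene_of`` maps transcript ids to gene ids; gene sets list gene ids.
    Called iff R^2 >= r2_threshold, regression p_adj < alpha, and at least
    one kept cis/trans target of the lncRNA belongs to the pathway.
    """
    targets: Dict[str, List[Tuple[str, str, float, float]]] = {}
    for c in cis:
        if c.kept:
            targets.setdefault(c.lncrna_id, []).append(
                (c.target_id, "cis", c.spearman_r, c.p_adj)
            )
    for c in trans:
        if c.kept:
            targets.setdefault(c.lncrna_id, []).append(
                (c.target_id, "trans", c.spearman_r, c.p_adj)
            )

    calls = []
    for fit in fits:
        members = set(sets[fit.set_name])
        support = [
            t
            for t in targets.get(fit.lncrna_id, [])
            if gene_of.get(t[0], t[0]) in members
        ]
        called = bool(
            fit.r_squared >= r2_threshold and fit.p_adj < alpha and support
        )
        calls.append(
            RegulatorCall(
                lncrna_id=fit.lncrna_id,
                set_name=fit.set_name,
                fit=fit,
                supporting_targets=support,
                called=called,
            )
        )
    return calls


def infer_regulators(
    catalog: AnnotationCatalog,
    genome: Mapping[str, str],
    matrix: ExpressionMatrix,
    sets: Mapping[str, Sequence[str]],
    lncrna_ids: Sequence[str],
    r2_threshold: float = R2_THRESHOLD,
    energy_cutoff: float = ENERGY_CUTOFF,
    window: int = CIS_WINDOW,
    var_threshold: float = VAR_THRESHOLD,
) -> List[RegulatorCall]:
    """The full regulator-inference chain over a catalog and matrix."""
    gene_of = {tid: t.gene_id for tid, t in catalog.transcripts.items()}
    pcs = []
    for name, members in sets.items():
        tx_members = [
            tid for tid in matrix.values.index if gene_of.get(tid) in set(members)
        ]
        pcs.append(
            compute_pathway_pcs(matrix, tx_members, var_threshold, set_name=name)
        )
    fits = fit_all_regressions(matrix, lncrna_ids, pcs)
    cis = predict_cis_targets(lncrna_ids, catalog, matrix, window)
    trans = predict_trans_targets(
        lncrna_ids, catalog, genome, matrix, energy_cutoff, window
    )
    return call_pathway_regulators(
        fits, cis, trans, sets, gene_of, r2_threshold=r2_threshold
    )
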