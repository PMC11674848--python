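"""Differential-transcript filtering, FDR control, enrichment statistics.

The differential filter follows the study design: a transcript is a DET
(differentially expressed transcript) between two groups when
|log2 FC| >= log2(1.3), BH-adjusted p < 0.05 and at least one group mean is
>= 1 (transcripts whose normalized abundance is below 1 in both groups are
excluded before testing).  The per-transcript test is a two-sided rank-sum
test — a documented stand-in for a count-model engine, feeding the same
thresholds.

Also here: the Benjamini–Hochberg step-up, a single-sample gene-set
enrichment score (rank-weighted ECDF difference, ssGSEA-style) and
one-sided hypergeometric over-representation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .io_formats import ExpressionMatrix

FC_THRESHOLD = 1.3
ALPHA = 0.05
MIN_MEAN = 1.0


# --- Benjamini–Hochberg ------------------------------------------------------

def bh_adjust(p_values: Sequence[float]) -> List[float]:
    """Benjamini–Hochberg step-up adjusted p-values, order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


# --- normalization -----------------------------------------------------------

def size_factor_normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Median-of-ratios size-factor scaling of a raw count matrix.

    Per-sample factors are medians of each sample's ratios to the geometric-
    mean reference transcript, over transcripts expressed in every sample;
    robust to composition shifts that bias within-sample normalizations
    (a planted up-regulated minority deflates everything else in TPM).
    """
    if counts.unit != "counts":
        raise ValueError("size factors are defined for raw counts")
    values = counts.values.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no transcript expressed in every sample")
    log_ref = np.log(values[positive]).mean(axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(values[positive]) - log_ref, axis=0))
    scaled = counts.values / factors
    return ExpressionMatrix(values=scaled, unit="counts", groups=dict(counts.groups))


# --- DET filter --------------------------------------------------------------

@dataclass
class DETRecord:
    transcript_id: str
    mean_a: float
    mean_b: float
    fc: float  # linear fold change, group_b over group_a
    log2fc: float
    p_value: float  # NaN when excluded before testing
    p_adj: float
    is_det: bool
    biotype: str = "other"
    tested: bool = True


def is_det(
    log2fc: float,
    p_adj: float,
    mean_a: float,
    mean_b: float,
    fc_threshold: float = FC_THRESHOLD,
    alpha: float = ALPHA,
    min_mean: float = MIN_MEAN,
) -> bool:
    """The DET decision rule at its stated boundaries (FC inclusive, p strict)."""
    return (
        abs(log2fc) >= math.log2(fc_threshold)
        and p_adj < alpha
        and max(mean_a, mean_b) >= min_mean
    )


def _fold_change(mean_a: float, mean_b: float) -> Tuple[float, float]:
    if mean_a == 0 and mean_b == 0:
        return 1.0, 0.0
    if mean_a == 0:
        return math.inf, math.inf
    if mean_b == 0:
        return 0.0, -math.inf
    fc = mean_b / mean_a
    return fc, math.log2(fc)


def det_filter(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    biotypes: Optional[Mapping[str, str]] = None,
    fc_threshold: float = FC_THRESHOLD,
    alpha: float = ALPHA,
    min_mean: float = MIN_MEAN,
) -> List[DETRecord]:
    """Differential filter between two groups of a normalized matrix.

    Transcripts with both group means below ``min_mean`` are excluded before
    testing (p set to NaN); BH adjustment runs across tested transcripts
    only.  Fold change is mean(group_b) / mean(group_a).
    """
    cols_a = matrix.samples_in(group_a)
    cols_b = matrix.samples_in(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    va = matrix.values[cols_a].to_numpy()
    vb = matrix.values[cols_b].to_numpy()
    means_a = va.mean(axis=1)
    means_b = vb.mean(axis=1)

    tested_idx: List[int] = []
    raw_p: List[float] = []
    for i in range(len(matrix.values)):
        if means_a[i] < min_mean and means_b[i] < min_mean:
            continue
        tested_idx.append(i)
        if np.all(va[i] == va[i][0]) and np.all(vb[i] == va[i][0]):
            raw_p.append(1.0)
        else:
            raw_p.append(
                float(stats.mannwhitneyu(va[i], vb[i], alternative="two-sided").pvalue)
            )
    adj = dict(zip(tested_idx, bh_adjust(raw_p)))
    raw = dict(zip(tested_idx, raw_p))

    records = []
    for i, tid in enumerate(matrix.transcript_ids):
        fc, log2fc = _fold_change(means_a[i], means_b[i])
        tested = i in adj
        p = raw.get(i, math.nan)
        p_a = adj.get(i, math.nan)
        records.append(
            DETRecord(
                transcript_id=tid,
                mean_a=float(means_a[i]),
                mean_b=float(means_b[i]),
                fc=fc,
                log2fc=log2fc,
                p_value=p,
                p_adj=p_a,
                is_det=tested
                and is_det(log2fc, p_a, means_a[i], means_b[i], fc_threshold, alpha, min_mean),
                biotype=(biotypes or {}).get(tid, "other"),
                tested=tested,
            )
        )
    return records


def det_composition(dets: Sequence[DETRecord]) -> Dict[str, Tuple[int, float]]:
    """Biotype -> (count, fraction) over records flagged as DETs."""
    hits = [d for d in dets if d.is_det]
    if not hits:
        return {}
    tally: Dict[str, int] = {}
    for d in hits:
        tally[d.biotype] = tally.get(d.biotype, 0) + 1
    return {bt: (n, n / len(hits)) for bt, n in tally.items()}


# --- single-sample enrichment ------------------------------------------------

def ssgsea_score(
    expression: Mapping[str, float],
    gene_set: Sequence[str],
    exponent: float = 0.25,
) -> float:
    """Single-sample enrichment score of a gene set in one expression column.

    Genes are ranked by expression, descending (ties broken by id).  The
    statistic walks the ranked list accumulating a weighted in-set ECDF
    (weights = rank-score**exponent, rank-score n..1 from the top) against
    the unweighted out-of-set ECDF, sums the difference at every position,
    divides by the number of ranked genes, and centers by the analytic
    null expectation so a random set scores ~0.  Positive: set genes sit
    high in the ranking; negative: low.  Rank-based, hence invariant under
    strictly monotone transforms of the expression values.
    """
    ids = sorted(expression, key=lambda g: (-expression[g], g))
    n = len(ids)
    members = set(gene_set)
    in_set = np.array([g in members for g in ids])
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError("gene set shares no ids with the expression column")
    if n_in == n:
        raise ValueError("gene set covers every expressed gene (empty complement)")

    rank_score = np.arange(n, 0, -1, dtype=float)  # n at the top of the ranking
    weights = rank_score ** exponent
    cum_in = np.cumsum(np.where(in_set, weights, 0.0))
    ecdf_in = cum_in / cum_in[-1]
    cum_out = np.cumsum(~in_set)
    ecdf_out = cum_out / cum_out[-1]
    raw = float(np.sum(ecdf_in - ecdf_out)) / n

    # set-size-free null expectation of the weighted-vs-unweighted walk
    cum_all = np.cumsum(weights)
    null = float(np.sum(cum_all / cum_all[-1] - np.arange(1, n + 1) / n)) / n
    return raw - null


def ssgsea_matrix(
    matrix: ExpressionMatrix,
    sets: Mapping[str, Sequence[str]],
    exponent: float = 0.25,
):
    """Scores for every (gene set, sample) pair as a DataFrame (sets x samples)."""
    import pandas as pd

    data = {}
    for sample in matrix.sample_ids:
        column = matrix.values[sample].to_dict()
        data[sample] = {
            name: ssgsea_score(column, members, exponent)
            for name, members in sets.items()
        }
    return pd.DataFrame(data)


# --- over-representation -----------------------------------------------------

@dataclass
class OverRepResult:
    set_name: str
    k_hits: int
    K_set: int
    n_selected: int
    N_universe: int
    p_value: float
    p_adj: float = math.nan


def hypergeom_overrep(
    selected: Set[str], gene_set: Set[str], universe: Set[str], set_name: str = ""
) -> OverRepResult:
    """Upper-tail hypergeometric P(X >= k) for set over-representation."""
    if not universe:
        raise ValueError("empty universe")
    if not gene_set <= universe or not selected <= universe:
        raise ValueError("selected and gene_set must be subsets of the universe")
    N = len(universe)
    K = len(gene_set)
    n = len(selected)
    k = len(selected & gene_set)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return OverRepResult(set_name, k, K, n, N, min(p, 1.0))


def overrepresentation_table(
    selected: Set[str],
    sets: Mapping[str, Sequence[str]],
    universe: Set[str],
) -> List[OverRepResult]:
    """Over-representation of every set, BH-adjusted across the pooled family."""
    results = [
        hypergeom_overrep(selected, set(members) & universe, universe, name)
        for name, members in sets.items()
    ]
    for res, adj in zip(results, bh_adjust([r.p_value for r in results])):
        res.p_adj = adj
    return results
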