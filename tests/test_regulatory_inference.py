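import math

import numpy as np
import pandas as pd
import pytest

from adtrx._tables import NN_STACK
from adtrx.io_formats import (
    AnnotationCatalog,
    ExpressionMatrix,
    GenomicInterval,
    TranscriptModel,
    reverse_complement,
)
from adtrx.regulatory_inference import (
    PathwayPCs,
    RegressionFit,
    call_pathway_regulators,
    cis_window_targets,
    compute_pathway_pcs,
    duplex_energy,
    fit_pc_regression,
    predict_cis_targets,
    predict_trans_targets,
    select_k,
    spearman_coexpression,
)
from oracles import duplex_oracle, ols_oracle


class TestSelectK:
    @pytest.mark.parametrize(
        "fractions,expect",
        [
            ((0.6, 0.2, 0.2), 1),  # threshold reached exactly -> inclusive
            ((0.5, 0.3, 0.2), 2),
            ((0.1,) * 10, 6),  # equal fractions: 6/10 = 0.6 exactly
            ((0.9, 0.1), 1),
        ],
    )
    def test_minimal_k(self, fractions, expect):
        assert select_k(fractions) == expect


def _expr_matrix(data: np.ndarray, prefix="g"):
    n_t, n_s = data.shape
    groups = {f"s{i}": "normal" for i in range(n_s)}
    df = pd.DataFrame(data, index=[f"{prefix}{i}" for i in range(n_t)],
                      columns=list(groups))
    return ExpressionMatrix(values=df - df.min().min() + 1.0, unit="TPM", groups=groups)


class TestPathwayPcs:
    def test_fractions_match_eigendecomposition(self):
        rng = np.random.default_rng(1)
        data = rng.normal(10, 2, size=(6, 40))
        m = _expr_matrix(data)
        pcs = compute_pathway_pcs(m, m.transcript_ids, set_name="S")
        X = m.values.to_numpy().T
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        eigvals = np.sort(np.linalg.eigvalsh(X.T @ X))[::-1]
        assert pcs.explained_fractions == pytest.approx(
            (eigvals / eigvals.sum()).tolist(), abs=1e-9
        )

    def test_k_is_minimal(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            data = rng.normal(10, 2, size=(int(rng.integers(3, 9)), 30))
            pcs = compute_pathway_pcs(_expr_matrix(data), [f"g{i}" for i in range(data.shape[0])])
            cum = np.cumsum(pcs.explained_fractions)
            assert cum[pcs.k - 1] >= 0.60 - 1e-9
            if pcs.k > 1:
                assert cum[pcs.k - 2] < 0.60

    def test_shared_factor_needs_one_pc(self):
        rng = np.random.default_rng(3)
        f = rng.normal(size=50)
        data = np.vstack([5 + f + 0.1 * rng.normal(size=50) for _ in range(5)])
        pcs = compute_pathway_pcs(_expr_matrix(data), [f"g{i}" for i in range(5)])
        assert pcs.k == 1

    def test_errors(self):
        m = _expr_matrix(np.random.default_rng(0).normal(size=(1, 10)))
        with pytest.raises(ValueError, match=">= 2"):
            compute_pathway_pcs(m, ["g0"])
        m2 = _expr_matrix(np.vstack([np.zeros(10), np.zeros(10), np.arange(10.0)]))
        with pytest.warns(UserWarning, match="zero-variance"):
            with pytest.raises(ValueError):
                compute_pathway_pcs(m2, ["g0", "g1", "g2"])


class TestPcRegression:
    def _pcs(self, X):
        return PathwayPCs("S", X - X.mean(0), [0.7, 0.3][: X.shape[1]], X.shape[1])

    def test_perfect_fit(self):
        rng = np.random.default_rng(4)
        pc1 = rng.normal(size=30)[:, None]
        fit = fit_pc_regression(3.0 + 2.0 * pc1[:, 0], self._pcs(pc1))
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.beta0 == pytest.approx(0.0, abs=1e-10)
        assert fit.p_value == pytest.approx(0.0, abs=1e-30)

    def test_noise_has_near_zero_r2(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 2))
        fit = fit_pc_regression(rng.normal(size=200), self._pcs(X))
        assert fit.r_squared < 0.05
        assert fit.p_value > 0.05

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n, k = int(rng.integers(10, 60)), int(rng.integers(1, 4))
            X = rng.normal(size=(n, k))
            y = rng.normal(size=n)
            fit = fit_pc_regression(y, self._pcs(X))
            beta, r2 = ols_oracle(X, y)
            assert fit.betas == pytest.approx(beta.tolist())
            assert fit.r_squared == pytest.approx(r2)

    def test_errors(self):
        X = np.random.default_rng(7).normal(size=(4, 3))
        with pytest.raises(ValueError, match="n > k"):
            fit_pc_regression(np.ones(4) + np.arange(4), self._pcs(X))
        X2 = np.ones((20, 2))  # rank deficient after centering
        with pytest.raises(ValueError):
            fit_pc_regression(np.random.default_rng(8).normal(size=20), self._pcs(X2))


class TestSpearman:
    def test_exact_values(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert spearman_coexpression(x, x)[0] == pytest.approx(1.0)
        assert spearman_coexpression(x, [-v for v in x])[0] == pytest.approx(-1.0)
        # ranks (1,2,3,4) vs (1,2,4,3): 1 - 6*2/(4*15) = 0.8
        assert spearman_coexpression(x, [1.0, 2.0, 4.0, 3.0])[0] == pytest.approx(0.8)

    def test_constant_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            r, p = spearman_coexpression([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert math.isnan(r) and math.isnan(p)

    def test_length_check(self):
        with pytest.raises(ValueError):
            spearman_coexpression([1.0, 2.0], [1.0, 2.0])


def _two_gene_catalog(gap: int):
    """lncRNA span [0, 1000); target gene starting 'gap' bp after it."""
    lnc = TranscriptModel(
        "lnc", "LG",
        (GenomicInterval("c", 0, 400), GenomicInterval("c", 600, 1000)),
    )
    t = TranscriptModel(
        "tg", "TG",
        (GenomicInterval("c", 1000 + gap, 1400 + gap),
         GenomicInterval("c", 1600 + gap, 2000 + gap)),
    )
    return AnnotationCatalog([lnc, t])


class TestCisTargets:
    def _matrix(self, correlated: bool):
        rng = np.random.default_rng(9)
        base = rng.normal(10, 2, size=30)
        other = base + 0.2 * rng.normal(size=30) if correlated else rng.normal(10, 2, size=30)
        groups = {f"s{i}": "normal" for i in range(30)}
        df = pd.DataFrame([base, other], index=["lnc", "tg"], columns=list(groups))
        return ExpressionMatrix(values=df - df.min().min() + 1, unit="TPM", groups=groups)

    def test_window_boundary_inclusive(self):
        # gap_to measures span distance: exactly 100 kb is in, one more is out
        cat = _two_gene_catalog(100_000)
        assert [t for t, _ in cis_window_targets(cat.transcripts["lnc"], cat)] == ["tg"]
        cat2 = _two_gene_catalog(100_001)
        assert cis_window_targets(cat2.transcripts["lnc"], cat2) == []

    def test_correlated_neighbor_kept(self):
        cat = _two_gene_catalog(50_000)
        cands = predict_cis_targets(["lnc"], cat, self._matrix(True))
        assert len(cands) == 1 and cands[0].kept
        assert cands[0].distance_bp == 50_000

    def test_uncorrelated_neighbor_rejected(self):
        cat = _two_gene_catalog(50_000)
        cands = predict_cis_targets(["lnc"], cat, self._matrix(False))
        assert len(cands) == 1 and not cands[0].kept


class TestDuplexEnergy:
    def test_no_complement_no_hit(self):
        hit = duplex_energy("A" * 30, "A" * 30)  # A pairs T only
        assert hit.energy == 0.0

    def test_short_input_no_hit(self):
        assert duplex_energy("ACGTACGTACG", "ACGT" * 10).energy == 0.0

    def test_perfect_12mer_uniform_table(self):
        table = {a + b: -1.0 for a in "ACGT" for b in "ACGT"}
        target = "GGGGGG" + "ACGTTGCAAGCT" + "GGGGGG"
        lnc = "TTTTTT" + reverse_complement("ACGTTGCAAGCT") + "TTTTTT"
        hit = duplex_energy(lnc, target, table)
        assert hit.energy == pytest.approx(-11.0)  # 11 stacks at -1 each

    def test_matches_exhaustive_window_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            lnc = "".join(rng.choice(list("ACGT"), size=int(rng.integers(12, 80))))
            tgt = "".join(rng.choice(list("ACGT"), size=int(rng.integers(12, 80))))
            assert duplex_energy(lnc, tgt).energy == pytest.approx(
                duplex_oracle(lnc, tgt, NN_STACK)
            )

    def test_symmetric_under_strand_swap(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            lnc = "".join(rng.choice(list("ACGT"), size=40))
            tgt = "".join(rng.choice(list("ACGT"), size=40))
            assert duplex_energy(lnc, tgt).energy == pytest.approx(
                duplex_energy(tgt, lnc).energy
            )

    def test_n_never_pairs(self):
        # N opposite N (or anything) must not extend a run
        lnc = "ACGTACGTACGTN" + "ACGT"
        tgt = "ACGTN" + "ACGTACGTACGT"
        assert duplex_energy(lnc, tgt).energy == pytest.approx(
            duplex_oracle(lnc, tgt, NN_STACK)
        )


class TestTransTargets:
    def _setup(self, energy_cutoff):
        # two genes 200 kb apart; lncRNA carries a 20-nt complement of the target
        rng = np.random.default_rng(12)
        tgt_seq = "".join(rng.choice(list("ACGT"), size=400))
        window = tgt_seq[100:120]
        lnc_seq = (
            "".join(rng.choice(list("ACGT"), size=100))
            + reverse_complement(window)
            + "".join(rng.choice(list("ACGT"), size=100))
        )
        genome = {"c": lnc_seq + "T" * 200_000 + tgt_seq}
        lnc = TranscriptModel("lnc", "LG", (GenomicInterval("c", 0, len(lnc_seq)),))
        tgt = TranscriptModel(
            "tg", "TG",
            (GenomicInterval("c", len(lnc_seq) + 200_000, len(lnc_seq) + 200_000 + 400),),
        )
        catalog = AnnotationCatalog([lnc, tgt])
        base = rng.normal(10, 2, size=30)
        groups = {f"s{i}": "normal" for i in range(30)}
        df = pd.DataFrame(
            [base, base + 0.2 * rng.normal(size=30)],
            index=["lnc", "tg"], columns=list(groups),
        )
        matrix = ExpressionMatrix(values=df - df.min().min() + 1, unit="TPM", groups=groups)
        return predict_trans_targets(
            ["lnc"], catalog, genome, matrix, energy_cutoff=energy_cutoff
        )

    def test_planted_complement_recovered(self):
        cands = self._setup(-10.0)
        assert len(cands) == 1 and cands[0].kept
        assert cands[0].hit.energy < -10.0

    def test_energy_cutoff_is_strict(self):
        # with the cutoff set exactly at the best energy, the pair must drop
        energy = self._setup(-10.0)[0].hit.energy
        assert self._setup(energy) == []
        assert len(self._setup(energy + 1e-9)) == 1


def _fit(lnc, s, r2, p_adj):
    return RegressionFit(lnc, s, [1.0], 0.0, r2, p_adj / 2, p_adj)


class TestRegulatorCalls:
    def _support(self, kept=True):
        from adtrx.regulatory_inference import CisCandidate

        return CisCandidate("L1", "t1", 500, 0.8, 1e-4, 1e-3, kept)

    def test_called_requires_all_three_criteria(self):
        sets = {"S": ["g1"]}
        gene_of = {"t1": "g1", "t2": "g2"}
        calls = call_pathway_regulators(
            [_fit("L1", "S", 0.7, 0.01)], [self._support()], [], sets, gene_of
        )
        assert calls[0].called

        # same fit but the only target is outside the pathway
        from adtrx.regulatory_inference import CisCandidate

        outside = CisCandidate("L1", "t2", 500, 0.8, 1e-4, 1e-3, True)
        calls = call_pathway_regulators(
            [_fit("L1", "S", 0.7, 0.01)], [outside], [], sets, gene_of
        )
        assert not calls[0].called

        for bad_fit in (_fit("L1", "S", 0.5, 0.01), _fit("L1", "S", 0.7, 0.2)):
            calls = call_pathway_regulators(
                [bad_fit], [self._support()], [], sets, gene_of
            )
            assert not calls[0].called

    def test_monotone_in_evidence(self):
        from adtrx.regulatory_inference import CisCandidate

        sets = {"S": ["g1", "g3"]}
        gene_of = {"t1": "g1", "t3": "g3"}
        fit = _fit("L1", "S", 0.7, 0.01)
        base = call_pathway_regulators([fit], [self._support()], [], sets, gene_of)
        extra = CisCandidate("L1", "t3", 900, 0.7, 1e-4, 1e-3, True)
        more = call_pathway_regulators(
            [fit], [self._support(), extra], [], sets, gene_of
        )
        assert base[0].called and more[0].called  # adding evidence never un-calls

        # raising the threshold never adds calls
        strict = call_pathway_regulators(
            [fit], [self._support()], [], sets, gene_of, r2_threshold=0.8
        )
        assert not strict[0].called
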