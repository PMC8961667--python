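"""The five EMT metrics: oracle agreement, contracts, and the panel."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp, pearsonr

from emtmet.emt_scores import (
    EMT_METRICS,
    score_76gs,
    score_emt_panel,
    score_ks,
    score_singscore,
    score_ssgsea,
)
from emtmet.io import ExpressionMatrix
from emtmet.scorers import SsgseaScorer, signed_ks_statistic
from emtmet.signatures import GeneSignature

from oracles import gs76_oracle, signed_ks_oracle, singscore_oracle, ssgsea_es_oracle


def _matrix(values, genes, samples):
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), dataset_id="t"
    )


class TestGS76:
    def test_matches_spreadsheet_oracle(self):
        rng = np.random.default_rng(1)
        genes = ["CDH1", "G1", "G2", "G3"]
        frame = pd.DataFrame(
            rng.normal(8, 2, (4, 4)), index=genes, columns=["a", "b", "c", "d"]
        )
        matrix = ExpressionMatrix(frame, dataset_id="t")
        sig = GeneSignature("g76toy", ("CDH1", "G1", "G2", "G3"))
        scores = score_76gs(matrix, sig)
        expected = gs76_oracle(frame.T, sig.genes)
        np.testing.assert_allclose(scores.to_numpy(), expected, atol=1e-9)

    def test_cohort_mean_zero(self, sign_dataset, registry):
        matrix, _ = sign_dataset
        scores = score_76gs(matrix, registry.gs76)
        assert abs(scores.mean()) < 1e-9

    def test_identical_samples_error(self):
        frame = pd.DataFrame(
            np.ones((3, 4)) * 5.0, index=["CDH1", "G1", "G2"], columns=list("abcd")
        )
        with pytest.raises(ValueError, match="zero variance"):
            score_76gs(ExpressionMatrix(frame, dataset_id="t"), GeneSignature("s", ("CDH1", "G1")))

    def test_missing_cdh1_errors(self):
        frame = pd.DataFrame(
            np.random.default_rng(0).normal(size=(3, 4)),
            index=["G1", "G2", "G3"], columns=list("abcd"),
        )
        with pytest.raises(ValueError, match="CDH1"):
            score_76gs(ExpressionMatrix(frame, dataset_id="t"), GeneSignature("s", ("G1", "G2")))

    def test_two_samples_error(self):
        frame = pd.DataFrame(
            [[1.0, 2.0], [2.0, 1.0]], index=["CDH1", "G1"], columns=["a", "b"]
        )
        with pytest.raises(ValueError, match="3 samples"):
            score_76gs(ExpressionMatrix(frame, dataset_id="t"), GeneSignature("s", ("CDH1", "G1")))

    def test_gene_shift_invariance(self):
        """Adding a constant to one gene's expression leaves centered scores unchanged."""
        rng = np.random.default_rng(5)
        genes = ["CDH1", "G1", "G2"]
        frame = pd.DataFrame(rng.normal(8, 2, (3, 5)), index=genes, columns=list("abcde"))
        sig = GeneSignature("s", tuple(genes))
        base = score_76gs(ExpressionMatrix(frame, dataset_id="t"), sig)
        shifted = frame.copy()
        shifted.loc["G1"] += 11.5
        moved = score_76gs(ExpressionMatrix(shifted, dataset_id="t"), sig)
        np.testing.assert_allclose(base.to_numpy(), moved.to_numpy(), atol=1e-9)


class TestKS:
    def test_separated_distributions_score_one(self):
        matrix = _matrix(
            [[1.0, 1.0], [2.0, 2.0], [5.0, 5.0], [6.0, 6.0]],
            ["E1", "E2", "M1", "M2"], ["s1", "s2"],
        )
        scores = score_ks(
            matrix, GeneSignature("e", ("E1", "E2")), GeneSignature("m", ("M1", "M2"))
        )
        assert scores.loc["s1"] == 1.0

    def test_antisymmetry_under_swap(self, toy_matrix):
        epi = GeneSignature("e", ("CDH1", "G1", "G2"))
        mes = GeneSignature("m", ("G3", "G4", "G5"))
        forward = score_ks(toy_matrix, epi, mes)
        backward = score_ks(toy_matrix, mes, epi)
        np.testing.assert_allclose(forward.to_numpy(), -backward.to_numpy(), atol=1e-12)

    def test_matches_bruteforce_oracle_and_scipy(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            e = rng.normal(0, 1, rng.integers(2, 8))
            m = rng.normal(0.5, 1, rng.integers(2, 8))
            got = signed_ks_statistic(e, m)
            assert got == pytest.approx(signed_ks_oracle(e, m), abs=1e-9)
            if got != 0.0:
                assert abs(got) == pytest.approx(ks_2samp(m, e).statistic, abs=1e-12)
            else:
                # exact one-sided tie is scored 0 by convention
                up = ks_2samp(m, e, alternative="less").statistic
                down = ks_2samp(m, e, alternative="greater").statistic
                assert up == pytest.approx(down, abs=1e-12)

    def test_range(self, sign_dataset, registry):
        matrix, _ = sign_dataset
        epi, mes = registry.ks_pair("cellline")
        scores = score_ks(matrix, epi, mes)
        assert ((scores >= -1.0) & (scores <= 1.0)).all()


class TestSsgsea:
    def test_matches_running_sum_oracle(self):
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(6)]
        frame = pd.DataFrame(
            rng.normal(8, 2, (6, 3)), index=genes, columns=["a", "b", "c"]
        )
        matrix = ExpressionMatrix(frame, dataset_id="t")
        sig = GeneSignature("s", ("G0", "G3"))
        es = score_ssgsea(matrix, sig, alpha=0.25, normalize=False)
        for sample in ["a", "b", "c"]:
            expected = ssgsea_es_oracle(frame[sample].to_dict(), sig.genes, alpha=0.25)
            assert es.loc[sample] == pytest.approx(expected, abs=1e-9)

    def test_top_ranked_signature_beats_bottom_ranked(self):
        genes = [f"G{i}" for i in range(8)]
        top = np.concatenate([np.full(2, 10.0), np.full(6, 1.0)])
        bottom = np.concatenate([np.full(2, 1.0), np.full(6, 10.0)])
        matrix = _matrix(np.c_[top, bottom], genes, ["hi", "lo"])
        es = score_ssgsea(matrix, GeneSignature("s", ("G0", "G1")), normalize=False)
        assert es.loc["hi"] > es.loc["lo"]

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        genes = [f"G{i}" for i in range(10)]
        frame = pd.DataFrame(rng.normal(0, 1, (10, 3)), index=genes, columns=list("abc"))
        sig = GeneSignature("s", ("G1", "G4", "G7"))
        base = score_ssgsea(ExpressionMatrix(frame, dataset_id="t"), sig, normalize=False)
        cubed = frame.copy()
        cubed["b"] = cubed["b"] ** 3
        moved = score_ssgsea(ExpressionMatrix(cubed, dataset_id="t"), sig, normalize=False)
        np.testing.assert_allclose(base.to_numpy(), moved.to_numpy(), atol=1e-9)

    def test_signature_covering_all_genes_errors(self):
        matrix = _matrix([[1.0, 2.0], [3.0, 4.0]], ["G0", "G1"], ["a", "b"])
        with pytest.raises(ValueError, match="out-of-set"):
            score_ssgsea(matrix, GeneSignature("s", ("G0", "G1")))

    def test_cross_check_against_gseapy(self):
        """Independent reference implementation agrees on ES and NES."""
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(12)
        genes = [f"G{i:03d}" for i in range(50)]
        frame = pd.DataFrame(
            rng.normal(8, 2, (50, 8)), index=genes,
            columns=[f"s{j}" for j in range(8)],
        )
        sig = GeneSignature("SET", tuple(genes[:12]))
        matrix = ExpressionMatrix(frame, dataset_id="t")
        es_mine = score_ssgsea(matrix, sig, alpha=0.25, normalize=False)
        nes_mine = score_ssgsea(matrix, sig, alpha=0.25, normalize=True)
        res = gseapy.ssgsea(
            data=frame, gene_sets={"SET": list(sig.genes)}, outdir=None,
            sample_norm_method="rank", weight=0.25, min_size=2, threads=1, seed=0,
        ).res2d.set_index("Name")
        es_ref = res["ES"].astype(float).reindex(frame.columns)
        nes_ref = res["NES"].astype(float).reindex(frame.columns)
        np.testing.assert_allclose(es_mine.to_numpy(), es_ref.to_numpy(), rtol=1e-6)
        np.testing.assert_allclose(nes_mine.to_numpy(), nes_ref.to_numpy(), rtol=1e-6)


class TestSingscore:
    def test_analytic_extremes(self):
        genes = [f"G{i}" for i in range(7)]
        top = np.arange(7.0)[::-1]  # G0, G1 highest
        matrix = _matrix(np.c_[top, top[::-1]], genes, ["top", "bottom"])
        sig = GeneSignature("s", ("G0", "G1"))
        scores = score_singscore(matrix, sig)
        assert scores.loc["top"] == pytest.approx(1.0, abs=1e-12)
        assert scores.loc["bottom"] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_rank_oracle(self):
        rng = np.random.default_rng(8)
        genes = [f"G{i}" for i in range(9)]
        frame = pd.DataFrame(rng.normal(0, 1, (9, 4)), index=genes, columns=list("abcd"))
        sig = GeneSignature("s", ("G2", "G5", "G6"))
        scores = score_singscore(ExpressionMatrix(frame, dataset_id="t"), sig)
        for sample in "abcd":
            expected = singscore_oracle(frame[sample].to_dict(), sig.genes)
            assert scores.loc[sample] == pytest.approx(expected, abs=1e-9)

    def test_rank_monotonicity(self):
        """Raising a signature gene past one more background gene raises the score."""
        genes = ["S1", "B1", "B2", "B3"]
        low = _matrix([[2.0, 2.0], [3.0, 3.0], [4.0, 4.0], [5.0, 5.0]], genes, ["x", "y"])
        high = _matrix([[3.5, 3.5], [3.0, 3.0], [4.0, 4.0], [5.0, 5.0]], genes, ["x", "y"])
        sig = GeneSignature("s", ("S1", "B3"))
        assert score_singscore(high, sig).loc["x"] > score_singscore(low, sig).loc["x"]

    def test_signature_equal_to_universe_errors(self):
        matrix = _matrix([[1.0, 2.0], [3.0, 4.0]], ["G0", "G1"], ["a", "b"])
        with pytest.raises(ValueError, match="degenerate"):
            score_singscore(matrix, GeneSignature("s", ("G0", "G1")))


class TestEMTPanel:
    def test_all_five_metrics_on_complete_fixture(self, sign_dataset, registry):
        matrix, _ = sign_dataset
        table = score_emt_panel(matrix, registry)
        assert tuple(table.metrics) == EMT_METRICS

    def test_missing_cdh1_isolates_gs76(self, sign_dataset, registry):
        matrix, _ = sign_dataset
        reduced = ExpressionMatrix(
            matrix.values.drop(index="CDH1"), dataset_id="no_cdh1"
        )
        with pytest.warns(UserWarning, match="gs76"):
            table = score_emt_panel(reduced, registry)
        assert "gs76" not in table.metrics
        assert "ks" in table.metrics
        assert "missing" in table.metadata["gs76"]

    def test_epithelial_samples_rank_high_on_epithelial_metrics(self, sign_dataset, registry):
        matrix, truth = sign_dataset
        table = score_emt_panel(matrix, registry)
        most_epithelial = truth.phi.nsmallest(10).index
        for metric in ("gs76", "epithelial_singscore"):
            scores = table.metric(metric)
            assert (scores.loc[most_epithelial] > scores.median()).all()


class TestSignRecovery:
    """Sign conventions on a cohort with a known latent EMT axis."""

    def test_axis_correlations(self, sign_dataset, registry):
        matrix, truth = sign_dataset
        table = score_emt_panel(matrix, registry)
        phi = truth.phi
        expected_signs = {
            "ks": +1, "gs76": -1,
            "epithelial_singscore": -1, "mesenchymal_singscore": +1,
            "hallmark_emt_ssgsea": +1,
        }
        for metric, sign in expected_signs.items():
            r = pearsonr(table.metric(metric), phi).statistic
            assert np.sign(r) == sign, metric
            assert abs(r) >= 0.8, metric

    def test_ks_correlates_with_singscores_in_expected_directions(
        self, sign_dataset, registry
    ):
        matrix, _ = sign_dataset
        table = score_emt_panel(matrix, registry)
        ks = table.metric("ks")
        assert pearsonr(ks, table.metric("mesenchymal_singscore")).statistic > 0
        assert pearsonr(ks, table.metric("epithelial_singscore")).statistic < 0
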