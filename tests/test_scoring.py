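import numpy as np
import pandas as pd
import pytest

from braincomm import scoring
from braincomm.resources import LRPair
from braincomm.scoring import (
    CellTypeProfile,
    build_profiles,
    score_gated,
    score_hill,
    score_product,
    score_regularized,
    tukey_trimean,
)
from conftest import make_adata

PAIR = [LRPair(("L",), ("R",))]


def profile_from(mean, trimean=None, detect=None, mu=1.0, types=("A", "B")):
    """Hand-built two-type profile over genes L and R."""
    genes = ["L", "R"]
    mk = lambda d: pd.DataFrame(d, index=list(types), columns=genes, dtype=float)
    mean = mk(mean)
    return CellTypeProfile(
        mean=mean,
        trimean=mk(trimean) if trimean is not None else mean.copy(),
        detect=mk(detect) if detect is not None else pd.DataFrame(
            1.0, index=list(types), columns=genes),
        n_cells=pd.Series(10, index=list(types)),
        mu=mu,
    )


class TestBuildProfiles:
    def test_summaries(self):
        counts = np.array([[1.0, 0], [2.0, 0], [3.0, 1]])
        adata = make_adata(counts)
        adata.uns["normalized"] = True
        adata.obs["cell_type"] = ["neurons"] * 3
        p = build_profiles(adata)
        assert p.mean.loc["neurons", "g0"] == pytest.approx(2.0)
        assert p.detect.loc["neurons", "g1"] == pytest.approx(1 / 3)
        assert p.mu == pytest.approx(counts.mean())

    def test_trimean_quartile_interpolation(self):
        # 9 values 0..8: (Q1 + 2*Q2 + Q3) / 4 = (2 + 8 + 6) / 4 = 4
        assert tukey_trimean(np.arange(9.0)) == pytest.approx(4.0)

    def test_small_types_excluded_with_warning(self, caplog):
        adata = make_adata(np.ones((5, 2)))
        adata.uns["normalized"] = True
        adata.obs["cell_type"] = ["neurons"] * 4 + ["microglia"]
        with caplog.at_level("WARNING"):
            p = build_profiles(adata)
        assert p.cell_types == ["neurons"]
        assert "excluding" in caplog.text

    def test_other_cells_excluded(self, annotated_adata):
        sub = annotated_adata[:30].copy()
        sub.obs["cell_type"] = ["neurons"] * 20 + ["other cells"] * 10
        assert build_profiles(sub).cell_types == ["neurons"]


class TestScoreHill:
    def test_half_saturation_and_zero(self):
        p = profile_from(mean=[[1, 1], [1, 1]],
                         trimean=[[np.sqrt(0.5), np.sqrt(0.5)], [0, 0]])
        s = score_hill(p, PAIR).scores
        assert s[("L_R", "A", "A")] == pytest.approx(0.5)  # l*r = 0.5
        assert s[("L_R", "B", "B")] == 0.0

    def test_saturates_monotonically(self):
        vals = []
        for lr in (1.0, 10.0, 100.0):
            p = profile_from(mean=[[1, 1], [1, 1]],
                             trimean=[[lr, 1.0], [0, 0]])
            vals.append(score_hill(p, PAIR).scores[("L_R", "A", "A")])
        assert vals == sorted(vals) and vals[-1] < 1.0


class TestScoreRegularized:
    def test_mu_fixed_point(self):
        p = profile_from(mean=[[2.0, 2.0], [0, 0]], mu=2.0)
        s = score_regularized(p, PAIR).scores
        assert s[("L_R", "A", "A")] == pytest.approx(0.5)
        assert s[("L_R", "B", "B")] == 0.0

    def test_monotone_in_ligand(self):
        prev = -1
        for l in (0.5, 1.0, 4.0):
            p = profile_from(mean=[[l, 1.0], [0, 0]], mu=1.0)
            v = score_regularized(p, PAIR).scores[("L_R", "A", "A")]
            assert v > prev
            prev = v

    def test_zero_matrix_rejected(self):
        p = profile_from(mean=[[0, 0], [0, 0]], mu=0.0)
        with pytest.raises(ValueError):
            score_regularized(p, PAIR)


class TestScoreProduct:
    def test_max_in_both_types_scores_100(self):
        p = profile_from(mean=[[5.0, 0.0], [0.0, 3.0]])
        s = score_product(p, PAIR).scores
        assert s[("L_R", "A", "B")] == pytest.approx(100.0)
        assert s[("L_R", "B", "A")] == 0.0

    def test_constant_nonzero_gene_scales_to_10(self):
        p = profile_from(mean=[[2.0, 2.0], [2.0, 2.0]])
        s = score_product(p, PAIR).scores
        assert np.allclose(s.values, 100.0)

    def test_zero_gene_scores_zero(self):
        p = profile_from(mean=[[0.0, 5.0], [0.0, 1.0]])
        assert (score_product(p, PAIR).scores == 0).all()

    def test_midscale_product(self):
        # scaled ligand 5 and receptor 2 -> score 10
        p = profile_from(mean=[[0.0, 0.0], [10.0, 10.0], [5.0, 2.0]],
                         types=("lo", "hi", "mid"))
        s = score_product(p, PAIR).scores
        assert s[("L_R", "mid", "mid")] == pytest.approx(10.0)


class TestScoreGated:
    def test_low_detection_is_absent(self):
        p = profile_from(mean=[[2.0, 2.0], [0.5, 0.5]],
                         detect=[[0.05, 0.9], [0.9, 0.9]])
        s = score_gated(p, PAIR).scores
        assert ("L_R", "A", "A") not in s.index  # ligand detected in 5% only

    def test_passing_product(self):
        p = profile_from(mean=[[2.0, 3.0], [0.5, 0.5]])
        s = score_gated(p, PAIR).scores
        assert s[("L_R", "A", "A")] == pytest.approx(6.0)

    def test_uniform_gene_never_passes(self):
        p = profile_from(mean=[[2.0, 2.0], [2.0, 2.0]])
        assert len(score_gated(p, PAIR).scores) == 0


class TestScorerContracts:
    @pytest.fixture(scope="class")
    def tables(self, annotated_adata, background_pairs):
        return scoring.score_all(annotated_adata, background_pairs, "sub1")

    def test_score_ranges(self, tables):
        assert ((tables["hill"].scores >= 0) & (tables["hill"].scores < 1)).all()
        assert ((tables["regularized"].scores >= 0) & (tables["regularized"].scores < 1)).all()
        assert ((tables["product"].scores >= 0) & (tables["product"].scores <= 100)).all()
        assert (tables["gated"].scores >= 0).all()

    def test_zero_ligand_propagates(self):
        # ligand zero in sender -> score 0 or absent for every scheme
        p = profile_from(mean=[[0.0, 2.0], [1.0, 1.0]], mu=1.0)
        assert score_hill(p, PAIR).scores[("L_R", "A", "A")] == 0.0
        assert score_regularized(p, PAIR).scores[("L_R", "A", "A")] == 0.0
        assert score_product(p, PAIR).scores[("L_R", "A", "A")] == 0.0
        assert ("L_R", "A", "A") not in score_gated(p, PAIR).scores.index

    def test_missing_subunit_gene_drops_pair(self, annotated_adata):
        pairs = [LRPair(("G0001",), ("NOSUCHGENE",)), LRPair(("G0001",), ("G0002",))]
        t = scoring.score_all(annotated_adata, pairs, "sub1")
        ids = t["hill"].scores.index.get_level_values("pair_id").unique()
        assert list(ids) == ["G0001_G0002"]

    def test_planted_signal_monotonicity(self):
        from braincomm import preprocess, simulate

        scores = []
        for fold in (2.0, 8.0):
            planted = (simulate.PlantedPair("G0001", "G0002", "neurons", "microglia",
                                            "AD", fold),)
            cfg = simulate.SimConfig(seed=21, n_cells_per_type=50, planted_pairs=planted)
            adata = simulate.simulate_sc(cfg, [{"sample": "S1", "disease": "AD"}])
            adata = preprocess.normalize_log(preprocess.filter_cells(adata))
            adata.obs["cell_type"] = adata.obs["true_cell_type"]
            t = scoring.score_all(adata, [LRPair(("G0001",), ("G0002",))], "s")
            key = ("G0001_G0002", "neurons", "microglia")
            scores.append([t[m].scores.get(key, 0.0) for m in scoring.METHODS])
        low, high = scores
        assert all(h >= l for l, h in zip(low, high))
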