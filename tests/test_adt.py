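import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from citepipe import adt
from citepipe.matrix_io import CountMatrix


def _count_matrix(rows, features=None):
    rows = np.atleast_2d(np.asarray(rows))
    features = features or [f"ab{j}" for j in range(rows.shape[1])]
    return CountMatrix(
        np.array([f"c{i}" for i in range(rows.shape[0])], dtype=object),
        np.array(features, dtype=object),
        rows,
        "antibody",
    )


class TestClr:
    def test_equal_counts_map_to_zero(self):
        norm = adt.clr_log2(_count_matrix([[0, 0, 0, 0]]))
        np.testing.assert_allclose(norm.values, 0.0)

    def test_hand_computed_two_feature_cell(self):
        # counts [3, 1], pseudocount 1: log2(4/sqrt(8)) = 0.5
        norm = adt.clr_log2(_count_matrix([[3, 1]]))
        np.testing.assert_allclose(norm.values, [[0.5, -0.5]], atol=1e-12)

    @given(st.lists(st.integers(0, 500), min_size=2, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, counts):
        # multiplying (count + pseudocount) uniformly by 2 leaves CLR unchanged
        base = adt.clr_log2(_count_matrix([counts])).values
        doubled = adt.clr_log2(_count_matrix([[2 * c + 1 for c in counts]])).values
        np.testing.assert_allclose(base, doubled, atol=1e-9)

    def test_requires_positive_pseudocount(self):
        with pytest.raises(ValueError):
            adt.clr_log2(_count_matrix([[1, 2]]), pseudocount=0)


class TestMixture:
    def test_recovers_well_separated_components(self, rng):
        x = np.concatenate([rng.normal(0, 1, 2500), rng.normal(4, 1, 2500)])
        fit = adt.fit_mixture(x)
        assert fit.converged
        assert abs(fit.mu_neg - 0) <= 0.1
        assert abs(fit.mu_pos - 4) <= 0.1
        assert 0.4 < fit.weight_neg < 0.6

    def test_all_identical_values_degenerate(self):
        fit = adt.fit_mixture(np.full(100, 2.0))
        assert fit.degenerate
        with pytest.raises(adt.DegenerateDataError):
            adt.threshold_from_mixture(fit)

    def test_likelihood_beats_single_normal(self, rng):
        x = np.concatenate([rng.normal(0, 1, 500), rng.normal(3, 0.5, 500)])
        fit = adt.fit_mixture(x)
        single = sps.norm.logpdf(x, x.mean(), x.std()).sum()
        assert fit.log_likelihood >= single

    def test_too_few_values_rejected(self, rng):
        with pytest.raises(ValueError, match="50"):
            adt.fit_mixture(rng.normal(size=20))

    def test_matches_sklearn_gmm(self, rng):
        """Independent cross-check of the EM fit against sklearn's GMM."""
        from sklearn.mixture import GaussianMixture

        x = np.concatenate([rng.normal(-1, 0.7, 3000), rng.normal(3, 1.2, 2000)])
        fit = adt.fit_mixture(x)
        gmm = GaussianMixture(2, n_init=5, random_state=0, tol=1e-6).fit(x[:, None])
        means = np.sort(gmm.means_.ravel())
        assert abs(fit.mu_neg - means[0]) < 0.05
        assert abs(fit.mu_pos - means[1]) < 0.05


class TestThreshold:
    def _fit(self, mu_neg=0.0, mu_pos=4.0, sd_neg=1.0, sd_pos=1.0, w=0.5):
        return adt.MixtureFit("ab", "all", mu_neg, sd_neg, mu_pos, sd_pos, w, True, 10, 0.0)

    def test_symmetric_fit_gives_midpoint(self):
        assert adt.threshold_from_mixture(self._fit()) == pytest.approx(2.0)

    def test_rare_positive_shifts_threshold_up(self):
        assert adt.threshold_from_mixture(self._fit(w=0.9)) > 2.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"sd_neg": 0.5, "sd_pos": 1.5},
            {"w": 0.8, "sd_neg": 1.2, "sd_pos": 0.6},
            {"mu_neg": -2, "mu_pos": 1, "w": 0.3},
        ],
    )
    def test_threshold_equals_bayes_rule_on_grid(self, kwargs):
        """Classifying by the threshold must agree with the two-component
        Bayes rule evaluated on a fine grid between the means."""
        fit = self._fit(**kwargs)
        thr = adt.threshold_from_mixture(fit)
        grid = np.linspace(fit.mu_neg, fit.mu_pos, 4001)
        post_pos = (1 - fit.weight_neg) * sps.norm.pdf(grid, fit.mu_pos, fit.sd_pos)
        post_neg = fit.weight_neg * sps.norm.pdf(grid, fit.mu_neg, fit.sd_neg)
        bayes = post_pos > post_neg
        by_threshold = grid > thr
        assert (bayes == by_threshold).mean() > 0.999

    def test_negative_reference_simulation(self, rng):
        x = rng.normal(0, 1, 5000)
        assert adt.threshold_from_negative_reference(x, k=3) == pytest.approx(3.0, abs=0.1)

    def test_negative_reference_constant_and_k0(self, rng):
        with pytest.warns(UserWarning):
            assert adt.threshold_from_negative_reference(np.full(10, 5.0), k=3) == 5.0
        x = rng.normal(2, 1, 500)
        assert adt.threshold_from_negative_reference(x, k=0) == pytest.approx(x.mean())


class TestThresholdTable:
    def test_background_only_marker_reports_failed(self, rng):
        counts = _count_matrix(
            rng.poisson(3, size=(500, 3)), features=["a", "b", "c"]
        )
        norm = adt.clr_log2(counts)
        table = adt.build_threshold_table(norm)
        assert (table["method"] == "failed").all()
        assert table["threshold"].isna().all()

    def test_bimodal_marker_thresholded(self, small_norm_and_thresholds):
        _, table, thresholds = small_norm_and_thresholds
        assert "CD3" in thresholds and "CD19" in thresholds
        assert np.isfinite(list(thresholds.values())).all()


class TestGating:
    def _norm(self, values, features):
        cells = np.array([f"c{i}" for i in range(len(values))], dtype=object)
        from citepipe.matrix_io import NormalizedMatrix

        return NormalizedMatrix(cells, np.array(features, dtype=object),
                                np.asarray(values, dtype=float), "clr_log2")

    MARKERS = ["CD3", "CD4", "CD8", "CD19", "CD14", "CD16"]
    THR = {m: 0.0 for m in MARKERS}

    def test_cd4_t_cell_definition(self):
        # CD19-, CD14-, CD16-, CD3+, CD4+, CD8-
        norm = self._norm([[1, 1, -1, -1, -1, -1]], self.MARKERS)
        assert adt.apply_gates(norm, self.THR).iloc[0] == "CD4T"

    def test_cd19_identifies_b_cells(self):
        norm = self._norm([[-1, -1, -1, 1, -1, -1]], self.MARKERS)
        assert adt.apply_gates(norm, self.THR).iloc[0] == "B"

    def test_all_negative_falls_through_to_other(self):
        norm = self._norm([[-1, -1, -1, -1, -1, -1]], self.MARKERS)
        assert adt.apply_gates(norm, self.THR).iloc[0] == "Other"

    def test_first_match_wins_order(self):
        # CD19+ AND CD3+CD4+ -> B by rule order
        norm = self._norm([[1, 1, -1, 1, -1, -1]], self.MARKERS)
        assert adt.apply_gates(norm, self.THR).iloc[0] == "B"

    def test_every_cell_assigned_exactly_one_type(self, rng):
        values = rng.normal(size=(200, 6))
        norm = self._norm(values, self.MARKERS)
        types = adt.apply_gates(norm, self.THR)
        assert len(types) == 200
        assert types.isin(["B", "Monocyte", "CD8T", "CD4T", "Other"]).all()

    def test_missing_threshold_is_config_error(self):
        norm = self._norm([[1, 1, -1, -1, -1, -1]], self.MARKERS)
        with pytest.raises(KeyError, match="CD16"):
            adt.apply_gates(norm, {m: 0.0 for m in self.MARKERS[:-1]})

    def test_overlapping_rule_sets_rejected(self):
        with pytest.raises(ValueError):
            adt.GatingRule("x", positive=("CD3",), negative=("CD3",))


def test_end_to_end_gating_accuracy(small_study, small_norm_and_thresholds):
    """Ground-truth major types recovered for nearly all non-doublet cells."""
    norm, _, thresholds = small_norm_and_thresholds
    types = adt.apply_gates(norm, thresholds)
    truth = small_study["truth"].cells
    singlet = truth[~truth["is_doublet"]]
    acc = (types.loc[singlet.index] == singlet["true_major"]).mean()
    assert acc >= 0.97
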