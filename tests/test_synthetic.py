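import numpy as np
import pandas as pd
import pytest

from citepipe import synthetic
from citepipe.synthetic import SimulationDesign, default_design, simulate_study


class TestDefaultDesign:
    def test_proportions_form_a_simplex(self):
        d = default_design()
        assert abs(sum(d.cluster_base_proportions) - 1.0) < 1e-9

    def test_contract_on_planted_effects(self):
        d = default_design()
        assert len(d.planted_abundance_effects) >= 1
        assert len(d.planted_de_effects) >= 3
        conditions = {c for _, c, _ in d.planted_de_effects}
        assert {"CAD+", "DM+", "female"} <= conditions

    def test_dispersions_positive(self):
        d = default_design()
        assert d.nb_dispersion_adt > 0 and d.nb_dispersion_gene > 0

    def test_panel_has_lineage_and_memory_markers(self):
        names = {ab.name for ab in default_design().antibody_panel}
        assert {"CD3", "CD4", "CD8", "CD19", "CD14", "CD16", "CD45RA", "CD197", "CCR2"} <= names
        assert len(names) == 49


class TestDesignValidation:
    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError):
            default_design(cluster_base_proportions=(0.5, 0.2, 0.1, 0.1, 0.05, 0.04))

    def test_bad_doublet_rate_rejected(self):
        with pytest.raises(ValueError):
            default_design(doublet_rate=0.6)

    def test_nonpositive_odds_ratio_rejected(self):
        with pytest.raises(ValueError):
            default_design(planted_abundance_effects=((5, "CAD+", 0.0),))

    def test_effect_on_unknown_gene_rejected(self):
        with pytest.raises(ValueError):
            default_design(planted_de_effects=(("NOPE", "CAD+", 1.0),))


class TestSimulateStudy:
    def test_zero_doublet_rate_yields_no_doublets(self):
        d = default_design(cells_per_subject=50, doublet_rate=0.0)
        *_, gt = simulate_study(d, seed=1)
        assert not gt.cells["is_doublet"].any()

    def test_same_seed_bit_identical(self):
        d = default_design(cells_per_subject=60)
        a1, g1, t1, m1, gt1 = simulate_study(d, seed=9)
        a2, g2, t2, m2, gt2 = simulate_study(d, seed=9)
        assert np.array_equal(a1.counts, a2.counts)
        assert np.array_equal(g1.counts, g2.counts)
        assert np.array_equal(t1.counts, t2.counts)
        pd.testing.assert_frame_equal(gt1.cells, gt2.cells)

    def test_doublet_fraction_near_design_rate(self, small_study):
        gt = small_study["truth"].cells
        rate = small_study["design"].doublet_rate
        n = len(gt)
        se = np.sqrt(rate * (1 - rate) / n)
        assert abs(gt["is_doublet"].mean() - rate) <= 3 * se

    def test_shapes_consistent(self, small_study):
        a, g, t = small_study["adt"], small_study["genes"], small_study["tags"]
        gt = small_study["truth"]
        assert a.shape[0] == g.shape[0] == t.shape[0] == len(gt.cells)
        assert a.shape[1] == 49
        assert g.shape[1] == small_study["design"].n_genes
        assert t.shape[1] == small_study["design"].n_subjects

    def test_doublets_carry_two_high_tags(self, small_study):
        tags = small_study["tags"].to_frame()
        gt = small_study["truth"].cells
        doublet_tags = tags.loc[gt.index[gt["is_doublet"]]]
        second_highest = np.sort(doublet_tags.to_numpy(), axis=1)[:, -2]
        assert (second_highest >= 20).mean() > 0.99

    def test_positive_populations_separate_from_background(self, small_study):
        """Cells of positive clusters sit above the latent component midpoint
        on the log2(count+1) scale for nearly all draws."""
        design, gt = small_study["design"], small_study["truth"]
        counts = small_study["adt"].to_frame()
        singlets = gt.cells[~gt.cells["is_doublet"]]
        log2c = np.log2(counts.loc[singlets.index] + 1)
        for ab in design.antibody_panel[:12]:
            thr = (ab.neg_mean + ab.pos_mean) / 2
            for k in ab.positive_in:
                members = singlets.index[singlets["true_cluster"] == k]
                assert (log2c.loc[members, ab.name] > thr).mean() >= 0.9

    def test_metadata_crosses_conditions(self, small_study):
        meta = small_study["meta"]
        assert set(meta["cad_class"]) == {"CAD+", "CAD-"}
        assert set(meta["dm"]) == {"DM+", "DM-"}
        assert set(meta["sex"]) == {"male", "female"}
        cadp = meta["cad_class"] == "CAD+"
        assert (meta.loc[cadp, "gensini_score"] > 30).all()
        assert (meta.loc[~cadp, "gensini_score"] < 6).all()


class TestAbundanceGroundTruth:
    def test_planted_odds_ratio_recovered(self):
        """Pooled empirical odds ratio of the depleted cluster matches the
        planted value (median over 20 replicate seeds within [0.4, 0.62])."""
        d = default_design()
        cluster, cond, orat = d.planted_abundance_effects[0]
        assert orat == 0.5
        ors = []
        for seed in range(20):
            counts, meta = synthetic.simulate_cluster_counts(d, seed=seed)
            mask = synthetic.condition_mask(meta, cond)
            x1 = counts.loc[mask, cluster].sum()
            n1 = counts.loc[mask].to_numpy().sum()
            x0 = counts.loc[~mask, cluster].sum()
            n0 = counts.loc[~mask].to_numpy().sum()
            ors.append((x1 / (n1 - x1)) / (x0 / (n0 - x0)))
        assert 0.4 <= np.median(ors) <= 0.62

    def test_membership_sampler_matches_full_simulation(self):
        """The cheap cluster-count path and simulate_study share the same
        per-subject proportion model."""
        d = default_design(cells_per_subject=400, doublet_rate=0.0)
        *_, meta, gt = simulate_study(d, seed=3)
        observed = (
            gt.cells.groupby("true_subject", observed=True)["true_cluster"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
        )
        expected = gt.subject_cluster_props
        err = (observed - expected).abs().to_numpy().max()
        assert err < 0.08
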