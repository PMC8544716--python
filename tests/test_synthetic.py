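import numpy as np
import pandas as pd
import pytest

from smcoloc.clustering import ClusterParams, density_cluster
from smcoloc.locdata import assign_to_cells
from smcoloc.synthetic import SceneConfig, simulate_maps_counts, simulate_scene


class TestSceneConfigValidation:
    def test_axial_precision_cannot_beat_lateral(self):
        with pytest.raises(ValueError, match="axial"):
            SceneConfig(sigma_xy=20.0, sigma_z=10.0)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(background_rate=-1.0)


class TestSimulateScene:
    def test_empty_expression_and_background_gives_empty_table(self):
        config = SceneConfig(n_cells=5, mean_srna=0.0, mean_mrna=0.0,
                             background_rate=0.0, n_marker_cells=0, seed=1)
        fov, truth = simulate_scene(config)
        assert len(fov.localizations) == 0
        assert truth.true_bound_fraction == 0.0

    def test_seed_determinism(self):
        config = SceneConfig(n_cells=10, seed=99)
        fov1, truth1 = simulate_scene(config)
        fov2, truth2 = simulate_scene(config)
        pd.testing.assert_frame_equal(fov1.localizations, fov2.localizations)
        pd.testing.assert_frame_equal(truth1.per_cell, truth2.per_cell)

    def test_localization_conservation(self):
        # without background, emitted localizations = sum of per-molecule N
        # (mRNA channel rows equal the mRNA molecule total, etc.)
        config = SceneConfig(n_cells=10, background_rate=0.0,
                             n_marker_cells=0, seed=3)
        fov, truth = simulate_scene(config)
        for channel in ("sRNA", "mRNA"):
            emitted = int((fov.localizations["channel"] == channel).sum())
            expected = int(truth.molecules.loc[
                truth.molecules["channel"] == channel, "n_locs"].sum())
            assert emitted == expected

    def test_truth_complexes_bounded_by_totals(self):
        _, truth = simulate_scene(SceneConfig(n_cells=50, seed=4))
        pc = truth.per_cell
        assert (pc["C"] <= np.minimum(pc["S"], pc["M"])).all()

    def test_degenerate_noise_free_scene_recovers_molecules_exactly(self):
        # sigma_pair = sigma_xy = sigma_z = 0 and a fixed 3-spot emitter:
        # clustering must find exactly one 3-spot cluster per molecule
        config = SceneConfig(
            n_cells=5, mean_srna=4.0, mean_mrna=0.0, sigma_pair=0.0,
            sigma_xy=0.0, sigma_z=0.0, spots_fixed=3,
            background_rate=0.0, n_marker_cells=0, seed=5,
        )
        fov, truth = simulate_scene(config)
        locs = assign_to_cells(fov.localizations, fov.rois)
        n_molecules = len(truth.molecules)
        assert n_molecules > 0
        found = 0
        for cell_id in truth.per_cell["cell_id"]:
            sub = locs[locs["cell_id"] == cell_id].reset_index(drop=True)
            clusters, noise = density_cluster(sub, ClusterParams(25.0, 2))
            assert noise == []
            assert all(c.n_spots == 3 for c in clusters)
            found += len(clusters)
        assert found == n_molecules

    def test_increasing_kd_decreases_bound_fraction(self):
        fractions = []
        for kd_v in (0.0, 66.0, 1e4):
            _, truth = simulate_scene(SceneConfig(n_cells=60, seed=6, kd_v=kd_v))
            fractions.append(truth.true_bound_fraction)
        assert fractions[0] > fractions[1] > fractions[2]

    def test_zero_kd_binds_min_of_totals(self):
        _, truth = simulate_scene(SceneConfig(n_cells=40, seed=7, kd_v=0.0))
        pc = truth.per_cell
        assert (pc["C"] == np.minimum(pc["S"], pc["M"])).all()

    def test_mrna_channel_carries_the_chromatic_shift(self):
        # noise-free degenerate emitters: marker molecules are shared between
        # channels, so the mRNA localization positions are exactly the sRNA
        # positions plus the chromatic shift
        shift = np.array([60.0, -40.0, 25.0])
        config = SceneConfig(n_cells=0, n_marker_cells=10, seed=8,
                             background_rate=0.0, sigma_xy=0.0, sigma_z=0.0,
                             spots_fixed=2, chromatic_shift=tuple(shift))
        fov, _ = simulate_scene(config)
        locs = fov.localizations
        a = np.unique(locs.loc[locs["channel"] == "sRNA",
                               ["x", "y", "z"]].to_numpy(), axis=0)
        b = np.unique(locs.loc[locs["channel"] == "mRNA",
                               ["x", "y", "z"]].to_numpy(), axis=0)
        np.testing.assert_allclose(b, a + shift, atol=1e-9)


class TestSimulateMapsCounts:
    def test_no_spikes_gives_pure_null(self):
        counts, _, spiked = simulate_maps_counts(
            n_genes=100, spike_gene_count=0, seed=1)
        assert not spiked.any()
        tagged = counts.filter(like="tagged").to_numpy().mean()
        control = counts.filter(like="control").to_numpy().mean()
        assert tagged == pytest.approx(control, rel=0.1)

    def test_seed_determinism(self):
        a = simulate_maps_counts(n_genes=50, seed=5)[0]
        b = simulate_maps_counts(n_genes=50, seed=5)[0]
        pd.testing.assert_frame_equal(a, b)

    def test_spiked_genes_scaled_in_tagged_group_only(self):
        counts, _, spiked = simulate_maps_counts(
            n_genes=200, baseline_mean=200.0, dispersion=0.0,
            spike_gene_count=10, spike_fold=8.0, seed=9)
        t = counts.filter(like="tagged")
        c = counts.filter(like="control")
        ratio = t.loc[spiked].to_numpy().mean() / c.loc[spiked].to_numpy().mean()
        assert ratio == pytest.approx(8.0, rel=0.15)
        null_ratio = t.loc[~spiked].to_numpy().mean() / c.loc[~spiked].to_numpy().mean()
        assert null_ratio == pytest.approx(1.0, rel=0.05)

    def test_lengths_within_stated_range(self):
        _, lengths, _ = simulate_maps_counts(n_genes=500, seed=2)
        assert lengths.between(200, 5000).all()

    def test_poisson_limit_when_dispersion_zero(self):
        counts, _, _ = simulate_maps_counts(
            n_genes=4000, dispersion=0.0, spike_gene_count=0,
            baseline_mean=100.0, seed=3)
        col = counts["tagged_1"].to_numpy()
        # Poisson: variance ~= mean (NB with dispersion 0.05 would be ~600)
        assert col.var() == pytest.approx(col.mean(), rel=0.1)
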