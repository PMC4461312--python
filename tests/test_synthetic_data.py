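import numpy as np
import pytest

from commsize import (
    DEFAULT_GRADIENT_DESIGN,
    GradientSpec,
    ParamRanges,
    SelectedSpec,
    build_selected_dataset,
    desk_scale_design,
    generate_suite,
    pielou_evenness,
    random_gradient_spec,
    simulate_gradient_dataset,
    summarize,
    taxon_response,
)
from commsize.synthetic_data import _geometric_counts, _solve_decay


class TestTaxonResponse:
    def test_maximum_at_optimum(self):
        assert taxon_response(50, mu=50, sigma=10, peak=100) == pytest.approx(100.0)

    def test_one_sigma_from_optimum(self):
        assert taxon_response(60, mu=50, sigma=10, peak=100) == pytest.approx(
            100 * np.exp(-0.5), abs=1e-9
        )

    def test_far_tail_vanishes(self):
        assert taxon_response(1e6, mu=50, sigma=10, peak=100) < 1e-12

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            taxon_response(0, mu=0, sigma=0, peak=1)


class TestSimulateGradient:
    def test_counts_are_rounded_curve_heights_at_fixed_positions(self):
        spec = GradientSpec(
            gradient_length=100,
            n_taxa=2,
            n_samples=2,
            taxon_params=((50.0, 10.0, 100.0), (50.0, 10.0, 50.0)),
            positions=(50.0, 60.0),
        )
        m = simulate_gradient_dataset(spec)
        # at the optimum: the peaks; one sigma away: 60.65 -> 61, 30.33 -> 30
        assert m.counts[0].tolist() == [100, 50]
        assert m.counts[1].tolist() == [61, 30]

    def test_structural_contract_of_design_row(self):
        spec = random_gradient_spec(20, 20, 100, seed=4)
        m = simulate_gradient_dataset(spec)
        assert m.n_samples == 20
        assert m.n_taxa <= 20
        assert (m.counts >= 0).all()

    def test_deterministic_given_seed(self):
        spec = random_gradient_spec(15, 10, 100, seed=11)
        assert simulate_gradient_dataset(spec) == simulate_gradient_dataset(spec)

    def test_too_many_samples_for_unique_positions(self):
        with pytest.raises(ValueError, match="uniform-real"):
            GradientSpec(
                gradient_length=10,
                n_taxa=2,
                n_samples=11,
                taxon_params=((5.0, 1.0, 10.0), (6.0, 1.0, 10.0)),
                position_mode="unique-integer",
            )

    def test_dense_designs_switch_to_uniform_real(self):
        spec = random_gradient_spec(200, 50, 100, seed=0)
        assert spec.position_mode == "uniform-real"
        assert simulate_gradient_dataset(spec).n_samples == 200

    def test_counts_unimodal_along_gradient(self):
        # response curves are unimodal, so ordered-by-position counts rise
        # then fall (ties from rounding allowed)
        spec = random_gradient_spec(50, 8, 100, seed=21)
        positions = tuple(float(g) for g in np.linspace(1, 100, 50))
        fixed = GradientSpec(
            gradient_length=100,
            n_taxa=8,
            n_samples=50,
            taxon_params=spec.taxon_params,
            positions=positions,
        )
        m = simulate_gradient_dataset(fixed)
        for col in m.counts.T:
            diffs = np.sign(np.diff(col))
            nonzero = diffs[diffs != 0]
            # rises (+1) may only be followed by falls (-1), never the reverse
            assert np.all(np.diff(nonzero) <= 0)

    def test_random_spec_ranges(self):
        for seed in range(30):
            spec = random_gradient_spec(10, 12, 100, seed=seed)
            params = np.asarray(spec.taxon_params)
            assert (params[:, 0] >= 1).all() and (params[:, 0] <= 100).all()
            assert (params[:, 1] >= 5).all() and (params[:, 1] <= 25).all()
            assert (params[:, 2] >= 1).all() and (params[:, 2] <= 100).all()

    def test_default_ranges_give_realistic_sample_sizes(self):
        # 20 samples x 20 taxa on a 100-unit gradient: median sample sizes
        # land in the hundreds-of-individuals regime
        medians = []
        for seed in range(10):
            spec = random_gradient_spec(20, 20, 100, seed=seed)
            medians.append(summarize(simulate_gradient_dataset(spec)).median_sample_size)
        assert 50 <= np.median(medians) <= 2000


class TestSelectedDatasets:
    @pytest.mark.parametrize("evenness_class", ["low", "high"])
    @pytest.mark.parametrize("richness", [10, 20, 50])
    def test_totals_and_target_evenness(self, evenness_class, richness):
        spec = SelectedSpec(n_samples=8, richness=richness, evenness_class=evenness_class)
        m = build_selected_dataset(spec)
        s = summarize(m)
        assert set(s.sample_size_per_sample) == {200}
        target = 0.58 if evenness_class == "low" else 0.79
        assert s.mean_evenness == pytest.approx(target, abs=0.05)

    def test_mixed_datasets_have_bimodal_evenness(self):
        spec = SelectedSpec(n_samples=10, richness=20, evenness_class="mixed")
        s = summarize(build_selected_dataset(spec))
        j = np.array(s.evenness_per_sample, dtype=float)
        assert ((np.abs(j - 0.58) < 0.05) | (np.abs(j - 0.79) < 0.05)).all()
        assert (np.abs(j - 0.58) < 0.05).any() and (np.abs(j - 0.79) < 0.05).any()

    def test_unit_decay_is_perfectly_even(self):
        counts = _geometric_counts(20, 1.0, 200)
        assert (counts == 10).all()
        assert pielou_evenness(counts) == pytest.approx(1.0)

    def test_unattainable_target_reports_range(self):
        with pytest.raises(ValueError, match="attainable"):
            _solve_decay(200, 0.58, 200)

    def test_structure_id_rotates_communities(self):
        a = build_selected_dataset(SelectedSpec(5, 10, "low", structure_id=1))
        b = build_selected_dataset(SelectedSpec(5, 10, "low", structure_id=3))
        assert not np.array_equal(a.counts, b.counts)
        # rows differ within a dataset (distinct communities)
        assert not np.array_equal(a.counts[0], a.counts[1])


class TestGenerateSuite:
    def test_one_replicate_per_row_covers_design(self):
        design = desk_scale_design(replicates=1)
        datasets, manifest = generate_suite(design, seed=3)
        assert len(datasets) == 22
        assert len(manifest) == 22
        assert manifest["gradient_size"].max() <= 100

    def test_full_design_row_count(self):
        assert len(DEFAULT_GRADIENT_DESIGN) == 22
        assert sum(r.replicates for r in DEFAULT_GRADIENT_DESIGN) == 220

    def test_manifest_reproduces_each_dataset(self):
        design = desk_scale_design(replicates=2)[:3]
        datasets, manifest = generate_suite(design, seed=8)
        row = manifest.iloc[4]
        spec = random_gradient_spec(
            n_samples=int(row["n_samples"]),
            n_taxa=int(row["n_taxa"]),
            gradient_length=int(row["gradient_size"]),
            seed=int(row["seed"]),
        )
        assert simulate_gradient_dataset(spec) == datasets[row["dataset_id"]]

    def test_suite_is_deterministic(self):
        design = desk_scale_design(replicates=1)[:4]
        a, _ = generate_suite(design, seed=5)
        b, _ = generate_suite(design, seed=5)
        assert all(a[k] == b[k] for k in a)

    def test_param_ranges_validation(self):
        with pytest.raises(ValueError):
            ParamRanges(sigma_lo=0.2, sigma_hi=0.1)
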