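"""Generator properties: determinism, physical ranges, noise calibration."""

import numpy as np
import pytest

from tfpdyn.classify import region_mean
from tfpdyn.relaxation import SpectrometerField, predict_relaxation
from tfpdyn.simulate import (
    DynamicsProfileSpec,
    default_region_scheme,
    make_profile,
    simulate_dataset,
    simulate_ensemble,
)


class TestMakeProfile:
    def test_deterministic_given_seed(self):
        spec = DynamicsProfileSpec(seed=42)
        a, b = make_profile(spec), make_profile(spec)
        assert set(a.params) == set(b.params)
        for rid in a.params:
            pa, pb = a.params[rid], b.params[rid]
            assert pa == pb
        assert a.flags == b.flags

    def test_different_seed_differs(self):
        a = make_profile(DynamicsProfileSpec(seed=1))
        b = make_profile(DynamicsProfileSpec(seed=2))
        assert any(a.params[r] != b.params[r] for r in a.params if r in b.params)

    def test_all_rigid_head_zero_sd(self):
        """With sd = 0 and no special sites every residue is model 1 at the mean."""
        spec = DynamicsProfileSpec(
            s2_by_region={k: (0.88, 0.0) for k in
                          ("head", "loop_I", "loop_II", "loop_III", "c_tail")},
            n_rex_sites=0, n_model5_sites=0, n_doubled=0, n_broadened=0,
            n_proline=0, tau_e_fraction_mobile=0.0, tau_e_fraction_rigid=0.0,
            seed=3,
        )
        truth = make_profile(spec)
        for p in truth.params.values():
            assert p.model_id == 1
            assert p.s2 == pytest.approx(0.88)

    def test_preset_region_means_ordered(self):
        """TFP-like preset: head > loop I > loop II > loop III in mean S^2."""
        truth = make_profile(DynamicsProfileSpec(seed=0))
        means = {k: v.mean for k, v in
                 region_mean(truth.s2_map(), truth.scheme).items()}
        assert means["head"] == pytest.approx(0.88, abs=0.02)
        assert means["loop_III"] == pytest.approx(0.66, abs=0.04)
        assert means["head"] > means["loop_I"] > means["loop_II"] > means["loop_III"]

    def test_physical_ranges(self):
        truth = make_profile(DynamicsProfileSpec(seed=9))
        for p in truth.params.values():
            assert 0.0 < p.order_parameter <= 1.0
            if p.rex is not None:
                assert p.rex >= 0.0

    def test_impossible_spec_rejected(self):
        with pytest.raises(ValueError):
            DynamicsProfileSpec(n_residues=60, n_rex_sites=59, n_model5_sites=10)


class TestSimulateDataset:
    def test_zero_noise_equals_forward_model(self):
        spec = DynamicsProfileSpec(n_residues=60, noise_rate_frac=0.0,
                                   noise_noe_abs=0.0, seed=4)
        truth = make_profile(spec)
        ds = simulate_dataset(truth, spec)
        rec = next(r for r in ds.records if r.field_mhz == 800.0 and r.r1 is not None)
        tr = predict_relaxation(truth.params[rec.residue_id], truth.tensor,
                                SpectrometerField(800.0, spec.temperature_k))
        assert rec.r1 == pytest.approx(tr.r1, rel=1e-12)
        assert rec.r2 == pytest.approx(tr.r2, rel=1e-12)
        assert rec.noe == pytest.approx(tr.noe, rel=1e-12)

    def test_two_field_design(self, noisy_dataset):
        """Full triple at 800 MHz; supplementary 600 MHz rows carry R2 only."""
        highs = [r for r in noisy_dataset.records if r.field_mhz == 800.0]
        lows = [r for r in noisy_dataset.records if r.field_mhz == 600.0]
        assert highs and lows
        assert all(r.r1 is not None and r.noe is not None for r in highs)
        assert all(r.r1 is None and r.noe is None and r.r2 is not None for r in lows)

    def test_noise_sigma_calibrated(self):
        """Empirical noise over 400 seeds within 5% of the specified sigma."""
        base = DynamicsProfileSpec(n_residues=60, noise_rate_frac=0.0,
                                   noise_noe_abs=0.0, seed=8)
        truth = make_profile(base)
        clean = simulate_dataset(truth, base)
        ref = next(r for r in clean.records
                   if r.field_mhz == 800.0 and r.r1 is not None)
        vals = []
        for seed in range(400):
            # same truth; only the measurement-noise seed varies
            spec = DynamicsProfileSpec(n_residues=60, seed=seed)
            ds = simulate_dataset(truth, spec)
            rec = ds.get(ref.residue_id, 800.0)
            vals.append(rec.r1)
        sigma_emp = np.std(vals, ddof=1)
        assert sigma_emp == pytest.approx(0.03 * ref.r1, rel=0.15)

    def test_reported_errors_positive(self, noisy_dataset):
        for r in noisy_dataset.records:
            if r.r2 is not None:
                assert r.r2_err > 0


class TestSimulateEnsemble:
    SCHEME = default_region_scheme(60)

    def test_zero_sigma_identical_models(self):
        ens = simulate_ensemble(20, self.SCHEME, {}, seed=0)
        assert np.allclose(ens.coords, ens.coords[0][None])

    def test_seeded_reproducibility(self):
        a = simulate_ensemble(10, self.SCHEME, {"loop_I": 1.0}, seed=5)
        b = simulate_ensemble(10, self.SCHEME, {"loop_I": 1.0}, seed=5)
        assert np.array_equal(a.coords, b.coords)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            simulate_ensemble(5, self.SCHEME, {"head": -0.1}, seed=0)

    def test_min_models(self):
        with pytest.raises(ValueError):
            simulate_ensemble(1, self.SCHEME, {}, seed=0)

    def test_globular_template_orientation_diversity(self):
        ens = simulate_ensemble(2, self.SCHEME, {}, seed=0, template="globular")
        nh = ens.nh_orientations(0)
        vecs = np.array(list(nh.values()))
        # mean of quasi-uniform unit vectors is near zero; parallel vectors
        # would give norm ~1
        assert np.linalg.norm(vecs.mean(axis=0)) < 0.3


class TestRegionScheme:
    def test_default_scheme_covers_all_but_first(self):
        scheme = default_region_scheme(100)
        uncovered = [r for r in range(1, 100) if scheme.region_of(r) is None]
        assert uncovered == []
        assert scheme.region_of(0) is None  # Met0 excluded
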