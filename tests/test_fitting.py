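"""Inverse-problem checks: decays, tau_R, diffusion tensor, residue models."""

import warnings

import numpy as np
import pytest

from tfpdyn.fitting import (
    DecayFit,
    RelaxationDataset,
    RelaxationRecord,
    estimate_tauR_initial,
    fit_diffusion,
    fit_exponential_decay,
    fit_residue_models,
    rigid_subset,
)
from tfpdyn.relaxation import (
    DiffusionTensor,
    ModelFreeParams,
    SpectrometerField,
    predict_relaxation,
)
from tfpdyn.simulate import (
    R1_DELAYS_S,
    R1_DUPLICATE_DELAYS_S,
    R2_CPMG_DELAYS_S,
    DynamicsProfileSpec,
    default_region_scheme,
    make_profile,
    simulate_dataset,
    simulate_decay_table,
    simulate_ensemble,
)


class TestExponentialDecay:
    def test_noiseless_r1_schedule(self):
        t = np.array(R1_DELAYS_S)
        res = fit_exponential_decay(t, 100.0 * np.exp(-1.0 * t))
        assert res.rate == pytest.approx(1.0, rel=1e-8)
        assert res.decaying

    def test_noiseless_cpmg_schedule(self):
        t = np.array(R2_CPMG_DELAYS_S)
        res = fit_exponential_decay(t, 50.0 * np.exp(-15.0 * t))
        assert res.rate == pytest.approx(15.0, rel=1e-8)

    def test_noisy_simulation_calibration(self):
        """500 noisy repeats at R = 1.5: mean within 1%, error bar honest.

        The reported uncertainty (from the duplicate-plane scatter) should
        match the empirical spread of recovered rates within ~30%.
        """
        rates, errs = [], []
        for seed in range(500):
            t, y = simulate_decay_table(
                1.5, noise_frac=0.02, seed=seed,
                delays_s=R1_DELAYS_S, duplicate_delays_s=R1_DUPLICATE_DELAYS_S,
            )
            res = fit_exponential_decay(t, np.abs(y))
            rates.append(res.rate)
            errs.append(res.rate_err)
        rates = np.array(rates)
        assert np.mean(rates) == pytest.approx(1.5, rel=0.01)
        assert np.mean(errs) == pytest.approx(np.std(rates), rel=0.30)

    def test_duplicate_scatter_used(self):
        t, y = simulate_decay_table(2.0, noise_frac=0.03, seed=1)
        res = fit_exponential_decay(t, np.abs(y))
        assert res.sigma_intensity is not None and res.sigma_intensity > 0

    def test_rescaling_invariance(self):
        t = np.array(R1_DELAYS_S)
        y = 100.0 * np.exp(-1.2 * t)
        a = fit_exponential_decay(t, y)
        b = fit_exponential_decay(t, 7.5 * y)
        assert a.rate == pytest.approx(b.rate, rel=1e-9)

    def test_non_decaying_flagged(self):
        t = np.array([0.1, 0.2, 0.4, 0.8])
        with pytest.warns(UserWarning):
            res = fit_exponential_decay(t, np.exp(+0.5 * t))
        assert not res.decaying

    def test_too_few_delays(self):
        with pytest.raises(ValueError):
            fit_exponential_decay([0.1, 0.1, 0.2], [1.0, 1.0, 0.9])


def _rigid_dataset(tau_r=5.0, s2=0.9, n=30, mhz=800.0):
    tensor = DiffusionTensor("isotropic", tau_r)
    f = SpectrometerField(mhz)
    records = []
    for rid in range(1, n + 1):
        tr = predict_relaxation(ModelFreeParams(1, s2=s2), tensor, f)
        records.append(RelaxationRecord(
            residue_id=rid, field_mhz=mhz,
            r1=tr.r1, r1_err=0.03 * tr.r1,
            r2=tr.r2, r2_err=0.03 * tr.r2,
            noe=tr.noe, noe_err=0.02,
        ))
    return RelaxationDataset("rigid", 310.15, records)


class TestTauRInitial:
    def test_noiseless_round_trip(self):
        ds = _rigid_dataset(tau_r=5.0)
        assert estimate_tauR_initial(ds) == pytest.approx(5.0, abs=0.05)

    def test_robust_to_exchange_sites(self):
        """rex = 5 s^-1 on 30% of residues: trimming keeps the estimate."""
        ds = _rigid_dataset(tau_r=5.0, n=30)
        tensor = DiffusionTensor("isotropic", 5.0)
        f = SpectrometerField(800.0)
        records = list(ds.records)
        for i in range(0, 9):
            old = records[i]
            tr = predict_relaxation(
                ModelFreeParams(3, s2=0.9, rex=5.0, rex_field_mhz=800.0), tensor, f
            )
            records[i] = RelaxationRecord(
                residue_id=old.residue_id, field_mhz=800.0,
                r1=tr.r1, r1_err=old.r1_err, r2=tr.r2, r2_err=old.r2_err,
                noe=tr.noe, noe_err=old.noe_err,
            )
        noisy = RelaxationDataset("rex30", 310.15, records)
        assert estimate_tauR_initial(noisy) == pytest.approx(5.0, rel=0.05)

    def test_empty_dataset_errors(self):
        with pytest.raises(ValueError):
            estimate_tauR_initial(RelaxationDataset("empty", 310.15, []))

    def test_rigid_subset_drops_mobile_and_flagged(self):
        ds = _rigid_dataset(n=10)
        records = list(ds.records)
        tensor = DiffusionTensor("isotropic", 5.0)
        tr = predict_relaxation(
            ModelFreeParams(2, s2=0.4, tau_e_ps=80.0), tensor, SpectrometerField(800.0)
        )
        records[0] = RelaxationRecord(residue_id=1, field_mhz=800.0,
                                      r1=tr.r1, r1_err=0.05, r2=tr.r2, r2_err=0.2,
                                      noe=tr.noe, noe_err=0.02)  # low NOE
        records[1] = RelaxationRecord(residue_id=2, field_mhz=800.0,
                                      r1=records[1].r1, r1_err=records[1].r1_err,
                                      r2=records[1].r2, r2_err=records[1].r2_err,
                                      noe=records[1].noe, noe_err=records[1].noe_err,
                                      flags={"broadened"})
        subset = rigid_subset(RelaxationDataset("mixed", 310.15, records))
        assert 1 not in subset and 2 not in subset
        assert len(subset) == 8


class TestDiffusionFit:
    def test_isotropic_round_trip(self, noiseless_dataset):
        tensor = fit_diffusion(noiseless_dataset)
        assert tensor.kind == "isotropic"
        assert tensor.tau_r_ns == pytest.approx(4.3, abs=0.02)

    def test_axial_on_isotropic_data_no_spurious_anisotropy(self, noiseless_dataset):
        """Axial fit of isotropic data must give anisotropy ~1."""
        scheme = default_region_scheme(60)
        structure = simulate_ensemble(3, scheme, {}, seed=9, template="globular")
        tensor = fit_diffusion(
            noiseless_dataset, structure=structure, kind="axially_symmetric",
            conformers=(0,),
        )
        assert 0.95 <= tensor.anisotropy <= 1.05
        assert tensor.tau_r_ns == pytest.approx(4.3, rel=0.02)

    def test_axial_requires_structure(self, noiseless_dataset):
        with pytest.raises(ValueError):
            fit_diffusion(noiseless_dataset, kind="axially_symmetric")


class TestResidueModels:
    def test_noiseless_round_trip_all_models(self):
        """Each generating model is re-selected and recovered to 3 sig figs."""
        tensor = DiffusionTensor("isotropic", 4.3)
        truth = {
            10: ModelFreeParams(1, s2=0.88),
            11: ModelFreeParams(2, s2=0.80, tau_e_ps=50.0),
            12: ModelFreeParams(3, s2=0.90, rex=4.0, rex_field_mhz=800.0),
            13: ModelFreeParams(4, s2=0.75, tau_e_ps=60.0, rex=3.5, rex_field_mhz=800.0),
            14: ModelFreeParams(5, s2_f=0.85, s2_s=0.75, tau_s_ns=1.5),
        }
        records = []
        for rid, p in truth.items():
            for mhz in (600.0, 800.0):
                tr = predict_relaxation(p, tensor, SpectrometerField(mhz))
                full = mhz == 800.0
                records.append(RelaxationRecord(
                    residue_id=rid, field_mhz=mhz,
                    r1=tr.r1 if full else None, r1_err=1e-3 * tr.r1 if full else None,
                    r2=tr.r2, r2_err=1e-3 * tr.r2,
                    noe=tr.noe if full else None, noe_err=1e-3 if full else None,
                ))
        ds = RelaxationDataset("five_models", 310.15, records)
        fit = fit_residue_models(ds, tensor, mc_reps=0)
        for rid, p in truth.items():
            rf = fit.residues[rid]
            assert rf.model_id == p.model_id, f"residue {rid}"
            assert rf.params.order_parameter == pytest.approx(p.order_parameter, rel=1e-3)
            if p.tau_e_ps:
                assert rf.params.tau_e_ps == pytest.approx(p.tau_e_ps, rel=1e-3)
            if p.rex:
                assert rf.params.rex == pytest.approx(p.rex, rel=1e-3)
            if p.model_id == 5:
                assert rf.params.s2_f == pytest.approx(p.s2_f, rel=1e-3)
                assert rf.params.tau_s_ns == pytest.approx(p.tau_s_ns, rel=1e-3)

    def test_order_invariance(self, noiseless_dataset, noiseless_tensor):
        fit_fwd = fit_residue_models(noiseless_dataset, noiseless_tensor, mc_reps=0)
        shuffled = RelaxationDataset(
            noiseless_dataset.name, noiseless_dataset.temperature_k,
            list(reversed(noiseless_dataset.records)),
        )
        fit_rev = fit_residue_models(shuffled, noiseless_tensor, mc_reps=0)
        for rid in fit_fwd.residues:
            a, b = fit_fwd.residues[rid], fit_rev.residues[rid]
            if a.params is None:
                assert b.params is None
                continue
            assert a.model_id == b.model_id
            assert a.params.order_parameter == pytest.approx(
                b.params.order_parameter, rel=1e-6
            )

    def test_excluded_flags_skip_residue(self):
        tensor = DiffusionTensor("isotropic", 4.3)
        tr = predict_relaxation(ModelFreeParams(1, s2=0.9), tensor, SpectrometerField(800.0))
        rec = RelaxationRecord(residue_id=5, field_mhz=800.0, r1=tr.r1, r1_err=0.05,
                               r2=tr.r2, r2_err=0.2, noe=tr.noe, noe_err=0.02,
                               flags={"proline"})
        fit = fit_residue_models(RelaxationDataset("p", 310.15, [rec]), tensor, mc_reps=0)
        assert fit.residues[5].params is None
        assert "proline" in fit.residues[5].skipped

    def test_single_r2_only_skipped_with_warning(self):
        tensor = DiffusionTensor("isotropic", 4.3)
        rec = RelaxationRecord(residue_id=6, field_mhz=600.0, r2=6.0, r2_err=0.2)
        with pytest.warns(UserWarning, match="residue 6"):
            fit = fit_residue_models(
                RelaxationDataset("r2only", 310.15, [rec]), tensor, mc_reps=0
            )
        assert fit.residues[6].skipped == "insufficient observables"

    def test_mc_uncertainty_consistency(self):
        """S^2 error bars from 100 vs 400 MC draws agree (~1/sqrt(reps))."""
        tensor = DiffusionTensor("isotropic", 4.3)
        p = ModelFreeParams(2, s2=0.8, tau_e_ps=50.0)
        records = []
        for mhz in (600.0, 800.0):
            tr = predict_relaxation(p, tensor, SpectrometerField(mhz))
            full = mhz == 800.0
            records.append(RelaxationRecord(
                residue_id=1, field_mhz=mhz,
                r1=tr.r1 if full else None, r1_err=0.03 * tr.r1 if full else None,
                r2=tr.r2, r2_err=0.03 * tr.r2,
                noe=tr.noe if full else None, noe_err=0.02 if full else None,
            ))
        ds = RelaxationDataset("mc", 310.15, records)
        e100 = fit_residue_models(ds, tensor, mc_reps=100, seed=5)
        e400 = fit_residue_models(ds, tensor, mc_reps=400, seed=6)
        s100 = e100.residues[1].param_errors["s2"]
        s400 = e400.residues[1].param_errors["s2"]
        assert s100 > 0 and s400 > 0
        assert s100 == pytest.approx(s400, rel=0.40)

    def test_second_field_never_widens_s2_interval(self):
        """Adding the low-field R2 row narrows (or keeps) the S^2 error."""
        tensor = DiffusionTensor("isotropic", 4.3)
        p = ModelFreeParams(2, s2=0.8, tau_e_ps=50.0)
        recs = {}
        for mhz in (600.0, 800.0):
            tr = predict_relaxation(p, tensor, SpectrometerField(mhz))
            full = mhz == 800.0
            recs[mhz] = RelaxationRecord(
                residue_id=1, field_mhz=mhz,
                r1=tr.r1 if full else None, r1_err=0.03 * tr.r1 if full else None,
                r2=tr.r2, r2_err=0.03 * tr.r2,
                noe=tr.noe if full else None, noe_err=0.02 if full else None,
            )
        one = RelaxationDataset("one", 310.15, [recs[800.0]])
        two = RelaxationDataset("two", 310.15, list(recs.values()))
        e_one = fit_residue_models(one, tensor, mc_reps=300, seed=3)
        e_two = fit_residue_models(two, tensor, mc_reps=300, seed=3)
        s_one = e_one.residues[1].param_errors["s2"]
        s_two = e_two.residues[1].param_errors["s2"]
        assert s_two <= s_one * 1.10  # 10% slack for MC sampling noise

    def test_duplicate_records_rejected(self):
        rec = RelaxationRecord(residue_id=1, field_mhz=800.0, r2=6.0, r2_err=0.2)
        with pytest.raises(ValueError, match="duplicate"):
            RelaxationDataset("dup", 310.15, [rec, rec])
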