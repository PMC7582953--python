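"""Forward-model checks: spectral densities, relaxation rates, Rex scaling.

The independent oracle below re-implements the two-Lorentzian spectral
density and the dipolar/CSA rate expressions from scratch with its own
separately typed constants, so agreement is a genuine cross-check of
the implementation, not a tautology.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tfpdyn.constants import NuclearConstants
from tfpdyn.relaxation import (
    DiffusionTensor,
    ModelFreeParams,
    OrientationRequiredError,
    SpectrometerField,
    predict_relaxation,
    rex_at_field,
    spectral_density,
)

# ---------------------------------------------------------------------------
# independent oracle (own constants, own arithmetic)

_O_GH = 2.6752218744e8
_O_GN = -2.7126e7
_O_HBAR = 1.054571817e-34
_O_MU0 = 4.0e-7 * math.pi


def oracle_j(omega, s2, tau_r_s, tau_e_s):
    tau_p = tau_r_s * tau_e_s / (tau_r_s + tau_e_s) if tau_e_s > 0 else 0.0
    j = s2 * tau_r_s / (1.0 + (omega * tau_r_s) ** 2)
    if tau_e_s > 0:
        j += (1.0 - s2) * tau_p / (1.0 + (omega * tau_p) ** 2)
    return 0.4 * j


def oracle_rates(s2, tau_r_ns, tau_e_ps, rex, mhz, r_nh=1.02, csa=-160.0):
    wh = 2.0 * math.pi * mhz * 1e6
    wn = wh * _O_GN / _O_GH
    tau_r = tau_r_ns * 1e-9
    tau_e = tau_e_ps * 1e-12
    d = _O_MU0 / (4 * math.pi) * _O_HBAR * _O_GH * _O_GN / (r_nh * 1e-10) ** 3
    d2 = d * d / 4.0
    c2 = (csa * 1e-6 * wn) ** 2 / 3.0
    jj = lambda w: oracle_j(abs(w), s2, tau_r, tau_e)
    r1 = d2 * (jj(wh - wn) + 3 * jj(wn) + 6 * jj(wh + wn)) + c2 * jj(wn)
    r2 = 0.5 * d2 * (4 * jj(0) + jj(wh - wn) + 3 * jj(wn) + 6 * jj(wh) + 6 * jj(wh + wn)) \
        + c2 / 6.0 * (4 * jj(0) + 3 * jj(wn)) + rex
    noe = 1.0 + (_O_GH / _O_GN) * d2 * (6 * jj(wh + wn) - jj(wh - wn)) / r1
    return r1, r2, noe


ISO5 = DiffusionTensor("isotropic", 5.0)


class TestSpectralDensity:
    def test_rigid_limit_j0(self):
        """J(0) = (2/5) tau_R for a rigid isotropic tumbler."""
        j0 = spectral_density(ModelFreeParams(1, s2=1.0), ISO5, 0.0)
        assert j0 == pytest.approx(2.0e-9, rel=1e-12)

    def test_tau_e_zero_degeneracy(self):
        """Model 2 with tau_e = 0 is exactly model 1 at every frequency."""
        m1 = ModelFreeParams(1, s2=0.8)
        m2 = ModelFreeParams(2, s2=0.8, tau_e_ps=0.0)
        for w in (0.0, 1e8, 5e9):
            assert spectral_density(m2, ISO5, w) == spectral_density(m1, ISO5, w)

    def test_against_independent_oracle(self):
        """Two-Lorentzian sum matches separately coded arithmetic."""
        f800 = SpectrometerField(800.0)
        params = ModelFreeParams(2, s2=0.85, tau_e_ps=50.0)
        tensor = DiffusionTensor("isotropic", 4.3)
        got = spectral_density(params, tensor, abs(f800.omega_n))
        wn = 2 * math.pi * 800e6 * _O_GN / _O_GH
        want = oracle_j(abs(wn), 0.85, 4.3e-9, 50e-12)
        assert got == pytest.approx(want, rel=1e-10)

    @settings(max_examples=60, deadline=None)
    @given(
        s2=st.floats(0.05, 1.0),
        tau_r=st.floats(1.0, 10.0),
        tau_e=st.floats(0.0, 500.0),
    )
    def test_j_positive_and_monotone(self, s2, tau_r, tau_e):
        """J(w) >= 0 and non-increasing in w for any valid parameters."""
        params = ModelFreeParams(2, s2=s2, tau_e_ps=tau_e)
        tensor = DiffusionTensor("isotropic", tau_r)
        omegas = np.linspace(0.0, 6e9, 40)
        j = np.array([spectral_density(params, tensor, w) for w in omegas])
        assert np.all(j > 0)
        assert np.all(np.diff(j) <= 1e-30)

    def test_model_nesting(self):
        """Models collapse onto one another at their boundary parameters."""
        tensor = DiffusionTensor("isotropic", 4.3)
        f = SpectrometerField(800.0)
        m2 = ModelFreeParams(2, s2=0.8, tau_e_ps=0.0)
        m1 = ModelFreeParams(1, s2=0.8)
        m4 = ModelFreeParams(4, s2=0.8, tau_e_ps=75.0, rex=0.0)
        m2b = ModelFreeParams(2, s2=0.8, tau_e_ps=75.0)
        # model 5 with S2_f = 1: slow motion only, tau_s plays tau_e's role
        m5 = ModelFreeParams(5, s2_f=1.0, s2_s=0.8, tau_s_ns=0.075)
        for a, b in ((m2, m1), (m4, m2b), (m5, m2b)):
            ta = predict_relaxation(a, tensor, f)
            tb = predict_relaxation(b, tensor, f)
            assert ta.r1 == pytest.approx(tb.r1, rel=1e-12)
            assert ta.r2 == pytest.approx(tb.r2, rel=1e-12)
            assert ta.noe == pytest.approx(tb.noe, rel=1e-12)

    def test_axial_requires_orientation(self):
        axial = DiffusionTensor("axially_symmetric", 4.3, anisotropy=1.4)
        with pytest.raises(OrientationRequiredError):
            spectral_density(ModelFreeParams(1, s2=0.9), axial, 1e8)

    def test_axial_reduces_to_isotropic(self):
        """Anisotropy 1 reproduces the isotropic J at any orientation."""
        axial = DiffusionTensor("axially_symmetric", 4.3, anisotropy=1.0)
        iso = DiffusionTensor("isotropic", 4.3)
        p = ModelFreeParams(2, s2=0.85, tau_e_ps=40.0)
        for ori in ([1, 0, 0], [0.3, -0.5, 0.8]):
            ja = spectral_density(p, axial, 2e8, nh_orientation=ori)
            ji = spectral_density(p, iso, 2e8)
            assert ja == pytest.approx(ji, rel=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ModelFreeParams(1, s2=1.2)
        with pytest.raises(ValueError):
            ModelFreeParams(3, s2=0.8)  # missing rex
        with pytest.raises(ValueError):
            ModelFreeParams(5, s2=0.5, s2_f=0.9, s2_s=0.9, tau_s_ns=1.0)  # 0.5 != 0.81
        with pytest.raises(ValueError):
            NuclearConstants(r_nh_angstrom=-1.0)


class TestPredictRelaxation:
    def test_oracle_equivalence_on_random_grid(self, rng):
        """Brute-force oracle agreement to 1e-10 over a 50-point grid."""
        tensor_cache = {}
        for _ in range(50):
            s2 = rng.uniform(0.3, 1.0)
            tau_r = rng.uniform(2.0, 8.0)
            tau_e = rng.uniform(0.0, 300.0)
            rex = rng.uniform(0.0, 8.0)
            mhz = rng.choice([600.0, 700.0, 800.0])
            params = ModelFreeParams(4, s2=s2, tau_e_ps=tau_e, rex=rex,
                                     rex_field_mhz=mhz)
            tensor = tensor_cache.setdefault(tau_r, DiffusionTensor("isotropic", tau_r))
            got = predict_relaxation(params, tensor, SpectrometerField(mhz))
            want = oracle_rates(s2, tau_r, tau_e, rex, mhz)
            assert got.r1 == pytest.approx(want[0], rel=1e-10)
            assert got.r2 == pytest.approx(want[1], rel=1e-10)
            assert got.noe == pytest.approx(want[2], rel=1e-10)

    def test_rex_additivity(self):
        """Rex = 4 s^-1 at the measurement field adds exactly 4 to R2."""
        tensor = DiffusionTensor("isotropic", 5.0)
        f = SpectrometerField(800.0)
        base = predict_relaxation(ModelFreeParams(2, s2=0.85, tau_e_ps=30.0), tensor, f)
        with_rex = predict_relaxation(
            ModelFreeParams(4, s2=0.85, tau_e_ps=30.0, rex=4.0, rex_field_mhz=800.0),
            tensor, f,
        )
        assert with_rex.r2 - base.r2 == pytest.approx(4.0, abs=1e-12)
        assert with_rex.r1 == base.r1
        assert with_rex.noe == base.noe

    def test_extreme_narrowing_limit(self):
        """Very fast tumbling matches the oracle's narrowing-limit NOE."""
        got = predict_relaxation(
            ModelFreeParams(1, s2=1.0), DiffusionTensor("isotropic", 1e-3),
            SpectrometerField(800.0),
        )
        want = oracle_rates(1.0, 1e-3, 0.0, 0.0, 800.0)
        assert got.noe == pytest.approx(want[2], rel=1e-10)
        assert got.noe < -2.0  # far from the slow-tumbling plateau near +0.8


class TestRexScaling:
    @pytest.mark.parametrize(
        "ref,target,expected",
        [
            ((3.0, 800.0), 600.0, 1.6875),
            ((3.0, 800.0), 800.0, 3.0),
            ((3.0, 800.0), 700.0, 2.296875),
        ],
    )
    def test_printed_thresholds(self, ref, target, expected):
        assert rex_at_field(ref[0], ref[1], target) == pytest.approx(expected, abs=1e-12)

    def test_round_trip_exact(self):
        """800 -> 600 -> 800 returns the input to within one ulp."""
        x = 3.7
        back = rex_at_field(rex_at_field(x, 800.0, 600.0), 600.0, 800.0)
        assert abs(back - x) <= math.ulp(x)

    def test_invalid_fields(self):
        with pytest.raises(ValueError):
            rex_at_field(3.0, -800.0, 600.0)
        with pytest.raises(ValueError):
            rex_at_field(3.0, 800.0, 0.0)
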