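import numpy as np
import pytest

from ossidrive import coupling as cp
from ossidrive import fem
from ossidrive.middle_ear import build_default_network

FREQS = np.geomspace(160, 8000, 12)
SMALL_STACK = dict(n_layers=5, layer_thickness=0.4e-3)


def small_model(with_rod=True, rod_E=116e9, v_rms=1.0, network=None):
    return cp.build_coupled(
        stack_spec=fem.StackSpec(**SMALL_STACK),
        rod_spec=cp.RodSpec(youngs_modulus=rod_E),
        network=network or build_default_network(),
        v_rms=v_rms, with_rod=with_rod)


class TestRod:
    def test_series_stiffness_identity(self):
        spec = cp.RodSpec(n_elements=6)
        rod = cp.build_rod(spec)
        # condense chain to tip stiffness with base fixed
        K = rod.K[1:, 1:]
        f = np.zeros(rod.ndof - 1)
        f[-1] = 1.0
        tip = np.linalg.solve(K, f)[-1]
        assert 1.0 / tip == pytest.approx(spec.axial_stiffness, rel=1e-12)

    def test_titanium_rod_stiffness_value(self):
        spec = cp.RodSpec(youngs_modulus=116e9, diameter=0.5e-3, length=2e-3)
        expect = 116e9 * np.pi * (0.25e-3) ** 2 / 2.0e-3   # = 1.139e7 N/m
        assert spec.axial_stiffness == pytest.approx(expect, rel=1e-12)
        assert spec.axial_stiffness == pytest.approx(1.1388e7, rel=1e-3)

    def test_element_count_invariance_static(self):
        for n in (1, 6):
            spec = cp.RodSpec(n_elements=n)
            rod = cp.build_rod(spec)
            K = rod.K[1:, 1:]
            f = np.zeros(rod.ndof - 1)
            f[-1] = 1.0
            tip = np.linalg.solve(K, f)[-1]
            assert 1.0 / tip == pytest.approx(spec.axial_stiffness, rel=1e-10)


class TestCouple:
    def test_dof_bookkeeping_without_rod(self):
        model = small_model(with_rod=False)
        assert model.rod is None
        assert model.ndof == model.stack.ndof + model.network.ndof

    def test_combined_stiffness_symmetric(self):
        model = small_model()
        d = abs(model.K - model.K.T).max()
        assert d < 1e-9 * abs(model.K).max()

    def test_zero_drive_zero_response(self):
        model = small_model(v_rms=0.0)
        sol = cp.harmonic_response(model, [1000.0])
        assert np.allclose(sol, 0.0)

    def test_rigid_rod_limit_matches_direct_tie(self):
        direct = small_model(with_rod=False)
        stiff = small_model(rod_E=1e15)
        d0 = np.abs(cp.transducer_drive(direct, 1.0, FREQS))
        d1 = np.abs(cp.transducer_drive(stiff, 1.0, FREQS))
        db = 20 * np.log10(d1 / d0)
        assert np.max(np.abs(db)) < 0.1


class TestTransducerDrive:
    def test_linearity(self):
        model = small_model()
        d1 = cp.transducer_drive(model, 1.0, FREQS)
        d2 = cp.transducer_drive(model, 5.0, FREQS)
        assert np.allclose(np.abs(d2), 5 * np.abs(d1), rtol=1e-12)

    def test_smoke_designed_device(self):
        model = cp.build_coupled(v_rms=10.5)  # 50-layer default
        d = cp.transducer_drive(model, 10.5, FREQS)
        assert np.all(np.isfinite(d))
        assert np.all(np.abs(d) > 0)

    def test_zero_drive_rejected(self):
        model = small_model()
        with pytest.raises(ValueError, match="drive"):
            cp.transducer_drive(model, 0.0, FREQS)

    def test_more_layers_more_output(self):
        net = build_default_network()
        out = {}
        for n in (25, 50):
            model = cp.build_coupled(
                stack_spec=fem.StackSpec(n_layers=n,
                                         layer_thickness=2e-3 / n),
                network=net, v_rms=10.5)
            out[n] = np.abs(cp.transducer_drive(model, 10.5, FREQS))
        assert np.all(out[50] > out[25])


@pytest.fixture(scope="module")
def layer_study_table():
    return cp.layer_number_study([10, 20, 40], frequencies=FREQS)


@pytest.fixture(scope="module")
def rod_study_tables():
    return cp.rod_stiffness_study(
        [116e9, 510e9, 1e15],
        stack_spec=fem.StackSpec(**SMALL_STACK), frequencies=FREQS)


class TestLayerStudy:
    @pytest.fixture
    def study(self, layer_study_table):
        return layer_study_table

    def test_complete_table(self, study):
        assert sorted(study.n_layers.unique()) == [10, 20, 40]
        assert len(study) == 3 * len(FREQS)

    def test_peq_monotone_in_layers(self, study):
        piv = study.pivot(index="frequency_hz", columns="n_layers",
                          values="peq_db")
        assert ((piv[20] > piv[10]) & (piv[40] > piv[20])).all()

    def test_doubling_layers_adds_6db_at_low_frequency(self, study):
        low = study[study.frequency_hz == study.frequency_hz.min()]
        d = low.set_index("n_layers").d_tr_m
        gain = 20 * np.log10(d[20] / d[10])
        assert gain == pytest.approx(6.0206, abs=0.5)
        gain2 = 20 * np.log10(d[40] / d[20])
        assert gain2 == pytest.approx(6.0206, abs=0.5)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            cp.layer_number_study([])


class TestRodStudy:
    @pytest.fixture
    def study(self, rod_study_tables):
        return rod_study_tables

    def test_output_shape(self, study):
        spectra, summary = study
        assert len(summary) == 3
        assert len(spectra) == 3 * len(FREQS)

    def test_softer_rod_larger_drop(self, study):
        _, summary = study
        s = summary.set_index("rod_E_gpa")
        assert s.loc[116.0, "max_drop_db"] >= s.loc[510.0, "max_drop_db"]

    def test_rigid_limit_negligible(self, study):
        _, summary = study
        s = summary.set_index("rod_E_gpa")
        assert s.loc[1e6, "max_abs_dh_db"] < 0.5
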