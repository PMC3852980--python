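"""Binding-parameter regression and the sklearn estimator surface."""

import numpy as np
import pytest
from sklearn.base import clone

from freesolvent import (
    FreeSolventModel,
    NoiseModel,
    OsmoticDataset,
    ValidationError,
    fit_binding_parameters,
)

GRID = tuple(np.linspace(50.0, 450.0, 15))


@pytest.fixture(scope="module")
def noiseless_bsa(scenarios=None):
    from freesolvent import preset_scenarios

    scen = preset_scenarios()["bsa_ph4.5"]
    return scen, scen.generate(conc_grid=GRID)


class TestParameterRecovery:
    def test_noiseless_recovery_both_parameters(self, noiseless_bsa):
        scen, ds = noiseless_bsa
        truth_nu1 = scen.hydration_mol_per_mol
        result = fit_binding_parameters(
            ds, init={"hydration": 3000.0, "ion_binding": 5.0}
        )
        assert result.converged
        assert result.hydration_mol_per_mol == pytest.approx(truth_nu1, rel=1e-3)
        assert result.ion_binding == pytest.approx(scen.ion_binding, rel=1e-3)
        assert result.rmse < 1.0  # Pa, against a ~1e5 Pa signal

    def test_one_dimensional_fit_leaves_fixed_parameter(self, noiseless_bsa):
        scen, ds = noiseless_bsa
        result = fit_binding_parameters(
            ds,
            fit_ion_binding=False,
            init={"hydration": 3000.0, "ion_binding": scen.ion_binding},
        )
        assert result.hydration_mol_per_mol == pytest.approx(
            scen.hydration_mol_per_mol, rel=1e-3
        )
        assert result.ion_binding == scen.ion_binding
        assert result.free_parameters == ("hydration",)

    def test_underdetermined_dataset_rejected(self, noiseless_bsa):
        scen, _ = noiseless_bsa
        ds = OsmoticDataset([300.0], [4.0e5], system=scen.system())
        with pytest.raises(ValidationError):
            fit_binding_parameters(ds)

    def test_objective_is_local_minimum_at_truth(self, noiseless_bsa):
        scen, ds = noiseless_bsa
        model = FreeSolventModel(
            hydration=scen.hydration_mol_per_mol,
            ion_binding=scen.ion_binding,
            protein_molar_mass=scen.protein.molar_mass,
            salt_molarity=scen.salt_molarity,
            salt_molar_mass=scen.salt.molar_mass,
            temperature=scen.temperature,
            partial_specific_volume=scen.partial_specific_volume,
        )
        X = ds.conc.reshape(-1, 1)

        def sse(nu1, nu3):
            m = clone(model).set_params(hydration=nu1, ion_binding=nu3)
            return float(np.sum((m.predict(X) - ds.pressure_Pa) ** 2))

        truth = sse(scen.hydration_mol_per_mol, scen.ion_binding)
        for d1 in (-50.0, 50.0):
            for d3 in (-1.0, 1.0):
                assert truth <= sse(
                    scen.hydration_mol_per_mol + d1, scen.ion_binding + d3
                )

    def test_fit_invariant_to_pressure_unit(self, noiseless_bsa, tmp_path):
        from freesolvent import read_dataset, write_dataset

        scen, ds = noiseless_bsa
        pa, mmhg = tmp_path / "pa.csv", tmp_path / "mmhg.csv"
        write_dataset(ds, pa, pressure_unit="Pa")
        write_dataset(ds, mmhg, pressure_unit="mmHg")
        init = {"hydration": 3000.0, "ion_binding": 5.0}
        fits = [
            fit_binding_parameters(read_dataset(p, system=scen.system()), init=init)
            for p in (pa, mmhg)
        ]
        assert fits[0].hydration_mol_per_mol == pytest.approx(
            fits[1].hydration_mol_per_mol, rel=1e-6
        )
        assert fits[0].ion_binding == pytest.approx(fits[1].ion_binding, rel=1e-6)

    def test_noisy_recovery_median_error(self):
        """2% multiplicative noise, 15 concentrations: ν12 recovered within
        a few percent in the median over replicates."""
        from freesolvent import preset_scenarios

        scen = preset_scenarios()["bsa_ph4.5"]
        truth = scen.hydration_mol_per_mol
        errors = []
        for rep in range(10):
            ds = scen.generate(
                noise=NoiseModel("multiplicative_gaussian", 0.02, seed=1000 + rep),
                conc_grid=GRID,
            )
            res = fit_binding_parameters(
                ds, init={"hydration": 3000.0, "ion_binding": 5.0}
            )
            errors.append(abs(res.hydration_mol_per_mol - truth) / truth)
        assert np.median(errors) <= 0.05


class TestEstimatorSurface:
    def test_get_set_params_and_clone(self):
        m = FreeSolventModel(hydration=4000.0, ion_binding=9.0)
        params = m.get_params()
        assert params["hydration"] == 4000.0
        m2 = clone(m).set_params(ion_binding=6.0)
        assert m2.get_params()["ion_binding"] == 6.0
        assert not hasattr(m2, "hydration_")

    def test_fit_sets_trailing_underscore_attributes(self, noiseless_bsa):
        scen, ds = noiseless_bsa
        m = FreeSolventModel(
            hydration=3000.0,
            ion_binding=5.0,
            protein_molar_mass=scen.protein.molar_mass,
            salt_molarity=scen.salt_molarity,
            salt_molar_mass=scen.salt.molar_mass,
            temperature=scen.temperature,
            partial_specific_volume=scen.partial_specific_volume,
        )
        m.fit(ds.conc.reshape(-1, 1), ds.pressure_Pa)
        assert m.converged_
        assert m.rmse_ >= 0
        assert set(m.stderr_) == {"hydration", "ion_binding"}
        assert m.hydration_g_per_g_ == pytest.approx(1.144, abs=5e-3)
        # R^2 against its own noiseless data is essentially 1
        assert m.score(ds.conc.reshape(-1, 1), ds.pressure_Pa) > 0.999999

    def test_predict_without_fit_uses_constructor_parameters(self):
        m = FreeSolventModel()
        pi = m.predict([[300.0]])
        assert pi.shape == (1,)
        assert pi[0] > 0

    def test_rejects_bad_inputs(self):
        m = FreeSolventModel()
        with pytest.raises(ValidationError):
            m.predict([[-5.0]])
        with pytest.raises(ValidationError):
            m.predict([[1.0, 2.0]])
        with pytest.raises(ValidationError):
            m.fit([[100.0], [200.0]], [1.0])
        with pytest.raises(ValidationError):
            FreeSolventModel(fit_hydration=False, fit_ion_binding=False).fit(
                [[100.0], [200.0]], [1.0, 2.0]
            )

    def test_cannot_fit_ion_binding_without_salt(self):
        m = FreeSolventModel(salt_molarity=0.0)
        with pytest.raises(ValidationError, match="salt-free"):
            m.fit([[100.0], [200.0]], [1.0, 2.0])
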