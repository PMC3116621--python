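"""Time courses, steady states, initial rates, scans and knockouts."""

import numpy as np
import pytest

import ptsei as P


@pytest.fixture(scope="module")
def env25(truth):
    return P.Environment.from_celsius(25.0, 7.0)


class TestTimeCourse:
    def test_no_enzyme_no_signal(self, truth, env25):
        spec = P.ExperimentSpec.model1(
            env=env25, EItotal=0.0, HPrtotal=1e-2, PEP0=0.1,
            observable="phospho_EI", times=np.linspace(0, 100, 5))
        traj = P.time_course(spec, truth)
        assert np.allclose(traj.values, 0.0)

    def test_no_pep_no_phosphorylation(self, truth, env25):
        spec = P.ExperimentSpec.model1(
            env=env25, EItotal=1e-3, PEP0=0.0,
            observable="phospho_EI", times=np.linspace(0, 500, 6))
        traj = P.time_course(spec, truth)
        assert np.allclose(traj.values, 0.0, atol=1e-12)

    def test_pure_hydrolysis_leaves_15_percent(self, truth, env25):
        frozen = truth.updated(k={kid: 0.0 for kid in truth.k
                                  if kid.startswith("kt:")})
        spec = P.ExperimentSpec.model1(
            env=env25, EItotal=0.0, HPrtotal=5e-3,
            observable="phospho_HPr", times=np.array([0.0, 1800.0]),
            initial={"HPrP": 5e-3})
        traj = P.time_course(spec, frozen)
        assert traj.values[-1] / 5e-3 == pytest.approx(0.15, rel=1e-6)

    def test_conservation_along_trajectory(self, truth, env25):
        spec = P.ExperimentSpec.model1(
            env=env25, EItotal=2e-3, HPrtotal=1e-2, PEP0=0.08, Pyr0=0.01,
            observable="total_phospho_protein", times=np.geomspace(1, 2000, 8))
        traj = P.time_course(spec, truth)
        for st in traj.states:
            assert st.EI_monomer_equivalents == pytest.approx(2e-3, rel=1e-9)
            part = P.partition_pools(truth, st.PEP, st.Pyr, env25)
            conc = P.microstate_concentrations(st, part)
            lhs = st.PEP + st.PTSP + conc["EIoPEP"] + st.Pi
            assert lhs == pytest.approx(0.08, rel=1e-7)
            assert st.HPr + st.HPrP == pytest.approx(1e-2, rel=1e-12)

    def test_grid_refinement_stability(self, truth, env25):
        times = np.geomspace(5, 600, 6)
        base = P.ExperimentSpec.model1(
            env=env25, EItotal=1e-3, HPrtotal=5e-3, PEP0=0.05,
            observable="total_phospho_protein", times=times, rtol=1e-8)
        fine = P.ExperimentSpec.model1(
            env=env25, EItotal=1e-3, HPrtotal=5e-3, PEP0=0.05,
            observable="total_phospho_protein", times=times, rtol=5e-9)
        a = P.time_course(base, truth).values
        b = P.time_course(fine, truth).values
        assert np.all(np.abs(a - b) <= 1e-3 * np.abs(a) + 1e-15)


class TestSteadyState:
    def test_zero_phosphorylation_means_zero_flux(self, truth, env25):
        nophos = truth.updated(k={kid: 0.0 for kid in truth.k
                                  if kid.startswith("kp:")})
        spec = P.ExperimentSpec.model2(env=env25, EItotal=2e-3, PEP=0.1,
                                       Pyr=0.0, HPr=0.01)
        st, dec = P.steady_state(spec, nophos)
        assert dec.total == pytest.approx(0.0, abs=1e-15)

    def test_residual_and_decomposition(self, truth, env25, model=None):
        spec = P.ExperimentSpec.model2(env=env25, EItotal=2e-3, PEP=0.1,
                                       Pyr=0.01, HPr=0.01)
        st, dec = P.steady_state(spec, truth)
        d = P.rhs_model2(st, truth, env25)
        assert max(abs(v) for v in d.values()) < 1e-12
        assert dec.monomer + dec.ZP + dec.ZP2 == pytest.approx(dec.total, rel=1e-10)
        assert st.EI_monomer_equivalents == pytest.approx(2e-3, rel=1e-9)

    def test_matches_long_integration(self, truth, env25):
        spec = P.ExperimentSpec.model2(env=env25, EItotal=1e-3, PEP=0.05,
                                       Pyr=0.0, HPr=0.02)
        st, _ = P.steady_state(spec, truth)
        tc = P.ExperimentSpec.model2(env=env25, EItotal=1e-3, PEP=0.05,
                                     Pyr=0.0, HPr=0.02,
                                     observable="Y_concentration",
                                     times=np.array([0.0, 1e6]), rtol=1e-10)
        traj = P.time_course(tc, truth)
        end = traj.states[-1]
        for a, b in zip(st.pools(), end.pools()):
            assert b == pytest.approx(a, rel=1e-6, abs=1e-12)

    def test_low_pep_validity_warning(self, truth, env25):
        spec = P.ExperimentSpec.model2(env=env25, EItotal=1e-3, PEP=5e-4,
                                       Pyr=0.0, HPr=0.01)
        with pytest.warns(UserWarning, match="sub-micromolar"):
            P.steady_state(spec, truth)


class TestInitialRate:
    def test_zero_hpr_zero_rate(self, truth, env25):
        spec = P.ExperimentSpec.model2(env=env25, EItotal=1e-3, PEP=0.1,
                                       Pyr=0.0, HPr=0.0)
        assert P.initial_rate(spec, truth) == 0.0

    def test_monotone_in_hpr(self, truth):
        env = P.Environment.from_celsius(25.0, 7.2)
        rates = []
        for hpr in (2e-3, 6e-3, 0.012, 0.024, 0.05):
            spec = P.ExperimentSpec.model2(env=env, EItotal=1.3e-3, PEP=2.0,
                                           Pyr=0.0, HPr=hpr)
            rates.append(P.initial_rate(spec, truth))
        assert all(b >= a * (1 - 1e-6) for a, b in zip(rates, rates[1:]))
        assert rates[-1] > 0

    def test_rate_proportional_to_enzyme_when_dilute(self, truth):
        """Doubling the enzyme doubles the rate once the catalytic turnover
        is isolated from the association equilibria (pre-dimerized enzyme,
        dissociative recycling off; with recycling on, slow bimolecular
        re-dimerization makes the flux genuinely superlinear in EI)."""
        nodis = truth.updated(k={kid: 0.0 for kid in truth.k
                                 if kid.startswith("kd:")})
        env = P.Environment.from_celsius(25.0, 7.2)
        r = []
        for ei in (2e-5, 4e-5):
            spec = P.ExperimentSpec.model2(env=env, EItotal=ei, PEP=2.0,
                                           Pyr=0.0, HPr=0.05,
                                           initial={"Z": ei / 2})
            r.append(P.initial_rate(spec, nodis))
        assert r[1] / r[0] == pytest.approx(2.0, rel=0.05)


class TestScan2D:
    def test_single_cell_equals_steady_state(self, truth, env25):
        spec = P.ExperimentSpec.model2(env=env25, EItotal=1e-3, PEP=0.1,
                                       Pyr=0.0, HPr=0.02)
        st, dec = P.steady_state(spec, truth)
        M, ok = P.scan_2d(spec, truth, [0.1], [0.0], "steady_rate")
        assert ok[0, 0]
        assert M[0, 0] == pytest.approx(dec.total, rel=1e-8)

    def test_decomposition_components_sum(self, truth, env25):
        spec = P.ExperimentSpec.model2(env=env25, EItotal=1e-3, PEP=0.1,
                                       Pyr=0.0, HPr=0.02)
        peps, pyrs = [0.05, 0.5], [0.0, 0.01]
        total, _ = P.scan_2d(spec, truth, peps, pyrs, "steady_rate")
        parts = [P.scan_2d(spec, truth, peps, pyrs, f"flux_{c}")[0]
                 for c in ("monomer", "ZP", "ZP2")]
        assert np.allclose(sum(parts), total, rtol=1e-8)

    def test_monomer_knockout_changes_y_map(self, truth, env25):
        """Without monomer transfer, free unphosphorylated monomers pile up
        at low PEP instead of peaking at balanced PEP/Pyr."""
        spec = P.ExperimentSpec.model2(env=env25, EItotal=5e-3, PEP=0.1,
                                       Pyr=0.0, HPr=0.04,
                                       observable="Y_concentration")
        peps = np.array([0.005, 0.05, 0.5, 5.0])
        pyrs = np.array([0.002])
        Y_full, ok1 = P.scan_2d(spec, truth, peps, pyrs, "Y_concentration")
        ko = P.variant_experiment(truth, "no_monomer_transfer")
        Y_ko, ok2 = P.scan_2d(spec, ko, peps, pyrs, "Y_concentration")
        assert ok1.all() and ok2.all()
        assert not np.allclose(Y_full, Y_ko, rtol=0.05)
        # knockout's Y maximum sits at the lowest PEP of the scan
        assert int(np.argmax(Y_ko[0])) == 0

    def test_unknown_quantity_rejected(self, truth, env25):
        spec = P.ExperimentSpec.model2(env=env25, EItotal=1e-3, PEP=0.1,
                                       Pyr=0.0, HPr=0.02)
        with pytest.raises(ValueError):
            P.scan_2d(spec, truth, [0.1], [0.0], "banana")


class TestKnockouts:
    def test_named_constants_zeroed_and_original_untouched(self, truth):
        before = dict(truth.k)
        ko = P.variant_experiment(truth, "no_second_phosphorylation")
        assert all(ko.k[kid] == 0.0 for kid in ko.k if kid.startswith("kp:ZP("))
        assert all(ko.k[kid] == truth.k[kid] for kid in ko.k
                   if not kid.startswith("kp:ZP("))
        assert truth.k == before

    def test_all_knockout_names(self, truth):
        prefixes = {
            "no_monomer_transfer": "kt:YP:",
            "no_Z_dissociation": "kd:Z(",
        }
        for name, prefix in prefixes.items():
            ko = P.variant_experiment(truth, name)
            assert all(ko.k[kid] == 0.0 for kid in ko.k if kid.startswith(prefix))
        cyc = P.variant_experiment(truth, "cyclic_only")
        assert all(cyc.k[kid] == 0.0 for kid in cyc.k
                   if kid.startswith(("kt:ZP:", "kt:ZP2:")))
        assert any(cyc.k[kid] > 0 for kid in cyc.k if kid.startswith("kt:YP:"))

    def test_none_is_identity_copy(self, truth):
        same = P.variant_experiment(truth, None)
        assert same.k == truth.k and same is not truth

    def test_unknown_knockout_rejected(self, truth):
        with pytest.raises(ValueError):
            P.variant_experiment(truth, "no_flux_capacitor")
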