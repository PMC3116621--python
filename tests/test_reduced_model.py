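"""Quasi-equilibrium partition, lumped rates and the Model I/II right-hand
sides, checked against the unreduced elementary mass-action system."""

import numpy as np
import pytest

import ptsei as P
from ptsei.reduced_model import POOLS


class TestPartition:
    def test_no_ligand_means_root_states_only(self, truth):
        part = P.partition_pools(truth, 0.0, 0.0)
        for pool, fr in part.fractions.items():
            for s, f in fr.items():
                bare = s.ligand_count("PEP") == 0 and s.ligand_count("Pyr") == 0
                assert f == pytest.approx(1.0 if bare else 0.0)

    def test_monomer_half_occupancy_at_K(self, truth):
        K = truth.site_K()["Kb:Y(e)>Y(f)"]
        part = P.partition_pools(truth, K, 0.0)
        fr = {s.label: f for s, f in part.fractions["Y"].items()}
        assert fr["Y(e)"] == pytest.approx(fr["Y(f)"])

    def test_fractions_normalized(self, model):
        f = model.fractions(0.2, 0.05)
        for p in POOLS:
            assert f[model.pool_slices[p]].sum() == pytest.approx(1.0)

    def test_partition_matches_elementary_equilibrium(self, truth, ref_env):
        """Independent oracle: the binding-only elementary system relaxed to
        equilibrium at clamped free ligands reproduces the analytic
        partition fractions."""
        eff = P.apply_environment(truth, ref_env)
        frozen = truth.updated(k={kid: 0.0 for kid in truth.k})
        eff0 = P.apply_environment(frozen, ref_env)
        sys_ = P.ElementarySystem(eff0, binding_rate=1e5)
        PEP, Pyr = 0.05, 0.3
        pools = {"Y": 1e-3, "Z": 5e-4, "ZP": 5e-4, "ZP2": 5e-4, "YP": 1e-3}
        y0 = sys_.initial(pools, PEP=PEP, Pyr=Pyr)
        # clamp free ligands by making the reservoir overwhelmingly large
        y0[sys_.i_small["PEP"]] = PEP
        y0[sys_.i_small["Pyr"]] = Pyr
        sol = sys_.simulate(y0, np.array([0.0, 50.0]), rtol=1e-10, atol=1e-16)
        yeq = sol.y[:, -1]
        PEP_eq = yeq[sys_.i_small["PEP"]]
        Pyr_eq = yeq[sys_.i_small["Pyr"]]
        part = P.partition_pools(truth, PEP_eq, Pyr_eq)
        for i, s in enumerate(sys_.states):
            tot = sum(yeq[j] for j, t in enumerate(sys_.states) if t.pool == s.pool)
            assert yeq[i] / tot == pytest.approx(
                part.fractions[s.pool][s], rel=1e-5, abs=1e-9)

    def test_rejects_nonfinite_ligands(self, model):
        with pytest.raises(ValueError):
            model.weights(float("nan"), 0.0)
        with pytest.raises(ValueError):
            model.weights(-0.1, 0.0)


class TestMicrostates:
    def test_sum_back_to_pool_totals(self, truth):
        part = P.partition_pools(truth, 0.1, 0.02)
        st = P.LumpedState(Y=1e-3, Z=4e-4, ZP=3e-4, ZP2=2e-4, YP=5e-4,
                           PEP=0.1, Pyr=0.02)
        conc = P.microstate_concentrations(st, part)
        for pool, total in zip(POOLS, st.pools()):
            got = sum(v for k, v in conc.items()
                      if not k.startswith("EIo") and k.startswith(pool + "("))
            assert got == pytest.approx(total, rel=1e-12, abs=1e-18)

    def test_bound_ligand_aggregates(self, truth):
        part0 = P.partition_pools(truth, 0.0, 0.0)
        st = P.LumpedState(Y=1e-3, Z=1e-4, ZP=1e-4, ZP2=1e-4, YP=1e-3)
        conc = P.microstate_concentrations(st, part0)
        assert conc["EIoPEP"] == 0.0 and conc["EIoPyr"] == 0.0
        part = P.partition_pools(truth, 0.5, 0.5)
        conc = P.microstate_concentrations(st, part)
        assert conc["EIoPEP"] > 0 and conc["EIoPyr"] > 0
        # dimers contribute per bound ligand: aggregate bounded by 2 x dimers + monomers
        cap = st.Y + st.YP + 2 * (st.Z + st.ZP + st.ZP2)
        assert conc["EIoPEP"] + conc["EIoPyr"] < cap


class TestLumpedRates:
    def test_zero_rate_constants_zero_rates(self, truth, ref_env):
        frozen = truth.updated(k={kid: 0.0 for kid in truth.k}, k9=0.0)
        part = P.partition_pools(frozen, 0.1, 0.0, ref_env)
        st = P.LumpedState(Y=1e-3, Z=1e-4, ZP=1e-4, ZP2=1e-4, YP=1e-3,
                           PEP=0.1, Pyr=0.0, HPr=0.01, HPrP=0.005)
        V = P.lumped_rates(st, part, frozen, ref_env)
        assert np.allclose(V, 0.0)

    def test_hydrolysis_first_order(self, truth, ref_env):
        part = P.partition_pools(truth, 0.1, 0.0, ref_env)
        st = P.LumpedState(Y=1e-3, PEP=0.1, HPr=0.01, HPrP=0.0)
        V = P.lumped_rates(st, part, truth, ref_env)
        assert V[8] == 0.0
        st.HPrP = 2e-3
        V = P.lumped_rates(st, part, truth, ref_env)
        assert V[8] == pytest.approx(truth.k9 * 2e-3)


class TestRhs:
    def test_all_rates_zero_gives_zero_derivatives(self, truth, ref_env):
        frozen = truth.updated(k={kid: 0.0 for kid in truth.k}, k9=0.0)
        totals = P.ConservedTotals(EItotal=2e-3, HPrtotal=1e-2, PEP0=0.1)
        st = P.LumpedState(Y=2e-3, HPr=1e-2)
        d = P.rhs_model1(st, totals, frozen, ref_env)
        for key in ("dY", "dZ", "dZP", "dYP", "dHPrP", "dPi"):
            assert d[key] == pytest.approx(0.0, abs=1e-18)

    def test_ei_conservation_is_analytic(self, truth, ref_env):
        totals = P.ConservedTotals(EItotal=2e-3, HPrtotal=1e-2, PEP0=0.1)
        st = P.LumpedState(Y=1e-3, Z=2e-4, ZP=1e-4, YP=1e-4, HPrP=1e-4)
        d = P.rhs_model1(st, totals, truth, ref_env)
        # dZP2/dt from the closure must cancel the other pool derivatives
        dZP2 = -(d["dY"] + 2 * d["dZ"] + 2 * d["dZP"] + d["dYP"]) / 2
        total_rate = d["dY"] + 2 * d["dZ"] + 2 * d["dZP"] + 2 * dZP2 + d["dYP"]
        assert total_rate == pytest.approx(0.0, abs=1e-20)

    def test_hpr_moiety_balance_without_hydrolysis(self, truth, ref_env):
        nohyd = truth.updated(k9=0.0)
        totals = P.ConservedTotals(EItotal=2e-3, HPrtotal=1e-2, PEP0=0.1)
        st = P.LumpedState(Y=1e-3, Z=2e-4, ZP=1e-4, YP=1e-4, HPrP=1e-4)
        d = P.rhs_model1(st, totals, nohyd, ref_env)
        V = d["V"]
        assert d["dHPrP"] == pytest.approx(V[4] + V[6] + V[7])
        # dHPr/dt = -dHPrP/dt by Eq HPr + HPrP = HPrtotal

    def test_model2_is_subsystem_of_model1(self, truth, ref_env, model):
        """With totals chosen so that the Model I closures solve to the
        Model II clamps, the enzyme-pool derivatives coincide."""
        PEPf, Pyrf, HPr = 0.08, 0.02, 0.01
        st = P.LumpedState(Y=6e-4, Z=2e-4, ZP=1.5e-4, ZP2=1e-4, YP=3e-4,
                           PEP=PEPf, Pyr=Pyrf, HPr=HPr, HPrP=0.0, Pi=0.0)
        part = P.partition_pools(truth, PEPf, Pyrf, ref_env)
        conc = P.microstate_concentrations(st, part)
        PTSP = st.PTSP
        totals = P.ConservedTotals(
            EItotal=st.EI_monomer_equivalents,
            HPrtotal=HPr,
            PEP0=PEPf + conc["EIoPEP"] + PTSP,
            Pyr0=Pyrf + conc["EIoPyr"] - PTSP,
            PTSP0=0.0,
        )
        d1 = P.rhs_model1(st, totals, truth, ref_env)
        assert d1["PEP"] == pytest.approx(PEPf, rel=1e-9)
        assert d1["Pyr"] == pytest.approx(Pyrf, rel=1e-9)
        d2 = P.rhs_model2(st, truth, ref_env)
        for key in ("dY", "dZ", "dZP", "dYP"):
            assert d2[key] == pytest.approx(d1[key], rel=1e-7, abs=1e-16)

    def test_negative_closure_raises(self, truth, ref_env):
        totals = P.ConservedTotals(EItotal=1e-3, HPrtotal=0.0)
        st = P.LumpedState(Y=2e-3)  # exceeds EItotal -> negative ZP2
        with pytest.raises(ValueError):
            P.rhs_model1(st, totals, truth, ref_env)


class TestFreeLigandClosure:
    @pytest.mark.parametrize("availE,availY", [
        (0.0, 0.0), (1e-4, 0.0), (0.0, 1e-3), (0.02, 0.01), (5.0, 2.0),
    ])
    def test_ligand_balance_residual(self, model, availE, availY):
        pools = np.array([1e-3, 5e-4, 5e-4, 3e-4, 1e-3])
        p, q = model.free_ligands(pools, availE, availY)
        frac = model.fractions(p, q)
        bE, bY = model.mean_bound(frac, pools)
        assert p + bE == pytest.approx(availE, abs=1e-11 * (1 + availE))
        assert q + bY == pytest.approx(availY, abs=1e-11 * (1 + availY))

    def test_strong_binding_regime(self, model):
        # enzyme in large excess over ligand: nearly everything bound
        pools = np.array([0.5, 0.2, 0.2, 0.1, 0.2])
        p, q = model.free_ligands(pools, 1e-4, 0.0)
        assert 0.0 <= p < 1e-4


def test_reduction_matches_elementary_system(truth, ref_env):
    """With binding rates far above the slowest slow step, pooled
    trajectories of the full elementary system converge to the reduced
    model after the boundary layer (single-draw check; the multi-draw sweep
    lives in the acceptance suite)."""
    eff = P.apply_environment(truth, ref_env)
    sys_ = P.ElementarySystem(eff, binding_rate=1e6)
    EI, HPr, PEP = 2e-3, 5e-3, 0.05
    y0 = sys_.initial({"Y": EI}, PEP=PEP, HPr=HPr)
    tgrid = np.geomspace(1.0, 300.0, 8)
    sol = sys_.simulate(y0, np.concatenate([[0.0], tgrid]), rtol=1e-10, atol=1e-17)
    pooled = sys_.pools_of(sol.y.T)

    spec = P.ExperimentSpec.model1(
        env=ref_env, EItotal=EI, HPrtotal=HPr, PEP0=PEP,
        observable="phospho_EI", times=tgrid)
    traj = P.time_course(spec, truth)
    for k, t in enumerate(tgrid, start=1):
        st = traj.states[k - 1]
        for pool, want in zip(POOLS, st.pools()):
            got = pooled[pool][k]
            assert got == pytest.approx(want, rel=0.01, abs=1e-6 * EI)
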