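"""Equilibration, stimulation trajectories, observables and 2C4 blocking."""

import numpy as np
import pandas as pd
import pytest

from herdyn.model import CompiledModel
from herdyn.parameters import default_parameters
from herdyn.simulate import (
    FIXTURE_PROFILES,
    CellLineProfile,
    StimulationProtocol,
    Trajectory,
    apply_block,
    compute_observables,
    equilibrate,
    run_protocol,
    simulate,
)
from herdyn.species import EARLY_ENDOSOME, SURFACE, enumerate_species


@pytest.fixture(scope="module")
def eq_parental(params):
    return equilibrate(FIXTURE_PROFILES["parental"], params)


@pytest.fixture(scope="module")
def eq_d20(params):
    return equilibrate(FIXTURE_PROFILES["HER2+3+"], params)


def test_parental_steady_state_has_200k_her1(eq_parental, model):
    totals = model.receptor_totals(eq_parental.state)
    assert totals[0] == pytest.approx(200_000, rel=1e-3)
    assert totals[1] == totals[2] == 0.0
    assert eq_parental.residual_norm < 1e-9


def test_zero_expression_equilibrates_to_zero_state(params):
    eq = equilibrate(CellLineProfile("empty", 0, 0, 0), params)
    assert np.all(eq.state == 0.0)
    assert np.all(eq.synthesis == 0.0)


def test_zero_synthesis_decays_toward_zero(params):
    # with synthesis off, any initial receptor load drains to degradation
    eq = equilibrate(FIXTURE_PROFILES["parental"], params)
    eq.synthesis[:] = 0.0
    prot = StimulationProtocol(0, 0, 2000.0, (0.0, 2000.0))
    traj = simulate(eq, prot, params)
    assert traj.states[-1].max() < 1e-3 * traj.states[0].max()


def test_surface_fraction_matches_linear_system_oracle(params, eq_parental):
    """The ligand-free HER1 distribution solves the 3-compartment balance."""
    from herdyn.simulate import _monomer_rates

    ss = enumerate_species()
    kt, kr, kl, kd = _monomer_rates(params, "HER1")
    q = eq_parental.synthesis[ss.state_index("R1", SURFACE)]
    A = np.array([
        [-kt, kr, 0.0],
        [kt, -(kr + kl), 0.0],
        [0.0, kl, -kd],
    ])
    x = np.linalg.solve(A, -np.array([q, 0.0, 0.0]))
    got = [eq_parental.state[ss.state_index("R1", c)]
           for c in ("surface", "early_endosome", "late_endosome")]
    np.testing.assert_allclose(got, x, rtol=1e-9)
    assert sum(x) == pytest.approx(200_000, rel=1e-6)


def test_zero_dose_trajectory_stays_at_steady_state(eq_d20, params):
    prot = StimulationProtocol(0, 0, 120.0, (0.0, 60.0, 120.0))
    traj = simulate(eq_d20, prot, params)
    for row in traj.states:
        np.testing.assert_allclose(row, eq_d20.state, rtol=1e-5, atol=1e-4)


def test_trajectory_nonnegative_and_mass_balanced(eq_d20, params, model):
    prot = StimulationProtocol(12, 40, 120.0, (0.0, 30.0, 120.0))
    traj = simulate(eq_d20, prot, params)
    assert np.all(traj.states >= 0.0)
    # receptor totals change only through synthesis - degradation
    model.synthesis = traj.equilibrium.synthesis
    counts = model.species.receptor_count_matrix()
    synth_totals = counts @ traj.equilibrium.synthesis.reshape(
        3, model.species.n_species).sum(axis=0)
    for k in range(len(traj.times)):
        y = traj.states[k]
        dy = model.rhs(0.0, y)
        total_rate = counts @ dy.reshape(3, model.species.n_species).sum(axis=0)
        expected = synth_totals - model.degradation_flux(y)
        np.testing.assert_allclose(total_rate, expected, rtol=1e-8, atol=1e-6)


def test_kd_invariance_in_no_trafficking_limit(params):
    """Doubling kon and koff together leaves the binding equilibrium fixed.

    Dimerization is switched off as well: the lumped collapse channel makes
    dimer abundances rate- (not just Kd-) dependent by construction.
    """
    def no_traffic(p):
        p = p.copy()
        p.kt = {k: 0.0 for k in p.kt}
        p.ke_her1_dimer_per_min = p.ke_her23_dimer_per_min = 0.0
        p.kc_s = p.kc_i = 0.0
        return p

    base = no_traffic(default_parameters())
    doubled = base.copy()
    for key in ("kon_egf_s", "koff_egf_s"):
        doubled.binding[key] = 2.0 * base.binding[key]

    prof = FIXTURE_PROFILES["parental"]
    prot = StimulationProtocol(12, 0, 600.0, (0.0, 600.0))
    ends = []
    for p in (base, doubled):
        eq = equilibrate(prof, p)
        traj = simulate(eq, prot, p)
        ends.append(traj.states[-1])
    np.testing.assert_allclose(ends[0], ends[1], rtol=1e-5, atol=1e-6)


def test_her2_3minus_profile_keeps_her23_species_empty(params):
    prot = StimulationProtocol(30, 0, 60.0, (0.0, 60.0))
    traj = run_protocol("HER2-3-", prot, params)
    ss = enumerate_species()
    for sp in ss:
        if any(r in ("HER2", "HER3") for r in sp.receptors):
            for comp in ss.compartments:
                assert np.all(traj.states[:, ss.state_index(sp.name, comp)] == 0)


# ---------------------------------------------------------------- observables
def test_phospho_readout_hand_evaluation(params, eq_d20):
    """[R12E]s=10 with pf12es=0.02, pf21es=0.05 gives pR1s=0.2, pR2s=0.5."""
    from herdyn.simulate import _phospho_signal

    p = params.copy()
    p.pf["pf12e_s"] = 0.02
    p.pf["pf21e_s"] = 0.05
    ss = enumerate_species()
    state = np.zeros((1, ss.n_states))
    state[0, ss.state_index("R12E", SURFACE)] = 10.0
    assert _phospho_signal(state, p, 1, SURFACE)[0] == pytest.approx(0.2)
    assert _phospho_signal(state, p, 2, SURFACE)[0] == pytest.approx(0.5)


def test_zero_pf_zeroes_phospho_but_not_mass(eq_d20, params):
    p = params.copy()
    p.pf = {k: 0.0 for k in p.pf}
    prot = StimulationProtocol(12, 40, 30.0, (0.0, 30.0))
    traj = simulate(eq_d20, prot, p)
    obs = compute_observables(traj, p)
    phospho = obs[obs.measurement.str.startswith("pR")]
    assert np.all(phospho.value == 0.0)
    mass = obs[obs.measurement.str.startswith("mR")]
    assert np.all(mass.value > 0.0)


def test_her3_homodimers_never_contribute_to_pr3(params):
    """R33H/R33HH abundance is invisible to pR3 (pf identically zero)."""
    from herdyn.simulate import PHOSPHO_CONTRIBUTIONS, _phospho_signal

    assert all(d not in ("R33H", "R33HH")
               for d, _ in PHOSPHO_CONTRIBUTIONS[3])
    ss = enumerate_species()
    state = np.zeros((1, ss.n_states))
    state[0, ss.state_index("R33HH", SURFACE)] = 1e6
    state[0, ss.state_index("R33H", SURFACE)] = 1e6
    assert _phospho_signal(state, params, 3, SURFACE)[0] == 0.0


def test_missing_pf_entry_is_hard_error(eq_d20, params):
    p = params.copy()
    del p.pf["pf23h_s"]
    prot = StimulationProtocol(0, 40, 10.0, (0.0, 10.0))
    traj = simulate(eq_d20, prot, p)
    with pytest.raises(KeyError, match="pf23h_s"):
        compute_observables(traj, p)


def test_internal_phospho_bounded_by_total(eq_d20, params):
    prot = StimulationProtocol(12, 40, 120.0,
                               (0.0, 10.0, 30.0, 60.0, 120.0))
    traj = simulate(eq_d20, prot, params)
    obs = compute_observables(traj).pivot(
        index="time_min", columns="measurement", values="value")
    for i in (1, 2, 3):
        assert np.all(obs[f"pR{i}i"] >= 0.0)
        assert np.all(obs[f"pR{i}i"] <= obs[f"pR{i}t"] + 1e-12)
        assert np.all(obs[f"mR{i}t"] >= 0.0)


def test_no_internalization_makes_internal_phospho_zero(params):
    p = params.copy()
    p.kt = {k: 0.0 for k in p.kt}
    p.ke_her1_dimer_per_min = p.ke_her23_dimer_per_min = 0.0
    prof = CellLineProfile("surface-only", 2e5, 6e5, 4e4)
    prot = StimulationProtocol(12, 40, 30.0, (0.0, 30.0))
    traj = run_protocol(prof, prot, p)
    obs = compute_observables(traj).pivot(
        index="time_min", columns="measurement", values="value")
    for i in (1, 2, 3):
        # root-solver roundoff in the HER2 equilibrium allows ~1e-9 residue
        assert np.all(obs[f"pR{i}i"].abs() < 1e-6)


def test_increasing_pf_increases_phospho(eq_d20, params):
    prot = StimulationProtocol(12, 40, 30.0, (0.0, 30.0))
    traj = simulate(eq_d20, prot, params)
    obs0 = compute_observables(traj, params)
    p2 = params.copy()
    p2.pf["pf23h_s"] = params.pf["pf23h_s"] * 2.0
    obs2 = compute_observables(traj, p2)
    a = obs0[(obs0.measurement == "pR2t") & (obs0.time_min == 30)].value.iloc[0]
    b = obs2[(obs2.measurement == "pR2t") & (obs2.time_min == 30)].value.iloc[0]
    assert b > a


# ------------------------------------------------------------------- blocking
def test_apply_block_examples(params):
    assert apply_block(params, 0.95).her2_available_fraction == pytest.approx(0.05)
    assert apply_block(params, 0.0).her2_available_fraction == 1.0
    with pytest.raises(ValueError):
        apply_block(params, 1.5)


def test_blocked_pool_excluded_from_reactions_but_counted_in_mass(params):
    p = apply_block(params, 0.95)
    eq = equilibrate(FIXTURE_PROFILES["HER2+3+"], p)
    model = CompiledModel(params=p)
    totals = model.receptor_totals(eq.state)
    assert totals[1] == pytest.approx(0.05 * 600_000, rel=1e-3)
    assert eq.sequestered_her2.sum() == pytest.approx(0.95 * 600_000, rel=1e-3)
    prot = StimulationProtocol(12, 40, 10.0, (0.0, 10.0), block_fraction=0.95)
    traj = run_protocol("HER2+3+", prot, params)
    obs = compute_observables(traj)
    mr2 = obs[obs.measurement == "mR2t"].value.iloc[0]
    assert mr2 == pytest.approx(600_000, rel=1e-3)


def test_full_block_silences_pr2(params):
    prot = StimulationProtocol(12, 40, 30.0, (0.0, 10.0, 30.0),
                               block_fraction=1.0)
    traj = run_protocol("HER2+3+", prot, params)
    obs = compute_observables(traj)
    assert np.all(obs[obs.measurement == "pR2t"].value == 0.0)


def test_pr2_monotone_in_block_fraction(params):
    values = []
    for frac in (0.0, 0.5, 0.95, 1.0):
        prot = StimulationProtocol(12, 40, 30.0, (10.0, 30.0),
                                   block_fraction=frac)
        traj = run_protocol("HER2+3+", prot, params)
        obs = compute_observables(traj)
        values.append(obs[obs.measurement == "pR2t"].value.to_numpy())
    for a, b in zip(values, values[1:]):
        assert np.all(b <= a + 1e-9)
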