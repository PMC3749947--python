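"""Dimer-contribution decomposition and expression-level scans."""

import numpy as np
import pandas as pd
import pytest

from herdyn.analysis import (
    SATURATING_PROTOCOL,
    GridSpec,
    decompose,
    dimer_pair,
    grid_scan,
    pair_fractions,
    panel_predict,
)
from herdyn.simulate import (
    CellLineProfile,
    StimulationProtocol,
    Trajectory,
    equilibrate,
    run_protocol,
)
from herdyn.species import SURFACE, enumerate_species


def _manual_trajectory(params, assignments, time=60.0):
    """A one-snapshot trajectory with hand-set species abundances."""
    ss = enumerate_species()
    state = np.zeros(ss.n_states)
    for (name, comp), value in assignments.items():
        state[ss.state_index(name, comp)] = value
    eq = equilibrate(CellLineProfile("manual", 0, 0, 0), params)
    prot = StimulationProtocol(0, 0, time, (time,))
    return Trajectory(np.array([time]), state[None, :], params, prot, eq)


def test_single_dimer_gets_full_fraction(params):
    traj = _manual_trajectory(params, {("R11EE", SURFACE): 42.0})
    dec = decompose(traj, params, time=60.0)
    her1 = dec[dec.receptor == "HER1"].set_index("dimer")
    assert her1.loc["R11EE", "fraction"] == pytest.approx(1.0)
    assert her1.drop("R11EE")["fraction"].sum() == 0.0


def test_equal_weighted_dimers_split_evenly(params):
    p = params.copy()
    p.pf["pf11e_s"] = p.pf["pf12e_s"] = 0.05
    traj = _manual_trajectory(p, {("R11E", SURFACE): 7.0,
                                  ("R12E", SURFACE): 7.0})
    dec = decompose(traj, p, time=60.0)
    her1 = dec[dec.receptor == "HER1"].set_index("dimer")
    assert her1.loc["R11E", "fraction"] == pytest.approx(0.5)
    assert her1.loc["R12E", "fraction"] == pytest.approx(0.5)


def test_hand_built_her2_fractions(params):
    """[R12E]=5 with pf21=0.1 and [R23H]=4 with pf23=0.05: 71.4% / 28.6%."""
    p = params.copy()
    p.pf["pf21e_s"], p.pf["pf23h_s"] = 0.1, 0.05
    p.pf["pf21e_i"] = p.pf["pf23h_i"] = 0.0
    p.pf["pf22_s"] = p.pf["pf22_i"] = 0.0
    traj = _manual_trajectory(p, {("R12E", SURFACE): 5.0,
                                  ("R23H", SURFACE): 4.0})
    dec = decompose(traj, p, time=60.0).set_index(["receptor", "dimer"])
    assert dec.loc[("HER2", "R12E"), "absolute"] == pytest.approx(0.5)
    assert dec.loc[("HER2", "R23H"), "absolute"] == pytest.approx(0.2)
    assert dec.loc[("HER2", "R12E"), "fraction"] == pytest.approx(5 / 7)
    assert dec.loc[("HER2", "R23H"), "fraction"] == pytest.approx(2 / 7)


def test_fractions_sum_to_one_where_signal_positive(params):
    traj = run_protocol("HER2+3+", SATURATING_PROTOCOL, params)
    dec = decompose(traj, params, time=60.0)
    sums = dec.groupby("receptor")["fraction"].sum()
    np.testing.assert_allclose(sums, 1.0, atol=1e-9)


def test_zeroing_a_pf_renormalizes_other_fractions(params):
    traj = run_protocol("HER2+3+", SATURATING_PROTOCOL, params)
    base = decompose(traj, params, time=60.0)
    p = params.copy()
    p.pf["pf23h_s"] = p.pf["pf23h_i"] = 0.0
    dropped = decompose(traj, p, time=60.0)
    b = base[base.receptor == "HER2"].set_index("dimer")
    d = dropped[dropped.receptor == "HER2"].set_index("dimer")
    assert d.loc["R23H", "absolute"] == 0.0
    keep = [x for x in b.index if x != "R23H"]
    # remaining absolute contributions unchanged; fractions renormalized
    np.testing.assert_allclose(d.loc[keep, "absolute"],
                               b.loc[keep, "absolute"])
    np.testing.assert_allclose(
        d.loc[keep, "fraction"],
        b.loc[keep, "absolute"] / b.loc[keep, "absolute"].sum())


def test_dimer_pair_rollup_names():
    assert dimer_pair("R11EE") == "R11"
    assert dimer_pair("R13EH") == "R13"
    assert dimer_pair("R22") == "R22"
    assert dimer_pair("R33HH") == "R33"


def test_grid_point_matches_single_run(params):
    spec = GridSpec(n_her1=1, n_her2=1, her1_range=(2e5, 2e5),
                    her2_range=(6e5, 6e5), her3=40_000)
    scan = grid_scan(params, spec)
    traj = run_protocol("HER2+3+", SATURATING_PROTOCOL, params)
    dec = decompose(traj, params, time=60.0)
    pr1 = dec[dec.receptor == "HER1"]["absolute"].sum()
    assert scan["pR1t"].iloc[0] == pytest.approx(pr1, rel=1e-6)


def test_grid_scan_caches_to_disk(params, tmp_path):
    spec = GridSpec(n_her1=2, n_her2=1)
    cache = tmp_path / "scan.csv"
    first = grid_scan(params, spec, cache_path=cache)
    assert cache.exists()
    second = grid_scan(params, spec, cache_path=cache)
    pd.testing.assert_frame_equal(
        first.reset_index(drop=True), second, check_dtype=False,
        check_exact=False, rtol=1e-12)


def test_grid_output_independent_of_evaluation_order(params):
    spec = GridSpec(n_her1=2, n_her2=2, her1_range=(1e4, 1e6),
                    her2_range=(1e4, 1e6))
    scan = grid_scan(params, spec).sort_values(["her1", "her2"])
    # evaluate the same points individually, in reverse order
    rows = []
    for her1 in spec.her1_values()[::-1]:
        for her2 in spec.her2_values()[::-1]:
            prof = CellLineProfile("x", her1, her2, spec.her3)
            traj = run_protocol(prof, SATURATING_PROTOCOL, params)
            dec = decompose(traj, params, time=60.0)
            rows.append({"her1": her1, "her2": her2,
                         "pR3t": dec[dec.receptor == "HER3"]["absolute"].sum()})
    manual = pd.DataFrame(rows).sort_values(["her1", "her2"])
    np.testing.assert_allclose(scan["pR3t"].to_numpy(),
                               manual["pR3t"].to_numpy(), rtol=1e-9)


def test_low_her2_grid_corner_favors_r13_over_r23(params):
    """With HER1 >> HER2, the R13 route dominates HER3 phosphorylation."""
    prof = CellLineProfile("corner", 1e6, 1e3, 40_000)
    traj = run_protocol(prof, SATURATING_PROTOCOL, params)
    pairs = pair_fractions(decompose(traj, params, time=60.0))
    her3 = pairs[pairs.receptor == "HER3"].set_index("pair")
    assert her3.loc["R23", "fraction"] < her3.loc["R13", "fraction"]


def test_pr3_nondecreasing_along_her2_axis(params):
    """HER3 phosphorylation rises with HER2 expression at fixed HER1."""
    values = []
    for her2 in (1e3, 1e4, 1e5, 1e6, 3e6):
        prof = CellLineProfile("sweep", 2e5, her2, 40_000)
        traj = run_protocol(prof, SATURATING_PROTOCOL, params)
        dec = decompose(traj, params, time=60.0)
        values.append(dec[dec.receptor == "HER3"]["absolute"].sum())
    assert np.all(np.diff(values) >= -1e-9)


def test_panel_of_one_equals_single_simulation(params):
    prof = CellLineProfile("solo", 2e5, 6e5, 4e4)
    panel = panel_predict(params, [prof])
    traj = run_protocol(prof, SATURATING_PROTOCOL, params)
    dec = decompose(traj, params, time=60.0)
    assert panel["pR2t"].iloc[0] == pytest.approx(
        dec[dec.receptor == "HER2"]["absolute"].sum(), rel=1e-9)


def test_higher_her2_line_has_higher_pr3(params):
    low = CellLineProfile("ADRr-like", 1.5e5, 2e4, 4e4)
    high = CellLineProfile("ADRrE2-like", 1.5e5, 8e5, 4e4)
    panel = panel_predict(params, [low, high]).set_index("cell_line")
    assert panel.loc["ADRrE2-like", "pR3t"] > panel.loc["ADRr-like", "pR3t"]


def test_empty_panel_gives_empty_table(params):
    panel = panel_predict(params, [])
    assert len(panel) == 0
    assert "pR1t" in panel.columns
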