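"""Equilibration, ligand-stimulation simulation and ELISA-like observables.

A simulation starts from the ligand-free steady state of the trafficking
network: constitutive synthesis of free monomers at the surface balanced by
internalization, recycling, late-endosome sorting and degradation.  Because
no ligand-induced dimers exist before stimulation, each receptor type obeys
an independent linear three-compartment balance which is solved in closed
form; synthesis rates are chosen so that total copies per receptor match
the cell line's expression level.

Observables mirror the ELISA design: per receptor i, total phospho (pRit =
surface + early-endosome phospho signal), internal phospho (pRii = EE
signal alone; the acid-stripping readout) and receptor mass (mRit = every
copy in every compartment, homodimers counted twice).  Phospho signals are
linear combinations pf x dimer abundance; late-endosome species contribute
to mass only.

The pertuzumab (2C4) blocking mode removes a fraction of cellular HER2 from
the dimerization-available pool (initial condition and synthesis feed).
The sequestered pool never reacts, so it remains at its own trafficking
steady state and contributes a constant offset to the HER2 mass observable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import CompiledModel
from .parameters import ParameterSet, default_parameters, derive_trafficking_rates
from .species import EARLY_ENDOSOME, LATE_ENDOSOME, SURFACE, enumerate_species

__all__ = [
    "CellLineProfile",
    "StimulationProtocol",
    "Equilibrium",
    "Trajectory",
    "FIXTURE_PROFILES",
    "equilibrate",
    "simulate",
    "compute_observables",
    "apply_block",
    "run_protocol",
    "PHOSPHO_CONTRIBUTIONS",
    "MEASUREMENTS",
]


@dataclass(frozen=True)
class CellLineProfile:
    """HER1-3 expression levels (total molecules/cell at steady state)."""

    name: str
    her1: float
    her2: float
    her3: float

    def __post_init__(self):
        if min(self.her1, self.her2, self.her3) < 0:
            raise ValueError("expression levels must be non-negative")

    def expression(self, receptor: str) -> float:
        return {"HER1": self.her1, "HER2": self.her2, "HER3": self.her3}[receptor]


#: the four study cell lines: parental 184A1 HMEs and the HER2/HER3
#: transductants (24H, B5, D20).  The parental line expresses ~200,000
#: EGFR molecules/cell; HER3-expressing lines sit near 40,000 copies.
FIXTURE_PROFILES: dict[str, CellLineProfile] = {
    "HER2-3-": CellLineProfile("HER2-3-", 200_000, 0, 0),
    "HER2+3-": CellLineProfile("HER2+3-", 200_000, 600_000, 0),
    "HER2-3+": CellLineProfile("HER2-3+", 200_000, 0, 40_000),
    "HER2+3+": CellLineProfile("HER2+3+", 200_000, 600_000, 40_000),
}
#: clone-name aliases
FIXTURE_PROFILES.update({
    "parental": FIXTURE_PROFILES["HER2-3-"],
    "24H": FIXTURE_PROFILES["HER2+3-"],
    "B5": FIXTURE_PROFILES["HER2-3+"],
    "D20": FIXTURE_PROFILES["HER2+3+"],
})


@dataclass(frozen=True)
class StimulationProtocol:
    """Ligand doses (ng/ml), duration and sampling grid (min)."""

    egf_ng_ml: float = 0.0
    hrg_ng_ml: float = 0.0
    duration_min: float = 120.0
    sample_times: tuple[float, ...] = (0.0, 10.0, 30.0, 60.0, 120.0)
    block_fraction: float = 0.0

    def __post_init__(self):
        if self.egf_ng_ml < 0 or self.hrg_ng_ml < 0:
            raise ValueError("ligand doses must be non-negative")
        if not 0 <= self.block_fraction <= 1:
            raise ValueError("block_fraction must lie in [0, 1]")
        if any(t < 0 or t > self.duration_min for t in self.sample_times):
            raise ValueError("sample times must lie within [0, duration]")


@dataclass
class Equilibrium:
    """Pre-stimulation steady state plus the matching synthesis rates."""

    profile: CellLineProfile
    state: np.ndarray
    synthesis: np.ndarray
    #: HER2 copies held out of the reactive pool by 2C4, per compartment
    sequestered_her2: np.ndarray
    residual_norm: float


@dataclass
class Trajectory:
    """Integrated state trajectory at the protocol's sample times."""

    times: np.ndarray
    states: np.ndarray  # (n_times, 51)
    params: ParameterSet
    protocol: StimulationProtocol
    equilibrium: Equilibrium

    @property
    def species(self):
        return enumerate_species()

    def state_at(self, time: float) -> np.ndarray:
        i = np.flatnonzero(np.isclose(self.times, time))
        if i.size == 0:
            raise ValueError(f"time {time} min not in the sampled trajectory")
        return self.states[i[0]]


def _monomer_rates(params: ParameterSet, receptor: str):
    """(kt, kr, kl, kd) for the free monomer of ``receptor``."""
    kx1, f1 = params.kx_her1_per_min, params.f_her1
    if receptor == "HER1":
        kx, f = kx1, f1
    else:
        kx, f = params.kx_her23_per_min, params.f_her23
    rates = derive_trafficking_rates(
        np.array([kx]), np.array([f]), params.delta1, kx1=kx1, f1=f1
    )
    return params.kt[receptor], rates.kr[0], rates.kl[0], rates.kd[0]


def _monomer_steady_state(params: ParameterSet, receptor: str, total: float):
    """Closed-form ligand-free steady state (surface, EE, LE, synthesis)."""
    if total == 0:
        return 0.0, 0.0, 0.0, 0.0
    kt, kr, kl, kd = _monomer_rates(params, receptor)
    # S + E + L = total with E = kt*S/(kr+kl), L = kl*E/kd
    e_per_s = kt / (kr + kl)
    l_per_s = e_per_s * kl / kd
    surface = total / (1.0 + e_per_s + l_per_s)
    ee = e_per_s * surface
    le = l_per_s * surface
    synthesis = kd * le  # = kl*ee: inflow balances degradation
    return surface, ee, le, synthesis


def _her2_steady_state(params: ParameterSet, total: float):
    """Ligand-free HER2 steady state including the constitutive R22 pool.

    HER2 needs no ligand to dimerize, so the pre-stimulation state couples
    the R2 monomer and R22 homodimer balances nonlinearly.  Unknowns are
    (R2s, R2e, R22s, R22e, synthesis); late-endosome pools follow linearly.
    Returns (R2 per compartment, R22 per compartment, synthesis rate).
    """
    from scipy.optimize import fsolve

    kt2, kr2, kl2, kd2 = _monomer_rates(params, "HER2")
    kc_s = params.rate_value("kc_s")
    kc_i = params.rate_value("kc_i")
    ku_s = params.ku["ku22_s"]
    ku_i = params.ku["ku22_i"]
    ke22 = params.ke_her23_dimer_per_min
    # R22 is a HER2-class species: same kx/f, hence same kr/kl/kd chain
    kr22, kl22, kd22 = kr2, kl2, kd2

    def residuals(x):
        r2s, r2e, d_s, d_e, q = x
        r2l = kl2 * r2e / kd2
        d_l = kl22 * d_e / kd22
        eq1 = q - kt2 * r2s + kr2 * r2e - 2 * kc_s * r2s ** 2 + 2 * ku_s * d_s
        eq2 = (kt2 * r2s - (kr2 + kl2) * r2e
               - 2 * kc_i * r2e ** 2 + 2 * ku_i * d_e)
        eq3 = kc_s * r2s ** 2 - ku_s * d_s - ke22 * d_s + kr22 * d_e
        eq4 = (ke22 * d_s + kc_i * r2e ** 2 - ku_i * d_e
               - (kr22 + kl22) * d_e)
        eq5 = (r2s + r2e + r2l) + 2 * (d_s + d_e + d_l) - total
        return [eq1, eq2, eq3, eq4, eq5]

    s0, e0, l0, q0 = _monomer_steady_state(params, "HER2", total)
    x0 = np.array([s0, e0, 1e-6 * total + 1.0, 1e-7 * total + 1.0, q0])
    sol, info, ier, msg = fsolve(residuals, x0, full_output=True, xtol=1e-13)
    if ier != 1 or np.max(np.abs(residuals(sol))) > 1e-6 * max(total, 1.0):
        raise RuntimeError(f"HER2 ligand-free steady state did not converge: {msg}")
    r2s, r2e, d_s, d_e, q = sol
    r2l = kl2 * r2e / kd2
    d_l = kl22 * d_e / kd22
    return (r2s, r2e, r2l), (d_s, d_e, d_l), q


def equilibrate(profile: CellLineProfile,
                params: ParameterSet | None = None,
                tol: float = 1e-9,
                model: CompiledModel | None = None) -> Equilibrium:
    """Ligand-free steady state consistent with constitutive turnover.

    Synthesis rates are solved so that total copies per receptor equal the
    profile's expression level; the result is verified by evaluating the
    full ODE right-hand side (relative residual below ``tol``).  HER1 and
    HER3 form no ligand-free dimers and obey independent linear
    three-compartment balances; HER2 additionally populates the
    constitutive R22 homodimer.
    """
    if params is None:
        params = default_parameters()
    if model is None:
        model = CompiledModel(params=params)
    ss = model.species
    state = np.zeros(model.n_states)
    synthesis = np.zeros(model.n_states)
    sequestered = np.zeros(3)

    for receptor, mono in (("HER1", "R1"), ("HER3", "R3")):
        total = profile.expression(receptor)
        s, e, l, q = _monomer_steady_state(params, receptor, total)
        state[ss.state_index(mono, SURFACE)] = s
        state[ss.state_index(mono, EARLY_ENDOSOME)] = e
        state[ss.state_index(mono, LATE_ENDOSOME)] = l
        synthesis[ss.state_index(mono, SURFACE)] = q

    her2_total = profile.her2
    avail = her2_total * params.her2_available_fraction
    seq_total = her2_total - avail
    if seq_total > 0:
        # the sequestered pool cannot dimerize: pure monomer trafficking
        s, e, l, _ = _monomer_steady_state(params, "HER2", seq_total)
        sequestered[:] = (s, e, l)
    if avail > 0:
        r2, r22, q = _her2_steady_state(params, avail)
        for comp, r2_val, r22_val in zip(
                (SURFACE, EARLY_ENDOSOME, LATE_ENDOSOME), r2, r22):
            state[ss.state_index("R2", comp)] = r2_val
            state[ss.state_index("R22", comp)] = r22_val
        synthesis[ss.state_index("R2", SURFACE)] = q

    model.synthesis = synthesis
    residual = model.rhs(0.0, state)
    scale = max(state.max(), 1.0)
    res_norm = float(np.abs(residual).max() / scale)
    if res_norm > tol:
        raise RuntimeError(
            f"equilibration failed: relative residual {res_norm:.3e} > {tol:.1e}"
        )
    totals = model.receptor_totals(state)
    targets = np.array([
        profile.her1,
        profile.her2 * params.her2_available_fraction,
        profile.her3,
    ])
    nz = targets > 0
    if np.any(np.abs(totals[nz] - targets[nz]) / targets[nz] > 1e-3):
        raise RuntimeError("equilibrated totals deviate >0.1% from the profile")
    return Equilibrium(profile, state, synthesis, sequestered, res_norm)


def simulate(equilibrium: Equilibrium,
             protocol: StimulationProtocol,
             params: ParameterSet | None = None,
             rtol: float = 1e-8, atol: float = 1e-10,
             model: CompiledModel | None = None) -> Trajectory:
    """Integrate the stimulation protocol from the pre-ligand steady state."""
    if params is None:
        params = default_parameters()
    if model is None:
        model = CompiledModel(params=params)
    model.synthesis = equilibrium.synthesis
    y0 = equilibrium.state.copy()
    y0[model.clamped[0]] = params.dose_to_nM("EGF", protocol.egf_ng_ml)
    y0[model.clamped[1]] = params.dose_to_nM("HRG", protocol.hrg_ng_ml)
    t_eval = np.asarray(sorted(set(protocol.sample_times)), dtype=float)
    sol = solve_ivp(
        model.rhs, (0.0, float(protocol.duration_min)), y0,
        method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol, jac=model.jac,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed at t={sol.t[-1] if sol.t.size else 0:.2f} min: "
            f"{sol.message}"
        )
    states = np.clip(sol.y.T, 0.0, None)  # clip integrator-scale negatives
    return Trajectory(sol.t, states, params, protocol, equilibrium)


#: receptor -> [(dimer species, pf base name)]; HER3 homodimers are absent
#: because their pf values are identically zero (HER3 lacks kinase activity)
PHOSPHO_CONTRIBUTIONS: dict[int, tuple[tuple[str, str], ...]] = {
    1: (("R11E", "pf11e"), ("R11EE", "pf11ee"), ("R12E", "pf12e"),
        ("R13E", "pf13e"), ("R13H", "pf13h"), ("R13EH", "pf13eh")),
    2: (("R12E", "pf21e"), ("R22", "pf22"), ("R23H", "pf23h")),
    3: (("R13E", "pf31e"), ("R13H", "pf31h"), ("R13EH", "pf31eh"),
        ("R23H", "pf32h")),
}

MEASUREMENTS = tuple(
    f"{kind}{i}{suffix}" for i in (1, 2, 3) for kind, suffix in
    (("pR", "t"), ("pR", "i"), ("mR", "t"))
)


def _phospho_signal(states: np.ndarray, params: ParameterSet,
                    receptor: int, compartment: str) -> np.ndarray:
    ss = enumerate_species()
    suffix = "s" if compartment == SURFACE else "i"
    signal = np.zeros(states.shape[0])
    for dimer, pf_base in PHOSPHO_CONTRIBUTIONS[receptor]:
        key = f"{pf_base}_{suffix}"
        if key not in params.pf:
            raise KeyError(
                f"phosphorylation factor {key} missing for contributing dimer "
                f"{dimer}"
            )
        signal += params.pf[key] * states[:, ss.state_index(dimer, compartment)]
    return signal


def compute_observables(traj: Trajectory,
                        params: ParameterSet | None = None) -> pd.DataFrame:
    """Tidy ELISA-equivalent observables (time_min, measurement, value).

    pRit = surface + EE phospho signal; pRii = EE signal only; mRit = total
    receptor copies over all compartments (homodimers twice), including any
    2C4-sequestered HER2 pool.
    """
    if params is None:
        params = traj.params
    ss = enumerate_species()
    counts = ss.receptor_count_matrix()
    per_comp = traj.states.reshape(len(traj.times), 3, ss.n_species)
    mass = np.einsum("rj,tcj->tr", counts, per_comp)  # (n_times, 3)
    mass[:, 1] += traj.equilibrium.sequestered_her2.sum()

    rows = []
    for i in (1, 2, 3):
        surf = _phospho_signal(traj.states, params, i, SURFACE)
        internal = _phospho_signal(traj.states, params, i, EARLY_ENDOSOME)
        for t, total, inner, m in zip(
                traj.times, surf + internal, internal, mass[:, i - 1]):
            rows.append((t, f"pR{i}t", total))
            rows.append((t, f"pR{i}i", inner))
            rows.append((t, f"mR{i}t", m))
    return pd.DataFrame(rows, columns=["time_min", "measurement", "value"])


def apply_block(params: ParameterSet, fraction: float) -> ParameterSet:
    """2C4 (pertuzumab) mode: sequester ``fraction`` of cellular HER2.

    The dimerization-available HER2 pool (initial condition and synthesis
    feed) shrinks to (1 - fraction) of nominal; the sequestered pool still
    traffics at monomer rates and counts toward the HER2 mass observable.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("block fraction must lie in [0, 1]")
    new = params.copy()
    new.her2_available_fraction = params.her2_available_fraction * (1.0 - fraction)
    return new


def run_protocol(profile: CellLineProfile | str,
                 protocol: StimulationProtocol,
                 params: ParameterSet | None = None,
                 rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
    """Convenience pipeline: block -> equilibrate -> simulate."""
    if isinstance(profile, str):
        profile = FIXTURE_PROFILES[profile]
    if params is None:
        params = default_parameters()
    if protocol.block_fraction > 0:
        params = apply_block(params, protocol.block_fraction)
    eq = equilibrate(profile, params)
    return simulate(eq, protocol, params)
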