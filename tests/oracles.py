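"""Independent oracles used by the test suite.

The stoichiometric oracle rebuilds the full derivative as S @ v from the
reaction list plus explicit transport pseudo-reactions, re-deriving every
rate from the parameter primitives.  It deliberately shares no assembly
code with ``CompiledModel.rhs``.
"""

import numpy as np

from herdyn.parameters import derive_trafficking_rates
from herdyn.species import (
    COMPARTMENTS,
    EARLY_ENDOSOME,
    LATE_ENDOSOME,
    SURFACE,
)


def stoichiometric_rhs(model, y, synthesis=None):
    """Derivative via an explicitly assembled stoichiometric matrix.

    Columns: one per biochemical reaction, then one per transport event
    (internalization, recycling, LE entry, degradation, ligand sorting and
    clearance) per species, then synthesis inflows.
    """
    ss = model.species
    params = model.params
    n = ss.n_states
    columns = []  # (stoichiometry vector, flux value)

    for rx in model.reactions:
        col = np.zeros(n)
        for name in rx.reactants:
            col[ss.state_index(name, rx.compartment)] -= 1.0
        for name in rx.products:
            col[ss.state_index(name, rx.compartment)] += 1.0
        k = params.rate_value(rx.rate_ref) * rx.factor
        flux = k
        for name in rx.reactants:
            flux = flux * y[ss.state_index(name, rx.compartment)]
        columns.append((col, flux))

    # transport: re-derive per-species rates from the primitives
    kx = np.array([params.species_kx_f(sp)[0] if sp.is_receptor_species
                   else params.kx_her1_per_min for sp in ss])
    f = np.array([params.species_kx_f(sp)[1] if sp.is_receptor_species
                  else params.f_her1 for sp in ss])
    rates = derive_trafficking_rates(
        kx, f, params.delta1, kx1=params.kx_her1_per_min, f1=params.f_her1)
    for j, sp in enumerate(ss):
        s = ss.state_index(sp.name, SURFACE)
        e = ss.state_index(sp.name, EARLY_ENDOSOME)
        l = ss.state_index(sp.name, LATE_ENDOSOME)
        if sp.is_receptor_species:
            k_int = params.species_internalization(sp)
            events = [
                ((s, -1.0), (e, +1.0), k_int * y[s]),     # internalization
                ((e, -1.0), (s, +1.0), rates.kr[j] * y[e]),  # recycling
                ((e, -1.0), (l, +1.0), rates.kl[j] * y[e]),  # LE entry
                ((l, -1.0), None, rates.kd[j] * y[l]),       # degradation
            ]
        else:
            events = [
                ((e, -1.0), (l, +1.0), params.ligand_ee_sort_per_min * y[e]),
                ((l, -1.0), None, params.ligand_le_deg_per_min * y[l]),
            ]
        for ev in events:
            col = np.zeros(n)
            col[ev[0][0]] += ev[0][1]
            if ev[1] is not None:
                col[ev[1][0]] += ev[1][1]
            columns.append((col, ev[2]))

    if synthesis is None:
        synthesis = model.synthesis
    for i in np.flatnonzero(synthesis):
        col = np.zeros(n)
        col[i] = 1.0
        columns.append((col, synthesis[i]))

    S = np.column_stack([c for c, _ in columns])
    v = np.array([fl for _, fl in columns])
    dy = S @ v
    dy[model.clamped] = 0.0  # extracellular ligand is held constant
    return dy
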