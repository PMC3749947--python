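"""The ODE right-hand side for the compartmental HER activation model.

The derivative of the 51-dimensional state combines

* mass-action reaction fluxes at the surface and in the early endosome,
* first-order internalization (kt for monomers, ke for dimers),
* recycling and late-endosome entry out of the early endosome,
* first-order degradation in the late endosome (trafficking only -- no
  biochemistry there), and
* constant synthesis of free receptor monomers delivered to the surface.

Extracellular (surface) free ligand is held constant: its state entries are
clamped (zero derivative) and stimulation protocols simply set their values.
Free ligand released inside the early endosome accumulates in the EE ligand
pool, participates in EE binding, and is lost to the late endosome by
sorting.
"""

from __future__ import annotations

import numpy as np

from .parameters import ParameterSet
from .reactions import Reaction, build_reactions
from .species import (
    COMPARTMENTS,
    EARLY_ENDOSOME,
    LATE_ENDOSOME,
    SURFACE,
    SpeciesSet,
    enumerate_species,
)

__all__ = ["CompiledModel", "ode_rhs"]


class CompiledModel:
    """Reaction network and trafficking rates compiled to fast arrays."""

    def __init__(self, species: SpeciesSet | None = None,
                 params: ParameterSet | None = None):
        from .parameters import default_parameters

        self.species = species if species is not None else enumerate_species()
        self.params = params if params is not None else default_parameters()
        self.reactions: list[Reaction] = build_reactions(self.species, self.params)
        self.n_states = self.species.n_states
        ss = self.species
        #: state indices whose derivative is clamped to zero (surface ligand)
        self.clamped = np.array(
            [ss.state_index("E", SURFACE), ss.state_index("H", SURFACE)]
        )
        self._compile_reactions()
        self._compile_trafficking()
        #: per-state constant synthesis (set per cell line at equilibration)
        self.synthesis = np.zeros(self.n_states)

    # ------------------------------------------------------------------
    def _compile_reactions(self) -> None:
        ss, params = self.species, self.params
        n_rx = len(self.reactions)
        self.rate_constants = np.empty(n_rx)
        self._r1 = np.empty(n_rx, dtype=np.intp)
        self._r2 = np.zeros(n_rx, dtype=np.intp)
        self._bimol = np.zeros(n_rx, dtype=bool)
        scat_rx, scat_sp, scat_coef = [], [], []
        clamped = set(self.clamped.tolist())
        for r, rx in enumerate(self.reactions):
            self.rate_constants[r] = params.rate_value(rx.rate_ref) * rx.factor
            idx = [ss.state_index(name, rx.compartment) for name in rx.reactants]
            self._r1[r] = idx[0]
            if len(idx) == 2:
                self._r2[r] = idx[1]
                self._bimol[r] = True
            net: dict[int, float] = {}
            for i in idx:
                net[i] = net.get(i, 0.0) - 1.0
            for name in rx.products:
                i = ss.state_index(name, rx.compartment)
                net[i] = net.get(i, 0.0) + 1.0
            for i, coef in net.items():
                if coef == 0.0 or i in clamped:
                    continue
                scat_rx.append(r)
                scat_sp.append(i)
                scat_coef.append(coef)
        self._scat_rx = np.array(scat_rx, dtype=np.intp)
        self._scat_sp = np.array(scat_sp, dtype=np.intp)
        self._scat_coef = np.array(scat_coef)

    def _compile_trafficking(self) -> None:
        ss, params = self.species, self.params
        n = self.n_states
        T = np.zeros((n, n))
        traffic = params.trafficking_for(list(ss))
        for j, sp in enumerate(ss):
            s = ss.state_index(sp.name, SURFACE)
            e = ss.state_index(sp.name, EARLY_ENDOSOME)
            l = ss.state_index(sp.name, LATE_ENDOSOME)
            if sp.is_receptor_species:
                k_int = params.species_internalization(sp)
                T[e, s] += k_int
                T[s, s] -= k_int
                T[s, e] += traffic.kr[j]
                T[l, e] += traffic.kl[j]
                T[e, e] -= traffic.kr[j] + traffic.kl[j]
                T[l, l] -= traffic.kd[j]
            else:  # free ligand: EE pool sorted to LE, LE pool degraded
                T[l, e] += params.ligand_ee_sort_per_min
                T[e, e] -= params.ligand_ee_sort_per_min
                T[l, l] -= params.ligand_le_deg_per_min
        T[self.clamped, :] = 0.0  # surface ligand is clamped
        self.transport = T
        self.trafficking = traffic

    # ------------------------------------------------------------------
    def fluxes(self, y: np.ndarray) -> np.ndarray:
        """Mass-action flux of every reaction at state ``y``."""
        v = self.rate_constants * y[self._r1]
        v[self._bimol] *= y[self._r2[self._bimol]]
        return v

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        """Time derivative of the full state vector (1/min)."""
        dy = self.transport @ y + self.synthesis
        v = self.fluxes(y)
        dy += np.bincount(
            self._scat_sp, weights=self._scat_coef * v[self._scat_rx],
            minlength=self.n_states,
        )
        return dy

    def jac(self, t: float, y: np.ndarray) -> np.ndarray:
        """Analytic Jacobian of :meth:`rhs` (transport + mass-action terms)."""
        n = self.n_states
        J = self.transport.copy()
        k = self.rate_constants
        # d(flux)/d(first reactant) and /d(second reactant)
        d1 = k.copy()
        d1[self._bimol] = k[self._bimol] * y[self._r2[self._bimol]]
        rx, sp, coef = self._scat_rx, self._scat_sp, self._scat_coef
        np.add.at(J.ravel(), sp * n + self._r1[rx], coef * d1[rx])
        bi = self._bimol[rx]
        d2 = k[rx[bi]] * y[self._r1[rx[bi]]]
        np.add.at(J.ravel(), sp[bi] * n + self._r2[rx[bi]], coef[bi] * d2)
        return J

    def receptor_totals(self, y: np.ndarray) -> np.ndarray:
        """Total HER1/2/3 copies across all compartments (homodimers x2)."""
        counts = self.species.receptor_count_matrix()
        per_comp = y.reshape(len(COMPARTMENTS), self.species.n_species)
        return counts @ per_comp.sum(axis=0)

    def degradation_flux(self, y: np.ndarray) -> np.ndarray:
        """Per-receptor-type degradation outflow from the late endosome."""
        ss = self.species
        counts = ss.receptor_count_matrix()
        le = y[2 * ss.n_species: 3 * ss.n_species]
        return counts @ (self.trafficking.kd * le)


def ode_rhs(state: np.ndarray, t: float, params: ParameterSet,
            protocol=None, model: CompiledModel | None = None) -> np.ndarray:
    """Standalone right-hand-side evaluation for a given state and protocol.

    ``protocol`` (if given) fixes the extracellular ligand concentrations;
    the corresponding state entries are overridden before evaluation.
    Rejects states of the wrong length or containing NaN.
    """
    y = np.asarray(state, dtype=float)
    if model is None:
        model = CompiledModel(params=params)
    if y.shape != (model.n_states,):
        raise ValueError(
            f"state must have length {model.n_states}, got shape {y.shape}"
        )
    if np.any(np.isnan(y)):
        raise ValueError("state contains NaN")
    if protocol is not None:
        y = y.copy()
        y[model.clamped[0]] = params.dose_to_nM("EGF", protocol.egf_ng_ml)
        y[model.clamped[1]] = params.dose_to_nM("HRG", protocol.hrg_ng_ml)
    return model.rhs(t, y)
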