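"""Assembly of the mass-action reaction network.

Reactions are generated for the cell surface and the early endosome only;
the late endosome is a trafficking-only compartment.  Reaction classes:

* ``ligand_on`` / ``ligand_off`` -- reversible ligand binding to a monomer
  or to an open slot of a dimer; an off event on a dimer that still holds
  another ligand leaves the dimer intact.
* ``ligand_off_with_dimer_collapse`` -- loss of the *sole* ligand from a
  singly-liganded dimer; modeled as one lumped event yielding two free
  monomers plus the ligand, so ligand-free unstable dimers are never
  tracked.
* ``dimer_on`` / ``dimer_off`` -- reversible dimerization at the common
  diffusion-limited forward rate kc; each of the ten dimer types has its
  own compartment-specific dissociation rate ku (20 free rates in total).

Dimerization is permitted between two monomers whenever each non-HER2
partner is ligand-bound (HER2, which has no ligand, dimerizes
constitutively); this is exactly the rule that populates the ten dimer
species and nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .parameters import ParameterSet
from .species import REACTIVE_COMPARTMENTS, LATE_ENDOSOME, SpeciesSet

__all__ = ["Reaction", "build_reactions"]


@dataclass(frozen=True)
class Reaction:
    """A single elementary (or lumped) reaction in one compartment."""

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_ref: str
    compartment: str
    rx_class: str
    #: statistical multiplicity (e.g. 2 for ligand loss from a doubly
    #: occupied homodimer, which has two equivalent occupied slots)
    factor: float = 1.0

    def __post_init__(self):
        if self.compartment == LATE_ENDOSOME:
            raise ValueError("no biochemical reactions in the late endosome")
        if not 1 <= len(self.reactants) <= 2:
            raise ValueError("reactions are uni- or bimolecular")


# (ligand, partner, product) ligand-binding events on monomers and on open
# dimer slots; rate refs are per-compartment templates ({c} -> s/i).
_LIGAND_ON = (
    ("E", "R1", "R1E", "kon_egf_{c}"),
    ("H", "R3", "R3H", "kon_hrg_{c}"),
    ("E", "R11E", "R11EE", "kon_egf_{c}"),
    ("H", "R33H", "R33HH", "kon_hrg_{c}"),
    ("H", "R13E", "R13EH", "kon_hrg_{c}"),
    # EGF binding to the open HER1 slot of an HRG-occupied R13: the factor-3
    # affinity penalty is carried by the off-rate, not here
    ("E", "R13H", "R13EH", "kon_egf_{c}"),
)

# ligand release that leaves a still-liganded dimer (or a monomer) behind
_LIGAND_OFF = (
    ("R1E", ("R1", "E"), "koff_egf_{c}", 1.0),
    ("R3H", ("R3", "H"), "koff_hrg_{c}", 1.0),
    ("R11EE", ("R11E", "E"), "koff_egf_{c}", 2.0),
    ("R33HH", ("R33H", "H"), "koff_hrg_{c}", 2.0),
    ("R13EH", ("R13H", "E"), "koff_egf_r13hrg_{c}", 1.0),
    ("R13EH", ("R13E", "H"), "koff_hrg_{c}", 1.0),
)

# loss of the sole ligand from a singly-liganded dimer: lumped collapse
_COLLAPSE = (
    ("R11E", ("R1", "R1", "E"), "koff_egf_{c}"),
    ("R12E", ("R1", "R2", "E"), "koff_egf_r12_{c}"),
    ("R13E", ("R1", "R3", "E"), "koff_egf_{c}"),
    ("R13H", ("R1", "R3", "H"), "koff_hrg_{c}"),
    ("R23H", ("R2", "R3", "H"), "koff_hrg_r23_{c}"),
    ("R33H", ("R3", "R3", "H"), "koff_hrg_{c}"),
)

# the ten dimerization equilibria: (partner, partner, dimer, ku key)
_DIMERIZATION = (
    ("R1E", "R1", "R11E", "ku11e"),
    ("R1E", "R1E", "R11EE", "ku11ee"),
    ("R1E", "R2", "R12E", "ku12e"),
    ("R1E", "R3", "R13E", "ku13e"),
    ("R1", "R3H", "R13H", "ku13h"),
    ("R1E", "R3H", "R13EH", "ku13eh"),
    ("R2", "R2", "R22", "ku22"),
    ("R2", "R3H", "R23H", "ku23h"),
    ("R3", "R3H", "R33H", "ku33h"),
    ("R3H", "R3H", "R33HH", "ku33hh"),
)


def build_reactions(species: SpeciesSet, params: ParameterSet) -> list[Reaction]:
    """Generate every reaction at the surface and the early endosome.

    Each reaction is tagged with a rate reference resolvable through
    ``params.rate_value``.  Raises if a reaction would involve a species
    absent from ``species``.
    """
    known = set(species.names)

    def check(*names: str) -> None:
        for n in names:
            if n not in known:
                raise ValueError(f"reaction references unknown species {n!r}")

    reactions: list[Reaction] = []
    for comp in REACTIVE_COMPARTMENTS:
        c = "s" if comp == "surface" else "i"
        for lig, partner, product, ref in _LIGAND_ON:
            check(lig, partner, product)
            reactions.append(Reaction(
                (lig, partner), (product,), ref.format(c=c), comp, "ligand_on"))
        for src, prods, ref, mult in _LIGAND_OFF:
            check(src, *prods)
            reactions.append(Reaction(
                (src,), prods, ref.format(c=c), comp, "ligand_off", factor=mult))
        for src, prods, ref in _COLLAPSE:
            check(src, *prods)
            reactions.append(Reaction(
                (src,), prods, ref.format(c=c), comp,
                "ligand_off_with_dimer_collapse"))
        for a, b, dimer, ku in _DIMERIZATION:
            check(a, b, dimer)
            reactions.append(Reaction(
                (a, b), (dimer,), f"kc_{c}", comp, "dimer_on"))
            reactions.append(Reaction(
                (dimer,), (a, b), f"{ku}_{c}", comp, "dimer_off"))
        # every rate reference must resolve against the parameter set
    for rx in reactions:
        params.rate_value(rx.rate_ref)
    return reactions
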