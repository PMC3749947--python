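"""Species enumeration for the HER1-3 activation network.

The model tracks 17 molecular species: the two ligands EGF (E) and HRG (H),
five receptor monomers (free and ligand-bound HER1/HER2/HER3), and the ten
homo- and hetero-dimers that can form after ligand addition.  HER2 has no
ligand; HER3 binds only HRG; HER1 binds only EGF.  Every species exists in
three compartments -- cell surface, early endosome (EE) and late endosome
(LE) -- giving 51 state variables.

The canonical state-vector layout is compartment-major, species-minor, with
0-based indexing: ``index = compartment_index * 17 + species_index``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "Species",
    "SpeciesSet",
    "ModelConfig",
    "enumerate_species",
    "COMPARTMENTS",
    "SURFACE",
    "EARLY_ENDOSOME",
    "LATE_ENDOSOME",
]

SURFACE = "surface"
EARLY_ENDOSOME = "early_endosome"
LATE_ENDOSOME = "late_endosome"
#: compartments in canonical order; biochemistry occurs only in the first two
COMPARTMENTS = (SURFACE, EARLY_ENDOSOME, LATE_ENDOSOME)
#: compartments where reactions are generated
REACTIVE_COMPARTMENTS = (SURFACE, EARLY_ENDOSOME)

VALID_RECEPTORS = ("HER1", "HER2", "HER3")
VALID_LIGANDS = ("EGF", "HRG")

#: which ligand each receptor can carry (HER2: none)
RECEPTOR_LIGAND = {"HER1": "EGF", "HER2": None, "HER3": "HRG"}


@dataclass(frozen=True)
class Species:
    """A molecular entity: ligand, receptor monomer, or receptor dimer.

    ``receptors`` lists the receptor slots (1 for monomers, 2 for dimers) and
    ``ligands`` the per-slot occupancy aligned with ``receptors`` (``None``
    for an empty slot).  Ligand species have no receptor slots.
    """

    name: str
    kind: str  # "ligand" | "monomer" | "dimer"
    receptors: tuple[str, ...] = ()
    ligands: tuple[str | None, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("ligand", "monomer", "dimer"):
            raise ValueError(f"unknown species kind {self.kind!r}")
        if len(self.receptors) != len(self.ligands):
            raise ValueError("receptors and ligands must align slot-by-slot")
        for rec, lig in zip(self.receptors, self.ligands):
            if rec not in VALID_RECEPTORS:
                raise ValueError(f"unknown receptor {rec!r}")
            if lig is not None and lig != RECEPTOR_LIGAND[rec]:
                raise ValueError(
                    f"illegal occupancy: {lig} cannot be carried by {rec}"
                )

    def receptor_count(self, receptor: str) -> int:
        """Number of copies of ``receptor`` in this species (dimers: up to 2)."""
        return sum(1 for r in self.receptors if r == receptor)

    @property
    def n_ligands(self) -> int:
        return sum(1 for l in self.ligands if l is not None)

    @property
    def is_receptor_species(self) -> bool:
        return self.kind in ("monomer", "dimer")


def _mono(name: str, receptor: str, ligand: str | None) -> Species:
    return Species(name, "monomer", (receptor,), (ligand,))


def _dimer(name: str, slots: Iterable[tuple[str, str | None]]) -> Species:
    slots = tuple(slots)
    return Species(
        name, "dimer", tuple(s[0] for s in slots), tuple(s[1] for s in slots)
    )


# Canonical enumeration.  The ten dimer types are exactly those that can be
# populated through ligand-induced dimerization plus the constitutively
# dimerizing HER2: R11E, R11EE, R12E, R13E, R13H, R13EH, R22, R23H, R33H,
# R33HH (Rij = HERi-HERj dimer; suffix E/H = bound EGF/HRG).
_CANONICAL: tuple[Species, ...] = (
    Species("E", "ligand"),
    Species("H", "ligand"),
    _mono("R1", "HER1", None),
    _mono("R1E", "HER1", "EGF"),
    _mono("R2", "HER2", None),
    _mono("R3", "HER3", None),
    _mono("R3H", "HER3", "HRG"),
    _dimer("R11E", [("HER1", "EGF"), ("HER1", None)]),
    _dimer("R11EE", [("HER1", "EGF"), ("HER1", "EGF")]),
    _dimer("R12E", [("HER1", "EGF"), ("HER2", None)]),
    _dimer("R13E", [("HER1", "EGF"), ("HER3", None)]),
    _dimer("R13H", [("HER1", None), ("HER3", "HRG")]),
    _dimer("R13EH", [("HER1", "EGF"), ("HER3", "HRG")]),
    _dimer("R22", [("HER2", None), ("HER2", None)]),
    _dimer("R23H", [("HER2", None), ("HER3", "HRG")]),
    _dimer("R33H", [("HER3", "HRG"), ("HER3", None)]),
    _dimer("R33HH", [("HER3", "HRG"), ("HER3", "HRG")]),
)


@dataclass(frozen=True)
class ModelConfig:
    """Structural configuration: which receptors and ligands are modeled."""

    receptors: tuple[str, ...] = VALID_RECEPTORS
    ligands: tuple[str, ...] = VALID_LIGANDS


class SpeciesSet:
    """The ordered species list and the canonical state-vector layout."""

    def __init__(self, species: tuple[Species, ...] = _CANONICAL):
        self.species = species
        self.names = tuple(s.name for s in species)
        self.n_species = len(species)
        self.compartments = COMPARTMENTS
        self.n_states = self.n_species * len(COMPARTMENTS)
        self._index = {name: i for i, name in enumerate(self.names)}
        self._comp_index = {c: i for i, c in enumerate(COMPARTMENTS)}

    def species_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown species {name!r}") from None

    def state_index(self, name: str, compartment: str) -> int:
        ci = self._comp_index[compartment]
        return ci * self.n_species + self.species_index(name)

    def state_labels(self) -> list[str]:
        return [
            f"{name}_{comp}" for comp in COMPARTMENTS for name in self.names
        ]

    def by_name(self, name: str) -> Species:
        return self.species[self.species_index(name)]

    def receptor_count_matrix(self):
        """(3, n_species) array of HER1/2/3 copy counts per species.

        Homodimers count their receptor twice; used for receptor-mass
        observables and conservation checks.
        """
        import numpy as np

        mat = np.zeros((3, self.n_species))
        for j, sp in enumerate(self.species):
            for i, rec in enumerate(VALID_RECEPTORS):
                mat[i, j] = sp.receptor_count(rec)
        return mat

    def __iter__(self):
        return iter(self.species)

    def __len__(self) -> int:
        return self.n_species


def enumerate_species(config: ModelConfig | None = None) -> SpeciesSet:
    """Build the complete species set in canonical order.

    The species list is structural: receptor expression levels affect initial
    conditions only, never the list itself.  Rejects configurations naming
    receptors outside HER1-3 or ligands outside {EGF, HRG}.
    """
    if config is None:
        config = ModelConfig()
    bad = [r for r in config.receptors if r not in VALID_RECEPTORS]
    if bad:
        raise ValueError(f"unsupported receptors: {bad}; model covers HER1-3")
    bad_l = [l for l in config.ligands if l not in VALID_LIGANDS]
    if bad_l:
        raise ValueError(f"unsupported ligands: {bad_l}; model covers EGF, HRG")
    return SpeciesSet()
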