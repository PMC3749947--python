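"""Rate constants, phosphorylation factors and trafficking parameters.

The parameter set is partitioned into *fixed* entries (ligand binding
kinetics, the common diffusion-limited dimerization rate, trafficking
constants -- all taken as known from the literature) and 47 *free* entries
estimated from data: the 20 dimer dissociation rates (10 dimer types x
{surface, early endosome}), the 26 phosphorylation factors (13 pf names x
2 compartments) and the single sorting parameter delta1.

Context-dependent ligand affinities are realized by scaling the ligand
off-rate inside the dimer while leaving the on-rate unchanged, so the Kd
ratios hold exactly:

* EGF in the HER1-HER2 dimer: Kd divided by 1.6 (60% stronger affinity),
* HRG in the HER2-HER3 dimer: Kd divided by 25,
* EGF in an HRG-occupied HER1-HER3 dimer: Kd multiplied by 3.

Units: receptors in molecules/cell; extracellular ligand in nM (doses in
ng/ml are converted via the ligand molecular weight); first-order rates in
1/min; kon in 1/(nM*min); kc in 1/((molecules/cell)*min).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .species import Species

__all__ = [
    "ParameterSet",
    "TraffickingRates",
    "default_parameters",
    "derive_trafficking_rates",
    "DIMER_KEYS",
    "PF_KEYS",
    "FREE_KU_NAMES",
    "FREE_PF_NAMES",
]

#: the ten dimer types carrying free dissociation rates, canonical order
DIMER_KEYS = ("11e", "11ee", "12e", "13e", "13h", "13eh", "22", "23h", "33h", "33hh")

#: the 13 pf names; pf<ij> reads "HERi phospho-signal from the HERi-HERj dimer"
#: (HER3 homodimers have pf identically 0 and are not parameters)
PF_KEYS = (
    "pf11e", "pf11ee", "pf12e", "pf13e", "pf13h", "pf13eh",
    "pf21e", "pf22", "pf23h",
    "pf31e", "pf31h", "pf31eh", "pf32h",
)

_COMP_SUFFIX = ("s", "i")  # surface, early endosome

FREE_KU_NAMES = tuple(f"ku{d}_{c}" for c in _COMP_SUFFIX for d in DIMER_KEYS)
FREE_PF_NAMES = tuple(f"{p}_{c}" for c in _COMP_SUFFIX for p in PF_KEYS)
#: canonical ordering of the 47 free parameters
FREE_NAMES = FREE_KU_NAMES + FREE_PF_NAMES + ("delta1",)


@dataclass(frozen=True)
class TraffickingRates:
    """Per-species recycling, late-endosome entry and degradation rates."""

    kr: np.ndarray  # recycling, 1/min
    kl: np.ndarray  # LE entry, 1/min
    kd: np.ndarray  # degradation, 1/min
    delta: np.ndarray  # LE entry/exit ratio, dimensionless


def derive_trafficking_rates(kx, f, delta1, kx1=None, f1=None) -> TraffickingRates:
    """Derive kr/kl/kd/delta for every species from kx, f and delta1.

    ``kx`` (endosomal exit rate, 1/min) and ``f`` (recycling fraction) are
    per-species; ``delta1`` is the LE entry/exit ratio for the reference
    species (the EGFR monomer, whose kx/f are ``kx1``/``f1``; these default
    to the first element of the inputs).  All other deltas follow from the
    assumption that molecules reaching the late endosome are degraded at a
    common rate:

        1 + 1/delta_i = kx1*(1-f1)*(1+1/delta1) / (kx_i*(1-f_i))

    and then kr_i = kx_i*f_i*(1+delta_i), kl_i = kx_i*(1-f_i)*(1+delta_i),
    kd_i = kl_i/delta_i.
    """
    kx = np.atleast_1d(np.asarray(kx, dtype=float))
    f = np.atleast_1d(np.asarray(f, dtype=float))
    if kx.shape != f.shape:
        raise ValueError("kx and f must have the same shape")
    if np.any(kx <= 0):
        raise ValueError("endosomal exit rates kx must be positive")
    if np.any((f < 0) | (f >= 1)):
        raise ValueError("recycling fractions must satisfy 0 <= f < 1")
    if not delta1 > 0:
        raise ValueError("delta1 must be positive")
    kx1 = float(kx[0]) if kx1 is None else float(kx1)
    f1 = float(f[0]) if f1 is None else float(f1)

    anchor = kx1 * (1.0 - f1) * (1.0 + 1.0 / delta1)
    ratio = anchor / (kx * (1.0 - f))  # = 1 + 1/delta_i
    if np.any(ratio <= 1.0):
        raise ValueError(
            "inconsistent trafficking parameters: derived delta would be "
            "non-positive (kx*(1-f) exceeds the reference late-endosome flux)"
        )
    delta = 1.0 / (ratio - 1.0)
    kr = kx * f * (1.0 + delta)
    kl = kx * (1.0 - f) * (1.0 + delta)
    kd = kl / delta
    return TraffickingRates(kr=kr, kl=kl, kd=kd, delta=delta)


@dataclass
class ParameterSet:
    """All model parameters with the fixed/free partition.

    ``ku`` and ``pf`` map the free-parameter names (e.g. ``ku11ee_s``,
    ``pf12e_i``) to values; ``binding`` holds the ligand on/off rates per
    compartment (keys like ``kon_egf_s``).  Trafficking constants are stored
    per receptor class; per-species values are resolved by
    :meth:`species_trafficking`.
    """

    # --- ligand binding (fixed, literature) ---
    binding: dict[str, float] = field(default_factory=dict)
    # Kd modifiers for ligand binding in a dimer context (fixed ratios)
    egf_r12_kd_divisor: float = 1.6   # 60% stronger EGF affinity in R12
    hrg_r23_kd_divisor: float = 25.0  # 25-fold stronger HRG affinity in R23
    egf_r13_hrg_kd_multiplier: float = 3.0  # HRG-bound R13 binds EGF 3x weaker
    # --- dimerization (kc fixed "diffusion-limited"; ku free) ---
    kc_s: float = 1.0e-5
    kc_i: float = 1.0e-5
    ku: dict[str, float] = field(default_factory=dict)
    # --- phosphorylation factors (free) ---
    pf: dict[str, float] = field(default_factory=dict)
    # --- trafficking (fixed except delta1) ---
    kt: dict[str, float] = field(default_factory=dict)  # monomer internalization
    ke_her1_dimer_per_min: float = 0.20
    ke_her23_dimer_per_min: float = 0.05
    kx_her1_per_min: float = 0.09
    kx_her23_per_min: float = 0.05
    f_her1: float = 0.50
    f_her23: float = 0.85
    delta1: float = 2.0  # free
    # --- receptor synthesis is solved per cell line at equilibration ---
    # --- ligand bookkeeping ---
    ligand_mw_kda: dict[str, float] = field(
        default_factory=lambda: {"EGF": 6.4, "HRG": 7.5}
    )
    ligand_ee_sort_per_min: float = 0.05
    ligand_le_deg_per_min: float = 0.05
    ee_volume_factor: float = 1.0  # bimolecular correction in the EE
    # --- pertuzumab-style HER2 sequestration ---
    her2_available_fraction: float = 1.0

    # ------------------------------------------------------------------
    def copy(self) -> "ParameterSet":
        new = dataclasses.replace(self)
        new.binding = dict(self.binding)
        new.ku = dict(self.ku)
        new.pf = dict(self.pf)
        new.kt = dict(self.kt)
        new.ligand_mw_kda = dict(self.ligand_mw_kda)
        return new

    # --- free-parameter interface -------------------------------------
    @staticmethod
    def free_names() -> tuple[str, ...]:
        return FREE_NAMES

    @property
    def n_free(self) -> int:
        return len(FREE_NAMES)

    def get_value(self, name: str) -> float:
        if name == "delta1":
            return self.delta1
        if name.startswith("ku"):
            return self.ku[name]
        if name.startswith("pf"):
            return self.pf[name]
        raise KeyError(f"unknown free parameter {name!r}")

    def set_value(self, name: str, value: float) -> None:
        if name == "delta1":
            self.delta1 = float(value)
        elif name.startswith("ku"):
            if name not in self.ku:
                raise KeyError(f"unknown dissociation rate {name!r}")
            self.ku[name] = float(value)
        elif name.startswith("pf"):
            if name not in self.pf:
                raise KeyError(f"unknown phosphorylation factor {name!r}")
            self.pf[name] = float(value)
        else:
            raise KeyError(f"unknown free parameter {name!r}")

    def free_values(self, names=None) -> np.ndarray:
        names = FREE_NAMES if names is None else names
        return np.array([self.get_value(n) for n in names])

    def with_free(self, updates: dict[str, float]) -> "ParameterSet":
        new = self.copy()
        for name, value in updates.items():
            new.set_value(name, value)
        return new

    # --- derived rate references --------------------------------------
    def rate_value(self, ref: str) -> float:
        """Resolve a rate-constant reference used by the reaction network.

        All bimolecular rates in the early endosome (kon and kc) carry the
        configurable compartment-volume correction factor.
        """
        if ref in self.binding:
            value = self.binding[ref]
            if ref.startswith("kon") and ref.endswith("_i"):
                value *= self.ee_volume_factor
            return value
        if ref.startswith("ku"):
            return self.ku[ref]
        if ref == "kc_s":
            return self.kc_s
        if ref == "kc_i":
            return self.kc_i * self.ee_volume_factor
        # contextual ligand off-rates (on-rate unchanged => Kd ratio exact)
        base, _, comp = ref.rpartition("_")
        if base == "koff_egf_r12":
            return self.binding[f"koff_egf_{comp}"] / self.egf_r12_kd_divisor
        if base == "koff_hrg_r23":
            return self.binding[f"koff_hrg_{comp}"] / self.hrg_r23_kd_divisor
        if base == "koff_egf_r13hrg":
            return self.binding[f"koff_egf_{comp}"] * self.egf_r13_hrg_kd_multiplier
        raise KeyError(f"unknown rate reference {ref!r}")

    def kd(self, ligand: str, context: str = "monomer", compartment: str = "s") -> float:
        """Equilibrium dissociation constant (nM) for a ligand in a context.

        ``context`` is one of ``monomer``, ``r12``, ``r23``, ``r13hrg``.
        """
        kon = self.binding[f"kon_{ligand.lower()}_{compartment}"]
        if context == "monomer":
            koff = self.binding[f"koff_{ligand.lower()}_{compartment}"]
        else:
            koff = self.rate_value(f"koff_{ligand.lower()}_{context}_{compartment}")
        return koff / kon

    # --- trafficking resolution ---------------------------------------
    def _traffic_class(self, sp: Species) -> str:
        """HER2/HER3-containing species traffic like HER2; pure-HER1 like EGFR."""
        if any(r in ("HER2", "HER3") for r in sp.receptors):
            return "her23"
        return "her1"

    def species_kx_f(self, sp: Species) -> tuple[float, float]:
        if self._traffic_class(sp) == "her1":
            return self.kx_her1_per_min, self.f_her1
        return self.kx_her23_per_min, self.f_her23

    def species_internalization(self, sp: Species) -> float:
        if sp.kind == "monomer":
            return self.kt[sp.receptors[0]]
        if sp.kind == "dimer":
            if self._traffic_class(sp) == "her1":
                return self.ke_her1_dimer_per_min
            return self.ke_her23_dimer_per_min
        return 0.0  # free ligand: pinocytosis ignored

    def trafficking_for(self, species_list) -> TraffickingRates:
        """kr/kl/kd/delta for receptor species (zeros for ligands)."""
        kx = np.empty(len(species_list))
        f = np.empty(len(species_list))
        mask = np.zeros(len(species_list), dtype=bool)
        for j, sp in enumerate(species_list):
            if sp.is_receptor_species:
                kx[j], f[j] = self.species_kx_f(sp)
                mask[j] = True
            else:
                kx[j], f[j] = self.kx_her1_per_min, self.f_her1  # placeholder
        rates = derive_trafficking_rates(
            kx, f, self.delta1, kx1=self.kx_her1_per_min, f1=self.f_her1
        )
        kr = np.where(mask, rates.kr, 0.0)
        kl = np.where(mask, rates.kl, 0.0)
        kd = np.where(mask, rates.kd, 0.0)
        delta = np.where(mask, rates.delta, np.nan)
        return TraffickingRates(kr=kr, kl=kl, kd=kd, delta=delta)

    # --- conversions ---------------------------------------------------
    def dose_to_nM(self, ligand: str, ng_per_ml: float) -> float:
        """ng/ml -> nM using the ligand molecular weight (kDa)."""
        return ng_per_ml / self.ligand_mw_kda[ligand]

    # --- validation ----------------------------------------------------
    def validate(self) -> None:
        problems = []
        for name in FREE_KU_NAMES:
            if name not in self.ku:
                problems.append(f"missing dissociation rate {name}")
            elif self.ku[name] < 0:
                problems.append(f"negative dissociation rate {name}")
        for name in FREE_PF_NAMES:
            if name not in self.pf:
                problems.append(f"missing phosphorylation factor {name}")
            elif self.pf[name] < 0:
                problems.append(f"negative phosphorylation factor {name}")
        for key in ("kon_egf_s", "koff_egf_s", "kon_egf_i", "koff_egf_i",
                    "kon_hrg_s", "koff_hrg_s", "kon_hrg_i", "koff_hrg_i"):
            if key not in self.binding:
                problems.append(f"missing binding rate {key}")
            elif self.binding[key] < 0:
                problems.append(f"negative binding rate {key}")
        if not 0 <= self.her2_available_fraction <= 1:
            problems.append("her2_available_fraction outside [0, 1]")
        if not self.delta1 > 0:
            problems.append("delta1 must be positive")
        for rec in ("HER1", "HER2", "HER3"):
            if rec not in self.kt:
                problems.append(f"missing monomer internalization rate kt[{rec}]")
        for fname, fval in (("f_her1", self.f_her1), ("f_her23", self.f_her23)):
            if not 0 <= fval < 1:
                problems.append(f"{fname} outside [0, 1)")
        if problems:
            raise ValueError(
                "invalid parameter set:\n  " + "\n  ".join(problems)
            )


def default_parameters() -> ParameterSet:
    """The shipped default ("truth") parameter set.

    Fixed rates follow the literature ranges for HER trafficking and ligand
    binding in mammary epithelial cells; free entries (ku, pf, delta1) are
    the ground-truth values used by the synthetic-data generator.  EE ligand
    binding for HRG is set equal to EE EGF binding; HER3 traffics like HER2.
    """
    binding = {
        # EGF-HER1: Kd ~2.5 nM at the surface, weaker in the acidic EE
        "kon_egf_s": 0.097, "koff_egf_s": 0.24,
        "kon_egf_i": 0.050, "koff_egf_i": 1.20,
        # HRG-HER3: Kd ~1.5 nM at the surface; EE kinetics set to EGF's
        "kon_hrg_s": 0.040, "koff_hrg_s": 0.06,
        "kon_hrg_i": 0.050, "koff_hrg_i": 1.20,
    }
    ku_surface = {
        "11e": 8.0, "11ee": 5.0, "12e": 10.0, "13e": 12.0, "13h": 12.0,
        "13eh": 10.0, "22": 30.0, "23h": 4.0, "33h": 40.0, "33hh": 30.0,
    }
    ku = {}
    for d, v in ku_surface.items():
        ku[f"ku{d}_s"] = v
        ku[f"ku{d}_i"] = 2.0 * v  # dimers are less stable in the acidic EE
    pf_surface = {
        "pf11e": 0.010, "pf11ee": 0.030, "pf12e": 0.20, "pf13e": 0.050,
        "pf13h": 0.050, "pf13eh": 0.080,
        "pf21e": 0.050, "pf22": 0.005, "pf23h": 0.050,
        "pf31e": 0.030, "pf31h": 0.030, "pf31eh": 0.050, "pf32h": 0.100,
    }
    pf = {}
    for p, v in pf_surface.items():
        pf[f"{p}_s"] = v
        pf[f"{p}_i"] = 0.4 * v  # reduced phosphorylation efficiency in the EE
    kt = {"HER1": 0.05, "HER2": 0.01, "HER3": 0.01}
    params = ParameterSet(binding=binding, ku=ku, pf=pf, kt=kt)
    params.validate()
    return params
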