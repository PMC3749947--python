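"""Configuration files, dataset I/O and run manifests.

The canonical model configuration is YAML with blocks ``ligands``,
``rates``, ``trafficking``, ``pf`` and ``expression``; keys carry their
units as suffixes (``_per_min``, ``_per_nM_min``, ``_per_cell``).  Datasets
are tidy CSV (the :data:`herdyn.synthetic.DATASET_COLUMNS` schema); fitted
solution sets serialize to JSON.  Every pipeline output can be accompanied
by a :class:`RunManifest` capturing the config hash, seeds and paths needed
to reproduce it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .parameters import (
    FREE_KU_NAMES,
    FREE_PF_NAMES,
    ParameterSet,
    default_parameters,
)
from .simulate import FIXTURE_PROFILES, MEASUREMENTS, CellLineProfile
from .synthetic import DATASET_COLUMNS

__all__ = [
    "CONFIG_VERSION",
    "ConfigError",
    "load_config",
    "dump_config",
    "default_config_dict",
    "read_dataset",
    "write_dataset",
    "RunManifest",
]

#: semantic version of the default configuration layout
CONFIG_VERSION = "1.0.0"

_BINDING_KEYS = {
    "kon_egf_s": "kon_egf_s_per_nM_min", "koff_egf_s": "koff_egf_s_per_min",
    "kon_egf_i": "kon_egf_i_per_nM_min", "koff_egf_i": "koff_egf_i_per_min",
    "kon_hrg_s": "kon_hrg_s_per_nM_min", "koff_hrg_s": "koff_hrg_s_per_min",
    "kon_hrg_i": "kon_hrg_i_per_nM_min", "koff_hrg_i": "koff_hrg_i_per_min",
}


class ConfigError(ValueError):
    """Raised with the full list of validation problems, not just the first."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__(
            "invalid model configuration:\n  " + "\n  ".join(problems)
        )


def default_config_dict() -> dict:
    """The shipped default configuration as a plain dict."""
    return _to_dict(default_parameters(), _unique_fixture_profiles())


def _unique_fixture_profiles() -> dict[str, CellLineProfile]:
    out, seen = {}, set()
    for name, prof in FIXTURE_PROFILES.items():
        if id(prof) not in seen and name == prof.name:
            out[name] = prof
            seen.add(id(prof))
    return out


def _to_dict(params: ParameterSet, profiles: dict[str, CellLineProfile]) -> dict:
    rates = {yaml_key: params.binding[k] for k, yaml_key in _BINDING_KEYS.items()}
    rates.update({
        "kc_s_per_molecule_min": params.kc_s,
        "kc_i_per_molecule_min": params.kc_i,
        "egf_r12_kd_divisor": params.egf_r12_kd_divisor,
        "hrg_r23_kd_divisor": params.hrg_r23_kd_divisor,
        "egf_r13_hrg_kd_multiplier": params.egf_r13_hrg_kd_multiplier,
        "ku_per_min": {k: params.ku[k] for k in FREE_KU_NAMES},
    })
    trafficking = {
        "kt_her1_per_min": params.kt["HER1"],
        "kt_her2_per_min": params.kt["HER2"],
        "kt_her3_per_min": params.kt["HER3"],
        "ke_her1_dimer_per_min": params.ke_her1_dimer_per_min,
        "ke_her23_dimer_per_min": params.ke_her23_dimer_per_min,
        "kx_her1_per_min": params.kx_her1_per_min,
        "kx_her23_per_min": params.kx_her23_per_min,
        "f_her1": params.f_her1,
        "f_her23": params.f_her23,
        "delta1": params.delta1,
        "ligand_ee_sort_per_min": params.ligand_ee_sort_per_min,
        "ligand_le_deg_per_min": params.ligand_le_deg_per_min,
        "ee_volume_factor": params.ee_volume_factor,
    }
    return {
        "config_version": CONFIG_VERSION,
        "ligands": {
            "egf_mw_kda": params.ligand_mw_kda["EGF"],
            "hrg_mw_kda": params.ligand_mw_kda["HRG"],
        },
        "rates": rates,
        "trafficking": trafficking,
        "pf": {k: params.pf[k] for k in FREE_PF_NAMES},
        "expression": {
            name: {
                "her1_per_cell": prof.her1,
                "her2_per_cell": prof.her2,
                "her3_per_cell": prof.her3,
            } for name, prof in profiles.items()
        },
    }


def dump_config(path, params: ParameterSet | None = None,
                profiles: dict[str, CellLineProfile] | None = None) -> None:
    """Write a model configuration YAML file."""
    if params is None:
        params = default_parameters()
    if profiles is None:
        profiles = _unique_fixture_profiles()
    Path(path).write_text(
        yaml.safe_dump(_to_dict(params, profiles), sort_keys=False)
    )


def load_config(path) -> tuple[ParameterSet, dict[str, CellLineProfile]]:
    """Load and validate a configuration; all schema problems are listed.

    Verifies the fixed/free partition: exactly 47 free parameters (20 dimer
    dissociation rates + 26 phosphorylation factors + delta1).
    """
    raw = yaml.safe_load(Path(path).read_text())
    problems: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(["configuration root must be a mapping"])
    for block in ("ligands", "rates", "trafficking", "pf", "expression"):
        if block not in raw:
            problems.append(f"missing block '{block}'")
    if problems:
        raise ConfigError(problems)

    params = default_parameters()
    lig = raw["ligands"]
    for key, name in (("egf_mw_kda", "EGF"), ("hrg_mw_kda", "HRG")):
        if key not in lig:
            problems.append(f"ligands: missing '{key}'")
        else:
            params.ligand_mw_kda[name] = float(lig[key])

    rates = raw["rates"]
    for attr, yaml_key in _BINDING_KEYS.items():
        if yaml_key not in rates:
            problems.append(f"rates: missing '{yaml_key}'")
        else:
            params.binding[attr] = float(rates[yaml_key])
    for attr, yaml_key in (
            ("kc_s", "kc_s_per_molecule_min"), ("kc_i", "kc_i_per_molecule_min"),
            ("egf_r12_kd_divisor", "egf_r12_kd_divisor"),
            ("hrg_r23_kd_divisor", "hrg_r23_kd_divisor"),
            ("egf_r13_hrg_kd_multiplier", "egf_r13_hrg_kd_multiplier")):
        if yaml_key not in rates:
            problems.append(f"rates: missing '{yaml_key}'")
        else:
            setattr(params, attr, float(rates[yaml_key]))
    ku = rates.get("ku_per_min", {})
    for name in FREE_KU_NAMES:
        if name not in ku:
            problems.append(f"rates.ku_per_min: missing '{name}'")
        else:
            params.ku[name] = float(ku[name])
    extra_ku = set(ku) - set(FREE_KU_NAMES)
    if extra_ku:
        problems.append(f"rates.ku_per_min: unknown entries {sorted(extra_ku)}")

    tr = raw["trafficking"]
    tr_map = {
        "ke_her1_dimer_per_min": "ke_her1_dimer_per_min",
        "ke_her23_dimer_per_min": "ke_her23_dimer_per_min",
        "kx_her1_per_min": "kx_her1_per_min",
        "kx_her23_per_min": "kx_her23_per_min",
        "f_her1": "f_her1", "f_her23": "f_her23", "delta1": "delta1",
        "ligand_ee_sort_per_min": "ligand_ee_sort_per_min",
        "ligand_le_deg_per_min": "ligand_le_deg_per_min",
        "ee_volume_factor": "ee_volume_factor",
    }
    for attr, yaml_key in tr_map.items():
        if yaml_key not in tr:
            problems.append(f"trafficking: missing '{yaml_key}'")
        else:
            setattr(params, attr, float(tr[yaml_key]))
    for rec in ("her1", "her2", "her3"):
        key = f"kt_{rec}_per_min"
        if key not in tr:
            problems.append(f"trafficking: missing '{key}'")
        else:
            params.kt[rec.upper()] = float(tr[key])

    pf = raw["pf"]
    for name in FREE_PF_NAMES:
        if name not in pf:
            problems.append(f"pf: missing '{name}'")
        else:
            params.pf[name] = float(pf[name])
    extra_pf = set(pf) - set(FREE_PF_NAMES)
    if extra_pf:
        problems.append(f"pf: unknown entries {sorted(extra_pf)}")

    profiles: dict[str, CellLineProfile] = {}
    for name, levels in raw["expression"].items():
        try:
            profiles[name] = CellLineProfile(
                name,
                float(levels["her1_per_cell"]),
                float(levels["her2_per_cell"]),
                float(levels["her3_per_cell"]),
            )
        except (KeyError, TypeError):
            problems.append(
                f"expression.{name}: needs her1/her2/her3 '_per_cell' entries"
            )
        except ValueError as err:
            problems.append(f"expression.{name}: {err}")

    n_free = len(FREE_KU_NAMES) + len(FREE_PF_NAMES) + 1
    if n_free != 47:  # partition check; structural, should never fire
        problems.append(f"free-parameter partition broken: {n_free} != 47")
    if not problems:
        try:
            params.validate()
        except ValueError as err:
            problems.extend(str(err).splitlines()[1:])
    if problems:
        raise ConfigError(problems)
    return params, profiles


def n_free_parameters(params: ParameterSet) -> int:
    return len(params.free_names())


# ---------------------------------------------------------------------------
def write_dataset(dataset: pd.DataFrame, path) -> None:
    """Write a tidy measurement dataset as UTF-8 CSV with header."""
    _validate_dataset(dataset)
    dataset.to_csv(path, index=False)


def read_dataset(path) -> pd.DataFrame:
    """Read and validate a tidy measurement dataset CSV."""
    df = pd.read_csv(path)
    _validate_dataset(df)
    return df


def _validate_dataset(df: pd.DataFrame) -> None:
    missing = set(DATASET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"dataset missing columns: {sorted(missing)}")
    unknown = set(df["measurement"].unique()) - set(MEASUREMENTS)
    if unknown:
        raise ValueError(f"unknown measurement labels: {sorted(unknown)}")
    if (df["value"] < 0).any():
        raise ValueError("negative measurement values are not allowed")


# ---------------------------------------------------------------------------
@dataclass
class RunManifest:
    """Provenance needed to reproduce a pipeline output bit-for-bit."""

    command: str
    seed: int | None
    config_hash: str
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    package_version: str = "0.1.0"
    config_version: str = CONFIG_VERSION
    created_unix: float = field(default_factory=time.time)

    @staticmethod
    def hash_config(params: ParameterSet,
                    profiles: dict[str, CellLineProfile] | None = None) -> str:
        payload = _to_dict(params, profiles or _unique_fixture_profiles())
        text = json.dumps(payload, sort_keys=True, default=float)
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, default=str)
        )
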