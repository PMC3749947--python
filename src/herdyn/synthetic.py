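"""ELISA-like synthetic datasets with the study's measurement structure.

The generator emulates the experimental design: four cell lines spanning
the HER2/HER3 on/off combinations, EGF dose series (0.6-30 ng/ml) and HRG
dose series (4-120 ng/ml) sampled at 0/10/30/60 min, detailed 2-hour time
courses for 12 ng/ml EGF and/or 40 ng/ml HRG covering total phospho (pRt),
internal phospho (pRi) and receptor mass (mRt), and HER2-blocking (2C4)
conditions read at 10 and 30 min.  Only receptors a line expresses are
measured.  Measurement noise is multiplicative lognormal with a
configurable CV, parameterized to be mean-preserving so replicate averages
converge to the noiseless model output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .parameters import ParameterSet, default_parameters
from .simulate import (
    FIXTURE_PROFILES,
    MEASUREMENTS,
    CellLineProfile,
    StimulationProtocol,
    compute_observables,
    run_protocol,
)

__all__ = [
    "Condition",
    "MeasurementDesign",
    "NoiseModel",
    "default_design",
    "generate",
    "DATASET_COLUMNS",
]

DATASET_COLUMNS = (
    "cell_line", "egf_ng_ml", "hrg_ng_ml", "block", "time_min",
    "measurement", "replicate", "value",
)

#: frozen dose grids; the study reports the ranges 0.6-30 (EGF) and
#: 4-120 ng/ml (HRG), sampled here at four roughly log-spaced doses
EGF_DOSES = (0.6, 3.0, 12.0, 30.0)
HRG_DOSES = (4.0, 12.0, 40.0, 120.0)
DOSE_TIMES = (0.0, 10.0, 30.0, 60.0)
TIMECOURSE_TIMES = (0.0, 5.0, 10.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0)
BLOCK_TIMES = (10.0, 30.0)


@dataclass(frozen=True)
class Condition:
    """One (cell line, treatment) combination with its sampling plan."""

    cell_line: str
    egf_ng_ml: float
    hrg_ng_ml: float
    block: float
    times: tuple[float, ...]
    measurements: tuple[str, ...]
    replicates: int = 2

    def __post_init__(self):
        if self.replicates < 2:
            raise ValueError("the design requires replicate count >= 2")
        unknown = set(self.measurements) - set(MEASUREMENTS)
        if unknown:
            raise ValueError(f"unknown measurement labels: {sorted(unknown)}")

    def protocol(self) -> StimulationProtocol:
        return StimulationProtocol(
            egf_ng_ml=self.egf_ng_ml, hrg_ng_ml=self.hrg_ng_ml,
            duration_min=max(self.times) if self.times else 0.0,
            sample_times=self.times, block_fraction=self.block,
        )


@dataclass(frozen=True)
class MeasurementDesign:
    """An ordered collection of measurement conditions."""

    conditions: tuple[Condition, ...]
    name: str = "custom"

    def n_records(self) -> int:
        return sum(
            len(c.times) * len(c.measurements) * c.replicates
            for c in self.conditions
        )

    def with_replicates(self, n: int) -> "MeasurementDesign":
        return MeasurementDesign(
            tuple(replace(c, replicates=n) for c in self.conditions), self.name
        )


def _expressed_measurements(profile: CellLineProfile, kinds: tuple[str, ...]
                            ) -> tuple[str, ...]:
    """Measurement labels restricted to receptors the line expresses."""
    out = []
    for i, level in ((1, profile.her1), (2, profile.her2), (3, profile.her3)):
        if level > 0:
            for kind in kinds:
                out.append(f"{kind[:2]}{i}{kind[2:]}")
    return tuple(out)


def default_design(replicates: int = 2,
                   cell_lines: tuple[str, ...] = ("HER2-3-", "HER2+3-",
                                                  "HER2-3+", "HER2+3+"),
                   ) -> MeasurementDesign:
    """The frozen study-emulating design for the fixture cell lines.

    Per line: EGF and HRG dose series (pRt at 0/10/30/60 min), three 2-hour
    time courses (12 ng/ml EGF, 40 ng/ml HRG, both; pRt + pRi + mRt), and
    2C4-blocked versions of the time-course treatments read at 10/30 min
    (pRt).  Only expressed receptors are measured.
    """
    conditions: list[Condition] = []
    for line in cell_lines:
        profile = FIXTURE_PROFILES[line]
        prt = _expressed_measurements(profile, ("pRt",))
        full = _expressed_measurements(profile, ("pRt", "pRi", "mRt"))
        for dose in EGF_DOSES:
            conditions.append(Condition(line, dose, 0.0, 0.0, DOSE_TIMES,
                                        prt, replicates))
        for dose in HRG_DOSES:
            conditions.append(Condition(line, 0.0, dose, 0.0, DOSE_TIMES,
                                        prt, replicates))
        for egf, hrg in ((12.0, 0.0), (0.0, 40.0), (12.0, 40.0)):
            conditions.append(Condition(line, egf, hrg, 0.0,
                                        TIMECOURSE_TIMES, full, replicates))
            conditions.append(Condition(line, egf, hrg, 0.95, BLOCK_TIMES,
                                        prt, replicates))
    return MeasurementDesign(tuple(conditions), name="study-default")


@dataclass(frozen=True)
class NoiseModel:
    """Mean-preserving multiplicative lognormal measurement noise.

    ``cv`` is the coefficient of variation per measurement; ``floor`` is a
    detection floor applied after noising.  cv = 0 reproduces the noiseless
    model output exactly.
    """

    cv: float = 0.10
    floor: float = 0.0

    def __post_init__(self):
        if self.cv < 0:
            raise ValueError("cv must be non-negative")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.cv == 0:
            noisy = np.asarray(values, dtype=float)
        else:
            sigma = np.sqrt(np.log1p(self.cv ** 2))
            z = rng.standard_normal(np.shape(values))
            noisy = values * np.exp(sigma * z - 0.5 * sigma ** 2)
        return np.maximum(noisy, self.floor)


def predict_condition(condition: Condition,
                      params: ParameterSet) -> pd.DataFrame:
    """Noiseless model observables for one condition (tidy, one per time)."""
    traj = run_protocol(condition.cell_line, condition.protocol(), params)
    obs = compute_observables(traj)
    obs = obs[obs["measurement"].isin(condition.measurements)]
    obs = obs[np.isin(obs["time_min"], condition.times)]
    return obs.reset_index(drop=True)


def generate(design: MeasurementDesign,
             truth: ParameterSet | None = None,
             noise: NoiseModel | None = None,
             seed: int = 0) -> pd.DataFrame:
    """Simulate every condition and draw noisy replicates.

    Deterministic given ``seed``.  The returned tidy frame has columns
    ``cell_line, egf_ng_ml, hrg_ng_ml, block, time_min, measurement,
    replicate, value`` and carries provenance in ``DataFrame.attrs``.
    """
    if truth is None:
        truth = default_parameters()
    if noise is None:
        noise = NoiseModel()
    rng = np.random.default_rng(seed)
    frames = []
    for cond in design.conditions:
        try:
            obs = predict_condition(cond, truth)
        except Exception as err:  # noqa: BLE001 - re-raise with condition id
            raise RuntimeError(
                f"simulation failed for condition {cond.cell_line} "
                f"EGF={cond.egf_ng_ml} HRG={cond.hrg_ng_ml} "
                f"block={cond.block}: {err}"
            ) from err
        for rep in range(1, cond.replicates + 1):
            frame = obs.copy()
            frame["cell_line"] = cond.cell_line
            frame["egf_ng_ml"] = cond.egf_ng_ml
            frame["hrg_ng_ml"] = cond.hrg_ng_ml
            frame["block"] = cond.block
            frame["replicate"] = rep
            frame["value"] = noise.apply(frame["value"].to_numpy(), rng)
            frames.append(frame)
    out = pd.concat(frames, ignore_index=True)[list(DATASET_COLUMNS)]
    out.attrs["design"] = design.name
    out.attrs["seed"] = seed
    out.attrs["noise_cv"] = noise.cv
    return out
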