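"""Multistart nonlinear least-squares estimation of the 47 free parameters.

Residuals are scaled per measurement type by the maximum observed value of
that type, so phosphorylation and mass measurements contribute comparably;
the fit quality metric is the RMSE of the scaled residual vector.  Free
rates and pf values are optimized in log10 space (their bounds span 3-6
decades); the sorting parameter delta1 is optimized linearly.  Initial
guesses are drawn uniformly in the transformed space: dissociation rates
from [1e-3, 1e3], pf values from [1e-6, 1] and delta1 from [0.1, 10].

The progressive strategy mirrors the staged study design: HER1-related
parameters are estimated first on the parental (HER2-3-) line; the result
seeds fits of the HER1-HER2 block (parental + HER2+3-) and the HER1-HER3
block (parental + HER2-3+); the final stage frees all 47 parameters on all
four lines with randomized guesses for the HER2-HER3 interaction.

Converged solutions close in RMSE to the best are grouped by k-means on
standardized log-parameters (k chosen by silhouette) and each cluster is
summarized by its minimum-RMSE representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import CompiledModel
from .parameters import FREE_NAMES, ParameterSet, default_parameters
from .simulate import (
    FIXTURE_PROFILES,
    StimulationProtocol,
    apply_block,
    compute_observables,
    equilibrate,
    simulate,
)

__all__ = [
    "FitProblem",
    "FitResult",
    "SolutionSet",
    "assemble_residuals",
    "residual_scales",
    "fit",
    "multistart_fit",
    "progressive_fit",
    "cluster_solutions",
    "param_receptors",
    "stage_free_names",
]

#: default sampling/bound ranges for the free parameters
KU_BOUNDS = (1e-3, 1e3)
PF_BOUNDS = (1e-6, 1.0)
DELTA1_BOUNDS = (0.1, 10.0)

#: scaled-residual value substituted when a candidate's simulation fails
PENALTY_RESIDUAL = 10.0


def param_receptors(name: str) -> frozenset[str]:
    """The set of receptors a free parameter refers to.

    ``ku13eh_s`` -> {HER1, HER3}; ``pf21e_i`` -> {HER1, HER2}; ``delta1``
    refers to the EGFR monomer sorting ratio -> {HER1}.
    """
    if name == "delta1":
        return frozenset({"HER1"})
    digits = name[2:4]
    return frozenset({f"HER{d}" for d in digits})


def stage_free_names(stage: str) -> tuple[str, ...]:
    """Free-parameter subsets for the progressive stages.

    ``her1``: parameters touching HER1 only (plus delta1); ``her1-her2`` /
    ``her1-her3``: the additional parameters of those interaction blocks;
    ``her2-her3``: the remaining HER2-HER3 block; ``all``: all 47.
    """
    her1 = tuple(n for n in FREE_NAMES if param_receptors(n) <= {"HER1"})
    if stage == "her1":
        return her1
    if stage == "all":
        return FREE_NAMES
    targets = {
        "her1-her2": {"HER1", "HER2"},
        "her1-her3": {"HER1", "HER3"},
        "her2-her3": {"HER2", "HER3"},
    }[stage]
    return tuple(
        n for n in FREE_NAMES
        if param_receptors(n) <= targets and n not in her1
    )


def residual_scales(dataset: pd.DataFrame) -> dict[str, float]:
    """Per-measurement-type scaling constants: the maximum observed value."""
    scales = dataset.groupby("measurement")["value"].max().to_dict()
    zero = [m for m, s in scales.items() if not s > 0]
    if zero:
        raise ValueError(
            f"cannot scale residuals: measurement types {zero} have "
            "non-positive maxima"
        )
    return scales


def assemble_residuals(dataset: pd.DataFrame, predictions: pd.DataFrame,
                       scales: dict[str, float] | None = None) -> np.ndarray:
    """Scaled residual vector (prediction - value)/scale over all records.

    ``predictions`` must cover every dataset record (matched on cell line,
    treatment, time and measurement); a missing prediction is a hard error.
    """
    if scales is None:
        scales = residual_scales(dataset)
    keys = ["cell_line", "egf_ng_ml", "hrg_ng_ml", "block", "time_min",
            "measurement"]
    merged = dataset.merge(
        predictions.rename(columns={"value": "prediction"}),
        on=keys, how="left", validate="many_to_one",
    )
    if merged["prediction"].isna().any():
        missing = merged[merged["prediction"].isna()][keys].drop_duplicates()
        raise ValueError(
            f"predictions missing for {len(missing)} dataset conditions, "
            f"e.g.\n{missing.head()}"
        )
    scale = merged["measurement"].map(scales).to_numpy()
    return (merged["prediction"].to_numpy() - merged["value"].to_numpy()) / scale


def rmse_of(residuals: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(residuals))))


@dataclass
class FitProblem:
    """A bound-constrained scaled least-squares problem over free parameters."""

    dataset: pd.DataFrame
    free_names: tuple[str, ...] = FREE_NAMES
    base_params: ParameterSet = field(default_factory=default_parameters)
    profiles: dict = field(default_factory=lambda: dict(FIXTURE_PROFILES))
    scales: dict[str, float] | None = None
    sim_rtol: float = 1e-6
    sim_atol: float = 1e-8

    def __post_init__(self):
        if self.scales is None:
            self.scales = residual_scales(self.dataset)
        self._conditions = []
        keys = ["cell_line", "egf_ng_ml", "hrg_ng_ml", "block"]
        for key, group in self.dataset.groupby(keys, sort=True):
            line, egf, hrg, block = key
            times = tuple(sorted(group["time_min"].unique()))
            protocol = StimulationProtocol(
                egf_ng_ml=egf, hrg_ng_ml=hrg,
                duration_min=max(times) if max(times) > 0 else 1.0,
                sample_times=times, block_fraction=block,
            )
            self._conditions.append((line, protocol))
        self.n_records = len(self.dataset)

    # --- transform between parameter values and optimizer space -------
    def _is_log(self, name: str) -> bool:
        return name != "delta1"

    def pack(self, values: dict[str, float] | np.ndarray) -> np.ndarray:
        if isinstance(values, dict):
            values = np.array([values[n] for n in self.free_names])
        return np.array([
            np.log10(v) if self._is_log(n) else v
            for n, v in zip(self.free_names, values)
        ])

    def unpack(self, x: np.ndarray) -> dict[str, float]:
        return {
            n: (10.0 ** xi if self._is_log(n) else float(xi))
            for n, xi in zip(self.free_names, x)
        }

    def bounds_for(self, name: str) -> tuple[float, float]:
        if name == "delta1":
            return DELTA1_BOUNDS
        return KU_BOUNDS if name.startswith("ku") else PF_BOUNDS

    def packed_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for n in self.free_names:
            b = self.bounds_for(n)
            if self._is_log(n):
                lo.append(np.log10(b[0]))
                hi.append(np.log10(b[1]))
            else:
                lo.append(b[0])
                hi.append(b[1])
        return np.array(lo), np.array(hi)

    def sample_start(self, rng: np.random.Generator) -> np.ndarray:
        lo, hi = self.packed_bounds()
        return rng.uniform(lo, hi)

    # --- forward model -------------------------------------------------
    def predictions(self, params: ParameterSet) -> pd.DataFrame:
        """Noiseless observables for every condition in the dataset."""
        model = CompiledModel(params=params)
        frames = []
        eq_cache: dict = {}
        for line, protocol in self._conditions:
            profile = self.profiles[line]
            key = (line, protocol.block_fraction)
            if key not in eq_cache:
                p_eff = params
                if protocol.block_fraction > 0:
                    p_eff = apply_block(params, protocol.block_fraction)
                eq_cache[key] = (equilibrate(profile, p_eff, model=model), p_eff)
            eq, p_eff = eq_cache[key]
            traj = simulate(eq, protocol, p_eff, rtol=self.sim_rtol,
                            atol=self.sim_atol, model=model)
            obs = compute_observables(traj)
            obs["cell_line"] = line
            obs["egf_ng_ml"] = protocol.egf_ng_ml
            obs["hrg_ng_ml"] = protocol.hrg_ng_ml
            obs["block"] = protocol.block_fraction
            frames.append(obs)
        return pd.concat(frames, ignore_index=True)

    def residuals_for_params(self, params: ParameterSet) -> np.ndarray:
        return assemble_residuals(self.dataset, self.predictions(params),
                                  self.scales)

    def residuals(self, x: np.ndarray) -> np.ndarray:
        """Optimizer-space residuals; simulation failure yields a penalty."""
        params = self.base_params.with_free(self.unpack(x))
        try:
            return self.residuals_for_params(params)
        except Exception:  # noqa: BLE001 - penalized, not fatal
            return np.full(self.n_records, PENALTY_RESIDUAL)

    def rmse(self, x: np.ndarray) -> float:
        return rmse_of(self.residuals(x))


@dataclass
class FitResult:
    """Terminal state of one local optimization run."""

    values: dict[str, float]
    x: np.ndarray
    rmse: float
    rmse_initial: float
    converged: bool
    nfev: int
    start_id: int = -1
    message: str = ""

    def params(self, base: ParameterSet) -> ParameterSet:
        return base.with_free(self.values)


@dataclass
class SolutionSet:
    """Converged fits plus (after clustering) labels and representatives."""

    problem: FitProblem
    results: list[FitResult]
    labels: np.ndarray | None = None
    n_clusters: int | None = None
    representatives: list[int] | None = None

    @property
    def best(self) -> FitResult:
        return min(self.results, key=lambda r: r.rmse)

    def rmses(self) -> np.ndarray:
        return np.array([r.rmse for r in self.results])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.results):
            row = {"start_id": r.start_id, "rmse": r.rmse,
                   "converged": r.converged}
            if self.labels is not None:
                row["cluster"] = self.labels[i]
                row["representative"] = (
                    self.representatives is not None
                    and i in self.representatives
                )
            row.update(r.values)
            rows.append(row)
        return pd.DataFrame(rows)

    def representative_results(self) -> list[FitResult]:
        if self.representatives is None:
            raise ValueError("solutions have not been clustered yet")
        return [self.results[i] for i in self.representatives]


def fit(problem: FitProblem, start, start_id: int = -1,
        max_nfev: int | None = 200, **ls_kwargs) -> FitResult:
    """One bound-constrained least-squares run from ``start``.

    ``start`` is a dict of parameter values or an optimizer-space vector.
    The terminal RMSE never exceeds the initial one (descent contract of
    trust-region least squares).
    """
    x0 = problem.pack(start) if isinstance(start, dict) else np.asarray(start)
    lo, hi = problem.packed_bounds()
    x0 = np.clip(x0, lo, hi)
    r0 = problem.residuals(x0)
    # finite-difference steps must dominate the integrator's noise floor
    ls_kwargs.setdefault("diff_step", 1e-3)
    sol = least_squares(
        problem.residuals, x0, bounds=(lo, hi), method="trf",
        max_nfev=max_nfev, **ls_kwargs,
    )
    rmse0 = rmse_of(r0)
    rmse1 = rmse_of(sol.fun)
    if rmse1 > rmse0:  # pathological step rejection: keep the start
        sol.x, rmse1 = x0, rmse0
    # a run stopped by the evaluation budget still counts if it improved
    converged = bool(sol.success) or rmse1 < rmse0
    return FitResult(
        values=problem.unpack(sol.x), x=sol.x, rmse=rmse1,
        rmse_initial=rmse0, converged=converged,
        nfev=sol.nfev, start_id=start_id, message=sol.message,
    )


def multistart_fit(problem: FitProblem, n_starts: int = 20, seed: int = 0,
                   starts: list | None = None, **fit_kwargs) -> SolutionSet:
    """Repeated local fits from prior-sampled (or supplied) starts.

    Deterministic given ``seed``: per-start substreams are spawned from one
    master seed.
    """
    streams = np.random.SeedSequence(seed).spawn(n_starts)
    results = []
    for i in range(n_starts):
        rng = np.random.default_rng(streams[i])
        if starts is not None:
            x0 = starts[i % len(starts)]
            if isinstance(x0, dict):
                x0 = problem.pack(x0)
            # jitter supplied starts (except the first pass) for diversity
            if i >= len(starts):
                lo, hi = problem.packed_bounds()
                x0 = np.clip(x0 + rng.normal(0, 0.2, x0.size), lo, hi)
        else:
            x0 = problem.sample_start(rng)
        results.append(fit(problem, x0, start_id=i, **fit_kwargs))
    if not any(r.converged for r in results):
        raise RuntimeError(
            "no multistart run converged; best terminal RMSE "
            f"{min(r.rmse for r in results):.4g}"
        )
    return SolutionSet(problem, results)


def _randomize_subset(problem: FitProblem, x: np.ndarray,
                      names: tuple[str, ...],
                      rng: np.random.Generator) -> np.ndarray:
    lo, hi = problem.packed_bounds()
    x = x.copy()
    idx = [problem.free_names.index(n) for n in names if n in problem.free_names]
    x[idx] = rng.uniform(lo[idx], hi[idx])
    return x


def progressive_fit(dataset: pd.DataFrame,
                    base_params: ParameterSet | None = None,
                    n_starts: int = 20, seed: int = 0,
                    profiles: dict | None = None,
                    sim_rtol: float = 1e-6, sim_atol: float = 1e-8,
                    **fit_kwargs) -> dict:
    """The three-stage progressive estimation over the four cell lines.

    ``dataset`` must contain all four fixture lines.  Returns a dict with
    the per-stage solution sets; ``"final"`` is the stage-3 SolutionSet
    over all 47 parameters.
    """
    if base_params is None:
        base_params = default_parameters()
    if profiles is None:
        profiles = dict(FIXTURE_PROFILES)
    lines = set(dataset["cell_line"].unique())
    needed = {"HER2-3-", "HER2+3-", "HER2-3+", "HER2+3+"}
    if not needed <= lines:
        raise ValueError(f"progressive fit needs all four lines; missing "
                         f"{sorted(needed - lines)}")
    ss = np.random.SeedSequence(seed).spawn(4)

    def subset(*which):
        return dataset[dataset["cell_line"].isin(which)].reset_index(drop=True)

    # stage 1: HER1 parameters on the parental line
    her1_names = stage_free_names("her1")
    prob1 = FitProblem(subset("HER2-3-"), free_names=her1_names,
                       base_params=base_params, profiles=profiles,
                       sim_rtol=sim_rtol, sim_atol=sim_atol)
    sols1 = multistart_fit(prob1, n_starts=n_starts,
                           seed=int(ss[0].generate_state(1)[0] % 2**31),
                           **fit_kwargs)
    best1 = sols1.best.values

    # stage 2: interaction blocks seeded from stage 1
    def stage2(stage: str, *lines_used) -> SolutionSet:
        names = her1_names + stage_free_names(stage)
        prob = FitProblem(subset(*lines_used), free_names=names,
                          base_params=base_params, profiles=profiles,
                          sim_rtol=sim_rtol, sim_atol=sim_atol)
        rng = np.random.default_rng(ss[1 if stage == "her1-her2" else 2])
        x_best1 = prob.pack({n: best1.get(n, 1.0) for n in names})
        seeded = np.array([n in best1 for n in names])
        starts = []
        for _ in range(max(2, n_starts // 4)):
            x0 = prob.sample_start(rng)
            x0[seeded] = x_best1[seeded]
            starts.append(x0)
        return multistart_fit(prob, n_starts=len(starts),
                              seed=int(rng.integers(2**31)), starts=starts,
                              **fit_kwargs)

    sols2a = stage2("her1-her2", "HER2-3-", "HER2+3-")
    sols2b = stage2("her1-her3", "HER2-3-", "HER2-3+")

    # stage 3: all 47 parameters, all lines, randomized HER2-HER3 guesses
    prob3 = FitProblem(dataset, free_names=FREE_NAMES,
                       base_params=base_params, profiles=profiles,
                       sim_rtol=sim_rtol, sim_atol=sim_atol)
    seed_values = dict(zip(FREE_NAMES, base_params.free_values(FREE_NAMES)))
    seed_values.update(best1)
    seed_values.update(sols2a.best.values)
    seed_values.update(sols2b.best.values)
    x_seed = prob3.pack(seed_values)
    rng3 = np.random.default_rng(ss[3])
    starts3 = [
        _randomize_subset(prob3, x_seed, stage_free_names("her2-her3"), rng3)
        for _ in range(n_starts)
    ]
    sols3 = multistart_fit(prob3, n_starts=n_starts,
                           seed=int(rng3.integers(2**31)), starts=starts3,
                           **fit_kwargs)
    return {"stage1": sols1, "stage2_her1her2": sols2a,
            "stage2_her1her3": sols2b, "final": sols3}


def cluster_solutions(solutions: SolutionSet, rmse_margin: float = 1.2,
                      k_range: tuple[int, int] = (2, 10),
                      seed: int = 0, rmse_floor: float = 0.0) -> SolutionSet:
    """Group retained solutions by k-means on standardized log-parameters.

    Solutions with RMSE within ``rmse_margin`` x best are retained; k is
    chosen by silhouette over ``k_range`` (capped below the number of
    distinct retained solutions); identical solutions collapse to one
    cluster.  Each cluster's minimum-RMSE member is its representative.

    ``rmse_floor`` sets an absolute retention level in scaled-RMSE units:
    on noiseless data the best RMSE approaches the integrator noise floor
    and a purely relative margin would retain almost nothing, so any
    solution at least that good is kept regardless of the ratio.
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    problem = solutions.problem
    cutoff = max(rmse_margin * solutions.best.rmse, rmse_floor)
    retained = [r for r in solutions.results
                if r.converged and r.rmse <= cutoff]
    if len(retained) < 2:
        raise ValueError(
            "need at least 2 retained solutions to cluster; got "
            f"{len(retained)}"
        )
    X = np.array([r.x for r in retained])
    std = X.std(axis=0)
    distinct = np.unique(np.round(X, 8), axis=0).shape[0]
    if distinct == 1 or np.all(std < 1e-10):
        labels = np.zeros(len(retained), dtype=int)
        best_k = 1
    else:
        Z = (X - X.mean(axis=0)) / np.where(std > 1e-12, std, 1.0)
        best_k, best_score, best_labels = 1, -np.inf, None
        for k in range(max(2, k_range[0]), min(k_range[1], distinct - 1) + 1):
            km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(Z)
            if len(np.unique(km.labels_)) < 2:
                continue
            score = silhouette_score(Z, km.labels_)
            if score > best_score:
                best_k, best_score, best_labels = k, score, km.labels_
        labels = (best_labels if best_labels is not None
                  else np.zeros(len(retained), dtype=int))
        best_k = len(np.unique(labels))
    reps = []
    for c in np.unique(labels):
        members = [i for i, l in enumerate(labels) if l == c]
        reps.append(min(members, key=lambda i: retained[i].rmse))
    return SolutionSet(problem, retained, labels=np.asarray(labels),
                       n_clusters=int(best_k), representatives=reps)
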