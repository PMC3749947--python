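"""Recover HER1-related parameters from noiseless synthetic data.

The estimation stage mirrors the staged strategy: HER1 dimerization
(ku11e/ku11ee), phosphorylation factors (pf11e/pf11ee, per compartment)
and the sorting parameter delta1 are fitted on the parental (HER2-3-)
line alone.  Starts are drawn from the prior ranges (ku in [1e-3, 1e3],
pf in [1e-6, 1], delta1 in [0.1, 10]).  With noiseless data the best run
should land on the ground truth.
"""

from herdyn import FitProblem, multistart_fit
from herdyn.estimate import stage_free_names
from herdyn.parameters import default_parameters
from herdyn.synthetic import Condition, MeasurementDesign, NoiseModel, generate

truth = default_parameters()
conditions = [
    Condition("HER2-3-", dose, 0.0, 0.0, (0.0, 10.0, 30.0, 60.0), ("pR1t",))
    for dose in (0.6, 3.0, 12.0, 30.0)
]
conditions.append(Condition(
    "HER2-3-", 12.0, 0.0, 0.0,
    (0.0, 5.0, 10.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0),
    ("pR1t", "pR1i", "mR1t"),
))
design = MeasurementDesign(tuple(conditions), name="her1-recovery")
data = generate(design, truth, NoiseModel(cv=0.0), seed=1)

problem = FitProblem(data, free_names=stage_free_names("her1"),
                     base_params=truth, sim_rtol=1e-5, sim_atol=1e-7)
solutions = multistart_fit(problem, n_starts=4, seed=7, max_nfev=80)

best = solutions.best
print(f"best of {len(solutions.results)} starts: scaled RMSE = {best.rmse:.2e}")
print(f"{'parameter':<12}{'truth':>10}{'fitted':>12}")
for name in problem.free_names:
    print(f"{name:<12}{truth.get_value(name):>10.4g}{best.values[name]:>12.4g}")
print("\nA scaled RMSE near zero with parameters at their true values "
      "demonstrates practical\nidentifiability of the HER1 block from "
      "dose-response + time-course data alone.")
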