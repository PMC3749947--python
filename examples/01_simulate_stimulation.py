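"""Simulate ligand stimulation of a HER2+3+ cell and print the observables.

Equilibrates the receptor trafficking network for a cell expressing
200,000 HER1, 600,000 HER2 and 40,000 HER3 molecules, then adds
12 ng/ml EGF + 40 ng/ml HRG for two hours.  The printed table holds the
ELISA-equivalent readouts: pRit = total phospho-receptor (arbitrary
units, pf x dimer abundance summed over surface + early endosome),
pRii = the endosomal part alone, mRit = total receptor copies including
the degrading late-endosome pool.
"""

import pandas as pd

from herdyn import StimulationProtocol, compute_observables, run_protocol

protocol = StimulationProtocol(
    egf_ng_ml=12.0, hrg_ng_ml=40.0, duration_min=120.0,
    sample_times=(0, 5, 10, 20, 30, 45, 60, 90, 120),
)
trajectory = run_protocol("HER2+3+", protocol)
observables = compute_observables(trajectory)

table = observables.pivot(index="time_min", columns="measurement",
                          values="value")
pd.set_option("display.width", 140)
print(table.round(1))
print(
    "\nPhosphorylation peaks within ~10-20 min and then relaxes as "
    "receptors internalize and degrade;\nreceptor mass (mRt) declines "
    "slowly because ligand-induced dimers are sorted to degradation."
)
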