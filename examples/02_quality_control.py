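"""Single-unit quality control with a planted unstable unit.

Five criteria must all pass: curation label, waveform stability between the
first and last 20% of spikes, refractory-violation fraction, an
exponential-like ISI distribution, and multivariate separation from
neighbouring clusters.  One unit is planted with a 30% amplitude drift and
should be the only rejection.
"""

from dataclasses import replace

import synchropipe as sp

config = replace(sp.state_preset("PD", seed=5), n_drift_units=1, drift_fraction=0.3)
session, truth = sp.emit_session(config)

report, accepted = sp.run_qc(session)
print(f"{len(accepted.trains)}/{len(session.trains)} units accepted")
rejected = report.table.loc[~report.table["accepted"], ["unit_id", "reason"]]
print("rejected units:")
print(rejected.to_string(index=False))
planted = [u["unit_id"] for u in truth["units"] if u["drift"]]
print(f"planted drift unit: {planted}  (reason should be 'stability')")
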