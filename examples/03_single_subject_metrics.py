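"""Single-trial quality metrics for one synthetic subject.

After correction, trials are epoched [-5, 25) s and scored against the
canonical HRF: scaled RMSE (lower is better), Fisher-z Spearman correlation
and contrast-to-noise ratio (higher is better).  The scored channel is the
strongest activation inside the task's a-priori region of interest,
selected from the GLM_ALL task GLM.
"""

import numpy as np

from nirsac import (
    HRFSpec,
    METHODS,
    SAParams,
    apply_correction,
    epoch_and_baseline,
    make_probe_layout,
    make_trial_schedule,
    preprocess_recording,
    select_best_channel,
    simulate_rest_recording,
    task_glm,
    trial_metrics,
)

layout = make_probe_layout()
schedule = make_trial_schedule("SIM", n_trials=5, seed=3)
raw = simulate_rest_recording(layout, schedule.end_time + 15, SAParams(), age=63.0, seed=3)
hemo, _ = preprocess_recording(
    raw, prune=True, schedule=schedule, hrf_spec=HRFSpec({6: 10.0, 8: 5.0})
)

corrected = {m: apply_correction(hemo, m).corrected for m in METHODS}
glm = task_glm(corrected["GLM_ALL"], schedule, mode="hrf")
channel = select_best_channel(glm, "SIM", "hbo")
print(f"selected channel (SIM, HbO): {channel}")

print(f"{'method':8s} {'sRMSE':>7s} {'COR':>7s} {'CNR':>7s}")
for method in METHODS:
    epochs = epoch_and_baseline(corrected[method], schedule)
    m = trial_metrics(epochs, channel, "hbo")
    print(f"{method:8s} {np.nanmean(m['srmse']):7.3f} "
          f"{np.nanmean(m['cor']):7.3f} {np.nanmean(m['cnr']):7.2f}")
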