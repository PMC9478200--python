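"""Linear PLS versus the PLS-score-fed BP neural net.

With a mildly saturating spectral response (gamma = 0.5) the relation
between the dominant score and the assayed total content is curved:
the linear model carries that curvature as bias, the two-hidden-node
network does not.
"""

import numpy as np

from nirquant import (TrainConfig, calibrate, default_config, fit_ann,
                      predict, r2_percent, reference_table, rmse, rpd,
                      simulate_dataset, split_dataset)

for gamma in (0.0, 0.5):
    spectra, refs, _ = simulate_dataset(default_config(seed=2, gamma=gamma))
    ids = list(spectra.sample_ids)
    cal_ids, _ = split_dataset(ids[:90], (2, 1), seed=3)
    cal, test = spectra.subset(cal_ids), spectra.subset(ids[90:])
    y_cal = reference_table(refs, cal.sample_ids)
    y_test = reference_table(refs, test.sample_ids)
    sd_cal = float(np.std(y_cal, ddof=1))

    pls_model = calibrate(cal, y_cal, (4000.0, 9000.0), "msc", rank=14)
    pls_rmsep = rmse(y_test, pls_model.predict(test))
    ann = fit_ann(pls_model.scores(cal), y_cal, hidden_size=2,
                  config=TrainConfig(seed=2, restarts=3))
    ann_pred = predict(ann, pls_model.scores(test))
    ann_rmsep = rmse(y_test, ann_pred)

    print(f"gamma={gamma}: PLS test RMSEP {pls_rmsep:.3f} "
          f"(RPD {rpd(sd_cal, pls_rmsep):.2f})  |  "
          f"PLS-BP-ANN RMSEP {ann_rmsep:.3f} "
          f"(RPD {rpd(sd_cal, ann_rmsep):.2f}, "
          f"R2 {r2_percent(y_test, ann_pred):.1f}%)")
# gamma=0: the truth is linear, the net has nothing to add.
# gamma=0.5: the hybrid usually recovers part of the curvature bias.
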