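"""Generate a synthetic NIR dataset and look at its reference statistics.

Draws 122 samples (the default study conditions), writes the two CSVs a
real acquisition would produce, and prints the content statistics of the
2:1 calibration/validation split of the 90 modeling samples.
"""

import numpy as np

from nirquant import (default_config, reference_table, simulate_dataset,
                      split_dataset, write_reference_values, write_spectra)

spectra, refs, truth = simulate_dataset(default_config(seed=1))
write_spectra(spectra, "scratch_spectra.csv")
write_reference_values(refs, "scratch_references.csv")

modeling = list(spectra.sample_ids)[:90]
cal_ids, val_ids = split_dataset(modeling, (2, 1), seed=2)
print(f"grid: {spectra.grid.n_points} points, "
      f"{spectra.grid.values[0]:.0f} -> {spectra.grid.values[-1]:.0f} cm^-1")
for name, ids in (("calibration", cal_ids), ("validation", val_ids)):
    y = reference_table(refs, ids, "total")
    print(f"{name:>11}: n={len(ids)}  total content "
          f"{y.min():.1f}-{y.max():.1f}, mean {y.mean():.1f}, "
          f"SD {y.std(ddof=1):.1f} mg/g")
totals = reference_table(refs, modeling, "total")
print(f"unqualified (< 5 mg/g): {100 * np.mean(totals < 5):.1f}% "
      "of modeling samples")
# The mean/SD mirror the concentration distributions the generator is
# parameterized with; the unqualified fraction is the tail below the
# pharmacopoeial quality threshold.
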