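"""Relative-improvement arithmetic over the published CASF-2016 table.

The table rows are the published RMSE/MAE/SD/CI/R of this model (v1/v2)
and four competing predictors on the CASF-2016 core set; the reporting
module recomputes the percentage improvements from those values.
"""

import json

from seqdta.benchmarks import (CASF2016, gap_to_second_best, improvement_table,
                               variant_performance_loss)

imp = improvement_table(CASF2016, "this-model-v1")
print("improvement of v1 over each competitor (%):")
print(json.dumps({m: {k: round(v, 2) for k, v in row.items()}
                  for m, row in imp.items()}, indent=2))

loss = variant_performance_loss(CASF2016, "this-model-v1", "this-model-v2")
print("performance loss of the pocket-free v2 variant (%):",
      {k: round(v, 2) for k, v in loss.items()})

gap = gap_to_second_best(CASF2016, "this-model-v1", "ci",
                         exclude=("this-model-v2",))
print(f"CI margin over the best competitor: {gap:.3f}")
# e.g. v1 improves RMSE over GraphscoreDTA by 9.27% and leads the best
# competing method by 0.010 CI.
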