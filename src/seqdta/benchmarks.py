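"""Published benchmark tables and the arithmetic derived from them.

The tables below are the published evaluation results of this model
(v1 = protein + pocket + ligand; v2 = protein + ligand) and of four
competing affinity predictors on the CASF-2016 and CASF-2013 core sets,
plus the model's own 10-fold cross-validation numbers on PDBbind v2020.
They are inputs to the reporting functions; reproducing them requires the
full external benchmark data and is out of scope here.

Loss-type measures (RMSE, MAE, SD) improve downward; CI and R improve
upward.  Relative improvement of ``ours`` over ``other`` is

    loss metric:  (other - ours) / other * 100
    gain metric:  (ours - other) / other * 100
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BenchmarkRow:
    rmse: float
    mae: float
    sd: float
    ci: float
    r: float


# Lower-is-better flags per metric
LOSS_METRICS = {"rmse": True, "mae": True, "sd": True, "ci": False, "r": False}

# 10-fold cross-validation and core-set results for this model
KFOLD_PDBBIND2020 = BenchmarkRow(rmse=0.877, mae=0.661, sd=0.843, ci=0.857, r=0.890)

CASF2016 = {
    "this-model-v1": BenchmarkRow(rmse=1.224, mae=1.003, sd=1.166, ci=0.820, r=0.845),
    "this-model-v2": BenchmarkRow(rmse=1.266, mae=1.014, sd=1.222, ci=0.812, r=0.827),
    "GraphscoreDTA": BenchmarkRow(rmse=1.349, mae=1.053, sd=1.281, ci=0.810, r=0.810),
    "DeepDTAF":      BenchmarkRow(rmse=1.356, mae=1.075, sd=1.337, ci=0.798, r=0.789),
    "DLSSAffinity":  BenchmarkRow(rmse=1.401, mae=1.134, sd=1.336, ci=0.794, r=0.789),
    "Pafnucy":       BenchmarkRow(rmse=1.423, mae=1.135, sd=1.378, ci=0.787, r=0.774),
}

CASF2013 = {
    "this-model-v2": BenchmarkRow(rmse=1.359, mae=1.102, sd=1.292, ci=0.810, r=0.819),
    "GraphscoreDTA": BenchmarkRow(rmse=1.542, mae=1.236, sd=1.479, ci=0.780, r=0.758),
    "DeepDTAF":      BenchmarkRow(rmse=1.791, mae=1.514, sd=1.780, ci=0.732, r=0.758),
    "DLSSAffinity":  BenchmarkRow(rmse=1.596, mae=1.304, sd=1.584, ci=0.746, r=0.732),
    "Pafnucy":       BenchmarkRow(rmse=1.623, mae=1.318, sd=1.613, ci=0.753, r=0.697),
}


def relative_improvement(ours: float, other: float, metric: str) -> float:
    """Percentage improvement of ``ours`` over ``other`` for ``metric``."""
    if metric not in LOSS_METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if LOSS_METRICS[metric]:
        return (other - ours) / other * 100.0
    return (ours - other) / other * 100.0


def improvement_table(table: dict[str, BenchmarkRow], ours: str) -> dict:
    """Relative improvements (%) of ``ours`` over every other method."""
    base = table[ours]
    out: dict[str, dict[str, float]] = {}
    for name, row in table.items():
        if name == ours:
            continue
        out[name] = {m: relative_improvement(getattr(base, m), getattr(row, m), m)
                     for m in LOSS_METRICS}
    return out


def variant_performance_loss(table: dict[str, BenchmarkRow],
                             full: str, reduced: str) -> dict[str, float]:
    """Percentage performance loss of ``reduced`` relative to ``full``
    (positive = the reduced variant is worse)."""
    f, r = table[full], table[reduced]
    out = {}
    for m, lower_better in LOSS_METRICS.items():
        fv, rv = getattr(f, m), getattr(r, m)
        out[m] = ((rv - fv) / fv if lower_better else (fv - rv) / fv) * 100.0
    return out


def gap_to_second_best(table: dict[str, BenchmarkRow], ours: str,
                       metric: str, exclude: tuple[str, ...] = ()) -> float:
    """Absolute margin between ``ours`` and the best competitor on ``metric``.

    ``exclude`` drops additional rows (e.g. one's own second variant) from
    the competitor pool.
    """
    base = getattr(table[ours], metric)
    others = [getattr(row, metric) for name, row in table.items()
              if name != ours and name not in exclude]
    if LOSS_METRICS[metric]:
        return min(others) - base
    return base - max(others)
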