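"""Model evaluation: R^2, RMSE and RPD for named sample sets.

Conventions: RMSE = sqrt(mean squared error) in % SSC; the headline R^2 is
1 - SS_res/SS_tot (squared Pearson correlation is also reported); RPD is
the evaluated set's own reference standard deviation (n-1 denominator)
divided by RMSE, so RPD * RMSE equals that SD exactly.  An RPD above ~2
conventionally marks a usable quantitative NIR model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class EvaluationReport:
    name: str
    n: int
    r2: float
    rmse: float
    rpd: float
    r2_pearson: float

    def to_dict(self) -> dict:
        return {
            "set": self.name,
            "n": self.n,
            "r2": self.r2,
            "rmse": self.rmse,
            "rpd": self.rpd,
            "r2_pearson": self.r2_pearson,
        }


def evaluate(y_true, y_pred, name: str = "prediction") -> EvaluationReport:
    """Score predictions against reference values.

    Requires at least 3 pairs and non-constant references.  A perfect fit
    reports RPD as +inf.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D and equally long")
    n = y_true.size
    if n < 3:
        raise ValueError("at least 3 samples are required")
    sd = float(np.std(y_true, ddof=1))
    if sd == 0:
        raise ValueError("reference values have zero variance; RPD undefined")
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    if np.std(y_pred) == 0:
        r2_pearson = 0.0
    else:
        r2_pearson = float(np.corrcoef(y_true, y_pred)[0, 1] ** 2)
    rpd = math.inf if rmse == 0 else sd / rmse
    return EvaluationReport(name=name, n=n, r2=r2, rmse=rmse, rpd=rpd,
                            r2_pearson=r2_pearson)


def report_table(reports) -> str:
    """Aligned text table for a list of reports."""
    header = f"{'set':<28}{'n':>5}{'R2':>8}{'RMSE%':>8}{'RPD':>7}"
    lines = [header, "-" * len(header)]
    for r in reports:
        lines.append(
            f"{r.name:<28}{r.n:>5}{r.r2:>8.3f}{r.rmse:>8.3f}{r.rpd:>7.2f}"
        )
    return "\n".join(lines)


__all__ = ["EvaluationReport", "evaluate", "report_table"]
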