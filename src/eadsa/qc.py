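"""Method-performance metrics: precision, accuracy, recovery, LLOQ.

All metrics are expressed in percent except the LLOQ, which is reported on
the concentration scale of the dilution series it is derived from.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


class QCError(ValueError):
    pass


@dataclass
class QCRecord:
    analyte_id: str
    metric: str      # cv_pct | accuracy_pct | extraction_eff_pct | lloq_ng_per_ml | r_squared | agreement_pct
    value: Optional[float]
    n: int
    context: str = ""


def cv_percent(values: Sequence[float]) -> float:
    """Coefficient of variation, percent, with the sample (n−1) SD."""
    v = np.asarray(values, float)
    if len(v) < 2:
        raise QCError("need at least 2 replicates for a CV")
    mean = v.mean()
    if mean == 0:
        raise QCError("CV undefined for zero mean")
    return 100.0 * v.std(ddof=1) / mean


def accuracy_percent(measured: float, predicted: float) -> float:
    """Agreement between a measured concentration and the model-predicted
    one: 100 × (1 − |measured − predicted| / predicted)."""
    if predicted <= 0:
        raise QCError("predicted concentration must be positive")
    return 100.0 * (1.0 - abs(measured - predicted) / predicted)


def apparent_extraction_efficiency(recovered_ng: float, added_ng: float) -> float:
    """Recovery of an added unlabelled spike, percent."""
    if added_ng <= 0:
        raise QCError("added amount must be positive")
    return 100.0 * recovered_ng / added_ng


def batch_agreement(conc_1: float, conc_2: float) -> float:
    """Agreement of two concentration estimates as 100 × min/max."""
    if conc_1 <= 0 or conc_2 <= 0:
        raise QCError("concentrations must be positive")
    return 100.0 * min(conc_1, conc_2) / max(conc_1, conc_2)


def lloq_by_dilution(
    series: Sequence[Tuple[float, float]], max_deviation_pct: float = 30.0
) -> Optional[float]:
    """Lower limit of quantification from a technical dilution ladder.

    ``series`` holds (expected_conc, measured_conc) pairs ordered by
    decreasing expected concentration.  The LLOQ is the smallest expected
    concentration whose relative deviation is below ``max_deviation_pct``
    *and* for which every higher concentration also passes; ``None`` when
    even the highest level fails.
    """
    if len(series) == 0:
        raise QCError("empty dilution series")
    expected = [e for e, _ in series]
    if any(b >= a for a, b in zip(expected, expected[1:])):
        raise QCError("series must be ordered by decreasing expected conc")
    lloq: Optional[float] = None
    for exp, meas in series:
        if exp <= 0:
            raise QCError("expected concentration must be positive")
        dev = 100.0 * abs(meas - exp) / exp
        if dev < max_deviation_pct:
            lloq = exp
        else:
            break
    return lloq


def qc_table(records: Sequence[QCRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {"analyte": r.analyte_id, "metric": r.metric, "value": r.value,
         "n": r.n, "context": r.context}
        for r in records
    ])


def replicate_qc(
    reports: Sequence[pd.DataFrame], min_replicates: int = 2
) -> pd.DataFrame:
    """Per-analyte %CV across replicate quantification reports."""
    if len(reports) < min_replicates:
        raise QCError("need at least 2 replicate reports")
    stacked = pd.concat(
        [r.set_index("analyte")["conc_ng_per_ml"] for r in reports], axis=1
    )
    records = []
    for analyte, row in stacked.iterrows():
        vals = row.dropna().to_numpy(float)
        if len(vals) < 2 or vals.mean() == 0:
            continue
        records.append(QCRecord(analyte, "cv_pct", cv_percent(vals), len(vals)))
    return qc_table(records)
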