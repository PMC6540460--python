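"""Accuracy grading of BP estimates against auscultatory references.

Two device-validation protocols are implemented:

* AAMI SP10 — pass requires mean error |ME| ≤ 5 mmHg and standard
  deviation of error SDE ≤ 8 mmHg;
* BHS letter grades from the fractions of absolute errors within
  5 / 10 / 15 mmHg: A ≥ (60, 85, 95)%, B ≥ (50, 75, 90)%,
  C ≥ (40, 65, 85)%, else D; a grade requires all three thresholds of
  its row.

The error sign convention is estimate − reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .climits import ConfidenceLimits
from .errors import ValidationError

__all__ = [
    "ErrorSummary",
    "error_summary",
    "aami_pass",
    "bhs_grade",
    "comparison_report",
]

logger = logging.getLogger(__name__)

_BHS_THRESHOLDS = (("A", (60.0, 85.0, 95.0)), ("B", (50.0, 75.0, 90.0)), ("C", (40.0, 65.0, 85.0)))


@dataclass(frozen=True)
class ErrorSummary:
    """ME / SDE / MAE and the BHS band fractions of one estimate stream."""

    me: float
    sde: float
    mae: float
    pct_within_5: float
    pct_within_10: float
    pct_within_15: float
    n: int


def error_summary(
    estimates: Sequence[float], references: Sequence[float]
) -> ErrorSummary:
    """Error statistics of estimates against references (estimate − reference)."""
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape:
        raise ValidationError(f"length mismatch: {est.shape} vs {ref.shape}")
    if est.ndim != 1 or len(est) < 2:
        raise ValidationError("need at least 2 paired values")
    e = est - ref
    abs_e = np.abs(e)
    return ErrorSummary(
        me=float(e.mean()),
        sde=float(e.std(ddof=1)),
        mae=float(abs_e.mean()),
        pct_within_5=float((abs_e <= 5).mean()),
        pct_within_10=float((abs_e <= 10).mean()),
        pct_within_15=float((abs_e <= 15).mean()),
        n=len(e),
    )


def aami_pass(summary: ErrorSummary) -> bool:
    """AAMI SP10 pass: |ME| ≤ 5 mmHg and SDE ≤ 8 mmHg."""
    return abs(summary.me) <= 5.0 and summary.sde <= 8.0


def bhs_grade(pct5: float, pct10: float, pct15: float) -> str:
    """BHS letter grade from band percentages (0–100 scale)."""
    bands = (float(pct5), float(pct10), float(pct15))
    for p in bands:
        if not 0 <= p <= 100:
            raise ValidationError(f"band percentage out of [0, 100]: {p}")
    if not bands[0] <= bands[1] <= bands[2]:
        raise ValidationError(f"band percentages must be non-decreasing: {bands}")
    for grade, thresholds in _BHS_THRESHOLDS:
        if all(p >= t for p, t in zip(bands, thresholds)):
            return grade
    return "D"


def summary_grade(summary: ErrorSummary) -> str:
    return bhs_grade(
        100 * summary.pct_within_5,
        100 * summary.pct_within_10,
        100 * summary.pct_within_15,
    )


def comparison_report(
    method_results: Mapping[str, Mapping[str, object]],
) -> dict[str, pd.DataFrame]:
    """Side-by-side method comparison tables.

    ``method_results`` maps a method name to a dict with keys ``"sbp"``
    and ``"dbp"`` (each an :class:`ErrorSummary`) and optionally
    ``"cls"`` (a list of :class:`ConfidenceLimits`).  Returns three
    frames: ``me_sde``, ``bhs`` (band percentages + grades) and, when any
    method supplies confidence limits, ``cl`` (across-subject mean ± sd
    of the limits and the mean interval width).
    """
    if not method_results:
        raise ValidationError("no method results supplied")
    me_rows, bhs_rows, cl_rows = [], [], []
    for name, res in method_results.items():
        sbp: ErrorSummary = res["sbp"]  # type: ignore[assignment]
        dbp: ErrorSummary = res["dbp"]  # type: ignore[assignment]
        me_rows.append(
            {
                "method": name,
                "sbp_me": sbp.me, "sbp_sde": sbp.sde,
                "dbp_me": dbp.me, "dbp_sde": dbp.sde,
                "sbp_aami_pass": aami_pass(sbp), "dbp_aami_pass": aami_pass(dbp),
            }
        )
        bhs_rows.append(
            {
                "method": name,
                "sbp_pct5": 100 * sbp.pct_within_5,
                "sbp_pct10": 100 * sbp.pct_within_10,
                "sbp_pct15": 100 * sbp.pct_within_15,
                "dbp_pct5": 100 * dbp.pct_within_5,
                "dbp_pct10": 100 * dbp.pct_within_10,
                "dbp_pct15": 100 * dbp.pct_within_15,
                "grade": f"{summary_grade(sbp)}/{summary_grade(dbp)}",
            }
        )
        cls_list: Sequence[ConfidenceLimits] | None = res.get("cls")  # type: ignore[assignment]
        if cls_list:
            s_lo = np.array([c.sbp_lower for c in cls_list])
            s_hi = np.array([c.sbp_upper for c in cls_list])
            d_lo = np.array([c.dbp_lower for c in cls_list])
            d_hi = np.array([c.dbp_upper for c in cls_list])
            ddof = 1 if len(cls_list) > 1 else 0
            cl_rows.append(
                {
                    "method": name,
                    "sbp_mean_width": float((s_hi - s_lo).mean()),
                    "sbp_width_sd": float((s_hi - s_lo).std(ddof=ddof)),
                    "dbp_mean_width": float((d_hi - d_lo).mean()),
                    "dbp_width_sd": float((d_hi - d_lo).std(ddof=ddof)),
                    "sbp_lower_mean": float(s_lo.mean()),
                    "sbp_lower_sd": float(s_lo.std(ddof=ddof)),
                    "sbp_upper_mean": float(s_hi.mean()),
                    "sbp_upper_sd": float(s_hi.std(ddof=ddof)),
                    "dbp_lower_mean": float(d_lo.mean()),
                    "dbp_lower_sd": float(d_lo.std(ddof=ddof)),
                    "dbp_upper_mean": float(d_hi.mean()),
                    "dbp_upper_sd": float(d_hi.std(ddof=ddof)),
                    "n_subjects": len(cls_list),
                }
            )
    report = {"me_sde": pd.DataFrame(me_rows), "bhs": pd.DataFrame(bhs_rows)}
    if cl_rows:
        report["cl"] = pd.DataFrame(cl_rows)
    else:
        logger.warning("no confidence limits supplied; CL table omitted")
    return report
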