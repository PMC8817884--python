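"""Regression evaluation stratified by anesthesia phase.

R2 = 1 - SSE/SST, RMSE = sqrt(mean squared error) and MAPE (mean absolute
percentage error) between reference and predicted depth, plus an
accuracy-within-tolerance rate (fraction of predictions within a depth-unit
band of the reference, default +/-10), reported per anesthesia phase
(induction / maintenance / recovery) and overall.

The RMSE often printed alongside these metrics in the monitoring
literature, sum(e_i - mean(e))/n without square or root, is identically
zero for any residuals; the standard definition is implemented instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MetricsReport",
    "r_squared",
    "rmse",
    "mape",
    "accuracy_within",
    "phase_report",
]

PHASE_ORDER = ("induction", "maintenance", "recovery", "whole")
DEFAULT_ACCURACY_TOL = 10.0


def _pair(observed, predicted, min_len: int = 1):
    o = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if o.size != p.size:
        raise ValueError(f"length mismatch: {o.size} vs {p.size}")
    if o.size < min_len:
        raise ValueError(f"need at least {min_len} paired values, got {o.size}")
    return o, p


def r_squared(observed, predicted) -> float:
    """Goodness of fit 1 - SSE/SST; NaN when the observations are constant."""
    o, p = _pair(observed, predicted, min_len=2)
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0:
        return float("nan")
    sse = float(np.sum((o - p) ** 2))
    return 1.0 - sse / sst


def rmse(observed, predicted) -> float:
    """Root mean squared error, in depth-index units."""
    o, p = _pair(observed, predicted)
    return float(np.sqrt(np.mean((o - p) ** 2)))


def mape(observed, predicted) -> float:
    """Mean absolute percentage error (%); undefined for zero observations."""
    o, p = _pair(observed, predicted)
    zeros = np.nonzero(o == 0)[0]
    if zeros.size:
        raise ValueError(
            f"MAPE undefined: observed is zero at indices {zeros[:10].tolist()}"
        )
    return float(np.mean(np.abs(o - p) / np.abs(o)) * 100.0)


def accuracy_within(observed, predicted, tol: float = DEFAULT_ACCURACY_TOL) -> float:
    """Fraction (%) of predictions within +/- ``tol`` depth units of target."""
    o, p = _pair(observed, predicted)
    return float(np.mean(np.abs(o - p) <= tol) * 100.0)


@dataclass
class MetricsReport:
    """Per-phase and overall metric rows in fixed phase order."""

    table: pd.DataFrame  # rows: phase, r2_pct, rmse, mape_pct, accuracy_pct, n

    def row(self, phase: str) -> pd.Series:
        hit = self.table[self.table["phase"] == phase]
        if hit.empty:
            raise KeyError(f"no row for phase {phase!r}")
        return hit.iloc[0]

    def write(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.4f")

    def __str__(self) -> str:
        lines = [f"{'Period of anesthesia':<22}{'R2(%)':>9}{'RMSE':>9}"
                 f"{'MAPE(%)':>9}{'Acc(%)':>9}{'n':>7}"]
        for _, r in self.table.iterrows():
            lines.append(
                f"{r['phase']:<22}{r['r2_pct']:>9.2f}{r['rmse']:>9.2f}"
                f"{r['mape_pct']:>9.2f}{r['accuracy_pct']:>9.2f}{int(r['n']):>7}"
            )
        return "\n".join(lines)


def phase_report(
    observed, predicted, phases, tol: float = DEFAULT_ACCURACY_TOL
) -> MetricsReport:
    """Metrics per anesthesia phase plus an overall ("whole") row."""
    o, p = _pair(observed, predicted)
    ph = np.asarray(phases, dtype=object)
    if ph.size != o.size:
        raise ValueError("phases must align with observed/predicted")
    known = set(PHASE_ORDER[:3])
    unknown = set(ph) - known
    if unknown:
        raise ValueError(f"unknown phase labels: {sorted(unknown)}")
    rows = []
    for phase in PHASE_ORDER:
        mask = np.ones(o.size, dtype=bool) if phase == "whole" else ph == phase
        n = int(mask.sum())
        if n == 0:
            continue
        oo, pp = o[mask], p[mask]
        rows.append(
            {
                "phase": phase,
                "r2_pct": r_squared(oo, pp) * 100.0 if n >= 2 else float("nan"),
                "rmse": rmse(oo, pp),
                "mape_pct": mape(oo, pp),
                "accuracy_pct": accuracy_within(oo, pp, tol),
                "n": n,
            }
        )
    return MetricsReport(pd.DataFrame(rows))
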