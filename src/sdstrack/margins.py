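"""PTV-margin comparison with and without surface depth-sensing data.

Each of several observers (radiation oncologists) sets per-axis PTV
margins for each patient twice: first blinded to the tracking data, then
with it.  The analysis pairs the two determinations per (patient,
observer), and reports per-axis means +/- sample SD under both conditions,
the mean paired difference, the percent change relative to the
without-tracking mean, and a two-sided paired t-test on the differences.

statsmodels-style surface: build a :class:`PairedMarginModel` from records
or a tidy DataFrame, ``fit()`` -> :class:`MarginComparisonResults` with a
``summary()`` table.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MarginRecord", "AxisComparison", "MarginComparisonResults",
           "PairedMarginModel", "compare_margins", "paired_t",
           "render_report", "parse_report", "load_margin_table"]

logger = logging.getLogger(__name__)

AXES = ("lr", "cc", "ap")
CONDITIONS = ("without_sds", "with_sds")


@dataclass(frozen=True)
class MarginRecord:
    """One observer's PTV margins (mm) for one patient under one condition."""

    patient_id: str
    observer_id: str
    condition: str
    lr: float
    cc: float
    ap: float

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, "
                             f"got {self.condition!r}")
        if min(self.lr, self.cc, self.ap) < 0:
            raise ValueError("margins must be >= 0 mm")


def paired_t(diffs) -> tuple[float, float]:
    """Two-sided paired t-test on a list of per-pair differences.

    t = mean(d) / (sd(d) / sqrt(n)) with sample SD; p from the
    t-distribution with n-1 degrees of freedom.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 paired differences")
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate differences: zero variance")
    t = float(np.mean(d) / (sd / math.sqrt(d.size)))
    p = float(2.0 * stats.t.sf(abs(t), df=d.size - 1))
    return t, p


@dataclass(frozen=True)
class AxisComparison:
    """Comparison of one anatomical axis across the paired determinations."""

    mean_without: float
    sd_without: float
    mean_with: float
    sd_with: float
    mean_difference: float
    sd_difference: float
    percent_change: int
    t_statistic: float | None
    p_value: float | None


class PairedMarginModel:
    """Paired comparison of PTV margins with vs without tracking data."""

    def __init__(self, records: list[MarginRecord]) -> None:
        self.records = list(records)
        self.pairs, self.excluded = self._pair(self.records)
        if len(self.pairs) < 2:
            raise ValueError("need at least 2 complete (patient, observer) pairs")

    @staticmethod
    def _pair(records: list[MarginRecord]):
        by_key: dict[tuple[str, str], dict[str, MarginRecord]] = {}
        for rec in records:
            by_key.setdefault((rec.patient_id, rec.observer_id), {})[rec.condition] = rec
        pairs, excluded = [], []
        for key, conds in sorted(by_key.items()):
            if set(conds) == set(CONDITIONS):
                pairs.append((conds["without_sds"], conds["with_sds"]))
            else:
                excluded.append(key)
                logger.warning("(patient=%s, observer=%s) present under only "
                               "one condition; excluded from paired analysis",
                               *key)
        return pairs, excluded

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PairedMarginModel":
        """Build from a tidy table with columns
        patient_id, observer_id, condition, lr, cc, ap."""
        required = {"patient_id", "observer_id", "condition", "lr", "cc", "ap"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"margin table missing columns: {sorted(missing)}")
        records = [MarginRecord(str(r.patient_id), str(r.observer_id),
                                str(r.condition), float(r.lr), float(r.cc),
                                float(r.ap))
                   for r in df.itertuples(index=False)]
        return cls(records)

    def fit(self) -> "MarginComparisonResults":
        axes: dict[str, AxisComparison] = {}
        for axis in AXES:
            without = np.array([getattr(w, axis) for w, _ in self.pairs])
            with_ = np.array([getattr(s, axis) for _, s in self.pairs])
            diffs = with_ - without
            try:
                t, p = paired_t(diffs)
            except ValueError:
                t, p = None, None   # zero-variance differences: t undefined
            mean_without = float(without.mean())
            mean_diff = float(diffs.mean())
            pct = (round(100.0 * mean_diff / mean_without)
                   if mean_without != 0 else 0)
            axes[axis] = AxisComparison(
                mean_without=mean_without,
                sd_without=float(np.std(without, ddof=1)),
                mean_with=float(with_.mean()),
                sd_with=float(np.std(with_, ddof=1)),
                mean_difference=mean_diff,
                sd_difference=float(np.std(diffs, ddof=1)),
                percent_change=int(pct),
                t_statistic=t, p_value=p)
        return MarginComparisonResults(axes=axes, n_pairs=len(self.pairs),
                                       excluded=self.excluded)


@dataclass
class MarginComparisonResults:
    """Per-axis paired-comparison estimates; see :func:`render_report`."""

    axes: dict[str, AxisComparison]
    n_pairs: int
    excluded: list

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for axis, c in self.axes.items():
            rows.append({
                "axis": axis.upper(),
                "mean_without_mm": c.mean_without, "sd_without_mm": c.sd_without,
                "mean_with_mm": c.mean_with, "sd_with_mm": c.sd_with,
                "mean_difference_mm": c.mean_difference,
                "sd_difference_mm": c.sd_difference,
                "percent_change": c.percent_change,
                "t_statistic": c.t_statistic, "p_value": c.p_value})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        def fmt_p(p):
            if p is None:
                return "undefined"
            return "<0.001" if p < 0.001 else f"{p:.3f}"

        lines = [
            "Paired PTV-margin comparison (with vs without depth-sensing data)",
            "=" * 66,
            f"paired (patient, observer) determinations: {self.n_pairs}",
        ]
        if self.excluded:
            lines.append(f"unpaired records excluded: {len(self.excluded)}")
        header = f"{'':14s}" + "".join(f"{ax.upper():>16s}" for ax in self.axes)
        lines += [header,
                  "Without (mm)  " + "".join(
                      f"{c.mean_without:8.1f} ± {c.sd_without:<5.1f}"
                      for c in self.axes.values()),
                  "With (mm)     " + "".join(
                      f"{c.mean_with:8.1f} ± {c.sd_with:<5.1f}"
                      for c in self.axes.values()),
                  "Difference    " + "".join(
                      f"{c.mean_difference:8.1f} ± {c.sd_difference:<5.1f}"
                      for c in self.axes.values()),
                  "Change (%)    " + "".join(
                      f"{c.percent_change:>15d}%" for c in self.axes.values()),
                  "p value       " + "".join(
                      f"{fmt_p(c.p_value):>16s}" for c in self.axes.values())]
        return "\n".join(lines)


def compare_margins(records: list[MarginRecord]) -> MarginComparisonResults:
    """Convenience wrapper: pair records and fit the comparison."""
    return PairedMarginModel(records).fit()


def load_margin_table(path: str | Path) -> pd.DataFrame:
    """Read a margin CSV (patient_id, observer_id, condition, lr, cc, ap)."""
    return pd.read_csv(path)


def render_report(results: MarginComparisonResults) -> str:
    """Delimited report mirroring the published margin-comparison layout.

    CSV with one row per quantity; margins at 1 decimal (mm), percent
    change as an integer, p at 3 decimals (blank when undefined).
    """
    if not results.axes:
        raise ValueError("empty comparison")
    buf = io.StringIO()
    axes = list(results.axes)
    buf.write("quantity," + ",".join(ax.upper() for ax in axes) + "\n")

    def row(name, values):
        buf.write(name + "," + ",".join(values) + "\n")

    row("mean_without_mm", [f"{results.axes[a].mean_without:.1f}" for a in axes])
    row("sd_without_mm", [f"{results.axes[a].sd_without:.1f}" for a in axes])
    row("mean_with_mm", [f"{results.axes[a].mean_with:.1f}" for a in axes])
    row("sd_with_mm", [f"{results.axes[a].sd_with:.1f}" for a in axes])
    row("difference_mm", [f"{results.axes[a].mean_difference:.1f}" for a in axes])
    row("sd_difference_mm", [f"{results.axes[a].sd_difference:.1f}" for a in axes])
    row("percent_change", [f"{results.axes[a].percent_change:d}" for a in axes])
    row("p_value", ["" if results.axes[a].p_value is None
                    else f"{results.axes[a].p_value:.3f}" for a in axes])
    return buf.getvalue()


def parse_report(text: str) -> pd.DataFrame:
    """Re-parse a :func:`render_report` CSV into a DataFrame (quantity-indexed)."""
    return pd.read_csv(io.StringIO(text), index_col="quantity")
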