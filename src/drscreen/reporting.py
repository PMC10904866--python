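"""Replicate aggregation and registry-style reports.

Final cumulative adherence rates per subregion are averaged over replicate
runs; dispersion is reported as the sample SD with Student-t confidence
intervals at 95% and 99% (n−1 degrees of freedom).  An optional reference
column of real regional adherence rates is shipped for comparison output
only — the synthetic population is not calibrated to reproduce it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import RunResult

logger = logging.getLogger(__name__)

__all__ = [
    "REAL_ADHERENCE_REFERENCE",
    "AdherenceReport",
    "summarize_replicates",
    "convergence_trace",
    "subgroup_report",
    "report_to_markdown",
]

#: Observed regional adherence rates (%) shipped purely as a comparison
#: reference; synthetic-population runs are not expected to match them.
REAL_ADHERENCE_REFERENCE: Dict[str, float] = {
    "Alto Minho": 74.10,
    "Ave": 72.09,
    "Cávado": 67.02,
    "Douro": 66.86,
    "Entre Douro e Vouga": 66.25,
    "Metropolitan Area of Porto": 63.38,
    "Tâmega e Sousa": 67.59,
    "Trás-os-Montes": 65.69,
}


@dataclass
class AdherenceReport:
    """Per-subregion replicate summary with confidence intervals."""

    table: pd.DataFrame
    metadata: Dict[str, object] = field(default_factory=dict)

    def __str__(self) -> str:  # pragma: no cover - convenience only
        return report_to_markdown(self)


def _t_interval(mean: float, sd: float, n: int, level: float) -> tuple:
    if n < 2 or not np.isfinite(sd):
        return (np.nan, np.nan)
    half = stats.t.ppf(0.5 + level / 2.0, df=n - 1) * sd / np.sqrt(n)
    return (mean - half, mean + half)


def summarize_replicates(
    results: Sequence[RunResult],
    reference: Optional[Mapping[str, float]] = None,
) -> AdherenceReport:
    """Mean, SD and t-based CI95/CI99 of final adherence rates per subregion.

    With fewer than two replicates the CIs are omitted with a warning.  When
    a reference table is given, the difference (mean − reference) and flags
    marking references outside each interval are added.
    """
    if len(results) == 0:
        raise ValueError("need at least one replicate")
    n = len(results)
    if n < 2:
        logger.warning("only %d replicate(s); confidence intervals omitted", n)
    rates = pd.concat([r.adherence_rates() for r in results], axis=1)
    rates.columns = range(n)
    rows = []
    for sub, row in rates.iterrows():
        vals = row.to_numpy(dtype=float)
        rows.append(_summary_row(sub, vals, n, reference))
    overall = np.array([r.overall_adherence() for r in results], dtype=float)
    rows.append(_summary_row("Overall", overall, n, None))
    table = pd.DataFrame(rows).set_index("subregion")
    meta = {
        "n_replicates": n,
        "seeds": [r.seed for r in results],
        "n_weeks": results[0].n_weeks,
    }
    return AdherenceReport(table=table, metadata=meta)


def _summary_row(sub: str, vals: np.ndarray, n: int, reference) -> dict:
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if n > 1 else np.nan
    ci95 = _t_interval(mean, sd, n, 0.95)
    ci99 = _t_interval(mean, sd, n, 0.99)
    row = {
        "subregion": sub,
        "mean_pct": mean,
        "sd_pct": sd,
        "ci95_lo": ci95[0],
        "ci95_hi": ci95[1],
        "ci99_lo": ci99[0],
        "ci99_hi": ci99[1],
    }
    if reference is not None:
        ref = reference.get(sub, np.nan)
        row["reference_pct"] = ref
        row["difference_pct"] = mean - ref if np.isfinite(ref) else np.nan
        if np.isfinite(ref) and np.isfinite(ci95[0]):
            row["outside_ci95"] = bool(ref < ci95[0] or ref > ci95[1])
            row["outside_ci99"] = bool(ref < ci99[0] or ref > ci99[1])
        else:
            row["outside_ci95"] = row["outside_ci99"] = False
    return row


def convergence_trace(result: RunResult) -> pd.DataFrame:
    """Weekly cumulative adherence % per subregion (plus overall).

    Weeks with no resolved decisions so far carry NaN for a subregion; the
    denominator (calls resolved) is monotone non-decreasing.
    """
    dec = result.events[result.events["event"].isin(("attend", "miss"))]
    if len(dec) == 0:
        raise ValueError("empty event log: no decisions to trace")
    weeks = np.arange(result.n_weeks)
    out = {}
    groups = list(dec.groupby("subregion")) + [("Overall", dec)]
    for sub, g in groups:
        att = np.bincount(g.loc[g["event"] == "attend", "week"], minlength=result.n_weeks)
        tot = np.bincount(g["week"], minlength=result.n_weeks)
        cum_att = np.cumsum(att)
        cum_tot = np.cumsum(tot)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[sub] = np.where(cum_tot > 0, 100.0 * cum_att / np.maximum(cum_tot, 1), np.nan)
    trace = pd.DataFrame(out, index=pd.Index(weeks, name="week"))
    return trace


def subgroup_report(
    results_by_subgroup: Mapping[str, Sequence[RunResult]],
    reference: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Stack per-subgroup replicate summaries into one table.

    ``results_by_subgroup`` maps a subgroup label (e.g. ``all``,
    ``cluster1``, ``cluster2``, ``train``, ``test``) to its replicate runs.
    """
    frames = []
    for label, results in results_by_subgroup.items():
        rep = summarize_replicates(results, reference=reference)
        t = rep.table.reset_index()
        t.insert(0, "subgroup", label)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def report_to_markdown(report: AdherenceReport) -> str:
    """Markdown rendering of the report table (3 significant decimals)."""
    t = report.table.reset_index()
    header = "| " + " | ".join(t.columns) + " |"
    sep = "|" + "|".join(["---"] * len(t.columns)) + "|"
    lines = [header, sep]
    for _, row in t.iterrows():
        cells = []
        for v in row:
            if isinstance(v, float):
                cells.append("" if not np.isfinite(v) else f"{v:.2f}")
            else:
                cells.append(str(v))
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)


def plot_trace(trace: pd.DataFrame, path) -> None:
    """Line plot of the convergence trace (one line per subregion)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    for col in trace.columns:
        ax.plot(trace.index, trace[col], label=col, lw=1.2 if col != "Overall" else 2.0)
    ax.set_xlabel("week")
    ax.set_ylabel("cumulative adherence (%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
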