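"""Paired per-patient comparison of dose-algorithm arms.

Each patient contributes a reference arm ("aaa") and up to two recomputed
arms ("axb_dm", "axb_dw").  Summaries report the mean +/- sample SD of the
per-patient ratio (recomputed/reference, as a percent) — not the ratio of
cohort means — together with a two-sided Wilcoxon signed-rank p-value on
the raw paired values.  Significance is read at 0.05, two-sided, with no
multiplicity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegeneratePairedSampleError

__all__ = [
    "REGIONS",
    "METRICS",
    "COMPARISONS",
    "CohortRecord",
    "PairedSummary",
    "WilcoxonResult",
    "ratio_percent",
    "percent_difference",
    "wilcoxon_signed_rank",
    "summarize_cohort",
    "tcp_comparison_table",
]

#: Row ordering of the summary table (soft tissue, lung, then whole target;
#: D95 tabulated for the whole target only; TCP summarised last).
REGIONS = ("PTV_SoftTissue", "PTV_Lung", "PTV_Whole")
METRICS = ("Dmean", "D2", "D98", "D95", "TCP")
COMPARISONS = ("axb_dm", "axb_dw")

#: Above this many nonzero differences the signed-rank test switches from
#: exact enumeration to the tie-corrected normal approximation.
EXACT_WILCOXON_LIMIT = 20


@dataclass(frozen=True)
class CohortRecord:
    """One (patient, region, metric) cell with all arms."""

    patient_id: str
    region: str
    metric: str
    value_aaa: float
    value_axb_dm: float | None = None
    value_axb_dw: float | None = None

    def arm(self, comparison: str) -> float | None:
        if comparison == "axb_dm":
            return self.value_axb_dm
        if comparison == "axb_dw":
            return self.value_axb_dw
        raise ValueError(f"unknown comparison {comparison!r}")


@dataclass(frozen=True)
class PairedSummary:
    """One summary row: per-patient ratio statistics plus the paired test."""

    region: str
    metric: str
    comparison: str
    mean_ratio_percent: float
    sd_ratio_percent: float
    p_value: float
    n: int
    method: str
    degenerate: bool = False


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    method: str
    n_used: int


def ratio_percent(value_axb: float, value_aaa: float) -> float:
    """``100 * value_axb / value_aaa``; the summary-table convention."""
    if not value_aaa > 0:
        raise ValueError("reference value must be > 0")
    return 100.0 * value_axb / value_aaa


def percent_difference(value_aaa: float, value_axb: float) -> float:
    """``100 * (value_aaa - value_axb) / value_aaa``; positive when the
    recomputed arm is lower.  Identity: ``percent_difference == 100 - ratio_percent``."""
    if not value_aaa > 0:
        raise ValueError("reference value must be > 0")
    return 100.0 * (value_aaa - value_axb) / value_aaa


def _exact_signed_rank_p(ranks: np.ndarray, w_obs: float) -> float:
    """Exact two-sided p over all sign assignments, via the rank-sum
    distribution (doubled ranks keep mid-ranks integral)."""
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: total + 1 - r]
    counts /= counts.sum()
    w2 = int(np.rint(2.0 * w_obs))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(pairs) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Differences ``d = a - b`` with ``d == 0`` discarded; ``|d|`` ranked with
    mid-ranks for ties; the statistic is the positive-rank sum.  The p-value
    is exact (full sign enumeration) for up to ``EXACT_WILCOXON_LIMIT``
    nonzero differences, else a tie-corrected normal approximation with
    continuity correction is used; ``method`` records which.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (a, b) value pairs")
    d = arr[:, 0] - arr[:, 1]
    d = d[d != 0]
    m = d.size
    if m == 0:
        raise DegeneratePairedSampleError("degenerate paired sample: all differences zero")
    ranks = sps.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())

    if m <= EXACT_WILCOXON_LIMIT:
        return WilcoxonResult(w, _exact_signed_rank_p(ranks, w), "exact", m)

    mu = m * (m + 1) / 4.0
    var = m * (m + 1) * (2 * m + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float(((tie_counts**3 - tie_counts) / 48.0).sum())
    cc = 0.5 * math.copysign(1.0, w - mu) if w != mu else 0.0
    z = (w - mu - cc) / math.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return WilcoxonResult(w, p, "normal", m)


def _order_key(region: str, metric: str) -> tuple[int, int]:
    r = REGIONS.index(region) if region in REGIONS else len(REGIONS)
    m = METRICS.index(metric) if metric in METRICS else len(METRICS)
    return (r, m)


def summarize_cohort(records) -> list[PairedSummary]:
    """Collapse per-patient records into per-(region, metric, comparison)
    summary rows, in the canonical table order.

    A cell where every patient has identical arms cannot be ranked; it is
    reported with ``p = 1.0`` and the ``degenerate`` flag instead of
    aborting the whole report.  A patient missing an arm that other
    patients provide raises a :class:`ValueError` naming the patient.
    """
    cells: dict[tuple[str, str], list[CohortRecord]] = {}
    for rec in records:
        cells.setdefault((rec.region, rec.metric), []).append(rec)

    rows: list[PairedSummary] = []
    for (region, metric) in sorted(cells, key=lambda k: _order_key(*k)):
        recs = cells[(region, metric)]
        for comparison in COMPARISONS:
            values = [(r.patient_id, r.value_aaa, r.arm(comparison)) for r in recs]
            n_present = sum(v is not None for _, _, v in values)
            if n_present == 0:
                continue
            missing = [pid for pid, _, v in values if v is None]
            if missing:
                raise ValueError(
                    f"missing arm {comparison!r} for patient(s) {missing} "
                    f"in cell ({region}, {metric})"
                )
            ratios = np.array([ratio_percent(v, a) for _, a, v in values])
            mean = float(ratios.mean())
            sd = float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0
            try:
                test = wilcoxon_signed_rank([(v, a) for _, a, v in values])
                p, method, degenerate = test.p_value, test.method, False
            except DegeneratePairedSampleError:
                p, method, degenerate = 1.0, "degenerate", True
            rows.append(
                PairedSummary(
                    region=region,
                    metric=metric,
                    comparison=comparison,
                    mean_ratio_percent=mean,
                    sd_ratio_percent=sd,
                    p_value=p,
                    n=len(values),
                    method=method,
                    degenerate=degenerate,
                )
            )
    return rows


def tcp_comparison_table(records) -> tuple[list[dict], dict]:
    """Per-patient %ΔD95 vs %ΔTCP rows plus cohort headline numbers.

    ``records`` must contain, for each patient, the whole-target D95 and TCP
    cells for both arms of interest.  Returns ``(rows, headline)`` where
    each row is ``{patient_id, comparison, pct_diff_d95, pct_diff_tcp}`` and
    ``headline`` holds the cohort mean and max %ΔTCP per comparison plus the
    median TCP per arm.
    """
    by_patient: dict[str, dict[str, CohortRecord]] = {}
    for rec in records:
        if rec.region == "PTV_Whole" and rec.metric in ("D95", "TCP"):
            by_patient.setdefault(rec.patient_id, {})[rec.metric] = rec

    rows: list[dict] = []
    tcp_per_arm: dict[str, list[float]] = {"aaa": [], "axb_dm": [], "axb_dw": []}
    for patient_id in sorted(by_patient):
        cell = by_patient[patient_id]
        if "D95" not in cell or "TCP" not in cell:
            raise ValueError(f"patient {patient_id!r} lacks a D95 or TCP record")
        tcp_per_arm["aaa"].append(cell["TCP"].value_aaa)
        for comparison in COMPARISONS:
            d95_axb = cell["D95"].arm(comparison)
            tcp_axb = cell["TCP"].arm(comparison)
            if d95_axb is None or tcp_axb is None:
                continue
            tcp_per_arm[comparison].append(tcp_axb)
            rows.append(
                {
                    "patient_id": patient_id,
                    "comparison": comparison,
                    "pct_diff_d95": percent_difference(cell["D95"].value_aaa, d95_axb),
                    "pct_diff_tcp": percent_difference(cell["TCP"].value_aaa, tcp_axb),
                }
            )
    if not rows:
        raise ValueError("no complete D95/TCP pairs in the records")

    headline: dict = {"pct_diff_tcp": {}, "median_tcp": {}}
    for comparison in COMPARISONS:
        diffs = [r["pct_diff_tcp"] for r in rows if r["comparison"] == comparison]
        if diffs:
            headline["pct_diff_tcp"][comparison] = {
                "mean": float(np.mean(diffs)),
                "max": float(np.max(diffs)),
            }
    for arm, values in tcp_per_arm.items():
        if values:
            headline["median_tcp"][arm] = float(np.median(values))
    return rows, headline
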