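"""Stage functions and the end-to-end pipeline.

Stages operate on a long-format metrics frame with columns
``patient_id, region, metric, arm, value`` so that the CLI subcommands
(simulate -> metrics -> tcp -> compare) compose to exactly the same result
as :func:`run_pipeline` on the same config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from . import cohort as cs
from .config import RunConfig
from .dvh import compute_cumulative_dvh, dose_at_volume, extract_metrics, split_target
from .io import ARMS, PatientData
from .radiobio import FractionationScheme, TCPModelParams, lq_bed, tcp_logistic
from .synthetic import simulate_cohort

__all__ = [
    "metrics_table",
    "add_tcp",
    "records_from_frame",
    "compare_frames",
    "run_pipeline",
]

log = logging.getLogger("boundarydose")

METRIC_COLUMNS = ["patient_id", "region", "metric", "arm", "value"]

#: metrics tabulated for the split parts; the whole target adds D95 (and the
#: TCP coverage quantile if configured differently)
_PART_METRICS = ("Dmean", "D2", "D98")


def _coverage_metric(coverage_percent: float) -> str:
    return f"D{coverage_percent:g}"


def metrics_table(
    patients: list[PatientData],
    bin_width_gy: float = 0.05,
    coverage_percent: float = 95.0,
) -> pd.DataFrame:
    """Per-patient dose metrics for the three regions and every arm.

    Regions: the whole target plus its lung and soft-tissue parts.  The
    whole target additionally carries D95 and, if different, the quantile
    used as the TCP model input.  Metrics of an empty part are omitted
    (absent rows), with a warning.
    """
    rows = []
    cov_metric = _coverage_metric(coverage_percent)
    for p in patients:
        ptv_lung, ptv_soft = split_target(p.ptv_mask, p.lung_mask)
        regions = {
            "PTV_Whole": p.ptv_mask,
            "PTV_Lung": ptv_lung,
            "PTV_SoftTissue": ptv_soft,
        }
        for region_name, mask in regions.items():
            if mask.is_empty():
                log.warning("patient %s: %s is empty; metrics omitted", p.patient_id, region_name)
                continue
            for arm in ARMS:
                if arm not in p.doses:
                    continue
                metrics = extract_metrics(p.doses[arm], mask, bin_width_gy)
                wanted = dict(zip(_PART_METRICS, (metrics.dmean, metrics.d2, metrics.d98)))
                if region_name == "PTV_Whole":
                    wanted["D95"] = metrics.d95
                    if cov_metric not in wanted:
                        dvh = compute_cumulative_dvh(p.doses[arm], mask, bin_width_gy)
                        wanted[cov_metric] = dose_at_volume(dvh, coverage_percent)
                for metric, value in wanted.items():
                    rows.append((p.patient_id, region_name, metric, arm, value))
        log.info("patient %s: metrics extracted", p.patient_id)
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def add_tcp(
    frame: pd.DataFrame,
    scheme: FractionationScheme,
    params: TCPModelParams,
    coverage_percent: float = 95.0,
) -> pd.DataFrame:
    """Append per-patient TCP rows computed from the whole-target coverage
    quantile (region ``PTV_Whole``, metric ``TCP``)."""
    cov_metric = _coverage_metric(coverage_percent)
    sel = frame[(frame.region == "PTV_Whole") & (frame.metric == cov_metric)]
    if sel.empty:
        raise ValueError(f"no {cov_metric} rows for PTV_Whole in the metrics frame")
    tcp_rows = [
        (row.patient_id, "PTV_Whole", "TCP", row.arm,
         tcp_logistic(lq_bed(row.value, scheme), params))
        for row in sel.itertuples()
    ]
    return pd.concat(
        [frame, pd.DataFrame(tcp_rows, columns=METRIC_COLUMNS)], ignore_index=True
    )


def records_from_frame(frame: pd.DataFrame) -> list[cs.CohortRecord]:
    """Pivot the long frame into per-(patient, region, metric) records."""
    records = []
    for (patient_id, region, metric), group in frame.groupby(
        ["patient_id", "region", "metric"], sort=True
    ):
        values = dict(zip(group.arm, group.value))
        if "aaa" not in values:
            raise ValueError(
                f"missing reference arm for patient {patient_id!r} ({region}, {metric})"
            )
        records.append(
            cs.CohortRecord(
                patient_id=patient_id,
                region=region,
                metric=metric,
                value_aaa=values["aaa"],
                value_axb_dm=values.get("axb_dm"),
                value_axb_dw=values.get("axb_dw"),
            )
        )
    return records


def compare_frames(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Summary table, per-patient %ΔD95/%ΔTCP table, and headline numbers."""
    records = records_from_frame(frame)
    summary = pd.DataFrame([dataclasses.asdict(s) for s in cs.summarize_cohort(records)])
    fig_rows, headline = cs.tcp_comparison_table(records)
    return summary, pd.DataFrame(fig_rows), headline


def _write_outputs(
    out_dir: Path,
    config: RunConfig,
    metrics: pd.DataFrame,
    summary: pd.DataFrame,
    fig2: pd.DataFrame,
    headline: dict,
) -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    nd = config.report.percent_decimals
    paths = {
        "metrics": out_dir / "metrics.csv",
        "summary": out_dir / "summary.csv",
        "tcp_by_patient": out_dir / "tcp_by_patient.csv",
        "headline": out_dir / "headline.json",
    }
    # %.17g round-trips doubles exactly, keeping staged CLI runs byte-identical
    metrics.to_csv(paths["metrics"], index=False, float_format="%.17g")
    summary = summary.assign(
        mean_ratio_percent=summary.mean_ratio_percent.round(nd),
        sd_ratio_percent=summary.sd_ratio_percent.round(nd),
    )
    summary.to_csv(paths["summary"], index=False)
    fig2 = fig2.assign(
        pct_diff_d95=fig2.pct_diff_d95.round(nd), pct_diff_tcp=fig2.pct_diff_tcp.round(nd)
    )
    fig2.to_csv(paths["tcp_by_patient"], index=False)
    report = {
        "seed": config.synthetic.seed,
        "config": config.echo(),
        "headline": headline,
    }
    paths["headline"].write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return paths


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate the configured cohort and write the full report bundle.

    Outputs: ``metrics.csv`` (long, full precision), ``summary.csv``
    (ratio-table shape, percents at the configured precision),
    ``tcp_by_patient.csv`` (per-patient %ΔD95 vs %ΔTCP) and
    ``headline.json`` (full precision, with the config echo and seed).
    Deterministic: identical config+seed reproduce every byte.
    """
    log.info("simulating cohort: n=%d seed=%d", config.synthetic.n_patients, config.synthetic.seed)
    patients = [PatientData.from_sim(s) for s in simulate_cohort(config.synthetic)]
    log.info("extracting metrics (bin width %.3f Gy)", config.dvh.bin_width_gy)
    rb = config.radiobiology
    frame = metrics_table(patients, config.dvh.bin_width_gy, rb.coverage_percent)
    frame = add_tcp(
        frame,
        FractionationScheme(rb.n_fractions, rb.alpha_beta_gy),
        TCPModelParams(rb.d50_bed_gy, rb.gamma),
        rb.coverage_percent,
    )
    log.info("comparing arms")
    summary, fig2, headline = compare_frames(frame)
    paths = _write_outputs(Path(out_dir), config, frame, summary, fig2, headline)
    log.info("report bundle written to %s", out_dir)
    return paths
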