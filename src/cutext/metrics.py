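"""Per-sample and per-cohort content-density metrics.

The headline measure is the CU/U ratio: content units (each credited once)
divided by total units, a content-density index sometimes called
"informativeness" in the discourse literature.  Cohort summaries report the
mean of per-sample ratios (not pooled CU over pooled U), matching how group
tables in picture-description studies are computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .annotator import CUAnnotation
from .tokenizer import TokenizedSample, count_units

METRIC_COLUMNS = [
    "sample_id",
    "group",
    "modality",
    "cu_count",
    "unit_count",
    "cu_u_ratio",
    "unambiguous_cu",
    "ambiguous_cu",
    "unambiguous_ratio",
    "self_ref_count",
]


@dataclass
class SampleMetrics:
    sample_id: str
    group: str
    modality: str
    cu_count: int
    unit_count: int
    cu_u_ratio: float  # NaN when unit_count == 0
    unambiguous_cu: int
    ambiguous_cu: int
    unambiguous_ratio: float  # NaN when cu_count == 0
    self_ref_count: int


def compute_sample_metrics(
    annotation: CUAnnotation, sample: TokenizedSample
) -> SampleMetrics:
    """Combine a sample's annotation and tokenization into one metrics row.

    An empty sample has an undefined ratio, reported as NaN (never a
    division failure) and excluded from aggregation.
    """
    if annotation.sample_id and sample.sample_id and annotation.sample_id != sample.sample_id:
        raise ValueError(
            f"annotation {annotation.sample_id!r} does not match sample {sample.sample_id!r}"
        )
    units = count_units(sample)
    cu = len(annotation.matched_entries)
    unamb = len(annotation.unambiguous_matched)
    amb = len(annotation.ambiguous_matched)
    return SampleMetrics(
        sample_id=sample.sample_id,
        group=sample.group,
        modality=sample.modality,
        cu_count=cu,
        unit_count=units,
        cu_u_ratio=cu / units if units > 0 else math.nan,
        unambiguous_cu=unamb,
        ambiguous_cu=amb,
        unambiguous_ratio=unamb / cu if cu > 0 else math.nan,
        self_ref_count=annotation.self_ref_count,
    )


def metrics_frame(metrics: Iterable[SampleMetrics]) -> pd.DataFrame:
    """Tidy per-sample table with the fixed metrics-CSV column order."""
    rows = [vars(m) for m in metrics]
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


NUMERIC_METRICS = METRIC_COLUMNS[3:]


def aggregate_cohort(
    metrics: Sequence[SampleMetrics],
    by: Sequence[str] = ("group", "modality"),
) -> pd.DataFrame:
    """Mean and sample SD (n-1 denominator) per cell for every metric.

    Returns a tidy table with one row per (cell, metric): columns are the
    grouping keys plus metric, n, mean, sd.  NaN values (undefined ratios of
    empty samples) are excluded per metric; a cell with a single observation
    has its SD reported as NaN.
    """
    if not metrics:
        raise ValueError("aggregate_cohort requires a non-empty metrics list")
    df = metrics_frame(metrics)
    long = df.melt(
        id_vars=list(by), value_vars=NUMERIC_METRICS,
        var_name="metric", value_name="value",
    ).dropna(subset=["value"])
    out = (
        long.groupby([*by, "metric"], sort=True)["value"]
        .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    return out


def flag_outliers(
    metrics: Sequence[SampleMetrics],
    metric_name: str = "cu_u_ratio",
    k: float = 1.0,
) -> tuple[list[str], list[str], float, float]:
    """Flag samples at least k SDs below/above the cohort mean of a metric.

    Returns (low_ids, high_ids, mean, sd).  This mirrors the qualitative
    outlier inspection of ratio distributions: low outliers tend to be
    samples padded with tangential or self-referential units, high outliers
    telegraphic CU lists.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    values = [
        (m.sample_id, getattr(m, metric_name))
        for m in metrics
        if not math.isnan(getattr(m, metric_name))
    ]
    if len(values) < 2:
        raise ValueError("flag_outliers requires at least 2 defined values")
    xs = [v for _, v in values]
    mean = sum(xs) / len(xs)
    sd = math.sqrt(sum((x - mean) ** 2 for x in xs) / (len(xs) - 1))
    if sd == 0.0:
        # no spread: nothing is an outlier
        return [], [], mean, sd
    low = [sid for sid, v in values if v <= mean - k * sd]
    high = [sid for sid, v in values if v >= mean + k * sd]
    return low, high, mean, sd
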