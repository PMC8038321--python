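"""Trend-directed percentile aggregation and classifier-table assembly.

Per-window features are collapsed to one sample per recording either by
the median (50th percentile, representative of basal activity) or by
trend-directed 10th/90th percentiles that target the contractile bursts:
features that increase in contractile periods as labor approaches
(amplitude, DF1, DF2, deciles, H/L ratio, time reversibility) take the
90th percentile; features that decrease (SMR, Lempel-Ziv complexities,
sample/fuzzy/spectral entropy, SD1, SD2, SD1/SD2) take the 10th.

Four classifier input sets are assembled: (1) 10th-90th percentiles of the
EHG features plus the six obstetric covariates; (2) 50th percentile plus
obstetric; (3) 10th-90th EHG only; (4) 50th EHG only. The positive class is
TTD <= 7 days (inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES
from .ingest import OBSTETRIC_FIELDS

logger = logging.getLogger(__name__)

#: Features with an increasing trend in contractile periods -> 90th percentile.
TREND_INCREASING: tuple[str, ...] = (
    "app",
    "df1",
    "df2",
    "hl_ratio",
    "d1",
    "d2",
    "d3",
    "d4",
    "d5",
    "d6",
    "d7",
    "d8",
    "d9",
    "timerev",
)

#: Features with a decreasing trend -> 10th percentile.
TREND_DECREASING: tuple[str, ...] = (
    "smr",
    "lz_bin",
    "lz_multi6",
    "sampen",
    "fuzzyen",
    "specen",
    "sd1",
    "sd2",
    "sd1_sd2",
)

#: Days-to-delivery threshold defining the positive (imminent) class.
TTD_THRESHOLD_DAYS = 7.0


@dataclass
class FeatureTable:
    """Classifier input table: one row per recording (or SMOTE sample)."""

    X: pd.DataFrame  # index: sample id, columns: feature names
    y: np.ndarray  # binary labels, 1 = TTD <= 7 days
    origin: np.ndarray  # "real" or "synthetic_smote" per row
    input_set: int

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        self.origin = np.asarray(self.origin, dtype=object)
        if not (len(self.X) == self.y.size == self.origin.size):
            raise ValueError("X, y and origin must align")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def n_samples(self) -> int:
        return len(self.X)


def aggregate_recording(window_features: pd.DataFrame, mode: str) -> pd.Series | None:
    """Collapse window features of one recording to 23 aggregate values.

    ``mode="p50"`` takes the per-feature median; ``mode="p10_90"`` the
    trend-directed percentile. Percentiles interpolate linearly between
    order statistics (the "type 7" convention). Windows where a feature is
    NaN are excluded for that feature only; a feature missing in all
    windows makes the recording unusable (returns None, logged).
    """
    if mode not in ("p50", "p10_90"):
        raise ValueError("mode must be 'p50' or 'p10_90'")
    vals: dict[str, float] = {}
    for name in FEATURE_NAMES:
        col = window_features[name].to_numpy(dtype=float)
        col = col[np.isfinite(col)]
        if col.size == 0:
            logger.warning("feature %s missing in all windows; recording excluded", name)
            return None
        if mode == "p50":
            q = 50.0
        else:
            q = 90.0 if name in TREND_INCREASING else 10.0
        vals[name] = float(np.percentile(col, q))
    return pd.Series(vals, index=list(FEATURE_NAMES))


def build_table(
    cohort: list[tuple[str, pd.DataFrame, dict, float]], input_set: int
) -> FeatureTable:
    """Assemble the classifier input table for one of the four input sets.

    ``cohort`` holds (recording id, window-feature frame, obstetric dict,
    ttd_days) per recording. Input sets 1/3 use the trend-directed
    10th-90th percentiles, 2/4 the median; 1/2 append the six obstetric
    covariates (recordings with missing obstetric fields are excluded with
    a named-field log entry). Recordings without any valid window are
    excluded.
    """
    if input_set not in (1, 2, 3, 4):
        raise ValueError("input_set must be 1, 2, 3 or 4")
    mode = "p10_90" if input_set in (1, 3) else "p50"
    with_obstetric = input_set in (1, 2)

    rows: list[pd.Series] = []
    ids: list[str] = []
    labels: list[int] = []
    for rec_id, wf, obstetric, ttd in cohort:
        if len(wf) == 0:
            logger.warning("recording %s: no windows; excluded", rec_id)
            continue
        agg = aggregate_recording(wf, mode)
        if agg is None:
            logger.warning("recording %s: aggregation failed; excluded", rec_id)
            continue
        if with_obstetric:
            missing = [
                f
                for f in OBSTETRIC_FIELDS
                if obstetric.get(f) is None or not np.isfinite(float(obstetric[f]))
            ]
            if missing:
                logger.warning(
                    "recording %s: missing obstetric fields %s; excluded", rec_id, missing
                )
                continue
            agg = pd.concat(
                [agg, pd.Series({f: float(obstetric[f]) for f in OBSTETRIC_FIELDS})]
            )
        rows.append(agg)
        ids.append(rec_id)
        labels.append(1 if ttd <= TTD_THRESHOLD_DAYS else 0)
    if not rows:
        raise ValueError("no usable recordings in cohort")
    X = pd.DataFrame(rows, index=ids)
    return FeatureTable(
        X=X,
        y=np.asarray(labels),
        origin=np.asarray(["real"] * len(ids), dtype=object),
        input_set=input_set,
    )
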