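"""Relative quantification of qPCR expression by the 2^-ddCt method.

A target transcript and a reference gene (e.g. GAPDH) are each measured in
triplicate on the same sample.  dCt = mean Ct(target) - mean Ct(reference)
normalises for input amount; ddCt = dCt(sample) - dCt(calibrator) expresses
the sample relative to a calibrator sample, and 2^-ddCt converts cycle
differences to fold expression (one cycle ~ a factor of two).

The calibrator convention is configurable because protocols differ: the
default uses the mean dCt of the control group, which sets the control
group's geometric-mean expression to 1; a fixed single reference sample is
also supported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CtRecord",
    "RelativeExpression",
    "summarize_triplicate",
    "relative_expression",
    "calibrator_delta_ct",
    "quantify_frame",
]

#: replicate-scatter QC threshold, in cycles (flag-only; no value is rejected)
DEFAULT_SD_THRESHOLD = 0.5


@dataclass(frozen=True)
class CtRecord:
    """Triplicate cycle-threshold measurements for one sample and one target."""

    subject_id: str
    target: str
    ct_target: tuple[float, float, float]
    ct_reference: tuple[float, float, float]

    def __post_init__(self) -> None:
        for channel, values in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            values = tuple(float(v) for v in values)
            if len(values) != 3:
                raise ValueError(f"{channel} must hold exactly three replicates, got {len(values)}")
            if not all(math.isfinite(v) and v >= 0 for v in values):
                raise ValueError(f"{channel} values must be finite and non-negative: {values}")
            object.__setattr__(self, channel, values)


@dataclass(frozen=True)
class RelativeExpression:
    """2^-ddCt result for one sample; ``value`` is dimensionless fold expression."""

    subject_id: str
    target: str
    delta_ct: float
    delta_delta_ct: float
    value: float
    flag: str = ""


def summarize_triplicate(
    values: Sequence[float], sd_threshold: float = DEFAULT_SD_THRESHOLD
) -> tuple[float, bool]:
    """Mean of a Ct triplicate, flagged when the replicate SD exceeds the threshold.

    Returns ``(mean, flagged)``.  The sample SD (ddof=1) is the usual qPCR
    replicate-scatter QC statistic.
    """
    arr = np.asarray(values, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"expected exactly three replicate values, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("replicate values must be finite")
    return float(arr.mean()), bool(arr.std(ddof=1) > sd_threshold)


def _record_delta_ct(record: CtRecord, sd_threshold: float) -> tuple[float, str]:
    mean_t, flag_t = summarize_triplicate(record.ct_target, sd_threshold)
    mean_r, flag_r = summarize_triplicate(record.ct_reference, sd_threshold)
    flags = []
    if flag_t:
        flags.append("target-replicate-sd")
    if flag_r:
        flags.append("reference-replicate-sd")
    return mean_t - mean_r, ";".join(flags)


def relative_expression(
    record: CtRecord,
    calibrator_delta_ct: float,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
) -> RelativeExpression:
    """2^-ddCt relative expression of ``record`` against a calibrator dCt."""
    if calibrator_delta_ct is None or not math.isfinite(float(calibrator_delta_ct)):
        raise ValueError("a finite calibrator delta-Ct is required")
    dct, flag = _record_delta_ct(record, sd_threshold)
    ddct = dct - float(calibrator_delta_ct)
    return RelativeExpression(
        subject_id=record.subject_id,
        target=record.target,
        delta_ct=dct,
        delta_delta_ct=ddct,
        value=2.0 ** (-ddct),
        flag=flag,
    )


def calibrator_delta_ct(
    records: Iterable[CtRecord],
    strategy: str = "control-mean",
    control_ids: Iterable[str] | None = None,
    subject_id: str | None = None,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
) -> float:
    """Calibrator dCt under the chosen strategy.

    ``control-mean``
        arithmetic mean dCt over the records whose subject id is in
        ``control_ids`` (all records when ``control_ids`` is None).
    ``fixed-subject``
        the dCt of the single record named by ``subject_id``.
    """
    records = list(records)
    if not records:
        raise ValueError("no Ct records supplied")
    if strategy == "control-mean":
        if control_ids is not None:
            control_ids = set(control_ids)
            records = [r for r in records if r.subject_id in control_ids]
            if not records:
                raise ValueError("no records belong to the control group")
        return float(np.mean([_record_delta_ct(r, sd_threshold)[0] for r in records]))
    if strategy == "fixed-subject":
        if subject_id is None:
            raise ValueError("fixed-subject strategy requires subject_id")
        for r in records:
            if r.subject_id == subject_id:
                return _record_delta_ct(r, sd_threshold)[0]
        raise KeyError(f"calibrator subject {subject_id!r} not among the records")
    raise ValueError(f"unknown calibrator strategy {strategy!r}")


def quantify_frame(
    ct_long: pd.DataFrame,
    strategy: str = "control-mean",
    control_ids: Iterable[str] | None = None,
    subject_id: str | None = None,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
) -> pd.DataFrame:
    """Quantify a long-format Ct table (one row per replicate).

    Expects columns ``subject_id, target, replicate, ct_target, ct_reference``.
    The calibrator is computed per target.  Returns one row per subject and
    target with ``delta_ct, delta_delta_ct, expression, flag``.
    """
    required = {"subject_id", "target", "replicate", "ct_target", "ct_reference"}
    missing = required - set(ct_long.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns: {sorted(missing)}")

    rows = []
    for target, sub in ct_long.groupby("target", sort=False):
        records = []
        for sid, reps in sub.groupby("subject_id", sort=False):
            reps = reps.sort_values("replicate")
            records.append(
                CtRecord(
                    subject_id=str(sid),
                    target=str(target),
                    ct_target=tuple(reps["ct_target"].astype(float)),
                    ct_reference=tuple(reps["ct_reference"].astype(float)),
                )
            )
        cal = calibrator_delta_ct(
            records, strategy=strategy, control_ids=control_ids,
            subject_id=subject_id, sd_threshold=sd_threshold,
        )
        for rec in records:
            res = relative_expression(rec, cal, sd_threshold)
            rows.append(
                {
                    "subject_id": res.subject_id,
                    "target": res.target,
                    "delta_ct": res.delta_ct,
                    "delta_delta_ct": res.delta_delta_ct,
                    "expression": res.value,
                    "flag": res.flag,
                }
            )
    return pd.DataFrame(rows)
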