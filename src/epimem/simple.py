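"""SIMPLE temporal-similarity score for temporal-order judgments.

In the SIMPLE framework, memory traces are located on a logarithmically
compressed time axis, so discriminating the order of two events depends on
their proximity in log time *at retrieval*.  For a pair of events with
encoding-to-retrieval retention delays ``T_i < T_j``, the temporal
similarity is::

    TS_ij = (T_i / T_j) ** c

where ``c`` is a power constant computed as the inverse of the range of the
log-transformed retention delays of a calibration set (here: all delays a
participant contributes within a task block).  TS lies in (0, 1]; equal
delays give TS = 1, and the extremes of the calibration set give exactly
``exp(-1)``.  Two events a fixed distance apart become *more* similar the
longer ago they happened — the compression that makes the score comparable
across protocols whose timescales differ by orders of magnitude.

Because TS depends only on the delay ratio and ``c`` only on the ratio of
the calibration extremes, multiplying every timestamp by a constant leaves
every score unchanged: the score is temporally scale-invariant by
construction, exactly in exact arithmetic and to machine precision in
floating point.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .types import Condition, DegenerateDataError, SimilarityCalibration

__all__ = [
    "retention_delay",
    "calibrate_c",
    "temporal_similarity",
    "score_order_trials",
    "CALIBRATION_SCOPES",
]

#: Task block per cue condition: object cues form one block; the two
#: place-cue conditions are administered intermixed in a second block.
BLOCK_OF_CONDITION = {
    Condition.TOobj.value: "obj",
    Condition.ev_TOloc.value: "loc",
    Condition.noe_TOloc.value: "loc",
}

CALIBRATION_SCOPES = ("per_participant_per_block", "per_participant_per_condition", "global")


def retention_delay(encode_time, retrieval_time):
    """Encoding-to-retrieval retention delay in seconds (vectorized).

    Raises :class:`DegenerateDataError` if any event was encoded at or after
    retrieval.
    """
    enc = np.asarray(encode_time, dtype=float)
    ret = np.asarray(retrieval_time, dtype=float)
    delay = ret - enc
    if np.any(delay <= 0):
        raise DegenerateDataError("retrieval must occur strictly after encoding")
    if delay.ndim == 0:
        return float(delay)
    return delay


def calibrate_c(delays: Iterable[float], scope: str = "") -> SimilarityCalibration:
    """Power constant from a set of retention delays.

    ``c = 1 / ln(max/min)`` — algebraically the inverse of the range of the
    log delays; computed from the single ratio so that rescaling all delays
    by a power of two reproduces ``c`` bit-for-bit.
    """
    d = np.asarray(list(delays) if not isinstance(delays, np.ndarray) else delays, dtype=float)
    if d.size < 2:
        raise DegenerateDataError(f"calibration needs >= 2 delays (scope {scope!r})")
    if np.any(d <= 0):
        raise DegenerateDataError(f"all delays must be positive (scope {scope!r})")
    dmin = float(np.min(d))
    dmax = float(np.max(d))
    if dmax == dmin:
        raise DegenerateDataError(f"degenerate delay range: all delays equal (scope {scope!r})")
    c = 1.0 / np.log(dmax / dmin)
    return SimilarityCalibration(c=float(c), delay_min=dmin, delay_max=dmax, scope=scope)


def temporal_similarity(t_i, t_j, c) -> np.ndarray | float:
    """TS = (smaller delay / larger delay) ** c, in (0, 1].

    Inputs may be given in either order; the smaller delay is placed in the
    numerator.  ``c`` may be a :class:`SimilarityCalibration` or a positive
    float.
    """
    if isinstance(c, SimilarityCalibration):
        c = c.c
    c = float(c)
    if c <= 0:
        raise DegenerateDataError(f"power constant c must be positive; got {c}")
    ti = np.asarray(t_i, dtype=float)
    tj = np.asarray(t_j, dtype=float)
    if np.any(ti <= 0) or np.any(tj <= 0):
        raise DegenerateDataError("retention delays must be positive")
    lo = np.minimum(ti, tj)
    hi = np.maximum(ti, tj)
    ts = (lo / hi) ** c
    if ts.ndim == 0:
        return float(ts)
    return ts


def _scope_keys(df: pd.DataFrame, scope: str) -> pd.Series:
    if scope == "per_participant_per_block":
        return df["participant_id"].astype(str) + "|" + df["condition"].map(BLOCK_OF_CONDITION)
    if scope == "per_participant_per_condition":
        return df["participant_id"].astype(str) + "|" + df["condition"].astype(str)
    if scope == "global":
        return pd.Series("global", index=df.index)
    raise ValueError(f"unknown calibration scope {scope!r}; expected one of {CALIBRATION_SCOPES}")


def score_order_trials(
    trials: pd.DataFrame,
    scope: str = "per_participant_per_block",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate order trials with their temporal-similarity score.

    Retention delays ``t_a``/``t_b`` are recomputed from each trial's own
    encoding timestamps and retrieval timestamp (the session advances trial
    by trial).  The power constant is calibrated per ``scope`` group over
    the union of all delays occurring in that group's trials.

    Returns the annotated copy of ``trials`` and a calibration table with
    one row per scope group (group, delay_min, delay_max, c, n_trials).
    Degenerate groups (all delays equal) raise, naming the group.
    """
    df = trials.copy()
    df["t_a"] = retention_delay(df["encode_a"].to_numpy(float), df["retrieval_time"].to_numpy(float))
    df["t_b"] = retention_delay(df["encode_b"].to_numpy(float), df["retrieval_time"].to_numpy(float))
    keys = _scope_keys(df, scope)
    records = []
    ts = np.empty(len(df), dtype=float)
    pos = {k: i for i, k in enumerate(df.index)}
    for key, idx in df.groupby(keys, sort=True).groups.items():
        sub = df.loc[idx]
        delays = np.concatenate([sub["t_a"].to_numpy(float), sub["t_b"].to_numpy(float)])
        cal = calibrate_c(delays, scope=str(key))
        vals = temporal_similarity(sub["t_a"].to_numpy(float), sub["t_b"].to_numpy(float), cal)
        for i, v in zip(idx, np.atleast_1d(vals)):
            ts[pos[i]] = v
        records.append(
            {
                "group": key,
                "scope": scope,
                "delay_min": cal.delay_min,
                "delay_max": cal.delay_max,
                "c": cal.c,
                "n_trials": len(sub),
            }
        )
    df["ts"] = ts
    calibrations = pd.DataFrame.from_records(records)
    return df, calibrations
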