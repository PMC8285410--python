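"""Temporal-order analyses: accuracy ANOVAs, similarity→RT slopes, and the
scale-invariance inference.

The central quantity is the per-participant robust regression slope of
reaction time (ms) on temporal similarity, computed on correct trials only,
separately for the three cue conditions.  Group-level inference then asks:

* does the encoding protocol change order accuracy? (one-way ANOVA for the
  object-cue task; 3 x 2 mixed ANOVA for the two place-cue conditions,
  with Tukey HSD on the protocol factor);
* do RTs rise with temporal similarity, and equally so across protocols
  whose timescales differ by orders of magnitude?  A 3 (cue condition,
  within) x 3 (protocol, between) mixed ANOVA on the slopes, a pooled
  one-sample t of per-subject mean slopes against zero, and a JZS Bayes
  factor quantifying evidence *for the null* of no between-protocol slope
  difference — the statistical embodiment of temporal scale invariance.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .stats import jzs_bayes_factor, mixed_anova, one_sample_t, robust_slope, tukey_hsd
from .types import (
    AnovaTable,
    BayesFactorResult,
    Condition,
    DegenerateDataError,
    TTestResult,
)

log = logging.getLogger("epimem")


def order_accuracy_anovas(trials_by_protocol: Mapping[str, pd.DataFrame]) -> dict:
    """Accuracy analyses of the order task.

    Returns the one-way between-protocol ANOVA on object-cue accuracy, the
    3 (protocol) x 2 (ev/noe place cue) mixed ANOVA, Tukey HSD on protocol
    for both, and the per-subject accuracy table.
    """
    recs = []
    for proto, trials in trials_by_protocol.items():
        acc = (
            trials.assign(correct=trials["correct"].astype(bool))
            .groupby(["participant_id", "condition"], observed=True)["correct"]
            .mean()
            .reset_index()
        )
        acc["experiment"] = proto
        recs.append(acc)
    acc = pd.concat(recs, ignore_index=True)

    obj = acc[acc["condition"] == Condition.TOobj.value]
    obj_groups = {
        p: g["correct"].to_numpy() for p, g in obj.groupby("experiment", sort=True)
    }
    anova_obj = mixed_anova(obj, dv="correct", subject="participant_id", between="experiment")

    loc = acc[acc["condition"].isin([Condition.ev_TOloc.value, Condition.noe_TOloc.value])]
    anova_loc = mixed_anova(
        loc, dv="correct", subject="participant_id", between="experiment", within="condition"
    )
    loc_means = loc.groupby(["experiment", "participant_id"], observed=True)["correct"].mean()
    tukey_loc = tukey_hsd({p: g.to_numpy() for p, g in loc_means.groupby("experiment")})

    return {
        "accuracy": acc,
        "anova_toobj": anova_obj,
        "tukey_toobj": tukey_hsd(obj_groups),
        "anova_toloc": anova_loc,
        "tukey_toloc_experiment": tukey_loc,
    }


def compute_slopes(trials: pd.DataFrame, min_trials: int = 5) -> pd.DataFrame:
    """Per participant x condition robust similarity→RT slope.

    Only correct trials enter the regression.  Cells with fewer than
    ``min_trials`` correct trials or constant similarity are excluded with
    a log entry (the record is simply absent).
    """
    if trials["ts"].isna().any():
        raise ValueError("trials must be scored (ts column complete) before slope fitting")
    recs = []
    correct = trials[trials["correct"].astype(bool)]
    for (pid, cond), cell in correct.groupby(["participant_id", "condition"], observed=True):
        x = cell["ts"].to_numpy(float)
        y = cell["rt"].to_numpy(float)
        try:
            beta = robust_slope(x, y, min_points=min_trials)
        except DegenerateDataError as exc:
            log.info("slope excluded for %s/%s: %s", pid, cond, exc)
            continue
        recs.append(
            {"participant_id": pid, "condition": cond, "beta": beta, "n_trials_used": len(cell)}
        )
    return pd.DataFrame.from_records(recs)


def slope_inference(
    slopes_by_protocol: Mapping[str, pd.DataFrame],
    bf_design: str = "mean_slopes",
    bf_scale: float | None = None,
) -> dict:
    """Group-level inference on the similarity→RT slopes.

    * 3 (cue condition, within) x 3 (protocol, between) mixed ANOVA;
      subjects missing any condition's slope are excluded (logged).
    * one-sample t of every subject's mean slope against 0 (pooled over
      protocols; df = total subjects - 1).
    * JZS Bayes factor for the between-protocol effect.  Default design
      collapses each subject to their mean slope across conditions (one
      value per subject, three groups); ``bf_design='per_condition'``
      instead averages BFs computed per cue condition.
    """
    frames = []
    for proto, sl in slopes_by_protocol.items():
        df = sl.copy()
        df["experiment"] = proto
        frames.append(df)
    slopes = pd.concat(frames, ignore_index=True)

    n_cond = slopes["condition"].nunique()
    counts = slopes.groupby("participant_id", observed=True)["condition"].nunique()
    complete_ids = counts[counts == n_cond].index
    dropped = counts.index.difference(complete_ids)
    if len(dropped):
        log.info("slope ANOVA: excluded %d subjects missing a condition slope", len(dropped))
    complete = slopes[slopes["participant_id"].isin(complete_ids)]

    anova = mixed_anova(
        complete, dv="beta", subject="participant_id", between="experiment", within="condition"
    )

    mean_slopes = complete.groupby(["experiment", "participant_id"], observed=True)["beta"].mean()
    pooled_t = one_sample_t(mean_slopes.to_numpy(), 0.0)

    bf_kwargs = {} if bf_scale is None else {"r": bf_scale}
    if bf_design == "mean_slopes":
        groups = {p: g.to_numpy() for p, g in mean_slopes.groupby("experiment")}
        bf = jzs_bayes_factor(groups, design="one_way", **bf_kwargs)
    elif bf_design == "per_condition":
        bfs = []
        for cond, sub in complete.groupby("condition", observed=True):
            groups = {p: g["beta"].to_numpy() for p, g in sub.groupby("experiment")}
            bfs.append(jzs_bayes_factor(groups, design="one_way", **bf_kwargs).bf10)
        bf = BayesFactorResult(
            bf10=float(np.mean(bfs)), prior="JZS (per-condition mean)", design="one_way"
        )
    else:
        raise ValueError(f"unknown bf_design {bf_design!r}")

    cond_means = (
        complete.groupby(["condition", "experiment"], observed=True)["beta"].mean().reset_index()
    )
    return {
        "slopes": slopes,
        "anova_slopes": anova,
        "pooled_t": pooled_t,
        "bf_experiment": bf,
        "condition_means": cond_means,
    }


def run_order_stage(trials_by_protocol: Mapping[str, pd.DataFrame]) -> dict:
    """Complete order stage: accuracy ANOVAs, slopes, slope inference."""
    out = order_accuracy_anovas(trials_by_protocol)
    slopes = {p: compute_slopes(t) for p, t in trials_by_protocol.items()}
    out.update(slope_inference(slopes))
    return out
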