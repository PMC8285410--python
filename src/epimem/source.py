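"""Explicit source-retrieval analyses.

Three questions, mirroring the structure of the study's first retrieval
task:

1. Does the encoding protocol change old/new recognition and the proportion
   of *Remember* (recollection) vs *Familiar* reports?  (one-way
   between-group ANOVAs, Tukey HSD post hocs)
2. Does source (place vs time) accuracy depend on confidence and protocol?
   (2 x 2 x 3 mixed ANOVA on per-subject cell accuracies, plus per-cell
   above-chance t-tests against the 2AFC chance level of 0.5)
3. Do accurate — and especially accurate *and confident* — source
   judgments predict a *Remember* report?  (random-intercept binomial
   logistic models per protocol)

The logistic design coding follows the bespoke scheme of the study:
``place``/``time`` are 1 for a correct source discrimination irrespective
of confidence; ``p_cf``/``t_cf`` are 1 only when the discrimination was
correct *and* followed by a high-confidence rating, 0 for every other
response combination.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .stats import fit_logistic_random_intercept, mixed_anova, one_sample_t, tukey_hsd
from .types import AnovaTable, LogisticFit, TTestResult

log = logging.getLogger("epimem")

MAIN_PREDICTORS = ["place", "time", "p_cf", "t_cf"]
INTERACTION_PREDICTORS = ["p_cf", "t_cf", "p_cf_x_t_cf"]


def summarize_source(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant summary of the source-retrieval task.

    Columns: ``recognition_acc`` (P(Rem or Fam | old)), ``rem_ratio``
    (Rem/(Rem+Fam) among recognized old items; absent when no old item was
    recognized) and the four source-accuracy cells ``place_high``,
    ``place_low``, ``time_high``, ``time_low`` (absent when the cell is
    empty, with a log entry).
    """
    recs = []
    for pid, df in trials.groupby("participant_id", sort=True):
        old = df[df["is_old"].astype(bool)]
        recognized = old[old["object_response"].isin(["Rem", "Fam"])]
        rec = {"participant_id": pid}
        rec["recognition_acc"] = len(recognized) / len(old) if len(old) else np.nan
        if len(recognized):
            rec["rem_ratio"] = (recognized["object_response"] == "Rem").mean()
        else:
            rec["rem_ratio"] = np.nan
            log.info("participant %s: rem_ratio undefined (no recognized old items)", pid)
        for src in ("place", "time"):
            for conf in ("high", "low"):
                cell = recognized[recognized[f"{src}_conf"] == conf]
                key = f"{src}_{conf}"
                if len(cell):
                    rec[key] = cell[f"{src}_correct"].astype(bool).mean()
                else:
                    rec[key] = np.nan
                    log.info("participant %s: empty source cell %s", pid, key)
        recs.append(rec)
    return pd.DataFrame.from_records(recs)


def build_design(trials: pd.DataFrame) -> pd.DataFrame:
    """Design rows for the recollection logistic models.

    One row per correctly recognized old item (response Rem or Fam), in
    input order.  ``y`` is 1 for Rem, 0 for Fam; predictor coding as
    described in the module docstring.
    """
    mask = trials["is_old"].astype(bool) & trials["object_response"].isin(["Rem", "Fam"])
    kept = trials[mask]
    out = pd.DataFrame(
        {
            "participant_id": kept["participant_id"].to_numpy(),
            "y": (kept["object_response"] == "Rem").astype(int).to_numpy(),
            "place": kept["place_correct"].astype(bool).astype(int).to_numpy(),
            "time": kept["time_correct"].astype(bool).astype(int).to_numpy(),
        }
    )
    out["p_cf"] = (
        kept["place_correct"].astype(bool) & (kept["place_conf"] == "high")
    ).astype(int).to_numpy()
    out["t_cf"] = (
        kept["time_correct"].astype(bool) & (kept["time_conf"] == "high")
    ).astype(int).to_numpy()
    return out


def fit_main_model(rows: pd.DataFrame, **kwargs) -> LogisticFit:
    """Rem-vs-Fam logistic model with predictors place, time, p_cf, t_cf
    and a subject random intercept."""
    if rows.empty:
        raise ValueError("no design rows (no correctly recognized old items)")
    return fit_logistic_random_intercept(rows, MAIN_PREDICTORS, outcome="y", **kwargs)


def fit_interaction_model(rows: pd.DataFrame, **kwargs) -> LogisticFit:
    """Confident-source model: p_cf, t_cf and their product.

    The interaction term asks whether confidently retrieving *both* sources
    adds Remember likelihood beyond the two additive effects.  When no
    trial has both indicators set the product column is constant and the
    engine drops it, flagging the fit.
    """
    if rows.empty:
        raise ValueError("no design rows")
    rows = rows.copy()
    rows["p_cf_x_t_cf"] = rows["p_cf"] * rows["t_cf"]
    return fit_logistic_random_intercept(rows, INTERACTION_PREDICTORS, outcome="y", **kwargs)


def run_source_anovas(
    summaries: Mapping[str, pd.DataFrame],
    correct_above_chance: bool = False,
) -> dict:
    """Group-level ANOVAs and above-chance tests over the three protocols.

    ``summaries`` maps protocol label -> :func:`summarize_source` output.
    Returns a dict with the recognition-accuracy one-way ANOVA (+ Tukey),
    the Rem-ratio one-way ANOVA, the source x confidence x experiment mixed
    ANOVA on the 2AFC cell accuracies, and per-cell one-sample t-tests
    against chance (0.5).  ``correct_above_chance`` applies a Bonferroni
    correction over the 12 cells (off by default, matching uncorrected
    per-cell reporting).
    """
    long_rows = []
    rec_groups = {}
    rem_groups = {}
    for proto, summ in summaries.items():
        rec_groups[proto] = summ["recognition_acc"].dropna().to_numpy()
        rr = summ["rem_ratio"].dropna()
        if len(rr) < len(summ):
            log.info("protocol %s: dropped %d participants with undefined rem_ratio", proto, len(summ) - len(rr))
        rem_groups[proto] = rr.to_numpy()
        for _, row in summ.iterrows():
            for src in ("place", "time"):
                for conf in ("high", "low"):
                    long_rows.append(
                        {
                            "participant_id": row["participant_id"],
                            "experiment": proto,
                            "source": src,
                            "confidence": conf,
                            "accuracy": row[f"{src}_{conf}"],
                        }
                    )
    cells = pd.DataFrame(long_rows)
    # the balanced engine needs complete subjects
    complete = cells.groupby("participant_id")["accuracy"].transform(lambda s: s.notna().all())
    n_drop = cells.loc[~complete, "participant_id"].nunique()
    if n_drop:
        log.info("mixed ANOVA on source cells: dropped %d incomplete participants", n_drop)
    cells_complete = cells[complete]
    anova_cells: AnovaTable | None = None
    if cells_complete["participant_id"].nunique() >= 6:
        anova_cells = mixed_anova(
            cells_complete,
            dv="accuracy",
            subject="participant_id",
            between="experiment",
            within=["source", "confidence"],
        )
    else:
        log.warning("source-cell ANOVA skipped: too few complete participants")

    def one_way(groups: dict[str, np.ndarray], label: str) -> AnovaTable:
        df = pd.DataFrame(
            [
                {"participant_id": f"{g}_{i}", "experiment": g, "v": v}
                for g, arr in groups.items()
                for i, v in enumerate(arr)
            ]
        )
        return mixed_anova(df, dv="v", subject="participant_id", between="experiment")

    above: list[dict] = []
    n_tests = 0
    for proto, summ in summaries.items():
        for src in ("place", "time"):
            for conf in ("high", "low"):
                vals = summ[f"{src}_{conf}"].dropna().to_numpy()
                if len(vals) < 2 or np.std(vals) == 0:
                    continue
                res = one_sample_t(vals, 0.5)
                above.append(
                    {
                        "experiment": proto,
                        "source": src,
                        "confidence": conf,
                        "mean": res.mean,
                        "t": res.t,
                        "df": res.df,
                        "p": res.p,
                    }
                )
                n_tests += 1
    above_df = pd.DataFrame.from_records(above)
    if correct_above_chance and len(above_df):
        above_df["p"] = np.minimum(above_df["p"] * n_tests, 1.0)

    return {
        "anova_recognition": one_way(rec_groups, "recognition"),
        "tukey_recognition": tukey_hsd(rec_groups),
        "anova_rem_ratio": one_way(rem_groups, "rem_ratio"),
        "anova_source_cells": anova_cells,
        "above_chance": above_df,
    }


def run_source_stage(trials_by_protocol: Mapping[str, pd.DataFrame]) -> dict:
    """Complete source stage: summaries, logistic fits per protocol, ANOVAs."""
    summaries = {p: summarize_source(t) for p, t in trials_by_protocol.items()}
    fits = {}
    fits_interaction = {}
    for proto, trials in trials_by_protocol.items():
        design = build_design(trials)
        fits[proto] = fit_main_model(design)
        fits_interaction[proto] = fit_interaction_model(design)
    out = run_source_anovas(summaries)
    out["summaries"] = summaries
    out["fits"] = fits
    out["fits_interaction"] = fits_interaction
    return out
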