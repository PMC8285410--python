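"""Synthetic episodic-memory experiment generator.

Produces complete datasets for the three encoding protocols (VR, RW, SL)
with the statistical structure the downstream analyses assume, so that the
whole pipeline is testable without human data:

* an encoding schedule per participant — 60 object-events (plus place-only
  events) at jittered-uniform times spanning an encoding duration drawn
  from the protocol's envelope;
* source-retrieval trials — old/new recognition, Remember/Familiar status,
  and place/time 2AFC correctness + confidence generated from a latent
  source-strength model (strength drives confidence and accuracy; accurate
  *and* confident source retrieval raises the Remember log-odds, with a
  Gaussian subject random intercept);
* temporal-order trials — event pairs whose encoding distances span the
  protocol's range approximately log-uniformly, each with its own retrieval
  timestamp advancing through the session; reaction time increases linearly
  with the pair's true temporal similarity and accuracy decreases with it.

Every draw flows from a single seed through per-stage, per-participant
``SeedSequence`` substreams, so identical configs give byte-identical
tables.  The generator's latent truths (subject intercepts, latent
strengths, true slopes) are exported in a separate truth table used only by
recovery tests, never by the analysis stages.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from . import simple
from .types import (
    Condition,
    DegenerateDataError,
    GenerativeParams,
    SimulationConfig,
    expit,
)

log = logging.getLogger("epimem")


# ---------------------------------------------------------------------------
# encoding schedules


def _jittered_times(n: int, span: float, rng: np.random.Generator, phase: float = 0.0) -> np.ndarray:
    """Strictly increasing times covering [0, span] (or interior, phase>0).

    Equal spacing plus uniform jitter of at most 40% of a step keeps the
    ordering strict while avoiding a perfectly regular grid.
    """
    if phase == 0.0:
        base = np.linspace(0.0, span, n)
        t = base.copy()
        if n > 2:
            step = span / (n - 1)
            t[1:-1] += rng.uniform(-0.4, 0.4, n - 2) * step
    else:
        step = span / n
        base = (np.arange(n) + phase) * step
        t = base + rng.uniform(-0.4, 0.4, n) * step
        t = np.clip(t, 1e-9, span - 1e-9)
        t.sort()
    return t


def generate_encoding_schedule(config: SimulationConfig, rng: Optional[np.random.Generator] = None):
    """Per-participant encoding events for one protocol.

    Returns ``(schedule, sessions)``: the event table (participant_id,
    event_id, encode_time, place_id, has_object) and a per-participant
    table with the drawn encoding span and the retrieval-session start time
    (span + retention draw).  Times are seconds from each participant's
    first object-event.
    """
    if config.n_objects < 2:
        raise DegenerateDataError("order task undefined with fewer than 2 objects")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    lo, hi = config.encoding_span
    rlo, rhi = config.retention
    recs = []
    sess = []
    for p in range(config.n_participants):
        pid = f"{config.protocol}{p:02d}"
        span = rng.uniform(lo, hi)
        obj_t = _jittered_times(config.n_objects, span, rng)
        for i, t in enumerate(obj_t):
            recs.append((pid, f"O{i:03d}", float(t), f"{pid}_PL{i:03d}", True))
        if config.n_place_only:
            noe_t = _jittered_times(config.n_place_only, span, rng, phase=0.5)
            for i, t in enumerate(noe_t):
                recs.append((pid, f"N{i:03d}", float(t), f"{pid}_PN{i:03d}", False))
        # retention spans orders of magnitude for RW: draw log-uniformly
        # there, uniformly for the narrow VR/SL windows
        if rhi / rlo > 10.0:
            retention = float(np.exp(rng.uniform(np.log(rlo), np.log(rhi))))
        else:
            retention = float(rng.uniform(rlo, rhi))
        sess.append((pid, float(span), retention, float(span + retention)))
    schedule = pd.DataFrame(recs, columns=["participant_id", "event_id", "encode_time", "place_id", "has_object"])
    sessions = pd.DataFrame(sess, columns=["participant_id", "encoding_span", "retention", "retrieval_start"])
    return schedule, sessions


# ---------------------------------------------------------------------------
# source-retrieval trials


def generate_source_trials(
    schedule: pd.DataFrame,
    params: GenerativeParams,
    retrieval_time,
    rng: np.random.Generator,
    p_recognize_old: float,
    n_new_foils: int = 30,
):
    """Source-retrieval trials (recognition + place/time 2AFC + confidence).

    ``retrieval_time`` may be a scalar or a per-participant mapping; it must
    be later than every encoding time.  Returns ``(trials, truth)`` where
    ``truth`` holds the latent subject intercepts and source strengths.
    """
    trials = []
    truth = []
    obj = schedule[schedule["has_object"].astype(bool)]
    for pid, ev in obj.groupby("participant_id", sort=True):
        rt_time = retrieval_time[pid] if hasattr(retrieval_time, "__getitem__") and not np.isscalar(retrieval_time) else retrieval_time
        if float(rt_time) <= float(ev["encode_time"].max()):
            raise DegenerateDataError(f"retrieval_time must be later than all encodings ({pid})")
        u = rng.normal(0.0, params.sigma_u)
        truth.append({"participant_id": pid, "kind": "subject_intercept", "event_id": "", "value": u})
        n_old = len(ev)
        recognized = rng.random(n_old) < p_recognize_old
        s_place = rng.lognormal(0.0, 1.0, n_old)
        s_time = rng.lognormal(0.0, 1.0, n_old)
        p_hc = s_place > params.theta_conf
        t_hc = s_time > params.theta_conf
        p_corr = rng.random(n_old) < expit(params.a0 + params.a1 * s_place)
        t_corr = rng.random(n_old) < expit(params.a0 + params.a1 * s_time)
        rem_logit = (
            params.gamma0
            + params.gamma_place * (p_corr & p_hc)
            + params.gamma_time * (t_corr & t_hc)
            + u
        )
        rem = rng.random(n_old) < expit(rem_logit)
        for i, (_, row) in enumerate(ev.iterrows()):
            if not recognized[i]:
                trials.append((pid, row["event_id"], True, "New", pd.NA, pd.NA, pd.NA, pd.NA))
                continue
            resp = "Rem" if rem[i] else "Fam"
            trials.append(
                (
                    pid,
                    row["event_id"],
                    True,
                    resp,
                    bool(p_corr[i]),
                    "high" if p_hc[i] else "low",
                    bool(t_corr[i]),
                    "high" if t_hc[i] else "low",
                )
            )
            truth.append({"participant_id": pid, "kind": "s_place", "event_id": row["event_id"], "value": s_place[i]})
            truth.append({"participant_id": pid, "kind": "s_time", "event_id": row["event_id"], "value": s_time[i]})
        fa = rng.random(n_new_foils) < params.p_false_alarm
        fa_rem = rng.random(n_new_foils) < params.p_rem_false_alarm
        for j in range(n_new_foils):
            resp = ("Rem" if fa_rem[j] else "Fam") if fa[j] else "New"
            trials.append((pid, f"F{j:03d}", False, resp, pd.NA, pd.NA, pd.NA, pd.NA))
    cols = ["participant_id", "event_id", "is_old", "object_response", "place_correct", "place_conf", "time_correct", "time_conf"]
    return pd.DataFrame(trials, columns=cols), pd.DataFrame(truth)


def generate_design_rows(
    n_subjects: int,
    n_trials: int,
    params: GenerativeParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Directly simulate logistic design rows (the recovery-study path).

    Applies the latent source-strength rules of :func:`generate_source_trials`
    to every trial (as if all old objects were recognized), returning the
    coded design (y, place, time, p_cf, t_cf, participant_id).  The true
    coefficients are ``params.gamma0/gamma_place/gamma_time`` on the
    intercept, p_cf and t_cf columns, and 0 on place and time.
    """
    n = n_subjects * n_trials
    pid = np.repeat([f"S{i:02d}" for i in range(n_subjects)], n_trials)
    u = np.repeat(rng.normal(0.0, params.sigma_u, n_subjects), n_trials)
    s_place = rng.lognormal(0.0, 1.0, n)
    s_time = rng.lognormal(0.0, 1.0, n)
    p_corr = rng.random(n) < expit(params.a0 + params.a1 * s_place)
    t_corr = rng.random(n) < expit(params.a0 + params.a1 * s_time)
    p_cf = p_corr & (s_place > params.theta_conf)
    t_cf = t_corr & (s_time > params.theta_conf)
    eta = params.gamma0 + params.gamma_place * p_cf + params.gamma_time * t_cf + u
    y = rng.random(n) < expit(eta)
    return pd.DataFrame(
        {
            "participant_id": pid,
            "y": y.astype(int),
            "place": p_corr.astype(int),
            "time": t_corr.astype(int),
            "p_cf": p_cf.astype(int),
            "t_cf": t_cf.astype(int),
        }
    )


# ---------------------------------------------------------------------------
# temporal-order trials


def _log_uniform_pairs(
    times: np.ndarray, n_pairs: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Sample event-index pairs whose encoding distances are roughly
    log-uniform over the attainable range."""
    n = len(times)
    if n < 2:
        raise DegenerateDataError("need at least 2 events to form order pairs")
    span = times[-1] - times[0]
    gaps = np.diff(np.sort(times))
    d_lo = max(float(np.min(gaps[gaps > 0])), span * 1e-4)
    d_hi = span * 0.95
    pairs = []
    for _ in range(n_pairs):
        d = float(np.exp(rng.uniform(np.log(d_lo), np.log(d_hi))))
        i = int(rng.integers(n))
        target = times[i] + d if rng.random() < 0.5 else times[i] - d
        j = int(np.argmin(np.abs(times - target)))
        if j == i:
            j = i + 1 if i + 1 < n else i - 1
        a, b = (i, j) if times[i] < times[j] else (j, i)
        pairs.append((a, b))
    return pairs


def generate_order_trials(
    schedule: pd.DataFrame,
    params: GenerativeParams,
    sessions: pd.DataFrame,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    calibration_scope: str = "per_participant_per_block",
):
    """Temporal-order judgment trials for all three cue conditions.

    Object-event pairs serve both the ``TOobj`` and ``ev_TOloc`` conditions
    (the place cues of ``ev_TOloc`` reference the very events probed with
    object cues, so matched pairs share their encoding distance); place-only
    events feed ``noe_TOloc``.  The session presents the object block first,
    then the intermixed place block, one trial every
    ``config.order_trial_spacing`` seconds, so each trial carries its own
    retrieval timestamp.  RT and correctness are drawn from the generative
    rules using the trial's true temporal similarity under
    ``calibration_scope``.

    Returns ``(trials, truth)``; truth records the per-condition true RT
    slope and intercept.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n_trials = config.n_order_trials
    spacing = config.order_trial_spacing
    sess = sessions.set_index("participant_id")
    frames = []
    for pid, ev in schedule.groupby("participant_id", sort=True):
        obj = ev[ev["has_object"].astype(bool)].sort_values("encode_time")
        noe = ev[~ev["has_object"].astype(bool)].sort_values("encode_time")
        if len(noe) < 2:
            raise DegenerateDataError(
                f"noe_TOloc undefined: participant {pid} has fewer than 2 no-object events"
            )
        t_obj = obj["encode_time"].to_numpy(float)
        t_noe = noe["encode_time"].to_numpy(float)
        id_obj = obj["event_id"].to_numpy()
        id_noe = noe["event_id"].to_numpy()
        start = float(sess.loc[pid, "retrieval_start"])

        obj_pairs = _log_uniform_pairs(t_obj, n_trials, rng)
        noe_pairs = _log_uniform_pairs(t_noe, n_trials, rng)
        ev_pairs = list(obj_pairs)
        rng.shuffle(ev_pairs)

        rows = []
        # block 1: object cues
        for (a, b) in obj_pairs:
            rows.append((Condition.TOobj.value, id_obj[a], id_obj[b], t_obj[a], t_obj[b]))
        # block 2: place cues, ev/noe intermixed
        loc_rows = [
            (Condition.ev_TOloc.value, id_obj[a], id_obj[b], t_obj[a], t_obj[b])
            for (a, b) in ev_pairs
        ] + [
            (Condition.noe_TOloc.value, id_noe[a], id_noe[b], t_noe[a], t_noe[b])
            for (a, b) in noe_pairs
        ]
        order = rng.permutation(len(loc_rows))
        rows.extend(loc_rows[i] for i in order)

        df = pd.DataFrame(rows, columns=["condition", "event_a", "event_b", "encode_a", "encode_b"])
        df.insert(0, "participant_id", pid)
        df["retrieval_time"] = start + spacing * np.arange(len(df))
        frames.append(df)

    trials = pd.concat(frames, ignore_index=True)
    scored, _ = simple.score_order_trials(trials, scope=calibration_scope)
    ts = scored["ts"].to_numpy(float)
    slope = np.array([params.rt_slope(c) for c in scored["condition"]])
    rt = params.rt_intercept + slope * ts + rng.normal(0.0, params.sigma_rt, len(scored))
    scored["rt"] = np.maximum(rt, params.rt_min)
    p_correct = expit(params.acc_d0 + params.acc_d1 * (1.0 - ts))
    scored["correct"] = rng.random(len(scored)) < p_correct
    truth = pd.DataFrame(
        {
            "condition": [c.value for c in Condition],
            "rt_slope": [params.rt_slope(c.value) for c in Condition],
            "rt_intercept": params.rt_intercept,
            "sigma_rt": params.sigma_rt,
            "acc_d0": params.acc_d0,
            "acc_d1": params.acc_d1,
        }
    )
    return scored, truth


# ---------------------------------------------------------------------------
# orchestration


def simulate_protocol(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Full synthetic dataset for one protocol.

    Returns a dict of tables: ``encoding``, ``sessions``, ``source``,
    ``order``, ``truth_source``, ``truth_order``.  Deterministic in
    ``config`` (including the seed).
    """
    proto_stream = {"VR": 11, "RW": 12, "SL": 13}[config.protocol]
    ss = np.random.SeedSequence([int(config.seed), proto_stream])
    r_enc, r_src, r_ord = (np.random.default_rng(s) for s in ss.spawn(3))
    schedule, sessions = generate_encoding_schedule(config, r_enc)
    retrieval = dict(zip(sessions["participant_id"], sessions["retrieval_start"]))
    source, truth_src = generate_source_trials(
        schedule,
        config.params,
        retrieval,
        r_src,
        p_recognize_old=config.p_recognize_old,
        n_new_foils=config.n_new_foils,
    )
    order, truth_ord = generate_order_trials(schedule, config.params, sessions, config, r_ord)
    log.info(
        "simulated %s: %d encoding events, %d source trials, %d order trials",
        config.protocol,
        len(schedule),
        len(source),
        len(order),
    )
    return {
        "encoding": schedule,
        "sessions": sessions,
        "source": source,
        "order": order,
        "truth_source": truth_src,
        "truth_order": truth_ord,
    }


def simulate_study(
    seed: int = 0, overrides: Optional[dict] = None
) -> dict[str, dict[str, pd.DataFrame]]:
    """Simulate all three protocols with per-protocol seed substreams.

    ``overrides`` maps :class:`SimulationConfig` / generative-parameter
    field names to values applied to every protocol.
    """
    out = {}
    for proto in ("VR", "RW", "SL"):
        kwargs = dict(overrides or {})
        params_kw = {}
        cfg_kw = {}
        for k, v in kwargs.items():
            if k in GenerativeParams.__dataclass_fields__:
                params_kw[k] = v
            else:
                cfg_kw[k] = v
        config = SimulationConfig(
            protocol=proto, seed=int(seed), params=GenerativeParams(**params_kw), **cfg_kw
        )
        out[proto] = simulate_protocol(config)
        out[proto]["config"] = config
    return out
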