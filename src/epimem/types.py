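"""Shared data model for the episodic-memory analysis pipeline.

The study design simulated and analysed here tests memory for object-events
("what") together with their spatial ("where") and temporal ("when") context,
after encoding under three protocols that differ enormously in temporal
scale:

* ``VR``  — virtual-reality town exploration, encoding span ~42 min,
  retention ~1 day;
* ``RW``  — real-world encoding via mobile phone over 3–17 days,
  retention hours to ~13 days;
* ``SL``  — standard laboratory trial sequence, encoding ~15 min,
  retention ~18 min.

All timestamps are real-valued seconds from a per-participant experiment
origin (the first encoding event).  Day:hour:minute:second presentation is
an I/O concern only; internal arithmetic is uniform across protocols.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# errors


class SchemaError(ValueError):
    """A trial table or config file does not match the documented schema."""


class InvariantViolation(ValueError):
    """Rows violate a record invariant; message carries the row numbers."""


class SeparationError(RuntimeError):
    """Logistic outcome is constant or perfectly separated."""


class DegenerateDataError(ValueError):
    """Input is degenerate for the requested computation (e.g. constant x)."""


# ---------------------------------------------------------------------------
# enumerations


class Protocol(str, enum.Enum):
    """Encoding protocol: virtual reality, real world, standard laboratory."""

    VR = "VR"
    RW = "RW"
    SL = "SL"


class Condition(str, enum.Enum):
    """Temporal-order retrieval cue condition.

    ``TOobj``: cue is the pair of encoded objects; ``ev_TOloc``: cue is the
    pair of places where object-events occurred; ``noe_TOloc``: cue is a pair
    of visited/seen places with no object-event.
    """

    TOobj = "TOobj"
    ev_TOloc = "ev_TOloc"
    noe_TOloc = "noe_TOloc"


CONDITIONS = [c.value for c in Condition]
PROTOCOLS = [p.value for p in Protocol]


def _dhms(days: int, hours: int, minutes: int, seconds: int) -> float:
    return ((days * 24 + hours) * 60 + minutes) * 60 + float(seconds)


#: Per-protocol spatio-temporal envelopes, in seconds.  Encoding span is the
#: time between the first and last object-event; retention is the time
#: between the last encoding event and the start of the retrieval session.
#: VR and SL envelopes follow the observed study ranges; the RW encoding
#: span covers the protocol's designed 3-17 day window.
PROTOCOL_ENVELOPES: dict[str, dict[str, tuple[float, float]]] = {
    "VR": {
        "encoding_span": (_dhms(0, 0, 42, 24), _dhms(0, 0, 42, 38)),
        "retention": (_dhms(0, 22, 2, 6), _dhms(1, 5, 51, 50)),
    },
    "RW": {
        "encoding_span": (_dhms(3, 0, 0, 0), _dhms(17, 0, 0, 0)),
        "retention": (_dhms(0, 2, 13, 4), _dhms(12, 16, 8, 30)),
    },
    "SL": {
        "encoding_span": (_dhms(0, 0, 14, 14), _dhms(0, 0, 15, 8)),
        "retention": (_dhms(0, 0, 11, 31), _dhms(0, 0, 23, 8)),
    },
}

#: Default probability of recognising an old object, per protocol.  The
#: ordering (RW lowest, SL highest) mirrors the qualitative between-protocol
#: differences in old/new recognition that the one-way recognition ANOVA and
#: its post-hoc contrasts are meant to pick up.
DEFAULT_P_RECOGNIZE: dict[str, float] = {"VR": 0.80, "RW": 0.70, "SL": 0.85}


# ---------------------------------------------------------------------------
# generative parameters


@dataclass
class GenerativeParams:
    """Parameters of the synthetic behavioural model.

    Source-memory arm: each recognised old object draws latent source
    strengths ``s_place, s_time ~ LogNormal(0, 1)``.  Confidence is high iff
    ``s > theta_conf``; 2AFC source accuracy is ``logistic(a0 + a1*s)``; the
    Remember (vs Familiar) report follows
    ``logit P(Rem) = gamma0 + gamma_place*1[place correct & confident]
    + gamma_time*1[time correct & confident] + u_subject`` with
    ``u_subject ~ N(0, sigma_u^2)``.

    Order arm: reaction time ``rt = rt_intercept + beta * TS + eps`` with
    ``eps ~ N(0, sigma_rt^2)``, truncated below at ``rt_min``; the slope
    ``beta`` is ``rt_slope_obj`` for object cues and ``rt_slope_loc`` for
    place cues.  Correctness follows
    ``P(correct) = logistic(acc_d0 + acc_d1*(1 - TS))``.
    """

    p_recognize_old: Optional[float] = None  # None -> protocol default
    p_false_alarm: float = 0.15
    p_rem_false_alarm: float = 0.3
    theta_conf: float = 1.0
    a0: float = -0.235
    a1: float = 0.603
    gamma0: float = -0.5
    gamma_place: float = 1.2
    gamma_time: float = 0.8
    sigma_u: float = 0.5
    rt_intercept: float = 1800.0
    rt_slope_obj: float = 900.0
    rt_slope_loc: float = 450.0
    sigma_rt: float = 300.0
    rt_min: float = 200.0
    acc_d0: float = 0.0
    acc_d1: float = 2.0

    def validate(self) -> None:
        for name in ("p_false_alarm", "p_rem_false_alarm"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise SchemaError(f"{name} must lie in (0, 1); got {v}")
        if self.p_recognize_old is not None and not 0.0 < self.p_recognize_old < 1.0:
            raise SchemaError(
                f"p_recognize_old must lie in (0, 1); got {self.p_recognize_old}"
            )
        if self.sigma_u < 0 or self.sigma_rt < 0:
            raise SchemaError("sigma_u and sigma_rt must be non-negative")
        if self.rt_min <= 0:
            raise SchemaError("rt_min must be positive")

    def rt_slope(self, condition: str) -> float:
        return self.rt_slope_obj if condition == Condition.TOobj.value else self.rt_slope_loc


@dataclass
class SimulationConfig:
    """Protocol envelope plus generative parameters and the RNG seed.

    The defaults (20 participants, 60 encoded objects per participant) are
    the study's per-protocol sample sizes; foil and order-trial counts were
    never reported and remain free parameters.
    """

    protocol: str = "VR"
    n_participants: int = 20
    n_objects: int = 60
    n_new_foils: int = 30
    n_place_only: int = 60
    n_order_trials: int = 40
    order_trial_spacing: float = 10.0  # s between successive retrieval trials
    encoding_span: Optional[tuple[float, float]] = None  # (min, max) s
    retention: Optional[tuple[float, float]] = None  # (min, max) s
    params: GenerativeParams = field(default_factory=GenerativeParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.protocol, Protocol):
            self.protocol = self.protocol.value
        if self.protocol not in PROTOCOLS:
            raise SchemaError(f"unknown protocol {self.protocol!r}; expected one of {PROTOCOLS}")
        env = PROTOCOL_ENVELOPES[self.protocol]
        if self.encoding_span is None:
            self.encoding_span = env["encoding_span"]
        if self.retention is None:
            self.retention = env["retention"]
        self.encoding_span = (float(self.encoding_span[0]), float(self.encoding_span[1]))
        self.retention = (float(self.retention[0]), float(self.retention[1]))
        self.validate()

    def validate(self) -> None:
        if self.n_objects < 2:
            raise SchemaError("n_objects must be >= 2 (order task undefined otherwise)")
        if self.n_participants < 1:
            raise SchemaError("n_participants must be >= 1")
        if self.n_new_foils < 0 or self.n_place_only < 0:
            raise SchemaError("counts must be non-negative")
        if self.n_order_trials < 2:
            raise SchemaError("n_order_trials must be >= 2")
        for name in ("encoding_span", "retention"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi <= 0:
                raise SchemaError(f"{name} bounds must be positive; got ({lo}, {hi})")
            if hi < lo:
                raise SchemaError(f"{name} max must be >= min")
        if self.order_trial_spacing <= 0:
            raise SchemaError("order_trial_spacing must be positive")
        self.params.validate()

    @property
    def p_recognize_old(self) -> float:
        if self.params.p_recognize_old is not None:
            return self.params.p_recognize_old
        return DEFAULT_P_RECOGNIZE[self.protocol]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["encoding_span"] = list(self.encoding_span)
        d["retention"] = list(self.retention)
        return d


# ---------------------------------------------------------------------------
# result containers


@dataclass
class SimilarityCalibration:
    """Power constant c for the temporal-similarity score.

    ``c = 1 / (ln(delay_max) - ln(delay_min))`` — the inverse of the range of
    the log-transformed retention delays of the calibration set.  ``scope``
    records the delay set used (e.g. participant x task block).
    """

    c: float
    delay_min: float
    delay_max: float
    scope: str = ""

    def __post_init__(self) -> None:
        if self.delay_min <= 0 or self.delay_max <= self.delay_min:
            raise DegenerateDataError(
                f"calibration requires 0 < delay_min < delay_max; "
                f"got ({self.delay_min}, {self.delay_max}) for scope {self.scope!r}"
            )


@dataclass
class LogisticFit:
    """Random-intercept binomial logistic fit (logit scale).

    ``ci_low/ci_high`` are Wald 95% intervals (estimate +/- 1.96 SE);
    ``sigma_u`` is the fitted standard deviation of the subject random
    intercept.
    """

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    sigma_u: float
    loglik: float
    converged: bool
    n_obs: int
    n_subjects: int
    diagnostic: str = ""
    dropped: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.names,
                "estimate": self.coef,
                "se": self.se,
                "z": self.z,
                "p": self.p,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )

    def __getitem__(self, name: str) -> float:
        return float(self.coef[self.names.index(name)])


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    mean: float
    n: int


@dataclass
class BayesFactorResult:
    """JZS Bayes factor.  ``bf10`` is evidence for the effect model over the
    null; ``bf01 = 1/bf10``."""

    bf10: float
    prior: str
    design: str

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


@dataclass
class AnovaTable:
    """ANOVA effects table with a design descriptor.

    ``table`` columns: effect, F, df_num, df_den, p, ss_effect, ss_error.
    """

    table: pd.DataFrame
    design: str = ""

    def effect(self, name: str) -> pd.Series:
        rows = self.table[self.table["effect"] == name]
        if rows.empty:
            raise KeyError(f"no effect named {name!r}; have {list(self.table['effect'])}")
        return rows.iloc[0]

    def p(self, name: str) -> float:
        return float(self.effect(name)["p"])

    def F(self, name: str) -> float:
        return float(self.effect(name)["F"])


def expit(x):
    """Numerically safe logistic function."""
    return 0.5 * (1.0 + np.tanh(np.asarray(x, dtype=float) / 2.0))


def dhms_to_seconds(text: str) -> float:
    """Parse a ``DAYS:HOURS:MINUTES:SECONDS`` string into seconds."""
    parts = text.split(":")
    if len(parts) != 4:
        raise SchemaError(f"expected D:H:M:S, got {text!r}")
    d, h, m, s = (float(p) for p in parts)
    return ((d * 24 + h) * 60 + m) * 60 + s


def seconds_to_dhms(seconds: float) -> str:
    """Format seconds as ``DAYS:HOURS:MINUTES:SECONDS`` (integer seconds)."""
    total = int(round(seconds))
    d, rem = divmod(total, 86400)
    h, rem = divmod(rem, 3600)
    m, s = divmod(rem, 60)
    return f"{d:02d}:{h:02d}:{m:02d}:{s:02d}"
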