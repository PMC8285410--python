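"""Trial-table and configuration I/O.

Tables are comma-separated UTF-8 text with a mandatory header row and "."
as decimal separator.  Every file written by the pipeline starts with a
single ``#``-prefixed metadata line carrying the effective config hash and
seed, so a run is reproducible bit-for-bit from its outputs.  Missing or
skipped responses are empty fields and are excluded listwise per analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .types import (
    CONDITIONS,
    GenerativeParams,
    InvariantViolation,
    SchemaError,
    SimulationConfig,
)

log = logging.getLogger("epimem")

ENCODING_COLUMNS = ["participant_id", "event_id", "encode_time", "place_id", "has_object"]
SOURCE_COLUMNS = [
    "participant_id",
    "event_id",
    "is_old",
    "object_response",
    "place_correct",
    "place_conf",
    "time_correct",
    "time_conf",
]
ORDER_COLUMNS = [
    "participant_id",
    "condition",
    "event_a",
    "event_b",
    "encode_a",
    "encode_b",
    "retrieval_time",
    "t_a",
    "t_b",
    "ts",
    "rt",
    "correct",
]

_SCHEMAS = {"source": SOURCE_COLUMNS, "order": ORDER_COLUMNS, "encoding": ENCODING_COLUMNS}

_BOOL_MAP = {"True": True, "False": False, "true": True, "false": False, "1": True, "0": False}


def _parse_bool(series: pd.Series, col: str, required: bool) -> pd.Series:
    out = pd.Series(pd.NA, index=series.index, dtype="boolean")
    filled = series.notna() & (series.astype(str).str.strip() != "")
    vals = series[filled].astype(str).str.strip()
    bad = ~vals.isin(_BOOL_MAP)
    if bad.any():
        rows = list(vals.index[bad][:10])
        raise SchemaError(f"column {col!r}: non-boolean values at rows {rows}")
    out[filled] = vals.map(_BOOL_MAP).astype("boolean")
    if required and (~filled).any():
        rows = list(series.index[~filled][:10])
        raise SchemaError(f"column {col!r}: missing required values at rows {rows}")
    return out


def _parse_float(series: pd.Series, col: str, required: bool = True) -> pd.Series:
    # round-trip exactness matters (files are re-read bit-for-bit), so parse
    # through Python's correctly rounded float() rather than pandas' parser
    out = np.full(len(series), np.nan)
    bad_rows = []
    for i, (idx, v) in enumerate(zip(series.index, series)):
        if v is pd.NA or v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        s = str(v).strip()
        if s == "":
            continue
        try:
            out[i] = float(s)
        except ValueError:
            bad_rows.append(idx)
    if bad_rows:
        raise SchemaError(f"column {col!r}: non-numeric values at rows {bad_rows[:10]}")
    if required and np.isnan(out).any():
        rows = list(series.index[np.isnan(out)][:10])
        raise SchemaError(f"column {col!r}: missing required values at rows {rows}")
    return pd.Series(out, index=series.index)


def validate_source(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a source-trial table; raises on invariant violations.

    Source fields (place/time correctness and confidence) must be present
    iff the trial is an old object answered Rem or Fam — the source 2AFC
    questions are only asked after a correct old recognition.
    """
    df = df.copy()
    df["is_old"] = _parse_bool(df["is_old"], "is_old", required=True)
    resp = df["object_response"].astype(str).str.strip()
    bad = ~resp.isin(["Rem", "Fam", "New"])
    if bad.any():
        raise SchemaError(
            f"object_response must be Rem/Fam/New; bad rows {list(df.index[bad][:10])}"
        )
    df["object_response"] = resp
    for col in ("place_correct", "time_correct"):
        df[col] = _parse_bool(df[col], col, required=False)
    for col in ("place_conf", "time_conf"):
        vals = df[col].where(df[col].notna() & (df[col].astype(str).str.strip() != ""), pd.NA)
        known = vals.isna() | vals.astype(str).isin(["high", "low"])
        if not known.all():
            raise SchemaError(
                f"column {col!r}: values must be high/low; bad rows "
                f"{list(df.index[~known][:10])}"
            )
        df[col] = vals
    eligible = df["is_old"].fillna(False).astype(bool) & df["object_response"].isin(["Rem", "Fam"])
    has_source = df[["place_correct", "place_conf", "time_correct", "time_conf"]].notna().any(axis=1)
    complete_source = df[["place_correct", "place_conf", "time_correct", "time_conf"]].notna().all(axis=1)
    bad_rows = df.index[(~eligible & has_source) | (eligible & ~complete_source)]
    if len(bad_rows):
        raise InvariantViolation(
            "source fields must be present iff is_old and response is Rem/Fam; "
            f"violating rows {list(bad_rows[:20])}"
        )
    return df


def validate_order(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an order-trial table (delays positive, TS in (0,1], RT > 0)."""
    df = df.copy()
    cond = df["condition"].astype(str).str.strip()
    bad = ~cond.isin(CONDITIONS)
    if bad.any():
        raise SchemaError(
            f"condition must be one of {CONDITIONS}; bad rows {list(df.index[bad][:10])}"
        )
    df["condition"] = cond
    for col in ("encode_a", "encode_b", "retrieval_time", "t_a", "t_b", "rt"):
        df[col] = _parse_float(df[col], col)
    df["ts"] = _parse_float(df["ts"], "ts", required=False)
    df["correct"] = _parse_bool(df["correct"], "correct", required=True)
    bad_rows = df.index[(df["t_a"] <= 0) | (df["t_b"] <= 0)]
    if len(bad_rows):
        raise InvariantViolation(f"retention delays must be positive; rows {list(bad_rows[:20])}")
    ts = df["ts"]
    bad_rows = df.index[ts.notna() & ((ts <= 0) | (ts > 1 + 1e-12))]
    if len(bad_rows):
        raise InvariantViolation(f"ts must lie in (0, 1]; rows {list(bad_rows[:20])}")
    bad_rows = df.index[df["rt"] <= 0]
    if len(bad_rows):
        raise InvariantViolation(f"rt must be positive; rows {list(bad_rows[:20])}")
    return df


def validate_encoding(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["encode_time"] = _parse_float(df["encode_time"], "encode_time")
    df["has_object"] = _parse_bool(df["has_object"], "has_object", required=True)
    bad_rows = df.index[df["encode_time"] < 0]
    if len(bad_rows):
        raise InvariantViolation(f"encode_time must be >= 0; rows {list(bad_rows[:20])}")
    dup = df.duplicated(subset=["participant_id", "event_id"])
    if dup.any():
        raise InvariantViolation(
            f"event_id must be unique within participant; rows {list(df.index[dup][:20])}"
        )
    return df


_VALIDATORS = {"source": validate_source, "order": validate_order, "encoding": validate_encoding}


def read_trials(path: str | Path, kind: str) -> pd.DataFrame:
    """Read and validate a trial table.

    ``kind`` selects the schema: ``source``, ``order`` or ``encoding``.
    Raises :class:`SchemaError` for missing columns or unparsable values
    (with row numbers) and :class:`InvariantViolation` for rows that parse
    but break a record invariant.
    """
    if kind not in _SCHEMAS:
        raise ValueError(f"kind must be one of {sorted(_SCHEMAS)}; got {kind!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    df = df.replace("", pd.NA)
    missing = [c for c in _SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    df = df[_SCHEMAS[kind]]
    out = _VALIDATORS[kind](df)
    log.info("read %d %s rows from %s", len(out), kind, path)
    return out


def _format_value(v) -> str:
    if v is pd.NA or v is None or (isinstance(v, float) and np.isnan(v)):
        return ""
    if isinstance(v, (bool, np.bool_)):
        return "True" if v else "False"
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    return str(v)


def write_trials(
    df: pd.DataFrame,
    path: str | Path,
    kind: str,
    meta: Optional[dict] = None,
) -> Path:
    """Write a validated trial table with a deterministic column order.

    The first line is a ``#`` metadata comment (config hash, seed, any extra
    keys in ``meta``); ``read_trials`` skips it.  A write→read→write cycle
    is byte-identical.
    """
    if kind not in _SCHEMAS:
        raise ValueError(f"kind must be one of {sorted(_SCHEMAS)}; got {kind!r}")
    cols = _SCHEMAS[kind]
    df = _VALIDATORS[kind](df.reindex(columns=cols))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = dict(meta or {})
    header = "# " + " ".join(f"{k}={v}" for k, v in sorted(meta.items())) if meta else "#"
    lines = [header, ",".join(cols)]
    for _, row in df.iterrows():
        lines.append(",".join(_format_value(row[c]) for c in cols))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    log.info("wrote %d %s rows to %s", len(df), kind, path)
    return path


# ---------------------------------------------------------------------------
# configuration


def config_hash(config: SimulationConfig) -> str:
    """Short stable hash of the effective configuration."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


_CONFIG_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)}
_PARAM_KEYS = {f.name for f in dataclasses.fields(GenerativeParams)}


def config_from_dict(raw: dict, source: str = "<dict>") -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a flat or nested mapping.

    Generative parameters may be given either nested under ``params`` or as
    top-level keys.  Unknown keys are an error (listed in the message); the
    full effective config is echoed to the log.
    """
    raw = dict(raw)
    path = source
    params_raw = dict(raw.pop("params", {}))
    unknown = [k for k in raw if k not in _CONFIG_KEYS and k not in _PARAM_KEYS]
    unknown += [k for k in params_raw if k not in _PARAM_KEYS]
    if unknown:
        raise SchemaError(f"{path}: unknown config keys {sorted(set(unknown))}")
    for k in list(raw):
        if k in _PARAM_KEYS and k not in _CONFIG_KEYS:
            params_raw[k] = raw.pop(k)
    cfg_kwargs = dict(raw)
    for key in ("encoding_span", "retention"):
        if key in cfg_kwargs and cfg_kwargs[key] is not None:
            cfg_kwargs[key] = tuple(cfg_kwargs[key])
    config = SimulationConfig(params=GenerativeParams(**params_raw), **cfg_kwargs)
    log.info("effective config (%s): %s", config_hash(config), json.dumps(config.to_dict()))
    return config


def load_config(path: str | Path) -> SimulationConfig:
    """Load a JSON configuration file; defaults fill omitted fields."""
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config must be a JSON object")
    return config_from_dict(raw, source=str(path))


def setup_logging(logfile: Optional[str | Path] = None, level: str = "INFO") -> None:
    """Plain-text run log with timestamps."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        Path(logfile).parent.mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
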