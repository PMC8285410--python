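"""Balanced mixed-design (split-plot) ANOVA, Tukey HSD and one-sample t.

The ANOVA engine handles one between-subject factor plus up to two
within-subject factors (or purely between / purely within one-way designs),
with subjects nested in the between factor.  Sums of squares are computed
by the classical balanced decomposition: for any margin ``F`` the
"uncorrected" sum of squares is ``U(F) = sum over cells of
(cell total)^2 / cell size``, and each effect and its subject-stratified
error term is an inclusion–exclusion combination of margins.  For balanced
data with sum-to-zero contrasts this equals the Type III decomposition.

Within-subject effects are tested against their own ``effect x
subject(group)`` error stratum; the between effect against
``subject(group)``.  Every subject must contribute exactly one observation
per within-cell; group sizes may differ (the design stays proportional, so
the decomposition is still orthogonal).  Incomplete designs raise — no
silent imputation or approximation.
"""

from __future__ import annotations

from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ..types import AnovaTable, DegenerateDataError, TTestResult

__all__ = ["mixed_anova", "tukey_hsd", "one_sample_t"]


def _uss(df: pd.DataFrame, dv: str, cols: Sequence[str]) -> float:
    """Uncorrected sum of squares for the margin defined by ``cols``."""
    if not cols:
        return float(df[dv].sum() ** 2 / len(df))
    g = df.groupby(list(cols), observed=True)[dv]
    return float((g.sum() ** 2 / g.count()).sum())


def _check_balance(df: pd.DataFrame, subject: str, between: Optional[str], within: list[str]):
    if within:
        cells = df.groupby([subject] + within, observed=True).size()
        if (cells != 1).any():
            raise DegenerateDataError(
                "design is unbalanced: every subject needs exactly one observation "
                "per within-cell combination"
            )
        per_subject = df.groupby(subject, observed=True).size()
        n_cells = int(np.prod([df[w].nunique() for w in within]))
        if (per_subject != n_cells).any():
            raise DegenerateDataError("design is incomplete: subjects missing within cells")
    if between is not None:
        gmap = df.groupby(subject, observed=True)[between].nunique()
        if (gmap != 1).any():
            raise DegenerateDataError("each subject must belong to exactly one between group")


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    between: Optional[str] = None,
    within: Optional[str | Sequence[str]] = None,
) -> AnovaTable:
    """Mixed-design ANOVA on a long-format table.

    Parameters
    ----------
    data : long-format DataFrame, one row per subject x within-cell.
    dv : dependent-variable column.
    subject : subject identifier column (nested in ``between`` if given).
    between : optional between-subject factor column.
    within : optional within-subject factor column(s), at most two.

    Returns an :class:`AnovaTable` with one row per testable effect (F,
    numerator/denominator df, p, sums of squares).
    """
    if within is None:
        within_list: list[str] = []
    elif isinstance(within, str):
        within_list = [within]
    else:
        within_list = list(within)
    if len(within_list) > 2:
        raise ValueError("at most two within-subject factors are supported")
    if between is None and not within_list:
        raise ValueError("need at least one factor")
    df = data.dropna(subset=[dv]).copy()
    _check_balance(df, subject, between, within_list)

    dv_vals = df[dv].to_numpy(float)
    N = len(df)
    U0 = float(dv_vals.sum() ** 2 / N)
    U_obs = float(np.sum(dv_vals**2))

    rows = []

    if between is not None and not within_list:
        # one-way between-subjects (one observation per subject)
        if (df.groupby(subject, observed=True).size() != 1).any():
            raise DegenerateDataError(
                "between-only design expects one observation per subject"
            )
        k = df[between].nunique()
        if k < 2:
            raise DegenerateDataError(f"between factor {between!r} needs >= 2 levels")
        ss_g = _uss(df, dv, [between]) - U0
        ss_e = U_obs - _uss(df, dv, [between])
        df_g, df_e = k - 1, N - k
        F = (ss_g / df_g) / (ss_e / df_e)
        rows.append((between, F, df_g, df_e, ss_g, ss_e))
        design = f"one-way between ({between}: {k} levels, N={N})"
        return _assemble(rows, design)

    subj = subject
    S_tot = df[subj].nunique()
    k = df[between].nunique() if between is not None else 1

    def U(*cols: str) -> float:
        return _uss(df, dv, [c for c in cols if c])

    b = between or ""
    U_G = U(b) if between else U0
    U_S = U(subj)
    df_subj_err = S_tot - k

    if between is not None:
        ss_g = U_G - U0
        ss_sg = U_S - U_G
        F = (ss_g / (k - 1)) / (ss_sg / df_subj_err)
        rows.append((between, F, k - 1, df_subj_err, ss_g, ss_sg))

    levels = {w: df[w].nunique() for w in within_list}

    for w in within_list:
        a = levels[w]
        ss_w = U(w) - U0
        U_WG = U(w, b) if between else U(w)
        U_WS = U(w, subj)
        ss_err = U_WS - U_WG - U_S + U_G
        df_err = (a - 1) * df_subj_err if between else (a - 1) * (S_tot - 1)
        if between is None:
            ss_err = U_WS - U(w) - U_S + U0
        F = (ss_w / (a - 1)) / (ss_err / df_err)
        rows.append((w, F, a - 1, df_err, ss_w, ss_err))
        if between is not None:
            ss_wg = U_WG - U(w) - U_G + U0
            df_wg = (a - 1) * (k - 1)
            F = (ss_wg / df_wg) / (ss_err / df_err)
            rows.append((f"{w}*{between}", F, df_wg, df_err, ss_wg, ss_err))

    if len(within_list) == 2:
        w1, w2 = within_list
        a, c = levels[w1], levels[w2]
        U_AB = U(w1, w2)
        ss_ab = U_AB - U(w1) - U(w2) + U0
        df_ab = (a - 1) * (c - 1)
        if between is not None:
            U_ABG = U(w1, w2, b)
            U_ABS = U(w1, w2, subj)
            ss_abg = U_ABG - U_AB - U(w1, b) - U(w2, b) + U(w1) + U(w2) + U_G - U0
            ss_err = (
                U_ABS - U_ABG - U(w1, subj) - U(w2, subj) + U(w1, b) + U(w2, b) + U_S - U_G
            )
            df_err = df_ab * df_subj_err
            rows.append((f"{w1}*{w2}", (ss_ab / df_ab) / (ss_err / df_err), df_ab, df_err, ss_ab, ss_err))
            df_abg = df_ab * (k - 1)
            rows.append(
                (
                    f"{w1}*{w2}*{between}",
                    (ss_abg / df_abg) / (ss_err / df_err),
                    df_abg,
                    df_err,
                    ss_abg,
                    ss_err,
                )
            )
        else:
            U_ABS = U(w1, w2, subj)
            ss_err = U_ABS - U_AB - U(w1, subj) - U(w2, subj) + U(w1) + U(w2) + U_S - U0
            df_err = df_ab * (S_tot - 1)
            rows.append((f"{w1}*{w2}", (ss_ab / df_ab) / (ss_err / df_err), df_ab, df_err, ss_ab, ss_err))

    parts = []
    if between:
        parts.append(f"between {between} ({k})")
    parts += [f"within {w} ({levels[w]})" for w in within_list]
    design = " x ".join(parts) + f"; {S_tot} subjects"
    return _assemble(rows, design)


def _assemble(rows, design: str) -> AnovaTable:
    recs = []
    for name, F, df1, df2, ss, ss_err in rows:
        if df1 <= 0 or df2 <= 0:
            continue
        F = max(float(F), 0.0)
        recs.append(
            {
                "effect": name,
                "F": F,
                "df_num": int(df1),
                "df_den": int(df2),
                "p": float(sps.f.sf(F, df1, df2)),
                "ss_effect": float(ss),
                "ss_error": float(ss_err),
            }
        )
    return AnovaTable(table=pd.DataFrame.from_records(recs), design=design)


def tukey_hsd(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """All-pairs Tukey HSD after a one-way between design.

    ``q = |mean_i - mean_j| / sqrt(MSE/2 * (1/n_i + 1/n_j))`` with the
    pooled within-group mean square; adjusted p from the studentized-range
    distribution with k groups and N-k error df (Tukey–Kramer for unequal
    group sizes).
    """
    names = list(groups)
    if len(names) < 2:
        raise DegenerateDataError("Tukey HSD needs at least 2 groups")
    arrays = {g: np.asarray(groups[g], dtype=float) for g in names}
    for g, arr in arrays.items():
        if arr.size < 2:
            raise DegenerateDataError(f"group {g!r} has fewer than 2 observations")
    k = len(names)
    N = sum(arr.size for arr in arrays.values())
    df_err = N - k
    mse = sum(np.sum((arr - arr.mean()) ** 2) for arr in arrays.values()) / df_err
    recs = []
    for g1, g2 in combinations(names, 2):
        a, bb = arrays[g1], arrays[g2]
        diff = a.mean() - bb.mean()
        se = np.sqrt(mse / 2.0 * (1.0 / a.size + 1.0 / bb.size))
        q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k, df_err))
        recs.append({"group_a": g1, "group_b": g2, "diff": diff, "q": q, "p_adj": min(max(p, 0.0), 1.0)})
    return pd.DataFrame.from_records(recs)


def one_sample_t(values, mu0: float = 0.0) -> TTestResult:
    """Two-sided one-sample t-test of the mean against ``mu0``."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise DegenerateDataError("one-sample t needs >= 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero variance")
    n = x.size
    t = (x.mean() - mu0) / (sd / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return TTestResult(t=float(t), df=n - 1, p=p, mean=float(x.mean()), n=n)
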