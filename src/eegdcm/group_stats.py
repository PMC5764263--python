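"""Group-level statistics on coupling parameters.

One-way ANOVA with directed edges as groups and subjects as observations,
paired two-sided t-tests between condition/response streams, and
Benjamini-Hochberg step-up FDR control.  Degenerate zero-variance cases get
documented conventions (p=1 for no signal, machine-minimum p for a nonzero
mean difference with zero spread) instead of exceptions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ExcludedEdgeError, InvalidDesignError, InvalidInputError


def one_way_anova(coupling_table: pd.DataFrame) -> dict:
    """Groups = edges (columns), observations = subject coupling values."""
    cols = list(coupling_table.columns)
    if len(cols) < 2:
        raise InvalidDesignError("ANOVA needs at least two edge groups")
    groups = [coupling_table[c].to_numpy(float) for c in cols]
    if any(len(g) < 2 for g in groups):
        raise InvalidDesignError("every group needs at least two observations")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return {"F_statistic": 0.0, "df_between": df_b, "df_within": df_w, "p": 1.0}
        return {
            "F_statistic": float("inf"),
            "df_between": df_b,
            "df_within": df_w,
            "p": float(np.finfo(float).tiny),
        }
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(scipy.stats.f.sf(F, df_b, df_w))
    return {"F_statistic": float(F), "df_between": df_b, "df_within": df_w, "p": p}


def paired_ttest(stream_a: pd.DataFrame, stream_b: pd.DataFrame, edge: str) -> dict:
    """Paired two-sided t-test on per-subject differences for one edge."""
    missing = [
        (name, e)
        for name, tbl in (("stream_a", stream_a), ("stream_b", stream_b))
        for e in [edge]
        if e not in tbl.columns
    ]
    if missing:
        raise ExcludedEdgeError(
            "edge missing from " + ", ".join(f"{n} ({e})" for n, e in missing)
        )
    a = stream_a[edge].to_numpy(float)
    b = stream_b[edge].to_numpy(float)
    if len(a) != len(b):
        raise InvalidInputError("paired test needs the same subjects in both streams")
    d = a - b
    n = len(d)
    if n < 2:
        raise InvalidDesignError("paired test needs at least two subjects")
    df = n - 1
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return {"t": 0.0, "df": df, "p": 1.0}
        t = float("inf") if d.mean() > 0 else float("-inf")
        return {"t": t, "df": df, "p": float(np.finfo(float).tiny)}
    t = d.mean() / (sd / np.sqrt(n))
    p = float(2 * scipy.stats.t.sf(abs(t), df))
    return {"t": float(t), "df": df, "p": max(p, float(np.finfo(float).tiny))}


def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: reject all p(i) with i <= max{i: p(i) <= i q / m}."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise InvalidInputError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresh = (np.arange(1, m + 1) / m) * q
    passing = np.nonzero(sorted_p <= thresh)[0]
    reject = np.zeros(m, dtype=bool)
    if passing.size:
        reject[order[: passing[-1] + 1]] = True
    return reject


def compare_streams(
    stream_a: pd.DataFrame,
    stream_b: pd.DataFrame,
    edges=None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-edge paired t-tests with BH correction, formatted as a report table."""
    if edges is None:
        edges = [c for c in stream_a.columns if c in stream_b.columns]
    rows = []
    for e in edges:
        res = paired_ttest(stream_a, stream_b, e)
        d = stream_a[e].to_numpy(float) - stream_b[e].to_numpy(float)
        rows.append((e, d.mean(), d.std(ddof=1), res["t"], res["df"], res["p"]))
    out = pd.DataFrame(
        rows, columns=["edge", "mean_diff", "sd_diff", "t", "df", "p_raw"]
    )
    out["significant_after_fdr"] = fdr_bh(out["p_raw"].to_numpy(), q)
    return out


def coupling_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) per edge, one row per directed edge."""
    rows = [
        (c, table[c].mean(), table[c].std(ddof=1)) for c in table.columns
    ]
    return pd.DataFrame(rows, columns=["edge", "mean", "sd"])
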