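"""Cross-scale statistics: observation alignment, correlations, yield ANOVA.

Per-plot/per-date observations from every sensing scale (RGB, multispectral,
thermal, bioristor, physiology) are aligned on (plot_id, DAT) with a
configurable date tolerance, pooled over treatments, and summarised as a
pairwise-complete Pearson correlation matrix.  Yield traits are compared
across irrigation treatments with a one-way ANOVA and all-pairs Tukey HSD
at alpha = 0.05, reported as a compact letter display (treatments sharing a
letter are not significantly different).

The Tukey HSD p-values are computed directly from the studentized range
distribution; the compact letter display uses the insert-and-absorb
algorithm.
"""

from __future__ import annotations

import json
import string
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "align_observations",
    "correlation_matrix",
    "CorrelationMatrix",
    "anova_tukey",
    "TukeyResult",
    "summary_stats",
    "build_report",
]

KEYS = ["plot_id", "dat"]


def _check_keys(name: str, df: pd.DataFrame) -> None:
    if not set(KEYS).issubset(df.columns):
        raise ValidationError(f"source {name!r} must have columns {KEYS}")
    if df.duplicated(KEYS).any():
        raise ValidationError(f"source {name!r} has duplicate (plot_id, dat) rows")


def align_observations(sources: dict[str, pd.DataFrame],
                       tolerance: int = 0) -> pd.DataFrame:
    """Outer-join observation tables on (plot_id, nearest DAT).

    ``sources`` maps a stage name to a table with ``plot_id``/``dat`` keys
    plus value columns.  A row of a later source joins an existing row when
    its DAT is the nearest within ``tolerance`` days; otherwise it opens a
    new row.  Unmatched cells stay missing.  Duplicate (plot, DAT) keys
    within a source, or a value column appearing in two sources, raise
    :class:`ValidationError`.
    """
    result: Optional[pd.DataFrame] = None
    seen_cols: set[str] = set()
    for name, df in sources.items():
        _check_keys(name, df)
        vals = [c for c in df.columns if c not in KEYS]
        dup = seen_cols.intersection(vals)
        if dup:
            raise ValidationError(f"variable(s) {sorted(dup)} supplied by two sources")
        seen_cols.update(vals)
        df = df.sort_values(KEYS, kind="stable").reset_index(drop=True)
        if result is None:
            result = df.copy()
            continue
        pieces = []
        for plot_id, left in result.groupby("plot_id", sort=True):
            right = df[df["plot_id"] == plot_id].drop(columns=["plot_id"])
            left = left.sort_values("dat")
            if right.empty:
                pieces.append(left)
                continue
            right = right.sort_values("dat")
            merged = pd.merge_asof(left, right, on="dat",
                                   direction="nearest", tolerance=tolerance)
            # any right row not claimed as a nearest-neighbour opens a new row
            used = set()
            for d in left["dat"]:
                gaps = (right["dat"] - d).abs()
                if gaps.min() <= tolerance:
                    used.add(right["dat"].iloc[int(gaps.argmin())])
            leftover = right[~right["dat"].isin(used)].copy()
            if not leftover.empty:
                leftover.insert(0, "plot_id", plot_id)
                merged = pd.concat([merged, leftover], ignore_index=True)
            pieces.append(merged)
        extra_plots = df[~df["plot_id"].isin(result["plot_id"])]
        if not extra_plots.empty:
            pieces.append(extra_plots)
        result = pd.concat(pieces, ignore_index=True)
    if result is None:
        raise ValidationError("no observation sources supplied")
    return result.sort_values(KEYS, kind="stable").reset_index(drop=True)


@dataclass
class CorrelationMatrix:
    """Pairwise-complete correlation estimates with per-pair sample sizes."""

    r: pd.DataFrame
    n: pd.DataFrame
    method: str = "pearson"


def correlation_matrix(table: pd.DataFrame, variables: list[str],
                       method: str = "pearson",
                       min_pairs: int = 3) -> CorrelationMatrix:
    """Pairwise-complete correlation matrix over the given columns.

    Cells with fewer than ``min_pairs`` complete pairs are missing (NaN),
    never zero; constant columns yield missing correlations with a warning.
    The diagonal is 1 wherever the variable is non-constant.
    """
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ValidationError(f"variables not in table: {missing}")
    sub = table[variables].astype(float)
    for v in variables:
        col = sub[v].dropna()
        if len(col) > 0 and col.nunique() == 1:
            warnings.warn(f"variable {v!r} is constant; correlations undefined",
                          stacklevel=2)
    r = sub.corr(method=method, min_periods=min_pairs)
    notna = sub.notna().astype(int)
    n = notna.T @ notna
    r = r.where(n >= min_pairs)
    np.fill_diagonal(r.values, np.where(np.diag(n) > 0, np.diag(r.values), np.nan))
    return CorrelationMatrix(r=r, n=n, method=method)


@dataclass
class TukeyResult:
    """One trait's treatment comparison: ANOVA, Tukey HSD, compact letters."""

    trait: str
    group_means: dict            # treatment -> mean
    letters: dict                # treatment -> compact letter(s)
    anova_p: float
    cv_percent: float            # 100 * sqrt(MSE) / grand mean
    pairwise_p: pd.DataFrame     # symmetric Tukey p-value matrix
    alpha: float = 0.05


def _compact_letter_display(groups: list, pairwise_p: pd.DataFrame,
                            means: dict, alpha: float) -> dict:
    """Insert-and-absorb compact letter display over a Tukey p matrix."""
    columns = [set(groups)]
    for i, gi in enumerate(groups):
        for gj in groups[i + 1:]:
            if pairwise_p.loc[gi, gj] > alpha:
                continue
            for col in [c for c in columns if gi in c and gj in c]:
                columns.remove(col)
                a, b = col - {gj}, col - {gi}
                for new in (a, b):
                    if not any(new <= other for other in columns):
                        columns.append(new)
    # absorb duplicates/subsets, then order letters by descending group mean
    columns = [c for c in columns
               if not any(c < other for other in columns) and c]
    columns.sort(key=lambda c: -max(means[g] for g in c))
    letters = {g: "" for g in groups}
    for letter, col in zip(string.ascii_lowercase, columns):
        for g in sorted(col, key=lambda g: -means[g]):
            letters[g] += letter
    return letters


def anova_tukey(yields: pd.DataFrame, trait: str, alpha: float = 0.05,
                group_col: str = "treatment") -> TukeyResult:
    """One-way ANOVA plus all-pairs Tukey HSD for one yield trait.

    Requires >= 2 treatments with >= 2 replicates each.  Pairwise p-values
    come from the studentized range distribution with the pooled MSE.
    """
    if trait not in yields.columns:
        raise ValidationError(f"trait {trait!r} not in the yield table")
    grouped = {g: sub[trait].dropna().to_numpy(dtype=float)
               for g, sub in yields.groupby(group_col)}
    groups = sorted(grouped, reverse=True)
    if len(groups) < 2:
        raise ValidationError("need at least 2 treatments")
    if any(len(v) < 2 for v in grouped.values()):
        raise ValidationError("every treatment needs at least 2 replicates")

    k = len(groups)
    n_total = sum(len(v) for v in grouped.values())
    df_err = n_total - k
    mse = sum(((v - v.mean()) ** 2).sum() for v in grouped.values()) / df_err
    grand = np.concatenate(list(grouped.values())).mean()
    means = {g: float(v.mean()) for g, v in grouped.items()}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        anova_p = float(sps.f_oneway(*[grouped[g] for g in groups]).pvalue)

    p = pd.DataFrame(np.ones((k, k)), index=groups, columns=groups)
    for i, gi in enumerate(groups):
        for gj in groups[i + 1:]:
            se = np.sqrt(mse / 2.0 * (1.0 / len(grouped[gi]) + 1.0 / len(grouped[gj])))
            if se == 0:
                pij = 1.0 if means[gi] == means[gj] else 0.0
            else:
                q = abs(means[gi] - means[gj]) / se
                pij = float(sps.studentized_range.sf(q, k, df_err))
            p.loc[gi, gj] = p.loc[gj, gi] = pij

    letters = _compact_letter_display(groups, p, means, alpha)
    cv = 100.0 * np.sqrt(mse) / grand if grand != 0 else np.nan
    return TukeyResult(trait=trait, group_means=means, letters=letters,
                       anova_p=anova_p, cv_percent=float(cv), pairwise_p=p,
                       alpha=alpha)


def summary_stats(yields: pd.DataFrame,
                  traits: tuple[str, ...] = ("marketable", "unripen",
                                             "rotten", "total"),
                  group_col: str = "treatment") -> pd.DataFrame:
    """Per-trait margin statistics across treatments.

    Replicates are first averaged within treatment; the reported ``mean`` is
    the unweighted arithmetic mean of the per-treatment values, and
    ``cv_across_means_percent`` their coefficient of variation.  Report
    output rounds to one decimal.
    """
    if yields.empty:
        raise ValidationError("empty yield table")
    present = [t for t in traits if t in yields.columns]
    if not present:
        raise ValidationError(f"none of the traits {traits} present")
    per_treatment = yields.groupby(group_col)[present].mean()
    mean = per_treatment.mean(axis=0)
    sd = per_treatment.std(axis=0, ddof=1)
    out = pd.DataFrame({
        "mean": mean,
        "cv_across_means_percent": 100.0 * sd / mean.where(mean != 0),
    })
    out.index.name = "trait"
    return out


def build_report(outputs: dict, seed: Optional[int] = None,
                 version: str = "unknown") -> dict:
    """Assemble the machine-readable run report.

    ``outputs`` may contain any of: ``rgb_indices``, ``spectral_indices``,
    ``cwsi``, ``bioristor_daily``, ``observations`` (DataFrames),
    ``correlation`` (:class:`CorrelationMatrix`), ``tukey`` (list of
    :class:`TukeyResult`), ``yield_summary`` (DataFrame),
    ``divergence_dat``, ``config`` (dict echo).  Missing stages are marked
    absent with a warning rather than failing (partial-pipeline contract).
    Rerunning with the same seed reproduces the report byte for byte.
    """
    report: dict = {"seed": seed, "version": version, "sections": {}}

    def frame(df: pd.DataFrame) -> list:
        return json.loads(df.replace({np.nan: None}).to_json(orient="records"))

    for name in ("rgb_indices", "spectral_indices", "cwsi", "bioristor_daily",
                 "observations"):
        if name in outputs and outputs[name] is not None:
            report["sections"][name] = frame(outputs[name])
        else:
            warnings.warn(f"report section {name!r} absent", stacklevel=2)
            report["sections"][name] = None

    corr = outputs.get("correlation")
    report["sections"]["correlation"] = None if corr is None else {
        "method": corr.method,
        "variables": list(corr.r.columns),
        "r": [[None if pd.isna(v) else round(float(v), 6) for v in row]
              for row in corr.r.values],
        "n": corr.n.values.tolist(),
    }
    tukey = outputs.get("tukey")
    report["sections"]["tukey"] = None if tukey is None else [
        {"trait": t.trait, "alpha": t.alpha, "anova_p": t.anova_p,
         "cv_percent": round(t.cv_percent, 4),
         "group_means": {str(k): round(v, 6) for k, v in t.group_means.items()},
         "letters": {str(k): v for k, v in t.letters.items()}}
        for t in tukey
    ]
    ys = outputs.get("yield_summary")
    report["sections"]["yield_summary"] = None if ys is None else {
        trait: round(float(row["mean"]), 1) for trait, row in ys.iterrows()
    }
    report["sections"]["divergence_dat"] = outputs.get("divergence_dat")
    report["config"] = outputs.get("config")
    return report
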