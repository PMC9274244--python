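"""Suppression-aware contingency analytics.

For each binned feature the scan cross-tabulates feature level × outcome
group, computes the Pearson chi-square statistic

    X² = Σ_ij (O_ij − E_ij)² / E_ij,   E_ij = row_i · col_j / n,

with NO continuity correction, on the table after rows/columns with a zero
margin are dropped; df = (r′−1)(k′−1) over the retained table, and p is the
upper-tail chi-square probability. A table reduced to fewer than two rows or
columns is degenerate: X² = 0, df = 0, p = 1. Family-wise control is
Bonferroni at threshold α/m over the m features scanned. Every serialized
report passes small-cell suppression: counts in [1, threshold−1] are
replaced by the non-disclosure marker ``ND``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .model import ConfigError, DomainError
from .feature_table import MISSING, level_order

ND = "ND"


@dataclass
class ContingencyResult:
    feature: str
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    observed: np.ndarray          # r × k integer counts
    expected: np.ndarray          # r × k expected counts (zero-margin rows/cols kept as 0)
    chi2: float
    df: int
    p: float
    n: int


@dataclass
class ComparisonReport:
    results: list[ContingencyResult]
    alpha: float
    m: int
    threshold: float = field(init=False)
    significant: dict[str, bool] = field(init=False)

    def __post_init__(self) -> None:
        self.threshold = self.alpha / self.m
        self.significant = {r.feature: r.p < self.threshold for r in self.results}


@dataclass
class SuppressedTable:
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    cells: list[list[str]]        # displayed values; small counts replaced by ND
    threshold: int


def contingency(
    ft: pd.DataFrame,
    feature: str,
    outcome_col: str = "outcome",
    row_labels: Optional[Sequence[str]] = None,
    col_labels: Optional[Sequence[str]] = None,
) -> tuple[np.ndarray, tuple[str, ...], tuple[str, ...]]:
    """Observed counts, rows = feature bins in scheme order, columns = outcome groups.

    Patients whose value for this feature is Missing are excluded (pairwise
    deletion), so exposure tables can have a smaller denominator than
    co-diagnosis tables.
    """
    for col in (feature, outcome_col):
        if col not in ft.columns:
            raise DomainError(f"column {col!r} not in feature table")
    sub = ft[ft[feature] != MISSING]
    if sub.empty:
        raise DomainError(f"feature {feature!r} is entirely Missing; empty table")
    # full scheme order (including empty levels) when values are canonical,
    # otherwise the sorted observed values
    if row_labels is None:
        canonical = level_order(feature)
        row_labels = list(canonical) if set(sub[feature]) <= set(canonical) \
            else sorted(set(sub[feature]))
    if col_labels is None:
        canonical = level_order(outcome_col)
        col_labels = list(canonical) if set(sub[outcome_col]) <= set(canonical) \
            else sorted(set(sub[outcome_col]))
    table = (
        pd.crosstab(sub[feature], sub[outcome_col])
        .reindex(index=row_labels, columns=col_labels, fill_value=0)
        .to_numpy(dtype=np.int64)
    )
    return table, tuple(row_labels), tuple(col_labels)


def pearson_chi_square(observed) -> tuple[float, int, float]:
    """(chi2, df, p) for an r × k table of non-negative counts.

    Zero-margin rows/columns are dropped before expected counts and df are
    computed; a table degenerating to df = 0 returns (0.0, 0, 1.0).
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2:
        raise DomainError("observed must be a 2-D table")
    if (obs < 0).any():
        raise DomainError("observed counts must be non-negative")
    n = obs.sum()
    if n <= 0:
        raise DomainError("all-zero contingency table")
    obs = obs[obs.sum(axis=1) > 0, :]
    obs = obs[:, obs.sum(axis=0) > 0]
    r, k = obs.shape
    df = (r - 1) * (k - 1)
    if df == 0:
        return 0.0, 0, 1.0
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    p = float(chi2_dist.sf(chi2, df))
    return chi2, df, p


def expected_counts(observed) -> np.ndarray:
    """Expected counts under independence, zero where a margin is zero."""
    obs = np.asarray(observed, dtype=float)
    n = obs.sum()
    if n <= 0:
        raise DomainError("all-zero contingency table")
    return np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n


def collapse_ge1(counts_by_level: dict) -> int:
    """Number of patients with ≥1 diagnosis from {0: a, 1: b, ">1": c} level counts."""
    vals = {str(k): v for k, v in counts_by_level.items()}
    for v in vals.values():
        if v < 0:
            raise DomainError("negative level count")
    return int(vals.get("1", 0) + vals.get(">1", 0))


def analyze_feature(ft: pd.DataFrame, feature: str, outcome_col: str = "outcome"
                    ) -> ContingencyResult:
    observed, rows, cols = contingency(ft, feature, outcome_col)
    chi2, df, p = pearson_chi_square(observed)
    return ContingencyResult(
        feature=feature,
        row_labels=rows,
        col_labels=cols,
        observed=observed,
        expected=expected_counts(observed),
        chi2=chi2,
        df=df,
        p=p,
        n=int(observed.sum()),
    )


def multiple_comparison_scan(
    ft: pd.DataFrame,
    outcome_col: str,
    features: Sequence[str],
    alpha: float = 0.05,
) -> ComparisonReport:
    """One contingency result per feature, Bonferroni threshold α/m, input order kept."""
    if not features:
        raise ConfigError("feature list for the scan is empty")
    results = [analyze_feature(ft, f, outcome_col) for f in features]
    return ComparisonReport(results=results, alpha=alpha, m=len(features))


# -- small-cell suppression ---------------------------------------------------


def _display(value: int, threshold: int) -> str:
    return ND if 1 <= value < threshold else str(int(value))


def suppress(observed, row_labels, col_labels, threshold: int = 10) -> SuppressedTable:
    """Replace counts in [1, threshold−1] by ``ND``; zeros and large counts display as-is."""
    if threshold < 2:
        raise ConfigError("suppression threshold must be ≥ 2")
    obs = np.asarray(observed)
    cells = [[_display(int(obs[i, j]), threshold) for j in range(obs.shape[1])]
             for i in range(obs.shape[0])]
    return SuppressedTable(tuple(row_labels), tuple(col_labels), cells, threshold)


def report_to_dict(report: ComparisonReport, threshold: int = 10) -> dict:
    """JSON-ready, suppressed rendering of a comparison report.

    Observed counts in [1, threshold−1] appear as ``ND``; row percentages are
    suppressed alongside their counts. Statistics are reported unsuppressed —
    they are aggregate, not cell-level, quantities.
    """
    out = {
        "alpha": report.alpha,
        "m": report.m,
        "bonferroni_threshold": report.threshold,
        "features": [],
    }
    for r in report.results:
        sup = suppress(r.observed, r.row_labels, r.col_labels, threshold)
        rows = []
        for i, lab in enumerate(r.row_labels):
            row_total = int(r.observed[i].sum())
            cells = []
            for j, col in enumerate(r.col_labels):
                shown = sup.cells[i][j]
                pct = (
                    None if shown == ND or row_total == 0
                    else round(100.0 * r.observed[i, j] / row_total, 2)
                )
                cells.append({"outcome": col, "count": shown, "row_pct": pct})
            rows.append({"level": lab, "cells": cells})
        out["features"].append({
            "feature": r.feature,
            "n": r.n,
            "chi2": r.chi2,
            "df": r.df,
            "p": r.p,
            "significant": report.significant[r.feature],
            "rows": rows,
        })
    return out


def report_to_json(report: ComparisonReport, threshold: int = 10) -> str:
    return json.dumps(report_to_dict(report, threshold), indent=2, ensure_ascii=False)


def report_to_markdown(report: ComparisonReport, threshold: int = 10) -> str:
    """Human-readable suppressed rendering, one block per feature."""
    d = report_to_dict(report, threshold)
    lines = [
        f"Bonferroni-corrected scan: alpha = {d['alpha']}, m = {d['m']}, "
        f"per-test threshold = {d['bonferroni_threshold']:.6g}",
        "",
    ]
    for feat in d["features"]:
        flag = " *" if feat["significant"] else ""
        lines.append(
            f"### {feat['feature']} (n = {feat['n']}) — "
            f"chi2 = {feat['chi2']:.4f}, df = {feat['df']}, p = {feat['p']:.4g}{flag}"
        )
        cols = [c["outcome"] for c in feat["rows"][0]["cells"]] if feat["rows"] else []
        lines.append("| level | " + " | ".join(cols) + " |")
        lines.append("|" + "---|" * (len(cols) + 1))
        for row in feat["rows"]:
            shown = []
            for c in row["cells"]:
                pct = "" if c["row_pct"] is None else f" ({c['row_pct']:.2f})"
                shown.append(f"{c['count']}{pct}")
            lines.append(f"| {row['level']} | " + " | ".join(shown) + " |")
        lines.append("")
    return "\n".join(lines)
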