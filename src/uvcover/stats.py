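"""Nonparametric statistics over a two-visit coverage cohort.

The battery mirrors standard practice for skewed, paired percentage data:
Shapiro-Wilk as the normality gate, Mann-Whitney U for independent
comparisons (region, gender, skin group, formulation), Wilcoxon signed
rank for the paired visit comparison, Spearman rank correlation between
regions, and a Pearson chi-square for the change in binary canthal
coverage.  Significance is declared at p < 0.05 throughout.

For small problems the Mann-Whitney and Wilcoxon p-values are exact: the
full permutation null (all group relabellings, or all sign assignments of
the nonzero differences) is enumerated over the observed midranks, which
handles ties correctly.  Enumeration is used whenever the outcome count
(C(n1+n2, n1), respectively 2^n) is at most 4096; larger samples use the
normal approximation with tie correction and a continuity correction,
and the choice is recorded in the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "StatsReport",
    "normality_test",
    "compare_groups",
    "compare_paired",
    "correlate",
    "canthus_change_test",
    "summarize",
    "BOX_PERCENTILES",
]

EXACT_MAX_OUTCOMES = 4096
BOX_PERCENTILES = (5, 25, 75, 95)


class TestResult(NamedTuple):
    statistic: float
    pvalue: float
    method: str
    z: float | None = None

    @property
    def significant(self) -> bool:
        return bool(self.pvalue < 0.05)


def _rankdata(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def normality_test(sample) -> TestResult:
    """Shapiro-Wilk normality test (gate for the nonparametric battery)."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk is unreliable above n=5000")
    if np.ptp(x) == 0:
        return TestResult(math.nan, math.nan, "shapiro-wilk (not applicable: constant sample)")
    stat, p = sps.shapiro(x)
    return TestResult(float(stat), float(p), "shapiro-wilk")


def _two_sided_from_tails(lo_tail: float, hi_tail: float) -> float:
    return min(1.0, 2.0 * min(lo_tail, hi_tail))


def _exact_mannwhitney_p(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Enumerate all C(n, n1) group assignments of the pooled midranks."""
    n = len(ranks)
    offset = n1 * (n1 + 1) / 2.0
    us = np.array(
        [sum(c) - offset for c in combinations(ranks, n1)], dtype=float
    )
    lo = np.mean(us <= u_obs + 1e-9)
    hi = np.mean(us >= u_obs - 1e-9)
    return _two_sided_from_tails(lo, hi)


def compare_groups(x, y, method: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test between independent samples.

    The reported statistic is U for the first sample.  Exact permutation
    enumeration over midranks when C(n1+n2, n1) <= 4096 (ties included);
    otherwise the normal approximation with tie correction and continuity
    correction.  ``method`` can force either path ("exact"/"approx").
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    use_exact = (
        method == "exact"
        or (method == "auto" and math.comb(n1 + n2, n1) <= EXACT_MAX_OUTCOMES)
    )
    if use_exact:
        p = _exact_mannwhitney_p(ranks, n1, u1)
        return TestResult(u1, p, "mann-whitney (exact enumeration)")

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return TestResult(u1, 1.0, "mann-whitney (degenerate: all values tied)")
    z = (u1 - mu - math.copysign(0.5, u1 - mu)) / math.sqrt(var) if u1 != mu else 0.0
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult(u1, p, "mann-whitney (normal approximation)", z=z)


def _exact_wilcoxon_p(abs_ranks: np.ndarray, w_obs: float) -> float:
    """Enumerate all 2^n sign assignments of the |difference| midranks."""
    totals = np.zeros(1)
    for r in abs_ranks:
        totals = np.concatenate([totals, totals + r])
    lo = np.mean(totals <= w_obs + 1e-9)
    hi = np.mean(totals >= w_obs - 1e-9)
    return _two_sided_from_tails(lo, hi)


def compare_paired(before, after, method: str = "auto") -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Differences are after - before; zero differences are dropped
    (Wilcoxon's original treatment).  The statistic is W+, the sum of the
    positive-difference ranks.  Exact sign-assignment enumeration when
    2^n <= 4096; otherwise the normal approximation with tie correction,
    reported with its Z value.  ``method`` can force either path.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 1.0, "wilcoxon (not applicable: all differences zero)")
    ranks = _rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    use_exact = (
        method == "exact"
        or (method == "auto" and n <= int(math.log2(EXACT_MAX_OUTCOMES)))
    )
    if use_exact:
        p = _exact_wilcoxon_p(ranks, w_plus)
        return TestResult(w_plus, p, "wilcoxon (exact enumeration)")

    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
        tie_counts**3 - tie_counts
    ) / 48.0
    if var <= 0:
        return TestResult(w_plus, 1.0, "wilcoxon (degenerate)")
    z = (w_plus - mu - math.copysign(0.5, w_plus - mu)) / math.sqrt(var) if w_plus != mu else 0.0
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult(w_plus, p, "wilcoxon (normal approximation)", z=z)


def correlate(x, y) -> TestResult:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(math.nan, math.nan, "spearman (not applicable: constant input)")
    rho, p = sps.spearmanr(x, y)
    return TestResult(float(rho), float(p), "spearman")


def pearson_correlate(x, y) -> TestResult:
    """Pearson correlation (reported alongside Spearman for the
    improvement-vs-initial analysis, matching how the original change
    analysis was labelled)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(math.nan, math.nan, "pearson (not applicable: constant input)")
    r, p = sps.pearsonr(x, y)
    return TestResult(float(r), float(p), "pearson")


def canthus_change_test(table, yates: bool = False) -> TestResult:
    """Pearson chi-square (1 df) on a 2x2 visit-by-coverage count table.

    Default is the textbook uncorrected statistic sum (O-E)^2 / E; the
    Yates continuity correction is optional.  A zero expected count is an
    error.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or np.any(obs < 0):
        raise ValueError("expected a 2x2 table of nonnegative counts")
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    if np.any(expected == 0):
        raise ValueError("zero expected count")
    diff = np.abs(obs - expected)
    if yates:
        diff = np.clip(diff - 0.5, 0.0, None)
    stat = float(np.sum(diff**2 / expected))
    p = float(sps.chi2.sf(stat, df=1))
    name = "chi-square (Yates)" if yates else "chi-square"
    return TestResult(stat, p, name)


# ---------------------------------------------------------------------------
# Cohort report


def _box_stats(values: np.ndarray) -> dict:
    values = np.asarray(values, dtype=float)
    out = {"n": int(values.size), "median": float(np.median(values))}
    pcts = np.percentile(values, BOX_PERCENTILES)  # linear interpolation
    out.update({f"p{q}": float(v) for q, v in zip(BOX_PERCENTILES, pcts)})
    return out


def _result_dict(res: TestResult) -> dict:
    out = {
        "test": res.method,
        "statistic": None if math.isnan(res.statistic) else float(res.statistic),
        "p": None if math.isnan(res.pvalue) else float(res.pvalue),
        "significant": res.significant if not math.isnan(res.pvalue) else None,
    }
    if res.z is not None:
        out["z"] = float(res.z)
    return out


@dataclass
class StatsReport:
    """Collection of analysis panels: group summaries, tests, p-values."""

    panels: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        import json

        return json.dumps(
            {"panels": self.panels, "warnings": self.warnings},
            indent=2,
            sort_keys=True,
            allow_nan=False,
        )

    def to_markdown(self) -> str:
        lines = ["# Coverage cohort report", ""]
        for name, panel in self.panels.items():
            lines.append(f"## {name}")
            lines.append("")
            for key, entry in panel.items():
                if isinstance(entry, dict) and "test" in entry:
                    p = entry.get("p")
                    ptxt = "n/a" if p is None else f"{p:.4g}"
                    stat = entry.get("statistic")
                    stxt = "n/a" if stat is None else f"{stat:.4g}"
                    flag = "*" if entry.get("significant") else ""
                    lines.append(f"- {key}: {entry['test']}, statistic={stxt}, p={ptxt}{flag}")
                elif isinstance(entry, dict) and "median" in entry:
                    lines.append(
                        f"- {key}: n={entry['n']}, median={entry['median']:.2f}, "
                        f"IQR=[{entry['p25']:.2f}, {entry['p75']:.2f}], "
                        f"whiskers=[{entry['p5']:.2f}, {entry['p95']:.2f}]"
                    )
                else:
                    lines.append(f"- {key}: {entry}")
            lines.append("")
        if self.warnings:
            lines.append("## Warnings")
            lines.extend(f"- {w}" for w in self.warnings)
            lines.append("")
        return "\n".join(lines)


_REGION_COLS = {"letterbox": "pct_letterbox", "rest": "pct_rest", "face": "pct_face"}


def _grouped_panel(
    df: pd.DataFrame, group_col: str, groups: tuple, report: StatsReport
) -> dict:
    """Per-region two-group comparison panel (Mann-Whitney)."""
    panel: dict = {}
    for region, col in _REGION_COLS.items():
        samples = []
        for g in groups:
            vals = df.loc[df[group_col] == g, col].to_numpy()
            if vals.size == 0:
                report.warnings.append(f"group {group_col}={g} empty; omitted")
                continue
            panel[f"{region} | {g}"] = _box_stats(vals)
            samples.append(vals)
        if len(samples) == 2:
            panel[f"{region} test"] = _result_dict(compare_groups(*samples))
    return panel


def summarize(cohort: pd.DataFrame, grouping: str) -> StatsReport:
    """Build the analysis panel for one grouping of the cohort table.

    Groupings: ``region`` (letterbox vs rest, visit 1), ``gender``,
    ``skin_group`` (Fitzpatrick 1-2 vs 3+), ``formulation`` (all visit 1,
    Mann-Whitney), and ``visit`` (paired Wilcoxon per region plus canthal
    coverage counts, the chi-square on the 2x2 canthal table, and the
    eyelid missed-percentage banding 0-10 / 10-20 / >20%).
    """
    report = StatsReport()
    df = cohort.copy()
    required = {"participant_id", "visit", "pct_face", "pct_letterbox", "pct_rest"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    v1 = df[df["visit"] == 1]

    if grouping == "region":
        panel = {
            "letterbox": _box_stats(v1["pct_letterbox"].to_numpy()),
            "rest": _box_stats(v1["pct_rest"].to_numpy()),
            "face": _box_stats(v1["pct_face"].to_numpy()),
            "normality letterbox": _result_dict(normality_test(v1["pct_letterbox"])),
            "normality rest": _result_dict(normality_test(v1["pct_rest"])),
            "letterbox vs rest": _result_dict(
                compare_groups(v1["pct_letterbox"], v1["pct_rest"])
            ),
            "letterbox vs rest correlation": _result_dict(
                correlate(v1["pct_letterbox"], v1["pct_rest"])
            ),
        }
        report.panels["region"] = panel
    elif grouping == "gender":
        report.panels["gender"] = _grouped_panel(v1, "gender", ("male", "female"), report)
    elif grouping == "skin_group":
        df2 = v1.assign(
            skin_group=np.where(v1["skin_type"] <= 2, "type 1-2", "type 3+")
        )
        report.panels["skin_group"] = _grouped_panel(
            df2, "skin_group", ("type 1-2", "type 3+"), report
        )
    elif grouping == "formulation":
        report.panels["formulation"] = _grouped_panel(
            v1, "formulation", ("cream", "spray"), report
        )
    elif grouping == "visit":
        report.panels["visit"] = _visit_panel(df, report)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return report


def _visit_panel(df: pd.DataFrame, report: StatsReport) -> dict:
    panel: dict = {}
    wide = df.pivot_table(
        index="participant_id", columns="visit",
        values=list(_REGION_COLS.values()), aggfunc="first",
    )
    visits = sorted(df["visit"].unique())
    if len(visits) < 2:
        report.warnings.append("single-visit cohort: paired visit analyses skipped")
        return panel
    for region, col in _REGION_COLS.items():
        pair = wide[col].dropna()
        b, a = pair[1].to_numpy(), pair[2].to_numpy()
        panel[f"{region} | visit 1"] = _box_stats(b)
        panel[f"{region} | visit 2"] = _box_stats(a)
        panel[f"{region} paired test"] = _result_dict(compare_paired(b, a))

    # improvement vs initial severity (eyelid letterbox)
    lb = wide["pct_letterbox"].dropna()
    change = (lb[1] - lb[2]).to_numpy()
    initial = lb[1].to_numpy()
    panel["eyelid change vs initial (spearman)"] = _result_dict(correlate(initial, change))
    panel["eyelid change vs initial (pearson)"] = _result_dict(
        pearson_correlate(initial, change)
    )

    bands = [(0, 10), (10, 20), (20, math.inf)]
    for v in visits:
        vals = df.loc[df["visit"] == v, "pct_letterbox"].to_numpy()
        panel[f"eyelid banding visit {v}"] = {
            ("0-10%" if hi == 10 else "10-20%" if hi == 20 else ">20%"): int(
                np.count_nonzero((vals > lo if lo else vals >= 0) & (vals <= hi))
            )
            for lo, hi in bands
        }

    if "canthus_covered" in df.columns:
        counts = []
        for v in (1, 2):
            sub = df[df["visit"] == v]
            not_cov = int((~sub["canthus_covered"].astype(bool)).sum())
            cov = int(sub["canthus_covered"].astype(bool).sum())
            counts.append([not_cov, cov])
            panel[f"canthus visit {v}"] = {"not_covered": not_cov, "covered": cov}
        try:
            panel["canthus change"] = _result_dict(canthus_change_test(counts))
        except ValueError as exc:
            report.warnings.append(f"canthus chi-square skipped: {exc}")
    return panel


def full_report(cohort: pd.DataFrame) -> StatsReport:
    """All analysis panels (region, gender, skin group, formulation, visit)."""
    report = StatsReport()
    for grouping in ("region", "gender", "skin_group", "formulation", "visit"):
        try:
            sub = summarize(cohort, grouping)
        except ValueError as exc:
            report.warnings.append(f"{grouping} panel skipped: {exc}")
            continue
        report.panels.update(sub.panels)
        report.warnings.extend(sub.warnings)
    return report
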