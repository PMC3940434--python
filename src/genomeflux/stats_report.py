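"""Statistical tests and tabular reports for the genome-flux results.

Thin, typed wrappers over scipy for the tests the analyses rely on
(two-sample t-tests from raw samples or printed (n, mean, sd) summaries,
Mann-Whitney U with exact small-sample enumeration, OLS R-squared),
plus grouped Lost/Retained summaries and the report emitters that lay
out per-genome flux totals, per-branch dN/dS comparisons and CAI blocks.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TwoSampleSummary",
    "TestResult",
    "t_test",
    "mann_whitney",
    "regression_r2",
    "grouped_metric_summary",
    "build_reports",
    "plot_rate_boxplot",
    "plot_grouped_bars",
]


@dataclass
class TwoSampleSummary:
    """Printed-table form of one sample: (n, mean, sd)."""

    n: int
    mean: float
    sd: float

    @classmethod
    def from_sample(cls, x) -> "TwoSampleSummary":
        x = np.asarray(x, dtype=float)
        return cls(n=len(x), mean=float(x.mean()), sd=float(x.std(ddof=1)) if len(x) > 1 else 0.0)


@dataclass
class TestResult:
    statistic: float
    df: float | None
    p_value: float
    sided: str
    method: str


def _as_summary(x) -> TwoSampleSummary:
    if isinstance(x, TwoSampleSummary):
        return x
    return TwoSampleSummary.from_sample(x)


def t_test(x, y, sided: str = "two", variant: str = "welch") -> TestResult:
    """Two-sample t-test from raw samples or (n, mean, sd) summaries.

    ``variant="welch"`` (default) uses unequal variances with
    Welch-Satterthwaite df; ``"pooled"`` is the classical Student test.
    ``sided="one"`` tests the alternative mean(x) > mean(y).
    """
    sx, sy = _as_summary(x), _as_summary(y)
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    if variant not in ("welch", "pooled"):
        raise ValueError("variant must be 'welch' or 'pooled'")
    if sx.n < 2 or sy.n < 2:
        raise ValueError("need n >= 2 in both groups")
    alternative = "greater" if sided == "one" else "two-sided"
    if sx.sd == 0 and sy.sd == 0:
        # degenerate samples: identical means are perfectly compatible
        if sx.mean == sy.mean:
            stat, p = 0.0, 1.0
        else:
            stat = math.inf if sx.mean > sy.mean else -math.inf
            p = 0.0 if (sided == "two" or stat > 0) else 1.0
        df = float(sx.n + sy.n - 2)
        return TestResult(statistic=stat, df=df, p_value=p, sided=sided, method=f"t-{variant}")
    stat, p = sps.ttest_ind_from_stats(
        sx.mean, sx.sd, sx.n, sy.mean, sy.sd, sy.n,
        equal_var=(variant == "pooled"), alternative=alternative,
    )
    if variant == "pooled":
        df = sx.n + sy.n - 2.0
    else:
        vx, vy = sx.sd**2 / sx.n, sy.sd**2 / sy.n
        df = (vx + vy) ** 2 / (vx**2 / (sx.n - 1) + vy**2 / (sy.n - 1)) if vx + vy > 0 else sx.n + sy.n - 2.0
    return TestResult(statistic=float(stat), df=float(df), p_value=float(p), sided=sided, method=f"t-{variant}")


def _u_statistic(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    ranks = sps.rankdata(np.concatenate([x, y]))
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2)


def mann_whitney(x, y, sided: str = "two", exact_limit: int = 400, enum_limit: int = 200_000) -> TestResult:
    """Mann-Whitney U test with exact small-sample handling.

    For n1*n2 <= ``exact_limit`` the exact null distribution is used
    (scipy's exact method without ties; full enumeration of group
    assignments when ties are present and the arrangement count is
    manageable); otherwise the normal approximation with tie
    correction.  ``sided="one"`` tests x stochastically greater.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    alternative = "greater" if sided == "one" else "two-sided"
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = n1 * n2 <= exact_limit
    if small and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative=alternative, method="exact")
        return TestResult(float(res.statistic), None, float(res.pvalue), sided, "mann-whitney-exact")
    if small and has_ties and math.comb(n1 + n2, n1) <= enum_limit:
        u_obs = _u_statistic(x, y)
        mu = n1 * n2 / 2
        count = total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(idx)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if sided == "one":
                count += u >= u_obs - 1e-12
            else:
                count += abs(u - mu) >= abs(u_obs - mu) - 1e-12
        return TestResult(u_obs, None, count / total, sided, "mann-whitney-enum")
    res = sps.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return TestResult(float(res.statistic), None, float(res.pvalue), sided, "mann-whitney-normal")


def regression_r2(x, y) -> tuple[float, float, float]:
    """OLS fit y = a + b x; returns (R^2, slope, intercept)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    fit = sps.linregress(x, y)
    return float(fit.rvalue**2), float(fit.slope), float(fit.intercept)


def grouped_metric_summary(
    families,
    group_labels: dict[str, str],
    metric: dict[str, float],
    na_label: str = "NA",
) -> pd.DataFrame:
    """Per-category (n, mean, sd) of a family metric.

    Families without a label fall in the ``na_label`` category; empty
    categories are reported with n = 0 and NaN summaries.
    """
    rows = {}
    for fam in families:
        cat = group_labels.get(fam, na_label)
        rows.setdefault(cat, []).append(metric.get(fam, np.nan))
    out = []
    for cat in sorted(rows):
        vals = np.array([v for v in rows[cat] if np.isfinite(v)], dtype=float)
        out.append(
            {
                "category": cat, "n": len(vals),
                "mean": float(vals.mean()) if len(vals) else np.nan,
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
            }
        )
    return pd.DataFrame(out)


def build_reports(
    results,
    partitions: dict | None = None,
    family_omega: dict[str, float] | None = None,
    cai_blocks: dict[str, dict] | None = None,
    out_dir=None,
) -> dict[str, pd.DataFrame]:
    """Assemble the tabular report bundle from upstream results.

    ``results`` is an :class:`~genomeflux.ancestral_content.AncestralContentResults`;
    optional inputs add per-branch Lost/Retained dN/dS comparisons (with
    one- and two-sided Welch and pooled t-tests) and per-reference-genome
    CAI blocks.  Reports are returned as DataFrames and, when
    ``out_dir`` is given, written as TSV with stable column order.
    """
    from .stats_report import t_test  # self-import keeps the public name

    reports: dict[str, pd.DataFrame] = {}
    reports["flux_per_genome"] = results.leaf_totals()
    reports["flux_per_branch"] = results.flux.per_branch.copy()

    if partitions is not None and family_omega is not None:
        rows = []
        for label in sorted(partitions):
            part = partitions[label]
            lost = np.array(
                [family_omega[f] for f in part.lost if np.isfinite(family_omega.get(f, np.nan))]
            )
            ret = np.array(
                [family_omega[f] for f in part.retained if np.isfinite(family_omega.get(f, np.nan))]
            )
            row = {
                "branch": label,
                "lost_n": len(lost),
                "lost_mean": lost.mean() if len(lost) else np.nan,
                "lost_sd": lost.std(ddof=1) if len(lost) > 1 else np.nan,
                "retained_n": len(ret),
                "retained_mean": ret.mean() if len(ret) else np.nan,
                "retained_sd": ret.std(ddof=1) if len(ret) > 1 else np.nan,
            }
            if len(lost) > 1 and len(ret) > 1:
                row["p_welch"] = t_test(lost, ret, sided="two", variant="welch").p_value
                row["p_pooled"] = t_test(lost, ret, sided="two", variant="pooled").p_value
                row["p_one_sided"] = t_test(lost, ret, sided="one", variant="welch").p_value
            rows.append(row)
        reports["lost_retained_omega"] = pd.DataFrame(rows)

    if cai_blocks is not None:
        rows = []
        for genome in sorted(cai_blocks):
            for branch in sorted(cai_blocks[genome]):
                rows.append({"reference_genome": genome, "branch": branch, **cai_blocks[genome][branch]})
        reports["cai_lost_retained"] = pd.DataFrame(rows)

    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in reports.items():
            frame.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.6g")
    return reports


def plot_rate_boxplot(values_by_group: dict[str, list[float]], path, ylabel: str = "dN") -> None:
    """Per-group boxplot of substitution rates (ecotype comparison)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = sorted(values_by_group)
    fig, ax = plt.subplots(figsize=(1.2 + 1.1 * len(groups), 4))
    ax.boxplot([values_by_group[g] for g in groups], tick_labels=groups, notch=True)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_grouped_bars(summary: pd.DataFrame, path, value: str = "mean", ylabel: str = "mean dN/dS") -> None:
    """Side-by-side bars of a per-category Lost/Retained summary.

    ``summary`` needs columns ``category``, ``group`` and the ``value``
    column (as from :func:`grouped_metric_summary` runs per group).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cats = sorted(summary["category"].unique())
    groups = sorted(summary["group"].unique())
    width = 0.8 / max(len(groups), 1)
    fig, ax = plt.subplots(figsize=(max(4.0, 0.5 * len(cats) + 1), 4))
    for gi, grp in enumerate(groups):
        sub = summary[summary["group"] == grp].set_index("category")
        vals = [sub[value].get(c, np.nan) for c in cats]
        ax.bar(np.arange(len(cats)) + gi * width, vals, width, label=grp)
    ax.set_xticks(np.arange(len(cats)) + width * (len(groups) - 1) / 2)
    ax.set_xticklabels(cats)
    ax.set_ylabel(ylabel)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
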