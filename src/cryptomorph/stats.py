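"""Nonparametric comparisons and run summaries.

Thin, typed wrappers around the standard rank tests (Mann-Whitney U with the
exact null for small tie-free samples and the tie/continuity-corrected
normal approximation otherwise; Kruskal-Wallis with tie correction), a
percentile bootstrap for the median, the per-metric clade comparison table
and the F1 run summary with box plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

#: switch to the normal approximation above this combined sample size
EXACT_MAX_N = 16

FIVE_METRICS = ["circularity", "eccentricity", "solidity", "extent",
                "minor_axis_length"]


@dataclass(frozen=True)
class UTestResult:
    u_statistic: float
    p_value: float
    n_x: int
    n_y: int
    method: str  # "exact" or "normal_approx"
    zero_variance: bool = False


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney_u(x, y, alternative: str = "two-sided",
                   method: str = "auto") -> UTestResult:
    """Two-sided Mann-Whitney U test.

    With ``method="auto"``: exact enumeration null when the combined sample
    is small (``n_x + n_y <= EXACT_MAX_N``) and tie-free; otherwise the
    normal approximation with tie correction and continuity correction.
    Identical constant samples are flagged and given p = 1.  ``method`` may
    force ``"exact"`` or ``"normal_approx"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is supported")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return UTestResult(
            u_statistic=len(x) * len(y) / 2.0, p_value=1.0,
            n_x=len(x), n_y=len(y), method="normal_approx",
            zero_variance=True,
        )
    if method == "auto":
        exact = (len(x) + len(y) <= EXACT_MAX_N) and not _has_ties(x, y)
    elif method == "exact":
        if _has_ties(x, y):
            raise ValueError("exact method requires tie-free samples")
        exact = True
    elif method == "normal_approx":
        exact = False
    else:
        raise ValueError(f"unknown method {method!r}")
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return UTestResult(
        u_statistic=float(res.statistic), p_value=float(res.pvalue),
        n_x=len(x), n_y=len(y),
        method="exact" if exact else "normal_approx",
    )


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-squared p-value."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def bootstrap_median_ci(values, n_boot: int = 2000, level: float = 0.95,
                        rng: np.random.Generator | None = None
                        ) -> tuple[float, float]:
    """Seeded percentile bootstrap confidence interval for the median."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values")
    rng = rng or np.random.default_rng(0)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    medians = np.median(values[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    return (float(np.quantile(medians, alpha)),
            float(np.quantile(medians, 1.0 - alpha)))


def compare_clade_metrics(table: pd.DataFrame, group_column: str = "clade",
                          metrics: list[str] | None = None) -> pd.DataFrame:
    """One two-sided Mann-Whitney test per shape metric between two groups.

    Returns per-metric group medians, U, unadjusted p and Bonferroni-adjusted
    p.  The planted-effect checks in this package key on the unadjusted
    values; the adjusted column is reported alongside.
    """
    metrics = metrics or FIVE_METRICS
    missing = [c for c in metrics + [group_column] if c not in table.columns]
    if missing:
        raise KeyError(f"missing columns: {missing}")
    levels = sorted(table[group_column].unique())
    if len(levels) != 2:
        raise ValueError(f"group column must have 2 levels, got {levels}")
    a, b = levels
    rows = []
    for m in metrics:
        x = table.loc[table[group_column] == a, m].to_numpy()
        y = table.loc[table[group_column] == b, m].to_numpy()
        r = mann_whitney_u(x, y)
        rows.append({
            "metric": m,
            f"median_{a}": float(np.median(x)),
            f"median_{b}": float(np.median(y)),
            "u_statistic": r.u_statistic,
            "p_value": r.p_value,
            "p_bonferroni": min(1.0, r.p_value * len(metrics)),
            "method": r.method,
        })
    return pd.DataFrame(rows)


def summarize_runs(results_list: list, out_dir: str | Path | None = None
                   ) -> pd.DataFrame:
    """Median/min/max/IQR of macro-F1 per configuration and test kind, with
    a bootstrap CI of the median; optionally writes a CSV and box plot."""
    rows = []
    boxes, labels = [], []
    for res in results_list:
        for kind in ("even", "full"):
            v = res.macro_f1_values(kind)
            if len(v) == 0:
                continue
            lo, hi = (np.nan, np.nan)
            if len(v) >= 2:
                lo, hi = bootstrap_median_ci(v, rng=np.random.default_rng(0))
            name = ("mixed" if res.mixed else "clade") + f"/{kind}"
            rows.append({
                "configuration": "mixed" if res.mixed else "clade",
                "test_kind": kind,
                "n_iterations": len(v),
                "median": float(np.median(v)),
                "min": float(v.min()),
                "max": float(v.max()),
                "iqr": float(np.percentile(v, 75) - np.percentile(v, 25)),
                "median_ci_low": lo,
                "median_ci_high": hi,
            })
            if kind == "even":
                boxes.append(v)
                labels.append(name)
    df = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "run_summary.csv", index=False)
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(boxes), 4))
        ax.boxplot(boxes, tick_labels=labels, whis=1.5)
        ax.set_ylabel("Even-test macro-F1")
        ax.set_ylim(0, 1.05)
        ax.axhline(0.5, ls="--", lw=0.8, color="grey")
        fig.tight_layout()
        fig.savefig(out_dir / "f1_boxplot.png", dpi=120)
        plt.close(fig)
    return df
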