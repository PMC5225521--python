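"""Median-split survival screening of differentially expressed genes.

Patients are split at the median expression of a gene (ties go to the low
group), the two groups are compared with the unweighted two-group log-rank
test, and p-values across genes are Benjamini-Hochberg adjusted. The
log-rank statistic is computed from the risk tables directly, which also
yields the direction of the worse-prognosis group (sign of O - E in the
high-expression group).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


def median_split(expression: pd.Series) -> pd.Series:
    """Label patients low/high by the median expression; ties go low.

    Patients with missing expression are dropped (logged). A degenerate
    split (everyone low) is logged as a warning.
    """
    expr = expression.dropna()
    n_missing = len(expression) - len(expr)
    if n_missing:
        log.info("median_split: dropped %d patients with missing expression", n_missing)
    if len(expr) < 2:
        raise ValueError("median split requires at least 2 patients")
    med = float(expr.median())
    groups = pd.Series(
        np.where(expr.to_numpy(dtype=float) <= med, "low", "high"),
        index=expr.index,
        name="group",
    )
    if (groups == "low").all():
        log.warning("median_split: degenerate split, all patients in the low group")
    return groups


@dataclass
class LogrankResult:
    chi_square: float
    p_value: float
    observed_high: float
    expected_high: float
    worse_group: str  # group with more deaths than expected


def logrank_test(records: pd.DataFrame) -> LogrankResult:
    """Two-group log-rank test.

    `records` needs columns time (>0), event (0/1) and group (two labels).
    The statistic is (sum(O - E))^2 / sum(V) with the hypergeometric
    variance at each distinct event time; p from chi-square with 1 df.
    """
    required = {"time", "event", "group"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    labels = sorted(records["group"].unique())
    if len(labels) != 2:
        raise ValueError("log-rank test requires exactly two non-empty groups")
    # "high" (or the second label) is the group whose O-E sign is reported
    g2 = "high" if "high" in labels else labels[1]
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    in_g2 = (records["group"] == g2).to_numpy()
    if (time <= 0).any():
        raise ValueError("survival times must be positive")

    o_minus_e = 0.0
    var = 0.0
    observed2 = 0.0
    expected2 = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = int(at_risk.sum())
        n2 = int((at_risk & in_g2).sum())
        d = int((event == 1)[time == t].sum())
        d2 = int(((event == 1) & in_g2)[time == t].sum())
        e2 = d * n2 / n
        observed2 += d2
        expected2 += e2
        o_minus_e += d2 - e2
        if n > 1:
            var += d * (n2 / n) * (1 - n2 / n) * (n - d) / (n - 1)
    if var == 0.0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = o_minus_e**2 / var
        p = float(stats.chi2.sf(chi2, df=1))
    worse = g2 if o_minus_e >= 0 else [lb for lb in labels if lb != g2][0]
    return LogrankResult(float(chi2), p, float(observed2), float(expected2), worse)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_genes(
    survival: pd.DataFrame, expression: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Median-split log-rank screen of every gene against patient survival.

    survival: frame indexed by patient with columns time, event.
    expression: genes x patients expression matrix.
    Returns per-gene (chi_square, p, p_adjusted, worse_group, significant).
    """
    rows = []
    for gene_id, expr in expression.iterrows():
        expr = expr.reindex(survival.index)
        groups = median_split(expr)
        records = survival.loc[groups.index, ["time", "event"]].copy()
        records["group"] = groups
        if records["group"].nunique() < 2:
            rows.append((gene_id, np.nan, np.nan, "na"))
            continue
        res = logrank_test(records)
        rows.append((gene_id, res.chi_square, res.p_value, res.worse_group))
    out = pd.DataFrame(rows, columns=["gene_id", "chi_square", "p", "worse_group"])
    ok = out["p"].notna()
    out["p_adjusted"] = np.nan
    out.loc[ok, "p_adjusted"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    out["significant"] = out["p_adjusted"] < alpha
    return out
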