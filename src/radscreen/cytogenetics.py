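"""Cytogenetic and reporter-assay summary statistics.

Metaphase spreads are scored for breaks, gaps and exchanges, dichotomized
into chromatid-type (one sister chromatid affected; damage in replicated
DNA) and chromosome-type (both chromatids; damage in unreplicated DNA).
Rates are reported per metaphase (mean +- sd) and, to refer them to the
whole population, per 100 cells by multiplying by the mitotic fraction
(the externally measured p-H3-positive percentage).  Sister chromatid
exchanges (SCEs), foci counts and GFP-reporter repair efficiencies reuse
the same group-summary and two-sample t-test machinery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

CHROMATID_CLASSES = ["chromatid_breaks", "chromatid_gaps", "chromatid_exchanges"]
CHROMOSOME_CLASSES = ["chromosome_breaks", "chromosome_gaps", "chromosome_exchanges"]
ABERRATION_CLASSES = CHROMATID_CLASSES + CHROMOSOME_CLASSES


def summarize_aberrations(records: pd.DataFrame,
                          by=("condition", "timepoint"),
                          mitotic_fraction: float | None = None) -> pd.DataFrame:
    """Class-wise and dichotomized aberration means +- sd per group.

    ``records`` holds one row per metaphase with the six class-count columns.
    Output has, per group, ``<class>_mean``/``<class>_sd`` for each class plus
    the derived ``chromatid_total``, ``chromosome_total`` and ``total``
    columns, and ``n`` metaphases.  Sample sd uses n-1.  When
    ``mitotic_fraction`` is given, ``total_per_100_cells`` (and the two
    dichotomy totals) are added via :func:`per_100_cells`.
    """
    if records.empty:
        raise ValueError("no metaphase records")
    missing = [c for c in ABERRATION_CLASSES if c not in records.columns]
    if missing:
        raise ValueError(f"missing aberration class column(s): {', '.join(missing)}")
    if (records[ABERRATION_CLASSES] < 0).any().any():
        raise ValueError("aberration counts must be non-negative")
    df = records.copy()
    df["chromatid_total"] = df[CHROMATID_CLASSES].sum(axis=1)
    df["chromosome_total"] = df[CHROMOSOME_CLASSES].sum(axis=1)
    df["total"] = df["chromatid_total"] + df["chromosome_total"]
    value_cols = ABERRATION_CLASSES + ["chromatid_total", "chromosome_total", "total"]
    by = [by] if isinstance(by, str) else list(by)
    grouped = df.groupby(by, observed=True)[value_cols]
    summary = grouped.agg(["mean", "std", "count"])
    out = pd.DataFrame(index=summary.index)
    for col in value_cols:
        out[f"{col}_mean"] = summary[(col, "mean")]
        out[f"{col}_sd"] = summary[(col, "std")]
    out["n"] = summary[(value_cols[0], "count")]
    if mitotic_fraction is not None:
        for col in ["chromatid_total", "chromosome_total", "total"]:
            out[f"{col}_per_100_cells"] = per_100_cells(out[f"{col}_mean"], mitotic_fraction)
    return out.reset_index()


def per_100_cells(mean_per_metaphase, mitotic_fraction):
    """Aberrations per 100 cells of the whole population.

    The per-metaphase mean only describes cells that reached mitosis;
    multiplying by the mitotic (p-H3-positive) fraction and by 100 refers the
    rate to 100 cells of the total population.
    """
    frac = np.asarray(mitotic_fraction, dtype=float)
    if ((frac < 0) | (frac > 1)).any():
        raise ValueError("mitotic_fraction must lie in [0, 1]")
    out = np.asarray(mean_per_metaphase, dtype=float) * frac * 100.0
    return float(out) if out.ndim == 0 else out


def sce_rate(records: pd.DataFrame, value_col: str = "sce",
             by: str = "condition") -> pd.DataFrame:
    """Mean +- sd sister chromatid exchanges per metaphase, per condition."""
    if records.empty:
        raise ValueError("no SCE records")
    if value_col not in records.columns:
        raise ValueError(f"missing column {value_col!r}")
    if (records[value_col] < 0).any():
        raise ValueError("SCE counts must be non-negative")
    g = records.groupby(by, observed=True)[value_col].agg(["mean", "std", "count"])
    return g.rename(columns={"mean": "sce_mean", "std": "sce_sd", "count": "n"}).reset_index()


def repair_efficiency(gfp_fraction_condition: float, gfp_fraction_control: float) -> float:
    """Control-relative reporter repair efficiency (1 = no change).

    Both arguments are GFP-positive percentages from the flow readout of an
    integrated DR-GFP (HR) or EJ5-GFP (NHEJ) reporter.
    """
    if gfp_fraction_control <= 0:
        raise ValueError("control GFP fraction must be > 0")
    if gfp_fraction_condition < 0:
        raise ValueError("condition GFP fraction must be >= 0")
    return float(gfp_fraction_condition / gfp_fraction_control)


def compare_groups(values_a, values_b, welch: bool = False) -> float:
    """Two-sided two-sample t-test p-value (Student by default, Welch switch)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 observations per group")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.pvalue)
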