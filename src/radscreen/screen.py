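"""Hit scoring for high-throughput clonogenic radiosensitivity screens.

The screen plates one well per siRNA target at 0 Gy and at the screening dose
(7 Gy in the assay this mirrors).  Per-target surviving fractions are
normalized to the same-run non-targeting (NT) controls and converted to an
R-score,

    R = (normalized SF - 1) / meanAD(normalized NT SF),

where meanAD is the mean absolute deviation about the mean (a config switch
selects the median-based MAD instead).  Negative R-scores denote
radiosensitization, so targets are ranked in ascending order.  Replicate
secondary-screen runs are combined by the rank product (geometric mean of
per-run ranks) with permutation p-values, and assay quality is monitored by
the Z-factor between positive (PRKDC-like) and NT controls.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

ROLE_SAMPLE = "sample"
ROLE_NT = "nt_control"
ROLE_POS = "pos_control"


def sf_from_wells(wells: pd.DataFrame, dose: float | None = None) -> pd.DataFrame:
    """Per-well surviving fraction from paired 0 Gy / dose plates.

    Each well position is paired across the unirradiated and irradiated copy
    of its plate within a run (the screening design: one siRNA per well, the
    whole plate replicated at both doses); SF = PE(dose)/PE(0) per well.
    ``dose`` defaults to the largest positive dose present.  Returns columns
    run_id, plate_id, well_id, gene_id, role, sf.
    """
    if dose is None:
        positive = wells.loc[wells["dose"] > 0, "dose"]
        if positive.empty:
            raise ValueError("no irradiated wells in table")
        dose = float(positive.max())
    keys = ["run_id", "plate_id", "well_id"]
    wells = wells.copy()
    # paired 0 Gy / irradiated plates carry a "-<dose>Gy" arm suffix
    wells["plate_id"] = wells["plate_id"].astype(str).str.replace(
        r"-[0-9.]+Gy$", "", regex=True)
    zero = wells[wells["dose"] == 0]
    irr = wells[wells["dose"] == dose]
    merged = zero.merge(irr, on=keys, suffixes=("_0", "_d"), how="outer", indicator=True)
    unpaired = merged[merged["_merge"] != "both"]
    if len(unpaired):
        ex = unpaired[keys].iloc[0].tolist()
        raise ValueError(f"well {ex} lacks a paired 0 Gy / {dose:g} Gy measurement")
    pe0 = merged["colonies_0"] / merged["cells_plated_0"]
    if (pe0 <= 0).any():
        bad = merged.loc[pe0 <= 0, keys].iloc[0].tolist()
        raise ValueError(f"well {bad} has zero 0 Gy plating efficiency; SF undefined")
    ped = merged["colonies_d"] / merged["cells_plated_d"]
    out = merged[keys].copy()
    out["gene_id"] = merged["target_0"]
    out["role"] = merged["role_0"] if "role_0" in merged else ROLE_SAMPLE
    out["sf"] = (ped / pe0).astype(float)
    return out


def normalize_sf(sf_table: pd.DataFrame) -> pd.DataFrame:
    """Divide each SF by the median NT-control SF of its run.

    The per-run median of non-targeting wells is the normalization reference;
    the median resists control outliers.  Adds a ``normalized_sf`` column.
    """
    out = sf_table.copy()
    out["normalized_sf"] = np.nan
    for run, grp in sf_table.groupby("run_id"):
        nt = grp.loc[grp["role"] == ROLE_NT, "sf"]
        if nt.empty:
            raise ValueError(f"run {run!r} has no non-targeting control wells")
        med = float(nt.median())
        if med <= 0:
            raise ValueError(f"run {run!r} NT median SF is not positive")
        out.loc[grp.index, "normalized_sf"] = grp["sf"] / med
    return out


def mean_abs_deviation(x, center: str = "mean") -> float:
    """mean |x - mean(x)| (``center='mean'``) or median |x - median(x)|."""
    x = np.asarray(x, dtype=float)
    if center == "mean":
        return float(np.mean(np.abs(x - x.mean())))
    if center == "median":
        return float(np.median(np.abs(x - np.median(x))))
    raise ValueError("center must be 'mean' or 'median'")


def r_score(normalized: pd.DataFrame, mad_center: str = "mean") -> pd.DataFrame:
    """R-score and ascending rank per gene, computed within each run.

    R = (normalized SF - 1) / meanAD(NT normalized SF).  Ranks (1 = most
    sensitizing, i.e. most negative R) are assigned to sample wells only,
    with average ranks on ties; control wells get an R-score but no rank.
    """
    out = normalize_sf(normalized) if "normalized_sf" not in normalized else normalized.copy()
    out["r_score"] = np.nan
    out["rank"] = np.nan
    for run, grp in out.groupby("run_id"):
        nt = grp.loc[grp["role"] == ROLE_NT, "normalized_sf"]
        if len(nt) < 2:
            raise ValueError(f"run {run!r} needs >= 2 NT wells for a deviation estimate")
        mad = mean_abs_deviation(nt, center=mad_center)
        if mad == 0:
            raise ValueError(f"run {run!r} NT wells have zero deviation; R-score undefined")
        out.loc[grp.index, "r_score"] = (grp["normalized_sf"] - 1.0) / mad
        samples = grp[grp["role"] == ROLE_SAMPLE]
        ranks = out.loc[samples.index, "r_score"].rank(method="average", ascending=True)
        out.loc[samples.index, "rank"] = ranks
    return out


def rank_product(tables) -> pd.DataFrame:
    """Combine per-run ascending ranks into a rank product per gene.

    ``tables`` is either a sequence of per-run frames with ``gene_id`` and
    ``rank`` columns, or one long frame with a ``run_id`` column.  Returns a
    frame indexed-free with gene_id, per-run ``rank_<i>`` columns and
    ``rp = (prod ranks)^(1/k)``, sorted ascending by rp (ties broken by mean
    rank then gene id, deterministically).
    """
    if isinstance(tables, pd.DataFrame):
        tables = [grp for _, grp in tables.groupby("run_id", sort=True)]
    tables = [t[t["rank"].notna()] if "rank" in t else t for t in tables]
    k = len(tables)
    if k < 2:
        raise ValueError("rank product needs >= 2 replicate runs")
    genes = set(tables[0]["gene_id"])
    mats = []
    for i, t in enumerate(tables):
        if set(t["gene_id"]) != genes:
            missing = genes.symmetric_difference(t["gene_id"])
            raise ValueError(f"gene set differs between runs (e.g. {sorted(missing)[:5]})")
        mats.append(t.set_index("gene_id")["rank"])
    ranks = pd.concat(mats, axis=1, keys=[f"rank_{i+1}" for i in range(k)])
    rp = np.exp(np.log(ranks.to_numpy(float)).mean(axis=1))
    out = ranks.reset_index().rename(columns={"index": "gene_id"})
    out["rp"] = rp
    out["_meanrank"] = ranks.mean(axis=1).to_numpy()
    out = (out.sort_values(["rp", "_meanrank", "gene_id"], ignore_index=True)
              .drop(columns="_meanrank"))
    return out


def _exhaustive_feasible(n_genes: int, k: int, limit: float = 1e6) -> bool:
    try:
        return math.factorial(n_genes) ** k <= limit
    except OverflowError:
        return False


def rank_product_pvalues(rp_result: pd.DataFrame, n_permutations: int = 10_000,
                         seed: int | None = None, method: str = "auto") -> pd.DataFrame:
    """Permutation p-values for rank products.

    The null permutes each run's rank column independently, so a gene's null
    ranks are uniform over the observed rank values of each run.  Monte Carlo
    p-values carry a +1 pseudo-count, p(g) = (1 + #{null rp <= rp_g}) / (1 + B),
    so they are valid (never zero).

    ``method='exhaustive'`` enumerates the collapsed null — independent
    uniform integer ranks over {1..n}^k per gene — and returns the exact
    tail probability P(null rp <= rp_g); no pseudo-count is needed because
    the observed rank tuple is itself part of the enumeration, so the
    p-value is at least 1/n^k.  ``'auto'`` chooses exhaustive when every
    distinct column permutation could be enumerated ((n!)^k <= 1e6) and
    Monte Carlo otherwise.
    """
    rank_cols = [c for c in rp_result.columns if c.startswith("rank_")]
    k = len(rank_cols)
    n = len(rp_result)
    if k < 2:
        raise ValueError("need rank columns from >= 2 runs")
    rp_obs = rp_result["rp"].to_numpy(float)
    eps = 1e-9
    if method == "auto":
        method = "exhaustive" if _exhaustive_feasible(n, k) else "permutation"
    out = rp_result.copy()
    if method == "exhaustive":
        products = np.array([math.prod(t) for t in
                             itertools.product(range(1, n + 1), repeat=k)], dtype=float)
        thresh = rp_obs**k
        counts = (products[None, :] <= thresh[:, None] * (1 + eps)).sum(axis=1)
        out["p_perm"] = counts / float(n**k)
        return out
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    rng = np.random.default_rng(seed)
    cols = [rp_result[c].to_numpy(float) for c in rank_cols]
    counts = np.zeros(n, dtype=np.int64)
    log_obs = k * np.log(rp_obs)
    for _ in range(n_permutations):
        log_rp = np.zeros(n)
        for col in cols:
            log_rp += np.log(rng.permutation(col))
        counts += log_rp <= log_obs + eps
    out["p_perm"] = (1.0 + counts) / (1.0 + n_permutations)
    return out


@dataclass
class ZFactorReport:
    """Separation of positive and negative screen controls (Zhang 1999)."""

    mu_pos: float
    sd_pos: float
    mu_neg: float
    sd_neg: float
    z_factor: float

    def summary(self) -> str:
        return (f"Z-factor: {self.z_factor:.4f}\n"
                f"  positive control: mu={self.mu_pos:.4f} sd={self.sd_pos:.4f}\n"
                f"  negative control: mu={self.mu_neg:.4f} sd={self.sd_neg:.4f}")


def z_factor(neg_values, pos_values) -> ZFactorReport:
    """Z-factor 1 - 3(sd_pos + sd_neg)/|mu_pos - mu_neg| on normalized SF."""
    neg = np.asarray(neg_values, dtype=float)
    pos = np.asarray(pos_values, dtype=float)
    if len(neg) < 2 or len(pos) < 2:
        raise ValueError("need >= 2 wells per control group")
    mu_n, mu_p = float(neg.mean()), float(pos.mean())
    sd_n, sd_p = float(neg.std(ddof=1)), float(pos.std(ddof=1))
    if mu_n == mu_p:
        raise ValueError("control means are equal; Z-factor undefined")
    z = 1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n)
    return ZFactorReport(mu_pos=mu_p, sd_pos=sd_p, mu_neg=mu_n, sd_neg=sd_n, z_factor=z)


def select_top_hits(ranking: pd.DataFrame, n: int = 240, by: str | None = None) -> list[str]:
    """First ``n`` gene ids by ascending score.

    ``by`` defaults to ``'rp'`` when a rank-product column is present
    (secondary screen) and ``'r_score'`` otherwise (primary screen).  Ties are
    broken by mean per-run rank (when available) then lexicographic gene id,
    so the selection is deterministic.  The screening design this mirrors
    carried the top 240 forward to confirmation.
    """
    if by is None:
        by = "rp" if "rp" in ranking.columns else "r_score"
    df = ranking
    if by == "r_score" and "role" in df.columns:
        df = df[df["role"] == ROLE_SAMPLE]
    if n > len(df):
        raise ValueError(f"requested top {n} of only {len(df)} genes")
    rank_cols = [c for c in df.columns if c.startswith("rank_")]
    keys = [by]
    sort_df = df.copy()
    if rank_cols:
        sort_df["_meanrank"] = sort_df[rank_cols].mean(axis=1)
        keys.append("_meanrank")
    elif "rank" in sort_df.columns:
        keys.append("rank")
    keys.append("gene_id")
    sort_df = sort_df.sort_values(keys, kind="mergesort", ignore_index=True)
    return sort_df["gene_id"].head(n).tolist()
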