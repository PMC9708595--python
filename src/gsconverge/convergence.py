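"""Per-frequency FDR control and cross-frequency convergence correlations.

Significance is controlled at 5% false discovery rate (Benjamini-Hochberg)
within each variant-frequency family across all analysed sets.  Convergence
between two arms (e.g. common vs ultra-rare PTV) is summarised by the
correlation of per-set enrichment betas — Pearson and Spearman both reported,
plus a weighted Pearson estimate with weights 1 / (se_a * se_b), so precisely
estimated pairs dominate.  The weighted estimator is invariant to rescaling
all weights by a positive constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ConvergenceResult:
    pair: tuple[str, str]
    n_sets: int
    pearson: float
    spearman: float
    weighted_pearson: float
    overlap_sets: tuple[str, ...] = ()
    table: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)


def bh_fdr(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags, in input order.

    NaN p-values (failed/skipped sets) are never rejected and do not count
    toward the family size.
    """
    p = np.asarray(pvals, dtype=float)
    flags = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if ok.sum() == 0:
        return flags
    if np.any((p[ok] <= 0.0) | (p[ok] > 1.0)):
        raise ValueError("p-values must lie in (0, 1]")
    if q <= 0.0:
        return flags
    flags[ok] = multipletests(p[ok], alpha=q, method="fdr_bh")[0]
    return flags


def weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted product-moment correlation with normalized weights."""
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    w = w / w.sum()
    mx, my = np.sum(w * x), np.sum(w * y)
    cov = np.sum(w * (x - mx) * (y - my))
    vx = np.sum(w * (x - mx) ** 2)
    vy = np.sum(w * (y - my) ** 2)
    return float(cov / np.sqrt(vx * vy))


def correlate_enrichment(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    pair: tuple[str, str] = ("a", "b"),
    fdr_q: float = 0.05,
) -> ConvergenceResult:
    """Convergence of per-set betas between two result tables.

    Tables need columns set_name, beta, se, p (one primary row per set).
    Pairs with missing beta/se on either side are dropped; at least 3 shared
    sets are required.  ``overlap_sets`` are the sets BH-significant in both
    families.
    """
    a = results_a[["set_name", "beta", "se", "p"]].rename(
        columns={"beta": "beta_a", "se": "se_a", "p": "p_a"}
    )
    b = results_b[["set_name", "beta", "se", "p"]].rename(
        columns={"beta": "beta_b", "se": "se_b", "p": "p_b"}
    )
    merged = a.merge(b, on="set_name", how="inner")
    merged = merged.dropna(subset=["beta_a", "se_a", "beta_b", "se_b"]).reset_index(drop=True)
    if len(merged) < 3:
        raise ValueError(f"need >= 3 shared sets with estimates, got {len(merged)}")
    if (merged["se_a"] <= 0).any() or (merged["se_b"] <= 0).any():
        raise ValueError("standard errors must be positive")
    merged["weight"] = 1.0 / (merged["se_a"] * merged["se_b"])

    x = merged["beta_a"].to_numpy()
    y = merged["beta_b"].to_numpy()
    pearson = float(stats.pearsonr(x, y).statistic)
    spearman = float(stats.spearmanr(x, y).statistic)
    wp = weighted_pearson(x, y, merged["weight"].to_numpy())

    sig_a = bh_fdr(merged["p_a"].to_numpy(), q=fdr_q)
    sig_b = bh_fdr(merged["p_b"].to_numpy(), q=fdr_q)
    overlap = tuple(merged.loc[sig_a & sig_b, "set_name"].sort_values())
    return ConvergenceResult(
        pair=pair,
        n_sets=len(merged),
        pearson=pearson,
        spearman=spearman,
        weighted_pearson=wp,
        overlap_sets=overlap,
        table=merged,
    )


def primary_rows(results: pd.DataFrame) -> pd.DataFrame:
    """Unconditioned, successful rows: one per analysed set."""
    mask = results["conditioned_on"].fillna("").eq("") & results["status"].isin(["ok", "firth"])
    return results.loc[mask].copy()


def apply_fdr(results: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """Flag BH-FDR significance within each variant-class family (primary rows only)."""
    out = results.copy()
    out["fdr_significant"] = False
    prim = out["conditioned_on"].fillna("").eq("")
    for vclass, sub in out.loc[prim].groupby("variant_class"):
        flags = bh_fdr(sub["p"].to_numpy(), q=q)
        out.loc[sub.index, "fdr_significant"] = flags
    return out


def convergence_report(
    common_results: pd.DataFrame,
    rare_results_by_class: dict[str, pd.DataFrame],
    fdr_q: float = 0.05,
) -> tuple[list[ConvergenceResult], pd.DataFrame]:
    """One ConvergenceResult per (common, rare-class) pair, plus a summary table.

    The headline pair is common vs ultra-rare PTV.  Raises if a rare table
    does not cover the common arm's analysed sets.
    """
    common_primary = primary_rows(common_results)
    out = []
    rows = []
    for vclass, rare in rare_results_by_class.items():
        rare_primary = primary_rows(rare)
        missing = set(common_primary["set_name"]) - set(rare_primary["set_name"])
        shared = set(common_primary["set_name"]) & set(rare_primary["set_name"])
        if len(shared) < 3:
            raise ValueError(
                f"{vclass}: fewer than 3 sets shared with the common arm; "
                f"missing e.g. {sorted(missing)[:5]}"
            )
        res = correlate_enrichment(common_primary, rare_primary,
                                   pair=("common", vclass), fdr_q=fdr_q)
        out.append(res)
        rows.append((vclass, res.n_sets, res.pearson, res.spearman,
                     res.weighted_pearson, len(res.overlap_sets),
                     ";".join(res.overlap_sets)))
    summary = pd.DataFrame(
        rows,
        columns=["rare_class", "n_sets", "pearson", "spearman",
                 "weighted_pearson", "n_overlap", "overlap_sets"],
    )
    return out, summary
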