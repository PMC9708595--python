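"""(Ultra-)rare variant classification, sample QC and burden regression.

Variant frequency classes (AF uses the combined cohort + reference panel
denominator 2 * panel_total_n):

* ``singleton`` (ultra-rare, URV): total allele count AC = 1 across cohort and
  reference panels combined;
* ``rare_incl``: AF < 0.1% (includes singletons);
* ``rare_excl``: AF < 0.1% and AC >= 2 (excludes singletons).

Each class is crossed with consequence (PTV vs synonymous); synonymous
variants serve as negative controls.  Enrichment per gene-set is the
coefficient of the per-individual qualifying-allele burden in a logistic
regression of case status, with sex, 10 PCs and (optionally) the exome-wide
qualifying count of the same class as covariates.  Sample QC excludes
individuals more than k = 4 unscaled median absolute deviations from the
cohort median synonymous count of the matching class.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._glm import firth_logit
from .common_enrichment import CollinearityError, EnrichmentResult
from .genesets import GeneSetCollection
from .synthetic_data import ExomeCohort

logger = logging.getLogger(__name__)

FREQ_CLASSES = ("urv", "rare", "rare_excl")
CONSEQUENCES = {"ptv": "PTV", "syn": "synonymous"}

VARIANT_CLASSES = tuple(f"{f}_{c}" for f in FREQ_CLASSES for c in CONSEQUENCES)


class DegenerateBurdenError(ValueError):
    """The burden score carries no information (constant)."""


def classify_variants(
    variants: pd.DataFrame, panel_total_n: int, af_max: float = 0.001
) -> pd.DataFrame:
    """Annotate variants with total AC, AF and the frequency-class flags."""
    if panel_total_n <= 0:
        raise ValueError("panel_total_n must be positive")
    v = variants.copy()
    if (v["ac_sample"] < 0).any() or (v["ac_ref"] < 0).any():
        raise ValueError("allele counts must be nonnegative")
    v["ac_total"] = v["ac_sample"] + v["ac_ref"]
    v["af"] = v["ac_total"] / (2.0 * panel_total_n)
    v["singleton"] = v["ac_total"] == 1
    # an unobserved allele (AC = 0) belongs to no frequency class
    v["rare_incl"] = (v["af"] < af_max) & (v["ac_total"] >= 1)
    v["rare_excl"] = v["rare_incl"] & (v["ac_total"] >= 2)
    return v


def class_mask(classified: pd.DataFrame, variant_class: str) -> pd.Series:
    """Boolean mask of qualifying variants for a crossed class label like 'urv_ptv'."""
    freq, cons = variant_class.rsplit("_", 1)
    if cons not in CONSEQUENCES:
        raise ValueError(f"unknown consequence in {variant_class!r}")
    flag = {"urv": "singleton", "rare": "rare_incl", "rare_excl": "rare_excl"}[freq]
    return classified[flag] & (classified["consequence"] == CONSEQUENCES[cons])


def sample_qc_mad(syn_counts: pd.Series, k: float = 4.0) -> pd.Series:
    """Keep flags: exclude |x - median| strictly greater than k * unscaled MAD.

    With MAD = 0 any nonzero deviation excludes, a deliberate edge of the
    unscaled definition.
    """
    if len(syn_counts) == 0:
        raise ValueError("need at least one individual")
    med = syn_counts.median()
    mad = (syn_counts - med).abs().median()
    return (syn_counts - med).abs() <= k * mad


def burden_score(
    cohort: ExomeCohort,
    members: set[str] | frozenset[str] | None,
    classified: pd.DataFrame,
    variant_class: str,
    individuals: pd.Index | None = None,
) -> pd.Series:
    """Per-individual qualifying allele count in the set (``members=None`` = exome-wide)."""
    mask = class_mask(classified, variant_class)
    if members is not None:
        known = set(classified["gene_id"].unique())
        unknown = set(members) - known
        if unknown:
            logger.info("%d set gene ids carry no variants / unknown", len(unknown))
        mask = mask & classified["gene_id"].isin(members)
    vids = classified.loc[mask, "variant_id"]
    idx = individuals if individuals is not None else pd.Index(cohort.individuals["iid"])
    carried = cohort.carriers[cohort.carriers["variant_id"].isin(set(vids))]
    counts = carried.groupby("iid")["n_alleles"].sum()
    return counts.reindex(idx, fill_value=0).astype(np.int64)


def _logit_fit(y: np.ndarray, X: pd.DataFrame) -> tuple[pd.Series, pd.Series, pd.Series, str]:
    """ML logistic fit with Firth fallback on separation/non-convergence."""
    Xc = sm.add_constant(X, has_constant="add")
    method = "ml"
    try:
        fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        ok = (
            fit.mle_retvals.get("converged", True)
            and np.all(np.isfinite(fit.bse))
            and np.all(np.abs(fit.params) < 30)
        )
    except Exception:
        ok = False
    if ok:
        return fit.params, fit.bse, fit.pvalues, method
    beta, se, _ = firth_logit(y.astype(float), Xc.to_numpy(dtype=float))
    from scipy import stats as sps

    params = pd.Series(beta, index=Xc.columns)
    bse = pd.Series(se, index=Xc.columns)
    zval = params / bse
    pvals = pd.Series(2.0 * sps.norm.sf(np.abs(zval)), index=Xc.columns)
    return params, bse, pvals, "firth"


def burden_regression(
    individuals: pd.DataFrame,
    burden: pd.Series,
    variant_class: str,
    exome_wide: pd.Series | None = None,
    conditioning: dict[str, pd.Series] | None = None,
    set_name: str = "",
) -> EnrichmentResult:
    """Logistic regression of case status on the burden score.

    Covariates: sex, PC1..PC10, optionally the exome-wide count of the same
    class, and any conditioning burden scores.  The reported beta is the
    per-allele log-odds with a two-sided Wald p.
    """
    y = individuals["case"].to_numpy()
    if len(np.unique(y)) < 2:
        raise DegenerateBurdenError("both case and control individuals are required")
    b = burden.loc[individuals["iid"]].to_numpy(dtype=float)
    if np.ptp(b) == 0.0:
        raise DegenerateBurdenError(f"set {set_name!r}: constant burden score")
    X = pd.DataFrame({"burden": b})
    X["sex"] = individuals["sex"].to_numpy(dtype=float)
    for j in range(10):
        X[f"PC{j + 1}"] = individuals[f"PC{j + 1}"].to_numpy(dtype=float)
    # zero-variance covariates are absorbed by the intercept
    X = X.loc[:, [c for c in X.columns if c == "burden" or np.ptp(X[c].to_numpy()) > 0]]
    if exome_wide is not None:
        X["exome_wide"] = exome_wide.loc[individuals["iid"]].to_numpy(dtype=float)
    cond_names: list[str] = []
    for name, score in (conditioning or {}).items():
        s = score.loc[individuals["iid"]].to_numpy(dtype=float)
        if np.ptp(s) == 0.0:
            logger.warning("conditioning burden %r is constant; dropped", name)
            continue
        if np.array_equal(s, b):
            raise CollinearityError(f"conditioning burden {name!r} identical to focal burden")
        X[f"cond_{name}"] = s
        cond_names.append(name)
    params, bse, pvals, method = _logit_fit(y, X)
    return EnrichmentResult(
        set_name,
        variant_class,
        n_genes=0,
        beta=float(params["burden"]),
        se=float(bse["burden"]),
        p=float(pvals["burden"]),
        conditioned_on=tuple(sorted(cond_names)),
        status="ok" if method == "ml" else "firth",
    )


def conditional_burden(
    individuals: pd.DataFrame,
    focal: pd.Series,
    conditioning: dict[str, pd.Series],
    variant_class: str,
    exome_wide: pd.Series | None = None,
    set_name: str = "",
) -> EnrichmentResult:
    """Burden regression with other sets' burden scores as covariates."""
    return burden_regression(
        individuals, focal, variant_class,
        exome_wide=exome_wide, conditioning=conditioning, set_name=set_name,
    )


def default_rare_conditioning_plan(
    collection: GeneSetCollection,
) -> list[tuple[str, tuple[str, ...]]]:
    """Intersection sets conditioned on parent cell-set burden, PI burden, and both."""
    plan = []
    for gs in collection:
        if gs.category == "intersection":
            parent = gs.name.removesuffix("_x_PI")
            plan.append((gs.name, (parent,)))
            plan.append((gs.name, ("PI",)))
            plan.append((gs.name, (parent, "PI")))
    return plan


def run_rare(
    cohort: ExomeCohort,
    collection: GeneSetCollection,
    classes: tuple[str, ...] = ("urv_ptv", "urv_syn", "rare_ptv", "rare_syn"),
    af_max: float = 0.001,
    mad_k: float = 4.0,
    adjust_exome_wide: bool = True,
    min_set_genes: int = 10,
    conditioning_plan: list[tuple[str, tuple[str, ...]]] | None = None,
) -> pd.DataFrame:
    """Full rare arm: classify, per-class MAD sample QC, one row per set x class.

    Per-set failures are recorded as status rows; the batch continues.
    """
    if len(cohort.individuals) == 0:
        raise ValueError("empty cohort")
    classified = classify_variants(cohort.variants, cohort.panel_total_n, af_max=af_max)
    all_iids = pd.Index(cohort.individuals["iid"])

    rows = []

    def _append(set_name, category, vclass, res: EnrichmentResult | None,
                status="ok", cond=(), n_genes=0):
        if res is None:
            rows.append((set_name, category, vclass, n_genes, np.nan, np.nan, np.nan,
                         ";".join(cond), status))
        else:
            rows.append((set_name, category, vclass, n_genes, res.beta, res.se,
                         res.p, ";".join(res.conditioned_on), res.status))

    for vclass in classes:
        freq = vclass.rsplit("_", 1)[0]
        syn_counts = burden_score(cohort, None, classified, f"{freq}_syn", all_iids)
        keep = sample_qc_mad(syn_counts, k=mad_k)
        ind = cohort.individuals.loc[keep.loc[all_iids].to_numpy()]
        kept_idx = pd.Index(ind["iid"])
        logger.info("%s: MAD QC keeps %d / %d individuals", vclass, len(ind), len(all_iids))
        exome_wide = (
            burden_score(cohort, None, classified, vclass, kept_idx)
            if adjust_exome_wide else None
        )
        set_scores: dict[str, pd.Series] = {}
        for gs in collection:
            set_scores[gs.name] = burden_score(
                cohort, gs.member_set(), classified, vclass, kept_idx
            )
        for gs in collection:
            if len(gs) < min_set_genes:
                _append(gs.name, gs.category, vclass, None, status="skipped_small",
                        n_genes=len(gs))
                continue
            try:
                res = burden_regression(
                    ind, set_scores[gs.name], vclass,
                    exome_wide=exome_wide, set_name=gs.name,
                )
                _append(gs.name, gs.category, vclass, res, n_genes=len(gs))
            except DegenerateBurdenError:
                _append(gs.name, gs.category, vclass, None, status="degenerate",
                        n_genes=len(gs))
        for set_name, cond_names in (conditioning_plan or []):
            if set_name not in collection.analysed:
                continue
            gs = collection.analysed[set_name]
            try:
                res = conditional_burden(
                    ind, set_scores[set_name],
                    {c: set_scores[c] for c in cond_names if c in set_scores},
                    vclass, exome_wide=exome_wide, set_name=set_name,
                )
                _append(set_name, gs.category, vclass, res, cond=cond_names,
                        n_genes=len(gs))
            except (DegenerateBurdenError, CollinearityError) as exc:
                _append(set_name, gs.category, vclass, None,
                        status=f"error:{type(exc).__name__}", cond=cond_names,
                        n_genes=len(gs))

    return pd.DataFrame(
        rows,
        columns=["set_name", "category", "variant_class", "n_genes",
                 "beta", "se", "p", "conditioned_on", "status"],
    )
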