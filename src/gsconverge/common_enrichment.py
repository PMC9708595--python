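"""LD-aware gene association and competitive gene-set regression on GWAS summary stats.

Pipeline: SNP QC (duplicates removed, INFO < 0.8 removed) -> SNPs assigned to
genes by closed-interval position (no window) -> per-gene statistic
T = sum of per-SNP chi-squares, with null distribution sum_i lambda_i chi2_1,
lambda_i the eigenvalues of the block correlation matrix R -> gene p-value by
Imhof inversion (three-moment fallback) -> probit gene z-scores -> competitive
linear regression of z on set membership plus gene-level covariates (gene
length, SNP count and their logs), optionally with conditioning set indicators
as additional covariates.  Inference is OLS, valid under the one-independent-
block-per-gene design of the synthetic data; a user-supplied gene correlation
matrix switches the set test to GLS for correlated-gene inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._quadform import P_CEIL, P_FLOOR, weighted_chi2_sf
from .genesets import GeneSetCollection
from .synthetic_data import LDReference

logger = logging.getLogger(__name__)

Z_CLAMP = 37.0  # double-precision probit limit
PSD_TOL = 1e-6


class DegenerateDesignError(ValueError):
    """Competitive regression cannot be formed (empty or universal set)."""


class CollinearityError(ValueError):
    """A conditioning indicator coincides with the focal membership."""


@dataclass(frozen=True)
class GeneStat:
    gene_id: str
    n_snps: int
    T: float
    p_gene: float
    z: float
    method: str


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    variant_class: str
    n_genes: int
    beta: float
    se: float
    p: float
    conditioned_on: tuple[str, ...] = ()
    status: str = "ok"
    fdr_significant: bool = False


def qc_gwas(gwas: pd.DataFrame, info_min: float = 0.8) -> pd.DataFrame:
    """Remove all copies of duplicated SNP ids, then SNPs with INFO < info_min."""
    n0 = len(gwas)
    dup = gwas["SNP"].duplicated(keep=False)
    out = gwas.loc[~dup]
    n_dup = n0 - len(out)
    out = out.loc[out["INFO"] >= info_min].reset_index(drop=True)
    logger.info("qc_gwas: %d duplicates removed, %d low-INFO removed, %d kept",
                n_dup, n0 - n_dup - len(out), len(out))
    if len(out) == 0:
        logger.warning("qc_gwas produced an empty summary table")
    return out


def annotate_snps(gwas: pd.DataFrame, genes: pd.DataFrame, window: int = 0) -> pd.DataFrame:
    """Assign SNPs to genes by 1-based closed-interval containment (+/- window).

    Returns a long (gene_id, SNP) table; SNPs in overlapping genes appear once
    per gene, SNPs in no gene are dropped.
    """
    pieces = []
    for chrom, gsub in genes.groupby("chrom", sort=True):
        ssub = gwas.loc[gwas["CHR"] == chrom]
        if ssub.empty:
            continue
        bp = ssub["BP"].to_numpy()
        for start, stop, gid in zip(
            gsub["start"].to_numpy(), gsub["stop"].to_numpy(), gsub["gene_id"].to_numpy()
        ):
            inside = (bp >= start - window) & (bp <= stop + window)
            if inside.any():
                pieces.append(pd.DataFrame({"gene_id": gid, "SNP": ssub["SNP"].to_numpy()[inside]}))
    if not pieces:
        return pd.DataFrame(columns=["gene_id", "SNP"])
    return pd.concat(pieces, ignore_index=True)


def gene_pvalue(snp_ps: np.ndarray, R: np.ndarray, gene_id: str = "") -> GeneStat:
    """Sum-of-chi-squares gene statistic with weighted-chi-square null tail."""
    p = np.asarray(snp_ps, dtype=float)
    if p.size == 0:
        raise ValueError("no SNP p-values supplied")
    if np.any((p <= 0.0) | (p > 1.0)):
        raise ValueError("SNP p-values must lie in (0, 1]; clamp zeros upstream")
    R = np.atleast_2d(np.asarray(R, dtype=float))
    if R.shape != (p.size, p.size):
        raise ValueError("R dimension does not match number of SNPs")
    lam = np.linalg.eigvalsh((R + R.T) / 2.0)
    if lam.min() < -PSD_TOL:
        raise ValueError(f"R is not positive semidefinite (min eigenvalue {lam.min():.3g})")
    chi = stats.chi2.isf(p, df=1)
    T = float(np.sum(chi))
    p_gene, method = weighted_chi2_sf(T, np.clip(lam, 0.0, None))
    p_gene = float(np.clip(p_gene, P_FLOOR, P_CEIL))
    z = float(np.clip(stats.norm.isf(p_gene), -Z_CLAMP, Z_CLAMP))
    return GeneStat(gene_id, p.size, T, p_gene, z, method)


def compute_gene_stats(
    gwas: pd.DataFrame, ld: LDReference, genes: pd.DataFrame, window: int = 0
) -> pd.DataFrame:
    """Gene-level statistics for every gene with at least one QC-passing SNP."""
    assign = annotate_snps(gwas, genes, window=window)
    kept = assign.groupby("gene_id")["SNP"].apply(list)
    pmap = gwas.set_index("SNP")["P"]
    rows = []
    for gid, snps in kept.items():
        if gid not in ld:
            continue
        block_snps, R = ld[gid]
        pos = {s: i for i, s in enumerate(block_snps)}
        idx = [pos[s] for s in snps if s in pos]
        if not idx:
            continue
        sub_snps = [block_snps[i] for i in idx]
        Rsub = R[np.ix_(idx, idx)]
        gs = gene_pvalue(pmap.loc[sub_snps].to_numpy(), Rsub, gene_id=gid)
        rows.append((gid, gs.n_snps, gs.T, gs.p_gene, gs.z, gs.method))
    out = pd.DataFrame(rows, columns=["gene_id", "n_snps", "T", "p_gene", "z", "method"])
    return out.merge(genes[["gene_id", "start", "stop"]], on="gene_id").assign(
        gene_length=lambda d: d["stop"] - d["start"] + 1
    )[["gene_id", "n_snps", "T", "p_gene", "z", "method", "gene_length"]]


def default_gene_covariates(gene_stats: pd.DataFrame) -> pd.DataFrame:
    """MAGMA-like covariates: gene length, SNP count, and their logs."""
    cov = pd.DataFrame(index=gene_stats.index)
    cov["gene_length"] = gene_stats["gene_length"].to_numpy(dtype=float)
    cov["n_snps"] = gene_stats["n_snps"].to_numpy(dtype=float)
    cov["log_gene_length"] = np.log(cov["gene_length"])
    cov["log_n_snps"] = np.log(cov["n_snps"])
    return cov


def _ols_set_test(
    z: np.ndarray,
    membership: np.ndarray,
    covariates: pd.DataFrame | None,
    conditioning: dict[str, np.ndarray] | None,
    one_sided: bool,
) -> tuple[float, float, float]:
    X = pd.DataFrame({"member": membership.astype(float)})
    if conditioning:
        for name, ind in conditioning.items():
            X[f"cond_{name}"] = np.asarray(ind, dtype=float)
    if covariates is not None:
        for c in covariates.columns:
            col = covariates[c].to_numpy(dtype=float)
            if np.ptp(col) > 0:  # constant covariates are absorbed by the intercept
                X[c] = col
    X = sm.add_constant(X, has_constant="add")
    if np.ptp(z) == 0.0:
        return 0.0, 0.0, 0.5
    fit = sm.OLS(z, X).fit()
    beta = float(fit.params["member"])
    se = float(fit.bse["member"])
    if one_sided:
        p = float(stats.t.sf(fit.tvalues["member"], fit.df_resid))
    else:
        p = float(fit.pvalues["member"])
    return beta, se, min(max(p, P_FLOOR), 1.0)


def competitive_test(
    gene_z: pd.Series,
    members: set[str] | frozenset[str],
    covariates: pd.DataFrame | None = None,
    set_name: str = "",
    one_sided: bool = True,
) -> EnrichmentResult:
    """Competitive test: is mean gene z inside the set above the outside mean?

    Linear regression of gene z on the membership indicator, an intercept and
    gene-level covariates; the reported p is one-sided for beta > 0 by default.
    """
    finite = np.isfinite(gene_z.to_numpy())
    z = gene_z.to_numpy()[finite]
    idx = gene_z.index[finite]
    m = np.asarray(idx.isin(members), dtype=int)
    if m.sum() < 2 or (len(m) - m.sum()) < 2:
        raise DegenerateDesignError(
            f"set {set_name!r}: needs >= 2 member and >= 2 non-member genes with finite z"
        )
    cov = covariates.loc[finite].reset_index(drop=True) if covariates is not None else None
    beta, se, p = _ols_set_test(z, m, cov, None, one_sided)
    return EnrichmentResult(set_name, "common", int(m.sum()), beta, se, p)


def conditional_competitive(
    gene_z: pd.Series,
    members: set[str] | frozenset[str],
    conditioning: dict[str, set[str]],
    covariates: pd.DataFrame | None = None,
    set_name: str = "",
    one_sided: bool = True,
) -> EnrichmentResult:
    """Competitive test with conditioning set indicators as extra covariates."""
    finite = np.isfinite(gene_z.to_numpy())
    z = gene_z.to_numpy()[finite]
    idx = gene_z.index[finite]
    m = np.asarray(idx.isin(members), dtype=int)
    cond_arrays = {}
    for name, cset in conditioning.items():
        ind = np.asarray(idx.isin(cset), dtype=int)
        if np.array_equal(ind, m):
            raise CollinearityError(
                f"conditioning set {name!r} is identical to the focal membership"
            )
        cond_arrays[name] = ind
    if m.sum() < 2 or (len(m) - m.sum()) < 2:
        raise DegenerateDesignError(f"set {set_name!r}: degenerate membership")
    cov = covariates.loc[finite].reset_index(drop=True) if covariates is not None else None
    beta, se, p = _ols_set_test(z, m, cov, cond_arrays, one_sided)
    return EnrichmentResult(
        set_name, "common", int(m.sum()), beta, se, p,
        conditioned_on=tuple(sorted(conditioning)),
    )


def default_conditioning_plan(collection: GeneSetCollection) -> list[tuple[str, tuple[str, ...]]]:
    """The study's conditioning schemes.

    Brain cell and intersection sets are conditioned on each brain-expressed
    background set; intersection sets additionally on their parent cell set,
    on PI, and on both.
    """
    plan: list[tuple[str, tuple[str, ...]]] = []
    backgrounds = list(collection.background)
    for gs in collection:
        if gs.category in ("human_cell", "mouse_cell", "intersection"):
            for bg in backgrounds:
                plan.append((gs.name, (bg,)))
        if gs.category == "intersection":
            parent = gs.name.removesuffix("_x_PI")
            plan.append((gs.name, (parent,)))
            plan.append((gs.name, ("PI",)))
            plan.append((gs.name, (parent, "PI")))
    return plan


def run_common(
    gwas: pd.DataFrame,
    ld: LDReference,
    genes: pd.DataFrame,
    collection: GeneSetCollection,
    conditioning_plan: list[tuple[str, tuple[str, ...]]] | None = None,
    info_min: float = 0.8,
    min_set_genes: int = 10,
    one_sided: bool = True,
) -> pd.DataFrame:
    """Full common-variant arm: QC, gene stats, one row per set (+conditioned rows).

    Per-set failures become status rows; the batch never aborts.
    """
    clean = qc_gwas(gwas, info_min=info_min)
    gene_stats = compute_gene_stats(clean, ld, genes)
    if gene_stats.empty:
        return pd.DataFrame(
            columns=["set_name", "category", "variant_class", "n_genes",
                     "beta", "se", "p", "conditioned_on", "status"]
        )
    gene_z = pd.Series(gene_stats["z"].to_numpy(), index=gene_stats["gene_id"])
    covariates = default_gene_covariates(gene_stats)

    rows = []

    def _append(set_name, category, res: EnrichmentResult | None, status="ok", cond=()):
        if res is None:
            rows.append((set_name, category, "common", 0, np.nan, np.nan, np.nan,
                         ";".join(cond), status))
        else:
            rows.append((res.set_name, category, "common", res.n_genes, res.beta,
                         res.se, res.p, ";".join(res.conditioned_on), res.status))

    for gs in collection:
        n_in_universe = int(gene_z.index.isin(gs.member_set()).sum())
        if n_in_universe < min_set_genes:
            _append(gs.name, gs.category, None, status="skipped_small")
            continue
        try:
            res = competitive_test(gene_z, gs.member_set(), covariates,
                                   set_name=gs.name, one_sided=one_sided)
            _append(gs.name, gs.category, res)
        except DegenerateDesignError:
            _append(gs.name, gs.category, None, status="degenerate")

    for set_name, cond_names in (conditioning_plan or []):
        if set_name not in collection.analysed:
            continue
        gs = collection.analysed[set_name]
        conditioning = {}
        missing = [c for c in cond_names
                   if c not in collection.analysed and c not in collection.background]
        if missing:
            _append(set_name, gs.category, None, status=f"missing_conditioning:{','.join(missing)}",
                    cond=cond_names)
            continue
        for c in cond_names:
            conditioning[c] = set(collection.get(c).members)
        try:
            res = conditional_competitive(gene_z, gs.member_set(), conditioning,
                                          covariates, set_name=set_name, one_sided=one_sided)
            _append(set_name, gs.category, res, cond=cond_names)
        except (DegenerateDesignError, CollinearityError) as exc:
            _append(set_name, gs.category, None, status=f"error:{type(exc).__name__}",
                    cond=cond_names)

    return pd.DataFrame(
        rows,
        columns=["set_name", "category", "variant_class", "n_genes",
                 "beta", "se", "p", "conditioned_on", "status"],
    )
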