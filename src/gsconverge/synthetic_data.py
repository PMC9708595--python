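"""Seeded generators for every pipeline input.

The real study analysed restricted data (case-control GWAS summary statistics,
an exome-sequenced case-control cohort, constraint scores, brain single-cell
expression).  This module emulates the *statistical structure* those analyses
assume so every downstream stage is verifiable:

* SNP z-scores with AR(1) block LD, one independent block per gene, and
  set-specific per-SNP effect-variance inflation (planted common-variant
  enrichment);
* a case-control exome cohort with Poisson qualifying-variant counts, a
  prospective logistic disease model with a planted per-allele burden log-odds
  in chosen causal sets, and synonymous variants that are null by construction;
* bimodal constraint (pLI) scores from a two-component Beta mixture so a
  pLI > 0.9 subset exists;
* expression matrices with disjoint planted marker genes per cell type and a
  mouse-to-human homology map with configurable coverage and ambiguity.

All randomness flows from ``SimConfig.seed`` through per-stage child seeds, so
identical configurations give bit-identical outputs.

None of the distributional choices below are claims about real schizophrenia
data; they are documented stand-ins (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .genesets import GeneSet, GeneSetCollection

__all__ = [
    "SimConfig",
    "LDReference",
    "ExomeCohort",
    "gen_gene_table",
    "gen_expression",
    "gen_homology",
    "gen_synaptic_annotation",
    "gen_gwas",
    "gen_exome_cohort",
]

DEFAULT_SYNAPTIC_SIZES = tuple(50 + 7 * i for i in range(35))


@dataclass(frozen=True)
class SimConfig:
    """Study-scale defaults for the synthetic inputs.

    The GWAS sample size mirrors the European schizophrenia GWAS (105,318
    individuals); cell-type counts mirror the 14 human and 24 mouse (level 1)
    brain cell types; the reference panel denominator mirrors the 188,023
    individuals used for singleton calling; the exome arm defaults to a
    balanced 4000/4000 cohort with a planted per-allele log-odds of 0.3.
    """

    n_genes: int = 12_000
    n_cell_types_human: int = 14
    n_cell_types_mouse: int = 24
    markers_per_type: int = 120
    synaptic_set_sizes: tuple[int, ...] = DEFAULT_SYNAPTIC_SIZES
    ld_block_size: int = 8
    ld_rho: float = 0.7
    gwas_n: int = 105_318
    tau2_null: float = 1e-6
    tau2_enriched: float = 5e-6
    enriched_set_names: tuple[str, ...] = ("PI", "human_ct01", "mouse_ct01")
    n_cases: int = 4000
    n_controls: int = 4000
    mu_ptv: float = 1e-4
    mu_syn: float = 5e-4
    burden_logor: float = 0.3
    ref_panel_n: int = 188_023
    seed: int = 0

    # stand-in nuisance parameters (not part of the study's printed constants)
    pli_p_hi: float = 0.15
    pli_beta_lo: tuple[float, float] = (0.5, 8.0)
    pli_beta_hi: tuple[float, float] = (8.0, 0.5)
    expr_marker_fold: float = 5.0
    expr_noise_sd: float = 0.3
    homology_coverage: float = 0.9
    homology_ambiguous_frac: float = 0.02
    singleton_frac: float = 0.5
    ref_ac_rate: float = 3.0
    dup_snp_frac: float = 0.0
    low_info_frac: float = 0.0
    sex_logor: float = 0.1
    pc1_logor: float = 0.05

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cell_types_human", "n_cell_types_mouse",
                     "markers_per_type", "ld_block_size", "gwas_n",
                     "n_cases", "n_controls", "ref_panel_n"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in [0, 1)")
        if self.tau2_null < 0 or self.tau2_enriched < 0:
            raise ValueError("tau2 values must be nonnegative")
        if self.mu_ptv < 0 or self.mu_syn < 0:
            raise ValueError("mutation rates must be nonnegative")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)

    def rng(self, stage: str) -> np.random.Generator:
        """Stage-scoped generator: stable against changes to other stages."""
        stage_key = int.from_bytes(stage.encode(), "little") % (2**31)
        return np.random.default_rng(np.random.SeedSequence([self.seed, stage_key]))


@dataclass
class LDReference:
    """Per-gene LD blocks: SNP id list plus correlation matrix (unit diagonal)."""

    blocks: dict[str, tuple[list[str], np.ndarray]]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.blocks

    def __getitem__(self, gene_id: str) -> tuple[list[str], np.ndarray]:
        return self.blocks[gene_id]


@dataclass
class ExomeCohort:
    """Individuals, qualifying variants and carrier incidence.

    ``individuals``: iid, case (0/1), sex (0/1), PC1..PC10.
    ``variants``: variant_id, gene_id, consequence (PTV|synonymous),
    ac_sample, ac_ref.
    ``carriers``: long table (variant_id, iid, n_alleles).
    ``panel_total_n``: cohort + reference individuals, the denominator for
    allele frequencies and singleton calling.
    """

    individuals: pd.DataFrame
    variants: pd.DataFrame
    carriers: pd.DataFrame
    panel_total_n: int


def gen_gene_table(cfg: SimConfig) -> pd.DataFrame:
    """Non-overlapping gene intervals on synthetic chromosomes with mixture pLI."""
    if cfg.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = cfg.rng("gene_table")
    n = cfg.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]
    n_chrom = min(22, n)
    chroms = np.sort(rng.integers(1, n_chrom + 1, size=n))
    lengths = np.maximum(200, np.exp(rng.normal(9.3, 0.9, size=n))).astype(np.int64)
    gaps = rng.integers(1_000, 50_000, size=n)
    starts = np.empty(n, dtype=np.int64)
    pos = {}
    for i in range(n):
        c = chroms[i]
        starts[i] = pos.get(c, 1) + gaps[i]
        pos[c] = starts[i] + lengths[i]
    is_hi = rng.random(n) < cfg.pli_p_hi
    pli = np.where(
        is_hi,
        rng.beta(*cfg.pli_beta_hi, size=n),
        rng.beta(*cfg.pli_beta_lo, size=n),
    )
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": [f"chr{c}" for c in chroms],
            "start": starts,
            "stop": starts + lengths - 1,
            "pli": pli,
        }
    )


def gen_expression(
    gene_ids: list[str],
    n_cell_types: int,
    markers_per_type: int,
    seed_rng: np.random.Generator,
    prefix: str = "ct",
    marker_fold: float = 5.0,
    noise_sd: float = 0.3,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Nonnegative genes x cell-types mean-expression matrix with planted markers.

    Each cell type receives ``markers_per_type`` disjoint marker genes whose
    expression in that type is multiplied by ``marker_fold``; with
    ``noise_sd = 0`` the specificity ranking is deterministic.  Returns the
    matrix and the planted marker assignment.
    """
    n_genes = len(gene_ids)
    if markers_per_type * n_cell_types > n_genes:
        raise ValueError("markers_per_type x n_cell_types exceeds n_genes")
    cols = [f"{prefix}{j + 1:02d}" for j in range(n_cell_types)]
    base = np.exp(seed_rng.normal(0.0, 1.0, size=n_genes))
    noise = np.exp(seed_rng.normal(0.0, noise_sd, size=(n_genes, n_cell_types)))
    expr = base[:, None] * noise
    marker_idx = seed_rng.choice(
        n_genes, size=markers_per_type * n_cell_types, replace=False
    )
    markers: dict[str, list[str]] = {}
    for j, col in enumerate(cols):
        idx = marker_idx[j * markers_per_type : (j + 1) * markers_per_type]
        expr[idx, j] *= marker_fold
        markers[col] = sorted(gene_ids[i] for i in idx)
    return pd.DataFrame(expr, index=pd.Index(gene_ids, name="gene_id"), columns=cols), markers


def gen_homology(
    genes: pd.DataFrame,
    coverage: float,
    seed_rng: np.random.Generator,
    ambiguous_frac: float = 0.0,
) -> pd.DataFrame:
    """Mouse-to-human pairs covering ~``coverage`` of genes.

    ``ambiguous_frac`` of the covered mouse genes additionally map to a second
    human gene, exercising the many-to-many dropping policy downstream.
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must be in [0, 1]")
    human = genes["gene_id"].to_numpy()
    covered = human[seed_rng.random(len(human)) < coverage]
    rows = [(f"mm_{h}", h) for h in covered]
    if ambiguous_frac > 0 and len(covered) > 1:
        amb = covered[seed_rng.random(len(covered)) < ambiguous_frac]
        extra_targets = seed_rng.choice(human, size=len(amb))
        for m, t in zip(amb, extra_targets):
            if t != m:
                rows.append((f"mm_{m}", t))
    df = pd.DataFrame(rows, columns=["source_id", "target_id"]).drop_duplicates()
    return df.sort_values(["source_id", "target_id"]).reset_index(drop=True)


def gen_synaptic_annotation(
    genes: pd.DataFrame,
    set_sizes: tuple[int, ...],
    seed_rng: np.random.Generator,
) -> list[GeneSet]:
    """One raw ontology-style set per requested size (without replacement within a set)."""
    ids = genes["gene_id"].to_numpy()
    out = []
    for i, size in enumerate(set_sizes):
        if size > len(ids):
            raise ValueError(f"synaptic set size {size} exceeds n_genes {len(ids)}")
        members = seed_rng.choice(ids, size=size, replace=False)
        out.append(GeneSet(f"synaptic_{i + 1:03d}", "synaptic", tuple(members)))
    return out


def _ar1_corr(m: int, rho: float) -> np.ndarray:
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def gen_gwas(
    genes: pd.DataFrame,
    cfg: SimConfig,
    enriched_sets: GeneSetCollection | list[GeneSet] | None = None,
) -> tuple[pd.DataFrame, LDReference]:
    """Per-gene LD blocks of summary z-scores with planted set-level inflation.

    Each gene hosts one AR(1) block of ``ld_block_size`` SNPs.  Per-SNP true
    effects b are N(0, tau2), with tau2 = ``tau2_enriched`` for genes in an
    enriched set and ``tau2_null`` otherwise; the observed z-vector per block
    is MVN(R b sqrt(N), R).  P is the two-sided normal tail of z.
    """
    if not 0.0 <= cfg.ld_rho < 1.0:
        raise ValueError("ld_rho must be in [0, 1) for a positive definite R")
    rng = cfg.rng("gwas")
    m = cfg.ld_block_size
    R = _ar1_corr(m, cfg.ld_rho)
    L = np.linalg.cholesky(R) if m > 1 else np.ones((1, 1))
    sqrt_n = np.sqrt(cfg.gwas_n)

    enriched_genes: set[str] = set()
    if enriched_sets is not None:
        sets = (
            [enriched_sets.get(n) for n in cfg.enriched_set_names if
             n in enriched_sets.analysed or n in enriched_sets.background]
            if isinstance(enriched_sets, GeneSetCollection)
            else list(enriched_sets)
        )
        for gs in sets:
            enriched_genes.update(gs.members)

    n_genes = len(genes)
    tau2 = np.where(
        genes["gene_id"].isin(enriched_genes).to_numpy(), cfg.tau2_enriched, cfg.tau2_null
    )
    # vectorized across genes: b ~ N(0, tau2 I), z = R b sqrt(N) + L eta
    b = rng.normal(0.0, 1.0, size=(n_genes, m)) * np.sqrt(tau2)[:, None]
    eta = rng.normal(0.0, 1.0, size=(n_genes, m))
    z = (b @ R.T) * sqrt_n + eta @ L.T

    rows = []
    blocks: dict[str, tuple[list[str], np.ndarray]] = {}
    info_all = 0.8 + 0.2 * rng.random(n_genes * m)
    gene_ids = genes["gene_id"].to_numpy()
    starts = genes["start"].to_numpy()
    stops = genes["stop"].to_numpy()
    chroms = genes["chrom"].to_numpy()
    for gi in range(n_genes):
        gid = gene_ids[gi]
        bps = np.linspace(starts[gi], stops[gi], m).astype(np.int64)
        snp_ids = [f"rs_{gid}_{j}" for j in range(m)]
        blocks[gid] = (snp_ids, R.copy())
        for j in range(m):
            rows.append((snp_ids[j], chroms[gi], int(bps[j]), z[gi, j], info_all[gi * m + j]))
    gwas = pd.DataFrame(rows, columns=["SNP", "CHR", "BP", "Z", "INFO"])
    p = 2.0 * stats.norm.sf(np.abs(gwas["Z"].to_numpy()))
    gwas["P"] = np.clip(p, 1e-300, 1.0)
    gwas["N"] = cfg.gwas_n
    gwas = gwas.drop(columns=["Z"])

    if cfg.low_info_frac > 0:
        low = rng.random(len(gwas)) < cfg.low_info_frac
        gwas.loc[low, "INFO"] = 0.2 + 0.6 * rng.random(int(low.sum()))
    if cfg.dup_snp_frac > 0:
        k = int(cfg.dup_snp_frac * len(gwas))
        if k > 0:
            dup = gwas.sample(n=k, random_state=int(rng.integers(2**31)))
            gwas = pd.concat([gwas, dup], ignore_index=True)

    return gwas[["SNP", "CHR", "BP", "P", "INFO", "N"]], LDReference(blocks)


def gen_exome_cohort(
    genes: pd.DataFrame,
    cfg: SimConfig,
    causal_sets: GeneSetCollection | list[GeneSet] | None = None,
) -> ExomeCohort:
    """Case-control cohort with Poisson qualifying variants and planted burden.

    Per gene and individual, qualifying PTV and synonymous allele counts are
    Poisson(mu_ptv) and Poisson(mu_syn).  Disease status is assigned by a
    prospective logistic model whose linear predictor adds ``burden_logor``
    per qualifying PTV allele in a causal-set gene (centred, so the realised
    case fraction tracks n_cases / (n_cases + n_controls)); synonymous
    variants never enter the predictor.  Each variant receives a
    reference-panel allele count, a configurable fraction of which is forced
    to zero so true singletons exist.
    """
    if cfg.n_cases < 1 or cfg.n_controls < 1:
        raise ValueError("n_cases and n_controls must be >= 1")
    rng = cfg.rng("exome")
    n_ind = cfg.n_cases + cfg.n_controls
    iids = [f"I{i:06d}" for i in range(n_ind)]

    causal_genes: set[str] = set()
    if causal_sets is not None:
        sets = (
            [causal_sets.get(n) for n in cfg.enriched_set_names
             if n in causal_sets.analysed or n in causal_sets.background]
            if isinstance(causal_sets, GeneSetCollection)
            else list(causal_sets)
        )
        for gs in sets:
            causal_genes.update(gs.members)

    gene_ids = genes["gene_id"].to_numpy()
    var_rows, car_var, car_iid = [], [], []
    for consequence, mu in (("PTV", cfg.mu_ptv), ("synonymous", cfg.mu_syn)):
        if mu == 0.0:
            continue
        totals = rng.poisson(n_ind * mu, size=len(gene_ids))
        for gi in np.nonzero(totals)[0]:
            gid = gene_ids[gi]
            carriers = rng.integers(0, n_ind, size=totals[gi])
            for k, ci in enumerate(carriers):
                vid = f"v_{gid}_{consequence[0]}{k}"
                var_rows.append((vid, gid, consequence))
                car_var.append(vid)
                car_iid.append(ci)

    variants = pd.DataFrame(var_rows, columns=["variant_id", "gene_id", "consequence"])
    carriers = pd.DataFrame(
        {
            "variant_id": car_var,
            "iid": [iids[i] for i in car_iid],
            "n_alleles": np.ones(len(car_var), dtype=np.int64),
        }
    )
    ac_sample = carriers.groupby("variant_id")["n_alleles"].sum()
    variants["ac_sample"] = variants["variant_id"].map(ac_sample).fillna(0).astype(np.int64)
    ref_ac = 1 + rng.poisson(cfg.ref_ac_rate, size=len(variants))
    force_zero = rng.random(len(variants)) < cfg.singleton_frac
    variants["ac_ref"] = np.where(force_zero, 0, ref_ac).astype(np.int64)

    # planted causal burden: qualifying PTV alleles in causal genes
    burden = np.zeros(n_ind)
    if causal_genes and len(variants):
        vmeta = variants.set_index("variant_id")
        cv = carriers.merge(
            vmeta.loc[
                (vmeta["consequence"] == "PTV") & vmeta["gene_id"].isin(causal_genes)
            ][[]],
            left_on="variant_id",
            right_index=True,
            how="inner",
        )
        counts = cv.groupby("iid")["n_alleles"].sum()
        idx = pd.Index(iids)
        burden[idx.get_indexer(counts.index)] = counts.to_numpy()

    sex = (rng.random(n_ind) < 0.5).astype(np.int64)
    pcs = rng.normal(0.0, 1.0, size=(n_ind, 10))
    alpha = np.log(cfg.n_cases / cfg.n_controls)
    eta = (
        alpha
        + cfg.burden_logor * (burden - burden.mean())
        + cfg.sex_logor * (sex - 0.5)
        + cfg.pc1_logor * pcs[:, 0]
    )
    case = (rng.random(n_ind) < 1.0 / (1.0 + np.exp(-eta))).astype(np.int64)

    individuals = pd.DataFrame({"iid": iids, "case": case, "sex": sex})
    for j in range(10):
        individuals[f"PC{j + 1}"] = pcs[:, j]
    return ExomeCohort(
        individuals=individuals,
        variants=variants,
        carriers=carriers,
        panel_total_n=max(cfg.ref_panel_n, n_ind),
    )
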