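"""Format readers/writers, run configuration and end-to-end orchestration.

Formats (all plain text, genomic coordinates 1-based inclusive throughout):

* GMT gene-sets: ``name <tab> description <tab> member...`` per line;
* sumstats TSV: SNP, CHR, BP, P, INFO, N;
* gene locations TSV: GENE, CHR, START, STOP; pLI TSV: GENE, PLI;
* LD blocks: long TSV gene_id, i, j, r (full symmetric matrix per block);
* expression TSV: gene_id index column + one column per cell type;
* homology TSV: source_id, target_id;
* minimal VCF (v4.2): INFO keys GENE, CSQ_CLASS in {PTV,SYN}, AC_REF;
  genotypes GT over cohort samples;
* covariates TSV: iid, case, sex, PC1..PC10.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .common_enrichment import default_conditioning_plan, run_common
from .convergence import apply_fdr, convergence_report
from .genesets import (
    GeneSet,
    GeneSetCollection,
    assemble,
    background_sets,
    filter_synaptic,
    intersect_pi,
    map_homologs,
    select_pi,
    select_top_expressed,
)
from .rare_enrichment import default_rare_conditioning_plan, run_rare
from .synthetic_data import (
    ExomeCohort,
    LDReference,
    SimConfig,
    gen_exome_cohort,
    gen_expression,
    gen_gene_table,
    gen_gwas,
    gen_homology,
    gen_synaptic_annotation,
)

logger = logging.getLogger(__name__)

SUMSTATS_COLUMNS = ["SNP", "CHR", "BP", "P", "INFO", "N"]
FLOAT_FMT = "%.10g"


class SchemaError(ValueError):
    """An input file does not match its documented schema."""


# ---------------------------------------------------------------------------
# GMT

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file; the description field carries the category."""
    coll = GeneSetCollection()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise SchemaError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, desc, *members = parts
        if len(set(members)) < len(members):
            logger.warning("%s:%d: duplicate members in %r collapsed", path, lineno, name)
        category = desc if desc in (
            "PI", "human_cell", "mouse_cell", "synaptic", "intersection", "background"
        ) else "synaptic"
        coll.add(GeneSet(name, category, tuple(members)))
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([gs.name, gs.category, *gs.members])
        for gs in coll.all_sets()
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# tabular inputs

def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_sumstats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, SUMSTATS_COLUMNS, path)
    try:
        df = df.astype({"BP": np.int64, "P": float, "INFO": float, "N": np.int64})
    except ValueError as exc:
        raise SchemaError(f"{path}: unparsable numeric field ({exc})") from exc
    logger.info("read %d SNP records from %s", len(df), path)
    return df[SUMSTATS_COLUMNS]


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    df[SUMSTATS_COLUMNS].to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_gene_loc(path: str | Path, pli_path: str | Path | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, ["GENE", "CHR", "START", "STOP"], path)
    out = df.rename(
        columns={"GENE": "gene_id", "CHR": "chrom", "START": "start", "STOP": "stop"}
    )
    out = out.astype({"start": np.int64, "stop": np.int64})
    if pli_path is not None:
        pli = pd.read_csv(pli_path, sep="\t")
        _require(pli, ["GENE", "PLI"], pli_path)
        out = out.merge(
            pli.rename(columns={"GENE": "gene_id", "PLI": "pli"}), on="gene_id", how="left"
        )
    return out


def write_gene_loc(genes: pd.DataFrame, path: str | Path, pli_path: str | Path | None = None) -> None:
    genes.rename(
        columns={"gene_id": "GENE", "chrom": "CHR", "start": "START", "stop": "STOP"}
    )[["GENE", "CHR", "START", "STOP"]].to_csv(path, sep="\t", index=False)
    if pli_path is not None:
        genes.rename(columns={"gene_id": "GENE", "pli": "PLI"})[["GENE", "PLI"]].to_csv(
            pli_path, sep="\t", index=False, float_format=FLOAT_FMT
        )


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise SchemaError(f"{path}: negative expression values")
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_homology(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, ["source_id", "target_id"], path)
    return df


def write_homology(hmap: pd.DataFrame, path: str | Path) -> None:
    hmap[["source_id", "target_id"]].to_csv(path, sep="\t", index=False)


def read_ld_blocks(path: str | Path) -> LDReference:
    """Long-format block bundle: gene_id, snp_i, snp_j, r (full matrices)."""
    df = pd.read_csv(path, sep="\t")
    _require(df, ["gene_id", "snp_i", "snp_j", "r"], path)
    blocks = {}
    for gid, sub in df.groupby("gene_id", sort=False):
        snps = list(dict.fromkeys(sub["snp_i"]))
        pos = {s: i for i, s in enumerate(snps)}
        m = len(snps)
        R = np.eye(m)
        R[sub["snp_i"].map(pos), sub["snp_j"].map(pos)] = sub["r"].to_numpy()
        blocks[gid] = (snps, R)
    return LDReference(blocks)


def write_ld_blocks(ld: LDReference, path: str | Path) -> None:
    frames = []
    for gid, (snps, R) in ld.blocks.items():
        m = len(snps)
        ii, jj = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": gid,
                    "snp_i": np.asarray(snps)[ii.ravel()],
                    "snp_j": np.asarray(snps)[jj.ravel()],
                    "r": R.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, ["iid", "case", "sex"] + [f"PC{i+1}" for i in range(10)], path)
    if not np.isfinite(df[[f"PC{i+1}" for i in range(10)]].to_numpy()).all():
        raise SchemaError(f"{path}: non-finite principal components")
    return df


def write_covariates(individuals: pd.DataFrame, path: str | Path) -> None:
    individuals.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# minimal VCF

VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">
##INFO=<ID=CSQ_CLASS,Number=1,Type=String,Description="Consequence class (PTV or SYN)">
##INFO=<ID=AC_REF,Number=1,Type=Integer,Description="Reference panel allele count">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1>
"""

_CSQ_OUT = {"PTV": "PTV", "synonymous": "SYN"}
_CSQ_IN = {"PTV": "PTV", "SYN": "synonymous"}


def write_vcf_min(cohort: ExomeCohort, path: str | Path) -> None:
    """One record per variant; carriers get 0/1 (or 1/1 for two alleles)."""
    iids = list(cohort.individuals["iid"])
    iid_pos = {s: i for i, s in enumerate(iids)}
    carr = cohort.carriers.groupby("variant_id")
    lines = [VCF_HEADER.rstrip("\n")]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(iids))
    for i, v in enumerate(cohort.variants.itertuples(index=False)):
        gts = ["0/0"] * len(iids)
        if v.variant_id in carr.groups:
            for c in carr.get_group(v.variant_id).itertuples(index=False):
                gts[iid_pos[c.iid]] = "1/1" if c.n_alleles >= 2 else "0/1"
        info = f"GENE={v.gene_id};CSQ_CLASS={_CSQ_OUT[v.consequence]};AC_REF={v.ac_ref}"
        lines.append(
            f"chr1\t{i + 1}\t{v.variant_id}\tA\tT\t.\tPASS\t{info}\tGT\t" + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf_min(path: str | Path, covariates: pd.DataFrame, panel_total_n: int) -> ExomeCohort:
    """Read the minimal VCF dialect back into an ExomeCohort."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    var_rows, car_rows = [], []
    n_skipped = 0
    for rec in vcf:
        gene = rec.INFO.get("GENE")
        csq = rec.INFO.get("CSQ_CLASS")
        ac_ref = rec.INFO.get("AC_REF")
        if gene is None or csq is None or ac_ref is None or csq not in _CSQ_IN:
            n_skipped += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types
        ac_sample = 0
        for si in np.nonzero((gt == 1) | (gt == 3))[0]:
            n_alleles = 2 if gt[si] == 3 else 1
            ac_sample += n_alleles
            car_rows.append((rec.ID, samples[si], n_alleles))
        var_rows.append((rec.ID, gene, _CSQ_IN[csq], ac_sample, int(ac_ref)))
    if n_skipped:
        logger.warning("%s: %d records lacked required INFO keys; skipped", path, n_skipped)
    variants = pd.DataFrame(
        var_rows, columns=["variant_id", "gene_id", "consequence", "ac_sample", "ac_ref"]
    )
    carriers = pd.DataFrame(car_rows, columns=["variant_id", "iid", "n_alleles"])
    individuals = covariates[covariates["iid"].isin(samples)].reset_index(drop=True)
    return ExomeCohort(individuals, variants, carriers, panel_total_n)


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Thresholds and paths for a full run; unknown YAML keys are rejected."""

    outdir: str = "results"
    seed: int = 0
    pli_threshold: float = 0.9
    top_n: int = 1600
    min_expr: float = 0.1
    min_synaptic: int = 50
    info_min: float = 0.8
    af_max: float = 0.001
    mad_k: float = 4.0
    fdr_q: float = 0.05
    min_set_genes: int = 10
    strict: bool = False
    rare_classes: tuple[str, ...] = ("urv_ptv", "urv_syn", "rare_ptv", "rare_syn")
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if not 0.0 <= self.pli_threshold <= 1.0:
            raise ValueError("pli_threshold must be in [0, 1]")
        if not 0.0 <= self.info_min <= 1.0:
            raise ValueError("info_min must be in [0, 1]")
        if not 0.0 < self.af_max < 0.5:
            raise ValueError("af_max must be in (0, 0.5)")
        if self.mad_k < 0 or self.fdr_q <= 0 or self.fdr_q > 1:
            raise ValueError("mad_k must be >= 0 and fdr_q in (0, 1]")


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim_raw = raw.pop("sim", {})
    known = {f.name for f in fields(RunConfig)} - {"sim"}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"{path}: unknown config key(s) {sorted(unknown)}")
    sim_known = {f.name for f in fields(SimConfig)}
    sim_unknown = set(sim_raw) - sim_known
    if sim_unknown:
        raise SchemaError(f"{path}: unknown sim key(s) {sorted(sim_unknown)}")
    for key in ("synaptic_set_sizes", "enriched_set_names", "pli_beta_lo", "pli_beta_hi"):
        if key in sim_raw and isinstance(sim_raw[key], list):
            sim_raw[key] = tuple(sim_raw[key])
    if "rare_classes" in raw and isinstance(raw["rare_classes"], list):
        raw["rare_classes"] = tuple(raw["rare_classes"])
    cfg = RunConfig(sim=SimConfig(**sim_raw), **raw)
    cfg.sim = cfg.sim.with_seed(cfg.seed if "seed" not in sim_raw else cfg.sim.seed)
    return cfg


# ---------------------------------------------------------------------------
# orchestration

def build_collection(
    genes: pd.DataFrame,
    expr_human: pd.DataFrame,
    expr_mouse: pd.DataFrame,
    homology: pd.DataFrame,
    synaptic_raw: list[GeneSet],
    cfg: RunConfig,
) -> GeneSetCollection:
    """Assemble the full analysed collection from raw inputs."""
    pi = select_pi(genes, threshold=cfg.pli_threshold)
    human_sets = [
        select_top_expressed(expr_human, ct, n=cfg.top_n, min_expr=cfg.min_expr,
                             category="human_cell", name=f"human_{ct}", strict=cfg.strict)
        for ct in expr_human.columns
    ]
    mouse_raw = [
        select_top_expressed(expr_mouse, ct, n=cfg.top_n, min_expr=cfg.min_expr,
                             category="mouse_cell", name=f"mouse_{ct}", strict=cfg.strict)
        for ct in expr_mouse.columns
    ]
    mouse_sets = map_homologs(mouse_raw, homology)
    synaptic = filter_synaptic(synaptic_raw, min_size=cfg.min_synaptic)
    intersections = intersect_pi(human_sets + mouse_sets, pi)
    backgrounds = background_sets(expr_human, min_expr=cfg.min_expr)
    return assemble(pi, human_sets, mouse_sets, synaptic, intersections, backgrounds)


def _rename_cell_sets(cfg: SimConfig) -> dict[str, str]:
    """Map generator cell-type names onto collection set names."""
    out = {}
    for j in range(cfg.n_cell_types_human):
        out[f"human_ct{j+1:02d}"] = f"human_hct{j+1:02d}"
    for j in range(cfg.n_cell_types_mouse):
        out[f"mouse_ct{j+1:02d}"] = f"mouse_mct{j+1:02d}"
    return out


def simulate_inputs(cfg: RunConfig) -> dict:
    """Generate every pipeline input (and the collection used to plant effects)."""
    sim = cfg.sim
    genes = gen_gene_table(sim)
    expr_human, _ = gen_expression(
        list(genes["gene_id"]), sim.n_cell_types_human, sim.markers_per_type,
        sim.rng("expr_human"), prefix="hct",
        marker_fold=sim.expr_marker_fold, noise_sd=sim.expr_noise_sd,
    )
    homology = gen_homology(genes, sim.homology_coverage, sim.rng("homology"),
                            ambiguous_frac=sim.homology_ambiguous_frac)
    mouse_ids = sorted(homology["source_id"].unique())
    expr_mouse, _ = gen_expression(
        mouse_ids, sim.n_cell_types_mouse,
        min(sim.markers_per_type, max(1, len(mouse_ids) // max(sim.n_cell_types_mouse, 1))),
        sim.rng("expr_mouse"), prefix="mct",
        marker_fold=sim.expr_marker_fold, noise_sd=sim.expr_noise_sd,
    )
    synaptic_raw = gen_synaptic_annotation(genes, sim.synaptic_set_sizes, sim.rng("synaptic"))
    collection = build_collection(genes, expr_human, expr_mouse, homology, synaptic_raw, cfg)

    enriched_names = [_rename_cell_sets(sim).get(n, n) for n in sim.enriched_set_names]
    planted = [collection.get(n) for n in enriched_names
               if n in collection.analysed or n in collection.background]
    gwas, ld = gen_gwas(genes, sim, planted)
    cohort = gen_exome_cohort(genes, sim, planted)
    return {
        "genes": genes,
        "expr_human": expr_human,
        "expr_mouse": expr_mouse,
        "homology": homology,
        "synaptic_raw": synaptic_raw,
        "collection": collection,
        "gwas": gwas,
        "ld": ld,
        "cohort": cohort,
        "planted": [gs.name for gs in planted],
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(cfg: RunConfig) -> dict:
    """simulate -> build-sets -> common-enrich -> rare-enrich -> converge.

    Writes all artifacts under ``cfg.outdir`` plus a manifest with the seed,
    a config hash and per-file checksums; identical config + seed reproduces
    identical checksums.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("stage 1/5: simulate")
    data = simulate_inputs(cfg)
    write_gene_loc(data["genes"], outdir / "gene_loc.tsv", outdir / "pli.tsv")
    write_expression(data["expr_human"], outdir / "expression_human.tsv")
    write_expression(data["expr_mouse"], outdir / "expression_mouse.tsv")
    write_homology(data["homology"], outdir / "homology.tsv")
    write_sumstats(data["gwas"], outdir / "sumstats.tsv")
    write_covariates(data["cohort"].individuals, outdir / "covariates.tsv")
    write_vcf_min(data["cohort"], outdir / "cohort.vcf")

    logger.info("stage 2/5: build-sets (%d analysed)", len(data["collection"]))
    write_gmt(data["collection"], outdir / "gene_sets.gmt")

    logger.info("stage 3/5: common-enrich")
    common = run_common(
        data["gwas"], data["ld"], data["genes"], data["collection"],
        conditioning_plan=default_conditioning_plan(data["collection"]),
        info_min=cfg.info_min, min_set_genes=cfg.min_set_genes,
    )
    common = apply_fdr(common, q=cfg.fdr_q)
    common.to_csv(outdir / "common_results.tsv", sep="\t", index=False,
                  float_format=FLOAT_FMT)

    logger.info("stage 4/5: rare-enrich")
    rare = run_rare(
        data["cohort"], data["collection"], classes=cfg.rare_classes,
        af_max=cfg.af_max, mad_k=cfg.mad_k, min_set_genes=cfg.min_set_genes,
        conditioning_plan=default_rare_conditioning_plan(data["collection"]),
    )
    rare = apply_fdr(rare, q=cfg.fdr_q)
    rare.to_csv(outdir / "rare_results.tsv", sep="\t", index=False,
                float_format=FLOAT_FMT)

    logger.info("stage 5/5: converge")
    rare_by_class = {v: rare[rare["variant_class"] == v] for v in cfg.rare_classes}
    results, summary = convergence_report(common, rare_by_class, fdr_q=cfg.fdr_q)
    summary.to_csv(outdir / "convergence.tsv", sep="\t", index=False,
                   float_format=FLOAT_FMT)
    pairs = pd.concat(
        [r.table.assign(rare_class=r.pair[1]) for r in results], ignore_index=True
    )
    pairs.to_csv(outdir / "convergence_pairs.tsv", sep="\t", index=False,
                 float_format=FLOAT_FMT)

    cfg_dict = asdict(cfg)
    # the output location identifies a run, not an analysis configuration
    hashed = {k: v for k, v in cfg_dict.items() if k != "outdir"}
    cfg_hash = hashlib.sha256(
        json.dumps(hashed, sort_keys=True, default=str).encode()
    ).hexdigest()
    artifacts = sorted(p for p in outdir.iterdir() if p.name != "manifest.json")
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg_hash,
        "config": cfg_dict,
        "planted_sets": data["planted"],
        "checksums": {p.name: _sha256(p) for p in artifacts},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return {
        "collection": data["collection"],
        "common": common,
        "rare": rare,
        "convergence": summary,
        "manifest": manifest,
    }
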