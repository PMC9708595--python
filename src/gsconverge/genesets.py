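"""Construction of the four analysed gene-set families plus conditioning backgrounds.

Families:

* **PI** — protein-truncating-variant-intolerant genes, defined as pLI strictly
  greater than a threshold (default 0.9); proxies for strong negative selection.
* **human_cell / mouse_cell** — per cell type, the top-N genes (default 1600) by
  expression specificity in brain single-cell/nucleus expression matrices; mouse
  sets are translated to human gene ids through a homology map.
* **synaptic** — ontology-derived sets retained when they hold at least
  ``min_size`` genes (default 50).
* **intersection** — each brain cell set intersected with the PI set.
* **background** — brain-expressed genes and their top expression fractions,
  used only as conditioning covariates, never counted as analysed sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES = ("PI", "human_cell", "mouse_cell", "synaptic", "intersection", "background")


class ConfigurationError(ValueError):
    """Raised when a request is inconsistent with the supplied data."""


@dataclass(frozen=True)
class GeneSet:
    """A named gene-set; members are stored sorted for determinism."""

    name: str
    category: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        object.__setattr__(self, "members", tuple(sorted(set(self.members))))

    def __len__(self) -> int:
        return len(self.members)

    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)


@dataclass
class GeneSetCollection:
    """Analysed sets (counted, tested) plus background sets (conditioning only)."""

    analysed: dict[str, GeneSet] = field(default_factory=dict)
    background: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, gs: GeneSet) -> None:
        target = self.background if gs.category == "background" else self.analysed
        if gs.name in self.analysed or gs.name in self.background:
            raise ValueError(f"duplicate gene-set name {gs.name!r}")
        target[gs.name] = gs

    def __len__(self) -> int:
        return len(self.analysed)

    def __iter__(self):
        return iter(self.analysed.values())

    def get(self, name: str) -> GeneSet:
        if name in self.analysed:
            return self.analysed[name]
        return self.background[name]

    def all_sets(self) -> list[GeneSet]:
        return list(self.analysed.values()) + list(self.background.values())


def select_pi(genes: pd.DataFrame, threshold: float = 0.9) -> GeneSet:
    """Genes with pLI strictly greater than ``threshold`` (constraint proxy)."""
    if "pli" not in genes.columns:
        raise ConfigurationError("gene table lacks a 'pli' column")
    if genes["pli"].isna().any():
        raise ConfigurationError("pLI missing for some genes")
    members = genes.loc[genes["pli"] > threshold, "gene_id"].tolist()
    return GeneSet("PI", "PI", tuple(members))


def specificity(expr: pd.DataFrame, cell_type: str, pseudocount: float = 0.01) -> pd.Series:
    """Expression in ``cell_type`` over the mean across all cell types."""
    if cell_type not in expr.columns:
        raise ConfigurationError(f"cell type {cell_type!r} not in expression matrix")
    grand = expr.mean(axis=1)
    return expr[cell_type] / (grand + pseudocount)


def select_top_expressed(
    expr: pd.DataFrame,
    cell_type: str,
    n: int = 1600,
    min_expr: float = 0.1,
    pseudocount: float = 0.01,
    category: str = "human_cell",
    name: str | None = None,
    strict: bool = False,
) -> GeneSet:
    """Top ``n`` genes by expression specificity in one cell type.

    Genes expressed below ``min_expr`` in that cell type are excluded before
    ranking.  Ties are broken lexicographically by gene id so the selection is
    reproducible.  In strict mode fewer than ``n`` qualifying genes is an
    error; in lenient mode all qualifying genes are returned with a warning.
    """
    spec = specificity(expr, cell_type, pseudocount)
    qualifying = spec[expr[cell_type] >= min_expr]
    if len(qualifying) < n:
        msg = f"{cell_type}: only {len(qualifying)} genes qualify (requested {n})"
        if strict:
            raise ConfigurationError(msg)
        logger.warning(msg)
    order = qualifying.rename("spec").rename_axis(None).to_frame()
    order["gid"] = order.index
    order = order.sort_values(["spec", "gid"], ascending=[False, True])
    members = tuple(order["gid"].head(n))
    return GeneSet(name or cell_type, category, members)


def map_homologs(mouse_sets: list[GeneSet], homology: pd.DataFrame) -> list[GeneSet]:
    """Translate mouse gene ids to human via a (source_id, target_id) table.

    Policy: a mouse gene mapping to more than one human gene is dropped (set
    inflation guard); unmapped members are dropped; duplicate human targets
    after translation are collapsed.  Dropped counts are logged.
    """
    targets = homology.groupby("source_id")["target_id"].apply(set)
    unique_map = {src: next(iter(tgt)) for src, tgt in targets.items() if len(tgt) == 1}
    ambiguous = {src for src, tgt in targets.items() if len(tgt) > 1}

    out = []
    for gs in mouse_sets:
        mapped, n_unmapped, n_ambig = [], 0, 0
        for m in gs.members:
            if m in unique_map:
                mapped.append(unique_map[m])
            elif m in ambiguous:
                n_ambig += 1
            else:
                n_unmapped += 1
        logger.info(
            "homology %s: %d mapped, %d unmapped dropped, %d many-to-many dropped",
            gs.name, len(set(mapped)), n_unmapped, n_ambig,
        )
        out.append(GeneSet(gs.name, gs.category, tuple(mapped)))
    return out


def filter_synaptic(raw_sets: list[GeneSet], min_size: int = 50) -> list[GeneSet]:
    """Retain ontology sets holding at least ``min_size`` genes (inclusive)."""
    return [
        GeneSet(gs.name, "synaptic", gs.members)
        for gs in raw_sets
        if len(gs) >= min_size
    ]


def intersect_pi(cell_sets: list[GeneSet], pi: GeneSet) -> list[GeneSet]:
    """One intersection set per brain cell set: members in both the cell set and PI."""
    pi_members = pi.member_set()
    out = []
    for gs in cell_sets:
        members = tuple(m for m in gs.members if m in pi_members)
        inter = GeneSet(f"{gs.name}_x_PI", "intersection", members)
        if len(inter) == 0:
            logger.warning("intersection %s is empty (retained, low power)", inter.name)
        out.append(inter)
    return out


def background_sets(
    expr_human: pd.DataFrame,
    fractions: tuple[float, ...] = (1.0, 0.5, 0.2, 0.1),
    min_expr: float = 0.1,
) -> list[GeneSet]:
    """Brain-expressed genes and their top expression fractions (conditioning only).

    Brain-expressed means expression at or above ``min_expr`` in at least one
    cell type; within those, top-f sets are ranked by overall mean expression
    (ties broken by gene id).
    """
    expressed = expr_human.index[(expr_human >= min_expr).any(axis=1)]
    ranked = (
        expr_human.loc[expressed]
        .mean(axis=1)
        .rename("mean_expr")
        .rename_axis(None)
        .to_frame()
        .assign(gid=lambda d: d.index)
        .sort_values(["mean_expr", "gid"], ascending=[False, True])
    )
    out = []
    for f in sorted(fractions, reverse=True):
        if not 0.0 < f <= 1.0:
            raise ConfigurationError(f"background fraction {f} outside (0, 1]")
        k = len(ranked) if f == 1.0 else int(f * len(ranked))
        name = "brain_all" if f == 1.0 else f"brain_top{int(round(f * 100))}"
        out.append(GeneSet(name, "background", tuple(ranked["gid"].head(k))))
    return out


def assemble(
    pi: GeneSet,
    human_sets: list[GeneSet],
    mouse_sets: list[GeneSet],
    synaptic_sets: list[GeneSet],
    intersections: list[GeneSet],
    backgrounds: list[GeneSet] | None = None,
) -> GeneSetCollection:
    """Assemble the analysis collection; backgrounds are stored separately.

    With the study configuration (1 PI + 14 human + 24 mouse + 35 synaptic +
    38 intersections) this yields 112 analysed sets.
    """
    coll = GeneSetCollection()
    for gs in [pi, *human_sets, *mouse_sets, *synaptic_sets, *intersections]:
        coll.add(gs)
    for gs in backgrounds or []:
        coll.add(gs)
    return coll
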