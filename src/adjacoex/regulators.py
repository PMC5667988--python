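"""Regulator set analysis and ceRNA candidate calling.

Covers four related set-algebra/statistics tasks on regulator->target
tables: Venn partitioning of named sets, hypergeometric shared-regulator
enrichment, activator/repressor classification of TFs by their
expression correlation with a target, and competing-endogenous-RNA
(ceRNA) calling for gene pairs. A ceRNA pair shares microRNA response
elements: both transcripts soak up the same miRNA pool, so their
expression is positively correlated while each is anti-correlated with
the shared miRNAs. The verdict requires all three signatures at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .correlation import bh_adjust, pearson
from .model import OmicsMatrix, RegulatorSetCollection, ValidationError

__all__ = [
    "VennPartition",
    "venn_partition",
    "shared_regulator_enrichment",
    "tf_sign_classification",
    "shared_mirnas",
    "mirna_anticorrelation",
    "CeRNACandidate",
    "cerna_candidates",
    "pathway_partition",
]


# ----------------------------------------------------------------- Venn logic


@dataclass
class VennPartition:
    """Disjoint membership cells of k named sets.

    A cell signature is a bit string over ``set_names`` ("110" = in the
    first two sets, not the third). Cells partition the union.
    """

    set_names: list[str]
    cells: dict[str, frozenset[str]]

    def cell(self, signature: str) -> frozenset[str]:
        return self.cells.get(signature, frozenset())

    @property
    def full_intersection(self) -> frozenset[str]:
        return self.cell("1" * len(self.set_names))

    def union_size(self) -> int:
        return sum(len(v) for v in self.cells.values())

    def to_table(self) -> pd.DataFrame:
        rows = []
        for sig in sorted(self.cells, key=lambda s: (-s.count("1"), s), reverse=False):
            names = [n for n, bit in zip(self.set_names, sig) if bit == "1"]
            rows.append(
                ("+".join(names), sig, len(self.cells[sig]),
                 ";".join(sorted(self.cells[sig])))
            )
        return pd.DataFrame(rows, columns=["sets", "signature", "size", "elements"])


def venn_partition(named_sets: dict[str, set[str]]) -> VennPartition:
    """Partition the union of 1-8 named sets into membership cells."""
    names = list(named_sets)
    if not 1 <= len(names) <= 8:
        raise ValidationError(f"need 1-8 sets, got {len(names)}")
    if len(set(names)) != len(names):
        raise ValidationError("set names collide")
    universe = set().union(*named_sets.values())
    cells: dict[str, set[str]] = {}
    for el in universe:
        sig = "".join("1" if el in named_sets[n] else "0" for n in names)
        cells.setdefault(sig, set()).add(el)
    return VennPartition(
        set_names=names, cells={k: frozenset(v) for k, v in cells.items()}
    )


# ----------------------------------------------------------------- enrichment


def shared_regulator_enrichment(
    sets: RegulatorSetCollection, query: set[str], universe: set[str]
) -> pd.DataFrame:
    """Hypergeometric over-representation of each regulator's targets in a query.

    Targets are intersected with the universe first; p is the one-sided
    upper tail P(X >= k) of drawing |query| genes from the universe, and
    q is BH across regulators. Sorted by ascending p.
    """
    if not query <= universe:
        raise ValidationError("query genes outside the declared universe")
    N, n_draw = len(universe), len(query)
    rows = []
    for (reg, src), targets in sorted(sets):
        t_in = targets & universe
        K = len(t_in)
        overlap = t_in & query
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n_draw)) if k > 0 else 1.0
        rows.append((reg, src, K, k, ";".join(sorted(overlap)), p))
    out = pd.DataFrame(
        rows, columns=["regulator", "source", "n_targets", "overlap", "covered", "p"]
    )
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.nan
    return out.sort_values(["p", "regulator"], kind="mergesort").reset_index(drop=True)


# ------------------------------------------------------------------- TF signs

ACTIVATOR_LIKE = "activator_like"
REPRESSOR_LIKE = "repressor_like"


def tf_sign_classification(
    tf_ids: list[str], expr: OmicsMatrix, target_gene: str
) -> tuple[pd.DataFrame, list[str]]:
    """Classify TFs as activator-like (r >= 0) or repressor-like (r < 0)
    by their expression correlation with a target gene.

    Returns the per-TF table (tf, r, p, n_used, sign_class) and the list
    of TFs excluded for missing/constant rows. r = 0 counts as
    activator-like — the boundary is a strict partition.
    """
    if target_gene not in expr:
        raise KeyError(f"target gene {target_gene!r} not in expression matrix")
    y = expr.row(target_gene)
    rows, excluded = [], []
    for tf in tf_ids:
        if tf not in expr:
            excluded.append(tf)
            continue
        try:
            res = pearson(expr.row(tf), y, id_a=tf, id_b=target_gene)
        except ValueError:
            excluded.append(tf)
            continue
        cls = ACTIVATOR_LIKE if res.r >= 0 else REPRESSOR_LIKE
        rows.append((tf, res.r, res.p_two_sided, res.n_used, cls))
    table = pd.DataFrame(rows, columns=["tf", "r", "p", "n_used", "sign_class"])
    return table, excluded


# -------------------------------------------------------------------- ceRNA


def shared_mirnas(
    gene_group: list[str],
    sets: RegulatorSetCollection,
    sources: list[str],
) -> tuple[dict[str, frozenset[str]], frozenset[str]]:
    """Per-source intersection of miRNAs targeting every gene of a group,
    plus the cross-source union of those intersections.

    Within one source, a miRNA is shared when the whole group lies in
    its target set. Order of the gene group is irrelevant.
    """
    if not gene_group:
        raise ValidationError("empty gene group")
    known = set(sets.sources())
    for src in sources:
        if src not in known:
            raise KeyError(f"unknown source {src!r}; have {sorted(known)}")
    group = set(gene_group)
    per_source: dict[str, frozenset[str]] = {}
    for src in sources:
        shared = {
            mirna
            for (mirna, s), targets in sets
            if s == src and group <= targets
        }
        per_source[src] = frozenset(shared)
    union = frozenset(set().union(*per_source.values())) if per_source else frozenset()
    return per_source, union


def mirna_anticorrelation(
    mirna: str,
    gene: str,
    mirna_expr: OmicsMatrix,
    expr: OmicsMatrix,
    alpha: float = 0.05,
) -> tuple[float, float, bool]:
    """Pearson r/p of a miRNA against a gene; flag true iff r < 0 and p < alpha."""
    me, ge = mirna_expr.align_columns(expr)
    res = pearson(me.row(mirna), ge.row(gene), id_a=mirna, id_b=gene)
    return res.r, res.p_two_sided, (res.r < 0 and res.p_two_sided < alpha)


@dataclass
class CeRNACandidate:
    gene_a: str
    gene_b: str
    per_source_shared: dict[str, frozenset[str]]
    shared_union: frozenset[str]
    pair_r: float
    pair_p: float
    anticorr_support: int
    supporting_mirnas: frozenset[str]
    verdict: bool

    @property
    def union_count(self) -> int:
        return len(self.shared_union)


def cerna_candidates(
    pairs: list[tuple[str, str]],
    sets: RegulatorSetCollection,
    expr: OmicsMatrix,
    mirna_expr: OmicsMatrix,
    sources: list[str] | None = None,
    min_shared: int = 5,
    r_pair_min: float = 0.6,
    min_support: int = 3,
    alpha: float = 0.05,
) -> list[CeRNACandidate]:
    """Call ceRNA candidate pairs.

    Verdict is true iff (1) the union of per-source shared miRNAs has at
    least ``min_shared`` members, (2) the pair's expression correlation
    is >= ``r_pair_min``, and (3) at least ``min_support`` shared miRNAs
    are anti-correlation-flagged with *both* genes. Raising any
    threshold can only flip verdicts true -> false.
    """
    if sources is None:
        sources = sets.sources()
    out = []
    for ga, gb in pairs:
        per_source, union = shared_mirnas([ga, gb], sets, sources)
        res = pearson(expr.row(ga), expr.row(gb), id_a=ga, id_b=gb)
        supporting = set()
        for m in union:
            if m not in mirna_expr:
                continue
            *_, fa = mirna_anticorrelation(m, ga, mirna_expr, expr, alpha)
            *_, fb = mirna_anticorrelation(m, gb, mirna_expr, expr, alpha)
            if fa and fb:
                supporting.add(m)
        verdict = (
            len(union) >= min_shared
            and res.r >= r_pair_min
            and len(supporting) >= min_support
        )
        out.append(
            CeRNACandidate(
                gene_a=ga,
                gene_b=gb,
                per_source_shared=per_source,
                shared_union=union,
                pair_r=res.r,
                pair_p=res.p_two_sided,
                anticorr_support=len(supporting),
                supporting_mirnas=frozenset(supporting),
                verdict=verdict,
            )
        )
    return out


# ------------------------------------------------------------------ pathways


def pathway_partition(gene_pathway_sets: dict[str, set[str]]) -> VennPartition:
    """Venn-partition pathway memberships of 2-8 genes (pathways are the
    elements; each cell lists pathways shared by exactly that gene combination)."""
    if not 2 <= len(gene_pathway_sets) <= 8:
        raise ValidationError(
            f"need 2-8 genes, got {len(gene_pathway_sets)}"
        )
    return venn_partition(gene_pathway_sets)
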