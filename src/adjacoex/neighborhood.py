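"""Genomic-neighborhood co-expression analysis.

Given a seed gene, profile genome-wide co-expression against it,
threshold the profile (r >= 0.6 by default, inclusive), summarise where
the surviving genes sit on the cytoband map, and cluster them into runs
of physically adjacent genes — the positional signature of co-regulated
blocks on an amplified chromosome arm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .correlation import bh_adjust, correlate_rows
from .model import GeneAnnotation, OmicsMatrix, ValidationError

__all__ = [
    "CoexpressionProfile",
    "NeighborhoodCluster",
    "seed_profile",
    "threshold_profile",
    "band_fractions",
    "adjacency_clusters",
]


@dataclass
class CoexpressionProfile:
    """Per-gene correlation (r, p, n_used) against one seed gene."""

    seed_gene: str
    entries: pd.DataFrame  # columns: gene_id, r, n_used, p, q
    exclusions: pd.DataFrame

    def r_of(self, gene_id: str) -> float:
        sub = self.entries.loc[self.entries["gene_id"] == gene_id, "r"]
        if sub.empty:
            raise KeyError(f"gene {gene_id!r} not in profile")
        return float(sub.iloc[0])


def seed_profile(expr: OmicsMatrix, seed: str) -> CoexpressionProfile:
    """Correlate every gene in the matrix against the seed gene's row."""
    if seed not in expr:
        raise KeyError(f"seed gene {seed!r} not in expression matrix")
    batch = correlate_rows(expr, expr, pairing="all-vs-seed", seed=seed)
    excl = batch[batch["r"].isna()].copy()
    good = batch[batch["r"].notna()].copy()
    good = good.rename(columns={"id_a": "gene_id"}).drop(columns=["id_b"])
    excl = excl.rename(columns={"id_a": "gene_id"}).drop(columns=["id_b"])
    excl["reason"] = "constant row or <3 shared observations"
    return CoexpressionProfile(
        seed_gene=seed,
        entries=good.reset_index(drop=True),
        exclusions=excl[["gene_id", "reason"]].reset_index(drop=True),
    )


def threshold_profile(profile: CoexpressionProfile, r_min: float = 0.6) -> set[str]:
    """Genes with r >= r_min against the seed, excluding the seed itself."""
    ent = profile.entries
    hits = ent.loc[ent["r"] >= r_min, "gene_id"]
    return set(hits) - {profile.seed_gene}


def band_fractions(
    genes: set[str], annotation: GeneAnnotation
) -> tuple[pd.DataFrame, list[str]]:
    """Per-cytoband count/fraction of a significant gene set.

    fraction = significant genes on the band / all annotated genes on
    the band. The one-sided hypergeometric upper-tail p asks whether the
    band holds more of the significant set than a uniform draw from all
    annotated genes would give; BH q is computed across bands. Genes
    missing from the annotation (or unbanded) are returned separately.
    """
    banded = [r for r in annotation if r.cytoband]
    skipped = sorted(
        g for g in genes if g not in annotation or not annotation[g].cytoband
    )
    usable = genes - set(skipped)

    by_band: dict[str, list[str]] = {}
    for rec in banded:
        by_band.setdefault(rec.cytoband, []).append(rec.gene_id)
    N = len(banded)
    n_draw = len(usable)
    rows = []
    for band, members in by_band.items():
        K = len(members)
        k = len(usable & set(members))
        frac = k / K if K else 0.0
        # upper tail: P(X >= k) when drawing n_draw genes from N with K successes
        p = float(stats.hypergeom.sf(k - 1, N, K, n_draw)) if k > 0 else 1.0
        rows.append((band, k, K, frac, p))
    table = pd.DataFrame(
        rows, columns=["band", "n_significant", "n_total", "fraction", "p"]
    ).sort_values("band", kind="mergesort").reset_index(drop=True)
    table["q"] = bh_adjust(table["p"].to_numpy()) if len(table) else np.nan
    return table, skipped


@dataclass
class NeighborhoodCluster:
    """A maximal run of physically adjacent genes passing the threshold."""

    members: list[str]  # in coordinate order
    band_span: str
    size: int
    min_r: float | None
    max_r: float | None
    gaps_used: int


def adjacency_clusters(
    genes: set[str],
    annotation: GeneAnnotation,
    max_gap: int = 0,
    min_size: int = 2,
    profile: CoexpressionProfile | None = None,
) -> list[NeighborhoodCluster]:
    """Cluster a significant gene set into runs of adjacent genes.

    Scanning genes in coordinate order per chromosome, a cluster is a
    maximal run of significant genes in which each interruption is at
    most ``max_gap`` consecutive non-significant genes. Clusters smaller
    than ``min_size`` are discarded. Output order follows coordinates
    and is invariant to the iteration order of ``genes``.
    """
    if max_gap < 0 or min_size < 1:
        raise ValidationError("max_gap must be >=0 and min_size >=1")

    def finish(run: list, out: list, gaps: int) -> None:
        if len(run) >= min_size:
            bands = [annotation[g].cytoband for g in run if annotation[g].cytoband]
            span = bands[0] if bands and bands[0] == bands[-1] else (
                f"{bands[0]}-{bands[-1]}" if bands else ""
            )
            rs = None
            if profile is not None:
                rs = [profile.r_of(g) for g in run]
            out.append(
                NeighborhoodCluster(
                    members=list(run),
                    band_span=span,
                    size=len(run),
                    min_r=min(rs) if rs else None,
                    max_r=max(rs) if rs else None,
                    gaps_used=gaps,
                )
            )

    clusters: list[NeighborhoodCluster] = []
    by_chrom: dict[str, list[str]] = {}
    for rec in annotation:
        by_chrom.setdefault(rec.interval.chrom, []).append(rec.gene_id)

    for chrom_genes in by_chrom.values():
        run: list[str] = []
        pending_gap = 0
        total_gaps = 0
        for gid in chrom_genes:
            if gid in genes:
                if run and pending_gap:
                    total_gaps += pending_gap
                pending_gap = 0
                run.append(gid)
            else:
                if not run:
                    continue
                pending_gap += 1
                if pending_gap > max_gap:
                    finish(run, clusters, total_gaps)
                    run, pending_gap, total_gaps = [], 0, 0
        finish(run, clusters, total_gaps)
    return clusters
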