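"""Pearson correlation with significance and multiplicity control.

The cis-effect screen correlates each gene's expression with its own
copy-number level; a gene is called cis-driven when r clears a
magnitude threshold and the two-sided p-value (from the exact t
transform, t = r*sqrt((n-2)/(1-r^2)) on n-2 df) clears alpha. Missing
values are pairwise-deleted, never imputed, and the effective sample
size is recorded per pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import OmicsMatrix, ValidationError

__all__ = [
    "CorrelationResult",
    "CisScreenReport",
    "ConstantInputError",
    "InsufficientDataError",
    "pearson",
    "correlate_rows",
    "bh_adjust",
    "cna_mrna_screen",
]


class ConstantInputError(ValueError):
    """A vector with zero variance has no defined Pearson correlation."""


class InsufficientDataError(ValueError):
    """Fewer than 3 paired non-missing observations."""


@dataclass(frozen=True)
class CorrelationResult:
    id_a: str
    id_b: str
    r: float
    n_used: int
    p_two_sided: float
    q_bh: float | None = None


def pearson(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    id_a: str = "x",
    id_b: str = "y",
) -> CorrelationResult:
    """Pearson r with a two-sided p-value from the t transform.

    NaN entries are pairwise-deleted; at least 3 paired observations
    and non-constant vectors are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    keep = ~(np.isnan(x) | np.isnan(y))
    xs, ys = x[keep], y[keep]
    n = xs.size
    if n < 3:
        raise InsufficientDataError(f"only {n} paired non-missing observations")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ConstantInputError(f"constant vector in pair ({id_a}, {id_b})")
    r, p = stats.pearsonr(xs, ys)
    return CorrelationResult(id_a=id_a, id_b=id_b, r=float(r), n_used=n, p_two_sided=float(p))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


PairingRule = Literal["matched", "all-vs-seed", "all-pairs"]


def correlate_rows(
    a: OmicsMatrix,
    b: OmicsMatrix,
    pairing: PairingRule | Iterable[tuple[str, str]] = "matched",
    seed: str | None = None,
) -> pd.DataFrame:
    """Correlate rows of two matrices after aligning shared samples.

    ``pairing`` is one of:

    - ``"matched"``: each row id present in both matrices against itself;
    - ``"all-vs-seed"``: every row of ``a`` against row ``seed`` of ``b``;
    - ``"all-pairs"``: full cross product of rows of ``a`` and of ``b``;
    - or an explicit iterable of (row-in-a, row-in-b) id pairs.

    Returns a frame with columns id_a, id_b, r, n_used, p, q (BH over
    the batch). Pairs that are constant or have <3 shared observations
    are returned with NaN statistics rather than silently dropped.
    """
    a, b = a.align_columns(b)
    if isinstance(pairing, str):
        if pairing == "matched":
            shared = [rid for rid in a.row_ids if rid in b]
            pairs = [(rid, rid) for rid in shared]
        elif pairing == "all-vs-seed":
            if seed is None:
                raise ValidationError("all-vs-seed pairing requires a seed row id")
            if seed not in b:
                raise KeyError(f"seed row {seed!r} not in matrix")
            pairs = [(rid, seed) for rid in a.row_ids]
        elif pairing == "all-pairs":
            pairs = [(ra, rb) for ra in a.row_ids for rb in b.row_ids]
        else:
            raise ValueError(f"unknown pairing rule {pairing!r}")
    else:
        pairs = list(pairing)

    rows = []
    for ra, rb in pairs:
        try:
            res = pearson(a.row(ra), b.row(rb), id_a=ra, id_b=rb)
            rows.append((ra, rb, res.r, res.n_used, res.p_two_sided))
        except (ConstantInputError, InsufficientDataError):
            rows.append((ra, rb, np.nan, 0, np.nan))
    out = pd.DataFrame(rows, columns=["id_a", "id_b", "r", "n_used", "p"])
    out["q"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out


@dataclass
class CisScreenReport:
    """Per-gene copy-number -> expression cis screen.

    ``results`` is sorted by descending r and carries a boolean
    ``cis_driven`` column; genes that could not be tested are listed in
    ``exclusions`` with a reason, never silently dropped.
    """

    results: pd.DataFrame
    exclusions: pd.DataFrame
    r_min: float
    alpha: float
    use_bh: bool = False

    def cis_genes(self) -> list[str]:
        return self.results.loc[self.results["cis_driven"], "gene_id"].tolist()


def cna_mrna_screen(
    cna: OmicsMatrix,
    expr: OmicsMatrix,
    r_min: float = 0.65,
    alpha: float = 1e-4,
    use_bh: bool = False,
) -> CisScreenReport:
    """Correlate each gene's expression with its own copy-number row.

    A gene is flagged cis-driven when r > ``r_min`` and its p-value
    (raw by default; BH-adjusted q when ``use_bh``) is <= ``alpha``.
    """
    cna_ids = set(cna.row_ids)
    expr_ids = set(expr.row_ids)
    excl = [
        (g, "missing from CNA matrix") for g in sorted(expr_ids - cna_ids)
    ] + [(g, "missing from expression matrix") for g in sorted(cna_ids - expr_ids)]

    batch = correlate_rows(expr, cna, pairing="matched")
    untestable = batch[batch["r"].isna()]
    for g in untestable["id_a"]:
        excl.append((g, "constant row or <3 shared observations"))
    batch = batch[batch["r"].notna()].copy()

    crit = batch["q"] if use_bh else batch["p"]
    batch["cis_driven"] = (batch["r"] > r_min) & (crit <= alpha)
    batch = batch.rename(columns={"id_a": "gene_id"}).drop(columns=["id_b"])
    batch = batch.sort_values("r", ascending=False, kind="mergesort").reset_index(
        drop=True
    )
    exclusions = pd.DataFrame(excl, columns=["gene_id", "reason"])
    return CisScreenReport(
        results=batch, exclusions=exclusions, r_min=r_min, alpha=alpha, use_bh=use_bh
    )
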