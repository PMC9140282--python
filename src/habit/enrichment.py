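"""Gene-set fold enrichment with Fisher's exact test.

For a focal gene set (e.g. an O-GlcNAc proteome) and an annotation category
(a phenotype term or a disease-gene orthology set) within a background
universe, the overlap is summarised by four counts: a genes in both the
focal set and the category, b genes in the focal set, c genes in the
category, d genes in the universe.  Fold enrichment is the annotation rate
inside the focal set relative to the rest of the universe,
(a/b) / ((c-a)/(d-b)); significance comes from the two-sided Fisher's exact
test on the corresponding 2x2 table, with Bonferroni-Holm correction across
the categories tested together.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import scipy.stats as sps

from .errors import InvalidInputError
from .stats_engine import holm_bonferroni

__all__ = [
    "OverlapCounts",
    "EnrichmentResult",
    "fold_enrichment",
    "fisher_exact_two_sided",
    "run_enrichment",
    "read_gene_list",
    "read_category_map",
]


@dataclass(frozen=True)
class OverlapCounts:
    """2x2 overlap counts: a=focal&annotated, b=focal, c=annotated, d=universe."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        a, b, c, d = self.a, self.b, self.c, self.d
        if min(a, b, c, d) < 0:
            raise InvalidInputError("counts must be non-negative")
        if not (a <= min(b, c) and b <= d and c <= d and a >= b + c - d):
            raise InvalidInputError(
                f"inconsistent overlap counts a={a}, b={b}, c={c}, d={d}"
            )

    @property
    def table(self) -> list[list[int]]:
        """The 2x2 contingency table [[a, b-a], [c-a, d-b-(c-a)]]."""
        a, b, c, d = self.a, self.b, self.c, self.d
        return [[a, b - a], [c - a, d - b - (c - a)]]


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    counts: OverlapCounts
    enrichment: float
    p_raw: float
    p_adj: float
    overlap_genes: tuple[str, ...]


def fold_enrichment(counts: OverlapCounts) -> float:
    """Fold enrichment (a/b) / ((c-a)/(d-b)).

    Returns 0 when the overlap is empty and +inf when the focal set
    captures every annotated gene (c-a = 0 with a > 0).
    """
    a, b, c, d = counts.a, counts.b, counts.c, counts.d
    if b == 0 or d <= b:
        raise InvalidInputError("fold enrichment needs b > 0 and d > b")
    if a == 0:
        return 0.0
    if c - a == 0:
        return math.inf
    return (a / b) / ((c - a) / (d - b))


def fisher_exact_two_sided(counts: OverlapCounts, method: str = "min_likelihood") -> float:
    """Two-sided Fisher's exact p for the overlap table.

    The default sums the probabilities of all tables (margins fixed) that
    are no more likely than the observed one — the convention of standard
    statistical software.  ``method="doubling"`` instead doubles the
    smaller one-sided tail (capped at 1).
    """
    table = counts.table
    if method == "min_likelihood":
        return float(sps.fisher_exact(table, alternative="two-sided")[1])
    if method == "doubling":
        p_less = sps.fisher_exact(table, alternative="less")[1]
        p_greater = sps.fisher_exact(table, alternative="greater")[1]
        return float(min(1.0, 2.0 * min(p_less, p_greater)))
    raise InvalidInputError(f"unknown two-sided method {method!r}")


def _fold(case_fold: bool, genes: Iterable[str]) -> set[str]:
    return {g.casefold() for g in genes} if case_fold else set(genes)


def run_enrichment(
    focal_set: Iterable[str],
    category_map: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    case_fold: bool = False,
    fisher_method: str = "min_likelihood",
) -> list[EnrichmentResult]:
    """Per-category fold enrichment and Fisher p, Holm-corrected.

    The family for the multiple-testing correction is exactly the set of
    categories passed in this call.  Gene identifiers match by exact string
    (optionally after case folding); ortholog mapping, where needed, must
    happen upstream.
    """
    uni = _fold(case_fold, universe)
    focal = _fold(case_fold, focal_set)
    stray = sorted(focal - uni)
    if stray:
        raise InvalidInputError(
            f"{len(stray)} focal gene(s) absent from the universe: "
            + ", ".join(stray[:10])
        )
    results = []
    for name, genes in category_map.items():
        cat = _fold(case_fold, genes)
        stray = sorted(cat - uni)
        if stray:
            raise InvalidInputError(
                f"category {name!r}: {len(stray)} gene(s) absent from the "
                "universe: " + ", ".join(stray[:10])
            )
        overlap = focal & cat
        counts = OverlapCounts(a=len(overlap), b=len(focal), c=len(cat), d=len(uni))
        results.append(
            (name, counts, fold_enrichment(counts),
             fisher_exact_two_sided(counts, method=fisher_method), overlap)
        )
    p_adj = holm_bonferroni([r[3] for r in results])
    return [
        EnrichmentResult(
            category=name,
            counts=counts,
            enrichment=enr,
            p_raw=p,
            p_adj=float(pa),
            overlap_genes=tuple(sorted(overlap)),
        )
        for (name, counts, enr, p, overlap), pa in zip(results, p_adj)
    ]


def read_gene_list(path) -> list[str]:
    """Read a plain-text one-gene-per-line list, skipping blanks."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def read_category_map(path, sep: str = "\t") -> dict[str, list[str]]:
    """Read a two-column (gene, category) table into {category: genes}."""
    mapping: dict[str, list[str]] = {}
    for i, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        parts = ln.split(sep)
        if len(parts) != 2:
            raise InvalidInputError(f"line {i}: expected 2 columns, got {len(parts)}")
        gene, cat = (p.strip() for p in parts)
        mapping.setdefault(cat, []).append(gene)
    return mapping
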