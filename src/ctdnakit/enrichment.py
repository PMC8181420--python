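"""Per-nucleotide allele proportions and pre/post-biopsy fold enrichment.

At each patient-specific somatic locus, tumor-guided amplicon deep sequencing
yields read counts for the four nucleotides in the pre-biopsy and post-biopsy
cell-free DNA pools.  The fold enrichment of a base is the ratio of its read
proportion (count over the stored total, which may exceed the four-base sum
because of other calls) in the post-biopsy pool to its proportion in the
pre-biopsy pool.  The fold at the known mutant base measures how much
circulating tumor DNA the biopsy released.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

import pandas as pd

BASES = ("A", "T", "C", "G")

__all__ = [
    "BASES",
    "NucleotideCounts",
    "PairedLocusCounts",
    "EnrichmentResult",
    "EnrichmentReport",
    "allele_proportions",
    "fold_enrichment",
    "enrichment_report",
    "render_fold",
]


@dataclass(frozen=True)
class NucleotideCounts:
    """A/T/C/G read counts plus an independently stored total at one locus.

    ``total`` is stored, not derived: instrument reports include calls other
    than the four canonical bases, so the total may exceed the four-base sum.
    """

    locus_id: str
    count_A: int
    count_T: int
    count_C: int
    count_G: int
    total: int

    def __post_init__(self) -> None:
        counts = self.base_counts
        for base, c in counts.items():
            if not isinstance(c, (int,)) or c < 0:
                raise ValueError(f"count_{base} must be a nonnegative integer, got {c!r}")
        if not isinstance(self.total, int) or self.total < 0:
            raise ValueError(f"total must be a nonnegative integer, got {self.total!r}")
        if self.total < max(counts.values()):
            raise ValueError(
                f"total ({self.total}) is smaller than the largest base count at {self.locus_id}"
            )

    @property
    def base_counts(self) -> dict[str, int]:
        return {
            "A": self.count_A,
            "T": self.count_T,
            "C": self.count_C,
            "G": self.count_G,
        }


@dataclass(frozen=True)
class PairedLocusCounts:
    """Pre- and post-biopsy nucleotide counts at one somatic locus.

    ``mutant_base`` is explicit input and never inferred from variant
    nomenclature: the assayed strand may differ from the transcript strand.
    """

    gene: str
    mutant_base: str
    ref_base: str
    pre: NucleotideCounts
    post: NucleotideCounts

    def __post_init__(self) -> None:
        if self.mutant_base not in BASES or self.ref_base not in BASES:
            raise ValueError("mutant_base and ref_base must each be one of A/T/C/G")
        if self.mutant_base == self.ref_base:
            raise ValueError("mutant_base must differ from ref_base")
        if self.pre.locus_id != self.post.locus_id:
            raise ValueError(
                f"pre and post counts refer to different loci: "
                f"{self.pre.locus_id!r} vs {self.post.locus_id!r}"
            )

    @property
    def locus_id(self) -> str:
        return self.pre.locus_id


def allele_proportions(counts: NucleotideCounts) -> dict[str, float]:
    """Proportion of reads supporting each base, over the stored total.

    The four proportions sum to at most 1 (strictly below 1 when the stored
    total exceeds the four-base sum).
    """
    if counts.total <= 0:
        raise ValueError(f"total must be positive at {counts.locus_id}")
    return {b: c / counts.total for b, c in counts.base_counts.items()}


def render_fold(value: Optional[float], mode: Literal["round", "trunc"] = "round") -> str:
    """One-decimal rendering of a fold value; undefined folds render blank.

    ``round`` is conventional half-up rounding; ``trunc`` truncates toward
    zero.  Undefined (``None``) never renders as 0 or infinity.
    """
    if value is None:
        return ""
    if value < 0:
        raise ValueError("fold values are nonnegative")
    if mode == "round":
        return f"{math.floor(value * 10 + 0.5) / 10:.1f}"
    if mode == "trunc":
        return f"{math.floor(value * 10) / 10:.1f}"
    raise ValueError(f"unknown rendering mode {mode!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-base fold enrichment at one locus.

    ``folds`` maps each base to post/pre proportion ratio, or ``None`` where
    the pre-biopsy count is zero (the fold is undefined, not zero or
    infinite).  Full precision is retained; one-decimal renderings are
    available through :meth:`rendered`.
    """

    gene: str
    locus_id: str
    mutant_base: str
    folds: Mapping[str, Optional[float]]
    pre_proportion: float
    post_proportion: float
    mutant_fold: Optional[float] = field(init=False, default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mutant_fold", self.folds[self.mutant_base])

    def rendered(self, mode: Literal["round", "trunc"] = "round") -> dict[str, str]:
        return {b: render_fold(v, mode) for b, v in self.folds.items()}


def fold_enrichment(pair: PairedLocusCounts) -> EnrichmentResult:
    """Post/pre ratio of per-base read proportions at one locus.

    fold(b) = [post.count_b / post.total] / [pre.count_b / pre.total];
    undefined when the pre-biopsy count of b is zero.
    """
    pre_prop = allele_proportions(pair.pre)
    post_prop = allele_proportions(pair.post)
    folds: dict[str, Optional[float]] = {}
    for b in BASES:
        folds[b] = post_prop[b] / pre_prop[b] if pre_prop[b] > 0 else None
    return EnrichmentResult(
        gene=pair.gene,
        locus_id=pair.locus_id,
        mutant_base=pair.mutant_base,
        folds=folds,
        pre_proportion=pre_prop[pair.mutant_base],
        post_proportion=post_prop[pair.mutant_base],
    )


@dataclass(frozen=True)
class EnrichmentReport:
    """One row per locus plus the across-loci mutant-fold range."""

    table: pd.DataFrame
    results: tuple[EnrichmentResult, ...]
    min_mutant_fold: float
    max_mutant_fold: float


def enrichment_report(
    pairs: Sequence[PairedLocusCounts],
    render: Literal["round", "trunc"] = "round",
) -> EnrichmentReport:
    """Tabulate counts, totals and per-base folds across assayed loci.

    Undefined folds render blank in the table.  The summary min/max is over
    the mutant-base folds (all defined by construction of the assay: the
    mutant allele was observed pre-biopsy or the fold is reported undefined
    and excluded from the range).
    """
    if not pairs:
        raise ValueError("at least one paired locus is required")
    seen: set[str] = set()
    rows = []
    results = []
    for pair in pairs:
        if pair.locus_id in seen:
            raise ValueError(f"duplicate locus_id {pair.locus_id!r}")
        seen.add(pair.locus_id)
        res = fold_enrichment(pair)
        results.append(res)
        row: dict[str, object] = {"locus_id": pair.locus_id, "gene": pair.gene}
        for b in BASES:
            row[f"pre_{b}"] = pair.pre.base_counts[b]
        row["pre_total"] = pair.pre.total
        for b in BASES:
            row[f"post_{b}"] = pair.post.base_counts[b]
        row["post_total"] = pair.post.total
        for b in BASES:
            row[f"fold_{b}"] = render_fold(res.folds[b], render)
        row["mutant_base"] = pair.mutant_base
        row["mutant_fold"] = res.mutant_fold
        rows.append(row)
    mutant_folds = [r.mutant_fold for r in results if r.mutant_fold is not None]
    if not mutant_folds:
        raise ValueError("no locus has a defined mutant fold")
    return EnrichmentReport(
        table=pd.DataFrame(rows),
        results=tuple(results),
        min_mutant_fold=min(mutant_folds),
        max_mutant_fold=max(mutant_folds),
    )
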