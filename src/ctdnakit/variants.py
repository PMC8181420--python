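"""Somatic-candidate prioritization from cohort variant calls.

Tumor variant calls from targeted RNA sequencing mix true somatic mutations
with germline polymorphisms and recurrent sequencing artifacts.  Likely
somatic candidates are selected by a fixed cascade: exonic SNVs with
alternative allele fraction <= 0.35, population minor allele frequency < 0.01
(for annotated variants), depth >= 50 reads, and site recurrence across the
cohort <= 25% of samples (more recurrent sites are treated as artifacts).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

REGION_CLASSES = ("exonic", "other")
CONSEQUENCES = ("missense", "synonymous", "nonsense", "other")

#: Most severe first; used to collapse multiple hits in one gene/sample cell.
CONSEQUENCE_SEVERITY = ("nonsense", "missense", "synonymous", "other")

FILTER_ORDER = ("region", "aaf", "maf", "depth", "recurrence")

__all__ = [
    "VariantCall",
    "FilterThresholds",
    "CandidateSet",
    "filter_candidates",
    "recurrence_fraction",
    "mutation_matrix",
    "FILTER_ORDER",
    "CONSEQUENCE_SEVERITY",
]


@dataclass(frozen=True)
class VariantCall:
    """One called variant in one sample.

    ``pop_maf`` is ``None`` for unannotated variants (absent from population
    databases); such calls pass the MAF filter.  Coordinates are 1-based as
    in VCF.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    aaf: float
    depth: int
    pop_maf: Optional[float]
    region_class: str
    consequence: str
    gene: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.pos < 1:
            raise ValueError("positions are 1-based; pos must be >= 1")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def site(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt)


@dataclass(frozen=True)
class FilterThresholds:
    """Cascade thresholds; defaults are the values the candidate definition
    above states (AAF 0.35, MAF 0.01, depth 50, recurrence 0.25).

    Boundary semantics: AAF <= max_aaf (inclusive), pop MAF < max_pop_maf
    (strict), depth >= min_depth (inclusive), recurrence excluded only when
    strictly above max_recurrence.
    """

    max_aaf: float = 0.35
    max_pop_maf: float = 0.01
    min_depth: int = 50
    max_recurrence: float = 0.25

    def __post_init__(self) -> None:
        if not 0 <= self.max_aaf <= 1:
            raise ValueError("max_aaf must be in [0, 1]")
        if not 0 <= self.max_pop_maf <= 0.5:
            raise ValueError("max_pop_maf must be in [0, 0.5]")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if not 0 <= self.max_recurrence <= 1:
            raise ValueError("max_recurrence must be in [0, 1]")


@dataclass(frozen=True)
class CandidateSet:
    """Filter output: surviving calls plus per-rule removal tallies.

    ``per_filter_tally`` counts removals in fixed application order
    (region -> aaf -> maf -> depth -> recurrence); the kept set itself is
    order-independent because every rule is a per-call predicate evaluated
    against the *input* cohort.
    """

    candidates: tuple[VariantCall, ...]
    per_filter_tally: Mapping[str, int]
    n_input: int
    n_samples: int
    dropped_non_snv: int = 0
    dropped_malformed: int = 0

    def by_sample(self) -> dict[str, list[VariantCall]]:
        out: dict[str, list[VariantCall]] = {}
        for call in self.candidates:
            out.setdefault(call.sample_id, []).append(call)
        return out


def recurrence_fraction(
    site: tuple[str, int, str],
    calls: Mapping[str, Sequence[VariantCall]],
) -> float:
    """Fraction of cohort samples carrying the exact chrom/pos/alt site.

    The denominator is all cohort samples (including samples without any
    call at the site), not just covered samples.
    """
    if not calls:
        raise ValueError("at least one sample is required")
    carriers = {
        sample
        for sample, sample_calls in calls.items()
        for c in sample_calls
        if c.site == site
    }
    return len(carriers) / len(calls)


def _is_malformed(call: VariantCall) -> bool:
    bad_aaf = not (0.0 <= call.aaf <= 1.0) or call.aaf != call.aaf
    bad_depth = call.depth < 0
    bad_maf = call.pop_maf is not None and not (0.0 <= call.pop_maf <= 0.5)
    return bad_aaf or bad_depth or bad_maf


def filter_candidates(
    calls: Mapping[str, Sequence[VariantCall]],
    thresholds: FilterThresholds = FilterThresholds(),
) -> CandidateSet:
    """Apply the somatic-candidate cascade to per-sample call lists.

    Keeps exactly the SNV calls satisfying all five predicates:
    region_class == "exonic", aaf <= max_aaf, (pop_maf unknown or
    pop_maf < max_pop_maf), depth >= min_depth, and site recurrence
    <= max_recurrence.  Recurrence is computed over the input cohort, so
    filtering is idempotent and the kept set does not depend on rule order.

    Non-SNV rows (indels/MNVs) and malformed rows (AAF outside [0, 1],
    negative depth) are dropped with logged counts before the cascade.
    """
    if len(calls) < 2:
        raise ValueError(
            "the recurrence filter is undefined for fewer than 2 samples; "
            f"got {len(calls)}"
        )
    n_samples = len(calls)

    snv_calls: dict[str, list[VariantCall]] = {s: [] for s in calls}
    dropped_non_snv = 0
    dropped_malformed = 0
    for sample, sample_calls in calls.items():
        for i, call in enumerate(sample_calls):
            if not call.is_snv:
                dropped_non_snv += 1
                continue
            if _is_malformed(call):
                dropped_malformed += 1
                logger.warning(
                    "dropping malformed call %d of sample %s at %s:%d (aaf=%r, depth=%r)",
                    i, sample, call.chrom, call.pos, call.aaf, call.depth,
                )
                continue
            snv_calls[sample].append(call)
    if dropped_non_snv:
        logger.info("dropped %d non-SNV calls", dropped_non_snv)

    # Recurrence is a fixed per-call predicate against the input cohort.
    site_carriers: dict[tuple[str, int, str], set[str]] = {}
    for sample, sample_calls in snv_calls.items():
        for call in sample_calls:
            site_carriers.setdefault(call.site, set()).add(sample)
    recurrence = {site: len(c) / n_samples for site, c in site_carriers.items()}

    predicates = {
        "region": lambda c: c.region_class == "exonic",
        "aaf": lambda c: c.aaf <= thresholds.max_aaf,
        "maf": lambda c: c.pop_maf is None or c.pop_maf < thresholds.max_pop_maf,
        "depth": lambda c: c.depth >= thresholds.min_depth,
        "recurrence": lambda c: recurrence[c.site] <= thresholds.max_recurrence,
    }

    tally = {name: 0 for name in FILTER_ORDER}
    kept: list[VariantCall] = []
    n_input = sum(len(v) for v in snv_calls.values())
    for sample in calls:
        for call in snv_calls[sample]:
            for name in FILTER_ORDER:
                if not predicates[name](call):
                    tally[name] += 1
                    break
            else:
                kept.append(call)

    return CandidateSet(
        candidates=tuple(kept),
        per_filter_tally=tally,
        n_input=n_input,
        n_samples=n_samples,
        dropped_non_snv=dropped_non_snv,
        dropped_malformed=dropped_malformed,
    )


def mutation_matrix(
    candidates: CandidateSet | Sequence[VariantCall],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Gene x sample matrix of the most severe consequence, plus totals.

    Each cell holds the highest-impact consequence present for that gene in
    that sample (nonsense > missense > synonymous > other), or "" when the
    gene is unmutated in the sample.  The totals count candidate variants
    (not cells) per consequence class — the numbers a waterfall plot legend
    reports.
    """
    calls = candidates.candidates if isinstance(candidates, CandidateSet) else tuple(candidates)
    if not calls:
        warnings.warn("empty candidate set: returning an empty mutation matrix")
        return pd.DataFrame(), {c: 0 for c in CONSEQUENCE_SEVERITY}

    severity_rank = {c: i for i, c in enumerate(CONSEQUENCE_SEVERITY)}
    genes = sorted({c.gene for c in calls})
    samples = sorted({c.sample_id for c in calls})
    matrix = pd.DataFrame("", index=pd.Index(genes, name="gene"),
                          columns=pd.Index(samples, name="sample"))
    totals = {c: 0 for c in CONSEQUENCE_SEVERITY}
    for call in calls:
        totals[call.consequence] = totals.get(call.consequence, 0) + 1
        current = matrix.at[call.gene, call.sample_id]
        if current == "" or severity_rank[call.consequence] < severity_rank.get(current, 99):
            matrix.at[call.gene, call.sample_id] = call.consequence
    return matrix, totals


def relax(thresholds: FilterThresholds, **changes: float) -> FilterThresholds:
    """Return thresholds with the given fields replaced (convenience)."""
    return replace(thresholds, **changes)
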