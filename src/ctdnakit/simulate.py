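"""Synthetic-data generators for every pipeline input.

Patient-level data behind the analysis are restricted, so each stage is
exercised on simulated inputs carrying the statistical structure the
analysis assumes:

* cohort variant lists mixing germline polymorphisms (AAF near 0.5/1.0 with
  database MAF), low-AAF private somatic SNVs, and recurrent artifacts
  shared across samples;
* pre/post amplicon pileups with binomially/multinomially sampled mutant
  reads at specified ctDNA fractions and a symmetric per-base miscall rate;
* Gaussian nucleosomal-ladder size traces (~165/380/630/870 bp plus a broad
  >1 kb tail);
* log-normal baseline plasma concentrations with an injury-release bump
  rising linearly to a per-patient peak time in [60, 120] min, then flat.

Every generator is a pure function of its config, including the seed.  True
class labels and closed-form expectations are returned or exposed so tests
can use them as oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .enrichment import BASES, NucleotideCounts, PairedLocusCounts
from .fragmentomics import FragmentProfile
from .stats import ConcentrationRecord
from .variants import VariantCall

__all__ = [
    "CohortSimConfig",
    "AmpliconSimConfig",
    "LadderSimConfig",
    "KineticsSimConfig",
    "SimulatedCohort",
    "simulate_variant_cohort",
    "simulate_amplicon_counts",
    "simulate_fragment_profile",
    "simulate_kinetics_cohort",
    "expected_base_proportions",
]


# ---------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class CohortSimConfig:
    """Cohort variant-list generator settings.

    Rates are per site: each site is germline, somatic, artifact, or absent.
    ``known_maf_distribution`` is ``(p_annotated, maf_low, maf_high)``: a
    germline site is database-annotated with probability ``p_annotated`` and
    then draws a log-uniform population MAF in ``[maf_low, maf_high]``
    (>= 0.01 so the MAF filter fires); otherwise its MAF is unknown.
    ``artifact_sample_fraction`` is the minimum fraction of samples sharing
    each artifact site; keep it above 0.25 so the recurrence filter fires.
    """

    n_samples: int = 8
    n_sites: int = 200
    germline_rate: float = 0.45
    somatic_rate: float = 0.10
    artifact_rate: float = 0.05
    somatic_aaf_range: tuple[float, float] = (0.02, 0.35)
    germline_aaf_center: float = 0.5
    depth_distribution: tuple[float, float] = (700.0, 0.3)
    exonic_fraction: float = 0.85
    known_maf_distribution: tuple[float, float, float] = (0.9, 0.01, 0.5)
    artifact_sample_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2 (recurrence filter undefined below)")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        for name in ("germline_rate", "somatic_rate", "artifact_rate",
                     "exonic_fraction", "artifact_sample_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.germline_rate + self.somatic_rate + self.artifact_rate > 1:
            raise ValueError("class rates must sum to <= 1")
        lo, hi = self.somatic_aaf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("somatic_aaf_range must lie within (0, 0.5]")
        mean, disp = self.depth_distribution
        if mean <= 0 or disp < 0:
            raise ValueError("depth mean must be > 0 and dispersion >= 0")
        p_ann, mlo, mhi = self.known_maf_distribution
        if not (0 <= p_ann <= 1 and 0 < mlo <= mhi <= 0.5):
            raise ValueError("known_maf_distribution must be (prob, low, high) with 0 < low <= high <= 0.5")


@dataclass(frozen=True)
class AmpliconSimConfig:
    """Forward model for one pre/post amplicon deep-sequencing pair.

    The true mutant-allele proportion in each pool is
    ``ctdna_fraction * tissue_aaf``; each read reports its true base with
    probability ``1 - error_rate`` and otherwise one of the other three
    bases uniformly (rate ``error_rate / 3`` each).
    """

    tissue_aaf: float = 0.5
    ctdna_fraction_pre: float = 0.01
    ctdna_fraction_post: float = 0.2
    depth_pre: int = 235_000
    depth_post: int = 235_000
    error_rate: float = 1e-3
    mutant_base: str = "T"
    ref_base: str = "C"
    gene: str = "SIM"
    locus_id: str = "sim_locus"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tissue_aaf", "ctdna_fraction_pre", "ctdna_fraction_post"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.depth_pre < 1 or self.depth_post < 1:
            raise ValueError("depths must be >= 1")
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        if self.mutant_base not in BASES or self.ref_base not in BASES:
            raise ValueError("bases must be one of A/T/C/G")
        if self.mutant_base == self.ref_base:
            raise ValueError("mutant_base must differ from ref_base")


@dataclass(frozen=True)
class LadderSimConfig:
    """Nucleosomal-ladder trace generator settings.

    Component k deposits mass ``molar_amounts[k] * peak_centers[k]`` spread
    as a Gaussian of sd ``peak_widths[k]`` around its center, so trapezoidal
    mass-to-molar back-conversion recovers ``molar_amounts``.
    ``long_tail_mass`` is mass in a broad >1 kb component emulating injury
    fragments; ``noise_sd`` is additive trace noise.
    """

    peak_orders: tuple[int, ...] = (1, 2, 3, 4)
    peak_centers: tuple[float, ...] = (165.0, 380.0, 630.0, 870.0)
    peak_widths: tuple[float, ...] = (12.0, 22.0, 30.0, 38.0)
    molar_amounts: tuple[float, ...] = (1.0, 0.25, 0.08, 0.03)
    long_tail_mass: float = 0.0
    long_tail_center: float = 1300.0
    long_tail_width: float = 250.0
    noise_sd: float = 0.0
    size_grid: tuple[float, float, float] = (25.0, 2000.0, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.peak_orders)
        if not (len(self.peak_centers) == len(self.peak_widths) == len(self.molar_amounts) == k):
            raise ValueError("peak_orders/centers/widths/molar_amounts must have equal lengths")
        if any(c2 <= c1 for c1, c2 in zip(self.peak_centers, self.peak_centers[1:])):
            raise ValueError("peak_centers must be strictly increasing")
        if any(w <= 0 for w in self.peak_widths):
            raise ValueError("peak_widths must be > 0")
        if any(m < 0 for m in self.molar_amounts):
            raise ValueError("molar_amounts must be >= 0")
        if self.long_tail_mass < 0 or self.noise_sd < 0:
            raise ValueError("long_tail_mass and noise_sd must be >= 0")
        lo, hi, step = self.size_grid
        if not (lo < hi and step > 0):
            raise ValueError("size_grid must be (min, max, step) with min < max and step > 0")


@dataclass(frozen=True)
class KineticsSimConfig:
    """Concentration-kinetics generator settings.

    Patient i has baseline B_i ~ lognormal and release amplitude A_i ~
    lognormal; the concentration at time t is
    ``B_i + A_i * r(t; tau_i) * (1 + noise)`` with r rising linearly from 0
    at t = 0 to 1 at the patient's peak time tau_i (uniform in
    ``peak_time_range``), then flat — a stated stand-in shape, since the
    study shows only that some patients peak at 60 min while others keep
    rising at 120 min.  Noise is Gaussian with coefficient of variation
    ``noise_cv`` on the release term only, so t = 0 returns the baseline.
    """

    n_patients: int = 6
    baseline_lognormal: tuple[float, float] = (math.log(3.0), 0.35)
    release_amplitude_lognormal: tuple[float, float] = (math.log(1.8), 0.5)
    release_scale: float = 1.0
    peak_time_range: tuple[float, float] = (60.0, 120.0)
    timepoints: tuple[int, ...] = (0, 10, 30, 60, 120)
    noise_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if list(self.timepoints) != sorted(self.timepoints) or self.timepoints[0] != 0:
            raise ValueError("timepoints must be sorted with the first equal to 0 (pre-biopsy)")
        lo, hi = self.peak_time_range
        if not (0 < lo <= hi):
            raise ValueError("peak_time_range must be positive with low <= high")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.release_scale < 0:
            raise ValueError("release_scale must be >= 0 (0 turns release off)")
        if self.baseline_lognormal[1] < 0 or self.release_amplitude_lognormal[1] < 0:
            raise ValueError("lognormal sdlog parameters must be >= 0")


# ---------------------------------------------------------------------------
# cohort variant lists

_SITE_CLASSES = ("germline", "somatic", "artifact")


@dataclass(frozen=True)
class SimulatedCohort:
    """Generated calls plus the true class labels used as test oracles."""

    calls: dict[str, list[VariantCall]]
    truth: pd.DataFrame = field(repr=False)

    @property
    def n_samples(self) -> int:
        return len(self.calls)


def _draw_depth(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Gamma-Poisson (negative-binomial) depths; Poisson when dispersion = 0."""
    if dispersion == 0:
        lam = np.full(size, mean)
    else:
        lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion, size=size)
    return np.maximum(rng.poisson(lam), 1)


def simulate_variant_cohort(config: CohortSimConfig) -> SimulatedCohort:
    """Generate per-sample variant-call lists with known class labels.

    Germline sites are carried by a per-site random fraction of samples at
    AAF near the het center (or near twice it for homozygotes) and, when
    annotated, a population MAF >= 0.01.  Somatic sites are private to one
    sample with AAF in ``somatic_aaf_range`` and MAF < 0.01 or unknown.
    Artifact sites appear in at least ``artifact_sample_fraction`` of
    samples at low AAF.
    """
    rng = np.random.default_rng(config.seed)
    samples = [f"S{i + 1:02d}" for i in range(config.n_samples)]
    calls: dict[str, list[VariantCall]] = {s: [] for s in samples}
    truth_rows: list[dict[str, object]] = []

    p_ann, maf_lo, maf_hi = config.known_maf_distribution
    mean_depth, disp = config.depth_distribution
    base_idx = np.arange(4)

    for site in range(config.n_sites):
        u = rng.random()
        if u < config.germline_rate:
            site_class = "germline"
        elif u < config.germline_rate + config.somatic_rate:
            site_class = "somatic"
        elif u < config.germline_rate + config.somatic_rate + config.artifact_rate:
            site_class = "artifact"
        else:
            continue  # absent everywhere

        chrom = "chr1"
        pos = 1_000 + 10 * site
        ref_i, alt_i = rng.choice(base_idx, size=2, replace=False)
        ref, alt = BASES[ref_i], BASES[alt_i]
        gene = f"GENE{site % 60:03d}"
        region = "exonic" if rng.random() < config.exonic_fraction else "other"
        consequence = str(rng.choice(
            ["missense", "synonymous", "nonsense", "other"], p=[0.5, 0.35, 0.05, 0.10]
        ))

        if site_class == "germline":
            carrier_prob = rng.uniform(0.2, 0.9)
            carriers = [s for s in samples if rng.random() < carrier_prob]
            if not carriers:
                carriers = [samples[int(rng.integers(config.n_samples))]]
            pop_maf = (
                float(np.exp(rng.uniform(np.log(max(maf_lo, 0.01)), np.log(maf_hi))))
                if rng.random() < p_ann
                else None
            )
        elif site_class == "somatic":
            carriers = [samples[int(rng.integers(config.n_samples))]]
            pop_maf = (
                float(np.exp(rng.uniform(np.log(1e-5), np.log(5e-3))))
                if rng.random() < 0.2
                else None
            )
        else:  # artifact: shared by at least the configured fraction
            k_min = max(1, math.ceil(config.artifact_sample_fraction * config.n_samples))
            k = int(rng.integers(k_min, config.n_samples + 1))
            carriers = list(rng.choice(samples, size=k, replace=False))
            pop_maf = None

        depths = _draw_depth(rng, mean_depth, disp, len(carriers))
        for carrier, depth in zip(carriers, depths):
            if site_class == "germline":
                hom = rng.random() < 1 / 3
                center = min(2 * config.germline_aaf_center, 1.0) if hom else config.germline_aaf_center
                aaf = float(np.clip(rng.normal(center, 0.04), 0.0, 1.0))
            elif site_class == "somatic":
                aaf = float(rng.uniform(*config.somatic_aaf_range))
            else:
                aaf = float(rng.uniform(0.01, 0.10))
            calls[carrier].append(
                VariantCall(
                    sample_id=carrier, chrom=chrom, pos=pos, ref=ref, alt=alt,
                    aaf=aaf, depth=int(depth), pop_maf=pop_maf,
                    region_class=region, consequence=consequence, gene=gene,
                )
            )
            truth_rows.append(
                {"sample_id": carrier, "chrom": chrom, "pos": pos, "ref": ref,
                 "alt": alt, "true_class": site_class, "pop_maf": pop_maf,
                 "region_class": region}
            )

    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "chrom", "pos", "ref", "alt", "true_class",
                 "pop_maf", "region_class"],
    )
    return SimulatedCohort(calls=calls, truth=truth)


# ---------------------------------------------------------------------------
# amplicon pileups


def expected_base_proportions(
    mutant_fraction: float, error_rate: float, mutant_base: str, ref_base: str
) -> dict[str, float]:
    """Closed-form expected read proportion of each base under the error model.

    A read's template is mutant with probability ``mutant_fraction`` else
    reference; it reports its template base with probability
    ``1 - error_rate`` and each other base with ``error_rate / 3``.
    """
    props = {}
    for b in BASES:
        p = 0.0
        for src, w in ((mutant_base, mutant_fraction), (ref_base, 1.0 - mutant_fraction)):
            p += w * ((1.0 - error_rate) if b == src else error_rate / 3.0)
        props[b] = p
    return props


def _sample_counts(
    rng: np.random.Generator, depth: int, props: dict[str, float], locus_id: str
) -> NucleotideCounts:
    counts = rng.multinomial(depth, [props[b] for b in BASES])
    by_base = dict(zip(BASES, (int(c) for c in counts)))
    return NucleotideCounts(
        locus_id=locus_id,
        count_A=by_base["A"], count_T=by_base["T"],
        count_C=by_base["C"], count_G=by_base["G"],
        total=depth,
    )


def simulate_amplicon_counts(config: AmpliconSimConfig) -> PairedLocusCounts:
    """Draw pre/post pileup counts by multinomial sampling at each depth.

    The simulated totals equal the multinomial depths exactly (no "other"
    calls); real-data readers must not assume this.
    """
    rng = np.random.default_rng(config.seed)
    m_pre = config.ctdna_fraction_pre * config.tissue_aaf
    m_post = config.ctdna_fraction_post * config.tissue_aaf
    pre = _sample_counts(
        rng, config.depth_pre,
        expected_base_proportions(m_pre, config.error_rate, config.mutant_base, config.ref_base),
        config.locus_id,
    )
    post = _sample_counts(
        rng, config.depth_post,
        expected_base_proportions(m_post, config.error_rate, config.mutant_base, config.ref_base),
        config.locus_id,
    )
    return PairedLocusCounts(
        gene=config.gene, mutant_base=config.mutant_base, ref_base=config.ref_base,
        pre=pre, post=post,
    )


# ---------------------------------------------------------------------------
# fragment-size traces


def simulate_fragment_profile(config: LadderSimConfig) -> FragmentProfile:
    """Synthesize a mass-concentration trace from a nucleosomal ladder.

    Component k contributes ``molar_amounts[k] * peak_centers[k]`` mass as a
    Gaussian density, so its trapezoidal mass area equals molar amount times
    length and mass-to-molar back-conversion is exact up to grid error.
    Additive Gaussian noise is clipped at zero (signal is a mass
    concentration).
    """
    lo, hi, step = config.size_grid
    sizes = np.arange(lo, hi + step / 2, step)
    for center, width in zip(config.peak_centers, config.peak_widths):
        if center - 4 * width < sizes[0] or center + 4 * width > sizes[-1]:
            raise ValueError(
                f"size grid [{sizes[0]}, {sizes[-1]}] must cover peak at "
                f"{center} bp +/- 4 x {width} bp"
            )
    signal = np.zeros_like(sizes)
    for center, width, molar in zip(config.peak_centers, config.peak_widths, config.molar_amounts):
        mass = molar * center
        signal += mass * np.exp(-0.5 * ((sizes - center) / width) ** 2) / (
            width * math.sqrt(2 * math.pi)
        )
    if config.long_tail_mass > 0:
        signal += config.long_tail_mass * np.exp(
            -0.5 * ((sizes - config.long_tail_center) / config.long_tail_width) ** 2
        ) / (config.long_tail_width * math.sqrt(2 * math.pi))
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        signal = signal + rng.normal(0.0, config.noise_sd, size=sizes.shape)
    return FragmentProfile(sizes=sizes, mass_signal=np.maximum(signal, 0.0))


# ---------------------------------------------------------------------------
# concentration kinetics


def simulate_kinetics_cohort(config: KineticsSimConfig) -> list[ConcentrationRecord]:
    """Generate per-patient concentration time courses.

    Concentrations are strictly positive: the multiplicative noise factor on
    the release term is clipped at zero, and baselines are lognormal.
    With ``noise_cv = 0`` each patient's course is non-decreasing up to the
    patient's peak time and flat after.
    """
    rng = np.random.default_rng(config.seed)
    mu_b, sd_b = config.baseline_lognormal
    mu_a, sd_a = config.release_amplitude_lognormal
    records: list[ConcentrationRecord] = []
    for i in range(config.n_patients):
        patient = f"P{i + 1:02d}"
        baseline = float(rng.lognormal(mu_b, sd_b))
        amplitude = config.release_scale * float(rng.lognormal(mu_a, sd_a))
        tau = float(rng.uniform(*config.peak_time_range))
        for t in config.timepoints:
            r = min(t / tau, 1.0)
            noise = rng.normal(0.0, config.noise_cv) if config.noise_cv > 0 else 0.0
            conc = baseline + amplitude * r * max(1.0 + noise, 0.0)
            records.append(
                ConcentrationRecord(patient_id=patient, timepoint=int(t), concentration=conc)
            )
    return records
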