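"""Readers and writers for the pipeline's interchange formats.

Tables are tab-separated UTF-8 with '.' as the decimal separator; fragment
traces are two-column CSV.  Every writer emits exactly the schema its
paired reader consumes, so writer/reader pairs are exact round trips.
The variant table also has a VCF dialect (parsed with cyvcf2) with AAF and
depth taken from per-sample FORMAT fields and population MAF, region class,
consequence and gene from INFO keys — no annotation is computed internally.
"""

from __future__ import annotations

import dataclasses
import logging
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .enrichment import BASES, NucleotideCounts, PairedLocusCounts
from .fragmentomics import FragmentProfile
from .stats import ConcentrationRecord, PairedComparison
from .variants import CandidateSet, FilterThresholds, VariantCall

logger = logging.getLogger(__name__)

__all__ = [
    "read_variant_table",
    "write_variant_table",
    "read_counts_table",
    "write_counts_table",
    "read_profile_csv",
    "write_profile_csv",
    "read_concentration_table",
    "write_concentration_table",
    "write_candidates_table",
    "write_matrix_table",
    "write_enrichment_table",
    "write_ladder_fit_table",
    "write_comparisons_table",
    "load_table2_counts",
    "read_sim_config",
    "write_sim_config",
    "PipelineSimConfig",
]

VARIANT_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "aaf", "depth",
    "pop_maf", "region_class", "consequence", "gene",
]

COUNTS_COLUMNS = [
    "locus_id", "gene", "phase", "A", "T", "C", "G", "total",
    "mutant_base", "ref_base",
]

#: INFO keys used by the VCF dialect; override via ``info_keys`` arguments.
DEFAULT_INFO_KEYS = {
    "pop_maf": "POP_MAF",
    "region_class": "REGION",
    "consequence": "CSQ",
    "gene": "GENE",
}


# ---------------------------------------------------------------------------
# variant tables


def write_variant_table(calls: Mapping[str, Sequence[VariantCall]], path: str | Path) -> None:
    rows = []
    for sample in calls:
        for c in calls[sample]:
            row = dataclasses.asdict(c)
            row["pop_maf"] = "" if c.pop_maf is None else repr(c.pop_maf)
            rows.append(row)
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def _read_variant_tsv(path: Path) -> dict[str, list[VariantCall]]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str},
                     float_precision="round_trip")
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table {path} is missing required columns: {missing}")
    out: dict[str, list[VariantCall]] = {}
    n_non_snv = 0
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            ref, alt = str(row.ref), str(row.alt)
            if len(ref) != 1 or len(alt) != 1:
                n_non_snv += 1
                continue
            pop_maf = None if pd.isna(row.pop_maf) else float(row.pop_maf)
            call = VariantCall(
                sample_id=str(row.sample_id), chrom=str(row.chrom), pos=int(row.pos),
                ref=ref, alt=alt, aaf=float(row.aaf), depth=int(row.depth),
                pop_maf=pop_maf, region_class=str(row.region_class),
                consequence=str(row.consequence), gene=str(row.gene),
            )
        except (ValueError, TypeError) as exc:
            logger.warning("skipping unparseable row at %s line %d: %s", path, line_no, exc)
            continue
        out.setdefault(call.sample_id, []).append(call)
    if n_non_snv:
        logger.info("dropped %d non-SNV rows from %s", n_non_snv, path)
    return out


def _read_variant_vcf(path: Path, info_keys: Mapping[str, str]) -> dict[str, list[VariantCall]]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out: dict[str, list[VariantCall]] = {s: [] for s in samples}
    n_non_snv = 0
    for variant in vcf:
        if len(variant.REF) != 1 or len(variant.ALT) != 1 or len(variant.ALT[0]) != 1:
            n_non_snv += 1
            continue
        raw_maf = variant.INFO.get(info_keys["pop_maf"])
        pop_maf = None if raw_maf is None else float(raw_maf)
        region = str(variant.INFO.get(info_keys["region_class"], "other"))
        consequence = str(variant.INFO.get(info_keys["consequence"], "other"))
        gene = str(variant.INFO.get(info_keys["gene"], "."))
        af = variant.format("AF")
        dp = variant.format("DP")
        if af is None or dp is None:
            raise ValueError(f"VCF {path} lacks per-sample AF/DP FORMAT fields")
        for i, sample in enumerate(samples):
            aaf = float(af[i][0])
            depth = int(dp[i][0])
            if np.isnan(aaf) or depth < 0:
                continue  # sample not called at this site
            out[sample].append(
                VariantCall(
                    sample_id=sample, chrom=variant.CHROM, pos=variant.POS,
                    ref=variant.REF, alt=variant.ALT[0], aaf=aaf, depth=depth,
                    pop_maf=pop_maf, region_class=region,
                    consequence=consequence, gene=gene,
                )
            )
    if n_non_snv:
        logger.info("dropped %d non-SNV records from %s", n_non_snv, path)
    return out


def read_variant_table(
    path: str | Path,
    dialect: str = "tsv",
    info_keys: Optional[Mapping[str, str]] = None,
) -> dict[str, list[VariantCall]]:
    """Read per-sample variant calls from a flat TSV or a VCF.

    Positions are 1-based; non-SNV rows are dropped with a logged count;
    unparseable rows are skipped with a logged line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_variant_tsv(path)
    if dialect == "vcf":
        return _read_variant_vcf(path, {**DEFAULT_INFO_KEYS, **(info_keys or {})})
    raise ValueError(f"unknown variant-table dialect {dialect!r}")


def write_variant_vcf(calls: Mapping[str, Sequence[VariantCall]], path: str | Path) -> None:
    """Write calls as a minimal VCF with AF/DP FORMAT and annotation INFO keys."""
    samples = sorted(calls)
    sites: dict[tuple[str, int, str, str], dict[str, VariantCall]] = {}
    for sample in samples:
        for c in calls[sample]:
            sites.setdefault((c.chrom, c.pos, c.ref, c.alt), {})[sample] = c
    contigs = sorted({key[0] for key in sites})
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines += [
        '##INFO=<ID=POP_MAF,Number=1,Type=Float,Description="Population minor allele frequency">',
        '##INFO=<ID=REGION,Number=1,Type=String,Description="Region class">',
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Predicted consequence">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AF,Number=1,Type=Float,Description="Alternative allele fraction">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for (chrom, pos, ref, alt) in sorted(sites):
        carriers = sites[(chrom, pos, ref, alt)]
        any_call = next(iter(carriers.values()))
        info = []
        if any_call.pop_maf is not None:
            info.append(f"POP_MAF={any_call.pop_maf:.6g}")
        info.append(f"REGION={any_call.region_class}")
        info.append(f"CSQ={any_call.consequence}")
        info.append(f"GENE={any_call.gene}")
        fields = [chrom, str(pos), ".", ref, alt, ".", "PASS", ";".join(info), "GT:AF:DP"]
        for sample in samples:
            c = carriers.get(sample)
            if c is None:
                fields.append("./.:.:.")
            else:
                fields.append(f"0/1:{c.aaf:.6g}:{c.depth}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# amplicon counts


def write_counts_table(pairs: Sequence[PairedLocusCounts], path: str | Path) -> None:
    rows = []
    for pair in pairs:
        for phase, counts in (("pre", pair.pre), ("post", pair.post)):
            rows.append({
                "locus_id": pair.locus_id, "gene": pair.gene, "phase": phase,
                **counts.base_counts, "total": counts.total,
                "mutant_base": pair.mutant_base, "ref_base": pair.ref_base,
            })
    pd.DataFrame(rows, columns=COUNTS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_counts_table(path: str | Path, thousands: Optional[str] = None) -> list[PairedLocusCounts]:
    """Read paired pre/post pileup counts; both phases required per locus.

    ``thousands`` accepts an explicit thousands-separator character for
    fixture files transcribed from printed tables (which may mix '.' and ','
    as grouping marks); leave ``None`` for pipeline-generated tables.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", thousands=thousands, dtype={"locus_id": str, "gene": str})
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"counts table {path} is missing required columns: {missing}")
    pairs: list[PairedLocusCounts] = []
    for locus_id, group in df.groupby("locus_id", sort=False):
        phases = dict(zip(group["phase"], group.index))
        if len(group) != 2 or set(phases) != {"pre", "post"}:
            raise ValueError(
                f"locus {locus_id!r} must have exactly one 'pre' and one 'post' row, "
                f"found phases {sorted(phases)}"
            )
        by_phase = {}
        for phase in ("pre", "post"):
            row = group.loc[phases[phase]]
            by_phase[phase] = NucleotideCounts(
                locus_id=str(locus_id),
                count_A=int(row["A"]), count_T=int(row["T"]),
                count_C=int(row["C"]), count_G=int(row["G"]),
                total=int(row["total"]),
            )
        first = group.iloc[0]
        pairs.append(
            PairedLocusCounts(
                gene=str(first["gene"]), mutant_base=str(first["mutant_base"]),
                ref_base=str(first["ref_base"]), pre=by_phase["pre"], post=by_phase["post"],
            )
        )
    return pairs


def load_table2_counts() -> list[PairedLocusCounts]:
    """The five assayed somatic loci shipped with the package (printed counts)."""
    with resources.as_file(resources.files("ctdnakit").joinpath("data/table2_counts.tsv")) as p:
        return read_counts_table(p)


# ---------------------------------------------------------------------------
# fragment profiles


def write_profile_csv(profile: FragmentProfile, path: str | Path) -> None:
    pd.DataFrame({"size_bp": profile.sizes, "signal": profile.mass_signal}).to_csv(
        path, index=False
    )


def read_profile_csv(path: str | Path) -> FragmentProfile:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("size_bp", "signal"):
        if col not in df.columns:
            raise ValueError(f"profile CSV {path} is missing required column {col!r}")
    return FragmentProfile(
        sizes=df["size_bp"].to_numpy(dtype=float),
        mass_signal=df["signal"].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# concentrations


def write_concentration_table(records: Sequence[ConcentrationRecord], path: str | Path) -> None:
    pd.DataFrame(
        [{"patient_id": r.patient_id, "timepoint_min": r.timepoint,
          "ng_per_ml": r.concentration} for r in records]
    ).to_csv(path, sep="\t", index=False)


def read_concentration_table(path: str | Path) -> list[ConcentrationRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str},
                     float_precision="round_trip")
    for col in ("patient_id", "timepoint_min", "ng_per_ml"):
        if col not in df.columns:
            raise ValueError(f"concentration table {path} is missing required column {col!r}")
    return [
        ConcentrationRecord(
            patient_id=str(r.patient_id), timepoint=int(r.timepoint_min),
            concentration=float(r.ng_per_ml),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# report writers


def write_candidates_table(candidate_set: CandidateSet, path: str | Path) -> None:
    write_variant_table(candidate_set.by_sample(), path)


def write_matrix_table(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def write_enrichment_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_ladder_fit_table(fit: "Any", path: str | Path) -> None:
    rows = [
        {"order": p.order, "center": p.center, "width": p.width,
         "mass_area": p.mass_area, "molar_amount": p.molar_amount}
        for p in fit.peaks
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_comparisons_table(comparisons: Sequence[PairedComparison], path: str | Path) -> None:
    rows = [
        {"timepoint_min": c.timepoint, "n": c.n,
         "median_pre": c.median_pre, "q1_pre": c.iqr_pre[0], "q3_pre": c.iqr_pre[1],
         "median_post": c.median_post, "q1_post": c.iqr_post[0], "q3_post": c.iqr_post[1],
         "W": c.W, "p_two_sided": c.p_two_sided}
        for c in comparisons
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# simulation / pipeline configuration


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [_to_plain(v) for v in obj]
    return obj


def _from_dict(cls: type, d: Mapping[str, Any]) -> Any:
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in d:
            v = d[f.name]
            if isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
    return cls(**kwargs)


@dataclasses.dataclass(frozen=True)
class PipelineSimConfig:
    """Everything the `simulate`/`all` pipeline stages need, in one document.

    The top-level ``seed`` deterministically reseeds every section (child
    seeds derived via numpy SeedSequence), so one integer reproduces the
    whole bundle.
    """

    cohort: "Any"
    amplicon: "Any"
    ladder_pre: "Any"
    ladder_post: "Any"
    kinetics: "Any"
    thresholds: FilterThresholds = FilterThresholds()
    max_order: int = 4
    seed: int = 0

    def reseeded(self, seed: Optional[int] = None) -> "PipelineSimConfig":
        master = self.seed if seed is None else seed
        children = np.random.SeedSequence(master).generate_state(5) % (2**31)
        return dataclasses.replace(
            self,
            seed=master,
            cohort=dataclasses.replace(self.cohort, seed=int(children[0])),
            amplicon=dataclasses.replace(self.amplicon, seed=int(children[1])),
            ladder_pre=dataclasses.replace(self.ladder_pre, seed=int(children[2])),
            ladder_post=dataclasses.replace(self.ladder_post, seed=int(children[3])),
            kinetics=dataclasses.replace(self.kinetics, seed=int(children[4])),
        )


def default_sim_config(seed: int = 0) -> PipelineSimConfig:
    """Study-condition defaults: pre-biopsy mono-dominant ladder; post-biopsy
    trace with proportionally larger multi-nucleosome peaks and a >1 kb tail."""
    from .simulate import (
        AmpliconSimConfig, CohortSimConfig, KineticsSimConfig, LadderSimConfig,
    )

    ladder_pre = LadderSimConfig(molar_amounts=(1.0, 0.25, 0.08, 0.03), noise_sd=0.05)
    ladder_post = LadderSimConfig(
        molar_amounts=(1.4, 0.65, 0.25, 0.12), long_tail_mass=40.0, noise_sd=0.05
    )
    return PipelineSimConfig(
        cohort=CohortSimConfig(),
        amplicon=AmpliconSimConfig(),
        ladder_pre=ladder_pre,
        ladder_post=ladder_post,
        kinetics=KineticsSimConfig(),
        seed=seed,
    ).reseeded(seed)


def write_sim_config(config: PipelineSimConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))


def read_sim_config(path: str | Path) -> PipelineSimConfig:
    from .simulate import (
        AmpliconSimConfig, CohortSimConfig, KineticsSimConfig, LadderSimConfig,
    )

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = yaml.safe_load(path.read_text())
    return PipelineSimConfig(
        cohort=_from_dict(CohortSimConfig, doc["cohort"]),
        amplicon=_from_dict(AmpliconSimConfig, doc["amplicon"]),
        ladder_pre=_from_dict(LadderSimConfig, doc["ladder_pre"]),
        ladder_post=_from_dict(LadderSimConfig, doc["ladder_post"]),
        kinetics=_from_dict(KineticsSimConfig, doc["kinetics"]),
        thresholds=_from_dict(FilterThresholds, doc.get("thresholds", {})),
        max_order=int(doc.get("max_order", 4)),
        seed=int(doc.get("seed", 0)),
    )
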