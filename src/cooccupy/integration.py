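"""Integration of ChIP binding with differential expression and spatial data.

Covers the RNA-seq side of the pipeline: the fold-change/FDR filter with
early/late stage classing, tissue-enrichment calls at 1.5x the cross-tissue
mean, hypergeometric bound-and-regulated intersections, the four-way
regulatory categorization from paired knockdown directions, and reporter-assay
summarization.

Direction semantics: expression *down* in a factor's knockdown (morpholino)
means that factor normally activates the gene; *up* means it represses.
"""

from __future__ import annotations

import math
import os
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import PeakAnnotation
from .stats import (
    chi_square_gof,
    hypergeom_upper_tail,
    ks_two_sample,
    t_two_sample,
)

__all__ = [
    "DifferentialRecord",
    "RegulatedGene",
    "SpatialProfile",
    "OverlapTest",
    "RegulatoryCategory",
    "DirectTargets",
    "ReporterCondition",
    "read_differential_table",
    "filter_differential",
    "spatial_enrichment",
    "spatial_profile",
    "pattern_distribution_test",
    "overlap_test",
    "regulatory_category",
    "categorize_genes",
    "direct_targets",
    "reporter_summary",
    "REGULATORY_CATEGORIES",
]

DEFAULT_EARLY_STAGES = ("NF9", "NF10")

REGULATORY_CATEGORIES = (
    "activated_by_both",
    "bcat_activated_sox17_repressed",
    "sox17_activated_bcat_repressed",
    "repressed_by_both",
)


@dataclass(frozen=True)
class DifferentialRecord:
    gene_id: str
    stage: str
    log2_fold_change: float
    fdr: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"fdr must lie in [0,1], got {self.fdr} for {self.gene_id}")


@dataclass(frozen=True)
class RegulatedGene:
    gene_id: str
    direction: str      # down_in_MO | up_in_MO
    stage_class: str    # early | late
    factor: str         # sox17 | bcat | ...
    first_stage: str    # earliest significant stage
    log2_fold_change: float


@dataclass(frozen=True)
class SpatialProfile:
    gene_id: str
    expression: dict[str, float]
    enriched_tissues: frozenset[str]


@dataclass(frozen=True)
class OverlapTest:
    universe_size: int
    set_a_size: int
    set_b_size: int
    overlap: int
    p_value: float


@dataclass(frozen=True)
class RegulatoryCategory:
    gene_id: str
    category: str


@dataclass(frozen=True)
class DirectTargets:
    genes: frozenset[str]
    peaks: frozenset[str]
    test: OverlapTest


def _stage_key(stage: str):
    m = re.fullmatch(r"NF(\d+(?:\.\d+)?)", stage)
    return (0, float(m.group(1))) if m else (1, stage)


def read_differential_table(path: str | os.PathLike) -> list[DifferentialRecord]:
    """TSV with columns gene_id, stage, log2FC, FDR (header required)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "stage", "log2FC", "FDR"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        DifferentialRecord(str(r.gene_id), str(r.stage), float(r.log2FC), float(r.FDR))
        for r in df.itertuples()
    ]


def filter_differential(
    records: Sequence[DifferentialRecord],
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    factor: str = "sox17",
    early_stages: Sequence[str] = DEFAULT_EARLY_STAGES,
    stage_order: Sequence[str] | None = None,
) -> list[RegulatedGene]:
    """Keep genes significant at any stage: |log2FC| > log2(fc) and FDR < cut.

    Direction and stage class come from the earliest significant stage; a
    stage is early when it belongs to ``early_stages``, late otherwise. Stage
    order defaults to numeric NF ordering (NF9 < NF10 < NF10.5 < ...); pass
    ``stage_order`` to override. Conflicting duplicate (gene, stage) rows are
    an error.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must exceed 1")
    lfc_cut = math.log2(fc_threshold)
    seen: dict[tuple[str, str], DifferentialRecord] = {}
    for r in records:
        key = (r.gene_id, r.stage)
        if key in seen and (
            seen[key].log2_fold_change != r.log2_fold_change or seen[key].fdr != r.fdr
        ):
            raise ValueError(f"conflicting duplicate rows for gene {r.gene_id} stage {r.stage}")
        seen[key] = r
    if stage_order is not None:
        rank = {s: i for i, s in enumerate(stage_order)}
        sort_key = lambda r: rank.get(r.stage, len(rank))
    else:
        sort_key = lambda r: _stage_key(r.stage)
    by_gene: dict[str, list[DifferentialRecord]] = {}
    for r in seen.values():
        by_gene.setdefault(r.gene_id, []).append(r)
    early = set(early_stages)
    out: list[RegulatedGene] = []
    for gene_id in sorted(by_gene):
        sig = [
            r
            for r in sorted(by_gene[gene_id], key=sort_key)
            if abs(r.log2_fold_change) > lfc_cut and r.fdr < fdr_threshold
        ]
        if not sig:
            continue
        first = sig[0]
        direction = "down_in_MO" if first.log2_fold_change < 0 else "up_in_MO"
        stage_class = "early" if first.stage in early else "late"
        out.append(
            RegulatedGene(gene_id, direction, stage_class, factor, first.stage,
                          first.log2_fold_change)
        )
    return out


def spatial_enrichment(
    profile: Mapping[str, float] | Sequence[float],
    ratio: float = 1.5,
) -> set[str]:
    """Tissues whose expression exceeds ``ratio`` times the cross-tissue mean.

    Accepts a tissue->value mapping or a plain sequence (tissues then named
    ``tissue1..tissueK``). Values must be nonnegative; at least two tissues
    are required. An all-zero profile has no enriched tissue.
    """
    if isinstance(profile, Mapping):
        labels = list(profile.keys())
        values = np.asarray([profile[t] for t in labels], dtype=float)
    else:
        values = np.asarray(profile, dtype=float)
        labels = [f"tissue{i + 1}" for i in range(values.size)]
    if values.size < 2:
        raise ValueError("profile needs at least 2 tissues")
    if np.any(values < 0):
        raise ValueError("negative expression value in profile")
    cutoff = ratio * values.mean()
    return {t for t, v in zip(labels, values) if v > cutoff}


def spatial_profile(
    gene_id: str, expression: Mapping[str, float], ratio: float = 1.5
) -> SpatialProfile:
    return SpatialProfile(
        gene_id, dict(expression), frozenset(spatial_enrichment(expression, ratio))
    )


def pattern_distribution_test(
    subset: Sequence,
    genome: Sequence,
    method: str = "chi_square",
) -> tuple[float, float]:
    """Compare a gene subset's distribution to the genome-wide background.

    ``chi_square`` treats the inputs as categorical labels and tests the
    subset's label counts against expected counts under genome proportions
    (df = #labels - 1); a label present in the subset but absent genome-wide
    is an error (merge labels first). ``ks`` treats the inputs as per-gene
    ordinal statistics (numeric) and runs the two-sided two-sample KS test.
    Returns ``(statistic, p)``.
    """
    if not len(subset) or not len(genome):
        raise ValueError("subset and genome samples must be non-empty")
    if method == "chi_square":
        genome_counts: dict = {}
        for lab in genome:
            genome_counts[lab] = genome_counts.get(lab, 0) + 1
        labels = sorted(genome_counts, key=str)
        missing = {lab for lab in subset if lab not in genome_counts}
        if missing:
            raise ValueError(
                f"labels {sorted(map(str, missing))} absent from genome background; "
                "merge rare labels before testing"
            )
        total = sum(genome_counts.values())
        props = [genome_counts[lab] / total for lab in labels]
        observed = [sum(1 for lab in subset if lab == label) for label in labels]
        return chi_square_gof(observed, props)
    if method == "ks":
        return ks_two_sample(list(subset), list(genome))
    raise ValueError(f"unknown method {method!r}")


def overlap_test(
    universe: Iterable[str], set_a: Iterable[str], set_b: Iterable[str]
) -> OverlapTest:
    """Upper-tail hypergeometric significance of |A ∩ B| within the universe."""
    uni = set(universe)
    if not uni:
        raise ValueError("universe is empty")
    a, b = set(set_a), set(set_b)
    stray = sorted((a | b) - uni)
    if stray:
        raise ValueError(f"sets contain genes outside the universe: {stray[:10]}")
    k = len(a & b)
    p = hypergeom_upper_tail(len(uni), len(a), len(b), k)
    return OverlapTest(len(uni), len(a), len(b), k, p)


_CATEGORY_MAP = {
    ("down", "down"): "activated_by_both",
    ("up", "down"): "bcat_activated_sox17_repressed",
    ("down", "up"): "sox17_activated_bcat_repressed",
    ("up", "up"): "repressed_by_both",
}


def _norm_direction(d: str) -> str:
    d = d.lower()
    if d in ("down", "down_in_mo"):
        return "down"
    if d in ("up", "up_in_mo"):
        return "up"
    raise ValueError(f"direction must be down(_in_MO) or up(_in_MO), got {d!r}")


def regulatory_category(direction_sox17mo: str, direction_bcatmo: str) -> str:
    """Four-way category from the two knockdown directions.

    Down in a factor's knockdown means that factor activates the gene, so
    (down, down) -> activated_by_both, (up, up) -> repressed_by_both, and the
    mixed pairs are the two discordant categories.
    """
    return _CATEGORY_MAP[(_norm_direction(direction_sox17mo), _norm_direction(direction_bcatmo))]


def categorize_genes(
    sox17_regulated: Sequence[RegulatedGene],
    bcat_regulated: Sequence[RegulatedGene],
    genes: Iterable[str] | None = None,
) -> list[RegulatoryCategory]:
    """Categorize every gene regulated in both knockdowns (or ``genes`` only)."""
    sox_dir = {g.gene_id: g.direction for g in sox17_regulated}
    bcat_dir = {g.gene_id: g.direction for g in bcat_regulated}
    shared = set(sox_dir) & set(bcat_dir)
    if genes is not None:
        shared &= set(genes)
    return [
        RegulatoryCategory(g, regulatory_category(sox_dir[g], bcat_dir[g]))
        for g in sorted(shared)
    ]


def direct_targets(
    bound_annotations: Sequence[PeakAnnotation],
    regulated: Sequence[RegulatedGene],
    universe: Iterable[str],
) -> DirectTargets:
    """Genes both bound (>= 1 annotated peak) and regulated, with their peaks
    and the hypergeometric significance of the intersection over ``universe``.

    Bound and regulated sets are restricted to the universe before testing.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe is empty")
    bound = {a.nearest_gene for a in bound_annotations if a.nearest_gene is not None} & uni
    reg = {g.gene_id for g in regulated} & uni
    targets = bound & reg
    peaks = frozenset(
        a.peak_id for a in bound_annotations if a.nearest_gene in targets
    )
    test = OverlapTest(len(uni), len(bound), len(reg), len(targets),
                       hypergeom_upper_tail(len(uni), len(bound), len(reg), len(targets)))
    return DirectTargets(frozenset(targets), peaks, test)


@dataclass(frozen=True)
class ReporterCondition:
    condition: str
    mean_ratio: float
    sd_ratio: float
    p_vs_reference: float | None
    degenerate: bool


def reporter_summary(
    firefly: Mapping[str, Sequence[float]],
    renilla: Mapping[str, Sequence[float]],
    reference_condition: str,
) -> list[ReporterCondition]:
    """Renilla-normalized luciferase summaries with t-tests vs a reference.

    Each replicate's activity is firefly/renilla; per condition the mean and
    sample SD (n-1) are reported with a two-sided pooled-variance t-test
    against the reference condition. Zero pooled variance is flagged
    degenerate (p = 0 for differing means, 1 otherwise).
    """
    if reference_condition not in firefly:
        raise ValueError(f"reference condition {reference_condition!r} absent")
    ratios: dict[str, np.ndarray] = {}
    for cond, ff in firefly.items():
        if cond not in renilla:
            raise ValueError(f"no renilla values for condition {cond!r}")
        ff = np.asarray(ff, dtype=float)
        rn = np.asarray(renilla[cond], dtype=float)
        if ff.size != rn.size:
            raise ValueError(f"condition {cond!r}: firefly/renilla replicate counts differ")
        if ff.size < 2:
            raise ValueError(f"condition {cond!r}: need >= 2 replicates")
        if np.any(rn <= 0):
            raise ValueError(f"condition {cond!r}: renilla values must be positive")
        ratios[cond] = ff / rn
    ref = ratios[reference_condition]
    out: list[ReporterCondition] = []
    for cond, r in ratios.items():
        if cond == reference_condition:
            out.append(
                ReporterCondition(cond, float(r.mean()), float(r.std(ddof=1)), None, False)
            )
            continue
        res = t_two_sample(r, ref, equal_variance=True)
        out.append(
            ReporterCondition(cond, float(r.mean()), float(r.std(ddof=1)), res.p, res.degenerate)
        )
    return out
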