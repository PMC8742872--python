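"""Allelic-imbalance testing in F1 hybrids and the RI-strain genotype-phenotype association."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import SampleSheet, VariantRecord

PROMOTER_CLASSES = ("shifting", "diff_expressed", "other")


@dataclass
class AseResult:
    variant: VariantRecord
    ref_total: int
    alt_total: int
    AI: float  # (ref - alt) / (ref + alt); positive toward the reference allele
    p_binomial: float
    significant: bool
    promoter_class: str | None = None
    promoter_id: str | None = None


@dataclass
class AssociationResult:
    grouping: list[str]
    group_values: dict[str, np.ndarray]
    statistic: float  # Mann-Whitney U of the first group
    p: float
    group_medians: dict[str, float]


def filter_variants_for_ase(variants: Sequence[VariantRecord], design: SampleSheet,
                            strain_a: str = "A", strain_b: str = "B",
                            f1_strain: str = "F1", min_reads: int = 10,
                            f1_min_replicates: int = 9) -> list[VariantRecord]:
    """Apply the three coverage/variability criteria for the F1 imbalance test.

    (i) total depth >= ``min_reads`` in every parental replicate of both
    strains; (ii) the pooled-majority allele differs between the parental
    strains; (iii) depth >= ``min_reads`` in at least ``f1_min_replicates``
    F1 replicates.
    """
    par_a = design.strain_samples(strain_a)
    par_b = design.strain_samples(strain_b)
    f1 = design.strain_samples(f1_strain)
    out = []
    for v in variants:
        depths = v.sample_allele_depths

        def depth(s: str) -> int:
            r, a = depths.get(s, (0, 0))
            return r + a

        if any(depth(s) < min_reads for s in par_a + par_b):
            continue
        ref_a = sum(depths.get(s, (0, 0))[0] for s in par_a)
        alt_a = sum(depths.get(s, (0, 0))[1] for s in par_a)
        ref_b = sum(depths.get(s, (0, 0))[0] for s in par_b)
        alt_b = sum(depths.get(s, (0, 0))[1] for s in par_b)
        if (ref_a >= alt_a) == (ref_b >= alt_b):  # same majority allele
            continue
        n_f1_ok = sum(depth(s) >= min_reads for s in f1)
        if n_f1_ok < f1_min_replicates:
            continue
        out.append(v)
    return out


def binom_p_half(k, n) -> np.ndarray:
    """Vectorised exact two-sided binomial p-value at p0 = 1/2.

    At p0 = 1/2 the minimum-likelihood and central definitions coincide:
    p = min(1, 2 * min(P(X <= k), P(X >= k))).
    """
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    lower = stats.binom.cdf(k, n, 0.5)
    upper = stats.binom.sf(k - 1, n, 0.5)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def ai_test(ref_total: int, alt_total: int) -> tuple[float, float]:
    """Allelic imbalance (ref - alt)/(ref + alt) and exact two-sided binomial p at 1/2."""
    total = ref_total + alt_total
    if total < 1:
        raise ValueError("ref_total + alt_total must be >= 1")
    ai = (ref_total - alt_total) / total
    p = float(stats.binomtest(ref_total, total, 0.5, alternative="two-sided").pvalue)
    return ai, p


def test_allelic_imbalance(variants: Sequence[VariantRecord], design: SampleSheet,
                           f1_strain: str = "F1", alpha: float = 0.05) -> list[AseResult]:
    """Pool F1 ref/alt depths per variant and run the binomial imbalance test."""
    f1 = design.strain_samples(f1_strain)
    results = []
    for v in variants:
        ref_total = sum(v.sample_allele_depths.get(s, (0, 0))[0] for s in f1)
        alt_total = sum(v.sample_allele_depths.get(s, (0, 0))[1] for s in f1)
        if ref_total + alt_total < 1:
            continue
        ai, p = ai_test(ref_total, alt_total)
        results.append(AseResult(variant=v, ref_total=ref_total, alt_total=alt_total,
                                 AI=ai, p_binomial=p, significant=p <= alpha))
    return results


def classify_variant_promoters(ase: Sequence[AseResult], promoters,
                               shift_calls, de: pd.DataFrame,
                               alpha: float = 0.05, lfc_min: float = 1.0) -> list[AseResult]:
    """Attach a promoter class to each result; variants outside promoters are dropped.

    Classes: ``shifting`` (variant inside a cluster with a significant shift
    call), ``diff_expressed`` (containing promoter has padj <= alpha and
    |log2fc| > lfc_min), else ``other``.
    """
    shifting_clusters = {c.cluster_id for c in shift_calls if c.significant}
    kept = []
    for r in ase:
        v = r.variant
        home = None
        for p in promoters:
            if p.chrom == v.chrom and p.start <= v.pos <= p.end:
                home = p
                break
        if home is None:
            continue
        r.promoter_id = home.promoter_id
        in_shift = any(
            tc.tc_id in shifting_clusters and tc.start <= v.pos <= tc.end
            for tc in home.clusters
        )
        if in_shift:
            r.promoter_class = "shifting"
        else:
            pid = home.promoter_id
            is_de = False
            if pid in de.index:
                row = de.loc[pid]
                is_de = bool(pd.notna(row["padj"]) and row["padj"] <= alpha
                             and abs(row["log2fc"]) > lfc_min)
            r.promoter_class = "diff_expressed" if is_de else "other"
        kept.append(r)
    return kept


def compare_promoter_classes(ase: Sequence[AseResult]) -> dict:
    """Fisher test of significant-AI proportions (shifting vs other) and
    Mann-Whitney on |AI| distributions; NA for empty classes."""
    by_class = {c: [r for r in ase if r.promoter_class == c] for c in PROMOTER_CLASSES}
    report: dict = {"n_by_class": {c: len(v) for c, v in by_class.items()}}
    shifting, other = by_class["shifting"], by_class["other"]
    if shifting and other:
        table = [
            [sum(r.significant for r in shifting), sum(not r.significant for r in shifting)],
            [sum(r.significant for r in other), sum(not r.significant for r in other)],
        ]
        _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
        report["fisher_table"] = table
        report["fisher_p"] = float(fisher_p)
        ai_s = np.abs([r.AI for r in shifting])
        ai_o = np.abs([r.AI for r in other])
        pooled = np.concatenate([ai_s, ai_o])
        if np.all(pooled == pooled[0]):
            report["mannwhitney_p"] = 1.0
        else:
            _, mw_p = stats.mannwhitneyu(ai_s, ai_o, alternative="two-sided")
            report["mannwhitney_p"] = float(mw_p)
    else:
        report["fisher_p"] = None
        report["mannwhitney_p"] = None
    return report


def region_normalized_count(target_region_count: int, reference_region_count: int) -> float:
    """Ratio of a target-region read count to a reference-region count."""
    if reference_region_count <= 0:
        raise ValueError("reference region count must be > 0")
    return target_region_count / reference_region_count


def genotype_association(genotypes: Sequence[str], values: Sequence[float]) -> AssociationResult:
    """Two-sided Mann-Whitney U between exactly two genotype groups (tie-corrected)."""
    genotypes = list(genotypes)
    values = np.asarray(values, dtype=float)
    groups = sorted(set(genotypes))
    if len(groups) != 2:
        raise ValueError(f"need exactly two genotype groups, got {groups}")
    split = {g: values[[i for i, x in enumerate(genotypes) if x == g]] for g in groups}
    for g, v in split.items():
        if len(v) < 2:
            raise ValueError(f"genotype group {g!r} has fewer than 2 strains")
    a, b = split[groups[0]], split[groups[1]]
    if np.array_equal(np.sort(a), np.sort(b)):
        u = len(a) * len(b) / 2.0
        p = 1.0
    else:
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return AssociationResult(
        grouping=groups, group_values=split, statistic=float(u), p=float(p),
        group_medians={g: float(np.median(v)) for g, v in split.items()},
    )
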