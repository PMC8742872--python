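"""Promoter-to-gene assignment, ranking, TSS-distance and CpG/TATA architecture classes."""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .clustering import PromoterRegion
from .model import GeneModel

log = logging.getLogger(__name__)

TSS_CLASSES = ("exact", "within_100", "within_1000", "unannotated", "intergenic")
ARCH_CLASSES = ("CpG_only", "TATA_only", "both", "neither")

# TATAWAWR, W = A/T, R = A/G
TATA_RE = re.compile("TATA[AT]A[AT][AG]")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PromoterAnnotation:
    promoter_id: str
    gene_id: str | None
    rank: int | None
    tss_class: str
    arch_class: str | None = None

    def __post_init__(self) -> None:
        if (self.gene_id is None) != (self.tss_class == "intergenic"):
            raise ValueError("tss_class must be 'intergenic' iff no gene assigned")


def gene_region(gene: GeneModel, upstream: int = 1000) -> tuple[int, int]:
    """Transcript span extended ``upstream`` bp past the strand-aware 5' end."""
    if gene.strand == "+":
        return max(1, gene.tx_start - upstream), gene.tx_end
    return gene.tx_start, gene.tx_end + upstream


def assign_and_rank(promoters: Sequence[PromoterRegion], genes: Sequence[GeneModel],
                    upstream: int = 1000,
                    ranking_samples: Sequence[str] | None = None) -> list[PromoterAnnotation]:
    """Assign promoters to strand-matched gene regions and rank by mean TPM.

    A promoter joins a gene iff its span intersects the gene region (longest
    transcript plus ``upstream`` bp 5' of the transcript start) on the same
    strand. Overlaps with several genes resolve to the gene whose region start
    is nearest to the promoter start. Within each gene, ranks 1..k follow
    descending mean TPM (ties by leftmost start). Intergenic promoters keep
    rank 1. Also sets ``gene_id``/``rank`` on the promoter objects.
    """
    regions = []
    for g in genes:
        lo, hi = gene_region(g, upstream)
        regions.append((g.chrom, g.strand, lo, hi, g))
    assigned: dict[str, GeneModel | None] = {}
    for p in promoters:
        hits = [(chrom, strand, lo, hi, g) for (chrom, strand, lo, hi, g) in regions
                if chrom == p.chrom and strand == p.strand
                and p.start <= hi and p.end >= lo]
        if not hits:
            gene = None
        elif len(hits) == 1:
            gene = hits[0][4]
        else:
            gene = min(hits, key=lambda h: abs(h[2] - p.start))[4]
            log.info("promoter %s overlaps %d gene regions; assigned to %s",
                     p.promoter_id, len(hits), gene.gene_id)
        assigned[p.promoter_id] = gene
        p.gene_id = gene.gene_id if gene is not None else None

    by_gene: dict[str, list[PromoterRegion]] = {}
    for p in promoters:
        if p.gene_id is not None:
            by_gene.setdefault(p.gene_id, []).append(p)
        else:
            p.rank = 1

    def _expr(p: PromoterRegion) -> float:
        tpm = p.expression
        if ranking_samples is not None:
            idx = [p.samples.index(s) for s in ranking_samples]
            tpm = tpm[idx]
        return float(np.mean(tpm))

    for gid, plist in by_gene.items():
        plist.sort(key=lambda p: (-_expr(p), p.start))
        for rank, p in enumerate(plist, 1):
            p.rank = rank

    out = []
    for p in promoters:
        gene = assigned[p.promoter_id]
        tss_class = "intergenic" if gene is None else \
            classify_tss_distance(p, gene.annotated_tss)
        out.append(PromoterAnnotation(
            promoter_id=p.promoter_id,
            gene_id=None if gene is None else gene.gene_id,
            rank=p.rank, tss_class=tss_class,
        ))
    return out


def span_distance(start: int, end: int, pos: int) -> int:
    """bp distance from a 1-based span to a position; 0 when contained."""
    if pos < start:
        return start - pos
    if pos > end:
        return pos - end
    return 0


def classify_tss_distance(promoter: PromoterRegion, annotated_tss: Iterable[int],
                          bins: tuple[int, int, int] = (0, 100, 1000)) -> str:
    """Class from the minimum distance of the promoter span to any annotated TSS."""
    tss = list(annotated_tss)
    if not tss:
        return "unannotated"
    d = min(span_distance(promoter.start, promoter.end, t) for t in tss)
    exact, near, far = bins
    if d <= exact:
        return "exact"
    if d <= near:
        return "within_100"
    if d <= far:
        return "within_1000"
    return "unannotated"


def classify_proximity(promoters: Sequence[PromoterRegion], external_tss: Iterable[int],
                       bins: Sequence[int] = (0, 100, 500)) -> dict[str, int | None]:
    """Bin index of each promoter's minimum distance to an external TSS set.

    Returns promoter_id -> smallest bin edge >= the distance, or ``None`` when
    the distance exceeds all bin edges (or the TSS set is empty).
    """
    tss = sorted(external_tss)
    out: dict[str, int | None] = {}
    for p in promoters:
        if not tss:
            out[p.promoter_id] = None
            continue
        d = min(span_distance(p.start, p.end, t) for t in tss)
        out[p.promoter_id] = next((edge for edge in bins if d <= edge), None)
    return out


def has_cpg_overlap(promoter: PromoterRegion, cpg_islands: pd.DataFrame,
                    flank: int = 200) -> bool:
    """True iff the promoter span extended by ``flank`` intersects any island."""
    lo, hi = promoter.start - flank, promoter.end + flank
    sel = cpg_islands["chrom"] == promoter.chrom
    isl = cpg_islands.loc[sel]
    return bool(((isl["start"] <= hi) & (isl["end"] >= lo)).any())


def has_tata(promoter: PromoterRegion, genome: dict[str, str],
             window: tuple[int, int] = (-500, 200),
             matcher=None) -> bool:
    """Scan the strand-oriented window around the dominant CTSS for TATAWAWR.

    ``matcher`` may replace the consensus regex with any callable
    ``str -> bool`` (e.g. a PWM threshold scorer).
    """
    seq = genome.get(promoter.chrom)
    if seq is None:
        raise KeyError(f"chromosome {promoter.chrom} absent from genome")
    peak = promoter.dominant_pos
    up, down = window
    if promoter.strand == "+":
        lo, hi = peak + up, peak + down
    else:
        lo, hi = peak - down, peak - up
    if lo < 1 or hi > len(seq):
        log.info("TATA window truncated at chromosome edge for %s", promoter.promoter_id)
        lo, hi = max(1, lo), min(len(seq), hi)
    sub = seq[lo - 1:hi].upper()
    if promoter.strand == "-":
        sub = revcomp(sub)
    if matcher is not None:
        return bool(matcher(sub))
    return TATA_RE.search(sub) is not None


def classify_arch(promoter: PromoterRegion, cpg_islands: pd.DataFrame,
                  genome: dict[str, str], cpg_flank: int = 200,
                  tata_window: tuple[int, int] = (-500, 200),
                  tata_matcher=None) -> str:
    cpg = has_cpg_overlap(promoter, cpg_islands, cpg_flank)
    tata = has_tata(promoter, genome, tata_window, tata_matcher)
    if cpg and tata:
        return "both"
    if cpg:
        return "CpG_only"
    if tata:
        return "TATA_only"
    return "neither"


def feature_distance(position_a: int, position_b: int, strand: str) -> tuple[int, str]:
    """Strand-aware distance and orientation of ``a`` relative to ``b``.

    Upstream means 5' of ``b`` on the given strand: on '+' that is a < b, on
    '-' a > b. Equal positions return orientation 'same'.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"bad strand {strand!r}")
    dist = abs(position_a - position_b)
    if dist == 0:
        return 0, "same"
    if strand == "+":
        orient = "upstream" if position_a < position_b else "downstream"
    else:
        orient = "upstream" if position_a > position_b else "downstream"
    return dist, orient
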