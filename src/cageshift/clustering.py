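"""Tag clustering, TPM normalisation and promoter-region grouping.

CTSSs within ``gap`` bp (single linkage, inclusive) merge into tag clusters;
clusters within ``promoter_gap`` bp edge-to-edge merge into promoter regions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import CtssMatrix

TPM_SCALE = 1e6


@dataclass
class TagCluster:
    """A run of CTSSs merged at the tag-cluster gap, with per-sample counts."""

    tc_id: str
    chrom: str
    strand: str
    start: int
    end: int
    member_positions: np.ndarray  # sorted 1-based positions
    member_counts: np.ndarray  # (n_members, n_samples)
    samples: list[str]
    tpm: np.ndarray | None = None  # per-sample, filled by normalize_tpm

    def __post_init__(self) -> None:
        self.member_positions = np.asarray(self.member_positions, dtype=np.int64)
        self.member_counts = np.atleast_2d(np.asarray(self.member_counts, dtype=np.int64))
        if self.member_counts.shape[0] != self.member_positions.size:
            raise ValueError("member_counts rows must match member_positions")
        if not (self.start <= self.dominant_pos <= self.end):
            raise AssertionError("dominant position outside cluster span")

    @property
    def counts(self) -> np.ndarray:
        """Per-sample counts summed over member positions."""
        return self.member_counts.sum(axis=0)

    @property
    def total_count(self) -> int:
        return int(self.member_counts.sum())

    @property
    def dominant_pos(self) -> int:
        """Member position with maximal aggregate count; ties -> smaller coordinate."""
        agg = self.member_counts.sum(axis=1)
        return int(self.member_positions[int(np.argmax(agg))])

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass
class PromoterRegion:
    """A 100 bp-scale grouping of tag clusters; the unit of promoter analysis."""

    promoter_id: str
    chrom: str
    strand: str
    start: int
    end: int
    clusters: list[TagCluster]
    gene_id: str | None = None
    rank: int | None = None

    @property
    def tc_ids(self) -> list[str]:
        return [tc.tc_id for tc in self.clusters]

    @property
    def samples(self) -> list[str]:
        return self.clusters[0].samples

    @property
    def counts(self) -> np.ndarray:
        """Per-sample raw counts summed over member clusters."""
        return np.sum([tc.counts for tc in self.clusters], axis=0)

    @property
    def expression(self) -> np.ndarray:
        """Per-sample TPM summed over member clusters."""
        if any(tc.tpm is None for tc in self.clusters):
            raise ValueError("TPM not computed; run normalize_tpm first")
        return np.sum([tc.tpm for tc in self.clusters], axis=0)

    @property
    def mean_expression(self) -> float:
        return float(self.expression.mean())

    @property
    def dominant_pos(self) -> int:
        """Dominant CTSS of the highest-count member cluster."""
        best = max(self.clusters, key=lambda tc: (tc.total_count, -tc.start))
        return best.dominant_pos


def dominant_ctss(cluster: TagCluster, matrix: CtssMatrix | None = None) -> int:
    """Position with maximal all-sample count; ties broken by smaller coordinate."""
    return cluster.dominant_pos


def cluster_ctss(matrix: CtssMatrix, gap: int = 20) -> list[TagCluster]:
    """Single-linkage merge of CTSSs within ``gap`` bp on the same chrom+strand."""
    if gap < 0:
        raise ValueError("gap must be >= 0")
    samples = matrix.samples
    clusters: list[TagCluster] = []
    df = matrix.df
    if not len(df):
        return clusters
    for (chrom, strand), block in df.groupby(["chrom", "strand"], sort=True):
        block = block.sort_values("pos")
        pos = block["pos"].to_numpy()
        counts = block[samples].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > gap) + 1
        for seg_pos, seg_counts in zip(np.split(pos, breaks), np.split(counts, breaks)):
            clusters.append(TagCluster(
                tc_id="", chrom=chrom, strand=strand,
                start=int(seg_pos[0]), end=int(seg_pos[-1]),
                member_positions=seg_pos, member_counts=seg_counts,
                samples=samples,
            ))
    clusters.sort(key=lambda tc: (tc.chrom, tc.start, tc.strand))
    for i, tc in enumerate(clusters, 1):
        tc.tc_id = f"TC{i:06d}"
    return clusters


def normalize_tpm(clusters: Sequence[TagCluster], sample_totals) -> list[TagCluster]:
    """Fill per-sample TPM: counts / sample_total * 1e6. Zero totals are an error."""
    totals = np.asarray([sample_totals[s] for s in clusters[0].samples], dtype=float) \
        if clusters else np.asarray([], dtype=float)
    if clusters and (totals <= 0).any():
        bad = [s for s, t in zip(clusters[0].samples, totals) if t <= 0]
        raise ValueError(f"zero/negative total count for sample(s) {bad}")
    for tc in clusters:
        tc.tpm = tc.counts / totals * TPM_SCALE
    return list(clusters)


def filter_clusters(clusters: Sequence[TagCluster], min_tpm: float = 1.0,
                    min_samples: int = 1) -> list[TagCluster]:
    """Keep clusters with TPM >= ``min_tpm`` (inclusive) in >= ``min_samples`` samples."""
    out = []
    for tc in clusters:
        if tc.tpm is None:
            raise ValueError("TPM not computed; run normalize_tpm first")
        if int((tc.tpm >= min_tpm).sum()) >= min_samples:
            out.append(tc)
    return out


def group_promoters(clusters: Sequence[TagCluster], gap: int = 100) -> list[PromoterRegion]:
    """Single-linkage grouping of clusters with edge distance <= ``gap``, same chrom+strand."""
    if gap < 0:
        raise ValueError("gap must be >= 0")
    by_key: dict[tuple[str, str], list[TagCluster]] = {}
    for tc in clusters:
        by_key.setdefault((tc.chrom, tc.strand), []).append(tc)
    promoters: list[PromoterRegion] = []
    for (chrom, strand) in sorted(by_key):
        tcs = sorted(by_key[(chrom, strand)], key=lambda t: (t.start, t.end))
        group: list[TagCluster] = []
        max_end = None
        for tc in tcs:
            if max_end is not None and tc.start - max_end > gap:
                promoters.append(_make_promoter(group, chrom, strand))
                group = []
                max_end = None
            group.append(tc)
            max_end = tc.end if max_end is None else max(max_end, tc.end)
        if group:
            promoters.append(_make_promoter(group, chrom, strand))
    promoters.sort(key=lambda p: (p.chrom, p.start, p.strand))
    for i, p in enumerate(promoters, 1):
        p.promoter_id = f"PR{i:06d}"
    return promoters


def _make_promoter(group: list[TagCluster], chrom: str, strand: str) -> PromoterRegion:
    return PromoterRegion(
        promoter_id="", chrom=chrom, strand=strand,
        start=min(tc.start for tc in group), end=max(tc.end for tc in group),
        clusters=list(group),
    )


def clusters_to_frame(clusters: Sequence[TagCluster]) -> pd.DataFrame:
    """Tabular view of clusters (one row per cluster; TPM columns if computed)."""
    rows = []
    for tc in clusters:
        row = {"tc_id": tc.tc_id, "chrom": tc.chrom, "strand": tc.strand,
               "start": tc.start, "end": tc.end, "dominant_pos": tc.dominant_pos,
               "n_ctss": tc.member_positions.size}
        row.update({f"count_{s}": int(c) for s, c in zip(tc.samples, tc.counts)})
        if tc.tpm is not None:
            row.update({f"tpm_{s}": float(t) for s, t in zip(tc.samples, tc.tpm)})
        rows.append(row)
    return pd.DataFrame(rows)


def promoters_to_frame(promoters: Sequence[PromoterRegion]) -> pd.DataFrame:
    rows = []
    for p in promoters:
        row = {"promoter_id": p.promoter_id, "chrom": p.chrom, "strand": p.strand,
               "start": p.start, "end": p.end, "tc_ids": ",".join(p.tc_ids),
               "gene_id": p.gene_id if p.gene_id is not None else "",
               "rank": p.rank if p.rank is not None else ""}
        try:
            row["mean_tpm"] = p.mean_expression
        except ValueError:
            pass
        rows.append(row)
    return pd.DataFrame(rows)
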