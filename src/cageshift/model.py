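"""Shared data model: genomes, variants, gene models, sample sheets and the CTSS matrix.

All internal coordinates are 1-based inclusive (GTF/VCF convention). BED
conversion to 0-based half-open happens only at the I/O boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

STRANDS = ("+", "-")

#: key columns of a CTSS table, in order
CTSS_KEY = ["chrom", "pos", "strand"]


@dataclass
class VariantRecord:
    """One biallelic variant with per-sample (ref, alt) allele depths."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    sample_allele_depths: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.chrom}:{self.pos}")
        for sample, (r, a) in self.sample_allele_depths.items():
            if r < 0 or a < 0:
                raise ValueError(f"negative allele depth for sample {sample!r} at {self.chrom}:{self.pos}")

    @property
    def vtype(self) -> str:
        """``"SNV"`` iff both alleles are single bases, else ``"indel"``."""
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def is_snv(self) -> bool:
        return self.vtype == "SNV"


@dataclass
class GeneModel:
    """A gene reduced to the span of its longest transcript plus its annotated TSSs."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int  # 1-based inclusive span of the longest transcript
    tx_end: int
    annotated_tss: frozenset[int] = field(default_factory=frozenset)
    cds_start: int | None = None
    named_regions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r} for gene {self.gene_id}")
        if self.tx_start > self.tx_end:
            raise ValueError(f"tx_start > tx_end for gene {self.gene_id}")
        self.annotated_tss = frozenset(self.annotated_tss)
        for tss in self.annotated_tss:
            if not (self.tx_start <= tss <= self.tx_end):
                raise ValueError(
                    f"annotated TSS {tss} outside transcript span "
                    f"[{self.tx_start},{self.tx_end}] for gene {self.gene_id}"
                )

    @property
    def tss_5prime(self) -> int:
        """Strand-aware 5' end of the longest-transcript span."""
        return self.tx_start if self.strand == "+" else self.tx_end


class SampleSheet:
    """Sample metadata table: sample_id, strain, sex, replicate, group."""

    REQUIRED = ["sample_id", "strain"]

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        for col in self.REQUIRED:
            if col not in frame.columns:
                raise ValueError(f"sample sheet missing required column {col!r}")
        if frame["sample_id"].duplicated().any():
            dups = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        for col in ("sex", "replicate", "group"):
            if col not in frame.columns:
                frame[col] = ""
        self.frame = frame.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    def strain_samples(self, strain: str) -> list[str]:
        sel = self.frame["strain"] == strain
        return self.frame.loc[sel, "sample_id"].tolist()

    @property
    def strains(self) -> list[str]:
        return sorted(self.frame["strain"].unique())

    @classmethod
    def from_tsv(cls, path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str, "strain": str}))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:
        return f"SampleSheet({len(self)} samples, strains={self.strains})"


class CtssMatrix:
    """Per-(chrom, pos, strand) CAGE 5'-end counts across named samples.

    Wraps a DataFrame with columns ``chrom, pos, strand, <sample...>`` sorted
    by key. Keys are unique; counts are non-negative integers.
    """

    def __init__(self, df: pd.DataFrame, samples: list[str] | None = None):
        df = df.copy()
        for col in CTSS_KEY:
            if col not in df.columns:
                raise ValueError(f"CTSS table missing column {col!r}")
        if samples is None:
            samples = [c for c in df.columns if c not in CTSS_KEY]
        missing = [s for s in samples if s not in df.columns]
        if missing:
            raise ValueError(f"CTSS table missing sample columns: {missing}")
        df = df[CTSS_KEY + list(samples)]
        if len(df):
            if (df["pos"] < 1).any():
                bad = df.loc[df["pos"] < 1].iloc[0]
                raise ValueError(f"CTSS position < 1 at {bad['chrom']}:{bad['pos']}")
            if not df["strand"].isin(STRANDS).all():
                raise ValueError("CTSS strand must be '+' or '-'")
            counts = df[list(samples)]
            if (counts.to_numpy() < 0).any():
                raise ValueError("negative CTSS counts")
            if df.duplicated(CTSS_KEY).any():
                bad = df.loc[df.duplicated(CTSS_KEY)].iloc[0]
                raise ValueError(
                    f"duplicate CTSS key {bad['chrom']}:{bad['pos']}:{bad['strand']}"
                )
        df["pos"] = df["pos"].astype(np.int64)
        df[list(samples)] = df[list(samples)].astype(np.int64)
        self.df = df.sort_values(CTSS_KEY, kind="mergesort").reset_index(drop=True)
        self._samples = list(samples)

    @property
    def samples(self) -> list[str]:
        return list(self._samples)

    @property
    def counts(self) -> np.ndarray:
        """(n_positions, n_samples) integer count array."""
        return self.df[self._samples].to_numpy()

    @property
    def sample_totals(self) -> pd.Series:
        return self.df[self._samples].sum()

    @property
    def n_positions(self) -> int:
        return len(self.df)

    @classmethod
    def empty(cls, samples: list[str]) -> "CtssMatrix":
        cols = {"chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=np.int64),
                "strand": pd.Series(dtype=str)}
        cols.update({s: pd.Series(dtype=np.int64) for s in samples})
        return cls(pd.DataFrame(cols), samples)

    @classmethod
    def from_entries(cls, entries: Mapping[tuple[str, int, str], Iterable[int]],
                     samples: list[str]) -> "CtssMatrix":
        rows = []
        for (chrom, pos, strand), vec in entries.items():
            vec = list(vec)
            if len(vec) != len(samples):
                raise ValueError(f"count vector length {len(vec)} != {len(samples)} samples")
            rows.append({"chrom": chrom, "pos": pos, "strand": strand,
                         **dict(zip(samples, vec))})
        if not rows:
            return cls.empty(samples)
        return cls(pd.DataFrame(rows), samples)

    def subset_samples(self, samples: list[str]) -> "CtssMatrix":
        return CtssMatrix(self.df[CTSS_KEY + list(samples)], samples)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CtssMatrix):
            return NotImplemented
        return self._samples == other._samples and self.df.equals(other.df)

    def __repr__(self) -> str:
        return f"CtssMatrix({self.n_positions} positions x {len(self._samples)} samples)"
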