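"""CTSS extraction from alignments and the cross-sample support filter."""
from __future__ import annotations

from collections import Counter
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .model import CTSS_KEY, CtssMatrix


def extract_ctss(alignments, sample_id: str, mapq_unique: int = 255,
                 single_end: bool = False, softclip_aware: bool = False) -> CtssMatrix:
    """Count CAGE-defined TSSs (unique R1 5' ends) from a SAM/BAM file.

    Retains first-in-pair, primary, non-duplicate alignments with mapping
    quality exactly ``mapq_unique``. A plus-strand read contributes its
    leftmost aligned base; a minus-strand read its rightmost. With
    ``softclip_aware`` the 5' end is shifted outward by the length of the
    leading soft-clip.
    """
    counts: Counter[tuple[str, int, str]] = Counter()
    with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.is_duplicate:
                continue
            if read.mapping_quality != mapq_unique:
                continue
            if read.is_paired:
                if not read.is_read1:
                    continue
            elif not single_end:
                raise ValueError(
                    f"unpaired read {read.query_name!r} in {alignments}; "
                    "pass single_end=True for unpaired data"
                )
            cigar = read.cigartuples or []
            if read.is_reverse:
                pos = read.reference_end  # 1-based rightmost aligned base
                if softclip_aware and cigar and cigar[-1][0] == 4:  # trailing S
                    pos += cigar[-1][1]
                strand = "-"
            else:
                pos = read.reference_start + 1
                if softclip_aware and cigar and cigar[0][0] == 4:  # leading S
                    pos -= cigar[0][1]
                strand = "+"
            counts[(read.reference_name, max(pos, 1), strand)] += 1
    return CtssMatrix.from_entries(
        {key: [n] for key, n in counts.items()}, [sample_id]
    )


def merge_samples(matrices: Sequence[CtssMatrix],
                  sample_order: Sequence[str] | None = None) -> CtssMatrix:
    """Outer-join single-sample matrices into one multi-sample matrix (absent = 0)."""
    if not matrices:
        raise ValueError("no matrices to merge")
    frames = []
    all_samples: list[str] = []
    for m in matrices:
        for s in m.samples:
            if s in all_samples:
                raise ValueError(f"duplicate sample id {s!r} across matrices")
            all_samples.append(s)
        frames.append(m.df.set_index(CTSS_KEY))
    merged = pd.concat(frames, axis=1).fillna(0).reset_index()
    if sample_order is not None:
        missing = set(sample_order) - set(all_samples)
        if missing:
            raise ValueError(f"sample sheet samples absent from matrices: {sorted(missing)}")
        all_samples = list(sample_order)
    return CtssMatrix(merged, all_samples)


def filter_ctss(matrix: CtssMatrix, min_samples: int = 3, min_count: int = 1) -> CtssMatrix:
    """Keep positions where at least ``min_samples`` samples have ``>= min_count`` reads."""
    if min_samples > len(matrix.samples):
        raise ValueError(
            f"min_samples={min_samples} exceeds number of samples ({len(matrix.samples)})"
        )
    support = (matrix.counts >= min_count).sum(axis=1)
    keep = support >= min_samples
    return CtssMatrix(matrix.df.loc[keep].reset_index(drop=True), matrix.samples)
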