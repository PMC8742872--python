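"""Readers/writers for FASTA, GTF, VCF, BED and CTSS tables, plus pseudo-genome construction."""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import CTSS_KEY, CtssMatrix, GeneModel, VariantRecord

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    """Load genome sequences as a {name: sequence} dict (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Pseudo-genome

@dataclass
class PseudoGenome:
    """Result of SNV substitution into a reference genome."""

    sequences: dict[str, str]
    n_substituted: int
    n_indels_skipped: int


def build_pseudo_genome(reference: dict[str, str],
                        variants: Iterable[VariantRecord]) -> PseudoGenome:
    """Substitute homozygous SNV alt alleles into ``reference``.

    Indels are skipped (counted and logged) so that the coordinate system of
    the output is identical to the input. Raises ``ValueError`` when an SNV's
    ref allele does not match the reference base, or lies beyond the
    chromosome end.
    """
    seqs = {name: bytearray(seq.upper(), "ascii") for name, seq in reference.items()}
    n_sub = 0
    n_indel = 0
    for v in variants:
        if not v.is_snv:
            n_indel += 1
            continue
        if v.chrom not in seqs:
            raise ValueError(f"SNV on unknown chromosome {v.chrom}:{v.pos}")
        chrom = seqs[v.chrom]
        if v.pos > len(chrom):
            raise ValueError(
                f"SNV beyond chromosome end at {v.chrom}:{v.pos} (length {len(chrom)})"
            )
        have = chr(chrom[v.pos - 1]).upper()
        if have != v.ref.upper():
            raise ValueError(
                f"reference mismatch at {v.chrom}:{v.pos}: expected {v.ref!r}, found {have!r}"
            )
        chrom[v.pos - 1] = ord(v.alt.upper())
        n_sub += 1
    if n_indel:
        log.info("pseudo-genome: skipped %d indel(s), substituted %d SNV(s)", n_indel, n_sub)
    return PseudoGenome(
        sequences={name: seq.decode("ascii") for name, seq in seqs.items()},
        n_substituted=n_sub,
        n_indels_skipped=n_indel,
    )


# ---------------------------------------------------------------------------
# Gene models (GTF)

def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from GTF/GFF.

    Per gene the longest transcript (maximal genomic span) defines the
    transcript span; every transcript contributes its strand-aware 5' end to
    ``annotated_tss``. Genes without transcript features are skipped with a
    warning.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    by_gene: dict[str, list] = {}
    order: list[str] = []
    for tx in db.features_of_type(("transcript", "mRNA")):
        gene_ids = tx.attributes.get("gene_id", [tx.id])
        gid = gene_ids[0]
        if gid not in by_gene:
            by_gene[gid] = []
            order.append(gid)
        by_gene[gid].append(tx)
    genes = []
    for gid in order:
        txs = by_gene[gid]
        longest = max(txs, key=lambda t: t.end - t.start)
        strand = longest.strand
        tss = frozenset(t.start if t.strand == "+" else t.end for t in txs)
        # TSSs of short transcripts may fall outside the longest-transcript
        # span that defines the gene region; those are dropped.
        inside = frozenset(p for p in tss if longest.start <= p <= longest.end)
        if len(inside) < len(tss):
            log.debug("gene %s: dropped %d TSS(s) outside longest-transcript span",
                      gid, len(tss) - len(inside))
        genes.append(GeneModel(
            gene_id=gid, chrom=longest.seqid, strand=strand,
            tx_start=longest.start, tx_end=longest.end, annotated_tss=inside,
        ))
    n_genes_declared = sum(1 for _ in db.features_of_type("gene"))
    if n_genes_declared > len(genes):
        log.warning("skipped %d gene(s) with no transcript features",
                    n_genes_declared - len(genes))
    return genes


def write_gene_models_gtf(genes: Sequence[GeneModel], path) -> None:
    """Emit gene models as a minimal GTF (one transcript per annotated TSS)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write("\t".join([g.chrom, "cageshift", "gene", str(g.tx_start),
                                str(g.tx_end), ".", g.strand, ".", attrs]) + "\n")
            for i, tss in enumerate(sorted(g.annotated_tss), 1):
                tid = f"{g.gene_id}.t{i}"
                if g.strand == "+":
                    start, end = tss, g.tx_end
                else:
                    start, end = g.tx_start, tss
                a = f'gene_id "{g.gene_id}"; transcript_id "{tid}";'
                fh.write("\t".join([g.chrom, "cageshift", "transcript", str(start),
                                    str(end), ".", g.strand, ".", a]) + "\n")
                fh.write("\t".join([g.chrom, "cageshift", "exon", str(start),
                                    str(end), ".", g.strand, ".", a]) + "\n")


# ---------------------------------------------------------------------------
# CTSS tables

def read_ctss_table(path) -> CtssMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    return CtssMatrix(df)


def write_ctss_table(matrix: CtssMatrix, path) -> None:
    matrix.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Variants (VCF)

def read_variants(path, split_multiallelic: bool = True) -> list[VariantRecord]:
    """Read a VCF with per-sample AD fields into ``VariantRecord`` objects.

    Multi-allelic sites are split into biallelic records (ref vs each alt)
    when ``split_multiallelic`` is true, else rejected. A record whose samples
    lack the AD field raises ``ValueError`` naming the sample.
    """
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) > 1 and not split_multiallelic:
                raise ValueError(f"multi-allelic record at {rec.chrom}:{rec.pos}")
            for ai, alt in enumerate(alts, start=1):
                depths: dict[str, tuple[int, int]] = {}
                for name in sample_names:
                    sample = rec.samples[name]
                    ad = sample.get("AD")
                    if ad is None or all(x is None for x in ad):
                        raise ValueError(
                            f"missing AD for sample {name!r} at {rec.chrom}:{rec.pos}"
                        )
                    ref_d = int(ad[0] or 0)
                    alt_d = int(ad[ai] or 0) if len(ad) > ai else 0
                    depths[name] = (ref_d, alt_d)
                out.append(VariantRecord(chrom=rec.chrom, pos=rec.pos,
                                         ref=rec.ref, alt=alt,
                                         sample_allele_depths=depths))
    return out


# ---------------------------------------------------------------------------
# BED (0-based half-open on disk; 1-based inclusive in memory)

def read_bed_intervals(path) -> pd.DataFrame:
    """Read BED3+ into a frame with 1-based inclusive ``start``/``end``."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={0: str})
    df["start"] = df["start"].astype(np.int64) + 1
    df["end"] = df["end"].astype(np.int64)
    return df


def write_bed_intervals(df: pd.DataFrame, path, name_col: str | None = None,
                        score_col: str | None = None,
                        strand_col: str | None = None) -> None:
    """Write intervals (1-based inclusive ``start``/``end``) as BED."""
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            fields = [str(row["chrom"]), str(int(row["start"]) - 1), str(int(row["end"]))]
            if name_col or score_col or strand_col:
                fields.append(str(row[name_col]) if name_col else ".")
                fields.append(str(row[score_col]) if score_col else "0")
                if strand_col:
                    fields.append(str(row[strand_col]))
            fh.write("\t".join(fields) + "\n")
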