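"""Synthetic CAGE experiment generator with planted ground truth.

Emits a self-contained fixture set — genome FASTA, GTF, CpG BED, CTSS count
matrix, optional SAM reads, F1 variant VCF, RI genotype/phenotype tables —
whose planted effects (alternative promoter usage, TSS shifts, allelic
imbalance, phenotype association) are recorded in a truth object for
parameter-recovery testing.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .io import write_bed_intervals, write_fasta, write_gene_models_gtf
from .model import CtssMatrix, GeneModel, SampleSheet
from .annotation import revcomp

TATA_MOTIF = "TATAAAAG"  # matches the TATAWAWR consensus


@dataclass
class SimConfig:
    """All knobs of the synthetic experiment; identical config => identical output."""

    seed: int = 0
    n_genes: int = 30
    two_promoter_prob: float = 0.6
    frac_sharp: float = 0.5
    sharp_decay: float = 0.5          # geometric tail decay of sharp profiles
    broad_sigma: tuple[float, float] = (15.0, 25.0)
    library_size: int = 100_000       # expected tags per sample
    nb_dispersion: float = 0.05
    n_replicates: int = 3             # per strain per sex
    gene_spacing: int = 10_000
    # planted alternative promoter usage (symmetric opposite effects on P1/P2)
    n_alt_genes: int = 0
    alt_log2fc: tuple[float, float] = (1.0, -1.0)
    # planted within-promoter shifts (strain A displaced downstream)
    n_shift_promoters: int = 0
    shift_offset: int = 40
    # planted F1 allelic imbalance
    n_ase_variants: int = 0
    n_null_ase_variants: int = 0
    ase_ai: float = 0.5
    ase_depth: int = 30
    # RI strain phenotypes
    n_ri_strains: int = 30
    phenotype_effect_sd: float = 0.0

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for key in ("alt_log2fc", "broad_sigma"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: list(v) if isinstance(v, tuple) else v
                            for k, v in asdict(self).items()}, fh)


@dataclass
class SimTruth:
    """Planted ground truth tables keyed by genomic coordinates."""

    genes: pd.DataFrame       # gene_id, chrom, strand, n_promoters, category, lfc_p1, lfc_p2
    promoters: pd.DataFrame   # gene_id, promoter_idx, chrom, strand, tss, arch,
                              # weight, shift_offset, shift_direction
    variants: pd.DataFrame = field(default_factory=pd.DataFrame)
    ri: pd.DataFrame = field(default_factory=pd.DataFrame)
    expected_sample_totals: dict = field(default_factory=dict)
    sample_total_sd: dict = field(default_factory=dict)


@dataclass
class SimulatedExperiment:
    genome: dict[str, str]
    genes: list[GeneModel]
    cpg_islands: pd.DataFrame  # chrom, start, end (1-based inclusive)
    matrix: CtssMatrix
    samplesheet: SampleSheet
    truth: SimTruth


def _rng(seed: int, *key) -> np.random.Generator:
    """Deterministic per-entity generator so entities do not perturb each other."""
    parts = [seed] + [zlib.crc32(str(k).encode()) for k in key]
    return np.random.default_rng(np.random.SeedSequence(parts))


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion < 1e-12:
        return int(rng.poisson(mean))
    n = 1.0 / dispersion
    return int(rng.negative_binomial(n, n / (n + mean)))


def _profile(arch: str, cfg: SimConfig, rng: np.random.Generator
             ) -> tuple[np.ndarray, np.ndarray]:
    """Base positional profile as (signed 5'->3' offsets, probabilities)."""
    if arch == "sharp":
        k = 10
        d = cfg.sharp_decay
        offsets = np.arange(0, k + 1)
        if d <= 0:
            probs = np.zeros(k + 1)
            probs[0] = 1.0
        else:
            probs = d ** offsets
    else:
        sigma = float(rng.uniform(*cfg.broad_sigma))
        half = int(np.ceil(3 * sigma))
        offsets = np.arange(-half, half + 1)
        probs = np.exp(-0.5 * (offsets / sigma) ** 2)
    probs = probs / probs.sum()
    return offsets, probs


def parental_samplesheet(cfg: SimConfig) -> SampleSheet:
    rows = []
    for strain in ("A", "B"):
        for sex in ("m", "f"):
            for rep in range(1, cfg.n_replicates + 1):
                rows.append({"sample_id": f"{strain}_{sex}{rep}", "strain": strain,
                             "sex": sex, "replicate": rep, "group": strain})
    return SampleSheet(pd.DataFrame(rows))


def f1_samplesheet(cfg: SimConfig) -> SampleSheet:
    rows = []
    for cross in ("AxB", "BxA"):
        for sex in ("m", "f"):
            for rep in range(1, cfg.n_replicates + 1):
                rows.append({"sample_id": f"F1{cross}_{sex}{rep}", "strain": "F1",
                             "sex": sex, "replicate": rep, "group": cross})
    return SampleSheet(pd.DataFrame(rows))


def simulate_ctss_experiment(cfg: SimConfig) -> SimulatedExperiment:
    """Generate genome, annotation, CpG islands and the parental CTSS matrix."""
    sheet = parental_samplesheet(cfg)
    samples = sheet.samples
    chrom = "chrS1"
    margin = 5_000
    glen = cfg.n_genes * cfg.gene_spacing + 2 * margin
    base_rng = _rng(cfg.seed, "genome")
    genome_arr = base_rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=glen)

    # --- plan genes and promoters -----------------------------------------
    gene_rows, prom_rows = [], []
    plan_rng = _rng(cfg.seed, "plan")
    n_two = 0
    for gi in range(cfg.n_genes):
        want_alt = gi < cfg.n_alt_genes
        two = want_alt or (plan_rng.random() < cfg.two_promoter_prob)
        strand = "+" if gi % 2 == 0 else "-"
        anchor = margin + gi * cfg.gene_spacing
        gid = f"G{gi + 1:04d}"
        step = 400 if strand == "+" else -400
        n_prom = 2 if two else 1
        n_two += two
        if want_alt:
            weights = np.array([0.5, 0.5])
            lfc = cfg.alt_log2fc
            category = "alt_usage"
        else:
            if n_prom == 2:
                w1 = float(plan_rng.uniform(0.55, 0.75))
                weights = np.array([w1, 1.0 - w1])
            else:
                weights = np.array([1.0])
            lfc = (0.0, 0.0)
            category = "null"
        gene_rows.append({"gene_id": gid, "chrom": chrom, "strand": strand,
                          "n_promoters": n_prom, "category": category,
                          "lfc_p1": lfc[0], "lfc_p2": lfc[1] if n_prom == 2 else np.nan})
        for pi in range(n_prom):
            prom_rows.append({"gene_id": gid, "promoter_idx": pi + 1, "chrom": chrom,
                              "strand": strand, "tss": anchor + pi * step,
                              "weight": weights[pi] / cfg.n_genes,
                              "lfc": lfc[pi] if category == "alt_usage" else 0.0,
                              "arch": "", "shift_offset": 0, "shift_direction": "none"})
    promoters = pd.DataFrame(prom_rows)
    genes_df = pd.DataFrame(gene_rows)

    # shift planting: P1 promoters of non-alt genes, broad architecture
    shiftable = promoters.index[
        (promoters["promoter_idx"] == 1)
        & promoters["gene_id"].isin(genes_df.loc[genes_df["category"] == "null", "gene_id"])
    ]
    if cfg.n_shift_promoters > len(shiftable):
        raise ValueError("not enough null genes to host planted shifts")
    shift_idx = list(shiftable[: cfg.n_shift_promoters])
    for idx in shift_idx:
        promoters.loc[idx, "shift_offset"] = cfg.shift_offset
        promoters.loc[idx, "shift_direction"] = "downstream_in_A"
        promoters.loc[idx, "arch"] = "broad"

    arch_rng = _rng(cfg.seed, "arch")
    for idx in promoters.index:
        if promoters.loc[idx, "arch"] == "":
            promoters.loc[idx, "arch"] = \
                "sharp" if arch_rng.random() < cfg.frac_sharp else "broad"

    # --- sequence features and CpG islands --------------------------------
    cpg_rows = []
    for _, pr in promoters.iterrows():
        tss, strand = int(pr["tss"]), pr["strand"]
        if pr["arch"] == "sharp":
            if strand == "+":
                start = tss - 31  # 1-based; motif occupies [tss-31, tss-24]
                motif = TATA_MOTIF
            else:
                start = tss + 24
                motif = revcomp(TATA_MOTIF)
            genome_arr[start - 1:start - 1 + len(motif)] = \
                np.frombuffer(motif.encode(), dtype=np.uint8)
        else:
            lo = tss - 100
            hi = tss + 100 + int(pr["shift_offset"])
            cpg_rows.append({"chrom": pr["chrom"], "start": lo, "end": hi})
    cpg = pd.DataFrame(cpg_rows, columns=["chrom", "start", "end"])

    # --- gene models -------------------------------------------------------
    gene_models = []
    for _, g in genes_df.iterrows():
        ptab = promoters.loc[promoters["gene_id"] == g["gene_id"]]
        tss_set = frozenset(int(t) for t in ptab["tss"])
        if g["strand"] == "+":
            tx_start, tx_end = min(tss_set), max(tss_set) + 3000
        else:
            tx_start, tx_end = min(tss_set) - 3000, max(tss_set)
        gene_models.append(GeneModel(
            gene_id=g["gene_id"], chrom=g["chrom"], strand=g["strand"],
            tx_start=tx_start, tx_end=tx_end, annotated_tss=tss_set,
        ))

    # --- counts ------------------------------------------------------------
    entries: dict[tuple[str, int, str], np.ndarray] = {}
    expected = {s: 0.0 for s in samples}
    total_var = {s: 0.0 for s in samples}
    strain_of = dict(zip(sheet.frame["sample_id"], sheet.frame["strain"]))
    for idx, pr in promoters.iterrows():
        prng = _rng(cfg.seed, "prom", idx)
        offsets, probs = _profile(pr["arch"], cfg, prng)
        sign = 1 if pr["strand"] == "+" else -1
        base_positions = int(pr["tss"]) + sign * offsets
        shifted_positions = base_positions + sign * int(pr["shift_offset"])
        for si, s in enumerate(samples):
            strain = strain_of[s]
            effect = 2.0 ** (pr["lfc"] / 2.0) if strain == "A" else 2.0 ** (-pr["lfc"] / 2.0)
            mean = pr["weight"] * cfg.library_size * effect
            expected[s] += mean
            total_var[s] += mean + cfg.nb_dispersion * mean ** 2
            total = _nb_draw(prng, mean, cfg.nb_dispersion)
            if total == 0:
                continue
            positions = shifted_positions if strain == "A" else base_positions
            alloc = prng.multinomial(total, probs)
            for pos, n in zip(positions, alloc):
                if n == 0:
                    continue
                key = (pr["chrom"], int(pos), pr["strand"])
                if key not in entries:
                    entries[key] = np.zeros(len(samples), dtype=np.int64)
                entries[key][si] += n
    matrix = CtssMatrix.from_entries(entries, samples)

    truth = SimTruth(
        genes=genes_df, promoters=promoters,
        expected_sample_totals=expected,
        sample_total_sd={s: float(np.sqrt(v)) for s, v in total_var.items()},
    )
    genome = {chrom: genome_arr.tobytes().decode("ascii")}
    return SimulatedExperiment(genome=genome, genes=gene_models, cpg_islands=cpg,
                               matrix=matrix, samplesheet=sheet, truth=truth)


# ---------------------------------------------------------------------------
# F1 allelic imbalance

_ALT_OF = {"A": "G", "C": "T", "G": "A", "T": "C"}


def simulate_f1_ase(cfg: SimConfig, experiment: SimulatedExperiment | None = None
                    ) -> tuple[list, pd.DataFrame, SampleSheet]:
    """Simulate F1 ref/alt allele depths with planted imbalance.

    Returns (variant records, truth table, combined sample sheet). When an
    ``experiment`` is given, variants are placed at its planted promoter TSSs
    (so they fall inside detected tag clusters); otherwise on a bare scaffold.
    Strain B is the reference strain (all-ref parental reads), strain A
    carries the alt allele. F1 ref counts are Binomial(depth, (1+AI)/2).
    """
    from .model import VariantRecord

    par = parental_samplesheet(cfg)
    f1 = f1_samplesheet(cfg)
    combined = SampleSheet(pd.concat([par.frame, f1.frame], ignore_index=True))

    n_total = cfg.n_ase_variants + cfg.n_null_ase_variants
    if experiment is not None:
        ptab = experiment.truth.promoters
        if n_total > len(ptab):
            raise ValueError("more ASE variants requested than planted promoters")
        sites = [(ptab.iloc[i]["chrom"], int(ptab.iloc[i]["tss"]))
                 for i in range(n_total)]
        genome = experiment.genome
    else:
        sites = [("chrS1", 1000 + 500 * i) for i in range(n_total)]
        genome = None

    records, truth_rows = [], []
    for vi, (chrom, pos) in enumerate(sites):
        vrng = _rng(cfg.seed, "ase", vi)
        ai = cfg.ase_ai if vi < cfg.n_ase_variants else 0.0
        ref = genome[chrom][pos - 1] if genome is not None else "A"
        if ref == "N":
            ref = "A"
        alt = _ALT_OF[ref]
        depths: dict[str, tuple[int, int]] = {}
        for s in par.samples:
            d = max(int(vrng.poisson(cfg.ase_depth)), 1)
            strain = s.split("_")[0]
            depths[s] = (0, d) if strain == "A" else (d, 0)
        for s in f1.samples:
            d = _nb_draw(vrng, cfg.ase_depth, cfg.nb_dispersion)
            r = int(vrng.binomial(d, (1.0 + ai) / 2.0)) if d > 0 else 0
            depths[s] = (r, d - r)
        records.append(VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                                     sample_allele_depths=depths))
        truth_rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                           "planted_ai": ai})
    return records, pd.DataFrame(truth_rows), combined


def write_vcf(records, samplesheet: SampleSheet, path) -> None:
    """Write variant records with per-sample AD (and DP/GT) to a plain-text VCF."""
    samples = samplesheet.samples
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = sorted({v.chrom for v in records})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for v in sorted(records, key=lambda r: (r.chrom, r.pos)):
            cells = []
            for s in samples:
                r, a = v.sample_allele_depths.get(s, (0, 0))
                if r > 0 and a > 0:
                    gt = "0/1"
                elif a > 0:
                    gt = "1/1"
                else:
                    gt = "0/0"
                cells.append(f"{gt}:{r},{a}")
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT:AD\t"
                     + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# RI strains

def simulate_ri_phenotypes(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Genotype and phenotype tables for ~n_ri_strains RI strains.

    Phenotype = baseline + effect*SD for GG strains + Gaussian noise (SD = 1).
    """
    rng = _rng(cfg.seed, "ri")
    strains = [f"RI{i + 1:02d}" for i in range(cfg.n_ri_strains)]
    genotypes = np.where(rng.random(cfg.n_ri_strains) < 0.5, "AA", "GG")
    baseline = 10.0
    pheno = baseline + cfg.phenotype_effect_sd * (genotypes == "GG") \
        + rng.normal(0.0, 1.0, cfg.n_ri_strains)
    geno_df = pd.DataFrame({"strain_id": strains, "genotype": genotypes})
    pheno_df = pd.DataFrame({"strain_id": strains, "phenotype": pheno})
    truth = pd.DataFrame({"strain_id": strains, "genotype": genotypes,
                          "effect_sd": cfg.phenotype_effect_sd})
    return geno_df, pheno_df, truth


# ---------------------------------------------------------------------------
# SAM emission (R1-only paired reads realizing the CTSS counts)

def write_sam_from_matrix(matrix: CtssMatrix, genome: dict[str, str], sample: str,
                          path, read_len: int = 100) -> None:
    """Write R1 alignments whose 5' ends realize one sample's CTSS counts."""
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome.items()]}
    refs = {name: i for i, name in enumerate(genome)}
    qid = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for _, row in matrix.df.iterrows():
            chrom, pos, strand = row["chrom"], int(row["pos"]), row["strand"]
            n = int(row[sample])
            clen = len(genome[chrom])
            for _ in range(n):
                qid += 1
                a = pysam.AlignedSegment()
                a.query_name = f"r{qid:07d}"
                a.reference_id = refs[chrom]
                a.mapping_quality = 255
                if strand == "+":
                    start0 = pos - 1
                    span = min(read_len, clen - start0)
                    a.flag = 0x1 | 0x2 | 0x20 | 0x40  # paired, proper, mate rev, R1
                else:
                    span = min(read_len, pos)
                    start0 = pos - span
                    a.flag = 0x1 | 0x2 | 0x10 | 0x40  # paired, proper, reverse, R1
                a.reference_start = start0
                a.cigartuples = [(0, span)]
                a.query_sequence = genome[chrom][start0:start0 + span]
                a.next_reference_id = refs[chrom]
                a.next_reference_start = start0
                a.template_length = span
                out.write(a)


# ---------------------------------------------------------------------------
# Fixture directory

def write_experiment(experiment: SimulatedExperiment, outdir,
                     cfg: SimConfig | None = None, with_sam: bool = False) -> dict[str, Path]:
    """Dump every fixture file the downstream CLI stages consume."""
    from .io import write_ctss_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "gtf": outdir / "genes.gtf",
        "cpg": outdir / "cpg.bed",
        "ctss": outdir / "ctss.matrix.tsv",
        "samplesheet": outdir / "samples.tsv",
        "truth_promoters": outdir / "truth.promoters.tsv",
        "truth_genes": outdir / "truth.genes.tsv",
    }
    write_fasta(experiment.genome, paths["genome"])
    write_gene_models_gtf(experiment.genes, paths["gtf"])
    write_bed_intervals(experiment.cpg_islands, paths["cpg"])
    write_ctss_table(experiment.matrix, paths["ctss"])
    experiment.samplesheet.to_tsv(paths["samplesheet"])
    experiment.truth.promoters.to_csv(paths["truth_promoters"], sep="\t", index=False)
    experiment.truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    if with_sam:
        for s in experiment.samplesheet.samples:
            p = outdir / f"{s}.sam"
            write_sam_from_matrix(experiment.matrix, experiment.genome, s, p)
            paths[f"sam_{s}"] = p
    return paths
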