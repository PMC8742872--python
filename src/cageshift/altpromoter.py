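"""Two-group negative-binomial differential test and alternative-promoter-usage calls.

The differential engine follows the standard bulk count-model recipe:
median-of-ratios size factors, per-feature method-of-moments dispersion with a
small floor, and a Wald test on the log2 fold change between the two strains
under an NB2 mean model, with Benjamini-Hochberg adjustment across features.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import PromoterRegion
from .model import SampleSheet

DISPERSION_FLOOR = 1e-8

CATEGORIES = ("single_predominant", "multi_no_de", "multi_same_direction",
              "alternative_usage")


@dataclass
class GeneAltUsageCall:
    gene_id: str
    category: str
    active_promoters: list[str]
    evidence: tuple[str, str] | None = None  # opposite-direction pair incl. P1

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"bad category {self.category!r}")
        if self.category == "alternative_usage" and self.evidence is None:
            raise ValueError("alternative_usage requires an evidence pair")


def activity_proportions(expression: Sequence[float]) -> np.ndarray:
    """Per-promoter share of a gene's aggregate expression; sums to 1."""
    expr = np.asarray(expression, dtype=float)
    total = expr.sum()
    if total <= 0:
        raise ValueError("gene has no positive aggregate expression")
    return expr / total


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors over features with all-positive counts."""
    counts = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts)
    log_geo = log_counts.mean(axis=1)
    usable = np.isfinite(log_geo)
    if not usable.any():
        # no feature expressed in every sample; fall back to total-count scaling
        totals = counts.sum(axis=0)
        return totals / np.exp(np.mean(np.log(totals)))
    ratios = log_counts[usable] - log_geo[usable, None]
    return np.exp(np.median(ratios, axis=0))


def estimate_dispersions(norm_counts: np.ndarray, group_idx: Sequence[np.ndarray],
                        floor: float = DISPERSION_FLOOR) -> np.ndarray:
    """Per-feature method-of-moments NB dispersion, pooled within groups.

    Uses within-group sample variances (ddof=1); alpha solves
    var = mu + alpha * mu^2, floored at ``floor``.
    """
    n_feat = norm_counts.shape[0]
    num = np.zeros(n_feat)
    den = np.zeros(n_feat)
    weight = 0.0
    for idx in group_idx:
        sub = norm_counts[:, idx]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        w = len(idx) - 1
        num += w * (var - mu)
        den += w * mu ** 2
        weight += w
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return np.maximum(alpha, floor)


def _fit_group_mean(y: np.ndarray, sf: np.ndarray, alpha: np.ndarray,
                    n_iter: int = 50, tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Newton solve for per-feature NB group means with known dispersion.

    Model: y_ij ~ NB(mean = sf_j * mu_i, dispersion alpha_i). Returns
    (mu_hat, fisher_information of log mu).
    """
    a = alpha[:, None]
    mu = np.maximum(np.average(y / sf[None, :], axis=1), 1e-8)
    beta = np.log(mu)
    for _ in range(n_iter):
        m = sf[None, :] * np.exp(beta)[:, None]
        denom = 1.0 + a * m
        score = ((y - m) / denom).sum(axis=1)
        info = (m * (1.0 + a * y) / denom ** 2).sum(axis=1)
        step = score / np.maximum(info, 1e-300)
        step = np.clip(step, -5.0, 5.0)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    mu = np.exp(beta)
    m = sf[None, :] * mu[:, None]
    fisher = (m / (1.0 + a * m)).sum(axis=1)
    return mu, fisher


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out


def test_differential(counts: pd.DataFrame, design: SampleSheet,
                      strain_a: str = "A", strain_b: str = "B") -> pd.DataFrame:
    """Per-feature NB Wald test of strain A vs strain B.

    ``counts``: features x samples integer frame (index = feature ids).
    Returns a frame with columns mean_expression, log2fc (A over B), se, p,
    padj; all-zero features are excluded from testing and reported NA.
    """
    samples_a = [s for s in design.strain_samples(strain_a) if s in counts.columns]
    samples_b = [s for s in design.strain_samples(strain_b) if s in counts.columns]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("need >= 2 replicates per strain")
    cols = samples_a + samples_b
    mat = counts[cols].to_numpy(dtype=float)
    sf = size_factors(mat)
    norm = mat / sf[None, :]
    nonzero = mat.sum(axis=1) > 0

    idx_a = np.arange(len(samples_a))
    idx_b = np.arange(len(samples_a), len(cols))
    result = pd.DataFrame(index=counts.index, columns=[
        "mean_expression", "log2fc", "se", "p", "padj"], dtype=float)
    result["mean_expression"] = norm.mean(axis=1)
    if nonzero.any():
        sub = mat[nonzero]
        alpha = estimate_dispersions(norm[nonzero], [idx_a, idx_b])
        mu_a, info_a = _fit_group_mean(sub[:, idx_a], sf[idx_a], alpha)
        mu_b, info_b = _fit_group_mean(sub[:, idx_b], sf[idx_b], alpha)
        # a half-count pseudo-mean keeps the fold change finite for one-sided zeros
        log2fc = np.log2(np.maximum(mu_a, 0.5)) - np.log2(np.maximum(mu_b, 0.5))
        se_log = np.sqrt(1.0 / np.maximum(info_a, 1e-300)
                         + 1.0 / np.maximum(info_b, 1e-300))
        wald = (np.log(np.maximum(mu_a, 0.5)) - np.log(np.maximum(mu_b, 0.5))) / se_log
        df = len(cols) - 2
        p = 2.0 * stats.t.sf(np.abs(wald), df)
        result.loc[nonzero, "log2fc"] = log2fc
        result.loc[nonzero, "se"] = se_log / np.log(2)
        result.loc[nonzero, "p"] = p
        result.loc[nonzero, "padj"] = bh_adjust(p)
    return result


def call_alt_usage(gene_id: str, promoters: Sequence[PromoterRegion],
                   de: pd.DataFrame, proportions: Mapping[str, float],
                   min_prop: float = 0.2, alpha: float = 0.05) -> GeneAltUsageCall:
    """Classify one gene's promoter usage between the two strains.

    Active promoters carry >= ``min_prop`` of the gene's aggregate expression.
    ``alternative_usage`` requires an active pair with padj <= ``alpha`` on
    both members, opposite log2fc signs, and the gene's P1 in the pair.
    """
    active = [p for p in promoters if proportions.get(p.promoter_id, 0.0) >= min_prop]
    if len(active) < 2:
        return GeneAltUsageCall(gene_id, "single_predominant",
                                [p.promoter_id for p in active])
    active_ids = [p.promoter_id for p in active]

    def _sig(pid: str) -> bool:
        if pid not in de.index:
            return False
        padj = de.loc[pid, "padj"]
        return bool(pd.notna(padj) and padj <= alpha)

    def _lfc(pid: str) -> float:
        return float(de.loc[pid, "log2fc"]) if pid in de.index else 0.0

    sig_ids = [pid for pid in active_ids if _sig(pid)]
    if not sig_ids:
        return GeneAltUsageCall(gene_id, "multi_no_de", active_ids)

    p1 = next((p for p in active if p.rank == 1), None)
    if p1 is not None and _sig(p1.promoter_id):
        for p in active:
            pid = p.promoter_id
            if pid == p1.promoter_id or not _sig(pid):
                continue
            if _lfc(pid) * _lfc(p1.promoter_id) < 0:
                return GeneAltUsageCall(gene_id, "alternative_usage", active_ids,
                                        evidence=(p1.promoter_id, pid))
    return GeneAltUsageCall(gene_id, "multi_same_direction", active_ids)


def call_alt_usage_all(promoters: Sequence[PromoterRegion], de: pd.DataFrame,
                       min_prop: float = 0.2, alpha: float = 0.05,
                       expression_samples: Sequence[str] | None = None
                       ) -> dict[str, GeneAltUsageCall]:
    """Run :func:`call_alt_usage` for every gene with assigned promoters."""
    by_gene: dict[str, list[PromoterRegion]] = {}
    for p in promoters:
        if p.gene_id is not None:
            by_gene.setdefault(p.gene_id, []).append(p)
    calls = {}
    for gid, plist in by_gene.items():
        expr = []
        for p in plist:
            tpm = p.expression
            if expression_samples is not None:
                idx = [p.samples.index(s) for s in expression_samples]
                tpm = tpm[idx]
            expr.append(float(np.mean(tpm)))
        if sum(expr) <= 0:
            continue
        props = dict(zip((p.promoter_id for p in plist),
                         activity_proportions(expr)))
        calls[gid] = call_alt_usage(gid, plist, de, props, min_prop, alpha)
    return calls
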