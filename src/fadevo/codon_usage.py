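"""Per-gene codon-usage-bias statistics and the four comparative analyses.

This module implements the parametric toolbox used to ask whether a gene
family's codon usage is compatible with its host genome (an HGT screen):

* RSCU — relative synonymous codon usage, count x degeneracy / family total;
* GC3s — G+C at third positions of synonymously degenerate codons;
* ENc — Wright's effective number of codons, from within-family codon
  "homozygosity" F, with CodonW-compatible conventions (class-mean F,
  imputation of a missing three-fold class, cap at the sense-codon count);
* the ENc-GC3s plot against Wright's mutation-only expectation
  ``ENc*(s) = 2 + s + 29 / (s^2 + (1-s)^2)``;
* PR2 — parity-rule-2 biases A3/(A3+T3) and G3/(G3+C3) over fourfold-
  degenerate families;
* the neutrality plot — OLS regression of GC12 on GC3 across genes;
* PCA of RSCU profiles across genes.

Statistics that are undefined on degenerate input are reported as None
(NA), never silently as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats

from .codes import ALL_CODONS, GeneticCode
from .seqio import CodingSequence

logger = logging.getLogger("fadevo")

#: Genes shorter than this many codons get a warning (ENc is noisy).
SHORT_GENE_WARN = 30
#: Genes shorter than this are excluded from gene-set analyses by default.
SHORT_GENE_EXCLUDE = 10


# --------------------------------------------------------------------------- #
# Counting
# --------------------------------------------------------------------------- #

@dataclass
class CodonCountTable:
    """Per-gene counts over all 64 codons; ``n`` counts sense codons only."""

    gene_id: str
    counts: Dict[str, int]
    code: GeneticCode

    @property
    def n(self) -> int:
        return sum(self.counts[c] for c in self.code.sense_codons)

    def family_counts(self, family: Tuple[str, ...]) -> List[int]:
        return [self.counts[c] for c in family]


def count_codons(cds: CodingSequence) -> CodonCountTable:
    """Exact codon counts for a validated CDS (no internal stops by construction)."""
    if cds.n_codons == 0:
        raise ValueError(f"gene {cds.id!r}: no codons after terminal-stop stripping")
    counts = {c: 0 for c in ALL_CODONS}
    for codon in cds.codons:
        counts[codon] += 1
    return CodonCountTable(gene_id=cds.id, counts=counts, code=cds.code)


# --------------------------------------------------------------------------- #
# Per-gene statistics
# --------------------------------------------------------------------------- #

def rscu(table: CodonCountTable) -> Dict[str, Optional[float]]:
    """RSCU(c) = count(c) * k / family total; None for unobserved families."""
    out: Dict[str, Optional[float]] = {}
    for fam in table.code.families.values():
        total = sum(table.counts[c] for c in fam)
        k = len(fam)
        for c in fam:
            out[c] = (table.counts[c] * k / total) if total > 0 else None
    return out


def gc3s(table: CodonCountTable) -> Optional[float]:
    """G+C fraction at third positions of codons in families with degeneracy >= 2."""
    num = 0
    denom = 0
    for fam in table.code.families.values():
        if len(fam) < 2:
            continue
        for c in fam:
            cnt = table.counts[c]
            denom += cnt
            if c[2] in "GC":
                num += cnt
    return num / denom if denom else None


def positional_gc(table: CodonCountTable) -> Tuple[float, float, float]:
    """GC fraction at codon positions 1, 2, 3 over all counted codons."""
    totals = [0, 0, 0]
    gc = [0, 0, 0]
    for codon, cnt in table.counts.items():
        if cnt == 0:
            continue
        for pos in range(3):
            totals[pos] += cnt
            if codon[pos] in "GC":
                gc[pos] += cnt
    if totals[0] == 0:
        raise ValueError(f"gene {table.gene_id!r}: empty count table")
    return tuple(g / t for g, t in zip(gc, totals))  # type: ignore[return-value]


def gc12(table: CodonCountTable) -> float:
    """Mean of first- and second-position GC over all codons."""
    g1, g2, _ = positional_gc(table)
    return (g1 + g2) / 2


def gc3(table: CodonCountTable) -> float:
    """Third-position GC over all codons (not restricted to degenerate families)."""
    return positional_gc(table)[2]


def enc(table: CodonCountTable, warn_below: int = SHORT_GENE_WARN) -> Optional[float]:
    """Wright's effective number of codons.

    Per family with n >= 2 observations: F = (n * sum p_i^2 - 1) / (n - 1)
    (the unbiased homozygosity estimator).  Per degeneracy class, F-bar is
    the mean over families with defined, positive F; families with F = 0
    are treated as uninformative, as in CodonW.  ENc is the sum over
    classes of (number of families in the class) / F-bar, with one-fold
    families contributing their count, a missing three-fold class imputed
    as (F2-bar + F4-bar)/2, and the result capped at the code's sense-codon
    count.  Returns None when any other class has no defined F-bar.
    """
    if table.n < warn_below:
        logger.warning(
            "gene %r has only %d sense codons (< %d); ENc will be noisy",
            table.gene_id, table.n, warn_below,
        )
    classes: Dict[int, List[float]] = {}
    class_sizes: Dict[int, int] = {}
    for fam in table.code.families.values():
        k = len(fam)
        class_sizes[k] = class_sizes.get(k, 0) + 1
        if k == 1:
            continue
        counts = [table.counts[c] for c in fam]
        n_f = sum(counts)
        if n_f < 2:
            continue
        sum_p2 = sum((c / n_f) ** 2 for c in counts)
        f_hat = (n_f * sum_p2 - 1) / (n_f - 1)
        if f_hat > 0:
            classes.setdefault(k, []).append(f_hat)

    fbar: Dict[int, float] = {k: float(np.mean(v)) for k, v in classes.items()}
    if 3 not in fbar and 3 in class_sizes and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2
    total = 0.0
    for k, n_families in sorted(class_sizes.items()):
        if k == 1:
            total += n_families
            continue
        if k not in fbar:
            return None
        total += n_families / fbar[k]
    return min(total, float(len(table.code.sense_codons)))


def enc_expected(s: float) -> float:
    """Wright's expected ENc under pure mutation pressure at GC3s = s.

    >>> enc_expected(0.5)
    60.5
    """
    if not (0 <= s <= 1):
        raise ValueError(f"GC3s fraction must be in [0, 1], got {s}")
    return 2 + s + 29 / (s**2 + (1 - s) ** 2)


@dataclass
class PR2Point:
    """Parity-rule-2 biases over fourfold-degenerate families only."""

    gene_id: str
    at_bias: Optional[float]  # A3 / (A3 + T3)
    gc_bias: Optional[float]  # G3 / (G3 + C3)


def pr2(table: CodonCountTable) -> PR2Point:
    counts = {b: 0 for b in "ACGT"}
    for fam in table.code.families.values():
        if len(fam) != 4:
            continue
        for c in fam:
            counts[c[2]] += table.counts[c]
    at = counts["A"] + counts["T"]
    gc = counts["G"] + counts["C"]
    return PR2Point(
        gene_id=table.gene_id,
        at_bias=counts["A"] / at if at else None,
        gc_bias=counts["G"] / gc if gc else None,
    )


@dataclass
class CUBStats:
    """Bundle of per-gene codon-usage statistics."""

    gene_id: str
    rscu: Dict[str, Optional[float]]
    gc3s: Optional[float]
    gc12: float
    gc3: float
    enc: Optional[float]
    n_codons: int
    pr2: PR2Point = None  # type: ignore[assignment]


def compute_stats(cds: CodingSequence) -> CUBStats:
    """All codon-usage statistics for one gene."""
    table = count_codons(cds)
    return CUBStats(
        gene_id=cds.id,
        rscu=rscu(table),
        gc3s=gc3s(table),
        gc12=gc12(table),
        gc3=gc3(table),
        enc=enc(table),
        n_codons=table.n,
        pr2=pr2(table),
    )


# --------------------------------------------------------------------------- #
# Cross-gene analyses
# --------------------------------------------------------------------------- #

@dataclass
class NeutralityFit:
    """OLS of GC12 on GC3 across genes: slope ~1 means mutation pressure
    dominates, ~0 means selection."""

    slope: float
    intercept: float
    r: float
    n_genes: int


def neutrality_fit(genes: Sequence[CUBStats]) -> NeutralityFit:
    pts = [(g.gc3, g.gc12) for g in genes if g.gc3 is not None and g.gc12 is not None]
    if len(pts) < 3:
        raise ValueError(f"neutrality fit needs >= 3 genes with defined GC12/GC3, got {len(pts)}")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in GC3 across genes; neutrality fit undefined")
    res = scipy_stats.linregress(x, y)
    return NeutralityFit(slope=float(res.slope), intercept=float(res.intercept),
                         r=float(res.rvalue), n_genes=len(pts))


@dataclass
class PCAResult:
    gene_ids: List[str]
    codons: List[str]
    scores: np.ndarray            # genes x components
    loadings: np.ndarray          # codons x components
    variance_fractions: np.ndarray


def rscu_pca(
    genes: Sequence[Mapping[str, Optional[float]]],
    code: GeneticCode,
    gene_ids: Optional[Sequence[str]] = None,
) -> PCAResult:
    """PCA of RSCU profiles over informative codons (families with k >= 2).

    NA entries (unobserved families) are imputed with the column mean
    (logged); the matrix is column-centered and decomposed by singular
    values.  Component signs are fixed so each loading vector's largest-
    magnitude entry is positive.
    """
    if len(genes) < 2:
        raise ValueError(f"PCA needs >= 2 genes, got {len(genes)}")
    codons = [c for fam in code.families.values() if len(fam) >= 2 for c in fam]
    codons.sort()
    if gene_ids is None:
        gene_ids = [f"gene{i}" for i in range(len(genes))]
    mat = np.full((len(genes), len(codons)), np.nan)
    for i, g in enumerate(genes):
        for j, c in enumerate(codons):
            v = g.get(c)
            if v is not None:
                mat[i, j] = v
    n_missing = int(np.isnan(mat).sum())
    if n_missing:
        logger.info("RSCU PCA: imputing %d missing entries with column means", n_missing)
        col_means = np.nanmean(np.where(np.isnan(mat), np.nan, mat), axis=0)
        col_means = np.where(np.isnan(col_means), 0.0, col_means)
        idx = np.where(np.isnan(mat))
        mat[idx] = col_means[idx[1]]
    centered = mat - mat.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = u * s
    loadings = vt.T
    total_var = (s**2).sum()
    var_frac = (s**2) / total_var if total_var > 0 else np.zeros_like(s)
    # sign convention: largest-|loading| entry positive per component
    for j in range(loadings.shape[1]):
        imax = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[imax, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(
        gene_ids=list(gene_ids),
        codons=codons,
        scores=scores,
        loadings=loadings,
        variance_fractions=var_frac,
    )


# --------------------------------------------------------------------------- #
# HGT screen
# --------------------------------------------------------------------------- #

@dataclass
class HGTScreenReport:
    """Comparative codon-usage report for a gene family vs its host genome.

    The verdict is descriptive only: it states whether the family's codon
    usage is consistent with the background genome's, it does not assert a
    transfer event.
    """

    table: pd.DataFrame              # per-gene ENc/GC3s/PR2/GC12/GC3 + set label
    neutrality: NeutralityFit        # fitted on the background set
    pca: PCAResult                   # family + background combined
    enc_pvalue: float
    gc3s_pvalue: float
    verdict: str
    alpha: float = 0.01

    @property
    def is_outlier(self) -> bool:
        return self.gc3s_pvalue < self.alpha or self.enc_pvalue < self.alpha


def _stats_frame(stats: Sequence[CUBStats], label: str) -> pd.DataFrame:
    rows = []
    for st in stats:
        rows.append(
            {
                "gene_id": st.gene_id,
                "set": label,
                "n_codons": st.n_codons,
                "enc": st.enc,
                "gc3s": st.gc3s,
                "enc_expected": enc_expected(st.gc3s) if st.gc3s is not None else None,
                "gc12": st.gc12,
                "gc3": st.gc3,
                "pr2_at_bias": st.pr2.at_bias,
                "pr2_gc_bias": st.pr2.gc_bias,
            }
        )
    return pd.DataFrame(rows)


def hgt_screen(
    family_genes: Sequence[CodingSequence],
    background_genes: Sequence[CodingSequence],
    alpha: float = 0.01,
    min_codons: int = SHORT_GENE_EXCLUDE,
) -> HGTScreenReport:
    """Compare a gene family's codon usage against a background gene set.

    Computes per-gene CUB statistics for both sets, Wright-curve expected
    values, PR2 points, a neutrality fit over the background, a combined
    RSCU PCA with family genes flagged, and two-sample rank-sum
    (Mann-Whitney, exact for small samples) comparisons of family vs
    background ENc and GC3s.
    """
    if not family_genes:
        raise ValueError("family gene set is empty")
    if not background_genes:
        raise ValueError("background gene set is empty")
    family_genes = [g for g in family_genes if g.n_codons >= min_codons]
    background_genes = [g for g in background_genes if g.n_codons >= min_codons]
    if not family_genes or not background_genes:
        raise ValueError(f"no genes with >= {min_codons} codons left to compare")
    fam_stats = [compute_stats(g) for g in family_genes]
    bg_stats = [compute_stats(g) for g in background_genes]
    table = pd.concat(
        [_stats_frame(fam_stats, "family"), _stats_frame(bg_stats, "background")],
        ignore_index=True,
    )
    fit = neutrality_fit(bg_stats)
    all_stats = fam_stats + bg_stats
    pca = rscu_pca(
        [s.rscu for s in all_stats],
        code=family_genes[0].code,
        gene_ids=[s.gene_id for s in all_stats],
    )

    def _ranksum(attr: str) -> float:
        fam = [getattr(s, attr) for s in fam_stats if getattr(s, attr) is not None]
        bg = [getattr(s, attr) for s in bg_stats if getattr(s, attr) is not None]
        if not fam or not bg:
            return float("nan")
        res = scipy_stats.mannwhitneyu(fam, bg, alternative="two-sided", method="auto")
        return float(res.pvalue)

    enc_p = _ranksum("enc")
    gc3s_p = _ranksum("gc3s")
    outlier = (gc3s_p < alpha) or (enc_p < alpha)
    verdict = (
        "family codon usage is a CUB outlier relative to the background genome"
        if outlier
        else "family codon usage is consistent with host genome CUB"
    )
    return HGTScreenReport(
        table=table,
        neutrality=fit,
        pca=pca,
        enc_pvalue=enc_p,
        gc3s_pvalue=gc3s_p,
        verdict=verdict,
        alpha=alpha,
    )
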