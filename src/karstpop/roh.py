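"""Run-of-homozygosity detection with sliding 20-SNP window rules,
f_ROH summaries, gene-overlap fractions, and the excess-homozygosity
inbreeding coefficient F.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Tuple

import numpy as np

from karstpop.datatypes import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GeneModel,
    GenotypeMatrix,
    PopulationMap,
    ROHParams,
    ROHSegment,
    VariantTable,
)

logger = logging.getLogger(__name__)


def detect_roh(
    individual: str,
    matrix: GenotypeMatrix,
    table: VariantTable,
    params: Optional[ROHParams] = None,
) -> list:
    """Detect runs of homozygosity for one individual.

    Rules, applied per chromosome over position-sorted SNPs:

    1. slide a ``window_snps`` window one SNP at a time; a window is
       "homozygous" when it holds at most ``max_het_per_window`` het calls
       and at most ``effective_max_missing`` missing calls;
    2. each SNP's hit rate is the fraction of windows containing it that
       are homozygous; a SNP is in-run when hit rate >= threshold;
    3. maximal stretches of in-run SNPs are split at inter-SNP gaps larger
       than ``max_gap_kb``, then filtered by the segment minima
       (``min_segment_snps``, ``min_segment_kb``) and the density rule
       (>= 1 SNP per ``min_density_kb_per_snp`` kb on average).

    Segment boundaries are the positions of the first and last in-run SNP.
    """
    if params is None:
        params = ROHParams()
    j = matrix.sample_index(individual)
    codes = matrix.codes[:, j]
    segments = []
    for c in dict.fromkeys(table.chrom.astype(str)):
        sel = np.nonzero(table.chrom == c)[0]
        p = table.pos[sel]
        order = np.argsort(p, kind="stable")
        p = p[order]
        g = codes[sel][order]
        segments.extend(_detect_roh_chrom(c, p, g, params))
    return segments


def _detect_roh_chrom(chrom: str, pos: np.ndarray, codes: np.ndarray,
                      params: ROHParams) -> list:
    n = len(pos)
    w = params.window_snps
    if n < w:
        logger.info("chromosome %s has %d < %d SNPs; no segments", chrom, n, w)
        return []
    het = (codes == HET).astype(np.int64)
    miss = (codes == MISSING).astype(np.int64)
    chet = np.concatenate([[0], np.cumsum(het)])
    cmiss = np.concatenate([[0], np.cumsum(miss)])
    n_win = n - w + 1
    starts = np.arange(n_win)
    win_het = chet[starts + w] - chet[starts]
    win_miss = cmiss[starts + w] - cmiss[starts]
    win_ok = (win_het <= params.max_het_per_window) & (
        win_miss <= params.effective_max_missing
    )
    cok = np.concatenate([[0], np.cumsum(win_ok.astype(np.int64))])
    idx = np.arange(n)
    lo = np.maximum(0, idx - w + 1)
    hi = np.minimum(idx, n_win - 1)
    n_containing = hi - lo + 1
    n_hit = cok[hi + 1] - cok[lo]
    in_run = n_hit / n_containing >= params.window_hit_threshold

    segments = []
    max_gap = params.max_gap_kb * 1000.0
    i = 0
    while i < n:
        if not in_run[i]:
            i += 1
            continue
        start = i
        k = i
        while k + 1 < n and in_run[k + 1] and (pos[k + 1] - pos[k]) <= max_gap:
            k += 1
        n_snps = k - start + 1
        length_bp = int(pos[k] - pos[start] + 1)
        if (
            n_snps >= params.min_segment_snps
            and length_bp / 1000.0 >= params.min_segment_kb
            and length_bp / 1000.0 / n_snps <= params.min_density_kb_per_snp
        ):
            segments.append(
                ROHSegment(
                    chrom=chrom,
                    start=int(pos[start]),
                    end=int(pos[k]),
                    n_snps=n_snps,
                )
            )
        i = k + 1
    return segments


def f_roh(
    segments: Sequence[ROHSegment],
    genome_length_bp: int,
    per_chrom: bool = False,
    chrom_lengths: Optional[dict] = None,
):
    """Fraction of the genome covered by ROH segments.

    With ``per_chrom=True`` (requires ``chrom_lengths``) a dict of
    per-chromosome fractions is returned instead.  Overlapping segments
    violate the caller contract and raise.
    """
    by_chrom: dict = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for c, segs in by_chrom.items():
        segs.sort(key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping ROH segments on {c}: "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )
    if per_chrom:
        if chrom_lengths is None:
            raise ValueError("per_chrom=True requires chrom_lengths")
        return {
            c: sum(s.length_bp for s in by_chrom.get(c, [])) / length
            for c, length in chrom_lengths.items()
        }
    total = sum(s.length_bp for segs in by_chrom.values() for s in segs)
    return total / genome_length_bp


def genes_in_roh_fraction(
    segments: Sequence[ROHSegment],
    gene_model: GeneModel,
    min_overlap_fraction: float = 0.5,
) -> float:
    """Fraction of genes overlapped by ROH segments over at least
    ``min_overlap_fraction`` of their span."""
    if len(gene_model) == 0:
        return 0.0
    by_chrom: dict = {}
    for seg in segments:
        # segment interval as half-open 0-based
        by_chrom.setdefault(seg.chrom, []).append((seg.start - 1, seg.end))
    for segs in by_chrom.values():
        segs.sort()
    n_in = 0
    for g in gene_model:
        overlap = 0
        for a, b in by_chrom.get(g.chrom, []):
            overlap += max(0, min(b, g.end) - max(a, g.start))
        if g.length > 0 and overlap / g.length >= min_overlap_fraction:
            n_in += 1
    return n_in / len(gene_model)


def excess_hom_F(
    individual: str,
    matrix: GenotypeMatrix,
    table: Optional[VariantTable] = None,
) -> Optional[float]:
    """Excess-homozygosity inbreeding coefficient

    F = (observed hom - expected hom) / (total called - expected hom),

    with expected homozygosity per site ``1 - 2p(1-p) * n/(n-1)`` from the
    full-sample alt-allele frequency (small-sample corrected).  Only sites
    called in the individual contribute.  Returns ``None`` when total
    equals expected (undefined, flagged).
    """
    j = matrix.sample_index(individual)
    codes = matrix.codes
    own = codes[:, j]
    called_mask = own != MISSING

    n_alleles = 2 * (codes != MISSING).sum(axis=1)
    alt = np.where(codes == HET, 1, 0).sum(axis=1) + 2 * np.where(
        codes == HOM_ALT, 1, 0
    ).sum(axis=1)
    usable = called_mask & (n_alleles >= 2)
    n = n_alleles[usable].astype(float)
    p = alt[usable] / n
    e_hom = float(np.sum(1.0 - 2.0 * p * (1.0 - p) * n / (n - 1.0)))
    o_hom = int(np.sum((own[usable] == HOM_REF) | (own[usable] == HOM_ALT)))
    total = int(usable.sum())
    if total == e_hom:
        logger.warning("excess_hom_F undefined for %s (total == expected)",
                       individual)
        return None
    return (o_hom - e_hom) / (total - e_hom)
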