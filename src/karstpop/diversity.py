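"""Nucleotide diversity, heterozygosity rates, NS/S ratios and kinship.

Window diversity uses the fixed window size as denominator (the convention
of the standard VCF tooling); population diversity is frequency-based over
all called alleles, not per-individual.
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
    VariantTable,
    WindowStat,
)

logger = logging.getLogger(__name__)

KINSHIP_BINS = (
    (0.354, "duplicate/MZ"),
    (0.177, "1st-degree"),
    (0.0884, "2nd-degree"),
    (0.0442, "3rd-degree"),
)


def site_pi(n_called_alleles: int, n_alt_alleles: int) -> float:
    """Per-site nucleotide diversity 2*j*(n-j) / (n*(n-1)).

    Equals the average pairwise difference over all pairs of called
    haplotypes.  Requires at least two called alleles.
    """
    n, j = n_called_alleles, n_alt_alleles
    if not 0 <= j <= n:
        raise ValueError("need 0 <= n_alt <= n_called")
    if n < 2:
        raise ValueError("site_pi needs >= 2 called alleles")
    return 2.0 * j * (n - j) / (n * (n - 1))


def population_site_pi(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    population: str,
) -> np.ndarray:
    """Vector of per-site pi values for one population.

    Sites with fewer than two called alleles get NaN (skipped, logged).
    """
    idx = popmap.indices(matrix.samples, population)
    codes = matrix.codes[:, idx]
    called = (codes != MISSING).sum(axis=1) * 2
    alt = np.where(codes == HET, 1, 0).sum(axis=1) + np.where(
        codes == HOM_ALT, 2, 0
    ).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * alt * (called - alt) / (called * (called - 1.0))
    skipped = called < 2
    if skipped.any():
        logger.info("population_site_pi: skipping %d sites with <2 called alleles",
                    int(skipped.sum()))
    pi[skipped] = np.nan
    return pi


def windowed_pi(
    chrom: np.ndarray,
    pos: np.ndarray,
    pi_values: np.ndarray,
    window_bp: int = 50_000,
    chrom_lengths: Optional[dict] = None,
) -> list:
    """Non-overlapping windowed diversity: per window, sum of per-site pi
    divided by the window size (per-bp; multiply by 100 for percent).

    Empty windows report 0 with ``n_variable_sites = 0``.  NaN site values
    (uncallable sites) are ignored.
    """
    out = []
    for c in dict.fromkeys(chrom.astype(str)):
        sel = chrom == c
        p = pos[sel]
        v = pi_values[sel]
        length = (
            chrom_lengths[c]
            if chrom_lengths and c in chrom_lengths
            else int(p.max()) if len(p) else 0
        )
        n_windows = (length + window_bp - 1) // window_bp
        win = (p - 1) // window_bp
        for w in range(n_windows):
            in_w = win == w
            vals = v[in_w]
            ok = ~np.isnan(vals)
            out.append(
                WindowStat(
                    chrom=c,
                    start=w * window_bp,
                    end=(w + 1) * window_bp,
                    n_variable_sites=int((vals[ok] > 0).sum()),
                    value=float(vals[ok].sum()) / window_bp,
                )
            )
    return out


def heterozygosity_rate(
    individual: str,
    matrix: GenotypeMatrix,
    table: Optional[VariantTable] = None,
    gene_model: Optional[GeneModel] = None,
    callable_length: Optional[int] = None,
    coding_callable_length: Optional[int] = None,
) -> dict:
    """Heterozygous sites per 1000 bp for one individual.

    Returns ``{"overall": rate, "coding": rate-or-None,
    "noncoding": rate-or-None}``; coding strata require a gene model and a
    variant table.  A stratum with zero callable length is flagged ``None``.
    """
    j = matrix.sample_index(individual)
    het = matrix.codes[:, j] == HET
    overall_callable = (
        callable_length
        if callable_length is not None
        else int(matrix.callable_length[j])
    )
    if overall_callable <= 0:
        raise ValueError("callable_length must be positive")
    result = {"overall": float(het.sum()) / overall_callable * 1000.0}
    result["coding"] = None
    result["noncoding"] = None
    if gene_model is not None and table is not None:
        cds = gene_model.cds_mask(table.chrom, table.pos)
        if coding_callable_length is None:
            coding_callable_length = sum(
                g.cds_end - g.cds_start for g in gene_model
            )
        noncoding_callable = overall_callable - coding_callable_length
        if coding_callable_length > 0:
            result["coding"] = (
                float(het[cds].sum()) / coding_callable_length * 1000.0
            )
        else:
            logger.warning("zero coding callable length for %s", individual)
        if noncoding_callable > 0:
            result["noncoding"] = (
                float(het[~cds].sum()) / noncoding_callable * 1000.0
            )
        else:
            logger.warning("zero non-coding callable length for %s", individual)
    return result


def ns_s_ratio(
    individual: str,
    matrix: GenotypeMatrix,
    table: VariantTable,
) -> Optional[float]:
    """Ratio of sites carrying >= 1 alt allele that are non-synonymous vs
    synonymous (most severe annotation represents the site).

    Returns ``None`` (flagged undefined) when the synonymous count is 0.
    """
    j = matrix.sample_index(individual)
    carries = (matrix.codes[:, j] == HET) | (matrix.codes[:, j] == HOM_ALT)
    classes = table.site_coding_classes()
    ns = int(np.sum(carries & (classes == "non_synonymous")))
    s = int(np.sum(carries & (classes == "synonymous")))
    if s == 0:
        logger.warning("ns_s_ratio undefined for %s: zero synonymous sites",
                       individual)
        return None
    return ns / s


def classify_kinship(phi: float) -> str:
    """Bin a kinship coefficient into the published degree classes."""
    if phi > KINSHIP_BINS[0][0]:
        return KINSHIP_BINS[0][1]
    for bound, label in KINSHIP_BINS[1:]:
        if phi >= bound:
            return label
    return "unrelated/>3rd-degree"


def king_kinship(
    individual_i: str,
    individual_j: str,
    matrix: GenotypeMatrix,
    min_sites: int = 100,
) -> Tuple[Optional[float], Optional[str], bool]:
    """Within-population kinship coefficient between two individuals.

    phi = (N_het,het - 2 * N_opposing_hom) / (N_het(i) + N_het(j)) over
    jointly called sites.  Returns ``(phi, degree_class, low_confidence)``;
    phi is ``None`` when the denominator is zero.
    """
    a = matrix.codes[:, matrix.sample_index(individual_i)]
    b = matrix.codes[:, matrix.sample_index(individual_j)]
    joint = (a != MISSING) & (b != MISSING)
    low_confidence = int(joint.sum()) < min_sites
    if low_confidence:
        logger.warning(
            "king_kinship: only %d jointly called sites for (%s, %s)",
            int(joint.sum()), individual_i, individual_j,
        )
    het_het = int(np.sum(joint & (a == HET) & (b == HET)))
    opposing = int(
        np.sum(
            joint
            & (((a == HOM_REF) & (b == HOM_ALT)) | ((a == HOM_ALT) & (b == HOM_REF)))
        )
    )
    n_het_i = int(np.sum(joint & (a == HET)))
    n_het_j = int(np.sum(joint & (b == HET)))
    denom = n_het_i + n_het_j
    if denom == 0:
        return None, None, low_confidence
    phi = (het_het - 2.0 * opposing) / denom
    return phi, classify_kinship(phi), low_confidence
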