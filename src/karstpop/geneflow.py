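"""ABBA-BABA D-statistics over population quartets with block-jackknife
significance.

Pattern sums are frequency-weighted over all called alleles per population
(population-mode computation); the outgroup polarizes the derived allele,
and sites where the outgroup is heterozygous, uncalled or polymorphic are
skipped.
"""

from __future__ import annotations

import logging
from typing import Optional, Tuple

import numpy as np

from karstpop.datatypes import (
    HET,
    HOM_ALT,
    MISSING,
    DStatResult,
    GenotypeMatrix,
    PopulationMap,
    SitePatternCounts,
    VariantTable,
)
from karstpop.load import polarize_derived

logger = logging.getLogger(__name__)

DEFAULT_BLOCK_SIZE = 5_000_000
MIN_BLOCKS = 10


def site_pattern_weights(
    p1: float, p2: float, p3: float, p_o: float
) -> Tuple[float, float]:
    """Frequency-weighted ABBA and BABA weights for one site.

    abba = (1-p1) * p2 * p3 * (1-pO); baba = p1 * (1-p2) * p3 * (1-pO),
    with derived-allele frequencies per population.
    """
    for name, p in (("p1", p1), ("p2", p2), ("p3", p3), ("pO", p_o)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    abba = (1.0 - p1) * p2 * p3 * (1.0 - p_o)
    baba = p1 * (1.0 - p2) * p3 * (1.0 - p_o)
    return abba, baba


def d_statistic(counts: SitePatternCounts) -> float:
    """D = (ABBA - BABA) / (ABBA + BABA); undefined when the denominator
    is zero."""
    total = counts.abba + counts.baba
    if total == 0:
        raise ValueError("d_statistic undefined: abba + baba == 0")
    return (counts.abba - counts.baba) / total


def _derived_freqs(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    population: str,
    derived: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-site derived-allele frequency and called-allele count for one
    population, given the polarization vector."""
    idx = popmap.indices(matrix.samples, population)
    codes = matrix.codes[:, idx]
    called = 2 * (codes != MISSING).sum(axis=1)
    alt = np.where(codes == HET, 1, 0).sum(axis=1) + 2 * np.where(
        codes == HOM_ALT, 1, 0
    ).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_alt = alt / called
    freq = np.where(derived == "alt", p_alt, 1.0 - p_alt)
    return freq, called


def site_pattern_counts(
    table: VariantTable,
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    quartet: Tuple[str, str, str, str],
    block_size_bp: int = DEFAULT_BLOCK_SIZE,
) -> SitePatternCounts:
    """Accumulate frequency-weighted ABBA/BABA sums over all usable sites,
    keeping per-block partial sums keyed by (chrom, block index).

    A site is skipped when any quartet population has zero called alleles
    or the outgroup does not polarize it.
    """
    p1_pop, p2_pop, p3_pop, out_pop = quartet
    if popmap.roles.get(out_pop) != "outgroup":
        logger.warning("quartet outgroup %r is not flagged outgroup in the "
                       "population map", out_pop)
    derived = polarize_derived(table, matrix, popmap)
    usable = derived != None  # noqa: E711
    freqs = {}
    for pop in quartet:
        f, called = _derived_freqs(matrix, popmap, pop, derived)
        freqs[pop] = f
        usable &= called > 0
    idx = np.nonzero(usable)[0]
    p1 = freqs[p1_pop][idx]
    p2 = freqs[p2_pop][idx]
    p3 = freqs[p3_pop][idx]
    p_o = freqs[out_pop][idx]
    abba = (1.0 - p1) * p2 * p3 * (1.0 - p_o)
    baba = p1 * (1.0 - p2) * p3 * (1.0 - p_o)
    informative = (abba + baba) > 0

    block_abba: dict = {}
    block_baba: dict = {}
    chroms = table.chrom[idx].astype(str)
    blocks = (table.pos[idx] - 1) // block_size_bp
    chrom_names, chrom_codes = np.unique(chroms, return_inverse=True)
    combined = chrom_codes * (int(blocks.max()) + 1 if len(blocks) else 1) + blocks
    uniq, inverse = np.unique(combined, return_inverse=True)
    abba_sums = np.bincount(inverse, weights=abba)
    baba_sums = np.bincount(inverse, weights=baba)
    for u, a_sum, b_sum in zip(uniq, abba_sums, baba_sums):
        span = int(blocks.max()) + 1 if len(blocks) else 1
        key = (str(chrom_names[u // span]), int(u % span))
        block_abba[key] = float(a_sum)
        block_baba[key] = float(b_sum)
    return SitePatternCounts(
        abba=float(abba.sum()),
        baba=float(baba.sum()),
        n_informative_sites=int(informative.sum()),
        block_abba=block_abba,
        block_baba=block_baba,
    )


def block_jackknife(counts: SitePatternCounts) -> Tuple[float, float]:
    """Delete-one-block jackknife standard error and Z for D.

    Requires >= 10 non-empty blocks; the caller should shrink the block
    size otherwise.  All-identical blocks give se = 0 and an infinite Z
    (flagged by the caller).
    """
    keys = sorted(counts.block_abba)
    n_blocks = len(keys)
    if n_blocks < MIN_BLOCKS:
        raise ValueError(
            f"block jackknife needs >= {MIN_BLOCKS} non-empty blocks, got "
            f"{n_blocks}; use a smaller block size"
        )
    abba_total = counts.abba
    baba_total = counts.baba
    d_full = d_statistic(counts)
    d_minus = np.empty(n_blocks)
    for i, key in enumerate(keys):
        a = abba_total - counts.block_abba[key]
        b = baba_total - counts.block_baba[key]
        if a + b == 0:
            raise ValueError("delete-one D undefined for a block")
        d_minus[i] = (a - b) / (a + b)
    mean = d_minus.mean()
    se = float(np.sqrt((n_blocks - 1) / n_blocks * np.sum((d_minus - mean) ** 2)))
    z = d_full / se if se > 0 else float("inf") * np.sign(d_full or 1.0)
    return se, float(z)


def compute_dstat(
    table: VariantTable,
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    quartet: Tuple[str, str, str, str],
    block_size_bp: int = DEFAULT_BLOCK_SIZE,
) -> DStatResult:
    """Full D-statistic for one quartet: pattern sums, D, jackknife se, Z."""
    counts = site_pattern_counts(table, matrix, popmap, quartet, block_size_bp)
    d = d_statistic(counts)
    se, z = block_jackknife(counts)
    return DStatResult(
        p1=quartet[0],
        p2=quartet[1],
        p3=quartet[2],
        outgroup=quartet[3],
        d=d,
        jackknife_se=se,
        z=z,
        n_blocks=len(counts.block_abba),
        n_informative_sites=counts.n_informative_sites,
    )
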