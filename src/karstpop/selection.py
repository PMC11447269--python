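"""Selection scans and variant screens: windowed diversity log-ratio,
cross-population extended haplotype homozygosity (XP-EHH), NG86 Ka/Ks, the
>=2-method sweep consensus, and private / fixed non-synonymous screens.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from karstpop import _codon
from karstpop.datatypes import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GeneModel,
    GenotypeMatrix,
    PopulationMap,
    ScreenHit,
    SweepCall,
    VariantTable,
    WindowStat,
    impact_rank,
)
from karstpop.diversity import population_site_pi

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# haplotype blocks and EHH


@dataclass
class HaplotypeBlock:
    """Phased haplotypes for one region: (n_haplotypes, n_snps) allele
    codes with strictly increasing positions."""

    haplotypes: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        if self.haplotypes.shape[0] % 2 != 0:
            raise ValueError("diploid sets need an even number of haplotypes")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.haplotypes.shape[1] != len(self.positions):
            raise ValueError("haplotype width must match positions")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]


def haplotype_block(
    table: VariantTable,
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    population: str,
    chrom: str,
    rng=None,
) -> HaplotypeBlock:
    """Extract one population's phased haplotypes for a chromosome.

    Unphased input triggers a pseudo-phasing fallback (random phase within
    each individual) with a loud warning; supply ``rng`` for determinism.
    """
    if matrix.haplotypes is None:
        raise ValueError("matrix carries no haplotypes")
    sel = np.nonzero(table.chrom == chrom)[0]
    idx = popmap.indices(matrix.samples, population)
    cols = np.sort(np.concatenate([[2 * j, 2 * j + 1] for j in idx]))
    haps = matrix.haplotypes[np.ix_(sel, cols)].T.copy()
    if not matrix.phased:
        logger.warning(
            "input is UNPHASED: applying random pseudo-phasing within "
            "individuals; haplotype statistics will be noisy"
        )
        rng = rng if rng is not None else np.random.default_rng(0)
        for pair in range(0, haps.shape[0], 2):
            flip = rng.random(haps.shape[1]) < 0.5
            a = haps[pair].copy()
            haps[pair, flip] = haps[pair + 1, flip]
            haps[pair + 1, flip] = a[flip]
    return HaplotypeBlock(haplotypes=haps, positions=table.pos[sel])


@dataclass
class EHHCurve:
    """EHH values aligned with the block's positions; 1.0 at the core."""

    positions: np.ndarray
    values: np.ndarray
    core_index: int


def ehh(block: HaplotypeBlock, core_index: int) -> EHHCurve:
    """Extended haplotype homozygosity decay from a core SNP.

    EHH at SNP x is the fraction of haplotype pairs identical over all
    SNPs strictly between the core and x inclusive of x, computed
    separately in each direction; EHH(core) = 1 by definition.  Requires
    >= 2 haplotypes.
    """
    haps = block.haplotypes
    n = haps.shape[0]
    if n < 2:
        raise ValueError("ehh needs >= 2 haplotypes")
    total_pairs = n * (n - 1) / 2.0
    n_snps = haps.shape[1]
    values = np.zeros(n_snps)
    values[core_index] = 1.0
    for step in (1, -1):
        labels = np.zeros(n, dtype=np.int64)
        k = core_index + step
        while 0 <= k < n_snps:
            # refine identity groups by the allele at SNP k
            combined = labels * (haps[:, k].max() + 2) + haps[:, k]
            _, labels = np.unique(combined, return_inverse=True)
            _, counts = np.unique(labels, return_counts=True)
            values[k] = float((counts * (counts - 1) / 2.0).sum()) / total_pairs
            k += step
    return EHHCurve(positions=block.positions, values=values,
                    core_index=core_index)


def ihh(curve: EHHCurve, cutoff: float = 0.05) -> float:
    """Integrated EHH: trapezoid integral over bp in each direction from
    the core until EHH drops below ``cutoff``; both directions summed."""
    total = 0.0
    pos = curve.positions
    vals = curve.values
    core = curve.core_index
    for step in (1, -1):
        prev_pos = pos[core]
        prev_val = 1.0
        k = core + step
        while 0 <= k < len(pos):
            total += 0.5 * (prev_val + vals[k]) * abs(int(pos[k]) - int(prev_pos))
            if vals[k] < cutoff:
                break
            prev_pos, prev_val = pos[k], vals[k]
            k += step
    return total


def xpehh(
    pop_a_block: HaplotypeBlock,
    pop_b_block: HaplotypeBlock,
    core_index: int,
    cutoff: float = 0.05,
) -> Optional[float]:
    """Raw cross-population score ln(iHH_A / iHH_B) at one core SNP.

    Both blocks must share the SNP grid.  Returns ``None`` (undefined)
    when either integral is zero.
    """
    if len(pop_a_block.positions) != len(pop_b_block.positions) or np.any(
        pop_a_block.positions != pop_b_block.positions
    ):
        raise ValueError("blocks must share the same SNP grid")
    ihh_a = ihh(ehh(pop_a_block, core_index), cutoff)
    ihh_b = ihh(ehh(pop_b_block, core_index), cutoff)
    if ihh_a == 0 or ihh_b == 0:
        return None
    return math.log(ihh_a / ihh_b)


def standardize_scores(
    scores: np.ndarray, outlier_quantile: float = 0.05
) -> Tuple[np.ndarray, np.ndarray]:
    """Z-transform raw scores (NaN entries are excluded from the mean/sd
    and never become outliers) and flag the top ``outlier_quantile`` of the
    upper tail, ties included.

    Returns ``(z_scores, outlier_mask)``.
    """
    scores = np.asarray(scores, dtype=float)
    ok = ~np.isnan(scores)
    if ok.sum() < 2:
        raise ValueError("need >= 2 defined scores to standardize")
    mean = scores[ok].mean()
    sd = scores[ok].std()
    if sd == 0:
        raise ValueError("cannot standardize constant scores")
    z = np.full_like(scores, np.nan)
    z[ok] = (scores[ok] - mean) / sd
    threshold = np.quantile(z[ok], 1.0 - outlier_quantile)
    outliers = ok & (z >= threshold)
    return z, outliers


def _trapezoid_until(core_pos, xs_pos, values, cutoff) -> float:
    """Trapezoid integral from (core_pos, 1.0) through successive points,
    stopping after the first point whose value drops below ``cutoff``."""
    if len(values) == 0:
        return 0.0
    v = np.concatenate([[1.0], values])
    p = np.concatenate([[core_pos], xs_pos]).astype(float)
    areas = 0.5 * (v[:-1] + v[1:]) * np.abs(np.diff(p))
    below = np.nonzero(values < cutoff)[0]
    stop = below[0] + 1 if len(below) else len(values)
    return float(areas[:stop].sum())


def ihh_profile(block: HaplotypeBlock, cutoff: float = 0.05) -> np.ndarray:
    """Integrated EHH at every SNP core of a block.

    Equivalent to ``ihh(ehh(block, i), cutoff)`` for every ``i`` but
    computed from precomputed per-pair mismatch bounds, so whole-genome
    scans stay fast.
    """
    haps = block.haplotypes
    pos = block.positions.astype(np.int64)
    n, s = haps.shape
    if n < 2:
        raise ValueError("ihh_profile needs >= 2 haplotypes")
    ia, ib = np.triu_indices(n, 1)
    diffs = haps[ia] != haps[ib]
    n_pairs = len(ia)
    idx = np.arange(s)
    # nextdiff[:, k]: first mismatch index >= k (sentinel s)
    nextdiff = np.minimum.accumulate(
        np.where(diffs, idx[None, :], s)[:, ::-1], axis=1
    )[:, ::-1]
    # prevdiff[:, k]: last mismatch index <= k (sentinel -1)
    prevdiff = np.maximum.accumulate(np.where(diffs, idx[None, :], -1), axis=1)
    out = np.zeros(s)
    for i in range(s):
        total = 0.0
        if i + 1 < s:
            d = np.sort(nextdiff[:, i + 1])
            xs = idx[i + 1 :]
            values = (n_pairs - np.searchsorted(d, xs, side="right")) / n_pairs
            total += _trapezoid_until(pos[i], pos[xs], values, cutoff)
        if i - 1 >= 0:
            d = np.sort(prevdiff[:, i - 1])
            xs = idx[i - 1 :: -1]
            values = np.searchsorted(d, xs, side="left") / n_pairs
            total += _trapezoid_until(pos[i], pos[xs], values, cutoff)
        out[i] = total
    return out


def xpehh_scan(
    table: VariantTable,
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    candidate: str,
    reference: str,
    cutoff: float = 0.05,
    outlier_quantile: float = 0.05,
    rng=None,
):
    """Score every SNP core with ln(iHH_candidate / iHH_reference),
    Z-transform genome-wide, and return per-site (raw, z, outlier) arrays
    aligned with the table.  Cores where either integral is zero are
    excluded from standardization."""
    raw = np.full(table.n_sites, np.nan)
    for chrom in dict.fromkeys(table.chrom.astype(str)):
        sel = np.nonzero(table.chrom == chrom)[0]
        if len(sel) < 2:
            continue
        cand = haplotype_block(table, matrix, popmap, candidate, chrom, rng)
        ref = haplotype_block(table, matrix, popmap, reference, chrom, rng)
        ihh_a = ihh_profile(cand, cutoff)
        ihh_b = ihh_profile(ref, cutoff)
        ok = (ihh_a > 0) & (ihh_b > 0)
        vals = np.full(len(sel), np.nan)
        vals[ok] = np.log(ihh_a[ok] / ihh_b[ok])
        raw[sel] = vals
    z, outliers = standardize_scores(raw, outlier_quantile)
    return raw, z, outliers


# ---------------------------------------------------------------------------
# windowed diversity ratio


def pi_ratio_windows(
    table: VariantTable,
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    reference: str,
    candidate: str,
    window_bp: int = 40_000,
    step_bp: int = 20_000,
    min_variable: int = 20,
    outlier_quantile: float = 0.05,
    chrom_lengths: Optional[dict] = None,
) -> Tuple[List[WindowStat], List[int]]:
    """Sliding-window ln(pi_reference / pi_candidate).

    The candidate population sits in the denominator, so swept candidate
    windows give large positive values.  Windows with fewer than
    ``min_variable`` variable sites (union of both populations) are
    excluded; a zero candidate diversity in a retained window yields
    ``inf`` and joins the outlier set.  Returns (windows, outlier indices);
    the outlier threshold is inclusive of ties.
    """
    pi_ref = population_site_pi(matrix, popmap, reference)
    pi_cand = population_site_pi(matrix, popmap, candidate)
    variable = (np.nan_to_num(pi_ref) > 0) | (np.nan_to_num(pi_cand) > 0)
    windows: List[WindowStat] = []
    for chrom in dict.fromkeys(table.chrom.astype(str)):
        sel = table.chrom == chrom
        p = table.pos[sel]
        ref_v = np.nan_to_num(pi_ref[sel])
        cand_v = np.nan_to_num(pi_cand[sel])
        var_v = variable[sel]
        length = (
            chrom_lengths[chrom]
            if chrom_lengths and chrom in chrom_lengths
            else (int(p.max()) if len(p) else 0)
        )
        start = 0
        while start < length:
            end = min(start + window_bp, length)
            in_w = (p > start) & (p <= end)
            n_var = int(var_v[in_w].sum())
            if n_var >= min_variable:
                a = float(ref_v[in_w].sum())
                b = float(cand_v[in_w].sum())
                if b == 0 and a == 0:
                    value = float("nan")
                elif b == 0:
                    value = float("inf")
                    logger.warning(
                        "window %s:%d-%d has zero candidate diversity; "
                        "value flagged infinite", chrom, start, end,
                    )
                elif a == 0:
                    value = float("-inf")
                else:
                    value = math.log(a / b)
                if not math.isnan(value):
                    windows.append(
                        WindowStat(
                            chrom=chrom, start=start, end=end,
                            n_variable_sites=n_var, value=value,
                        )
                    )
            if end == length:
                break
            start += step_bp
    values = np.array([w.value for w in windows])
    if len(values) == 0:
        return windows, []
    finite = values[np.isfinite(values)]
    if len(finite) == 0:
        threshold = -math.inf
    else:
        threshold = np.quantile(finite, 1.0 - outlier_quantile)
    outliers = [
        i for i, v in enumerate(values) if v >= threshold or math.isinf(v) and v > 0
    ]
    return windows, outliers


# ---------------------------------------------------------------------------
# Ka/Ks (NG86 with Jukes-Cantor correction)


def _validate_cds(seq: str) -> str:
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for k, codon in enumerate(codons):
        if any(b not in _codon.BASES for b in codon):
            raise ValueError(f"non-ACGT base in codon {codon!r}")
        if _codon.translate(codon) == "*" and k < len(codons) - 1:
            raise ValueError("internal stop codon")
    return seq


def _jukes_cantor(p: float) -> Optional[float]:
    if p == 0:
        return 0.0
    if p >= 0.75:
        logger.warning("proportion %.3f >= 0.75: corrected distance "
                       "undefined (saturation)", p)
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def kaks_ng86(cds_a: str, cds_b: str):
    """NG86 Ka, Ks and their ratio for two aligned CDS sequences.

    Synonymous/non-synonymous site counts are averaged over the two
    sequences; observed differences are averaged over shortest mutational
    paths; proportions are Jukes-Cantor corrected.  The ratio is ``None``
    when Ks is 0 or a distance saturates.
    """
    a = _validate_cds(cds_a)
    b = _validate_cds(cds_b)
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    syn_sites_a = syn_sites_b = 0.0
    syn_diff = nonsyn_diff = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        sa, _ = _codon.syn_nonsyn_site_fractions(ca)
        sb, _ = _codon.syn_nonsyn_site_fractions(cb)
        syn_sites_a += sa
        syn_sites_b += sb
        sd, nd = _codon.count_syn_nonsyn_differences(ca, cb)
        syn_diff += sd
        nonsyn_diff += nd
    s_sites = (syn_sites_a + syn_sites_b) / 2.0
    n_sites = len(a) - s_sites
    ps = syn_diff / s_sites if s_sites > 0 else 0.0
    pn = nonsyn_diff / n_sites if n_sites > 0 else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    if ka is None or ks is None or ks == 0:
        ratio = None
    else:
        ratio = ka / ks
    return ka, ks, ratio


def kaks_gene_flags(
    seq_pairs: Dict[str, Tuple[str, str]], ratio_threshold: float = 1.0
) -> set:
    """Flag genes whose NG86 Ka/Ks exceeds ``ratio_threshold`` (undefined
    ratios never flag)."""
    flagged = set()
    for gene, (cds_a, cds_b) in seq_pairs.items():
        _, _, ratio = kaks_ng86(cds_a, cds_b)
        if ratio is not None and ratio > ratio_threshold:
            flagged.add(gene)
    return flagged


# ---------------------------------------------------------------------------
# consensus and screens


def consensus_sweep(
    method_windows: Dict[str, Iterable],
    gene_model: GeneModel,
) -> List[SweepCall]:
    """Combine per-method flagged windows/genes into per-gene sweep calls.

    Each method maps to an iterable of flagged ``(chrom, start, end)``
    half-open windows (any bp overlap flags a gene) or plain gene ids.
    Consensus is true iff >= 2 methods flag the gene.
    """
    per_method_genes: Dict[str, set] = {}
    for method, flagged in method_windows.items():
        genes = set()
        for item in flagged:
            if isinstance(item, str):
                genes.add(item)
                continue
            chrom, start, end = item
            for g in gene_model:
                if g.chrom == chrom and g.start < end and start < g.end:
                    genes.add(g.gene_id)
        per_method_genes[method] = genes
    calls = []
    for g in gene_model:
        flags = {
            method: g.gene_id in genes
            for method, genes in per_method_genes.items()
        }
        calls.append(SweepCall(gene_id=g.gene_id, flags=flags))
    return calls


def _background_alt_freq(codes_row, bg_idx) -> Optional[float]:
    alt = called = 0
    for j in bg_idx:
        c = int(codes_row[j])
        if c == MISSING:
            continue
        called += 2
        alt += {HOM_REF: 0, HET: 1, HOM_ALT: 2}[c]
    return alt / called if called else None


def private_nonsyn_screen(
    table: VariantTable,
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    target_population: str,
    mode: str = "private",
    max_background_freq: float = 0.2895,
    candidate_genes: Optional[Sequence[str]] = None,
) -> List[ScreenHit]:
    """Non-synonymous variants homozygous-alternate in every target
    individual and absent (mode ``private``) or rare (mode ``fixed``,
    background frequency <= ``max_background_freq``, boundary inclusive)
    in the background populations.

    Sites with any uncalled target individual are ineligible.  The most
    severe annotation represents each site.
    """
    if mode not in ("private", "fixed"):
        raise ValueError("mode must be 'private' or 'fixed'")
    tgt_idx = popmap.indices(matrix.samples, target_population)
    if len(tgt_idx) == 0:
        raise ValueError(f"no individuals in population {target_population!r}")
    bg_idx = np.concatenate(
        [popmap.indices(matrix.samples, p) for p in popmap.backgrounds()]
    ) if popmap.backgrounds() else np.array([], dtype=int)
    gene_filter = set(candidate_genes) if candidate_genes is not None else None
    hits: List[ScreenHit] = []
    for i in range(table.n_sites):
        effs = table.effects[i]
        if not effs:
            continue
        worst = max(effs, key=lambda e: impact_rank(e.impact_category))
        if worst.coding_class != "non_synonymous":
            continue
        if gene_filter is not None and worst.gene_id not in gene_filter:
            continue
        tgt = matrix.codes[i, tgt_idx]
        if np.any(tgt == MISSING) or not np.all(tgt == HOM_ALT):
            continue
        bg_freq = _background_alt_freq(matrix.codes[i], bg_idx)
        bg_freq = 0.0 if bg_freq is None else bg_freq
        if mode == "private" and bg_freq != 0.0:
            continue
        if mode == "fixed" and bg_freq > max_background_freq:
            continue
        hits.append(
            ScreenHit(
                gene_id=worst.gene_id,
                chrom=str(table.chrom[i]),
                pos=int(table.pos[i]),
                ref=str(table.ref[i]),
                alt=str(table.alt[i]),
                tier="private" if bg_freq == 0.0 else "fixed_with_background",
                background_max_freq=bg_freq,
                stop_gained=any(e.effect_term == "stop_gained" for e in effs),
            )
        )
    return hits


def stop_gained_screen(
    table: VariantTable,
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    target_population: str,
    candidate_genes: Optional[Sequence[str]] = None,
) -> List[ScreenHit]:
    """Premature-stop variants homozygous-alternate in every target
    individual, optionally restricted to a candidate gene list."""
    tgt_idx = popmap.indices(matrix.samples, target_population)
    bg_idx = np.concatenate(
        [popmap.indices(matrix.samples, p) for p in popmap.backgrounds()]
    ) if popmap.backgrounds() else np.array([], dtype=int)
    gene_filter = set(candidate_genes) if candidate_genes is not None else None
    hits: List[ScreenHit] = []
    for i in range(table.n_sites):
        stop_annotations = [
            e for e in table.effects[i] if e.effect_term == "stop_gained"
        ]
        if not stop_annotations:
            continue
        gene = stop_annotations[0].gene_id
        if gene_filter is not None and gene not in gene_filter:
            continue
        tgt = matrix.codes[i, tgt_idx]
        if np.any(tgt == MISSING) or not np.all(tgt == HOM_ALT):
            continue
        bg_freq = _background_alt_freq(matrix.codes[i], bg_idx)
        bg_freq = 0.0 if bg_freq is None else bg_freq
        hits.append(
            ScreenHit(
                gene_id=gene,
                chrom=str(table.chrom[i]),
                pos=int(table.pos[i]),
                ref=str(table.ref[i]),
                alt=str(table.alt[i]),
                tier="private" if bg_freq == 0.0 else "fixed_with_background",
                background_max_freq=bg_freq,
                stop_gained=True,
            )
        )
    return hits
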