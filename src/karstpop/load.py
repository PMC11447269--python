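"""Conservation-score-based genetic load: outgroup polarization, the
shared-monomorphic-site filter, masked vs realized load, effect-category
genotype proportions, and one-way ANOVA comparisons between populations.

"Masked" load sums the conservation scores of deleterious derived alleles
carried heterozygously; "realized" load sums them for homozygous derived
genotypes; both are divided by the individual's number of called genotypes
in the analysis set (one shared denominator by default).
"""

from __future__ import annotations

import itertools
import logging
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from karstpop.datatypes import (
    HET,
    HOM_ALT,
    HOM_REF,
    IMPACT_CATEGORIES,
    MISSING,
    GenotypeMatrix,
    LoadReport,
    PopulationMap,
    VariantTable,
)

logger = logging.getLogger(__name__)

DEFAULT_GERP_THRESHOLD = 4.0


def polarize_derived(
    table: VariantTable,
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
) -> np.ndarray:
    """Per-site derived allele from the outgroup genotypes.

    Returns an object array with entries ``"ref"``, ``"alt"`` or ``None``
    (excluded: outgroup het, missing everywhere, or polymorphic).
    """
    out_pop = popmap.outgroup()
    if out_pop is None:
        raise ValueError("population map defines no outgroup")
    idx = popmap.indices(matrix.samples, out_pop)
    codes = matrix.codes[:, idx]
    called = codes != MISSING
    n_called = called.sum(axis=1)
    any_het = ((codes == HET) & called).any(axis=1)
    all_ref = ((codes == HOM_REF) | ~called).all(axis=1)
    all_alt = ((codes == HOM_ALT) | ~called).all(axis=1)
    derived = np.full(table.n_sites, None, dtype=object)
    ok = (n_called > 0) & ~any_het
    derived[ok & all_ref] = "alt"
    derived[ok & all_alt] = "ref"
    n_excluded = int((derived == None).sum())  # noqa: E711
    logger.info("polarize_derived: %d of %d sites excluded",
                n_excluded, table.n_sites)
    return derived


def shared_site_filter(
    table: VariantTable,
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    species_set: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Indices of sites retained after removing positions where every
    called individual across ``species_set`` is homozygous for the same
    allele (sites with no calls at all are likewise dropped)."""
    if species_set is None:
        species_set = [popmap.target()] + popmap.backgrounds()
    idx = np.concatenate(
        [popmap.indices(matrix.samples, pop) for pop in species_set]
    )
    codes = matrix.codes[:, idx]
    called = codes != MISSING
    n_called = called.sum(axis=1)
    all_ref = ((codes == HOM_REF) | ~called).all(axis=1)
    all_alt = ((codes == HOM_ALT) | ~called).all(axis=1)
    shared = (n_called == 0) | ((n_called > 0) & (all_ref | all_alt))
    keep = np.nonzero(~shared)[0]
    logger.info("shared_site_filter: removed %d of %d sites",
                table.n_sites - len(keep), table.n_sites)
    return keep


def genetic_load(
    individual: str,
    matrix: GenotypeMatrix,
    table: VariantTable,
    derived: np.ndarray,
    gerp_threshold: float = DEFAULT_GERP_THRESHOLD,
    realized_denominator: Optional[int] = None,
) -> Tuple[float, float, int]:
    """Masked and realized load for one individual.

    ``derived`` is the polarization vector from :func:`polarize_derived`;
    sites with ``None`` are excluded.  Returns ``(masked, realized,
    n_called)``; both loads share the per-individual called-genotype
    denominator unless ``realized_denominator`` overrides it.
    """
    j = matrix.sample_index(individual)
    codes = matrix.codes[:, j]
    eligible = derived != None  # noqa: E711
    called = eligible & (codes != MISSING)
    n_called = int(called.sum())
    if n_called == 0:
        logger.warning("genetic_load undefined for %s: no called genotypes",
                       individual)
        return float("nan"), float("nan"), 0
    with np.errstate(invalid="ignore"):
        deleterious = table.gerp >= gerp_threshold
    hom_derived_code = np.where(derived == "alt", HOM_ALT, HOM_REF)
    masked_sum = float(table.gerp[called & deleterious & (codes == HET)].sum())
    realized_sum = float(
        table.gerp[called & deleterious & (codes == hom_derived_code)].sum()
    )
    denom_r = realized_denominator if realized_denominator else n_called
    return masked_sum / n_called, realized_sum / denom_r, n_called


def effect_category_proportions(
    individual: str,
    matrix: GenotypeMatrix,
    table: VariantTable,
    mode: str = "all",
    n_called: Optional[int] = None,
) -> dict:
    """Per-impact-category fraction of called genotypes carrying the
    annotated (alt) allele.

    ``mode="all"`` counts het and hom-alt genotypes; ``mode="homozygous_only"``
    counts hom-alt only.  The most severe annotation represents each site.
    """
    if mode not in ("all", "homozygous_only"):
        raise ValueError("mode must be 'all' or 'homozygous_only'")
    j = matrix.sample_index(individual)
    codes = matrix.codes[:, j]
    if n_called is None:
        n_called = int((codes != MISSING).sum())
    impacts = table.site_impacts()
    if mode == "all":
        carries = (codes == HET) | (codes == HOM_ALT)
    else:
        carries = codes == HOM_ALT
    out = {}
    for category in IMPACT_CATEGORIES:
        count = int(np.sum(carries & (impacts == category)))
        out[category] = count / n_called if n_called else float("nan")
    return out


def load_reports(
    table: VariantTable,
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    gerp_threshold: float = DEFAULT_GERP_THRESHOLD,
    individuals: Optional[Sequence[str]] = None,
) -> list:
    """Full pipeline: shared-site filter -> outgroup polarization -> per-
    individual loads and effect-category proportions for the ingroup."""
    keep = shared_site_filter(table, matrix, popmap)
    table_f = table.take(keep)
    matrix_f = matrix.take(keep)
    derived = polarize_derived(table_f, matrix_f, popmap)
    eligible = np.nonzero(derived != None)[0]  # noqa: E711
    table_a = table_f.take(eligible)
    matrix_a = matrix_f.take(eligible)
    derived_a = derived[eligible]
    if individuals is None:
        ingroup = [popmap.target()] + popmap.backgrounds()
        individuals = [
            s for s in matrix.samples if popmap.assignments[s] in ingroup
        ]
    reports = []
    for sample in individuals:
        masked, realized, n_called = genetic_load(
            sample, matrix_a, table_a, derived_a, gerp_threshold
        )
        reports.append(
            LoadReport(
                individual_id=sample,
                masked_load=masked,
                realized_load=realized,
                n_called=n_called,
                category_proportions_all=effect_category_proportions(
                    sample, matrix_a, table_a, "all", n_called
                ),
                category_proportions_hom=effect_category_proportions(
                    sample, matrix_a, table_a, "homozygous_only", n_called
                ),
            )
        )
    return reports


def one_way_anova(groups: dict, benjamini_hochberg: bool = False) -> dict:
    """Classic one-way ANOVA across >= 2 groups of per-individual values,
    with all pairwise contrasts reported alongside.

    Returns ``{"F": ..., "p": ..., "degenerate": bool, "pairwise":
    {(a, b): p, ...}}``.  Zero within-group variance everywhere flags the
    p value as degenerate rather than raising.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("one_way_anova needs >= 2 groups")
    arrays = [np.asarray(groups[name], dtype=float) for name in names]
    for name, arr in zip(names, arrays):
        if len(arr) < 2:
            raise ValueError(f"group {name!r} needs >= 2 values")
    total_n = sum(len(a) for a in arrays)
    if total_n <= len(arrays):
        raise ValueError("total df must exceed the number of groups")
    degenerate = all(np.allclose(a, a[0]) for a in arrays)
    if degenerate:
        means_equal = np.allclose(
            [a.mean() for a in arrays], arrays[0].mean()
        )
        f_stat = 0.0 if means_equal else float("inf")
        p_val = 1.0 if means_equal else 0.0
        logger.warning("one_way_anova: zero within-group variance; "
                       "p value degenerate")
    else:
        f_stat, p_val = stats.f_oneway(*arrays)
        f_stat, p_val = float(f_stat), float(p_val)
    pairwise = {}
    for a, b in itertools.combinations(names, 2):
        ga, gb = np.asarray(groups[a], float), np.asarray(groups[b], float)
        if np.allclose(ga, ga[0]) and np.allclose(gb, gb[0]):
            pairwise[(a, b)] = 1.0 if np.isclose(ga.mean(), gb.mean()) else 0.0
        else:
            pairwise[(a, b)] = float(stats.f_oneway(ga, gb)[1])
    if benjamini_hochberg and pairwise:
        keys = list(pairwise)
        pvals = np.array([pairwise[k] for k in keys])
        order = np.argsort(pvals)
        m = len(pvals)
        adjusted = np.empty(m)
        running_min = 1.0
        for rank_pos in range(m - 1, -1, -1):
            k = order[rank_pos]
            running_min = min(running_min, pvals[k] * m / (rank_pos + 1))
            adjusted[k] = running_min
        pairwise = {k: float(adjusted[i]) for i, k in enumerate(keys)}
    return {"F": f_stat, "p": p_val, "degenerate": degenerate,
            "pairwise": pairwise}
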