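"""Shared data model: variant tables, genotype matrices, population maps,
gene models and small result records used across all analysis modules.

Conventions
-----------
Genotype codes are diploid and unphased at the matrix level:
``HOM_REF=0``, ``HET=1``, ``HOM_ALT=2``, ``MISSING=-1``.  Phased haplotypes,
when available, live alongside the codes as a ``(n_sites, 2 * n_samples)``
array of alt-allele indicators (``-1`` for missing).

Coordinates are 1-based inclusive at the file boundary (VCF convention);
internal *intervals* (gene spans, windows, planted segments) are half-open
0-based.  Report writers convert back.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

# Diploid genotype codes.
HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

IMPACT_CATEGORIES = ("HIGH", "MODERATE", "LOW", "MODIFIER")
_IMPACT_RANK = {"HIGH": 3, "MODERATE": 2, "LOW": 1, "MODIFIER": 0}

# Fixed, versioned effect-term -> coding-class mapping (v1).  Anything not
# listed maps to "other".
NON_SYNONYMOUS_TERMS = frozenset(
    {"missense_variant", "stop_gained", "stop_lost", "start_lost"}
)
SYNONYMOUS_TERMS = frozenset({"synonymous_variant", "stop_retained_variant"})
CODING_CLASS_MAP_VERSION = 1


def coding_class_of(effect_term: str) -> str:
    """Map a controlled-vocabulary effect term to a coding class."""
    if effect_term in NON_SYNONYMOUS_TERMS:
        return "non_synonymous"
    if effect_term in SYNONYMOUS_TERMS:
        return "synonymous"
    return "other"


def impact_rank(impact_category: str) -> int:
    """Severity rank of an impact category (HIGH=3 ... MODIFIER=0)."""
    return _IMPACT_RANK[impact_category]


@dataclass(frozen=True)
class EffectAnnotation:
    """One functional-effect annotation of a variant site."""

    gene_id: str
    effect_term: str
    impact_category: str
    coding_class: str = field(default="")

    def __post_init__(self) -> None:
        if self.impact_category not in _IMPACT_RANK:
            raise ValueError(
                f"impact_category must be one of {IMPACT_CATEGORIES}, "
                f"got {self.impact_category!r}"
            )
        if not self.coding_class:
            object.__setattr__(
                self, "coding_class", coding_class_of(self.effect_term)
            )


@dataclass
class VariantTable:
    """Per-site records aligned with a :class:`GenotypeMatrix` row-for-row.

    ``gerp`` uses NaN for "absent"; ``ancestral`` uses ``None`` for unknown.
    ``ann_raw`` keeps the raw annotation string (or ``None``) so round-trips
    are lossless; ``effects`` holds the parsed annotations.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    ancestral: np.ndarray
    gerp: np.ndarray
    effects: list
    ann_raw: list

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def take(self, idx: np.ndarray) -> "VariantTable":
        idx = np.asarray(idx)
        return VariantTable(
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            ancestral=self.ancestral[idx],
            gerp=self.gerp[idx],
            effects=[self.effects[i] for i in idx],
            ann_raw=[self.ann_raw[i] for i in idx],
        )

    def worst_effect(self, i: int) -> Optional[EffectAnnotation]:
        """Most severe annotation at site ``i`` (HIGH > ... > MODIFIER)."""
        effs = self.effects[i]
        if not effs:
            return None
        return max(effs, key=lambda e: impact_rank(e.impact_category))

    def site_impacts(self) -> np.ndarray:
        """Per-site most-severe impact category ('' when unannotated)."""
        out = np.empty(self.n_sites, dtype=object)
        for i in range(self.n_sites):
            eff = self.worst_effect(i)
            out[i] = eff.impact_category if eff is not None else ""
        return out

    def site_coding_classes(self) -> np.ndarray:
        """Per-site coding class of the most severe annotation."""
        out = np.empty(self.n_sites, dtype=object)
        for i in range(self.n_sites):
            eff = self.worst_effect(i)
            out[i] = eff.coding_class if eff is not None else "other"
        return out


@dataclass
class GenotypeMatrix:
    """Sites x individuals diploid genotype codes plus optional phased
    haplotypes and per-individual callable length (bp)."""

    codes: np.ndarray
    samples: list
    callable_length: np.ndarray
    haplotypes: Optional[np.ndarray] = None
    phased: bool = False

    @property
    def n_sites(self) -> int:
        return self.codes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.codes.shape[1]

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def take(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            codes=self.codes[idx],
            samples=list(self.samples),
            callable_length=self.callable_length.copy(),
            haplotypes=None if self.haplotypes is None else self.haplotypes[idx],
            phased=self.phased,
        )


@dataclass
class PopulationMap:
    """individual -> population assignment with per-population roles
    (``target`` / ``background`` / ``outgroup``)."""

    assignments: dict
    roles: dict

    def __post_init__(self) -> None:
        outgroups = [p for p, r in self.roles.items() if r == "outgroup"]
        if len(outgroups) > 1:
            raise ValueError(
                f"at most one outgroup population allowed, got {outgroups}"
            )
        for pop in set(self.assignments.values()):
            self.roles.setdefault(pop, "background")

    def populations(self) -> list:
        seen: dict = {}
        for pop in self.assignments.values():
            seen.setdefault(pop, None)
        return list(seen)

    def members(self, population: str) -> list:
        return [s for s, p in self.assignments.items() if p == population]

    def indices(self, samples: Sequence[str], population: str) -> np.ndarray:
        members = set(self.members(population))
        return np.array(
            [i for i, s in enumerate(samples) if s in members], dtype=int
        )

    def outgroup(self) -> Optional[str]:
        for pop, role in self.roles.items():
            if role == "outgroup":
                return pop
        return None

    def target(self) -> Optional[str]:
        for pop, role in self.roles.items():
            if role == "target":
                return pop
        return None

    def backgrounds(self) -> list:
        return [p for p, r in self.roles.items() if r == "background"]


@dataclass
class Gene:
    """One gene with a single contiguous CDS interval (half-open 0-based)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    cds_start: int
    cds_end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """Ordered collection of genes; provides interval lookups."""

    genes: list

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterable[Gene]:
        return iter(self.genes)

    def by_id(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def cds_mask(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Boolean mask of 1-based positions falling inside any CDS."""
        mask = np.zeros(len(pos), dtype=bool)
        for g in self.genes:
            sel = (chrom == g.chrom) & (pos > g.cds_start) & (pos <= g.cds_end)
            mask |= sel
        return mask

    def gene_mask(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        mask = np.zeros(len(pos), dtype=bool)
        for g in self.genes:
            sel = (chrom == g.chrom) & (pos > g.start) & (pos <= g.end)
            mask |= sel
        return mask


@dataclass
class WindowStat:
    """One genomic window statistic (half-open interval)."""

    chrom: str
    start: int
    end: int
    n_variable_sites: int
    value: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("window end must exceed start")
        if self.n_variable_sites < 0:
            raise ValueError("n_variable_sites must be >= 0")


@dataclass
class ROHParams:
    """Window rules and segment minima for run-of-homozygosity detection.

    ``max_missing_per_window`` keeps the published value 50 for provenance;
    the detector caps it at ``window_snps`` because no 20-SNP window can hold
    50 missing calls (missingness then never breaks a window).
    """

    window_snps: int = 20
    max_het_per_window: int = 1
    max_missing_per_window: int = 50
    window_hit_threshold: float = 0.05
    min_segment_snps: int = 50
    min_segment_kb: float = 100.0
    min_density_kb_per_snp: float = 50.0
    max_gap_kb: float = 100.0

    def __post_init__(self) -> None:
        for name in (
            "window_snps",
            "max_missing_per_window",
            "min_segment_snps",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("min_segment_kb", "min_density_kb_per_snp", "max_gap_kb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.window_hit_threshold <= 1:
            raise ValueError("window_hit_threshold must be in (0, 1]")
        if self.max_het_per_window < 0:
            raise ValueError("max_het_per_window must be >= 0")

    @property
    def effective_max_missing(self) -> int:
        return min(self.max_missing_per_window, self.window_snps)


@dataclass
class ROHSegment:
    """One homozygous run; start/end are the 1-based positions of the first
    and last SNP of the run."""

    chrom: str
    start: int
    end: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


@dataclass
class LoadReport:
    """Per-individual masked and realized load plus effect-category
    genotype proportions in the two counting modes."""

    individual_id: str
    masked_load: float
    realized_load: float
    n_called: int
    category_proportions_all: dict
    category_proportions_hom: dict


@dataclass
class SitePatternCounts:
    """Weighted ABBA/BABA sums with per-block partials for the jackknife."""

    abba: float
    baba: float
    n_informative_sites: int
    block_abba: dict
    block_baba: dict


@dataclass
class DStatResult:
    """D-statistic for one population quartet with jackknife significance."""

    p1: str
    p2: str
    p3: str
    outgroup: str
    d: float
    jackknife_se: float
    z: float
    n_blocks: int
    n_informative_sites: int


@dataclass
class SweepCall:
    """Per-gene flags from the selection methods and the >=2-method
    consensus verdict."""

    gene_id: str
    flags: dict
    consensus: bool = field(init=False)

    def __post_init__(self) -> None:
        self.consensus = sum(bool(v) for v in self.flags.values()) >= 2


@dataclass
class ScreenHit:
    """One variant passing a private / fixed-with-background screen."""

    gene_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    tier: str
    background_max_freq: float
    stop_gained: bool = False

    def __post_init__(self) -> None:
        if self.tier == "private" and self.background_max_freq != 0:
            raise ValueError("private hits must have background_max_freq == 0")
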