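"""Synthetic dataset generator.

Produces a file bundle (VCF + GFF3 + conservation-score track + popmap +
callability table + truth JSON) with the statistical structure the
downstream analyses assume: a three-ingroup-populations + one-outgroup
design on a fixed ``((target, (A, B)), outgroup)`` tree, controllable
inbreeding (planted runs of homozygosity), deleterious-allele placement,
migration, sweep regions, and a gene model with codon-consistent effect
annotations.

Generation is genealogy-free: sites are i.i.d. given per-population derived
allele frequencies drawn from a hierarchical Balding–Nichols model on the
fixed tree.  All randomness flows from a single integer seed through one
named generator, so a config + seed determines the bundle byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from karstpop import _codon
from karstpop.datatypes import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    EffectAnnotation,
    Gene,
    GeneModel,
    GenotypeMatrix,
    PopulationMap,
    VariantTable,
)
from karstpop import io_core

logger = logging.getLogger(__name__)

_MIN_ROH_INTERVAL = 200_000  # bp; exceeds the detector's segment minima

# (ref_codon, codon_pos, alt_base) triples that create a premature stop.
_STOP_RECIPES = {0: ("CAA", "T"), 1: ("TCA", "A"), 2: ("TAC", "A")}


@dataclass
class SimConfig:
    """Full specification of one synthetic bundle."""

    seed: int = 0
    genome: list = field(default_factory=lambda: [("chr1", 500_000)])
    n_per_population: dict = field(
        default_factory=lambda: {
            "target": 4,
            "backgroundA": 8,
            "backgroundB": 8,
            "outgroup": 1,
        }
    )
    mutation_density: float = 2.0  # expected SNPs per kb
    f_roh: dict = field(default_factory=dict)  # population -> fraction
    deleterious_fraction: float = 0.15
    gerp_neutral: tuple = (-2.0, 3.9)
    gerp_deleterious: tuple = (4.0, 8.0)
    gerp_coverage: float = 1.0  # fraction of sites present in the track
    migration: float = 0.0  # backgroundA-derived alleles into target
    sweep_regions: list = field(default_factory=list)  # (chrom, start0, end, factor)
    n_genes: int = 20
    gene_length: int = 6_000
    cds_fraction: float = 0.5
    drift: dict = field(
        default_factory=lambda: {
            "root_ingroup": 0.05,
            "ingroup_target": 0.25,
            "ingroup_ab": 0.05,
            "ab_a": 0.12,
            "ab_b": 0.12,
        }
    )
    root_beta: tuple = (0.8, 1.5)
    ref_is_ancestral_prob: float = 0.8
    outgroup_ancestral_fraction: float = 0.97
    deleterious_hom_bias: float = 0.0  # extra homozygosity in target
    n_private_nonsyn: int = 0
    n_stop_gained: int = 0
    missing_rate: float = 0.0
    gerp_threshold: float = 4.0  # used only for truth bookkeeping
    compute_truth: bool = True  # skip the (slower) load/screen truth scans

    def __post_init__(self) -> None:
        self.genome = [(str(c), int(l)) for c, l in self.genome]
        for name in (
            "deleterious_fraction",
            "gerp_coverage",
            "migration",
            "ref_is_ancestral_prob",
            "deleterious_hom_bias",
            "missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.95 <= self.outgroup_ancestral_fraction <= 1.0:
            raise ValueError("outgroup_ancestral_fraction must be >= 0.95")
        for pop, f in self.f_roh.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"f_roh[{pop!r}] must be in [0, 1]")
        chroms = {c for c, _ in self.genome}
        for region in self.sweep_regions:
            chrom, start, end = region[0], int(region[1]), int(region[2])
            factor = float(region[3])
            if chrom not in chroms:
                raise ValueError(f"sweep region on unknown chromosome {chrom!r}")
            length = dict(self.genome)[chrom]
            if not 0 <= start < end <= length:
                raise ValueError(f"sweep region {region} outside chromosome")
            if not 0.0 < factor <= 1.0:
                raise ValueError("diversity_reduction factor must be in (0, 1]")

    @property
    def genome_length(self) -> int:
        return sum(l for _, l in self.genome)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "genome" in raw:
            raw["genome"] = [tuple(item) for item in raw["genome"]]
        if "sweep_regions" in raw:
            raw["sweep_regions"] = [tuple(item) for item in raw["sweep_regions"]]
        for key in ("gerp_neutral", "gerp_deleterious", "root_beta"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["genome"] = [list(item) for item in self.genome]
        d["sweep_regions"] = [list(item) for item in self.sweep_regions]
        return d


@dataclass
class TruthRecord:
    """Ground truth for one simulated bundle, recomputable from the files."""

    seed: int
    migration: float
    ancestral: list
    roh_intervals: dict  # sample -> [[chrom, start0, end], ...]
    f_roh: dict  # sample -> fraction
    masked_load: dict  # sample -> value
    realized_load: dict
    n_called: dict
    sweep_genes: list
    private_hits: list  # [[chrom, pos, gene_id], ...]
    fixed_hits: list
    stop_hits: list

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        raw = json.loads(Path(path).read_text())
        return cls(**raw)


@dataclass
class SimBundle:
    """In-memory simulated dataset plus its truth; ``write`` emits files."""

    config: SimConfig
    table: VariantTable
    matrix: GenotypeMatrix
    popmap: PopulationMap
    gene_model: GeneModel
    truth: TruthRecord
    # per-population true derived-allele frequencies (in-memory only)
    pop_freqs: Optional[dict] = None

    def write(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "data.vcf",
            "gff3": outdir / "genes.gff3",
            "gerp": outdir / "gerp.tsv",
            "popmap": outdir / "popmap.tsv",
            "callable": outdir / "callable.tsv",
            "truth": outdir / "truth.json",
        }
        io_core.write_vcf(self.table, self.matrix, paths["vcf"], contigs=self.config.genome)
        io_core.write_gff3(self.gene_model, paths["gff3"])
        io_core.write_gerp(self.table, paths["gerp"])
        io_core.write_popmap(self.popmap, paths["popmap"])
        io_core.write_callable(self.matrix, paths["callable"])
        self.truth.to_json(paths["truth"])
        return paths


# ---------------------------------------------------------------------------
# building blocks


def _balding_nichols(rng, p: np.ndarray, f: float) -> np.ndarray:
    """Drift allele frequencies by one branch with differentiation ``f``."""
    if f <= 0:
        return p.copy()
    p = np.clip(p, 1e-9, 1 - 1e-9)
    scale = (1.0 - f) / f
    return rng.beta(p * scale, (1.0 - p) * scale)


def _place_genes(rng, genome, n_genes, gene_length, cds_fraction) -> GeneModel:
    total = sum(l for _, l in genome)
    genes = []
    counter = 0
    for chrom, length in genome:
        n_here = int(round(n_genes * length / total))
        if n_here == 0:
            continue
        slack = length - n_here * gene_length
        if slack < 0:
            raise ValueError(
                f"chromosome {chrom} too short for {n_here} genes of "
                f"{gene_length} bp"
            )
        gaps = rng.dirichlet(np.ones(n_here + 1)) * slack
        cursor = 0.0
        cds_len = int(gene_length * cds_fraction) // 3 * 3
        for g in range(n_here):
            cursor += gaps[g]
            start = int(cursor)
            end = start + gene_length
            cursor = float(end)
            cds_start = start + (gene_length - cds_len) // 2
            counter += 1
            genes.append(
                Gene(
                    gene_id=f"G{counter:04d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    cds_start=cds_start,
                    cds_end=cds_start + cds_len,
                )
            )
    return GeneModel(genes=genes)


def _sample_roh_intervals(rng, chrom_lengths, fraction: float):
    """Disjoint half-open intervals per chromosome summing to ``fraction``
    of each chromosome, every interval >= 200 kb."""
    intervals = []
    for chrom, length in chrom_lengths:
        target = fraction * length
        if target <= 0:
            continue
        if target < _MIN_ROH_INTERVAL and fraction < 1.0:
            raise ValueError(
                f"chromosome {chrom} too short to host a {fraction:.2f} "
                f"ROH fraction with >= {_MIN_ROH_INTERVAL} bp intervals"
            )
        target = min(target, float(length))
        lengths = []
        rem = target
        max_piece = max(2 * _MIN_ROH_INTERVAL, target / 4)
        while rem > 0:
            if rem < 2 * _MIN_ROH_INTERVAL:
                lengths.append(rem)
                rem = 0.0
            else:
                piece = rng.uniform(
                    _MIN_ROH_INTERVAL, min(max_piece, rem - _MIN_ROH_INTERVAL)
                )
                lengths.append(piece)
                rem -= piece
        lengths = [int(round(x)) for x in lengths]
        total = sum(lengths)
        gaps = rng.dirichlet(np.ones(len(lengths) + 1)) * (length - total)
        cursor = 0.0
        for g, piece in zip(gaps, lengths):
            cursor += g
            start = int(cursor)
            intervals.append((chrom, start, start + piece))
            cursor = float(start + piece)
    return intervals


def plant_roh(
    haplotypes: np.ndarray,
    individual: int,
    target_f_roh: float,
    rng,
    *,
    chrom: np.ndarray,
    pos: np.ndarray,
    genome,
):
    """Copy one haplotype over the other inside sampled intervals so the
    individual's genome fraction in runs of homozygosity is ``target_f_roh``.

    Returns the list of planted half-open intervals.  ``haplotypes`` is
    modified in place.
    """
    if not 0.0 <= target_f_roh <= 1.0:
        raise ValueError("target_f_roh must be in [0, 1]")
    if target_f_roh == 0.0:
        return []
    intervals = _sample_roh_intervals(rng, genome, target_f_roh)
    a, b = 2 * individual, 2 * individual + 1
    for c, start, end in intervals:
        sel = (chrom == c) & (pos > start) & (pos <= end)
        haplotypes[sel, b] = haplotypes[sel, a]
    return intervals


def plant_sweep(
    haplotypes: np.ndarray,
    hap_columns: np.ndarray,
    site_index: np.ndarray,
    diversity_reduction: float,
    rng,
) -> None:
    """Copy one randomly chosen haplotype across sqrt(1 - factor) of the
    population's haplotypes inside the region, so pairwise diversity there
    drops to about ``diversity_reduction`` of its pre-sweep value."""
    if not 0.0 < diversity_reduction <= 1.0:
        raise ValueError("diversity_reduction must be in (0, 1]")
    n = len(hap_columns)
    n_copy = int(round(math.sqrt(1.0 - diversity_reduction) * n))
    if n_copy == 0:
        return
    donor = int(rng.choice(hap_columns))
    recipients = rng.choice(hap_columns, size=n_copy, replace=False)
    block = haplotypes[np.ix_(site_index, [donor])]
    haplotypes[np.ix_(site_index, recipients)] = block


# ---------------------------------------------------------------------------
# truth scans (independent, literal re-derivations from the final arrays)


def _polarize_codes(codes, out_idx):
    """Per-site derived allele ('ref'/'alt'/None) from outgroup genotypes."""
    derived = []
    for i in range(codes.shape[0]):
        out_codes = [int(codes[i, j]) for j in out_idx if codes[i, j] != MISSING]
        if not out_codes or any(c == HET for c in out_codes):
            derived.append(None)
        elif all(c == HOM_REF for c in out_codes):
            derived.append("alt")
        elif all(c == HOM_ALT for c in out_codes):
            derived.append("ref")
        else:
            derived.append(None)
    return derived


def _truth_loads(table, codes, popmap, samples, threshold):
    in_pops = [popmap.target()] + popmap.backgrounds()
    in_idx = [
        j for j, s in enumerate(samples) if popmap.assignments[s] in in_pops
    ]
    out_idx = [
        j
        for j, s in enumerate(samples)
        if popmap.roles.get(popmap.assignments[s]) == "outgroup"
    ]
    # shared-site filter: drop sites where every called ingroup genotype is
    # the same homozygote (or nothing is called at all)
    keep = []
    for i in range(codes.shape[0]):
        calls = {int(codes[i, j]) for j in in_idx if codes[i, j] != MISSING}
        if calls and not (len(calls) == 1 and calls <= {HOM_REF, HOM_ALT}):
            keep.append(i)
    derived = _polarize_codes(codes, out_idx)
    analysis = [i for i in keep if derived[i] is not None]
    masked, realized, n_called = {}, {}, {}
    for j in in_idx:
        sample = samples[j]
        m_sum = r_sum = 0.0
        called = 0
        for i in analysis:
            code = int(codes[i, j])
            if code == MISSING:
                continue
            called += 1
            score = table.gerp[i]
            if not (score == score) or score < threshold:  # NaN-safe
                continue
            hom_derived = HOM_ALT if derived[i] == "alt" else HOM_REF
            if code == HET:
                m_sum += score
            elif code == hom_derived:
                r_sum += score
        masked[sample] = m_sum / called if called else float("nan")
        realized[sample] = r_sum / called if called else float("nan")
        n_called[sample] = called
    return masked, realized, n_called


def _truth_screens(table, codes, popmap, samples, max_background_freq):
    target = popmap.target()
    tgt_idx = [j for j, s in enumerate(samples) if popmap.assignments[s] == target]
    bg_pops = popmap.backgrounds()
    bg_idx = [
        j for j, s in enumerate(samples) if popmap.assignments[s] in bg_pops
    ]
    private, fixed, stops = [], [], []
    for i in range(table.n_sites):
        effs = table.effects[i]
        if not effs:
            continue
        worst = max(effs, key=lambda e: {"HIGH": 3, "MODERATE": 2, "LOW": 1,
                                         "MODIFIER": 0}[e.impact_category])
        tgt_codes = [int(codes[i, j]) for j in tgt_idx]
        all_hom_alt = bool(tgt_codes) and all(c == HOM_ALT for c in tgt_codes)
        alt_alleles = called_alleles = 0
        for j in bg_idx:
            c = int(codes[i, j])
            if c == MISSING:
                continue
            called_alleles += 2
            alt_alleles += {HOM_REF: 0, HET: 1, HOM_ALT: 2}[c]
        bg_freq = alt_alleles / called_alleles if called_alleles else 0.0
        record = [str(table.chrom[i]), int(table.pos[i]), worst.gene_id]
        if worst.coding_class == "non_synonymous" and all_hom_alt:
            if bg_freq == 0.0:
                private.append(record)
            if bg_freq <= max_background_freq:
                fixed.append(record)
        if all_hom_alt and any(e.effect_term == "stop_gained" for e in effs):
            stops.append(record)
    return private, fixed, stops


# ---------------------------------------------------------------------------
# main entry point


def simulate_dataset(config: SimConfig) -> SimBundle:
    """Generate a full synthetic bundle from ``config``.

    Deterministic: the same config (including seed) produces identical
    arrays and, through :meth:`SimBundle.write`, byte-identical files.
    """
    rng = np.random.default_rng(config.seed)
    pops = list(config.n_per_population)
    roles = {}
    for pop in pops:
        if pop == "target":
            roles[pop] = "target"
        elif pop == "outgroup":
            roles[pop] = "outgroup"
        else:
            roles[pop] = "background"
    if "target" not in roles.values() or "outgroup" not in roles.values():
        raise ValueError("config must define 'target' and 'outgroup' populations")
    backgrounds = [p for p in pops if roles[p] == "background"]
    if len(backgrounds) < 2:
        raise ValueError("config needs at least two background populations")
    pop_a, pop_b = backgrounds[0], backgrounds[1]

    samples, assignments = [], {}
    for pop in pops:
        for k in range(config.n_per_population[pop]):
            name = f"{pop}_{k + 1}"
            samples.append(name)
            assignments[name] = pop
    popmap = PopulationMap(assignments=assignments, roles=roles)

    # --- positions -------------------------------------------------------
    chrom_list, pos_list = [], []
    for chrom, length in config.genome:
        n = rng.poisson(length * config.mutation_density / 1000.0)
        n = min(n, length)
        positions = np.sort(rng.choice(length, size=n, replace=False)) + 1
        chrom_list.append(np.full(n, chrom, dtype=object))
        pos_list.append(positions.astype(np.int64))
    chrom = np.concatenate(chrom_list) if chrom_list else np.array([], dtype=object)
    pos = np.concatenate(pos_list) if pos_list else np.array([], dtype=np.int64)
    n_sites = len(pos)

    gene_model = _place_genes(
        rng, config.genome, config.n_genes, config.gene_length, config.cds_fraction
    )

    # --- per-site gene / CDS context ------------------------------------
    site_gene = np.full(n_sites, "", dtype=object)
    in_cds = np.zeros(n_sites, dtype=bool)
    frame = np.zeros(n_sites, dtype=np.int8)
    for g in gene_model:
        sel = (chrom == g.chrom) & (pos > g.start) & (pos <= g.end)
        site_gene[sel] = g.gene_id
        csel = (chrom == g.chrom) & (pos > g.cds_start) & (pos <= g.cds_end)
        in_cds |= csel
        frame[csel] = (pos[csel] - 1 - g.cds_start) % 3

    # --- bases and effect annotations -----------------------------------
    ref = np.empty(n_sites, dtype=object)
    alt = np.empty(n_sites, dtype=object)
    effects: list = [None] * n_sites
    sense = _codon.SENSE_CODONS
    codon_idx = rng.integers(0, len(sense), size=n_sites)
    alt_choice = rng.integers(0, 3, size=n_sites)
    base_idx = rng.integers(0, 4, size=n_sites)
    others = {b: [x for x in _codon.BASES if x != b] for b in _codon.BASES}
    for i in range(n_sites):
        if in_cds[i]:
            k = int(frame[i])
            codon = sense[codon_idx[i]]
            ref[i] = codon[k]
            alt[i] = others[ref[i]][alt_choice[i]]
            term, impact = _codon.classify_codon_change(
                codon, _codon.mutate(codon, k, alt[i])
            )
            effects[i] = (term, impact, site_gene[i])
        else:
            ref[i] = _codon.BASES[base_idx[i]]
            alt[i] = others[ref[i]][alt_choice[i]]
            if site_gene[i]:
                effects[i] = ("intron_variant", "MODIFIER", site_gene[i])
            else:
                effects[i] = ("intergenic_region", "MODIFIER", "")

    # --- conservation scores --------------------------------------------
    deleterious = rng.random(n_sites) < config.deleterious_fraction
    gerp = np.where(
        deleterious,
        rng.uniform(*config.gerp_deleterious, size=n_sites),
        rng.uniform(*config.gerp_neutral, size=n_sites),
    )
    covered = rng.random(n_sites) < config.gerp_coverage
    gerp = np.where(covered, gerp, np.nan)

    # --- ancestral orientation and population frequencies ---------------
    ref_is_anc = rng.random(n_sites) < config.ref_is_ancestral_prob
    ancestral = np.where(ref_is_anc, ref, alt).astype(object)

    p_root = rng.beta(*config.root_beta, size=n_sites)
    p_ingroup = _balding_nichols(rng, p_root, config.drift["root_ingroup"])
    p_target = _balding_nichols(rng, p_ingroup, config.drift["ingroup_target"])
    p_ab = _balding_nichols(rng, p_ingroup, config.drift["ingroup_ab"])
    p_bg = {
        pop_a: _balding_nichols(rng, p_ab, config.drift["ab_a"]),
        pop_b: _balding_nichols(rng, p_ab, config.drift["ab_b"]),
    }

    # --- haplotype draws (derived-allele indicators) --------------------
    n_samples = len(samples)
    hap_derived = np.zeros((n_sites, 2 * n_samples), dtype=np.int8)
    col = 0
    pop_columns: dict = {}
    for pop in pops:
        n_h = 2 * config.n_per_population[pop]
        cols = np.arange(col, col + n_h)
        pop_columns[pop] = cols
        if roles[pop] == "outgroup":
            hom_derived = rng.random(n_sites) >= config.outgroup_ancestral_fraction
            for c in cols:
                hap_derived[:, c] = hom_derived
        elif pop == "target":
            draws = rng.random((n_sites, n_h)) < p_target[:, None]
            if config.migration > 0:
                mig = rng.random((n_sites, n_h)) < config.migration
                donor = rng.random((n_sites, n_h)) < p_bg[pop_a][:, None]
                draws = np.where(mig, donor, draws)
            hap_derived[:, cols] = draws
        else:
            hap_derived[:, cols] = rng.random((n_sites, n_h)) < p_bg[pop][:, None]
        col += n_h

    # convert derived indicators to alt-allele indicators
    haps = np.where(
        ref_is_anc[:, None], hap_derived, 1 - hap_derived
    ).astype(np.int8)

    # --- deleterious-allele placement bias in the target ----------------
    if config.deleterious_hom_bias > 0:
        del_idx = np.nonzero(deleterious)[0]
        for j, s in enumerate(samples):
            if assignments[s] != "target":
                continue
            force = del_idx[
                rng.random(len(del_idx)) < config.deleterious_hom_bias
            ]
            haps[force, 2 * j + 1] = haps[force, 2 * j]

    # --- sweeps ----------------------------------------------------------
    sweep_genes = []
    for region in config.sweep_regions:
        r_chrom, start, end, factor = region[0], int(region[1]), int(region[2]), float(region[3])
        swept_pop = region[4] if len(region) > 4 else "target"
        sel = np.nonzero((chrom == r_chrom) & (pos > start) & (pos <= end))[0]
        plant_sweep(haps, pop_columns[swept_pop], sel, factor, rng)
        for g in gene_model:
            if g.chrom == r_chrom and g.start < end and start < g.end:
                if g.gene_id not in sweep_genes:
                    sweep_genes.append(g.gene_id)

    # --- planted runs of homozygosity -----------------------------------
    roh_intervals: dict = {s: [] for s in samples}
    f_roh_truth: dict = {s: 0.0 for s in samples}
    for j, s in enumerate(samples):
        fraction = config.f_roh.get(assignments[s], config.f_roh.get(s, 0.0))
        if fraction > 0:
            intervals = plant_roh(
                haps, j, fraction, rng, chrom=chrom, pos=pos, genome=config.genome
            )
            roh_intervals[s] = [[c, int(a), int(b)] for c, a, b in intervals]
            f_roh_truth[s] = sum(b - a for _, a, b in intervals) / config.genome_length

    # --- planted private non-synonymous and stop-gained variants --------
    protected = np.zeros(n_sites, dtype=bool)
    tgt_cols = pop_columns["target"]
    bg_cols = np.concatenate([pop_columns[p] for p in (pop_a, pop_b)])
    out_cols = pop_columns["outgroup"]

    def _force_genotypes(i: int) -> None:
        haps[i, tgt_cols] = 1
        haps[i, bg_cols] = 0
        haps[i, out_cols] = 0
        ancestral[i] = ref[i]
        protected[i] = True

    if config.n_private_nonsyn > 0:
        missense = np.nonzero(
            np.array([e[0] == "missense_variant" for e in effects]) & ~protected
        )[0]
        if len(missense) < config.n_private_nonsyn:
            raise ValueError(
                f"only {len(missense)} missense sites available for "
                f"{config.n_private_nonsyn} planted private variants"
            )
        chosen = rng.choice(missense, size=config.n_private_nonsyn, replace=False)
        for i in np.sort(chosen):
            _force_genotypes(int(i))

    if config.n_stop_gained > 0:
        cds_idx = np.nonzero(in_cds & ~protected)[0]
        if len(cds_idx) < config.n_stop_gained:
            raise ValueError("not enough CDS sites for planted stop variants")
        chosen = rng.choice(cds_idx, size=config.n_stop_gained, replace=False)
        for i in np.sort(chosen):
            i = int(i)
            k = int(frame[i])
            codon, alt_base = _STOP_RECIPES[k]
            ref[i] = codon[k]
            alt[i] = alt_base
            effects[i] = ("stop_gained", "HIGH", site_gene[i])
            _force_genotypes(i)

    # --- missingness and genotype codes ---------------------------------
    if config.missing_rate > 0:
        miss = rng.random((n_sites, n_samples)) < config.missing_rate
        miss[protected] = False
    else:
        miss = np.zeros((n_sites, n_samples), dtype=bool)

    # allele-sum coding: 0=hom ref, 1=het, 2=hom alt
    codes = (haps[:, 0::2] + haps[:, 1::2]).astype(np.int8)
    codes[miss] = MISSING
    hap_out = haps.copy()
    hap_out[np.repeat(miss, 2, axis=1)] = -1

    callable_length = np.array(
        [
            int(config.genome_length * rng.uniform(0.85, 0.95))
            for _ in samples
        ],
        dtype=np.int64,
    )

    # --- assemble table + matrix ----------------------------------------
    ann_raw, parsed = [], []
    for i in range(n_sites):
        term, impact, gene = effects[i]
        raw = f"{term}|{impact}|{alt[i]}|{gene}|sim"
        ann_raw.append(raw)
        parsed.append(
            [EffectAnnotation(gene_id=gene, effect_term=term, impact_category=impact)]
        )

    table = VariantTable(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        ancestral=ancestral,
        gerp=gerp,
        effects=parsed,
        ann_raw=ann_raw,
    )
    matrix = GenotypeMatrix(
        codes=codes,
        samples=samples,
        callable_length=callable_length,
        haplotypes=hap_out,
        phased=True,
    )

    # --- truth -----------------------------------------------------------
    if config.compute_truth:
        masked, realized, n_called = _truth_loads(
            table, codes, popmap, samples, config.gerp_threshold
        )
        private, fixed, stops = _truth_screens(
            table, codes, popmap, samples, max_background_freq=0.2895
        )
    else:
        masked, realized, n_called = {}, {}, {}
        private, fixed, stops = [], [], []
    truth = TruthRecord(
        seed=config.seed,
        migration=config.migration,
        ancestral=[str(a) for a in ancestral],
        roh_intervals=roh_intervals,
        f_roh=f_roh_truth,
        masked_load=masked,
        realized_load=realized,
        n_called=n_called,
        sweep_genes=sweep_genes,
        private_hits=private,
        fixed_hits=fixed,
        stop_hits=stops,
    )
    return SimBundle(
        config=config,
        table=table,
        matrix=matrix,
        popmap=popmap,
        gene_model=gene_model,
        truth=truth,
        pop_freqs={"target": p_target, pop_a: p_bg[pop_a], pop_b: p_bg[pop_b]},
    )
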