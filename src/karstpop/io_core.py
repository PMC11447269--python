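"""Input/output layer: read and validate VCF, population map, conservation
score track, gene model and callability inputs into the shared data model;
apply site-level filters; parse effect annotations.

The VCF reader is backed by :mod:`cyvcf2` (gzip-aware).  The writer emits
plain uncompressed VCF so bundles survive text-only archiving; the reader
accepts both.
"""

from __future__ import annotations

import gzip
import logging
import re
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from cyvcf2 import VCF

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
    coding_class_of,
)

logger = logging.getLogger(__name__)

_KNOWN_EFFECT_RE = re.compile(r"[a-z0-9_]+$")
_IMPACTS = {"HIGH", "MODERATE", "LOW", "MODIFIER"}

# cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
_CYVCF2_CODE = {0: HOM_REF, 1: HET, 3: HOM_ALT, 2: MISSING}


def parse_effect_annotation(ann_field: str):
    """Parse a pipe-delimited, comma-separated annotation field.

    Two field layouts are accepted per entry:

    - ``effect|impact|...|gene|...`` (effect first), and
    - ``allele|effect|impact|gene|...`` (the common annotator layout).

    Malformed entries are skipped with a logged warning.
    """
    annotations = []
    if not ann_field:
        return annotations
    for entry in ann_field.split(","):
        parts = entry.split("|")
        try:
            if len(parts) >= 2 and parts[1] in _IMPACTS:
                effect, impact = parts[0], parts[1]
                gene = parts[3] if len(parts) > 3 else ""
            elif len(parts) >= 3 and parts[2] in _IMPACTS:
                effect, impact = parts[1], parts[2]
                gene = parts[3] if len(parts) > 3 else ""
            else:
                raise ValueError("no impact field")
            if not effect or not _KNOWN_EFFECT_RE.match(effect):
                raise ValueError(f"unrecognised effect term {effect!r}")
        except ValueError as exc:
            logger.warning("skipping malformed annotation entry %r: %s", entry, exc)
            continue
        annotations.append(
            EffectAnnotation(
                gene_id=gene,
                effect_term=effect,
                impact_category=impact,
                coding_class=coding_class_of(effect),
            )
        )
    return annotations


def read_popmap(path) -> PopulationMap:
    """Read a 2-3 column tab-separated individual/population[/role] map."""
    assignments: dict = {}
    roles: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"popmap line needs >=2 columns: {line!r}")
            sample, pop = parts[0], parts[1]
            if sample in assignments:
                raise ValueError(f"duplicate individual {sample!r} in popmap")
            assignments[sample] = pop
            if len(parts) >= 3 and parts[2]:
                role = parts[2]
                if roles.get(pop, role) != role:
                    raise ValueError(f"conflicting roles for population {pop!r}")
                roles[pop] = role
    return PopulationMap(assignments=assignments, roles=roles)


def read_gerp(path) -> dict:
    """Read a 3-column (chrom, pos, score) track into a dict keyed by
    (chrom, pos).  Duplicate positions are a hard error."""
    scores: dict = {}
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos_s, score_s = line.split("\t")[:3]
            key = (chrom, int(pos_s))
            if key in scores:
                raise ValueError(f"duplicate GERP record at {chrom}:{pos_s}")
            scores[key] = float(score_s)
    return scores


def read_callable(path) -> dict:
    """Read a 2-column (individual, callable_bp) table."""
    out: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, value = line.split("\t")[:2]
            out[sample] = int(float(value))
    return out


_GFF_ATTR_RE = re.compile(r"(?:^|;)\s*(ID|Parent|gene_id)=([^;]+)")


def _gff_gene_id(attributes: str) -> str:
    ids = dict(_GFF_ATTR_RE.findall(attributes))
    value = ids.get("gene_id") or ids.get("Parent") or ids.get("ID") or ""
    return value.split(":")[-1]


def read_gff3(path) -> GeneModel:
    """Read gene and CDS features from a GFF3 file.

    Genes must have an ``ID``; CDS rows attach by ``Parent`` (or
    ``gene_id``).  Multiple CDS rows per gene are merged into their
    enclosing span (the model stores one contiguous CDS interval).
    """
    genes: dict = {}
    cds: dict = {}
    order: list = []
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            chrom, _, ftype, start_s, end_s, _, strand, _, attrs = parts[:9]
            start0, end = int(start_s) - 1, int(end_s)
            gid = _gff_gene_id(attrs)
            if ftype == "gene":
                genes[gid] = (chrom, start0, end, strand)
                order.append(gid)
            elif ftype == "CDS":
                lo, hi = cds.get(gid, (start0, end))
                cds[gid] = (min(lo, start0), max(hi, end))
    out = []
    for gid in order:
        chrom, start0, end, strand = genes[gid]
        cstart, cend = cds.get(gid, (start0, start0))
        out.append(
            Gene(
                gene_id=gid,
                chrom=chrom,
                start=start0,
                end=end,
                cds_start=cstart,
                cds_end=cend,
                strand=strand,
            )
        )
    return GeneModel(genes=out)


def read_variant_table(
    vcf_path,
    popmap_path,
    gerp_path=None,
    callable_path=None,
) -> Tuple[VariantTable, GenotypeMatrix, PopulationMap]:
    """Read a multi-sample VCF plus its side tables into the data model.

    Sites are ordered by (chrom, pos).  Conservation scores join by exact
    (chrom, pos) match; sites without a record carry NaN.  Every VCF sample
    must appear in the popmap (hard error naming the sample otherwise).
    """
    popmap = read_popmap(popmap_path)
    gerp = read_gerp(gerp_path) if gerp_path is not None else {}

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    for sample in samples:
        if sample not in popmap.assignments:
            raise ValueError(f"sample {sample!r} in VCF missing from popmap")

    chroms, poss, refs, alts, ancs, gerps = [], [], [], [], [], []
    effects, ann_raw = [], []
    codes_rows, hap_rows = [], []
    all_phased = True

    for variant in vcf:
        alt_alleles = variant.ALT
        alt = alt_alleles[0] if alt_alleles else ""
        chroms.append(variant.CHROM)
        poss.append(variant.POS)
        refs.append(variant.REF)
        alts.append(alt)
        aa = variant.INFO.get("AA")
        ancs.append(aa if aa in (variant.REF, alt) else None)
        score = variant.INFO.get("GERP")
        if score is None:
            score = gerp.get((variant.CHROM, variant.POS), np.nan)
        gerps.append(float(score))
        raw = variant.INFO.get("ANN")
        ann_raw.append(raw)
        effects.append(parse_effect_annotation(raw) if raw else [])

        codes_rows.append(
            [_CYVCF2_CODE.get(int(g), MISSING) for g in variant.gt_types]
        )
        hap_row = []
        for gt in variant.genotypes:
            a, b = gt[0], gt[1]
            phased = bool(gt[2]) if len(gt) > 2 else False
            if a < 0 or b < 0:
                hap_row.extend([-1, -1])
            else:
                hap_row.extend([min(a, 1), min(b, 1)])
                if not phased and a != b:
                    all_phased = False
        hap_rows.append(hap_row)
    vcf.close()

    chrom_arr = np.array(chroms, dtype=object)
    pos_arr = np.array(poss, dtype=np.int64)
    order = np.lexsort((pos_arr, chrom_arr.astype(str)))

    table = VariantTable(
        chrom=chrom_arr,
        pos=pos_arr,
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        ancestral=np.array(ancs, dtype=object),
        gerp=np.array(gerps, dtype=float),
        effects=effects,
        ann_raw=ann_raw,
    ).take(order)

    codes = np.array(codes_rows, dtype=np.int8)[order] if codes_rows else np.zeros(
        (0, len(samples)), dtype=np.int8
    )
    haps = np.array(hap_rows, dtype=np.int8)[order] if hap_rows else np.zeros(
        (0, 2 * len(samples)), dtype=np.int8
    )

    if callable_path is not None:
        table_call = read_callable(callable_path)
        callable_length = np.array(
            [table_call[s] for s in samples], dtype=np.int64
        )
    else:
        logger.warning(
            "no callability table supplied; defaulting callable_length to "
            "the number of variant sites per individual"
        )
        callable_length = np.full(len(samples), codes.shape[0], dtype=np.int64)

    matrix = GenotypeMatrix(
        codes=codes,
        samples=samples,
        callable_length=callable_length,
        haplotypes=haps,
        phased=all_phased,
    )
    return table, matrix, popmap


def filter_sites(
    table: VariantTable,
    matrix: GenotypeMatrix,
    max_missing: float = 0.10,
    biallelic_snps_only: bool = True,
) -> Tuple[VariantTable, GenotypeMatrix]:
    """Retain biallelic SNPs whose missing-genotype fraction is <=
    ``max_missing``; order is preserved.  Idempotent."""
    keep = np.ones(table.n_sites, dtype=bool)
    if biallelic_snps_only:
        for i in range(table.n_sites):
            ref, alt = table.ref[i], table.alt[i]
            if len(ref) != 1 or len(alt) != 1 or ref == alt or not alt:
                keep[i] = False
    if matrix.n_samples > 0:
        missing_frac = (matrix.codes == MISSING).mean(axis=1)
        keep &= missing_frac <= max_missing
    n_removed = int((~keep).sum())
    logger.info(
        "filter_sites: retained %d of %d sites (%d removed)",
        int(keep.sum()),
        table.n_sites,
        n_removed,
    )
    if keep.sum() == 0:
        logger.warning("filter_sites produced an empty table")
    idx = np.nonzero(keep)[0]
    return table.take(idx), matrix.take(idx)


_GT_STR = {HOM_REF: ("0", "0"), HET: ("0", "1"), HOM_ALT: ("1", "1")}


def write_vcf(table: VariantTable, matrix: GenotypeMatrix, path,
              contigs: Optional[list] = None) -> None:
    """Write the table and matrix to an uncompressed VCF.

    Haplotypes (when present) define the written phased genotypes;
    otherwise genotype codes are written with an arbitrary phase order.
    """
    path = Path(path)
    lines = ["##fileformat=VCFv4.2"]
    if contigs:
        for name, length in contigs:
            lines.append(f"##contig=<ID={name},length={length}>")
    else:
        for name in dict.fromkeys(table.chrom.astype(str)):
            lines.append(f"##contig=<ID={name}>")
    lines += [
        '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">',
        '##INFO=<ID=GERP,Number=1,Type=Float,Description="Conservation score">',
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.samples),
    ]
    haps = matrix.haplotypes
    sep = "|" if matrix.phased else "/"
    for i in range(table.n_sites):
        info_parts = []
        if table.ancestral[i] is not None:
            info_parts.append(f"AA={table.ancestral[i]}")
        if not np.isnan(table.gerp[i]):
            info_parts.append(f"GERP={table.gerp[i]:.4f}")
        if table.ann_raw[i]:
            info_parts.append(f"ANN={table.ann_raw[i]}")
        info = ";".join(info_parts) if info_parts else "."
        gts = []
        for j in range(matrix.n_samples):
            if haps is not None:
                a, b = haps[i, 2 * j], haps[i, 2 * j + 1]
                gts.append("./." if a < 0 else f"{a}{sep}{b}")
            else:
                code = int(matrix.codes[i, j])
                gts.append(
                    "./." if code == MISSING else sep.join(_GT_STR[code])
                )
        lines.append(
            "\t".join(
                [
                    str(table.chrom[i]),
                    str(int(table.pos[i])),
                    ".",
                    str(table.ref[i]),
                    str(table.alt[i]),
                    ".",
                    "PASS",
                    info,
                    "GT",
                ]
                + gts
            )
        )
    path.write_text("\n".join(lines) + "\n")


def write_popmap(popmap: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        for sample, pop in popmap.assignments.items():
            role = popmap.roles.get(pop, "background")
            fh.write(f"{sample}\t{pop}\t{role}\n")


def write_gerp(table: VariantTable, path) -> None:
    with open(path, "w") as fh:
        for i in range(table.n_sites):
            if not np.isnan(table.gerp[i]):
                fh.write(
                    f"{table.chrom[i]}\t{int(table.pos[i])}\t{table.gerp[i]:.4f}\n"
                )


def write_callable(matrix: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        for sample, length in zip(matrix.samples, matrix.callable_length):
            fh.write(f"{sample}\t{int(length)}\n")


def write_gff3(gene_model: GeneModel, path) -> None:
    lines = ["##gff-version 3"]
    for g in gene_model:
        attrs = f"ID={g.gene_id}"
        lines.append(
            "\t".join(
                [g.chrom, "karstpop", "gene", str(g.start + 1), str(g.end),
                 ".", g.strand, ".", attrs]
            )
        )
        if g.cds_end > g.cds_start:
            lines.append(
                "\t".join(
                    [g.chrom, "karstpop", "CDS", str(g.cds_start + 1),
                     str(g.cds_end), ".", g.strand, "0",
                     f"ID={g.gene_id}.cds;Parent={g.gene_id}"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")
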