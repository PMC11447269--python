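"""Standard codon table helpers shared by the simulator (effect assignment)
and the Ka/Ks estimator."""

from __future__ import annotations

from itertools import permutations

BASES = "ACGT"

# Standard genetic code; '*' marks stop codons.
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")
SENSE_CODONS = sorted(c for c in CODON_TABLE if c not in STOP_CODONS)


def translate(codon: str) -> str:
    return CODON_TABLE[codon.upper()]


def mutate(codon: str, position: int, base: str) -> str:
    return codon[:position] + base + codon[position + 1 :]


def classify_codon_change(ref_codon: str, alt_codon: str):
    """Classify a single-codon substitution into (effect_term, impact).

    Mirrors the annotator vocabulary used throughout the package.
    """
    ref_aa = translate(ref_codon)
    alt_aa = translate(alt_codon)
    if ref_aa == alt_aa:
        if ref_aa == "*":
            return "stop_retained_variant", "LOW"
        return "synonymous_variant", "LOW"
    if alt_aa == "*":
        return "stop_gained", "HIGH"
    if ref_aa == "*":
        return "stop_lost", "HIGH"
    return "missense_variant", "MODERATE"


def syn_nonsyn_site_fractions(codon: str):
    """NG86 per-codon synonymous / non-synonymous site counts.

    Each codon position contributes ``f/3`` synonymous sites where ``f`` is
    the fraction of its three possible point mutations that preserve the
    amino acid.  Mutations to stop codons count as non-synonymous.
    """
    syn = 0.0
    aa = translate(codon)
    for k in range(3):
        for b in BASES:
            if b == codon[k]:
                continue
            if translate(mutate(codon, k, b)) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def count_syn_nonsyn_differences(codon_a: str, codon_b: str):
    """NG86 observed synonymous / non-synonymous differences between two
    codons, averaged over all shortest mutational paths.

    Paths passing through a stop codon are discarded unless every path
    does so.
    """
    diff_positions = [k for k in range(3) if codon_a[k] != codon_b[k]]
    if not diff_positions:
        return 0.0, 0.0
    path_counts = []
    for order in permutations(diff_positions):
        syn = nonsyn = 0.0
        current = codon_a
        through_stop = False
        for k in order:
            nxt = mutate(current, k, codon_b[k])
            if translate(nxt) == "*" and nxt != codon_b:
                through_stop = True
            if translate(nxt) == translate(current):
                syn += 1.0
            else:
                nonsyn += 1.0
            current = nxt
        path_counts.append((syn, nonsyn, through_stop))
    usable = [(s, n) for s, n, stop in path_counts if not stop]
    if not usable:
        usable = [(s, n) for s, n, _ in path_counts]
    syn = sum(s for s, _ in usable) / len(usable)
    nonsyn = sum(n for _, n in usable) / len(usable)
    return syn, nonsyn
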