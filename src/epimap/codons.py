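"""Human codon usage and the default "non-rare" reverse-translation table.

Usage fractions are the widely tabulated human (Homo sapiens) codon usage
frequencies per amino acid.  The default table for oligo design keeps only
codons used in at least 10% of occurrences of their amino acid ("non-rare"),
sampled uniformly; the threshold and weighting are swappable.
"""

from __future__ import annotations

from .core import AA_ORDER, CodonTable, EpimapError

#: Human codon usage fractions per amino acid (fraction of that amino acid's
#: occurrences encoded by each codon).
HUMAN_CODON_USAGE: dict[str, dict[str, float]] = {
    "A": {"GCT": 0.26, "GCC": 0.40, "GCA": 0.23, "GCG": 0.11},
    "C": {"TGT": 0.45, "TGC": 0.55},
    "D": {"GAT": 0.46, "GAC": 0.54},
    "E": {"GAA": 0.42, "GAG": 0.58},
    "F": {"TTT": 0.45, "TTC": 0.55},
    "G": {"GGT": 0.16, "GGC": 0.34, "GGA": 0.25, "GGG": 0.25},
    "H": {"CAT": 0.41, "CAC": 0.59},
    "I": {"ATT": 0.36, "ATC": 0.48, "ATA": 0.16},
    "K": {"AAA": 0.42, "AAG": 0.58},
    "L": {
        "TTA": 0.07,
        "TTG": 0.13,
        "CTT": 0.13,
        "CTC": 0.20,
        "CTA": 0.07,
        "CTG": 0.41,
    },
    "M": {"ATG": 1.00},
    "N": {"AAT": 0.46, "AAC": 0.54},
    "P": {"CCT": 0.28, "CCC": 0.33, "CCA": 0.27, "CCG": 0.11},
    "Q": {"CAA": 0.25, "CAG": 0.75},
    "R": {
        "CGT": 0.08,
        "CGC": 0.19,
        "CGA": 0.11,
        "CGG": 0.21,
        "AGA": 0.20,
        "AGG": 0.20,
    },
    "S": {
        "TCT": 0.18,
        "TCC": 0.22,
        "TCA": 0.15,
        "TCG": 0.06,
        "AGT": 0.15,
        "AGC": 0.24,
    },
    "T": {"ACT": 0.24, "ACC": 0.36, "ACA": 0.28, "ACG": 0.12},
    "V": {"GTT": 0.18, "GTC": 0.24, "GTA": 0.11, "GTG": 0.47},
    "W": {"TGG": 1.00},
    "Y": {"TAT": 0.43, "TAC": 0.57},
}


def nonrare_human_codon_table(
    min_fraction: float = 0.10,
    weighting: str = "uniform",
) -> CodonTable:
    """Codon table restricted to codons above ``min_fraction`` human usage.

    ``weighting`` is ``"uniform"`` (default: each retained codon equally
    likely) or ``"usage"`` (retained codons weighted by usage fraction).
    Every amino acid is guaranteed at least one codon: if the threshold
    would remove all codons for a residue, its most-used codon is kept.
    """
    if weighting not in {"uniform", "usage"}:
        raise EpimapError(f"unknown weighting {weighting!r}")
    codons: dict[str, tuple[str, ...]] = {}
    weights: dict[str, tuple[float, ...]] = {}
    for aa in AA_ORDER:
        usage = HUMAN_CODON_USAGE[aa]
        kept = [(c, f) for c, f in usage.items() if f >= min_fraction]
        if not kept:
            kept = [max(usage.items(), key=lambda cf: cf[1])]
        codons[aa] = tuple(c for c, _ in kept)
        if weighting == "uniform":
            weights[aa] = tuple(1.0 for _ in kept)
        else:
            weights[aa] = tuple(f for _, f in kept)
    return CodonTable(codons=codons, weights=weights)
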