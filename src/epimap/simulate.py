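"""Synthetic screens and proteomes with known ground truth.

The generator emulates the sampling structure of a pooled selection screen:
library composition is drawn from a Dirichlet (concentration 50 per oligo,
mimicking realistic synthesis/cloning skew), the presort input sample is a
multinomial draw of the configured sequencing depth over those frequencies,
and each sorted replicate is a multinomial draw over frequencies proportional
to input frequency times the peptide's activation.  Activation is
baseline 1.0 for null peptides (so null fold enrichment centers on 1) plus a
planted activation weight for cognate peptides; mutant tiles of a known
footprint get ``1 + weight * s_true``, so the footprint can be rebuilt from
the simulated screen and compared with truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    AA_INDEX,
    AA_ORDER,
    EpimapError,
    MutagenesisFootprint,
    ProteinRecord,
    ScreenCounts,
)
from .footprint import annotations_from_tiles
from .tiling import reverse_translate, saturation_mutagenesis

#: Activation of a peptide the TCR does not recognize; null FE centers on 1.
BASELINE_ACTIVATION = 1.0

#: Default planted activation weight of a cognate (fully recognized) peptide,
#: comparable to the strongest screen enrichments.
DEFAULT_COGNATE_WEIGHT = 100.0


@dataclass
class SimulationConfig:
    """Study conditions of a simulated screen."""

    seed: int = 0
    n_peptides: int = 1000
    n_codon_variants: int = 2
    replicates: int = 3
    depth: int = 1_000_000
    input_dispersion: float = 50.0
    planted: Mapping[str, float] = field(default_factory=dict)
    baseline: float = BASELINE_ACTIVATION

    def validate(self) -> None:
        if self.depth <= 0:
            raise EpimapError("sequencing depth must be positive")
        if self.n_peptides < 1 or self.n_codon_variants < 1 or self.replicates < 1:
            raise EpimapError("peptides, variants and replicates must be >= 1")
        if self.input_dispersion <= 0:
            raise EpimapError("input_dispersion must be positive")
        for pep, w in self.planted.items():
            if not np.isfinite(w) or w < 0:
                raise EpimapError(f"activation weight for {pep!r} must be finite and >= 0")


def _sample_counts(
    activation: np.ndarray,
    n_oligos: int,
    oligo_peptide_idx: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    input_freq = rng.dirichlet(np.full(n_oligos, config.input_dispersion))
    cols = {"input": rng.multinomial(config.depth, input_freq)}
    sorted_w = input_freq * activation[oligo_peptide_idx]
    sorted_freq = sorted_w / sorted_w.sum()
    for r in range(1, config.replicates + 1):
        cols[f"sorted_rep_{r}"] = rng.multinomial(config.depth, sorted_freq)
    return pd.DataFrame(cols)


def simulate_screen(
    config: SimulationConfig,
) -> tuple[ScreenCounts, pd.Series, pd.DataFrame]:
    """Simulate a pooled screen of null peptides with planted cognate hits.

    Returns the counts, the oligo -> peptide map, and a per-peptide truth
    table with the planted activation and expected fold enrichment.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    peptides = [f"pep{i:05d}" for i in range(config.n_peptides)]
    unknown = set(config.planted) - set(peptides)
    if unknown:
        raise EpimapError(f"planted peptide {sorted(unknown)[0]!r} not in library")
    activation = np.array(
        [config.baseline + config.planted.get(p, 0.0) for p in peptides]
    )

    n_oligos = config.n_peptides * config.n_codon_variants
    pep_idx = np.repeat(np.arange(config.n_peptides), config.n_codon_variants)
    counts = _sample_counts(activation, n_oligos, pep_idx, config, rng)
    oligo_ids = [
        f"{peptides[i]}#v{v + 1}"
        for i in range(config.n_peptides)
        for v in range(config.n_codon_variants)
    ]
    counts.index = pd.Index(oligo_ids, name="oligo_id")
    roles = {c: ("input" if c == "input" else "sorted") for c in counts.columns}
    oligo_map = pd.Series(
        [peptides[i] for i in pep_idx], index=counts.index, name="peptide_id"
    )
    mean_act = activation.mean()
    truth = pd.DataFrame(
        {
            "activation": activation,
            "expected_fe": activation / mean_act,
        },
        index=pd.Index(peptides, name="peptide_id"),
    )
    return ScreenCounts(counts, roles), oligo_map, truth


def simulate_footprint_screen(
    footprint_truth: MutagenesisFootprint,
    config: SimulationConfig,
    cognate_weight: float = DEFAULT_COGNATE_WEIGHT,
    flanked_span: tuple[int, int] | None = None,
    codon_seed_offset: int = 1,
) -> tuple[ScreenCounts, pd.Series, pd.DataFrame, list[str]]:
    """Simulate a saturation-mutagenesis screen driven by a known footprint.

    The mutant library (19 substitutions at every footprint position, in the
    footprint's context, plus two WT controls) is built, reverse-translated
    into ``config.n_codon_variants`` oligos each, and screened with mutant
    activation ``baseline + cognate_weight * s_true`` (WT controls get
    ``baseline + cognate_weight``).

    Returns counts, the oligo -> peptide map, the mutant annotation table and
    the WT control peptide ids.
    """
    config.validate()
    positions = footprint_truth.positions
    if positions != list(range(positions[0], positions[-1] + 1)):
        raise EpimapError("footprint positions must be contiguous to simulate a screen")
    span = flanked_span or (positions[0], positions[-1] + 1)
    tiles = saturation_mutagenesis(
        footprint_truth.context_sequence,
        epitope_span=span,
        flank=0,
        context_id="sim",
        n_wt_controls=2,
    )
    annotations = annotations_from_tiles(tiles)
    wt_ids = [t.tile_id for t in tiles if t.kind == "wt_control"]
    peptides = [t.tile_id for t in tiles]

    col = {p: j for j, p in enumerate(positions)}
    activation = np.empty(len(tiles))
    for i, tile in enumerate(tiles):
        if tile.kind == "wt_control":
            s_true = 1.0
        else:
            s_true = footprint_truth.s[AA_INDEX[tile.meta.mut_aa], col[tile.meta.position]]
            if not np.isfinite(s_true):
                s_true = 0.0
        activation[i] = config.baseline + cognate_weight * s_true

    rng = np.random.default_rng(config.seed)
    oligos = reverse_translate(
        tiles,
        n_variants=config.n_codon_variants,
        seed=config.seed + codon_seed_offset,
    )
    pep_of = {t.tile_id: i for i, t in enumerate(tiles)}
    pep_idx = np.array([pep_of[o.tile_id] for o in oligos])
    counts = _sample_counts(activation, len(oligos), pep_idx, config, rng)
    counts.index = pd.Index([o.oligo_id for o in oligos], name="oligo_id")
    roles = {c: ("input" if c == "input" else "sorted") for c in counts.columns}
    oligo_map = pd.Series(
        [peptides[i] for i in pep_idx], index=counts.index, name="peptide_id"
    )
    return ScreenCounts(counts, roles), oligo_map, annotations, wt_ids


def make_toy_proteome(
    seed: int,
    n_proteins: int,
    length_range: tuple[int, int],
    planted_kmers: Mapping[str, int] | None = None,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Random proteome with k-mers planted at recorded loci.

    Background residues are i.i.d. uniform over the 20 amino acids; each
    planted k-mer is written over the background at a random locus (planted
    k-mers never overwrite each other).  Returns the proteins and a truth
    table (kmer, protein_id, offset).
    """
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise EpimapError("bad length range")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AA_ORDER))
    seqs = [
        "".join(aa[rng.integers(20, size=rng.integers(lo, hi + 1))])
        for _ in range(n_proteins)
    ]
    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n_proteins)}
    truth_rows = []
    for kmer, copies in (planted_kmers or {}).items():
        for _ in range(copies):
            for _attempt in range(1000):
                i = int(rng.integers(n_proteins))
                if len(seqs[i]) < len(kmer):
                    continue
                off = int(rng.integers(len(seqs[i]) - len(kmer) + 1))
                span = (off, off + len(kmer))
                if any(span[0] < e and s < span[1] for s, e in occupied[i]):
                    continue
                seqs[i] = seqs[i][: span[0]] + kmer + seqs[i][span[1] :]
                occupied[i].append(span)
                truth_rows.append((kmer, f"prot{i:04d}", off))
                break
            else:
                raise EpimapError(f"could not place planted k-mer {kmer!r}")
    proteins = [ProteinRecord(f"prot{i:04d}", s) for i, s in enumerate(seqs)]
    truth = pd.DataFrame(truth_rows, columns=["kmer", "protein_id", "offset"])
    return proteins, truth
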