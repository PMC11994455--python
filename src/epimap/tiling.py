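"""Peptide library design: tiling, N-terminal concatenation, de Bruijn
sampling, saturation mutagenesis, and reverse translation into oligos.

Four library styles are produced, all as :class:`~epimap.core.PeptideTile`
lists that :func:`reverse_translate` turns into synthesis-ready oligos:

* **window/offset tiling** — fixed-length peptides walked along each protein
  (e.g. 90-aa tiles at 22-aa offset across a proteome, or 56-aa tiles at
  28-aa offset), optionally with an extra C-terminal tile so the protein end
  is always covered;
* **N-terminal concatenations** — short N-terminal fragments prefixed with a
  spacer residue and concatenated in groups, giving start codons extra
  representation;
* **de Bruijn-sampled tiles** — a fixed budget of window-length tiles chosen
  greedily so that k-mer coverage across the proteome is as uniform as the
  budget allows;
* **saturation mutagenesis** — every position of an epitope (plus flanking
  residues) substituted to each of the 19 alternative amino acids within a
  fixed peptide context, with unmutated wild-type control tiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .codons import nonrare_human_codon_table
from .core import (
    AA_INDEX,
    AA_ORDER,
    CodonTable,
    EpimapError,
    MutationMeta,
    OligoRecord,
    PeptideTile,
    ProteinRecord,
)

logger = logging.getLogger(__name__)

_NT_ALPHABET = frozenset("ACGT")


@dataclass(frozen=True)
class TilingSpec:
    """Parameters of a window/offset tiling library."""

    window: int
    offset: int
    include_cterm: bool = True
    adaptor5: str = ""
    adaptor3: str = ""
    n_codon_variants: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.offset <= self.window:
            raise EpimapError(f"need 1 <= offset <= window, got {self.offset}, {self.window}")
        if self.n_codon_variants < 1:
            raise EpimapError("n_codon_variants must be >= 1")


def tile_protein(protein: ProteinRecord, spec: TilingSpec) -> list[PeptideTile]:
    """Cut one protein into window-length tiles at a fixed offset.

    Tiles start at 0, offset, 2*offset, ... while they fit.  With
    ``include_cterm``, if the last arithmetic tile does not end at the
    protein's C terminus an extra tile over the final ``window`` residues is
    appended so every residue is covered.  A protein shorter than the window
    yields a single full-length tile.
    """
    L = len(protein)
    seq = protein.sequence
    if L <= spec.window:
        return [
            PeptideTile(
                tile_id=f"{protein.id}|0-{L}",
                parent_id=protein.id,
                start=0,
                end=L,
                sequence=seq,
                kind="internal",
            )
        ]
    tiles = []
    for start in range(0, L - spec.window + 1, spec.offset):
        end = start + spec.window
        tiles.append(
            PeptideTile(
                tile_id=f"{protein.id}|{start}-{end}",
                parent_id=protein.id,
                start=start,
                end=end,
                sequence=seq[start:end],
                kind="internal",
            )
        )
    if spec.include_cterm and tiles[-1].end != L:
        start = L - spec.window
        tiles.append(
            PeptideTile(
                tile_id=f"{protein.id}|{start}-{L}",
                parent_id=protein.id,
                start=start,
                end=L,
                sequence=seq[start:],
                kind="c_terminal",
            )
        )
    return tiles


def tile_proteome(proteins: Iterable[ProteinRecord], spec: TilingSpec) -> list[PeptideTile]:
    """Tile every protein in a collection (see :func:`tile_protein`)."""
    out: list[PeptideTile] = []
    for protein in proteins:
        out.extend(tile_protein(protein, spec))
    return out


def concat_nterm_fragments(
    proteins: Sequence[ProteinRecord],
    frag_len: int = 29,
    group_size: int = 3,
    spacer_aa: str = "D",
) -> list[PeptideTile]:
    """Concatenate spacer-prefixed N-terminal fragments into composite tiles.

    Each unit is ``spacer_aa`` followed by the first ``frag_len`` residues of
    one protein; ``group_size`` units are joined per tile (sequentially, in
    input order).  Leftover fragments form a final, shorter concatenation.
    Proteins not starting with methionine are skipped with a warning;
    proteins shorter than ``frag_len`` contribute their whole sequence.
    """
    if not proteins:
        raise EpimapError("no proteins to concatenate")
    if spacer_aa not in AA_INDEX:
        raise EpimapError(f"spacer {spacer_aa!r} is not a canonical residue")
    units: list[tuple[str, str]] = []
    for protein in proteins:
        if not protein.sequence.startswith("M"):
            logger.warning("protein %r does not start with M; skipped", protein.id)
            warnings.warn(
                f"protein {protein.id!r} does not start with M; skipped", stacklevel=2
            )
            continue
        units.append((protein.id, spacer_aa + protein.sequence[:frag_len]))
    if not units:
        raise EpimapError("no methionine-initiated proteins to concatenate")
    tiles = []
    for i in range(0, len(units), group_size):
        group = units[i : i + group_size]
        seq = "".join(u for _, u in group)
        ids = "+".join(pid for pid, _ in group)
        tiles.append(
            PeptideTile(
                tile_id=f"nterm|{ids}",
                parent_id="synthetic",
                start=0,
                end=len(seq),
                sequence=seq,
                kind="n_term_concat",
            )
        )
    return tiles


def _candidate_tiles(proteins: Sequence[ProteinRecord], window: int) -> list[PeptideTile]:
    cands: list[PeptideTile] = []
    for protein in proteins:
        L = len(protein)
        if L <= window:
            cands.append(
                PeptideTile(
                    tile_id=f"{protein.id}|0-{L}",
                    parent_id=protein.id,
                    start=0,
                    end=L,
                    sequence=protein.sequence,
                    kind="internal",
                )
            )
            continue
        for start in range(0, L - window + 1):
            cands.append(
                PeptideTile(
                    tile_id=f"{protein.id}|{start}-{start + window}",
                    parent_id=protein.id,
                    start=start,
                    end=start + window,
                    sequence=protein.sequence[start : start + window],
                    kind="internal",
                )
            )
    return cands


def kmer_multiset(sequence: str, k: int) -> list[str]:
    """All k-mers of a sequence (the whole sequence if shorter than k)."""
    if len(sequence) < k:
        return [sequence]
    return [sequence[i : i + k] for i in range(len(sequence) - k + 1)]


def debruijn_sample_tiles(
    proteins: Sequence[ProteinRecord],
    window: int,
    target_count: int,
    k: int = 8,
    seed: int = 0,
) -> list[PeptideTile]:
    """Select ``target_count`` window-length tiles with near-uniform k-mer coverage.

    Candidate tiles are every possible start in every protein (a protein
    shorter than the window contributes its full sequence).  Tiles are chosen
    greedily: at each step the candidate whose k-mers currently have the
    lowest mean coverage (over already-selected tiles) is taken, ties broken
    uniformly at random under ``seed``.  Deterministic given the seed.
    """
    if target_count < 1:
        raise EpimapError("target_count must be >= 1")
    cands = _candidate_tiles(proteins, window)
    if target_count > len(cands):
        raise EpimapError(
            f"target_count {target_count} exceeds {len(cands)} candidate starts"
        )
    if target_count == len(cands):
        return cands

    # index k-mers once; coverage[] counts occurrences in selected tiles
    kmer_ids: dict[str, int] = {}
    cand_kmers: list[np.ndarray] = []
    for tile in cands:
        ids = []
        for km in kmer_multiset(tile.sequence, k):
            ids.append(kmer_ids.setdefault(km, len(kmer_ids)))
        cand_kmers.append(np.array(ids, dtype=np.intp))
    coverage = np.zeros(len(kmer_ids), dtype=float)

    rng = np.random.default_rng(seed)
    remaining = list(range(len(cands)))
    chosen: list[int] = []
    for _ in range(target_count):
        means = np.array([coverage[cand_kmers[i]].mean() for i in remaining])
        best = np.flatnonzero(means == means.min())
        pick = remaining.pop(best[rng.integers(len(best))])
        chosen.append(pick)
        np.add.at(coverage, cand_kmers[pick], 1.0)
    return [cands[i] for i in chosen]


def saturation_mutagenesis(
    context: str,
    epitope_span: tuple[int, int],
    flank: int = 2,
    context_id: str = "synthetic",
    n_wt_controls: int = 2,
) -> list[PeptideTile]:
    """Enumerate all single-substitution mutants of an epitope in its context.

    Every position of ``epitope_span`` (0-based half-open within ``context``)
    expanded by ``flank`` residues on each side is substituted to each of the
    19 alternative amino acids, each mutant carried in the full context.
    ``n_wt_controls`` unmutated copies of the context are appended as
    wild-type controls.
    """
    lo, hi = epitope_span
    lo -= flank
    hi += flank
    if not (0 <= lo < hi <= len(context)):
        raise EpimapError(
            f"epitope span {epitope_span} with flank {flank} falls outside the context"
        )
    bad = set(context) - set(AA_ORDER)
    if bad:
        raise EpimapError(f"context contains non-canonical residues {sorted(bad)}")
    tiles: list[PeptideTile] = []
    for pos in range(lo, hi):
        wt = context[pos]
        for mut in AA_ORDER:
            if mut == wt:
                continue
            seq = context[:pos] + mut + context[pos + 1 :]
            tiles.append(
                PeptideTile(
                    tile_id=f"{context_id}|{pos}{wt}{mut}",
                    parent_id="synthetic",
                    start=0,
                    end=len(seq),
                    sequence=seq,
                    kind="mutant",
                    meta=MutationMeta(position=pos, wt_aa=wt, mut_aa=mut),
                )
            )
    for i in range(n_wt_controls):
        tiles.append(
            PeptideTile(
                tile_id=f"{context_id}|WT{i + 1}",
                parent_id="synthetic",
                start=0,
                end=len(context),
                sequence=context,
                kind="wt_control",
            )
        )
    return tiles


def _sample_nt(peptide: str, table: CodonTable, rng: np.random.Generator) -> str:
    parts = []
    for aa in peptide:
        codons = table.codons[aa]
        if len(codons) == 1:
            parts.append(codons[0])
        else:
            w = np.asarray(table.weights[aa], dtype=float)
            parts.append(codons[rng.choice(len(codons), p=w / w.sum())])
    return "".join(parts)


def _rotate_variant(base_nt: str, peptide: str, table: CodonTable, seen: set[str]) -> str:
    # Deterministic fallback: swap one codon at a time, scanning positions
    # left to right and alternatives in table order.
    for i, aa in enumerate(peptide):
        for codon in table.codons[aa]:
            cand = base_nt[: 3 * i] + codon + base_nt[3 * i + 3 :]
            if cand not in seen:
                return cand
    raise EpimapError(
        "cannot generate another distinct codon variant for peptide "
        f"{peptide!r} under the given codon table"
    )


def reverse_translate(
    tiles: Sequence[PeptideTile],
    codon_table: CodonTable | None = None,
    n_variants: int = 2,
    seed: int = 0,
    max_retries: int = 100,
) -> list[OligoRecord]:
    """Reverse-translate tiles into ``n_variants`` distinct oligos each.

    Codons are sampled per residue from ``codon_table`` (default: non-rare
    human codons, uniform).  Variants of one tile are guaranteed pairwise
    distinct: sampling is retried up to ``max_retries`` times on collision,
    then a deterministic single-codon rotation is applied.  Deterministic
    given ``seed``.
    """
    if n_variants < 1:
        raise EpimapError("n_variants must be >= 1")
    table = codon_table or nonrare_human_codon_table()
    rng = np.random.default_rng(seed)
    oligos: list[OligoRecord] = []
    for tile in tiles:
        seen: set[str] = set()
        for v in range(1, n_variants + 1):
            nt = None
            for _ in range(max_retries):
                cand = _sample_nt(tile.sequence, table, rng)
                if cand not in seen:
                    nt = cand
                    break
            if nt is None:
                nt = _rotate_variant(next(iter(seen)), tile.sequence, table, seen)
            seen.add(nt)
            oligos.append(
                OligoRecord(
                    oligo_id=f"{tile.tile_id}#v{v}",
                    tile_id=tile.tile_id,
                    variant_index=v,
                    insert_nt=nt,
                )
            )
    return oligos


def add_adaptors(
    oligos: Sequence[OligoRecord], adaptor5: str, adaptor3: str
) -> list[OligoRecord]:
    """Populate ``full_nt = adaptor5 + insert + adaptor3`` on every oligo."""
    for ad in (adaptor5, adaptor3):
        if not set(ad) <= _NT_ALPHABET:
            raise EpimapError(f"adaptor {ad!r} contains non-ACGT characters")
    return [
        OligoRecord(
            oligo_id=o.oligo_id,
            tile_id=o.tile_id,
            variant_index=o.variant_index,
            insert_nt=o.insert_nt,
            full_nt=adaptor5 + o.insert_nt + adaptor3,
        )
        for o in oligos
    ]
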