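"""Domain types shared by every stage of the pipeline.

The package moves peptides through four representations: proteins are cut
into :class:`PeptideTile` objects, tiles are reverse-translated into
:class:`OligoRecord` objects, screen sequencing counts over oligos become
per-peptide enrichment statistics, and a saturation-mutagenesis screen is
summarized as a :class:`MutagenesisFootprint` — the 20 x N position-specific
scoring matrix (PSSM) of TCR reactivity relative to wild type that drives
proteome scanning.

Conventions fixed here and relied on everywhere else:

* coordinates are 0-based, half-open;
* amino-acid matrix rows are in fixed alphabetical single-letter order
  (``A, C, D, ... Y``), see :data:`AA_ORDER`;
* footprint entries ``s_ij`` live on [0, 1] (0 = no TCR activation,
  1 = activation at least as strong as wild type) with NaN marking
  substitutions that were never measured.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical amino acids in fixed alphabetical single-letter order.
#: This is the row order of every 20 x N matrix the package writes.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

#: Residue codes that can appear in ORF translations but have no PSSM row.
AMBIGUOUS_RESIDUES = frozenset("XBZUJO*")

#: Tile kinds a PeptideTile may carry.
TILE_KINDS = frozenset(
    {"internal", "c_terminal", "n_term_concat", "mutant", "wt_control", "control"}
)

_NT_ALPHABET = frozenset("ACGT")


class EpimapError(ValueError):
    """Base class for domain validation errors."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence; the unit of tiling and scanning."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise EpimapError("protein id must be non-empty")
        if not self.sequence:
            raise EpimapError(f"protein {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MutationMeta:
    """Single-substitution annotation for a mutant tile.

    ``position`` is 0-based within the tile's context sequence.
    """

    position: int
    wt_aa: str
    mut_aa: str

    def __post_init__(self) -> None:
        if self.wt_aa == self.mut_aa:
            raise EpimapError("mutation must change the residue")
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in AA_INDEX:
                raise EpimapError(f"non-canonical residue in mutation: {aa!r}")


@dataclass(frozen=True)
class PeptideTile:
    """A designed peptide with provenance coordinates on its parent protein.

    ``start``/``end`` are 0-based half-open residue coordinates on the parent.
    Tiles without a real parent (concatenations, mutants of a printed context)
    use ``parent_id="synthetic"`` with coordinates on their own sequence.
    """

    tile_id: str
    parent_id: str
    start: int
    end: int
    sequence: str
    kind: str = "internal"
    meta: MutationMeta | None = None

    def __post_init__(self) -> None:
        if self.kind not in TILE_KINDS:
            raise EpimapError(f"unknown tile kind {self.kind!r}")
        if self.end - self.start != len(self.sequence):
            raise EpimapError(
                f"tile {self.tile_id!r}: span [{self.start},{self.end}) does not "
                f"match sequence length {len(self.sequence)}"
            )
        if self.kind == "mutant":
            if self.meta is None:
                raise EpimapError(f"mutant tile {self.tile_id!r} lacks mutation meta")
            pos = self.meta.position
            if not 0 <= pos < len(self.sequence):
                raise EpimapError(f"mutant tile {self.tile_id!r}: position out of range")
            if self.sequence[pos] != self.meta.mut_aa:
                raise EpimapError(
                    f"mutant tile {self.tile_id!r}: sequence does not carry the "
                    f"annotated substitution at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OligoRecord:
    """A reverse-translated nucleotide realization of a tile.

    ``variant_index`` distinguishes synonymous codon variants of the same
    peptide (>= 1).  ``full_nt`` is the synthesis sequence
    ``adaptor5 + insert_nt + adaptor3``; it is ``None`` until adaptors are
    attached.
    """

    oligo_id: str
    tile_id: str
    variant_index: int
    insert_nt: str
    full_nt: str | None = None

    def __post_init__(self) -> None:
        if self.variant_index < 1:
            raise EpimapError("variant_index must be >= 1")
        if len(self.insert_nt) % 3 != 0:
            raise EpimapError(f"oligo {self.oligo_id!r}: insert length not a codon multiple")
        if not set(self.insert_nt) <= _NT_ALPHABET:
            raise EpimapError(f"oligo {self.oligo_id!r}: non-ACGT characters in insert")


@dataclass(frozen=True)
class CodonTable:
    """Amino acid -> ordered list of allowed codons with sampling weights."""

    codons: Mapping[str, tuple[str, ...]]
    weights: Mapping[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        for aa in AA_ORDER:
            if not self.codons.get(aa):
                raise EpimapError(f"codon table lacks codons for {aa}")
            if len(self.codons[aa]) != len(self.weights[aa]):
                raise EpimapError(f"codon/weight length mismatch for {aa}")
            if any(w <= 0 for w in self.weights[aa]):
                raise EpimapError(f"non-positive codon weight for {aa}")

    def n_codons(self, aa: str) -> int:
        return len(self.codons[aa])


class ScreenCounts:
    """Oligo x sample integer count table with sample role labels.

    Parameters
    ----------
    counts
        DataFrame indexed by oligo id with one column per sequencing sample.
    roles
        Mapping sample id -> role, where the role is ``"input"`` for the
        presort library or ``"sorted"`` for a selected replicate.
    """

    def __init__(self, counts: pd.DataFrame, roles: Mapping[str, str]):
        counts = counts.copy()
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()][0]
            raise EpimapError(f"duplicate oligo id {dup!r}")
        if counts.columns.has_duplicates:
            raise EpimapError("duplicate sample id")
        if set(roles) != set(counts.columns):
            raise EpimapError("roles must label exactly the count columns")
        bad = set(roles.values()) - {"input", "sorted"}
        if bad:
            raise EpimapError(f"unknown sample roles: {sorted(bad)}")
        neg = counts.lt(0)
        if neg.any().any():
            col = neg.any()[neg.any()].index[0]
            row = counts.index[neg[col]][0]
            raise EpimapError(f"negative count at oligo {row!r}, sample {col!r}")
        if not all(np.issubdtype(d, np.integer) for d in counts.dtypes):
            if not np.allclose(counts.to_numpy(), counts.to_numpy().round()):
                raise EpimapError("counts must be integers")
            counts = counts.round().astype(np.int64)
        self.counts = counts
        self.roles = dict(roles)
        if not self.input_columns:
            raise EpimapError("need at least one input sample")
        if not self.sorted_columns:
            raise EpimapError("need at least one sorted sample")

    @property
    def input_columns(self) -> list[str]:
        return [c for c in self.counts.columns if self.roles[c] == "input"]

    @property
    def sorted_columns(self) -> list[str]:
        return [c for c in self.counts.columns if self.roles[c] == "sorted"]

    @property
    def oligo_ids(self) -> list[str]:
        return list(self.counts.index)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ScreenCounts)
            and self.roles == other.roles
            and self.counts.equals(other.counts)
        )


class EnrichmentTable:
    """Per-peptide fold-enrichment summary of a screen.

    ``table`` is indexed by peptide id with one ``fe_<replicate>`` column per
    sorted replicate plus ``geomean`` and, when significance was computed,
    ``p_value`` and ``fdr``.
    """

    def __init__(self, table: pd.DataFrame):
        fe_cols = [c for c in table.columns if c.startswith("fe_")]
        if not fe_cols:
            raise EpimapError("enrichment table needs at least one fe_ column")
        if "geomean" not in table.columns:
            raise EpimapError("enrichment table needs a geomean column")
        if (table[fe_cols + ["geomean"]].to_numpy() < 0).any():
            raise EpimapError("fold enrichment must be non-negative")
        if "fdr" in table.columns:
            fdr = table["fdr"].to_numpy()
            if ((fdr < 0) | (fdr > 1)).any():
                raise EpimapError("fdr must lie in [0, 1]")
        self.table = table

    @property
    def replicate_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("fe_")]

    @property
    def geomean(self) -> pd.Series:
        return self.table["geomean"]


class MutagenesisFootprint:
    """The 20 x N PSSM of WT-relative TCR reactivity from saturation mutagenesis.

    Parameters
    ----------
    context_sequence
        Amino-acid sequence of the peptide context that was mutagenized.
    positions
        0-based context positions covered by mutagenesis (epitope + flanks),
        strictly increasing.
    s
        Array of shape (20, len(positions)); rows follow :data:`AA_ORDER`.
        Entries lie on [0, 1]; NaN marks unmeasured substitutions.  The
        wild-type cell of every position equals 1 by construction.
    """

    def __init__(
        self,
        context_sequence: str,
        positions: Sequence[int],
        s: np.ndarray,
    ):
        positions = list(positions)
        s = np.asarray(s, dtype=float)
        if s.shape != (20, len(positions)):
            raise EpimapError(f"s must be 20 x {len(positions)}, got {s.shape}")
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise EpimapError("positions must be strictly increasing")
        if positions and not (0 <= positions[0] and positions[-1] < len(context_sequence)):
            raise EpimapError("positions fall outside the context sequence")
        finite = s[np.isfinite(s)]
        if ((finite < 0) | (finite > 1)).any():
            raise EpimapError("footprint entries must lie on [0, 1]")
        for j, pos in enumerate(positions):
            wt = context_sequence[pos]
            if wt not in AA_INDEX:
                raise EpimapError(f"non-canonical WT residue {wt!r} at position {pos}")
            if not np.isclose(s[AA_INDEX[wt], j], 1.0):
                raise EpimapError(f"WT cell at position {pos} must equal 1")
        self.context_sequence = context_sequence
        self.positions = positions
        self.s = s

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def wt_residues(self) -> list[str]:
        return [self.context_sequence[p] for p in self.positions]

    @property
    def column_labels(self) -> list[str]:
        """``pos:wt`` labels used as CSV header, e.g. ``25:S``."""
        return [f"{p}:{self.context_sequence[p]}" for p in self.positions]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MutagenesisFootprint):
            return NotImplemented
        return (
            self.context_sequence == other.context_sequence
            and self.positions == other.positions
            and np.array_equal(self.s, other.s, equal_nan=True)
        )


@dataclass
class ScoringWeights:
    """Position and residue weights derived from a footprint.

    ``p`` holds the per-position weights (0 outside the epitope interval,
    ``q_j / max(q)`` inside, clipped to [0, 1]); ``q`` the per-position
    information values; ``interval`` the 0-based half-open epitope interval on
    footprint positions; ``a`` the residue weights (uniform 1 by default).
    """

    p: np.ndarray
    q: np.ndarray
    interval: tuple[int, int]
    a: np.ndarray = field(default_factory=lambda: np.ones(20))

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.a.shape != (20,):
            raise EpimapError("residue weights must have one entry per amino acid")
        lo, hi = self.interval
        if not (0 <= lo < hi <= len(self.p)):
            raise EpimapError(f"bad interval [{lo},{hi}) for {len(self.p)} positions")
        if ((self.p < 0) | (self.p > 1)).any():
            raise EpimapError("position weights must lie on [0, 1]")
        outside = np.ones(len(self.p), dtype=bool)
        outside[lo:hi] = False
        if self.p[outside].any():
            raise EpimapError("position weights must be 0 outside the interval")


def validate_proteome(
    records: Iterable[ProteinRecord],
    policy: str = "drop",
) -> list[ProteinRecord]:
    """Validate a protein collection for tiling and scanning.

    Sequences are uppercased.  Records containing residues outside the
    20-letter canonical alphabet (``X``, ``B``, ``Z``, ``U``, ``*``, ...) are
    handled per ``policy``:

    * ``"drop"`` (default) — exclude the record with a logged warning; PSSM
      rows exist only for canonical residues, so such proteins cannot be
      scored anyway;
    * ``"error"`` — raise on the first offending record.

    Raises on an empty collection and on duplicate ids.
    """
    if policy not in {"drop", "error"}:
        raise EpimapError(f"unknown policy {policy!r}")
    seen: set[str] = set()
    out: list[ProteinRecord] = []
    for rec in records:
        if rec.id in seen:
            raise EpimapError(f"duplicate protein id {rec.id!r}")
        seen.add(rec.id)
        seq = rec.sequence.upper()
        bad = set(seq) - set(AA_ORDER)
        if bad:
            msg = f"protein {rec.id!r} contains non-canonical residues {sorted(bad)}"
            if policy == "error":
                raise EpimapError(msg)
            logger.warning("%s; dropped", msg)
            warnings.warn(f"{msg}; dropped", stacklevel=2)
            continue
        out.append(ProteinRecord(rec.id, seq))
    if not seen:
        raise EpimapError("empty proteome")
    return out
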