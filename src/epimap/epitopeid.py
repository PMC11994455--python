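"""Proteome scanning for TCR cross-reactive peptides from a mutagenesis footprint.

The footprint's 20 x N matrix s_ij (WT-relative reactivity of substitution i
at position j) is first condensed into per-position information values

    q_j = (-s_WT,j + sum_i (1 - s_ij)) / (20 - 1),

the average activation decrease caused by substituting position j (with the
denominator renormalized to the number of measured substitutions when cells
are missing).  The epitope interval is the continuous range spanning all
positions with q_j >= 0.5 * max(q); positions outside it receive position
weight p_j = 0, positions inside p_j = q_j / max(q).  A query k-mer x of
length N is then scored

    S(x) = sum_j p_j * a_{x_j} * s_{x_j, j},

a position-weighted PSSM lookup (a_i are residue weights, uniform 1 by
default), and reported as the percentage of the theoretical maximum
S_max = sum_j p_j * max(a); the wild-type epitope scores exactly 100%.
Sliding this score across every k-mer of a proteome ranks candidate
cross-reactive peptides, optionally restricted to a precomputed list of
MHC-binding peptides.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    AA_INDEX,
    EpimapError,
    MutagenesisFootprint,
    ProteinRecord,
    ScoringWeights,
)

logger = logging.getLogger(__name__)

#: Columns of a scan result table, in output order.
SCAN_COLUMNS = ["rank", "percent_score", "kmer", "protein_id", "offset", "raw_score"]


class NoEpitopeError(EpimapError):
    """Raised when no position shows a positive activation decrease."""


def compute_position_information(
    fp: MutagenesisFootprint, variant: str = "printed"
) -> np.ndarray:
    """Per-position information q_j: average activation decrease on substitution.

    ``variant="printed"`` evaluates q_j = (-s_WT,j + sum_i (1-s_ij)) / m with
    m the number of measured substitutions at position j (m = 19 when fully
    observed); it reaches 18/19, not 1, when every substitution abolishes
    activation.  ``variant="mean_decrease"`` drops the -s_WT,j term, giving
    the plain mean of (1 - s_ij) over measured substitutions, which reaches 1
    in the same case.
    """
    if variant not in {"printed", "mean_decrease"}:
        raise EpimapError(f"unknown q variant {variant!r}")
    q = np.empty(fp.n_positions)
    for j, pos in enumerate(fp.positions):
        wt_row = AA_INDEX[fp.context_sequence[pos]]
        col = fp.s[:, j]
        sub = np.delete(col, wt_row)
        sub = sub[np.isfinite(sub)]
        if len(sub) == 0:
            raise EpimapError(f"position {pos} has no measured substitutions")
        total = float(np.sum(1.0 - sub))
        if variant == "printed":
            q[j] = (-1.0 + total) / len(sub)  # s_WT,j = 1 by construction
        else:
            q[j] = total / len(sub)
    return q


def define_epitope_interval(q: np.ndarray) -> tuple[int, int]:
    """Continuous range spanning all positions with q_j >= 0.5 * max(q).

    Qualifying positions need not be contiguous; the spanning half-open range
    [min, max+1) is returned.  Raises :class:`NoEpitopeError` when
    max(q) <= 0 (no position loses activation on substitution).
    """
    q = np.asarray(q, dtype=float)
    qmax = q.max()
    if qmax <= 0:
        raise NoEpitopeError("no epitope detected: max(q) <= 0")
    idx = np.flatnonzero(q >= 0.5 * qmax)
    return int(idx[0]), int(idx[-1]) + 1


def position_weights(q: np.ndarray, interval: tuple[int, int]) -> np.ndarray:
    """p_j = q_j / max(q) inside the interval (clipped to [0,1]), 0 outside."""
    q = np.asarray(q, dtype=float)
    p = np.zeros_like(q)
    lo, hi = interval
    p[lo:hi] = np.clip(q[lo:hi] / q.max(), 0.0, 1.0)
    return p


def make_scoring_weights(
    fp: MutagenesisFootprint,
    residue_weights: np.ndarray | None = None,
    q_variant: str = "printed",
) -> ScoringWeights:
    """Derive q, the epitope interval and position weights from a footprint."""
    q = compute_position_information(fp, variant=q_variant)
    interval = define_epitope_interval(q)
    p = position_weights(q, interval)
    a = np.ones(20) if residue_weights is None else np.asarray(residue_weights, float)
    return ScoringWeights(p=p, q=q, interval=interval, a=a)


def _scan_block(weights: ScoringWeights, n_positions: int, window: int | None) -> tuple[int, int]:
    """Contiguous block of footprint positions scored against a query k-mer.

    Defaults to the epitope interval itself; a wider window keeps the
    interval inside the block, anchored at the interval start and clipped to
    fit the footprint.
    """
    lo, hi = weights.interval
    if window is None:
        window = hi - lo
    if window < hi - lo:
        raise EpimapError(
            f"window {window} is smaller than the epitope interval [{lo},{hi})"
        )
    if window > n_positions:
        raise EpimapError(f"window {window} exceeds {n_positions} footprint positions")
    start = min(lo, n_positions - window)
    return start, start + window


def _contributions(fp: MutagenesisFootprint, weights: ScoringWeights) -> np.ndarray:
    """C[i, j] = (p_j * a_i) * s_ij with NaN cells contributing 0."""
    if len(weights.p) != fp.n_positions:
        raise EpimapError("weights do not match the footprint's positions")
    W = weights.p[None, :] * weights.a[:, None]
    return W * np.nan_to_num(fp.s, nan=0.0)


def max_score(weights: ScoringWeights) -> float:
    """Theoretical maximum S_max = sum_j p_j * max(a) (WT cells are 1)."""
    return float(weights.p.sum() * weights.a.max())


def score_sequence(
    kmer: str,
    fp: MutagenesisFootprint,
    weights: ScoringWeights,
    window: int | None = None,
) -> float:
    """Raw score S of one query k-mer against the footprint.

    The k-mer length must equal the scan window (default: the epitope
    interval width).
    """
    block_lo, block_hi = _scan_block(weights, fp.n_positions, window)
    if len(kmer) != block_hi - block_lo:
        raise EpimapError(
            f"k-mer length {len(kmer)} does not match scan window {block_hi - block_lo}"
        )
    C = _contributions(fp, weights)
    S = 0.0
    for j in range(block_lo, block_hi):
        aa = kmer[j - block_lo]
        if aa not in AA_INDEX:
            raise EpimapError(f"residue {aa!r} has no matrix row")
        S += C[AA_INDEX[aa], j]
    return S


def _rank_dense(percent: np.ndarray) -> np.ndarray:
    # dense 1-based ranks on descending percent; ties share a rank
    uniq = np.unique(-percent)
    return np.searchsorted(uniq, -percent) + 1


def scan_proteome(
    proteins: Iterable[ProteinRecord],
    fp: MutagenesisFootprint,
    weights: ScoringWeights | None = None,
    window: int | None = None,
    unique: bool = False,
) -> pd.DataFrame:
    """Score every k-mer of a proteome against the footprint and rank them.

    Every window-length substring of every protein (increment one residue) is
    scored; proteins shorter than the window are skipped with a warning.
    Results are sorted by descending percent score with deterministic
    tie-breaks (k-mer lexicographic, then protein id, then offset) and carry
    dense 1-based ranks on the percent score.  ``unique=True`` keeps only the
    first occurrence of each distinct k-mer.

    Returns a DataFrame with columns ``rank, percent_score, kmer, protein_id,
    offset, raw_score``.
    """
    if weights is None:
        weights = make_scoring_weights(fp)
    block_lo, block_hi = _scan_block(weights, fp.n_positions, window)
    N = block_hi - block_lo
    C = _contributions(fp, weights)
    smax = max_score(weights)
    if smax <= 0:
        raise EpimapError("maximum score is not positive; weights are degenerate")

    kmers: list[str] = []
    pids: list[str] = []
    offsets: list[int] = []
    scores: list[np.ndarray] = []
    n_scanned = 0
    for protein in proteins:
        L = len(protein)
        if L < N:
            logger.warning("protein %r shorter than window %d; skipped", protein.id, N)
            warnings.warn(
                f"protein {protein.id!r} shorter than window {N}; skipped",
                stacklevel=2,
            )
            continue
        n_scanned += 1
        codes = np.fromiter(
            (AA_INDEX[aa] for aa in protein.sequence), dtype=np.intp, count=L
        )
        n_kmers = L - N + 1
        S = np.zeros(n_kmers)
        for j in range(N):
            S += C[codes[j : j + n_kmers], block_lo + j]
        scores.append(S)
        seq = protein.sequence
        kmers.extend(seq[o : o + N] for o in range(n_kmers))
        pids.extend([protein.id] * n_kmers)
        offsets.extend(range(n_kmers))
    if n_scanned == 0:
        raise EpimapError("empty proteome after filtering")

    raw = np.concatenate(scores)
    percent = 100.0 * raw / smax
    df = pd.DataFrame(
        {
            "percent_score": percent,
            "kmer": kmers,
            "protein_id": pids,
            "offset": offsets,
            "raw_score": raw,
        }
    )
    df = df.sort_values(
        ["percent_score", "kmer", "protein_id", "offset"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    if unique:
        df = df.drop_duplicates(subset="kmer", keep="first").reset_index(drop=True)
    df["rank"] = _rank_dense(df["percent_score"].to_numpy())
    return df[SCAN_COLUMNS]


def filter_binders(results: pd.DataFrame, binder_kmers: Iterable[str]) -> pd.DataFrame:
    """Keep only k-mers present in a precomputed MHC-binder list; re-rank densely."""
    binders = set(binder_kmers)
    out = results[results["kmer"].isin(binders)].reset_index(drop=True).copy()
    if len(out):
        out["rank"] = _rank_dense(out["percent_score"].to_numpy())
    return out[SCAN_COLUMNS]
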