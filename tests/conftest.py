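"""Shared fixtures and the independent naive-scan oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest

from epimap import AA_INDEX, AA_ORDER, MutagenesisFootprint

# Published mutagenesis contexts (epitope flanked by its natural context).
SIINFEKL_CONTEXT = "LPFASGTMSMLVLLPDEVSGLEQLESIINFEKLTEWTSSNVMEERKIKVYLPRMKME"
SIINFEKL_SPAN = (25, 33)
MAGEA3_CONTEXT = "VIFSKASSSLQLVFGIELMEVDPIGHLYIFATCLGLSYDGLLGDNQIMPKAGLLIIV"
MAGEA3_SPAN = (19, 28)
PP65_TILE = "RLKAESTVAPEEDTDEDSDNEIHNPAVFTWPPWQAGILARNLVPMVATVQSGARA"

MUTAGENESIS_ADAPTOR5 = "ACCCGTCACCGGCCA"
MUTAGENESIS_ADAPTOR3 = "GGGCTCGCCACGTCG"


def make_random_footprint(
    seed: int,
    context_len: int = 30,
    first_pos: int = 8,
    n_positions: int = 13,
    strict_core: tuple[int, int] | None = (2, 11),
    missing_frac: float = 0.0,
) -> MutagenesisFootprint:
    """Random valid footprint; core positions have low s, flanks high."""
    rng = np.random.default_rng(seed)
    aa = np.array(list(AA_ORDER))
    context = "".join(aa[rng.integers(20, size=context_len)])
    positions = list(range(first_pos, first_pos + n_positions))
    s = rng.uniform(0, 1, (20, n_positions))
    if strict_core is not None:
        lo, hi = strict_core
        s[:, lo:hi] = rng.uniform(0, 0.3, (20, hi - lo))
        s[:, :lo] = rng.uniform(0.7, 1.0, (20, lo))
        s[:, hi:] = rng.uniform(0.7, 1.0, (20, n_positions - hi))
    if missing_frac > 0:
        mask = rng.random((20, n_positions)) < missing_frac
        s[mask] = np.nan
    for j, pos in enumerate(positions):
        s[AA_INDEX[context[pos]], j] = 1.0
    fp = MutagenesisFootprint(context, positions, s)
    return fp


def naive_scan(proteins, fp, weights, window=None):
    """Brute-force per-k-mer scoring loop: the oracle the vectorized scan
    must reproduce bit-exactly (same float operations, same order)."""
    lo, hi = weights.interval
    N = (hi - lo) if window is None else window
    start = min(lo, fp.n_positions - N)
    smax = float(weights.p.sum() * weights.a.max())
    rows = []
    for prot in proteins:
        if len(prot.sequence) < N:
            continue
        for off in range(len(prot.sequence) - N + 1):
            kmer = prot.sequence[off : off + N]
            S = 0.0
            for j in range(N):
                i = AA_INDEX[kmer[j]]
                sij = fp.s[i, start + j]
                if not math.isfinite(sij):
                    sij = 0.0
                S += (weights.p[start + j] * weights.a[i]) * sij
            rows.append([100.0 * S / smax, kmer, prot.id, off, S])
    rows.sort(key=lambda r: (-r[0], r[1], r[2], r[3]))
    ranks, prev, r = [], None, 0
    for row in rows:
        if row[0] != prev:
            r += 1
            prev = row[0]
        ranks.append(r)
    return [[rk] + row for rk, row in zip(ranks, rows)]


@pytest.fixture
def random_footprint():
    return make_random_footprint(seed=11)
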