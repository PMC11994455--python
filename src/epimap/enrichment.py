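"""Deconvolution of pooled-screen counts into per-peptide enrichment.

The selection readout of a screen is, per peptide, the fold enrichment (FE):
the fractional abundance of the peptide among sorted (selected) cells divided
by its fractional abundance in the presort input library.  Synonymous codon
variants of one peptide are collapsed by their median FE, replicates are
summarized by the geometric mean, and significance is assessed by permuting
the oligo-to-peptide assignment (a published count-based tool such as Mageck
can be substituted for this last step; the permutation test is deliberately
assumption-light plumbing).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .core import EnrichmentTable, EpimapError, ScreenCounts


def fractional_abundance(
    counts: ScreenCounts | pd.DataFrame, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Per-sample frequencies: (count + pseudocount) normalized per column."""
    if pseudocount < 0:
        raise EpimapError("pseudocount must be >= 0")
    df = counts.counts if isinstance(counts, ScreenCounts) else counts
    shifted = df.astype(float) + pseudocount
    sums = shifted.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise EpimapError(f"all-zero sample column {zero.index[0]!r}")
    return shifted / sums


def fold_enrichment(
    freq: pd.DataFrame, input_column: str, sorted_columns: Sequence[str]
) -> pd.DataFrame:
    """FE per oligo and sorted replicate: sorted frequency / input frequency."""
    if input_column not in freq.columns:
        raise EpimapError(f"missing input column {input_column!r}")
    missing = [c for c in sorted_columns if c not in freq.columns]
    if missing:
        raise EpimapError(f"missing sorted columns {missing}")
    inp = freq[input_column]
    if (inp <= 0).any():
        raise EpimapError("input frequencies must be positive (use a pseudocount)")
    return freq[list(sorted_columns)].div(inp, axis=0)


def collapse_codons(
    fe: pd.DataFrame, oligo_to_peptide: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Collapse codon-variant FE to per-peptide FE by the per-replicate median."""
    mapping = pd.Series(dict(oligo_to_peptide)) if not isinstance(
        oligo_to_peptide, pd.Series
    ) else oligo_to_peptide
    unmapped = fe.index.difference(mapping.index)
    if len(unmapped):
        raise EpimapError(f"unmapped oligo id {unmapped[0]!r}")
    labels = mapping.reindex(fe.index)
    return fe.groupby(labels, sort=True).median()


def geomean_across_replicates(fe_per_peptide: pd.DataFrame) -> pd.Series:
    """Geometric mean of FE across replicates; a zero in any replicate gives 0."""
    vals = fe_per_peptide.to_numpy(dtype=float)
    if (vals < 0).any():
        raise EpimapError("fold enrichment must be non-negative")
    with np.errstate(divide="ignore"):
        gm = np.exp(np.mean(np.log(vals), axis=1, where=vals > 0))
    gm = np.where((vals == 0).any(axis=1), 0.0, gm)
    # all-positive rows: plain geometric mean
    pos = (vals > 0).all(axis=1)
    gm[pos] = np.exp(np.log(vals[pos]).mean(axis=1))
    return pd.Series(gm, index=fe_per_peptide.index, name="geomean")


def _null_geomeans(
    fe_values: np.ndarray,
    labels: np.ndarray,
    peptides: np.ndarray,
    rng: np.random.Generator,
) -> pd.Series:
    perm = rng.permutation(len(labels))
    df = pd.DataFrame(fe_values[perm])
    grouped = df.groupby(labels, sort=True).median()
    return geomean_across_replicates(grouped).reindex(peptides)


def permutation_significance(
    fe: pd.DataFrame,
    oligo_to_peptide: Mapping[str, str] | pd.Series,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation p-values and BH FDR for per-peptide geomean enrichment.

    The null is built by shuffling which oligos belong to which peptide
    (variant-group sizes preserved), recomputing the codon collapse and the
    replicate geometric mean each time.  For each peptide,
    ``p = (1 + #{null >= observed}) / (1 + n_permutations)``.
    """
    if n_permutations < 100:
        raise EpimapError("need at least 100 permutations")
    mapping = pd.Series(dict(oligo_to_peptide)) if not isinstance(
        oligo_to_peptide, pd.Series
    ) else oligo_to_peptide
    if len(fe.index) < mapping.nunique():
        raise EpimapError("fewer oligos than peptides")
    observed_pep = collapse_codons(fe, mapping)
    observed = geomean_across_replicates(observed_pep)
    peptides = observed.index.to_numpy()

    labels = mapping.reindex(fe.index).to_numpy()
    vals = fe.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(peptides), dtype=np.int64)
    obs = observed.to_numpy()
    for _ in range(n_permutations):
        null = _null_geomeans(vals, labels, peptides, rng).to_numpy()
        exceed += null >= obs
    p = (1 + exceed) / (1 + n_permutations)
    fdr = false_discovery_control(p, method="bh")
    out = observed_pep.copy()
    out.columns = [f"fe_{c}" for c in observed_pep.columns]
    out["geomean"] = observed
    out["p_value"] = p
    out["fdr"] = fdr
    return out


def run_enrichment(
    counts: ScreenCounts,
    oligo_to_peptide: Mapping[str, str] | pd.Series,
    pseudocount: float = 0.5,
    n_permutations: int | None = 1000,
    seed: int = 0,
) -> EnrichmentTable:
    """Full deconvolution: counts -> per-peptide FE, geomean, p, FDR.

    Each sorted replicate is compared against the (single) input column.
    Set ``n_permutations=None`` to skip the significance stage.
    """
    inputs = counts.input_columns
    if len(inputs) != 1:
        raise EpimapError(f"expected exactly one input column, got {inputs}")
    freq = fractional_abundance(counts, pseudocount)
    fe = fold_enrichment(freq, inputs[0], counts.sorted_columns)
    if n_permutations is None:
        pep = collapse_codons(fe, oligo_to_peptide)
        table = pep.copy()
        table.columns = [f"fe_{c}" for c in pep.columns]
        table["geomean"] = geomean_across_replicates(pep)
        return EnrichmentTable(table)
    return EnrichmentTable(
        permutation_significance(fe, oligo_to_peptide, n_permutations, seed)
    )
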