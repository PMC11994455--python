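"""Build the saturation-mutagenesis footprint (20 x N reactivity PSSM).

Each cell s_ij is the enrichment of the mutant carrying substitution i at
mutagenized position j, relative to the wild-type peptide's enrichment,
clipped to [0, 1]: 0 means the substitution abolished TCR activation, 1 means
activation at least as strong as wild type.  Wild-type cells are 1 by
construction; substitutions never measured stay NaN and are excluded from all
downstream sums.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    AA_INDEX,
    AA_ORDER,
    EnrichmentTable,
    EpimapError,
    MutagenesisFootprint,
    MutationMeta,
    PeptideTile,
)


def annotations_from_tiles(tiles: Iterable[PeptideTile]) -> pd.DataFrame:
    """Mutant annotation table (tile_id, position, wt_aa, mut_aa) from tiles."""
    rows = [
        (t.tile_id, t.meta.position, t.meta.wt_aa, t.meta.mut_aa)
        for t in tiles
        if t.kind == "mutant"
    ]
    return pd.DataFrame(rows, columns=["peptide_id", "position", "wt_aa", "mut_aa"])


def build_footprint(
    enrichment: EnrichmentTable | pd.Series,
    annotations: pd.DataFrame | Mapping[str, MutationMeta],
    wt_peptide_ids: Sequence[str],
    context_sequence: str,
    positions: Sequence[int] | None = None,
) -> MutagenesisFootprint:
    """Assemble a footprint from per-peptide enrichment of a mutagenesis screen.

    Parameters
    ----------
    enrichment
        Per-peptide geometric-mean fold enrichment (an
        :class:`~epimap.core.EnrichmentTable` or a Series indexed by peptide).
    annotations
        Mutant annotations: DataFrame with columns ``peptide_id``,
        ``position``, ``wt_aa``, ``mut_aa`` (or a mapping peptide ->
        :class:`~epimap.core.MutationMeta`).  Each (position, mut_aa) pair may
        be annotated at most once.
    wt_peptide_ids
        Ids of the unmutated wild-type control peptides; their geometric-mean
        enrichment is the denominator of every cell.
    positions
        Mutagenized context positions; inferred from the annotations when
        omitted.
    """
    fe = enrichment.geomean if isinstance(enrichment, EnrichmentTable) else enrichment
    if isinstance(annotations, Mapping):
        annotations = pd.DataFrame(
            [
                (pid, m.position, m.wt_aa, m.mut_aa)
                for pid, m in annotations.items()
            ],
            columns=["peptide_id", "position", "wt_aa", "mut_aa"],
        )
    if not wt_peptide_ids:
        raise EpimapError("need at least one WT control peptide")
    missing = [p for p in wt_peptide_ids if p not in fe.index]
    if missing:
        raise EpimapError(f"WT control {missing[0]!r} absent from enrichment")
    wt_fe = fe.loc[list(wt_peptide_ids)].to_numpy(dtype=float)
    if (wt_fe <= 0).any():
        raise EpimapError("WT control fold enrichment must be positive")
    fe_wt = float(np.exp(np.log(wt_fe).mean()))

    dup = annotations.duplicated(subset=["position", "mut_aa"])
    if dup.any():
        row = annotations[dup].iloc[0]
        raise EpimapError(
            f"duplicate annotation for position {row.position}, substitution {row.mut_aa}"
        )
    if positions is None:
        positions = sorted(annotations["position"].unique())
    positions = list(positions)
    col = {p: j for j, p in enumerate(positions)}

    s = np.full((20, len(positions)), np.nan)
    for j, pos in enumerate(positions):
        wt = context_sequence[pos]
        s[AA_INDEX[wt], j] = 1.0
    for row in annotations.itertuples(index=False):
        if row.position not in col:
            raise EpimapError(f"annotation position {row.position} not in positions")
        if context_sequence[row.position] != row.wt_aa:
            raise EpimapError(
                f"annotation WT {row.wt_aa!r} disagrees with context at {row.position}"
            )
        if row.peptide_id not in fe.index:
            continue  # synthesized but unmeasured: stays NaN
        val = float(fe.loc[row.peptide_id]) / fe_wt
        s[AA_INDEX[row.mut_aa], col[row.position]] = min(max(val, 0.0), 1.0)
    return MutagenesisFootprint(context_sequence, positions, s)


def footprint_to_frame(fp: MutagenesisFootprint) -> pd.DataFrame:
    """20-row DataFrame view: rows amino acids, columns ``pos:wt`` labels."""
    return pd.DataFrame(fp.s, index=list(AA_ORDER), columns=fp.column_labels)


def plot_heatmap(fp: MutagenesisFootprint, path: str) -> None:
    """Render the footprint as a heatmap image (NaN cells blank)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 0.4 * fp.n_positions), 6))
    masked = np.ma.masked_invalid(fp.s)
    im = ax.imshow(masked, aspect="auto", cmap="viridis", vmin=0, vmax=1)
    ax.set_yticks(range(20), list(AA_ORDER))
    ax.set_xticks(range(fp.n_positions), fp.column_labels, rotation=90)
    ax.set_xlabel("mutagenized position (pos:WT)")
    ax.set_ylabel("substituted amino acid")
    fig.colorbar(im, ax=ax, label="reactivity relative to WT")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
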