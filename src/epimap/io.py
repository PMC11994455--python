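"""Readers and writers for the package's file formats.

FASTA (proteins, oligo inserts) goes through Biopython; count tables and
manifests are plain TSV via pandas; footprints are a CSV matrix (rows = amino
acids in fixed alphabetical order, columns = ``pos:wt`` labels, missing cells
written as ``NaN``) plus a JSON sidecar carrying the context sequence and
positions.  All round trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    AA_ORDER,
    EpimapError,
    MutagenesisFootprint,
    OligoRecord,
    PeptideTile,
    ProteinRecord,
    ScreenCounts,
)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    records = [
        ProteinRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise EpimapError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def write_oligo_fasta(oligos: Iterable[OligoRecord], path: str | Path) -> None:
    """Synthesis FASTA: full oligo (with adaptors) when present, else insert."""
    SeqIO.write(
        (
            SeqRecord(Seq(o.full_nt or o.insert_nt), id=o.oligo_id, description="")
            for o in oligos
        ),
        str(path),
        "fasta",
    )


def write_manifest(
    tiles: Sequence[PeptideTile], oligos: Sequence[OligoRecord], path: str | Path
) -> None:
    """TSV manifest joining tiles and their oligo realizations."""
    by_tile = {t.tile_id: t for t in tiles}
    rows = []
    for o in oligos:
        t = by_tile[o.tile_id]
        mut = f"{t.meta.position}{t.meta.wt_aa}>{t.meta.mut_aa}" if t.meta else ""
        rows.append(
            (
                t.tile_id,
                t.parent_id,
                t.start,
                t.end,
                t.kind,
                t.sequence,
                mut,
                o.variant_index,
                o.insert_nt,
                o.full_nt or "",
            )
        )
    pd.DataFrame(
        rows,
        columns=[
            "tile_id",
            "parent_id",
            "start",
            "end",
            "kind",
            "peptide",
            "mutation",
            "variant",
            "insert_nt",
            "full_nt",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path, roles: Mapping[str, str] | str | Path) -> ScreenCounts:
    """Read an oligo x sample count TSV; ``roles`` maps columns to
    input/sorted (inline mapping or a YAML sidecar path)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = df.lt(0)
    if bad.any().any():
        col = bad.any()[bad.any()].index[0]
        row = df.index[bad[col]][0]
        raise EpimapError(f"{path}: negative count at row {row!r}, column {col!r}")
    if isinstance(roles, (str, Path)):
        with open(roles) as fh:
            roles = yaml.safe_load(fh)
    return ScreenCounts(df, roles)


def write_counts_tsv(counts: ScreenCounts, path: str | Path, roles_path: str | Path | None = None) -> None:
    counts.counts.to_csv(path, sep="\t", index_label="oligo_id")
    if roles_path is not None:
        with open(roles_path, "w") as fh:
            yaml.safe_dump(counts.roles, fh)


def read_oligo_map(path: str | Path) -> pd.Series:
    """Two-column TSV (oligo_id, peptide_id) -> Series oligo -> peptide."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise EpimapError(f"{path}: need oligo_id and peptide_id columns")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="peptide_id")


def write_footprint(fp: MutagenesisFootprint, csv_path: str | Path) -> None:
    """Write the 20 x N matrix CSV and its JSON sidecar (``<csv>.json``)."""
    df = pd.DataFrame(fp.s, index=list(AA_ORDER), columns=fp.column_labels)
    df.to_csv(csv_path, index_label="aa", na_rep="NaN", float_format="%.17g")
    sidecar = {
        "context_sequence": fp.context_sequence,
        "positions": fp.positions,
        "wt_residues": fp.wt_residues,
    }
    with open(f"{csv_path}.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_footprint(csv_path: str | Path) -> MutagenesisFootprint:
    df = pd.read_csv(csv_path, index_col=0, float_precision="round_trip")
    if list(df.index) != list(AA_ORDER):
        raise EpimapError(f"{csv_path}: rows must be the 20 amino acids in order")
    with open(f"{csv_path}.json") as fh:
        sidecar = json.load(fh)
    positions = [int(lbl.split(":")[0]) for lbl in df.columns]
    if positions != list(sidecar["positions"]):
        raise EpimapError(f"{csv_path}: header positions disagree with sidecar")
    return MutagenesisFootprint(
        sidecar["context_sequence"], positions, df.to_numpy(dtype=float)
    )


def write_scan_results(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_binder_list(path: str | Path) -> set[str]:
    """Plain-text binder list, one peptide per line; blank lines ignored."""
    with open(path) as fh:
        return {line.strip().upper() for line in fh if line.strip()}
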