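"""Readers and writers for the pipeline's tabular dialects.

All text formats are UTF-8 with a header row, '.' decimal separator and
no thousands separators; TSV for tables emitted by annotation /
orthology tooling, CSV for the trait table, standard newick for trees.
CRLF and LF line endings are accepted identically.  Malformed files
raise :class:`FormatError` carrying the offending file (and, where
determinable, location) rather than propagating a bare pandas error.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .classify import IRG_CLASSES, DomainArchitecture, RepertoireCounts
from .geneloss import LossSummary, PanGeneMatrix
from .pgls import load_tree

__all__ = [
    "FormatError",
    "read_domain_table",
    "write_domain_table",
    "read_repertoire_counts",
    "write_repertoire_counts",
    "read_pangene_matrix",
    "write_pangene_matrix",
    "read_trait_table",
    "write_trait_table",
    "read_newick",
    "write_results",
    "write_loss_summaries",
]


class FormatError(ValueError):
    """A file violated the expected dialect."""

    def __init__(self, path, message: str):
        super().__init__(f"{path}: {message}")
        self.path = str(path)


def _read_table(path, sep: str, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except Exception as exc:  # pandas raises many flavours
        raise FormatError(path, f"unreadable table: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(path, f"missing required columns {missing}")
    return df


def read_domain_table(path) -> list[DomainArchitecture]:
    """Read a per-species domain-annotation TSV.

    Columns: ``protein_id``, ``species_id``, ``domains`` (comma-separated
    ordered tokens).  Extra columns (e.g. a generator's ``true_class``)
    are ignored.
    """
    df = _read_table(path, "\t", ("protein_id", "species_id", "domains"))
    archs = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        toks = [t for t in str(row.domains).split(",") if t.strip()]
        if not toks:
            raise FormatError(path, f"line {i}: empty domain list")
        archs.append(DomainArchitecture(row.protein_id, toks, source=str(path)))
    return archs


def write_domain_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_repertoire_counts(counts: list[RepertoireCounts], path) -> None:
    rows = [
        {"species_id": rc.species_id, **{c.value: rc.counts[c] for c in IRG_CLASSES}}
        for rc in counts
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_repertoire_counts(path) -> list[RepertoireCounts]:
    req = ("species_id",) + tuple(c.value for c in IRG_CLASSES)
    df = _read_table(path, "\t", req)
    out = []
    for i, row in df.iterrows():
        try:
            counts = {c: int(row[c.value]) for c in IRG_CLASSES}
        except ValueError as exc:
            raise FormatError(path, f"row {i + 2}: non-integer count ({exc})") from exc
        out.append(RepertoireCounts(species_id=row["species_id"], counts=counts))
    return out


_BOOL = {"1": True, "0": False, "true": True, "false": False, "True": True, "False": False}


def read_pangene_matrix(path, triplicate_id: str | None = None) -> PanGeneMatrix:
    """Read a pan-gene TSV (one triplicate).

    Columns: ``orthogroup_id``, ``crop_species``, ``wild_species``,
    ``outgroup_species``, presence flags ``crop``/``wild``/``outgroup``
    (0/1), ``outgroup_gene_id`` (empty when absent), ``is_irg`` (0/1).
    """
    req = (
        "orthogroup_id", "crop_species", "wild_species", "outgroup_species",
        "crop", "wild", "outgroup", "outgroup_gene_id", "is_irg",
    )
    df = _read_table(path, "\t", req)
    if df.empty:
        raise FormatError(path, "no orthogroup rows")
    for col in ("crop", "wild", "outgroup", "is_irg"):
        bad = ~df[col].isin(_BOOL)
        if bad.any():
            line = int(df.index[bad][0]) + 2
            raise FormatError(
                path, f"line {line}, column {col!r}: not a 0/1 flag ({df.loc[bad, col].iloc[0]!r})"
            )
        df[col] = df[col].map(_BOOL)
    tid = triplicate_id or str(df["crop_species"].iloc[0])
    return PanGeneMatrix(
        triplicate_id=tid,
        crop_species=df["crop_species"].iloc[0],
        wild_species=df["wild_species"].iloc[0],
        outgroup_species=df["outgroup_species"].iloc[0],
        table=df[
            ["orthogroup_id", "crop", "wild", "outgroup", "outgroup_gene_id", "is_irg"]
        ].reset_index(drop=True),
    )


def write_pangene_matrix(m: PanGeneMatrix, path) -> None:
    df = m.table.copy()
    for col in ("crop", "wild", "outgroup", "is_irg"):
        df[col] = df[col].astype(bool).astype(int)
    df.insert(1, "crop_species", m.crop_species)
    df.insert(2, "wild_species", m.wild_species)
    df.insert(3, "outgroup_species", m.outgroup_species)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_trait_table(path) -> pd.DataFrame:
    """Read the crop trait CSV (crop_id, response, predictors)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(path, f"unreadable CSV: {exc}") from exc
    if "crop_id" not in df.columns:
        raise FormatError(path, "missing required column 'crop_id'")
    return df


def write_trait_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def read_newick(path):
    """Read and validate a newick tree (branch lengths mandatory)."""
    try:
        return load_tree(str(path), is_path=True)
    except ValueError as exc:
        raise FormatError(path, str(exc)) from exc


def write_results(df: pd.DataFrame, path) -> None:
    """Write a results table at full float precision."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.17g")


def write_loss_summaries(summaries: list[LossSummary], path) -> None:
    rows = [vars(s) for s in summaries]
    write_results(pd.DataFrame(rows), path)
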