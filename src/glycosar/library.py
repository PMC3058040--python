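"""Peptide library model: residue variants, anchor substitutions, indicators.

The glycopeptide scaffold keeps an invariant template (the CII259-273 minimal
epitope backbone) and varies two anchor positions, p260 and p263, over sets of
(un)natural amino-acid building blocks. Because most building blocks are
unnatural, residue codes are free string tokens rather than one-letter IUPAC
symbols.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ResidueVariant",
    "PeptideVariant",
    "enumerate_library",
    "encode_indicators",
    "decode_indicators",
    "read_residue_set",
    "write_library",
    "designed_residues",
]

ANCHOR_POSITIONS = ("p260", "p263")


@dataclass(frozen=True)
class ResidueVariant:
    """One amino-acid building block available at an anchor position."""

    code: str
    name: str = ""
    descriptors: dict[str, float] | None = None
    natural: bool = False


@dataclass(frozen=True)
class PeptideVariant:
    """A template peptide with substitutions at the two anchor positions."""

    id: str
    p260: str
    p263: str
    template: tuple[str, ...] = field(default=())

    def anchors(self) -> tuple[str, str]:
        return (self.p260, self.p263)


def _check_unique(codes, what: str) -> list[str]:
    codes = list(codes)
    if not codes:
        raise ValueError(f"{what} must be non-empty")
    dupes = pd.Series(codes).duplicated()
    if dupes.any():
        raise ValueError(f"duplicate codes in {what}: {sorted(set(np.array(codes)[dupes]))}")
    return codes


def enumerate_library(
    p260_set,
    p263_set,
    template=(),
) -> list[PeptideVariant]:
    """Enumerate the full factorial library over two anchor residue sets.

    Returns ``|p260_set| * |p263_set|`` peptides in deterministic p260-major
    order, with ids of the form ``"<p260code>_<p263code>"``. Residue sets may
    be code strings or :class:`ResidueVariant` objects.
    """
    codes260 = [r.code if isinstance(r, ResidueVariant) else str(r) for r in p260_set]
    codes263 = [r.code if isinstance(r, ResidueVariant) else str(r) for r in p263_set]
    _check_unique(codes260, "p260 set")
    _check_unique(codes263, "p263 set")
    tmpl = tuple(template)
    return [
        PeptideVariant(id=f"{a}_{b}", p260=a, p263=b, template=tmpl)
        for a in codes260
        for b in codes263
    ]


def encode_indicators(
    peptides,
    p260_levels,
    p263_levels,
) -> pd.DataFrame:
    """Binary indicator design matrix for anchor identities.

    One 0/1 column per (position, residue) level, position-major with levels
    in lexicographic order within a position; every row has exactly one 1
    among the p260 columns and one among the p263 columns (row sum 2).
    """
    lv260 = sorted(_check_unique(p260_levels, "p260 levels"))
    lv263 = sorted(_check_unique(p263_levels, "p263 levels"))
    cols = [f"p260:{c}" for c in lv260] + [f"p263:{c}" for c in lv263]
    rows = []
    ids = []
    for pep in peptides:
        if pep.p260 not in lv260:
            raise ValueError(f"peptide {pep.id}: p260 residue {pep.p260!r} not in level list")
        if pep.p263 not in lv263:
            raise ValueError(f"peptide {pep.id}: p263 residue {pep.p263!r} not in level list")
        row = np.zeros(len(cols), dtype=int)
        row[lv260.index(pep.p260)] = 1
        row[len(lv260) + lv263.index(pep.p263)] = 1
        rows.append(row)
        ids.append(pep.id)
    if not rows:
        raise ValueError("no peptides to encode")
    return pd.DataFrame(rows, index=ids, columns=cols)


def decode_indicators(matrix: pd.DataFrame) -> list[tuple[str, str, str]]:
    """Recover (id, p260, p263) tuples from an indicator matrix."""
    out = []
    for pid, row in matrix.iterrows():
        hits = row[row == 1].index
        p260 = [c.split(":", 1)[1] for c in hits if c.startswith("p260:")]
        p263 = [c.split(":", 1)[1] for c in hits if c.startswith("p263:")]
        if len(p260) != 1 or len(p263) != 1:
            raise ValueError(f"row {pid} is not a valid indicator row")
        out.append((str(pid), p260[0], p263[0]))
    return out


# ---------------------------------------------------------------------------
# I/O and shipped residue sets
# ---------------------------------------------------------------------------

def read_residue_set(path) -> list[ResidueVariant]:
    """Read a residue set from TSV/CSV with columns code, name, [descriptors]."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if "code" not in df.columns:
        raise ValueError(f"{path}: missing required 'code' column")
    _check_unique(df["code"].astype(str), f"residue set {path.name}")
    desc_cols = [
        c for c in df.columns if c not in {"code", "name", "natural", "position"}
    ]
    out = []
    for _, row in df.iterrows():
        desc = (
            {c: float(row[c]) for c in desc_cols} if desc_cols else None
        )
        out.append(
            ResidueVariant(
                code=str(row["code"]),
                name=str(row.get("name", "")),
                descriptors=desc,
                natural=bool(row.get("natural", False)),
            )
        )
    return out


def write_library(peptides, path) -> None:
    """Write a peptide library as TSV (id, p260, p263)."""
    pd.DataFrame(
        [(p.id, p.p260, p.p263) for p in peptides], columns=["id", "p260", "p263"]
    ).to_csv(path, sep="\t", index=False)


def designed_residues(position: str) -> list[ResidueVariant]:
    """The 7+7 residues carried forward into the designed library.

    p260 (Aq P1 pocket): Ile, homoleucine, cyclohexylglycine,
    cyclopropylalanine, 4-thiazolylalanine, Gln and 2-aminoindane-2-carboxylic
    acid (Aic). p263 (Aq P4 / DR4 P1): Phe, 4-fluorophenylalanine,
    m-methylphenylalanine, 3-cyclohexylalanine, Tyr, 4-pyridylalanine and
    4-thiazolylalanine.
    """
    from .responses import _fixture_path

    if position not in ANCHOR_POSITIONS:
        raise ValueError(f"position must be one of {ANCHOR_POSITIONS}")
    df = pd.read_csv(_fixture_path("designed_residues.tsv"), sep="\t")
    df = df[df["position"] == position]
    _check_unique(df["code"].astype(str), f"designed {position} set")
    return [
        ResidueVariant(
            code=str(r["code"]), name=str(r["name"]), natural=bool(r["natural"])
        )
        for _, r in df.iterrows()
    ]
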