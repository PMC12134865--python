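"""Text I/O for the pipeline's one file dialect.

Matrices are tab-delimited UTF-8: rows are features, the first column
holds feature IDs, the header row holds sample IDs, and missing cells
are written as ``NA``. Group labels travel in a two-column
sample/group table. Gene sets use the GMT convention (name, description,
then member IDs, tab-separated); a signed signature becomes two sets,
``NAME_UP`` and ``NAME_DOWN``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from sigrev.containers import OmicsMatrix, PerturbationReference
from sigrev.signature import SignatureEntry, SignedSignature

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_groups",
    "write_groups",
    "read_omics",
    "write_omics",
    "read_table",
    "write_table",
    "read_gmt",
    "write_gmt",
    "signature_to_gmt",
    "signature_from_gmt",
    "read_reference",
    "write_reference",
]

NA = "NA"


def read_matrix(path) -> pd.DataFrame:
    """Read a feature-by-sample matrix; ``NA`` cells become NaN."""
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[NA], keep_default_na=False
    )
    if df.index.duplicated().any():
        dups = list(df.index[df.index.duplicated()])
        raise ValueError(f"{path}: duplicate feature IDs: {dups[:5]}")
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep=NA, index_label="feature_id")


def read_groups(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["sample_id", "group"]:
        raise ValueError(
            f"{path}: expected columns sample_id, group; got {list(df.columns[:2])}"
        )
    return pd.Series(df["group"].to_numpy(), index=df["sample_id"], name="group")


def write_groups(groups: pd.Series, path) -> None:
    pd.DataFrame({"sample_id": groups.index, "group": groups.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_omics(matrix_path, groups_path, group_levels=None) -> OmicsMatrix:
    return OmicsMatrix(read_matrix(matrix_path), read_groups(groups_path), group_levels)


def write_omics(matrix: OmicsMatrix, matrix_path, groups_path) -> None:
    write_matrix(matrix.values, matrix_path)
    write_groups(matrix.groups, groups_path)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep=NA, index=False)


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file into {set name: member IDs}.

    Malformed lines (< 3 tab-separated fields) raise with the line
    number.
    """
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT requires name, description and "
                    f">= 1 member, found {len(fields)} field(s)"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = fields[2:]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "sigrev") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def signature_to_gmt(sig: SignedSignature, path, name: str = "SIGNATURE") -> None:
    write_gmt({f"{name}_UP": sig.up_ids, f"{name}_DOWN": sig.down_ids}, path)


def signature_from_gmt(path, name: str = "SIGNATURE", source: str = "literature") -> SignedSignature:
    sets = read_gmt(path)
    up = sets.get(f"{name}_UP", [])
    down = sets.get(f"{name}_DOWN", [])
    if not up and not down:
        raise ValueError(f"{path}: no {name}_UP / {name}_DOWN sets found")
    src = frozenset([source])
    entries = [SignatureEntry(f, "up", src) for f in up] + [
        SignatureEntry(f, "down", src) for f in down
    ]
    return SignedSignature(entries=entries)


def read_reference(path) -> PerturbationReference:
    """Read a drug-by-gene reference matrix (drugs as rows)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return PerturbationReference(df)


def write_reference(ref: PerturbationReference, path) -> None:
    ref.values.to_csv(path, sep="\t", index_label="drug_id")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
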