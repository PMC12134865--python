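"""Annotation-driven filtering of significant reversers into candidates.

Selection criteria are hard boolean gates applied conjunctively: a drug
is retained iff it is a significant reverser AND FDA-approved AND
available AND has no prior bladder-cancer association AND no reported
carcinogenicity. Every rejected drug carries the full list of gates it
failed.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["ANNOTATION_COLUMNS", "apply_shortlist"]

ANNOTATION_COLUMNS = [
    "drug_id",
    "fda_approved",
    "prior_bladder_cancer_association",
    "carcinogenicity_reported",
    "available",
    "drug_class",
]

_GATES = [
    # (column, value required to pass, rejection reason)
    ("fda_approved", True, "not FDA-approved"),
    ("available", True, "not available"),
    ("prior_bladder_cancer_association", False, "prior bladder cancer association"),
    ("carcinogenicity_reported", False, "carcinogenicity"),
]


def apply_shortlist(
    ranked: pd.DataFrame, annotations: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter ranked significant drugs through the annotation gates.

    Parameters
    ----------
    ranked
        Output of :func:`sigrev.connectivity.rank_drugs` (or any table
        with ``drug_id``; a boolean ``significant`` column, if present,
        restricts the candidate pool to flagged drugs).
    annotations
        Table with the columns of :data:`ANNOTATION_COLUMNS`; every
        candidate drug must have exactly one row.

    Returns
    -------
    (candidates, rejections)
        ``candidates`` keeps the ranked columns plus ``drug_class``;
        ``rejections`` has one row per rejected drug with a
        semicolon-joined ``reasons`` column.
    """
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in annotations.columns]
    if missing_cols:
        raise ValueError(f"annotation table lacks columns: {missing_cols}")
    if annotations["drug_id"].duplicated().any():
        dups = annotations.loc[annotations["drug_id"].duplicated(), "drug_id"]
        raise ValueError(f"duplicate annotation rows for drugs: {list(dups)[:5]}")
    flag_cols = [c for c in ANNOTATION_COLUMNS if c not in ("drug_id", "drug_class")]
    if annotations[flag_cols].isna().to_numpy().any():
        raise ValueError("annotation flags must be explicit booleans, no missing values")

    pool = ranked
    if "significant" in ranked.columns:
        pool = ranked[ranked["significant"]]
    ann = annotations.set_index("drug_id")
    absent = [d for d in pool["drug_id"] if d not in ann.index]
    if absent:
        raise KeyError(f"no annotation row for drug(s): {absent[:5]}")

    kept_rows, rej_rows = [], []
    for _, row in pool.iterrows():
        a = ann.loc[row["drug_id"]]
        reasons = [reason for col, ok, reason in _GATES if bool(a[col]) is not ok]
        if reasons:
            rej_rows.append((row["drug_id"], ";".join(reasons)))
        else:
            out = dict(row)
            out["drug_class"] = a["drug_class"]
            kept_rows.append(out)

    candidates = pd.DataFrame(kept_rows, columns=list(ranked.columns) + ["drug_class"])
    rejections = pd.DataFrame(rej_rows, columns=["drug_id", "reasons"])
    return candidates, rejections
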