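"""Consolidation of multi-source signed features into one disease
signature, and random partitioning of the signature into query tag sets.

A feature enters the signature when every source that reports it agrees
on its direction (present in one source only counts as "unique" and is
kept); any directional disagreement — across sources, or within one
source after protein-to-gene harmonization — routes the feature to the
exclusion list with a reason. The signature is then split into K
near-equal random subsets whose up/down tag lists are the connectivity
queries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SignatureEntry",
    "SignedSignature",
    "SignaturePartition",
    "harmonize_ids",
    "consolidate",
    "partition",
]

log = logging.getLogger(__name__)

DIRECTIONS = ("up", "down")
SOURCES = ("transcriptomics", "proteomics", "literature")


@dataclass(frozen=True)
class SignatureEntry:
    feature_id: str
    direction: str
    sources: frozenset[str]

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {self.direction!r}")
        if not self.sources:
            raise ValueError(f"entry {self.feature_id} has no source")


@dataclass
class SignedSignature:
    """Signed up/down feature sets with provenance and exclusions."""

    entries: list[SignatureEntry] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (feature, reason)

    def __post_init__(self) -> None:
        ids = [e.feature_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("signature entries must be unique per feature")
        overlap = set(ids) & {f for f, _ in self.excluded}
        if overlap:
            raise ValueError(f"features both included and excluded: {sorted(overlap)[:5]}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def up_ids(self) -> list[str]:
        return [e.feature_id for e in self.entries if e.direction == "up"]

    @property
    def down_ids(self) -> list[str]:
        return [e.feature_id for e in self.entries if e.direction == "down"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": [e.feature_id for e in self.entries],
                "direction": [e.direction for e in self.entries],
                "sources": [",".join(sorted(e.sources)) for e in self.entries],
            }
        )

    def exclusions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.excluded, columns=["feature_id", "reason"])

    @classmethod
    def from_lists(
        cls, up: list[str], down: list[str], source: str = "transcriptomics"
    ) -> "SignedSignature":
        """Build a single-source signature from plain up/down ID lists."""
        dup = set(up) & set(down)
        if dup:
            raise ValueError(f"features listed both up and down: {sorted(dup)[:5]}")
        src = frozenset([source])
        entries = [SignatureEntry(f, "up", src) for f in up] + [
            SignatureEntry(f, "down", src) for f in down
        ]
        return cls(entries=entries)


@dataclass
class SignaturePartition:
    """Disjoint near-equal random fragments of a parent signature."""

    subsets: list[SignedSignature]
    seed: int

    @property
    def K(self) -> int:
        return len(self.subsets)


def harmonize_ids(
    features: list[tuple[str, str]], mapping: dict[str, str] | None = None
) -> list[tuple[str, str]]:
    """Map (feature, direction) pairs onto one gene-level namespace.

    Mapped duplicates with one direction collapse to a single entry;
    conflicting directions are both kept so downstream consolidation
    records the conflict. Unmapped features pass through under their
    own ID with a logged warning.
    """
    mapping = mapping or {}
    unmapped = [f for f, _ in features if f not in mapping and mapping]
    if unmapped:
        log.warning(
            "%d features not covered by the ID mapping, carried through as-is "
            "(e.g. %s)", len(unmapped), unmapped[:5],
        )
    seen: dict[tuple[str, str], None] = {}
    for f, d in features:
        seen.setdefault((mapping.get(f, f), d), None)
    return list(seen.keys())


def _directions_by_feature(features: list[tuple[str, str]]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for f, d in features:
        if d not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {d!r} for {f}")
        out.setdefault(f, set()).add(d)
    return out


def consolidate(
    deg_list: list[tuple[str, str]],
    dap_list: list[tuple[str, str]],
    literature_list: list[tuple[str, str]],
) -> SignedSignature:
    """Merge signed feature lists from the three sources.

    A feature reported with one direction everywhere it appears is
    included with the union of its sources ("consistent" if >= 2
    sources, "unique" if one); any disagreement — between sources or
    within a source — excludes it with reason "directional conflict".
    The result is order-independent and sorted by feature ID.
    """
    per_source = {
        "transcriptomics": _directions_by_feature(list(deg_list)),
        "proteomics": _directions_by_feature(list(dap_list)),
        "literature": _directions_by_feature(list(literature_list)),
    }
    all_ids = sorted(set().union(*[set(d) for d in per_source.values()]))
    entries: list[SignatureEntry] = []
    excluded: list[tuple[str, str]] = []
    for fid in all_ids:
        directions: set[str] = set()
        sources: set[str] = set()
        for src, table in per_source.items():
            if fid in table:
                directions |= table[fid]
                sources.add(src)
        if len(directions) > 1:
            excluded.append((fid, "directional conflict"))
        else:
            entries.append(SignatureEntry(fid, directions.pop(), frozenset(sources)))
    return SignedSignature(entries=entries, excluded=excluded)


def partition(
    signature: SignedSignature, K: int, seed: int = 0, stratify: bool = False
) -> SignaturePartition:
    """Randomly split a signature into K near-equal subsets.

    Assignment is uniform without replacement; subset sizes differ by at
    most one. With ``stratify=True`` the up and down features are split
    separately so each subset preserves the parent's direction ratio
    (default off: the split is fully random, so small subsets may be
    one-sided — downstream scoring handles one-sided tag sets).
    """
    n = len(signature)
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if K > n:
        raise ValueError(f"K ({K}) exceeds the number of signature entries ({n})")
    rng = np.random.default_rng(seed)
    entries = sorted(signature.entries, key=lambda e: e.feature_id)

    def split(items: list[SignatureEntry]) -> list[list[SignatureEntry]]:
        order = rng.permutation(len(items))
        shuffled = [items[i] for i in order]
        return [list(chunk) for chunk in np.array_split(np.array(shuffled, dtype=object), K)]

    if stratify:
        ups = [e for e in entries if e.direction == "up"]
        downs = [e for e in entries if e.direction == "down"]
        # pair the larger up-chunks with the smaller down-chunks so total
        # subset sizes still differ by at most one
        chunks = [u + d for u, d in zip(split(ups), list(reversed(split(downs))))]
    else:
        chunks = split(entries)
    subsets = [SignedSignature(entries=list(chunk)) for chunk in chunks]
    return SignaturePartition(subsets=subsets, seed=seed)
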