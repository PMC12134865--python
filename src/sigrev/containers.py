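"""In-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class OmicsMatrix:
    """A feature-by-sample abundance matrix with a two-level group label.

    Parameters
    ----------
    values
        DataFrame with features as rows and samples as columns. ``NaN``
        marks a missing (undetected) cell; transcriptomic matrices carry
        no missing cells, proteomic ones may.
    groups
        Series mapping each sample ID to its group label. Exactly two
        distinct labels are required.
    group_levels
        Ordered pair ``(group1, group2)``; differential statistics are
        oriented group2-vs-group1 (e.g. invasive vs non-invasive).
    """

    values: pd.DataFrame
    groups: pd.Series
    group_levels: tuple[str, str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"samples without a group label: {missing[:5]}")
        levels = pd.unique(self.groups)
        if self.group_levels is None:
            if len(levels) != 2:
                raise ValueError(
                    f"expected exactly 2 group levels, found {len(levels)}: {list(levels)}"
                )
            self.group_levels = (str(levels[0]), str(levels[1]))
        else:
            self.group_levels = tuple(self.group_levels)  # type: ignore[assignment]
            unknown = set(levels) - set(self.group_levels)
            if unknown:
                raise ValueError(f"group labels outside declared levels: {sorted(unknown)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def group_columns(self, level: str) -> list[str]:
        return list(self.groups.index[self.groups == level])

    def group_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return the (features x n1, features x n2) value blocks."""
        g1, g2 = self.group_levels
        a1 = self.values[self.group_columns(g1)].to_numpy(dtype=float)
        a2 = self.values[self.group_columns(g2)].to_numpy(dtype=float)
        return a1, a2

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())


@dataclass
class PerturbationReference:
    """Drug-instance x gene matrix of differential-expression scores.

    Each row is one drug treatment profile over a common gene universe;
    no missing cells are allowed because every gene must receive a rank.
    """

    values: pd.DataFrame  # drugs x genes

    def __post_init__(self) -> None:
        if self.values.isna().to_numpy().any():
            raise ValueError("perturbation reference must not contain missing cells")
        if self.values.columns.duplicated().any():
            dups = list(self.values.columns[self.values.columns.duplicated()])
            raise ValueError(f"duplicate gene IDs in reference: {dups[:5]}")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_drugs(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]
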