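"""Per-feature two-group differential statistics and selection rules.

The workhorse test is the Mann-Whitney U (exact by enumeration for
small tie-free samples, normal approximation with tie correction
otherwise), with the rank-sum AUC ``U / (n1 * n2)`` as a discriminatory
filter and BH (default) or Bonferroni multiplicity adjustment.
Transcriptomic selection keeps features with adjusted p below alpha and
discriminatory AUC at or above ``auc_min``; proteomic selection applies
the dual-platform rule: significant in at least one platform, detected
in more than ``detect_min`` of samples in at least one platform,
directionally concordant among significant platforms, and not on the
contaminant list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from sigrev.containers import OmicsMatrix

__all__ = [
    "FeatureStat",
    "SelectionRule",
    "mann_whitney",
    "auc_from_u",
    "adjust_pvalues",
    "transcriptomic_stats",
    "proteomic_stats",
    "select_degs",
    "exclude_contaminants",
    "stats_frame",
]

log = logging.getLogger(__name__)

#: sample-size bound below which the exact U distribution is used
#: (enumeration is cheap and the normal approximation is poor there).
EXACT_MAX_N = 12

#: fixed column order of emitted FeatureStat tables.
STAT_COLUMNS = [
    "feature_id",
    "log_fc",
    "p_value",
    "p_adjusted",
    "auc",
    "detect_frac_g1",
    "detect_frac_g2",
    "direction",
    "n_used_g1",
    "n_used_g2",
]


@dataclass
class FeatureStat:
    """Differential summary for one feature (group2 vs group1).

    ``auc`` is oriented "group2 higher": the probability that a random
    group-2 value exceeds a random group-1 value, ties counting half.
    ``p_value`` is ``nan`` for untestable features (< 2 usable values in
    a group).
    """

    feature_id: str
    log_fc: float
    p_value: float
    p_adjusted: float
    auc: float
    detect_frac_g1: float
    detect_frac_g2: float
    direction: str
    n_used_g1: int
    n_used_g2: int

    @property
    def testable(self) -> bool:
        return np.isfinite(self.p_value)

    @property
    def auc_discriminatory(self) -> float:
        """Orientation-free AUC: max(auc, 1 - auc)."""
        return max(self.auc, 1.0 - self.auc)


@dataclass
class SelectionRule:
    """Thresholds of the DEG/DAP selection funnel."""

    alpha: float = 0.05
    adjust_method: str = "BH"
    auc_min: float = 0.6
    detect_min: float = 0.10
    auc_strict: bool = False  # False: AUC >= auc_min; True: strictly >
    require_platform_agreement: bool = True
    contaminants: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for name in ("alpha", "auc_min", "detect_min"):
            v = float(getattr(self, name))
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.adjust_method not in ("BH", "Bonferroni"):
            raise ValueError(f"unknown adjust_method {self.adjust_method!r}")
        self.contaminants = frozenset(self.contaminants)

    def auc_passes(self, auc_discriminatory: float) -> bool:
        if self.auc_strict:
            return auc_discriminatory > self.auc_min
        return auc_discriminatory >= self.auc_min


def mann_whitney(values_g1, values_g2) -> tuple[float, float]:
    """Two-sided Mann-Whitney test oriented group2-over-group1.

    Returns ``(U, p)`` where U counts group-2-over-group-1 wins with
    ties counted one half. Missing (NaN) values are dropped first. The
    p-value is exact (full permutation distribution) when
    ``n1 + n2 <= 12`` and there are no ties, and the normal
    approximation with tie correction otherwise.

    Raises ``ValueError`` when either group has fewer than 2 usable
    values; callers flag such features untestable rather than aborting.
    """
    g1 = np.asarray(values_g1, dtype=float)
    g2 = np.asarray(values_g2, dtype=float)
    g1 = g1[np.isfinite(g1)]
    g2 = g2[np.isfinite(g2)]
    if g1.size < 2 or g2.size < 2:
        raise ValueError(
            f"need >= 2 usable values per group, got {g1.size} and {g2.size}"
        )
    pooled = np.concatenate([g1, g2])
    has_ties = np.unique(pooled).size < pooled.size
    small = g1.size + g2.size <= EXACT_MAX_N
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        g2, g1, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


def auc_from_u(U: float, n1: int, n2: int) -> float:
    """Rank-sum AUC, ``U / (n1 * n2)``, for U oriented group2-over-group1."""
    nmax = n1 * n2
    if not 0 <= U <= nmax:
        raise ValueError(f"U must lie in [0, {nmax}], got {U}")
    return float(U) / nmax


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Multiplicity adjustment, order-preserving.

    ``BH`` is the step-up FDR procedure with monotonicity enforcement,
    ``Bonferroni`` is ``min(1, m * p)``. NaN entries (untestable
    features) are passed through as NaN and do not count toward m.
    """
    p = np.asarray(p, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.sum() == 0:
        return out
    key = {"BH": "fdr_bh", "Bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    out[finite] = multipletests(p[finite], method=key)[1]
    return out


def _feature_stats_one(
    fid: str, a1: np.ndarray, a2: np.ndarray
) -> FeatureStat:
    v1 = a1[np.isfinite(a1)]
    v2 = a2[np.isfinite(a2)]
    d1 = v1.size / a1.size
    d2 = v2.size / a2.size
    if v1.size >= 2 and v2.size >= 2:
        U, p = mann_whitney(v1, v2)
        auc = auc_from_u(U, v1.size, v2.size)
        log_fc = float(np.mean(np.log2(v2)) - np.mean(np.log2(v1)))
    else:
        p, auc, log_fc = np.nan, np.nan, np.nan
    direction = "up" if (np.isfinite(log_fc) and log_fc > 0) else "down"
    return FeatureStat(
        feature_id=fid,
        log_fc=log_fc,
        p_value=p,
        p_adjusted=np.nan,
        auc=auc,
        detect_frac_g1=d1,
        detect_frac_g2=d2,
        direction=direction,
        n_used_g1=int(v1.size),
        n_used_g2=int(v2.size),
    )


def _per_feature_stats(matrix: OmicsMatrix) -> list[FeatureStat]:
    a1, a2 = matrix.group_arrays()
    n1, n2 = a1.shape[1], a2.shape[1]
    ids = matrix.feature_ids
    complete = not matrix.values.isna().to_numpy().any()
    if complete and n1 + n2 > EXACT_MAX_N:
        # one vectorized asymptotic call covers every feature
        res = sps.mannwhitneyu(
            a2, a1, axis=1, alternative="two-sided",
            method="asymptotic", use_continuity=False,
        )
        auc = res.statistic / (n1 * n2)
        log_fc = np.log2(a2).mean(axis=1) - np.log2(a1).mean(axis=1)
        return [
            FeatureStat(
                feature_id=ids[i],
                log_fc=float(log_fc[i]),
                p_value=float(res.pvalue[i]),
                p_adjusted=np.nan,
                auc=float(auc[i]),
                detect_frac_g1=1.0,
                detect_frac_g2=1.0,
                direction="up" if log_fc[i] > 0 else "down",
                n_used_g1=n1,
                n_used_g2=n2,
            )
            for i in range(len(ids))
        ]
    return [_feature_stats_one(ids[i], a1[i], a2[i]) for i in range(len(ids))]


def _adjust_in_place(stats: list[FeatureStat], method: str) -> None:
    adj = adjust_pvalues([s.p_value for s in stats], method)
    for s, a in zip(stats, adj):
        s.p_adjusted = float(a)


def transcriptomic_stats(
    matrix: OmicsMatrix, adjust_method: str = "BH"
) -> list[FeatureStat]:
    """Per-feature differential statistics for a complete matrix.

    log-fold change is ``mean(log2 group2) - mean(log2 group1)``.
    """
    stats = _per_feature_stats(matrix)
    _adjust_in_place(stats, adjust_method)
    return stats


def select_degs(stats: list[FeatureStat], rule: SelectionRule) -> list[str]:
    """Feature IDs passing adjusted p < alpha and the discriminatory AUC gate."""
    return [
        s.feature_id
        for s in stats
        if s.testable
        and s.p_adjusted < rule.alpha
        and rule.auc_passes(s.auc_discriminatory)
    ]


def exclude_contaminants(
    feature_ids: list[str], contaminants
) -> tuple[list[str], list[str]]:
    """Split features into (retained, excluded-as-contaminant)."""
    cont = set(contaminants)
    retained = [f for f in feature_ids if f not in cont]
    excluded = [f for f in feature_ids if f in cont]
    return retained, excluded


def proteomic_stats(
    matrix_a: OmicsMatrix,
    matrix_b: OmicsMatrix,
    rule: SelectionRule | None = None,
) -> tuple[list[FeatureStat], list[str], pd.DataFrame]:
    """Dual-platform differential statistics and DAP selection.

    Each platform is tested separately with pairwise missing-value
    exclusion (never imputation) and a per-platform BH family. A
    feature is a DAP iff it is significant in at least one platform,
    detected in more than ``detect_min`` of samples in at least one
    platform, its log-fold-change signs agree among the platforms in
    which it is significant, and it is not a listed contaminant.

    Returns the merged per-feature statistics (log_fc is the mean of
    available platform values; p and AUC are taken from the more
    significant platform; detection fractions are per-platform maxima),
    the selected DAP IDs, and an exclusion table (feature_id, reason).
    """
    if rule is None:
        rule = SelectionRule()
    if list(matrix_a.feature_ids) != list(matrix_b.feature_ids):
        raise ValueError("platform matrices must share feature identifiers")
    if list(matrix_a.sample_ids) != list(matrix_b.sample_ids):
        raise ValueError("platform matrices must share sample identifiers")

    per_platform = []
    for m in (matrix_a, matrix_b):
        st = _per_feature_stats(m)
        _adjust_in_place(st, rule.adjust_method)
        per_platform.append(st)

    merged: list[FeatureStat] = []
    selected: list[str] = []
    exclusions: list[tuple[str, str]] = []
    for sa, sb in zip(*per_platform):
        fid = sa.feature_id
        platform_stats = [sa, sb]
        sig = [
            s for s in platform_stats if s.testable and s.p_adjusted < rule.alpha
        ]
        detect = [
            (s.n_used_g1 + s.n_used_g2)
            / (len(matrix_a.sample_ids))
            for s in platform_stats
        ]
        fcs = [s.log_fc for s in platform_stats if np.isfinite(s.log_fc)]
        best = min(
            platform_stats,
            key=lambda s: s.p_adjusted if np.isfinite(s.p_adjusted) else np.inf,
        )
        mean_fc = float(np.mean(fcs)) if fcs else np.nan
        stat = FeatureStat(
            feature_id=fid,
            log_fc=mean_fc,
            p_value=best.p_value,
            p_adjusted=best.p_adjusted,
            auc=best.auc,
            detect_frac_g1=max(sa.detect_frac_g1, sb.detect_frac_g1),
            detect_frac_g2=max(sa.detect_frac_g2, sb.detect_frac_g2),
            direction="up" if (np.isfinite(mean_fc) and mean_fc > 0) else "down",
            n_used_g1=max(sa.n_used_g1, sb.n_used_g1),
            n_used_g2=max(sa.n_used_g2, sb.n_used_g2),
        )
        merged.append(stat)

        if not any(d > rule.detect_min for d in detect):
            exclusions.append((fid, "low detection"))
            continue
        if not sig:
            exclusions.append((fid, "not significant"))
            continue
        signs = {np.sign(s.log_fc) for s in sig if np.isfinite(s.log_fc)}
        if rule.require_platform_agreement and len(signs) > 1:
            exclusions.append((fid, "directional conflict"))
            log.info("feature %s excluded: directional conflict between platforms", fid)
            continue
        if fid in rule.contaminants:
            exclusions.append((fid, "contaminant"))
            continue
        if signs:
            agreed = sig[0].log_fc if len(sig) == 1 else float(np.mean([s.log_fc for s in sig]))
            stat.direction = "up" if agreed > 0 else "down"
        selected.append(fid)

    excl = pd.DataFrame(exclusions, columns=["feature_id", "reason"])
    return merged, selected, excl


def stats_frame(stats: list[FeatureStat]) -> pd.DataFrame:
    """FeatureStat list as a DataFrame in the documented column order."""
    return pd.DataFrame([vars(s) for s in stats], columns=STAT_COLUMNS)
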