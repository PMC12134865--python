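"""Two-tag weighted Kolmogorov-Smirnov connectivity scoring.

Each drug profile in the perturbation reference is reduced to a ranking
of the gene universe (rank 1 = most up-regulated). The enrichment score
of a tag set at ascending rank positions p(1..t) in a universe of n is

    a  = max_j [ j/t - p(j)/n ]
    b  = max_j [ p(j)/n - (j-1)/t ]
    ES = a  if a > b  else  -b

so ES > 0 means the tag concentrates toward the top of the ranking.
The raw connectivity score combines the up- and down-tag enrichment:
zero when both share a sign (incoherent query), otherwise
``es_up - es_down``; a drug that reverses the disease signature drives
the up tags down and the down tags up, giving a negative score.
Significance is a one-sided permutation test for negative enrichment
with tags re-drawn uniformly from the gene universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sigrev.containers import PerturbationReference
from sigrev.signature import SignaturePartition

__all__ = [
    "ConnectivityResult",
    "rank_genes",
    "ks_enrichment",
    "connectivity_score",
    "normalize_scores",
    "permutation_p",
    "query",
    "rank_drugs",
]

log = logging.getLogger(__name__)


@dataclass
class ConnectivityResult:
    """Per-drug connectivity summary across partition subsets.

    ``es_up``/``es_down`` are means over subsets (for K = 1 they are the
    plain enrichment scores). ``per_partition`` rows are
    (subset index, es_up, es_down, raw, norm, p).
    """

    drug_id: str
    es_up: float
    es_down: float
    raw_score: float
    norm_score: float
    p_perm: float
    aggregate_score: float
    aggregate_p: float
    per_partition: list[tuple[int, float, float, float, float, float]] = field(
        default_factory=list
    )


def rank_genes(profile: pd.Series) -> pd.Series:
    """1-based ranking of one drug profile, descending value.

    Rank 1 is the most up-regulated gene; ties are broken by stable
    gene-ID (lexicographic) order.
    """
    values = profile.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("profile contains non-finite values")
    ids = profile.index.to_numpy(dtype=object)
    order = np.lexsort((ids, -values))  # primary: value desc; secondary: ID asc
    ranks = np.empty(len(values), dtype=int)
    ranks[order] = np.arange(1, len(values) + 1)
    return pd.Series(ranks, index=profile.index, name="rank")


def _es_many(positions: np.ndarray, n: int) -> np.ndarray:
    """Vectorized ES for a batch of tag sets.

    ``positions`` has shape (B, t) with ascending 1-based ranks per row.
    """
    B, t = positions.shape
    j = np.arange(1, t + 1)
    a = (j / t - positions / n).max(axis=1)
    b = (positions / n - (j - 1) / t).max(axis=1)
    return np.where(a > b, a, -b)


def ks_enrichment(positions, n: int) -> float:
    """Enrichment score of one tag set; positions strictly increasing in [1, n]."""
    pos = np.asarray(positions, dtype=float)
    if pos.size == 0:
        raise ValueError("empty tag set: ES undefined; caller must handle")
    if not (1 <= pos[0] and pos[-1] <= n and np.all(np.diff(pos) > 0)):
        raise ValueError(f"positions must be strictly increasing within [1, {n}]")
    return float(_es_many(pos[None, :], n)[0])


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def connectivity_score(es_up: float, es_down: float) -> float:
    """Raw two-tag score: 0 if both ES share a sign, else es_up - es_down."""
    if _sign(es_up) != 0 and _sign(es_up) == _sign(es_down):
        return 0.0
    return es_up - es_down


def normalize_scores(raw) -> np.ndarray:
    """Scale raw scores to [-1, 1] within each sign class.

    Positive scores are divided by the maximum positive score, negative
    by the magnitude of the most negative; zeros stay zero, so sign and
    within-sign-class order are preserved.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("need at least one score")
    out = np.zeros_like(raw)
    pos, neg = raw > 0, raw < 0
    if pos.any():
        out[pos] = raw[pos] / raw[pos].max()
    if neg.any():
        out[neg] = raw[neg] / abs(raw[neg].min())
    return out


def _raw_from_positions(
    up_pos: np.ndarray | None, down_pos: np.ndarray | None, n: int
) -> np.ndarray:
    """Batch raw scores from (possibly one-sided) tag position arrays."""
    if up_pos is None and down_pos is None:
        raise ValueError("both tag sets empty")
    if up_pos is None:
        return -_es_many(down_pos, n)
    if down_pos is None:
        return _es_many(up_pos, n)
    es_u = _es_many(up_pos, n)
    es_d = _es_many(down_pos, n)
    same = (np.sign(es_u) == np.sign(es_d)) & (np.sign(es_u) != 0)
    return np.where(same, 0.0, es_u - es_d)


def _null_raws(
    n: int, t_up: int, t_down: int, B: int, rng: np.random.Generator
) -> np.ndarray:
    """B raw scores under uniformly re-drawn tags on a fixed universe.

    A uniformly drawn tag on any fixed ranking occupies uniformly random
    positions, so the null depends only on (n, t_up, t_down) and can be
    shared across drugs.
    """
    t = t_up + t_down
    if t > n:
        raise ValueError(f"t_up + t_down ({t}) exceeds universe size ({n})")
    # B independent draws of t distinct positions each
    keys = rng.random((B, n))
    picks = np.argpartition(keys, t - 1, axis=1)[:, :t] + 1  # 1-based ranks
    up = np.sort(picks[:, :t_up], axis=1) if t_up else None
    down = np.sort(picks[:, t_up:], axis=1) if t_down else None
    return _raw_from_positions(up, down, n)


def permutation_p(
    raw_obs: float,
    n: int,
    t_up: int,
    t_down: int,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
    null_raws: np.ndarray | None = None,
) -> float:
    """One-sided permutation p for negative enrichment.

    ``p = (1 + #{raw_perm <= raw_obs}) / (B + 1)`` with permuted tags of
    the observed sizes drawn uniformly without replacement from the gene
    universe. A precomputed ``null_raws`` array may be supplied.
    """
    if null_raws is None:
        if B < 100:
            raise ValueError(f"B must be >= 100, got {B}")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        null_raws = _null_raws(n, t_up, t_down, B, rng)
    B = len(null_raws)
    return float((1 + np.sum(null_raws <= raw_obs)) / (B + 1))


def _tag_positions(rank_row: np.ndarray, idx: np.ndarray) -> np.ndarray | None:
    if idx.size == 0:
        return None
    return np.sort(rank_row[idx])[None, :]


def query(
    part: SignaturePartition,
    reference: PerturbationReference,
    B: int = 1000,
    seed: int = 0,
) -> list[ConnectivityResult]:
    """Score every reference drug against every signature subset.

    Tag genes absent from the reference universe are dropped with a
    logged count. Per subset, raw scores are normalized across drugs;
    per-drug significance comes from the shared permutation null for
    that subset's tag sizes. The aggregate score is the mean of
    per-subset normalized scores; the aggregate p is the permutation p
    of the mean raw score under jointly re-drawn tags for all subsets.
    """
    if B < 100:
        raise ValueError(f"B must be >= 100, got {B}")
    n = reference.n_genes
    gene_pos = {g: i for i, g in enumerate(reference.gene_ids)}
    rng = np.random.default_rng(seed)

    # rank matrix: ranks[d, i] = rank of gene i in drug d's profile
    vals = reference.values.to_numpy(dtype=float)
    ids = np.array(reference.gene_ids, dtype=object)
    ranks = np.empty_like(vals, dtype=int)
    for d in range(vals.shape[0]):
        order = np.lexsort((ids, -vals[d]))
        ranks[d, order] = np.arange(1, n + 1)

    subset_tags = []
    n_dropped = 0
    for sub in part.subsets:
        up = np.array([gene_pos[g] for g in sub.up_ids if g in gene_pos], dtype=int)
        down = np.array([gene_pos[g] for g in sub.down_ids if g in gene_pos], dtype=int)
        n_dropped += (len(sub.up_ids) - up.size) + (len(sub.down_ids) - down.size)
        if up.size == 0 and down.size == 0:
            raise ValueError("a partition subset has no tag genes in the reference universe")
        if up.size == 0 or down.size == 0:
            log.info("degenerate one-sided tag set in subset (up=%d, down=%d)", up.size, down.size)
        subset_tags.append((up, down))
    if n_dropped:
        log.info("dropped %d tag genes absent from the reference universe", n_dropped)

    n_drugs = reference.n_drugs
    K = len(subset_tags)
    es_up = np.full((K, n_drugs), np.nan)
    es_down = np.full((K, n_drugs), np.nan)
    raw = np.zeros((K, n_drugs))
    norm = np.zeros((K, n_drugs))
    pval = np.zeros((K, n_drugs))
    nulls = np.zeros((K, B))
    null_cache: dict[tuple[int, int], np.ndarray] = {}

    for k, (up_idx, down_idx) in enumerate(subset_tags):
        for d in range(n_drugs):
            up_pos = _tag_positions(ranks[d], up_idx)
            down_pos = _tag_positions(ranks[d], down_idx)
            if up_pos is not None:
                es_up[k, d] = _es_many(up_pos, n)[0]
            if down_pos is not None:
                es_down[k, d] = _es_many(down_pos, n)[0]
            raw[k, d] = _raw_from_positions(up_pos, down_pos, n)[0]
        norm[k] = normalize_scores(raw[k])
        sizes = (up_idx.size, down_idx.size)
        if sizes not in null_cache:
            null_cache[sizes] = _null_raws(n, sizes[0], sizes[1], B, rng)
        nulls[k] = null_cache[sizes]
        pval[k] = (1 + (null_cache[sizes][None, :] <= raw[k][:, None]).sum(axis=1)) / (B + 1)

    agg_score = norm.mean(axis=0)
    agg_raw = raw.mean(axis=0)
    null_agg = nulls.mean(axis=0)
    agg_p = (1 + (null_agg[None, :] <= agg_raw[:, None]).sum(axis=1)) / (B + 1)

    results = []
    for d, drug in enumerate(reference.drug_ids):
        per_part = [
            (k, float(es_up[k, d]), float(es_down[k, d]), float(raw[k, d]),
             float(norm[k, d]), float(pval[k, d]))
            for k in range(K)
        ]
        results.append(
            ConnectivityResult(
                drug_id=drug,
                es_up=float(np.nanmean(es_up[:, d])) if not np.all(np.isnan(es_up[:, d])) else np.nan,
                es_down=float(np.nanmean(es_down[:, d])) if not np.all(np.isnan(es_down[:, d])) else np.nan,
                raw_score=float(agg_raw[d]),
                norm_score=float(norm[0, d]) if K == 1 else float(agg_score[d]),
                p_perm=float(pval[0, d]) if K == 1 else float(agg_p[d]),
                aggregate_score=float(agg_score[d]),
                aggregate_p=float(agg_p[d]),
                per_partition=per_part,
            )
        )
    return results


def rank_drugs(results: list[ConnectivityResult], alpha: float = 0.05) -> pd.DataFrame:
    """Order drugs most-negative-aggregate first with a significance flag.

    A drug is flagged significant when its aggregate score is negative
    (signature reversal) and its aggregate permutation p is below
    ``alpha``. Ties in score are broken by drug ID.
    """
    if not results:
        raise ValueError("no connectivity results to rank")
    df = pd.DataFrame(
        {
            "drug_id": [r.drug_id for r in results],
            "es_up": [r.es_up for r in results],
            "es_down": [r.es_down for r in results],
            "raw_score": [r.raw_score for r in results],
            "norm_score": [r.norm_score for r in results],
            "aggregate_score": [r.aggregate_score for r in results],
            "aggregate_p": [r.aggregate_p for r in results],
        }
    )
    df["significant"] = (df["aggregate_score"] < 0) & (df["aggregate_p"] < alpha)
    df = df.sort_values(
        ["aggregate_score", "drug_id"], kind="mergesort"
    ).reset_index(drop=True)
    return df


def per_partition_frame(results: list[ConnectivityResult]) -> pd.DataFrame:
    """Long-format per-subset detail table."""
    rows = []
    for r in results:
        for k, eu, ed, rw, nm, p in r.per_partition:
            rows.append((r.drug_id, k, eu, ed, rw, nm, p))
    return pd.DataFrame(
        rows, columns=["drug_id", "subset", "es_up", "es_down", "raw", "norm", "p_perm"]
    )
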