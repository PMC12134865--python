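"""Synthetic data generators for every input the pipeline consumes.

The generators emulate the statistical structure the downstream analysis
assumes: two-group cohorts with a planted fraction of shifted features,
dual-platform proteomic re-analyses of the same samples with
missing-at-random detection, a signed literature list partly concordant
with the omics, a perturbation reference with planted signature
reversers/mimics, and noisy four-parameter-logistic dose-response
curves. All randomness flows from a single integer seed through a named
``numpy.random.Generator``; identical spec + seed gives bit-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from sigrev.containers import OmicsMatrix, PerturbationReference
from sigrev.signature import SignedSignature

__all__ = [
    "CohortSpec",
    "ReferenceSpec",
    "gen_transcriptomic_cohort",
    "gen_proteomic_cohort",
    "gen_literature_features",
    "gen_reference",
    "gen_dose_response",
    "gen_annotations",
]

#: default two-level group labels: group1 = non-invasive analog,
#: group2 = invasive analog.
GROUP_LEVELS = ("NMIBC", "MIBC")

# log2-abundance scale of the base model; only ranks are consumed
# downstream, so the family (log-normal) is a convenience choice.
_BASE_MEAN = 7.0
_BASE_MEAN_SD = 1.5
_WITHIN_SD = 1.0


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic two-group cohort.

    ``effect_size`` is the standardized mean shift (in units of the
    within-group SD on the log2 scale) planted in shifted features;
    ``missing_rate`` and ``platform_corr`` only apply to the proteomic
    (dual-platform) mode.
    """

    n_group1: int = 20
    n_group2: int = 20
    n_features: int = 1000
    frac_shifted: float = 0.1
    effect_size: float = 1.5
    missing_rate: float = 0.0
    platform_corr: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_group1", "n_group2"):
            if int(getattr(self, name)) < 2:
                raise ValueError(f"{name} must be >= 2, got {getattr(self, name)}")
        if int(self.n_features) < 1:
            raise ValueError(f"n_features must be >= 1, got {self.n_features}")
        for name in ("frac_shifted", "missing_rate", "platform_corr"):
            v = float(getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not math.isfinite(self.effect_size):
            raise ValueError(f"effect_size must be finite, got {self.effect_size}")


@dataclass(frozen=True)
class ReferenceSpec:
    """Parameters of a synthetic perturbation reference.

    ``reversal_strength`` scales how strongly planted drugs (anti-)align
    with the signed signature, in units of the per-cell noise SD.
    """

    n_drugs: int = 50
    n_genes: int = 1000
    n_reversers: int = 3
    n_mimics: int = 0
    reversal_strength: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_drugs < 1 or self.n_genes < 1:
            raise ValueError("n_drugs and n_genes must be >= 1")
        if self.n_reversers < 0 or self.n_mimics < 0:
            raise ValueError("n_reversers and n_mimics must be >= 0")
        if self.n_reversers + self.n_mimics > self.n_drugs:
            raise ValueError(
                f"n_reversers + n_mimics ({self.n_reversers + self.n_mimics}) "
                f"exceeds n_drugs ({self.n_drugs})"
            )
        if self.reversal_strength < 0:
            raise ValueError(f"reversal_strength must be >= 0, got {self.reversal_strength}")


def _feature_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def _sample_frame(spec: CohortSpec) -> tuple[list[str], pd.Series]:
    g1, g2 = GROUP_LEVELS
    s1 = [f"N{i + 1:03d}" for i in range(spec.n_group1)]
    s2 = [f"M{i + 1:03d}" for i in range(spec.n_group2)]
    groups = pd.Series(
        [g1] * spec.n_group1 + [g2] * spec.n_group2, index=s1 + s2, name="group"
    )
    return s1 + s2, groups


def _plant_truth(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Choose shifted features; exactly round(frac*n), split evenly
    between up and down with an odd remainder assigned to up."""
    n_shift = round(spec.frac_shifted * spec.n_features)
    ids = np.array(_feature_ids(spec.n_features))
    chosen = rng.choice(spec.n_features, size=n_shift, replace=False)
    chosen.sort()
    n_up = (n_shift + 1) // 2
    direction = np.array(["up"] * n_up + ["down"] * (n_shift - n_up))
    return pd.DataFrame({"feature_id": ids[chosen], "direction": direction})


def _shift_matrix(spec: CohortSpec, truth: pd.DataFrame) -> np.ndarray:
    """Additive group-2 shift on the log2 scale, features x samples."""
    ids = _feature_ids(spec.n_features)
    pos = {f: i for i, f in enumerate(ids)}
    shift = np.zeros((spec.n_features, spec.n_group1 + spec.n_group2))
    delta = spec.effect_size * _WITHIN_SD
    for f, d in zip(truth["feature_id"], truth["direction"]):
        shift[pos[f], spec.n_group1 :] = delta if d == "up" else -delta
    return shift


def gen_transcriptomic_cohort(spec: CohortSpec) -> tuple[OmicsMatrix, pd.DataFrame]:
    """Generate a complete (no-missing) transcriptomic cohort.

    Returns the abundance matrix plus the truth table of planted
    features (``feature_id``, ``direction``).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    truth = _plant_truth(spec, rng)
    n_samp = spec.n_group1 + spec.n_group2
    mu = rng.normal(_BASE_MEAN, _BASE_MEAN_SD, size=(spec.n_features, 1))
    log2x = mu + _shift_matrix(spec, truth) + rng.normal(
        0.0, _WITHIN_SD, size=(spec.n_features, n_samp)
    )
    samples, groups = _sample_frame(spec)
    values = pd.DataFrame(
        np.exp2(log2x), index=_feature_ids(spec.n_features), columns=samples
    )
    return OmicsMatrix(values, groups, GROUP_LEVELS), truth


def gen_proteomic_cohort(
    spec: CohortSpec,
) -> tuple[OmicsMatrix, OmicsMatrix, pd.DataFrame]:
    """Generate two pseudo-platform re-analyses of one proteomic cohort.

    Both matrices share feature and sample identifiers and the planted
    group shift; they decompose each log2 cell into a shared
    sample-level component (weight ``sqrt(platform_corr)``) plus
    platform-specific noise, so the per-feature cross-platform
    correlation equals ``platform_corr`` and the two matrices coincide
    at ``platform_corr = 1``. Cells are then masked missing completely
    at random at ``missing_rate`` per platform.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    truth = _plant_truth(spec, rng)
    n_samp = spec.n_group1 + spec.n_group2
    mu = rng.normal(_BASE_MEAN, _BASE_MEAN_SD, size=(spec.n_features, 1))
    shift = _shift_matrix(spec, truth)
    common = rng.normal(0.0, _WITHIN_SD, size=(spec.n_features, n_samp))
    rho = float(spec.platform_corr)
    samples, groups = _sample_frame(spec)
    ids = _feature_ids(spec.n_features)

    mats = []
    for _platform in ("a", "b"):
        noise = rng.normal(0.0, _WITHIN_SD, size=(spec.n_features, n_samp))
        log2x = mu + shift + math.sqrt(rho) * common + math.sqrt(1.0 - rho) * noise
        x = np.exp2(log2x)
        mask = rng.random(size=x.shape) < spec.missing_rate
        x[mask] = np.nan
        mats.append(
            OmicsMatrix(pd.DataFrame(x, index=ids, columns=samples), groups, GROUP_LEVELS)
        )
    return mats[0], mats[1], truth


def gen_literature_features(
    n: int,
    frac_contradictory: float,
    truth: pd.DataFrame,
    seed: int = 0,
    universe: list[str] | None = None,
) -> pd.DataFrame:
    """Generate a signed literature feature list.

    Draws preferentially from the planted (truth) features and flips the
    direction of exactly ``round(frac_contradictory * n)`` of them to
    exercise the directional-conflict exclusion rule. If ``universe`` is
    given, features beyond the planted set are drawn from it with a
    random direction (they have no truth direction to contradict).
    """
    if not 0.0 <= frac_contradictory <= 1.0:
        raise ValueError(f"frac_contradictory must lie in [0, 1], got {frac_contradictory}")
    rng = np.random.default_rng(seed)
    planted = list(truth["feature_id"])
    extra = [] if universe is None else [f for f in universe if f not in set(planted)]
    if n > len(planted) + len(extra):
        raise ValueError(
            f"requested {n} literature features but only "
            f"{len(planted) + len(extra)} are available"
        )
    n_contra = round(frac_contradictory * n)
    n_planted = min(n, len(planted))
    if n_contra > n_planted:
        raise ValueError(
            f"{n_contra} contradictory entries requested but only "
            f"{n_planted} planted features are drawn"
        )
    pick = rng.choice(len(planted), size=n_planted, replace=False)
    chosen = truth.iloc[np.sort(pick)].reset_index(drop=True)
    flip = rng.choice(n_planted, size=n_contra, replace=False)
    directions = chosen["direction"].to_numpy().copy()
    opposite = {"up": "down", "down": "up"}
    for i in flip:
        directions[i] = opposite[directions[i]]
    rows = list(zip(chosen["feature_id"], directions))
    if n > n_planted:
        more = rng.choice(len(extra), size=n - n_planted, replace=False)
        for i in np.sort(more):
            rows.append((extra[i], rng.choice(["up", "down"])))
    return pd.DataFrame(rows, columns=["feature_id", "direction"])


def gen_reference(
    spec: ReferenceSpec, signature: SignedSignature
) -> tuple[PerturbationReference, pd.DataFrame]:
    """Generate a perturbation reference with planted reversers/mimics.

    Null drugs are iid standard-normal profiles. A planted reverser
    subtracts ``reversal_strength`` times the signature's signed
    indicator (+1 for up features, -1 for down) from its profile, so its
    ranking anti-correlates with the signature; a mimic adds it.
    Returns the reference and a drug-label table
    (``drug_id``, ``role`` in {reverser, mimic, null}).
    """
    spec.validate()
    genes = [f"G{i + 1:0{max(4, len(str(spec.n_genes)))}d}" for i in range(spec.n_genes)]
    gene_set = set(genes)
    missing = [e.feature_id for e in signature.entries if e.feature_id not in gene_set]
    if missing:
        raise ValueError(
            f"{len(missing)} signature features missing from the reference "
            f"gene universe, e.g. {missing[:5]}"
        )
    rng = np.random.default_rng(spec.seed)
    signed = np.zeros(spec.n_genes)
    pos = {g: i for i, g in enumerate(genes)}
    for e in signature.entries:
        signed[pos[e.feature_id]] = 1.0 if e.direction == "up" else -1.0

    width = max(3, len(str(spec.n_drugs)))
    drugs = [f"drug{i + 1:0{width}d}" for i in range(spec.n_drugs)]
    roles = np.array(["null"] * spec.n_drugs, dtype=object)
    planted = rng.choice(spec.n_drugs, size=spec.n_reversers + spec.n_mimics, replace=False)
    roles[planted[: spec.n_reversers]] = "reverser"
    roles[planted[spec.n_reversers :]] = "mimic"

    values = rng.normal(0.0, 1.0, size=(spec.n_drugs, spec.n_genes))
    values[roles == "reverser"] -= spec.reversal_strength * signed
    values[roles == "mimic"] += spec.reversal_strength * signed
    ref = PerturbationReference(pd.DataFrame(values, index=drugs, columns=genes))
    labels = pd.DataFrame({"drug_id": drugs, "role": roles})
    return ref, labels


def gen_dose_response(
    ic50: float,
    hill: float = 1.0,
    bottom: float = 0.0,
    top: float = 100.0,
    concentrations: list[float] | np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Generate a dose-response table from a 4PL curve plus Gaussian noise.

    Model: ``R(c) = bottom + (top - bottom) / (1 + (c / ic50)^hill)``,
    i.e. response falls from ``top`` toward ``bottom`` with increasing
    concentration (an inhibition curve); at ``c = ic50`` the noiseless
    response is the midpoint ``(top + bottom) / 2``. Default
    concentrations span 0.1-100 in micromol/L on a log grid, matching a
    typical 8-point viability titration.
    """
    if concentrations is None:
        concentrations = np.logspace(-1, 2, 8)
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0")
    if not top > bottom:
        raise ValueError(f"top ({top}) must exceed bottom ({bottom})")
    if ic50 <= 0:
        raise ValueError(f"ic50 must be > 0, got {ic50}")
    rng = np.random.default_rng(seed)
    c = np.repeat(conc, n_replicates)
    resp = bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)
    resp = resp + rng.normal(0.0, noise_sd, size=c.shape)
    return pd.DataFrame(
        {
            "concentration": c,
            "replicate": np.tile(np.arange(1, n_replicates + 1), len(conc)),
            "response": resp,
        }
    )


def gen_annotations(
    drug_ids: list[str],
    labels: pd.DataFrame | None = None,
    seed: int = 0,
    p_approved: float = 0.7,
    p_available: float = 0.9,
    p_prior_association: float = 0.2,
    p_carcinogenic: float = 0.2,
) -> pd.DataFrame:
    """Generate a drug annotation table for the shortlist stage.

    Flags are drawn independently per drug; drugs labelled ``reverser``
    in ``labels`` receive all-passing flags so end-to-end recovery runs
    have a deterministic ground truth.
    """
    rng = np.random.default_rng(seed)
    n = len(drug_ids)
    ann = pd.DataFrame(
        {
            "drug_id": drug_ids,
            "fda_approved": rng.random(n) < p_approved,
            "prior_bladder_cancer_association": rng.random(n) < p_prior_association,
            "carcinogenicity_reported": rng.random(n) < p_carcinogenic,
            "available": rng.random(n) < p_available,
            "drug_class": "unclassified",
        }
    )
    if labels is not None:
        reversers = set(labels.loc[labels["role"] == "reverser", "drug_id"])
        mask = ann["drug_id"].isin(reversers)
        ann.loc[mask, ["fda_approved", "available"]] = True
        ann.loc[mask, ["prior_bladder_cancer_association", "carcinogenicity_reported"]] = False
    return ann


def with_seed(spec, seed: int):
    """Return a copy of a spec with a different seed (specs are frozen)."""
    return replace(spec, seed=seed)
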