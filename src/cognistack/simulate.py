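"""Synthetic case-control and staging cohorts.

The generator emulates the statistical structure the classification
pipeline assumes: two feature blocks (a "cognitive" and a
"socio-cognitive" battery), a sparse subset of features whose group
means differ by a specified standardized effect size, exchangeable
correlation within each block, age/gender confounding injected through
per-feature covariate loadings, and missing-completely-at-random
feature cells.

Feature model.  Within a block, each subject's feature vector is

    x_j = delta_g(j) + sqrt(rho) * u + sqrt(1 - rho) * e_j
          + lam_age_j * a_z + lam_gender_j * (g - 1/2)

where ``u`` is a subject-level common factor, ``e_j`` independent unit
normals (giving exchangeable correlation ``rho``), ``a_z`` the
subject's age standardized by the cohort-level mixture moments (so
between-group age differences propagate into the features), ``g`` the
binary gender indicator, and ``delta_g(j)`` the group mean shift.  The
shift equals the requested Cohen's d times the nominal within-group SD
implied by the loadings, so at zero loadings the planted effects are
exactly the standardized mean differences.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .data import CASE, CONTROL, SubjectTable

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "generate_cohort",
    "inject_missingness",
    "discovery_cohort_spec",
    "staging_cohort_spec",
    "DEFAULT_MODALITY_SIZES",
]

#: feature counts of the two test batteries the generator emulates
DEFAULT_MODALITY_SIZES = {"cognitive": 52, "sociocognitive": 37}


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort.

    ``group_labels`` maps each group to the diagnostic label written in
    the output table ("control"/"case", or a stage name such as "CHR"
    for unlabeled cohorts).  ``group_effect`` scales the planted mean
    shifts per group (controls 0, cases 1; staging groups may sit in
    between).
    """

    cohort: str
    n_per_group: Mapping[str, int]
    group_labels: Mapping[str, str]
    group_effect: Mapping[str, float]
    n_features: Mapping[str, int]
    effect_sizes: Mapping[str, np.ndarray]
    block_correlation: float = 0.2
    covariate_loadings: Mapping[str, np.ndarray] = dataclasses.field(default_factory=dict)
    age_mean: Mapping[str, float] = dataclasses.field(default_factory=dict)
    age_sd: Mapping[str, float] = dataclasses.field(default_factory=dict)
    male_prob: Mapping[str, float] = dataclasses.field(default_factory=dict)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.block_correlation < 1.0:
            raise ValueError("block_correlation must lie in [0, 1)")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        for modality, nf in self.n_features.items():
            d = np.asarray(self.effect_sizes[modality], dtype=float)
            if d.shape != (nf,):
                raise ValueError(
                    f"effect_sizes[{modality!r}] has shape {d.shape}, expected ({nf},)"
                )
            lam = self.covariate_loadings.get(modality)
            if lam is not None and np.asarray(lam).shape != (nf, 2):
                raise ValueError(
                    f"covariate_loadings[{modality!r}] must have shape ({nf}, 2)"
                )
        for g in self.n_per_group:
            if g not in self.group_labels:
                raise ValueError(f"group {g!r} has no label")

    @property
    def n_total(self) -> int:
        return int(sum(self.n_per_group.values()))


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """What was actually planted, for downstream recovery checks."""

    informative_feature_indices: Mapping[str, tuple[int, ...]]
    true_effect_sizes: Mapping[str, np.ndarray]
    generating_seed: int


def _pooled_age_moments(spec: CohortSpec) -> tuple[float, float]:
    """Mean/SD of the cohort-level age mixture implied by the spec."""
    w = np.array([spec.n_per_group[g] for g in spec.n_per_group], dtype=float)
    w /= w.sum()
    mu = np.array([spec.age_mean.get(g, 30.0) for g in spec.n_per_group])
    sd = np.array([spec.age_sd.get(g, 10.0) for g in spec.n_per_group])
    m = float(w @ mu)
    v = float(w @ (sd**2 + mu**2) - m**2)
    return m, max(np.sqrt(v), 1e-12)


def generate_cohort(spec: CohortSpec) -> tuple[SubjectTable, GroundTruth]:
    """Draw one cohort according to ``spec``.

    Identical spec + seed yields a byte-identical table.  Labels and
    covariates are always complete; only feature cells can be missing.
    """
    rng = np.random.default_rng(spec.seed)
    age_pool_mean, age_pool_sd = _pooled_age_moments(spec)

    rows: list[pd.DataFrame] = []
    counter = 0
    for group, n in spec.n_per_group.items():
        age = rng.normal(spec.age_mean.get(group, 30.0), spec.age_sd.get(group, 10.0), size=n)
        gender = (rng.random(n) < spec.male_prob.get(group, 0.5)).astype(int)
        block: dict[str, np.ndarray] = {}
        for modality, nf in spec.n_features.items():
            d = np.asarray(spec.effect_sizes[modality], dtype=float)
            rho = spec.block_correlation
            common = rng.standard_normal((n, 1))
            noise = rng.standard_normal((n, nf))
            x = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * noise
            lam = spec.covariate_loadings.get(modality)
            if lam is not None:
                lam = np.asarray(lam, dtype=float)
                a_z = (age - age_pool_mean) / age_pool_sd
                x = x + np.outer(a_z, lam[:, 0]) + np.outer(gender - 0.5, lam[:, 1])
                # nominal within-group SD once covariate variance is folded in
                p = spec.male_prob.get(group, 0.5)
                sigma = np.sqrt(1.0 + lam[:, 0] ** 2 + lam[:, 1] ** 2 * p * (1.0 - p))
            else:
                sigma = np.ones(nf)
            x = x + spec.group_effect.get(group, 0.0) * d * sigma
            block[modality] = x
        frame = {
            "subject_id": [f"{spec.cohort}-{group}-{counter + i:04d}" for i in range(n)],
            "cohort": spec.cohort,
            "label": spec.group_labels[group],
            "age": age,
            "gender": gender,
        }
        counter += n
        df = pd.DataFrame(frame)
        for modality in spec.n_features:
            cols = [f"{modality}_{j:02d}" for j in range(spec.n_features[modality])]
            df = pd.concat([df, pd.DataFrame(block[modality], columns=cols, index=df.index)], axis=1)
        rows.append(df)

    data = pd.concat(rows, ignore_index=True)
    modalities = {
        m: tuple(f"{m}_{j:02d}" for j in range(nf)) for m, nf in spec.n_features.items()
    }
    table = SubjectTable(data, modalities)
    if spec.missing_rate > 0.0:
        table = inject_missingness(table, spec.missing_rate, seed=int(rng.integers(2**31)))

    truth = GroundTruth(
        informative_feature_indices={
            m: tuple(int(j) for j in np.flatnonzero(np.asarray(spec.effect_sizes[m], dtype=float)))
            for m in spec.n_features
        },
        true_effect_sizes={m: np.asarray(spec.effect_sizes[m], dtype=float) for m in spec.n_features},
        generating_seed=spec.seed,
    )
    return table, truth


def inject_missingness(table: SubjectTable, rate: float, seed: int) -> SubjectTable:
    """Blank feature cells independently with probability ``rate`` (MCAR).

    Labels and covariates are never touched.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("missing rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = table
    for modality in table.modalities:
        x = table.features(modality)
        mask = rng.random(x.shape) < rate
        x = x.copy()
        x[mask] = np.nan
        out = out.with_features(modality, x)
    return out


# ---------------------------------------------------------------------------
# Ready-made specs emulating the study cohorts
# ---------------------------------------------------------------------------

_AGE = {  # group -> (mean, sd), mirroring the published demographics
    "HC1": (26.57, 7.55),
    "BD": (38.08, 13.66),
    "HC2": (26.40, 6.87),
    "SCZ": (31.58, 8.99),
    "CHR": (19.80, 4.54),
    "FEP": (22.40, 5.20),
}
_MALE_P = {
    "HC1": 36 / 95,
    "BD": 30 / 59,
    "HC2": 88 / 195,
    "SCZ": 89 / 118,
    "CHR": 24 / 35,
    "FEP": 17 / 29,
}


def _default_effects(n_features: Mapping[str, int], n_informative: int, d: float) -> dict[str, np.ndarray]:
    out = {}
    for m, nf in n_features.items():
        e = np.zeros(nf)
        e[: min(n_informative, nf)] = d
        out[m] = e
    return out


def _default_loadings(n_features: Mapping[str, int], age: float, gender: float) -> dict[str, np.ndarray]:
    return {m: np.tile([age, gender], (nf, 1)) for m, nf in n_features.items()}


def discovery_cohort_spec(
    cohort: str,
    control_group: str,
    case_group: str,
    n_controls: int,
    n_cases: int,
    n_features: Mapping[str, int] | None = None,
    n_informative: int = 5,
    effect_size: float = 1.2,
    block_correlation: float = 0.2,
    age_loading: float = 0.15,
    gender_loading: float = 0.15,
    missing_rate: float = 0.05,
    seed: int = 0,
) -> CohortSpec:
    """Case-control cohort with sparse planted effects and confounding.

    Defaults emulate the discovery cohorts: ~2:1 control:case ratio,
    52 cognitive + 37 socio-cognitive features, five informative
    features per block with d = 1.2, mild exchangeable block
    correlation, and 5% MCAR missingness.
    """
    nf = dict(n_features or DEFAULT_MODALITY_SIZES)
    return CohortSpec(
        cohort=cohort,
        n_per_group={control_group: n_controls, case_group: n_cases},
        group_labels={control_group: CONTROL, case_group: CASE},
        group_effect={control_group: 0.0, case_group: 1.0},
        n_features=nf,
        effect_sizes=_default_effects(nf, n_informative, effect_size),
        block_correlation=block_correlation,
        covariate_loadings=_default_loadings(nf, age_loading, gender_loading),
        age_mean={g: _AGE.get(g, (30.0, 10.0))[0] for g in (control_group, case_group)},
        age_sd={g: _AGE.get(g, (30.0, 10.0))[1] for g in (control_group, case_group)},
        male_prob={g: _MALE_P.get(g, 0.5) for g in (control_group, case_group)},
        missing_rate=missing_rate,
        seed=seed,
    )


def staging_cohort_spec(
    stage: str,
    n_subjects: int,
    effect_fraction: float,
    n_features: Mapping[str, int] | None = None,
    n_informative: int = 5,
    effect_size: float = 1.2,
    block_correlation: float = 0.2,
    age_loading: float = 0.15,
    gender_loading: float = 0.15,
    missing_rate: float = 0.05,
    seed: int = 0,
) -> CohortSpec:
    """Unlabeled intermediate cohort (e.g. CHR or FEP).

    ``effect_fraction`` places the group on the control-case axis:
    first-episode subjects are generated patient-like (fraction 1),
    clinical-high-risk subjects intermediate (fraction ~0.5).
    """
    nf = dict(n_features or DEFAULT_MODALITY_SIZES)
    return CohortSpec(
        cohort=stage,
        n_per_group={stage: n_subjects},
        group_labels={stage: stage},
        group_effect={stage: effect_fraction},
        n_features=nf,
        effect_sizes=_default_effects(nf, n_informative, effect_size),
        block_correlation=block_correlation,
        covariate_loadings=_default_loadings(nf, age_loading, gender_loading),
        age_mean={stage: _AGE.get(stage, (25.0, 5.0))[0]},
        age_sd={stage: _AGE.get(stage, (25.0, 5.0))[1]},
        male_prob={stage: _MALE_P.get(stage, 0.5)},
        missing_rate=missing_rate,
        seed=seed,
    )
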