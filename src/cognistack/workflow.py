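"""Three-phase orchestration.

Phase 1 trains, per discovery cohort, the two unimodal classifiers and
the stacked multimodal classifier under nested CV (optionally with a
permutation test).  Phase 2 cross-applies each cohort's frozen models
to the other cohort (reversal validation, no retraining).  Phase 3
applies the frozen stacked models to the unlabeled staging cohorts and
compares decision-score distributions across groups by ANOVA.

Every run writes a config snapshot, the master seed and versioned
artifacts into the output directory; nothing is overwritten silently.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path

import numpy as np
import yaml

from . import io as cio
from .config import PipelineConfig
from .data import SubjectTable
from .evaluate import compare_decision_scores, oocv_apply, permutation_test
from .nested_cv import NestedCVResult, run_nested_cv
from .selection import aggregate_selection_probabilities
from .stacking import build_meta_features, oocv_stacked, run_stacking


class OrchestrationError(RuntimeError):
    """A phase is missing the artifacts of an earlier phase."""


@dataclasses.dataclass
class RunConfig:
    """Paths plus pipeline knobs for a full three-phase run."""

    cohort_paths: dict[str, str]  # cohort name -> CSV (two discovery cohorts)
    staging_paths: dict[str, str] = dataclasses.field(default_factory=dict)
    modalities: tuple[str, ...] = ("cognitive", "sociocognitive")
    outdir: str = "runs"
    n_permutations: int = 0  # 0 skips the permutation test
    pipeline: PipelineConfig = dataclasses.field(default_factory=PipelineConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        pipeline = PipelineConfig.from_dict(raw.pop("pipeline", {}))
        raw["modalities"] = tuple(raw.get("modalities", ("cognitive", "sociocognitive")))
        return cls(pipeline=pipeline, **raw)


def _outdir(config: RunConfig, phase: int) -> Path:
    out = Path(config.outdir) / f"phase{phase}"
    out.mkdir(parents=True, exist_ok=True)
    return out


def _snapshot(config: RunConfig, out: Path) -> None:
    snap = out / "config.json"
    if not snap.exists():
        snap.write_text(
            json.dumps(
                {
                    "pipeline": config.pipeline.to_dict(),
                    "config_hash": config.pipeline.config_hash(),
                    "modalities": list(config.modalities),
                    "n_permutations": config.n_permutations,
                },
                indent=1,
            )
        )


def train_cohort(
    table: SubjectTable, config: RunConfig, cohort: str, out: Path
) -> dict[str, NestedCVResult]:
    """Unimodal + stacked nested CV for one discovery cohort."""
    results: dict[str, NestedCVResult] = {}
    for modality in config.modalities:
        res = run_nested_cv(table, modality, config.pipeline)
        results[modality] = res
        tag = f"{cohort}_{modality}"
        cio.save_ensembles(res.ensembles, out / f"{tag}_ensembles.json", config.pipeline)
        res.records.to_csv(out / f"{tag}_decisions.csv", index=False)
        cio.save_json({"metrics": res.metrics.to_dict()}, out / f"{tag}_metrics.json", config.pipeline)
        masks = [m for e in res.ensembles for m in e.masks()]
        probs = aggregate_selection_probabilities(masks, table.feature_names(modality))
        probs.as_frame().to_csv(out / f"{tag}_selection_probabilities.csv", index=False)
        if config.n_permutations > 0:
            null = permutation_test(
                res, table, config.n_permutations,
                seed=config.pipeline.seed_for("perm", zlib.crc32(tag.encode())),
            )
            cio.save_json(
                {
                    "observed_bac": null.observed_bac,
                    "p_value": null.p_value,
                    "p_value_conservative": null.p_value_conservative,
                    "n_permutations": null.n_permutations,
                },
                out / f"{tag}_permutation.json",
                config.pipeline,
            )
    meta = build_meta_features(table, {m: results[m].records for m in config.modalities})
    stack = run_stacking(meta, config.pipeline)
    results["stack"] = stack
    tag = f"{cohort}_stack"
    cio.save_ensembles(stack.ensembles, out / f"{tag}_ensembles.json", config.pipeline)
    stack.records.to_csv(out / f"{tag}_decisions.csv", index=False)
    cio.save_json({"metrics": stack.metrics.to_dict()}, out / f"{tag}_metrics.json", config.pipeline)
    return results


def run_phase1(config: RunConfig) -> Path:
    out = _outdir(config, 1)
    _snapshot(config, out)
    for cohort, path in config.cohort_paths.items():
        table = cio.load_subject_table(path)
        train_cohort(table, config, cohort, out)
    return out


def _load_phase1(config: RunConfig, cohort: str):
    out = Path(config.outdir) / "phase1"
    needed = [out / f"{cohort}_{m}_ensembles.json" for m in (*config.modalities, "stack")]
    missing = [str(p) for p in needed if not p.exists()]
    if missing:
        raise OrchestrationError(f"phase-1 artifacts missing: {missing}")
    unimodal = {m: cio.load_ensembles(out / f"{cohort}_{m}_ensembles.json") for m in config.modalities}
    stack = cio.load_ensembles(out / f"{cohort}_stack_ensembles.json")
    return unimodal, stack


def run_phase2(config: RunConfig) -> Path:
    """Reversal validation: each cohort's frozen models applied to the other."""
    out = _outdir(config, 2)
    _snapshot(config, out)
    cohorts = list(config.cohort_paths)
    if len(cohorts) != 2:
        raise OrchestrationError("phase 2 expects exactly two discovery cohorts")
    tables = {c: cio.load_subject_table(p) for c, p in config.cohort_paths.items()}
    for source, target in (cohorts, cohorts[::-1]):
        unimodal, stack = _load_phase1(config, source)
        for modality, ens in unimodal.items():
            records, metrics = oocv_apply(ens, tables[target])
            tag = f"{source}_to_{target}_{modality}"
            records.to_csv(out / f"{tag}_decisions.csv", index=False)
            cio.save_json({"metrics": metrics.to_dict()}, out / f"{tag}_metrics.json", config.pipeline)
        records, metrics = oocv_stacked(unimodal, stack, tables[target])
        tag = f"{source}_to_{target}_stack"
        records.to_csv(out / f"{tag}_decisions.csv", index=False)
        cio.save_json({"metrics": metrics.to_dict()}, out / f"{tag}_metrics.json", config.pipeline)
    return out


def run_phase3(config: RunConfig) -> Path:
    """Staging: frozen stacked models score the unlabeled cohorts; decision
    scores are compared across groups by ANOVA with post-hoc contrasts."""
    out = _outdir(config, 3)
    _snapshot(config, out)
    if not config.staging_paths:
        raise OrchestrationError("phase 3 requires at least one staging cohort path")
    staging = {name: cio.load_subject_table(p) for name, p in config.staging_paths.items()}
    for cohort, path in config.cohort_paths.items():
        unimodal, stack = _load_phase1(config, cohort)
        discovery = cio.load_subject_table(path)
        disc_records, _ = oocv_stacked(unimodal, stack, discovery)
        groups: dict[str, np.ndarray] = {}
        labels = discovery.labels
        for label in np.unique(labels):
            sel = disc_records.loc[np.asarray(labels) == label, "decision_score"]
            groups[str(label)] = sel.to_numpy()
        for name, table in staging.items():
            records, _ = oocv_stacked(unimodal, stack, table)
            records.to_csv(out / f"{cohort}_stack_on_{name}_decisions.csv", index=False)
            groups[name] = records["decision_score"].to_numpy()
        cmp = compare_decision_scores(groups)
        cio.save_json(
            {
                "anova_F": cmp.anova_F,
                "anova_p": cmp.anova_p,
                "pairwise": {f"{a}|{b}": p for (a, b), p in cmp.pairwise.items()},
                "group_means": cmp.group_means,
                "group_ses": cmp.group_ses,
            },
            out / f"{cohort}_stack_staging_anova.json",
            config.pipeline,
        )
    return out


def run_phase(phase: int, config: RunConfig) -> Path:
    if phase == 1:
        return run_phase1(config)
    if phase == 2:
        return run_phase2(config)
    if phase == 3:
        return run_phase3(config)
    raise ValueError("phase must be 1, 2 or 3")
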