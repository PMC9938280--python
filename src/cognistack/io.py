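"""Reading and writing the pipeline's artifacts.

Feature tables travel as plain CSV (one row per subject; feature
columns prefixed by modality).  Models and metrics are versioned JSON.
Every artifact written by a run embeds the config hash and master seed
so no result can silently drift from its provenance.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .data import MANDATORY_COLS, SchemaError, SubjectTable, infer_modalities
from .nested_cv import EnsembleModel
from .simulate import GroundTruth

ARTIFACT_VERSION = 1

DEFAULT_PREFIXES = {"cognitive": "cognitive_", "sociocognitive": "sociocognitive_", "meta": "score_"}


def save_subject_table(table: SubjectTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def load_subject_table(
    path: str | Path, modality_prefixes: dict[str, str] | None = None
) -> SubjectTable:
    """Load a cohort CSV; missing feature cells stay missing.

    Errors name the offending column: absent mandatory columns raise a
    schema error, non-numeric feature cells a parse error.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in MANDATORY_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {missing}")
    modalities = infer_modalities(df.columns, modality_prefixes or DEFAULT_PREFIXES)
    if not modalities:
        raise SchemaError(f"{path}: no feature columns matched the modality prefixes")
    for mod, cols in modalities.items():
        for c in cols:
            try:
                df[c] = pd.to_numeric(df[c])
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"{path}: non-numeric value in feature column {c!r}") from exc
    return SubjectTable(df, dict(modalities))


def _provenance(config: PipelineConfig) -> dict:
    return {"version": ARTIFACT_VERSION, "config_hash": config.config_hash(), "seed": config.seed}


def save_json(obj: dict, path: str | Path, config: PipelineConfig | None = None) -> None:
    path = Path(path)
    if path.exists():
        raise FileExistsError(f"refusing to overwrite existing artifact {path}")
    payload = dict(obj)
    if config is not None:
        payload["_provenance"] = _provenance(config)
    path.write_text(json.dumps(_jsonable(payload), indent=1))


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(x: Any) -> Any:
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        v = float(x)
        return "inf" if np.isinf(v) else v
    if isinstance(x, float) and np.isinf(x):
        return "inf"
    if dataclasses.is_dataclass(x) and not isinstance(x, type):
        return _jsonable(dataclasses.asdict(x))
    return x


def save_ensembles(
    ensembles: list[EnsembleModel], path: str | Path, config: PipelineConfig
) -> None:
    save_json({"ensembles": [e.to_dict() for e in ensembles]}, path, config)


def load_ensembles(path: str | Path) -> list[EnsembleModel]:
    payload = load_json(path)
    return [EnsembleModel.from_dict(d) for d in payload["ensembles"]]


def save_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "informative_feature_indices": {
                    m: list(v) for m, v in truth.informative_feature_indices.items()
                },
                "true_effect_sizes": {m: v.tolist() for m, v in truth.true_effect_sizes.items()},
                "generating_seed": truth.generating_seed,
            },
            indent=1,
        )
    )
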