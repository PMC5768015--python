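"""File round-tripping for cohorts (CSV), models and protocols (JSON).

CSV dialect is fixed: comma-separated, UTF-8, '.' decimal, header mandatory.
Units live in column names (``…_cgy``, ``…_pct``, ``…_cc``) because plan
metrics mix Gy/cGy/%/cc.  JSON is written with sorted keys and a fixed
indent so round trips are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import pandas as pd

from .errors import SchemaError
from .model import (
    DEFAULT_FITTING_SPEC,
    ConstraintRule,
    GeneralSettings,
    KnowledgeModel,
)
from .protocol import Protocol, ProtocolEntry

__all__ = [
    "read_cohort",
    "write_cohort",
    "model_to_json",
    "model_from_json",
    "model_from_json_str",
    "protocol_to_json",
    "protocol_from_json",
    "protocol_to_csv",
]

_KNOWN_COHORT_COLUMNS = {"patient_id", "rtl"} | {ms.column for ms in DEFAULT_FITTING_SPEC}


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV; requires the 'rtl' column, preserves extras."""
    df = pd.read_csv(path)
    if "rtl" not in df.columns:
        raise SchemaError(f"{path}: cohort CSV lacks required column 'rtl'")
    if "patient_id" in df.columns and df["patient_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicated patient_id values")
    unknown = [c for c in df.columns if c not in _KNOWN_COHORT_COLUMNS]
    if unknown:
        warnings.warn(f"cohort CSV has unrecognized columns (preserved): {unknown}", stacklevel=2)
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Model JSON


def _require(obj: dict, key: str, pointer: str):
    if key not in obj:
        raise SchemaError(f"{pointer}/{key}: missing required key")
    return obj[key]


def _rule_to_dict(rule: ConstraintRule) -> dict:
    metric: dict = {"kind": rule.metric_kind}
    if rule.dose_gy is not None:
        metric["dose_gy"] = rule.dose_gy
    if rule.model_type == "linear":
        model = {
            "type": "linear",
            "slope": rule.slope,
            "intercept": rule.intercept,
            "shift": rule.shift,
        }
    else:
        model = {"type": "constant", "value": rule.value}
    return {
        "organ": rule.organ,
        "metric": metric,
        "model": model,
        "unit": rule.unit,
        "priority": rule.priority,
        "compromise": rule.compromise,
    }


def _rule_from_dict(obj: dict, pointer: str) -> ConstraintRule:
    metric = _require(obj, "metric", pointer)
    model = _require(obj, "model", pointer)
    mtype = _require(model, "type", f"{pointer}/model")
    priority = _require(obj, "priority", pointer)
    if priority not in ("high", "low"):
        raise SchemaError(f"{pointer}/priority: must be 'high' or 'low', got {priority!r}")
    compromise = _require(obj, "compromise", pointer)
    if not isinstance(compromise, bool):
        raise SchemaError(f"{pointer}/compromise: must be a boolean")
    try:
        if mtype == "linear":
            return ConstraintRule(
                organ=_require(obj, "organ", pointer),
                metric_kind=_require(metric, "kind", f"{pointer}/metric"),
                dose_gy=metric.get("dose_gy"),
                unit=_require(obj, "unit", pointer),
                priority=priority,
                compromise=compromise,
                model_type="linear",
                slope=float(_require(model, "slope", f"{pointer}/model")),
                intercept=float(_require(model, "intercept", f"{pointer}/model")),
                shift=float(model.get("shift", 0.0)),
            )
        if mtype == "constant":
            return ConstraintRule(
                organ=_require(obj, "organ", pointer),
                metric_kind=_require(metric, "kind", f"{pointer}/metric"),
                dose_gy=metric.get("dose_gy"),
                unit=_require(obj, "unit", pointer),
                priority=priority,
                compromise=compromise,
                model_type="constant",
                value=float(_require(model, "value", f"{pointer}/model")),
            )
    except SchemaError:
        raise
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{pointer}: {exc}") from exc
    raise SchemaError(f"{pointer}/model/type: unknown type {mtype!r}")


def _model_to_dict(model: KnowledgeModel) -> dict:
    return {
        "format": "liverkbp-model",
        "version": 1,
        "organs": [_rule_to_dict(r) for r in model.rules],
        "general_settings": dataclasses.asdict(model.general_settings),
        "provenance": model.provenance,
    }


def _model_from_dict(data: dict) -> KnowledgeModel:
    organs = _require(data, "organs", "")
    if not isinstance(organs, list) or not organs:
        raise SchemaError("/organs: must be a non-empty list")
    rules = tuple(_rule_from_dict(o, f"/organs/{i}") for i, o in enumerate(organs))
    gs_raw = data.get("general_settings", {})
    known = {f.name for f in dataclasses.fields(GeneralSettings)}
    bad = set(gs_raw) - known
    if bad:
        raise SchemaError(f"/general_settings: unknown keys {sorted(bad)}")
    return KnowledgeModel(
        rules=rules,
        general_settings=GeneralSettings(**gs_raw),
        provenance=data.get("provenance", {}),
    )


def model_to_json(model: KnowledgeModel, path) -> None:
    Path(path).write_text(
        json.dumps(_model_to_dict(model), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def model_from_json(path) -> KnowledgeModel:
    return model_from_json_str(Path(path).read_text(encoding="utf-8"))


def model_from_json_str(text: str) -> KnowledgeModel:
    return _model_from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# Protocol JSON / CSV


def protocol_to_json(protocol: Protocol, path) -> None:
    data = {
        "format": "liverkbp-protocol",
        "version": 1,
        "patient_id": protocol.patient_id,
        "rtl": protocol.rtl,
        "entries": [
            {
                "organ": e.organ,
                "metric_kind": e.metric_kind,
                "dose_gy": e.dose_gy,
                "bound": e.bound,
                "unit": e.unit,
                "priority": e.priority,
                "compromise": e.compromise,
                "constraint": e.constraint_text,
            }
            for e in protocol.entries
        ],
        "general_settings": dataclasses.asdict(protocol.general_settings),
    }
    Path(path).write_text(
        json.dumps(data, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def protocol_from_json(path) -> Protocol:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    entries = []
    for i, e in enumerate(data.get("entries", [])):
        pointer = f"/entries/{i}"
        entries.append(
            ProtocolEntry(
                organ=_require(e, "organ", pointer),
                metric_kind=_require(e, "metric_kind", pointer),
                dose_gy=e.get("dose_gy"),
                bound=int(_require(e, "bound", pointer)),
                unit=_require(e, "unit", pointer),
                priority=_require(e, "priority", pointer),
                compromise=bool(_require(e, "compromise", pointer)),
            )
        )
    if not entries:
        raise SchemaError("/entries: must be a non-empty list")
    return Protocol(
        patient_id=_require(data, "patient_id", ""),
        rtl=float(_require(data, "rtl", "")),
        entries=tuple(entries),
        general_settings=GeneralSettings(**data.get("general_settings", {})),
    )


def protocol_to_csv(protocol: Protocol, path) -> None:
    """Human-facing protocol table: organ, constraint, priority, compromise."""
    pd.DataFrame(
        [
            {
                "organ_at_risk": e.organ,
                "constraint": e.constraint_text,
                "priority": e.priority.capitalize(),
                "compromise": "Yes" if e.compromise else "No",
            }
            for e in protocol.entries
        ]
    ).to_csv(path, index=False)
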