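"""JSON serialization for models, datasets, settings, results and analyses.

All documents are plain JSON with a ``format`` stamp naming the schema
version.  Validation is explicit: malformed documents raise
:class:`~moietykit.errors.SchemaError` messages that name the offending
field.  Unknown extra fields are ignored on read (and, for models,
preserved through a round-trip).

Schemas (v1)
------------

model ``moietykit-model-v1``::

    {"format": "moietykit-model-v1", "name": str,
     "moieties": [{"name": str, "nickname": str,
                   "labellable_atoms": {isotope: int},
                   "states": [state-label, ...]}],
     "molecules": [{"name": str, "moieties": [moiety-name, ...],
                    "total_labellable_atoms": {isotope: int}}],
     "relationships": [{"dependent": {"moiety": str, "state": str},
                        "terms": [{"moiety": str, "state": str,
                                   "coefficient": number}]}]}

dataset ``moietykit-dataset-v1``::

    {"format": "moietykit-dataset-v1", "name": str,
     "molecules": {molecule-name: [{"labelingIsotopes": state-label,
                                    "height": number >= 0,
                                    "heightSE": number}, ...]}}

State labels are dot-separated ``isotope_count`` parts ("13C_0",
"13C_6.18O_5").  Optimization settings, results and analyses use the
``moietykit-optimization-v1`` / ``-result-v1`` / ``-analysis-v1`` stamps;
settings accept both camelCase (``stepNumber``) and snake_case keys.

Manifests are plain-text files with one filepath per line; they chain the
modeling step (result paths) to analysis and analysis to ranking.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from . import saga
from .errors import SchemaError
from .model import Moiety, MoietyModel, Molecule, Relationship, parse_state_label
from .modeling import (
    Dataset,
    ObjectiveSpec,
    Observation,
    OptimizationResult,
    OptimizationSettings,
    Repetition,
)
from .analysis import ModelAnalysis, ParameterStats

__all__ = [
    "read_model", "write_model",
    "read_dataset", "write_dataset",
    "read_optimization_settings", "write_optimization_settings",
    "read_result", "write_result",
    "read_analysis", "write_analysis", "analysis_report",
    "read_manifest", "append_manifest",
]

_MODEL_KEYS = {"format", "name", "moieties", "molecules", "relationships"}


def _require(doc: dict, key: str, typ, where: str):
    if key not in doc:
        raise SchemaError(f"{where}: missing required field {key!r}")
    value = doc[key]
    if typ is float:
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise SchemaError(f"{where}: field {key!r} must be a number")
        return float(value)
    if not isinstance(value, typ):
        raise SchemaError(f"{where}: field {key!r} must be {typ.__name__}")
    return value


def _atom_map(doc: dict, key: str, where: str) -> dict[str, int]:
    raw = _require(doc, key, dict, where)
    out: dict[str, int] = {}
    for iso, n in raw.items():
        if not isinstance(n, int) or isinstance(n, bool) or n < 0:
            raise SchemaError(
                f"{where}: {key}[{iso!r}] must be a non-negative integer"
            )
        out[iso] = n
    return out


def _load(path) -> dict:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON ({exc})") from None
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: top-level document must be an object")
    return doc


def _dump(doc: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, allow_nan=True)
        fh.write("\n")


# -- models ----------------------------------------------------------------


def model_to_doc(model: MoietyModel) -> dict:
    doc: dict[str, Any] = {
        "format": "moietykit-model-v1",
        "name": model.name,
        "moieties": [
            {
                "name": m.name,
                "nickname": m.nickname,
                "labellable_atoms": dict(m.labellable_atoms),
                "states": m.state_labels(),
            }
            for m in model.moieties
        ],
        "molecules": [
            {
                "name": mol.name,
                "moieties": [m.name for m in mol.moieties],
                "total_labellable_atoms": dict(mol.total_labellable_atoms),
            }
            for mol in model.molecules
        ],
        "relationships": [
            {
                "dependent": {"moiety": rel.dependent[0], "state": rel.dependent[1]},
                "terms": [
                    {"moiety": m, "state": s, "coefficient": c}
                    for m, s, c in rel.terms
                ],
            }
            for rel in model.relationships
        ],
    }
    doc.update(model.extra)
    return doc


def model_from_doc(doc: dict, where: str = "model") -> MoietyModel:
    name = _require(doc, "name", str, where)
    moieties = []
    for i, mdoc in enumerate(_require(doc, "moieties", list, where)):
        w = f"{where}.moieties[{i}]"
        if not isinstance(mdoc, dict):
            raise SchemaError(f"{w}: must be an object")
        states = _require(mdoc, "states", list, w)
        for s in states:
            if not isinstance(s, str):
                raise SchemaError(f"{w}: states must be state-label strings")
            try:
                parse_state_label(s)
            except ValueError as exc:
                raise SchemaError(f"{w}: bad state label {s!r} ({exc})") from None
        moieties.append(
            Moiety(
                _require(mdoc, "name", str, w),
                _atom_map(mdoc, "labellable_atoms", w),
                states,
                nickname=mdoc.get("nickname", ""),
            )
        )
    by_name = {m.name: m for m in moieties}
    molecules = []
    for i, mol in enumerate(_require(doc, "molecules", list, where)):
        w = f"{where}.molecules[{i}]"
        if not isinstance(mol, dict):
            raise SchemaError(f"{w}: must be an object")
        member_names = _require(mol, "moieties", list, w)
        members = []
        for mn in member_names:
            if mn not in by_name:
                raise SchemaError(f"{w}: unknown moiety name {mn!r}")
            members.append(by_name[mn])
        molecules.append(
            Molecule(
                _require(mol, "name", str, w),
                members,
                _atom_map(mol, "total_labellable_atoms", w),
            )
        )
    relationships = []
    for i, rel in enumerate(doc.get("relationships", [])):
        w = f"{where}.relationships[{i}]"
        if not isinstance(rel, dict):
            raise SchemaError(f"{w}: must be an object")
        dep = _require(rel, "dependent", dict, w)
        terms = _require(rel, "terms", list, w)
        relationships.append(
            Relationship(
                (_require(dep, "moiety", str, f"{w}.dependent"),
                 _require(dep, "state", str, f"{w}.dependent")),
                [
                    (
                        _require(t, "moiety", str, f"{w}.terms[{j}]"),
                        _require(t, "state", str, f"{w}.terms[{j}]"),
                        _require(t, "coefficient", float, f"{w}.terms[{j}]"),
                    )
                    for j, t in enumerate(terms)
                ],
            )
        )
    model = MoietyModel(name, moieties, molecules, relationships)
    model.extra = {k: v for k, v in doc.items() if k not in _MODEL_KEYS}
    return model


def read_model(path) -> MoietyModel:
    return model_from_doc(_load(path), where=str(path))


def write_model(model: MoietyModel, path) -> None:
    _dump(model_to_doc(model), path)


# -- datasets --------------------------------------------------------------


def dataset_to_doc(dataset: Dataset) -> dict:
    return {
        "format": "moietykit-dataset-v1",
        "name": dataset.name,
        "molecules": {
            mol: [
                {
                    "labelingIsotopes": o.labeling_isotopes,
                    "height": o.height,
                    "heightSE": o.height_se,
                }
                for o in obs
            ]
            for mol, obs in dataset.observations.items()
        },
    }


def dataset_from_doc(doc: dict, where: str = "dataset") -> Dataset:
    name = _require(doc, "name", str, where)
    molecules = _require(doc, "molecules", dict, where)
    observations: dict[str, list[Observation]] = {}
    for mol, entries in molecules.items():
        if not isinstance(entries, list):
            raise SchemaError(f"{where}.molecules[{mol!r}]: must be a list")
        parsed = []
        for j, e in enumerate(entries):
            w = f"{where}.molecules[{mol!r}][{j}]"
            if not isinstance(e, dict):
                raise SchemaError(f"{w}: must be an object")
            label = e.get("labelingIsotopes", e.get("labeling_isotopes"))
            if not isinstance(label, str):
                raise SchemaError(f"{w}: missing required field 'labelingIsotopes'")
            try:
                parse_state_label(label)
            except ValueError as exc:
                raise SchemaError(f"{w}: bad labelingIsotopes {label!r} ({exc})") from None
            height = _require(e, "height", float, w)
            if height < 0:
                raise SchemaError(f"{w}: field 'height' must be >= 0")
            se = e.get("heightSE", e.get("height_se", 0.0))
            if not isinstance(se, (int, float)) or isinstance(se, bool):
                raise SchemaError(f"{w}: field 'heightSE' must be a number")
            parsed.append(Observation(label, height, float(se)))
        observations[mol] = parsed
    return Dataset(name=name, observations=observations)


def read_dataset(path) -> Dataset:
    return dataset_from_doc(_load(path), where=str(path))


def write_dataset(dataset: Dataset, path) -> None:
    _dump(dataset_to_doc(dataset), path)


# -- optimization settings -------------------------------------------------

_SAGA_KEYS = {
    "stepNumber": "step_number",
    "temperatureStepSize": "temperature_step_size",
    "alpha": "alpha",
    "crossoverRate": "crossover_rate",
    "mutationRate": "mutation_rate",
    "populationSize": "population_size",
    "startTemperature": "start_temperature",
    "crossoverVariant": "crossover_variant",
}


def settings_from_doc(doc: dict, where: str = "settings") -> OptimizationSettings:
    saga_doc = doc.get("saga", {})
    if not isinstance(saga_doc, dict):
        raise SchemaError(f"{where}: field 'saga' must be an object")
    kwargs = {}
    for camel, snake in _SAGA_KEYS.items():
        if camel in saga_doc:
            kwargs[snake] = saga_doc[camel]
        elif snake in saga_doc:
            kwargs[snake] = saga_doc[snake]
    try:
        saga_settings = saga.SagaSettings(**kwargs)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{where}.saga: {exc}") from None
    obj_doc = doc.get("objective", {})
    if isinstance(obj_doc, str):
        obj_doc = {"kind": obj_doc}
    if not isinstance(obj_doc, dict):
        raise SchemaError(f"{where}: field 'objective' must be an object or string")
    try:
        objective = ObjectiveSpec(
            kind=obj_doc.get("kind", "absolute_difference"),
            epsilon=obj_doc.get("epsilon", 1e-10),
        )
        return OptimizationSettings(
            method=doc.get("method", "SAGA"),
            saga=saga_settings,
            repetitions=doc.get("repetitions", 100),
            dataset_mode=doc.get("datasetMode", doc.get("dataset_mode", "split")),
            objective=objective,
            seed=doc.get("seed", 0),
            polish=doc.get("polish", False),
            polish_method=doc.get("polishMethod", doc.get("polish_method", "L-BFGS-B")),
            combined_shared=doc.get("combinedShared", doc.get("combined_shared", False)),
            renormalize_observed=doc.get(
                "renormalizeObserved", doc.get("renormalize_observed", False)
            ),
        )
    except ValueError as exc:
        raise SchemaError(f"{where}: {exc}") from None


def settings_to_doc(settings: OptimizationSettings) -> dict:
    return {
        "format": "moietykit-optimization-v1",
        "method": settings.method,
        "saga": {camel: getattr(settings.saga, snake) for camel, snake in _SAGA_KEYS.items()},
        "repetitions": settings.repetitions,
        "datasetMode": settings.dataset_mode,
        "objective": {"kind": settings.objective.kind, "epsilon": settings.objective.epsilon},
        "seed": settings.seed,
        "polish": settings.polish,
        "polishMethod": settings.polish_method,
        "combinedShared": settings.combined_shared,
        "renormalizeObserved": settings.renormalize_observed,
    }


def read_optimization_settings(path) -> OptimizationSettings:
    return settings_from_doc(_load(path), where=str(path))


def write_optimization_settings(settings: OptimizationSettings, path) -> None:
    _dump(settings_to_doc(settings), path)


# -- results ---------------------------------------------------------------


def write_result(result: OptimizationResult, path) -> None:
    doc = {
        "format": "moietykit-result-v1",
        "model": result.model_name,
        "datasets": result.dataset_names,
        "settings": settings_to_doc(result.settings),
        "allInfeasible": result.all_infeasible,
        "blocks": {
            name: [
                {"params": r.params.tolist(), "energy": r.energy} for r in reps
            ]
            for name, reps in result.blocks.items()
        },
    }
    _dump(doc, path)


def read_result(path) -> OptimizationResult:
    doc = _load(path)
    where = str(path)
    blocks_doc = _require(doc, "blocks", dict, where)
    blocks = {}
    for name, reps in blocks_doc.items():
        if not isinstance(reps, list):
            raise SchemaError(f"{where}.blocks[{name!r}]: must be a list")
        blocks[name] = [
            Repetition(
                params=np.array(_require(r, "params", list, f"{where}.blocks[{name!r}]")),
                energy=_require(r, "energy", float, f"{where}.blocks[{name!r}]"),
            )
            for r in reps
        ]
    return OptimizationResult(
        model_name=_require(doc, "model", str, where),
        dataset_names=list(doc.get("datasets", [])),
        blocks=blocks,
        settings=settings_from_doc(doc.get("settings", {}), where=f"{where}.settings"),
        all_infeasible=bool(doc.get("allInfeasible", False)),
    )


# -- analyses --------------------------------------------------------------


def _num(x):
    """JSON-safe float (inf/nan become strings on write)."""
    if x is None:
        return None
    if math.isinf(x) or math.isnan(x):
        return str(x)
    return x


def _unnum(x):
    if x is None or isinstance(x, (int, float)):
        return x
    return float(x)


def write_analysis(analysis: ModelAnalysis, path) -> None:
    doc = {
        "format": "moietykit-analysis-v1",
        "model": analysis.model_name,
        "k": analysis.k,
        "n": analysis.n,
        "RSS": analysis.rss,
        "AIC": _num(analysis.aic),
        "AICc": _num(analysis.aicc),
        "BIC": _num(analysis.bic),
        "parameterStats": {
            block: [dataclasses.asdict(p) for p in stats]
            for block, stats in analysis.parameter_stats.items()
        },
        "intensityStats": {
            ds: frame.to_dict(orient="list")
            for ds, frame in analysis.intensity_stats.items()
        },
        "bestParams": {b: p.tolist() for b, p in analysis.best_params.items()},
        "bestEnergies": analysis.best_energies,
    }
    _dump(doc, path)


def read_analysis(path) -> ModelAnalysis:
    import pandas as pd

    doc = _load(path)
    where = str(path)
    return ModelAnalysis(
        model_name=_require(doc, "model", str, where),
        k=_require(doc, "k", int, where),
        n=_require(doc, "n", int, where),
        rss=_require(doc, "RSS", float, where),
        aic=_unnum(doc.get("AIC")),
        aicc=_unnum(doc.get("AICc")),
        bic=_unnum(doc.get("BIC")),
        parameter_stats={
            block: [ParameterStats(**p) for p in stats]
            for block, stats in doc.get("parameterStats", {}).items()
        },
        intensity_stats={
            ds: pd.DataFrame(cols) for ds, cols in doc.get("intensityStats", {}).items()
        },
        best_params={b: np.array(p) for b, p in doc.get("bestParams", {}).items()},
        best_energies=dict(doc.get("bestEnergies", {})),
    )


def analysis_report(analysis: ModelAnalysis) -> str:
    """Human-readable text summary of a model analysis."""
    lines = [
        f"Model: {analysis.model_name}",
        f"k (fitted parameters): {analysis.k}",
        f"n (data points): {analysis.n}",
        f"RSS: {analysis.rss:.6g}",
        f"AIC: {analysis.aic:.6g}" if analysis.aic is not None else "AIC: undefined",
        f"AICc: {analysis.aicc:.6g}" if analysis.aicc is not None else "AICc: undefined",
        f"BIC: {analysis.bic:.6g}" if analysis.bic is not None else "BIC: undefined",
        "",
    ]
    for block, stats in analysis.parameter_stats.items():
        lines.append(f"[{block}] best energy = {analysis.best_energies.get(block, float('nan')):.6g}")
        lines.append(f"{'parameter':<28}{'mean':>10}{'sd':>10}{'min':>10}{'max':>10}")
        for p in stats:
            lines.append(
                f"{p.name:<28}{p.mean:>10.4f}{p.sd:>10.4f}{p.min:>10.4f}{p.max:>10.4f}"
            )
        lines.append("")
    return "\n".join(lines)


# -- manifests -------------------------------------------------------------


def read_manifest(path) -> list[Path]:
    """Read a plain-text manifest (one filepath per line).

    Every listed path must exist at read time.
    """
    paths = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        p = Path(line)
        if not p.exists():
            raise FileNotFoundError(f"manifest {path}: listed file {line!r} does not exist")
        paths.append(p)
    return paths


def append_manifest(path, entry) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "a") as fh:
        fh.write(str(entry) + "\n")
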