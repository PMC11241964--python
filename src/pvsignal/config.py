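"""Study configuration: event definitions, class map, confounders, thresholds.

Defaults reproduce the study design this package implements: a composite
delirium outcome ({"Delirium", "Confusional state", "Disorientation"}) with
three sensitivity definitions nested around it, six antidepressant exposure
classes plus opioid/bisphosphonate controls, and an adjustment set of
age band (65-74 vs 75+), sex, region, four co-prescription classes
(opioids N02, antipsychotics N05A, anxiolytics N05B, hypnotics N05C) and a
dictionary of delirium-predisposing illnesses coded as single preferred
terms.  Everything is overridable from a YAML file; see
:func:`load_study_config`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .cohort_builder import ConfounderSpec
from .disproportionality import ModelOptions
from .errors import ConfigError
from .icsr_model import (
    ClassDef,
    ClassMap,
    EventDefinition,
    default_class_map,
)

PRIMARY = "primary"
SENSITIVITY_I = "sensitivity_i"
SENSITIVITY_II = "sensitivity_ii"
SENSITIVITY_III = "sensitivity_iii"

#: nested event definitions: (i) ⊆ primary ⊆ (ii) ⊆ (iii)
_DEF_I = frozenset({"Delirium", "Confusional state"})
_DEF_PRIMARY = _DEF_I | {"Disorientation"}
_DEF_II = _DEF_PRIMARY | {"Circadian rhythm sleep disorder"}
_DEF_III = _DEF_II | {"Hallucinations"}

HYPONATRAEMIA_PT = "Hyponatraemia"


def default_event_definitions() -> dict[str, EventDefinition]:
    return {
        PRIMARY: EventDefinition(PRIMARY, _DEF_PRIMARY),
        SENSITIVITY_I: EventDefinition(SENSITIVITY_I, _DEF_I),
        SENSITIVITY_II: EventDefinition(SENSITIVITY_II, _DEF_II),
        SENSITIVITY_III: EventDefinition(SENSITIVITY_III, _DEF_III),
    }


def default_confounders() -> list[ConfounderSpec]:
    """Demographics, co-prescription classes, and illness preferred terms."""
    specs = [
        ConfounderSpec("age_band", "demographic", "age_band"),
        ConfounderSpec("sex", "demographic", "sex"),
        ConfounderSpec("region", "demographic", "region"),
        ConfounderSpec("opioids", "drug_atc", "N02"),
        ConfounderSpec("antipsychotics", "drug_atc", "N05A"),
        ConfounderSpec("anxiolytics", "drug_atc", "N05B"),
        ConfounderSpec("hypnotics", "drug_atc", "N05C"),
    ]
    illnesses = {
        "constipation": "Constipation",
        "urinary_retention": "Urinary retention",
        "alcohol_use": "Alcohol use",
        "infection": "Infection",
        "drug_misuse": "Drug misuse",
        "dementia": "Dementia",
        "dehydration": "Dehydration",
        "hyponatremia": HYPONATRAEMIA_PT,
        "anticholinergic_syndrome": "Anticholinergic syndrome",
        "hypoglycemia": "Hypoglycaemia",
        "seizure": "Seizure",
        "drug_abuse": "Drug abuse",
        "drug_dependence": "Drug dependence",
        "drug_withdrawal": "Drug withdrawal syndrome",
        "cns_vascular_disorder": "Cerebrovascular accident",
        "hearing_impairment": "Hypoacusis",
        "visual_impairment": "Visual impairment",
    }
    specs.extend(
        ConfounderSpec(label, "event_pt", pt) for label, pt in illnesses.items()
    )
    return specs


@dataclass(frozen=True)
class StudyConfig:
    """Everything the analysis pipeline needs besides the data."""

    event_definitions: dict[str, EventDefinition] = field(
        default_factory=default_event_definitions
    )
    class_map: ClassMap = field(default_factory=default_class_map)
    confounders: list[ConfounderSpec] = field(default_factory=default_confounders)
    min_age: int = 65
    age_bands: tuple[tuple[int, int | None], ...] = ((65, 74), (75, None))
    frequent_drug_threshold: int = 1000
    model: ModelOptions = field(default_factory=ModelOptions)
    joint_exposure_model: bool = True
    per_drug_include_other_classes: bool = False
    complete_case_vars: tuple[str, ...] = ("sex",)
    seed: int = 0

    def __post_init__(self):
        if PRIMARY not in self.event_definitions:
            raise ConfigError("event_definitions: a 'primary' definition is required")
        lo, hi = self.age_bands[0]
        if lo != self.min_age:
            raise ConfigError(
                f"age_bands: first band must start at min_age={self.min_age}, got {lo}"
            )
        prev_hi = hi
        for lo, hi in self.age_bands[1:]:
            if prev_hi is None or lo != prev_hi + 1:
                raise ConfigError("age_bands must partition [min_age, inf) contiguously")
            prev_hi = hi
        if prev_hi is not None:
            raise ConfigError("age_bands: the last band must be open-ended (null upper bound)")

    def definition(self, name: str) -> EventDefinition:
        if name not in self.event_definitions:
            raise ConfigError(
                f"unknown event definition {name!r}; known: {list(self.event_definitions)}"
            )
        return self.event_definitions[name]


def _parse_event_definitions(node: dict, base: dict[str, EventDefinition]):
    defs = dict(base)
    for name, terms in node.items():
        if not isinstance(terms, (list, tuple)) or not terms:
            raise ConfigError(f"event_definitions.{name}: must be a non-empty list of terms")
        defs[name] = EventDefinition(name, frozenset(str(t) for t in terms))
    return defs


def _parse_class_block(name: str, node: dict) -> ClassDef:
    if not isinstance(node, dict):
        raise ConfigError(f"class_map.{name}: expected a mapping with names/atc_prefixes")
    extra = set(node) - {"names", "atc_prefixes"}
    if extra:
        raise ConfigError(f"class_map.{name}: unknown key(s) {sorted(extra)}")
    try:
        return ClassDef(
            names=frozenset(node.get("names", []) or []),
            atc_prefixes=frozenset(node.get("atc_prefixes", []) or []),
        )
    except ConfigError as exc:
        raise ConfigError(f"class_map.{name}: {exc}") from exc


def _parse_class_map(node: dict, base: ClassMap) -> ClassMap:
    classes = dict(base.classes)
    controls = dict(base.controls)
    for label, block in node.items():
        if label == "controls":
            for clabel, cblock in (block or {}).items():
                controls[clabel] = _parse_class_block(f"controls.{clabel}", cblock)
        else:
            if label not in classes:
                raise ConfigError(
                    f"class_map.{label}: unknown class label; known: {sorted(classes)}"
                )
            classes[label] = _parse_class_block(label, block)
    return ClassMap(classes=classes, controls=controls)


def _parse_confounders(node) -> list[ConfounderSpec]:
    if not isinstance(node, list):
        raise ConfigError("confounders: expected a list of {label, kind, matcher}")
    specs = []
    for i, item in enumerate(node):
        if not isinstance(item, dict) or "label" not in item or "kind" not in item:
            raise ConfigError(f"confounders[{i}]: each entry needs label and kind")
        try:
            specs.append(
                ConfounderSpec(
                    str(item["label"]), str(item["kind"]), str(item.get("matcher", ""))
                )
            )
        except ConfigError as exc:
            raise ConfigError(f"confounders[{i}]: {exc}") from exc
    return specs


def load_study_config(path: str | Path | None = None) -> StudyConfig:
    """Load a :class:`StudyConfig` from YAML, filling defaults.

    An empty (or absent) file yields the full default configuration.
    Validation errors name the offending key.
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("study config: top level must be a mapping")
    known = {
        "event_definitions",
        "class_map",
        "confounders",
        "controls",
        "age",
        "frequent_drug_threshold",
        "model",
        "joint_exposure_model",
        "per_drug_include_other_classes",
        "complete_case_vars",
        "seed",
    }
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"study config: unknown top-level key(s) {sorted(unknown)}")

    cfg = StudyConfig()
    kwargs: dict = {}
    if "event_definitions" in raw:
        kwargs["event_definitions"] = _parse_event_definitions(
            raw["event_definitions"] or {}, cfg.event_definitions
        )
    class_node = dict(raw.get("class_map") or {})
    if "controls" in raw:  # allow controls as a top-level alias
        class_node["controls"] = raw["controls"]
    if class_node:
        kwargs["class_map"] = _parse_class_map(class_node, cfg.class_map)
    if "confounders" in raw:
        kwargs["confounders"] = _parse_confounders(raw["confounders"])
    age = raw.get("age") or {}
    if "min" in age:
        kwargs["min_age"] = int(age["min"])
    if "bands" in age:
        bands = tuple(
            (int(b[0]), None if b[1] is None else int(b[1])) for b in age["bands"]
        )
        kwargs["age_bands"] = bands
    if "frequent_drug_threshold" in raw:
        kwargs["frequent_drug_threshold"] = int(raw["frequent_drug_threshold"])
    model = raw.get("model") or {}
    if model:
        extra = set(model) - {"tolerance", "max_iter", "zero_cell_correction"}
        if extra:
            raise ConfigError(f"model: unknown key(s) {sorted(extra)}")
        kwargs["model"] = ModelOptions(
            tolerance=float(model.get("tolerance", 1e-8)),
            max_iter=int(model.get("max_iter", 100)),
            zero_cell_correction=str(model.get("zero_cell_correction", "haldane_anscombe")),
        )
    for key in ("joint_exposure_model", "per_drug_include_other_classes"):
        if key in raw:
            kwargs[key] = bool(raw[key])
    if "complete_case_vars" in raw:
        kwargs["complete_case_vars"] = tuple(raw["complete_case_vars"])
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    return replace(cfg, **kwargs)
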