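"""Synthetic ICSR databases with known ground-truth drug->event effects.

Spontaneous-reporting databases are proprietary, so the pipeline is
exercised on simulated line listings whose generative process makes the
target of the adjusted analysis exact: with confounder indicators
``Z_j ~ Bernoulli(pi_j)``, drug exposures
``X_d ~ Bernoulli(logistic(alpha_d + sum_j delta_dj Z_j))`` and case status
``Y ~ Bernoulli(logistic(beta0 + sum_d beta_d X_d + sum_j gamma_j Z_j))``,
the true adjusted odds ratio of drug *d* is exactly ``exp(beta_d)``,
which :class:`GroundTruth` records.  A parallel hyponatremia pathway
``H ~ Bernoulli(logistic(eta0 + sum_d eta_d X_d))`` lets drugs raise the
joint "delirium + hyponatraemia" outcome without raising delirium itself.

Demographics default to the reporting profile of older-adult
pharmacovigilance data: 41% of reports in the 65-74 band (59% in 75+),
54% women, a small fraction of missing sex.  Sampling uses one seeded
stream with a fixed draw order (demographics -> confounders -> drugs ->
case -> hyponatremia -> events), so a config plus seed is fully
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError
from .icsr_model import (
    DEFAULT_REGIONS,
    DrugEntry,
    EventEntry,
    Report,
    ReportSet,
    load_drug_dictionary,
)

HYPONATRAEMIA_PT = "Hyponatraemia"

#: reporter-role sampling weights for exposed drugs (suspect, concomitant, interacting)
ROLE_WEIGHTS = {"suspect": 0.70, "concomitant": 0.25, "interacting": 0.05}

DEFAULT_CASE_TERMS = {"Delirium": 0.3, "Confusional state": 0.5, "Disorientation": 0.2}

DEFAULT_BACKGROUND_POOL = {
    "Nausea": 1.0,
    "Rash": 1.0,
    "Headache": 1.0,
    "Dizziness": 1.0,
    "Fall": 1.0,
    "Fatigue": 1.0,
    "Pruritus": 1.0,
    "Vomiting": 1.0,
    "Diarrhoea": 1.0,
    "Insomnia": 1.0,
}


def logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def logit(p: float) -> float:
    return math.log(p / (1.0 - p))


@dataclass(frozen=True)
class ConfounderEffect:
    """A generative confounder.

    ``kind="event_pt"``: when present (``Z=1``) the marker PT is added to
    the report's events.  ``kind="drug_atc"``: the marker names a drug
    (resolved through the drug dictionary) added as a concomitant entry.
    ``case_effect`` (gamma) is the log-OR on case status; ``exposure_effects``
    (delta, per drug name) are log-ORs on drug exposure — nonzero gamma and
    delta together induce confounding.
    """

    label: str
    kind: str  # "event_pt" | "drug_atc"
    marker: str
    prevalence: float
    case_effect: float = 0.0
    exposure_effects: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of the ICSR-generating process."""

    n_reports: int
    drugs: dict[str, float]  # drug name -> baseline exposure prevalence, logit scale
    case_intercept: float  # beta0
    case_effects: dict[str, float] = field(default_factory=dict)  # beta_d, log-OR
    confounders: tuple[ConfounderEffect, ...] = ()
    p_age_band: float = 0.41  # P(65-74); the rest falls in 75+
    p_female: float = 0.54
    p_sex_missing: float = 0.005
    region_weights: dict[str, float] = field(
        default_factory=lambda: {r: 0.2 for r in DEFAULT_REGIONS}
    )
    case_terms: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CASE_TERMS))
    hyponatremia_intercept: float = -6.0  # eta0; ~0.25% baseline
    hyponatremia_effects: dict[str, float] = field(default_factory=dict)  # eta_d
    background_pt_pool: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND_POOL)
    )
    scenario: str = "custom"
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports < 1:
            raise ConfigError(f"n_reports must be >= 1, got {self.n_reports}")
        for name, p in (
            ("p_age_band", self.p_age_band),
            ("p_female", self.p_female),
            ("p_sex_missing", self.p_sex_missing),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        total = sum(self.region_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"region_weights must sum to 1 (got {total})")
        if not self.drugs:
            raise ConfigError("at least one drug must be specified")
        for d in self.case_effects:
            if d not in self.drugs:
                raise ConfigError(f"case_effects: drug {d!r} not in drugs")
        for d in self.hyponatremia_effects:
            if d not in self.drugs:
                raise ConfigError(f"hyponatremia_effects: drug {d!r} not in drugs")
        for c in self.confounders:
            if c.kind not in ("event_pt", "drug_atc"):
                raise ConfigError(f"confounder {c.label!r}: invalid kind {c.kind!r}")
            if not 0.0 <= c.prevalence <= 1.0:
                raise ConfigError(f"confounder {c.label!r}: prevalence outside [0, 1]")
            for d in c.exposure_effects:
                if d not in self.drugs:
                    raise ConfigError(
                        f"confounder {c.label!r}: exposure effect for unknown drug {d!r}"
                    )
        if not self.case_terms:
            raise ConfigError("case_terms must be non-empty")
        if not self.background_pt_pool:
            raise ConfigError("background_pt_pool must be non-empty")


@dataclass(frozen=True)
class GroundTruth:
    """True estimands of a generated dataset, keyed like GeneratorConfig.drugs."""

    true_or: dict[str, float]  # exp(beta_d): adjusted delirium odds ratio
    true_hypo_or: dict[str, float]  # exp(eta_d): hyponatremia-pathway odds ratio
    scenario: str

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "true_or": dict(self.true_or),
            "true_hypo_or": dict(self.true_hypo_or),
        }


def generate_reports(config: GeneratorConfig) -> tuple[ReportSet, GroundTruth]:
    """Sample a ReportSet from the generative model (deterministic per config).

    Draw order: demographics, confounder indicators, drug exposures and
    roles, case status, hyponatremia status, event assembly (case term,
    background terms).  Every report ends with at least one event: reports
    with no case, hyponatremia, or confounder event receive 1-3 background
    preferred terms.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    drug_names = list(config.drugs)
    dictionary = load_drug_dictionary()

    # demographics
    band_6574 = rng.random(n) < config.p_age_band
    ages = np.where(
        band_6574,
        rng.integers(65, 75, size=n),
        rng.integers(75, 96, size=n),  # 75+ band truncated at 95
    )
    sex_missing = rng.random(n) < config.p_sex_missing
    female = rng.random(n) < config.p_female
    regions_levels = list(config.region_weights)
    region_idx = rng.choice(
        len(regions_levels), size=n, p=list(config.region_weights.values())
    )

    # confounder indicators
    Z = np.column_stack(
        [rng.random(n) < c.prevalence for c in config.confounders]
    ) if config.confounders else np.zeros((n, 0), dtype=bool)

    # drug exposures and roles
    X = np.zeros((n, len(drug_names)), dtype=bool)
    for j, name in enumerate(drug_names):
        eta = np.full(n, config.drugs[name])
        for k, c in enumerate(config.confounders):
            delta = c.exposure_effects.get(name, 0.0)
            if delta:
                eta = eta + delta * Z[:, k]
        X[:, j] = rng.random(n) < logistic(eta)
    role_codes = rng.choice(
        len(ROLE_WEIGHTS), size=X.shape, p=list(ROLE_WEIGHTS.values())
    )
    role_names = list(ROLE_WEIGHTS)

    # case status
    eta_case = np.full(n, config.case_intercept)
    for j, name in enumerate(drug_names):
        beta = config.case_effects.get(name, 0.0)
        if beta:
            eta_case = eta_case + beta * X[:, j]
    for k, c in enumerate(config.confounders):
        if c.case_effect:
            eta_case = eta_case + c.case_effect * Z[:, k]
    Y = rng.random(n) < logistic(eta_case)

    # hyponatremia status
    eta_h = np.full(n, config.hyponatremia_intercept)
    for j, name in enumerate(drug_names):
        eta = config.hyponatremia_effects.get(name, 0.0)
        if eta:
            eta_h = eta_h + eta * X[:, j]
    H = rng.random(n) < logistic(eta_h)

    # event assembly
    case_terms = list(config.case_terms)
    ct_w = np.array(list(config.case_terms.values()), dtype=float)
    ct_w = ct_w / ct_w.sum()
    case_term_idx = rng.choice(len(case_terms), size=n, p=ct_w)

    event_confs = [
        (k, c) for k, c in enumerate(config.confounders) if c.kind == "event_pt"
    ]
    drug_confs = [
        (k, c) for k, c in enumerate(config.confounders) if c.kind == "drug_atc"
    ]
    has_conf_event = (
        np.logical_or.reduce([Z[:, k] for k, _ in event_confs])
        if event_confs
        else np.zeros(n, dtype=bool)
    )
    needs_background = ~(Y | H | has_conf_event)
    m = int(needs_background.sum())
    bg_pool = list(config.background_pt_pool)
    bg_w = np.array(list(config.background_pt_pool.values()), dtype=float)
    bg_w = bg_w / bg_w.sum()
    bg_counts = rng.integers(1, 4, size=m)
    bg_flat = rng.choice(len(bg_pool), size=int(bg_counts.sum()), p=bg_w)
    bg_splits = np.split(bg_flat, np.cumsum(bg_counts)[:-1]) if m else []

    conf_drug_entries = {
        k: DrugEntry(
            c.marker,
            frozenset(dictionary.get(c.marker.lower(), frozenset())),
            "concomitant",
        )
        for k, c in drug_confs
    }

    # entries and event terms are immutable; build each distinct one once
    drug_entry_cache = {
        (j, rc): DrugEntry(
            drug_names[j],
            frozenset(dictionary.get(drug_names[j], frozenset())),
            role_names[rc],
        )
        for j in range(len(drug_names))
        for rc in range(len(role_names))
    }
    event_cache: dict[str, EventEntry] = {}

    def _pt(pt: str) -> EventEntry:
        e = event_cache.get(pt)
        if e is None:
            e = event_cache[pt] = EventEntry(pt)
        return e

    exposed_drugs: list[list[int]] = [[] for _ in range(n)]
    for j in range(len(drug_names)):
        for i in np.flatnonzero(X[:, j]):
            exposed_drugs[i].append(j)

    id_width = len(str(n))
    reports: list[Report] = []
    bg_i = 0
    for i in range(n):
        drugs: list[DrugEntry] = [
            drug_entry_cache[(j, role_codes[i, j])] for j in exposed_drugs[i]
        ]
        conf_drug_names = {d.drug_name for d in drugs}
        for k, _c in drug_confs:
            if Z[i, k]:
                e = conf_drug_entries[k]
                if e.drug_name not in conf_drug_names:
                    drugs.append(e)

        pts: list[str] = []
        if Y[i]:
            pts.append(case_terms[case_term_idx[i]])
        if H[i]:
            pts.append(HYPONATRAEMIA_PT)
        for k, c in event_confs:
            if Z[i, k] and c.marker not in pts:
                pts.append(c.marker)
        if needs_background[i]:
            for t in bg_splits[bg_i]:
                term = bg_pool[int(t)]
                if term not in pts:
                    pts.append(term)
            bg_i += 1

        reports.append(
            Report(
                report_id=f"R{i + 1:0{id_width}d}",
                age_years=int(ages[i]),
                sex="" if sex_missing[i] else ("F" if female[i] else "M"),
                region=regions_levels[region_idx[i]],
                drugs=tuple(drugs),
                events=tuple(_pt(p) for p in pts),
            )
        )

    truth = GroundTruth(
        true_or={d: math.exp(config.case_effects.get(d, 0.0)) for d in drug_names},
        true_hypo_or={
            d: math.exp(config.hyponatremia_effects.get(d, 0.0)) for d in drug_names
        },
        scenario=config.scenario,
    )
    return ReportSet(reports, provenance=f"synthetic:{config.scenario}"), truth


# ---------------------------------------------------------------------------
# preset scenarios
# ---------------------------------------------------------------------------

PRESETS = ("null", "single_effect", "confounded", "study_like", "controls")

LOG3 = math.log(3.0)


def preset_scenario(name: str, n_reports: int | None = None, seed: int = 0) -> GeneratorConfig:
    """Fully specified generator configs for the standard test scenarios.

    null          three drugs, every effect zero (signal-rule calibration).
    single_effect one drug with a true adjusted OR of 3 (parameter recovery).
    confounded    one drug with no direct effect but a shared cause
                  (dementia: gamma = delta = log 3) inducing a spurious
                  crude association.
    study_like    six antidepressant classes with heterogeneous true ORs,
                  an opioid co-prescription confounder, a dementia
                  confounder linked to antidepressant use, and an
                  SSRI-specific hyponatremia pathway.
    controls      morphine (true OR 3) and alendronate (true OR 1) for the
                  positive/negative control harness.
    """
    if name == "null":
        cfg = GeneratorConfig(
            n_reports=5000,
            drugs={
                "citalopram": logit(0.12),
                "amitriptyline": logit(0.08),
                "venlafaxine": logit(0.08),
            },
            case_intercept=logit(0.10),
            scenario="null",
            seed=seed,
        )
    elif name == "single_effect":
        cfg = GeneratorConfig(
            n_reports=50_000,
            drugs={"citalopram": logit(0.15)},
            case_intercept=logit(0.08),
            case_effects={"citalopram": LOG3},
            scenario="single_effect",
            seed=seed,
        )
    elif name == "confounded":
        cfg = GeneratorConfig(
            n_reports=20_000,
            drugs={"amitriptyline": logit(0.15)},
            case_intercept=logit(0.08),
            case_effects={"amitriptyline": 0.0},
            confounders=(
                ConfounderEffect(
                    label="dementia",
                    kind="event_pt",
                    marker="Dementia",
                    prevalence=0.30,
                    case_effect=LOG3,
                    exposure_effects={"amitriptyline": LOG3},
                ),
            ),
            scenario="confounded",
            seed=seed,
        )
    elif name == "study_like":
        drugs = {
            "amitriptyline": logit(0.030),  # NSMRI
            "citalopram": logit(0.040),  # SSRI
            "sertraline": logit(0.030),  # SSRI
            "venlafaxine": logit(0.025),  # SNRI
            "duloxetine": logit(0.020),  # SNRI
            "moclobemide": logit(0.008),  # MAOI
            "mirtazapine": logit(0.020),  # ALPHA2
            "mianserin": logit(0.010),  # ALPHA2
            "trazodone": logit(0.020),  # OTHER
            "bupropion": logit(0.015),  # OTHER
        }
        cfg = GeneratorConfig(
            n_reports=30_000,
            drugs=drugs,
            case_intercept=logit(0.085),
            case_effects={
                "amitriptyline": math.log(1.8),
                "citalopram": math.log(1.5),
                "sertraline": 0.0,
                "venlafaxine": 0.0,
                "duloxetine": 0.0,
                "moclobemide": math.log(3.0),
                "mirtazapine": math.log(1.3),
                "mianserin": math.log(1.7),
                "trazodone": math.log(1.5),
                "bupropion": math.log(1.2),
            },
            confounders=(
                ConfounderEffect(
                    label="opioid_coprescription",
                    kind="drug_atc",
                    marker="tramadol",
                    prevalence=0.34,
                    case_effect=math.log(2.0),
                ),
                ConfounderEffect(
                    label="dementia",
                    kind="event_pt",
                    marker="Dementia",
                    prevalence=0.02,
                    case_effect=math.log(3.0),
                    exposure_effects={d: math.log(1.5) for d in drugs},
                ),
            ),
            hyponatremia_intercept=logit(0.02),
            hyponatremia_effects={"citalopram": math.log(4.0), "sertraline": math.log(4.0)},
            scenario="study_like",
            seed=seed,
        )
    elif name == "controls":
        cfg = GeneratorConfig(
            n_reports=30_000,
            drugs={
                "morphine": logit(0.15),
                "alendronate": logit(0.08),
                "citalopram": logit(0.08),
            },
            case_intercept=logit(0.08),
            case_effects={"morphine": LOG3, "alendronate": 0.0, "citalopram": math.log(1.5)},
            scenario="controls",
            seed=seed,
        )
    else:
        raise ConfigError(f"unknown preset {name!r}; valid presets: {PRESETS}")
    if n_reports is not None:
        cfg = replace(cfg, n_reports=n_reports)
    return cfg
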