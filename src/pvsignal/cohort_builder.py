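"""From reports to analysis-ready arrays.

This module turns a :class:`~pvsignal.icsr_model.ReportSet` into the
ingredients of a case/non-case analysis: eligibility filtering with an
auditable exclusion log, binary case labelling against a composite event
definition, role-agnostic exposure labelling (a report is exposed if the
drug appears in any role), and the dummy-coded design matrix of the
confounder-adjusted logistic model.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, PvSignalError
from .icsr_model import (
    MISSING,
    ClassMap,
    EventDefinition,
    Report,
    ReportSet,
    is_valid_atc,
    pt_key,
)

logger = logging.getLogger(__name__)

CONFOUNDER_KINDS = ("demographic", "drug_atc", "event_pt")


@dataclass(frozen=True)
class ConfounderSpec:
    """One adjustment covariate.

    kind="demographic": matcher names the variable (age_band, sex, region).
    kind="drug_atc":    matcher is an ATC prefix; the covariate is 1 iff any
                        drug on the report carries a code under the prefix.
    kind="event_pt":    matcher is a preferred term; the covariate is 1 iff
                        the PT occurs among the report's events.
    """

    label: str
    kind: str
    matcher: str = ""

    def __post_init__(self):
        if self.kind not in CONFOUNDER_KINDS:
            raise ConfigError(
                f"confounder {self.label!r}: kind {self.kind!r} not in {CONFOUNDER_KINDS}"
            )
        if self.kind == "drug_atc" and not is_valid_atc(self.matcher.upper()):
            raise ConfigError(
                f"confounder {self.label!r}: malformed ATC prefix {self.matcher!r}"
            )
        if self.kind == "event_pt" and not self.matcher.strip():
            raise ConfigError(f"confounder {self.label!r}: empty PT matcher")


@dataclass
class ExclusionLog:
    """Chained accounting of cohort filters (name, n before, n excluded, n after)."""

    steps: list[tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, name: str, n_before: int, n_excluded: int) -> None:
        n_after = n_before - n_excluded
        if self.steps and self.steps[-1][3] != n_before:
            raise PvSignalError(
                f"exclusion log broken: step {name!r} starts at {n_before}, "
                f"previous ended at {self.steps[-1][3]}"
            )
        self.steps.append((name, n_before, n_excluded, n_after))

    def extend(self, other: "ExclusionLog") -> None:
        for name, n_before, n_excluded, _ in other.steps:
            self.add(name, n_before, n_excluded)

    @property
    def n_final(self) -> int | None:
        return self.steps[-1][3] if self.steps else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps, columns=["filter", "n_before", "n_excluded", "n_after"]
        )


def restrict_age(report_set: ReportSet, min_age: int = 65) -> tuple[ReportSet, ExclusionLog]:
    """Keep reports with known age >= *min_age*; missing ages are excluded here."""
    if min_age < 0:
        raise ConfigError(f"min_age must be >= 0, got {min_age}")
    keep = {
        r.report_id
        for r in report_set
        if r.age_years is not None and r.age_years >= min_age
    }
    log = ExclusionLog()
    log.add(f"age >= {min_age} (missing age excluded)", len(report_set), len(report_set) - len(keep))
    return report_set.subset(keep), log


#: fraction of missing values above which complete-case exclusion warrants a warning
COMPLETE_CASE_WARN_FRACTION = 0.01


def apply_complete_case(
    report_set: ReportSet, required_vars: tuple[str, ...] = ("sex",)
) -> tuple[ReportSet, ExclusionLog]:
    """Drop reports missing any required covariate (complete-case analysis).

    A warning is emitted when more than 1% of reports are missing a required
    variable — the conventional point at which imputation would be weighed
    instead.  Region is normally kept as its own "Unknown" level and need
    not be required.
    """
    allowed = {"sex", "region"}
    bad = set(required_vars) - allowed
    if bad:
        raise ConfigError(f"required_vars must be within {allowed}, got {sorted(bad)}")
    log = ExclusionLog()
    n = len(report_set)
    if not required_vars:
        log.add("complete case (no required vars)", n, 0)
        return report_set, log
    missing = {
        r.report_id
        for r in report_set
        if any(getattr(r, var) == MISSING for var in required_vars)
    }
    if n and len(missing) / n > COMPLETE_CASE_WARN_FRACTION:
        warnings.warn(
            f"complete-case analysis drops {len(missing)}/{n} reports "
            f"({100 * len(missing) / n:.1f}% > 1%); consider imputation",
            stacklevel=2,
        )
    keep = set(report_set.report_ids()) - missing
    log.add(f"complete case on {','.join(required_vars)}", n, len(missing))
    return report_set.subset(keep), log


def label_cases(report_set: ReportSet, event_definition: EventDefinition) -> pd.Series:
    """Binary case vector: 1 iff any event PT is in the definition's term set."""
    keys = event_definition.keys
    return pd.Series(
        [int(bool(keys & r.event_keys)) for r in report_set],
        index=pd.Index(report_set.report_ids(), name="report_id"),
        name=f"case[{event_definition.name}]",
        dtype=np.int8,
    )


def _drug_matches_selector(report: Report, selector: str, class_map: ClassMap | None) -> bool:
    if class_map is not None and selector in class_map.all_labels:
        cdef = class_map.get(selector)
        return any(cdef.matches(d) for d in report.drugs)
    name = selector.strip().lower()
    return any(d.drug_name == name for d in report.drugs)


def label_exposure(
    report_set: ReportSet, selector: str, class_map: ClassMap | None = None
) -> pd.Series:
    """Binary exposure vector for a class label or a single drug name.

    Exposure is role-agnostic: suspect, concomitant and interacting entries
    all count.  If *class_map* is provided and *selector* is not one of its
    labels, an all-uppercase selector is treated as a mistyped class label
    and rejected; anything else is matched as a drug name.
    """
    if class_map is not None and selector not in class_map.all_labels:
        if selector.upper() == selector and not selector.islower():
            raise ConfigError(
                f"unknown class label {selector!r}; known: {class_map.all_labels}"
            )
    return pd.Series(
        [int(_drug_matches_selector(r, selector, class_map)) for r in report_set],
        index=pd.Index(report_set.report_ids(), name="report_id"),
        name=f"exposed[{selector}]",
        dtype=np.int8,
    )


def frequent_drugs(
    report_set: ReportSet, class_map: ClassMap, threshold: int = 1000
) -> dict[str, list[str]]:
    """Antidepressant drugs mentioned in strictly more than *threshold* reports.

    Counts distinct reports (a drug mentioned twice in one report counts
    once), over the whole report set regardless of the event reported.
    Returns ``{class label: [drug names]}`` in class-map order, drugs by
    descending report count then name.
    """
    if threshold < 1:
        raise ConfigError(f"frequent_drug_threshold must be >= 1, got {threshold}")
    counts: Counter[str] = Counter()
    drug_class: dict[str, str] = {}
    for r in report_set:
        seen: set[str] = set()
        for d in r.drugs:
            if d.drug_name in seen:
                continue
            seen.add(d.drug_name)
            if d.drug_name not in drug_class:
                for label in class_map.labels:
                    if class_map.classes[label].matches(d):
                        drug_class[d.drug_name] = label
                        break
                else:
                    drug_class[d.drug_name] = ""
            if drug_class[d.drug_name]:
                counts[d.drug_name] += 1
    out: dict[str, list[str]] = {label: [] for label in class_map.labels}
    for name, cnt in counts.items():
        if cnt > threshold:  # strictly greater: "more than"
            out[drug_class[name]].append(name)
    for label in out:
        out[label].sort(key=lambda n: (-counts[n], n))
    return out


@dataclass
class DesignMatrix:
    """Covariate matrix for the logistic model (no intercept column).

    ``roles`` maps each column to "exposure" or "adjustment"; constant
    adjustment columns are dropped and listed in ``dropped``; ``notes``
    records coding choices (reference levels, overlap exclusions).
    """

    X: pd.DataFrame
    roles: dict[str, str]
    dropped: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def exposure_columns(self) -> list[str]:
        return [c for c, r in self.roles.items() if r == "exposure"]

    @property
    def adjustment_columns(self) -> list[str]:
        return [c for c, r in self.roles.items() if r == "adjustment"]


def build_design_matrix(
    report_set: ReportSet,
    exposure_selectors: list[str],
    confounder_specs: list[ConfounderSpec],
    class_map: ClassMap | None = None,
    include_age_band: bool = True,
) -> DesignMatrix:
    """Assemble the dummy-coded design matrix.

    Exposure columns come from :func:`label_exposure`.  Demographic
    adjustment uses reference levels age 65-74, sex F, and the most
    frequent region (exposure estimates are invariant to this choice).
    Missing region becomes its own "Unknown" level.  When an exposure of
    interest falls inside a drug-ATC confounder's prefix (e.g. positive
    control N02AA inside the opioid confounder N02), that confounder column
    is computed excluding the exposure's drugs to avoid built-in
    collinearity; the exclusion is noted.

    A constant exposure column is an error (the estimate would not exist);
    constant adjustment columns are dropped and logged.
    """
    idx = pd.Index(report_set.report_ids(), name="report_id")
    cols: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}
    dropped: list[str] = []
    notes: list[str] = []

    exposure_matchers = []
    for sel in exposure_selectors:
        vec = label_exposure(report_set, sel, class_map)
        cols[sel] = vec.to_numpy()
        roles[sel] = "exposure"
        if class_map is not None and sel in class_map.all_labels:
            cdef = class_map.get(sel)
            exposure_matchers.append(cdef.matches)
        else:
            name = sel.strip().lower()
            exposure_matchers.append(lambda d, _n=name: d.drug_name == _n)

    def is_exposure_drug(d) -> bool:
        return any(m(d) for m in exposure_matchers)

    demo_wanted = {s.matcher or s.label for s in confounder_specs if s.kind == "demographic"}
    if include_age_band and ("age_band" in demo_wanted or not demo_wanted):
        cols["age_75plus"] = np.array(
            [int(r.age_years is not None and r.age_years >= 75) for r in report_set],
            dtype=np.int8,
        )
        roles["age_75plus"] = "adjustment"
        notes.append("age band reference level: 65-74")
    if "sex" in demo_wanted or not demo_wanted:
        cols["sex_M"] = np.array([int(r.sex == "M") for r in report_set], dtype=np.int8)
        roles["sex_M"] = "adjustment"
        notes.append("sex reference level: F")
    if "region" in demo_wanted or not demo_wanted:
        regions = pd.Series(
            [r.region if r.region != MISSING else "Unknown" for r in report_set], index=idx
        )
        ref = regions.value_counts().idxmax()
        notes.append(f"region reference level: {ref} (most frequent)")
        for level in sorted(regions.unique()):
            if level == ref:
                continue
            name = f"region_{level}"
            cols[name] = (regions == level).to_numpy().astype(np.int8)
            roles[name] = "adjustment"

    for spec in confounder_specs:
        if spec.kind == "demographic":
            continue
        if spec.kind == "drug_atc":
            prefix = spec.matcher.upper()
            overlap_seen = False
            vals = np.zeros(len(report_set), dtype=np.int8)
            for i, r in enumerate(report_set):
                hit = False
                for d in r.drugs:
                    if any(code.startswith(prefix) for code in d.atc_codes):
                        if is_exposure_drug(d):
                            overlap_seen = True
                            continue
                        hit = True
                        break
                vals[i] = int(hit)
            if overlap_seen:
                notes.append(
                    f"confounder {spec.label!r} (ATC {prefix}) computed excluding "
                    "the exposure drugs to avoid built-in collinearity"
                )
        else:  # event_pt
            key = pt_key(spec.matcher)
            vals = np.array(
                [int(key in r.event_keys) for r in report_set], dtype=np.int8
            )
        cols[spec.label] = vals
        roles[spec.label] = "adjustment"

    X = pd.DataFrame(cols, index=idx)
    for c in list(X.columns):
        if X[c].nunique() <= 1:
            if roles[c] == "exposure":
                raise PvSignalError(
                    f"exposure column {c!r} is constant; the exposure effect "
                    "cannot be estimated"
                )
            X = X.drop(columns=[c])
            del roles[c]
            dropped.append(c)
            logger.info("dropped constant adjustment column %r", c)
    return DesignMatrix(X=X.astype(float), roles=roles, dropped=dropped, notes=notes)
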