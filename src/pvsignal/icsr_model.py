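"""Data model and file I/O for individual case safety reports (ICSRs).

An ICSR is one spontaneous report of suspected adverse drug events for one
patient: demographics, a list of drug entries (with ATC codes and a reporter
role), and a list of adverse-event preferred terms (PTs).  The on-disk
representation is a relational line listing of three CSV tables (reports,
drugs, events) joined on ``report_id``; see :func:`read_reports`.

Event terms are flat PT strings matched exactly after canonicalization
(trimmed, internal whitespace collapsed, case-insensitive); no hierarchical
terminology is traversed.  Drug names are resolved to ATC codes through a
packaged drug dictionary that can be replaced by the caller.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import ConfigError, FormatError, IntegrityError

logger = logging.getLogger(__name__)

SEX_LEVELS = ("F", "M")
MISSING = ""
DEFAULT_REGIONS = ("Africa", "Americas", "Asia", "Europe", "Oceania")
ROLES = ("suspect", "concomitant", "interacting")

#: most-causal-first ordering used when collapsing duplicate drug rows
_ROLE_PRIORITY = {"suspect": 0, "interacting": 1, "concomitant": 2}

#: ATC codes/prefixes: letter, 2 digits, letter, letter, 2 digits — truncatable
_ATC_RE = re.compile(r"^[A-Z]([0-9]{2}([A-Z]([A-Z]([0-9]{2})?)?)?)?$")


def canonical_pt(pt: str) -> str:
    """Trim and collapse internal whitespace of a preferred term."""
    return " ".join(str(pt).split())


def pt_key(pt: str) -> str:
    """Case-insensitive matching key for a preferred term."""
    return canonical_pt(pt).casefold()


def is_valid_atc(code: str) -> bool:
    """True if *code* is a lexically valid ATC code or prefix (1-7 chars)."""
    return bool(_ATC_RE.match(code))


@dataclass(frozen=True)
class EventEntry:
    """One adverse-event preferred term on a report."""

    pt: str

    def __post_init__(self):
        canon = canonical_pt(self.pt)
        if not canon:
            raise ValueError("event preferred term must be non-empty")
        object.__setattr__(self, "pt", canon)
        object.__setattr__(self, "_key", canon.casefold())

    @property
    def key(self) -> str:
        return self._key


@dataclass(frozen=True)
class DrugEntry:
    """One drug mention on a report.

    ``role`` records how the reporter characterized the drug (suspect,
    concomitant, or interacting); exposure definitions downstream are
    role-agnostic, so the role only matters for provenance.
    """

    drug_name: str
    atc_codes: frozenset[str] = frozenset()
    role: str = "suspect"

    def __post_init__(self):
        name = canonical_pt(self.drug_name).lower()
        if not name:
            raise ValueError("drug_name must be non-empty")
        object.__setattr__(self, "drug_name", name)
        codes = frozenset(str(c).strip().upper() for c in self.atc_codes if str(c).strip())
        for code in codes:
            if not is_valid_atc(code):
                raise ValueError(f"invalid ATC code {code!r} for drug {name!r}")
        object.__setattr__(self, "atc_codes", codes)
        if self.role not in ROLES:
            raise ValueError(f"invalid role {self.role!r}; expected one of {ROLES}")


@dataclass(frozen=True)
class Report:
    """One individual case safety report."""

    report_id: str
    age_years: int | None
    sex: str  # "F", "M", or "" (missing)
    region: str
    drugs: tuple[DrugEntry, ...] = ()
    events: tuple[EventEntry, ...] = ()

    def __post_init__(self):
        if not str(self.report_id):
            raise ValueError("report_id must be non-empty")
        if self.age_years is not None and not (0 <= int(self.age_years) <= 130):
            raise ValueError(f"age_years {self.age_years} outside [0, 130]")
        if self.sex not in SEX_LEVELS and self.sex != MISSING:
            raise ValueError(f"sex must be F, M or missing, got {self.sex!r}")
        if not self.events:
            raise ValueError(f"report {self.report_id!r} has no events")
        object.__setattr__(self, "drugs", tuple(self.drugs))
        object.__setattr__(self, "events", tuple(self.events))

    @property
    def event_keys(self) -> frozenset[str]:
        keys = self.__dict__.get("_event_keys")
        if keys is None:
            keys = frozenset(e.key for e in self.events)
            object.__setattr__(self, "_event_keys", keys)
        return keys


@dataclass
class ReportSet:
    """A collection of reports with derived counters.

    ``counters`` is always recomputed from ``reports`` so it cannot drift.
    """

    reports: list[Report]
    provenance: str = ""

    def __post_init__(self):
        seen: set[str] = set()
        for r in self.reports:
            if r.report_id in seen:
                raise IntegrityError(f"duplicate report_id {r.report_id!r}")
            seen.add(r.report_id)

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self):
        return iter(self.reports)

    @property
    def counters(self) -> dict[str, int]:
        return {
            "n_reports": len(self.reports),
            "n_missing_sex": sum(1 for r in self.reports if r.sex == MISSING),
            "n_missing_age": sum(1 for r in self.reports if r.age_years is None),
        }

    def report_ids(self) -> list[str]:
        return [r.report_id for r in self.reports]

    def subset(self, keep_ids: set[str], provenance: str | None = None) -> "ReportSet":
        return ReportSet(
            [r for r in self.reports if r.report_id in keep_ids],
            provenance=provenance if provenance is not None else self.provenance,
        )


@dataclass(frozen=True)
class EventDefinition:
    """A named composite adverse event: a set of preferred terms."""

    name: str
    terms: frozenset[str]

    def __post_init__(self):
        if not self.terms:
            raise ConfigError(f"event definition {self.name!r}: terms must be non-empty")
        object.__setattr__(self, "terms", frozenset(canonical_pt(t) for t in self.terms))

    @property
    def keys(self) -> frozenset[str]:
        return frozenset(t.casefold() for t in self.terms)

    def matches(self, report: Report) -> bool:
        return bool(self.keys & report.event_keys)


ANTIDEPRESSANT_CLASSES = ("NSMRI", "SSRI", "SNRI", "MAOI", "ALPHA2", "OTHER")
CONTROL_CLASSES = ("POS_CONTROL", "NEG_CONTROL")


@dataclass(frozen=True)
class ClassDef:
    """Membership rule for one drug class: explicit names and/or ATC prefixes."""

    names: frozenset[str] = frozenset()
    atc_prefixes: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "names", frozenset(n.strip().lower() for n in self.names))
        prefixes = frozenset(p.strip().upper() for p in self.atc_prefixes)
        for p in prefixes:
            if not is_valid_atc(p):
                raise ConfigError(f"malformed ATC prefix {p!r}")
        object.__setattr__(self, "atc_prefixes", prefixes)

    def matches(self, entry: DrugEntry) -> bool:
        if entry.drug_name in self.names:
            return True
        return any(code.startswith(p) for code in entry.atc_codes for p in self.atc_prefixes)


@dataclass(frozen=True)
class ClassMap:
    """Drug-class vocabulary: the six antidepressant classes plus controls.

    The six antidepressant classes must be pairwise disjoint at the
    drug-name level (prefix overlap is ruled out by the default prefixes
    being distinct fourth-level ATC groups).
    """

    classes: dict[str, ClassDef]
    controls: dict[str, ClassDef]

    def __post_init__(self):
        for label in self.classes:
            if label not in ANTIDEPRESSANT_CLASSES:
                raise ConfigError(
                    f"class_map: unknown class label {label!r}; "
                    f"expected one of {ANTIDEPRESSANT_CLASSES}"
                )
        for label in self.controls:
            if label not in CONTROL_CLASSES:
                raise ConfigError(
                    f"class_map.controls: unknown label {label!r}; "
                    f"expected one of {CONTROL_CLASSES}"
                )
        labels = list(self.classes)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                overlap = self.classes[a].names & self.classes[b].names
                if overlap:
                    raise ConfigError(
                        f"class_map: classes {a} and {b} share drug names {sorted(overlap)}"
                    )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.classes)

    @property
    def all_labels(self) -> tuple[str, ...]:
        return tuple(self.classes) + tuple(self.controls)

    def get(self, label: str) -> ClassDef:
        if label in self.classes:
            return self.classes[label]
        if label in self.controls:
            return self.controls[label]
        raise ConfigError(f"unknown class label {label!r}; known: {self.all_labels}")


def default_class_map() -> ClassMap:
    """The default antidepressant class map.

    NSMRIs, SSRIs and MAOIs are defined by ATC fourth-level prefixes
    (N06AA, N06AB, N06AF/N06AG).  SNRIs and alpha-2-adrenergic receptor
    antagonists sit inside ATC N06AX ("other antidepressants"), so they are
    split out by drug name and the OTHER class lists the remaining N06AX
    members explicitly.  Controls: natural opium alkaloids (N02AA) positive,
    bisphosphonates (M05BA) negative.
    """
    return ClassMap(
        classes={
            "NSMRI": ClassDef(atc_prefixes={"N06AA"}),
            "SSRI": ClassDef(atc_prefixes={"N06AB"}),
            "SNRI": ClassDef(
                names={
                    "venlafaxine",
                    "desvenlafaxine",
                    "duloxetine",
                    "milnacipran",
                    "levomilnacipran",
                }
            ),
            "MAOI": ClassDef(atc_prefixes={"N06AF", "N06AG"}),
            "ALPHA2": ClassDef(names={"mirtazapine", "mianserin", "setiptiline"}),
            "OTHER": ClassDef(
                names={
                    "trazodone",
                    "bupropion",
                    "vortioxetine",
                    "agomelatine",
                    "tianeptine",
                    "nefazodone",
                    "vilazodone",
                    "reboxetine",
                    "hypericum",
                }
            ),
        },
        controls={
            "POS_CONTROL": ClassDef(atc_prefixes={"N02AA"}),
            "NEG_CONTROL": ClassDef(atc_prefixes={"M05BA"}),
        },
    )


def map_drug_to_classes(drug_entry: DrugEntry, class_map: ClassMap) -> set[str]:
    """Class labels (including control classes) that *drug_entry* belongs to.

    A label is returned iff the drug name is listed for that class or any
    of the drug's ATC codes starts with one of the class's ATC prefixes;
    explicit drug names take precedence, but both routes are checked so a
    name listed in one class never suppresses a prefix match in another.
    The result is deterministic and empty for non-member drugs.
    """
    out: set[str] = set()
    for label in class_map.all_labels:
        if class_map.get(label).matches(drug_entry):
            out.add(label)
    return out


# ---------------------------------------------------------------------------
# drug dictionary
# ---------------------------------------------------------------------------

def load_drug_dictionary(path: str | Path | None = None) -> dict[str, frozenset[str]]:
    """Load a ``drug_name -> set of ATC codes`` dictionary from CSV.

    Without a path, the packaged dictionary is used; it covers the
    antidepressants analyzed per-drug, the opioid and bisphosphonate
    control classes, the co-prescription confounder classes, and a
    selection of background drugs.
    """
    if path is None:
        ref = resources.files("pvsignal").joinpath("data/drug_dictionary.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["drug_name", "atc_codes"], "drug_dictionary")
    out: dict[str, frozenset[str]] = {}
    for _, row in df.iterrows():
        name = canonical_pt(row["drug_name"]).lower()
        codes = frozenset(c.strip().upper() for c in row["atc_codes"].split(";") if c.strip())
        out[name] = codes
    return out


# ---------------------------------------------------------------------------
# CSV line-listing I/O
# ---------------------------------------------------------------------------

REPORTS_COLUMNS = ["report_id", "age_years", "sex", "region"]
DRUGS_COLUMNS = ["report_id", "drug_name", "atc_codes", "role"]
EVENTS_COLUMNS = ["report_id", "pt"]


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{name}: missing required column(s) {missing}")


def read_reports(
    reports_path: str | Path,
    drugs_path: str | Path,
    events_path: str | Path,
    drug_dictionary: dict[str, frozenset[str]] | None = None,
) -> ReportSet:
    """Read a three-table CSV line listing into a :class:`ReportSet`.

    Drug and event rows are joined on ``report_id``.  Drug names absent
    from *drug_dictionary* resolve to an empty ATC set (logged); ATC codes
    present in the drugs table are unioned with the dictionary's.  Reports
    with zero event rows are rejected (dropped and logged) since an ICSR
    reports at least one adverse event.  Duplicate (report, drug) rows are
    collapsed to one entry keeping the most causal role
    (suspect > interacting > concomitant).
    """
    if drug_dictionary is None:
        drug_dictionary = load_drug_dictionary()

    reports_df = pd.read_csv(reports_path, dtype=str, keep_default_na=False)
    drugs_df = pd.read_csv(drugs_path, dtype=str, keep_default_na=False)
    events_df = pd.read_csv(events_path, dtype=str, keep_default_na=False)
    _require_columns(reports_df, REPORTS_COLUMNS, "reports.csv")
    _require_columns(drugs_df, DRUGS_COLUMNS, "drugs.csv")
    _require_columns(events_df, EVENTS_COLUMNS, "events.csv")

    ids = reports_df["report_id"].tolist()
    dup = reports_df["report_id"][reports_df["report_id"].duplicated()].unique().tolist()
    if dup:
        raise IntegrityError(f"duplicate report_id in reports.csv: {dup}")
    id_set = set(ids)
    for name, df in (("drugs.csv", drugs_df), ("events.csv", events_df)):
        dangling = sorted(set(df["report_id"]) - id_set)
        if dangling:
            raise IntegrityError(f"{name}: rows reference absent report_id(s) {dangling}")

    drugs_by_id: dict[str, list[DrugEntry]] = {rid: [] for rid in ids}
    unknown_names: set[str] = set()
    for row in drugs_df.itertuples(index=False):
        name = canonical_pt(row.drug_name).lower()
        codes = set(c.strip().upper() for c in str(row.atc_codes).split(";") if c.strip())
        dict_codes = drug_dictionary.get(name)
        if dict_codes:
            codes |= set(dict_codes)
        elif not codes:
            unknown_names.add(name)
        role = str(row.role).strip().lower() or "suspect"
        if role not in ROLES:
            raise FormatError(f"drugs.csv: invalid role {row.role!r} for report {row.report_id!r}")
        drugs_by_id[row.report_id].append(DrugEntry(name, frozenset(codes), role))
    if unknown_names:
        logger.warning(
            "%d drug name(s) not in the drug dictionary resolved to empty ATC sets: %s",
            len(unknown_names),
            sorted(unknown_names)[:10],
        )

    events_by_id: dict[str, list[EventEntry]] = {rid: [] for rid in ids}
    for row in events_df.itertuples(index=False):
        events_by_id[row.report_id].append(EventEntry(row.pt))

    reports: list[Report] = []
    n_no_events = 0
    for row in reports_df.itertuples(index=False):
        rid = row.report_id
        if not events_by_id[rid]:
            n_no_events += 1
            continue
        age = None if str(row.age_years).strip() == "" else int(str(row.age_years).strip())
        sex = str(row.sex).strip()
        reports.append(
            Report(
                report_id=rid,
                age_years=age,
                sex=sex,
                region=str(row.region).strip(),
                drugs=tuple(_collapse_duplicates(drugs_by_id[rid])),
                events=tuple(events_by_id[rid]),
            )
        )
    if n_no_events:
        logger.warning("rejected %d report(s) with zero event rows", n_no_events)
    return ReportSet(reports, provenance=str(reports_path))


def _collapse_duplicates(entries: list[DrugEntry]) -> list[DrugEntry]:
    """Collapse duplicate drug rows keeping the most causal role."""
    by_name: dict[str, DrugEntry] = {}
    order: list[str] = []
    for e in entries:
        if e.drug_name not in by_name:
            by_name[e.drug_name] = e
            order.append(e.drug_name)
        else:
            prev = by_name[e.drug_name]
            role = min(prev.role, e.role, key=_ROLE_PRIORITY.__getitem__)
            by_name[e.drug_name] = replace(
                prev, atc_codes=prev.atc_codes | e.atc_codes, role=role
            )
    return [by_name[n] for n in order]


def write_reports(report_set: ReportSet, out_dir: str | Path) -> dict[str, Path]:
    """Write a ReportSet as the three-table CSV line listing.

    ``read_reports(**write_reports(S))`` reproduces ``S`` field for field;
    multiple ATC codes are semicolon-joined (sorted for determinism).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rep_rows, drug_rows, event_rows = [], [], []
    for r in report_set:
        rep_rows.append(
            {
                "report_id": r.report_id,
                "age_years": "" if r.age_years is None else r.age_years,
                "sex": r.sex,
                "region": r.region,
            }
        )
        for d in r.drugs:
            drug_rows.append(
                {
                    "report_id": r.report_id,
                    "drug_name": d.drug_name,
                    "atc_codes": ";".join(sorted(d.atc_codes)),
                    "role": d.role,
                }
            )
        for e in r.events:
            event_rows.append({"report_id": r.report_id, "pt": e.pt})
    paths = {
        "reports_path": out / "reports.csv",
        "drugs_path": out / "drugs.csv",
        "events_path": out / "events.csv",
    }
    pd.DataFrame(rep_rows, columns=REPORTS_COLUMNS).to_csv(paths["reports_path"], index=False)
    pd.DataFrame(drug_rows, columns=DRUGS_COLUMNS).to_csv(paths["drugs_path"], index=False)
    pd.DataFrame(event_rows, columns=EVENTS_COLUMNS).to_csv(paths["events_path"], index=False)
    return paths
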