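import pandas as pd
import pytest

from pvsignal import (
    DrugEntry,
    EventEntry,
    Report,
    ReportSet,
    StudyConfig,
    default_class_map,
)


@pytest.fixture(scope="session")
def study_config() -> StudyConfig:
    return StudyConfig()


@pytest.fixture(scope="session")
def class_map():
    return default_class_map()


def make_report(
    rid: str,
    age: int | None = 70,
    sex: str = "F",
    region: str = "Europe",
    drugs: list[tuple[str, str, str]] = (),
    events: list[str] = ("Rash",),
) -> Report:
    """Terse report builder: drugs as (name, atc, role) triples, events as PTs."""
    return Report(
        report_id=rid,
        age_years=age,
        sex=sex,
        region=region,
        drugs=tuple(
            DrugEntry(n, frozenset([a]) if a else frozenset(), role) for n, a, role in drugs
        ),
        events=tuple(EventEntry(pt) for pt in events),
    )


@pytest.fixture
def small_report_set() -> ReportSet:
    """Six hand-built reports covering cases, exposures, and confounders."""
    return ReportSet(
        [
            make_report(
                "R1",
                age=70,
                drugs=[("citalopram", "N06AB04", "concomitant")],
                events=["Confusional state", "Rash"],
            ),
            make_report(
                "R2",
                age=80,
                sex="M",
                drugs=[("morphine", "N02AA01", "suspect")],
                events=["Delirium", "Hyponatraemia"],
            ),
            make_report(
                "R3",
                age=66,
                drugs=[("mirtazapine", "N06AX11", "suspect")],
                events=["Hallucinations"],
            ),
            make_report("R4", age=90, events=["Rash"], drugs=[("metformin", "A10BA02", "suspect")]),
            make_report(
                "R5",
                age=75,
                sex="M",
                region="Asia",
                drugs=[("sertraline", "N06AB06", "suspect"), ("tramadol", "N02AX02", "concomitant")],
                events=["Disorientation", "Dementia"],
            ),
            make_report("R6", age=68, events=["Nausea"]),
        ]
    )


def write_listing(tmp_path, rows_reports, rows_drugs, rows_events):
    """Write raw CSV line-listing tables and return the three paths."""
    rp = tmp_path / "reports.csv"
    dp = tmp_path / "drugs.csv"
    ep = tmp_path / "events.csv"
    pd.DataFrame(rows_reports, columns=["report_id", "age_years", "sex", "region"]).to_csv(
        rp, index=False
    )
    pd.DataFrame(rows_drugs, columns=["report_id", "drug_name", "atc_codes", "role"]).to_csv(
        dp, index=False
    )
    pd.DataFrame(rows_events, columns=["report_id", "pt"]).to_csv(ep, index=False)
    return rp, dp, ep
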