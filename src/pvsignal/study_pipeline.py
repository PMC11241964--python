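"""End-to-end orchestration of the disproportionality analyses.

Each ``run_*`` function takes a raw :class:`~pvsignal.icsr_model.ReportSet`
and a :class:`~pvsignal.config.StudyConfig`, applies the eligibility
filters (age >= 65, complete case on sex), and returns an analysis table —
a tidy DataFrame with one row per (analysis, exposure): the 2x2 counts, the
crude r-OR with Woolf CI, the adjusted r-OR with Wald CI from the
confounder-adjusted logistic model, and the signal classification of the
adjusted estimate.  Exclusion logs and VIF diagnostics ride along in
``DataFrame.attrs``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__ as _version
from .cohort_builder import (
    ExclusionLog,
    apply_complete_case,
    build_design_matrix,
    frequent_drugs,
    label_cases,
    label_exposure,
    restrict_age,
)
from .config import HYPONATRAEMIA_PT, PRIMARY, StudyConfig
from .disproportionality import (
    LOW_COUNT_THRESHOLD,
    RorEstimate,
    adjusted_ror,
    classify_signal,
    compute_vif,
    crude_ror,
    fit_logistic,
    tabulate,
)
from .errors import PvSignalError
from .icsr_model import ReportSet

logger = logging.getLogger(__name__)

ANALYSIS_COLUMNS = [
    "analysis_id",
    "outcome",
    "exposure",
    "n_exposed_cases",
    "a",
    "b",
    "c",
    "d",
    "ror_crude",
    "ror_crude_low",
    "ror_crude_high",
    "ror_adj",
    "ror_adj_low",
    "ror_adj_high",
    "signal_crude",
    "signal",
    "flags",
]


def _prepare_cohort(
    report_set: ReportSet, config: StudyConfig
) -> tuple[ReportSet, ExclusionLog]:
    cohort, log = restrict_age(report_set, config.min_age)
    cohort, cc_log = apply_complete_case(cohort, config.complete_case_vars)
    log.extend(cc_log)
    return cohort, log


def _row(
    analysis_id: str,
    outcome: str,
    exposure: str,
    table,
    crude: RorEstimate | None,
    adjusted: RorEstimate | None,
    error: str = "",
) -> dict:
    flags = []
    if (crude and crude.low_count_flag) or (adjusted and adjusted.low_count_flag):
        flags.append("low_count")
    if error:
        flags.append(error)
    return {
        "analysis_id": analysis_id,
        "outcome": outcome,
        "exposure": exposure,
        "n_exposed_cases": table.a,
        "a": table.a,
        "b": table.b,
        "c": table.c,
        "d": table.d,
        "ror_crude": crude.point if crude else np.nan,
        "ror_crude_low": crude.ci_low if crude else np.nan,
        "ror_crude_high": crude.ci_high if crude else np.nan,
        "ror_adj": adjusted.point if adjusted else np.nan,
        "ror_adj_low": adjusted.ci_low if adjusted else np.nan,
        "ror_adj_high": adjusted.ci_high if adjusted else np.nan,
        "signal_crude": classify_signal(crude) if crude else "",
        "signal": classify_signal(adjusted) if adjusted else "",
        "flags": ";".join(flags),
    }


def _analyse_exposures(
    cohort: ReportSet,
    config: StudyConfig,
    case_vector: pd.Series,
    exposures: list[str],
    analysis_id: str,
    outcome: str,
    confounder_specs=None,
    joint: bool | None = None,
    include_age_band: bool = True,
) -> pd.DataFrame:
    """Crude + adjusted rows for a list of exposure selectors.

    In the joint model all exposures enter one logistic fit; otherwise one
    model is fit per exposure.  A separation or fitting failure in
    per-exposure mode fails only that row; in joint mode it fails the whole
    analysis (reported on every row).
    """
    specs = config.confounders if confounder_specs is None else confounder_specs
    joint = config.joint_exposure_model if joint is None else joint
    rows = []
    crude_by_exposure: dict[str, tuple] = {}
    for sel in exposures:
        vec = label_exposure(cohort, sel, config.class_map)
        table = tabulate(case_vector, vec)
        crude = crude_ror(table, config.model.zero_cell_correction)
        crude_by_exposure[sel] = (table, crude)

    def _drop_inestimable_adjustments(dm, y):
        """Drop adjustment columns with an empty outcome cell (their MLE is
        infinite — quasi-separation); exposures are never dropped here."""
        yb = y.to_numpy().astype(bool)
        for col in dm.adjustment_columns:
            x = dm.X[col].to_numpy().astype(bool)
            if not (yb & x).any() or not (~yb & x).any():
                dm.X = dm.X.drop(columns=[col])
                del dm.roles[col]
                dm.dropped.append(col)
                logger.info("dropped adjustment column %r (empty outcome cell)", col)
        return dm

    adjusted_by_exposure: dict[str, RorEstimate | None] = {}
    errors: dict[str, str] = {}
    vif_table = None
    # exposures with no exposed outcome events have an infinite adjusted MLE;
    # they keep their corrected crude estimate and are left out of the fit
    estimable = [sel for sel in exposures if crude_by_exposure[sel][0].a > 0]
    for sel in exposures:
        if sel not in estimable:
            adjusted_by_exposure[sel] = None
            errors[sel] = "no_exposed_outcome_events"

    if joint:
        try:
            if not estimable:
                raise PvSignalError("no estimable exposures")
            dm = build_design_matrix(
                cohort, estimable, specs, config.class_map, include_age_band
            )
            dm = _drop_inestimable_adjustments(dm, case_vector)
            fit = fit_logistic(dm, case_vector, config.model)
            vif_table = compute_vif(dm) if dm.X.shape[1] >= 2 else None
            for sel in estimable:
                adjusted_by_exposure[sel] = adjusted_ror(
                    fit, sel, crude_by_exposure[sel][0].a
                )
        except PvSignalError as exc:
            logger.warning("joint model for %s failed: %s", analysis_id, exc)
            for sel in estimable:
                adjusted_by_exposure[sel] = None
                errors[sel] = f"model_error:{exc.__class__.__name__}"
    else:
        for sel in estimable:
            try:
                dm = build_design_matrix(
                    cohort, [sel], specs, config.class_map, include_age_band
                )
                dm = _drop_inestimable_adjustments(dm, case_vector)
                fit = fit_logistic(dm, case_vector, config.model)
                adjusted_by_exposure[sel] = adjusted_ror(
                    fit, sel, crude_by_exposure[sel][0].a
                )
            except PvSignalError as exc:
                logger.warning("model for %s/%s failed: %s", analysis_id, sel, exc)
                adjusted_by_exposure[sel] = None
                errors[sel] = f"model_error:{exc.__class__.__name__}"

    for sel in exposures:
        table, crude = crude_by_exposure[sel]
        rows.append(
            _row(
                analysis_id,
                outcome,
                sel,
                table,
                crude,
                adjusted_by_exposure[sel],
                errors.get(sel, ""),
            )
        )
    out = pd.DataFrame(rows, columns=ANALYSIS_COLUMNS)
    if vif_table is not None:
        # plain nested dict: DataFrame-valued attrs break pandas concat
        out.attrs["vif"] = {
            col: {"vif": float(r["vif"]), "flagged": bool(r["flagged"])}
            for col, r in vif_table.iterrows()
        }
    return out


def run_primary(report_set: ReportSet, config: StudyConfig) -> pd.DataFrame:
    """Class-level analysis of the primary outcome, one row per class."""
    cohort, log = _prepare_cohort(report_set, config)
    cases = label_cases(cohort, config.definition(PRIMARY))
    out = _analyse_exposures(
        cohort,
        config,
        cases,
        list(config.class_map.labels),
        analysis_id="primary",
        outcome=PRIMARY,
    )
    out.attrs["exclusions"] = log
    return out


def run_per_drug(report_set: ReportSet, config: StudyConfig) -> pd.DataFrame:
    """Per-drug analysis of the most frequently reported antidepressants.

    Eligible drugs are those mentioned in strictly more than
    ``frequent_drug_threshold`` reports (counted on the full report set,
    before case restriction).  Each drug gets its own model: the drug
    indicator plus confounders, without the drug's own class indicator
    (and by default without any class indicators).
    """
    per_class = frequent_drugs(report_set, config.class_map, config.frequent_drug_threshold)
    cohort, log = _prepare_cohort(report_set, config)
    cases = label_cases(cohort, config.definition(PRIMARY))
    frames = []
    for class_label in config.class_map.labels:
        for drug in per_class.get(class_label, []):
            extra_classes = (
                [c for c in config.class_map.labels if c != class_label]
                if config.per_drug_include_other_classes
                else []
            )
            frame = _analyse_exposures(
                cohort,
                config,
                cases,
                [drug, *extra_classes],
                analysis_id=f"per_drug:{class_label}",
                outcome=PRIMARY,
                joint=True if extra_classes else False,
            )
            frames.append(frame[frame["exposure"] == drug])
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=ANALYSIS_COLUMNS)
    )
    out.attrs["exclusions"] = log
    return out


def run_age_subgroups(report_set: ReportSet, config: StudyConfig) -> pd.DataFrame:
    """Primary analysis repeated within each age band.

    The age-band covariate is constant inside a band and is therefore
    omitted from the subgroup design matrices.
    """
    cohort, log = _prepare_cohort(report_set, config)
    frames = []
    for lo, hi in config.age_bands:
        label = f"age_{lo}_{hi if hi is not None else 'plus'}"
        keep = {
            r.report_id
            for r in cohort
            if r.age_years is not None
            and r.age_years >= lo
            and (hi is None or r.age_years <= hi)
        }
        band = cohort.subset(keep, provenance=f"{cohort.provenance}|{label}")
        cases = label_cases(band, config.definition(PRIMARY))
        frames.append(
            _analyse_exposures(
                band,
                config,
                cases,
                list(config.class_map.labels),
                analysis_id=label,
                outcome=PRIMARY,
                include_age_band=False,
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.attrs["exclusions"] = log
    return out


def run_concomitant(report_set: ReportSet, config: StudyConfig) -> pd.DataFrame:
    """Concomitant delirium + hyponatremia outcome, one row per class.

    The outcome is a primary-definition case that also reports the
    "Hyponatraemia" PT; the hyponatremia adjustment covariate is removed
    (it is part of the outcome).
    """
    cohort, log = _prepare_cohort(report_set, config)
    delirium = label_cases(cohort, config.definition(PRIMARY))
    hypo_key = HYPONATRAEMIA_PT.casefold()
    has_hypo = pd.Series(
        [int(hypo_key in r.event_keys) for r in cohort],
        index=delirium.index,
        dtype=np.int8,
    )
    outcome_vec = (delirium.astype(bool) & has_hypo.astype(bool)).astype(np.int8)
    specs = [
        s
        for s in config.confounders
        if not (s.kind == "event_pt" and s.matcher.casefold() == hypo_key)
    ]
    out = _analyse_exposures(
        cohort,
        config,
        outcome_vec,
        list(config.class_map.labels),
        analysis_id="concomitant_hyponatremia",
        outcome="delirium+hyponatraemia",
        confounder_specs=specs,
    )
    out.attrs["exclusions"] = log
    return out


def run_sensitivity(report_set: ReportSet, config: StudyConfig) -> pd.DataFrame:
    """Primary analysis under the three alternative delirium definitions.

    ``concordant_with_primary`` marks rows whose signal status matches the
    primary analysis for the same class.
    """
    cohort, log = _prepare_cohort(report_set, config)
    primary_cases = label_cases(cohort, config.definition(PRIMARY))
    primary_tbl = _analyse_exposures(
        cohort,
        config,
        primary_cases,
        list(config.class_map.labels),
        analysis_id="primary",
        outcome=PRIMARY,
    )
    primary_signal = dict(zip(primary_tbl["exposure"], primary_tbl["signal"]))
    frames = []
    for name in ("sensitivity_i", "sensitivity_ii", "sensitivity_iii"):
        cases = label_cases(cohort, config.definition(name))
        frame = _analyse_exposures(
            cohort,
            config,
            cases,
            list(config.class_map.labels),
            analysis_id=name,
            outcome=name,
        )
        frame["concordant_with_primary"] = [
            s == primary_signal.get(e, "") for e, s in zip(frame["exposure"], frame["signal"])
        ]
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    out.attrs["exclusions"] = log
    return out


NOT_EVALUABLE = "not_evaluable"


@dataclass
class ControlValidation:
    """Outcome of the positive/negative control harness.

    ``passed`` iff the positive control is a signal and the negative
    control is not; controls absent from the data are reported as
    not evaluable, never as a silent pass.
    """

    positive: RorEstimate | None
    positive_status: str
    negative: RorEstimate | None
    negative_status: str

    @property
    def passed(self) -> bool:
        return self.positive_status == "signal" and self.negative_status == "no_signal"


def run_controls(report_set: ReportSet, config: StudyConfig) -> ControlValidation:
    """Adjusted r-ORs for the positive and negative control exposures.

    The positive control (natural opium alkaloids, ATC N02AA) must flag as
    a signal and the negative control (bisphosphonates, M05BA) must not.
    The opioid confounder column automatically excludes the N02AA drugs
    (see cohort_builder), so the positive control is not adjusted away.
    """
    cohort, _ = _prepare_cohort(report_set, config)
    cases = label_cases(cohort, config.definition(PRIMARY))
    results: dict[str, tuple[RorEstimate | None, str]] = {}
    for label in ("POS_CONTROL", "NEG_CONTROL"):
        vec = label_exposure(cohort, label, config.class_map)
        if vec.sum() == 0 or tabulate(cases, vec).a == 0:
            results[label] = (None, NOT_EVALUABLE)
            continue
        try:
            dm = build_design_matrix(cohort, [label], config.confounders, config.class_map)
            fit = fit_logistic(dm, cases, config.model)
            est = adjusted_ror(fit, label, tabulate(cases, vec).a)
            results[label] = (est, classify_signal(est))
        except PvSignalError as exc:
            logger.warning("control %s not evaluable: %s", label, exc)
            results[label] = (None, NOT_EVALUABLE)
    return ControlValidation(
        positive=results["POS_CONTROL"][0],
        positive_status=results["POS_CONTROL"][1],
        negative=results["NEG_CONTROL"][0],
        negative_status=results["NEG_CONTROL"][1],
    )


ANALYSES = ("primary", "per_drug", "age", "concomitant", "sensitivity", "controls")

_RUNNERS = {
    "primary": run_primary,
    "per_drug": run_per_drug,
    "age": run_age_subgroups,
    "concomitant": run_concomitant,
    "sensitivity": run_sensitivity,
}


def run_study(
    report_set: ReportSet, config: StudyConfig, analyses: tuple[str, ...] = ANALYSES
) -> dict:
    """Run the requested analyses; returns {name: AnalysisTable or ControlValidation}."""
    out: dict = {}
    for name in analyses:
        if name == "controls":
            out[name] = run_controls(report_set, config)
        elif name in _RUNNERS:
            out[name] = _RUNNERS[name](report_set, config)
        else:
            raise PvSignalError(f"unknown analysis {name!r}; valid: {ANALYSES}")
    return out


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def _config_hash(config: StudyConfig) -> str:
    blob = repr(config).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def export_results(
    results: dict,
    out_dir,
    config: StudyConfig | None = None,
    formats: tuple[str, ...] = ("csv", "json", "forest_tsv", "markdown"),
) -> dict[str, object]:
    """Write analysis outputs to *out_dir*.

    results.csv concatenates every AnalysisTable (full precision);
    forest.tsv holds (label, point, lo, hi, group) per adjusted estimate for
    plotting; run_manifest.json records the config hash, seed, software
    version, exclusion accounting, VIF tables, the number of tests
    performed, and control-validation status; exclusions.csv and vif.csv
    mirror the attrs.  Display rounding (2 decimals, as in "3.35
    [3.25-3.44]") applies only to the markdown rendering.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, object] = {}

    tables = {k: v for k, v in results.items() if isinstance(v, pd.DataFrame)}
    controls = {k: v for k, v in results.items() if isinstance(v, ControlValidation)}
    combined = (
        pd.concat(tables.values(), ignore_index=True)
        if tables
        else pd.DataFrame(columns=ANALYSIS_COLUMNS)
    )

    if "csv" in formats:
        path = out / "results.csv"
        combined.to_csv(path, index=False)
        written["results_csv"] = path
    if "forest_tsv" in formats:
        forest = pd.DataFrame(
            {
                "label": combined["exposure"],
                "point": combined["ror_adj"],
                "lo": combined["ror_adj_low"],
                "hi": combined["ror_adj_high"],
                "group": combined["analysis_id"],
            }
        )
        path = out / "forest.tsv"
        forest.to_csv(path, sep="\t", index=False)
        written["forest_tsv"] = path
    if "markdown" in formats:
        lines = ["| analysis | exposure | n cases exp. | crude r-OR [95% CI] | adjusted r-OR [95% CI] | signal |",
                 "|---|---|---|---|---|---|"]

        def _fmt(point, lo, hi):
            if pd.isna(point):
                return "—"
            return f"{point:.2f} [{lo:.2f}-{hi:.2f}]"

        for r in combined.itertuples(index=False):
            lines.append(
                f"| {r.analysis_id} | {r.exposure} | {r.n_exposed_cases} "
                f"| {_fmt(r.ror_crude, r.ror_crude_low, r.ror_crude_high)} "
                f"| {_fmt(r.ror_adj, r.ror_adj_low, r.ror_adj_high)} | {r.signal} |"
            )
        path = out / "results.md"
        path.write_text("\n".join(lines) + "\n")
        written["results_md"] = path

    exclusion_frames = []
    vif_frames = []
    for name, table in tables.items():
        log = table.attrs.get("exclusions")
        if log is not None:
            df = log.to_frame()
            df.insert(0, "analysis", name)
            exclusion_frames.append(df)
        vif = table.attrs.get("vif")
        if vif is not None:
            df = pd.DataFrame(
                [(col, v["vif"], v["flagged"]) for col, v in vif.items()],
                columns=["column", "vif", "flagged"],
            )
            df.insert(0, "analysis", name)
            vif_frames.append(df)
    if exclusion_frames:
        path = out / "exclusions.csv"
        pd.concat(exclusion_frames, ignore_index=True).to_csv(path, index=False)
        written["exclusions_csv"] = path
    if vif_frames:
        path = out / "vif.csv"
        pd.concat(vif_frames, ignore_index=True).to_csv(path, index=False)
        written["vif_csv"] = path

    if "json" in formats:
        manifest = {
            "software": {"name": "pvsignal", "version": _version},
            "seed": config.seed if config is not None else None,
            "config_hash": _config_hash(config) if config is not None else None,
            "n_tests": int(combined["signal"].astype(bool).size),
            "analyses": sorted(tables),
            "exclusions": {
                name: table.attrs["exclusions"].steps
                for name, table in tables.items()
                if "exclusions" in table.attrs
            },
            "controls": {
                name: {
                    "positive_status": cv.positive_status,
                    "negative_status": cv.negative_status,
                    "passed": cv.passed,
                }
                for name, cv in controls.items()
            },
        }
        path = out / "run_manifest.json"
        path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
        written["run_manifest_json"] = path
    return written
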