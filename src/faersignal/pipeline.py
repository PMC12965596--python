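"""End-to-end analysis orchestration.

Stage order mirrors the study design: ingest -> deduplicate -> select the
primary-suspect cohort -> baseline characteristics -> SOC- and PT-level
disproportionality -> sensitivity re-analysis with co-medication
exclusion -> age-subgroup re-analysis -> time-to-onset modeling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import pandas as pd

from . import cohort as cohort_mod
from . import dispro, io, tto
from .cohort import (BASELINE_STRATA, SUBGROUP_STRATA, DedupResult, SocMap,
                     age_in_years, age_stratum, deduplicate,
                     reports_with_drug, select_primary_suspect)
from .dispro import (ContingencyTable, GpsPrior, SignalThresholds,
                     build_tables, compute_metrics, gps_fit)
from .errors import ConfigError, DataError
from .io import DrugRow, ReactionRow, ReportRecord, TherapyRow

logger = logging.getLogger(__name__)

#: occupation codes treated as healthcare professionals
HCP_CODES = {"MD", "PH", "OT", "HP", "RN"}
NON_HCP_CODES = {"CN", "LW"}


@dataclass
class Dataset:
    """Typed four-table dataset, the unit the pipeline consumes."""

    reports: List[ReportRecord]
    drug_rows: List[DrugRow]
    reac_rows: List[ReactionRow]
    ther_rows: List[TherapyRow]

    @classmethod
    def from_dir(cls, data_dir: Union[str, Path],
                 delimiter: str = "$") -> "Dataset":
        tables = io.read_dataset(data_dir, delimiter)
        return cls(tables["DEMO"], tables["DRUG"], tables["REAC"],
                   tables["THER"])

    @classmethod
    def from_synthetic(cls, sdata) -> "Dataset":
        """Adopt an in-memory :class:`faersignal.synth.SyntheticDataset`."""
        def cols(frame, names):
            return [frame[n].tolist() for n in names]

        fda_cache: Dict[str, object] = {}

        def full_date(text):
            d = fda_cache.get(text)
            if d is None:
                d = io.parse_date(text).to_date()
                fda_cache[text] = d
            return d

        reports = [
            ReportRecord(
                primaryid=pid, caseid=cid, fda_dt=full_date(fda),
                event_dt=io.parse_date(ev),
                age=None if pd.isna(age) else float(age),
                age_cod=cod or None, sex=sex or None, occp_cod=occ or None,
                reporter_country=ctry or None)
            for pid, cid, fda, ev, age, cod, sex, occ, ctry in zip(*cols(
                sdata.demo,
                ["primaryid", "caseid", "fda_dt", "event_dt", "age",
                 "age_cod", "sex", "occp_cod", "reporter_country"]))]
        drug_rows = [
            DrugRow(pid, seq, role, name)
            for pid, seq, role, name in zip(*cols(
                sdata.drug, ["primaryid", "drug_seq", "role_cod",
                             "drugname"]))]
        reac_rows = [
            ReactionRow(pid, pt)
            for pid, pt in zip(*cols(sdata.reac, ["primaryid", "pt"]))]
        ther_rows = [
            TherapyRow(pid, seq, io.parse_date(start))
            for pid, seq, start in zip(*cols(
                sdata.ther, ["primaryid", "dsg_drug_seq", "start_dt"]))]
        return cls(reports, drug_rows, reac_rows, ther_rows)


@dataclass
class AnalysisConfig:
    target_synonyms: List[str]
    soc_map: Optional[SocMap] = None
    thresholds: SignalThresholds = field(default_factory=SignalThresholds)
    sensitivity_exclude_synonyms: List[str] = field(default_factory=list)
    age_strata: Tuple = SUBGROUP_STRATA
    top_k: int = 50
    match_mode: str = "word"
    yates: bool = True
    tto_ceiling_days: int = tto.DEFAULT_CEILING_DAYS
    early_window_days: int = 30

    def __post_init__(self):
        if self.top_k < 1:
            raise ConfigError("top_k", "must be >= 1")
        if not self.target_synonyms:
            raise ConfigError("target_synonyms", "must be non-empty")


def percent(count: int, total: int) -> float:
    """Percentage rounded half-up to one decimal, as printed in reports."""
    if total == 0:
        raise DataError("cannot compute a percentage of an empty cohort")
    exact = Decimal(100) * Decimal(count) / Decimal(total)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class BaselineSummary:
    """Counts and percentages of cohort characteristics (Table-1 style)."""

    total: int
    sections: Dict[str, List[Tuple[str, int, float]]]

    def lookup(self, section: str, label: str) -> Tuple[int, float]:
        for lab, count, pct in self.sections[section]:
            if lab == label:
                return count, pct
        raise KeyError(f"{label!r} not in section {section!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for section, entries in self.sections.items():
            for label, count, pct in entries:
                rows.append((section, label, count, pct))
        return pd.DataFrame(
            rows, columns=["section", "label", "count", "percent"])


def run_baseline(cohort_reports: Sequence[ReportRecord],
                 strata=BASELINE_STRATA) -> BaselineSummary:
    """Baseline characteristics; percentages are shares of the full cohort."""
    total = len(cohort_reports)
    if total == 0:
        raise DataError("empty cohort")

    def tally(counter: Dict[str, int], order: Optional[List[str]] = None):
        labels = order if order is not None else sorted(
            counter, key=lambda k: (-counter[k], k))
        return [(lab, counter.get(lab, 0), percent(counter.get(lab, 0), total))
                for lab in labels]

    sex_counts: Dict[str, int] = {"F": 0, "M": 0, "Missing": 0}
    age_counts: Dict[str, int] = {s[0]: 0 for s in strata}
    age_counts["Missing"] = 0
    occ_counts = {"Healthcare professional": 0,
                  "Non-healthcare professional": 0, "Missing": 0}
    country_counts: Dict[str, int] = {}
    year_counts: Dict[str, int] = {}

    for r in cohort_reports:
        sex = r.sex if r.sex in ("F", "M") else "Missing"
        sex_counts[sex] += 1
        stratum = age_stratum(age_in_years(r.age, r.age_cod), strata)
        age_counts[stratum or "Missing"] += 1
        occ = (r.occp_cod or "").upper()
        if occ in HCP_CODES:
            occ_counts["Healthcare professional"] += 1
        elif occ in NON_HCP_CODES:
            occ_counts["Non-healthcare professional"] += 1
        else:
            occ_counts["Missing"] += 1
        country = r.reporter_country or "Missing"
        country_counts[country] = country_counts.get(country, 0) + 1
        year = str(r.fda_dt.year)
        year_counts[year] = year_counts.get(year, 0) + 1

    top_countries = sorted(
        (c for c in country_counts if c != "Missing"),
        key=lambda c: (-country_counts[c], c))[:10]
    sections = {
        "sex": tally(sex_counts, ["F", "M", "Missing"]),
        "age": tally(age_counts, [s[0] for s in strata] + ["Missing"]),
        "reporter": tally(occ_counts, ["Healthcare professional",
                                       "Non-healthcare professional",
                                       "Missing"]),
        "country": tally(country_counts, top_countries),
        "year": tally(year_counts, sorted(year_counts)),
    }
    return BaselineSummary(total=total, sections=sections)


# --------------------------------------------------------------------------
# signal tables

SIGNAL_COLUMNS = ["term", "count", "ror", "ror_lo", "ror_hi", "prr", "chi2",
                  "ebgm", "ebgm05", "ic", "ic025", "flag_ror", "flag_prr",
                  "flag_bcpnn", "flag_mgps", "positive"]


def _metrics_frame(tables: Dict[str, ContingencyTable], prior: GpsPrior,
                   thresholds: SignalThresholds, yates: bool) -> pd.DataFrame:
    rows = []
    for term in sorted(tables):
        t = tables[term]
        m = compute_metrics(t, prior, thresholds, yates=yates)
        rows.append((term, t.a, m.ror, m.ror_lo, m.ror_hi, m.prr, m.chi2,
                     m.ebgm, m.ebgm05, m.ic, m.ic025,
                     m.flags.get("ror", False), m.flags.get("prr", False),
                     m.flags.get("bcpnn", False), m.flags.get("mgps", False),
                     m.positive))
    return pd.DataFrame(rows, columns=SIGNAL_COLUMNS)


def _distinct_pairs(reac_rows: Iterable[ReactionRow], pids: Set[int]
                    ) -> List[Tuple[int, str]]:
    return [(r.primaryid, r.pt) for r in reac_rows if r.primaryid in pids]


def fit_database_prior(reports: Sequence[ReportRecord],
                       drug_rows: Sequence[DrugRow],
                       reac_rows: Sequence[ReactionRow],
                       **fit_kwargs) -> GpsPrior:
    """MGPS prior fitted over every drug-event pair in the database."""
    pids = {r.primaryid for r in reports}
    drugs = pd.DataFrame(
        [(d.primaryid, d.drugname) for d in drug_rows
         if d.primaryid in pids],
        columns=["pid", "drug"]).drop_duplicates()
    reacs = pd.DataFrame(
        [(r.primaryid, r.pt) for r in reac_rows if r.primaryid in pids],
        columns=["pid", "term"]).drop_duplicates()
    n_total = len(pids)
    merged = drugs.merge(reacs, on="pid")
    a_counts = merged.groupby(["drug", "term"])["pid"].nunique()
    drug_margin = drugs.groupby("drug")["pid"].nunique()
    term_margin = reacs.groupby("term")["pid"].nunique()

    tables = []
    for (drug, term), a in a_counts.items():
        nd = int(drug_margin[drug])
        ne = int(term_margin[term])
        tables.append(ContingencyTable(
            int(a), nd - int(a), ne - int(a), n_total - nd - ne + int(a)))
    logger.info("fitting MGPS prior on %d drug-event pairs", len(tables))
    return gps_fit(tables, **fit_kwargs)


def run_level_analysis(cohort_pids: Set[int], dataset: Dataset,
                       level: str, config: AnalysisConfig,
                       prior: GpsPrior,
                       analysis_pids: Optional[Set[int]] = None
                       ) -> pd.DataFrame:
    """Signal table at PT or SOC level for the given cohort.

    ``analysis_pids`` restricts the whole analysis universe (defaults to
    every deduplicated report backing ``dataset``); cohort reports outside
    it are ignored.
    """
    if level not in ("PT", "SOC"):
        raise ConfigError("level", f"must be PT or SOC, got {level!r}")
    if analysis_pids is None:
        analysis_pids = {r.primaryid for r in dataset.reports}
    cohort_pids = cohort_pids & analysis_pids

    all_pairs = _distinct_pairs(dataset.reac_rows, analysis_pids)
    if level == "SOC":
        if config.soc_map is None:
            raise ConfigError("soc_map", "SOC-level analysis needs a map")
        mapped = []
        unmapped = 0
        for pid, pt in all_pairs:
            soc = config.soc_map.lookup(pt)
            if soc == cohort_mod.UNMAPPED:
                unmapped += 1
                continue
            mapped.append((pid, soc))
        if unmapped:
            logger.warning("excluded %d unmapped PT pairs at SOC level",
                           unmapped)
        all_pairs = mapped
    cohort_pairs = [(pid, term) for pid, term in all_pairs
                    if pid in cohort_pids]
    tables = build_tables(cohort_pairs, all_pairs)
    return _metrics_frame(tables, prior, config.thresholds, config.yates)


def top_positive(table: pd.DataFrame, top_k: int) -> pd.DataFrame:
    """Positive rows ranked by descending count, ties lexicographic."""
    positive = table[table["positive"]]
    ranked = positive.sort_values(
        ["count", "term"], ascending=[False, True], kind="stable")
    return ranked.head(top_k).reset_index(drop=True)


def run_sensitivity(cohort_pids: Set[int], dataset: Dataset,
                    exclude_synonyms: Sequence[str], level: str,
                    config: AnalysisConfig, prior: GpsPrior
                    ) -> Tuple[pd.DataFrame, Set[int]]:
    """Re-run the level analysis after dropping cohort reports that list
    any excluded co-medication in any role; background is untouched."""
    all_pids = {r.primaryid for r in dataset.reports}
    if exclude_synonyms:
        tainted = reports_with_drug(dataset.drug_rows, exclude_synonyms,
                                    config.match_mode)
    else:
        tainted = set()
    dropped = cohort_pids & tainted
    sens_cohort = cohort_pids - dropped
    analysis_pids = all_pids - dropped
    table = run_level_analysis(sens_cohort, dataset, level, config, prior,
                               analysis_pids=analysis_pids)
    return table, sens_cohort


def run_age_subgroups(cohort_pids: Set[int], dataset: Dataset,
                      level: str, config: AnalysisConfig, prior: GpsPrior
                      ) -> Dict[str, pd.DataFrame]:
    """Per-stratum signal tables; missing ages drop out of every stratum.

    Each stratum cohort is compared against the full (non-cohort)
    background; cohort reports outside the stratum are excluded.
    """
    by_pid = {r.primaryid: r for r in dataset.reports}
    all_pids = set(by_pid)
    background = all_pids - cohort_pids
    strata_pids: Dict[str, Set[int]] = {s[0]: set() for s in config.age_strata}
    for pid in cohort_pids:
        r = by_pid[pid]
        stratum = age_stratum(age_in_years(r.age, r.age_cod),
                              config.age_strata)
        if stratum is not None:
            strata_pids[stratum].add(pid)

    out: Dict[str, pd.DataFrame] = {}
    for label, pids in strata_pids.items():
        if not pids:
            logger.warning("age stratum %s has no cohort reports", label)
            out[label] = pd.DataFrame(columns=SIGNAL_COLUMNS)
            continue
        out[label] = run_level_analysis(
            pids, dataset, level, config, prior,
            analysis_pids=pids | background)
    return out


# --------------------------------------------------------------------------
# full run

@dataclass
class AnalysisResult:
    dedup: DedupResult
    cohort_pids: Set[int]
    baseline: BaselineSummary
    prior: GpsPrior
    pt_table: pd.DataFrame
    pt_top: pd.DataFrame
    soc_table: Optional[pd.DataFrame]
    sensitivity_table: Optional[pd.DataFrame]
    sensitivity_cohort: Optional[Set[int]]
    subgroup_tables: Dict[str, pd.DataFrame]
    tto_records: List[tto.TTORecord]
    tto_tally: Dict[str, int]
    tto_summary: Optional[tto.TTOSummary]
    weibull_fit: Optional[tto.WeibullFit]
    stage_counts: Dict[str, int]


def run_full_analysis(dataset: Dataset, config: AnalysisConfig,
                      prior: Optional[GpsPrior] = None) -> AnalysisResult:
    stage_counts = {"raw_reports": len(dataset.reports)}

    dedup = deduplicate(dataset.reports)
    survivors = dedup.survivors
    survivor_ids = dedup.survivor_ids
    stage_counts["deduplicated"] = len(survivors)
    logger.info("deduplicated: %d -> %d reports",
                len(dataset.reports), len(survivors))

    cohort_pids = select_primary_suspect(
        survivors, dataset.drug_rows, config.target_synonyms,
        config.match_mode)
    stage_counts["cohort"] = len(cohort_pids)
    if not cohort_pids:
        raise DataError(
            "primary-suspect cohort is empty; no DRUGNAME matched the "
            "target synonym list")
    logger.info("primary-suspect cohort: %d reports", len(cohort_pids))

    cohort_reports = [r for r in survivors if r.primaryid in cohort_pids]
    baseline = run_baseline(cohort_reports)

    surviving_dataset = Dataset(
        reports=survivors,
        drug_rows=[d for d in dataset.drug_rows
                   if d.primaryid in survivor_ids],
        reac_rows=[r for r in dataset.reac_rows
                   if r.primaryid in survivor_ids],
        ther_rows=[t for t in dataset.ther_rows
                   if t.primaryid in survivor_ids])

    if prior is None:
        prior = fit_database_prior(
            survivors, surviving_dataset.drug_rows,
            surviving_dataset.reac_rows)

    pt_table = run_level_analysis(cohort_pids, surviving_dataset, "PT",
                                  config, prior)
    pt_top = top_positive(pt_table, config.top_k)

    soc_table = None
    if config.soc_map is not None:
        soc_table = run_level_analysis(cohort_pids, surviving_dataset,
                                       "SOC", config, prior)

    sensitivity_table = None
    sensitivity_cohort = None
    if config.sensitivity_exclude_synonyms:
        sensitivity_table, sensitivity_cohort = run_sensitivity(
            cohort_pids, surviving_dataset,
            config.sensitivity_exclude_synonyms, "PT", config, prior)
        stage_counts["sensitivity_cohort"] = len(sensitivity_cohort)

    subgroup_tables = run_age_subgroups(cohort_pids, surviving_dataset,
                                        "PT", config, prior)

    matcher = cohort_mod.DrugMatcher(config.target_synonyms,
                                     config.match_mode)
    suspect_seqs: Dict[int, Set[int]] = {}
    for d in surviving_dataset.drug_rows:
        if (d.primaryid in cohort_pids and d.role_cod == "PS"
                and matcher.matches(d.drugname)):
            suspect_seqs.setdefault(d.primaryid, set()).add(d.drug_seq)
    tto_records, tto_tally = tto.compute_tto(
        cohort_reports, surviving_dataset.ther_rows, suspect_seqs,
        ceiling_days=config.tto_ceiling_days)
    stage_counts["tto_valid"] = len(tto_records)

    tto_summary = None
    weibull = None
    if tto_records:
        tto_summary = tto.summarize_tto(tto_records,
                                        config.early_window_days)
        if len(tto_records) >= 10:
            weibull = tto.fit_weibull(tto_records)

    return AnalysisResult(
        dedup=dedup, cohort_pids=cohort_pids, baseline=baseline,
        prior=prior, pt_table=pt_table, pt_top=pt_top, soc_table=soc_table,
        sensitivity_table=sensitivity_table,
        sensitivity_cohort=sensitivity_cohort,
        subgroup_tables=subgroup_tables, tto_records=tto_records,
        tto_tally=tto_tally, tto_summary=tto_summary, weibull_fit=weibull,
        stage_counts=stage_counts)


# --------------------------------------------------------------------------
# table round-trips

def write_signal_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g",
                 lineterminator="\n")


def read_signal_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
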