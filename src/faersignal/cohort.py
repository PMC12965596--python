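"""Report deduplication, primary-suspect cohort selection, PT->SOC mapping.

Deduplication follows the FDA case-collapsing rules: within a CASEID the
report with the most recent FDA receipt date survives; ties on receipt
date are broken by the highest PRIMARYID.  Both rules collapse into one
lexicographic key, which makes the operation total, order-invariant and
idempotent.
"""

from __future__ import annotations

import logging
import re
from functools import cached_property
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

from .errors import ConfigError
from .io import DrugRow, ReportRecord

logger = logging.getLogger(__name__)

REMOVED_OLDER_FDA = "older_fda_dt"
REMOVED_LOWER_PID = "lower_primaryid"
UNMAPPED = "UNMAPPED"


@dataclass
class DedupResult:
    survivors: List[ReportRecord]
    removed: List[Tuple[int, str]]  # (primaryid, reason)

    @cached_property
    def survivor_ids(self) -> Set[int]:
        return {r.primaryid for r in self.survivors}


def deduplicate(reports: Sequence[ReportRecord]) -> DedupResult:
    """Collapse reports to one survivor per CASEID.

    Keep max FDA_DT per case; among receipt-date ties keep max PRIMARYID.
    Deterministic for any input order and idempotent.
    """
    best: Dict[int, ReportRecord] = {}
    for r in reports:
        cur = best.get(r.caseid)
        if cur is None or (r.fda_dt, r.primaryid) > (cur.fda_dt, cur.primaryid):
            best[r.caseid] = r
    survivors = []
    removed = []
    for r in reports:
        winner = best[r.caseid]
        if r.primaryid == winner.primaryid:
            survivors.append(r)
        elif r.fda_dt < winner.fda_dt:
            removed.append((r.primaryid, REMOVED_OLDER_FDA))
        else:
            removed.append((r.primaryid, REMOVED_LOWER_PID))
    return DedupResult(survivors=survivors, removed=removed)


_PUNCT_RE = re.compile(r"[^\w\s]|_")
_WS_RE = re.compile(r"\s+")


def normalize_drugname(name: str) -> str:
    """Lower-case, strip punctuation, collapse whitespace."""
    return _WS_RE.sub(" ", _PUNCT_RE.sub(" ", name.lower())).strip()


def load_synonyms(path: Union[str, Path]) -> List[str]:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return [ln for ln in lines if ln and not ln.startswith("#")]


class DrugMatcher:
    """Synonym matcher over verbatim DRUGNAME strings.

    ``mode='word'`` (default) requires the normalized synonym to appear as
    a whole token sequence inside the normalized drug name;
    ``mode='substring'`` relaxes to plain containment.
    """

    def __init__(self, synonyms: Sequence[str], mode: str = "word"):
        if not synonyms:
            raise ConfigError("synonym_list", "must be non-empty")
        if mode not in ("word", "substring"):
            raise ConfigError("match_mode", f"unknown mode {mode!r}")
        self.mode = mode
        self._normalized = [normalize_drugname(s) for s in synonyms]
        if mode == "word":
            pattern = "|".join(
                r"\b" + re.escape(s) + r"\b" for s in self._normalized)
            self._regex = re.compile(pattern)
        self._cache: Dict[str, bool] = {}

    def matches(self, drugname: str) -> bool:
        hit = self._cache.get(drugname)
        if hit is None:
            norm = normalize_drugname(drugname)
            if self.mode == "word":
                hit = self._regex.search(norm) is not None
            else:
                hit = any(s in norm for s in self._normalized)
            self._cache[drugname] = hit
        return hit


def select_primary_suspect(reports: Sequence[ReportRecord],
                           drug_rows: Sequence[DrugRow],
                           synonyms: Sequence[str],
                           mode: str = "word") -> Set[int]:
    """PRIMARYIDs whose report names a matching drug with role PS.

    Unknown role codes are counted and excluded from PS selection.
    """
    matcher = DrugMatcher(synonyms, mode)
    known = {"PS", "SS", "C", "I"}
    report_ids = {r.primaryid for r in reports}
    unknown_roles = 0
    cohort: Set[int] = set()
    for row in drug_rows:
        if row.role_cod not in known:
            unknown_roles += 1
            continue
        if row.role_cod != "PS" or row.primaryid not in report_ids:
            continue
        if matcher.matches(row.drugname):
            cohort.add(row.primaryid)
    if unknown_roles:
        logger.warning("excluded %d drug rows with unknown role codes",
                       unknown_roles)
    return cohort


def reports_with_drug(drug_rows: Sequence[DrugRow],
                      synonyms: Sequence[str],
                      mode: str = "word") -> Set[int]:
    """PRIMARYIDs mentioning a matching drug in ANY role (for exclusions)."""
    matcher = DrugMatcher(synonyms, mode)
    return {row.primaryid for row in drug_rows if matcher.matches(row.drugname)}


@dataclass
class SocMap:
    """PT -> primary SOC lookup; unknown terms land in ``UNMAPPED``."""

    mapping: Dict[str, str]
    version: str = "fixture"
    _unmapped_seen: Set[str] = field(default_factory=set, repr=False)

    @classmethod
    def from_file(cls, path: Union[str, Path], delimiter: Optional[str] = None,
                  version: Optional[str] = None) -> "SocMap":
        mapping: Dict[str, str] = {}
        for ln in Path(path).read_text().splitlines():
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split(delimiter) if delimiter else ln.split("\t")
            if len(parts) < 2:
                continue
            mapping[parts[0].strip()] = parts[1].strip()
        return cls(mapping=mapping, version=version or Path(path).name)

    def lookup(self, pt: str) -> str:
        soc = self.mapping.get(pt)
        if soc is None:
            if pt not in self._unmapped_seen:
                self._unmapped_seen.add(pt)
                logger.warning("PT %r has no SOC mapping", pt)
            return UNMAPPED
        return soc

    @property
    def unmapped_count(self) -> int:
        return len(self._unmapped_seen)


def map_pt_to_soc(pt_list: Iterable[str], soc_map: SocMap
                  ) -> List[Tuple[str, str]]:
    """Pair every PT with exactly one SOC (or the UNMAPPED bucket)."""
    return [(pt, soc_map.lookup(pt)) for pt in pt_list]


# Age stratification -------------------------------------------------------

#: Table-1 style strata for baseline summaries
BASELINE_STRATA = (("<18", 0.0, 18.0), ("18-65", 18.0, 66.0),
                   (">65", 66.0, float("inf")))
#: subgroup-analysis strata (65 falls in the oldest group)
SUBGROUP_STRATA = (("<18", 0.0, 18.0), ("18-64", 18.0, 65.0),
                   (">=65", 65.0, float("inf")))

_AGE_TO_YEARS = {"YR": 1.0, "DEC": 10.0}


def age_in_years(age: Optional[float], age_cod: Optional[str]
                 ) -> Optional[float]:
    """Convert AGE to years; only YR and DEC codes are converted.

    A missing unit code is taken as years (the FAERS default); any other
    unit is left unconverted and reported as missing for stratification.
    """
    if age is None:
        return None
    cod = (age_cod or "YR").upper()
    factor = _AGE_TO_YEARS.get(cod)
    if factor is None:
        return None
    return age * factor


def age_stratum(age_years: Optional[float],
                strata=BASELINE_STRATA) -> Optional[str]:
    if age_years is None:
        return None
    for label, lo, hi in strata:
        if lo <= age_years < hi:
            return label
    return None
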