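"""Synthetic FAERS-dialect data with planted ground truth.

The generator produces DEMO/DRUG/REAC/THER tables in which every quantity
downstream stages estimate is known by construction: disproportionality
ratios planted per (drug, event) pair, injected duplicate report groups
with an unambiguous intended survivor, and Weibull-distributed onset
latencies.  Output is a pure function of :class:`SynthConfig` (seed
included), so identical configs give byte-identical files.

Generation model: each report gets exactly one primary-suspect (PS) drug;
events occur as independent Bernoulli draws per (report, event) at
``background_rate``, multiplied by the planted rate ratio for reports
whose PS drug carries a planted signal on that event.  Under this model
the odds-ratio truth for a planted pair equals the configured ratio (to
first order in the background rate).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import TABLE_COLUMNS

#: PT assigned to reports for which no Bernoulli event fired (every report
#: must carry at least one reaction row); deliberately outside the
#: EVENT_* vocabulary so planted-signal bookkeeping stays clean.
FILLER_PT = "UNSPECIFIED REACTION"

_CHUNK = 50_000  # report rows per event-matrix chunk; fixed for determinism

_SEX_LEVELS = np.array(["F", "M"])
_SEX_PROBS = np.array([0.59, 0.41])
_OCCP_LEVELS = np.array(["MD", "PH", "OT", "CN", "LW"])
_OCCP_PROBS = np.array([0.40, 0.15, 0.15, 0.25, 0.05])
_COUNTRY_LEVELS = np.array(
    ["GB", "US", "FR", "DE", "IT", "JP", "SE", "CA", "ES", "NL", "OTHER"])
_COUNTRY_PROBS = np.array(
    [0.27, 0.19, 0.10, 0.09, 0.05, 0.04, 0.03, 0.03, 0.02, 0.02, 0.16])


@dataclass
class SynthConfig:
    n_reports: int = 10_000
    n_drugs: int = 20
    n_events: int = 100
    target_drug_name: str = "MIRTAZAPINE"
    background_rate: float = 0.01
    planted_signals: List[Tuple[str, str, float]] = field(default_factory=list)
    duplicate_rate: float = 0.05
    partial_date_rate: float = 0.05
    missing_demo_rate: float = 0.10
    tto_shape: float = 0.49
    tto_scale: float = 57.1
    tto_valid_rate: float = 0.85
    date_window: Tuple[_dt.date, _dt.date] = (
        _dt.date(2010, 1, 1), _dt.date(2024, 12, 31))
    concomitant_mean: float = 0.5
    embellish_rate: float = 0.0
    seed: int = 0

    def drug_vocabulary(self) -> List[str]:
        return [self.target_drug_name] + [
            f"DRUG {i:04d}" for i in range(1, self.n_drugs)]

    def event_vocabulary(self) -> List[str]:
        return [f"EVENT {i:04d}" for i in range(1, self.n_events + 1)]

    def validate(self) -> None:
        for name in ("n_reports", "n_drugs", "n_events"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(name, "must be a positive integer")
        if not (0.0 < self.background_rate < 1.0):
            raise ConfigError("background_rate", "must be in (0, 1)")
        for name in ("duplicate_rate", "partial_date_rate",
                     "missing_demo_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ConfigError(name, "must be in [0, 1)")
        if not (0.0 <= self.tto_valid_rate <= 1.0):
            raise ConfigError("tto_valid_rate", "must be in [0, 1]")
        if self.tto_shape <= 0:
            raise ConfigError("tto_shape", "must be positive")
        if self.tto_scale <= 0:
            raise ConfigError("tto_scale", "must be positive")
        if self.date_window[0] > self.date_window[1]:
            raise ConfigError("date_window", "start must not exceed end")
        if not self.target_drug_name:
            raise ConfigError("target_drug_name", "must be non-empty")
        drugs = set(self.drug_vocabulary())
        events = set(self.event_vocabulary())
        for drug, event, ratio in self.planted_signals:
            if drug not in drugs:
                raise ConfigError("planted_signals",
                                  f"drug {drug!r} not in vocabulary")
            if event not in events:
                raise ConfigError("planted_signals",
                                  f"event {event!r} not in vocabulary")
            if ratio <= 0:
                raise ConfigError("planted_signals",
                                  f"rate ratio {ratio} must be > 0")
            if self.background_rate * ratio >= 1.0:
                raise ConfigError(
                    "planted_signals",
                    f"background_rate * {ratio} must stay below 1")


@dataclass
class DuplicateGroup:
    caseid: int
    member_primaryids: List[int]
    survivor_primaryid: int


@dataclass
class GroundTruthManifest:
    planted: List[Tuple[str, str, float]]
    duplicate_groups: List[DuplicateGroup]
    corrupted: Dict[int, str]          # primaryid -> corruption kind
    tto_shape: float
    tto_scale: float
    n_base_reports: int
    n_injected_duplicates: int

    def expected_survivors(self, all_primaryids: Sequence[int]) -> set:
        removed = set()
        for g in self.duplicate_groups:
            removed.update(g.member_primaryids)
            removed.discard(g.survivor_primaryid)
        return set(all_primaryids) - removed

    def to_text(self) -> str:
        lines = [f"n_base_reports={self.n_base_reports}",
                 f"n_injected_duplicates={self.n_injected_duplicates}",
                 f"tto_shape={self.tto_shape}",
                 f"tto_scale={self.tto_scale}"]
        for drug, event, ratio in self.planted:
            lines.append(f"planted={drug}|{event}|{ratio}")
        for g in self.duplicate_groups:
            members = ",".join(str(p) for p in g.member_primaryids)
            lines.append(
                f"dup_group={g.caseid}|{members}|{g.survivor_primaryid}")
        for pid, kind in sorted(self.corrupted.items()):
            lines.append(f"corrupted={pid}|{kind}")
        return "\n".join(lines) + "\n"


@dataclass
class SyntheticDataset:
    """In-memory four-table dataset plus its ground-truth manifest."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    manifest: GroundTruthManifest


_EPOCH_ORDINAL = _dt.date(1970, 1, 1).toordinal()


def _ordinal_to_yyyymmdd(ordinals: np.ndarray) -> np.ndarray:
    days = np.asarray(ordinals, dtype=np.int64) - _EPOCH_ORDINAL
    iso = np.datetime_as_string(days.astype("datetime64[D]"), unit="D")
    return np.char.replace(iso, "-", "").astype(object)


def _draw_categorical(rng, levels, probs, n, missing_rate):
    idx = rng.choice(len(levels), size=n, p=probs / probs.sum())
    values = np.asarray(levels, dtype=object)[idx]
    if missing_rate > 0:
        values[rng.random(n) < missing_rate] = ""
    return values


def simulate(config: SynthConfig) -> SyntheticDataset:
    """Generate the full dataset in memory; deterministic in ``config``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(config.n_reports)
    drugs = np.array(config.drug_vocabulary(), dtype=object)
    events = np.array(config.event_vocabulary(), dtype=object)
    event_index = {e: j for j, e in enumerate(events)}
    drug_index = {d: j for j, d in enumerate(drugs)}

    pid0, cid0 = 10_000_000, 5_000_000
    pids = pid0 + np.arange(n, dtype=np.int64)
    caseids = cid0 + np.arange(n, dtype=np.int64)

    # --- drugs -----------------------------------------------------------
    ps_drug_idx = rng.integers(0, len(drugs), size=n)

    # per-drug event-probability multipliers from planted signals
    multipliers = np.ones((len(drugs), len(events)))
    for drug, event, ratio in config.planted_signals:
        multipliers[drug_index[drug], event_index[event]] = ratio
    planted_drug_rows = np.where((multipliers != 1.0).any(axis=1))[0]

    # concomitant drugs never come from the planted/target set so planted
    # pairs stay confined to the PS cohort of their drug
    conc_pool = np.array(
        [j for j in range(len(drugs))
         if j != 0 and j not in set(planted_drug_rows)], dtype=np.int64)
    n_extra = rng.poisson(config.concomitant_mean, size=n)
    np.minimum(n_extra, 4, out=n_extra)
    if len(conc_pool) == 0:
        n_extra[:] = 0
    total_extra = int(n_extra.sum())
    extra_drug_idx = (conc_pool[rng.integers(0, len(conc_pool), total_extra)]
                      if total_extra else np.empty(0, dtype=np.int64))
    extra_roles = np.array(["SS", "C", "I"], dtype=object)[
        rng.integers(0, 3, total_extra)]

    # --- events ----------------------------------------------------------
    pair_pid: List[np.ndarray] = []
    pair_evt: List[np.ndarray] = []
    base_p = config.background_rate
    for lo in range(0, n, _CHUNK):
        hi = min(lo + _CHUNK, n)
        u = rng.random((hi - lo, len(events)))
        p = np.full((hi - lo, len(events)), base_p)
        chunk_drug = ps_drug_idx[lo:hi]
        for dj in planted_drug_rows:
            mask = chunk_drug == dj
            if mask.any():
                p[mask] = base_p * multipliers[dj]
        ri, ci = np.nonzero(u < p)
        pair_pid.append(pids[lo:hi][ri])
        pair_evt.append(ci)
    evt_pid = np.concatenate(pair_pid) if pair_pid else np.empty(0, np.int64)
    evt_col = np.concatenate(pair_evt) if pair_evt else np.empty(0, np.int64)

    has_event = np.zeros(n, dtype=bool)
    has_event[evt_pid - pid0] = True
    filler_pids = pids[~has_event]

    # --- dates -----------------------------------------------------------
    start_ord = config.date_window[0].toordinal()
    end_ord = config.date_window[1].toordinal()
    event_ord = rng.integers(start_ord, end_ord + 1, size=n)
    fda_ord = event_ord + rng.integers(0, 121, size=n)

    tto_valid = rng.random(n) < config.tto_valid_rate
    latency = np.round(
        config.tto_scale * rng.weibull(config.tto_shape, size=n)
    ).astype(np.int64)
    ther_start_ord = event_ord - latency

    # --- demographics ----------------------------------------------------
    mr = config.missing_demo_rate
    sex = _draw_categorical(rng, _SEX_LEVELS, _SEX_PROBS, n, mr)
    occp = _draw_categorical(rng, _OCCP_LEVELS, _OCCP_PROBS, n, mr)
    country = _draw_categorical(rng, _COUNTRY_LEVELS, _COUNTRY_PROBS, n, mr)
    stratum = rng.choice(3, size=n, p=[0.035, 0.61, 0.355])
    age = np.select(
        [stratum == 0, stratum == 1, stratum == 2],
        [rng.integers(1, 18, n), rng.integers(18, 66, n),
         rng.integers(66, 96, n)]).astype(float)
    age_missing = rng.random(n) < mr
    age[age_missing] = np.nan

    # --- duplicates ------------------------------------------------------
    n_dup = int(round(config.duplicate_rate * n))
    dup_base = np.sort(rng.integers(0, n, size=n_dup)) if n_dup else \
        np.empty(0, dtype=np.int64)
    dup_equal_fda = rng.random(n_dup) < 0.25
    dup_pids = pid0 + n + np.arange(n_dup, dtype=np.int64)

    groups: Dict[int, List[int]] = {}
    dup_fda = np.empty(n_dup, dtype=np.int64)
    group_max_fda: Dict[int, int] = {}
    for j in range(n_dup):
        b = int(dup_base[j])
        prev = group_max_fda.get(b, int(fda_ord[b]))
        if dup_equal_fda[j]:
            dup_fda[j] = prev
        else:
            dup_fda[j] = prev + 1 + int(rng.integers(0, 30))
        group_max_fda[b] = int(dup_fda[j])
        groups.setdefault(b, []).append(j)

    duplicate_groups = []
    for b, members in sorted(groups.items()):
        member_pids = [int(pids[b])] + [int(dup_pids[j]) for j in members]
        keys = [(int(fda_ord[b]), int(pids[b]))] + [
            (int(dup_fda[j]), int(dup_pids[j])) for j in members]
        survivor = member_pids[int(np.argmax(
            [k[0] * 10**10 + k[1] for k in keys]))]
        duplicate_groups.append(
            DuplicateGroup(int(caseids[b]), member_pids, survivor))

    # --- assemble demo ---------------------------------------------------
    all_pids = np.concatenate([pids, dup_pids])
    all_caseids = np.concatenate([caseids, caseids[dup_base]])
    all_fda_ord = np.concatenate([fda_ord, dup_fda])
    base_of = np.concatenate([np.arange(n), dup_base])  # row -> base report

    event_dt = _ordinal_to_yyyymmdd(event_ord)
    start_dt_full = _ordinal_to_yyyymmdd(ther_start_ord)

    demo = pd.DataFrame({
        "primaryid": all_pids,
        "caseid": all_caseids,
        "fda_dt": _ordinal_to_yyyymmdd(all_fda_ord),
        "event_dt": event_dt[base_of],
        "age": age[base_of],
        "age_cod": np.where(np.isnan(age[base_of]), "", "YR"),
        "sex": sex[base_of],
        "occp_cod": occp[base_of],
        "reporter_country": country[base_of],
    })

    # --- drug table ------------------------------------------------------
    ps_names = drugs[ps_drug_idx]
    if config.embellish_rate > 0:
        decorate = rng.random(n) < config.embellish_rate
        style = rng.integers(0, 3, size=n)
        ps_names = ps_names.copy()
        for i in np.where(decorate)[0]:
            name = ps_names[i]
            ps_names[i] = (f"{name} 15MG TAB", f"BRANDX ({name})",
                           f"{name}.")[style[i]]

    extra_rep = np.repeat(np.arange(n), n_extra)
    drug_pid = np.concatenate([pids, pids[extra_rep]])
    drug_seq = np.concatenate([np.ones(n, np.int64),
                               2 + _within_group_counter(extra_rep)])
    drug_role = np.concatenate([np.full(n, "PS", dtype=object), extra_roles])
    drug_name = np.concatenate([ps_names, drugs[extra_drug_idx]])

    order = np.argsort(drug_pid, kind="stable")
    drug_df = pd.DataFrame({
        "primaryid": drug_pid[order],
        "drug_seq": drug_seq[order],
        "role_cod": drug_role[order],
        "drugname": drug_name[order],
    })

    # --- reac table ------------------------------------------------------
    reac_pid = np.concatenate([evt_pid, filler_pids])
    reac_pt = np.concatenate([
        events[evt_col],
        np.full(len(filler_pids), FILLER_PT, dtype=object)])
    order = np.argsort(reac_pid, kind="stable")
    reac_df = pd.DataFrame({"primaryid": reac_pid[order],
                            "pt": reac_pt[order]})

    # --- ther table ------------------------------------------------------
    start_dt = np.where(tto_valid, start_dt_full, "")
    ther_df = pd.DataFrame({
        "primaryid": pids,
        "dsg_drug_seq": np.ones(n, np.int64),
        "start_dt": start_dt,
    })

    # replicate drug/reac/ther rows for duplicate reports (tables are
    # sorted by primaryid, so row ranges come from searchsorted)
    if n_dup:
        base_pid_of_dup = pids[dup_base]

        def _replicate(tbl: pd.DataFrame) -> pd.DataFrame:
            p = tbl["primaryid"].to_numpy()
            lo = np.searchsorted(p, base_pid_of_dup, "left")
            hi = np.searchsorted(p, base_pid_of_dup, "right")
            counts = hi - lo
            if counts.sum() == 0:
                return tbl
            offsets = _within_group_counter(
                np.repeat(np.arange(n_dup), counts))
            idx = np.repeat(lo, counts) + offsets
            extra = tbl.iloc[idx].copy()
            extra["primaryid"] = np.repeat(dup_pids, counts)
            return pd.concat([tbl, extra], ignore_index=True)

        drug_df = _replicate(drug_df).sort_values(
            ["primaryid", "drug_seq"], kind="stable", ignore_index=True)
        reac_df = _replicate(reac_df).sort_values(
            ["primaryid", "pt"], kind="stable", ignore_index=True)
        ther_df = _replicate(ther_df).sort_values(
            ["primaryid", "dsg_drug_seq"], kind="stable", ignore_index=True)

    # --- date corruption -------------------------------------------------
    demo, ther_df, corrupted = corrupt_dates(
        demo, ther_df, config.partial_date_rate,
        rng=np.random.default_rng(config.seed + 0x5EED))

    manifest = GroundTruthManifest(
        planted=list(config.planted_signals),
        duplicate_groups=duplicate_groups,
        corrupted=corrupted,
        tto_shape=config.tto_shape,
        tto_scale=config.tto_scale,
        n_base_reports=n,
        n_injected_duplicates=n_dup,
    )
    return SyntheticDataset(demo, drug_df, reac_df, ther_df, manifest)


def _within_group_counter(group_ids: np.ndarray) -> np.ndarray:
    """0,1,2,... within runs of equal (sorted) group ids."""
    if len(group_ids) == 0:
        return np.empty(0, dtype=np.int64)
    starts = np.r_[0, np.flatnonzero(np.diff(group_ids)) + 1]
    idx = np.arange(len(group_ids), dtype=np.int64)
    return idx - np.repeat(idx[starts], np.diff(np.r_[starts, len(group_ids)]))


def corrupt_dates(demo: pd.DataFrame, ther: pd.DataFrame, rate: float,
                  seed: Optional[int] = None, rng=None
                  ) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[int, str]]:
    """Degrade a fraction of EVENT_DT/START_DT values.

    Each selected report suffers one corruption drawn uniformly from:
    truncating EVENT_DT or START_DT to month or year precision, or moving
    START_DT after EVENT_DT.  Returns new frames plus a map
    primaryid -> corruption kind.  ``rate=0`` returns the inputs untouched.
    """
    if not (0.0 <= rate < 1.0):
        raise ConfigError("partial_date_rate", "must be in [0, 1)")
    if rate == 0.0:
        return demo, ther, {}
    if rng is None:
        rng = np.random.default_rng(seed)

    demo = demo.copy()
    ther = ther.copy()
    hit = rng.random(len(demo)) < rate
    kinds = np.array(["event_month", "event_year", "start_month",
                      "start_year", "negative"], dtype=object)
    kind_draw = kinds[rng.integers(0, len(kinds), size=len(demo))]
    corrupted: Dict[int, str] = {}

    ther_start = dict(zip(ther["primaryid"], ther.index))
    event_vals = demo["event_dt"].to_numpy(dtype=object, copy=True)
    start_vals = ther["start_dt"].to_numpy(dtype=object, copy=True)

    for i in np.where(hit)[0]:
        pid = int(demo["primaryid"].iat[i])
        kind = kind_draw[i]
        if kind.startswith("event"):
            v = event_vals[i]
            if len(v) != 8:
                continue
            event_vals[i] = v[:6] if kind == "event_month" else v[:4]
        else:
            ti = ther_start.get(pid)
            if ti is None:
                continue
            v = start_vals[ti]
            if len(v) != 8:
                continue
            if kind == "start_month":
                start_vals[ti] = v[:6]
            elif kind == "start_year":
                start_vals[ti] = v[:4]
            else:  # negative: push start after the event date
                ev = event_vals[i]
                if len(ev) != 8:
                    continue
                base = _dt.date(int(ev[:4]), int(ev[4:6]), int(ev[6:8]))
                shifted = base.toordinal() + 30 + int(rng.integers(0, 170))
                d = _dt.date.fromordinal(shifted)
                start_vals[ti] = f"{d.year:04d}{d.month:02d}{d.day:02d}"
        corrupted[pid] = str(kind)
    demo["event_dt"] = event_vals
    ther["start_dt"] = start_vals
    return demo, ther, corrupted


# ---------------------------------------------------------------------------
# file output

def _age_str(v) -> str:
    return "" if pd.isna(v) else f"{v:g}"


def write_files(dataset: SyntheticDataset, out_dir: Union[str, Path],
                delimiter: str = "$") -> Dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    frames = {
        "DEMO": dataset.demo.assign(age=dataset.demo["age"].map(_age_str)),
        "DRUG": dataset.drug,
        "REAC": dataset.reac,
        "THER": dataset.ther,
    }
    for kind, frame in frames.items():
        path = out_dir / f"{kind}.txt"
        frame = frame.copy()
        frame.columns = TABLE_COLUMNS[kind]
        frame.to_csv(path, sep=delimiter, index=False, lineterminator="\n")
        paths[kind] = path
    manifest_path = out_dir / "manifest.txt"
    manifest_path.write_text(dataset.manifest.to_text())
    paths["MANIFEST"] = manifest_path
    return paths


def generate_dataset(config: SynthConfig, out_dir: Union[str, Path]
                     ) -> Tuple[Dict[str, Path], GroundTruthManifest]:
    """Generate and write the file set; returns (paths, manifest)."""
    dataset = simulate(config)
    return write_files(dataset, out_dir), dataset.manifest


def write_soc_map(config: SynthConfig, path: Union[str, Path],
                  n_socs: int = 10, delimiter: str = "\t") -> Path:
    """Deterministic PT -> SOC fixture map covering the event vocabulary."""
    path = Path(path)
    lines = []
    for j, event in enumerate(config.event_vocabulary()):
        lines.append(f"{event}{delimiter}SOC {(j % n_socs) + 1:02d}")
    lines.append(f"{FILLER_PT}{delimiter}SOC {n_socs:02d}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_synonyms(names: Sequence[str], path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text("\n".join(names) + "\n")
    return path
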