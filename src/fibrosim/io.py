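"""Readers, writers and built-in fixtures for paired-biopsy study data.

Two long-format CSV schemas are supported, matching the two shapes in which
paired-biopsy fibrosis data are published:

``transitions`` — one row per (initial stage, final stage) cell::

    study_id, arm, time_months, initial_stage, final_stage, count

``distributions`` — one row per stage of a baseline or follow-up marginal
(used when a study reports only the initial and final stage distributions of
each arm, without per-patient pairing)::

    study_id, arm, time_months, timepoint, stage, count

where ``timepoint`` is ``initial`` or ``final``.  JSON mirrors of both are
accepted (a dict with a ``rows`` list of records).  Stages are 0-based
integers 0-4 throughout.  All files are UTF-8 with a header row.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    N_STAGES,
    CohortDistribution,
    RateParameters,
    ScaleFactors,
    TransitionTable,
)

__all__ = [
    "ArmSummary",
    "StudyDataset",
    "ParseError",
    "read_transition_data",
    "write_transition_table",
    "write_study",
    "read_parameters",
    "write_parameters",
    "read_cohort",
    "write_cohort",
    "builtin_fixtures",
    "fixture_parameters",
    "fixture_mix",
    "fixture_cusi",
]

logger = logging.getLogger(__name__)

TRANSITION_COLUMNS = ["study_id", "arm", "time_months", "initial_stage", "final_stage", "count"]
DISTRIBUTION_COLUMNS = ["study_id", "arm", "time_months", "timepoint", "stage", "count"]


class ParseError(ValueError):
    """Raised for malformed study files; names the offending field and row."""


@dataclass
class ArmSummary:
    """Initial and final stage distributions of one trial arm.

    Totals may differ: patients lost to follow-up appear only in the initial
    distribution (dropout is represented, never imputed).
    """

    arm: str
    initial: CohortDistribution
    final: CohortDistribution
    time_months: float
    study_id: str = "study"

    def __post_init__(self) -> None:
        if not self.time_months > 0:
            raise ValueError("time_months must be > 0")


@dataclass
class StudyDataset:
    """A collection of transition tables and/or arm summaries from one study."""

    study_id: str
    entries: list[TransitionTable | ArmSummary] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("a study dataset needs at least one entry")

    @property
    def patient_total(self) -> float:
        total = 0.0
        for e in self.entries:
            total += e.grand_total if isinstance(e, TransitionTable) else e.initial.total
        return total

    @property
    def times(self) -> list[float]:
        return sorted({float(e.time_months) for e in self.entries})


# ---------------------------------------------------------------------------
# parsing helpers


def _check_stage(value, row: int, column: str) -> int:
    try:
        stage = int(value)
    except (TypeError, ValueError):
        raise ParseError(f"row {row}: column '{column}' is not an integer stage: {value!r}")
    if not 0 <= stage < N_STAGES:
        raise ParseError(f"row {row}: column '{column}' must be a stage index 0-4, got {stage}")
    return stage


def _check_count(value, row: int) -> float:
    try:
        count = float(value)
    except (TypeError, ValueError):
        raise ParseError(f"row {row}: column 'count' is not a number: {value!r}")
    if not np.isfinite(count) or count < 0:
        raise ParseError(f"row {row}: column 'count' must be >= 0, got {count}")
    return count


def _check_time(value, row: int) -> float:
    try:
        t = float(value)
    except (TypeError, ValueError):
        raise ParseError(f"row {row}: column 'time_months' is not a number: {value!r}")
    if not t > 0:
        raise ParseError(f"row {row}: column 'time_months' must be > 0, got {t}")
    return t


def _load_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        rows = payload["rows"] if isinstance(payload, dict) and "rows" in payload else payload
        return pd.DataFrame(rows)
    return pd.read_csv(path, encoding="utf-8")


def read_transition_data(path: str | Path) -> StudyDataset:
    """Read a study file in either schema into a validated :class:`StudyDataset`.

    The schema is detected from the header.  Malformed rows are reported with
    their (1-based, data) row number and the offending field.
    """
    frame = _load_frame(path)
    cols = list(frame.columns)
    if set(TRANSITION_COLUMNS) <= set(cols):
        return _parse_transitions(frame)
    if set(DISTRIBUTION_COLUMNS) <= set(cols):
        return _parse_distributions(frame)
    raise ParseError(
        f"unrecognized header {cols}; expected columns {TRANSITION_COLUMNS} "
        f"or {DISTRIBUTION_COLUMNS}"
    )


def _parse_transitions(frame: pd.DataFrame) -> StudyDataset:
    groups: dict[tuple, np.ndarray] = {}
    for i, rec in enumerate(frame.to_dict("records"), start=1):
        for col in TRANSITION_COLUMNS:
            if pd.isna(rec.get(col, np.nan)):
                raise ParseError(f"row {i}: missing value in column '{col}'")
        key = (str(rec["study_id"]), str(rec["arm"]), _check_time(rec["time_months"], i))
        a = _check_stage(rec["initial_stage"], i, "initial_stage")
        b = _check_stage(rec["final_stage"], i, "final_stage")
        cell = groups.setdefault(key, np.zeros((N_STAGES, N_STAGES)))
        cell[a, b] += _check_count(rec["count"], i)
    entries: list[TransitionTable | ArmSummary] = [
        TransitionTable(t, counts, study_id=sid, arm=arm)
        for (sid, arm, t), counts in groups.items()
    ]
    study_ids = sorted({e.study_id for e in entries})
    return StudyDataset("+".join(study_ids), entries)


def _parse_distributions(frame: pd.DataFrame) -> StudyDataset:
    groups: dict[tuple, dict[str, np.ndarray]] = {}
    for i, rec in enumerate(frame.to_dict("records"), start=1):
        for col in DISTRIBUTION_COLUMNS:
            if pd.isna(rec.get(col, np.nan)):
                raise ParseError(f"row {i}: missing value in column '{col}'")
        timepoint = str(rec["timepoint"]).strip().lower()
        if timepoint not in ("initial", "final"):
            raise ParseError(
                f"row {i}: column 'timepoint' must be 'initial' or 'final', got {rec['timepoint']!r}"
            )
        key = (str(rec["study_id"]), str(rec["arm"]), _check_time(rec["time_months"], i))
        stage = _check_stage(rec["stage"], i, "stage")
        pair = groups.setdefault(key, {"initial": np.zeros(N_STAGES), "final": np.zeros(N_STAGES)})
        pair[timepoint][stage] += _check_count(rec["count"], i)
    entries: list[TransitionTable | ArmSummary] = [
        ArmSummary(arm, CohortDistribution(d["initial"]), CohortDistribution(d["final"]), t, study_id=sid)
        for (sid, arm, t), d in groups.items()
    ]
    study_ids = sorted({e.study_id for e in entries})
    return StudyDataset("+".join(study_ids), entries)


# ---------------------------------------------------------------------------
# writers


def _entry_rows(entry: TransitionTable | ArmSummary) -> list[dict]:
    rows = []
    if isinstance(entry, TransitionTable):
        for a in range(N_STAGES):
            for b in range(N_STAGES):
                rows.append(
                    dict(
                        study_id=entry.study_id,
                        arm=entry.arm,
                        time_months=entry.time_months,
                        initial_stage=a,
                        final_stage=b,
                        count=entry.counts[a, b],
                    )
                )
    else:
        for timepoint, dist in (("initial", entry.initial), ("final", entry.final)):
            for s in range(N_STAGES):
                rows.append(
                    dict(
                        study_id=entry.study_id,
                        arm=entry.arm,
                        time_months=entry.time_months,
                        timepoint=timepoint,
                        stage=s,
                        count=dist.counts[s],
                    )
                )
    return rows


def _write_rows(rows: list[dict], path: str | Path) -> None:
    path = Path(path)
    frame = pd.DataFrame(rows)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps({"rows": rows}, indent=1), encoding="utf-8")
    else:
        frame.to_csv(path, index=False, encoding="utf-8")


def write_transition_table(table: TransitionTable, path: str | Path) -> None:
    """Write one table in the ``transitions`` schema; round-trips losslessly."""
    _write_rows(_entry_rows(table), path)


def write_study(dataset: StudyDataset, path: str | Path) -> None:
    """Write a dataset; all entries must share one schema (table or summary)."""
    kinds = {isinstance(e, TransitionTable) for e in dataset.entries}
    if len(kinds) > 1:
        raise ValueError("cannot mix transition tables and arm summaries in one file")
    rows = [r for e in dataset.entries for r in _entry_rows(e)]
    _write_rows(rows, path)


# ---------------------------------------------------------------------------
# parameter and cohort files


def read_parameters(path: str | Path) -> tuple[RateParameters, ScaleFactors]:
    """Read a JSON parameter file.

    Schema: ``{"tau_forward": [4 floats, months], "tau_backward": [4 floats],
    "progressor_fraction": float, "alpha": [4 floats]|null, "beta": [8
    floats]|null}``.  Mean times tau are the stored convention (as printed in
    the source tables); rates are their reciprocals.
    """
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return _parameters_from_dict(payload)


def _parameters_from_dict(payload: dict) -> tuple[RateParameters, ScaleFactors]:
    for key in ("tau_forward", "tau_backward", "progressor_fraction"):
        if key not in payload:
            raise ParseError(f"parameter file missing field '{key}'")
    params = RateParameters.from_tau(
        payload["tau_forward"], payload["tau_backward"], payload["progressor_fraction"]
    )
    factors = ScaleFactors(payload.get("alpha"), payload.get("beta"))
    return params, factors


def write_parameters(
    params: RateParameters, path: str | Path, factors: ScaleFactors | None = None
) -> None:
    factors = factors or ScaleFactors()
    payload = {
        "tau_forward": [float(t) for t in params.tau_forward],
        "tau_backward": [float(t) for t in params.tau_backward],
        "progressor_fraction": float(params.progressor_fraction),
        "alpha": None if factors.alpha is None else [float(a) for a in factors.alpha],
        "beta": None if factors.beta is None else [float(b) for b in factors.beta],
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_cohort(path: str | Path) -> CohortDistribution:
    """Read a cohort CSV with columns ``stage`` (0-4) and ``count``."""
    frame = pd.read_csv(path, encoding="utf-8")
    if not {"stage", "count"} <= set(frame.columns):
        raise ParseError("cohort file needs columns 'stage' and 'count'")
    counts = np.zeros(N_STAGES)
    for i, rec in enumerate(frame.to_dict("records"), start=1):
        counts[_check_stage(rec["stage"], i, "stage")] += _check_count(rec["count"], i)
    return CohortDistribution(counts)


def write_cohort(dist: CohortDistribution, path: str | Path) -> None:
    pd.DataFrame({"stage": np.arange(N_STAGES), "count": dist.counts}).to_csv(
        Path(path), index=False, encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# built-in fixtures


def _data_text(name: str) -> str:
    return resources.files("fibrosim.data").joinpath(name).read_text(encoding="utf-8")


def fixture_parameters(name: str) -> RateParameters:
    """Named parameter sets: ``fitted``, ``placebo``, ``pioglitazone``.

    * ``fitted`` — natural-history rates estimated from observational
      paired-biopsy studies (advice-only care).
    * ``placebo`` — fitted rates with the placebo-arm forward scale factors
      already applied (diet-and-exercise advice inside a trial).
    * ``pioglitazone`` — placebo rates with the drug scale factors applied to
      all eight rates.
    """
    payload = json.loads(_data_text("parameters.json"))
    if name not in payload:
        raise KeyError(f"unknown parameter fixture {name!r}; have {sorted(payload)}")
    params, _ = _parameters_from_dict(payload[name])
    return params


def fixture_mix(name: str) -> np.ndarray:
    """Named initial stage mixes (proportions summing to 1).

    ``typical`` is the published typical NAFLD/NASH cohort mix (35% F0, 44%
    F1, 10% F2, 12% F3, 0% F4).  The raw percentages sum to 1.01; they are
    renormalized proportionally (logged once).  ``f2f3`` is an advanced
    cohort with 50% F2 and 50% F3.  ``cusi_pooled`` pools the baseline
    distributions of both pioglitazone-trial arms.
    """
    mixes = {
        "typical": np.array([0.35, 0.44, 0.10, 0.12, 0.0]),
        "f2f3": np.array([0.0, 0.0, 0.5, 0.5, 0.0]),
        "cusi_pooled": np.array([35.0, 44.0, 10.0, 12.0, 0.0]),
    }
    if name not in mixes:
        raise KeyError(f"unknown mix fixture {name!r}; have {sorted(mixes)}")
    raw = mixes[name]
    total = raw.sum()
    if not np.isclose(total, 1.0):
        if name == "typical":
            logger.warning(
                "mix %r proportions sum to %.4g; renormalizing to 1", name, total
            )
        raw = raw / total
    return raw


def fixture_cusi() -> StudyDataset:
    """The 18-month placebo-controlled pioglitazone trial arm summaries."""
    import io as _stdio

    frame = pd.read_csv(_stdio.StringIO(_data_text("cusi_trial.csv")))
    return _parse_distributions(frame)


def builtin_fixtures() -> dict:
    """All built-in fixtures in one dictionary.

    Keys: ``fitted``, ``placebo``, ``pioglitazone`` (parameter sets),
    ``cusi`` (study dataset), ``typical_mix``, ``f2f3_mix``, ``cusi_pooled_mix``
    (stage proportion vectors), ``cusi_placebo_initial`` and
    ``cusi_pioglitazone_initial`` (cohort distributions).
    """
    cusi = fixture_cusi()
    arms = {e.arm: e for e in cusi.entries}
    return {
        "fitted": fixture_parameters("fitted"),
        "placebo": fixture_parameters("placebo"),
        "pioglitazone": fixture_parameters("pioglitazone"),
        "cusi": cusi,
        "typical_mix": fixture_mix("typical"),
        "f2f3_mix": fixture_mix("f2f3"),
        "cusi_pooled_mix": fixture_mix("cusi_pooled"),
        "cusi_placebo_initial": arms["placebo"].initial,
        "cusi_pioglitazone_initial": arms["pioglitazone"].initial,
    }
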