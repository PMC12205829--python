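"""Data model and CSV I/O for full-body-illusion trait-rating studies.

A study bundles four behavioral components collected from participants who
take part in dyads (pairs of friends):

* trait ratings (1-9) of 120 adjectives, once about the friend before the
  illusion conditions and once about the self inside each of four conditions;
* 7-statement illusion questionnaires (-3..+3) after each condition;
* old/new recognition-memory responses for the rated adjectives plus an
  equal number of unstudied foils;
* 100 Hz skin-conductance traces with knife-threat event markers.

Everything is stored long-format in plain CSV (UTF-8, comma separated,
header row, ``.`` decimal).  Missing ratings (response timeouts) are empty
cells, never sentinel numbers.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONDITIONS = ("syncSelf", "asyncSelf", "syncFriend", "asyncFriend")
STATEMENTS = ("I1", "I2", "I3", "C1", "C2", "C3", "C4", "L1")
ILLUSION_STATEMENTS = ("I1", "I2", "I3")
CONTROL_STATEMENTS = ("C1", "C2", "C3", "C4")
SAMPLING_RATE_HZ = 100
MAX_TRAITS_PER_CONDITION = 30

RATING_COLUMNS = (
    "participant_id", "dyad_id", "target", "condition",
    "trait_id", "rating", "reaction_time_s",
)
QUESTIONNAIRE_COLUMNS = ("participant_id", "condition", "statement_id", "rating")
MEMORY_COLUMNS = (
    "participant_id", "trait_id", "status", "encoding_condition",
    "rated_at_encoding", "response",
)
SCR_COLUMNS = ("participant_id", "condition", "sample_index", "conductance_uS")
SCR_EVENT_COLUMNS = ("participant_id", "condition", "onset_s", "repetition")

_FILES = {
    "ratings": "ratings.csv",
    "questionnaires": "questionnaires.csv",
    "memory": "memory.csv",
    "scr": "scr.csv",
    "scr_events": "scr_events.csv",
}


class SchemaError(ValueError):
    """A study component violates the data-model invariants."""


class MissingComponentError(FileNotFoundError):
    """A required study CSV is absent from the input directory."""


@dataclass
class ScrRecording:
    """One participant x condition conductance trace with threat events."""

    participant_id: str
    condition: str
    samples: np.ndarray  # microsiemens, 100 Hz
    events: list  # of (onset_s, repetition)
    sampling_rate: int = SAMPLING_RATE_HZ

    @property
    def duration_s(self) -> float:
        return (len(self.samples) - 1) / self.sampling_rate


@dataclass
class StudyDataset:
    """Bundle of every component of one (real or synthetic) experiment."""

    ratings: pd.DataFrame
    questionnaires: pd.DataFrame
    memory: pd.DataFrame
    scr: pd.DataFrame
    scr_events: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def participants(self) -> list:
        return sorted(self.ratings["participant_id"].unique())

    def recording(self, participant_id: str, condition: str) -> ScrRecording:
        t = self.scr[
            (self.scr["participant_id"] == participant_id)
            & (self.scr["condition"] == condition)
        ].sort_values("sample_index")
        ev = self.scr_events[
            (self.scr_events["participant_id"] == participant_id)
            & (self.scr_events["condition"] == condition)
        ]
        if t.empty:
            raise KeyError(f"no SCR trace for {participant_id}/{condition}")
        return ScrRecording(
            participant_id=participant_id,
            condition=condition,
            samples=t["conductance_uS"].to_numpy(dtype=float),
            events=list(zip(ev["onset_s"].tolist(), ev["repetition"].tolist())),
        )

    def iter_recordings(self):
        ev_groups = {k: g for k, g in
                     self.scr_events.groupby(["participant_id", "condition"],
                                             sort=False)}
        for (pid, cond), t in self.scr.groupby(["participant_id", "condition"],
                                               sort=False):
            ev = ev_groups.get((pid, cond))
            events = (list(zip(ev["onset_s"].tolist(),
                               ev["repetition"].tolist()))
                      if ev is not None else [])
            yield ScrRecording(
                participant_id=pid, condition=cond,
                samples=t.sort_values("sample_index")["conductance_uS"]
                         .to_numpy(dtype=float),
                events=events)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for df in (self.ratings, self.questionnaires, self.memory,
                   self.scr, self.scr_events):
            h.update(df.to_csv(index=False).encode())
        return h.hexdigest()


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise SchemaError(f"schema violation: {message}")


def validate_study(ds: StudyDataset) -> None:
    """Check every data-model invariant; raise :class:`SchemaError` on failure."""
    r = ds.ratings
    _require(list(r.columns) == list(RATING_COLUMNS), "ratings columns")
    bad_target = ~r["target"].isin(["self", "friend"])
    _require(not bad_target.any(), f"bad target at rows {list(r.index[bad_target])[:5]}")
    rated = r["rating"].notna()
    vals = r.loc[rated, "rating"].astype(float)
    out = (vals < 1) | (vals > 9) | (vals != vals.round())
    _require(not out.any(),
             f"rating outside 1-9 at rows {list(vals.index[out])[:5]}")
    # timeout rows may not carry a reaction time
    _require(not (r["rating"].isna() & r["reaction_time_s"].notna()).any(),
             "reaction time present on a timeout row")
    rt = r["reaction_time_s"].dropna()
    _require((rt >= 0).all(), "negative reaction time")

    selfr = r[r["target"] == "self"]
    _require(selfr["condition"].isin(CONDITIONS).all(),
             "self rating with missing/unknown condition")
    friendr = r[r["target"] == "friend"]
    _require(friendr["condition"].isna().all(),
             "friend rating carries a condition (friend task precedes conditions)")
    # each (participant, self trait) sits in exactly one condition
    per_trait = selfr.groupby(["participant_id", "trait_id"])["condition"].nunique()
    _require((per_trait == 1).all(), "self trait assigned to multiple conditions")
    per_cell = selfr.groupby(["participant_id", "condition"])["trait_id"].nunique()
    _require((per_cell <= MAX_TRAITS_PER_CONDITION).all(),
             f"more than {MAX_TRAITS_PER_CONDITION} traits in one condition")

    q = ds.questionnaires
    _require(list(q.columns) == list(QUESTIONNAIRE_COLUMNS), "questionnaire columns")
    _require(q["statement_id"].isin(STATEMENTS).all(), "unknown statement id")
    _require(q["condition"].isin(CONDITIONS).all(), "unknown questionnaire condition")
    qv = q["rating"].astype(float)
    _require(((qv >= -3) & (qv <= 3) & (qv == qv.round())).all(),
             "questionnaire rating outside -3..+3")
    dup = q.groupby(["participant_id", "condition", "statement_id"]).size()
    _require((dup <= 1).all(), "duplicate questionnaire statement")

    m = ds.memory
    _require(list(m.columns) == list(MEMORY_COLUMNS), "memory columns")
    _require(m["status"].isin(["old", "new"]).all(), "bad memory status")
    _require(m["response"].isin(["old", "new", "timeout"]).all(), "bad memory response")
    new_rows = m[m["status"] == "new"]
    _require(new_rows["encoding_condition"].isna().all(),
             "new memory item carries an encoding condition")
    counts = m.groupby(["participant_id", "status"]).size()
    _require((counts <= 120).all(), "more than 120 old or new memory items")

    s = ds.scr
    _require(list(s.columns) == list(SCR_COLUMNS), "scr columns")
    e = ds.scr_events
    _require(list(e.columns) == list(SCR_EVENT_COLUMNS), "scr event columns")
    if len(e):
        _require(e["repetition"].between(1, 12).all(), "repetition outside 1-12")
        per_cond = e.groupby(["participant_id", "condition"]).size()
        _require((per_cond == 3).all(), "conditions must hold 3 threat events")
        uniq = e.groupby("participant_id")["repetition"].nunique()
        tot = e.groupby("participant_id").size()
        _require((uniq == tot).all(), "repetition indices repeat within participant")

    # participant ids consistent across components
    pids = set(r["participant_id"])
    for name, df in (("questionnaires", q), ("memory", m),
                     ("scr", s), ("scr_events", e)):
        extra = set(df["participant_id"]) - pids
        _require(not extra, f"{name} references unknown participants {sorted(extra)[:3]}")


def _read_csv(path: Path, **kwargs) -> pd.DataFrame:
    if not path.exists():
        raise MissingComponentError(f"missing component: {path.name}")
    return pd.read_csv(path, **kwargs)


def read_study(dir_path) -> StudyDataset:
    """Read and validate a study directory written in the package CSV dialect."""
    d = Path(dir_path)
    str_cols = {"participant_id": str, "dyad_id": str, "trait_id": str,
                "target": str, "condition": str, "statement_id": str,
                "status": str, "encoding_condition": str, "response": str}
    ratings = _read_csv(d / _FILES["ratings"], dtype=str_cols)
    ratings["rating"] = ratings["rating"].astype("Float64").astype("Int64")
    ratings["reaction_time_s"] = ratings["reaction_time_s"].astype(float)
    quest = _read_csv(d / _FILES["questionnaires"], dtype=str_cols)
    quest["rating"] = quest["rating"].astype(int)
    memory = _read_csv(d / _FILES["memory"], dtype=str_cols)
    memory["rated_at_encoding"] = memory["rated_at_encoding"].map(
        {"true": True, "false": False, True: True, False: False}
    )
    if memory["rated_at_encoding"].isna().any():
        raise SchemaError("schema violation: rated_at_encoding not true/false")
    scr = _read_csv(d / _FILES["scr"], dtype=str_cols)
    scr["sample_index"] = scr["sample_index"].astype(int)
    scr["conductance_uS"] = scr["conductance_uS"].astype(float)
    events = _read_csv(d / _FILES["scr_events"], dtype=str_cols)
    events["onset_s"] = events["onset_s"].astype(float)
    events["repetition"] = events["repetition"].astype(int)
    ds = StudyDataset(ratings=ratings, questionnaires=quest, memory=memory,
                      scr=scr, scr_events=events,
                      meta={"source": "file", "path": str(d), "seed": None})
    validate_study(ds)
    return ds


def write_study(ds: StudyDataset, dir_path) -> None:
    """Write a validated dataset as the five study CSVs (deterministic bytes)."""
    validate_study(ds)
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    ds.ratings.to_csv(d / _FILES["ratings"], index=False)
    ds.questionnaires.to_csv(d / _FILES["questionnaires"], index=False)
    mem = ds.memory.copy()
    mem["rated_at_encoding"] = mem["rated_at_encoding"].map({True: "true", False: "false"})
    mem.to_csv(d / _FILES["memory"], index=False)
    ds.scr.to_csv(d / _FILES["scr"], index=False)
    ds.scr_events.to_csv(d / _FILES["scr_events"], index=False)


def filter_rated(ratings: pd.DataFrame) -> pd.DataFrame:
    """Keep only trials answered with a button press (drop timeout rows).

    Idempotent; the memory and clustering stages operate on its output.
    """
    return ratings[ratings["rating"].notna()].copy()
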