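"""Pay-to-know task structure and trial-table I/O.

The task presents, on each trial, a single trait word (positive or negative
valence) and two options: "to know" (TK) the evaluation one received on that
trait, or "not to know" (NTK).  The options carry token payoffs whose
difference Δm = payoff_TK − payoff_NTK spans the seven levels −3…3; choosing
TK when Δm ≤ 0 is *costly* knowing.  A full schedule has 126 trials: 18 per
Δm level, 9 of each valence within a level.

This module holds the trial-level data model (:class:`TrialDesign`,
:class:`ChoiceRecord`, :class:`TaskSchedule`), the seeded schedule builder,
and CSV/JSON readers and writers used across the pipeline.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, SchemaError, ValidationError

__all__ = [
    "DELTA_M_LEVELS",
    "TrialDesign",
    "ChoiceRecord",
    "TaskSchedule",
    "build_task_schedule",
    "records_to_frame",
    "frame_to_records",
    "read_choice_table",
    "write_choice_table",
    "write_results",
    "read_results",
]

DELTA_M_LEVELS = (-3, -2, -1, 0, 1, 2, 3)
TRIALS_PER_LEVEL = 18          # 9 positive + 9 negative traits per Δm level
N_TRIALS = len(DELTA_M_LEVELS) * TRIALS_PER_LEVEL  # 126

_VALENCES = ("positive", "negative")
_SIDES = ("left", "right")
_FRAMES = ("gain", "loss")
_CHOICES = ("TK", "NTK")
_EXPERIMENTS = ("exp1", "exp2", "exp3", "exp4", "exp5", "synthetic")
_SOURCES = ("social", "nonsocial")
_TREATMENTS = ("none", "placebo", "oxytocin")


@dataclass(frozen=True)
class TrialDesign:
    """Design cells of one trial (no behaviour)."""

    trial_index: int            # 1-based position in the session
    trait_id: str
    valence: str                # 'positive' | 'negative'
    payoff_tk: int              # tokens for the to-know option
    payoff_ntk: int             # tokens for the not-to-know option
    tk_side: str                # screen side of the TK option
    frame: str                  # 'gain' (payoffs >= 0) or 'loss' (<= 0)

    @property
    def delta_m(self) -> int:
        return self.payoff_tk - self.payoff_ntk

    def __post_init__(self) -> None:
        if self.trial_index < 1:
            raise ValidationError(f"trial_index must be >= 1, got {self.trial_index}")
        if self.valence not in _VALENCES:
            raise ValidationError(f"valence must be one of {_VALENCES}, got {self.valence!r}")
        if self.tk_side not in _SIDES:
            raise ValidationError(f"tk_side must be one of {_SIDES}, got {self.tk_side!r}")
        if self.frame not in _FRAMES:
            raise ValidationError(f"frame must be one of {_FRAMES}, got {self.frame!r}")
        if self.delta_m not in DELTA_M_LEVELS:
            raise ValidationError(
                f"delta_m={self.delta_m} outside the task's payoff-difference levels {DELTA_M_LEVELS}"
            )
        if self.frame == "gain" and (self.payoff_tk < 0 or self.payoff_ntk < 0):
            raise ValidationError("gain frame requires both payoffs >= 0")
        if self.frame == "loss" and (self.payoff_tk > 0 or self.payoff_ntk > 0):
            raise ValidationError("loss frame requires both payoffs <= 0")


@dataclass(frozen=True)
class ChoiceRecord:
    """One trial's design plus the observed choice — the atom of every analysis."""

    subject_id: str
    design: TrialDesign
    choice: str                          # 'TK' | 'NTK'
    experiment: str = "synthetic"
    source: str = "social"               # who produced the evaluation
    treatment: str = "none"
    session_order: Optional[int] = None
    rt_s: Optional[float] = None
    self_relevance: Optional[int] = None  # -10 (not like me) .. 10 (exactly like me)

    def __post_init__(self) -> None:
        if self.choice not in _CHOICES:
            raise ValidationError(f"choice must be one of {_CHOICES}, got {self.choice!r}")
        if self.experiment not in _EXPERIMENTS:
            raise ValidationError(f"experiment must be one of {_EXPERIMENTS}, got {self.experiment!r}")
        if self.source not in _SOURCES:
            raise ValidationError(f"source must be one of {_SOURCES}, got {self.source!r}")
        if self.treatment not in _TREATMENTS:
            raise ValidationError(f"treatment must be one of {_TREATMENTS}, got {self.treatment!r}")
        if self.self_relevance is not None and not (-10 <= self.self_relevance <= 10):
            raise ValidationError(
                f"self_relevance={self.self_relevance} outside [-10, 10]"
            )


@dataclass(frozen=True)
class TaskSchedule:
    """An ordered 126-trial session design, reproducible from its seed."""

    trials: tuple[TrialDesign, ...]
    seed: int

    def __post_init__(self) -> None:
        counts: dict[tuple[int, str], int] = {}
        for t in self.trials:
            counts[(t.delta_m, t.valence)] = counts.get((t.delta_m, t.valence), 0) + 1
        if len(self.trials) != N_TRIALS:
            raise ValidationError(f"schedule must have {N_TRIALS} trials, got {len(self.trials)}")
        for dm in DELTA_M_LEVELS:
            for val in _VALENCES:
                if counts.get((dm, val), 0) != TRIALS_PER_LEVEL // 2:
                    raise ValidationError(
                        f"cell (delta_m={dm}, {val}) has {counts.get((dm, val), 0)} trials, "
                        f"expected {TRIALS_PER_LEVEL // 2}"
                    )


def build_task_schedule(seed: int, frame: str = "gain", base_payoff: int | None = None) -> TaskSchedule:
    """Build a seeded 126-trial schedule.

    The NTK payoff is fixed at ``base_payoff`` (default +5 in the gain frame,
    −5 in the loss frame) and the TK payoff is ``base_payoff + Δm``, so only
    the payoff difference varies, as in the task.  Trait words are drawn from
    a fixed pool of 63 positive and 63 negative identifiers and randomly
    paired with payoff cells; the TK option's screen side is randomized 50/50
    per trial; trial order is a seeded shuffle.
    """
    if seed < 0:
        raise InvalidConfigError("seed must be a non-negative integer")
    if frame not in _FRAMES:
        raise InvalidConfigError(f"frame must be one of {_FRAMES}")
    if base_payoff is None:
        base_payoff = 5 if frame == "gain" else -5
    if frame == "gain" and base_payoff < 3:
        raise InvalidConfigError(
            f"gain frame needs base_payoff >= 3 so no payoff is negative (got {base_payoff})"
        )
    if frame == "loss" and base_payoff > -3:
        raise InvalidConfigError(
            f"loss frame needs base_payoff <= -3 so no payoff is positive (got {base_payoff})"
        )

    rng = np.random.default_rng(seed)
    traits = {
        "positive": [f"pos_{i:02d}" for i in range(1, 64)],
        "negative": [f"neg_{i:02d}" for i in range(1, 64)],
    }
    # random word–payoff pairing within each valence
    for val in _VALENCES:
        rng.shuffle(traits[val])

    cells: list[tuple[int, str, str]] = []
    cursor = {"positive": 0, "negative": 0}
    for dm in DELTA_M_LEVELS:
        for val in _VALENCES:
            for _ in range(TRIALS_PER_LEVEL // 2):
                cells.append((dm, val, traits[val][cursor[val]]))
                cursor[val] += 1

    order = rng.permutation(len(cells))
    sides = rng.integers(0, 2, size=len(cells))
    trials = []
    for idx, (cell_i, side_i) in enumerate(zip(order, sides), start=1):
        dm, val, trait = cells[cell_i]
        trials.append(
            TrialDesign(
                trial_index=idx,
                trait_id=trait,
                valence=val,
                payoff_tk=base_payoff + dm,
                payoff_ntk=base_payoff,
                tk_side=_SIDES[side_i],
                frame=frame,
            )
        )
    return TaskSchedule(trials=tuple(trials), seed=seed)


# ---------------------------------------------------------------------------
# tabular I/O

_COLUMNS = [
    "subject_id", "experiment", "source", "treatment", "session_order",
    "trial_index", "trait_id", "valence", "payoff_tk", "payoff_ntk",
    "delta_m", "tk_side", "frame", "choice", "rt_s", "self_relevance",
]
_REQUIRED = [c for c in _COLUMNS if c not in ("session_order", "rt_s", "self_relevance", "delta_m")]


def records_to_frame(records: Iterable[ChoiceRecord]) -> pd.DataFrame:
    """Flatten records to the canonical one-row-per-trial table."""
    rows = []
    for r in records:
        d = r.design
        rows.append({
            "subject_id": r.subject_id, "experiment": r.experiment,
            "source": r.source, "treatment": r.treatment,
            "session_order": r.session_order, "trial_index": d.trial_index,
            "trait_id": d.trait_id, "valence": d.valence,
            "payoff_tk": d.payoff_tk, "payoff_ntk": d.payoff_ntk,
            "delta_m": d.delta_m, "tk_side": d.tk_side, "frame": d.frame,
            "choice": r.choice, "rt_s": r.rt_s, "self_relevance": r.self_relevance,
        })
    return pd.DataFrame(rows, columns=_COLUMNS)


def _opt_int(v):
    if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v):
        return None
    return int(v)


def frame_to_records(df: pd.DataFrame) -> list[ChoiceRecord]:
    """Parse the canonical table back into validated records.

    Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` (carrying the row index) for invariant
    violations, including a ``delta_m`` column inconsistent with the payoffs.
    """
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            design = TrialDesign(
                trial_index=int(row.trial_index),
                trait_id=str(row.trait_id),
                valence=str(row.valence),
                payoff_tk=int(row.payoff_tk),
                payoff_ntk=int(row.payoff_ntk),
                tk_side=str(row.tk_side),
                frame=str(row.frame),
            )
            if "delta_m" in df.columns and not pd.isna(getattr(row, "delta_m", None)):
                if int(row.delta_m) != design.delta_m:
                    raise ValidationError(
                        f"delta_m={int(row.delta_m)} inconsistent with payoffs "
                        f"({design.payoff_tk} - {design.payoff_ntk})"
                    )
            rt = getattr(row, "rt_s", None)
            records.append(ChoiceRecord(
                subject_id=str(row.subject_id),
                design=design,
                choice=str(row.choice),
                experiment=str(row.experiment),
                source=str(row.source),
                treatment=str(row.treatment),
                session_order=_opt_int(getattr(row, "session_order", None)),
                rt_s=None if rt is None or pd.isna(rt) else float(rt),
                self_relevance=_opt_int(getattr(row, "self_relevance", None)),
            ))
        except ValidationError as e:
            raise ValidationError(str(e.args[0] if e.row is None else e.args[0]), row=i) from e
        except (ValueError, TypeError) as e:
            raise ValidationError(str(e), row=i) from e
    return records


def read_choice_table(path: str | Path) -> list[ChoiceRecord]:
    """Read a CSV trial table into validated :class:`ChoiceRecord` objects."""
    df = pd.read_csv(path)
    return frame_to_records(df)


def write_choice_table(records: Iterable[ChoiceRecord] | pd.DataFrame, path: str | Path) -> None:
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# structured results (JSON)

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {"__dataclass__": type(obj).__name__,
                "fields": {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}}
    if isinstance(obj, pd.DataFrame):
        return {"__frame__": True, "records": json.loads(obj.to_json(orient="table"))}
    if isinstance(obj, pd.Series):
        return {"__series__": True, "data": {str(k): _jsonable(v) for k, v in obj.items()}}
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_results(bundle, path: str | Path, seeds: dict[str, int] | None = None) -> None:
    """Serialize any of the package's result objects to JSON.

    The envelope records the package version and the seeds that produced the
    result so every file is self-describing and auditable.
    """
    from . import __version__

    payload = {
        "package": "paytoknow",
        "version": __version__,
        "seeds": seeds or {},
        "kind": type(bundle).__name__,
        "payload": _jsonable(bundle),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, allow_nan=False)


def read_results(path: str | Path) -> dict:
    """Read a :func:`write_results` file back as plain python structures."""
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
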