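"""CSV/JSON formats and provenance sidecars for the pipeline.

Two plain CSV formats (RFC 4180, UTF-8, '.' decimal):

* trials — one row per judgment:
  ``participant_id, task, trial_index, level_index, ratio_label, n_red,
  n_black, correct_color, response_color``.  Rows are validated against the
  ratio-level table (counts must match the level) and grouped into
  :class:`~ansacuity.staircase.SessionRecord` objects in file order.
* cohort — one row per participant:
  ``participant_id, education_years, age_years, gender, computer_first,
  logw_cards, logw_computer``.

Generating configs are JSON renderings of
:class:`~ansacuity.synthetic.GenerativeParams`.  Every file writer can drop a
``<name>.meta.json`` sidecar carrying the seed, the SHA-256 of the canonical
config JSON and the package version, so outputs are traceable to the exact
configuration that produced them.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .psychophysics import Trial
from .staircase import SessionRecord, level_table
from .synthetic import GenerativeParams

__all__ = [
    "TrialsParseError",
    "CohortParseError",
    "TRIALS_COLUMNS",
    "COHORT_COLUMNS",
    "read_trials",
    "write_trials",
    "read_cohort",
    "write_cohort",
    "load_params",
    "save_params",
    "config_hash",
    "write_sidecar",
]

TRIALS_COLUMNS = (
    "participant_id",
    "task",
    "trial_index",
    "level_index",
    "ratio_label",
    "n_red",
    "n_black",
    "correct_color",
    "response_color",
)

COHORT_COLUMNS = (
    "participant_id",
    "education_years",
    "age_years",
    "gender",
    "computer_first",
    "logw_cards",
    "logw_computer",
)


class TrialsParseError(ValueError):
    """Malformed trials CSV; the message names the offending row."""


class CohortParseError(ValueError):
    """Malformed cohort CSV."""


def _level_by_index() -> dict:
    return {lev.index: lev for lev in level_table()}


def write_trials(records, path) -> None:
    """Serialize sessions to the trials CSV (lossless round-trip)."""
    rows = []
    for rec in records:
        for t in rec.trials:
            n_red = t.n_large if t.correct_color == "red" else t.n_small
            n_black = t.n_large if t.correct_color == "black" else t.n_small
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "task": rec.task,
                    "trial_index": t.trial_index,
                    "level_index": t.level_index,
                    "ratio_label": _level_by_index()[t.level_index].ratio_label,
                    "n_red": n_red,
                    "n_black": n_black,
                    "correct_color": t.correct_color,
                    "response_color": t.response_color,
                }
            )
    pd.DataFrame(rows, columns=list(TRIALS_COLUMNS)).to_csv(path, index=False)


def read_trials(path) -> list[SessionRecord]:
    """Parse and validate a trials CSV into session records.

    Sessions are the maximal runs of consecutive rows sharing
    ``(participant_id, task)``; row numbers in error messages are 1-based
    data rows (the header is row 0).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(TRIALS_COLUMNS) - set(df.columns)
    if missing:
        raise TrialsParseError(f"trials file missing columns: {sorted(missing)}")
    levels = _level_by_index()
    by_label = {lev.ratio_label: lev for lev in level_table()}
    sessions: list[SessionRecord] = []
    current_key: tuple[str, str] | None = None
    current: list[Trial] = []

    def flush() -> None:
        if current_key is not None and current:
            sessions.append(
                SessionRecord(
                    participant_id=current_key[0],
                    task=current_key[1],
                    trials=tuple(current),
                    seed=-1,
                )
            )

    for i, row in enumerate(df.itertuples(index=False), start=1):
        where = f"row {i}"
        task = row.task
        if task not in ("cards", "computer"):
            raise TrialsParseError(f"{where}: unknown task label {task!r}")
        try:
            trial_index = int(row.trial_index)
            level_index = int(row.level_index)
            n_red = int(row.n_red)
            n_black = int(row.n_black)
        except (TypeError, ValueError) as exc:
            raise TrialsParseError(f"{where}: non-integer numeric field ({exc})") from None
        if level_index not in levels:
            raise TrialsParseError(f"{where}: level_index {level_index} out of range")
        lev = levels[level_index]
        if by_label.get(row.ratio_label) is not lev:
            raise TrialsParseError(
                f"{where}: ratio_label {row.ratio_label!r} does not match level {level_index}"
            )
        if {n_red, n_black} != {lev.n_small, lev.n_large}:
            raise TrialsParseError(
                f"{where}: counts ({n_red}, {n_black}) must be "
                f"{{{lev.n_small}, {lev.n_large}}} for ratio {lev.ratio_label}"
            )
        if row.correct_color not in ("red", "black") or row.response_color not in ("red", "black"):
            raise TrialsParseError(f"{where}: colors must be 'red' or 'black'")
        expected_correct = "red" if n_red > n_black else "black"
        if n_red != n_black and row.correct_color != expected_correct:
            raise TrialsParseError(
                f"{where}: correct_color {row.correct_color!r} contradicts counts "
                f"(red={n_red}, black={n_black})"
            )
        try:
            trial = Trial(
                n_small=min(n_red, n_black),
                n_large=max(n_red, n_black),
                correct_color=row.correct_color,
                response_color=row.response_color,
                level_index=level_index,
                task=task,
                trial_index=trial_index,
            )
        except ValueError as exc:
            raise TrialsParseError(f"{where}: {exc}") from None
        key = (row.participant_id, task)
        if key != current_key:
            flush()
            current_key, current = key, []
        current.append(trial)
    flush()
    return sessions


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort = cohort[list(COHORT_COLUMNS)]
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise CohortParseError(f"cohort file missing columns: {sorted(missing)}")
    edu = df["education_years"]
    if not ((edu >= 0) & (edu <= 16) & (edu == edu.astype(int))).all():
        raise CohortParseError("education_years must be integers in 0..16")
    if df["participant_id"].duplicated().any():
        raise CohortParseError("duplicate participant_id rows in cohort file")
    df["computer_first"] = df["computer_first"].astype(bool)
    return df


def load_params(path) -> GenerativeParams:
    with open(path, "r", encoding="utf-8") as fh:
        return GenerativeParams.from_dict(json.load(fh))


def save_params(params: GenerativeParams, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(params.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def config_hash(params: GenerativeParams) -> str:
    canonical = json.dumps(params.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


def write_sidecar(data_path, params: GenerativeParams, extra: dict | None = None) -> Path:
    """Drop ``<data_path>.meta.json`` recording seed, config hash, version."""
    meta = {
        "seed": params.seed,
        "config_sha256": config_hash(params),
        "ansacuity_version": __version__,
    }
    if extra:
        meta.update(extra)
    side = Path(str(data_path) + ".meta.json")
    with open(side, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return side
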