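"""Study configuration and serialization of elicitation data.

Response records travel as JSON lines — one respondent per line,
``{"id": ..., "ranking": [attribute names], "choices": [[bool, ...], ...]}``
with ``true`` meaning the target alternative was chosen — or as a flat CSV
(one row per respondent, columns ``ranking_1..n`` then ``q_1..q_K`` in
trade-off-major order).  Fitted parameters serialize as JSON
``{"mu": [...], "phi": x}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .dirichlet import DirichletParams
from .elicit import ResponseRecord
from .scales import AttributeScale

__all__ = [
    "StudyConfig",
    "write_records_jsonl",
    "read_records_jsonl",
    "write_records_csv",
    "read_records_csv",
    "write_params",
    "read_params",
    "write_weights_csv",
    "read_weights_csv",
]


@dataclass(frozen=True)
class StudyConfig:
    """Attribute scales plus elicitation and fitting settings for a study."""

    attributes: tuple[AttributeScale, ...]
    steps_per_tradeoff: int = 2
    question_budget: int | None = None
    sml_m: int = 500
    sml_seed: int = 0

    def __post_init__(self) -> None:
        names = [a.name for a in self.attributes]
        if len(names) < 2:
            raise ValueError("need at least 2 attributes")
        if len(set(names)) != len(names):
            raise ValueError(f"attribute names must be unique, got {names}")
        if self.steps_per_tradeoff < 0 or self.sml_m < 1:
            raise ValueError("steps_per_tradeoff must be >= 0 and sml m >= 1")

    @property
    def n(self) -> int:
        return len(self.attributes)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.attributes)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        attrs = tuple(
            AttributeScale(name=a["name"], worst=float(a["worst"]), best=float(a["best"]))
            for a in d["attributes"]
        )
        sml = d.get("sml", {})
        return cls(
            attributes=attrs,
            steps_per_tradeoff=int(d.get("steps_per_tradeoff", 2)),
            question_budget=d.get("question_budget"),
            sml_m=int(sml.get("m", 500)),
            sml_seed=int(sml.get("seed", 0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "attributes": [
                {"name": a.name, "worst": a.worst, "best": a.best} for a in self.attributes
            ],
            "steps_per_tradeoff": self.steps_per_tradeoff,
            "question_budget": self.question_budget,
            "sml": {"m": self.sml_m, "seed": self.sml_seed},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


# ----------------------------------------------------------------------
# response records
# ----------------------------------------------------------------------

def _record_to_dict(record: ResponseRecord, names: Sequence[str]) -> dict:
    return {
        "id": record.id,
        "ranking": [names[i] for i in record.ranking],
        "choices": [list(map(bool, c)) for c in record.choices],
    }


def _record_from_dict(d: dict, names: Sequence[str], lineno: int) -> ResponseRecord:
    try:
        ranking = tuple(names.index(a) for a in d["ranking"])
        choices = tuple(tuple(bool(x) for x in c) for c in d["choices"])
        return ResponseRecord(ranking=ranking, choices=choices, id=str(d.get("id", "")))
    except (KeyError, ValueError) as exc:
        raise ValueError(f"malformed response record on line {lineno}: {exc}") from exc


def write_records_jsonl(
    records: Iterable[ResponseRecord], names: Sequence[str], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(json.dumps(_record_to_dict(r, list(names))) + "\n")


def read_records_jsonl(path: str | Path, names: Sequence[str]) -> list[ResponseRecord]:
    names = list(names)
    records, errors = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                records.append(_record_from_dict(json.loads(line), names, lineno))
            except (ValueError, json.JSONDecodeError) as exc:
                errors.append(f"line {lineno}: {exc}")
    if errors:
        raise ValueError("malformed response record(s):\n" + "\n".join(errors))
    return records


def write_records_csv(
    records: Sequence[ResponseRecord], names: Sequence[str], path: str | Path
) -> None:
    """Flat spreadsheet dialect: ranking_1..n, then q_1..q_K (1 = target)."""
    names = list(names)
    n = len(names)
    rows = []
    for r in records:
        row: dict = {"id": r.id}
        for k, idx in enumerate(r.ranking, start=1):
            row[f"ranking_{k}"] = names[idx]
        q = 1
        for c in r.choices:
            for ans in c:
                row[f"q_{q}"] = int(ans)
                q += 1
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_records_csv(
    path: str | Path, names: Sequence[str], steps_per_tradeoff: int
) -> list[ResponseRecord]:
    names = list(names)
    n = len(names)
    df = pd.read_csv(path)
    records = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        ranking = [d[f"ranking_{k}"] for k in range(1, n + 1)]
        q_cols = sorted(
            (c for c in d if c.startswith("q_") and pd.notna(d[c])),
            key=lambda c: int(c.split("_")[1]),
        )
        answers = [bool(int(d[c])) for c in q_cols]
        if steps_per_tradeoff and len(answers) % steps_per_tradeoff:
            raise ValueError(
                f"row {lineno}: {len(answers)} answers is not a whole number of "
                f"trade-offs at {steps_per_tradeoff} steps each"
            )
        choices = [
            answers[k : k + steps_per_tradeoff]
            for k in range(0, len(answers), steps_per_tradeoff)
        ] if steps_per_tradeoff else []
        records.append(
            _record_from_dict(
                {"id": d.get("id", ""), "ranking": ranking, "choices": choices},
                names,
                lineno,
            )
        )
    return records


# ----------------------------------------------------------------------
# parameters and weight tables
# ----------------------------------------------------------------------

def write_params(params: DirichletParams, path: str | Path) -> None:
    Path(path).write_text(params.to_json() + "\n")


def read_params(path: str | Path) -> DirichletParams:
    return DirichletParams.from_json(Path(path).read_text())


def write_weights_csv(W: np.ndarray, names: Sequence[str], path: str | Path) -> None:
    pd.DataFrame(np.asarray(W), columns=list(names)).to_csv(path, index=False)


def read_weights_csv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(dtype=float)
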