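"""Plain-text serialization of cohort datasets.

A dataset is a directory holding ``participants.csv``, ``trials.csv`` and
``provenance.json``. Orientations and sides are coded L/R, cue indices and
trials are 1-based. The round-trip is lossless for everything the analysis
consumes (scores, true parameters, blocks, responses, provenance).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CONDITIONS, CohortDataset, Participant
from .task import SIDE_CODES, SIDE_LABELS, TaskBlock

TRIAL_COLUMNS = [
    "participant_id",
    "condition",
    "trial",
    "cue_top",
    "cue_mid",
    "cue_bot",
    "target",
    "relevant_cue",
    "valid",
    "response",
    "shift_trial",
]

PARAM_NAMES = ("h", "gamma", "epsilon")


class ParseError(ValueError):
    """Malformed dataset file; the message carries the offending row."""


def trials_frame(dataset: CohortDataset) -> pd.DataFrame:
    rows = []
    for p in dataset.participants:
        for cond, block in p.blocks.items():
            resp = p.responses[cond]
            for t in range(block.n_trials):
                rows.append(
                    (
                        p.id,
                        cond,
                        t + 1,
                        SIDE_LABELS[int(block.cues[t, 0])],
                        SIDE_LABELS[int(block.cues[t, 1])],
                        SIDE_LABELS[int(block.cues[t, 2])],
                        SIDE_LABELS[int(block.target[t])],
                        int(block.relevant_cue[t]) + 1,
                        int(block.valid[t]),
                        SIDE_LABELS[int(resp[t])],
                        block.shift_trial,
                    )
                )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def participants_frame(dataset: CohortDataset) -> pd.DataFrame:
    rows = []
    for p in dataset.participants:
        row = {
            "participant_id": p.id,
            "ocir_total": p.ocir,
            "dass_anxiety": p.dass.get("anxiety"),
            "dass_stress": p.dass.get("stress"),
            "dass_depression": p.dass.get("depression"),
        }
        for cond in p.true_params:
            for name in PARAM_NAMES:
                row[f"true_{name}_{cond}"] = p.true_params[cond][name]
        rows.append(row)
    return pd.DataFrame(rows)


def write_dataset(dataset: CohortDataset, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    trials_frame(dataset).to_csv(path / "trials.csv", index=False)
    participants_frame(dataset).to_csv(path / "participants.csv", index=False)
    (path / "provenance.json").write_text(
        json.dumps(dataset.provenance, indent=2, sort_keys=True)
    )
    return path


def _decode_side(value, row: int, column: str) -> int:
    if value not in SIDE_CODES:
        raise ParseError(f"row {row}: {column} must be L or R, got {value!r}")
    return SIDE_CODES[value]


def _read_csv(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise ParseError(f"missing file {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError(
            f"{path.name} is empty; missing header columns {required}"
        ) from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path.name}: missing required columns {missing}")
    return df


def read_dataset(path: str | Path) -> CohortDataset:
    path = Path(path)
    trials = _read_csv(path / "trials.csv", TRIAL_COLUMNS)
    parts = _read_csv(
        path / "participants.csv", ["participant_id", "ocir_total"]
    )
    prov_path = path / "provenance.json"
    provenance = json.loads(prov_path.read_text()) if prov_path.exists() else {}

    participants = []
    for _, prow in parts.iterrows():
        pid = prow["participant_id"]
        ocir = int(prow["ocir_total"])
        if not (0 <= ocir <= 50):
            raise ParseError(f"participant {pid}: ocir_total {ocir} outside 0..50")
        dass = {
            k: (int(prow[f"dass_{k}"]) if pd.notna(prow.get(f"dass_{k}")) else None)
            for k in ("anxiety", "stress", "depression")
        }
        true_params = {}
        for cond in CONDITIONS:
            cols = {n: f"true_{n}_{cond}" for n in PARAM_NAMES}
            if all(c in prow.index and pd.notna(prow[c]) for c in cols.values()):
                true_params[cond] = {n: float(prow[c]) for n, c in cols.items()}

        blocks, responses = {}, {}
        sub = trials[trials["participant_id"] == pid]
        if sub.empty:
            raise ParseError(f"participant {pid} has no trial rows")
        for cond, grp in sub.groupby("condition", sort=False):
            grp = grp.sort_values("trial")
            n = len(grp)
            if list(grp["trial"]) != list(range(1, n + 1)):
                raise ParseError(
                    f"participant {pid}, condition {cond}: non-contiguous trials"
                )
            cues = np.empty((n, 3), dtype=np.int8)
            target = np.empty(n, dtype=np.int8)
            resp = np.empty(n, dtype=np.int8)
            relevant = np.empty(n, dtype=np.int8)
            valid = np.empty(n, dtype=bool)
            for i, (idx, row) in enumerate(grp.iterrows()):
                rownum = idx + 2  # header + 1-based
                for j, col in enumerate(("cue_top", "cue_mid", "cue_bot")):
                    cues[i, j] = _decode_side(row[col], rownum, col)
                target[i] = _decode_side(row["target"], rownum, "target")
                resp[i] = _decode_side(row["response"], rownum, "response")
                rc = int(row["relevant_cue"])
                if rc not in (1, 2, 3):
                    raise ParseError(f"row {rownum}: relevant_cue {rc} not in 1..3")
                relevant[i] = rc - 1
                valid[i] = bool(int(row["valid"]))
            blocks[cond] = TaskBlock(
                condition=cond,
                cues=cues,
                target=target,
                relevant_cue=relevant,
                valid=valid,
                shift_trial=int(grp["shift_trial"].iloc[0]),
                cue_validity=1.0 if cond == "deterministic" else 0.75,
            )
            responses[cond] = resp
        participants.append(
            Participant(
                id=pid,
                ocir=ocir,
                dass=dass,
                true_params=true_params,
                blocks=blocks,
                responses=responses,
            )
        )
    return CohortDataset(participants=participants, provenance=provenance)
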