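"""Patient-level three-way data partition with k-fold replication.

Splitting is done on patient identifiers, never on pixels or captures, so a
patient's images can never leak between training, validation and test — the
inter-patient validation setting. Each fold is an independent seeded random
60/20/20 partition of the roster.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

TRAIN_FRACTION = 0.6
VAL_FRACTION = 0.2


@dataclass
class FoldSpec:
    """One fold: disjoint patient-id sets covering the full roster."""

    fold_id: int
    train_patients: list[str]
    val_patients: list[str]
    test_patients: list[str]

    def __post_init__(self) -> None:
        tr, va, te = map(set, (self.train_patients, self.val_patients, self.test_patients))
        if tr & va or tr & te or va & te:
            raise ValueError(f"fold {self.fold_id}: splits overlap")
        if not (tr and va and te):
            raise ValueError(f"fold {self.fold_id}: every split needs >= 1 patient")

    def split_of(self, patient_id: str) -> str:
        for name, members in (
            ("train", self.train_patients),
            ("val", self.val_patients),
            ("test", self.test_patients),
        ):
            if patient_id in members:
                return name
        raise KeyError(patient_id)

    def to_dict(self) -> dict:
        return {
            "fold_id": self.fold_id,
            "train": list(self.train_patients),
            "val": list(self.val_patients),
            "test": list(self.test_patients),
        }


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def make_folds(
    roster: list[str], k: int = 5, seed: int | None = None
) -> list[FoldSpec]:
    """Draw ``k`` independent random 60/20/20 patient-level partitions.

    Sizes: train = round(0.6 m), val = round(0.2 m), test = remainder, each
    clamped to at least one patient. Deterministic given ``seed``.
    """
    roster = sorted(set(map(str, roster)))
    m = len(roster)
    if m < 5:
        raise ValueError(f"roster of {m} patients is too small (need >= 5)")
    n_train = max(1, _round_half_up(TRAIN_FRACTION * m))
    n_val = max(1, _round_half_up(VAL_FRACTION * m))
    if n_train + n_val >= m:  # keep at least one test patient
        n_train = m - n_val - 1
    rng = np.random.default_rng(seed)
    folds = []
    for fold_id in range(1, k + 1):
        perm = rng.permutation(m)
        ids = [roster[i] for i in perm]
        folds.append(
            FoldSpec(
                fold_id=fold_id,
                train_patients=sorted(ids[:n_train]),
                val_patients=sorted(ids[n_train : n_train + n_val]),
                test_patients=sorted(ids[n_train + n_val :]),
            )
        )
    return folds


def write_folds(folds: list[FoldSpec], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps([f.to_dict() for f in folds], indent=1))


def read_folds(path: str | Path) -> list[FoldSpec]:
    raw = json.loads(Path(path).read_text())
    return [
        FoldSpec(d["fold_id"], d["train"], d["val"], d["test"]) for d in raw
    ]
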