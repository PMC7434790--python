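"""Item bank, response recoding/scoring, and response-matrix I/O.

The scale modelled here is a 12-item polytomous questionnaire (the
traditional-Chinese Nonrestorative Sleep Scale, NRSS) in which most items
are answered on a 1-10 visual scale and collapsed to five scored
categories, two items are answered directly on 1-5, and six items are
reverse coded so that a higher total score always means more restorative
sleep.  Everything scale-specific (raw ranges, reverse flags, content
domains) lives in :class:`ItemDefinition` records so other instruments can
be described by the same machinery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ItemDefinition",
    "ResponseMatrix",
    "ValidationError",
    "default_bank",
    "recode_raw",
    "recode_matrix",
    "total_score",
    "read_responses",
    "write_responses",
    "load_bank",
    "save_bank",
]


class ValidationError(ValueError):
    """Raised when responses or bank definitions violate their contracts."""


@dataclass(frozen=True)
class ItemDefinition:
    """Definition of a single polytomous item.

    Parameters
    ----------
    item_id : str
        Short label, e.g. ``"Q1"``.
    n_raw_categories : int
        Number of response options on the administered form (10 or 5 for
        the NRSS).
    n_scored_categories : int
        Number of scored categories after collapsing (5 for the NRSS).
    reverse_coded : bool
        If True, scored category ``s`` is mapped to ``K + 1 - s``.
    domain : str
        Content domain the item belongs to.
    text : str
        Free-text item stem (informational only).
    """

    item_id: str
    n_raw_categories: int = 10
    n_scored_categories: int = 5
    reverse_coded: bool = False
    domain: str = ""
    text: str = ""

    def __post_init__(self) -> None:
        if self.n_scored_categories < 2:
            raise ValidationError(
                f"{self.item_id}: need at least 2 scored categories"
            )
        if self.n_raw_categories < self.n_scored_categories:
            raise ValidationError(
                f"{self.item_id}: raw categories ({self.n_raw_categories}) "
                f"fewer than scored ({self.n_scored_categories})"
            )


# Content domains of the 12-item NRSS.  Which six items are reverse coded
# and which two items use the raw 1-5 scale are not pinned down by the
# instrument's published scoring description; the defaults below (symptom
# items Q4-Q7, Q11, Q12 reversed; Q4 and Q5 on 1-5) are the package's
# documented assumption and can be overridden by supplying a bank file.
_DEFAULT_BANK_SPEC = [
    ("Q1", "refreshment", False, 10, "rate the quality of your sleep"),
    ("Q2", "refreshment", False, 10, "sleep is restoring or refreshing?"),
    ("Q3", "refreshment", False, 10,
     "felt rested if you've slept for your usual amount of time?"),
    ("Q4", "symptoms", True, 5,
     "had physical sensations or unusual feelings?"),
    ("Q5", "symptoms", True, 5,
     "headaches, body pain, numbness, or tingling?"),
    ("Q6", "symptoms", True, 10,
     "physical or medical problems are dragging you down?"),
    ("Q7", "symptoms", True, 10,
     "have a sense of panic, or physical symptoms of panic?"),
    ("Q8", "daytime", False, 10, "memory and concentration?"),
    ("Q9", "daytime", False, 10, "level of daytime energy?"),
    ("Q10", "daytime", False, 10, "alert during the daytime?"),
    ("Q11", "affective", True, 10,
     "depressed or down if you didn't sleep well?"),
    ("Q12", "affective", True, 10,
     "irritable or 'gotten the blahs' if you didn't sleep well"),
]


def default_bank() -> list[ItemDefinition]:
    """The shipped 12-item NRSS bank (see module docstring for caveats)."""
    return [
        ItemDefinition(item_id=iid, n_raw_categories=nraw,
                       n_scored_categories=5, reverse_coded=rev,
                       domain=dom, text=text)
        for iid, dom, rev, nraw, text in _DEFAULT_BANK_SPEC
    ]


def recode_raw(raw_value: int, item: ItemDefinition) -> int:
    """Map a raw response onto the scored 1..K scale.

    Adjacent raw options on a wide (e.g. 1-10) scale are collapsed in
    pairs (ceil(raw/2)); items already on the scored scale pass through.
    Reverse-coded items are then flipped, ``s -> K + 1 - s``.
    """
    if not (1 <= raw_value <= item.n_raw_categories):
        raise ValidationError(
            f"{item.item_id}: raw value {raw_value} outside "
            f"1..{item.n_raw_categories}"
        )
    if item.n_raw_categories == item.n_scored_categories:
        scored = int(raw_value)
    else:
        per = item.n_raw_categories // item.n_scored_categories
        scored = int(-(-raw_value // per))  # ceiling division
    if item.reverse_coded:
        scored = item.n_scored_categories + 1 - scored
    return scored


def recode_matrix(raw: np.ndarray, bank: Sequence[ItemDefinition]) -> np.ndarray:
    """Vectorised :func:`recode_raw` over a persons x items raw matrix."""
    raw = np.asarray(raw)
    if raw.ndim != 2 or raw.shape[1] != len(bank):
        raise ValidationError("raw matrix shape does not match bank")
    out = np.empty_like(raw, dtype=int)
    for j, item in enumerate(bank):
        col = raw[:, j]
        bad = (col < 1) | (col > item.n_raw_categories)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"{item.item_id}: raw value {col[row]} at row {row} outside "
                f"1..{item.n_raw_categories}"
            )
        if item.n_raw_categories == item.n_scored_categories:
            scored = col.astype(int)
        else:
            per = item.n_raw_categories // item.n_scored_categories
            scored = -(-col // per)
        if item.reverse_coded:
            scored = item.n_scored_categories + 1 - scored
        out[:, j] = scored
    return out


@dataclass
class ResponseMatrix:
    """Persons x items matrix of scored categories plus metadata.

    ``values`` holds scored categories on the external 1..K scale; the
    :attr:`codes` view (0..K-1) is what the IRT machinery consumes.
    """

    values: np.ndarray
    bank: list[ItemDefinition]
    group: Optional[np.ndarray] = None
    criterion: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if self.values.ndim != 2:
            raise ValidationError("values must be 2-D (persons x items)")
        if self.values.shape[0] < 1:
            raise ValidationError("need at least one person")
        if self.values.shape[1] != len(self.bank):
            raise ValidationError(
                f"{self.values.shape[1]} columns but bank has "
                f"{len(self.bank)} items"
            )
        for j, item in enumerate(self.bank):
            col = self.values[:, j]
            bad = (col < 1) | (col > item.n_scored_categories)
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"{item.item_id}: scored value {col[row]} at row {row} "
                    f"outside 1..{item.n_scored_categories}"
                )
        if self.group is not None:
            self.group = np.asarray(self.group)
            if len(self.group) != self.n_persons:
                raise ValidationError("group length != number of persons")
            if len(np.unique(self.group)) < 2:
                raise ValidationError("group must have at least 2 levels")
        if self.criterion is not None:
            self.criterion = np.asarray(self.criterion, dtype=float)
            if len(self.criterion) != self.n_persons:
                raise ValidationError("criterion length != number of persons")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.bank]

    @property
    def codes(self) -> np.ndarray:
        """0-based category codes used internally by the GPCM."""
        return self.values - 1

    def column(self, item_id: str) -> int:
        try:
            return self.item_ids.index(item_id)
        except ValueError:
            raise KeyError(f"unknown item id {item_id!r}") from None

    def subset(self, item_ids: Sequence[str]) -> "ResponseMatrix":
        """A new matrix restricted to ``item_ids`` (order preserved)."""
        cols = [self.column(i) for i in item_ids]
        return ResponseMatrix(
            values=self.values[:, cols],
            bank=[self.bank[c] for c in cols],
            group=self.group,
            criterion=self.criterion,
        )


def total_score(matrix: ResponseMatrix, subset: Optional[Sequence[str]] = None
                ) -> np.ndarray:
    """Per-person summed score over ``subset`` (default: all items)."""
    ids = list(subset) if subset is not None else matrix.item_ids
    if not ids:
        raise ValidationError("subset must be non-empty")
    cols = [matrix.column(i) for i in ids]
    return matrix.values[:, cols].sum(axis=1)


def read_responses(path: str | Path, bank: Sequence[ItemDefinition],
                   drop_missing: bool = False) -> ResponseMatrix:
    """Read a scored response CSV (one column per item id).

    Optional ``group`` and ``criterion`` columns are picked up when
    present.  Missing values are rejected unless ``drop_missing`` asks for
    listwise deletion.
    """
    df = pd.read_csv(path)
    ids = [it.item_id for it in bank]
    missing_cols = [i for i in ids if i not in df.columns]
    if missing_cols:
        raise ValidationError(f"CSV missing item columns: {missing_cols}")
    sub = df[ids]
    if sub.isna().any().any():
        if drop_missing:
            keep = ~sub.isna().any(axis=1)
            df = df.loc[keep]
            sub = df[ids]
        else:
            raise ValidationError(
                "missing values present; pass drop_missing=True for "
                "listwise deletion"
            )
    arr = sub.to_numpy()
    if not np.all(np.equal(np.mod(arr, 1), 0)):
        raise ValidationError("non-integer response values in CSV")
    group = df["group"].to_numpy() if "group" in df.columns else None
    criterion = (df["criterion"].to_numpy(dtype=float)
                 if "criterion" in df.columns else None)
    return ResponseMatrix(values=arr.astype(int), bank=list(bank),
                          group=group, criterion=criterion)


def write_responses(matrix: ResponseMatrix, path: str | Path) -> None:
    """Write a response matrix to CSV (round-trips with read_responses)."""
    df = pd.DataFrame(matrix.values, columns=matrix.item_ids)
    if matrix.group is not None:
        df["group"] = matrix.group
    if matrix.criterion is not None:
        crit = matrix.criterion
        if np.allclose(crit, np.round(crit)):
            crit = crit.astype(int)
        df["criterion"] = crit
    df.to_csv(path, index=False)


def save_bank(bank: Sequence[ItemDefinition], path: str | Path) -> None:
    """Serialise a bank to JSON or YAML (by extension)."""
    records = [asdict(it) for it in bank]
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(records, sort_keys=False))
    else:
        path.write_text(json.dumps(records, indent=1))


def load_bank(path: str | Path) -> list[ItemDefinition]:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        records = yaml.safe_load(text)
    else:
        records = json.loads(text)
    return [ItemDefinition(**r) for r in records]
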