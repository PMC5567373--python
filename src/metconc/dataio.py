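"""Reading, writing, transforming and splitting metabolite concentration data.

The modelled response throughout the package is ``-logC``: the negative
base-10 logarithm of an intracellular concentration expressed in mol/L.
A :class:`Dataset` is an ordered collection of metabolite x organism
records, each carrying the concentration and/or its ``-logC`` transform
plus a train/test split label.

Files are plain TSV with the literal ``NA`` for missing values.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

NA = "NA"
SPLIT_LABELS = ("train", "test", "unassigned")

__all__ = [
    "MetaboliteRecord",
    "Dataset",
    "neg_log_transform",
    "split_random",
    "split_non_overlap",
    "read_metabolite_table",
    "write_metabolite_table",
    "row_key",
    "write_manifest",
]


def neg_log_transform(concentration: float) -> float:
    """Return ``-log10`` of a molar concentration.

    Parameters
    ----------
    concentration : float
        Intracellular concentration in mol/L; must be a positive, finite
        real number.

    Raises
    ------
    ValueError
        If the concentration is missing, non-finite or not strictly
        positive.
    """
    if concentration is None or (isinstance(concentration, float) and math.isnan(concentration)):
        raise ValueError("concentration is missing; cannot compute -logC")
    c = float(concentration)
    if not math.isfinite(c) or c <= 0.0:
        raise ValueError(f"concentration must be a positive finite value in mol/L, got {concentration!r}")
    return -math.log10(c)


@dataclass
class MetaboliteRecord:
    """One metabolite in one organism.

    At least one of ``concentration`` (mol/L) and ``neg_log_c`` must be
    present for a record used in modelling; when both are given they must
    agree to 1e-9. A missing value is represented by ``None``.
    """

    metabolite_id: str
    name: str = ""
    organism: str = ""
    concentration: float | None = None
    neg_log_c: float | None = None
    split: str = "unassigned"

    def __post_init__(self) -> None:
        if not self.metabolite_id:
            raise ValueError("metabolite_id must be non-empty")
        if self.split not in SPLIT_LABELS:
            raise ValueError(f"split must be one of {SPLIT_LABELS}, got {self.split!r}")
        if self.concentration is not None:
            if self.concentration <= 0 or not math.isfinite(self.concentration):
                raise ValueError(
                    f"{self.metabolite_id}: concentration must be positive, got {self.concentration!r}"
                )
            derived = neg_log_transform(self.concentration)
            if self.neg_log_c is None:
                self.neg_log_c = derived
            elif abs(self.neg_log_c - derived) > 1e-9:
                raise ValueError(
                    f"{self.metabolite_id}: neg_log_c={self.neg_log_c} inconsistent with "
                    f"-log10(concentration)={derived}"
                )

    @property
    def key(self) -> tuple[str, str]:
        return (self.metabolite_id, self.organism)


def row_key(metabolite_id: str, organism: str) -> str:
    """Canonical string key for a metabolite x organism row."""
    return f"{metabolite_id}:{organism}"


@dataclass
class Dataset:
    """Ordered collection of :class:`MetaboliteRecord` with provenance."""

    records: list[MetaboliteRecord] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.records]
        if len(keys) != len(set(keys)):
            seen: set[tuple[str, str]] = set()
            dupes = sorted({k for k in keys if k in seen or seen.add(k)})
            raise ValueError(f"duplicate metabolite_id/organism pairs: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MetaboliteRecord]:
        return iter(self.records)

    def subset(self, split: str) -> "Dataset":
        if split not in SPLIT_LABELS:
            raise ValueError(f"unknown split label {split!r}")
        return Dataset([r for r in self.records if r.split == split], dict(self.provenance))

    @property
    def train(self) -> "Dataset":
        return self.subset("train")

    @property
    def test(self) -> "Dataset":
        return self.subset("test")

    def row_keys(self) -> list[str]:
        return [row_key(r.metabolite_id, r.organism) for r in self.records]

    def neg_log_c(self) -> pd.Series:
        """Response vector indexed by row key (missing values as NaN)."""
        return pd.Series(
            [r.neg_log_c if r.neg_log_c is not None else np.nan for r in self.records],
            index=self.row_keys(),
            name="neg_log_c",
            dtype=float,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metabolite_id": [r.metabolite_id for r in self.records],
                "name": [r.name for r in self.records],
                "organism": [r.organism for r in self.records],
                "concentration_molar": [r.concentration for r in self.records],
                "neg_log_c": [r.neg_log_c for r in self.records],
                "split": [r.split for r in self.records],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: dict | None = None) -> "Dataset":
        records = []
        for row in frame.itertuples(index=False):
            conc = getattr(row, "concentration_molar", None)
            nlc = getattr(row, "neg_log_c", None)
            records.append(
                MetaboliteRecord(
                    metabolite_id=str(row.metabolite_id),
                    name=str(getattr(row, "name", "") or ""),
                    organism=str(getattr(row, "organism", "") or ""),
                    concentration=None if conc is None or pd.isna(conc) else float(conc),
                    neg_log_c=None if nlc is None or pd.isna(nlc) else float(nlc),
                    split=str(getattr(row, "split", "unassigned") or "unassigned"),
                )
            )
        return cls(records, provenance or {})


def write_metabolite_table(dataset: Dataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path, sep="\t", index=False, na_rep=NA)


def read_metabolite_table(path: str | Path) -> Dataset:
    frame = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    required = {"metabolite_id", "organism"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return Dataset.from_frame(frame, provenance={"source": str(path)})


def _assign(dataset: Dataset, train_keys: set[tuple[str, str]]) -> Dataset:
    records = [
        replace(r, split="train" if r.key in train_keys else "test") for r in dataset.records
    ]
    return Dataset(records, dict(dataset.provenance))


def split_random(dataset: Dataset, n_train: int, seed: int) -> Dataset:
    """Random, unstratified train/test partition.

    Exactly ``n_train`` records are labelled ``train`` and the remainder
    ``test``; the same seed always yields the same partition.
    """
    n = len(dataset)
    if n_train <= 0 or n_train >= n:
        raise ValueError(f"n_train must be in (0, {n}), got {n_train}")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)[:n_train]
    train_keys = {dataset.records[i].key for i in idx}
    out = _assign(dataset, train_keys)
    out.provenance.update({"split": "random", "n_train": n_train, "split_seed": seed})
    return out


def split_non_overlap(dataset: Dataset, n_train_target: int, seed: int) -> Dataset:
    """Partition keeping all records of a shared metabolite on one side.

    Records sharing a ``metabolite_id`` (the same compound measured in
    several organisms) are assigned as a block, so the test set never
    contains a compound also present in training. Blocks are placed
    greedily by descending size (seeded shuffle breaks ties) on whichever
    side keeps the train count closest to ``n_train_target``.
    """
    n = len(dataset)
    if n_train_target <= 0 or n_train_target >= n:
        raise ValueError(f"n_train_target must be in (0, {n}), got {n_train_target}")
    groups: dict[str, list[MetaboliteRecord]] = {}
    for r in dataset.records:
        groups.setdefault(r.metabolite_id, []).append(r)
    n_test_target = n - n_train_target
    for mid, members in groups.items():
        if len(members) > max(n_train_target, n_test_target):
            raise ValueError(
                f"group {mid!r} has {len(members)} records, larger than both sides "
                f"({n_train_target}/{n_test_target}); non-overlap split impossible"
            )
    rng = np.random.default_rng(seed)
    order = list(groups)
    rng.shuffle(order)
    order.sort(key=lambda mid: -len(groups[mid]))  # stable: shuffle breaks size ties

    train_keys: set[tuple[str, str]] = set()
    n_train = n_test = 0
    for mid in order:
        size = len(groups[mid])
        # place on the side that keeps the achieved train size nearest target
        go_train = abs(n_train + size - n_train_target) < abs(n_train - n_train_target) or (
            abs(n_train + size - n_train_target) == abs(n_train - n_train_target)
            and n_train <= n_test
        )
        if go_train:
            train_keys.update(r.key for r in groups[mid])
            n_train += size
        else:
            n_test += size
    if n_train == 0 or n_test == 0:
        # degenerate greedy outcome; move the smallest group to the empty side
        mid = order[-1]
        if n_train == 0:
            train_keys.update(r.key for r in groups[mid])
        else:
            train_keys.difference_update(r.key for r in groups[mid])
    out = _assign(dataset, train_keys)
    out.provenance.update(
        {"split": "non_overlap", "n_train_target": n_train_target, "split_seed": seed}
    )
    return out


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    *,
    inputs: Iterable[str | Path] = (),
    seeds: dict | None = None,
    counts: dict | None = None,
    extra: dict | None = None,
) -> dict:
    """Write a JSON run-manifest (input hashes, seeds, counts) and return it."""
    import metconc

    manifest = {
        "metconc_version": metconc.__version__,
        "inputs": {str(p): _sha256(p) for p in inputs if Path(p).exists()},
        "seeds": seeds or {},
        "counts": counts or {},
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
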