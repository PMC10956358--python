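"""Domain types, activity-unit conversion, dataset partitioning, and CSV I/O.

Activity conventions
--------------------
IC50 values are nanomolar; pIC50 is the negative base-10 logarithm of the
*molar* concentration, hence ``pic50 = 9 - log10(ic50_nM)``.  Inputs in other
units must be converted by the caller before construction.

CSV conventions
---------------
Comma-separated, UTF-8, ``.`` decimal, header row required.  A QSAR dataset
table has an ``id`` column, an activity column (``pic50`` and/or ``ic50_nM``),
an optional ``set`` column (``train``/``test``), and one numeric column per
descriptor.  Missing cells are rejected, never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Compound",
    "QSARDataset",
    "ActivityLabel",
    "pic50_from_ic50",
    "ic50_from_pic50",
    "split_dataset",
    "read_qsar_csv",
    "write_qsar_csv",
    "read_property_csv",
]

_RESERVED_COLUMNS = {"id", "pic50", "ic50_nM", "set"}


def pic50_from_ic50(ic50_nM: float) -> float:
    """Convert a nanomolar IC50 to pIC50 (``9 - log10(ic50_nM)``).

    Raises
    ------
    ValueError
        If ``ic50_nM`` is non-positive or non-finite.
    """
    ic50_nM = float(ic50_nM)
    if not math.isfinite(ic50_nM) or ic50_nM <= 0:
        raise ValueError(f"IC50 must be a positive finite value in nM, got {ic50_nM!r}")
    return 9.0 - math.log10(ic50_nM)


def ic50_from_pic50(pic50: float) -> float:
    """Inverse of :func:`pic50_from_ic50`: nanomolar IC50 from pIC50."""
    pic50 = float(pic50)
    if not math.isfinite(pic50):
        raise ValueError(f"pIC50 must be finite, got {pic50!r}")
    return 10.0 ** (9.0 - pic50)


@dataclass
class Compound:
    """One compound: identifier, activity, and an ordered descriptor map."""

    id: str
    descriptors: dict[str, float]
    pic50: float | None = None
    ic50_nM: float | None = None

    def __post_init__(self) -> None:
        if self.ic50_nM is not None:
            if not math.isfinite(self.ic50_nM) or self.ic50_nM <= 0:
                raise ValueError(
                    f"compound {self.id!r}: IC50 must be positive, got {self.ic50_nM!r}"
                )
            implied = pic50_from_ic50(self.ic50_nM)
            if self.pic50 is None:
                self.pic50 = implied
            elif abs(self.pic50 - implied) > 1e-9:
                raise ValueError(
                    f"compound {self.id!r}: pic50={self.pic50} inconsistent with "
                    f"ic50_nM={self.ic50_nM} (implies {implied})"
                )
        for name, value in self.descriptors.items():
            if not math.isfinite(value):
                raise ValueError(
                    f"compound {self.id!r}: descriptor {name!r} is not finite"
                )


@dataclass
class ActivityLabel:
    """Binary activity call at a strict pIC50 threshold."""

    id: str
    active: bool
    threshold: float = 6.5

    @classmethod
    def from_pic50(cls, id: str, pic50: float, threshold: float = 6.5) -> "ActivityLabel":
        return cls(id=id, active=pic50 > threshold, threshold=threshold)


@dataclass
class QSARDataset:
    """Compounds x descriptors x activities with an optional train/test partition."""

    compounds: list[Compound]
    descriptor_names: list[str]
    partition: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.compounds]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate compound ids: {dupes}")
        if len(set(self.descriptor_names)) != len(self.descriptor_names):
            raise ValueError("descriptor names must be unique")
        for c in self.compounds:
            missing = [d for d in self.descriptor_names if d not in c.descriptors]
            if missing:
                raise ValueError(f"compound {c.id!r} missing descriptors {missing}")
        for pid, label in self.partition.items():
            if pid not in set(ids):
                raise ValueError(f"partition references unknown id {pid!r}")
            if label not in ("train", "test"):
                raise ValueError(f"partition label must be train/test, got {label!r}")

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.compounds]

    @property
    def n(self) -> int:
        return len(self.compounds)

    @property
    def p(self) -> int:
        return len(self.descriptor_names)

    def X(self, subset: str | None = None) -> np.ndarray:
        """Descriptor matrix (n x p) for all compounds or one partition side."""
        rows = self._select(subset)
        return np.array(
            [[c.descriptors[d] for d in self.descriptor_names] for c in rows],
            dtype=float,
        ).reshape(len(rows), len(self.descriptor_names))

    def y(self, subset: str | None = None) -> np.ndarray:
        rows = self._select(subset)
        vals = []
        for c in rows:
            if c.pic50 is None:
                raise ValueError(f"compound {c.id!r} has no activity value")
            vals.append(c.pic50)
        return np.array(vals, dtype=float)

    def subset_ids(self, subset: str) -> list[str]:
        return [c.id for c in self._select(subset)]

    def _select(self, subset: str | None) -> list[Compound]:
        if subset is None:
            return self.compounds
        if subset not in ("train", "test"):
            raise ValueError(f"subset must be 'train' or 'test', got {subset!r}")
        if not self.partition:
            raise ValueError("dataset has no partition; call split_dataset first")
        return [c for c in self.compounds if self.partition.get(c.id) == subset]


def split_dataset(
    dataset: QSARDataset,
    test_ids: list[str] | None = None,
    n_test: int | None = None,
    seed: int | None = None,
) -> QSARDataset:
    """Assign every compound to train or test.

    Either pass explicit ``test_ids`` (honored verbatim) or ``n_test`` with a
    ``seed`` for reproducible uniform sampling without replacement.  Returns a
    new dataset; the input is not mutated.
    """
    ids = dataset.ids
    if test_ids is not None:
        if n_test is not None:
            raise ValueError("pass either test_ids or n_test, not both")
        if len(set(test_ids)) != len(test_ids):
            raise ValueError("duplicate ids in test_ids")
        unknown = [t for t in test_ids if t not in set(ids)]
        if unknown:
            raise ValueError(f"unknown ids in test_ids: {unknown}")
        if len(test_ids) >= len(ids):
            raise ValueError("test set must be smaller than the dataset")
        chosen = list(test_ids)
    else:
        if n_test is None:
            raise ValueError("pass test_ids or n_test")
        if n_test >= len(ids):
            raise ValueError(f"n_test={n_test} must be < n={len(ids)}")
        if n_test < 0:
            raise ValueError("n_test must be non-negative")
        rng = np.random.default_rng(seed)
        chosen = [ids[i] for i in sorted(rng.choice(len(ids), size=n_test, replace=False))]
    partition = {i: ("test" if i in set(chosen) else "train") for i in ids}
    return QSARDataset(
        compounds=list(dataset.compounds),
        descriptor_names=list(dataset.descriptor_names),
        partition=partition,
    )


def read_qsar_csv(path) -> QSARDataset:
    """Read a QSAR dataset CSV (see module docstring for the column layout)."""
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    if "id" not in df.columns:
        raise ValueError("missing required column 'id'")
    if "pic50" not in df.columns and "ic50_nM" not in df.columns:
        raise ValueError("missing activity column: need 'pic50' or 'ic50_nM'")
    if df["id"].duplicated().any():
        dupes = sorted(df.loc[df["id"].duplicated(), "id"].unique().tolist())
        raise ValueError(f"duplicate compound ids: {dupes}")
    descriptor_names = [c for c in df.columns if c not in _RESERVED_COLUMNS]
    for col in descriptor_names + [c for c in ("pic50", "ic50_nM") if c in df.columns]:
        if df[col].isna().any():
            rows = df.index[df[col].isna()].tolist()
            raise ValueError(f"missing value in column {col!r} at rows {rows}")
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"non-numeric value in column {col!r}")
    compounds = []
    for _, row in df.iterrows():
        compounds.append(
            Compound(
                id=str(row["id"]),
                descriptors={d: float(row[d]) for d in descriptor_names},
                pic50=float(row["pic50"]) if "pic50" in df.columns else None,
                ic50_nM=float(row["ic50_nM"]) if "ic50_nM" in df.columns else None,
            )
        )
    partition = {}
    if "set" in df.columns:
        partition = {str(r["id"]): str(r["set"]) for _, r in df.iterrows()}
    return QSARDataset(compounds, descriptor_names, partition)


def write_qsar_csv(dataset: QSARDataset, path) -> None:
    """Write a dataset so that ``read_qsar_csv`` round-trips it exactly."""
    records = []
    for c in dataset.compounds:
        rec: dict[str, object] = {"id": c.id}
        if c.pic50 is not None:
            rec["pic50"] = repr(c.pic50)
        if c.ic50_nM is not None:
            rec["ic50_nM"] = repr(c.ic50_nM)
        for d in dataset.descriptor_names:
            rec[d] = repr(c.descriptors[d])
        if dataset.partition:
            rec["set"] = dataset.partition[c.id]
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def read_property_csv(path, required: list[str] | None = None) -> pd.DataFrame:
    """Read a generic per-compound property table keyed by ``id``."""
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    if "id" not in df.columns:
        raise ValueError("missing required column 'id'")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
    if df["id"].duplicated().any():
        raise ValueError("duplicate ids in property table")
    return df
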