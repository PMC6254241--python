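"""Reading, aggregating and writing mass-at-age data.

Raw inputs are one row per fish (age in years from otoliths, mass in grams).
Fitting operates on class averages: per age class the mean age, mean mass and
class size.  Age classes with few fish can be merged into contiguous groups
so that each class average rests on a reasonable sample; the bundled Walleye
table (male *Sander vitreus*, Lake Erie) is the canonical example, with 13
classes aggregated from 20,166 fish and the old-age classes merged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "MergeSpec",
    "identity_merge",
    "read_raw_records",
    "aggregate_classes",
    "table1_fixture",
    "walleye_table1",
    "WALLEYE_MERGE",
    "write_results",
    "read_results",
]


@dataclass(frozen=True)
class Dataset:
    """Ordered mass-at-age class averages with class sizes.

    ages   : mean age per class (years), strictly increasing
    masses : mean mass per class (grams)
    sizes  : number of fish per class
    """

    ages: np.ndarray
    masses: np.ndarray
    sizes: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "ages", np.asarray(self.ages, dtype=float))
        object.__setattr__(self, "masses", np.asarray(self.masses, dtype=float))
        object.__setattr__(self, "sizes", np.asarray(self.sizes, dtype=int))
        if not (self.ages.shape == self.masses.shape == self.sizes.shape):
            raise ValueError("ages, masses and sizes must have equal length")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("class ages must be strictly increasing")
        if np.any(self.sizes < 1):
            raise ValueError("class sizes must be >= 1")
        if np.any(self.masses <= 0):
            raise ValueError("class mean masses must be positive")

    @property
    def n_classes(self) -> int:
        return len(self.ages)

    def __len__(self) -> int:
        return self.n_classes

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "") -> "Dataset":
        """Build from a frame with columns age, mass and (optionally) size."""
        sizes = df["size"] if "size" in df.columns else np.ones(len(df), dtype=int)
        return cls(df["age"].to_numpy(), df["mass"].to_numpy(), np.asarray(sizes), label)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "mass": self.masses, "size": self.sizes})


class MergeSpec:
    """Ordered grouping of integer age classes into output classes.

    Each group is a contiguous run of integer ages mapped onto one output
    class; groups must be disjoint and together cover every age class present
    in the records being aggregated.
    """

    def __init__(self, groups: Iterable[Sequence[int]]):
        self.groups = [tuple(int(x) for x in g) for g in groups]
        seen: set[int] = set()
        for g in self.groups:
            if len(g) == 0:
                raise ValueError("empty merge group")
            if list(g) != list(range(g[0], g[-1] + 1)):
                raise ValueError(f"merge group {g} is not a contiguous age run")
            if seen & set(g):
                raise ValueError(f"merge group {g} overlaps a previous group")
            seen |= set(g)

    def covers(self, ages: Iterable[int]) -> bool:
        members = set().union(*(set(g) for g in self.groups))
        return set(int(a) for a in ages) <= members

    def __iter__(self):
        return iter(self.groups)

    def __len__(self) -> int:
        return len(self.groups)


def identity_merge(ages: Iterable[int]) -> MergeSpec:
    """One output class per distinct integer age."""
    return MergeSpec([(int(a),) for a in sorted(set(int(a) for a in ages))])


#: Class grouping used for the Walleye table: ages 0-8 kept as single classes,
#: 9+10 merged, 11 kept, 12+13 merged, 14-20 merged.
WALLEYE_MERGE = MergeSpec(
    [(i,) for i in range(9)] + [(9, 10), (11,), (12, 13), tuple(range(14, 21))]
)


def read_raw_records(path: str | Path) -> pd.DataFrame:
    """Read a raw age-mass CSV (columns ``age``, ``mass``; extras ignored).

    Validates that ages are non-negative and masses strictly positive,
    naming the offending row on failure.
    """
    df = pd.read_csv(path)
    missing = {"age", "mass"} - set(df.columns)
    if missing:
        raise ValueError(f"raw records file {path} lacks columns: {sorted(missing)}")
    records = df[["age", "mass"]].copy()
    for col in ("age", "mass"):
        coerced = pd.to_numeric(records[col], errors="coerce")
        bad = coerced.isna() & records[col].notna() | records[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(f"non-numeric {col} in data row {row} of {path}")
        records[col] = coerced.astype(float)
    if (records["age"] < 0).any():
        row = int(np.flatnonzero(records["age"] < 0)[0])
        raise ValueError(f"negative age in data row {row} of {path}")
    if (records["mass"] <= 0).any():
        row = int(np.flatnonzero(records["mass"] <= 0)[0])
        raise ValueError(f"non-positive mass in data row {row} of {path}")
    return records


def aggregate_classes(records: pd.DataFrame, merge: MergeSpec) -> Dataset:
    """Pivot raw records into class averages under a merge specification.

    For each output class the mean age and mean mass are arithmetic means over
    all member records (so merged classes get record-weighted fractional mean
    ages), and the class size is the member count.
    """
    ages = records["age"].to_numpy(dtype=float)
    masses = records["mass"].to_numpy(dtype=float)
    age_class = np.rint(ages).astype(int)
    if not merge.covers(age_class):
        uncovered = sorted(set(age_class) - set().union(*(set(g) for g in merge)))
        raise ValueError(f"age classes {uncovered} not covered by merge spec")
    out_age, out_mass, out_size = [], [], []
    for group in merge:
        mask = np.isin(age_class, group)
        n = int(mask.sum())
        if n == 0:
            continue
        out_age.append(ages[mask].mean())
        out_mass.append(masses[mask].mean())
        out_size.append(n)
    order = np.argsort(out_age)
    return Dataset(
        np.asarray(out_age)[order],
        np.asarray(out_mass)[order],
        np.asarray(out_size)[order],
    )


# Average weight-at-age for male Walleye (Sander vitreus), Lake Erie:
# 13 classes aggregated from 20,166 fish; masses printed to one decimal.
_WALLEYE_ROWS = [
    (0.0, 192.1, 14),
    (1.0, 423.7, 4009),
    (2.0, 761.8, 5181),
    (3.0, 1018.0, 3870),
    (4.0, 1221.6, 2262),
    (5.0, 1442.8, 1519),
    (6.0, 1644.5, 1471),
    (7.0, 1802.0, 690),
    (8.0, 1880.7, 446),
    (9.5, 1895.3, 430),  # classes 9 + 10
    (11.0, 1982.6, 105),
    (12.4, 2140.4, 104),  # classes 12 + 13
    (15.3, 2228.5, 65),  # classes 14-20
]


def table1_fixture() -> Dataset:
    """The bundled Walleye class-average table (13 classes, N fish = 20,166)."""
    ages, masses, sizes = zip(*_WALLEYE_ROWS)
    return Dataset(np.array(ages), np.array(masses), np.array(sizes), label="walleye")


# Preferred public alias; `table1_fixture` is kept for symmetry with the
# tabular origin of the data.
walleye_table1 = table1_fixture


def write_results(results, path: str | Path) -> None:
    """Write fit results as CSV with columns a,b,m0,p,q,SSR,m_max.

    ``results`` is an iterable of fit results (anything exposing ``pair``,
    ``params`` and ``sse``).  An infinite asymptotic mass (q == 0, unbounded
    growth) is serialized as an empty cell.
    """
    from .growth import asymptotic_mass

    results = list(results)
    if not results:
        raise ValueError("no results to write")
    rows = []
    for r in results:
        mmax = asymptotic_mass(r.pair, r.params)
        rows.append(
            {
                "a": r.pair.a,
                "b": r.pair.b,
                "m0": r.params.m0,
                "p": r.params.p,
                "q": r.params.q,
                "SSR": r.sse,
                "m_max": mmax if math.isfinite(mmax) else np.nan,
            }
        )
    pd.DataFrame(rows, columns=["a", "b", "m0", "p", "q", "SSR", "m_max"]).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results CSV written by :func:`write_results`."""
    return pd.read_csv(path)
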