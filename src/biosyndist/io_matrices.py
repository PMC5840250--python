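"""Input/output for the matrix and tree artifacts of the pipeline.

Three tabular kinds are handled, all as labelled CSV (UTF-8, ``.`` decimal,
``,`` or ``;`` delimited, auto-detected):

* sample × compound quantity matrices (rows = samples by default),
* compound × feature presence/absence matrices (features are enzymes,
  chemical classes, functional groups, ...),
* square labelled distance matrices.

Trees are serialized as Newick with branch lengths; leaf labels such as
``(E)-β-ocimene`` that contain Newick metacharacters are quoted so an
independent parser recovers them verbatim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .biosyn_tree import BiosynTree

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "SampleCompoundMatrix",
    "CompoundFeatureMatrix",
    "DistanceMatrix",
    "read_sample_matrix",
    "read_feature_matrix",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_newick",
    "write_newick",
    "align_compounds",
]


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


def _check_unique(labels: Sequence[str], what: str) -> list[str]:
    labels = [str(x) for x in labels]
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate {what} label: {lab!r}")
        seen.add(lab)
    return labels


@dataclass
class SampleCompoundMatrix:
    """Quantities (or 0/1 presences) of each compound in each sample.

    Rows are samples, columns compounds; absent compounds are 0.  Every
    sample must contain at least one compound (a profile with nothing in it
    has no defined composition).
    """

    sample_ids: list[str]
    compound_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.compound_ids = _check_unique(self.compound_ids, "compound")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.compound_ids)):
            raise ValidationError(
                f"value block has shape {self.values.shape}, expected "
                f"({len(self.sample_ids)}, {len(self.compound_ids)})"
            )
        if np.isnan(self.values).any():
            i, j = np.argwhere(np.isnan(self.values))[0]
            raise ValidationError(
                f"non-numeric entry at sample {self.sample_ids[i]!r}, "
                f"compound {self.compound_ids[j]!r}"
            )
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative quantity at sample {self.sample_ids[i]!r}, "
                f"compound {self.compound_ids[j]!r}: {self.values[i, j]}"
            )
        empty = np.flatnonzero(self.values.sum(axis=1) == 0)
        if empty.size:
            raise ValidationError(
                f"sample {self.sample_ids[empty[0]]!r} contains no compound "
                "(all entries zero)"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.compound_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleCompoundMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def select_compounds(self, compound_ids: Sequence[str]) -> "SampleCompoundMatrix":
        """Restrict to (and reorder by) the given compounds."""
        df = self.to_frame()
        missing = [c for c in compound_ids if c not in df.columns]
        if missing:
            raise ValidationError(f"compounds not in sample matrix: {missing}")
        return SampleCompoundMatrix.from_frame(df[list(compound_ids)])


@dataclass
class CompoundFeatureMatrix:
    """0/1 incidence of biosynthetic features (enzymes, classes) per compound.

    Every compound needs at least one feature: a compound with no recorded
    biosynthetic information cannot be placed in the tree.
    """

    compound_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.compound_ids = _check_unique(self.compound_ids, "compound")
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.compound_ids), len(self.feature_ids)):
            raise ValidationError(
                f"value block has shape {self.values.shape}, expected "
                f"({len(self.compound_ids)}, {len(self.feature_ids)})"
            )
        bad = ~np.isin(self.values, (0.0, 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"entry for compound {self.compound_ids[i]!r}, feature "
                f"{self.feature_ids[j]!r} is {self.values[i, j]!r}, not 0/1"
            )
        self.values = self.values.astype(int)
        empty = np.flatnonzero(self.values.sum(axis=1) == 0)
        if empty.size:
            raise ValidationError(
                f"compound {self.compound_ids[empty[0]]!r} has no feature "
                "(all-zero row)"
            )

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.compound_ids, columns=self.feature_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CompoundFeatureMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def select_compounds(self, compound_ids: Sequence[str]) -> "CompoundFeatureMatrix":
        df = self.to_frame()
        missing = [c for c in compound_ids if c not in df.index]
        if missing:
            raise ValidationError(f"compounds not in feature matrix: {missing}")
        return CompoundFeatureMatrix.from_frame(df.loc[list(compound_ids)])


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix with a zero diagonal."""

    ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.ids = _check_unique(self.ids, "id")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"distance block has shape {self.values.shape}, expected ({n}, {n})"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-9, rtol=0.0):
            i, j = np.argwhere(
                ~np.isclose(self.values, self.values.T, atol=1e-9, rtol=0.0)
            )[0]
            raise ValidationError(
                f"matrix not symmetric at ({self.ids[i]!r}, {self.ids[j]!r})"
            )
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            i = int(np.argmax(np.abs(np.diag(self.values))))
            raise ValidationError(f"non-zero diagonal at {self.ids[i]!r}")
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative distance at ({self.ids[i]!r}, {self.ids[j]!r})"
            )
        # enforce exact structural properties after tolerance checks
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    def __len__(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    @classmethod
    def from_condensed(cls, ids: Sequence[str], condensed: np.ndarray) -> "DistanceMatrix":
        from scipy.spatial.distance import squareform

        return cls(list(ids), squareform(np.asarray(condensed, dtype=float)))


# ---------------------------------------------------------------------------
# CSV readers / writers


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    # sep=None + python engine sniffs "," vs ";"
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_sample_matrix(
    path: str | Path, orientation: str = "samples_as_rows"
) -> SampleCompoundMatrix:
    """Read a sample × compound quantity table.

    Blank cells mean the compound is absent and are read as 0.  With
    ``orientation="samples_as_cols"`` the table is transposed first, for
    files that put compounds in rows.
    """
    if orientation not in ("samples_as_rows", "samples_as_cols"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    df = _read_table(path)
    if orientation == "samples_as_cols":
        df = df.T
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric entry in {path}: {exc}") from exc
    df = df.fillna(0.0)
    return SampleCompoundMatrix.from_frame(df)


_TRUTHY = {"1", "1.0", "TRUE", "T", "YES", "Y"}
_FALSY = {"0", "0.0", "FALSE", "F", "NO", "N"}


def read_feature_matrix(path: str | Path) -> CompoundFeatureMatrix:
    """Read a compound × feature presence/absence table.

    Entries must be 0/1 (TRUE/FALSE accepted); blanks are an error because
    presence or absence of a feature must be asserted explicitly.
    """
    df = _read_table(path)
    out = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                raise ValidationError(
                    f"missing presence/absence value for compound "
                    f"{df.index[i]!r}, feature {df.columns[j]!r}"
                )
            token = str(cell).strip().upper()
            if token in _TRUTHY:
                out[i, j] = 1.0
            elif token in _FALSY:
                out[i, j] = 0.0
            else:
                raise ValidationError(
                    f"entry {cell!r} for compound {df.index[i]!r}, feature "
                    f"{df.columns[j]!r} is not 0/1"
                )
    return CompoundFeatureMatrix(list(df.index), list(df.columns), out)


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = _read_table(path).astype(float)
    if list(df.index) != list(df.columns):
        raise ValidationError(
            f"distance matrix in {path} has mismatched row/column labels"
        )
    return DistanceMatrix(list(df.index), df.to_numpy())


def write_distance_matrix(d: DistanceMatrix, path: str | Path) -> None:
    d.to_frame().to_csv(path, float_format="%.17g")


def align_compounds(
    samples: SampleCompoundMatrix,
    features: CompoundFeatureMatrix,
    drop_missing: bool = False,
) -> tuple[SampleCompoundMatrix, CompoundFeatureMatrix]:
    """Reconcile the compound sets of the two input matrices.

    Compounds in the sample matrix without a feature annotation are a hard
    error by default; with ``drop_missing=True`` they are removed with a
    warning (silently dropping them would change distances invisibly).
    Feature rows for compounds never observed in any sample are harmless and
    simply ignored.
    """
    have = set(features.compound_ids)
    missing = [c for c in samples.compound_ids if c not in have]
    if missing:
        if not drop_missing:
            raise ValidationError(
                "compounds without feature annotation: "
                + ", ".join(repr(c) for c in missing)
                + " (pass drop_missing=True to discard them)"
            )
        logger.warning(
            "dropping %d compound(s) without feature annotation: %s",
            len(missing),
            ", ".join(missing),
        )
        keep = [c for c in samples.compound_ids if c in have]
        samples = samples.select_compounds(keep)
    features = features.select_compounds(samples.compound_ids)
    return samples, features


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree: "BiosynTree", path: str | Path) -> None:
    """Write the tree as Newick with branch lengths (labels quoted as needed)."""
    Path(path).write_text(tree.to_newick() + "\n", encoding="utf-8")


def read_newick(path: str | Path) -> "BiosynTree":
    from .biosyn_tree import BiosynTree

    text = Path(path).read_text(encoding="utf-8")
    return BiosynTree.from_newick(text)
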