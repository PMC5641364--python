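"""Latent structure: Q-matrices, symptom profiles, and the 2**K class space.

A diagnostic classification model (DCM) represents a respondent's latent
state as a binary *symptom profile* alpha = (alpha_1, ..., alpha_K), one
bit per diagnostic criterion. K criteria yield 2**K latent classes. The
Q-matrix declares, for each instrument item, which criteria the item
measures; every downstream module (estimation, model selection, screening,
scoring) consumes the class space and the Q-matrix defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QMatrix",
    "LatentClassSpace",
    "enumerate_classes",
    "reduce_profile",
    "read_qmatrix",
    "write_qmatrix",
]

_MAX_K = 20


@dataclass(frozen=True)
class QMatrix:
    """Item-by-criterion binary incidence matrix.

    Parameters
    ----------
    entries : (J, K) ndarray of 0/1
        ``entries[j, k] == 1`` iff criterion ``k`` is measured by item ``j``.
    item_ids : sequence of str
        J item labels. Defaults to ``"item1" ... "itemJ"``.
    criterion_ids : sequence of str
        K criterion labels. Defaults to ``"S1" ... "SK"``.
    """

    entries: np.ndarray
    item_ids: tuple = field(default=None)
    criterion_ids: tuple = field(default=None)

    def __post_init__(self):
        entries = np.asarray(self.entries)
        if entries.ndim != 2:
            raise ValueError("Q-matrix must be 2-dimensional")
        if not np.isin(entries, (0, 1)).all():
            bad = np.argwhere(~np.isin(entries, (0, 1)))[0]
            raise ValueError(
                f"Q-matrix entries must be 0/1; offending entry at "
                f"row {bad[0]}, column {bad[1]}"
            )
        entries = entries.astype(np.int8)
        row_sums = entries.sum(axis=1)
        if (row_sums < 1).any():
            j = int(np.flatnonzero(row_sums < 1)[0])
            raise ValueError(f"item row {j} measures no criterion (all-zero row)")
        col_sums = entries.sum(axis=0)
        if (col_sums < 1).any():
            # a partial item pool may leave criteria uncovered; estimation
            # and item drops enforce coverage strictly
            import warnings

            bare = np.flatnonzero(col_sums < 1).tolist()
            warnings.warn(
                f"criterion column(s) {bare} measured by no item",
                stacklevel=2,
            )
        object.__setattr__(self, "entries", entries)
        item_ids = self.item_ids
        if item_ids is None:
            item_ids = tuple(f"item{j + 1}" for j in range(entries.shape[0]))
        crit_ids = self.criterion_ids
        if crit_ids is None:
            crit_ids = tuple(f"S{k + 1}" for k in range(entries.shape[1]))
        item_ids = tuple(str(i) for i in item_ids)
        crit_ids = tuple(str(c) for c in crit_ids)
        if len(item_ids) != entries.shape[0]:
            raise ValueError("item_ids length does not match number of rows")
        if len(crit_ids) != entries.shape[1]:
            raise ValueError("criterion_ids length does not match number of columns")
        object.__setattr__(self, "item_ids", item_ids)
        object.__setattr__(self, "criterion_ids", crit_ids)

    @property
    def n_items(self) -> int:
        return self.entries.shape[0]

    @property
    def n_criteria(self) -> int:
        return self.entries.shape[1]

    def kstar(self, j: int) -> int:
        """Number of criteria measured by item ``j`` (row sum K_j*)."""
        return int(self.entries[j].sum())

    def row(self, j: int) -> np.ndarray:
        return self.entries[j]

    def item_index(self, item_id: str) -> int:
        try:
            return self.item_ids.index(str(item_id))
        except ValueError:
            raise KeyError(f"unknown item id {item_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries,
            index=pd.Index(self.item_ids, name="item"),
            columns=list(self.criterion_ids),
        )

    def drop_items(self, item_ids) -> "QMatrix":
        """Return a Q-matrix without the named items.

        Raises if a drop would leave a criterion unmeasured; callers that
        must guard against this check coverage first.
        """
        drop = {str(i) for i in item_ids}
        keep = [j for j, i in enumerate(self.item_ids) if i not in drop]
        if not keep:
            raise ValueError("cannot drop every item")
        cov_before = self.entries.sum(axis=0)
        cov_after = self.entries[keep].sum(axis=0)
        lost = np.flatnonzero((cov_before > 0) & (cov_after == 0))
        if lost.size:
            raise ValueError(
                f"dropping would leave criterion "
                f"{self.criterion_ids[int(lost[0])]} unmeasured"
            )
        return QMatrix(
            self.entries[keep],
            item_ids=tuple(self.item_ids[j] for j in keep),
            criterion_ids=self.criterion_ids,
        )

    def __eq__(self, other):
        return (
            isinstance(other, QMatrix)
            and np.array_equal(self.entries, other.entries)
            and self.item_ids == other.item_ids
            and self.criterion_ids == other.criterion_ids
        )


class LatentClassSpace:
    """All 2**K symptom profiles in a fixed, deterministic order.

    Ordering is binary counting with criterion 1 as the least-significant
    bit: class ``c`` has profile ``((c >> k) & 1 for k in range(K))``. The
    fixed order makes posterior vectors comparable across runs and rules
    out label switching.
    """

    def __init__(self, n_criteria: int):
        if not (1 <= n_criteria <= _MAX_K):
            raise ValueError(
                f"number of criteria must be in [1, {_MAX_K}], got {n_criteria}"
            )
        self.n_criteria = int(n_criteria)
        ids = np.arange(2**self.n_criteria, dtype=np.int64)
        # profiles[c, k] = bit k of c
        self.profiles = ((ids[:, None] >> np.arange(self.n_criteria)) & 1).astype(
            np.int8
        )
        self.counts = self.profiles.sum(axis=1)

    @property
    def n_classes(self) -> int:
        return self.profiles.shape[0]

    def class_of(self, profile) -> int:
        """Index of the class with the given profile."""
        profile = np.asarray(profile, dtype=np.int64)
        if profile.shape != (self.n_criteria,):
            raise ValueError("profile length does not match number of criteria")
        return int((profile << np.arange(self.n_criteria)).sum())

    def __len__(self) -> int:
        return self.n_classes

    def __repr__(self) -> str:
        return f"LatentClassSpace(K={self.n_criteria}, classes={self.n_classes})"


def enumerate_classes(n_criteria: int) -> LatentClassSpace:
    """Enumerate all 2**K symptom profiles for K criteria."""
    return LatentClassSpace(n_criteria)


def reduce_profile(profile, qrow) -> np.ndarray:
    """Restrict a K-profile to the criteria an item measures.

    Returns the K_j*-length sub-profile (criterion order preserved) used by
    the item response functions: only measured criteria affect an item's
    endorsement probability.
    """
    profile = np.asarray(profile, dtype=np.int8)
    qrow = np.asarray(qrow, dtype=np.int8)
    if profile.shape != qrow.shape:
        raise ValueError("profile and q-row lengths differ")
    if qrow.sum() < 1:
        raise ValueError("item q-row measures no criterion")
    return profile[qrow == 1]


def read_qmatrix(path) -> QMatrix:
    """Read a Q-matrix CSV (first column item id, one column per criterion)."""
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"non-binary Q-matrix entry {values[r, c]!r} at item "
            f"{df.index[r]!r}, criterion {df.columns[c]!r}"
        )
    return QMatrix(
        values,
        item_ids=tuple(str(i) for i in df.index),
        criterion_ids=tuple(str(c) for c in df.columns),
    )


def write_qmatrix(q: QMatrix, path) -> None:
    """Write a Q-matrix to CSV; ``read_qmatrix(write_qmatrix(q)) == q``."""
    q.to_frame().to_csv(path)
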