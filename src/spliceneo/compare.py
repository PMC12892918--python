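"""Cross-sample set comparisons: Jaccard similarity and PSI-directionality concordance."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class LabeledSet:
    """A named collection of identifiers (event keys or peptide sequences)."""

    label: str
    members: frozenset

    @classmethod
    def of(cls, label: str, members) -> "LabeledSet":
        return cls(label=label, members=frozenset(members))


def jaccard(a: LabeledSet, b: LabeledSet) -> float:
    """|a n b| / |a u b|; 0 when both sets are empty."""
    union = a.members | b.members
    if not union:
        return 0.0
    return len(a.members & b.members) / len(union)


def jaccard_matrix(sets: list[LabeledSet]) -> pd.DataFrame:
    """Symmetric pairwise Jaccard matrix, labels as index/columns."""
    if len(sets) < 2:
        raise ValueError("need >= 2 sets")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise ValueError("set labels must be unique")
    n = len(sets)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = jaccard(sets[i], sets[j])
    return pd.DataFrame(mat, index=labels, columns=labels)


class NoSharedEvents(ValueError):
    """Concordance is undefined with zero shared significant events."""


def directional_concordance(
    diff_a: pd.DataFrame, diff_b: pd.DataFrame
) -> tuple[int, float, int]:
    """PSI-directionality agreement between two differential tables.

    Over events significant in BOTH tables (each table's own
    ``passes_filters`` verdict), the percentage sharing the sign of
    delta_psi.  Events with delta_psi == 0 in either table are excluded
    and counted.  Returns (shared_n, concordance_percent, n_zero_excluded).
    """
    def sig(df: pd.DataFrame) -> pd.DataFrame:
        return df[df["passes_filters"].astype(bool)].set_index("event_id")

    a, b = sig(diff_a), sig(diff_b)
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise NoSharedEvents("no events significant in both tables")
    da = a.loc[shared, "delta_psi"].to_numpy(dtype=float)
    db = b.loc[shared, "delta_psi"].to_numpy(dtype=float)
    nonzero = (da != 0) & (db != 0)
    n_zero = int((~nonzero).sum())
    da, db = da[nonzero], db[nonzero]
    if len(da) == 0:
        raise NoSharedEvents("all shared events have delta_psi == 0")
    agree = float(np.mean(np.sign(da) == np.sign(db)) * 100.0)
    return int(len(da)), agree, n_zero
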