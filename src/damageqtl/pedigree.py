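"""Numerator relationship matrix from a pedigree (tabular method)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PedigreeMatrix", "build_pedigree_A", "CyclicPedigreeError"]


class CyclicPedigreeError(ValueError):
    """Raised when the pedigree contains a cycle."""


@dataclass
class PedigreeMatrix:
    """Additive (numerator) relationship matrix A over ordered individuals."""

    ids: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        n = len(self.ids)
        if self.A.shape != (n, n):
            raise ValueError("A shape does not match ids")
        if not np.allclose(self.A, self.A.T):
            raise ValueError("A must be symmetric")

    def submatrix(self, ids: list[str]) -> np.ndarray:
        """A restricted to (and ordered by) the given individuals."""
        index = {g: i for i, g in enumerate(self.ids)}
        missing = [g for g in ids if g not in index]
        if missing:
            raise KeyError(f"individuals absent from pedigree: {missing[:5]}")
        idx = [index[g] for g in ids]
        return self.A[np.ix_(idx, idx)]


def build_pedigree_A(
    pedigree: pd.DataFrame, auto_founders: bool = True
) -> PedigreeMatrix:
    """Build the additive relationship matrix by the recursive tabular method.

    ``pedigree`` needs columns id, sire, dam; missing parents (NaN, empty or
    '0') denote founders. Parents that appear only in the sire/dam columns
    are added as founders when ``auto_founders`` is true, otherwise they
    raise. For individual j with parents (s, d):
    a_ij = (a_is + a_id) / 2 for previously placed i, and
    a_jj = 1 + a_sd / 2.
    """

    def _norm(v) -> str | None:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        s = str(v).strip()
        return None if s in ("", "0", ".", "NA", "nan") else s

    parents: dict[str, tuple[str | None, str | None]] = {}
    for _, row in pedigree.iterrows():
        iid = _norm(row["id"])
        if iid is None:
            raise ValueError("pedigree contains an empty id")
        if iid in parents:
            raise ValueError(f"duplicate pedigree entry for {iid}")
        parents[iid] = (_norm(row["sire"]), _norm(row["dam"]))

    known = set(parents)
    for s, d in list(parents.values()):
        for p in (s, d):
            if p is not None and p not in known:
                if not auto_founders:
                    raise ValueError(f"unknown parent {p} not marked as founder")
                parents[p] = (None, None)
                known.add(p)

    # topological order: founders first, offspring after both parents
    order: list[str] = []
    placed: set[str] = set()
    pending = dict(parents)
    while pending:
        ready = [
            i for i, (s, d) in pending.items()
            if (s is None or s in placed) and (d is None or d in placed)
        ]
        if not ready:
            raise CyclicPedigreeError(
                f"pedigree is cyclic or unresolvable near: {sorted(pending)[:5]}"
            )
        for i in sorted(ready):
            order.append(i)
            placed.add(i)
            del pending[i]

    n = len(order)
    index = {g: i for i, g in enumerate(order)}
    A = np.zeros((n, n))
    for j, iid in enumerate(order):
        s, d = parents[iid]
        si = index[s] if s is not None else None
        di = index[d] if d is not None else None
        for i in range(j):
            a_is = A[i, si] if si is not None else 0.0
            a_id = A[i, di] if di is not None else 0.0
            A[i, j] = A[j, i] = 0.5 * (a_is + a_id)
        a_sd = A[si, di] if (si is not None and di is not None) else 0.0
        A[j, j] = 1.0 + 0.5 * a_sd
    return PedigreeMatrix(ids=order, A=A)
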