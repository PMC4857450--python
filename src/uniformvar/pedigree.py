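"""Numerator relationship matrix among sires (tabular method).

The additive-genetic covariance of the sire effects in the DHGLM is
``(1/4) G (x) A`` with ``A`` the pedigree numerator relationship matrix.
Unknown parents are treated as unrelated, non-inbred founders; no genetic
groups are fitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import PedigreeEntry


class PedigreeError(ValueError):
    pass


@dataclass
class RelationshipMatrix:
    """Additive relationships ``A`` among an ordered list of subjects."""

    ids: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.index = {s: i for i, s in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.A)

    def export_triplets(self, path: str | Path) -> None:
        """Write the non-zero entries as (row_id, col_id, value) text."""
        with open(path, "w") as fh:
            fh.write("row_id,col_id,value\n")
            for i, ri in enumerate(self.ids):
                for j in range(i, len(self.ids)):
                    v = self.A[i, j]
                    if v != 0.0:
                        fh.write(f"{ri},{self.ids[j]},{v:.10g}\n")


def _toposort(entries: list[PedigreeEntry]) -> list[PedigreeEntry]:
    """Order parents before offspring; raise listing a cycle if one exists."""
    by_id = {e.id: e for e in entries}
    order: list[PedigreeEntry] = []
    state: dict[str, int] = {}  # 0 visiting, 1 done

    for root in by_id:
        if root in state:
            continue
        stack = [(root, False)]
        path: list[str] = []
        while stack:
            node, processed = stack.pop()
            if processed:
                path.pop()
                state[node] = 1
                order.append(by_id[node])
                continue
            if state.get(node) == 1:
                continue
            if state.get(node) == 0:
                cyc = path[path.index(node):] + [node]
                raise PedigreeError(f"pedigree cycle: {' -> '.join(cyc)}")
            state[node] = 0
            path.append(node)
            stack.append((node, True))
            e = by_id[node]
            for parent in (e.sire_id, e.dam_id):
                if parent is not None and parent in by_id and state.get(parent) != 1:
                    stack.append((parent, False))
    return order


def build_relationship_matrix(
    entries: list[PedigreeEntry], subjects: list[str]
) -> RelationshipMatrix:
    """Tabular-method A restricted to ``subjects`` (ancestors handled internally).

    a_ij = (a_{i,sire(j)} + a_{i,dam(j)}) / 2 for i before j in a topological
    order; a_jj = 1 + a_{sire(j),dam(j)} / 2.  Parents absent from the pedigree
    are founders.
    """
    by_id = {e.id: e for e in entries}
    missing = [s for s in subjects if s not in by_id]
    if missing:
        raise KeyError(f"subjects not in pedigree: {missing[:5]}")

    ordered = _toposort(entries)
    ids = [e.id for e in ordered]
    pos = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    for j, e in enumerate(ordered):
        si = pos.get(e.sire_id) if e.sire_id in pos else None
        di = pos.get(e.dam_id) if e.dam_id in pos else None
        for i in range(j):
            v = 0.0
            if si is not None:
                v += 0.5 * A[i, si]
            if di is not None:
                v += 0.5 * A[i, di]
            A[i, j] = A[j, i] = v
        f = 0.5 * A[si, di] if (si is not None and di is not None) else 0.0
        A[j, j] = 1.0 + f

    idx = [pos[s] for s in subjects]
    return RelationshipMatrix(ids=list(subjects), A=A[np.ix_(idx, idx)].copy())
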