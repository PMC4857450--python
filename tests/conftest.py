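import numpy as np
import pandas as pd
import pytest

from uniformvar.io import PhenotypeTable, PedigreeEntry
from uniformvar.pedigree import RelationshipMatrix


@pytest.fixture
def tiny_table() -> PhenotypeTable:
    """Three purebred hens (2 sires) + two crossbred cages, handwritten."""
    rows = []
    for hen, sire, n in (("h1", "s1", 6), ("h2", "s1", 5), ("h3", "s2", 4)):
        for k in range(n):
            rows.append(dict(record_id=f"{hen}r{k}", population="purebred",
                             hen_id=hen, cage_id=hen, sire_id=sire,
                             hatch_week=1, laying_date=k % 3, line=pd.NA,
                             tier=pd.NA, period=1 + k % 2, age_weeks=30,
                             y=100.0 + 3 * k))
    for cage, sire, n in (("c1", "s1", 5), ("c2", "s2", 5)):
        for k in range(n):
            rows.append(dict(record_id=f"{cage}r{k}", population="crossbred",
                             hen_id=pd.NA, cage_id=cage, sire_id=sire,
                             hatch_week=pd.NA, laying_date=pd.NA, line=1,
                             tier=2, period=1, age_weeks=38, y=90.0 + 2 * k))
    return PhenotypeTable(pd.DataFrame(rows))


@pytest.fixture
def halfsib_pedigree() -> list[PedigreeEntry]:
    return [
        PedigreeEntry("S"),
        PedigreeEntry("B", sire_id="S"),
        PedigreeEntry("C", sire_id="S"),
    ]


def recursive_relationship(entries):
    """Brute-force oracle for A: a_ij = (a_{i,s(j)} + a_{i,d(j)})/2."""
    by_id = {e.id: e for e in entries}
    memo: dict[tuple[str, str], float] = {}
    order = {e.id: i for i, e in enumerate(entries)}  # parents listed first

    def a(i: str, j: str) -> float:
        if order[i] > order[j]:
            i, j = j, i
        key = (i, j)
        if key in memo:
            return memo[key]
        ej = by_id[j]
        if i == j:
            s, d = ej.sire_id, ej.dam_id
            val = 1.0 + (0.5 * a(s, d) if s in by_id and d in by_id else 0.0)
        else:
            val = 0.0
            if ej.sire_id in by_id:
                val += 0.5 * a(i, ej.sire_id)
            if ej.dam_id in by_id:
                val += 0.5 * a(i, ej.dam_id)
        memo[key] = val
        return val

    ids = [e.id for e in entries]
    n = len(ids)
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            A[i, j] = a(ids[i], ids[j])
    return ids, A


@pytest.fixture
def random_pedigree_factory():
    """Random acyclic pedigrees (parents precede offspring by construction)."""

    def make(n: int, seed: int) -> list[PedigreeEntry]:
        rng = np.random.default_rng(seed)
        entries = [PedigreeEntry("a0"), PedigreeEntry("a1")]
        for i in range(2, n):
            sire = f"a{rng.integers(0, i)}" if rng.random() < 0.8 else None
            dam = f"a{rng.integers(0, i)}" if rng.random() < 0.8 else None
            if sire is not None and sire == dam:
                dam = None
            entries.append(PedigreeEntry(f"a{i}", sire_id=sire, dam_id=dam))
        return entries

    return make
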