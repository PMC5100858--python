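"""Shared fixtures: small hand-built pedigrees and random pedigree factories."""

import numpy as np
import pytest

from purgekit import IndividualRecord, Pedigree


def ped_from_rows(rows):
    """rows: (id, sire, dam[, fitness]) with '0'/None for unknown parents."""
    recs = []
    for row in rows:
        ind, sire, dam = row[0], row[1], row[2]
        fit = row[3] if len(row) > 3 else None
        recs.append(
            IndividualRecord(
                id=str(ind),
                sire=None if sire in (None, "0", 0) else str(sire),
                dam=None if dam in (None, "0", 0) else str(dam),
                fitness=fit,
            )
        )
    return Pedigree(recs)


@pytest.fixture
def trio():
    return ped_from_rows([("1", 0, 0, 1.0), ("2", 0, 0, 0.9), ("3", "1", "2", 0.8)])


@pytest.fixture
def fullsib1():
    """Founders A,B; full sibs C,D; X their offspring (F_X = 0.25)."""
    return ped_from_rows(
        [("A", 0, 0), ("B", 0, 0), ("C", "A", "B"), ("D", "A", "B"),
         ("X", "C", "D")]
    )


@pytest.fixture
def fullsib2():
    """Two generations of full-sib mating; final offspring has F = 0.375."""
    return ped_from_rows(
        [("A", 0, 0), ("B", 0, 0), ("C", "A", "B"), ("D", "A", "B"),
         ("E", "C", "D"), ("F", "C", "D"), ("X", "E", "F")]
    )


def sib_line(generations):
    """Repeated full-sib mating: each generation is a sib pair from the
    previous pair's offspring."""
    rows = [("S0a", 0, 0), ("S0b", 0, 0)]
    for t in range(1, generations + 1):
        rows.append((f"S{t}a", f"S{t-1}a", f"S{t-1}b"))
        rows.append((f"S{t}b", f"S{t-1}a", f"S{t-1}b"))
    return ped_from_rows(rows)


def random_small_pedigree(rng, n_max=8):
    """Random acyclic pedigree of <= n_max individuals; each individual's
    parents are drawn (possibly unknown) among earlier individuals."""
    n = int(rng.integers(3, n_max + 1))
    rows = []
    for i in range(n):
        if i < 2 or rng.random() < 0.25:
            rows.append((str(i), 0, 0))
        else:
            s = int(rng.integers(0, i))
            d = int(rng.integers(0, i))
            if s == d:
                d = (d + 1) % i if i > 1 else 0
            rows.append((str(i), str(s) if rng.random() < 0.9 else 0, str(d)))
    return ped_from_rows(rows)
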