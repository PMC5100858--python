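"""Pedigree parsing, validation and topological ordering.

A pedigree is a set of individual records (id, sire, dam, fitness,
optional covariates) whose parent graph is acyclic.  All coefficient
recursions in :mod:`purgekit.coefficients` process individuals in a
topological order (every individual after both of its known parents),
so the order is computed once here and stored on the ``Pedigree``.

Conventions
-----------
* Unknown parents are coded ``"0"`` in files (configurable) and stored
  as index ``-1``.  An unknown parent side behaves as an anonymous,
  unrelated, noninbred founder in every recursion.
* Parents that are referenced but never listed as rows are auto-created
  as founders with missing fitness (a warning is logged); this is common
  in real studbooks and can be switched off.
* Missing fitness is allowed: such individuals still contribute pedigree
  links (and coefficients) but are dropped from estimation.
* IDs are opaque strings; no numeric ordering is ever inferred from them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IndividualRecord",
    "Pedigree",
    "PedigreeError",
    "CycleError",
    "read_pedigree",
    "write_pedigree",
    "topological_order",
    "noninbred_reference_set",
]

log = logging.getLogger(__name__)


class PedigreeError(ValueError):
    """Invalid pedigree structure or record."""


class CycleError(PedigreeError):
    """The parent graph contains a cycle."""


@dataclass(frozen=True)
class IndividualRecord:
    """One pedigree row.

    ``sire``/``dam`` are labels of other records or ``None`` for an
    unknown parent.  ``fitness`` is a nonnegative real or ``None``.
    """

    id: str
    sire: str | None = None
    dam: str | None = None
    fitness: float | None = None
    covariates: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not str(self.id):
            raise PedigreeError("individual id must be nonempty")
        if self.sire is not None and str(self.sire) == str(self.id):
            raise PedigreeError(f"individual {self.id!r} lists itself as sire")
        if self.dam is not None and str(self.dam) == str(self.id):
            raise PedigreeError(f"individual {self.id!r} lists itself as dam")
        if self.fitness is not None:
            w = float(self.fitness)
            if not np.isfinite(w) or w < 0:
                raise PedigreeError(
                    f"individual {self.id!r} has invalid fitness {self.fitness!r}"
                )


class Pedigree:
    """Validated, topologically ordered pedigree.

    Parameters
    ----------
    records
        Individual records; order of appearance is remembered and used
        to break ties in the topological order.
    auto_founders
        If True (default), parents referenced but not listed are created
        as founder records (missing fitness) with a logged warning;
        otherwise such references raise :class:`PedigreeError`.
    """

    def __init__(
        self, records: Iterable[IndividualRecord], auto_founders: bool = True
    ) -> None:
        records = list(records)
        ids = [str(r.id) for r in records]
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise PedigreeError(f"duplicate individual id {i!r}")
            seen.add(i)

        # auto-create referenced-but-missing parents as founders
        missing: list[str] = []
        for r in records:
            for par in (r.sire, r.dam):
                if par is not None and str(par) not in seen:
                    missing.append(str(par))
                    seen.add(str(par))
        if missing:
            if not auto_founders:
                raise PedigreeError(
                    "parents referenced but not listed as rows: "
                    + ", ".join(repr(m) for m in missing)
                )
            log.warning(
                "auto-created %d founder record(s) for parents not listed as rows: %s",
                len(missing),
                ", ".join(missing[:10]) + ("..." if len(missing) > 10 else ""),
            )
            records = [IndividualRecord(id=m) for m in missing] + records

        self.records: list[IndividualRecord] = records
        self.ids: list[str] = [str(r.id) for r in records]
        self.index: dict[str, int] = {i: k for k, i in enumerate(self.ids)}
        n = len(records)

        def _pidx(lbl: str | None) -> int:
            return -1 if lbl is None else self.index[str(lbl)]

        self.sire_idx = np.array([_pidx(r.sire) for r in records], dtype=np.int64)
        self.dam_idx = np.array([_pidx(r.dam) for r in records], dtype=np.int64)
        self.fitness = np.array(
            [np.nan if r.fitness is None else float(r.fitness) for r in records]
        )
        ncov = max((len(r.covariates) for r in records), default=0)
        for r in records:
            if r.covariates and len(r.covariates) != ncov:
                raise PedigreeError(
                    f"individual {r.id!r} has {len(r.covariates)} covariates, expected {ncov}"
                )
        self.covariates = np.array(
            [list(r.covariates) if r.covariates else [0.0] * ncov for r in records]
        ).reshape(n, ncov)

        self.depth = self._compute_depth()
        # stable sort: depth first, input position breaks ties
        self.order = np.argsort(self.depth, kind="stable").astype(np.int64)

    # ------------------------------------------------------------------

    def _compute_depth(self) -> np.ndarray:
        """Kahn's algorithm over parent->child edges; errors on cycles."""
        n = self.n
        children: list[list[int]] = [[] for _ in range(n)]
        indeg = np.zeros(n, dtype=np.int64)
        for i in range(n):
            for p in (self.sire_idx[i], self.dam_idx[i]):
                if p >= 0:
                    children[p].append(i)
                    indeg[i] += 1
        depth = np.zeros(n, dtype=np.int64)
        queue = [i for i in range(n) if indeg[i] == 0]
        done = 0
        head = 0
        while head < len(queue):
            v = queue[head]
            head += 1
            done += 1
            for c in children[v]:
                depth[c] = max(depth[c], depth[v] + 1)
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if done < n:
            raise CycleError(
                "pedigree contains a cycle: " + " -> ".join(self._find_cycle())
            )
        return depth

    def _find_cycle(self) -> list[str]:
        """Locate one parent-link cycle for the error message."""
        color = {}  # 0 unseen implicit, 1 on stack, 2 done
        parent_of = lambda i: [p for p in (self.sire_idx[i], self.dam_idx[i]) if p >= 0]
        for start in range(self.n):
            if color.get(start):
                continue
            stack = [(start, iter(parent_of(start)))]
            color[start] = 1
            path = [start]
            while stack:
                v, it = stack[-1]
                nxt = next(it, None)
                if nxt is None:
                    stack.pop()
                    path.pop()
                    color[v] = 2
                    continue
                if color.get(nxt) == 1:
                    k = path.index(nxt)
                    return [self.ids[i] for i in path[k:]] + [self.ids[nxt]]
                if not color.get(nxt):
                    color[nxt] = 1
                    path.append(nxt)
                    stack.append((nxt, iter(parent_of(nxt))))
        return []  # pragma: no cover

    # ------------------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def founders(self) -> list[str]:
        """IDs with both parents unknown."""
        mask = (self.sire_idx < 0) & (self.dam_idx < 0)
        return [self.ids[i] for i in np.flatnonzero(mask)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": self.ids,
                "sire": ["0" if p < 0 else self.ids[p] for p in self.sire_idx],
                "dam": ["0" if p < 0 else self.ids[p] for p in self.dam_idx],
                "fitness": self.fitness,
            }
        )
        for j in range(self.covariates.shape[1]):
            df[f"cov{j + 1}"] = self.covariates[:, j]
        return df

    def __repr__(self) -> str:  # pragma: no cover
        return f"Pedigree(n={self.n}, founders={len(self.founders)})"


def topological_order(p: Pedigree) -> list[str]:
    """IDs in topological order (depth, then input order).

    Every individual appears after both of its known parents; ties are
    broken by position in the input, so the order is deterministic.
    """
    return [p.ids[i] for i in p.order]


# ----------------------------------------------------------------------
# I/O


def read_pedigree(
    path,
    has_header: bool = False,
    n_covariates: int = 0,
    unknown_parent: str = "0",
    missing_fitness: Sequence[str] = ("NA", "na", "NaN", "nan", "-"),
    auto_founders: bool = True,
) -> Pedigree:
    """Read a whitespace/TSV pedigree table.

    Columns: id, sire, dam, fitness, then ``n_covariates`` numeric
    covariates.  ``unknown_parent`` (default ``"0"``) marks an unknown
    parent; any code in ``missing_fitness`` marks missing fitness.
    """
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=0 if has_header else None,
        dtype=str,
        comment="#",
        skip_blank_lines=True,
    )
    need = 4 + n_covariates
    if df.shape[1] < need:
        raise PedigreeError(
            f"pedigree file has {df.shape[1]} columns, expected at least {need}"
        )
    miss = {str(m) for m in missing_fitness}
    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2 if has_header else 1):
        vals = [str(v).strip() for v in row]
        ind, sire, dam, wstr = vals[:4]
        fitness: float | None
        if wstr in miss or wstr == "":
            fitness = None
        else:
            try:
                fitness = float(wstr)
            except ValueError:
                raise PedigreeError(
                    f"non-numeric fitness {wstr!r} on row {row_no}"
                ) from None
        covs = []
        for c in vals[4 : 4 + n_covariates]:
            try:
                covs.append(float(c))
            except ValueError:
                raise PedigreeError(
                    f"non-numeric covariate {c!r} on row {row_no}"
                ) from None
        records.append(
            IndividualRecord(
                id=ind,
                sire=None if sire == unknown_parent else sire,
                dam=None if dam == unknown_parent else dam,
                fitness=fitness,
                covariates=tuple(covs),
            )
        )
    return Pedigree(records, auto_founders=auto_founders)


def write_pedigree(p: Pedigree, path, coefficients=None) -> None:
    """Write a normalized pedigree TSV.

    If ``coefficients`` (a :class:`purgekit.coefficients.CoefficientTable`)
    is given, F, Fa and one ``g@d`` column per requested d are appended
    at full double precision so output is bit-exactly reproducible.
    """
    df = p.to_dataframe()
    df["fitness"] = [
        "NA" if not np.isfinite(w) else repr(float(w)) for w in p.fitness
    ]
    if coefficients is not None:
        df["F"] = [repr(float(v)) for v in coefficients.F]
        df["Fa"] = [repr(float(v)) for v in coefficients.Fa]
        for k, d in enumerate(coefficients.d_values):
            df[f"g@{d:g}"] = [repr(float(v)) for v in coefficients.g[:, k]]
    df.to_csv(path, sep="\t", index=False)


def noninbred_reference_set(p: Pedigree, F: np.ndarray, Fa: np.ndarray) -> set[str]:
    """IDs with F = Fa = 0 and nonmissing fitness.

    This is the reference set whose mean (log-)fitness anchors the
    regression intercept; an empty set is an error because the intercept
    must then be supplied by the user.
    """
    mask = (np.asarray(F) == 0) & (np.asarray(Fa) == 0) & np.isfinite(p.fitness)
    ids = {p.ids[i] for i in np.flatnonzero(mask)}
    if not ids:
        raise PedigreeError(
            "no noninbred individuals with noninbred ancestors (F = Fa = 0) and "
            "recorded fitness; supply the base-population intercept explicitly"
        )
    return ids
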