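"""Pedigree coefficients: coancestry, inbreeding, ancestral and purged inbreeding.

Implements the tabular (matrix) method for Malécot coancestry ``f`` and
Wright inbreeding ``F``, Ballou's ancestral inbreeding ``Fa``, and the
purged analogues: the purged coancestry ``gamma`` and purged inbreeding
``g`` of the inbreeding-purging (IP) model, for arbitrary pedigrees with
overlapping generations, plus the discrete-generation variant and the
per-interval inbreeding-rate reliability check.

The purged coancestry recursion processed in topological order is, for a
new individual X with parents P1, P2 and inbreeding F_X,

    gamma(X, Y) = 1/2 [gamma(P1, Y) + gamma(P2, Y)] (1 - d F_X)

for every previously processed Y, with the self term

    gamma(X, X) = 1/2 (1 + g_X)(1 - 2 d F_X),    g_X = gamma(P1, P2).

X is always the expanded (younger) member of a pair; with overlapping
generations "younger" means later in topological order (depth, then
input order).  Unknown parents contribute gamma = 0 (base-population
convention: noninbred, unrelated, unpurged).

The discrete-generation variant replaces the two factors
(1 - d F_A)(1 - d F_B) accumulated along a pair's two parental
expansions by the joint factor [1 - d (F_A + F_B)]:

    gamma(A, B) = 1/4 [gamma(C,E) + gamma(D,E) + gamma(C,H) + gamma(D,H)]
                  [1 - d (F_A + F_B)]

where C, D are A's parents and E, H are B's parents.  The former
slightly overrates gamma by the cross term d^2 F_A F_B; the two agree
very closely (correlation > 0.999 on bottlenecked pedigrees).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedigree import Pedigree, PedigreeError

__all__ = [
    "CoefficientTable",
    "PurgedCoancestryState",
    "ReliabilityReport",
    "coancestry_matrix",
    "inbreeding_F",
    "ancestral_Fa",
    "purged_inbreeding",
    "purged_inbreeding_grid",
    "purged_inbreeding_nonoverlapping",
    "delta_F_reliability",
    "compute_coefficients",
]


@dataclass
class CoefficientTable:
    """Per-individual F, Fa and g(d) for one or many d values."""

    ids: list[str]
    F: np.ndarray  # (n,)
    Fa: np.ndarray  # (n,)
    d_values: np.ndarray  # (m,)
    g: np.ndarray  # (n, m)


@dataclass
class PurgedCoancestryState:
    """Pairwise purged coancestry table at a single d (plus plain f)."""

    ids: list[str]
    gamma: np.ndarray  # (n, n) symmetric
    f: np.ndarray  # (n, n) symmetric Malécot coancestry
    d: float


@dataclass
class ReliabilityReport:
    """Per-interval inbreeding rate and the d > 2*deltaF reliability flag."""

    interval_bounds: np.ndarray  # (k+1,) bin edges in generations
    mean_F: np.ndarray  # (k+1,) mean inbreeding at each bin
    delta_F: np.ndarray  # (k,) per-interval (F' - F)/(1 - F), floored at 0
    reliable: np.ndarray  # (k,) bool, d > 2 deltaF
    d: float


def _topo_parents(p: Pedigree) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parent positions in topological coordinates; ``n`` is the sentinel
    for an unknown parent (a zero row/column in every table)."""
    n = p.n
    rank = np.empty(n, dtype=np.int64)
    rank[p.order] = np.arange(n)
    sire = p.sire_idx[p.order]
    dam = p.dam_idx[p.order]
    s = np.where(sire >= 0, rank[np.clip(sire, 0, None)], n)
    d = np.where(dam >= 0, rank[np.clip(dam, 0, None)], n)
    return s, d, rank


def coancestry_matrix(p: Pedigree) -> np.ndarray:
    """Malécot coancestry f for all pairs, by the tabular method.

    Founder diagonal is 1/2; founders are unrelated to nondescendants;
    for a new X with parents P1, P2: f(X, Y) = [f(P1,Y) + f(P2,Y)]/2 and
    f(X, X) = [1 + f(P1, P2)]/2.  Rows/columns follow ``p.ids`` order.
    """
    n = p.n
    s, d, rank = _topo_parents(p)
    f = np.zeros((n + 1, n + 1))
    for i in range(n):
        si, di = s[i], d[i]
        if i:
            row = 0.5 * (f[si, :i] + f[di, :i])
            f[i, :i] = row
            f[:i, i] = row
        f[i, i] = 0.5 * (1.0 + f[si, di])
    return f[np.ix_(rank, rank)]


def inbreeding_F(p: Pedigree, f: np.ndarray | None = None) -> np.ndarray:
    """Wright's inbreeding coefficient: the coancestry of the parents.

    Individuals with an unknown parent side have F = 0 on that side
    (coancestry with an anonymous unrelated founder).
    """
    if f is None:
        f = coancestry_matrix(p)
    known = (p.sire_idx >= 0) & (p.dam_idx >= 0)
    F = np.zeros(p.n)
    F[known] = f[p.sire_idx[known], p.dam_idx[known]]
    return F


def ancestral_Fa(p: Pedigree, F: np.ndarray | None = None) -> np.ndarray:
    """Ballou's ancestral inbreeding coefficient.

    Fa(X) = 1/2 [Fa(S) + (1 - Fa(S)) F(S) + Fa(D) + (1 - Fa(D)) F(D)],
    founders (and unknown parent sides) contribute 0.
    """
    if F is None:
        F = inbreeding_F(p)
    Fa = np.zeros(p.n)
    for i in p.order:
        acc = 0.0
        for par in (p.sire_idx[i], p.dam_idx[i]):
            if par >= 0:
                acc += Fa[par] + (1.0 - Fa[par]) * F[par]
        Fa[i] = 0.5 * acc
    return Fa


def _check_d(d: float) -> float:
    d = float(d)
    if not (0.0 <= d <= 0.5):
        raise ValueError(
            f"purging coefficient d = {d} outside the model's admissible range [0, 0.5]"
        )
    return d


def purged_inbreeding(
    p: Pedigree, d: float, F: np.ndarray | None = None
) -> tuple[np.ndarray, PurgedCoancestryState]:
    """Purged inbreeding g and the full purged-coancestry table at one d.

    Overlapping-generation recursion (see module docstring).  At d = 0
    the recursion reduces to Malécot coancestry, so g equals F.
    """
    d = _check_d(d)
    n = p.n
    if F is None:
        F = inbreeding_F(p)
    s, dm, rank = _topo_parents(p)
    Ft = F[p.order]
    gamma = np.zeros((n + 1, n + 1))
    g = np.zeros(n)
    for i in range(n):
        si, di = s[i], dm[i]
        gi = gamma[si, di]  # 0 if either parent unknown
        g[i] = gi
        if i:
            row = 0.5 * (gamma[si, :i] + gamma[di, :i]) * (1.0 - d * Ft[i])
            gamma[i, :i] = row
            gamma[:i, i] = row
        gamma[i, i] = 0.5 * (1.0 + gi) * (1.0 - 2.0 * d * Ft[i])
    inv = np.empty(n, dtype=np.int64)
    inv[p.order] = np.arange(n)
    state = PurgedCoancestryState(
        ids=list(p.ids),
        gamma=gamma[np.ix_(inv, inv)],
        f=coancestry_matrix(p),
        d=d,
    )
    out = np.empty(n)
    out[p.order] = g
    return out, state


def purged_inbreeding_grid(
    p: Pedigree,
    d_values,
    F: np.ndarray | None = None,
    chunk: int = 64,
) -> np.ndarray:
    """g for every individual over a grid of d values, shape (n, m).

    Same recursion as :func:`purged_inbreeding` vectorized over d in
    chunks to bound memory at ``chunk * (n+1)^2`` doubles.
    """
    d_values = np.atleast_1d(np.asarray(d_values, dtype=float))
    for d in d_values:
        _check_d(d)
    n = p.n
    if F is None:
        F = inbreeding_F(p)
    s, dm, _ = _topo_parents(p)
    Ft = F[p.order]
    out = np.empty((n, len(d_values)))
    for lo in range(0, len(d_values), chunk):
        dv = d_values[lo : lo + chunk][:, None]  # (c, 1)
        c = dv.shape[0]
        gamma = np.zeros((c, n + 1, n + 1))
        for i in range(n):
            si, di = s[i], dm[i]
            gi = gamma[:, si, di]
            out[i, lo : lo + c] = gi
            if i:
                row = 0.5 * (gamma[:, si, :i] + gamma[:, di, :i]) * (
                    1.0 - dv * Ft[i]
                )
                gamma[:, i, :i] = row
                gamma[:, :i, i] = row
            gamma[:, i, i] = 0.5 * (1.0 + gi) * (1.0 - 2.0 * dv[:, 0] * Ft[i])
    res = np.empty_like(out)
    res[p.order] = out
    return res


def _generation_layers(p: Pedigree) -> list[np.ndarray]:
    """Discrete generations from topological depth, validated.

    Every non-founder must have both parents exactly one layer above
    (unknown parent sides are allowed only for individuals in layer 1,
    where the anonymous founder slots into layer 0).
    """
    depth = p.depth
    for i in range(p.n):
        if p.sire_idx[i] < 0 and p.dam_idx[i] < 0:
            continue
        for par in (p.sire_idx[i], p.dam_idx[i]):
            pd_ = 0 if par < 0 else depth[par]
            if pd_ != depth[i] - 1:
                raise PedigreeError(
                    f"pedigree is not organized in discrete generations near "
                    f"individual {p.ids[i]!r}; use the overlapping-generation method"
                )
    return [np.flatnonzero(depth == t) for t in range(int(depth.max()) + 1)]


def purged_inbreeding_nonoverlapping(
    p: Pedigree, d: float, F: np.ndarray | None = None, return_blocks: bool = False
):
    """Purged inbreeding for discrete-generation pedigrees.

    Grandparental recursion with the joint factor [1 - d (F_A + F_B)]
    (module docstring); the self term is the same as in the overlapping
    method.  Returns g, or (g, blocks) with one pairwise gamma block per
    generation when ``return_blocks`` is set.
    """
    d = _check_d(d)
    if F is None:
        F = inbreeding_F(p)
    layers = _generation_layers(p)
    n = p.n
    g = np.zeros(n)
    blocks: list[tuple[np.ndarray, np.ndarray]] = []

    # layer 0: founders, gamma = I/2 with a trailing zero row/col sentinel
    members = layers[0]
    m = len(members)
    G_prev = np.zeros((m + 1, m + 1))
    G_prev[:m, :m] = 0.5 * np.eye(m)
    pos_prev = {idx: k for k, idx in enumerate(members)}
    blocks.append((members, G_prev[:m, :m].copy()))

    for t in range(1, len(layers)):
        members = layers[t]
        m = len(members)
        sent = len(pos_prev)
        ps = np.array([pos_prev.get(p.sire_idx[i], sent) for i in members])
        pd_ = np.array([pos_prev.get(p.dam_idx[i], sent) for i in members])
        Fm = F[members]
        quad = (
            G_prev[np.ix_(ps, ps)]
            + G_prev[np.ix_(ps, pd_)]
            + G_prev[np.ix_(pd_, ps)]
            + G_prev[np.ix_(pd_, pd_)]
        )
        G = 0.25 * quad * (1.0 - d * (Fm[:, None] + Fm[None, :]))
        gi = G_prev[ps, pd_]
        g[members] = gi
        np.fill_diagonal(G, 0.5 * (1.0 + gi) * (1.0 - 2.0 * d * Fm))
        blocks.append((members, G.copy()))
        G_prev = np.zeros((m + 1, m + 1))
        G_prev[:m, :m] = G
        pos_prev = {idx: k for k, idx in enumerate(members)}

    if return_blocks:
        return g, blocks
    return g


def delta_F_reliability(
    p: Pedigree,
    F: np.ndarray | None = None,
    generation_interval: float = 1.0,
    d: float = 0.0,
    ages: np.ndarray | None = None,
) -> ReliabilityReport:
    """Per-interval inbreeding rate deltaF = (F' - F)/(1 - F) and the
    reliability criterion d > 2 deltaF for IP predictions.

    Individuals are binned by ``ages`` if given, otherwise by topological
    depth, into intervals of width ``generation_interval``.  A negative
    raw deltaF (mean F decreasing, e.g. after new founders enter) is
    floored at 0.
    """
    if F is None:
        F = inbreeding_F(p)
    t = np.asarray(ages, dtype=float) if ages is not None else p.depth.astype(float)
    bins = np.round(t / float(generation_interval)).astype(int)
    levels = np.unique(bins)
    meanF = np.array([F[bins == b].mean() for b in levels])
    if len(levels) < 2:
        return ReliabilityReport(
            interval_bounds=levels.astype(float) * generation_interval,
            mean_F=meanF,
            delta_F=np.zeros(0),
            reliable=np.zeros(0, dtype=bool),
            d=float(d),
        )
    dF = (meanF[1:] - meanF[:-1]) / (1.0 - meanF[:-1])
    dF = np.clip(dF, 0.0, 1.0)
    return ReliabilityReport(
        interval_bounds=levels.astype(float) * generation_interval,
        mean_F=meanF,
        delta_F=dF,
        reliable=float(d) > 2.0 * dF,
        d=float(d),
    )


def compute_coefficients(p: Pedigree, d_values) -> CoefficientTable:
    """F, Fa and g over a set of d values in one pass."""
    f = coancestry_matrix(p)
    F = inbreeding_F(p, f)
    Fa = ancestral_Fa(p, F)
    d_values = np.atleast_1d(np.asarray(d_values, dtype=float))
    g = purged_inbreeding_grid(p, d_values, F=F)
    return CoefficientTable(ids=list(p.ids), F=F, Fa=Fa, d_values=d_values, g=g)
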