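"""Bipartite ant-plant interaction networks and network-level metrics.

A network at one elevation is an integer incidence matrix ``a_ij`` counting
plant individuals of species *i* (rows) occupied by ant species *j*
(columns).  All metrics are computed from first principles on the count
matrix:

* connectance — realized fraction of possible links (binary);
* generality / vulnerability — weighted effective number of plant partners
  per ant species / ant partners per plant species (exponential Shannon
  entropy of each column / row, weighted by marginal totals);
* H2' — network-level specialization: the deviation of the observed
  interaction-frequency entropy from its marginal-constrained maximum,
  scaled by the feasible entropy range, so 0 means random partner use and
  1 means maximal specialization given the marginal totals;
* Barber's bipartite modularity Q, optimized by seeded label propagation
  with local moves and module merges.

Undefined metrics (empty or degenerate networks) propagate as NaN and are
never silently replaced by 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

UNCERTAIN_LABEL = "uncertain"

#: Midpoints (percent missing leaf area) of the four ordinal damage
#: categories 0%, <5%, 5-33%, >33%: arithmetic midpoints of [0,0], (0,5),
#: [5,33], (33,100].
HERBIVORY_MIDPOINTS = (0.0, 2.5, 19.0, 66.5)


class EmptyNetworkError(ValueError):
    """Raised when an operation requires a non-empty network."""


@dataclass(frozen=True, eq=False)
class BipartiteNetwork:
    """Quantitative plant x ant interaction matrix at one elevation.

    Rows are plant species, columns ant species; ``counts[i, j]`` is the
    number of plant individuals of species ``plant_labels[i]`` occupied by
    ``ant_labels[j]``.  After construction no row or column is all zero.
    """

    plant_labels: tuple
    ant_labels: tuple
    counts: np.ndarray
    elevation: float | None = None

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (len(self.plant_labels), len(self.ant_labels)):
            raise ValueError("counts shape does not match label lengths")
        if counts.size and counts.min() < 0:
            raise ValueError("interaction counts must be non-negative")
        if counts.size:
            if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
                raise ValueError("network contains an all-zero row or column; prune first")

    # -- basic descriptors -------------------------------------------------
    @property
    def m(self) -> int:
        """Grand total of interaction events."""
        return int(self.counts.sum())

    @property
    def n_plants(self) -> int:
        return len(self.plant_labels)

    @property
    def n_ants(self) -> int:
        return len(self.ant_labels)

    @property
    def plant_degrees(self) -> np.ndarray:
        """Row marginals k_i (events per plant species)."""
        return self.counts.sum(axis=1)

    @property
    def ant_degrees(self) -> np.ndarray:
        """Column marginals d_j (events per ant species)."""
        return self.counts.sum(axis=0)

    @property
    def is_empty(self) -> bool:
        return self.counts.size == 0

    @classmethod
    def empty(cls, elevation: float | None = None) -> "BipartiteNetwork":
        """Typed explicitly-empty network (no occupied records)."""
        return cls((), (), np.zeros((0, 0), dtype=np.int64), elevation)

    @classmethod
    def from_counts(cls, counts, plant_labels=None, ant_labels=None,
                    elevation=None) -> "BipartiteNetwork":
        """Build from a raw matrix, pruning all-zero rows/columns."""
        counts = np.asarray(counts, dtype=np.int64)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-d matrix")
        n_i, n_j = counts.shape
        plant_labels = tuple(plant_labels) if plant_labels is not None else tuple(
            f"P{i + 1:02d}" for i in range(n_i))
        ant_labels = tuple(ant_labels) if ant_labels is not None else tuple(
            f"A{j + 1:02d}" for j in range(n_j))
        keep_rows = counts.sum(axis=1) > 0
        keep_cols = counts.sum(axis=0) > 0
        counts = counts[np.ix_(keep_rows, keep_cols)]
        if counts.size == 0:
            return cls.empty(elevation)
        plant_labels = tuple(l for l, k in zip(plant_labels, keep_rows) if k)
        ant_labels = tuple(l for l, k in zip(ant_labels, keep_cols) if k)
        return cls(plant_labels, ant_labels, counts, elevation)

    # -- IO ----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.plant_labels),
                            columns=list(self.ant_labels))

    def to_tsv(self, path) -> None:
        """Write a labelled incidence matrix (rows = plants, cols = ants)."""
        self.to_frame().to_csv(path, sep="\t", index_label="plant_species")

    @classmethod
    def from_tsv(cls, path, elevation: float | None = None) -> "BipartiteNetwork":
        frame = pd.read_csv(path, sep="\t", index_col="plant_species")
        if frame.size == 0:
            return cls.empty(elevation)
        return cls(tuple(frame.index), tuple(frame.columns),
                   frame.to_numpy(dtype=np.int64), elevation)


def build_network(records: pd.DataFrame, elevation: float,
                  exclude_uncertain: bool = True) -> BipartiteNetwork:
    """Aggregate occupied census records at one elevation into a network.

    Records whose ant is ``"uncertain"`` (resident but not collected) are
    excluded when ``exclude_uncertain`` (they have no species identity).
    Species labels are sorted lexicographically for determinism.  If no
    usable record exists the result is a typed empty network, not an error.
    """
    sub = records[records["elevation_m"] == elevation]
    sub = sub[(sub["occupied"].astype(int) == 1) & (sub["ant_species"] != "")]
    sub = sub[sub["ant_species"].notna()]
    if exclude_uncertain:
        sub = sub[sub["ant_species"] != UNCERTAIN_LABEL]
    if len(sub) == 0:
        return BipartiteNetwork.empty(elevation)
    table = pd.crosstab(sub["plant_species"], sub["ant_species"])
    table = table.sort_index(axis=0).sort_index(axis=1)
    return BipartiteNetwork(tuple(table.index), tuple(table.columns),
                            table.to_numpy(dtype=np.int64), elevation)


# ---------------------------------------------------------------------------
# Entropy helpers
# ---------------------------------------------------------------------------

def _shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def shannon_h2(counts: np.ndarray) -> float:
    """Two-dimensional Shannon entropy H2 = -sum p_ij ln p_ij, p = a/m."""
    counts = np.asarray(counts, dtype=float)
    m = counts.sum()
    if m <= 0:
        return float("nan")
    return _shannon(counts.ravel() / m)


def connectance(net: BipartiteNetwork) -> float:
    """Realized fraction of possible links; NaN for an empty network."""
    if net.is_empty or net.m < 1:
        return float("nan")
    return float((net.counts > 0).sum() / (net.n_plants * net.n_ants))


def _effective_partners(counts: np.ndarray, axis: int) -> float:
    # axis=0: entropy down each column (partners of each ant) -> generality
    # axis=1: entropy along each row (partners of each plant) -> vulnerability
    counts = np.asarray(counts, dtype=float)
    m = counts.sum()
    marg = counts.sum(axis=0) if axis == 0 else counts.sum(axis=1)
    out = 0.0
    for idx, total in enumerate(marg):
        if total <= 0:
            continue
        col = counts[:, idx] if axis == 0 else counts[idx, :]
        out += (total / m) * np.exp(_shannon(col / total))
    return float(out)


def generality(net: BipartiteNetwork) -> float:
    """Weighted mean effective number of plant species per ant species."""
    if net.is_empty or net.m < 1:
        return float("nan")
    return _effective_partners(net.counts, axis=0)


def vulnerability(net: BipartiteNetwork) -> float:
    """Weighted mean effective number of ant species per plant species."""
    if net.is_empty or net.m < 1:
        return float("nan")
    return _effective_partners(net.counts, axis=1)


# ---------------------------------------------------------------------------
# H2' — specialization relative to the feasible entropy range
# ---------------------------------------------------------------------------

def _xlogx(a: np.ndarray | float) -> np.ndarray | float:
    a = np.asarray(a, dtype=float)
    out = np.zeros_like(a)
    mask = a > 0
    out[mask] = a[mask] * np.log(a[mask])
    return out


def _h2_of_matrix(a: np.ndarray) -> float:
    # H2 = ln m - (1/m) sum a ln a  (numerically convenient form)
    m = a.sum()
    return float(np.log(m) - _xlogx(a).sum() / m)


def _h2_min_matrix(k: np.ndarray, d: np.ndarray,
                   match_first: bool = False) -> np.ndarray:
    """Greedy descending-marginal filling: concentrate mass, low entropy.

    ``match_first`` prefers exact k_i == d_j pairs before the plain
    largest-with-largest rule; both variants are tried and the lower-entropy
    result kept by the caller.
    """
    k = np.array(k, dtype=np.int64)
    d = np.array(d, dtype=np.int64)
    a = np.zeros((len(k), len(d)), dtype=np.int64)
    while k.sum() > 0:
        i = j = -1
        if match_first:
            pos_k = np.where(k > 0)[0]
            pos_d = np.where(d > 0)[0]
            matches = [(k[ii], ii, jj) for ii in pos_k for jj in pos_d
                       if k[ii] == d[jj]]
            if matches:
                _, i, j = max(matches)
        if i < 0:
            i = int(np.argmax(k))
            j = int(np.argmax(d))
        t = min(k[i], d[j])
        a[i, j] += t
        k[i] -= t
        d[j] -= t
    return a


def _h2_max_matrix(k: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Proportional allocation with largest-remainder integer rounding."""
    k = np.asarray(k, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    m = k.sum()
    expected = np.outer(k, d) / m
    a = np.floor(expected).astype(np.int64)
    frac = expected - a
    row_def = k - a.sum(axis=1)
    col_def = d - a.sum(axis=0)
    while row_def.sum() > 0:
        eligible = (row_def[:, None] > 0) & (col_def[None, :] > 0)
        masked = np.where(eligible, frac, -1.0)
        i, j = np.unravel_index(int(np.argmax(masked)), masked.shape)
        a[i, j] += 1
        row_def[i] -= 1
        col_def[j] -= 1
        frac[i, j] -= 1.0  # deprioritize repeated picks of the same cell
    return a


def _swap_improve(a: np.ndarray, maximize: bool, max_sweeps: int = 200) -> np.ndarray:
    """Pairwise 2x2 marginal-preserving transfers improving the entropy.

    For the maximum, single-unit moves toward evenness; for the minimum,
    full-block transfers toward concentration.  Stops at a local optimum.
    A swap changes sum a ln a only through the four touched cells, so the
    inner loop works off a precomputed x ln x table.
    """
    n_i, n_j = a.shape
    if n_i < 2 or n_j < 2:
        return a.copy()
    m = int(a.sum())
    table = [0.0] + [v * float(np.log(v)) for v in range(1, m + 1)]
    cells = [[int(v) for v in row] for row in a]

    for _ in range(max_sweeps):
        improved = False
        for i1 in range(n_i):
            row1 = cells[i1]
            for j1 in range(n_j):
                v11 = row1[j1]
                if v11 == 0:
                    continue
                for i2 in range(n_i):
                    if i2 == i1:
                        continue
                    row2 = cells[i2]
                    for j2 in range(n_j):
                        if j2 == j1:
                            continue
                        v22 = row2[j2]
                        if v22 == 0:
                            continue
                        v11 = row1[j1]
                        if v11 == 0:
                            break
                        t = 1 if maximize else min(v11, v22)
                        v12 = row1[j2]
                        v21 = row2[j1]
                        change = (table[v11 - t] + table[v12 + t] +
                                  table[v21 + t] + table[v22 - t] -
                                  table[v11] - table[v12] -
                                  table[v21] - table[v22])
                        # maximize H2  <=> decrease sum a ln a
                        if (maximize and change < -1e-12) or \
                           (not maximize and change > 1e-12):
                            row1[j1] = v11 - t
                            row1[j2] = v12 + t
                            row2[j1] = v21 + t
                            row2[j2] = v22 - t
                            improved = True
        if not improved:
            break
    return np.array(cells, dtype=np.int64)


def _h2_min_matrix_randomized(k: np.ndarray, d: np.ndarray, rng) -> np.ndarray:
    """Randomized greedy: exact k_i == d_j matches first, otherwise one of
    the two largest remaining rows x columns at random."""
    k = np.array(k, dtype=np.int64)
    d = np.array(d, dtype=np.int64)
    a = np.zeros((len(k), len(d)), dtype=np.int64)
    while k.sum() > 0:
        pos_k = np.where(k > 0)[0]
        pos_d = np.where(d > 0)[0]
        matches = [(k[ii], ii, jj) for ii in pos_k for jj in pos_d
                   if k[ii] == d[jj]]
        if matches:
            _, i, j = max(matches)
        else:
            top_k = pos_k[np.argsort(k[pos_k])[::-1][:2]]
            top_d = pos_d[np.argsort(d[pos_d])[::-1][:2]]
            i = int(rng.choice(top_k))
            j = int(rng.choice(top_d))
        t = min(k[i], d[j])
        a[i, j] += t
        k[i] -= t
        d[j] -= t
    return a


def _h2_max_matrix_randomized(k: np.ndarray, d: np.ndarray, rng) -> np.ndarray:
    """Proportional floor allocation with randomized largest-remainder fill."""
    k = np.asarray(k, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    m = k.sum()
    expected = np.outer(k, d) / m
    a = np.floor(expected).astype(np.int64)
    frac = expected - a
    row_def = k - a.sum(axis=1)
    col_def = d - a.sum(axis=0)
    while row_def.sum() > 0:
        eligible = np.argwhere((row_def[:, None] > 0) & (col_def[None, :] > 0))
        weights = frac[eligible[:, 0], eligible[:, 1]] + 0.1
        pick = eligible[rng.choice(len(eligible), p=weights / weights.sum())]
        i, j = int(pick[0]), int(pick[1])
        a[i, j] += 1
        row_def[i] -= 1
        col_def[j] -= 1
        frac[i, j] = max(frac[i, j] - 1.0, 0.0)
    return a


@lru_cache(maxsize=16384)
def _h2_extrema_cached(k_sorted: tuple, d_sorted: tuple) -> tuple:
    k = np.array(k_sorted, dtype=np.int64)
    d = np.array(d_sorted, dtype=np.int64)
    candidates = [
        _h2_min_matrix(k, d),
        _h2_min_matrix(k, d, match_first=True),
    ]
    # deterministic randomized-greedy restarts, seeded from the marginals;
    # they rescue rare greedy ties, which only bite on small matrices, so
    # restart counts taper off as the swap improvement takes over
    m = int(k.sum())
    n_min_restarts, n_max_restarts = (6, 4) if m <= 40 else (2, 1)
    rng = np.random.default_rng(abs(hash((k_sorted, d_sorted))) % (2 ** 31))
    for _ in range(n_min_restarts):
        candidates.append(_h2_min_matrix_randomized(k, d, rng))
    h2_min = min(_h2_of_matrix(_swap_improve(a, maximize=False))
                 for a in candidates)
    max_candidates = [_h2_max_matrix(k, d)]
    for _ in range(n_max_restarts):
        max_candidates.append(_h2_max_matrix_randomized(k, d, rng))
    h2_max = max(_h2_of_matrix(_swap_improve(a, maximize=True))
                 for a in max_candidates)
    return h2_min, h2_max


def h2_extrema(plant_degrees, ant_degrees) -> tuple:
    """Heuristic (H2min, H2max) over integer matrices with these marginals.

    Entropy extrema depend only on the marginal multisets, so keys are
    sorted for caching.
    """
    k = tuple(sorted((int(v) for v in plant_degrees), reverse=True))
    d = tuple(sorted((int(v) for v in ant_degrees), reverse=True))
    if sum(k) != sum(d):
        raise ValueError("row and column totals disagree")
    return _h2_extrema_cached(k, d)


def h2_prime_from_h2(h2: float, h2_min: float, h2_max: float) -> float:
    if h2_max - h2_min < 1e-9:
        return float("nan")
    return float(np.clip((h2_max - h2) / (h2_max - h2_min), 0.0, 1.0))


def h2_prime(net: BipartiteNetwork) -> float:
    """Network specialization H2' in [0, 1]; NaN when degenerate.

    H2' = (H2max - H2) / (H2max - H2min) with H2max/H2min the heuristic
    extrema of the interaction entropy over non-negative integer matrices
    sharing the observed marginal totals; clamped to [0, 1].
    """
    if net.is_empty or net.m < 2:
        return float("nan")
    if net.n_plants < 2 and net.n_ants < 2:
        return float("nan")
    h2_min, h2_max = h2_extrema(net.plant_degrees, net.ant_degrees)
    return h2_prime_from_h2(_h2_of_matrix(net.counts), h2_min, h2_max)


# ---------------------------------------------------------------------------
# Barber modularity
# ---------------------------------------------------------------------------

@dataclass
class ModulePartition:
    """Module assignment for every plant and ant species, with its Q."""

    plant_modules: dict
    ant_modules: dict
    q: float = float("nan")

    def arrays(self, net: BipartiteNetwork) -> tuple:
        try:
            r = np.array([self.plant_modules[l] for l in net.plant_labels], dtype=np.int64)
            c = np.array([self.ant_modules[l] for l in net.ant_labels], dtype=np.int64)
        except KeyError as err:
            raise ValueError(f"partition does not cover species {err.args[0]!r}") from err
        return r, c


def _q_value(counts: np.ndarray, r: np.ndarray, c: np.ndarray) -> float:
    m = counts.sum()
    if m == 0:
        return 0.0
    k = counts.sum(axis=1)
    d = counts.sum(axis=0)
    q = 0.0
    for mod in np.unique(np.concatenate([r, c])):
        rows = r == mod
        cols = c == mod
        w = counts[rows][:, cols].sum()
        q += w / m - (k[rows].sum() / m) * (d[cols].sum() / m)
    return float(q)


def barber_q(net: BipartiteNetwork, partition: ModulePartition) -> float:
    """Barber's bipartite modularity of a given partition.

    Q = (1/m) sum_ij [a_ij - k_i d_j / m] * 1(module(plant i) = module(ant j)).
    """
    if net.is_empty:
        raise EmptyNetworkError("modularity of an empty network is undefined")
    r, c = partition.arrays(net)
    return _q_value(net.counts, r, c)


def _local_moves(counts, k, d, m, r, c, rng) -> bool:
    """One full pass of best single-node module moves; True if any applied.

    Moving a row node i into module b changes Q by
    (w_i(b) - w_i(own))/m - k_i (D_b - D_own)/m^2 where w_i(b) is i's
    interaction weight into columns of module b and D_b the column-marginal
    mass of module b (symmetrically for column nodes).  An extra slot acts
    as a fresh empty module.
    """
    n_i, n_j = counts.shape
    moved = False
    order = rng.permutation(n_i + n_j)
    for node in order:
        n_mods = max(int(r.max()), int(c.max())) + 1
        if node < n_i:
            i = int(node)
            w = np.zeros(n_mods + 1)
            np.add.at(w, c, counts[i, :])
            opp = np.zeros(n_mods + 1)
            np.add.at(opp, c, d)
            deg = k[i]
            own = int(r[i])
        else:
            j = int(node - n_i)
            w = np.zeros(n_mods + 1)
            np.add.at(w, r, counts[:, j])
            opp = np.zeros(n_mods + 1)
            np.add.at(opp, r, k)
            deg = d[j]
            own = int(c[j])
        gain = w / m - deg * opp / (m * m)
        best = int(np.argmax(gain))
        if gain[best] > gain[own] + 1e-12:
            if node < n_i:
                r[i] = best
            else:
                c[j] = best
            moved = True
    return moved


def _merge_modules(counts, k, d, m, r, c, threshold: float = 1e-12) -> bool:
    """Greedy best-pair module merge; True if a merge improved Q."""
    mods = np.unique(np.concatenate([r, c]))
    if len(mods) < 2:
        return False
    best_gain = threshold
    best_pair = None
    big_k = {mod: k[r == mod].sum() for mod in mods}
    big_d = {mod: d[c == mod].sum() for mod in mods}
    for ai in range(len(mods)):
        for bi in range(ai + 1, len(mods)):
            a_mod, b_mod = mods[ai], mods[bi]
            w_cross = counts[np.ix_(r == a_mod, c == b_mod)].sum() + \
                counts[np.ix_(r == b_mod, c == a_mod)].sum()
            gain = w_cross / m - (big_k[a_mod] * big_d[b_mod] +
                                  big_k[b_mod] * big_d[a_mod]) / (m * m)
            if gain > best_gain:
                best_gain = gain
                best_pair = (a_mod, b_mod)
    if best_pair is None:
        return False
    a_mod, b_mod = best_pair
    r[r == b_mod] = a_mod
    c[c == b_mod] = a_mod
    return True


def optimize_modularity(net: BipartiteNetwork, rng=None, restarts: int = 20,
                        seed: int | None = None) -> ModulePartition:
    """Best Barber-Q partition over seeded label-propagation restarts.

    Each restart runs single-node best moves to convergence, then greedy
    module merges, alternating until neither improves.  The trivial
    one-module partition is always among the candidates, so the returned
    Q is never below 0.  Deterministic given the seed/rng.
    """
    if net.is_empty:
        raise EmptyNetworkError("cannot partition an empty network")
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = net.counts
    n_i, n_j = counts.shape
    k = counts.sum(axis=1).astype(float)
    d = counts.sum(axis=0).astype(float)
    m = float(counts.sum())

    def refine(r, c):
        for _ in range(200):
            any_move = False
            while _local_moves(counts, k, d, m, r, c, rng):
                any_move = True
            if _merge_modules(counts, k, d, m, r, c):
                any_move = True
            if not any_move:
                break
        return r, c

    best_q = -np.inf
    best = None
    for restart in range(max(1, restarts)):
        if restart == 0:
            r = np.arange(n_i, dtype=np.int64)
            c = np.arange(n_i, n_i + n_j, dtype=np.int64)
        elif restart == 1:
            r = np.zeros(n_i, dtype=np.int64)
            c = np.zeros(n_j, dtype=np.int64)
        elif restart % 2 == 0 and best is not None:
            # iterated local search: perturb the incumbent
            r, c = best[0].copy(), best[1].copy()
            fresh = np.arange(n_i + n_j) + max(int(r.max()), int(c.max())) + 1
            mask_r = rng.random(n_i) < 0.3
            mask_c = rng.random(n_j) < 0.3
            r[mask_r] = fresh[:n_i][mask_r]
            c[mask_c] = fresh[n_i:][mask_c]
        else:
            n_mods = int(rng.integers(1, n_i + n_j + 1))
            r = rng.integers(0, n_mods, size=n_i)
            c = rng.integers(0, n_mods, size=n_j)
        r, c = refine(r, c)
        q = _q_value(counts, r, c)
        if q > best_q + 1e-12:
            best_q = q
            best = (r.copy(), c.copy())
    r, c = best
    # canonicalize: coarsest partition among those attaining the same Q
    # (collapses Q-neutral splits such as the single-interaction network)
    while _merge_modules(counts, k, d, m, r, c, threshold=-1e-12):
        pass
    # canonical module ids in order of first appearance (plants then ants)
    remap = {}
    for lab in list(r) + list(c):
        if lab not in remap:
            remap[lab] = len(remap)
    plant_modules = {l: remap[v] for l, v in zip(net.plant_labels, r)}
    ant_modules = {l: remap[v] for l, v in zip(net.ant_labels, c)}
    part = ModulePartition(plant_modules, ant_modules)
    part.q = barber_q(net, part)
    return part


# ---------------------------------------------------------------------------
# MetricSet and descriptive indices
# ---------------------------------------------------------------------------

@dataclass
class MetricSet:
    """The five network-level indices plus richness for one network.

    Undefined entries are NaN and propagate into downstream statistics.
    """

    connectance: float = float("nan")
    generality: float = float("nan")
    vulnerability: float = float("nan")
    h2_prime: float = float("nan")
    modularity_q: float = float("nan")
    plant_richness: int = 0
    ant_richness: int = 0

    def as_dict(self) -> dict:
        return {
            "plant_richness": self.plant_richness,
            "ant_richness": self.ant_richness,
            "connectance": self.connectance,
            "generality": self.generality,
            "vulnerability": self.vulnerability,
            "h2_prime": self.h2_prime,
            "modularity_q": self.modularity_q,
        }


METRIC_NAMES = ("plant_richness", "ant_richness", "connectance", "generality",
                "vulnerability", "h2_prime", "modularity_q")


def metric_set(net: BipartiteNetwork, seed: int | None = 0,
               modularity_restarts: int = 20,
               include_modularity: bool = True) -> MetricSet:
    """All network-level metrics for one network.

    ``include_modularity=False`` skips the (comparatively expensive)
    modularity optimization, leaving NaN — used for resampling replicates
    where only cheap metrics are banded.
    """
    if net.is_empty:
        return MetricSet()
    ms = MetricSet(
        connectance=connectance(net),
        generality=generality(net),
        vulnerability=vulnerability(net),
        h2_prime=h2_prime(net),
        plant_richness=net.n_plants,
        ant_richness=net.n_ants,
    )
    if include_modularity:
        part = optimize_modularity(net, seed=seed, restarts=modularity_restarts)
        ms.modularity_q = part.q
    return ms


def herbivory_index(herbivory_counts, midpoints=HERBIVORY_MIDPOINTS) -> float:
    """Mean percent leaf damage: leaf-count-weighted category midpoints.

    NaN when no leaf was counted.
    """
    counts = np.asarray(herbivory_counts, dtype=float)
    if counts.shape[-1] != 4 or (counts < 0).any():
        raise ValueError("expected 4 non-negative leaf counts")
    total = counts.sum()
    if total == 0:
        return float("nan")
    return float((counts * np.asarray(midpoints)).sum() / total)


def occupancy_rate(records: pd.DataFrame, plant_species: str | None = None,
                   elevation: float | None = None) -> float:
    """Fraction of censused individuals that are ant-occupied.

    ``"uncertain"`` occupants count as occupied (the plant clearly hosts a
    colony even if the ant was not collected).
    """
    sub = records
    if plant_species is not None:
        sub = sub[sub["plant_species"] == plant_species]
    if elevation is not None:
        sub = sub[sub["elevation_m"] == elevation]
    if len(sub) == 0:
        raise ValueError("no censused individuals in the requested scope")
    return float(sub["occupied"].astype(int).mean())
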