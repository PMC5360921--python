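"""Resampling procedures: rarefaction prediction bands and marginal-
preserving Monte Carlo nulls for network specialization.

Two questions are separated here.  First, how much of the elevational
change in network metrics is explained by declining ant-plant abundance
alone?  Answered by rarefaction: pool the interaction events of the two
lowest elevations, repeatedly subsample them *without replacement* down to
the abundance observed at each higher elevation, and band each metric by
the 2.5/97.5 percentiles of the replicates.  An observed value outside its
band indicates reorganization beyond what smaller sample size produces.

Second, is the observed specialization H2' larger than expected if ants
colonized plants at random given how common each species is?  Answered by
the classic two-way-table randomization (Patefield): draw integer matrices
with exactly the observed row and column totals via sequential
conditional multivariate-hypergeometric fills, and compute a one-tailed
add-one Monte Carlo p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import (
    UNCERTAIN_LABEL,
    BipartiteNetwork,
    METRIC_NAMES,
    connectance,
    generality,
    h2_extrema,
    h2_prime,
    h2_prime_from_h2,
    _h2_of_matrix,
    metric_set,
    optimize_modularity,
    vulnerability,
)

BAND_METRICS_DEFAULT = ("plant_richness", "ant_richness", "connectance",
                        "generality", "vulnerability", "h2_prime",
                        "modularity_q")


def _replicate_metrics(net: BipartiteNetwork, metrics, seed: int,
                       modularity_restarts: int) -> dict:
    """Only the requested metrics for one rarefied replicate."""
    out = {}
    for name in metrics:
        if net.is_empty:
            out[name] = 0 if name.endswith("richness") else float("nan")
        elif name == "plant_richness":
            out[name] = net.n_plants
        elif name == "ant_richness":
            out[name] = net.n_ants
        elif name == "connectance":
            out[name] = connectance(net)
        elif name == "generality":
            out[name] = generality(net)
        elif name == "vulnerability":
            out[name] = vulnerability(net)
        elif name == "h2_prime":
            out[name] = h2_prime(net)
        elif name == "modularity_q":
            out[name] = optimize_modularity(
                net, seed=seed, restarts=modularity_restarts).q
        else:
            raise ValueError(f"unknown metric {name!r}")
    return out


def pool_community(records: pd.DataFrame, elevations_to_pool=(700.0, 800.0),
                   exclude_uncertain: bool = True) -> list:
    """Interaction events (plant, ant) pooled over the given elevations.

    Each occupied, identified-ant record becomes one event; the result is an
    order-independent multiset, returned sorted for determinism.
    """
    pool_set = {float(e) for e in elevations_to_pool}
    sub = records[records["elevation_m"].astype(float).isin(pool_set)]
    sub = sub[(sub["occupied"].astype(int) == 1) & (sub["ant_species"] != "")]
    sub = sub[sub["ant_species"].notna()]
    if exclude_uncertain:
        sub = sub[sub["ant_species"] != UNCERTAIN_LABEL]
    events = sorted(zip(sub["plant_species"], sub["ant_species"]))
    return events


def network_from_events(events, elevation: float | None = None) -> BipartiteNetwork:
    """Aggregate a multiset of (plant, ant) events into a network."""
    if len(events) == 0:
        return BipartiteNetwork.empty(elevation)
    frame = pd.DataFrame(events, columns=["plant_species", "ant_species"])
    table = pd.crosstab(frame["plant_species"], frame["ant_species"])
    table = table.sort_index(axis=0).sort_index(axis=1)
    return BipartiteNetwork(tuple(table.index), tuple(table.columns),
                            table.to_numpy(dtype=np.int64), elevation)


class _EncodedPool:
    """Integer-coded event pool for fast repeated rarefaction."""

    def __init__(self, events):
        self.events = list(events)
        plants = sorted({p for p, _ in self.events})
        ants = sorted({a for _, a in self.events})
        self.plant_labels = tuple(plants)
        self.ant_labels = tuple(ants)
        p_index = {p: i for i, p in enumerate(plants)}
        a_index = {a: j for j, a in enumerate(ants)}
        self.rows = np.array([p_index[p] for p, _ in self.events], dtype=np.int64)
        self.cols = np.array([a_index[a] for _, a in self.events], dtype=np.int64)

    def __len__(self):
        return len(self.events)

    def sample_network(self, n: int, rng) -> BipartiteNetwork:
        idx = rng.choice(len(self.events), size=n, replace=False)
        counts = np.zeros((len(self.plant_labels), len(self.ant_labels)),
                          dtype=np.int64)
        np.add.at(counts, (self.rows[idx], self.cols[idx]), 1)
        return BipartiteNetwork.from_counts(counts, self.plant_labels,
                                            self.ant_labels)


def rarefy(pool, n: int, rng) -> BipartiteNetwork:
    """Subsample ``n`` events uniformly without replacement; build the network."""
    if not 1 <= n <= len(pool):
        raise ValueError(
            f"cannot rarefy to n={n} from a pool of {len(pool)} events")
    if not isinstance(pool, _EncodedPool):
        pool = _EncodedPool(pool)
    return pool.sample_network(n, rng)


@dataclass
class PredictionBand:
    """Per-elevation, per-metric percentile bounds of rarefied replicates."""

    elevation: float
    metric: str
    lower: float
    upper: float
    n_replicates: int
    n_undefined: int
    unreliable: bool     # > 50% of replicates undefined

    def contains(self, value: float) -> bool:
        if np.isnan(value) or np.isnan(self.lower):
            return False
        return bool(self.lower - 1e-12 <= value <= self.upper + 1e-12)


def prediction_bands(pool: list, target_sizes: dict, n_replicates: int = 1000,
                     seed: int = 0, metrics=BAND_METRICS_DEFAULT,
                     modularity_restarts: int = 5,
                     return_replicates: bool = False):
    """95% rarefaction prediction bands for every metric x elevation.

    ``target_sizes`` maps elevation -> observed interaction-event count.
    Each elevation gets its own child RNG stream keyed by (seed, elevation),
    so adding an elevation never perturbs the draws of the others.
    Percentiles use linear interpolation between order statistics;
    replicates where a metric is undefined are dropped from the percentile
    computation and counted in ``n_undefined``.
    """
    include_modularity = "modularity_q" in metrics
    encoded = pool if isinstance(pool, _EncodedPool) else _EncodedPool(pool)
    bands = []
    replicate_store = {}
    for elevation in sorted(target_sizes):
        n = int(target_sizes[elevation])
        if n > len(encoded):
            raise ValueError(
                f"target size {n} at {elevation} m exceeds pool size {len(encoded)}")
        if n < 1:
            continue
        rng = np.random.default_rng([int(seed), int(elevation)])
        values = {name: np.empty(n_replicates) for name in metrics}
        for rep in range(n_replicates):
            net = encoded.sample_network(n, rng)
            ms = _replicate_metrics(net, metrics, seed=int(seed) + rep,
                                    modularity_restarts=modularity_restarts)
            for name in metrics:
                values[name][rep] = ms[name]
        replicate_store[elevation] = values
        for name in metrics:
            vals = values[name]
            defined = vals[~np.isnan(vals)]
            n_undef = int(np.isnan(vals).sum())
            if len(defined) == 0:
                lower = upper = float("nan")
            else:
                lower = float(np.percentile(defined, 2.5))
                upper = float(np.percentile(defined, 97.5))
            bands.append(PredictionBand(
                elevation=float(elevation), metric=name, lower=lower,
                upper=upper, n_replicates=n_replicates, n_undefined=n_undef,
                unreliable=n_undef > n_replicates / 2))
    if return_replicates:
        return bands, replicate_store
    return bands


def bands_frame(bands) -> pd.DataFrame:
    return pd.DataFrame([{
        "elevation_m": b.elevation, "metric": b.metric, "lower": b.lower,
        "upper": b.upper, "n_replicates": b.n_replicates,
        "n_undefined": b.n_undefined, "unreliable": b.unreliable,
    } for b in bands])


# ---------------------------------------------------------------------------
# Marginal-preserving two-way-table null
# ---------------------------------------------------------------------------

def patefield_counts(row_sums: np.ndarray, col_sums: np.ndarray, rng) -> np.ndarray:
    """Random integer table with exactly the given marginals.

    Sequential rows: row i is a multivariate-hypergeometric allocation of
    k_i events over the remaining column capacities — the classic two-way-
    table randomization.
    """
    row_sums = np.asarray(row_sums, dtype=np.int64)
    remaining = np.asarray(col_sums, dtype=np.int64).copy()
    out = np.zeros((len(row_sums), len(remaining)), dtype=np.int64)
    for i, k in enumerate(row_sums[:-1]):
        draw = rng.multivariate_hypergeometric(remaining, int(k))
        out[i] = draw
        remaining -= draw
    out[-1] = remaining
    return out


def patefield_null(net: BipartiteNetwork, rng) -> BipartiteNetwork:
    """One marginal-preserving randomization of a network."""
    if net.is_empty or net.m < 1:
        raise ValueError("cannot randomize an empty network")
    counts = patefield_counts(net.plant_degrees, net.ant_degrees, rng)
    return BipartiteNetwork(net.plant_labels, net.ant_labels, counts,
                            net.elevation)


@dataclass
class NullTestResult:
    """Monte Carlo comparison of an observed metric against null draws."""

    metric: str
    observed: float
    null_values: np.ndarray
    p_value: float
    tail: str = "greater"
    n_null: int = 0


def h2_significance(net: BipartiteNetwork, n_null: int = 1000, rng=None,
                    seed: int | None = None,
                    tail: str = "greater") -> NullTestResult:
    """One-tailed Monte Carlo test of H2' against the marginal-preserving null.

    p = (1 + #{null >= observed}) / (n_null + 1).  Because every null draw
    shares the observed marginals, the feasible entropy extrema are computed
    once and reused; H2 values are rounded to 12 decimals before comparison
    so that replicate matrices with identical count multisets tie exactly.
    """
    observed = h2_prime(net)
    if np.isnan(observed):
        return NullTestResult("h2_prime", observed, np.array([]), float("nan"),
                              tail, n_null)
    if rng is None:
        rng = np.random.default_rng(seed)
    h2_min, h2_max = h2_extrema(net.plant_degrees, net.ant_degrees)
    null_values = np.empty(n_null)
    for i in range(n_null):
        counts = patefield_counts(net.plant_degrees, net.ant_degrees, rng)
        null_values[i] = h2_prime_from_h2(_h2_of_matrix(counts), h2_min, h2_max)
    obs_r = np.round(observed, 12)
    null_r = np.round(null_values, 12)
    if tail == "greater":
        extreme = int((null_r >= obs_r).sum())
    elif tail == "two-sided":
        center = float(np.median(null_r))
        extreme = int((np.abs(null_r - center) >= abs(obs_r - center)).sum())
    else:
        raise ValueError("tail must be 'greater' or 'two-sided'")
    p = (1 + extreme) / (n_null + 1)
    return NullTestResult("h2_prime", observed, null_values, float(p), tail,
                          n_null)
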