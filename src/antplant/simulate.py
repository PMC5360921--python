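"""Synthetic ant-plant census generator.

Emulates a transect census of understorey ant-plants along a tropical
elevational gradient: 10 transects at 100 m intervals from 700 to
1600 m a.s.l., ~23 myrmecophyte species and ~10 ant inhabitant species with
overlapping elevational ranges, declining abundance and richness with
elevation, exactly one resident ant species per occupied plant, a
specialization-controlled partner-assignment process, and ordinal herbivory
damage increasing with elevation.

Each species has a Gaussian elevational range kernel hard-truncated at
3 SD, so species genuinely drop out of the community (turnover) rather than
merely thinning.  Plant individuals at an elevation are Poisson with mean

    peak_abundance * kernel(elevation) * decline_rate**((e - e0)/100)

and, if occupied, receive exactly one ant species by a single categorical
draw with weight (preference x local ant availability): the plant's
affinity vector times each ant's range kernel at that elevation, so ants
outside their range are never drawn and rare edge-of-range ants rarely.
Affinities are drawn once per plant, exponentiated by a concentration
exponent gamma and renormalized: gamma = 0 gives uniform partner use,
large gamma concentrates each plant on a single ant.  Gamma itself may
shift with elevation (``specialization_gamma_slope``), emulating reduced
choosiness where partners are scarce; the shift is what drives declining
network specialization upslope.

A configurable fraction of occupied records has its ant relabelled
``"uncertain"`` (resident but not collected), to exercise the downstream
exclusion rule.  Heights and DBH are lognormal schema-fidelity fields that
feed no in-scope statistic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .network import UNCERTAIN_LABEL

CENSUS_COLUMNS = (
    "tree_id", "elevation_m", "plant_species", "occupied", "ant_species",
    "height_m", "dbh_cm", "herb_cat1", "herb_cat2", "herb_cat3", "herb_cat4",
)


class CensusFormatError(ValueError):
    """Malformed census table; message carries the offending row number."""


@dataclass(frozen=True)
class SpeciesPool:
    """One species' elevational niche and partner-affinity profile.

    ``affinity`` is the normalized partner-weight vector after exponentiation
    by the community's specialization exponent gamma; ``base_affinity``
    retains the raw (pre-exponentiation) weights so the census generator can
    re-concentrate them with an elevation-shifted gamma.
    """

    species_id: str
    trophic_side: str                # "plant" or "ant"
    range_center: float              # m a.s.l.
    range_width: float               # Gaussian SD, metres
    peak_abundance: float            # expected individuals/transect at center
    affinity: np.ndarray             # normalized weights over partner species
    base_affinity: np.ndarray | None = None

    def __post_init__(self):
        if self.trophic_side not in ("plant", "ant"):
            raise ValueError("trophic_side must be 'plant' or 'ant'")
        if not self.range_width > 0:
            raise ValueError("range_width must be positive")
        if self.peak_abundance < 0:
            raise ValueError("peak_abundance must be non-negative")
        affinity = np.asarray(self.affinity, dtype=float)
        if affinity.size == 0 or not (affinity > 0).any():
            raise ValueError("affinity needs at least one positive entry")
        object.__setattr__(self, "affinity", affinity)
        if self.base_affinity is not None:
            object.__setattr__(self, "base_affinity",
                               np.asarray(self.base_affinity, dtype=float))

    def kernel(self, elevation: float) -> float:
        """Gaussian range kernel, hard-truncated at 3 SD."""
        z = (elevation - self.range_center) / self.range_width
        if abs(z) > 3.0:
            return 0.0
        return float(np.exp(-0.5 * z * z))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic census.

    Defaults are the census structure the analysis assumes: ten 100 m
    elevational steps from 700 to 1600 m, 23 plant and 10 ant species,
    multiplicative abundance decline per 100 m, occupancy of common hosts
    near 0.72 at the bottom of the gradient declining upslope, moderate
    partner specialization, and ordinal herbivory shifting toward heavier
    damage with elevation via a cumulative-logit model.
    """

    elevations: tuple = tuple(range(700, 1601, 100))
    n_plant_species: int = 23
    n_ant_species: int = 10
    abundance_decline_rate: float = 0.82     # multiplicative per 100 m
    specialization_gamma: float = 2.5
    specialization_gamma_slope: float = -0.25   # gamma shift per 100 m, floor 0
    occupancy_curve: tuple | None = None     # per-elevation P(occupied)
    herbivory_base_logits: tuple = (0.4, 2.0, 4.0)   # ordered cut-points
    herbivory_elevation_slope: float = 0.15  # logit shift per 100 m
    uncertain_fraction: float = 0.08
    plant_peak_abundance: float = 8.0        # mean peak individuals/transect
    range_width_m: float = 200.0             # median Gaussian SD of ranges
    range_width_sigma: float = 0.25          # lognormal spread of widths
    center_beta: tuple = (1.0, 2.2)          # low-elevation skew of centers
    center_pad_m: float = 150.0
    mean_leaves: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.n_plant_species < 1 or self.n_ant_species < 1:
            raise ValueError("species counts must be >= 1")
        elev = tuple(float(e) for e in self.elevations)
        if len(elev) == 0 or any(b <= a for a, b in zip(elev, elev[1:])):
            raise ValueError("elevations must be strictly increasing")
        object.__setattr__(self, "elevations", elev)
        if self.specialization_gamma < 0:
            raise ValueError("specialization_gamma must be >= 0")
        if self.abundance_decline_rate <= 0:
            raise ValueError("abundance_decline_rate must be positive")
        if not 0.0 <= self.uncertain_fraction <= 1.0:
            raise ValueError("uncertain_fraction must be in [0, 1]")
        if self.occupancy_curve is None:
            occ = tuple(float(v) for v in np.linspace(0.72, 0.45, len(elev)))
        else:
            occ = tuple(float(p) for p in self.occupancy_curve)
        if len(occ) != len(elev):
            raise ValueError("occupancy_curve must match elevations in length")
        if any(not 0.0 <= p <= 1.0 for p in occ):
            raise ValueError("occupancy probabilities must be in [0, 1]")
        object.__setattr__(self, "occupancy_curve", occ)
        cuts = tuple(float(cc) for cc in self.herbivory_base_logits)
        if len(cuts) != 3 or any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("herbivory cut-points must be 3 strictly increasing values")
        object.__setattr__(self, "herbivory_base_logits", cuts)

    # -- scenario presets --------------------------------------------------
    @classmethod
    def abundance_only(cls, **kwargs) -> "SimulationConfig":
        """Turnover disabled: every range spans all elevations; only the
        multiplicative abundance decline acts.  High-elevation communities
        are then true rarefied versions of low-elevation ones."""
        kwargs.setdefault("range_width_m", 1e5)
        kwargs.setdefault("range_width_sigma", 0.0)
        kwargs.setdefault("specialization_gamma_slope", 0.0)
        return cls(**kwargs)

    @classmethod
    def with_turnover(cls, **kwargs) -> "SimulationConfig":
        """Default study conditions: truncated ranges create genuine
        species turnover on top of the abundance decline."""
        return cls(**kwargs)

    def occupancy_at(self, elevation: float) -> float:
        return self.occupancy_curve[self.elevations.index(float(elevation))]

    def gamma_at(self, elevation: float) -> float:
        """Specialization exponent at an elevation (shifted, floored at 0)."""
        e0 = min(self.elevations)
        return max(self.specialization_gamma +
                   self.specialization_gamma_slope * (elevation - e0) / 100.0,
                   0.0)

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in data.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("elevations", "occupancy_curve", "herbivory_base_logits",
                    "center_beta"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


def sample_species_pools(config: SimulationConfig, rng) -> tuple:
    """Draw plant and ant species pools for one community realization.

    Returns ``(plants, ants)``.  Range centers are spread over the padded
    elevational span with a low-elevation skew (most tropical myrmecophytes
    and their ants are lowland species), widths are lognormal around the
    configured median, and each plant's affinity over ants is a gamma draw
    exponentiated by ``specialization_gamma`` and renormalized.
    """
    lo = min(config.elevations) - config.center_pad_m
    hi = max(config.elevations) + config.center_pad_m
    a_beta, b_beta = config.center_beta

    def draw_side(side, n, peak_mean, partner_count):
        pools = []
        for idx in range(n):
            center = lo + (hi - lo) * rng.beta(a_beta, b_beta)
            width = config.range_width_m * np.exp(
                rng.normal(0.0, config.range_width_sigma))
            peak = peak_mean * np.exp(rng.normal(0.0, 0.4))
            base = rng.gamma(1.0, 1.0, size=partner_count)
            base_store = None
            if side == "plant":
                top = base.max()
                base = base / top if top > 0 else np.ones(partner_count)
                base_store = base
                gamma = config.specialization_gamma
                weights = np.ones(partner_count) if gamma == 0 else base ** gamma
                if not (weights > 0).any():
                    weights = np.ones(partner_count)
            else:
                weights = np.ones(partner_count)
            pools.append(SpeciesPool(
                species_id=f"{'P' if side == 'plant' else 'A'}{idx + 1:02d}",
                trophic_side=side,
                range_center=float(center),
                range_width=float(width),
                peak_abundance=float(peak),
                affinity=weights / weights.sum(),
                base_affinity=base_store,
            ))
        return pools

    plants = draw_side("plant", config.n_plant_species,
                       config.plant_peak_abundance, config.n_ant_species)
    ants = draw_side("ant", config.n_ant_species, 1.0, config.n_plant_species)
    return plants, ants


def _herbivory_probs(config: SimulationConfig, elevation: float) -> np.ndarray:
    eta = config.herbivory_elevation_slope * (elevation - min(config.elevations)) / 100.0
    cum = 1.0 / (1.0 + np.exp(-(np.asarray(config.herbivory_base_logits) - eta)))
    probs = np.diff(np.concatenate([[0.0], cum, [1.0]]))
    return np.clip(probs, 0.0, 1.0) / np.clip(probs, 0.0, 1.0).sum()


def generate_census(config: SimulationConfig, pools, rng) -> pd.DataFrame:
    """Simulate the full transect census as a CensusRecord table.

    Deterministic given (config, pools, rng state): the iteration order is
    fixed (elevation, then plant species, then individual), so the same seed
    yields a byte-identical CSV.
    """
    plants, ants = pools
    if len(plants) == 0 or len(ants) == 0:
        raise ValueError("empty species pools")
    e0 = min(config.elevations)
    rows = []
    tree_counter = 0
    for e_idx, elevation in enumerate(config.elevations):
        decline = config.abundance_decline_rate ** ((elevation - e0) / 100.0)
        p_occ = config.occupancy_curve[e_idx]
        herb_p = _herbivory_probs(config, elevation)
        ant_kernels = np.array([a.kernel(elevation) for a in ants])
        available = ant_kernels > 0
        gamma_e = config.gamma_at(elevation)
        for plant in plants:
            lam = plant.peak_abundance * plant.kernel(elevation) * decline
            n_ind = int(rng.poisson(lam)) if lam > 0 else 0
            if plant.base_affinity is not None:
                pref = plant.base_affinity ** gamma_e
            else:
                pref = plant.affinity
            # encounter rate: intrinsic preference x local ant availability
            weights = pref * ant_kernels
            if weights.sum() == 0 and available.any():
                weights = available.astype(float)
            if weights.sum() > 0:
                weights = weights / weights.sum()
            for _ in range(n_ind):
                tree_counter += 1
                occupied = int(rng.random() < p_occ)
                ant_label = ""
                if occupied and available.any():
                    ant_label = ants[int(rng.choice(len(ants), p=weights))].species_id
                    if config.uncertain_fraction > 0 and \
                            rng.random() < config.uncertain_fraction:
                        ant_label = UNCERTAIN_LABEL
                elif occupied:
                    occupied = 0   # no colonists available at this elevation
                height = min(float(np.exp(rng.normal(np.log(4.0), 0.5))), 15.0)
                dbh = float(np.exp(rng.normal(np.log(5.0), 0.5)))
                n_leaves = 1 + int(rng.poisson(config.mean_leaves - 1))
                herb = rng.multinomial(n_leaves, herb_p)
                rows.append((
                    f"T{tree_counter:05d}", float(elevation), plant.species_id,
                    occupied, ant_label, round(height, 2), round(dbh, 2),
                    int(herb[0]), int(herb[1]), int(herb[2]), int(herb[3]),
                ))
    return pd.DataFrame(rows, columns=list(CENSUS_COLUMNS))


def simulate_census(config: SimulationConfig | None = None,
                    seed: int | None = None) -> pd.DataFrame:
    """Convenience wrapper: pools + census from one seed."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pools = sample_species_pools(config, rng)
    return generate_census(config, pools, rng)


# ---------------------------------------------------------------------------
# Census CSV IO
# ---------------------------------------------------------------------------

def write_census(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_census(path) -> pd.DataFrame:
    """Read and validate a census CSV; errors carry data-row numbers."""
    records = pd.read_csv(path, dtype={"ant_species": "string"})
    missing = set(CENSUS_COLUMNS) - set(records.columns)
    if missing:
        raise CensusFormatError(f"missing columns: {sorted(missing)}")
    records["ant_species"] = records["ant_species"].fillna("").astype(str)
    return validate_census(records)


def validate_census(records: pd.DataFrame) -> pd.DataFrame:
    records = records.copy()
    if "ant_species" in records:
        records["ant_species"] = records["ant_species"].fillna("").astype(str)
    for row_pos, (_, row) in enumerate(records.iterrows(), start=2):
        if row["occupied"] not in (0, 1):
            raise CensusFormatError(f"row {row_pos}: occupied must be 0 or 1")
        if int(row["occupied"]) == 0 and row["ant_species"] != "":
            raise CensusFormatError(
                f"row {row_pos}: unoccupied record carries an ant species")
        if int(row["occupied"]) == 1 and row["ant_species"] == "":
            raise CensusFormatError(
                f"row {row_pos}: occupied record lacks an ant species")
        herb = [row[f"herb_cat{c}"] for c in range(1, 5)]
        if any(pd.isna(h) or h < 0 for h in herb):
            raise CensusFormatError(
                f"row {row_pos}: herbivory counts must be non-negative")
    return records
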