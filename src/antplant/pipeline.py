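"""End-to-end elevational network analysis: census -> networks -> metrics ->
rarefaction bands -> null tests -> trend tests -> report.

The public surface follows the model/results idiom: build an
:class:`ElevationalNetworkModel` from a census table (observed CSV or the
synthetic generator), call :meth:`~ElevationalNetworkModel.fit`, and read
estimates, bands, tests and diagnostics off the returned
:class:`ElevationalNetworkResults`, whose :meth:`summary` prints the whole
analysis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .network import (
    BipartiteNetwork, METRIC_NAMES, UNCERTAIN_LABEL, build_network,
    herbivory_index, metric_set, occupancy_rate,
)
from .nulls import (
    BAND_METRICS_DEFAULT, bands_frame, h2_significance, pool_community,
    prediction_bands,
)
from .simulate import (
    SimulationConfig, read_census, simulate_census, validate_census,
    write_census,
)
from .trends import DEFAULT_TREND_SPECS, trend_table, trends_frame


@dataclass
class AnalysisConfig:
    """Configuration of one full pipeline run."""

    census_path: str | None = None          # either a CSV path ...
    simulation: SimulationConfig | None = None   # ... or simulate
    pooled_elevations: tuple = (700.0, 800.0)
    band_replicates: int = 1000
    n_null: int = 1000
    n_perm: int = 10000
    modularity_restarts: int = 20
    band_modularity_restarts: int = 5
    exclude_uncertain: bool = True
    drop_top_elevation: bool = False
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        for name in ("band_replicates", "n_null", "n_perm"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["pooled_elevations"] = list(self.pooled_elevations)
        if self.simulation is not None:
            sim = dataclasses.asdict(self.simulation)
            data["simulation"] = {
                k: (list(v) if isinstance(v, tuple) else v) for k, v in sim.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if data.get("simulation") is not None:
            sim = data["simulation"]
            for key in ("elevations", "occupancy_curve", "herbivory_base_logits",
                        "center_beta"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            data["simulation"] = SimulationConfig(**sim)
        if "pooled_elevations" in data:
            data["pooled_elevations"] = tuple(data["pooled_elevations"])
        return cls(**data)


class ElevationalNetworkModel:
    """Elevational bipartite-network analysis of an ant-plant census.

    Parameters
    ----------
    census : pandas.DataFrame
        Census table in the standard schema (one row per surveyed tree).
    pooled_elevations : tuple of float
        Elevations pooled into the low-elevation reference community for
        rarefaction (the two lowest transects by default).
    exclude_uncertain : bool
        Drop records whose resident ant could not be identified from the
        networks (they still count as occupied for occupancy rates).
    """

    def __init__(self, census: pd.DataFrame, pooled_elevations=(700.0, 800.0),
                 exclude_uncertain: bool = True):
        self.census = validate_census(census)
        self.elevations = tuple(sorted(self.census["elevation_m"].astype(float).unique()))
        if len(self.elevations) == 0:
            raise ValueError("census contains no records")
        self.pooled_elevations = tuple(
            float(e) for e in pooled_elevations if float(e) in self.elevations)
        if not self.pooled_elevations:
            # degenerate input: fall back to the lowest available elevation
            self.pooled_elevations = (self.elevations[0],)
        self.exclude_uncertain = exclude_uncertain

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ElevationalNetworkModel":
        return cls(read_census(path), **kwargs)

    @classmethod
    def from_simulation(cls, config: SimulationConfig | None = None,
                        seed: int | None = None, **kwargs) -> "ElevationalNetworkModel":
        return cls(simulate_census(config, seed=seed), **kwargs)

    # ------------------------------------------------------------------
    def networks(self) -> dict:
        return {e: build_network(self.census, e, self.exclude_uncertain)
                for e in self.elevations}

    def record_accounting(self) -> pd.DataFrame:
        """Per-elevation census accounting: every row used or explained."""
        rows = []
        for e in self.elevations:
            sub = self.census[self.census["elevation_m"].astype(float) == e]
            occupied = sub["occupied"].astype(int) == 1
            uncertain = occupied & (sub["ant_species"] == UNCERTAIN_LABEL)
            used = occupied & ~uncertain if self.exclude_uncertain else occupied
            rows.append({
                "elevation_m": e,
                "n_censused": len(sub),
                "n_unoccupied": int((~occupied).sum()),
                "n_uncertain_excluded": int(uncertain.sum()) if self.exclude_uncertain else 0,
                "n_network_events": int(used.sum()),
            })
        return pd.DataFrame(rows)

    # ------------------------------------------------------------------
    def fit(self, seed: int = 0, band_replicates: int = 1000,
            n_null: int = 1000, n_perm: int = 10000,
            modularity_restarts: int = 20, band_modularity_restarts: int = 5,
            band_metrics=BAND_METRICS_DEFAULT,
            drop_top_elevation: bool = False) -> "ElevationalNetworkResults":
        """Run the full analysis; deterministic given ``seed``."""
        census = self.census
        elevations = list(self.elevations)
        if drop_top_elevation and len(elevations) > 1:
            elevations = elevations[:-1]

        networks = {e: build_network(census, e, self.exclude_uncertain)
                    for e in elevations}
        metrics = metrics_for_networks(networks, seed=seed,
                                       modularity_restarts=modularity_restarts)

        pool = pool_community(census, self.pooled_elevations,
                              self.exclude_uncertain)
        target_sizes = {e: net.m for e, net in networks.items()
                        if 1 <= net.m <= len(pool)}
        notices = []
        skipped = [e for e, net in networks.items() if net.m > len(pool)]
        if skipped:
            notices.append(
                f"elevations {skipped} exceed the pooled community size; no band")
        if len(pool) == 0:
            notices.append("pooled community is empty; no prediction bands")
            bands = []
        else:
            bands = prediction_bands(
                pool, target_sizes, n_replicates=band_replicates, seed=seed,
                metrics=band_metrics,
                modularity_restarts=band_modularity_restarts)
        bands_df = bands_frame(bands) if bands else pd.DataFrame(
            columns=["elevation_m", "metric", "lower", "upper",
                     "n_replicates", "n_undefined", "unreliable"])

        outside = _outside_band_flags(metrics, bands_df)

        null_rows = []
        for idx, (e, net) in enumerate(networks.items()):
            res = h2_significance(net, n_null=n_null,
                                  rng=np.random.default_rng([int(seed), 101, int(e)]))
            null_rows.append({
                "elevation_m": e, "metric": "h2_prime",
                "observed": res.observed, "p": res.p_value, "tail": res.tail,
                "n_null": res.n_null,
            })
        null_df = pd.DataFrame(null_rows)

        trends = trend_table(metrics, n_perm=n_perm, seed=seed)
        trends_df = trends_frame(trends)
        if len(metrics) > 1:
            sens = trend_table(metrics.iloc[:-1], n_perm=n_perm, seed=seed)
            sensitivity_df = trends_frame(sens)
        else:
            sensitivity_df = trends_df.iloc[0:0].copy()
            notices.append("single elevation: sensitivity trends empty")
        if len(metrics) < 3:
            notices.append("fewer than 3 elevations: regression trends undefined")

        occupancy = occupancy_table(census)
        herbivory = herbivory_table(census)

        metadata = {
            "seed": int(seed),
            "band_replicates": int(band_replicates),
            "n_null": int(n_null),
            "n_perm": int(n_perm),
            "modularity_restarts": int(modularity_restarts),
            "exclude_uncertain": bool(self.exclude_uncertain),
            "pooled_elevations": [float(e) for e in self.pooled_elevations],
            "drop_top_elevation": bool(drop_top_elevation),
            "antplant_version": __version__,
        }
        return ElevationalNetworkResults(
            model=self, networks=networks, metrics=metrics, bands=bands_df,
            outside_band=outside, null_tests=null_df, trends=trends_df,
            sensitivity_trends=sensitivity_df, occupancy=occupancy,
            herbivory=herbivory, record_log=self.record_accounting(),
            notices=notices, metadata=metadata)


def metrics_for_networks(networks: dict, seed: int = 0,
                         modularity_restarts: int = 20) -> pd.DataFrame:
    """Per-elevation MetricSet table (modularity seeded per elevation)."""
    rows = {}
    for e, net in networks.items():
        if net.is_empty:
            ms = metric_set(net)
        else:
            ms = metric_set(net, include_modularity=False)
            # modularity seeded per elevation, so results are identical
            # whether networks come from memory or from dumped TSVs
            from .network import optimize_modularity
            rng = np.random.default_rng([int(seed), 7, int(e)])
            ms.modularity_q = optimize_modularity(
                net, rng=rng, restarts=modularity_restarts).q
        row = ms.as_dict()
        row["m"] = net.m
        rows[e] = row
    frame = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    frame.index.name = "elevation_m"
    return frame


def _outside_band_flags(metrics: pd.DataFrame, bands: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for _, band in bands.iterrows():
        e = band["elevation_m"]
        name = band["metric"]
        if e not in metrics.index or name not in metrics.columns:
            continue
        value = metrics.loc[e, name]
        if np.isnan(value) or np.isnan(band["lower"]):
            flag = np.nan
        else:
            flag = float(not (band["lower"] - 1e-12 <= value <= band["upper"] + 1e-12))
        rows.append({"elevation_m": e, "metric": name, "observed": value,
                     "lower": band["lower"], "upper": band["upper"],
                     "outside_band": flag, "unreliable": band["unreliable"]})
    return pd.DataFrame(rows)


def occupancy_table(census: pd.DataFrame) -> pd.DataFrame:
    """Occupancy rate per plant species (pooled) and per elevation."""
    rows = []
    for species in sorted(census["plant_species"].unique()):
        rows.append({"plant_species": species, "elevation_m": np.nan,
                     "n": int((census["plant_species"] == species).sum()),
                     "occupancy": occupancy_rate(census, species)})
        sub = census[census["plant_species"] == species]
        for e in sorted(sub["elevation_m"].astype(float).unique()):
            rows.append({"plant_species": species, "elevation_m": e,
                         "n": int((sub["elevation_m"] == e).sum()),
                         "occupancy": occupancy_rate(census, species, e)})
    return pd.DataFrame(rows)


def herbivory_table(census: pd.DataFrame) -> pd.DataFrame:
    """Mean per-tree herbivory index (percent leaf damage) per elevation."""
    rows = []
    herb_cols = [f"herb_cat{c}" for c in range(1, 5)]
    for e in sorted(census["elevation_m"].astype(float).unique()):
        sub = census[census["elevation_m"].astype(float) == e]
        idx = [herbivory_index(r) for r in sub[herb_cols].to_numpy()]
        idx = [v for v in idx if not np.isnan(v)]
        rows.append({"elevation_m": e, "n_trees": len(idx),
                     "mean_herbivory_pct": float(np.mean(idx)) if idx else np.nan})
    return pd.DataFrame(rows)


@dataclass
class ElevationalNetworkResults:
    """Fitted elevational network analysis.

    Attributes are tidy tables: ``metrics`` (one row per elevation),
    ``bands`` and ``outside_band`` (elevation x metric), ``null_tests``
    (H2' Monte Carlo tests), ``trends`` and ``sensitivity_trends``
    (elevational trend tests with and without the topmost elevation),
    ``occupancy``, ``herbivory`` and the census ``record_log``.
    """

    model: ElevationalNetworkModel
    networks: dict
    metrics: pd.DataFrame
    bands: pd.DataFrame
    outside_band: pd.DataFrame
    null_tests: pd.DataFrame
    trends: pd.DataFrame
    sensitivity_trends: pd.DataFrame
    occupancy: pd.DataFrame
    herbivory: pd.DataFrame
    record_log: pd.DataFrame
    notices: list
    metadata: dict

    def summary(self) -> str:
        lines = []
        add = lines.append
        add("Elevational ant-plant network analysis")
        add("=" * 54)
        add(f"seed={self.metadata['seed']}  "
            f"band_replicates={self.metadata['band_replicates']}  "
            f"n_null={self.metadata['n_null']}  n_perm={self.metadata['n_perm']}")
        add(f"pooled elevations for rarefaction: "
            f"{self.metadata['pooled_elevations']}")
        add("")
        add("Per-elevation network metrics")
        add("-" * 54)
        add(self.metrics.round(3).to_string())
        add("")
        add("H2' Monte Carlo significance (marginal-preserving null)")
        add("-" * 54)
        add(self.null_tests.round(4).to_string(index=False))
        add("")
        add("Elevational trend tests")
        add("-" * 54)
        add(self.trends.round(4).to_string(index=False))
        if len(self.sensitivity_trends):
            add("")
            add("Sensitivity: topmost elevation excluded")
            add(self.sensitivity_trends.round(4).to_string(index=False))
        if len(self.outside_band):
            n_out = int(self.outside_band["outside_band"].sum())
            add("")
            add(f"Observed values outside their 95% rarefaction band: {n_out} "
                f"of {int(self.outside_band['outside_band'].notna().sum())}")
        for notice in self.notices:
            add(f"note: {notice}")
        return "\n".join(lines)

    def save(self, output_dir) -> Path:
        """Write all tables, dumped networks and the summary to a directory."""
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_census(self.model.census, out / "census.csv")
        self.metrics.to_csv(out / "metrics.csv")
        self.bands.to_csv(out / "bands.csv", index=False)
        self.outside_band.to_csv(out / "outside_band.csv", index=False)
        self.null_tests.to_csv(out / "null_tests.csv", index=False)
        self.trends.to_csv(out / "trends.csv", index=False)
        self.sensitivity_trends.to_csv(out / "sensitivity_trends.csv", index=False)
        self.occupancy.to_csv(out / "occupancy.csv", index=False)
        self.herbivory.to_csv(out / "herbivory.csv", index=False)
        self.record_log.to_csv(out / "record_log.csv", index=False)
        net_dir = out / "networks"
        net_dir.mkdir(exist_ok=True)
        for e, net in self.networks.items():
            if not net.is_empty:
                net.to_tsv(net_dir / f"network_{int(e)}m.tsv")
        (out / "summary.txt").write_text(self.summary() + "\n")
        (out / "run_metadata.yaml").write_text(
            yaml.safe_dump(self.metadata, sort_keys=False))
        return out

    def plot_metrics(self, path=None):
        """Quick-look figure: observed metrics vs elevation with their bands."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        names = [n for n in METRIC_NAMES if n in self.metrics.columns]
        fig, axes = plt.subplots(2, 4, figsize=(16, 7))
        for ax, name in zip(axes.ravel(), names):
            sub = self.bands[self.bands["metric"] == name]
            if len(sub):
                ax.bar(sub["elevation_m"], sub["upper"] - sub["lower"],
                       bottom=sub["lower"], width=60, color="0.8",
                       label="95% rarefaction band")
            ax.plot(self.metrics.index, self.metrics[name], "ko-", ms=4,
                    label="observed")
            ax.set_title(name)
            ax.set_xlabel("elevation (m a.s.l.)")
        for ax in axes.ravel()[len(names):]:
            ax.axis("off")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def run_analysis(config: AnalysisConfig) -> ElevationalNetworkResults:
    """Execute a configured pipeline run (and save it if output_dir set)."""
    if config.census_path is not None:
        model = ElevationalNetworkModel.from_csv(
            config.census_path, pooled_elevations=config.pooled_elevations,
            exclude_uncertain=config.exclude_uncertain)
    else:
        sim = config.simulation or SimulationConfig()
        model = ElevationalNetworkModel.from_simulation(
            sim, seed=config.seed, pooled_elevations=config.pooled_elevations,
            exclude_uncertain=config.exclude_uncertain)
    results = model.fit(
        seed=config.seed, band_replicates=config.band_replicates,
        n_null=config.n_null, n_perm=config.n_perm,
        modularity_restarts=config.modularity_restarts,
        band_modularity_restarts=config.band_modularity_restarts,
        drop_top_elevation=config.drop_top_elevation)
    if config.output_dir is not None:
        results.save(config.output_dir)
    return results
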