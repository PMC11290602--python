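"""End-to-end orchestration: configuration, stages, artifacts, manifest.

``run_analysis`` wires the stages together — tree input (or a synthetic
scenario), stem ages, rates and quantiles, MPD dispersion against the
permutation null, the optional pure-birth simulation null, and the optional
per-quantile richness maps — writing tabular outputs, figures and a MANIFEST
that records the seed, a config hash, package version and warnings.  The
defaults are the reference settings of the analysis: five quantiles, 1000
permutation replicates, 1000 simulated trees of 10,000 tips sliced at the
last fifth, a 1-degree grid.
"""

from __future__ import annotations

import hashlib
import json
import logging
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from numpy.random import SeedSequence

from . import __version__
from .errors import DivArrestError, TreeFormatError
from .treeio import (
    TreeSet, check_ultrametric, read_family_csv, read_tree_set, summarize_ages,
)
from .rates import make_rate_table
from .dispersion import dispersion_over_tree_set, plot_dispersion
from .famsim import simulation_null, plot_simulation_null
from .spatial import (
    presence_absence, quantile_maps, plot_quantile_maps, read_bbox_csv,
)
from .synthetic_data import ScenarioConfig, generate_scenario, write_scenario

log = logging.getLogger(__name__)

# master-seed fan-out: one named substream per stage so toggling a stage
# never changes another stage's draws
_STAGE_STREAMS = {"synthetic": 10, "dispersion": 11, "famsim": 12}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    ss = SeedSequence(master_seed, spawn_key=(_STAGE_STREAMS[stage],))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Settings of a full run; defaults are the reference analysis settings."""

    trees: str | None = None
    richness: str | None = None
    ranges: str | None = None
    scenario: ScenarioConfig | None = None
    k: int = 5
    n_permutations: int = 1000
    n_sims: int = 1000
    n_sim_tips: int = 10000
    slice_fraction: float = 0.8
    target_ages: list[float] = field(default_factory=list)
    resolution: float = 1.0
    seed: int = 0
    run_simnull: bool = False
    run_spatial: bool = True
    outdir: str = "divarrest_out"

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "scenario" in data and data["scenario"] is not None:
            data["scenario"] = ScenarioConfig(**data["scenario"])
        return cls(**data)


def validate_inputs(paths: dict[str, str]) -> list[str]:
    """Check input files for structural problems without mutating them.

    ``paths`` may contain 'trees' and 'richness' (and optionally 'ranges').
    Returns a list of human-readable issues; empty means clean.
    """
    issues: list[str] = []
    tree_set = None
    if "trees" in paths:
        try:
            tree_set = read_tree_set(paths["trees"])
        except DivArrestError as exc:
            issues.append(f"trees: {exc}")
        if tree_set is not None:
            try:
                tree_set.validate()
            except DivArrestError as exc:
                issues.append(f"trees: {exc}")
            for i, tree in enumerate(tree_set):
                for node in tree.preorder_node_iter():
                    e = node.edge
                    if e.length is not None and e.length < 0:
                        path_labels = []
                        up = node
                        while up is not None:
                            path_labels.append(
                                up.taxon.label if up.taxon else "<internal>")
                            up = up.parent_node
                        issues.append(
                            f"trees: tree {i + 1} negative branch length "
                            f"at node path {'/'.join(reversed(path_labels))}"
                        )
                try:
                    check_ultrametric(tree)
                except DivArrestError as exc:
                    issues.append(f"trees: tree {i + 1}: {exc}")
    richness = None
    if "richness" in paths:
        try:
            richness = read_family_csv(paths["richness"])
        except DivArrestError as exc:
            issues.append(f"richness: {exc}")
        if richness is not None and (richness["n_species"] < 1).any():
            bad = richness.loc[richness["n_species"] < 1, "family"].tolist()
            issues.append(f"richness: non-positive n_species for {bad[:10]}")
    if tree_set is not None and richness is not None:
        tree_fams = set(tree_set.families)
        csv_fams = set(richness["family"])
        for fam in sorted(csv_fams - tree_fams)[:20]:
            issues.append(f"agreement: family {fam!r} in richness CSV "
                          "missing from trees")
        for fam in sorted(tree_fams - csv_fams)[:20]:
            issues.append(f"agreement: family {fam!r} in trees missing "
                          "from richness CSV")
    return issues


def _load_inputs(config: RunConfig, outdir: Path, manifest: dict):
    """Return (tree_set, family_table, ranges_df_or_None)."""
    if config.scenario is not None:
        scenario = generate_scenario(config.scenario)
        paths = write_scenario(scenario, outdir / "synthetic")
        manifest["artifacts"].update({f"synthetic_{k}": v
                                      for k, v in paths.items()})
        return scenario.tree_set, scenario.family_table, scenario.ranges
    if config.trees is None or config.richness is None:
        raise TreeFormatError(
            "either a scenario or both tree and richness inputs are required")
    tree_set = read_tree_set(config.trees)
    tree_set.validate()
    family_table = summarize_ages(tree_set)
    richness = read_family_csv(config.richness).set_index("family")["n_species"]
    family_table = family_table.with_richness(richness)
    ranges = None
    if config.ranges:
        ranges = pd.read_csv(config.ranges)
    return tree_set, family_table, ranges


def run_analysis(config: RunConfig) -> dict:
    """Execute the pipeline; returns the manifest dictionary.

    Any stage failure raises after the MANIFEST (with its completion
    state) is written, so partial outputs remain inspectable.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": __version__,
        "artifacts": {},
        "completed": [],
        "warnings": [],
        "summary": {},
    }
    import matplotlib
    matplotlib.use("Agg", force=True)
    import matplotlib.pyplot as plt

    try:
        tree_set, family_table, ranges = _load_inputs(config, outdir, manifest)
        log.info("inputs: %d trees, %d families",
                 len(tree_set), len(family_table.families))
        manifest["completed"].append("inputs")

        rate_table = make_rate_table(family_table, k=config.k)
        rate_path = outdir / "rate_table.csv"
        rate_table.to_csv(rate_path, index=False)
        manifest["artifacts"]["rate_table"] = str(rate_path)
        fig, ax = plt.subplots(figsize=(8, 3))
        ordered = rate_table.sort_values(["rate", "family"])
        cmap = plt.get_cmap("viridis")
        ax.bar(np.arange(len(ordered)), ordered["rate"],
               color=[cmap((q - 1) / max(config.k - 1, 1))
                      for q in ordered["quantile"]])
        ax.set_xlabel("families (sorted by rate)")
        ax.set_ylabel("ln(N) / stem age (1/Myr)")
        fig.savefig(outdir / "rates.png", dpi=150)
        plt.close(fig)
        manifest["artifacts"]["rates_figure"] = str(outdir / "rates.png")
        manifest["completed"].append("rates")

        disp = dispersion_over_tree_set(
            tree_set, rate_table, n_reps=config.n_permutations,
            seed=stage_seed(config.seed, "dispersion"),
        )
        disp_path = outdir / "dispersion.csv"
        disp.per_tree.to_csv(disp_path, index=False)
        (outdir / "trend.json").write_text(json.dumps(disp.trend, indent=2))
        ax = plot_dispersion(disp)
        ax.figure.savefig(outdir / "dispersion.png", dpi=150)
        plt.close(ax.figure)
        manifest["artifacts"].update({
            "dispersion": str(disp_path),
            "trend": str(outdir / "trend.json"),
            "dispersion_figure": str(outdir / "dispersion.png"),
        })
        manifest["summary"]["trend"] = disp.trend
        manifest["summary"]["flag_rates"] = (
            disp.flag_rates().to_dict(orient="index"))
        manifest["completed"].append("dispersion")

        if config.run_simnull:
            targets = config.target_ages or [None]
            for target in targets:
                sim = simulation_null(
                    n_sims=config.n_sims, n_tips=config.n_sim_tips,
                    fraction=config.slice_fraction, target_root_age=target,
                    k=config.k, seed=stage_seed(config.seed, "famsim"),
                )
                tag = "unit" if target is None else f"{target:g}"
                sim_path = outdir / f"simnull_{tag}.csv"
                sim.mpd_table.to_csv(sim_path, index=False)
                ax = plot_simulation_null(sim)
                ax.figure.savefig(outdir / f"simnull_{tag}.png", dpi=150)
                plt.close(ax.figure)
                manifest["artifacts"][f"simnull_{tag}"] = str(sim_path)
                if sim.n_redraws:
                    manifest["warnings"].append(
                        f"simnull_{tag}: {sim.n_redraws} degenerate "
                        "simulations redrawn")
            manifest["completed"].append("simnull")

        if config.run_spatial and ranges is not None:
            range_csv = outdir / "ranges_input.csv"
            ranges.to_csv(range_csv, index=False)
            pam = presence_absence(read_bbox_csv(range_csv),
                                   resolution=config.resolution)
            grids = quantile_maps(pam, rate_table)
            for q, grid in grids.items():
                path = outdir / f"richness_q{q}.csv"
                grid.write_csv(path)
                manifest["artifacts"][f"richness_q{q}"] = str(path)
            fig = plot_quantile_maps(grids)
            fig.savefig(outdir / "richness_maps.png", dpi=150)
            plt.close(fig)
            manifest["artifacts"]["maps_figure"] = str(outdir / "richness_maps.png")
            manifest["completed"].append("spatial")
    finally:
        (outdir / "MANIFEST.json").write_text(
            json.dumps(manifest, indent=2, default=str))
    return manifest
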