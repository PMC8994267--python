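"""End-to-end pipeline driver: synth -> fit HMM -> fit SSF -> simulate ->
habitat use & connectivity.

``run_pipeline`` executes the whole chain on a synthetic valley (or on
user-supplied tracks) under a single master seed, writing per-stage outputs
and manifests into an output directory.  The same driver backs the command
line interface and the reproducibility script.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from movescape import io as mio
from movescape.connectivity import (
    connectivity_ratio,
    equal_area_bins,
    high_quality_proportion,
    patch_traversal_count,
    percent_intact,
    spearman_validation,
    transect_crossing_count,
    utilization_distribution,
)
from movescape.hmm import (
    DecaySpec,
    HmmParams,
    MovementHMM,
    build_steps,
    decay_model_selection,
)
from movescape.landscape import (
    LandscapeConfig,
    ScenarioSpec,
    apply_future_development,
    availability_mask,
    generate_labelled_tracks,
    generate_landscape,
)
from movescape.simulate import ScenarioBundle, SimConfig, simulate_ensemble
from movescape.ssf import DesignSpec, StepSelectionModel, sample_available_steps

__all__ = [
    "RunConfig",
    "default_true_hmm",
    "default_true_ssf",
    "make_scenarios",
    "run_pipeline",
]

SEASONS = ("spring", "summer", "fall", "winter")


def default_true_hmm() -> HmmParams:
    """Ground-truth movement parameters for the synthetic study system.

    Slow (foraging/resting): short steps (mean 50 m), weak reversal bias;
    fast (travelling): long steps (mean 500 m), directional persistence.
    Animals switch to the fast state near towns and in high trail density
    (unit-magnitude logit coefficients), with a diurnal cycle.
    """
    return HmmParams(
        mu=np.array([50.0, 500.0]),
        sigma=np.array([50.0, 400.0]),
        angle_mean=np.array([np.pi, 0.0]),
        kappa=np.array([0.5, 2.0]),
        beta=np.array(
            [
                # intercept, c_hour, town_dist, trail_density
                [-2.0, -1.0, -1.0, 1.0],
                [-1.0, 1.0, 1.0, -1.0],
            ]
        ),
        covariate_names=("c_hour", "town_dist", "trail_density"),
    )


def default_design_spec() -> DesignSpec:
    return DesignSpec.default(
        habitat_layers=("habitat",),
        anthropogenic_layers=("town_prox", "trail_density"),
        quadratic=("trail_density",),
        onoff_classes=("trail",),
        movement=True,
        interactions=True,
    )


def default_true_ssf() -> dict[str, float]:
    """Ground-truth selection coefficients for the synthetic system.

    Strong avoidance of town proximity that wanes in the fast state and at
    night; humped response to trail density; trails avoided when slow but
    selected as travel routes when fast.
    """
    spec = default_design_spec()
    truth = {t: 0.0 for t in spec.terms}
    truth.update(
        {
            "habitat": 1.0,
            "town_prox": -8.0,
            "town_prox:p_fast": 4.0,
            "town_prox:c_hour": 1.5,
            "trail_density": -0.4,
            "trail_density:p_fast": 0.2,
            "trail_density:c_hour": 0.1,
            "trail_density^2": -0.1,
            "on_trail": -0.5,
            "on_trail:p_fast": 1.0,
        }
    )
    return truth


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    output_dir: str = "movescape_run"
    master_seed: int = 0
    species: str = "wolf"
    seasons: tuple[str, ...] = ("summer",)
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    n_animals: int = 15
    n_steps_per_animal: int = 360
    tracks_csv: str | None = None  # if given, skip synthetic track stage
    decay_candidates: tuple[DecaySpec, ...] = (
        DecaySpec("capped_linear", 5000.0),
        DecaySpec("capped_linear", 2500.0),
        DecaySpec("exp_decay", 1000.0),
    )
    sim: SimConfig = field(default_factory=lambda: SimConfig(n_paths=300))
    scenarios: tuple[str, ...] = ("reference", "current", "future")
    n_informal_trails: int = 6
    town_expansion_m: float = 600.0
    run_stepwise: bool = False

    def __post_init__(self):
        bad = set(self.seasons) - set(SEASONS)
        if bad:
            raise ValueError(f"unknown seasons: {sorted(bad)}")
        if self.species == "grizzly_bear" and "winter" in self.seasons:
            raise ValueError("no winter season for grizzly bears (hibernation)")


def make_scenarios(stack, scene, config: RunConfig, seeds: mio.SeedRegistry):
    """Reference / current / future scenario specs for a landscape.

    Reference restores developed cells to available habitat and flags
    anthropogenic coefficients for zeroing; future expands the second town's
    footprint and adds informal trails (seeded), recomputing trail density
    and the mask.
    """
    geom = stack.geometry
    specs = {}
    if "reference" in config.scenarios:
        ref_mask = availability_mask(
            stack.layers["barren"], stack.layers["slope"], [], geom,
            include_developed=False,
        )
        specs["reference"] = ScenarioSpec(
            name="reference", mask_override=ref_mask, zero_anthropogenic=True
        )
    if "current" in config.scenarios:
        specs["current"] = ScenarioSpec(name="current")
    if "future" in config.scenarios:
        rng = np.random.default_rng(seeds.get("future-development"))
        import shapely
        from shapely.geometry import LineString

        # expand the eastern town's footprint
        grown = shapely.buffer(
            scene.towns[-1], config.town_expansion_m, quad_segs=2
        ).intersection(shapely.box(*geom.bounds))
        # informal trails: short random spurs near the towns
        informal = []
        for _ in range(config.n_informal_trails):
            town = scene.towns[rng.integers(len(scene.towns))]
            cx, cy = town.centroid.x, town.centroid.y
            ang = rng.uniform(0, 2 * np.pi)
            length = rng.uniform(1500.0, 4000.0)
            x0, y0, x1, y1 = geom.bounds
            ex = np.clip(cx + length * np.cos(ang), x0 + 1, x1 - 1)
            ey = np.clip(cy + length * np.sin(ang), y0 + 1, y1 - 1)
            informal.append(LineString([(cx, cy), (ex, ey)]))
        fut_stack, fut_scene = apply_future_development(
            stack, scene, new_town_polygons=[grown], informal_trails=informal
        )
        specs["future"] = ScenarioSpec(
            name="future",
            layer_overrides={"trail_density": fut_stack.layers["trail_density"]},
            mask_override=fut_stack.availability_mask,
        )
        specs["_future_scene"] = fut_scene
    return specs


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain and return artifacts and summary metrics."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = mio.SeedRegistry(config.master_seed)
    results: dict = {"config": config, "seeds": seeds}

    # -- stage 1: landscape + tracks ----------------------------------------
    stack, scene = generate_landscape(config.landscape, seeds.get("landscape"))
    results["stack"], results["scene"] = stack, scene
    true_hmm = default_true_hmm()
    true_ssf = default_true_ssf()
    spec = default_design_spec()
    results["true_hmm"], results["true_ssf"] = true_hmm, true_ssf

    if config.tracks_csv is None:
        tracks_df = generate_labelled_tracks(
            stack, scene, true_hmm, true_ssf,
            n_animals=config.n_animals, n_steps=config.n_steps_per_animal,
            seed=seeds.get("tracks"),
        )
        tracks_path = out / "tracks.csv"
        tracks_df.drop(columns="true_state").to_csv(tracks_path, index=False)
        results["tracks_df"] = tracks_df
    else:
        tracks_path = Path(config.tracks_csv)
    tracks = mio.read_tracks(tracks_path)
    mio.write_manifest(
        out / "manifest_tracks.json", "tracks", seeds.get("tracks"),
        {"n_tracks": len(tracks), "source": str(tracks_path)},
    )

    # -- stage 2: movement HMM ----------------------------------------------
    fit_kwargs = {"n_restarts": 10, "n_polish": 2, "seed": seeds.get("hmm-init")}
    best_decay, decay_table = decay_model_selection(
        tracks, stack, list(config.decay_candidates), fit_kwargs=fit_kwargs
    )
    series = [build_steps(t, stack, decay=best_decay) for t in tracks]
    hmm_fit = MovementHMM(series).fit(**fit_kwargs)
    results["decay_table"] = decay_table
    results["best_decay"] = best_decay
    results["hmm_fit"] = hmm_fit
    decay_table.to_csv(out / "hmm_decay_selection.csv")
    (out / "hmm_summary.txt").write_text(hmm_fit.summary())

    # -- stage 3: step selection --------------------------------------------
    p_fast = hmm_fit.smoothed_state_probs()
    strata = sample_available_steps(
        series, p_fast, stack.geometry, seed=seeds.get("availability")
    )
    model = StepSelectionModel.from_strata(strata, stack, scene, spec)
    ssf_fit = model.fit()
    results["ssf_fit"] = ssf_fit
    results["strata"] = strata
    if config.run_stepwise:
        from movescape.ssf import qic_backward_selection

        spec_sel, ssf_fit, qic_trace = qic_backward_selection(
            strata, stack, scene, spec
        )
        results["qic_trace"] = qic_trace
        results["ssf_fit"] = ssf_fit
        spec = spec_sel
    (out / "ssf_summary.txt").write_text(ssf_fit.summary())
    pd.DataFrame(
        {"coef": ssf_fit.params, "robust_se": ssf_fit.bse}
    ).to_csv(out / "ssf_coefficients.csv")

    # -- stage 4: simulation per scenario -----------------------------------
    scenario_specs = make_scenarios(stack, scene, config, seeds)
    ensembles = {}
    bundles = {}
    for name in config.scenarios:
        sc = scenario_specs[name]
        sim_scene = scenario_specs.get("_future_scene", scene) \
            if name == "future" else scene
        bundle = ScenarioBundle.build(
            stack, sim_scene, sc, hmm_fit.params, spec, ssf_fit.params
        )
        cfg = SimConfig(
            n_paths=config.sim.n_paths,
            steps_per_path=config.sim.steps_per_path,
            fixes_per_day=config.sim.fixes_per_day,
            n_candidates=config.sim.n_candidates,
            seed=seeds.get(f"simulation-{name}"),
        )
        ensembles[name] = simulate_ensemble(cfg, bundle)
        bundles[name] = bundle
    results["ensembles"] = ensembles
    results["bundles"] = bundles

    # -- stage 5: habitat use & connectivity --------------------------------
    geom = stack.geometry
    clip = min(config.sim.clip_buffer_m, 0.2 * min(geom.width, geom.height))
    uds = {
        name: utilization_distribution(ens, geom, "combined", clip_buffer_m=clip)
        for name, ens in ensembles.items()
    }
    results["uds"] = uds
    summary: dict = {}

    # the UD is only defined inside the clip window; bin over that interior
    X, Y = geom.cell_centres()
    x0, y0, x1, y1 = geom.bounds
    interior = (
        (X >= x0 + clip) & (X < x1 - clip) & (Y >= y0 + clip) & (Y < y1 - clip)
    )
    bin_mask = stack.availability_mask & interior
    results["bin_mask"] = bin_mask

    if "current" in uds:
        binmap = equal_area_bins(uds["current"], bin_mask)
        results["binmap"] = binmap
        # validate predicted use against the observed (input) GPS locations
        gx = np.concatenate([t.x for t in tracks])
        gy = np.concatenate([t.y for t in tracks])
        aids = np.concatenate(
            [np.repeat(t.animal_id, len(t)) for t in tracks]
        )
        rho, per_animal = spearman_validation(binmap, gx, gy, aids)
        summary["spearman_rho_pooled"] = rho
        results["spearman_per_animal"] = per_animal

    if scene.focal_area is not None:
        props = {}
        for name, ud in uds.items():
            bm = equal_area_bins(ud, bin_mask)
            props[name] = high_quality_proportion(
                bm, scene.focal_area, bin_mask
            )
        summary["high_quality_proportion"] = props
        if "reference" in props:
            summary["percent_intact"] = {
                name: percent_intact(p, props["reference"])
                for name, p in props.items()
            }

    if "reference" in ensembles:
        ref = ensembles["reference"]
        n_ref_patch = patch_traversal_count(ref, *scene.patches[:2])
        n_ref_cross = {
            i: transect_crossing_count(ref, tr)
            for i, tr in enumerate(scene.transects)
        }
        conn_rows = []
        for name, ens in ensembles.items():
            n_patch = patch_traversal_count(ens, *scene.patches[:2])
            conn_rows.append(
                {
                    "scenario": name, "metric": "patch",
                    **connectivity_ratio(
                        n_patch, n_ref_patch, ens.n_paths, ref.n_paths,
                        seed=seeds.get("connectivity-ci"),
                    ),
                }
            )
            for i, tr in enumerate(scene.transects):
                n_cross = transect_crossing_count(ens, tr)
                conn_rows.append(
                    {
                        "scenario": name, "metric": f"transect_{i}",
                        **connectivity_ratio(
                            n_cross, n_ref_cross[i], ens.n_paths, ref.n_paths,
                            seed=seeds.get("connectivity-ci"),
                        ),
                    }
                )
        conn = pd.DataFrame(conn_rows)
        results["connectivity"] = conn
        conn.to_csv(out / "connectivity.csv", index=False)
        summary["connectivity"] = conn.to_dict("records")

    results["summary"] = summary
    with open(out / "results.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    mio.write_manifest(
        out / "manifest_run.json", "pipeline", config.master_seed,
        {"seeds": seeds.issued, "scenarios": list(config.scenarios)},
    )
    return results
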