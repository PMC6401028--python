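"""End-to-end pipeline: ingest/simulate -> cover/BRI -> climate metrics ->
site table -> univariate screen -> model comparison -> NMDS -> PERMANOVA ->
sampling sufficiency, with a reproducible run manifest.

Stage order mirrors the analysis chain: score the bleaching response, derive
the thermal and disturbance predictors, screen them one at a time, compare
multi-term models, then ask what structures the community as a whole.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, bri, community, gam, simulate, sites, stats, sufficiency, survey, thermal

log = logging.getLogger("reefpulse")

#: Table-1-style predictor set screened against BRI.
SCREEN_PREDICTORS = [
    "MaxDHW_event", "MaxSST_event", "WkDHW4", "WkDHW8", "PAR",
    "CV_SST", "sigma_mon", "sigma_wk", "MaxSST_avg", "MMM",
    "MaxDHW_avg", "WkDHW4_avg", "WkDHW8_avg", "fDHW4", "fDHW8",
    "depth", "chl_a", "chl_a_avg", "expos", "waveh", "RA_POR",
    "lat", "long",
]

DEFAULT_MODELS = [
    {"name": "PAR+fDHW4", "smooth": ["PAR", "fDHW4"]},
    {"name": "PAR+fDHW4+CV_SST+chl_a",
     "smooth": ["PAR", "fDHW4", "CV_SST", "chl_a"]},
    {"name": "fDHW4+CV_SST+chl_a", "smooth": ["fDHW4", "CV_SST", "chl_a"]},
    {"name": "fDHW4+CV_SST+chl_a+RA_POR",
     "smooth": ["fDHW4", "CV_SST", "chl_a", "RA_POR"]},
    {"name": "GLM:PAR*fDHW4", "linear": ["PAR", "fDHW4"],
     "interactions": [["PAR", "fDHW4"]]},
]
DEFAULT_NESTED = [["PAR+fDHW4", "PAR+fDHW4+CV_SST+chl_a"]]

DEFAULT_PERMANOVA_TERMS = ["pop_metric", "fDHW4", "CV_SST", "chl_a"]


@dataclass
class RunManifest:
    """Record of one pipeline run: config snapshot, input digests, seed,
    package version, per-stage outputs and warnings."""

    config: dict
    seed: int
    version: str = __version__
    input_digests: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    defaults_used: list = field(default_factory=list)

    def write(self, path: Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {
                    "config": self.config,
                    "seed": self.seed,
                    "version": self.version,
                    "input_digests": self.input_digests,
                    "outputs": self.outputs,
                    "warnings": self.warnings,
                    "defaults_used": self.defaults_used,
                },
                fh,
                sort_keys=True,
            )


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a key/value mapping")
    return cfg


def _write(df: pd.DataFrame, out_dir: Path, name: str, manifest: RunManifest, index=True):
    path = out_dir / name
    if path.exists():
        raise FileExistsError(f"stage output already exists (write-once): {path}")
    df.to_csv(path, index=index)
    manifest.outputs[name.split(".")[0]] = str(path)
    log.info("wrote %s", path)


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> RunManifest:
    """Execute the full analysis from a config mapping (or YAML path).

    The config either names input files (``inputs: {survey, sst, env,
    villages}``) or a ``simulate`` stanza (``preset: gilberts-like`` plus
    ScenarioConfig overrides).  Each stage's table is written once under
    ``out_dir``; a stage failure aborts with the stage name attached to the
    raised error together with the partial manifest.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    if out_dir is None:
        out_dir = config.get("out_dir", "reefpulse_run")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = RunManifest(config=config, seed=seed)

    has_inputs = "inputs" in config
    has_sim = "simulate" in config
    if not has_inputs and not has_sim:
        raise ValueError("config needs an 'inputs' or 'simulate' stanza")

    stage = "ingest"
    try:
        if has_sim:
            sim_cfg = dict(config["simulate"] or {})
            sim_cfg.pop("preset", None)
            sim_cfg.setdefault("seed", seed)
            scen = simulate.ScenarioConfig(**sim_cfg)
            manifest.defaults_used.append(
                f"simulate: ScenarioConfig defaults for keys not overridden "
                f"(n_sites={scen.n_sites}, event_boost={scen.event_boost})"
            )
            world = simulate.simulate_site_set(scen)
            ds = world["survey"]
            site_table = world["site_table"]
            sst_series = world["sst"]
            event_win = world["event_window"]
        else:
            paths = config["inputs"]
            for key in ("survey", "sst", "env", "villages"):
                if key not in paths:
                    raise ValueError(f"inputs stanza missing {key!r}")
                manifest.input_digests[key] = _digest(paths[key])
            ds = survey.read_point_counts(paths["survey"])
            sst_series = thermal.read_sst_table(paths["sst"])
            env = pd.read_csv(paths["env"])
            villages = sites.read_villages(paths["villages"])
            event_win = tuple(config.get("event_window", ("2009-06-01", "2010-05-31")))
            therm = thermal.site_metric_table(sst_series, event_win)
            pop = sites.population_metric(villages)
            summaries = survey.taxon_summaries(ds, by_depth=False)
            site_table, report = sites.assemble_site_table(
                env, thermal=therm, ra_por=summaries["RA_POR"], pop_metric=pop
            )
            if report:
                manifest.warnings.append(f"join report: {report}")

        stage = "cover"
        cover = survey.compute_cover(ds)
        _write(cover, out_dir, "cover.csv", manifest)

        stage = "community_matrix"
        counts = survey.live_coral_taxon_counts(ds, by_depth=False)
        min_share = float(config.get("min_share", 0.005))
        comm = survey.build_community_matrix(counts, min_share=min_share)
        _write(comm, out_dir, "community_matrix.csv", manifest)

        stage = "bri"
        bri_site = bri.bri_table(ds, by_taxon=False).set_index("site_id")
        bri_taxon = bri.bri_table(ds, by_taxon=True)
        _write(bri_site, out_dir, "bri_site.csv", manifest)
        _write(bri_taxon, out_dir, "bri_taxon.csv", manifest, index=False)

        stage = "climate"
        if has_sim:
            therm = thermal.site_metric_table(sst_series, event_win)
            summaries = survey.taxon_summaries(ds, by_depth=False)
            site_table = site_table.drop(columns=["RA_POR"], errors="ignore").join(
                summaries["RA_POR"]
            )
        _write(therm, out_dir, "climate_metrics.csv", manifest)

        stage = "site_table"
        table = site_table.join(bri_site["bri"])
        _write(table, out_dir, "site_table.csv", manifest)

        stage = "screen"
        predictors = [p for p in SCREEN_PREDICTORS if p in table.columns]
        screen = stats.univariate_screen(table["bri"], table[predictors])
        manifest.defaults_used.append(
            f"screen: Bonferroni family size m={screen.attrs['family_size']}"
        )
        _write(screen, out_dir, "screen.csv", manifest)

        stage = "models"
        model_specs = config.get("models", DEFAULT_MODELS)
        nested = config.get("nested_pairs", DEFAULT_NESTED)
        fits = {}
        for spec in model_specs:
            fits[spec["name"]] = gam.fit_response_model(
                table,
                "bri",
                smooth=spec.get("smooth", ()),
                linear=spec.get("linear", ()),
                interactions=[tuple(p) for p in spec.get("interactions", ())],
                k=int(config.get("basis_dim", 3)),
                basis=config.get("basis", "cr"),
            )
        ranking, anodev = gam.compare_models(
            fits, [tuple(p) for p in nested if p[0] in fits and p[1] in fits]
        )
        _write(ranking, out_dir, "model_ranking.csv", manifest)
        _write(anodev, out_dir, "analysis_of_deviance.csv", manifest, index=False)

        stage = "nmds"
        dist = community.bray_curtis(comm)
        _write(dist, out_dir, "bray_curtis.csv", manifest)
        nm = community.nmds(
            dist,
            n_restarts=int(config.get("nmds_restarts", 20)),
            seed=seed,
        )
        _write(nm.coordinates, out_dir, "nmds_coordinates.csv", manifest)
        manifest.outputs["nmds_stress"] = float(nm.stress)

        stage = "permanova"
        terms = config.get("permanova_terms", DEFAULT_PERMANOVA_TERMS)
        terms = [t for t in terms if t in table.columns]
        perm = community.permanova(
            dist,
            table.loc[dist.index, terms],
            n_perm=int(config.get("n_perm", 999)),
            seed=seed,
        )
        manifest.defaults_used.append(
            f"permanova: sequential SS, term order {terms}, "
            f"n_perm={perm.attrs['n_perm']}"
        )
        _write(perm, out_dir, "permanova.csv", manifest)

        stage = "sufficiency"
        suff_site = config.get("sufficiency_site") or ds.sites[0]
        curve = sufficiency.cover_cv_curve(
            ds.subset(site_id=suff_site),
            n_reps=int(config.get("sufficiency_reps", 1000)),
            seed=seed,
        )
        _write(curve.to_long(), out_dir, "sufficiency.csv", manifest, index=False)
        n_min = sufficiency.minimal_images(curve)
        manifest.outputs["minimal_images"] = n_min if n_min is None else int(n_min)

    except Exception as exc:
        exc.stage = stage  # type: ignore[attr-defined]
        exc.manifest = manifest  # type: ignore[attr-defined]
        raise

    manifest.write(out_dir / "manifest.yaml")
    return manifest
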