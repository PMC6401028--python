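"""Synthetic reef scenarios: ENSO-modulated SST, bleaching surveys, communities.

The generator emulates the statistical structure the analysis assumes for a
central-equatorial-Pacific atoll chain: weekly SST with a small (~2 degC
range) seasonal cycle and an interannual AR(1) component whose amplitude is
largest at the equator and decays with latitude (a minimal stand-in for
ENSO, not a climate model); planted multi-week heat-stress events; ordered
bleaching severities driven by event heat stress and light and damped by
historical stress frequency, scaled by taxon susceptibility (high for
*Acropora*/*Pocillopora*, low for *Porites rus*, massive *Porites* and
*Heliopora*); and Dirichlet-multinomial coral communities whose *Porites
rus* share grows with the local human-population metric.

All draws flow from one seeded generator; each site uses the substream
``default_rng([seed, site_index, stage])`` so stages are independently
reproducible.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import sites as sites_mod
from . import thermal
from .survey import BLEACH_STATES, SurveyDataset
from .thermal import SSTSeries

WEEKS_PER_YEAR = 365.25 / 7.0

#: Relative bleaching susceptibility by taxon (1 = most susceptible).
DEFAULT_SUSCEPTIBILITY = {
    "acropora": 1.0,
    "pocillopora": 0.9,
    "montipora": 0.7,
    "millepora": 0.6,
    "lobophyllia": 0.6,
    "favites": 0.5,
    "favia": 0.5,
    "goniastrea": 0.5,
    "leptastrea": 0.5,
    "hydnophora": 0.5,
    "pavona": 0.5,
    "fungia": 0.4,
    "porites_branching": 0.5,
    "unidentified": 0.5,
    "porites_massive": 0.25,
    "heliopora": 0.2,
    "porites_rus": 0.15,
}

#: Dirichlet concentrations per atoll group: an Acropora-dominated northern
#: atoll, a massive-Porites/Heliopora/Pocillopora middle atoll, and a mixed
#: urbanized atoll whose Porites rus share is inflated by the population
#: metric at simulation time.
DEFAULT_COMMUNITY_ALPHA = {
    "tarawa": {
        "porites_rus": 2.0, "heliopora": 2.0, "porites_massive": 1.5,
        "pocillopora": 1.5, "acropora": 0.6, "montipora": 0.6,
        "favites": 0.6, "favia": 0.4, "lobophyllia": 0.4, "pavona": 0.4,
    },
    "abaiang": {
        "heliopora": 3.0, "porites_massive": 3.0, "pocillopora": 3.0,
        "porites_rus": 0.6, "acropora": 0.6, "montipora": 0.8,
        "favites": 0.8, "goniastrea": 0.5, "leptastrea": 0.4, "fungia": 0.4,
    },
    "butaritari": {
        "acropora": 8.0, "montipora": 1.5, "pocillopora": 1.2,
        "porites_massive": 1.0, "porites_branching": 0.8, "favites": 0.8,
        "favia": 0.6, "goniastrea": 0.6, "hydnophora": 0.5, "millepora": 0.5,
        "lobophyllia": 0.5, "pavona": 0.5, "fungia": 0.4, "porites_rus": 0.3,
    },
}

#: Benthic categories other than live/bleached/recently-dead coral, and the
#: probability a point lands in each (the coral complement).
DEFAULT_BACKGROUND = {
    "coral_dead_turf": 0.10,
    "coral_dead_cca": 0.05,
    "macroalgae": 0.12,
    "turf_algae": 0.10,
    "cca": 0.08,
    "sand": 0.12,
    "rubble": 0.08,
}


@dataclass
class ScenarioConfig:
    """Parameters of a synthetic multi-site scenario.

    Climate: ``seasonal_amplitude`` 1.0 degC gives the ~2 degC annual range
    of near-equatorial reefs.  ``enso_amplitude`` is the nominal equatorial
    stationary sd (degC) of the interannual AR(1) component, decaying as
    exp(-|lat|/``lat_scale``); the defaults put ~1.4 degC at the most
    equatorial sites (year-to-year variability about twice the seasonal sd,
    the regime emulated) falling to ~0.4 degC at the northern atoll, which
    sits at the edge of the equatorial current's ENSO response.  ``event_years`` get a
    raised-cosine SST boost (peak ``event_boost`` degC over ``event_duration``
    weeks, centred mid-November).

    Bleaching: latent site severity
    ``eta = b_base + b_stress*MaxDHW + b_par*(PAR - par_ref)
    - b_history*hist_scale*fDHW4``
    (units: per degC-week, per mol photons m-2 d-1, dimensionless), scaled by
    taxon susceptibility; a point's severity class is an exponential draw
    with mean eta binned at equally spaced thresholds, so eta <= 0 means
    every point scores normal.
    """

    n_sites: int = 14
    seed: int = 0
    # site layout: (atoll, latitude) tuples; populated in __post_init__
    site_plan: list = field(default_factory=list)
    # SST
    mean_sst: float = 29.0
    seasonal_amplitude: float = 1.0
    seasonal_peak_doy: int = 105          # boreal-spring thermal maximum
    enso_amplitude: float = 4.0
    lat_scale: float = 1.3
    ar1_annual_corr: float = 0.5
    noise_sd: float = 0.25
    start_year: int = 1985
    end_year: int = 2012
    event_years: tuple = (2004, 2009)
    event_boost: float = 2.5
    event_duration: int = 16              # weeks
    # bleaching response
    b_base: float = 0.2               # background severity: even the least
                                      # stressed sites show a little bleaching
    b_stress: float = 0.05
    b_par: float = 0.15
    b_history: float = 2.0
    par_ref: float = 46.0
    hist_scale: float = 1.0
    severity_step: float = 0.35           # latent threshold spacing
    susceptibility: dict = field(default_factory=lambda: dict(DEFAULT_SUSCEPTIBILITY))
    # community
    community_alpha: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_COMMUNITY_ALPHA.items()
    })
    pop_effect: float = 1.2               # log-scale boost of P. rus weight per
                                          # unit of the population metric
    # survey design
    points_per_image: int = 50
    images_per_transect: int = 25
    coral_cover: float = 0.35
    background: dict = field(default_factory=lambda: dict(DEFAULT_BACKGROUND))
    # environment gradients (PAR rises away from the equator during events;
    # chlorophyll and the interannual amplitude fall)
    par_lat_slope: float = 2.0
    chl_base: float = 0.38
    chl_lat_slope: float = -0.05
    waveh_base: float = 1.0
    waveh_lat_slope: float = 0.15

    def __post_init__(self):
        if not self.site_plan:
            self.site_plan = default_site_plan(self.n_sites)
        if len(self.site_plan) != self.n_sites:
            raise ValueError("site_plan length must equal n_sites")
        if self.event_duration <= 0:
            raise ValueError("event duration must be positive")
        for v in (self.enso_amplitude, self.seasonal_amplitude, self.noise_sd,
                  self.b_stress, self.b_par, self.b_history):
            if v < 0:
                raise ValueError("scale and effect parameters must be >= 0")

    def gamma(self, lat: float) -> float:
        """Interannual SST amplitude (degC) at a given latitude."""
        return self.enso_amplitude * float(np.exp(-abs(lat) / self.lat_scale))


def default_site_plan(n_sites: int) -> list[tuple[str, str, float, bool]]:
    """(site_id, atoll, latitude, urbanized) tuples for an n-site chain split
    over three atoll groups; the urbanized sites sit in the first atoll."""
    if n_sites < 4:
        raise ValueError("need >= 4 sites")
    groups = [("tarawa", 1.35, True), ("abaiang", 1.85, False), ("butaritari", 3.10, False)]
    base = n_sites // 3
    counts = [base + (1 if i < n_sites % 3 else 0) for i in range(3)]
    plan = []
    for (atoll, lat0, urban), cnt in zip(groups, counts):
        for j in range(cnt):
            plan.append(
                (f"{atoll[:3].upper()}{j+1:02d}", atoll, lat0 + 0.05 * j, urban)
            )
    return plan


# --- SST ---------------------------------------------------------------------

def simulate_sst(cfg: ScenarioConfig, site_index: int = 0) -> SSTSeries:
    """Weekly SST for one site: mean + seasonal sinusoid + latitude-scaled
    AR(1) interannual component + white noise + planted event boosts."""
    site_id, _, lat, _ = cfg.site_plan[site_index]
    rng = np.random.default_rng([cfg.seed, site_index, 0])
    weeks = pd.date_range(
        f"{cfg.start_year}-01-01", f"{cfg.end_year}-12-31", freq="7D"
    )
    n = len(weeks)
    doy = weeks.dayofyear.to_numpy()
    seasonal = cfg.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - cfg.seasonal_peak_doy) / 365.25
    )
    gamma = cfg.gamma(lat)
    rho = cfg.ar1_annual_corr ** (1.0 / WEEKS_PER_YEAR)
    inter = np.zeros(n)
    if gamma > 0:
        innov_sd = gamma * np.sqrt(1 - rho**2)
        inter[0] = rng.normal(0.0, gamma)
        eps = rng.normal(0.0, innov_sd, size=n - 1)
        for t in range(1, n):
            inter[t] = rho * inter[t - 1] + eps[t - 1]
    noise = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else 0.0
    # Event weeks: the warm phase overrides the (weak) seasonal cycle, so the
    # seasonal component is held at its annual maximum and the raised-cosine
    # boost rides on top — a peak boost of +2.5 degC then exceeds the MMM by
    # construction and accumulates bleaching-level DHW.
    boost = np.zeros(n)
    in_any_event = np.zeros(n, dtype=bool)
    for yr in cfg.event_years:
        center = pd.Timestamp(f"{yr}-11-15")
        offset_weeks = (weeks - center).days / 7.0
        half = cfg.event_duration / 2.0
        in_event = np.abs(offset_weeks) <= half
        in_any_event |= in_event
        boost[in_event] += cfg.event_boost * 0.5 * (
            1 + np.cos(np.pi * offset_weeks[in_event] / half)
        )
    seasonal = np.where(in_any_event, cfg.seasonal_amplitude, seasonal)
    sst = cfg.mean_sst + seasonal + inter + noise + boost
    return SSTSeries(site_id, weeks, sst, baseline_window=(cfg.start_year, 2009))


def event_window(cfg: ScenarioConfig, year: int) -> tuple[str, str]:
    """Analysis window spanning an event year and the following spring."""
    return (f"{year}-06-01", f"{year + 1}-05-31")


# --- communities and environment ---------------------------------------------

def _site_env_row(cfg, site_index, rng):
    site_id, atoll, lat, urban = cfg.site_plan[site_index]
    return {
        "site_id": site_id,
        "atoll": atoll,
        "lat": lat,
        "long": 173.0 + 0.1 * site_index,
        "depth": 11.0,
        "PAR": cfg.par_ref + cfg.par_lat_slope * (lat - 2.0) + rng.normal(0, 0.4),
        "chl_a": max(0.05, cfg.chl_base + cfg.chl_lat_slope * lat + rng.normal(0, 0.02)),
        "chl_a_avg": max(0.05, cfg.chl_base + cfg.chl_lat_slope * lat + rng.normal(0, 0.015)),
        "waveh": cfg.waveh_base + cfg.waveh_lat_slope * lat + rng.normal(0, 0.05),
        "expos": int(rng.integers(1, 5)),
    }


def simulate_villages(cfg: ScenarioConfig) -> pd.DataFrame:
    """Closest-village records: large, near villages at urbanized sites."""
    rows = []
    for i, (site_id, _, _, urban) in enumerate(cfg.site_plan):
        rng = np.random.default_rng([cfg.seed, i, 1])
        if urban:
            pop = float(rng.integers(8000, 16000))
            dist = float(rng.uniform(1.0, 2.5))
        else:
            pop = float(rng.integers(200, 900))
            dist = float(rng.uniform(2.0, 6.0))
        rows.append(
            {"site_id": site_id, "village_id": f"{site_id}_v1",
             "population": pop, "coast_dist_km": dist}
        )
    return pd.DataFrame(rows)


def simulate_communities(
    cfg: ScenarioConfig, pop_metric: pd.Series
) -> dict[str, np.ndarray]:
    """True coral-community shares per site: a Dirichlet draw from the atoll's
    concentration vector, with the *Porites rus* weight inflated by
    exp(pop_effect x pop_metric) before renormalization."""
    taxa = community_taxa(cfg)
    out = {}
    for i, (site_id, atoll, _, _) in enumerate(cfg.site_plan):
        rng = np.random.default_rng([cfg.seed, i, 2])
        alpha = np.array([cfg.community_alpha[atoll].get(t, 0.0) for t in taxa])
        alpha = np.where(alpha > 0, alpha, 1e-12)
        w = rng.dirichlet(alpha)
        j = taxa.index("porites_rus")
        w[j] *= np.exp(cfg.pop_effect * float(pop_metric[site_id]))
        out[site_id] = w / w.sum()
    return out


def community_taxa(cfg: ScenarioConfig) -> list[str]:
    taxa = sorted({t for d in cfg.community_alpha.values() for t in d})
    return taxa


def sample_community_counts(
    cfg: ScenarioConfig, communities: dict[str, np.ndarray], n_points: int | None = None,
) -> pd.DataFrame:
    """Multinomial coral-point counts per site at the transect coral budget
    (sites x taxa), the sampled analogue of the true shares."""
    taxa = community_taxa(cfg)
    if n_points is None:
        n_points = int(
            cfg.points_per_image * cfg.images_per_transect * cfg.coral_cover
        )
    rows = {}
    for i, (site_id, _, _, _) in enumerate(cfg.site_plan):
        rng = np.random.default_rng([cfg.seed, i, 3])
        rows[site_id] = rng.multinomial(n_points, communities[site_id])
    return pd.DataFrame.from_dict(rows, orient="index", columns=taxa).sort_index()


# --- surveys -----------------------------------------------------------------

def latent_severity(cfg: ScenarioConfig, max_dhw: float, par: float, fdhw4: float) -> float:
    """Site-level latent bleaching severity (dimensionless, >= 0 active)."""
    return (
        cfg.b_base
        + cfg.b_stress * max_dhw
        + cfg.b_par * (par - cfg.par_ref)
        - cfg.b_history * cfg.hist_scale * fdhw4
    )


def simulate_survey(
    cfg: ScenarioConfig,
    site_index: int,
    eta: float,
    true_community: np.ndarray,
    year: int,
    depth_band: str = "deep_10_12m",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Point records for one site-transect under latent severity ``eta``.

    Each point is background or coral per the configured cover; coral points
    draw a taxon from the true community and a severity class from the
    exponential-latent ordered model (eta <= 0 gives all-normal corals).
    """
    taxa = community_taxa(cfg)
    if abs(float(np.sum(true_community)) - 1.0) > 1e-9:
        raise ValueError("true community shares must sum to 1")
    site_id, atoll, _, _ = cfg.site_plan[site_index]
    if rng is None:
        rng = np.random.default_rng([cfg.seed, site_index, 4, year])
    bg_cats = list(cfg.background)
    bg_p = np.array([cfg.background[c] for c in bg_cats])
    bg_p = bg_p / bg_p.sum() * (1.0 - cfg.coral_cover)
    cats = ["__coral__"] + bg_cats
    probs = np.concatenate([[cfg.coral_cover], bg_p])

    n_img, n_pt = cfg.images_per_transect, cfg.points_per_image
    total = n_img * n_pt
    which = rng.choice(len(cats), size=total, p=probs)
    taxon_idx = rng.choice(len(taxa), size=total, p=true_community)
    thresholds = cfg.severity_step * np.arange(1, 7)

    sus = np.array([cfg.susceptibility.get(t, 0.5) for t in taxa])
    records = []
    sev_draws = rng.exponential(1.0, size=total)  # scaled per point below
    for idx in range(total):
        img, pt = divmod(idx, n_pt)
        cat = cats[which[idx]]
        if cat == "__coral__":
            taxon = taxa[taxon_idx[idx]]
            scale = eta * sus[taxon_idx[idx]]
            if scale <= 0:
                sev = 0
            else:
                sev = int(np.searchsorted(thresholds, sev_draws[idx] * scale))
            state = BLEACH_STATES[sev]
            if sev == 0 or sev == 1:
                label = "coral"
            elif sev < 6:
                label = "coral_bleached"
            else:
                label = "coral_recently_dead"
            records.append((site_id, atoll, depth_band, year, "T1",
                            img + 1, pt + 1, label, taxon, state))
        elif cat in ("coral_dead_turf", "coral_dead_cca"):
            taxon = taxa[taxon_idx[idx]] if rng.random() < 0.5 else "unidentified"
            records.append((site_id, atoll, depth_band, year, "T1",
                            img + 1, pt + 1, cat, taxon, None))
        else:
            records.append((site_id, atoll, depth_band, year, "T1",
                            img + 1, pt + 1, cat, None, None))
    return pd.DataFrame(
        records,
        columns=["site_id", "atoll", "depth_band", "year", "transect",
                 "image", "point", "label", "taxon", "bleach_state"],
    )


# --- full scenario -----------------------------------------------------------

def simulate_site_set(
    cfg: ScenarioConfig | None = None,
    include_surveys: bool = True,
    survey_year: int = 2010,
) -> dict:
    """Emit a complete multi-site scenario.

    Returns a dict with ``sst`` (site -> SSTSeries), ``site_table`` (env +
    thermal metrics + pop_metric per site), ``communities`` (true shares),
    ``community_counts`` (multinomial sample at the transect coral budget),
    ``villages``, ``truth`` (the planted parameters), and — unless
    ``include_surveys`` is off — ``survey`` (a SurveyDataset over all sites)
    and ``bri_truth`` (latent severities per site).
    """
    if cfg is None:
        cfg = ScenarioConfig()
    event_year = max(y for y in cfg.event_years if y < survey_year) if any(
        y < survey_year for y in cfg.event_years
    ) else cfg.event_years[0]
    window = event_window(cfg, event_year)

    sst = {}
    env_rows = []
    therm_rows = []
    for i, (site_id, atoll, lat, urban) in enumerate(cfg.site_plan):
        s = simulate_sst(cfg, i)
        sst[site_id] = s
        mmm = thermal.monthly_climatology_mmm(s)["MMM"]
        dhw = thermal.dhw_series(s, mmm)
        ev = thermal.event_stress_metrics(s, dhw, window)
        hist = thermal.historical_climate_metrics(s, mmm=mmm, dhw=dhw)
        env_rng = np.random.default_rng([cfg.seed, i, 5])
        env_rows.append(_site_env_row(cfg, i, env_rng))
        row = {"site_id": site_id}
        row.update({k: v for k, v in ev.__dict__.items() if k != "event_window"})
        row.update(hist.__dict__)
        therm_rows.append(row)

    env = pd.DataFrame(env_rows)
    therm = pd.DataFrame(therm_rows).set_index("site_id")
    villages = simulate_villages(cfg)
    pop = sites_mod.population_metric(villages)
    communities = simulate_communities(cfg, pop)
    counts = sample_community_counts(cfg, communities)

    site_table, _ = sites_mod.assemble_site_table(
        env, thermal=therm, pop_metric=pop
    )

    etas = {}
    for i, (site_id, *_rest) in enumerate(cfg.site_plan):
        etas[site_id] = latent_severity(
            cfg,
            therm.loc[site_id, "MaxDHW_event"],
            site_table.loc[site_id, "PAR"],
            therm.loc[site_id, "fDHW4"],
        )

    out = {
        "config": cfg,
        "sst": sst,
        "site_table": site_table,
        "villages": villages,
        "pop_metric": pop,
        "communities": communities,
        "community_counts": counts,
        "event_window": window,
        "truth": {
            "pop_effect": cfg.pop_effect,
            "b_stress": cfg.b_stress,
            "b_par": cfg.b_par,
            "b_history": cfg.b_history,
            "gamma": {sid: cfg.gamma(lat) for sid, _, lat, _ in cfg.site_plan},
            "latent_severity": etas,
        },
    }
    if include_surveys:
        frames = [
            simulate_survey(cfg, i, etas[cfg.site_plan[i][0]],
                            communities[cfg.site_plan[i][0]], survey_year)
            for i in range(cfg.n_sites)
        ]
        out["survey"] = SurveyDataset(
            pd.concat(frames, ignore_index=True),
            cfg.points_per_image,
            cfg.images_per_transect,
        )
    return out


def gilberts_like(seed: int = 0, **overrides) -> ScenarioConfig:
    """The default 14-site, three-atoll scenario preset."""
    return ScenarioConfig(seed=seed, **overrides)
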