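"""Synthetic donor cohorts with planted morphology-function relationships.

Emulates a cohort of cultured bone-marrow stromal-cell (BM-MSC) donor
populations: each donor carries latent morphology traits (cell/nucleus size
and width-to-length geometry, cytoskeletal filament density) plus a
functional assay panel (15-day growth curves in triplicate, alizarin-red
osteogenic AU, Oil-Red-O lipid %, ALP activity, CD-marker percentages).

Donor-level associations between traits and outcomes are planted through a
Gaussian copula: every trait and every outcome is a strictly monotone
transform of a latent standard normal, and a target Spearman correlation
``r_s`` between a trait and an outcome is induced by giving their latents
Pearson correlation ``rho = 2 sin(pi r_s / 6)`` (the exact bivariate-normal
relationship). Because the downstream screen is rank-based, the targets
survive all the marginal transforms.

Default effect sizes are the study's headline associations: nucleus
width/length vs osteogenic outcome (r_s = -0.5), mean cell area vs
proliferation AUC (r_s = -0.5), nucleus width/length vs CD146+ % (-0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .assays import (GROWTH_DAYS, AssayPanel, growth_auc,
                     population_doubling_time)


class ConfigError(ValueError):
    """Invalid cohort / effect configuration."""


#: Latent donor traits (each a monotone transform of a standard normal).
TRAITS = ("mean_cell_area", "cell_wl_ratio", "mean_nucleus_area",
          "nucleus_wl_ratio", "texture_intensity")

#: Outcomes that may carry planted effects.
OUTCOMES = ("osteo_au", "adipo_pct", "proliferation_auc", "alp_activity",
            "cd146_pct", "cd271_pct", "alp_pos_pct")

DEFAULT_EFFECTS: dict[tuple[str, str], float] = {
    ("nucleus_wl_ratio", "osteo_au"): -0.5,
    ("mean_cell_area", "proliferation_auc"): -0.5,
    ("nucleus_wl_ratio", "cd146_pct"): -0.5,
}

# Cohort-level marginal parameters. Areas are log-normal, ratios
# logit-normal (guaranteed support); medians/spreads chosen to mimic the
# wide inter-donor histograms of cultured BM-MSCs at subconfluence.
COHORT = dict(
    cell_area_median=8000.0, cell_area_sdlog=0.35,      # um^2
    cell_wl_mean=0.40, cell_wl_sdlogit=0.45,
    nucleus_area_median=360.0, nucleus_area_sdlog=0.20,  # um^2
    nucleus_wl_mean=0.72, nucleus_wl_sdlogit=0.35,
    texture_sdlog=0.30,
    pdt_mean_hours=76.5, pdt_sdlog=0.35,                 # cohort mean PDT
    osteo_mean=50.0, osteo_sd=20.0,                      # alizarin AU
    adipo_median_pct=8.0, adipo_sdlog=0.60,              # lipid area %
    alp_activity_median=0.40, alp_activity_sdlog=0.35,
)

#: Flow-cytometry marker percentages: (cohort mean, SD), clipped to [0,100].
CD_MARKERS = {
    "cd44_pct": (99.87, 0.21), "cd73_pct": (99.75, 0.28),
    "cd90_pct": (99.24, 0.81), "cd105_pct": (99.88, 0.08),
    "alp_pos_pct": (26.0, 16.0), "cd146_pct": (62.0, 30.0),
    "cd271_pct": (26.0, 25.0),
}

# Cell-to-cell (within-donor) spreads, scaled by EffectConfig.within_donor_scale.
WITHIN_DONOR = dict(cell_area_sdlog=0.35, cell_wl_sd=0.10,
                    nucleus_area_sdlog=0.18, nucleus_wl_sd=0.07)

# Latent correlation between cell-area and nucleus-area traits (bigger cells
# tend to carry bigger nuclei).
_AREA_COUPLING = 0.5


def spearman_to_pearson(r_s: float) -> float:
    """Latent-normal Pearson correlation inducing Spearman ``r_s``."""
    return 2.0 * math.sin(math.pi * r_s / 6.0)


@dataclass(frozen=True)
class EffectConfig:
    """Cohort size, planted effects, and noise settings for the generator."""

    n_donors: int = 56
    cells_per_donor: int = 1000
    effects: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS))
    growth_noise_cv: float = 0.10        # replicate count noise (log-normal)
    growth_carrying_capacity: float = 4e5
    growth_seed_count: float = 1000.0    # cells seeded per well
    within_donor_scale: float = 1.0      # multiplies cell-to-cell spreads
    seed: int = 0

    def validate(self) -> None:
        if self.n_donors < 1:
            raise ConfigError("n_donors must be >= 1")
        if self.cells_per_donor < 1:
            raise ConfigError("cells_per_donor must be >= 1")
        if self.within_donor_scale < 0:
            raise ConfigError("within_donor_scale must be >= 0")
        for (trait, outcome), r in self.effects.items():
            if trait not in TRAITS:
                raise ConfigError(f"unknown trait {trait!r}")
            if outcome not in OUTCOMES:
                raise ConfigError(f"unknown outcome {outcome!r}")
            if abs(r) >= 1.0:
                raise ConfigError(
                    f"target correlation magnitude for {(trait, outcome)} "
                    f"must be < 1, got {r}")
        # every outcome's residual variance must stay positive
        for outcome in OUTCOMES:
            self._outcome_weights(outcome)

    def _outcome_weights(self, outcome: str) -> tuple[np.ndarray, float]:
        """Latent loadings w per trait and residual SD s for one outcome."""
        w = np.zeros(len(TRAITS))
        for (trait, out), r in self.effects.items():
            if out == outcome:
                w[TRAITS.index(trait)] = spearman_to_pearson(r)
        sigma = np.eye(len(TRAITS))
        i, j = TRAITS.index("mean_cell_area"), TRAITS.index("mean_nucleus_area")
        sigma[i, j] = sigma[j, i] = _AREA_COUPLING
        resid_var = 1.0 - float(w @ sigma @ w)
        if resid_var <= 0:
            raise ConfigError(
                f"planted effects on {outcome!r} leave no residual variance")
        return w, math.sqrt(resid_var)


@dataclass(frozen=True)
class DonorTruth:
    """One donor's latent morphology ground truth."""

    donor_id: str
    mean_cell_area: float      # um^2, mean of the per-cell distribution
    cell_wl_ratio: float       # (0, 1]
    mean_nucleus_area: float   # um^2
    nucleus_wl_ratio: float    # (0, 1]
    texture_intensity: float   # >= 0, relative filament density
    latent_noise_sd: Mapping[str, float] = field(default_factory=dict)
    latents: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (0 < self.cell_wl_ratio <= 1 and 0 < self.nucleus_wl_ratio <= 1):
            raise ValueError("width/length ratios must lie in (0, 1]")
        if self.mean_cell_area <= 0 or self.mean_nucleus_area <= 0:
            raise ValueError("areas must be strictly positive")
        if self.mean_nucleus_area >= self.mean_cell_area:
            raise ValueError("nucleus must fit inside cell")
        if self.texture_intensity < 0:
            raise ValueError("texture_intensity must be >= 0")


def _trait_latents(config: EffectConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw the (n_donors, n_traits) latent normal matrix."""
    n = config.n_donors
    z = rng.standard_normal((n, len(TRAITS)))
    i, j = TRAITS.index("mean_cell_area"), TRAITS.index("mean_nucleus_area")
    z[:, j] = _AREA_COUPLING * z[:, i] + math.sqrt(1 - _AREA_COUPLING**2) * z[:, j]
    return z


def _truth_from_latents(donor_id: str, z: np.ndarray,
                        config: EffectConfig) -> DonorTruth:
    c, s = COHORT, config.within_donor_scale
    zmap = dict(zip(TRAITS, z))
    return DonorTruth(
        donor_id=donor_id,
        mean_cell_area=c["cell_area_median"]
        * math.exp(c["cell_area_sdlog"] * zmap["mean_cell_area"]),
        cell_wl_ratio=float(expit(logit(c["cell_wl_mean"])
                                  + c["cell_wl_sdlogit"] * zmap["cell_wl_ratio"])),
        mean_nucleus_area=c["nucleus_area_median"]
        * math.exp(c["nucleus_area_sdlog"] * zmap["mean_nucleus_area"]),
        nucleus_wl_ratio=float(expit(logit(c["nucleus_wl_mean"])
                                     + c["nucleus_wl_sdlogit"] * zmap["nucleus_wl_ratio"])),
        texture_intensity=math.exp(c["texture_sdlog"] * zmap["texture_intensity"]),
        latent_noise_sd={k: v * s for k, v in WITHIN_DONOR.items()},
        latents={t: float(v) for t, v in zmap.items()},
    )


def generate_cohort(config: EffectConfig) -> list[DonorTruth]:
    """Draw ``config.n_donors`` donor truths (deterministic in the seed)."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    z = _trait_latents(config, rng)
    return [_truth_from_latents(f"D{i:03d}", z[i], config)
            for i in range(config.n_donors)]


def _logistic_counts(pdt_hours: float, config: EffectConfig,
                     days=GROWTH_DAYS) -> np.ndarray:
    """Noiseless logistic growth counts at the sampling days."""
    n0 = config.growth_seed_count
    k = config.growth_carrying_capacity
    rate = math.log(2.0) / pdt_hours  # per hour
    t = 24.0 * np.asarray(days, dtype=float)
    growth = np.exp(rate * t)
    return k * n0 * growth / (k + n0 * (growth - 1.0))


def simulate_assays(donor: DonorTruth, config: EffectConfig, seed) -> AssayPanel:
    """Simulate one donor's functional assay panel.

    Outcome latents are ``z_out = w . z_traits + s * eps`` with loadings
    ``w`` derived from the planted Spearman targets, so every outcome is a
    monotone transform of a normal correlated with its trait as configured.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    z_traits = np.array([donor.latents[t] for t in TRAITS])
    c = COHORT

    z_out = {}
    for outcome in OUTCOMES:  # fixed order => reproducible stream
        w, s = config._outcome_weights(outcome)
        z_out[outcome] = float(w @ z_traits) + s * rng.standard_normal()

    # proliferation: doubling time log-normal around the cohort mean; higher
    # proliferation latent => faster growth => lower PDT, higher AUC
    sd = c["pdt_sdlog"]
    pdt_true = math.exp(math.log(c["pdt_mean_hours"]) - 0.5 * sd * sd
                        - sd * z_out["proliferation_auc"])
    clean = _logistic_counts(pdt_true, config)
    cv = config.growth_noise_cv
    noise = np.exp(cv * rng.standard_normal((len(GROWTH_DAYS), 3))
                   - 0.5 * cv * cv) if cv > 0 else np.ones((len(GROWTH_DAYS), 3))
    counts = clean[:, None] * noise
    growth = pd.DataFrame({
        "day": np.repeat(GROWTH_DAYS, 3),
        "replicate": np.tile([1, 2, 3], len(GROWTH_DAYS)),
        "count": counts.ravel(),
    })
    day_means = counts.mean(axis=1)
    auc = growth_auc(GROWTH_DAYS, day_means)
    try:
        pdt = population_doubling_time(day_means[GROWTH_DAYS.index(1)],
                                       day_means[GROWTH_DAYS.index(6)])
    except ValueError:
        pdt = float("nan")

    cd = {}
    for marker, (mu, sd_m) in CD_MARKERS.items():
        z = z_out.get(marker, None)
        if z is None:
            z = rng.standard_normal()
        cd[marker] = float(np.clip(mu + sd_m * z, 0.0, 100.0))

    return AssayPanel(
        donor_id=donor.donor_id,
        growth=growth,
        proliferation_auc=auc,
        pdt_hours=pdt,
        alizarin_au=float(np.clip(c["osteo_mean"] + c["osteo_sd"]
                                  * z_out["osteo_au"], 0.5, None)),
        alp_activity=c["alp_activity_median"]
        * math.exp(c["alp_activity_sdlog"] * z_out["alp_activity"]),
        lipid_pct=float(np.clip(c["adipo_median_pct"]
                                * math.exp(c["adipo_sdlog"] * z_out["adipo_pct"]),
                                0.05, 95.0)),
        cd_markers=cd,
    )


def simulate_cohort(config: EffectConfig) -> tuple[list[DonorTruth], list[AssayPanel]]:
    """Cohort truths plus per-donor assay panels, one seed stream."""
    truths = generate_cohort(config)
    children = np.random.SeedSequence([config.seed, 1]).spawn(len(truths))
    panels = [simulate_assays(d, config, s) for d, s in zip(truths, children)]
    return truths, panels


# ---------------------------------------------------------------------------
# Donor-level feature table (fast path that bypasses image rendering)
# ---------------------------------------------------------------------------

SER_PATTERNS = ("spot", "edge", "ridge", "saddle", "valley", "hole",
                "bright", "dark")
SER_CHANNELS = ("dapi", "actin", "tubulin")
_SER_BASE = dict(spot=0.06, edge=0.10, ridge=0.12, saddle=0.04,
                 valley=0.05, hole=0.05, bright=0.15, dark=0.12)

_MORPH_MEANS = (
    "cell_area_mean", "cell_width_mean", "cell_length_mean",
    "cell_wl_ratio_mean", "cell_roundness_mean",
    "nucleus_area_mean", "nucleus_width_mean", "nucleus_length_mean",
    "nucleus_wl_ratio_mean", "nucleus_roundness_mean",
)
_MORPH_SDS = tuple(name.replace("_mean", "_sd") for name in _MORPH_MEANS)
_ACTIN_MORPH = ("cell_area_actin_mean", "cell_wl_ratio_actin_mean")
_SER_COLUMNS = tuple(f"ser_{p}_{ch}_mean" for ch in SER_CHANNELS
                     for p in SER_PATTERNS)

#: Predictor columns entering the multivariable analysis: the donor-mean
#: morphology and texture summaries (within-donor SD columns are carried in
#: the table but are dispersion metadata, not morphology predictors).
PREDICTOR_COLUMNS = _MORPH_MEANS + _ACTIN_MORPH + _SER_COLUMNS

#: Within-donor dispersion columns (present in the table, not predictors).
DISPERSION_COLUMNS = _MORPH_SDS

#: Outcome columns carried alongside the predictors.
OUTCOME_COLUMNS = ("osteo_au", "adipo_pct", "proliferation_auc", "pdt_hours",
                   "alp_activity") + tuple(CD_MARKERS)

# Donor-level dispersion of derived geometry summaries beyond the pure
# ellipse model (log-scale); keeps derived columns informative but not
# collinear with the primary traits.
_DERIVED_JITTER = 0.08
_ROUNDNESS_JITTER = 0.12


def _ellipse_axes(area: float, wl: float) -> tuple[float, float]:
    """(length, width) of the ellipse with given area and width/length."""
    length = math.sqrt(4.0 * area / (math.pi * wl))
    return length, length * wl


def generate_feature_table(config: EffectConfig) -> pd.DataFrame:
    """One row per donor: aggregated morphology/texture features + outcomes.

    Shares the latent draw of :func:`generate_cohort` under the same seed;
    feature means carry the sampling error of averaging
    ``cells_per_donor`` cells, derived geometry summaries carry additional
    donor-level dispersion, SER texture summaries load on per-channel
    texture latents.
    """
    truths, panels = simulate_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    j = config.within_donor_scale / math.sqrt(config.cells_per_donor)
    w = WITHIN_DONOR
    rows = []
    for truth, panel in zip(truths, panels):
        g = rng.standard_normal
        area = truth.mean_cell_area * math.exp(w["cell_area_sdlog"] * j * g())
        wl = float(np.clip(truth.cell_wl_ratio + w["cell_wl_sd"] * j * g(),
                           0.02, 1.0))
        narea = truth.mean_nucleus_area * math.exp(
            w["nucleus_area_sdlog"] * j * g())
        nwl = float(np.clip(truth.nucleus_wl_ratio
                            + w["nucleus_wl_sd"] * j * g(), 0.02, 1.0))
        clen, cwid = _ellipse_axes(area, wl)
        nlen, nwid = _ellipse_axes(narea, nwl)
        s = config.within_donor_scale
        row = {
            "donor_id": truth.donor_id,
            "n_cells": config.cells_per_donor,
            "cell_area_mean": area,
            "cell_width_mean": cwid * math.exp(_DERIVED_JITTER * g()),
            "cell_length_mean": clen * math.exp(_DERIVED_JITTER * g()),
            "cell_wl_ratio_mean": wl,
            "cell_roundness_mean": float(np.clip(
                wl * math.exp(_ROUNDNESS_JITTER * g()), 0.02, 1.0)),
            "nucleus_area_mean": narea,
            "nucleus_width_mean": nwid * math.exp(_DERIVED_JITTER * g()),
            "nucleus_length_mean": nlen * math.exp(_DERIVED_JITTER * g()),
            "nucleus_wl_ratio_mean": nwl,
            "nucleus_roundness_mean": float(np.clip(
                nwl * math.exp(_ROUNDNESS_JITTER * g()), 0.02, 1.0)),
            # within-donor spreads as measured summaries (0 when the
            # within-donor scale is 0)
            "cell_area_sd": area * w["cell_area_sdlog"] * s * math.exp(0.1 * g()) if s else 0.0,
            "cell_width_sd": cwid * 0.2 * s * math.exp(0.1 * g()) if s else 0.0,
            "cell_length_sd": clen * 0.2 * s * math.exp(0.1 * g()) if s else 0.0,
            "cell_wl_ratio_sd": w["cell_wl_sd"] * s * math.exp(0.1 * g()) if s else 0.0,
            "cell_roundness_sd": 0.1 * s * math.exp(0.1 * g()) if s else 0.0,
            "nucleus_area_sd": narea * w["nucleus_area_sdlog"] * s * math.exp(0.1 * g()) if s else 0.0,
            "nucleus_width_sd": nwid * 0.1 * s * math.exp(0.1 * g()) if s else 0.0,
            "nucleus_length_sd": nlen * 0.1 * s * math.exp(0.1 * g()) if s else 0.0,
            "nucleus_wl_ratio_sd": w["nucleus_wl_sd"] * s * math.exp(0.1 * g()) if s else 0.0,
            "nucleus_roundness_sd": 0.08 * s * math.exp(0.1 * g()) if s else 0.0,
            "cell_area_actin_mean": truth.mean_cell_area * math.exp(0.10 * g()),
            "cell_wl_ratio_actin_mean": float(np.clip(
                truth.cell_wl_ratio + 0.05 * g(), 0.02, 1.0)),
        }
        chan_latents = {
            "tubulin": truth.latents["texture_intensity"],
            "actin": g(),
            "dapi": g(),
        }
        for chan in SER_CHANNELS:
            for pat in SER_PATTERNS:
                load = 0.6 if (chan == "tubulin" and pat in ("ridge", "edge")) else 0.2
                row[f"ser_{pat}_{chan}_mean"] = float(np.clip(
                    _SER_BASE[pat] * math.exp(load * chan_latents[chan]
                                              + 0.25 * g()),
                    1e-4, 0.9))
        row.update(panel.as_row())
        rows.append(row)
    table = pd.DataFrame(rows)
    ordered = (["donor_id", "n_cells"] + list(PREDICTOR_COLUMNS)
               + list(DISPERSION_COLUMNS) + list(OUTCOME_COLUMNS))
    return table[ordered]


def with_effects(config: EffectConfig,
                 effects: Mapping[tuple[str, str], float]) -> EffectConfig:
    """Copy of ``config`` with a replaced effect map."""
    return replace(config, effects=dict(effects))
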