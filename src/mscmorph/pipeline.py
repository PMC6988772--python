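"""End-to-end orchestration: simulate -> (render -> segment -> extract ->
aggregate) -> bivariate screen -> group comparison -> stability selection.

A run is one immutable output directory holding every intermediate table,
a manifest (seed, config hash, package versions) and a plain-text report.
Two modes exist: ``table`` draws the donor feature table directly from the
latent cohort (fast path for the statistics), ``render`` additionally
renders fields per donor and recovers the features through the imaging
stages before the same analyses.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assays import classify_differentiation
from .features import aggregate_donor, extract_cell_table
from .rendering import DEFAULT_RENDER, RenderConfig, render_field, write_field
from .segment import (DEFAULT_CONFIG as DEFAULT_SEG, SegmentationConfig,
                      exclude_border_pair, segment_cells, segment_nuclei)
from .stabsel import StabilityConfig, aic_ladder, stability_selection
from .stats import correlate_screen, roc_auc, screen_table, ttest_unpaired
from .synth import (OUTCOME_COLUMNS, PREDICTOR_COLUMNS, EffectConfig,
                    generate_feature_table, simulate_cohort)

logger = logging.getLogger(__name__)

#: Default bivariate screen: (morphology feature, outcome) column pairs.
DEFAULT_PAIRS = (
    ("nucleus_wl_ratio_mean", "osteo_au"),
    ("nucleus_wl_ratio_mean", "adipo_pct"),
    ("nucleus_wl_ratio_mean", "cd146_pct"),
    ("nucleus_wl_ratio_mean", "alp_activity"),
    ("nucleus_area_mean", "proliferation_auc"),
    ("nucleus_area_mean", "osteo_au"),
    ("cell_area_mean", "proliferation_auc"),
    ("cell_area_mean", "osteo_au"),
    ("cell_area_mean", "adipo_pct"),
    ("cell_area_mean", "cd146_pct"),
    ("cell_wl_ratio_mean", "proliferation_auc"),
    ("ser_ridge_tubulin_mean", "proliferation_auc"),
    ("ser_ridge_tubulin_mean", "cd271_pct"),
)


@dataclass
class RunConfig:
    """Everything a reproducible run needs."""

    effect: EffectConfig = field(default_factory=EffectConfig)
    segmentation: SegmentationConfig = field(default_factory=lambda: DEFAULT_SEG)
    render: RenderConfig = field(default_factory=lambda: DEFAULT_RENDER)
    stability: StabilityConfig = field(default_factory=StabilityConfig)
    pairs: tuple = DEFAULT_PAIRS
    mode: str = "table"              # "table" | "render"
    fields_per_donor: int = 2        # render mode only
    min_cells: int = 50              # aggregation minimum in render mode
    write_images: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("table", "render"):
            raise ValueError("mode must be 'table' or 'render'")
        self.effect.validate()
        self.stability.validate()
        table_cols = set(PREDICTOR_COLUMNS) | set(OUTCOME_COLUMNS)
        for x, y in self.pairs:
            for name in (x, y):
                if name not in table_cols:
                    raise ValueError(f"pair column {name!r} is not produced "
                                     "by the feature table")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effect"]["effects"] = {f"{t}->{o}": r for (t, o), r
                                  in self.effect.effects.items()}
        d["pairs"] = [list(p) for p in self.pairs]
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        eff = raw.pop("effect", {})
        effects = eff.pop("effects", None)
        if effects is not None:
            eff["effects"] = {tuple(k.split("->")): v
                              for k, v in effects.items()}
        kwargs = {}
        if eff:
            kwargs["effect"] = EffectConfig(**eff)
        for key, klass in (("segmentation", SegmentationConfig),
                           ("render", RenderConfig),
                           ("stability", StabilityConfig)):
            sub = raw.pop(key, None)
            if sub:
                if "shape" in sub:
                    sub["shape"] = tuple(sub["shape"])
                kwargs[key] = klass(**sub)
        pairs = raw.pop("pairs", None)
        if pairs is not None:
            kwargs["pairs"] = tuple(tuple(p) for p in pairs)
        kwargs.update(raw)
        return cls(**kwargs)


def _donor_table_from_images(config: RunConfig, outdir: Path) -> pd.DataFrame:
    """Render, segment, extract, and aggregate; join assay panels."""
    truths, panels = simulate_cohort(config.effect)
    per_cell_frames = []
    for truth in truths:
        for f in range(config.fields_per_donor):
            field_img, gt = render_field(truth, f, config.seed, config.render)
            nuclei = segment_nuclei(field_img.channels["dapi"],
                                    config.segmentation)
            cells = segment_cells(field_img.channels["tubulin"], nuclei,
                                  config.segmentation)
            cells, nuclei = exclude_border_pair(cells, nuclei)
            per_cell_frames.append(extract_cell_table(
                field_img.channels, cells, nuclei,
                pixel_size=config.render.pixel_size,
                donor_id=truth.donor_id, field_id=f))
            if config.write_images:
                imgdir = outdir / "images"
                imgdir.mkdir(exist_ok=True)
                write_field(field_img, gt,
                            imgdir / f"{truth.donor_id}_f{f:02d}")
    per_cell = pd.concat([f for f in per_cell_frames if not f.empty],
                         ignore_index=True)
    per_cell.to_csv(outdir / "per_cell.csv", index=False)
    logger.info("extracted %d cells from %d donors", len(per_cell),
                len(truths))
    rows = []
    for truth, panel in zip(truths, panels):
        records = per_cell[per_cell["donor_id"] == truth.donor_id]
        if records.empty:
            logger.warning("donor %s: no retained cells after border "
                           "exclusion; dropped from the donor table",
                           truth.donor_id)
            continue
        profile = aggregate_donor(records, min_cells=config.min_cells)
        row = profile.as_row()
        row.update(panel.as_row())
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute all stages into ``outdir``; returns the run directory."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("stage simulate: %d donors (mode=%s)",
                config.effect.n_donors, config.mode)
    if config.mode == "table":
        donor_table = generate_feature_table(config.effect)
        predictors = list(PREDICTOR_COLUMNS)
    else:
        donor_table = _donor_table_from_images(config, outdir)
        predictors = [c for c in donor_table.columns
                      if c.endswith(("_mean", "_sd", "_cv"))
                      and donor_table[c].notna().all()]
    donor_table.to_csv(outdir / "donor_table.csv", index=False)

    logger.info("stage screen: %d pairs at ROUT Q=1%%", len(config.pairs))
    pairs = [p for p in config.pairs
             if p[0] in donor_table.columns and p[1] in donor_table.columns]
    if len(donor_table) >= 4:
        screen = screen_table(correlate_screen(donor_table, pairs))
    else:
        logger.warning("screen skipped: fewer than 4 donors")
        screen = screen_table([])
    screen.to_csv(outdir / "correlations.csv", index=False)
    if len(screen):
        logger.info("screen: %d outliers removed in total",
                    int(screen["n_outliers"].sum()))

    # group comparison (nucleus geometry between high-OB and high-AD donors)
    if len(donor_table) >= 4:
        group = classify_differentiation(donor_table["osteo_au"],
                                         donor_table["adipo_pct"],
                                         donor_ids=donor_table["donor_id"])
        donor_table = donor_table.assign(diff_group=group.to_numpy())
    else:
        donor_table = donor_table.assign(diff_group="unclassified")
    comp_rows = []
    ob = donor_table.loc[donor_table["diff_group"] == "high_OB",
                         "nucleus_wl_ratio_mean"]
    ad = donor_table.loc[donor_table["diff_group"] == "high_AD",
                         "nucleus_wl_ratio_mean"]
    if len(ob) >= 2 and len(ad) >= 2:
        t, p = ttest_unpaired(ob, ad)
        both = pd.concat([ob, ad])
        labels = np.concatenate([np.ones(len(ob)), np.zeros(len(ad))])
        roc = roc_auc(both.to_numpy(), labels)
        comp_rows.append({
            "feature": "nucleus_wl_ratio_mean", "n_high_OB": len(ob),
            "n_high_AD": len(ad), "t": t, "p": p, "auc": roc.auc,
            "auc_oriented": roc.auc_oriented, "ci_low": roc.ci_low,
            "ci_high": roc.ci_high, "ci_level_pct": roc.ci_level_pct,
        })
    else:
        logger.warning("group comparison skipped: a group has < 2 donors")
    pd.DataFrame(comp_rows, columns=[
        "feature", "n_high_OB", "n_high_AD", "t", "p", "auc", "auc_oriented",
        "ci_low", "ci_high", "ci_level_pct"]).to_csv(
            outdir / "group_comparison.csv", index=False)

    logger.info("stage stability selection (q=%s, theta=%.2f, PFER=%.1f)",
                config.stability.q or "from bound", config.stability.theta,
                config.stability.pfer)
    X = donor_table[predictors].to_numpy(dtype=float)
    for outcome, log_flag, tag in (("osteo_au", False, "osteo"),
                                   ("adipo_pct", True, "adipo")):
        stab_path = outdir / f"stability_{tag}.csv"
        aic_path = outdir / f"aic_{tag}.csv"
        if len(donor_table) < 10:
            logger.warning("%s: cohort too small for stability selection "
                           "(n=%d < 10); writing empty tables", tag,
                           len(donor_table))
            pd.DataFrame(columns=["variable", "selection_probability",
                                  "stable"]).to_csv(stab_path, index=False)
            pd.DataFrame(columns=["model", "covariates", "aic", "n"]).to_csv(
                aic_path, index=False)
            continue
        y = donor_table[outcome].to_numpy(dtype=float)
        y = np.log(y) if log_flag else y
        result = stability_selection(X, y, config.stability,
                                     variable_names=predictors)
        result.as_frame().to_csv(stab_path, index=False)
        ranking = [predictors[j] for j in result.ranking()]
        ladder = aic_ladder(donor_table, outcome, ranking,
                            log_outcome=log_flag)
        ladder.as_frame().to_csv(aic_path, index=False)
        logger.info("%s: %d stable variable(s)", tag, len(result.stable_set))

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    make_report(outdir)
    return outdir


def make_report(run_dir) -> str:
    """Human-readable summary of a completed run; writes report.txt."""
    run_dir = Path(run_dir)
    lines = ["Morphology-to-function screening report",
             "=" * 44, ""]
    screen_path = run_dir / "correlations.csv"
    if not screen_path.exists():
        raise FileNotFoundError("stage 'screen' output missing "
                                f"({screen_path})")
    screen = pd.read_csv(screen_path)
    lines.append("Bivariate screen (ROUT-filtered Spearman)")
    lines.append(f"{'pair':<52}{'r_s':>7}{'p':>10}{'n':>5}")
    for _, r in screen.iterrows():
        lines.append(f"{r['x'] + ' vs ' + r['y']:<52}"
                     f"{r['r_s']:>7.2f}{r['p']:>10.4f}{r['n_used']:>5d}")
    lines.append("")

    comp_path = run_dir / "group_comparison.csv"
    if comp_path.exists():
        comp = pd.read_csv(comp_path)
        lines.append("Group comparison (high-OB vs high-AD donors)")
        if comp.empty:
            lines.append("  not computed (insufficient group sizes)")
        for _, r in comp.iterrows():
            lines.append(
                f"  {r['feature']}: t = {r['t']:.2f}, p = {r['p']:.4f}, "
                f"AUC = {r['auc']:.2f} "
                f"({r['ci_low']:.2f} to {r['ci_high']:.2f}, "
                f"{r['ci_level_pct']:.1f}% CI), "
                f"n = {int(r['n_high_OB'])}/{int(r['n_high_AD'])}")
        lines.append("")

    for tag, label in (("osteo", "osteogenic"), ("adipo", "adipogenic (log)")):
        stab_path = run_dir / f"stability_{tag}.csv"
        if not stab_path.exists():
            raise FileNotFoundError(f"stage 'stability' output missing "
                                    f"({stab_path})")
        stab = pd.read_csv(stab_path)
        lines.append(f"Stability selection, {label} outcome")
        if stab.empty or not stab["stable"].any():
            lines.append("  no stable predictors at the threshold")
        for _, r in stab.head(6).iterrows():
            flag = "*" if r["stable"] else " "
            lines.append(f"  {flag} {r['variable']:<32} "
                         f"pi = {r['selection_probability']:.2f}")
        aic_path = run_dir / f"aic_{tag}.csv"
        if aic_path.exists():
            aic = pd.read_csv(aic_path)
            if not aic.empty:
                best = aic.loc[aic["aic"].idxmin(), "model"]
                lines.append("  AIC ladder: " + ", ".join(
                    f"{r['model']} = {r['aic']:.1f}"
                    for _, r in aic.iterrows()) + f" (best: {best})")
        lines.append("")
    text = "\n".join(lines)
    (run_dir / "report.txt").write_text(text)
    return text
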