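"""One-command orchestration: ingest or simulate, extract, fit, compare.

The pipeline runs the full analysis chain — daily CPUE standardization,
phenology extraction, per-species trends, group and sex comparisons — and
writes tidy CSV artifacts plus a run manifest (config hash, seed,
package version, per-stage row counts).  All outputs are deterministic
functions of the inputs and the seed, so a manifest suffices to
regenerate every artifact bit-identically.
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
from .groups import (DEFAULT_ALPHA_GRID, GroupComparison, compare_groups,
                     sex_group_analysis)
from .io import daily_cpue_table, read_captures, read_effort, read_species_metadata
from .phenology import PhenologyExtractor
from .simulate import SimulationConfig, SpeciesSpec, default_config, \
    simulate_station_dataset, write_dataset
from .trends import SpeciesTrendEstimator

log = logging.getLogger("phenopass")

__all__ = ["RunConfig", "RunResult", "run_pipeline"]

METRICS = ("start", "peak", "end", "window")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; defaults are the study constants
    (7-day MA, 10% threshold, <5-captures exclusion, 3-year minimum)."""

    outdir: str = "phenopass_run"
    captures_path: str | None = None
    effort_path: str | None = None
    species_meta_path: str | None = None
    simulate: bool = False
    simulate_overrides: dict = field(default_factory=dict)
    ma_window: int = 7
    threshold_frac: float = 0.1
    min_captures: int = 5
    min_years: int = 3
    cpue_scale: float = 100.0
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "alpha_grid" in raw:
            raw["alpha_grid"] = tuple(raw["alpha_grid"])
        return cls(**raw)

    def config_hash(self) -> str:
        # outdir is excluded: where artifacts land does not change what they are
        payload = {k: v for k, v in dataclasses.asdict(self).items()
                   if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    status: str  # "success" | "partial" | "failure"
    outputs: dict[str, Path]
    warnings: list[str]
    manifest: dict


def _simulation_config(cfg: RunConfig) -> SimulationConfig:
    over = dict(cfg.simulate_overrides)
    species = over.pop("species", None)
    sim = default_config(seed=cfg.seed, **{k: v for k, v in over.items()})
    if species is not None:
        sim.species = [SpeciesSpec(**s) for s in species]
    return sim


def _comparison_frames(comps: dict[str, GroupComparison]):
    slope_rows, contrast_rows, letter_rows = [], [], []
    for metric, comp in comps.items():
        s = comp.slopes.copy()
        s.insert(0, "metric", metric)
        slope_rows.append(s)
        bmap = {frozenset(b.pair): b for b in comp.brackets}
        c = comp.contrasts.copy()
        c.insert(0, "metric", metric)
        c["alpha_low"] = [np.nan if bmap[frozenset((a, b))].low is None
                          else bmap[frozenset((a, b))].low
                          for a, b in zip(c["group_a"], c["group_b"])]
        c["alpha_high"] = [np.nan if bmap[frozenset((a, b))].high is None
                           else bmap[frozenset((a, b))].high
                           for a, b in zip(c["group_a"], c["group_b"])]
        contrast_rows.append(c)
        for g in comp.groupings:
            for grp, letters in sorted(g.letters.items()):
                letter_rows.append({"metric": metric, "alpha": g.alpha,
                                    "group": grp, "letters": letters})
    return (pd.concat(slope_rows, ignore_index=True),
            pd.concat(contrast_rows, ignore_index=True),
            pd.DataFrame(letter_rows))


def _comparison_text(comps: dict[str, GroupComparison]) -> str:
    lines = []
    for metric, comp in comps.items():
        lines.append(f"== {metric} ==")
        if comp.dropped_groups:
            lines.append(f"groups dropped (truncation): {', '.join(comp.dropped_groups)}")
        lines.append(
            f"overall year trend (additive model): "
            f"{comp.overall_year_slope:+.3f} d/yr, t = {comp.overall_year_t:.3f}"
        )
        for _, r in comp.slopes.iterrows():
            lines.append(
                f"  {r['group']}: {r['slope']:+.2f} ± {r['se']:.2f} d/yr "
                f"(p = {r['p_value']:.3g})"
            )
        for _, r in comp.contrasts.iterrows():
            lines.append(
                f"  {r['group_a']} vs {r['group_b']}: diff {r['estimate']:+.2f} "
                f"± {r['se']:.2f}, p = {r['p_value']:.3g}"
            )
        for b in comp.brackets:
            lo = "p < " + format(b.high, "g") if b.low is None else None
            hi = "p > " + format(b.low, "g") if b.high is None else None
            msg = lo or hi or f"{b.low:g} < p < {b.high:g}"
            lines.append(f"  separation bracket {b.pair[0]}–{b.pair[1]}: {msg}")
        lines.append("")
    return "\n".join(lines)


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Run every stage and write artifacts under ``cfg.outdir``.

    Returns a :class:`RunResult`; status is ``partial`` when some
    comparison could not be fitted (each failure is a warning naming the
    stage) and ``failure`` when no analyzable data survives ingestion.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    warnings_: list[str] = []
    counts: dict[str, int] = {}

    if cfg.simulate:
        sim = _simulation_config(cfg)
        dataset = simulate_station_dataset(sim)
        paths = write_dataset(dataset, outdir / "inputs")
        outputs.update({f"input_{k}": v for k, v in paths.items()})
        cap_path, eff_path, meta_path = (paths["captures"], paths["effort"],
                                         paths["species_meta"])
        log.info("simulated %d capture rows over %d species",
                 len(dataset.captures), len(sim.species))
    else:
        if not (cfg.captures_path and cfg.effort_path and cfg.species_meta_path):
            raise ValueError("need captures/effort/species metadata paths "
                             "(or simulate: true)")
        cap_path, eff_path, meta_path = (cfg.captures_path, cfg.effort_path,
                                         cfg.species_meta_path)

    captures = read_captures(cap_path)
    effort = read_effort(eff_path)
    meta = read_species_metadata(meta_path)
    if captures.empty:
        raise ValueError("no capture records in input")
    counts["capture_rows"] = len(captures)
    counts["effort_days"] = len(effort)

    cpue = daily_cpue_table(captures, effort, species=list(meta["species"]),
                            scale=cfg.cpue_scale)
    outputs["cpue"] = outdir / "cpue.csv"
    cpue.to_csv(outputs["cpue"], index=False)
    counts["cpue_rows"] = len(cpue)

    extractor = PhenologyExtractor(ma_window=cfg.ma_window,
                                   threshold_frac=cfg.threshold_frac,
                                   min_captures=cfg.min_captures)
    metrics = extractor.fit_transform(cpue)
    counts["species_years"] = len(metrics)
    counts["species_years_excluded"] = int(metrics["excluded"].sum())
    counts["species_years_analyzed"] = len(metrics) - counts["species_years_excluded"]
    assert counts["species_years"] == (counts["species_years_excluded"]
                                       + counts["species_years_analyzed"])
    log.info("%d species-years: %d analyzed, %d excluded (<%d captures)",
             len(metrics), counts["species_years_analyzed"],
             counts["species_years_excluded"], cfg.min_captures)
    for flag in ("start_truncated", "end_truncated"):
        log.info("%s in %d species-years", flag,
                 int(metrics.loc[~metrics["excluded"], flag].sum()))
    outputs["metrics"] = outdir / "metrics.csv"
    metrics.to_csv(outputs["metrics"], index=False)
    if counts["species_years_analyzed"] == 0:
        raise ValueError("all species-years excluded (<%d captures each); "
                         "nothing to analyze" % cfg.min_captures)

    trend_est = SpeciesTrendEstimator(min_years=cfg.min_years).fit(metrics)
    trends_table = trend_est.summary_table(meta)
    outputs["trends"] = outdir / "trends.csv"
    trends_table.to_csv(outputs["trends"], index=False, float_format="%.4f")
    counts["species_with_trends"] = int(trend_est.trends_["defined"].groupby(
        trend_est.trends_["species"]).any().sum())

    metrics_g = metrics.merge(meta[["species", "wintering_group"]], on="species")
    comps: dict[str, GroupComparison] = {}
    for metric in METRICS:
        try:
            comps[metric] = compare_groups(
                metrics_g, metric=metric, alpha_grid=tuple(cfg.alpha_grid))
        except Exception as exc:  # noqa: BLE001 - surfaced as partial status
            warnings_.append(f"group comparison for {metric!r} failed: {exc}")
            log.warning("group comparison for %s failed: %s", metric, exc)
    if comps:
        slopes, contrasts, letters = _comparison_frames(comps)
        outputs["group_slopes"] = outdir / "group_slopes.csv"
        slopes.to_csv(outputs["group_slopes"], index=False, float_format="%.6g")
        outputs["group_contrasts"] = outdir / "group_contrasts.csv"
        contrasts.to_csv(outputs["group_contrasts"], index=False, float_format="%.6g")
        outputs["group_letters"] = outdir / "group_letters.csv"
        letters.to_csv(outputs["group_letters"], index=False)
        outputs["comparison_report"] = outdir / "comparison.txt"
        outputs["comparison_report"].write_text(_comparison_text(comps))

    # sex-specific analysis over dimorphic species
    try:
        dim = meta.loc[meta["dimorphic"], "species"]
        sex_frames = []
        for sex in ("male", "female"):
            sub = captures.loc[(captures["sex"] == sex)
                               & captures["species"].isin(dim)]
            if sub.empty:
                continue
            cp = daily_cpue_table(sub, effort, species=sorted(sub["species"].unique()),
                                  scale=cfg.cpue_scale)
            m = extractor.transform(cp)
            m["sex"] = sex
            sex_frames.append(m)
        if sex_frames:
            metrics_by_sex = pd.concat(sex_frames, ignore_index=True)
            sex_res = sex_group_analysis(metrics_by_sex, meta,
                                         alpha_grid=tuple(cfg.alpha_grid))
            wide = sex_res.species_trends.pivot(
                index=["wintering_group", "species"], columns="sex",
                values=["slope", "se", "p_value"])
            wide.columns = [f"{sex}_{v}" for v, sex in wide.columns]
            outputs["sex_trends"] = outdir / "sex_trends.csv"
            wide.reset_index().to_csv(outputs["sex_trends"], index=False,
                                      float_format="%.4f")
            report = {f"peak, {sex}s, groups compared": comp
                      for sex, comp in sex_res.by_sex.items()}
            report.update({f"peak, sexes within {grp}": comp
                           for grp, comp in sex_res.within_group.items()})
            outputs["sex_report"] = outdir / "sex_comparison.txt"
            outputs["sex_report"].write_text(_comparison_text(report))
            counts["dimorphic_species_years"] = len(metrics_by_sex)
    except Exception as exc:  # noqa: BLE001
        warnings_.append(f"sex-specific analysis failed: {exc}")
        log.warning("sex-specific analysis failed: %s", exc)

    cfg_dict = dataclasses.asdict(cfg)
    cfg_dict.pop("outdir")
    manifest = {
        "config": cfg_dict,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "phenopass_version": __version__,
        "row_counts": counts,
        "outputs": {k: str(v.relative_to(outdir)) for k, v in outputs.items()},
        "warnings": warnings_,
    }
    outputs["manifest"] = outdir / "manifest.json"
    outputs["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                              default=str) + "\n")
    status = "partial" if warnings_ else "success"
    return RunResult(status=status, outputs=outputs, warnings=warnings_,
                     manifest=manifest)
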