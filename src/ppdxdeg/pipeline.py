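"""End-to-end orchestration: simulate or load data, run every analysis
stage, and render the three report tables (crystallinity per period,
crack morphology per period, shoulder area per period with the
consecutive-period comparisons).

All randomness flows from named per-stage seeds in the configuration;
nothing is seeded from the wall clock, so a fixed config reproduces a
run byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import crackmorph, degstats, dsc, specquant, synthgen

logger = logging.getLogger("ppdxdeg")

__all__ = ["RunConfig", "DegradationReport", "run_synthetic", "run_user_data"]

_CSV_FLOAT = "%.10g"


@dataclass
class RunConfig:
    """Everything a run needs; seeds are explicit and per-stage."""

    periods: Sequence[int] = (0, 4, 8, 16, 24)
    seeds: dict = field(
        default_factory=lambda: {"spectra": 10, "cracks": 11, "dsc": 12}
    )
    baseline_method: str = "asls"
    baseline_params: dict = field(default_factory=dict)
    grid_layout: tuple = (8, 8, 12.9, 11.4)
    amplitude_cv: float = 0.05
    crack_periods: Sequence[int] = (8, 16, 24)
    n_cracks: int = 120
    dH_ref: float = dsc.DH_REF_PPDX_J_PER_G
    dsc_window: tuple = (81.0, 129.0)
    dsc_replicates: int = 3
    dsc_noise_sd: float = 0.005
    alpha_family: float = 0.05
    output_dir: str = "ppdxdeg_run"
    # user-data mode: per-period artifact paths
    user_spectra: dict = field(default_factory=dict)       # week -> manifest
    user_masks: dict = field(default_factory=dict)         # week -> [paths]
    user_thermograms: dict = field(default_factory=dict)   # week -> [paths]

    def __post_init__(self):
        p = list(self.periods)
        if p != sorted(p) or len(set(p)) != len(p):
            raise ValueError("periods must be strictly increasing")
        for key in ("spectra", "cracks", "dsc"):
            if key not in self.seeds:
                raise ValueError(f"missing seed for stage {key!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        d = asdict(self)
        d["periods"] = list(self.periods)
        d["grid_layout"] = list(self.grid_layout)
        d["dsc_window"] = list(self.dsc_window)
        d["crack_periods"] = list(self.crack_periods)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class DegradationReport:
    """The three journal-style tables plus the comparison table."""

    crystallinity: pd.DataFrame
    cracks: pd.DataFrame
    shoulder: pd.DataFrame
    comparisons: pd.DataFrame
    shoulder_metrics: dict = field(default_factory=dict)  # week -> [areas]

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.crystallinity.to_csv(
            directory / "crystallinity_by_period.csv",
            index=False,
            float_format=_CSV_FLOAT,
        )
        self.cracks.to_csv(
            directory / "crack_morphology_by_period.csv",
            index=False,
            float_format=_CSV_FLOAT,
        )
        self.shoulder.to_csv(
            directory / "shoulder_area_by_period.csv",
            index=False,
            float_format=_CSV_FLOAT,
        )
        self.comparisons.to_csv(
            directory / "shoulder_comparisons.csv",
            index=False,
            float_format=_CSV_FLOAT,
        )


# ---------------------------------------------------------------------------
# table builders
# ---------------------------------------------------------------------------


def _shoulder_table(metrics_by_week: Mapping[int, Sequence[float]]) -> pd.DataFrame:
    rows = []
    for wk in sorted(metrics_by_week):
        s = degstats.summarize(metrics_by_week[wk])
        rows.append(
            {
                "week": wk,
                "n": s.n,
                "mean": s.mean,
                "sd": s.sd,
                "median": s.median,
                "q1": s.q1,
                "q3": s.q3,
                "normality_p": s.normality_p,
                "normal": s.normal,
                "display": s.render(),
            }
        )
    return pd.DataFrame(rows)


def _comparison_table(results: Sequence[degstats.ComparisonResult]) -> pd.DataFrame:
    if not results:
        return pd.DataFrame(
            columns=[
                "week_a", "week_b", "W", "p_value",
                "alpha_per_test", "significant", "direction",
            ]
        )
    return pd.DataFrame(
        [
            {
                "week_a": r.pair[0],
                "week_b": r.pair[1],
                "W": r.statistic_W,
                "p_value": r.p_value,
                "alpha_per_test": r.alpha_per_test,
                "significant": r.significant,
                "direction": r.direction,
            }
            for r in results
        ]
    )


def _crack_table(
    records_by_week: Mapping[int, Sequence[crackmorph.CrackRecord]]
) -> pd.DataFrame:
    rows = []
    for wk in sorted(records_by_week):
        recs = records_by_week[wk]
        if not recs:
            rows.append(
                {"week": wk, "descriptor": "no cracks detected", "n": 0,
                 "mean": None, "sd": None, "median": None}
            )
            continue
        summaries = crackmorph.summarize_cracks(recs)
        for d, s in summaries.items():
            rows.append(
                {"week": wk, "descriptor": d, "n": s.n,
                 "mean": s.mean, "sd": s.sd, "median": s.median}
            )
    return pd.DataFrame(rows)


def _analyze_metrics(
    config: RunConfig, metrics_by_week: Mapping[int, Sequence[float]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    shoulder = _shoulder_table(metrics_by_week)
    if len(metrics_by_week) < 2:
        logger.info(
            "only one period present: comparison table left empty"
        )
        return shoulder, _comparison_table([])
    comps = degstats.compare_series(
        {k: list(v) for k, v in metrics_by_week.items()},
        alpha_family=config.alpha_family,
    )
    return shoulder, _comparison_table(comps)


# ---------------------------------------------------------------------------
# synthetic end-to-end run
# ---------------------------------------------------------------------------


def run_synthetic(config: RunConfig) -> DegradationReport:
    """Generate a full synthetic study and analyse it.

    Writes all intermediate artifacts (spectra CSVs + manifests, PGM
    masks + ground truth, thermogram CSVs), the four report CSVs and a
    run manifest into ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- spectra ---------------------------------------------------------
    stage = "synthgen/spectra"
    try:
        profiles = [
            p
            for p in synthgen.default_degradation_profiles()
            if p.week in set(config.periods)
        ]
        grids = synthgen.generate_degradation_series(
            profiles,
            layout=tuple(config.grid_layout),
            seed=config.seeds["spectra"],
            amplitude_cv=config.amplitude_cv,
        )
        for wk, grid in grids.items():
            specquant.write_grid(grid, out / "spectra" / f"week{wk:02d}")
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    stage = "specquant"
    metrics_by_week = {}
    try:
        for wk, grid in grids.items():
            ms = specquant.grid_shoulder_metrics(
                grid, config.baseline_method, **config.baseline_params
            )
            metrics_by_week[wk] = [m.normalized_area for m in ms]
            pd.DataFrame(
                {
                    "week": wk,
                    "row": [grid.position(i)[0] for i in range(len(ms))],
                    "col": [grid.position(i)[1] for i in range(len(ms))],
                    "normalized_area": [m.normalized_area for m in ms],
                    "peak_height": [m.peak_height_1732 for m in ms],
                }
            ).to_csv(
                out / "spectra" / f"week{wk:02d}_metrics.csv",
                index=False,
                float_format=_CSV_FLOAT,
            )
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    # --- cracks ----------------------------------------------------------
    stage = "synthgen/cracks + crackmorph"
    records_by_week = {}
    try:
        (out / "masks").mkdir(exist_ok=True)
        for wk in config.crack_periods:
            if wk not in set(config.periods):
                continue
            spec = synthgen.table2_crack_spec(wk, n_cracks=config.n_cracks)
            mask, truth = synthgen.generate_crack_mask(
                spec, seed=config.seeds["cracks"] + wk
            )
            crackmorph.write_mask(mask, out / "masks" / f"week{wk:02d}.pgm")
            pd.DataFrame([asdict(t) for t in truth]).to_csv(
                out / "masks" / f"week{wk:02d}_truth.csv",
                index=False,
                float_format=_CSV_FLOAT,
            )
            records = crackmorph.measure_all(mask)
            records_by_week[wk] = records
            crackmorph.records_to_dataframe(records).to_csv(
                out / "masks" / f"week{wk:02d}_cracks.csv",
                index=False,
                float_format=_CSV_FLOAT,
            )
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    # --- DSC -------------------------------------------------------------
    stage = "synthgen/dsc + dsc"
    cryst_rows = []
    try:
        (out / "dsc").mkdir(exist_ok=True)
        for prof in profiles:
            tgs = []
            for rep in range(config.dsc_replicates):
                tg = synthgen.generate_thermogram(
                    prof.crystallinity_pct,
                    dH_ref=config.dH_ref,
                    noise_sd=config.dsc_noise_sd,
                    seed=config.seeds["dsc"] + 100 * prof.week + rep,
                )
                dsc.write_thermogram_csv(
                    tg, out / "dsc" / f"week{prof.week:02d}_rep{rep}.csv"
                )
                tgs.append(tg)
            res = dsc.replicate_crystallinity(
                tgs, tuple(config.dsc_window), config.dH_ref
            )
            cryst_rows.append(
                {
                    "week": prof.week,
                    "n": res["n"],
                    "crystallinity_mean_pct": res["mean"],
                    "crystallinity_sd_pct": res["sd"],
                }
            )
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    stage = "degstats"
    try:
        shoulder, comparisons = _analyze_metrics(config, metrics_by_week)
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    report = DegradationReport(
        crystallinity=pd.DataFrame(cryst_rows),
        cracks=_crack_table(records_by_week),
        shoulder=shoulder,
        comparisons=comparisons,
        shoulder_metrics=metrics_by_week,
    )
    report.write(out)
    _write_manifest(config, out)
    return report


def _write_manifest(config: RunConfig, out: Path) -> None:
    from . import __version__

    manifest = {
        "config": asdict(config),
        "config_digest": config.digest(),
        "seeds": config.seeds,
        "package_version": __version__,
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str)
    )


# ---------------------------------------------------------------------------
# user-data run
# ---------------------------------------------------------------------------


def run_user_data(config: RunConfig) -> DegradationReport:
    """Run the analysis stages on user-supplied files.

    ``config.user_spectra`` maps week -> grid manifest JSON,
    ``config.user_masks`` maps week -> list of mask paths, and
    ``config.user_thermograms`` maps week -> list of thermogram CSVs.
    Missing modalities yield a partial report (logged); masks of one
    period must share a pixel size.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    metrics_by_week: dict[int, list[float]] = {}
    for wk, manifest in sorted(config.user_spectra.items()):
        grid = specquant.read_grid_manifest(manifest)
        ms = specquant.grid_shoulder_metrics(
            grid, config.baseline_method, **config.baseline_params
        )
        metrics_by_week[int(wk)] = [m.normalized_area for m in ms]

    records_by_week: dict[int, list[crackmorph.CrackRecord]] = {}
    for wk, paths in sorted(config.user_masks.items()):
        masks = [crackmorph.read_mask(p) for p in paths]
        sizes = {m.pixel_size for m in masks}
        if len(sizes) > 1:
            raise ValueError(
                f"week {wk}: masks mix pixel sizes {sorted(sizes)} — "
                "ambiguous scaling"
            )
        records: list[crackmorph.CrackRecord] = []
        for m in masks:
            records.extend(crackmorph.measure_all(m))
        records_by_week[int(wk)] = records

    cryst_rows = []
    for wk, paths in sorted(config.user_thermograms.items()):
        tgs = [dsc.read_thermogram_csv(p) for p in paths]
        res = dsc.replicate_crystallinity(
            tgs, tuple(config.dsc_window), config.dH_ref
        )
        cryst_rows.append(
            {
                "week": int(wk),
                "n": res["n"],
                "crystallinity_mean_pct": res["mean"],
                "crystallinity_sd_pct": res["sd"],
            }
        )

    for name, present in (
        ("spectra", metrics_by_week),
        ("masks", records_by_week),
        ("thermograms", cryst_rows),
    ):
        if not present:
            logger.warning("no %s supplied: report section left empty", name)

    if metrics_by_week:
        shoulder, comparisons = _analyze_metrics(config, metrics_by_week)
    else:
        shoulder, comparisons = pd.DataFrame(), _comparison_table([])

    report = DegradationReport(
        crystallinity=pd.DataFrame(cryst_rows),
        cracks=_crack_table(records_by_week),
        shoulder=shoulder,
        comparisons=comparisons,
        shoulder_metrics=metrics_by_week,
    )
    report.write(out)
    _write_manifest(config, out)
    return report
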