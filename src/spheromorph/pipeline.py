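"""End-to-end orchestration: simulate -> measure -> fit -> test.

One :class:`RunConfig` drives everything.  Every default a user might
reasonably dispute (noise level, perimeter estimator, compactness tolerance
kappa*, tie rules) is surfaced in the config, and a run re-executed from the
same config and seed reproduces identical outputs: all randomness flows from
the single seed through fixed-order child seeds.
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

from . import growth, morphometry, stats, synthetic

logger = logging.getLogger(__name__)


@dataclass
class ProfileConfig:
    """One simulated culture: subtype phenotype plus imaging schedule."""

    name: str
    tau: float
    irregularity_base: float
    irregularity_slope: float
    growth_coupling: float = 1.0
    times: list[float] = field(default_factory=lambda: [3.0, 8.0, 16.0])
    n_spheroids: int = 200
    d0_mean: float = 40.0
    d0_sd: float = 8.0

    def to_profile(self) -> synthetic.SubtypeProfile:
        return synthetic.SubtypeProfile(
            name=self.name, tau=self.tau,
            irregularity_base=self.irregularity_base,
            irregularity_slope=self.irregularity_slope,
            growth_coupling=self.growth_coupling,
        )


def _default_profiles() -> list[ProfileConfig]:
    return [
        ProfileConfig(
            name="mesenchymal-like", tau=2.5,
            irregularity_base=0.10, irregularity_slope=0.0,
            times=[3.0, 8.0, 16.0],
        ),
        ProfileConfig(
            name="proneural-like", tau=5.0,
            irregularity_base=0.15, irregularity_slope=0.15,
            growth_coupling=0.5,
            times=[1.0, 7.0, 14.0, 18.0],
        ),
    ]


@dataclass
class RunConfig:
    seed: int = 0
    profiles: list[ProfileConfig] = field(default_factory=_default_profiles)
    pixel_size: float = 0.5            # um/pixel
    perimeter_estimator: str = "crofton"
    # cell-count simulation / fitting
    n0_cells: float = 4e4              # initial cells per biosphere
    count_noise_cv: float = 0.05
    count_times: list[float] = field(
        default_factory=lambda: [0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0]
    )
    n_count_replicates: int = 3
    window_min_points: int = 4
    # verdict / test parameters
    kappa_star: float = 1.5
    alpha: float = 0.01
    # cohort simulation
    n_tumors: int = 100
    volume_median: float = 29.09       # cm^3
    volume_log_sd: float = 0.9
    sphericity_volume_coupling: float = 0.12
    cohort_irregularity_base: float = 0.55
    outdir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "profiles" in d:
            d["profiles"] = [
                p if isinstance(p, ProfileConfig) else ProfileConfig(**p)
                for p in d["profiles"]
            ]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        payload = {k: v for k, v in self.to_dict().items()
                   if k != "outdir"}  # paths are not scientific content
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """Machine-readable results of one pipeline run."""

    config_hash: str
    seed: int
    cultures: dict[str, dict] = field(default_factory=dict)
    cohort: dict | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1, default=float))
        return path


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2 ** 31))


def _fit_counts(config: RunConfig, pconf: ProfileConfig,
                rng: np.random.Generator) -> tuple[growth.GrowthFit, list]:
    """Fit tau on each simulated count replicate; keep the median-tau fit."""
    fits = []
    for r in range(config.n_count_replicates):
        series = synthetic.generate_count_series(
            config.n0_cells, pconf.tau, config.count_times,
            noise_cv=config.count_noise_cv, seed=_child_seed(rng),
            culture_id=pconf.name, replicate_id=f"rep{r}",
        )
        window = growth.select_exponential_window(
            series, min_points=config.window_min_points
        )
        fits.append(growth.fit_exponential(series, window=window))
    fits.sort(key=lambda f: f.tau)
    return fits[len(fits) // 2], fits


def run_invitro_analysis(config: RunConfig) -> RunReport:
    """Simulate, measure and score every configured culture profile.

    For each profile: generate count series and fit tau inside the
    automatically selected exponential window; generate the spheroid
    timecourse; measure all masks; score compactness against the spherical
    prediction; run the small-vs-large circularity variance test.
    """
    if not config.profiles:
        raise ValueError("config.profiles must not be empty")
    report = RunReport(config_hash=config.content_hash(), seed=config.seed)
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.yaml").write_text(
            yaml.safe_dump(config.to_dict(), sort_keys=True))

    master = np.random.default_rng(config.seed)
    for pconf in config.profiles:
        stage = f"culture {pconf.name}"
        try:
            fit, fits = _fit_counts(config, pconf, master)
            tc = synthetic.generate_biosphere_timecourse(
                pconf.to_profile(), pconf.n_spheroids, pconf.times,
                d0_mean=pconf.d0_mean, d0_sd=pconf.d0_sd,
                pixel_size=config.pixel_size, seed=_child_seed(master),
            )
            all_masks = [m for t in pconf.times for m in tc.masks[t]]
            measures = morphometry.measure_table(
                all_masks, estimator=config.perimeter_estimator
            )
            logger.info("%s: measured %d/%d objects", stage,
                        len(measures), len(all_masks))
            compact = growth.compactness_report(
                measures, fit, kappa_star=config.kappa_star
            )
            var_test, strat = stats.circularity_variance_test(measures)
        except Exception as exc:
            raise RuntimeError(f"stage failed: {stage}: {exc}") from exc

        report.cultures[pconf.name] = {
            "growth_fit": {
                "tau_d": fit.tau,
                "doubling_time_d": fit.doubling_time,
                "n0": fit.n0,
                "r_squared": fit.r_squared,
                "fit_window_d": list(fit.fit_window),
                "tau_replicates_d": [f.tau for f in fits],
            },
            "compactness": {
                "verdict": compact.verdict,
                "kappa_star": compact.kappa_star,
                "kappa": compact.table["kappa"].tolist(),
                "times_d": compact.table["time_d"].tolist(),
            },
            "circularity_variance": {
                "W": var_test.statistic,
                "p_value": var_test.p_value,
                "df": [var_test.df1, var_test.df2],
                "group_sizes": list(var_test.group_sizes),
                "group_variances": list(var_test.group_variances),
                "area_threshold_um2": strat.threshold,
                "reject_at_alpha": bool(var_test.p_value < config.alpha),
            },
        }
        if outdir:
            safe = pconf.name.replace("/", "_")
            measures.to_csv(outdir / f"measures_{safe}.csv", index=False)
            compact.table.to_csv(
                outdir / f"compactness_{safe}.csv", index=False)
    if outdir:
        report.write(outdir / "report.json")
    return report


def run_cohort_analysis(config: RunConfig) -> RunReport:
    """Simulate a tumour cohort and test sphericity of small vs large.

    Generates the cohort, measures sphericity of each rasterised volume,
    stratifies at the median measured volume and applies the Mann-Whitney
    test to the two sphericity groups.
    """
    report = RunReport(config_hash=config.content_hash(), seed=config.seed)
    master = np.random.default_rng(config.seed)
    try:
        vols, truth = synthetic.generate_cohort(
            config.n_tumors,
            volume_median=config.volume_median,
            volume_log_sd=config.volume_log_sd,
            sphericity_volume_coupling=config.sphericity_volume_coupling,
            irregularity_base=config.cohort_irregularity_base,
            seed=_child_seed(master),
        )
        records = [morphometry.sphericity(v) for v in vols]
        table = pd.DataFrame(
            {
                "tumor_id": [r.tumor_id for r in records],
                "volume_cm3": [r.volume for r in records],
                "surface_cm2": [r.surface_area for r in records],
                "sphericity": [r.sphericity for r in records],
            }
        )
        strat = stats.stratify_by_median(
            table, "volume_cm3", id_column="tumor_id")
        small = table["volume_cm3"] <= strat.threshold
        test = stats.mann_whitney(
            table.loc[small, "sphericity"],
            table.loc[~small, "sphericity"],
        )
    except Exception as exc:
        raise RuntimeError(f"stage failed: cohort analysis: {exc}") from exc

    report.cohort = {
        "n_tumors": int(len(table)),
        "threshold_volume_cm3": strat.threshold,
        "median_sphericity_small": test.medians[0],
        "median_sphericity_large": test.medians[1],
        "mann_whitney_u": test.u,
        "p_value": test.p_value,
        "method": test.method,
        "reject_at_alpha": bool(test.p_value < config.alpha),
    }
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "cohort_sphericity.csv", index=False)
        report.write(outdir / "cohort_report.json")
    return report
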