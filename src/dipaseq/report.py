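"""End-to-end report: simulate -> DE -> DiPa -> migration -> morphometry.

The default configuration reproduces the synthetic analogue of the study:
3 arms x 4 stages x 5 mice, negative-binomial counts with stage-attenuated
rescue, and log-normal-mixture diameters whose dilated fraction grows
under bile-duct ligation and shrinks under treatment in proportion to the
stage's rescue attenuation. Everything is seeded, and the report manifest
records a checksum for every artifact, so one config + seed is
byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dipaseq import io as dio
from dipaseq.de import (
    classify_volcano,
    filter_genes,
    normalize_log2,
    pca_summary,
    size_factors,
    test_contrast,
)
from dipaseq.dipa import build_dipa_table, pattern_group_sizes, rescue_summary
from dipaseq.migration import check_conservation, migration_matrix
from dipaseq.morphometry import (
    abnormal_subset,
    subsample_stability,
    summarize_diameters,
    tukey_fence,
)
from dipaseq.simulate import ARMS, STAGES, SimConfig, make_design, simulate_counts, simulate_diameters


@dataclass
class RunConfig:
    """Thresholds, seeds and sizes of one end-to-end run.

    Fold-change thresholds are entered on the linear scale (1.5-fold
    volcano band, 17-fold extreme region) and converted to log2
    internally.
    """

    outdir: str = "dipaseq_report"
    seed: int = 0
    organ: str = "KIDNEY"
    # DE thresholds
    fold_change: float = 1.5
    alpha: float = 0.05
    extreme_fold: float = 17.0
    min_total: int = 10
    pseudocount: float = 1.0
    use_adjusted: bool = True
    # simulation sizes
    n_genes: int = 2000
    n_per_group: int = 5
    sim: dict = field(default_factory=dict)  # extra SimConfig overrides
    # morphometry simulation
    diameters_per_stratum: int = 50_000
    subset_sizes: list[int] = field(default_factory=lambda: [10_000, 1_000])
    dilated_fraction_sham: float = 0.02
    dilated_fraction_bdl: float = 0.25
    make_plots: bool = False

    def validate(self) -> None:
        if self.fold_change <= 1 or self.extreme_fold <= 1:
            raise ValueError("linear fold-change thresholds must exceed 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.min_total < 0:
            raise ValueError("min_total must be >= 0")
        if any(s < 1 for s in self.subset_sizes):
            raise ValueError("subset sizes must be >= 1")

    @property
    def tau(self) -> float:
        return float(np.log2(self.fold_change))

    @property
    def extreme_log2(self) -> float:
        return float(np.log2(self.extreme_fold))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = dio.read_yaml(path) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _sim_config(cfg: RunConfig) -> SimConfig:
    overrides = dict(cfg.sim)
    return SimConfig(
        n_genes=cfg.n_genes, n_per_group=cfg.n_per_group, seed=cfg.seed, **overrides
    )


def _diameter_params(cfg: RunConfig, attenuation: dict[str, float]) -> tuple[list[str], dict, dict]:
    """Stratum list and per-stratum mixture parameters.

    BDL raises the dilated fraction; treatment pulls it back toward sham
    by the stage's attenuation, mirroring the rescue model of the counts.
    """
    strata: list[str] = []
    fractions: dict[str, float] = {}
    params: dict[str, tuple[float, float]] = {}
    span = cfg.dilated_fraction_bdl - cfg.dilated_fraction_sham
    for stage in STAGES:
        a = float(attenuation.get(stage, 1.0))
        for arm in ARMS:
            stratum = f"{arm}_{stage}"
            strata.append(stratum)
            params[stratum] = (0.0, 0.35)
            if arm == "SHAM_VEH":
                fractions[stratum] = cfg.dilated_fraction_sham
            elif arm == "BDL_VEH":
                fractions[stratum] = cfg.dilated_fraction_bdl
            else:
                fractions[stratum] = cfg.dilated_fraction_sham + span * (1.0 - a)
    return strata, params, fractions


def run_report(cfg: RunConfig) -> dict:
    """Run the full synthetic pipeline and write the artifact bundle.

    Returns the manifest (also written as ``manifest.json``): thresholds,
    seeds, library versions and a sha256 checksum per artifact.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def emit(path: Path) -> Path:
        artifacts.append(path)
        return path

    stage = "simulate"
    try:
        design = make_design(STAGES, ARMS, cfg.n_per_group, organ=cfg.organ)
        simcfg = _sim_config(cfg)
        counts, truth = simulate_counts(design, simcfg)
        dio.write_samples(design, emit(outdir / "samples.tsv"))
        dio.write_counts(counts, emit(outdir / "counts.tsv"))
        dio.write_table(truth, emit(outdir / "truth.tsv"), index=False)

        stage = "de"
        kept = filter_genes(counts, cfg.min_total)
        factors = size_factors(kept)
        em = normalize_log2(kept, factors, cfg.pseudocount)
        coords, evr = pca_summary(em, n_top_variance_genes=min(500, len(em)))
        dio.write_table(coords, emit(outdir / "pca_coordinates.tsv"))
        dio.write_json(
            {"explained_variance_ratio": [float(v) for v in evr]},
            emit(outdir / "pca_summary.json"),
        )

        stage = "dipa"
        volcano = {}
        rescue = {}
        dipa_tables = {}
        for st in STAGES:
            cx = test_contrast(em, design, "SHAM_VEH", "BDL_VEH", stage=st)
            cy = test_contrast(em, design, "SHAM_VEH", "BDL_TRT", stage=st)
            _, vx = classify_volcano(cx, cfg.tau, cfg.alpha, cfg.use_adjusted)
            _, vy = classify_volcano(cy, cfg.tau, cfg.alpha, cfg.use_adjusted)
            volcano[st] = {
                "vehicle": dataclasses.asdict(vx),
                "treated": dataclasses.asdict(vy),
            }
            up, down = rescue_summary(vx, vy, organ=cfg.organ, stage=st)
            rescue[st] = {
                "UP": dataclasses.asdict(up),
                "DOWN": dataclasses.asdict(down),
            }
            dt = build_dipa_table(
                cx, cy, cfg.tau, cfg.alpha, cfg.use_adjusted, cfg.extreme_log2
            )
            dipa_tables[st] = dt
            dio.write_table(cx, emit(outdir / f"contrast_bdl_vs_sham_{st}.tsv"))
            dio.write_table(cy, emit(outdir / f"contrast_trt_vs_sham_{st}.tsv"))
            dio.write_table(dt, emit(outdir / f"dipa_{st}.tsv"))
        dio.write_json(volcano, emit(outdir / "volcano_summaries.json"))
        dio.write_json(rescue, emit(outdir / "rescue_summaries.json"))
        dio.write_json(
            {st: pattern_group_sizes(dt) for st, dt in dipa_tables.items()},
            emit(outdir / "pattern_group_sizes.json"),
        )

        stage = "migrate"
        mm = migration_matrix(dipa_tables["S1"], dipa_tables["S4"], "S1", "S4")
        conservation = check_conservation(
            mm, dipa_tables["S1"]["label"].value_counts().to_dict()
        )
        dio.write_table(mm.table, emit(outdir / "migration_S1_S4.tsv"))
        dio.write_json(conservation, emit(outdir / "migration_conservation.json"))

        stage = "morphometry"
        strata, params, fractions = _diameter_params(cfg, simcfg.rescue_attenuation)
        diam, _ = simulate_diameters(
            strata,
            cfg.diameters_per_stratum,
            base_lognormal_params=params,
            dilated_fraction=fractions,
            seed=cfg.seed + 1,
        )
        dio.write_diameters(diam, emit(outdir / "diameters.tsv"))
        sham = diam.loc[diam["stratum"].str.startswith("SHAM_VEH"), "value"]
        fence = tukey_fence(sham)
        dio.write_json(dataclasses.asdict(fence), emit(outdir / "fence.json"))
        _, fractions_obs = abnormal_subset(diam, fence)
        dio.write_table(fractions_obs.to_frame(), emit(outdir / "abnormal_fractions.tsv"))
        dio.write_table(summarize_diameters(diam, "all"), emit(outdir / "diameter_summary_all.tsv"))
        dio.write_table(
            summarize_diameters(diam, "abnormal", fence),
            emit(outdir / "diameter_summary_abnormal.tsv"),
        )
        stability = subsample_stability(diam, cfg.subset_sizes, seed=cfg.seed + 2)
        dio.write_table(stability.per_stratum, emit(outdir / "subsample_stability.tsv"), index=False)
        dio.write_table(stability.per_size_max, emit(outdir / "subsample_stability_max.tsv"))

        if cfg.make_plots:
            stage = "plots"
            from dipaseq import plotting

            for st in STAGES:
                plotting.save_dipa_plot(
                    dipa_tables[st], outdir / f"dipa_{st}.svg", tau=cfg.tau,
                    extreme_log2=cfg.extreme_log2,
                )
    except Exception as exc:
        raise RuntimeError(f"report stage {stage!r} failed: {exc}") from exc

    versions = {}
    for mod in ("numpy", "scipy", "pandas", "statsmodels", "sklearn"):
        versions[mod] = __import__(mod).__version__
    manifest = {
        "config": dataclasses.asdict(cfg),
        "thresholds": {
            "tau_log2": cfg.tau,
            "alpha": cfg.alpha,
            "extreme_log2": cfg.extreme_log2,
        },
        "versions": versions,
        "artifacts": {p.name: _sha256(p) for p in sorted(artifacts)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
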