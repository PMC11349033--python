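"""End-to-end driver: simulate -> fit -> enrich -> blocktest -> compare.

A :class:`RunConfig` (loadable from YAML) fixes every knob and the master
seed; :func:`run_pipeline` executes the stages in order, writing each
stage's JSON artifacts plus a provenance manifest (resolved config,
package/library versions, per-stage timings) into the run directory. Runs
are deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .block_analysis import (
    block_significance_report,
    fit_block_models,
    permuted_block_null,
)
from .data_model import build_block_map, build_edge_index, write_dataset, write_partition, write_results
from .edge_models import (
    METHODS,
    FeatureSelectionConfig,
    LSVRConfig,
    run_method,
)
from .enrichment import (
    EnrichmentConfig,
    fwer_pvalues,
    mcc_reliability,
    observed_block_statistics,
    permutation_null,
)
from .resampling import make_splits
from .stats_compare import compare_models
from .synthetic import EffectSpec, FamilyLayout, generate_partition, generate_dataset

logger = logging.getLogger("netla")

__all__ = ["RunConfig", "PRESETS", "run_pipeline", "load_config"]

# scale presets: problem sizes for a quick smoke run, a laptop-scale run and
# a full-size run
PRESETS = {
    "smoke": dict(
        parcel_count=30, n_networks=3, n_families=60, n_repetitions=20,
        n_permutations=50, block_draws=10,
    ),
    "desk": dict(
        parcel_count=60, n_networks=6, n_families=150, n_repetitions=100,
        n_permutations=200, block_draws=50,
    ),
    "full": dict(
        parcel_count=333, n_networks=13, n_families=420, n_repetitions=1000,
        n_permutations=1000, block_draws=1000,
    ),
}


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    out_dir: str = "netla_run"
    scale: str = "desk"
    methods: tuple = ("pearson", "lsvr_inverted")
    scheme: str = "RS2"
    test_frac: float = 0.2
    parcel_count: int = 60
    n_networks: int = 6
    n_families: int = 150
    members: tuple = (1, 3)
    age_range: tuple = (22.0, 35.0)
    planted_block: int | None = 0
    planted_r: float = 0.3
    n_repetitions: int = 100
    n_permutations: int = 200
    block_draws: int = 50
    z_threshold: float = 2.0
    k_best: int = 1000
    seed: int = 0
    run_block_analysis: bool = False

    def __post_init__(self):
        if self.scale not in PRESETS:
            raise ValueError(f"unknown scale preset '{self.scale}'")
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method '{m}'")
        if self.parcel_count < self.n_networks * 2:
            raise ValueError("need at least 2 parcels per network")
        if not 0 < self.test_frac < 1:
            raise ValueError("test_frac must be in (0, 1)")

    @classmethod
    def from_preset(cls, scale: str, **overrides) -> "RunConfig":
        kwargs = dict(PRESETS[scale], scale=scale)
        kwargs.update(overrides)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        d["members"] = list(self.members)
        d["age_range"] = list(self.age_range)
        return d


def load_config(path) -> RunConfig:
    """Load a YAML run configuration, applying its scale preset first."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    scale = raw.pop("scale", "desk")
    for key in ("methods", "members", "age_range"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig.from_preset(scale, **raw)


def _network_sizes(parcel_count: int, n_networks: int) -> list[int]:
    base = parcel_count // n_networks
    sizes = [base] * n_networks
    for i in range(parcel_count - base * n_networks):
        sizes[i] += 1
    return sizes


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the summary dict written to the run dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "netla_version": __version__,
        "numpy_version": np.__version__,
        "config": config.to_dict(),
        "timings_s": {},
    }
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    summary: dict = {}

    def _stage(name):
        logger.info("stage: %s", name)
        return time.perf_counter()

    try:
        # ------------------------------------------------------------------
        t0 = _stage("simulate")
        partition = generate_partition(
            config.parcel_count, _network_sizes(config.parcel_count, config.n_networks)
        )
        index = build_edge_index(config.parcel_count)
        block_map = build_block_map(partition, index)
        effects = EffectSpec()
        if config.planted_block is not None:
            from .synthetic import beta_for_target_r

            effects = EffectSpec(
                block_betas={
                    int(config.planted_block): beta_for_target_r(
                        config.planted_r, EffectSpec()
                    )
                }
            )
        layout = FamilyLayout(
            n_families=config.n_families,
            members=tuple(config.members),
            age_range=tuple(config.age_range),
        )
        ds1, ds2 = generate_dataset(partition, layout, effects, seed=config.seed)
        write_partition(partition, out / "partition.tsv")
        write_dataset(ds1, out / "edges_day1.h5", out / "phenotypes_day1.csv")
        write_dataset(ds2, out / "edges_day2.h5", out / "phenotypes_day2.csv")
        manifest["timings_s"]["simulate"] = time.perf_counter() - t0

        # ------------------------------------------------------------------
        t0 = _stage("fit")
        lsvr_config = LSVRConfig()
        fs_config = FeatureSelectionConfig(k=min(config.k_best, index.edge_count))
        splits1 = make_splits(
            ds1, config.scheme, config.test_frac, config.n_repetitions,
            seed=[config.seed, 1],
        )
        splits2 = make_splits(
            ds2, config.scheme, config.test_frac, config.n_repetitions,
            seed=[config.seed, 2],
        )
        method_results = {}
        fit_summary = {}
        for method in config.methods:
            res = run_method(
                ds1, ds2, method, splits1, splits2,
                lsvr_config=lsvr_config, fs_config=fs_config,
                z_threshold=config.z_threshold,
            )
            method_results[method] = res
            fit_summary[method] = {
                "mean_r": res.mean_r(),
                "icc21": res.icc,
            }
        write_results(fit_summary, out / "fit_metrics.json")
        summary["fit"] = fit_summary
        manifest["timings_s"]["fit"] = time.perf_counter() - t0

        # ------------------------------------------------------------------
        t0 = _stage("enrich")
        enr_config = EnrichmentConfig(
            z_threshold=config.z_threshold,
            n_permutations=config.n_permutations,
            seed=int(np.random.default_rng([config.seed, 3]).integers(2**31)),
        )
        enrich_summary = {}
        for method, res in method_results.items():
            per_day = {}
            sig_masks = {}
            for day, wmap, ds in (
                (1, res.mean_map_day1, ds1),
                (2, res.mean_map_day2, ds2),
            ):
                stats_obs = observed_block_statistics(
                    wmap, block_map, config.z_threshold
                )
                null = permutation_null(
                    ds, method, enr_config, block_map,
                    lsvr_config=lsvr_config, fs_config=fs_config,
                )
                fwer = fwer_pvalues(stats_obs, null)
                sig_masks[day] = fwer < 0.05
                per_day[f"day{day}"] = [
                    dataclasses.asdict(s) for s in stats_obs
                ]
            mcc = mcc_reliability(sig_masks[1], sig_masks[2])
            enrich_summary[method] = {
                "blocks": per_day,
                "mcc": dataclasses.asdict(mcc),
                "overlap_mean": float(
                    np.mean(res.strong_counts / max(res.n_masks, 1))
                )
                if res.strong_counts is not None
                else None,
            }
        write_results(enrich_summary, out / "enrichment.json")
        summary["enrichment"] = {
            m: {"mcc": v["mcc"]["mcc"]} for m, v in enrich_summary.items()
        }
        manifest["timings_s"]["enrich"] = time.perf_counter() - t0

        # ------------------------------------------------------------------
        if config.run_block_analysis:
            t0 = _stage("blocktest")
            small_splits = splits1[: min(10, len(splits1))]
            block_results = fit_block_models(ds1, block_map, small_splits)
            for b, res_b in block_results.items():
                res_b.permuted_r = permuted_block_null(
                    ds1, b, block_map, small_splits,
                    n_permutations=config.block_draws, seed=config.seed,
                )
            report = block_significance_report(block_results)
            report.to_csv(out / "block_report.csv", index=False)
            summary["block_analysis"] = {
                "n_significant_perm": int(report["sig_perm"].sum()),
                "n_blocks": len(report),
            }
            manifest["timings_s"]["blocktest"] = time.perf_counter() - t0

        # ------------------------------------------------------------------
        t0 = _stage("compare")
        compare_summary = {}
        lsvr_like = [
            m for m in config.methods if m in ("pearson_fs_lsvr", "lsvr", "lsvr_inverted")
        ]
        if len(lsvr_like) >= 2:
            n_tr = len(splits1[0].train)
            n_te = len(splits1[0].test)
            a, b = lsvr_like[0], lsvr_like[1]
            ra = np.array([m.r for m in method_results[a].metrics_day1])
            rb = np.array([m.r for m in method_results[b].metrics_day1])
            cmp_res = compare_models(ra, rb, n_tr, n_te, a, b, n_tests=1)
            compare_summary[f"{a}_vs_{b}"] = {
                "t": cmp_res.t,
                "p": cmp_res.p,
                "significant": cmp_res.significant,
            }
        write_results(compare_summary, out / "comparisons.json")
        summary["comparisons"] = compare_summary
        manifest["timings_s"]["compare"] = time.perf_counter() - t0
    except Exception as err:  # keep partial outputs, report the stage
        manifest["failed"] = repr(err)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    write_results(summary, out / "summary.json")
    return summary
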