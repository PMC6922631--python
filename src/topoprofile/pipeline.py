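"""End-to-end orchestration with YAML config and deterministic seeding.

``run_cohort`` executes preprocess -> progression -> metrics/design ->
profile (ISRA + sparsify + grouping + model selection + inference);
``run_individuals`` adds per-subject profiles and the cohort-space outputs.
Every stage writes plain CSV/JSON artifacts into the output directory and
derives its randomness from one global seed through named substreams.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atlas import read_atlas
from .cohort import preprocess, read_cohort_table
from .cohortspace import assign_and_flag, confusion_matrix
from .connectome import average_connectomes, read_adjacency, spatial_distance_matrix
from .errors import DataError, SchemaError
from .metrics import build_design_matrix, compute_node_metrics, select_epicenter
from .profile import (
    bootstrap_profiles,
    fit_cohort_profile,
    group_descriptors,
    isra_fit,
    model_selection,
    permutation_test,
    sparsify,
    variance_explained,
)
from .progression import ProgressionConfig, fit_progression, individual_rates, max_rates

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated run settings; paths are checked at load time."""

    cohort_path: str = ""
    atlas_path: str = ""
    connectome_paths: list = field(default_factory=list)
    out_dir: str = "topoprofile_out"
    schema: dict = field(default_factory=dict)
    covariate_set: list = field(default_factory=lambda: ["tiv", "sex", "age"])
    drop_regions: list = field(default_factory=list)
    fit_nuisance_on: str = "control"
    progression: dict = field(default_factory=dict)
    sparsity_threshold: float = 0.10
    bootstrap_B: int = 100
    permutation_B: int = 999
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for p in [cfg.cohort_path, cfg.atlas_path, *cfg.connectome_paths]:
            if p and not Path(p).exists():
                raise SchemaError(f"configured path does not exist: {p}")
        if not cfg.connectome_paths:
            raise SchemaError("config must list at least one connectome path")
        return cfg

    def substream(self, stage: str) -> int:
        """Stable per-stage seed derived from the global seed."""
        stages = ["progression", "bootstrap", "permutation", "individuals", "simulate"]
        return int((self.seed * 1009 + stages.index(stage) + 1) % (2**31 - 1))


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=float)


def load_inputs(config: RunConfig):
    """Atlas + cohort per the config's schema and covariate set."""
    atlas = read_atlas(config.atlas_path)
    schema = dict(config.schema) if config.schema else {}
    if "covariates" not in schema:
        schema["covariates"] = {c: c for c in config.covariate_set if c != "age"}
    cohort = read_cohort_table(config.cohort_path, schema=schema)
    return atlas, cohort


def run_cohort(config: RunConfig) -> dict:
    """Full cohort pipeline; returns the report dict it also writes."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas, cohort = load_inputs(config)
    z = preprocess(
        cohort, atlas,
        covariate_set=tuple(config.covariate_set),
        drop_list=tuple(config.drop_regions),
        fit_on=config.fit_nuisance_on,
    )
    z.volumes.to_csv(out / "zscores.csv")

    mats = [read_adjacency(p, atlas=atlas) for p in config.connectome_paths]
    conn = average_connectomes(mats, atlas=atlas)
    raw_metrics = compute_node_metrics(conn)
    dist = spatial_distance_matrix(atlas)
    subject_epi, cohort_epi = select_epicenter(z)
    design = build_design_matrix(raw_metrics, conn, dist, cohort_epi, atlas)
    design.to_csv(out / "design_matrix.csv")

    pcfg = ProgressionConfig(**config.progression) if config.progression else None
    model = fit_progression(z, pcfg, seed=config.substream("progression"))
    model.save(out / "progression")
    rates = max_rates(model)
    profile = fit_cohort_profile(rates, design, threshold=config.sparsity_threshold)
    profile.to_frame().rename_axis("metric").to_csv(out / "profile.csv")

    selection = model_selection(rates.Y.to_numpy(), design)
    selection.rename_axis("model").to_csv(out / "model_selection.csv")
    r2 = variance_explained(rates.Y.to_numpy(), design)
    perm = permutation_test(
        rates.Y.to_numpy(), design, B=config.permutation_B,
        seed=config.substream("permutation"),
    )
    perm.rename_axis("metric").to_csv(out / "permutation.csv")
    boots, boot_summary = bootstrap_profiles(
        z, design, B=config.bootstrap_B, seed=config.substream("bootstrap"),
        progression_config=pcfg, threshold=config.sparsity_threshold,
    )
    boot_summary.rename_axis("metric").to_csv(out / "bootstrap.csv")

    report = {
        "seed": config.seed,
        "epicenter": cohort_epi,
        "n_subjects": z.n_subjects,
        "n_regions": len(z.regions),
        "converged": model.converged,
        "weights": profile.beta.to_dict(),
        "weights_sparse": profile.beta_sparse.to_dict(),
        "descriptor_sums": profile.descriptor_sums.to_dict(),
        "descriptor_percent": group_descriptors(profile, percentages=True).to_dict(),
        "r2": r2.to_dict(),
        "aic_full": profile.aic,
        "aic_best_single": float(
            selection.drop(index="full_profile")["aic"].min()
        ),
    }
    _write_json(report, out / "cohort_report.json")
    return report


def run_individuals(config: RunConfig, cohort_profiles: dict | None = None) -> dict:
    """Per-subject profiles plus cohort-space assignment artifacts.

    ``cohort_profiles`` maps cohort label -> 5-vector descriptor coordinates;
    when omitted, the single own-cohort profile from the cohort run is used
    (assignment then degenerates, so supplying several cohorts is the
    intended use).
    """
    out = Path(config.out_dir)
    if not (out / "progression.json").exists():
        raise DataError("cohort artifacts missing; run run_cohort first")
    from .progression import ProgressionModel

    model = ProgressionModel.load(out / "progression")
    design_df = pd.read_csv(out / "design_matrix.csv", index_col=0)
    with open(out / "cohort_report.json") as fh:
        report = json.load(fh)

    rates_j = individual_rates(model)
    rows = {}
    for s in rates_j.Yj.index:
        prof = sparsify(isra_fit(rates_j.Yj.loc[s].to_numpy(), design_df),
                        config.sparsity_threshold)
        rows[s] = prof.descriptor_sums
    coords = pd.DataFrame(rows).T
    coords.rename_axis("subject").to_csv(out / "individual_coords.csv")

    if cohort_profiles is None:
        cohort_profiles = {"cohort": pd.Series(report["descriptor_sums"])}
    cohort_coords = pd.DataFrame(cohort_profiles).T
    cohort_coords.columns = coords.columns
    summary = {"seed": config.seed, "n_individuals": int(len(coords))}
    if len(cohort_coords) >= 2:
        own = pd.Series(list(cohort_profiles)[0], index=coords.index)
        result = assign_and_flag(coords, cohort_coords, own)
        result.to_csv(out / "individuals.csv")
        confusion_matrix(result).rename_axis("true").to_csv(out / "confusion_matrix.csv")
        summary["outlier_rate"] = float(result.outlier.mean())
    else:
        # single reference profile: report distances only
        ref = cohort_coords.iloc[0].to_numpy(float)
        dist = np.linalg.norm(coords.to_numpy(float) - ref, axis=1)
        pd.Series(dist, index=coords.index, name="distance").rename_axis(
            "subject"
        ).to_csv(out / "individuals.csv")
        summary["mean_distance"] = float(dist.mean())
    _write_json(summary, out / "individual_report.json")
    return summary
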