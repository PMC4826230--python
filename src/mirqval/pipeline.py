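"""End-to-end orchestration: simulate/load -> curate -> normalize -> test ->
concordance -> classify, with a reproducibility manifest.

A single :class:`RunConfig` (usually parsed from YAML) drives the run.  The
master seed spawns independent child seeds per stage, so adding or removing a
late stage never perturbs the randomness of earlier ones, and rerunning the
same config reproduces every artifact bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .simulate import (
    SimulationConfig,
    ControlProfile,
    generate_study,
    generate_screening_stats,
)
from .curation import curate_matrix, expressed_panel
from .normalization import rank_controls, delta_ct
from .differential import two_group_stats, anova_three_group, venn_partition
from .concordance import match_identifiers, directional_concordance
from .classification import ClassifierConfig, cross_validate, permutation_null

__all__ = ["RunConfig", "RunConfigError", "run_all"]


class RunConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``inputs`` (paths to wells/annotation tables, optional
    screening and identifier-mapping tables) or ``simulation`` (a
    :class:`SimulationConfig`) must be given.
    """

    outdir: str = "mirqval_run"
    seed: int = 0
    simulation: SimulationConfig | None = None
    inputs: dict[str, str] | None = None
    screening_noise_sd: float = 0.05
    ct_limit: float = 25.0
    quality_min: float = 0.65
    na_limit: int = 10
    candidates: tuple[str, ...] = ("RNU6B", "RNU24", "RNU44", "RNU48", "RPL21")
    reference: str = "RNU44"
    contrasts: tuple[tuple[str, str], ...] = (("NSCLC", "control"), ("NSCLC", "COPD"))
    alpha: float = 0.05
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    run_classification: bool = True

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise RunConfigError(
                "exactly one of 'simulation' and 'inputs' must be configured"
            )
        if self.inputs is not None:
            for key in ("wells", "annotation"):
                if key not in self.inputs:
                    raise RunConfigError(f"inputs must provide a '{key}' path")
                if not Path(self.inputs[key]).exists():
                    raise RunConfigError(f"input file not found: {self.inputs[key]}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            profiles = sim.pop("control_profiles", None)
            if profiles is not None:
                sim["control_profiles"] = tuple(
                    ControlProfile(p["name"], float(p["mean_ct"]), float(p["sd_ct"]))
                    for p in profiles
                )
            sim = SimulationConfig(**sim)
        clf = raw.pop("classifier", None)
        kwargs: dict[str, Any] = dict(raw)
        if sim is not None:
            kwargs["simulation"] = sim
        if clf is not None:
            kwargs["classifier"] = ClassifierConfig(
                **{**clf, "panel_sizes": tuple(clf.get("panel_sizes", (5, 10, 50)))}
            )
        if "contrasts" in kwargs:
            kwargs["contrasts"] = tuple(tuple(c) for c in kwargs["contrasts"])
        if "candidates" in kwargs:
            kwargs["candidates"] = tuple(kwargs["candidates"])
        return cls(**kwargs)


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    fields = asdict(config)
    fields.pop("outdir", None)  # where artifacts land does not change them
    payload = json.dumps(fields, sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_all(config: RunConfig) -> Path:
    """Execute every stage and write all artifacts plus ``manifest.json``.

    Returns the output directory.  Any stage failure propagates with the
    stage name prefixed to the error message.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }
    seeds = np.random.SeedSequence(config.seed).spawn(6)
    stage_seed = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]

    def stage(name: str):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # pragma: no cover - error path
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc

        return wrap

    # -- stage 1: obtain data ------------------------------------------------
    screening = mapping = truth = None
    if config.simulation is not None:
        sim_cfg = config.simulation
        sim_cfg = SimulationConfig(**{**sim_cfg.__dict__, "seed": stage_seed[0]}) \
            if sim_cfg.seed == 0 else sim_cfg
        wells, annotation, truth = stage("simulate")(lambda: generate_study(sim_cfg))
        screening = generate_screening_stats(
            truth, noise_sd=config.screening_noise_sd, seed=stage_seed[1]
        )
        mio.write_table(wells, out / "wells.tsv")
        mio.write_table(annotation, out / "annotation.tsv")
        mio.write_table(truth.table, out / "ground_truth.tsv")
        mio.write_table(screening, out / "screening.tsv")
        controls = tuple(sim_cfg.control_names)
    else:
        wells = mio.read_wells(config.inputs["wells"])
        annotation = mio.read_annotation(config.inputs["annotation"])
        if "screening" in config.inputs:
            screening = mio.read_table(config.inputs["screening"])
        if "mapping" in config.inputs:
            mapping = mio.read_table(config.inputs["mapping"])
        controls = config.candidates
    groups = annotation.set_index("sample_id")["group"]
    manifest["stages"]["data"] = {
        "n_wells": int(len(wells)),
        "n_samples": int(annotation.shape[0]),
        "n_assays": int(wells["assay_id"].nunique()),
    }

    # -- stage 2: curation ---------------------------------------------------
    curated = stage("curation")(
        lambda: curate_matrix(
            wells,
            na_limit=config.na_limit,
            ct_limit=config.ct_limit,
            quality_min=config.quality_min,
        )
    )
    panel = expressed_panel(curated, controls=controls)
    mio.write_matrix(curated.values, out / "ct_matrix.tsv")
    mio.write_table(
        pd.DataFrame(
            [(a, r) for a, r in curated.dropped_assays.items()],
            columns=["assay_id", "reason"],
        ),
        out / "dropped_assays.tsv",
    )
    manifest["stages"]["curation"] = {
        "n_assays_kept": len(curated.assays),
        "n_assays_dropped": len(curated.dropped_assays),
        "n_expressed_targets": len(panel),
        "n_imputed_cells": int(curated.na_mask.to_numpy().sum()),
    }

    # -- stage 3: control ranking + delta-Ct --------------------------------
    available = [c for c in config.candidates if c in curated.values.index]
    if len(available) < 2:
        raise RuntimeError(
            "stage 'normalization' failed: fewer than two candidate controls "
            "survived curation"
        )
    matched_screening = None
    if screening is not None:
        matched, unmatched = match_identifiers(
            screening, list(curated.values.index), mapping=mapping
        )
        matched_screening = matched
        manifest["stages"]["identifier_matching"] = {
            "n_matched": int(len(matched)),
            "n_unmatched": int(len(unmatched)),
        }
    report = stage("normalization")(
        lambda: rank_controls(
            curated,
            groups,
            available,
            screening=matched_screening,
            contrast=config.contrasts[0],
        )
    )
    mio.write_matrix(report.table, out / "control_stability.tsv")
    reference = config.reference if config.reference in available else report.best()
    delta = delta_ct(curated, reference)
    mio.write_matrix(delta.values, out / "delta_ct.tsv")
    manifest["stages"]["normalization"] = {
        "reference": reference,
        "most_stable": report.best(),
    }

    # -- stage 4: differential ----------------------------------------------
    target_delta = delta.values.loc[[a for a in panel if a in delta.values.index]]
    stats_by_contrast = {}
    for contrast in config.contrasts:
        ms = stage("differential")(
            lambda c=contrast: two_group_stats(target_delta, groups, c)
        )
        stats_by_contrast[contrast] = ms
        mio.write_matrix(ms.table, out / f"stats_{contrast[0]}_vs_{contrast[1]}.tsv")
    if groups.nunique() >= 3:
        anova = anova_three_group(target_delta, groups)
        mio.write_matrix(anova, out / "anova.tsv")
        manifest["stages"]["anova"] = {
            "n_significant_raw": int((anova["p"] < config.alpha).sum()),
            "n_significant_adjusted": int((anova["q"] < config.alpha).sum()),
        }
    if len(config.contrasts) >= 2:
        venn = venn_partition(
            stats_by_contrast[config.contrasts[0]],
            stats_by_contrast[config.contrasts[1]],
            alpha=config.alpha,
        )
        (out / "venn.json").write_text(json.dumps(venn.counts(), indent=2))
        manifest["stages"]["venn"] = venn.counts()

    # -- stage 5: concordance -----------------------------------------------
    if matched_screening is not None:
        rep = stage("concordance")(
            lambda: directional_concordance(
                matched_screening,
                stats_by_contrast[config.contrasts[0]],
                alpha=config.alpha,
            )
        )
        manifest["stages"]["concordance"] = {
            "n_matched": rep.n_matched,
            "n_significant": rep.n_significant,
            "n_concordant": rep.n_concordant,
            "percent_concordant": rep.percent_concordant,
            "binomial_p": rep.binomial_p,
            "pearson_r": rep.pearson_r,
        }
        (out / "concordance.json").write_text(
            json.dumps(manifest["stages"]["concordance"], indent=2)
        )

    # -- stage 6: classification --------------------------------------------
    if config.run_classification:
        clf_cfg = ClassifierConfig(
            **{**config.classifier.__dict__, "seed": stage_seed[5]}
        )
        result = stage("classification")(
            lambda: cross_validate(target_delta, groups, config.contrasts[0], clf_cfg)
        )
        null = permutation_null(
            target_delta, groups, config.contrasts[0], clf_cfg,
            panel_size=clf_cfg.panel_sizes[0],
        )
        summary = {
            str(k): {
                "accuracy": p.accuracy,
                "sensitivity": p.sensitivity,
                "specificity": p.specificity,
                "auc": p.auc,
                "ci_accuracy": list(p.ci_accuracy),
                "top_markers": p.consensus_panel()[: k],
            }
            for k, p in result.panels.items()
        }
        summary["permutation_null"] = {
            "panel_size": null.panel_size,
            "mean_accuracy": float(null.accuracies.mean()),
            "empirical_p": null.empirical_p,
        }
        (out / "classification.json").write_text(json.dumps(summary, indent=2))
        manifest["stages"]["classification"] = {
            str(k): {"accuracy": p.accuracy, "auc": p.auc}
            for k, p in result.panels.items()
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
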