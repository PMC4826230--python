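"""Seeded generator of Fluidigm-style well-level qRT-PCR datasets.

The generator emulates a dynamic-array validation study: a panel of target
miRNA assays plus a handful of endogenous small-RNA controls, each measured
in triplicate on every sample, with per-well amplification-curve quality
scores, outright well failures, and censoring of late threshold cycles.
Ground truth (baseline Ct per assay and the signed group shifts planted per
contrast) is returned alongside the raw wells so every downstream stage can
be tested against known answers.

The well model is hierarchical: a merged per-sample Ct is drawn as
``baseline + group shift + N(0, biological_sd)`` and the three replicate
wells scatter around it with ``N(0, replicate_sd)``.  Quality scores are
Beta-distributed, with "good" wells peaking near 1 and failed wells peaking
near 0.4 so that the 0.65 curation threshold is exercised from both sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "ControlProfile",
    "SimulationConfig",
    "GroundTruth",
    "SimulationConfigError",
    "generate_study",
    "generate_screening_stats",
    "DEFAULT_CONTROLS",
    "DEFAULT_GROUPS",
    "CONTRASTS",
]


class SimulationConfigError(ValueError):
    """Raised when a :class:`SimulationConfig` field is invalid; names the field."""


@dataclass(frozen=True)
class ControlProfile:
    """Abundance profile of one endogenous control (mean/SD on the Ct scale)."""

    name: str
    mean_ct: float
    sd_ct: float


#: Default endogenous-control abundance tiers.  RNU48 is the highest expressed
#: (mean Ct 8, SD 1.4), followed by RNU44 (mean 12, SD 2.1); RNU6B sits at the
#: low-abundance end (mean 20.9, SD 2.0).  RNU24 and RPL21 are modelled as low
#: abundant, RNU24 with the tightest spread of the five.
DEFAULT_CONTROLS: tuple[ControlProfile, ...] = (
    ControlProfile("RNU48", 8.0, 1.4),
    ControlProfile("RNU44", 12.0, 2.1),
    ControlProfile("RNU6B", 20.9, 2.0),
    ControlProfile("RNU24", 22.0, 1.1),
    ControlProfile("RPL21", 21.0, 2.3),
)

#: Default cohort: 74 lung-cancer (NSCLC) patients, 26 COPD patients and
#: 20 unaffected controls.
DEFAULT_GROUPS: dict[str, int] = {"NSCLC": 74, "COPD": 26, "control": 20}

#: The two validation contrasts for which effects are planted.
CONTRASTS: tuple[tuple[str, str], ...] = (("NSCLC", "control"), ("NSCLC", "COPD"))


@dataclass
class SimulationConfig:
    """Parameters of one simulated validation study.

    Parameters
    ----------
    n_per_group
        Samples per group label; every count must be >= 2.
    n_assays
        Number of target (non-control) assays on the panel.
    control_profiles
        Endogenous controls with their Ct-scale abundance tiers.
    n_planted
        Number of truly differential target assays *per contrast*.
    effect_size
        Magnitude of the planted group shift, in Ct cycles (|DeltaDeltaCt|).
    biological_sd
        Between-sample SD intrinsic to a target assay, in cycles (on top of
        the shared loading offset).
    loading_sd
        SD of a per-sample global Ct offset shared by every assay on the
        array (RNA input / efficiency variation).  Delta-Ct normalization
        removes this component exactly, which is its purpose.  A control's
        profile SD is its *total* SD; the intrinsic part is
        ``sqrt(max(sd_ct**2 - loading_sd**2, 0))``.
    replicate_sd
        Within-triplicate technical SD around the merged Ct, in cycles.
    dropout_base
        Baseline probability that a well fails outright, independent of Ct.
    quality_good, quality_failed
        (alpha, beta) of the Beta distributions generating quality scores for
        good and failed wells.
    ct_ceiling
        Cycles beyond which a well is censored (no amplification recorded).
    target_ct_range
        Uniform range from which target-assay baseline Cts are drawn.
    seed
        Seed for the single random generator; identical seeds give
        byte-identical outputs.
    """

    n_per_group: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    n_assays: int = 235
    control_profiles: Sequence[ControlProfile] = DEFAULT_CONTROLS
    n_planted: int = 30
    effect_size: float = 2.0
    biological_sd: float = 1.0
    loading_sd: float = 1.0
    replicate_sd: float = 0.25
    dropout_base: float = 0.02
    quality_good: tuple[float, float] = (9.0, 1.5)
    quality_failed: tuple[float, float] = (4.0, 6.0)
    ct_ceiling: float = 28.0
    target_ct_range: tuple[float, float] = (12.0, 24.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_per_group:
            raise SimulationConfigError("n_per_group: at least one group required")
        for g, n in self.n_per_group.items():
            if int(n) < 2:
                raise SimulationConfigError(f"n_per_group[{g}]: group counts must be >= 2")
        if self.n_assays < 1:
            raise SimulationConfigError("n_assays: must be >= 1")
        if not (0.0 <= self.dropout_base <= 1.0):
            raise SimulationConfigError("dropout_base: probability must be in [0, 1]")
        for name in ("biological_sd", "loading_sd", "replicate_sd", "effect_size"):
            if getattr(self, name) < 0:
                raise SimulationConfigError(f"{name}: must be >= 0")
        for name in ("quality_good", "quality_failed"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise SimulationConfigError(f"{name}: Beta parameters must be > 0")
        profiles = list(self.control_profiles)
        for p in profiles:
            if p.sd_ct < 0:
                raise SimulationConfigError(f"control_profiles[{p.name}].sd_ct: must be >= 0")
            if self.ct_ceiling <= p.mean_ct:
                raise SimulationConfigError(
                    f"ct_ceiling: must exceed every control mean (violated by {p.name})"
                )
        if len({p.name for p in profiles}) != len(profiles):
            raise SimulationConfigError("control_profiles: duplicate control names")
        if 2 * self.n_planted > self.n_assays:
            raise SimulationConfigError(
                "n_planted: the two contrasts' planted sets must fit among n_assays"
            )
        lo, hi = self.target_ct_range
        if not (0 < lo < hi):
            raise SimulationConfigError("target_ct_range: need 0 < low < high")

    @property
    def control_names(self) -> list[str]:
        return [p.name for p in self.control_profiles]


@dataclass
class GroundTruth:
    """Per-assay truth of a simulated study.

    ``table`` holds one row per assay with its baseline Ct, a control flag and,
    for every contrast ``(A, B)``, the signed true shift of group A relative to
    group B in cycles (column ``shift_A_vs_B``) plus a planted flag.
    Non-planted assays have a contrast shift of exactly zero and planted shifts
    have magnitude equal to the configured effect size.
    """

    table: pd.DataFrame
    contrasts: tuple[tuple[str, str], ...] = CONTRASTS

    @staticmethod
    def shift_column(contrast: tuple[str, str]) -> str:
        return f"shift_{contrast[0]}_vs_{contrast[1]}"

    def shifts(self, contrast: tuple[str, str]) -> pd.Series:
        return self.table.set_index("assay_id")[self.shift_column(contrast)]

    def planted_assays(self, contrast: tuple[str, str]) -> list[str]:
        col = f"planted_{contrast[0]}_vs_{contrast[1]}"
        return self.table.loc[self.table[col], "assay_id"].tolist()

    @property
    def target_assays(self) -> list[str]:
        return self.table.loc[~self.table["is_control"], "assay_id"].tolist()


def _group_offsets(
    cfg: SimulationConfig, rng: np.random.Generator, target_ids: list[str]
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Choose planted assays and build per-group Ct offsets.

    Assays planted for the first contrast (A vs reference group B) receive the
    same shift in every non-reference group, so all other contrasts stay
    exactly null for them; assays planted for the second contrast (A vs C)
    receive a shift only in group C.
    """
    n = len(target_ids)
    planted_a = np.zeros(n, dtype=bool)
    planted_b = np.zeros(n, dtype=bool)
    idx = rng.choice(n, size=min(2 * cfg.n_planted, n), replace=False)
    planted_a[idx[: cfg.n_planted]] = True
    planted_b[idx[cfg.n_planted : 2 * cfg.n_planted]] = True
    signs_a = rng.choice([-1.0, 1.0], size=n)
    signs_b = rng.choice([-1.0, 1.0], size=n)

    (grp_a, grp_ref), (_, grp_c) = CONTRASTS
    offsets = {g: np.zeros(n) for g in cfg.n_per_group}
    shift_a = np.where(planted_a, signs_a * cfg.effect_size, 0.0)
    shift_b = np.where(planted_b, signs_b * cfg.effect_size, 0.0)
    if grp_a in offsets:
        offsets[grp_a] += shift_a
    if grp_c in offsets:
        offsets[grp_c] += shift_a  # keeps A-vs-C null for contrast-1 assays
        offsets[grp_c] -= shift_b  # A minus C equals +shift_b for contrast-2 assays

    truth = pd.DataFrame(
        {
            "assay_id": target_ids,
            f"shift_{grp_a}_vs_{grp_ref}": shift_a,
            f"planted_{grp_a}_vs_{grp_ref}": planted_a,
            f"shift_{grp_a}_vs_{grp_c}": shift_b,
            f"planted_{grp_a}_vs_{grp_c}": planted_b,
        }
    )
    return truth, offsets


def _assign_kits(group: str, n: int) -> list[str]:
    # COPD samples mirror the study design (all miRNeasy); other groups
    # alternate so every kit subset contains both contrast groups.
    if group == "COPD":
        return ["miRNeasy"] * n
    return [("miRNeasy" if i % 2 else "PAXgene") for i in range(n)]


def generate_study(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate one validation study.

    Returns
    -------
    wells
        Long-format table with one row per well: ``sample_id``, ``assay_id``,
        ``replicate`` (1..3), ``ct`` (NaN for wells without amplification) and
        ``quality`` in [0, 1].
    annotation
        One row per sample: ``sample_id``, ``group``, ``kit``, ``plate``.
    truth
        :class:`GroundTruth` for the panel (controls carry zero shift).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    groups = list(cfg.n_per_group)
    sample_ids: list[str] = []
    sample_group: list[str] = []
    kits: list[str] = []
    for g in groups:
        n = int(cfg.n_per_group[g])
        ids = [f"{g}_{i + 1:03d}" for i in range(n)]
        sample_ids += ids
        sample_group += [g] * n
        kits += _assign_kits(g, n)
    n_samples = len(sample_ids)
    plates = [(i % 2) + 1 for i in range(n_samples)]  # round-robin across 2 arrays
    annotation = pd.DataFrame(
        {"sample_id": sample_ids, "group": sample_group, "kit": kits, "plate": plates}
    )

    target_ids = [f"miR-{i + 1:04d}" for i in range(cfg.n_assays)]
    truth_targets, offsets = _group_offsets(cfg, rng, target_ids)
    lo, hi = cfg.target_ct_range
    target_baseline = rng.uniform(lo, hi, size=cfg.n_assays)

    control_ids = cfg.control_names
    control_baseline = np.array([p.mean_ct for p in cfg.control_profiles])
    # profile SDs are total SDs; the shared loading offset accounts for part
    control_sd = np.sqrt(
        np.maximum(
            np.array([p.sd_ct for p in cfg.control_profiles]) ** 2
            - cfg.loading_sd**2,
            0.0,
        )
    )

    assay_ids = target_ids + control_ids
    baseline = np.concatenate([target_baseline, control_baseline])
    bio_sd = np.concatenate(
        [np.full(cfg.n_assays, cfg.biological_sd), control_sd]
    )
    n_assays_total = len(assay_ids)

    # per-assay group offset matrix (assay x sample), controls carry no shift
    offset_mat = np.zeros((n_assays_total, n_samples))
    group_arr = np.asarray(sample_group)
    for g in groups:
        cols = group_arr == g
        offset_mat[: cfg.n_assays, cols] = offsets[g][:, None]

    loading = rng.normal(0.0, 1.0, size=n_samples) * cfg.loading_sd
    merged = (
        baseline[:, None]
        + offset_mat
        + loading[None, :]
        + rng.normal(0.0, 1.0, size=(n_assays_total, n_samples)) * bio_sd[:, None]
    )
    reps = merged[:, :, None] + rng.normal(
        0.0, 1.0, size=(n_assays_total, n_samples, 3)
    ) * cfg.replicate_sd
    reps = np.maximum(reps, 1e-3)  # Ct is a positive cycle count

    # Failure model: baseline dropout plus a logistic rise in the last five
    # cycles below the ceiling; censored wells (Ct past the ceiling) never
    # amplify.  Half of the failed wells record no Ct at all, the other half
    # record the Ct but draw a low quality score.
    p_fail = cfg.dropout_base + (1.0 - cfg.dropout_base) * expit(
        (reps - (cfg.ct_ceiling - 2.5)) / 0.8
    )
    failed = rng.random(reps.shape) < p_fail
    censored = reps > cfg.ct_ceiling
    failed |= censored
    no_ct = failed & (rng.random(reps.shape) < 0.5)
    no_ct |= censored

    ga, gb = cfg.quality_good
    fa, fb = cfg.quality_failed
    q_good = rng.beta(ga, gb, size=reps.shape)
    q_fail = rng.beta(fa, fb, size=reps.shape)
    quality = np.where(failed, q_fail, q_good)

    ct = reps.copy()
    ct[no_ct] = np.nan

    wells = pd.DataFrame(
        {
            "sample_id": np.repeat(sample_ids, n_assays_total * 3).tolist(),
            "assay_id": np.tile(np.repeat(assay_ids, 3), n_samples).tolist(),
            "replicate": np.tile([1, 2, 3], n_assays_total * n_samples),
            # transpose to sample-major order so the table reads plate-like
            "ct": np.transpose(ct, (1, 0, 2)).reshape(-1),
            "quality": np.transpose(quality, (1, 0, 2)).reshape(-1),
        }
    )

    truth_controls = pd.DataFrame({"assay_id": control_ids})
    for (a, b) in CONTRASTS:
        truth_controls[f"shift_{a}_vs_{b}"] = 0.0
        truth_controls[f"planted_{a}_vs_{b}"] = False
    truth_tab = pd.concat([truth_targets, truth_controls], ignore_index=True)
    truth_tab.insert(1, "baseline_ct", baseline)
    truth_tab.insert(2, "is_control", [False] * cfg.n_assays + [True] * len(control_ids))

    return wells, annotation, GroundTruth(truth_tab)


def generate_screening_stats(
    truth: GroundTruth,
    noise_sd: float,
    seed: int,
    contrast: tuple[str, str] = ("NSCLC", "control"),
    snr: float = 3.0,
) -> pd.DataFrame:
    """Simulate the per-assay statistics of an earlier screening study.

    For every target assay the screening AUC deviates from 0.5 with the sign
    of the true contrast shift (saturating with effect magnitude) plus
    Gaussian noise of SD ``noise_sd``; the screening p-value comes from a
    Gaussian test statistic centred at ``snr * shift``, so null assays yield
    uniform p-values and planted assays concentrate at small p.

    Returns a table with ``assay_id``, ``auc`` and ``p_value`` columns.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    targets = truth.table.loc[~truth.table["is_control"]]
    shift = targets[GroundTruth.shift_column(contrast)].to_numpy(dtype=float)

    auc = 0.5 + 0.3 * np.tanh(shift / 1.5)
    if noise_sd > 0:
        auc = auc + rng.normal(0.0, noise_sd, size=auc.shape)
    auc = np.clip(auc, 1e-3, 1.0 - 1e-3)

    z = snr * shift + rng.normal(0.0, 1.0, size=shift.shape)
    pvals = 2.0 * norm.sf(np.abs(z))

    return pd.DataFrame(
        {"assay_id": targets["assay_id"].to_numpy(), "auc": auc, "p_value": pvals}
    )
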