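"""Endogenous-control evaluation and delta-Ct normalization.

Candidate reference genes are scored four ways: mean/SD and coefficient of
variation on the Ct scale, CV on the linearized 2^-Ct scale, a model-based
stability value in the spirit of the NormFinder variance-decomposition
approach (Andersen-style: intragroup variance plus shrunken intergroup bias,
lower is more stable), and — when statistics from an earlier screening study
are available — the concordance between validation AUCs computed under each
candidate normalization and the screening AUCs.  The chosen reference then
yields a delta-Ct matrix: DeltaCt(assay, sample) = Ct(assay, sample) -
Ct(reference, sample), so higher DeltaCt means lower expression relative to
the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .curation import CuratedCtMatrix

__all__ = [
    "NormalizationError",
    "ControlStabilityReport",
    "DeltaCtMatrix",
    "coefficient_of_variation",
    "normfinder_stability",
    "rank_controls",
    "delta_ct",
]


class NormalizationError(ValueError):
    pass


@dataclass
class DeltaCtMatrix:
    """Delta-Ct values (assay x sample) relative to one endogenous control."""

    values: pd.DataFrame
    reference: str

    @property
    def assays(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ControlStabilityReport:
    """Per-candidate control summary.

    ``table`` has one row per candidate with columns ``mean_ct``, ``sd_ct``,
    ``cv_ct``, ``cv_linear``, ``stability`` and matching ``rank_*`` columns
    (rank 1 = best, i.e. smallest criterion).  When screening statistics were
    supplied it gains ``concordance_r`` (Pearson correlation between the
    validation AUCs under that candidate's normalization and the screening
    AUCs) with ``rank_concordance`` (rank 1 = largest r), and
    ``raw_ct_concordance`` holds the un-normalized (raw Ct) reference value.
    """

    table: pd.DataFrame
    raw_ct_concordance: float | None = None

    def best(self, criterion: str = "stability") -> str:
        return str(self.table[criterion].idxmin())


def _as_frame(curated: CuratedCtMatrix | pd.DataFrame) -> pd.DataFrame:
    return curated.values if isinstance(curated, CuratedCtMatrix) else curated


def coefficient_of_variation(values: Sequence[float], scale: str = "ct") -> float:
    """Sample CV (SD / mean) of Ct values, on the ``ct`` or ``linear`` scale.

    On the linear scale each Ct is first transformed to 2**-Ct (relative
    abundance), which typically reorders candidates because the transform is
    convex in -Ct.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise NormalizationError("CV needs at least two values")
    if np.isnan(v).any():
        raise NormalizationError("CV input contains missing values")
    if scale == "linear":
        v = np.exp2(-v)
    elif scale != "ct":
        raise NormalizationError(f"unknown scale {scale!r}")
    mean = v.mean()
    if mean == 0:
        raise NormalizationError("CV undefined for zero-mean values")
    return float(v.std(ddof=1) / mean)


def _stability_components(
    y: np.ndarray, group_idx: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Variance components of the grouped stability model.

    ``y`` is genes x samples on the Ct (log) scale, already restricted to the
    candidate set.  Samples are centered by their candidate-set mean, then for
    each gene i and group g the intragroup variance sigma2[i, g] and the
    intergroup bias d[i, g] (deviation of the gene's group mean from its
    overall mean, on centered data) are estimated.  The candidate-set
    centering inflates the naive per-gene sample variances, which is undone by
    the standard unbiasing step (requires >= 3 candidates; with exactly 2 the
    naive variances are used).  Returns (d, sigma2, var_d, gamma2) where
    var_d[i, g] = sigma2[i, g] / n_g is the sampling variance of d and gamma2
    is the between-gene variance of the true biases, estimated by moments.
    """
    n_genes = y.shape[0]
    n_groups = len(group_idx)
    z = y - y.mean(axis=0, keepdims=True)

    m = np.empty((n_genes, n_groups))
    s2 = np.empty((n_genes, n_groups))
    k = np.empty(n_groups)
    for g, idx in enumerate(group_idx):
        zg = z[:, idx]
        k[g] = idx.size
        m[:, g] = zg.mean(axis=1)
        s2[:, g] = zg.var(axis=1, ddof=1)

    if n_genes >= 3:
        total = s2.sum(axis=0) * n_genes / (n_genes - 1.0)
        sigma2 = (s2 - total[None, :] / n_genes**2) * n_genes / (n_genes - 2.0)
        sigma2 = np.maximum(sigma2, 0.0)
    else:
        sigma2 = s2

    d = m - m.mean(axis=1, keepdims=True)
    var_d = sigma2 / k[None, :]
    gamma2 = max(
        0.0,
        float(
            (d**2).sum() / ((n_genes - 1.0) * max(n_groups - 1.0, 1.0))
            - var_d.mean()
        ),
    )
    return d, sigma2, var_d, gamma2


def normfinder_stability(
    curated: CuratedCtMatrix | pd.DataFrame,
    groups: pd.Series | None,
    candidates: Sequence[str],
) -> pd.Series:
    """Model-based stability per candidate control; lower is more stable.

    With group labels, each candidate's stability averages over groups the
    magnitude of its shrunken intergroup bias plus its intragroup variation
    term (both in cycles):
    ``rho_i = mean_g( |d_ig| * g2/(g2 + v_ig) + sqrt(v_ig) )``
    with ``v_ig = sigma2_ig / n_g`` and ``g2`` the moment estimate of the
    between-gene bias variance; the shrinkage pulls noisy bias estimates
    toward zero while the sqrt(v) term charges the candidate for its
    intragroup noise.  Without group labels the stability degrades to the SD
    of the candidate across samples after candidate-set centering.
    """
    df = _as_frame(curated)
    candidates = list(candidates)
    missing = [c for c in candidates if c not in df.index]
    if missing:
        raise NormalizationError(f"candidate controls absent from matrix: {missing}")
    if len(candidates) < 2:
        raise NormalizationError("need at least two candidate controls")
    y = df.loc[candidates].to_numpy(dtype=float)

    if groups is None:
        z = y - y.mean(axis=0, keepdims=True)
        return pd.Series(z.std(axis=1, ddof=1), index=candidates, name="stability")

    groups = groups.reindex(df.columns)
    if groups.isna().any():
        raise NormalizationError("group labels missing for some samples")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise NormalizationError("grouped stability needs at least two groups")
    group_idx = []
    garr = groups.to_numpy()
    for lab in labels:
        idx = np.flatnonzero(garr == lab)
        if idx.size < 2:
            raise NormalizationError(
                f"group {lab!r} has fewer than 2 samples; drop it or use groups=None"
            )
        group_idx.append(idx)

    d, _, var_d, gamma2 = _stability_components(y, group_idx)
    shrink = gamma2 / (gamma2 + var_d) if gamma2 > 0 else np.zeros_like(var_d)
    rho = (np.abs(d) * shrink + np.sqrt(var_d)).mean(axis=1)
    return pd.Series(rho, index=candidates, name="stability")


def _validation_aucs(
    ct: pd.DataFrame,
    groups: pd.Series,
    contrast: tuple[str, str],
    assays: Sequence[str],
) -> pd.Series:
    from .differential import auc as _auc

    groups = groups.reindex(ct.columns)
    mask_a = (groups == contrast[0]).to_numpy()
    mask_b = (groups == contrast[1]).to_numpy()
    out = {}
    for a in assays:
        row = ct.loc[a].to_numpy(dtype=float)
        out[a] = _auc(
            np.concatenate([row[mask_a], row[mask_b]]),
            np.array([contrast[0]] * mask_a.sum() + [contrast[1]] * mask_b.sum()),
            positive=contrast[0],
        )
    return pd.Series(out)


def rank_controls(
    curated: CuratedCtMatrix | pd.DataFrame,
    groups: pd.Series | None,
    candidates: Sequence[str],
    screening: pd.DataFrame | None = None,
    contrast: tuple[str, str] = ("NSCLC", "control"),
) -> ControlStabilityReport:
    """Score and rank candidate endogenous controls on every criterion.

    ``groups`` maps sample id to group label (may be None for ungrouped
    stability).  When a screening table (``assay_id``, ``auc``) is given, the
    per-assay validation AUCs for ``contrast`` are recomputed under each
    candidate's delta-Ct normalization and correlated with the screening
    AUCs; the raw-Ct (no normalization) correlation is reported alongside as
    a baseline.  Stability uses only the two contrast groups when group
    labels are available.
    """
    df = _as_frame(curated)
    candidates = list(candidates)
    for c in candidates:
        if c not in df.index:
            raise NormalizationError(f"candidate control {c!r} absent from matrix")

    rows = {}
    for c in candidates:
        v = df.loc[c]
        rows[c] = {
            "mean_ct": float(v.mean()),
            "sd_ct": float(v.std(ddof=1)),
            "cv_ct": coefficient_of_variation(v, "ct"),
            "cv_linear": coefficient_of_variation(v, "linear"),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")

    if len(candidates) == 1:
        # a lone candidate has no reference set to center against; its overall
        # SD stands in for stability and it ranks first trivially
        stab = pd.Series(
            {candidates[0]: float(df.loc[candidates[0]].std(ddof=1))}, name="stability"
        )
    elif groups is not None:
        sub = groups[groups.isin(contrast)]
        if sub.nunique() == 2 and sub.value_counts().min() >= 2:
            keep = groups.isin(contrast)
            stab = normfinder_stability(
                df.loc[:, groups.index[keep]], groups[keep], candidates
            )
        else:
            stab = normfinder_stability(df, None, candidates)
    else:
        stab = normfinder_stability(df, None, candidates)
    table["stability"] = stab

    raw_r = None
    if screening is not None:
        if groups is None:
            raise NormalizationError("screening concordance requires group labels")
        screen = screening.set_index("assay_id")["auc"]
        targets = [a for a in df.index if a in screen.index and a not in candidates]
        if len(targets) < 3:
            raise NormalizationError("fewer than 3 assays shared with screening table")
        screen_vec = screen.loc[targets]
        raw_auc = _validation_aucs(df, groups, contrast, targets)
        raw_r = float(pearsonr(raw_auc.loc[targets], screen_vec)[0])
        conc = {}
        for c in candidates:
            delta = df.loc[targets].sub(df.loc[c], axis=1)
            val_auc = _validation_aucs(delta, groups, contrast, targets)
            conc[c] = float(pearsonr(val_auc.loc[targets], screen_vec)[0])
        table["concordance_r"] = pd.Series(conc)
        table["rank_concordance"] = (
            table["concordance_r"].rank(ascending=False, method="min").astype(int)
        )

    for crit in ("sd_ct", "cv_ct", "cv_linear", "stability"):
        table[f"rank_{crit}"] = table[crit].rank(method="min").astype(int)

    return ControlStabilityReport(table=table, raw_ct_concordance=raw_r)


def delta_ct(
    curated: CuratedCtMatrix | pd.DataFrame, reference: str
) -> DeltaCtMatrix:
    """Subtract the reference control's Ct from every assay, per sample.

    The reference row is excluded from the result.  Delta-Ct is invariant to
    any per-sample additive shift of the raw Cts (loading/efficiency
    effects), which is the point of within-sample normalization.
    """
    df = _as_frame(curated)
    if reference not in df.index:
        if isinstance(curated, CuratedCtMatrix) and reference in curated.dropped_assays:
            raise NormalizationError(
                f"reference {reference!r} was dropped during curation: "
                f"{curated.dropped_assays[reference]}"
            )
        raise NormalizationError(f"reference {reference!r} absent from matrix")
    ref = df.loc[reference]
    if ref.isna().any():
        raise NormalizationError(f"reference {reference!r} has missing values")
    values = df.drop(index=reference).sub(ref, axis=1)
    return DeltaCtMatrix(values=values, reference=reference)
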