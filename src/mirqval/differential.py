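"""Per-assay differential-abundance statistics on delta-Ct values.

For a pairwise contrast (A, B) each assay gets a two-sided Welch t-test p, a
two-sided Wilcoxon/Mann-Whitney rank-sum p, a Benjamini-Hochberg adjusted q
across the tested panel, and a Mann-Whitney AUC.  The AUC orientation is
fixed: the first-named group of the contrast is the positive class, so the
AUC is the probability that a random positive-group sample has the *larger*
delta-Ct (ties count one half).  Because higher delta-Ct means lower
expression, AUC < 0.5 reads as "up-regulated in the positive group".  A
three-group one-way ANOVA and the Venn partition of significant up/down sets
across two contrasts complete the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .normalization import DeltaCtMatrix

__all__ = [
    "DifferentialError",
    "MarkerStatsTable",
    "VennPartition",
    "auc",
    "two_group_stats",
    "bh_adjust",
    "anova_three_group",
    "venn_partition",
]


class DifferentialError(ValueError):
    pass


def _as_frame(delta) -> pd.DataFrame:
    return delta.values if isinstance(delta, DeltaCtMatrix) else delta


def auc(values, labels, positive) -> float:
    """Mann-Whitney AUC of ``values`` for the ``positive`` group.

    Equals U / (n_pos * n_other) where U counts pairs in which the positive
    sample exceeds the other sample, ties contributing one half.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = values[labels == positive]
    neg = values[labels != positive]
    if pos.size == 0 or neg.size == 0:
        raise DifferentialError("AUC needs samples in both groups")
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (pos.size * neg.size))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, ties preserved)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DifferentialError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class MarkerStatsTable:
    """Per-assay statistics for one two-group contrast.

    ``table`` is indexed by assay with columns ``p_t`` (Welch), ``p_w``
    (rank-sum), ``q`` (BH over the panel, on the base test given by
    ``q_base``), ``auc``, ``direction`` and the two group means.  ``contrast``
    records (positive group, other group); the positive group is always the
    first-named one.
    """

    table: pd.DataFrame
    contrast: tuple[str, str]
    q_base: str = "p_t"

    @property
    def assays(self) -> list[str]:
        return list(self.table.index)

    def significant(self, alpha: float = 0.05, adjusted: bool = False) -> pd.DataFrame:
        col = "q" if adjusted else self.q_base
        return self.table[self.table[col] < alpha]


def two_group_stats(
    delta,
    groups: pd.Series,
    contrast: tuple[str, str],
    q_base: str = "p_t",
) -> MarkerStatsTable:
    """Welch t, rank-sum, BH q and AUC per assay for one contrast.

    ``groups`` maps sample id to group label; only samples belonging to the
    two contrast groups are used.  ``q_base`` selects which p-value family the
    BH adjustment runs on (``p_t`` by default, ``p_w`` optional).
    """
    df = _as_frame(delta)
    a, b = contrast
    groups = groups.reindex(df.columns)
    mask_a = (groups == a).to_numpy()
    mask_b = (groups == b).to_numpy()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise DifferentialError(
            f"contrast {a!r} vs {b!r}: both groups need >= 2 samples"
        )
    xa = df.to_numpy(dtype=float)[:, mask_a]
    xb = df.to_numpy(dtype=float)[:, mask_b]

    p_t = stats.ttest_ind(xa, xb, axis=1, equal_var=False).pvalue
    # degenerate zero-variance, equal-mean assays: no evidence against the null
    same = (xa.std(axis=1) == 0) & (xb.std(axis=1) == 0)
    equal_means = same & (xa.mean(axis=1) == xb.mean(axis=1))
    p_t = np.where(equal_means, 1.0, p_t)

    n1, n2 = xa.shape[1], xb.shape[1]
    u = stats.mannwhitneyu(xa, xb, axis=1, alternative="two-sided")
    p_w = u.pvalue
    aucs = u.statistic / (n1 * n2)

    q = bh_adjust(p_t if q_base == "p_t" else p_w)
    direction = np.where(aucs < 0.5, f"up_in_{a}", f"down_in_{a}")
    direction = np.where(aucs == 0.5, "none", direction)

    table = pd.DataFrame(
        {
            "p_t": p_t,
            "p_w": p_w,
            "q": q,
            "auc": aucs,
            "direction": direction,
            f"mean_{a}": xa.mean(axis=1),
            f"mean_{b}": xb.mean(axis=1),
        },
        index=df.index,
    )
    return MarkerStatsTable(table=table, contrast=contrast, q_base=q_base)


def anova_three_group(delta, groups: pd.Series) -> pd.DataFrame:
    """One-way fixed-effects ANOVA across all groups, per assay, with BH q.

    Returns a table indexed by assay with ``F``, ``p``, ``q`` and
    ``top_group`` — the group with the highest mean delta-Ct, i.e. the lowest
    relative expression.
    """
    df = _as_frame(delta)
    groups = groups.reindex(df.columns)
    labels = pd.unique(groups.dropna())
    if len(labels) < 3:
        raise DifferentialError("three-group ANOVA needs at least 3 groups")
    arrays = []
    for lab in labels:
        idx = (groups == lab).to_numpy()
        if idx.sum() < 2:
            raise DifferentialError(f"group {lab!r} has fewer than 2 samples")
        arrays.append(df.to_numpy(dtype=float)[:, idx])
    res = stats.f_oneway(*arrays, axis=1)
    means = np.stack([arr.mean(axis=1) for arr in arrays], axis=1)
    top = np.asarray(labels)[means.argmax(axis=1)]
    pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    return pd.DataFrame(
        {"F": res.statistic, "p": pvals, "q": bh_adjust(pvals), "top_group": top},
        index=df.index,
    )


@dataclass
class VennPartition:
    """Up/down significant sets of two contrasts and their pairwise overlaps.

    ``sets`` maps the four labels (``up_<contrast1>``, ``down_<contrast1>``,
    ``up_<contrast2>``, ``down_<contrast2>``) to assay-id sets; ``overlaps``
    maps each unordered label pair to the intersection.
    """

    sets: dict[str, set[str]]
    overlaps: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        out = {k: len(v) for k, v in self.sets.items()}
        out.update({f"{a} & {b}": len(v) for (a, b), v in self.overlaps.items()})
        return out


def venn_partition(
    stats_a: MarkerStatsTable,
    stats_b: MarkerStatsTable,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> VennPartition:
    """Split each contrast's significant assays by direction and intersect.

    Discordant-direction overlaps (up in one contrast, down in the other) are
    reported like any other pair — a marker can rise against one comparison
    group and fall against the other.
    """
    def direction_sets(ms: MarkerStatsTable) -> tuple[set[str], set[str], str]:
        sig = ms.significant(alpha=alpha, adjusted=use_adjusted)
        name = f"{ms.contrast[0]}_vs_{ms.contrast[1]}"
        up = set(sig.index[sig["direction"] == f"up_in_{ms.contrast[0]}"])
        down = set(sig.index[sig["direction"] == f"down_in_{ms.contrast[0]}"])
        return up, down, name

    up_a, down_a, name_a = direction_sets(stats_a)
    up_b, down_b, name_b = direction_sets(stats_b)
    sets = {
        f"up_{name_a}": up_a,
        f"down_{name_a}": down_a,
        f"up_{name_b}": up_b,
        f"down_{name_b}": down_b,
    }
    labels = list(sets)
    overlaps = {
        (la, lb): sets[la] & sets[lb]
        for i, la in enumerate(labels)
        for lb in labels[i + 1 :]
    }
    return VennPartition(sets=sets, overlaps=overlaps)
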