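"""Cross-platform agreement between a screening study and the validation run.

A marker validated on a second platform should at minimum be dysregulated in
the same direction: the sign of (AUC - 0.5) should agree between platforms.
This module matches assay identifiers across naming revisions, restricts to
markers that were significant in the screening study (unadjusted p below
alpha, to avoid biasing the comparison by different panel sizes), counts
directional agreement, and attaches two significance statements: an exact
binomial test of the concordant count against coin-flipping, and a 2x2
Fisher exact test of validation significance against concordance.  It also
scores overall agreement as the Pearson correlation of the matched AUC
vectors, and compares two sample subsets (e.g. RNA extraction kits) by
correlating their per-assay summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .curation import CuratedCtMatrix
from .differential import MarkerStatsTable, auc as _auc

__all__ = [
    "ConcordanceError",
    "ConcordanceReport",
    "SubsetComparison",
    "match_identifiers",
    "directional_concordance",
    "auc_correlation",
    "subset_comparison",
]


class ConcordanceError(ValueError):
    pass


@dataclass
class ConcordanceReport:
    """Directional-concordance summary for one contrast.

    ``percent_concordant`` is 100 * n_concordant / n_significant and is NaN
    (with ``undefined`` True) when no screening-significant marker survives
    matching.  ``binomial_p`` is the two-sided exact test of n_concordant
    successes in n_significant trials against 0.5; ``fisher_p`` comes from
    the 2x2 table (significant in validation) x (concordant).  Markers whose
    AUC is exactly 0.5 on either platform carry no direction and are
    excluded, counted in ``n_indeterminate``.
    """

    n_matched: int
    n_significant: int
    n_concordant: int
    n_indeterminate: int
    percent_concordant: float
    binomial_p: float
    fisher_p: float | None
    pearson_r: float | None
    pearson_p: float | None
    discordant: pd.DataFrame = field(default_factory=pd.DataFrame)
    undefined: bool = False


def match_identifiers(
    screen: pd.DataFrame,
    validation_ids,
    mapping: pd.DataFrame | dict | None = None,
    allow_many_to_one: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Join screening rows onto validation assay ids, optionally via a map.

    ``mapping`` translates old identifiers to current ones (two columns
    ``old_id``/``new_id``, or a dict); ids without a mapping entry are kept
    as-is.  The join is an exact string match.  Returns the matched screening
    table (with an ``assay_id`` column holding the validation id) and the
    list of screening ids that found no partner — callers must report that
    count rather than silently dropping it.  Two screening rows resolving to
    one validation assay raise unless ``allow_many_to_one``.
    """
    screen = screen.copy()
    if "assay_id" not in screen.columns:
        raise ConcordanceError("screening table needs an 'assay_id' column")
    if mapping is not None:
        if isinstance(mapping, pd.DataFrame):
            mapping = dict(zip(mapping["old_id"], mapping["new_id"]))
        screen["assay_id"] = [mapping.get(i, i) for i in screen["assay_id"]]

    valid = set(validation_ids)
    matched_mask = screen["assay_id"].isin(valid)
    matched = screen.loc[matched_mask].copy()
    unmatched = screen.loc[~matched_mask, "assay_id"].tolist()

    dupes = matched["assay_id"][matched["assay_id"].duplicated()].unique()
    if len(dupes) and not allow_many_to_one:
        raise ConcordanceError(
            f"multiple screening rows map to validation assay(s) {list(dupes)}; "
            "pass allow_many_to_one=True to keep the first"
        )
    if len(dupes):
        matched = matched.drop_duplicates(subset="assay_id", keep="first")
    return matched, unmatched


def _directions(auc_values: np.ndarray) -> np.ndarray:
    return np.sign(auc_values - 0.5)


def directional_concordance(
    screen: pd.DataFrame,
    valid: MarkerStatsTable | pd.DataFrame,
    alpha: float = 0.05,
) -> ConcordanceReport:
    """Directional agreement on screening-significant markers.

    ``screen`` must hold ``assay_id``, ``auc`` and ``p_value`` (already
    matched to validation identifiers); ``valid`` is the validation marker
    table with ``auc`` (and, for the Fisher variant, a p-value column).
    """
    vtab = valid.table if isinstance(valid, MarkerStatsTable) else valid
    p_col = valid.q_base if isinstance(valid, MarkerStatsTable) else None
    screen = screen.set_index("assay_id") if "assay_id" in screen.columns else screen
    shared = [a for a in screen.index if a in vtab.index]
    n_matched = len(shared)
    if n_matched == 0:
        raise ConcordanceError("no shared assays between screening and validation")
    s = screen.loc[shared]
    v = vtab.loc[shared]

    sig = s["p_value"] < alpha
    s_sig = s.loc[sig]
    v_sig = v.loc[sig.index[sig]]

    dir_s = _directions(s_sig["auc"].to_numpy(dtype=float))
    dir_v = _directions(v_sig["auc"].to_numpy(dtype=float))
    determinate = (dir_s != 0) & (dir_v != 0)
    n_indet = int((~determinate).sum())
    n_significant = int(determinate.sum())
    concordant = determinate & (dir_s == dir_v)
    n_concordant = int(concordant.sum())

    if n_significant == 0:
        return ConcordanceReport(
            n_matched=n_matched,
            n_significant=0,
            n_concordant=0,
            n_indeterminate=n_indet,
            percent_concordant=float("nan"),
            binomial_p=float("nan"),
            fisher_p=None,
            pearson_r=None,
            pearson_p=None,
            undefined=True,
        )

    percent = 100.0 * n_concordant / n_significant
    binom_p = stats.binomtest(n_concordant, n_significant, 0.5).pvalue

    fisher_p = None
    if p_col is not None and p_col in v_sig.columns:
        sig_in_valid = (v_sig[p_col] < alpha).to_numpy()[determinate]
        conc = concordant.to_numpy()[determinate] if hasattr(concordant, "to_numpy") else concordant[determinate]
        tab = np.array(
            [
                [(sig_in_valid & conc).sum(), (sig_in_valid & ~conc).sum()],
                [(~sig_in_valid & conc).sum(), (~sig_in_valid & ~conc).sum()],
            ]
        )
        fisher_p = float(stats.fisher_exact(tab)[1])

    r = p = None
    if n_matched >= 3:
        sv = s["auc"].to_numpy(dtype=float)
        vv = v["auc"].to_numpy(dtype=float)
        if sv.min() < sv.max() and vv.min() < vv.max():
            r, p = (float(x) for x in stats.pearsonr(sv, vv))

    disc_idx = s_sig.index[determinate & ~concordant]
    discordant = pd.DataFrame(
        {
            "screening_auc": s_sig.loc[disc_idx, "auc"],
            "validation_auc": v_sig.loc[disc_idx, "auc"],
        }
    )
    return ConcordanceReport(
        n_matched=n_matched,
        n_significant=n_significant,
        n_concordant=n_concordant,
        n_indeterminate=n_indet,
        percent_concordant=percent,
        binomial_p=float(binom_p),
        fisher_p=fisher_p,
        pearson_r=r,
        pearson_p=p,
        discordant=discordant,
    )


def auc_correlation(
    screen_auc, valid_auc
) -> tuple[float, float]:
    """Pearson correlation (r, p) between matched screening and validation AUCs."""
    x = np.asarray(screen_auc, dtype=float)
    y = np.asarray(valid_auc, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ConcordanceError("need >= 3 matched AUC pairs of equal length")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ConcordanceError("AUC correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class SubsetComparison:
    """Agreement of two sample subsets measured on the same assay panel."""

    ct_r: float
    ct_p: float
    auc_r: float | None
    auc_p: float | None
    n_assays: int
    warning: str | None = None


def subset_comparison(
    curated_a: CuratedCtMatrix | pd.DataFrame,
    curated_b: CuratedCtMatrix | pd.DataFrame,
    groups_a: pd.Series,
    groups_b: pd.Series,
    contrast: tuple[str, str],
) -> SubsetComparison:
    """Correlate per-assay summaries of two disjoint sample subsets.

    Two Pearson correlations are computed over the shared assay panel: of the
    per-assay mean Cts of each subset, and of the per-assay AUCs for
    ``contrast`` computed within each subset.  When a subset lacks one of the
    contrast groups the AUC variant is skipped with a warning.
    """
    df_a = curated_a.values if isinstance(curated_a, CuratedCtMatrix) else curated_a
    df_b = curated_b.values if isinstance(curated_b, CuratedCtMatrix) else curated_b
    shared = [a for a in df_a.index if a in df_b.index]
    if len(shared) < 3:
        raise ConcordanceError("subsets share fewer than 3 assays")
    df_a, df_b = df_a.loc[shared], df_b.loc[shared]

    ct_r, ct_p = (float(x) for x in stats.pearsonr(df_a.mean(axis=1), df_b.mean(axis=1)))

    auc_r = auc_p = None
    warning = None
    ga = groups_a.reindex(df_a.columns)
    gb = groups_b.reindex(df_b.columns)
    ok = all((g == lab).sum() >= 1 for g in (ga, gb) for lab in contrast)
    if not ok:
        warning = (
            f"AUC comparison skipped: a subset lacks one of the contrast "
            f"groups {contrast}"
        )
    else:
        def subset_aucs(df: pd.DataFrame, g: pd.Series) -> np.ndarray:
            lab = g.to_numpy()
            return np.array(
                [_auc(df.loc[a].to_numpy(), lab, positive=contrast[0]) for a in shared]
            )

        aa = subset_aucs(df_a, ga)
        ab = subset_aucs(df_b, gb)
        auc_r, auc_p = (float(x) for x in stats.pearsonr(aa, ab))

    return SubsetComparison(
        ct_r=ct_r, ct_p=ct_p, auc_r=auc_r, auc_p=auc_p,
        n_assays=len(shared), warning=warning,
    )
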