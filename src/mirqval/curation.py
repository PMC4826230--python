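"""Well-level Ct curation: replicate filtering, merging, dropping, imputation.

Raw triplicate wells are reduced to a final assay x sample Ct matrix in four
steps: (1) individual wells are discarded when they show no amplification,
lie beyond the linear range of detection (Ct above 25 cycles by default) or
fail the amplification-curve quality score threshold (0.65 by default);
(2) the surviving replicates of each sample x assay cell are merged to their
median; (3) a cell with no surviving replicate becomes NA, and any assay with
more than ``na_limit`` NA cells (10 by default) is dropped from the panel;
(4) remaining NA cells are imputed with the global (all samples pooled)
mean of that assay's observed merged Cts.  Provenance — which cells were NA,
how many replicates survived per cell, which assays were dropped and why —
is retained alongside the values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CurationError",
    "CuratedCtMatrix",
    "FAIL_NO_AMPLIFICATION",
    "FAIL_OUT_OF_RANGE",
    "FAIL_LOW_QUALITY",
    "DEFAULT_CT_LIMIT",
    "DEFAULT_QUALITY_MIN",
    "DEFAULT_NA_LIMIT",
    "filter_replicate",
    "filter_wells",
    "merge_replicates",
    "curate_matrix",
    "expressed_panel",
]

FAIL_NO_AMPLIFICATION = "no_amplification"
FAIL_OUT_OF_RANGE = "out_of_range"
FAIL_LOW_QUALITY = "low_quality"

DEFAULT_CT_LIMIT = 25.0
DEFAULT_QUALITY_MIN = 0.65
DEFAULT_NA_LIMIT = 10


class CurationError(ValueError):
    """Raised on malformed well data or impossible curation requests."""


@dataclass
class CuratedCtMatrix:
    """Final Ct matrix (assays as rows, samples as columns) with provenance.

    ``values`` holds the merged-and-imputed Cts and contains no missing
    entries; ``na_mask`` flags the cells that were NA before imputation;
    ``replicate_counts`` gives the number of replicates that survived
    filtering in each cell; ``dropped_assays`` maps each removed assay to a
    human-readable reason.
    """

    values: pd.DataFrame
    na_mask: pd.DataFrame
    replicate_counts: pd.DataFrame
    dropped_assays: dict[str, str] = field(default_factory=dict)

    @property
    def assays(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def _check_quality(quality: float) -> None:
    if not np.isnan(quality) and not (0.0 <= quality <= 1.0):
        raise CurationError(f"quality score {quality!r} outside [0, 1]")


def filter_replicate(
    ct: float,
    quality: float,
    ct_limit: float = DEFAULT_CT_LIMIT,
    quality_min: float = DEFAULT_QUALITY_MIN,
) -> tuple[bool, str | None]:
    """Decide whether a single well passes curation.

    A well fails when its Ct is absent (``no_amplification``), exceeds the
    linear detection range (``out_of_range``) or its quality score falls
    strictly below the threshold (``low_quality``); boundary values pass.
    Returns ``(passed, reason)`` with ``reason`` ``None`` on pass.
    """
    _check_quality(quality)
    if ct is None or np.isnan(ct):
        return False, FAIL_NO_AMPLIFICATION
    if ct > ct_limit:
        return False, FAIL_OUT_OF_RANGE
    if np.isnan(quality) or quality < quality_min:
        return False, FAIL_LOW_QUALITY
    return True, None


def filter_wells(
    wells: pd.DataFrame,
    ct_limit: float = DEFAULT_CT_LIMIT,
    quality_min: float = DEFAULT_QUALITY_MIN,
) -> pd.DataFrame:
    """Vectorised :func:`filter_replicate` over a well table.

    Returns a copy with boolean ``passed`` and string ``fail_reason`` columns.
    """
    ct = wells["ct"].to_numpy(dtype=float)
    quality = wells["quality"].to_numpy(dtype=float)
    bad_q = ~np.isnan(quality) & ((quality < 0.0) | (quality > 1.0))
    if bad_q.any():
        raise CurationError(
            f"quality score {quality[bad_q][0]!r} outside [0, 1]"
        )
    no_amp = np.isnan(ct)
    out_of_range = ~no_amp & (ct > ct_limit)
    low_q = ~no_amp & ~out_of_range & (np.isnan(quality) | (quality < quality_min))
    out = wells.copy()
    out["passed"] = ~(no_amp | out_of_range | low_q)
    reason = np.full(len(wells), "", dtype=object)
    reason[no_amp] = FAIL_NO_AMPLIFICATION
    reason[out_of_range] = FAIL_OUT_OF_RANGE
    reason[low_q] = FAIL_LOW_QUALITY
    out["fail_reason"] = reason
    return out


def merge_replicates(
    wells: pd.DataFrame,
    ct_limit: float = DEFAULT_CT_LIMIT,
    quality_min: float = DEFAULT_QUALITY_MIN,
) -> float:
    """Merge the replicate wells of one sample x assay cell.

    Returns the median Ct of the replicates that pass filtering (the midpoint
    of the two survivors when one replicate failed), or NaN when none pass.
    """
    if wells["sample_id"].nunique() > 1 or wells["assay_id"].nunique() > 1:
        raise CurationError("merge_replicates received wells from multiple cells")
    flagged = filter_wells(wells, ct_limit=ct_limit, quality_min=quality_min)
    passing = flagged.loc[flagged["passed"], "ct"]
    if passing.empty:
        return float("nan")
    return float(np.median(passing.to_numpy()))


def curate_matrix(
    wells: pd.DataFrame,
    na_limit: int = DEFAULT_NA_LIMIT,
    ct_limit: float = DEFAULT_CT_LIMIT,
    quality_min: float = DEFAULT_QUALITY_MIN,
) -> CuratedCtMatrix:
    """Build the final Ct matrix from a long-format well table.

    Wells are filtered and merged per cell; assays with more than ``na_limit``
    NA cells are dropped; remaining NAs are imputed with the assay's global
    mean.  An assay whose cells are all NA but whose NA count does not exceed
    ``na_limit`` cannot be imputed and raises :class:`CurationError`.
    """
    if na_limit < 0:
        raise CurationError("na_limit must be >= 0")
    required = {"sample_id", "assay_id", "ct", "quality"}
    missing = required - set(wells.columns)
    if missing:
        raise CurationError(f"well table lacks columns: {sorted(missing)}")
    if wells.empty:
        raise CurationError("well table is empty")

    flagged = filter_wells(wells, ct_limit=ct_limit, quality_min=quality_min)
    passing = flagged.loc[flagged["passed"]]

    # preserve first-appearance order of assays and samples
    assay_order = pd.unique(wells["assay_id"])
    sample_order = pd.unique(wells["sample_id"])

    grouped = passing.groupby(["assay_id", "sample_id"], sort=False)["ct"]
    merged = grouped.median().unstack()
    counts = grouped.size().unstack()
    merged = merged.reindex(index=assay_order, columns=sample_order)
    counts = counts.reindex(index=assay_order, columns=sample_order).fillna(0).astype(int)

    na_mask = merged.isna()
    na_counts = na_mask.sum(axis=1)
    to_drop = na_counts[na_counts > na_limit]
    dropped = {
        str(a): f"{int(n)} NA cells exceed limit of {na_limit}"
        for a, n in to_drop.items()
    }
    kept = merged.drop(index=to_drop.index)
    kept_mask = na_mask.drop(index=to_drop.index)
    kept_counts = counts.drop(index=to_drop.index)

    all_na = kept_mask.all(axis=1)
    if all_na.any():
        raise CurationError(
            f"assay {all_na.idxmax()!r} has only NA cells and cannot be imputed"
        )
    row_means = kept.mean(axis=1, skipna=True)
    values = kept.T.fillna(row_means).T

    return CuratedCtMatrix(
        values=values,
        na_mask=kept_mask,
        replicate_counts=kept_counts,
        dropped_assays=dropped,
    )


def expressed_panel(
    curated: CuratedCtMatrix, controls: tuple[str, ...] | list[str] = ()
) -> list[str]:
    """Target assays that survived curation (endogenous controls excluded)."""
    control_set = set(controls)
    return [a for a in curated.assays if a not in control_set]
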