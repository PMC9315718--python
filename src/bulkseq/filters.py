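"""Quality filtering of two-bulk SNP tables.

Noise in bulked-segregant data comes mostly from badly genotyped or badly
covered sites: filtering on total depth, per-bulk depth, the absolute
depth difference between bulks, and genotype quality removes them before
any statistic is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .snptable import validate_snp_table

logger = logging.getLogger(__name__)

#: Fixed rule order used for first-failing-rule attribution.
RULE_ORDER = ("informative", "total_dp", "bulk_dp", "dp_diff", "gq")


@dataclass(frozen=True)
class FilterSpec:
    """Which filtering rules to apply; ``None`` disables a rule.

    Boundary values pass: a record with ``gq == min_gq`` is kept.

    Attributes
    ----------
    min_total_dp : minimum ``DP.HIGH + DP.LOW``.
    min_bulk_dp : minimum DP in *each* bulk.
    max_abs_dp_diff : maximum ``|DP.HIGH - DP.LOW|``.
    min_gq : minimum GQ in *each* bulk.
    require_informative : require ``AD_REF + AD_ALT >= 1`` in both bulks
        (on by default — every downstream statistic divides by the
        per-bulk allele total).
    """

    min_total_dp: int | None = None
    min_bulk_dp: int | None = None
    max_abs_dp_diff: int | None = None
    min_gq: int | None = None
    require_informative: bool = True

    def __post_init__(self) -> None:
        for name in ("min_total_dp", "min_bulk_dp", "max_abs_dp_diff", "min_gq"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


@dataclass
class FilterReport:
    """Bookkeeping of a filtering pass.

    ``removed_by_rule`` attributes each removed SNP to the *first* rule it
    fails, in the fixed order informative, total depth, per-bulk depth,
    depth difference, GQ, so per-rule counts are deterministic.
    """

    n_input: int
    n_kept: int
    n_removed: int
    removed_by_rule: dict[str, int] = field(default_factory=dict)


def _fail_masks(table: pd.DataFrame, spec: FilterSpec) -> dict[str, np.ndarray]:
    n = len(table)
    masks: dict[str, np.ndarray] = {}
    dp_hi = table["DP.HIGH"].to_numpy()
    dp_lo = table["DP.LOW"].to_numpy()
    if spec.require_informative:
        inf_hi = (table["AD_REF.HIGH"] + table["AD_ALT.HIGH"]).to_numpy() >= 1
        inf_lo = (table["AD_REF.LOW"] + table["AD_ALT.LOW"]).to_numpy() >= 1
        masks["informative"] = ~(inf_hi & inf_lo)
    else:
        masks["informative"] = np.zeros(n, dtype=bool)
    masks["total_dp"] = (
        dp_hi + dp_lo < spec.min_total_dp
        if spec.min_total_dp is not None
        else np.zeros(n, dtype=bool)
    )
    masks["bulk_dp"] = (
        (dp_hi < spec.min_bulk_dp) | (dp_lo < spec.min_bulk_dp)
        if spec.min_bulk_dp is not None
        else np.zeros(n, dtype=bool)
    )
    masks["dp_diff"] = (
        np.abs(dp_hi - dp_lo) > spec.max_abs_dp_diff
        if spec.max_abs_dp_diff is not None
        else np.zeros(n, dtype=bool)
    )
    masks["gq"] = (
        (table["GQ.HIGH"].to_numpy() < spec.min_gq)
        | (table["GQ.LOW"].to_numpy() < spec.min_gq)
        if spec.min_gq is not None
        else np.zeros(n, dtype=bool)
    )
    return masks


def filter_snps(
    table: pd.DataFrame, spec: FilterSpec, verbose: bool = False
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply *spec* to *table*; return the kept records and a report.

    Record order is preserved.  Filtering is idempotent and each rule is
    monotone: tightening a threshold never keeps more SNPs.
    """
    validate_snp_table(table)
    masks = _fail_masks(table, spec)
    removed_by_rule: dict[str, int] = {}
    attributed = np.zeros(len(table), dtype=bool)
    for rule in RULE_ORDER:
        first_fail = masks[rule] & ~attributed
        removed_by_rule[rule] = int(first_fail.sum())
        attributed |= masks[rule]
    kept = table.loc[~attributed].reset_index(drop=True)
    report = FilterReport(
        n_input=len(table),
        n_kept=len(kept),
        n_removed=int(attributed.sum()),
        removed_by_rule=removed_by_rule,
    )
    if verbose:
        logger.info(
            "kept %d / removed %d (by rule: %s)",
            report.n_kept,
            report.n_removed,
            report.removed_by_rule,
        )
    return kept, report
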