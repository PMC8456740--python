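"""Parent-of-origin expression bias in the endosperm.

The endosperm is triploid with two maternal and one paternal genome copy, so
the neutral expectation for the maternal expression ratio
maternal / (maternal + paternal) is 2/3, not 1/2.  Bias of a gene group is
assessed against the empirical all-genes background distribution with a
two-sided Wilcoxon rank-sum test and Benjamini-Hochberg correction across
the compared groups; direction is maternal when the group median exceeds the
background median.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._stats import bh_adjust, wilcoxon_rank_sum

NEUTRAL_MATERNAL_FRACTION = 2.0 / 3.0


def maternal_ratio(maternal_reads: int, paternal_reads: int) -> float:
    """Maternal read counts over total read counts; NaN when both are zero."""
    if maternal_reads < 0 or paternal_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = maternal_reads + paternal_reads
    if total == 0:
        return float("nan")
    return maternal_reads / total


def add_ratios(records: pd.DataFrame) -> pd.DataFrame:
    """Append a ``ratio`` column to an allelic count table.

    Requires columns gene_id, maternal_reads, paternal_reads (and typically
    condition).  Genes with zero total reads get NaN ratios.
    """
    out = records.copy()
    total = out["maternal_reads"] + out["paternal_reads"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["ratio"] = np.where(total > 0, out["maternal_reads"] / total, np.nan)
    return out


def min_coverage_filter(records: pd.DataFrame, min_total: int = 10) -> pd.DataFrame:
    """Keep genes with at least ``min_total`` allele-resolved reads."""
    total = records["maternal_reads"] + records["paternal_reads"]
    return records[total >= min_total].reset_index(drop=True)


def group_bias_test(
    group_ratios: dict[str, np.ndarray],
    background_ratios: np.ndarray,
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Test each gene group's maternal-ratio distribution against background.

    Returns one row per group with n, medians, raw p, BH q (across the groups
    actually tested) and direction ("maternal" / "paternal" / none when the
    medians are equal).  Groups below ``min_group_size`` are flagged and
    excluded from the BH family.
    """
    background = np.asarray(background_ratios, dtype=float)
    background = background[~np.isnan(background)]
    if background.size == 0:
        raise ValueError("background is empty")
    bg_median = float(np.median(background))
    rows = []
    for name, ratios in group_ratios.items():
        vals = np.asarray(ratios, dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size < min_group_size:
            rows.append((name, vals.size, np.nan, np.nan, None, True))
            continue
        if vals.size == background.size and np.array_equal(
            np.sort(vals), np.sort(background)
        ):
            p, direction = 1.0, None
        else:
            p = wilcoxon_rank_sum(vals, background)
            med = float(np.median(vals))
            direction = (
                "maternal" if med > bg_median else "paternal" if med < bg_median else None
            )
        rows.append((name, vals.size, float(np.median(vals)), p, direction, False))
    out = pd.DataFrame(
        rows, columns=["group", "n", "median_ratio", "p", "direction", "flagged_small"]
    )
    out["background_median"] = bg_median
    out["q"] = np.nan
    tested = out.index[~out["p"].isna()]
    if len(tested):
        out.loc[tested, "q"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    return out
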