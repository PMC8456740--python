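"""Expression normalisation, germination time courses and change classes.

Expression values are reads per kilobase per million mapped reads (RPKM).
Time-course analysis follows the germination design: per-gene profiles are
rescaled by their mean across time points, and each group of genes is tested
at every time point against the 1-hour-of-imbibition reference with a
two-sided Wilcoxon rank-sum test.

Expression-change classes use the standard thresholds: up when log2FC >= 1
and p < 0.05, down when log2FC <= -1 and p < 0.05, non-expressed below an
RPKM floor in every sample, stable otherwise.  (Read literally, the source
figure legend would also gate "stably expressed" on p < 0.05; "expressed but
neither up nor down" is used instead so the four classes partition all
genes.)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import wilcoxon_rank_sum

CHANGE_CLASSES = ("up", "down", "stable", "non_expressed")
DEFAULT_EXPRESSED_RPKM = 1.0


@dataclass
class ExpressionMatrix:
    """RPKM values (genes x samples) plus per-sample metadata.

    ``samples`` is indexed by sample name with columns timepoint (hours of
    imbibition), genotype and replicate; every column of ``values`` must have
    a metadata row.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in self.values.columns if c not in self.samples.index]
        if missing:
            raise ValueError(f"samples missing metadata: {missing}")
        for col in ("timepoint", "genotype", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet lacks column {col!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def timepoints(self) -> list[float]:
        return sorted(self.samples["timepoint"].unique())

    def timepoint_means(self, genotype: str | None = None) -> pd.DataFrame:
        """Genes x timepoints matrix of replicate-mean RPKM."""
        samples = self.samples
        if genotype is not None:
            samples = samples[samples["genotype"] == genotype]
        cols = {}
        for tp, grp in samples.groupby("timepoint"):
            cols[tp] = self.values[grp.index].mean(axis=1)
        return pd.DataFrame(cols)

    def write(self, values_path, samples_path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="gene_id")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample")

    @classmethod
    def read(cls, values_path, samples_path) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col="gene_id")
        samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
        return cls(values, samples)


def rpkm(read_count: float, gene_length_bp: float, library_mapped_reads: float) -> float:
    """Reads per kilobase of gene per million mapped reads."""
    if gene_length_bp <= 0:
        raise ValueError("gene length must be positive")
    if library_mapped_reads <= 0:
        raise ValueError("library size must be positive")
    return read_count / (gene_length_bp / 1e3 * library_mapped_reads / 1e6)


def relative_profile(timepoint_matrix: pd.DataFrame) -> tuple[pd.DataFrame, set[str]]:
    """Per-gene profiles divided by the gene's mean across time points.

    Returns (profiles, flagged) where ``flagged`` collects genes whose mean is
    zero (their profile rows are NaN, not zero).
    """
    means = timepoint_matrix.mean(axis=1)
    flagged = set(timepoint_matrix.index[means == 0])
    with np.errstate(invalid="ignore", divide="ignore"):
        profiles = timepoint_matrix.div(means, axis=0)
    profiles.loc[list(flagged)] = np.nan
    return profiles, flagged


def timepoint_shift_test(
    group_profiles: pd.DataFrame,
    reference_timepoint: float,
    min_genes: int = 3,
) -> pd.DataFrame:
    """Per-timepoint Wilcoxon rank-sum p-values of a gene group's relative
    values against the reference time point (two-sided).

    Rows with any NaN profile value are dropped; groups smaller than
    ``min_genes`` yield NaN p-values with a flag.
    """
    profiles = group_profiles.dropna()
    if reference_timepoint not in profiles.columns:
        raise ValueError(f"reference timepoint {reference_timepoint} not in profiles")
    ref = profiles[reference_timepoint].to_numpy()
    rows = []
    too_small = len(profiles) < min_genes
    for tp in profiles.columns:
        if too_small:
            rows.append((tp, np.nan, len(profiles), True))
            continue
        vals = profiles[tp].to_numpy()
        if tp == reference_timepoint or np.array_equal(vals, ref):
            p = 1.0
        else:
            p = wilcoxon_rank_sum(vals, ref)
        rows.append((tp, p, len(profiles), False))
    return pd.DataFrame(rows, columns=["timepoint", "p", "n_genes", "flagged_small"])


def classify_change(log2fc: float, p: float, expressed: bool) -> str:
    """Expression-change class from fold change, p-value and expression flag."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if not expressed:
        return "non_expressed"
    if log2fc >= 1 and p < 0.05:
        return "up"
    if log2fc <= -1 and p < 0.05:
        return "down"
    return "stable"


def classify_de_table(de: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`classify_change` over a DE table.

    Requires columns gene_id, log2fc, p and boolean expressed.
    """
    out = de.copy()
    if not out["p"].between(0, 1).all():
        raise ValueError("p-values must lie in [0, 1]")
    expressed = out["expressed"].astype(bool)
    sig = out["p"] < 0.05
    out["class"] = np.select(
        [~expressed, (out["log2fc"] >= 1) & sig, (out["log2fc"] <= -1) & sig],
        ["non_expressed", "up", "down"],
        default="stable",
    )
    return out


def simple_de_for_fixtures(
    matrix: ExpressionMatrix,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    expressed_rpkm: float = DEFAULT_EXPRESSED_RPKM,
) -> pd.DataFrame:
    """Plain two-group differential-expression table for synthetic runs.

    log2 fold change of mean RPKM (pseudo-count 1) and a Welch t-test on
    log2(RPKM + 1).  This is a deliberately simple fixture generator, not a
    count-model DE method; real DE tables are consumed as input.
    """
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("need at least two replicates per group")
    a = matrix.values[list(samples_a)].to_numpy()
    b = matrix.values[list(samples_b)].to_numpy()
    log2fc = np.log2(b.mean(axis=1) + 1) - np.log2(a.mean(axis=1) + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(
            np.log2(b + 1), np.log2(a + 1), axis=1, equal_var=False
        )
    p = np.where(np.isnan(p), 1.0, p)
    expressed = (np.concatenate([a, b], axis=1) >= expressed_rpkm).any(axis=1)
    de = pd.DataFrame(
        {
            "gene_id": matrix.values.index,
            "log2fc": log2fc,
            "p": p,
            "expressed": expressed,
        }
    )
    return classify_de_table(de)
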