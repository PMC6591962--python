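"""Differential methylation between plasma cfDNA and WBC genomic DNA.

Screens every CGCGCGG marker row for a methylation difference between the
two groups with a two-tailed Mann-Whitney-Wilcoxon test, adjusts p-values
with the Benjamini-Hochberg step-up procedure, and flags loci with a group
mean MePM fold change above threshold in either direction (plasma-hyper or
WBC-hyper) — the volcano-plot analysis of a paired plasma/WBC cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: group-mean pseudocount (MePM) used so fold changes stay finite when one
#: group's mean is 0; the marker criteria make WBC means of exactly 0 common.
DEFAULT_PSEUDOCOUNT = 0.1


def mww_test(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-tailed Mann-Whitney-Wilcoxon p-value.

    Exact null enumeration when both groups have at most 8 observations and
    the pooled data carry no ties; the normal approximation with tie
    correction (and continuity correction) otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0  # no rank separation at all
    has_ties = len(np.unique(pooled)) < pooled.size
    if a.size <= 8 and b.size <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DifferentialResult:
    """Per-locus table plus the thresholds that produced the flags."""

    table: pd.DataFrame
    fc_threshold: float
    fdr_threshold: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def identify_dm_sites(
    matrix: pd.DataFrame,
    groups: Mapping[str, str],
    group_a: str = "plasma",
    group_b: str = "WBC",
    fc_threshold: float = 5.0,
    fdr_threshold: float = 0.05,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> DifferentialResult:
    """Flag differentially methylated loci between two sample groups.

    A locus is significant when |fold change| of the pseudocounted group
    means exceeds ``fc_threshold`` in either direction and its BH q-value is
    below ``fdr_threshold``.  ``direction`` records which group is
    hypermethylated; fold_change is reported as mean_a / mean_b (both plus
    pseudocount), so plasma-hyper loci have fold_change > fc_threshold and
    WBC-hyper loci fold_change < 1/fc_threshold.
    """
    cols_a = [s for s in matrix.columns if groups.get(s) == group_a]
    cols_b = [s for s in matrix.columns if groups.get(s) == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {len(cols_a)} {group_a!r} / {len(cols_b)} {group_b!r}"
        )
    va = matrix[cols_a].to_numpy(dtype=float)
    vb = matrix[cols_b].to_numpy(dtype=float)
    mean_a = va.mean(axis=1)
    mean_b = vb.mean(axis=1)
    fc = (mean_a + pseudocount) / (mean_b + pseudocount)
    pvals = np.array([mww_test(va[i], vb[i]) for i in range(matrix.shape[0])])
    qvals = bh_fdr(pvals)
    direction = np.where(fc >= 1.0, f"{group_a}-hyper", f"{group_b}-hyper")
    effect = np.maximum(fc, 1.0 / fc)
    significant = (effect > fc_threshold) & (qvals < fdr_threshold)

    table = pd.DataFrame(
        {
            f"mean_{group_a}": mean_a,
            f"mean_{group_b}": mean_b,
            "fold_change": fc,
            "log2_fold_change": np.log2(fc),
            "p_value": pvals,
            "q_value": qvals,
            "neg_log10_q": -np.log10(np.maximum(qvals, np.finfo(float).tiny)),
            "direction": direction,
            "significant": significant,
        },
        index=matrix.index,
    )
    return DifferentialResult(table=table, fc_threshold=fc_threshold, fdr_threshold=fdr_threshold)


def write_volcano_tsv(result: DifferentialResult, path) -> None:
    result.table.to_csv(path, sep="\t", index_label="marker")


def write_significant_bed(result: DifferentialResult, sites, path) -> None:
    """BED of significant loci (marker CpG positions)."""
    from .quantify import site_index, split_marker_key

    lookup = site_index(sites)
    with open(path, "w") as fh:
        for key, row in result.significant.iterrows():
            site_id, j = split_marker_key(str(key))
            s = lookup[site_id]
            pos = s.motif_start + s.cpg_offsets[j - 1]
            fh.write(f"{s.chrom}\t{pos}\t{pos + 2}\t{key}\t0\t{s.strand}\t{row['direction']}\n")
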