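"""Tissue-specific hypermethylated marker selection and aggregation.

A CGCGCGG marker (a site/CpG-index pair) is tissue-specific when it is
strongly hypermethylated in exactly one of the reference tissues and silent
in white blood cells.  Selection applies five criteria to each candidate:

  (i)   tissue-specificity index tau > 0.9 across the reference tissues;
  (ii)  MePM > 10 in the most hypermethylated tissue;
  (iii) 90th-percentile MePM exactly 0 in a WBC training cohort;
  (iv)  mean liver MePM < 1 when the top tissue is not the liver
        (the liver dominates plasma cfDNA, so liver cross-reactivity in a
        non-liver marker would be fatal for deconvolution);
  (v)   the marker CpG lies < 60 bp from the CGCGCGG anchor.

Tissues for which the full criteria yield nothing (lung and muscle in
practice — their methylomes are less distinctive) are retried without the
tau restriction.  For deconvolution, each tissue's markers are aggregated
by summing all but the panel-wise largest, which keeps the aggregate linear
in the mixing fraction while damping single-marker outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_TISSUES = (
    "liver", "lung", "stomach", "colon", "kidney", "pancreas", "muscle", "skin",
)


def tau_index(values: Sequence[float]) -> float:
    """Tissue-specificity index tau in [0, 1].

    tau = sum_i (1 - x_i / max(x)) / (N - 1); 1 for expression confined to a
    single tissue, 0 for a perfectly uniform profile.  Undefined (raises)
    for an all-zero vector or fewer than two tissues.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("tau needs at least two tissues")
    if np.any(x < 0):
        raise ValueError("tau is defined for non-negative values")
    m = x.max()
    if m == 0:
        raise ValueError("tau undefined for an all-zero profile")
    return float(np.sum(1.0 - x / m) / (x.size - 1))


def percentile_nearest_rank(values: Sequence[float], q: float) -> float:
    """Nearest-rank (type 1) percentile: smallest value with cdf >= q/100.

    Chosen so "90th percentile MePM = 0" over a 29-sample training set is an
    exact, reproducible equality test.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0:
        raise ValueError("empty sample")
    k = int(np.ceil(q / 100.0 * x.size))
    return float(x[max(k, 1) - 1])


@dataclass
class MarkerSet:
    """Selected markers with their selection-rule audit trail.

    ``table``   — selected markers only: source tissue, tau, criterion stats.
    ``by_tissue`` — tissue label -> list of marker keys.
    ``trail``   — every candidate with the first criterion that rejected it
                  (empty string = selected), in evaluation order
                  (v) distance, (iii) WBC, (ii) level, (i) tau, (iv) liver.
    """

    table: pd.DataFrame
    by_tissue: dict[str, list[str]] = field(default_factory=dict)
    trail: pd.DataFrame | None = None

    @property
    def markers(self) -> list[str]:
        return list(self.table.index)

    def counts(self) -> dict[str, int]:
        return {t: len(m) for t, m in self.by_tissue.items()}

    def subset(self, keep: Sequence[str]) -> "MarkerSet":
        keep = [m for m in self.table.index if m in set(keep)]
        table = self.table.loc[keep]
        by_tissue = {
            t: [m for m in ms if m in set(keep)] for t, ms in self.by_tissue.items()
        }
        return MarkerSet(table=table, by_tissue=by_tissue, trail=self.trail)


def _source_tissue(row: pd.Series, tissues: Sequence[str]) -> str:
    # ties broken by fixed tissue order (liver first); ties are measure-zero
    # on real data but routine on synthetic zeros
    vals = row[list(tissues)].to_numpy(dtype=float)
    return tissues[int(np.argmax(vals))]


def select_tissue_markers(
    tissue_means: pd.DataFrame,
    wbc_training: pd.DataFrame,
    distances: pd.Series,
    tissues: Sequence[str] = DEFAULT_TISSUES,
    tau_threshold: float = 0.9,
    min_source_mepm: float = 10.0,
    max_liver_mepm: float = 1.0,
    max_distance_bp: int = 60,
    wbc_percentile: float = 90.0,
    fallback_tissues: Sequence[str] = ("lung", "muscle"),
) -> MarkerSet:
    """Apply the five marker criteria to every candidate row.

    Parameters
    ----------
    tissue_means : DataFrame
        Candidate markers x tissues, mean MePM per reference tissue.
    wbc_training : DataFrame
        Candidate markers x WBC training samples (MePM).
    distances : Series
        Marker CpG to CGCGCGG anchor distance in bp per candidate.
    fallback_tissues :
        Tissues rerun without the tau criterion when the strict pass yields
        zero markers for them.

    Criteria are evaluated in the order (v), (iii), (ii), (i), (iv) so the
    rejection trail is deterministic.
    """
    tissues = list(tissues)
    missing = [t for t in tissues if t not in tissue_means.columns]
    if missing:
        raise ValueError(f"tissue_means lacks columns: {missing}")
    if len(tissues) < 2:
        raise ValueError("need at least two tissues")
    if wbc_training.shape[1] == 0:
        raise ValueError("WBC training set is empty")
    candidates = tissue_means.index
    wbc_training = wbc_training.reindex(candidates)

    records = []
    for key in candidates:
        row = tissue_means.loc[key]
        vals = row[tissues].to_numpy(dtype=float)
        src = _source_tissue(row, tissues)
        max_mepm = float(vals.max())
        tau = tau_index(vals) if max_mepm > 0 else np.nan
        wbc_p90 = percentile_nearest_rank(wbc_training.loc[key].to_numpy(), wbc_percentile)
        liver_mean = float(row["liver"]) if "liver" in row.index else 0.0
        dist = float(distances.loc[key])

        rejected_by = ""
        if not dist < max_distance_bp:
            rejected_by = "v:distance"
        elif wbc_p90 != 0.0:
            rejected_by = "iii:wbc"
        elif not max_mepm > min_source_mepm:
            rejected_by = "ii:level"
        elif not (np.isfinite(tau) and tau > tau_threshold):
            rejected_by = "i:tau"
        elif src != "liver" and not liver_mean < max_liver_mepm:
            rejected_by = "iv:liver"

        records.append(
            dict(
                marker=key,
                source_tissue=src,
                tau=tau,
                max_mepm=max_mepm,
                wbc_p90=wbc_p90,
                liver_mean=liver_mean,
                distance_bp=dist,
                rejected_by=rejected_by,
                tau_waived=False,
            )
        )
    trail = pd.DataFrame.from_records(records).set_index("marker")

    # lung/muscle fallback: retry without the tau restriction (criteria
    # ii-v unchanged) for fallback tissues that came out empty
    for t in fallback_tissues:
        if t not in tissues:
            continue
        selected_t = trail[(trail["rejected_by"] == "") & (trail["source_tissue"] == t)]
        if len(selected_t):
            continue
        retry = trail[(trail["source_tissue"] == t) & (trail["rejected_by"] == "i:tau")]
        for key in retry.index:
            liver_ok = (
                trail.loc[key, "source_tissue"] == "liver"
                or trail.loc[key, "liver_mean"] < max_liver_mepm
            )
            if liver_ok:
                trail.loc[key, "rejected_by"] = ""
                trail.loc[key, "tau_waived"] = True
            else:
                trail.loc[key, "rejected_by"] = "iv:liver"

    selected = trail[trail["rejected_by"] == ""].drop(columns=["rejected_by"])
    by_tissue = {
        t: list(selected.index[selected["source_tissue"] == t]) for t in tissues
    }
    return MarkerSet(table=selected, by_tissue=by_tissue, trail=trail)


def aggregate_markers(values: pd.Series | Sequence[float], exclude=None) -> float:
    """Combine one tissue's marker values into a single scalar.

    Sums the values after dropping one marker: ``exclude`` (a label, the
    panel-defined largest marker of the tissue) when given, else the
    per-sample maximum.  A single marker is returned unchanged.  The fixed
    panel-defined exclusion keeps the aggregate a linear function of the
    underlying per-marker values, which the deconvolution's linear mixture
    model requires.
    """
    s = pd.Series(values, dtype=float) if not isinstance(values, pd.Series) else values.astype(float)
    if len(s) == 0:
        raise ValueError("cannot aggregate an empty marker list")
    if len(s) == 1:
        return float(s.iloc[0])
    if exclude is not None:
        if exclude not in s.index:
            raise KeyError(f"excluded marker {exclude!r} not among values")
        return float(s.drop(index=exclude).sum())
    return float(s.sum() - s.max())


def panel_max_marker(panel: pd.DataFrame, markers: Sequence[str], tissue: str) -> str | None:
    """The reference-panel-defined largest marker of a tissue (to exclude)."""
    if len(markers) <= 1:
        return None
    col = panel.loc[list(markers), tissue]
    return col.idxmax()


def filter_hcc_safe_markers(
    marker_set: MarkerSet,
    tumor_matrix: pd.DataFrame,
    adjacent_matrix: pd.DataFrame,
    alpha: float = 0.05,
    tumor_p90_max: float = 10.0,
) -> MarkerSet:
    """Drop markers confounded by hepatocellular-carcinoma hypermethylation.

    Liver markers survive when a one-tailed MWW test (tumor > adjacent
    non-cancerous liver) is *not* significant (P > alpha); markers of other
    tissues survive when the tumor 90th-percentile MePM stays below
    ``tumor_p90_max``.
    """
    keep = []
    for key, row in marker_set.table.iterrows():
        if key not in tumor_matrix.index:
            raise KeyError(f"marker {key} missing from tumor matrix")
        tum = tumor_matrix.loc[key].to_numpy(dtype=float)
        if row["source_tissue"] == "liver":
            if key not in adjacent_matrix.index:
                raise KeyError(f"marker {key} missing from adjacent-tissue matrix")
            adj = adjacent_matrix.loc[key].to_numpy(dtype=float)
            if np.all(tum == adj[0]) and np.all(adj == adj[0]):
                keep.append(key)  # identical constant groups: no evidence (p = 1)
                continue
            p = stats.mannwhitneyu(tum, adj, alternative="greater").pvalue
            if p > alpha:
                keep.append(key)
        else:
            if percentile_nearest_rank(tum, 90.0) < tumor_p90_max:
                keep.append(key)
    return marker_set.subset(keep)


def expression_zscores(expression: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores of log2(x+1) expression across tissues."""
    lx = np.log2(expression.astype(float) + 1.0)
    mu = lx.mean(axis=1)
    sd = lx.std(axis=1, ddof=0)
    return lx.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)


def annotate_intragenic_tissue_genes(
    marker_positions: pd.DataFrame,
    expression: pd.DataFrame,
    gene_models: pd.DataFrame,
    z_threshold: float = 1.5,
    tss_offset: int = 300,
) -> pd.DataFrame:
    """Flag markers inside the gene body of a tissue-specific gene.

    The intragenic region runs from 300 bp downstream of the transcription
    start site to 300 bp downstream of the transcription end site
    (strand-aware, half-open).  A gene is tissue-specific in tissue t when
    its expression z-score (log2 scale, across tissues) exceeds
    ``z_threshold`` there.  A marker is annotated when it lies intragenic in
    a gene that is tissue-specific in the *marker's* source tissue; the
    ``concordant`` column records whether the gene's top expression tissue
    equals the marker's source tissue.

    marker_positions: index = marker keys, columns chrom, pos, source_tissue.
    gene_models: columns gene, chrom, tss, tes, strand (tss > tes on '-').
    """
    z = expression_zscores(expression)
    out = []
    for key, mrow in marker_positions.iterrows():
        hit_gene, hit_z, concordant = "", np.nan, False
        for _, g in gene_models.iterrows():
            if g["chrom"] != mrow["chrom"]:
                continue
            if g["strand"] == "+":
                lo, hi = g["tss"] + tss_offset, g["tes"] + tss_offset
            elif g["strand"] == "-":
                lo, hi = g["tes"] - tss_offset, g["tss"] - tss_offset
            else:
                raise ValueError(f"gene {g['gene']}: bad strand {g['strand']!r}")
            if lo >= hi:
                raise ValueError(f"gene {g['gene']}: degenerate intragenic interval")
            if not (lo <= mrow["pos"] < hi):
                continue
            src = mrow["source_tissue"]
            if g["gene"] not in z.index or src not in z.columns:
                continue
            zval = z.loc[g["gene"], src]
            if pd.notna(zval) and zval > z_threshold:
                hit_gene, hit_z = g["gene"], float(zval)
                concordant = expression.loc[g["gene"]].idxmax() == src
                break
        out.append(
            dict(marker=key, gene=hit_gene, z_source=hit_z,
                 intragenic=bool(hit_gene), concordant=concordant)
        )
    return pd.DataFrame.from_records(out).set_index("marker")
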