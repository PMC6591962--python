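"""Per-molecule methylation calls to MePM matrices.

MCTA-Seq amplifies CpG-island loci anchored at a CGCGCGG 7-mer and reports,
for each sequenced molecule, the methylation state of up to 10 CpG sites
downstream of the anchor.  The quantification unit here is the *fully
methylated molecule* (FMM) at a given downstream CpG index ``j``: a molecule
counts as an FMM at ``j`` when every CpG from the first up to the j-th is
methylated.  FMM counts are normalised by the sample's total number of
uniquely mapped reads and expressed as methylated alleles per million mapped
reads (MePM).

The marker unit throughout the package is the pair ``(site_id, cpg_index)``,
keyed in matrices as the string ``"site_id:cpg_index"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MOLECULE_COLUMNS = ("site_id", "sample_id", "states")

#: columns expected in a sample-metadata frame (indexed by sample_id)
META_COLUMNS = ("group", "total_mapped_reads", "duplication_rate")


@dataclass(frozen=True)
class CGCGCGGSite:
    """One CGCGCGG-anchored locus with its downstream CpG offsets.

    Parameters
    ----------
    site_id : str
        Unique locus identifier.
    chrom, motif_start, strand :
        Genomic location of the 7-mer anchor (0-based start).
    cpg_offsets : tuple of int
        Base-pair distance from the anchor to each downstream CpG,
        strictly increasing, at most 10 entries (CpG indices 1..10).
    """

    site_id: str
    chrom: str
    motif_start: int
    strand: str = "+"
    cpg_offsets: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        offs = tuple(int(o) for o in self.cpg_offsets)
        if not 1 <= len(offs) <= 10:
            raise ValueError(
                f"site {self.site_id}: need 1..10 CpG offsets, got {len(offs)}"
            )
        if any(o <= 0 for o in offs) or any(
            b <= a for a, b in zip(offs, offs[1:])
        ):
            raise ValueError(
                f"site {self.site_id}: offsets must be positive and strictly increasing"
            )
        object.__setattr__(self, "cpg_offsets", offs)

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_offsets)

    def marker_key(self, cpg_index: int) -> str:
        return f"{self.site_id}:{cpg_index}"


def site_index(sites: Iterable[CGCGCGGSite]) -> dict[str, CGCGCGGSite]:
    return {s.site_id: s for s in sites}


def marker_keys(sites: Iterable[CGCGCGGSite]) -> list[str]:
    """All (site, cpg_index) row keys, in site order, index-major."""
    return [s.marker_key(j) for s in sites for j in range(1, s.n_cpgs + 1)]


def split_marker_key(key: str) -> tuple[str, int]:
    site_id, _, j = key.rpartition(":")
    return site_id, int(j)


def _leading_ones(states: str) -> int:
    n = 0
    for c in states:
        if c != "1":
            break
        n += 1
    return n


def validate_molecules(molecules: pd.DataFrame) -> pd.DataFrame:
    """Check a molecule table's shape and state alphabet; returns it unchanged."""
    missing = [c for c in MOLECULE_COLUMNS if c not in molecules.columns]
    if missing:
        raise ValueError(f"molecule table missing columns: {missing}")
    if len(molecules):
        states = molecules["states"].astype(str)
        bad = ~states.str.fullmatch(r"[01]{1,10}")
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} molecule(s) with states not a 0/1 string of length 1..10"
            )
    return molecules


def count_fmm(
    molecules: pd.DataFrame,
    sites: Iterable[CGCGCGGSite] | Mapping[str, CGCGCGGSite],
    site_id: str,
    cpg_index: int,
) -> int:
    """Number of molecules at ``site_id`` fully methylated through ``cpg_index``.

    A molecule is an FMM at index ``j`` when its first ``j`` CpG states are
    all 1.  Counts unique molecules (one table row each); duplicate-read
    multiplicities in an optional ``copies`` column do not contribute.
    """
    lookup = sites if isinstance(sites, Mapping) else site_index(sites)
    if site_id not in lookup:
        raise KeyError(f"unknown site: {site_id}")
    site = lookup[site_id]
    if not 1 <= cpg_index <= 10:
        raise ValueError(f"cpg_index must be in 1..10, got {cpg_index}")
    if cpg_index > site.n_cpgs:
        raise ValueError(
            f"cpg_index {cpg_index} exceeds the {site.n_cpgs} CpGs of site {site_id}"
        )
    if not len(molecules):
        return 0
    sub = molecules.loc[molecules["site_id"] == site_id, "states"]
    if not len(sub):
        return 0
    return int((sub.astype(str).map(_leading_ones) >= cpg_index).sum())


def compute_mepm(
    molecules: pd.DataFrame,
    meta: pd.DataFrame,
    sites: Sequence[CGCGCGGSite],
) -> pd.DataFrame:
    """FMM counts per (site, CpG index, sample), scaled to per-million reads.

    MePM(site, j, sample) = FMM count * 1e6 / total_mapped_reads.  The row
    index covers every (site, cpg_index) pair defined by ``sites`` — also
    those with zero observed molecules — keyed ``"site_id:cpg_index"``; the
    columns are the samples of ``meta`` (indexed by sample_id).

    Raises if a sample present in ``molecules`` has no metadata row or a
    non-positive read count.
    """
    validate_molecules(molecules if len(molecules) else pd.DataFrame(columns=MOLECULE_COLUMNS))
    if "total_mapped_reads" not in meta.columns:
        raise ValueError("meta must carry a total_mapped_reads column")
    reads = meta["total_mapped_reads"]
    if (reads <= 0).any():
        bad = list(meta.index[reads <= 0])
        raise ValueError(f"non-positive total_mapped_reads for sample(s): {bad}")

    rows = marker_keys(sites)
    counts = pd.DataFrame(0.0, index=rows, columns=list(meta.index))

    if len(molecules):
        unknown = set(molecules["sample_id"]) - set(meta.index)
        if unknown:
            raise ValueError(f"molecules reference samples without metadata: {sorted(unknown)}")
        mol = molecules[["site_id", "sample_id"]].copy()
        mol["run"] = molecules["states"].astype(str).map(_leading_ones)
        depth = {s.site_id: s.n_cpgs for s in sites}
        mol = mol[mol["site_id"].isin(depth)]
        # each molecule with leading-ones run r is an FMM at indices 1..min(r, n_cpgs)
        for (site_id, sample_id), runs in mol.groupby(["site_id", "sample_id"])["run"]:
            ncp = depth[site_id]
            hist = np.bincount(np.minimum(runs.to_numpy(), ncp), minlength=ncp + 1)
            fmm_at = np.cumsum(hist[::-1])[::-1][1:]  # counts with run >= j, j=1..ncp
            for j in range(1, ncp + 1):
                counts.loc[f"{site_id}:{j}", sample_id] = fmm_at[j - 1]

    return counts * 1.0e6 / reads.reindex(counts.columns).to_numpy()


def effective_duplication_rate(molecules: pd.DataFrame) -> float:
    """Observed duplication rate of a molecule table: total reads / unique molecules.

    Uses the ``copies`` column (duplicate-read multiplicity, >= 1); a table
    without one is duplicate-free (rate 1.0).
    """
    if not len(molecules):
        return 1.0
    if "copies" not in molecules.columns:
        return 1.0
    copies = molecules["copies"].to_numpy()
    if (copies < 1).any():
        raise ValueError("copies must be >= 1")
    return float(copies.sum()) / len(molecules)


def normalize_duplication(
    molecules_a: pd.DataFrame,
    molecules_b: pd.DataFrame,
    meta: pd.DataFrame,
    sites: Sequence[CGCGCGGSite],
    seed: int = 0,
    mode: str = "downsample",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Bring a plasma/WBC pair to the same effective duplication rate.

    Matched plasma and WBC libraries are sequenced to different duplication
    rates (around 1.4 vs 1.3 in healthy pairs); comparing their MePM values
    requires equalising the rate.  The member with the higher
    ``duplication_rate`` (from ``meta``, one row per sample, exactly two) is
    adjusted down to the lower rate.

    mode="downsample" (default): duplicate reads (``copies`` beyond the first
    per molecule) are removed at random, seeded, until the table's total read
    count matches the target rate within one read; unique molecules — hence
    FMM counts — are untouched while ``total_mapped_reads`` shrinks by the
    same factor.  mode="rescale": no molecules are touched; the read total is
    scaled multiplicatively.  Both return the two recomputed MePM matrices
    and the adjusted metadata.
    """
    if len(meta) != 2:
        raise ValueError("normalize_duplication expects metadata for exactly two samples")
    rates = meta["duplication_rate"].astype(float)
    if (rates < 1).any():
        raise ValueError("duplication_rate must be >= 1")
    meta = meta.copy()
    tables = {meta.index[0]: molecules_a.copy(), meta.index[1]: molecules_b.copy()}

    lo_rate = float(rates.min())
    hi_sample = rates.idxmax()
    if rates.iloc[0] != rates.iloc[1]:
        tab = tables[hi_sample]
        hi_rate = float(rates[hi_sample])
        if mode == "rescale" or not len(tab):
            meta.loc[hi_sample, "total_mapped_reads"] = int(
                round(meta.loc[hi_sample, "total_mapped_reads"] * lo_rate / hi_rate)
            )
        elif mode == "downsample":
            if "copies" not in tab.columns:
                tab["copies"] = 1
            copies = tab["copies"].to_numpy().astype(int)
            n_unique = len(tab)
            target_total = int(round(lo_rate * n_unique))
            n_remove = int(copies.sum()) - target_total
            if n_remove > 0:
                rng = np.random.default_rng(seed)
                # removable units: one per duplicate read beyond the first copy
                owners = np.repeat(np.arange(n_unique), copies - 1)
                if n_remove > len(owners):
                    n_remove = len(owners)
                drop = rng.choice(len(owners), size=n_remove, replace=False)
                dec = np.bincount(owners[drop], minlength=n_unique)
                copies = copies - dec
                tab["copies"] = copies
                old_total = meta.loc[hi_sample, "total_mapped_reads"]
                meta.loc[hi_sample, "total_mapped_reads"] = int(
                    round(old_total * copies.sum() / (copies.sum() + n_remove))
                )
            tables[hi_sample] = tab
        else:
            raise ValueError(f"unknown mode: {mode}")
        meta.loc[hi_sample, "duplication_rate"] = effective_duplication_rate(
            tables[hi_sample]
        ) if mode == "downsample" and len(tables[hi_sample]) else lo_rate

    mat_a = compute_mepm(tables[meta.index[0]], meta.iloc[[0]], sites)
    mat_b = compute_mepm(tables[meta.index[1]], meta.iloc[[1]], sites)
    return mat_a, mat_b, meta


def assert_monotone(matrix: pd.DataFrame) -> None:
    """Assert MePM is non-increasing in CpG index within each site (all samples)."""
    by_site: dict[str, list[tuple[int, str]]] = {}
    for key in matrix.index:
        site_id, j = split_marker_key(key)
        by_site.setdefault(site_id, []).append((j, key))
    for site_id, pairs in by_site.items():
        pairs.sort()
        keys = [k for _, k in pairs]
        vals = matrix.loc[keys].to_numpy()
        if np.any(np.diff(vals, axis=0) > 1e-9):
            raise AssertionError(f"MePM increases with CpG index at site {site_id}")
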