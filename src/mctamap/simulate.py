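"""Synthetic MCTA-Seq-like data with the structure the analysis assumes.

The generator states a world of 8 reference tissues, each contributing a
set of hypermethylated CGCGCGG markers (counts mirroring the real panel:
59 liver, 8 lung, 9 stomach, 20 colon, 13 kidney, 18 pancreas, 11 muscle,
8 skin) whose source-tissue MePM is uniform in [10, 100] and (by default)
exactly zero in every other tissue and in white blood cells.  Sequencing a
sample at ``total_reads`` mapped reads turns each marker's mixture MePM
into a Poisson count with rate

    total_reads / 1e6 * sum_k fraction_k * MT_ik ,

the natural model for rare-molecule counting, and emits one fully
methylated MoleculeRecord per count.  Plasma is modelled as WBC plus small
tissue fractions; spike-in series mix one or two tissues into WBC over a
fraction grid with matched WBC-only replicates for detection-limit
testing.

Optional knobs exist purely to exercise downstream filters: a WBC leak
rate (non-specific background MePM in WBC), partially methylated
background molecules (never fully methylated, so they must be removed by
the FMM filter), and decoy markers that violate individual selection
criteria (far CpGs at >= 60 bp, two-tissue markers with low tau,
WBC-leaky markers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as mio
from .quantify import CGCGCGGSite

DEFAULT_TISSUES = (
    "liver", "lung", "stomach", "colon", "kidney", "pancreas", "muscle", "skin",
)
#: marker counts per tissue, in DEFAULT_TISSUES order
DEFAULT_MARKERS_PER_TISSUE = (59, 8, 9, 20, 13, 18, 11, 8)


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world of the synthetic MCTA-Seq experiment.

    Defaults mirror the real study design: 8 tissues with the panel's
    marker counts, source-tissue MePM uniform in [10, 100], zero WBC leak,
    3e6 uniquely mapped reads per sample, a 29-sample WBC training cohort
    and 14 WBC/plasma pairs whose plasma carries a ~1.3% liver fraction
    (the healthy-median liver contribution).
    """

    tissues: tuple[str, ...] = DEFAULT_TISSUES
    markers_per_tissue: tuple[int, ...] = DEFAULT_MARKERS_PER_TISSUE
    source_mepm_range: tuple[float, float] = (10.0, 100.0)
    wbc_leak_rate: float = 0.0
    total_mapped_reads: int = 3_000_000
    n_wbc_training: int = 29
    n_pairs: int = 14
    plasma_fractions: tuple[tuple[str, float], ...] = (("liver", 0.013),)
    background_molecule_rate: float = 0.0  # non-FMM molecules (MePM units)
    n_decoy_far: int = 0       # CpG >= 60 bp from anchor (criterion v)
    n_decoy_shared: int = 0    # hypermethylated in two tissues (low tau)
    n_decoy_leaky: int = 0     # hypermethylated in WBC (criterion iii)
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.markers_per_tissue) != len(self.tissues):
            raise ValueError("markers_per_tissue must match the tissue labels")
        if any(int(m) < 1 for m in self.markers_per_tissue):
            raise ValueError("markers_per_tissue entries must all be >= 1")
        if self.total_mapped_reads < 10_000:
            raise ValueError("total_mapped_reads must be >= 10,000")
        lo, hi = self.source_mepm_range
        if lo < 10 or hi <= lo:
            raise ValueError("source_mepm_range must be an interval with lower bound >= 10")
        if self.wbc_leak_rate < 0 or self.background_molecule_rate < 0:
            raise ValueError("rates must be non-negative")
        if min(self.n_decoy_far, self.n_decoy_shared, self.n_decoy_leaky) < 0:
            raise ValueError("decoy counts must be non-negative")


@dataclass
class PanelBundle:
    """A generated world: site definitions, true rates, and WBC cohorts."""

    config: SimulationConfig
    sites: list[CGCGCGGSite]
    panel: pd.DataFrame          # markers x tissues, true MePM
    marker_info: pd.DataFrame    # source_tissue, cpg_index, distance_bp, decoy
    wbc_rates: pd.Series         # true WBC MePM per marker
    wbc_training: pd.DataFrame   # markers x training samples, observed MePM
    wbc_training_meta: pd.DataFrame
    pairs: dict | None = None    # simulated WBC/plasma pairs (filled on request)

    @property
    def markers(self) -> list[str]:
        return list(self.panel.index)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mio.write_sites_bed(self.sites, outdir / "sites.bed")
        mio.write_matrix(self.panel, outdir / "panel_truth.tsv")
        self.marker_info.to_csv(outdir / "marker_info.tsv", sep="\t", index_label="marker")
        mio.write_matrix(self.wbc_training, outdir / "wbc_training_mepm.tsv")
        mio.write_meta(self.wbc_training_meta, outdir / "wbc_training_meta.tsv")


def _make_marker_site(idx: int, cpg_index: int, distance_bp: int, rng: np.random.Generator) -> CGCGCGGSite:
    """One synthetic site whose ``cpg_index``-th CpG sits ``distance_bp`` from
    the anchor; markers are spaced 10 kb apart on synthetic chromosomes."""
    chrom = f"chr{idx % 22 + 1}"
    start = 10_000 * (idx + 1)
    n_extra = int(rng.integers(0, 3))  # 0-2 CpGs beyond the marker index
    n_cpgs = min(cpg_index + n_extra, 10)
    # offsets strictly increasing with the marker CpG pinned at distance_bp
    before = np.sort(rng.choice(np.arange(2, distance_bp), size=cpg_index - 1, replace=False)) if cpg_index > 1 else np.array([], dtype=int)
    after = distance_bp + np.cumsum(rng.integers(2, 10, size=n_cpgs - cpg_index)) if n_cpgs > cpg_index else np.array([], dtype=int)
    offsets = tuple(int(o) for o in np.concatenate([before, [distance_bp], after]))
    return CGCGCGGSite(site_id=f"site{idx:04d}", chrom=chrom, motif_start=start,
                       strand="+" if idx % 2 == 0 else "-", cpg_offsets=offsets)


def generate_reference_panel(config: SimulationConfig) -> PanelBundle:
    """Build the tissue reference panel plus WBC training samples.

    Each marker's true MePM in its source tissue is drawn uniformly from
    ``source_mepm_range`` and is zero elsewhere; WBC rates equal
    ``wbc_leak_rate`` everywhere.  Decoy markers (if requested) violate one
    selection criterion each.  The 29 WBC training samples are sequenced
    (Poisson counts at ``total_mapped_reads``) from the WBC truth.
    Deterministic under a fixed config seed.
    """
    rng = np.random.default_rng(config.seed)
    tissues = list(config.tissues)
    lo, hi = config.source_mepm_range

    sites: list[CGCGCGGSite] = []
    rows = []
    info = []
    wbc = []
    idx = 0

    def add_marker(source: str, mepm_by_tissue: dict, wbc_rate: float,
                   decoy: str, distance: int | None = None) -> None:
        nonlocal idx
        cpg_index = int(rng.integers(1, 6))
        if distance is None:
            distance = int(rng.integers(max(2, 2 * cpg_index), 59))
        site = _make_marker_site(idx, cpg_index, distance, rng)
        sites.append(site)
        key = site.marker_key(cpg_index)
        rows.append(pd.Series({t: mepm_by_tissue.get(t, 0.0) for t in tissues}, name=key))
        info.append(dict(marker=key, source_tissue=source, cpg_index=cpg_index,
                         distance_bp=distance, decoy=decoy))
        wbc.append(wbc_rate)
        idx += 1

    for t, n in zip(tissues, config.markers_per_tissue):
        for _ in range(int(n)):
            add_marker(t, {t: float(rng.uniform(lo, hi))}, config.wbc_leak_rate, "")

    for _ in range(config.n_decoy_far):
        t = tissues[int(rng.integers(len(tissues)))]
        add_marker(t, {t: float(rng.uniform(lo, hi))}, config.wbc_leak_rate,
                   "far", distance=int(rng.integers(60, 120)))
    for _ in range(config.n_decoy_shared):
        t1, t2 = rng.choice(len(tissues), size=2, replace=False)
        v = float(rng.uniform(lo, hi))
        # second tissue at >= 0.75x keeps tau = (7 - r)/7 below the 0.9 cut
        add_marker(tissues[t1], {tissues[t1]: v, tissues[t2]: v * float(rng.uniform(0.75, 1.0))},
                   config.wbc_leak_rate, "shared")
    for _ in range(config.n_decoy_leaky):
        t = tissues[int(rng.integers(len(tissues)))]
        add_marker(t, {t: float(rng.uniform(lo, hi))}, float(rng.uniform(5.0, 20.0)), "leaky")

    panel = pd.DataFrame(rows)
    panel.index.name = "marker"
    marker_info = pd.DataFrame.from_records(info).set_index("marker")
    wbc_rates = pd.Series(wbc, index=panel.index, name="wbc_mepm")

    # sequence the WBC training cohort from the WBC truth
    scale = config.total_mapped_reads / 1.0e6
    train_counts = rng.poisson(
        np.broadcast_to((wbc_rates.to_numpy() * scale)[:, None],
                        (len(panel), config.n_wbc_training)))
    cols = [f"wbc_train{i:02d}" for i in range(config.n_wbc_training)]
    wbc_training = pd.DataFrame(train_counts / scale, index=panel.index, columns=cols)
    wbc_training_meta = pd.DataFrame(
        {"group": "WBC", "total_mapped_reads": config.total_mapped_reads,
         "duplication_rate": 1.0},
        index=pd.Index(cols, name="sample_id"),
    )
    return PanelBundle(
        config=config, sites=sites, panel=panel, marker_info=marker_info,
        wbc_rates=wbc_rates, wbc_training=wbc_training,
        wbc_training_meta=wbc_training_meta,
    )


def expected_mepm(panel_bundle: PanelBundle, fractions: Mapping[str, float]) -> pd.Series:
    """Closed-form mixture MePM per marker: sum_k f_k MT_ik + f_wbc * leak."""
    f_tissue = sum(fractions.values())
    if any(v < 0 for v in fractions.values()):
        raise ValueError("fractions must be non-negative")
    if f_tissue > 1 + 1e-12:
        raise ValueError(f"fractions sum to {f_tissue:.4f} > 1")
    mix = pd.Series(0.0, index=panel_bundle.panel.index)
    for t, f in fractions.items():
        if t not in panel_bundle.panel.columns:
            raise KeyError(f"unknown tissue {t!r}")
        mix = mix + f * panel_bundle.panel[t]
    return mix + (1.0 - f_tissue) * panel_bundle.wbc_rates


def _emit_molecules(
    bundle: PanelBundle,
    sample_id: str,
    counts: np.ndarray,
    rng: np.random.Generator,
    duplication_rate: float,
    background_counts: np.ndarray | None = None,
) -> pd.DataFrame:
    """Turn per-marker FMM counts (and optional non-FMM background counts)
    into a molecule table.  FMMs are methylated through the marker CpG and
    Bernoulli(0.3) beyond it; background molecules carry an unmethylated
    first CpG so no FMM filter at any index can pass them."""
    info = bundle.marker_info
    site_by_id = {s.site_id: s for s in bundle.sites}
    recs: list[tuple[str, str, str, int]] = []
    for marker, n in zip(bundle.markers, counts):
        if n == 0:
            continue
        site_id = marker.rpartition(":")[0]
        j = info.loc[marker, "cpg_index"]
        ncp = site_by_id[site_id].n_cpgs
        tail = rng.random(size=(int(n), ncp - j)) < 0.3
        for row in range(int(n)):
            states = "1" * int(j) + "".join("1" if b else "0" for b in tail[row])
            copies = 1 + int(rng.poisson(max(duplication_rate - 1.0, 0.0)))
            recs.append((site_id, sample_id, states, copies))
    if background_counts is not None:
        for marker, n in zip(bundle.markers, background_counts):
            if n == 0:
                continue
            site_id = marker.rpartition(":")[0]
            ncp = site_by_id[site_id].n_cpgs
            for _ in range(int(n)):
                rest = rng.random(size=ncp - 1) < 0.5
                states = "0" + "".join("1" if b else "0" for b in rest)
                copies = 1 + int(rng.poisson(max(duplication_rate - 1.0, 0.0)))
                recs.append((site_id, sample_id, states, copies))
    return pd.DataFrame(recs, columns=["site_id", "sample_id", "states", "copies"])


def simulate_sample(
    bundle: PanelBundle,
    fractions: Mapping[str, float],
    total_reads: int | None = None,
    seed: int | np.random.Generator = 0,
    sample_id: str = "sim",
    group: str = "plasma",
    duplication_rate: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Sequence one mixture sample; the WBC share is 1 - sum(fractions).

    Per-marker FMM counts are Poisson with rate
    ``total_reads/1e6 * expected_mepm``; returns (molecule table, metadata
    row, truth = expected MePM per marker).  ``total_reads = 0`` yields an
    empty molecule table (MePM undefined; metadata records 0 reads).
    """
    if total_reads is None:
        total_reads = bundle.config.total_mapped_reads
    if total_reads < 0:
        raise ValueError("total_reads must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    truth = expected_mepm(bundle, fractions)
    meta = pd.DataFrame(
        {"group": group, "total_mapped_reads": int(total_reads),
         "duplication_rate": duplication_rate},
        index=pd.Index([sample_id], name="sample_id"),
    )
    if total_reads == 0:
        empty = pd.DataFrame(columns=["site_id", "sample_id", "states", "copies"])
        return empty, meta, truth
    scale = total_reads / 1.0e6
    counts = rng.poisson(truth.to_numpy() * scale)
    bg = None
    if bundle.config.background_molecule_rate > 0:
        bg = rng.poisson(np.full(len(truth), bundle.config.background_molecule_rate * scale))
    molecules = _emit_molecules(bundle, sample_id, counts, rng, duplication_rate, bg)
    return molecules, meta, truth


def simulate_pairs(
    bundle: PanelBundle, seed: int = 0
) -> dict[str, pd.DataFrame]:
    """The matched WBC/plasma cohort: n_pairs WBC samples (pure background)
    and n_pairs plasma samples carrying ``config.plasma_fractions``.
    Duplication rates are drawn from the observed healthy-pair statistics
    (plasma 1.4 +/- 0.3, WBC 1.3 +/- 0.1), truncated at 1."""
    cfg = bundle.config
    rng = np.random.default_rng(seed)
    mols, metas = [], []
    for i in range(cfg.n_pairs):
        d_wbc = max(1.0, float(rng.normal(1.3, 0.1)))
        d_pla = max(1.0, float(rng.normal(1.4, 0.3)))
        m, meta, _ = simulate_sample(
            bundle, {}, cfg.total_mapped_reads, rng,
            sample_id=f"wbc{i:02d}", group="WBC", duplication_rate=d_wbc)
        mols.append(m); metas.append(meta)
        m, meta, _ = simulate_sample(
            bundle, dict(cfg.plasma_fractions), cfg.total_mapped_reads, rng,
            sample_id=f"plasma{i:02d}", group="plasma", duplication_rate=d_pla)
        mols.append(m); metas.append(meta)
    molecules = pd.concat(mols, ignore_index=True) if mols else pd.DataFrame(
        columns=["site_id", "sample_id", "states", "copies"])
    meta = pd.concat(metas)
    return {"molecules": molecules, "meta": meta}


def simulate_tissue_samples(
    bundle: PanelBundle, n_per_tissue: Mapping[str, int] | int = 2, seed: int = 0
) -> dict[str, pd.DataFrame]:
    """Pure-tissue reference samples (fraction 1.0 of one tissue each)."""
    cfg = bundle.config
    rng = np.random.default_rng(seed)
    mols, metas = [], []
    for t in cfg.tissues:
        n = n_per_tissue if isinstance(n_per_tissue, int) else n_per_tissue.get(t, 2)
        for i in range(n):
            m, meta, _ = simulate_sample(
                bundle, {t: 1.0}, cfg.total_mapped_reads, rng,
                sample_id=f"{t}{i:02d}", group=t)
            mols.append(m); metas.append(meta)
    molecules = pd.concat(mols, ignore_index=True)
    meta = pd.concat(metas)
    return {"molecules": molecules, "meta": meta}


@dataclass
class SpikeInDataset:
    sample_id: str
    fractions: dict[str, float]
    replicate: int
    molecules: pd.DataFrame
    meta: pd.DataFrame
    truth: pd.Series


def simulate_mixture_series(
    bundle: PanelBundle,
    tissue: str | Sequence[str],
    fraction_grid: Sequence[float] | Sequence[Sequence[float]],
    replicates: int = 10,
    total_reads: int | None = None,
    seed: int = 0,
    null_replicates: int | None = None,
) -> tuple[list[SpikeInDataset], list[SpikeInDataset]]:
    """Serial spike-in series of one or two tissues into WBC.

    ``fraction_grid`` holds per-level fractions: scalars for a single
    tissue, or per-tissue sequences for multi-tissue spikes.  Returns
    (spiked datasets, matched WBC-only null datasets); the null count
    defaults to ``replicates``.
    """
    tissue_list = [tissue] if isinstance(tissue, str) else list(tissue)
    grid = list(fraction_grid)
    if not grid:
        raise ValueError("fraction_grid must be non-empty")
    rng = np.random.default_rng(seed)
    if null_replicates is None:
        null_replicates = replicates

    spiked: list[SpikeInDataset] = []
    for level in grid:
        fr = [level] if np.isscalar(level) else list(level)
        if len(fr) != len(tissue_list):
            raise ValueError("grid entry length must match the spiked tissues")
        fractions = {t: float(f) for t, f in zip(tissue_list, fr)}
        for rep in range(replicates):
            label = "_".join(f"{t}{f:g}" for t, f in fractions.items())
            sid = f"spike_{label}_r{rep}"
            m, meta, truth = simulate_sample(
                bundle, fractions, total_reads, rng, sample_id=sid, group="spike")
            spiked.append(SpikeInDataset(sid, fractions, rep, m, meta, truth))

    nulls: list[SpikeInDataset] = []
    for rep in range(null_replicates):
        sid = f"null_r{rep}"
        m, meta, truth = simulate_sample(
            bundle, {}, total_reads, rng, sample_id=sid, group="WBC")
        nulls.append(SpikeInDataset(sid, {}, rep, m, meta, truth))
    return spiked, nulls


def write_truth_json(bundle: PanelBundle, datasets: Sequence[SpikeInDataset], path) -> None:
    mio.write_json(
        {
            "tissues": list(bundle.config.tissues),
            "panel": {m: {t: float(bundle.panel.loc[m, t]) for t in bundle.panel.columns}
                      for m in bundle.markers},
            "samples": {d.sample_id: d.fractions for d in datasets},
        },
        path,
    )
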