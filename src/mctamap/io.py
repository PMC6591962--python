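"""Readers/writers for the package's plain-text interchange formats.

All tables are UTF-8 TSV with a header row.  Site definitions travel as
BED6+1 (0-based, half-open; column 7 = comma-separated CpG offsets), marker
sets as BED6+ with the source tissue and per-tissue reference MePM appended.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .quantify import CGCGCGGSite


def read_molecules(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str, "sample_id": str, "states": str})
    return df


def write_molecules(molecules: pd.DataFrame, path: str | Path) -> None:
    molecules.to_csv(path, sep="\t", index=False)


def read_meta(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """MePM matrix TSV, row key "site_id:cpg_index" in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="marker")


def write_sites_bed(sites: Sequence[CGCGCGGSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            offsets = ",".join(str(o) for o in s.cpg_offsets)
            fh.write(
                f"{s.chrom}\t{s.motif_start}\t{s.motif_start + 7}\t{s.site_id}\t0\t{s.strand}\t{offsets}\n"
            )


def read_sites_bed(path: str | Path) -> list[CGCGCGGSite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, _end, name, _score, strand, offsets = line.split("\t")[:7]
            sites.append(
                CGCGCGGSite(
                    site_id=name,
                    chrom=chrom,
                    motif_start=int(start),
                    strand=strand,
                    cpg_offsets=tuple(int(o) for o in offsets.split(",")),
                )
            )
    return sites


def write_marker_bed(
    marker_table: pd.DataFrame,
    sites: Sequence[CGCGCGGSite],
    panel: pd.DataFrame,
    path: str | Path,
) -> None:
    """Selected markers as BED6+: name = site:cpg_index, score = tau*1000,
    extra columns = source tissue then reference MePM per tissue."""
    lookup = {s.site_id: s for s in sites}
    with open(path, "w") as fh:
        tissues = list(panel.columns)
        fh.write(
            "#chrom\tstart\tend\tname\tscore\tstrand\tsource_tissue\t"
            + "\t".join(f"mepm_{t}" for t in tissues)
            + "\n"
        )
        for key, row in marker_table.iterrows():
            site_id, _, j = str(key).rpartition(":")
            s = lookup[site_id]
            pos = s.motif_start + s.cpg_offsets[int(j) - 1]
            score = int(round(1000 * row["tau"])) if pd.notna(row.get("tau")) else 0
            vals = "\t".join(f"{panel.loc[key, t]:.6g}" for t in tissues)
            fh.write(
                f"{s.chrom}\t{pos}\t{pos + 2}\t{key}\t{score}\t{s.strand}\t"
                f"{row['source_tissue']}\t{vals}\n"
            )


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
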