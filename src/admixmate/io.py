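"""Text-format input/output: run configs (YAML), tract tables (BED-like),
mating-pair tables (CSV)."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .genome import GenomeMap, Individual
from .sim import SimConfig

__all__ = [
    "load_config",
    "save_config",
    "write_tracts_bed",
    "read_tracts_bed",
    "tract_lengths_from_bed",
]

BED_COLUMNS = ("chrom", "start", "end", "source", "individual_id", "haplotype")


def load_config(path: str | Path) -> SimConfig:
    """Read a SimConfig from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return SimConfig.from_dict(data or {})


def save_config(config: SimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def write_tracts_bed(
    population: Iterable[Individual], gmap: GenomeMap, path: str | Path
) -> int:
    """Write all local-ancestry tracts as 6-column BED-like text.

    Columns: chrom (``chr1``..), start, end (0-based half-open, bp, local
    to the chromosome), source (1/2), individual_id, haplotype (1/2).
    Returns the number of tracts written.
    """
    n = 0
    with open(path, "w") as fh:
        for ind in population:
            for hap_idx, hap in enumerate((ind.hap1, ind.hap2), start=1):
                for c, start, end, source in hap.iter_chrom_tracts(gmap):
                    fh.write(
                        f"chr{c + 1}\t{start}\t{end}\t{source}\t{ind.id}\t{hap_idx}\n"
                    )
                    n += 1
    return n


def read_tracts_bed(path: str | Path) -> pd.DataFrame:
    """Read a 6-column tract BED into a DataFrame."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=BED_COLUMNS,
        dtype={
            "chrom": str,
            "start": np.int64,
            "end": np.int64,
            "source": np.int64,
            "individual_id": np.int64,
            "haplotype": np.int64,
        },
    )
    if np.any(df["end"] <= df["start"]):
        raise ValueError("tract end must exceed start")
    return df


def tract_lengths_from_bed(
    df: pd.DataFrame, source: int | str = "both"
) -> np.ndarray:
    """Tract lengths in bp from a BED table, optionally filtered by source."""
    if source not in (1, 2, "both"):
        raise ValueError("source must be 1, 2 or 'both'")
    if source != "both":
        df = df[df["source"] == source]
    return (df["end"] - df["start"]).to_numpy(np.int64)
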