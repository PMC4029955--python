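"""Genetic map handling (HapMap-style text: position, rate cM/Mb, cumulative cM)."""

from __future__ import annotations

import numpy as np
import pandas as pd


class GeneticMap:
    """Piecewise-linear genetic map per chromosome.

    Between map points the cumulative cM is interpolated linearly; beyond
    either end positions are extrapolated at the rate recorded at the
    nearest terminal map point.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"chrom", "pos_bp", "rate_cM_per_Mb", "cM"}
        if not required.issubset(table.columns):
            raise ValueError(f"genetic map needs columns {sorted(required)}")
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, float, float]] = {}
        for chrom, sub in table.groupby("chrom", sort=False):
            pos = sub["pos_bp"].to_numpy(dtype=float)
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"genetic map not sorted by position on {chrom}")
            cm = sub["cM"].to_numpy(dtype=float)
            rate = sub["rate_cM_per_Mb"].to_numpy(dtype=float)
            self._by_chrom[str(chrom)] = (pos, cm, rate[0], rate[-1])
        self.table = table

    def interpolate_cM(self, chrom: str, pos_bp) -> np.ndarray | float:
        """Genetic position(s) in cM for physical position(s) on ``chrom``."""
        if str(chrom) not in self._by_chrom:
            raise KeyError(f"chromosome {chrom!r} not in genetic map")
        pos, cm, rate_lo, rate_hi = self._by_chrom[str(chrom)]
        q = np.atleast_1d(np.asarray(pos_bp, dtype=float))
        out = np.interp(q, pos, cm)
        below = q < pos[0]
        above = q > pos[-1]
        out[below] = cm[0] - (pos[0] - q[below]) * rate_lo / 1e6
        out[above] = cm[-1] + (q[above] - pos[-1]) * rate_hi / 1e6
        return out if np.ndim(pos_bp) else float(out[0])


def read_genetic_map(path) -> GeneticMap:
    """Read a HapMap-format genetic map.

    Accepts either 4 columns (chrom, position, rate, cumulative cM) or the
    3-column single-chromosome variant (position, rate, cumulative cM).
    """
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    if df.shape[1] == 3:
        df.columns = ["pos_bp", "rate_cM_per_Mb", "cM"]
        df.insert(0, "chrom", "1")
    elif df.shape[1] >= 4:
        df = df.iloc[:, :4]
        df.columns = ["chrom", "pos_bp", "rate_cM_per_Mb", "cM"]
    else:
        raise ValueError("genetic map must have 3 or 4 columns")
    df["chrom"] = df["chrom"].astype(str)
    return GeneticMap(df)


def write_genetic_map(gmap: GeneticMap, path) -> None:
    gmap.table.to_csv(path, sep="\t", index=False)


def attach_genetic_positions(variants: pd.DataFrame, gmap: GeneticMap) -> pd.DataFrame:
    """Fill the gmap_cM column of a variant table from a genetic map."""
    out = variants.copy()
    for chrom, sub in out.groupby("chrom", sort=False):
        out.loc[sub.index, "gmap_cM"] = gmap.interpolate_cM(
            str(chrom), sub["pos_bp"].to_numpy()
        )
    return out
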