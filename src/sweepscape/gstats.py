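"""Multilocus-genotype (MLG) expected-homozygosity statistics for unphased data.

A specimen's MLG over a window is its dosage string (0/1/2 per site, with a
distinct symbol for missing).  With g_1 >= g_2 >= ... the sorted MLG
frequencies:

    G1  = sum g_i^2
    G12 = (g_1 + g_2)^2 + sum_{i>=3} g_i^2
    G123 = (g_1 + g_2 + g_3)^2 + sum_{i>=4} g_i^2
    G2/G1 = (G1 - g_1^2) / G1

G12/G123 are the unphased analogues of the haplotype H12 statistic: pooling
the top classes makes the statistic sensitive to both hard sweeps (one
dominant MLG) and soft sweeps (a few); G2/G1 separates the two regimes
(low under a single dominant class, high under several).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix


@dataclass
class GStatsWindow:
    window_index: int
    first_pos: int
    last_pos: int
    mean_pos: float
    spectrum: np.ndarray  # sorted descending, sums to 1
    G1: float
    G12: float
    G123: float
    G2_over_G1: float


def g_statistics(spectrum) -> tuple[float, float, float, float]:
    """(G1, G12, G123, G2/G1) from an MLG frequency spectrum.

    The spectrum must sum to 1 (tolerance 1e-9); it is sorted internally.
    Absent second/third classes count as 0.
    """
    g = np.sort(np.asarray(spectrum, dtype=float))[::-1]
    if g.size == 0:
        raise ValueError("empty spectrum")
    if abs(g.sum() - 1.0) > 1e-9:
        raise ValueError("spectrum must sum to 1")
    sq = g**2
    g1 = float(sq.sum())
    top2 = g[:2].sum()
    top3 = g[:3].sum()
    g12 = float(top2**2 + sq[2:].sum())
    g123 = float(top3**2 + sq[3:].sum())
    g2g1 = float((g1 - g[0] ** 2) / g1)
    return g1, g12, g123, g2g1


def mlg_windows(
    gm: GenotypeMatrix,
    window: int = 500,
    step: int = 50,
    drop_missing_sites: bool = False,
) -> list[GStatsWindow]:
    """Sliding variant-count windows of MLG spectra with G statistics.

    Missing dosages become their own MLG symbol by default (dropping sites
    would desynchronise windows across specimens and imputation would
    fabricate genotypes); ``drop_missing_sites`` removes any site with a
    missing call instead.
    """
    if drop_missing_sites:
        gm = gm.take_sites(~(gm.dosage == MISSING).any(axis=1))
    V = gm.n_sites
    if V < window:
        warnings.warn(f"only {V} variants for window={window}; no windows emitted")
        return []
    out = []
    starts = list(range(0, V - window + 1, step))
    if starts[-1] != V - window:
        starts.append(V - window)
    for w, start in enumerate(starts):
        block = gm.dosage[start:start + window]  # sites x samples
        pos = gm.pos[start:start + window]
        cols = [block[:, j].tobytes() for j in range(gm.n_samples)]
        _, counts = np.unique(cols, return_counts=True)
        spectrum = np.sort(counts / counts.sum())[::-1]
        g1, g12, g123, g2g1 = g_statistics(spectrum)
        out.append(
            GStatsWindow(
                window_index=w,
                first_pos=int(pos[0]),
                last_pos=int(pos[-1]),
                mean_pos=float(pos.mean()),
                spectrum=spectrum,
                G1=g1, G12=g12, G123=g123, G2_over_G1=g2g1,
            )
        )
    return out


def gstats_frame(windows: list[GStatsWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "window_index": [w.window_index for w in windows],
            "first_pos": [w.first_pos for w in windows],
            "last_pos": [w.last_pos for w in windows],
            "mean_pos": [w.mean_pos for w in windows],
            "G1": [w.G1 for w in windows],
            "G12": [w.G12 for w in windows],
            "G123": [w.G123 for w in windows],
            "G2_G1": [w.G2_over_G1 for w in windows],
        }
    )
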