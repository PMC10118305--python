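"""Focal-region haplotype-cluster analysis (resistance-locus style report).

A partial sweep at an insecticide-resistance locus leaves a diagnostic
signature in a region PCA: specimens homozygous for the swept haplotype,
heterozygotes, and wild-type homozygotes form three roughly equidistant
clusters along one component.  This module groups the region PCA into
clusters, contrasts diversity and differentiation between them, and tables
genotypes and pairwise LD at named focal sites (e.g. knockdown-resistance
mutations in the voltage-gated sodium channel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .popgen import PCAResult, pca, r2_matrix, windowed_fst_bp, windowed_pi
from .types import MISSING, CohortPanel, GenotypeMatrix, MaskTrack


@dataclass(frozen=True)
class FocalSite:
    label: str
    chrom: str
    pos: int


@dataclass
class FocalSiteSet:
    sites: list[FocalSite]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FocalSiteSet":
        return cls([FocalSite(str(r.label), str(r.chrom), int(r.pos))
                    for r in df.itertuples()])


@dataclass
class ClusterAssignment:
    labels: dict[str, str]  # sample -> {top, middle, bottom, unassigned}
    method: dict = field(default_factory=dict)

    def samples_in(self, label: str) -> list[str]:
        return [s for s, l in self.labels.items() if l == label]


def region_pca(
    gm: GenotypeMatrix,
    chrom: str,
    start: int,
    end: int,
    maf_min: float = 0.0,
    scaler: str = "patterson",
    min_gq: int | None = 20,
    n_components: int = 10,
) -> PCAResult:
    """PCA of all SNPs inside a region (no MAF filter by default: a focal
    region analysis keeps every segregating site).  Loadings cover PCs 1-2
    and beyond."""
    sel = (gm.chrom == chrom) & (gm.pos >= start) & (gm.pos <= end)
    sub = gm.take_sites(sel)
    if sub.n_sites < 2:
        raise ValueError("fewer than 2 SNPs in the region")
    return pca(sub, maf_min=maf_min, scaler=scaler, min_gq=min_gq,
               n_components=n_components)


def loading_outliers(
    result: PCAResult, pc: int = 2, threshold: float = 0.025
) -> np.ndarray:
    """Indices (into the PCA's SNP set) with |loading| above the threshold."""
    load = result.loadings[:, pc - 1]
    return np.nonzero(np.abs(load) > threshold)[0]


def assign_pca_clusters(
    result: PCAResult, k: int = 3, seed: int = 0, n_restarts: int = 50,
    pcs: tuple[int, ...] = (1, 2),
) -> ClusterAssignment:
    """Centroid-based partition of the chosen PCs (default 1-2) into k
    clusters.

    ``pcs=(1,)`` clusters on the dominant axis alone, useful when the
    haplotype structure lives entirely on PC1 and PC2 is noise.  The
    cluster with the lowest mean on the last chosen PC is labelled
    "bottom", the highest "top"; any between are "middle".  Deterministic
    given the seed.
    """
    from sklearn.cluster import KMeans

    cols = [p - 1 for p in pcs]
    X = result.coords[:, cols]
    if k > X.shape[0]:
        raise ValueError("more clusters than samples")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    idx = km.fit_predict(X)
    occupied = np.unique(idx)
    if len(occupied) < k:
        raise ValueError(
            f"only {len(occupied)} of {k} clusters are non-empty "
            "(degenerate coordinates)"
        )
    mean_last = {c: X[idx == c, -1].mean() for c in occupied}
    order = sorted(occupied, key=lambda c: mean_last[c])
    names = {}
    names[order[0]] = "bottom"
    names[order[-1]] = "top"
    for c in order[1:-1]:
        names[c] = "middle"
    labels = {s: names[c] for s, c in zip(result.sample_ids, idx)}
    return ClusterAssignment(labels, method={"k": k, "seed": seed,
                                             "n_restarts": n_restarts})


def assign_threshold_clusters(
    result: PCAResult, pc: int = 2, cuts: tuple[float, float] = (-0.5, 0.5)
) -> ClusterAssignment:
    """Manual PC-threshold assignment (for reproducing figure-driven groupings)."""
    lo, hi = cuts
    vals = result.coords[:, pc - 1]
    labels = {}
    for s, v in zip(result.sample_ids, vals):
        labels[s] = "bottom" if v < lo else ("top" if v > hi else "middle")
    return ClusterAssignment(labels, method={"pc": pc, "cuts": cuts})


def cluster_diversity(
    gm: GenotypeMatrix,
    assignment: ClusterAssignment,
    window: int = 500_000,
    step: int = 50_000,
    mask: MaskTrack | None = None,
    chrom_length: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Sliding-window nucleotide diversity per cluster.

    Clusters contributing fewer than 2 called alleles at a site give that
    site zero weight; windows with zero accessible bases are NaN.
    """
    out = {}
    for label in ("top", "middle", "bottom"):
        members = assignment.samples_in(label)
        if not members:
            continue
        sub = gm.take_samples(members)
        out[label] = windowed_pi(sub, window=window, step=step, mask=mask,
                                 chrom_length=chrom_length)
    return out


def cluster_fst(
    gm: GenotypeMatrix,
    assignment: ClusterAssignment,
    window: int = 50_000,
    step: int = 5_000,
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """bp-windowed Weir-Cockerham theta-hat between top and bottom clusters."""
    top = assignment.samples_in("top")
    bottom = assignment.samples_in("bottom")
    if len(top) < 2 or len(bottom) < 2:
        raise ValueError("top and bottom clusters each need >= 2 samples")
    return windowed_fst_bp(gm, [top, bottom], window=window, step=step,
                           chrom_length=chrom_length)


def focal_genotype_table(
    gm: GenotypeMatrix,
    panel: CohortPanel,
    focal: FocalSiteSet,
    min_gq: int = 20,
) -> pd.DataFrame:
    """Genotype-class counts per cohort at each focal site.

    Genotypes below ``min_gq`` are masked first, so per-cohort totals can
    differ between sites.  A focal position absent from the matrix is
    reported as a NO-CALL row (the uncalled-locus case), never as zeros.
    """
    from .filtering import mask_low_gq

    masked = mask_low_gq(gm, min_gq=min_gq)
    rows = []
    for site in focal.sites:
        sel = (masked.chrom == site.chrom) & (masked.pos == site.pos)
        if not sel.any():
            for cohort in panel.cohorts:
                rows.append((site.label, site.chrom, site.pos, cohort,
                             "NO-CALL", len(panel.samples_in(cohort))))
            continue
        i = int(np.nonzero(sel)[0][0])
        for cohort in panel.cohorts:
            cols = [masked.sample_ids.index(s)
                    for s in panel.samples_in(cohort)
                    if s in masked.sample_ids]
            d = masked.dosage[i, cols]
            for cls, name in ((0, "hom_ref"), (1, "het"), (2, "hom_alt")):
                rows.append((site.label, site.chrom, site.pos, cohort, name,
                             int((d == cls).sum())))
            rows.append((site.label, site.chrom, site.pos, cohort, "missing",
                         int((d == MISSING).sum())))
    return pd.DataFrame(
        rows, columns=["label", "chrom", "pos", "cohort", "genotype", "count"]
    )


def focal_ld_matrix(
    gm: GenotypeMatrix,
    focal: FocalSiteSet,
    min_gq: int = 20,
    samples: list[str] | None = None,
    exempt_from_gq: set[str] | None = None,
) -> pd.DataFrame:
    """Pairwise dosage r^2 between focal sites (unit diagonal; NaN rows for
    monomorphic or absent sites).

    Shares the dosage-correlation kernel with the windowed LD statistic.
    ``exempt_from_gq`` names focal labels whose genotypes skip the GQ mask
    (for loci regenotyped by other means).
    """
    from .filtering import mask_low_gq

    if samples is not None:
        gm = gm.take_samples(samples)
    masked = mask_low_gq(gm, min_gq=min_gq)
    labels = [s.label for s in focal.sites]
    vecs = np.full((len(labels), gm.n_samples), MISSING, dtype=np.int8)
    found = np.zeros(len(labels), dtype=bool)
    for k, site in enumerate(focal.sites):
        sel = (gm.chrom == site.chrom) & (gm.pos == site.pos)
        if not sel.any():
            continue
        i = int(np.nonzero(sel)[0][0])
        src = gm if (exempt_from_gq and site.label in exempt_from_gq) else masked
        vecs[k] = src.dosage[i]
        found[k] = True
    m = r2_matrix(vecs)
    m[~found, :] = np.nan
    m[:, ~found] = np.nan
    np.fill_diagonal(m, np.where(found, 1.0, np.nan))
    return pd.DataFrame(m, index=labels, columns=labels)
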