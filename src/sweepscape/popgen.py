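"""Windowed diversity and differentiation statistics and dosage PCA.

Statistics operate on unphased allele dosages.  Windowed values are
returned as DataFrames with 1-based inclusive bp bounds (or variant-index
bounds for variant-count windows); undefined windows carry NaN, never 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import MISSING, CohortPanel, GenotypeMatrix, MaskTrack


def site_pi(x: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Per-site unbiased heterozygosity 2x(n-x)/(n(n-1))."""
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    out = np.zeros_like(x)
    ok = n > 1
    out[ok] = 2.0 * x[ok] * (n[ok] - x[ok]) / (n[ok] * (n[ok] - 1.0))
    return out


def _window_spans(gm: GenotypeMatrix, chrom: str, window: int, step: int | None,
                  chrom_length: int | None) -> list[tuple[int, int]]:
    pos = gm.pos[gm.chrom == chrom]
    length = chrom_length if chrom_length is not None else (
        int(pos.max()) if len(pos) else window
    )
    step = step or window
    spans = []
    start = 1
    while start <= length:
        spans.append((start, min(start + window - 1, length)))
        if start + window - 1 >= length:
            break
        start += step
    return spans


def windowed_pi(
    gm: GenotypeMatrix,
    window: int = 500_000,
    step: int | None = None,
    mask: MaskTrack | None = None,
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """Nucleotide diversity per window: site-pi sum over accessible bases.

    Accessible bases = window length minus masked bases, so the estimate is
    consistent with SNP sets from which masked regions were removed.  Fully
    masked windows are NaN.
    """
    x, n = gm.alt_counts()
    pi = site_pi(x, n)
    rows = []
    for chrom in pd.unique(gm.chrom):
        on = gm.chrom == chrom
        cpos = gm.pos[on]
        cpi = pi[on]
        for start, end in _window_spans(gm, chrom, window, step, chrom_length):
            lo, hi = np.searchsorted(cpos, (start, end + 1))
            n_var = hi - lo
            span = end - start + 1
            masked_b = mask.masked_bases(chrom, start, end) if mask else 0
            access = span - masked_b
            value = cpi[lo:hi].sum() / access if access > 0 else np.nan
            rows.append((chrom, start, end, value, n_var, access))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "value",
                       "n_variants", "n_accessible_bases"]
    )


def tajimas_d_constants(n: int) -> dict[str, float]:
    """The standard normalising constants for sample size n (alleles)."""
    if n < 4:
        raise ValueError("Tajima's D requires at least 4 sampled alleles")
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    return {"a1": a1, "a2": a2, "e1": c1 / a1, "e2": c2 / (a1**2 + a2)}


def tajimas_d(pi_sum: float, S: int, n: int) -> float:
    """Tajima's D from a window's pi sum, segregating-site count and n."""
    if S < 1:
        return float("nan")
    c = tajimas_d_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (pi_sum - S / c["a1"]) / np.sqrt(var)


def windowed_tajimas_d(
    gm: GenotypeMatrix,
    window: int = 500_000,
    step: int | None = None,
    min_variants: int = 3,
    call_rate_min: float = 0.75,
    per_site_n: bool = False,
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """Tajima's D per window.

    By default n is fixed at 2 x samples and sites with call rate below
    ``call_rate_min`` are dropped, keeping the normalising constants
    window-invariant; ``per_site_n=True`` instead uses the mean called
    allele count of each window's sites for the constants.
    """
    x, n = gm.alt_counts()
    n_fixed = 2 * gm.n_samples
    ok = (n >= call_rate_min * n_fixed) & (x > 0) & (x < n)
    pi = site_pi(x, n)
    rows = []
    for chrom in pd.unique(gm.chrom):
        on = gm.chrom == chrom
        cpos, cpi, cok, cn = gm.pos[on], pi[on], ok[on], n[on]
        for start, end in _window_spans(gm, chrom, window, step, chrom_length):
            lo, hi = np.searchsorted(cpos, (start, end + 1))
            sel = cok[lo:hi]
            S = int(sel.sum())
            if S < min_variants:
                rows.append((chrom, start, end, np.nan, S, end - start + 1))
                continue
            n_eff = int(round(cn[lo:hi][sel].mean())) if per_site_n else n_fixed
            d = tajimas_d(float(cpi[lo:hi][sel].sum()), S, n_eff)
            rows.append((chrom, start, end, d, S, end - start + 1))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "value",
                       "n_variants", "n_accessible_bases"]
    )


# ---------------------------------------------------------------------------
# Weir-Cockerham FST


def wc_components(gm: GenotypeMatrix, groups: list[list[str]]
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir-Cockerham (1984) variance components a, b, c.

    ``groups`` is a list of sample-id lists (one per population).  Uses
    observed heterozygosity; sites with fewer than 2 called individuals in
    any population get zero components (they contribute nothing).
    """
    r = len(groups)
    if r < 2:
        raise ValueError("need at least two populations")
    idx = []
    for g in groups:
        if not g:
            raise ValueError("empty population")
        idx.append([gm.sample_ids.index(s) for s in g])

    ni = np.empty((gm.n_sites, r))
    pi_ = np.empty((gm.n_sites, r))
    hi = np.empty((gm.n_sites, r))
    for k, cols in enumerate(idx):
        d = gm.dosage[:, cols]
        called = d != MISSING
        cnt = called.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            alt = np.where(called, d, 0).sum(axis=1)
            pi_[:, k] = np.where(cnt > 0, alt / (2.0 * cnt), np.nan)
            hi[:, k] = np.where(cnt > 0,
                                (np.where(called, d, 0) == 1).sum(axis=1) / cnt,
                                np.nan)
        ni[:, k] = cnt

    valid = (ni >= 2).all(axis=1)
    a = np.zeros(gm.n_sites)
    b = np.zeros(gm.n_sites)
    c = np.zeros(gm.n_sites)
    if not valid.any():
        return a, b, c
    nv = ni[valid]
    pv = pi_[valid]
    hv = hi[valid]
    nbar = nv.mean(axis=1)
    nc = (r * nbar - (nv**2).sum(axis=1) / (r * nbar)) / (r - 1.0)
    pbar = (nv * pv).sum(axis=1) / (r * nbar)
    s2 = (nv * (pv - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1.0) * nbar)
    hbar = (nv * hv).sum(axis=1) / (r * nbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        av = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0)
            / (nbar - 1.0)
        )
        bv = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
    cv = hbar / 2.0
    a[valid], b[valid], c[valid] = av, bv, cv
    return a, b, c


def pairwise_fst(
    gm: GenotypeMatrix,
    panel: CohortPanel,
    pair: tuple[str, str],
    window_variants: int = 500_000,
) -> tuple[pd.DataFrame, float]:
    """Windowed (ratio-of-sums over variant-count windows) and genome-wide
    Weir-Cockerham theta-hat between two cohorts."""
    groups = [panel.samples_in(c) for c in pair]
    a, b, c = wc_components(gm, groups)
    tot = a + b + c
    genome = float(a.sum() / tot.sum()) if tot.sum() > 0 else float("nan")
    rows = []
    for start in range(0, gm.n_sites, window_variants):
        end = min(start + window_variants, gm.n_sites)
        denom = tot[start:end].sum()
        theta = a[start:end].sum() / denom if denom > 0 else np.nan
        rows.append(
            (gm.chrom[start], start, end, theta, end - start, np.nan)
        )
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "value",
                       "n_variants", "n_accessible_bases"]
    )
    return df, genome


def windowed_fst_bp(
    gm: GenotypeMatrix,
    groups: list[list[str]],
    window: int,
    step: int | None = None,
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """bp-windowed Weir-Cockerham theta-hat (for region reports)."""
    a, b, c = wc_components(gm, groups)
    tot = a + b + c
    rows = []
    for chrom in pd.unique(gm.chrom):
        on = gm.chrom == chrom
        cpos = gm.pos[on]
        ca, ctot = a[on], tot[on]
        for start, end in _window_spans(gm, chrom, window, step, chrom_length):
            lo, hi = np.searchsorted(cpos, (start, end + 1))
            denom = ctot[lo:hi].sum()
            theta = ca[lo:hi].sum() / denom if denom > 0 else np.nan
            rows.append((chrom, start, end, theta, hi - lo, end - start + 1))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "value",
                       "n_variants", "n_accessible_bases"]
    )


# ---------------------------------------------------------------------------
# linkage disequilibrium (dosage-correlation r^2, phase-free)


def r2_matrix(dosage: np.ndarray) -> np.ndarray:
    """Pairwise squared Pearson correlation of dosage rows (sites x samples).

    Each pair uses samples called at both sites; pairs with a zero-variance
    member are NaN.  This is the standard phase-free dosage-correlation LD
    estimator.
    """
    d = np.asarray(dosage, dtype=float)
    d[np.asarray(dosage) == MISSING] = np.nan
    V = d.shape[0]
    out = np.full((V, V), np.nan)
    complete = ~np.isnan(d).any(axis=0)
    if complete.all():
        dd = d - d.mean(axis=1, keepdims=True)
        sd = dd.std(axis=1)
        ok = sd > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (dd @ dd.T) / d.shape[1] / np.outer(sd, sd)
        corr[~ok, :] = np.nan
        corr[:, ~ok] = np.nan
        out = corr**2
    else:
        for i in range(V):
            out[i, i] = 1.0
            for j in range(i + 1, V):
                both = ~np.isnan(d[i]) & ~np.isnan(d[j])
                if both.sum() < 2:
                    continue
                xi, xj = d[i, both], d[j, both]
                if xi.std() == 0 or xj.std() == 0:
                    continue
                r = np.corrcoef(xi, xj)[0, 1]
                out[i, j] = out[j, i] = r**2
    np.fill_diagonal(out, 1.0)
    return out


def windowed_mean_r2(
    gm: GenotypeMatrix,
    window: int = 100_000,
    step: int | None = None,
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """Mean pairwise dosage r^2 per window; NaN with fewer than 2 variants."""
    rows = []
    for chrom in pd.unique(gm.chrom):
        on = gm.chrom == chrom
        cpos = gm.pos[on]
        cdos = gm.dosage[on]
        for start, end in _window_spans(gm, chrom, window, step, chrom_length):
            lo, hi = np.searchsorted(cpos, (start, end + 1))
            n_var = hi - lo
            if n_var < 2:
                rows.append((chrom, start, end, np.nan, n_var, end - start + 1))
                continue
            m = r2_matrix(cdos[lo:hi])
            iu = np.triu_indices(n_var, k=1)
            vals = m[iu]
            value = np.nanmean(vals) if np.isfinite(vals).any() else np.nan
            rows.append((chrom, start, end, value, n_var, end - start + 1))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "value",
                       "n_variants", "n_accessible_bases"]
    )


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    coords: np.ndarray  # samples x k
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # snps_used x k
    snp_index: np.ndarray  # indices into the input matrix
    sample_ids: list[str]


def pca(
    gm: GenotypeMatrix,
    maf_min: float = 0.05,
    scaler: str = "patterson",
    mask: MaskTrack | None = None,
    n_components: int = 10,
    min_gq: int | None = 20,
) -> PCAResult:
    """Dosage PCA with per-SNP loadings.

    Genotypes below ``min_gq`` are masked first; SNPs are dropped when
    their minor allele frequency is ``maf_min`` or less, when they fall in
    ``mask``, or when they are non-SNP/multi-allelic/monomorphic.  Missing
    dosages are mean-imputed per site before centering; Patterson scaling
    divides by sqrt(p(1-p)) with p the mean dosage / 2.
    """
    from .filtering import mask_low_gq

    if min_gq is not None:
        gm = mask_low_gq(gm, min_gq=min_gq)
    x, n = gm.alt_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(n > 0, x / n, np.nan)
    maf = np.minimum(af, 1 - af)
    keep = gm.is_snp & gm.is_biallelic & (n > 0) & (maf > maf_min)
    if mask is not None:
        keep &= ~mask.contains(gm.chrom, gm.pos)
    snp_index = np.nonzero(keep)[0]
    if len(snp_index) < 2 or gm.n_samples < 2:
        raise ValueError("need at least 2 samples and 2 SNPs after filtering")

    d = gm.dosage[snp_index].astype(float)
    miss = gm.dosage[snp_index] == MISSING
    d[miss] = np.nan
    mean = np.nanmean(d, axis=1, keepdims=True)
    d = np.where(np.isnan(d), mean, d)
    centered = d - mean
    if scaler == "patterson":
        p = mean.ravel() / 2.0
        denom = np.sqrt(p * (1 - p))
        centered = centered / denom[:, None]
    elif scaler != "none":
        raise ValueError(f"unknown scaler {scaler!r}")

    X = centered.T  # samples x snps
    k = min(n_components, min(X.shape))
    U, Sv, Vt = np.linalg.svd(X, full_matrices=False)
    coords = U[:, :k] * Sv[:k]
    total_var = (Sv**2).sum()
    evr = (Sv[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    loadings = Vt[:k].T  # snps x k, unit-norm per component
    return PCAResult(
        coords=coords,
        explained_variance_ratio=evr,
        loadings=loadings,
        snp_index=snp_index,
        sample_ids=list(gm.sample_ids),
    )
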