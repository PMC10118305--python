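"""Composite-likelihood-ratio sweep scan against an empirical background SFS.

The background model is the empirical site frequency spectrum of all SNPs
segregating in the focal cohort.  The sweep model distorts that spectrum at
each test site using the star-like hitchhiking approximation: each of the n
sampled lineages escapes the sweep independently with probability
``p_e = 1 - exp(-Lambda * d)`` (d = genetic distance to the test site;
larger Lambda means more escape, i.e. a weaker or more distant sweep).
Given e escaped lineages, an effective sample of e+1 lineages is drawn from
the background spectrum (hypergeometric projection); one of them, uniformly
chosen, is the ancestor of the n-e swept lineages.  The likelihood
conditions on polymorphism, matching an input of segregating SNPs.

At every grid site the scan maximises the composite log-likelihood over a
log-spaced Lambda grid that always includes a neutral sentinel (p_e = 1),
so CLR = 2 * (max ll_sweep - ll_0) is non-negative by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import binom

from .types import CohortPanel, GenotypeMatrix, RecombinationMap


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


@dataclass
class SFSpectrum:
    """Background site frequency spectrum over derived-allele classes 1..n-1.

    A folded spectrum is stored in symmetrised unfolded form (each folded
    class's mass split evenly between count j and n-j), which keeps the
    hypergeometric projection and the sweep distortion exact; observed
    minor-allele classes are compared against re-folded model vectors.
    """

    n_background: int
    counts: np.ndarray  # length n_background - 1, classes 1..n-1
    folded: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.n_background - 1,):
            raise ValueError("counts must cover classes 1..n_background-1")
        if np.any(self.counts < 0):
            raise ValueError("negative SFS count")
        if self.counts.sum() <= 0:
            raise ValueError("empty spectrum")

    def probs(self) -> np.ndarray:
        """Normalised spectrum over classes 1..n-1."""
        return self.counts / self.counts.sum()


def fold_vector(vec: np.ndarray) -> np.ndarray:
    """Fold a probability vector over classes 1..n-1 to minor classes 1..n//2."""
    n = len(vec) + 1
    half = n // 2
    out = np.empty(half)
    for j in range(1, half + 1):
        if j == n - j:
            out[j - 1] = vec[j - 1]
        else:
            out[j - 1] = vec[j - 1] + vec[n - j - 1]
    return out


def empirical_sfs(
    gm: GenotypeMatrix,
    panel: CohortPanel,
    cohort: str,
    folded: bool = True,
    n_background: int | None = None,
) -> SFSpectrum:
    """Empirical background SFS from all SNPs segregating in the cohort.

    Sites with missing genotypes are projected down to ``n_background``
    alleles (hypergeometric expectation) before tallying; the default
    n_background is the smallest called-allele count among segregating
    sites, so every site contributes.  Fully called data project
    identically.
    """
    sub = gm.take_samples(panel.samples_in(cohort))
    x, n = sub.alt_counts()
    seg = (x > 0) & (x < n) & sub.is_snp & sub.is_biallelic
    x, n = x[seg], n[seg]
    if len(x) == 0:
        raise ValueError(f"no segregating sites in cohort {cohort!r}")
    if n_background is None:
        n_background = int(n.min())
    m = n_background
    counts = np.zeros(m - 1)
    for xi, ni in zip(x, n):
        if ni < m:
            continue
        if ni == m:
            counts[xi - 1] += 1.0
            continue
        j = np.arange(0, m + 1)
        logp = (_log_comb(xi, j) + _log_comb(ni - xi, m - j) - _log_comb(ni, m))
        with np.errstate(invalid="ignore"):
            pj = np.exp(logp)
        pj[~np.isfinite(pj)] = 0.0
        counts += pj[1:m]
    if folded:
        sym = np.empty_like(counts)
        for j in range(1, m):
            sym[j - 1] = 0.5 * (counts[j - 1] + counts[m - j - 1])
        counts = sym
    return SFSpectrum(n_background=m, counts=counts, folded=folded)


def project_sfs(spec: SFSpectrum, m: int) -> np.ndarray:
    """Hypergeometric projection to m alleles: probability vector over 0..m.

    q_j(m) = sum_k p_k C(k,j) C(n-k, m-j) / C(n, m); monomorphic classes
    j = 0 and j = m carry the mass of sites that lose their polymorphism
    in the subsample.
    """
    n = spec.n_background
    if not (1 <= m <= n):
        raise ValueError(f"projection size {m} outside [1, {n}]")
    p = spec.probs()
    k = np.arange(1, n)[:, None]
    j = np.arange(0, m + 1)[None, :]
    logw = _log_comb(k, j) + _log_comb(n - k, m - j) - _log_comb(n, m)
    with np.errstate(invalid="ignore"):
        w = np.exp(logw)
    w[(j > k) | ((m - j) > (n - k))] = 0.0
    return p @ w


@dataclass
class _SweepTables:
    """Cached projections of one background spectrum."""

    spec: SFSpectrum
    _proj: dict[int, np.ndarray] = field(default_factory=dict)

    def projection(self, m: int) -> np.ndarray:
        if m not in self._proj:
            self._proj[m] = project_sfs(self.spec, m)
        return self._proj[m]


def sweep_site_spectrum(
    spec: SFSpectrum, n: int, p_e: float, _tables: _SweepTables | None = None
) -> np.ndarray:
    """Expected SFS at a swept site, conditioned on polymorphism.

    Returns a probability vector over derived counts 1..n-1 (symmetrised
    classes when the background is folded; use :func:`fold_vector` to
    compare against minor-allele counts).  ``p_e = 1`` returns the
    conditioned background projection exactly.
    """
    if not (0.0 <= p_e <= 1.0):
        raise ValueError("p_e must be in [0, 1]")
    if n < 2:
        raise ValueError("n must be >= 2")
    if n > spec.n_background:
        raise ValueError("n exceeds the background sample size")
    tables = _tables or _SweepTables(spec)
    full = np.zeros(n + 1)  # over b = 0..n
    weights = binom.pmf(np.arange(0, n + 1), n, p_e)
    for e in range(0, n + 1):
        w = weights[e]
        if w == 0.0:
            continue
        if e == n:
            full += w * tables.projection(n)
            continue
        q = tables.projection(e + 1)  # over j = 0..e+1
        j = np.arange(0, e + 2)
        anc = j / (e + 1.0)  # ancestor of the swept lineages is derived
        # derived ancestor: b = j - 1 + n - e ; otherwise b = j
        for jj in j:
            if q[jj] == 0.0:
                continue
            full[jj] += w * q[jj] * (1.0 - anc[jj])
            if anc[jj] > 0.0:
                full[jj - 1 + n - e] += w * q[jj] * anc[jj]
    poly = full[1:n]
    total = poly.sum()
    if total < 1e-300:
        raise FloatingPointError("fully swept; no polymorphism expected")
    return poly / total


@dataclass
class ScanResult:
    """Per-grid-site composite likelihood ratios."""

    chrom: np.ndarray
    positions: np.ndarray
    clr: np.ndarray
    lambda_hat: np.ndarray  # NaN where the neutral sentinel maximises

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.clr = np.asarray(self.clr, dtype=float)
        self.lambda_hat = np.asarray(self.lambda_hat, dtype=float)
        if np.any(self.clr < -1e-9):
            raise ValueError("negative CLR")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "position": self.positions,
             "clr": self.clr, "lambda_hat": self.lambda_hat}
        )

    @classmethod
    def concat(cls, parts: list["ScanResult"]) -> "ScanResult":
        return cls(
            chrom=np.concatenate([p.chrom for p in parts]),
            positions=np.concatenate([p.positions for p in parts]),
            clr=np.concatenate([p.clr for p in parts]),
            lambda_hat=np.concatenate([p.lambda_hat for p in parts]),
        )


def default_lambda_grid(d_min: float, d_max: float, n_points: int = 32
                        ) -> np.ndarray:
    """Log-spaced Lambda grid spanning escape scales from one grid step to
    the chunk width: Lambda = ln 2 / d gives p_e = 0.5 at distance d."""
    lam_hi = np.log(2.0) / max(d_min, 1e-12)
    lam_lo = np.log(2.0) / max(d_max, 1e-12)
    return np.geomspace(lam_lo, lam_hi, n_points)


def _site_table(gm, panel, cohort, spec):
    sub = gm.take_samples(panel.samples_in(cohort))
    x, n = sub.alt_counts()
    seg = (x > 0) & (x < n) & sub.is_snp & sub.is_biallelic & (n <= spec.n_background) \
        & (n >= 2)
    x, n, pos, chrom = x[seg], n[seg], sub.pos[seg], sub.chrom[seg]
    if spec.folded:
        x = np.minimum(x, n - x)
        # a folded count equal to exactly n/2 is its own fold class
    return chrom, pos, x, n


def _log_tables(spec, tables, n, pe_bins, folded):
    """log P(class | p_e bin) matrix, shape (n_bins, n_classes_for_n)."""
    out = []
    for pe in pe_bins:
        vec = sweep_site_spectrum(spec, n, pe, _tables=tables)
        if folded:
            vec = fold_vector(vec)
            vec = vec / vec.sum()
        with np.errstate(divide="ignore"):
            out.append(np.log(np.maximum(vec, 1e-300)))
    return np.vstack(out)


def clr_scan(
    gm: GenotypeMatrix,
    panel: CohortPanel,
    cohort: str,
    spec: SFSpectrum,
    grid_spacing: int = 1000,
    lambda_grid: np.ndarray | None = None,
    lambda_points: int = 32,
    recomb_map: RecombinationMap | None = None,
    rate_cm_per_bp: float = 1e-6,
    chunk_size: int = 50_000_000,
    chunk_overlap: int = 5_000_000,
    n_pe_bins: int = 64,
) -> ScanResult:
    """Composite-likelihood-ratio scan over a ~1 kb grid of test sites.

    Distances are genetic (cM) when a recombination map is given, otherwise
    physical distance times ``rate_cm_per_bp``.  Chromosomes are processed
    in 50 Mb chunks overlapping by 5 Mb; overlapping grid sites keep the
    value from the chunk whose centre is nearer.  p_e values are discretised
    to ``n_pe_bins`` bins when evaluating site likelihoods.
    """
    tables = _SweepTables(spec)
    chrom_all, pos_all, x_all, n_all = _site_table(gm, panel, cohort, spec)
    if len(pos_all) == 0:
        raise ValueError("no usable segregating sites for the scan")

    # discretise p_e; dense near 1 where the spectrum approaches background.
    # p_e = 0 exactly (a grid site on a SNP under total sweep) has no
    # polymorphic mass, so the smallest bin is a tiny positive value whose
    # spectrum assigns polymorphic observations ~zero likelihood.
    pe_bins = np.unique(np.concatenate([
        [1e-9],
        np.linspace(0.0, 1.0, n_pe_bins)[1:],
        1.0 - np.geomspace(1e-6, 1.0, n_pe_bins // 2 + 1)[:-1],
    ]))

    parts = []
    for chrom in pd.unique(chrom_all):
        on = chrom_all == chrom
        pos, x, n = pos_all[on], x_all[on], n_all[on]
        if recomb_map is not None:
            gpos = recomb_map.genetic_position(chrom, pos)
        else:
            gpos = pos.astype(float) * rate_cm_per_bp

        lo, hi = int(pos.min()), int(pos.max())
        grid = np.arange(lo, hi + 1, grid_spacing, dtype=np.int64)
        if lambda_grid is None:
            span_cm = max(gpos.max() - gpos.min(), 1e-9)
            d_min = span_cm * grid_spacing / max(hi - lo, 1)
            lam = default_lambda_grid(d_min, span_cm, lambda_points)
        else:
            lam = np.asarray(lambda_grid, dtype=float)
        if len(lam) == 0:
            raise ValueError("empty Lambda grid")

        chunk_results: list[tuple[float, ScanResult]] = []
        starts = list(range(lo, hi + 1, chunk_size - chunk_overlap)) or [lo]
        for cstart in starts:
            cend = min(cstart + chunk_size, hi + 1)
            gsel = (grid >= cstart) & (grid < cend)
            if not gsel.any():
                continue
            ssel = (pos >= cstart) & (pos < cend)
            res = _scan_chunk(
                spec, tables, pe_bins, lam,
                grid[gsel], pos[ssel], gpos[ssel], x[ssel], n[ssel],
                recomb_map, chrom, grid_spacing, rate_cm_per_bp,
            )
            center = 0.5 * (cstart + cend)
            chunk_results.append((center, ScanResult(
                chrom=np.full(gsel.sum(), chrom, dtype=object),
                positions=grid[gsel], clr=res[0], lambda_hat=res[1],
            )))
            if cend >= hi + 1:
                break

        # overlap resolution: keep the value from the nearer chunk centre
        clr = np.full(len(grid), np.nan)
        lam_hat = np.full(len(grid), np.nan)
        best_dist = np.full(len(grid), np.inf)
        for center, part in chunk_results:
            idx = np.searchsorted(grid, part.positions)
            dist = np.abs(part.positions - center)
            take = dist < best_dist[idx]
            clr[idx[take]] = part.clr[take]
            lam_hat[idx[take]] = part.lambda_hat[take]
            best_dist[idx[take]] = dist[take]
        parts.append(ScanResult(
            chrom=np.full(len(grid), chrom, dtype=object),
            positions=grid, clr=clr, lambda_hat=lam_hat,
        ))
    return ScanResult.concat(parts)


def _scan_chunk(spec, tables, pe_bins, lam, grid, pos, gpos, x, n,
                recomb_map, chrom, grid_spacing, rate_cm_per_bp):
    S = len(pos)
    uniq_n = np.unique(n)
    # per-site lookup: M[bin, site] = log P(x_site | p_e bin)
    M = np.empty((len(pe_bins), S))
    ll0 = np.empty(S)
    for nv in uniq_n:
        sel = n == nv
        table = _log_tables(spec, tables, int(nv), pe_bins, spec.folded)
        M[:, sel] = table[:, x[sel] - 1]
        # null: background projection conditioned on polymorphism (p_e = 1)
        null_vec = sweep_site_spectrum(spec, int(nv), 1.0, _tables=tables)
        if spec.folded:
            null_vec = fold_vector(null_vec)
            null_vec = null_vec / null_vec.sum()
        ll0[sel] = np.log(np.maximum(null_vec, 1e-300))[x[sel] - 1]
    ll0_sum = ll0.sum()

    if recomb_map is not None:
        grid_g = recomb_map.genetic_position(chrom, grid)
    else:
        grid_g = grid.astype(float) * rate_cm_per_bp

    clr = np.empty(len(grid))
    lam_hat = np.empty(len(grid))
    site_idx = np.arange(S)
    for gi, g in enumerate(grid_g):
        d = np.abs(gpos - g)
        best_ll = ll0_sum  # neutral sentinel (p_e = 1 everywhere)
        best_lam = np.nan
        for lv in lam:
            pe = 1.0 - np.exp(-lv * d)
            bins = np.searchsorted(pe_bins, pe)
            np.clip(bins, 0, len(pe_bins) - 1, out=bins)
            ll = M[bins, site_idx].sum()
            if ll > best_ll + 1e-12:
                best_ll = ll
                best_lam = lv
        clr[gi] = 2.0 * (best_ll - ll0_sum)
        lam_hat[gi] = best_lam
    return clr, lam_hat
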