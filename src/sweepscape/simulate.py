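"""Synthetic cohort, sweep, relatedness, quality and annotation generators.

Two complementary genotype generators are provided:

* :func:`simulate_neutral_panel` draws site-independent genotypes for several
  cohorts under the Balding--Nichols drift model around a neutral (1/p) site
  frequency spectrum.  It produces no linkage disequilibrium and is valid for
  SFS-based statistics only (pi, Tajima's D, FST, SFS projection).
* :func:`simulate_wf_sweep` is a forward diploid Wright--Fisher simulation
  with recombination and multiplicative selection, initialised at neutral
  mutation--drift equilibrium in linkage equilibrium.  The selected phase
  generates the haplotype structure (hitchhiking, LD) that haplotype-aware
  statistics need; use it for CLR localisation, G statistics and the focal
  locus report.

All generators are pure functions of their seeds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    CohortPanel,
    GeneModel,
    GeneSetCatalog,
    GenotypeMatrix,
    MaskTrack,
    SiteQuality,
)

_BASES = np.array(list("ACGT"), dtype=object)


@dataclass
class SimTruth:
    """Ground-truth record of every injected feature of a simulation."""

    seed: int
    kind: str
    params: dict = field(default_factory=dict)
    cohort_F: dict = field(default_factory=dict)
    sweeps: list = field(default_factory=list)  # dicts: position, s, final_freq, ...
    relatives: list = field(default_factory=list)  # dicts: parents, child
    good_sites: np.ndarray | None = None  # quality-synthesis truth labels
    theta: float | None = None
    restarts: int = 0

    def to_json(self, path) -> None:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))

        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, default=default, indent=1)


def _draw_positions(rng: np.random.Generator, n: int, L: int) -> np.ndarray:
    """n distinct 1-based positions on [1, L], sorted."""
    if n > L:
        raise ValueError(f"cannot place {n} sites on {L} bp")
    got: set[int] = set()
    while len(got) < n:
        got.update(rng.integers(1, L + 1, size=2 * (n - len(got))).tolist())
        if len(got) > n:
            got = set(list(got)[:n]) if len(got) == n else got
    pos = np.sort(np.fromiter(got, dtype=np.int64, count=len(got)))
    if len(pos) > n:
        pos = np.sort(rng.choice(pos, size=n, replace=False))
    return pos


def _random_alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    ref = rng.choice(4, size=n)
    alt = (ref + rng.integers(1, 4, size=n)) % 4
    return _BASES[ref], _BASES[alt]


def _panel_frame(cohort_sizes: dict[str, int], continents: dict[str, str] | None,
                 rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for cohort, size in cohort_sizes.items():
        cont = (continents or {}).get(cohort, "Americas")
        for k in range(size):
            rows.append(
                {
                    "sample": f"{cohort}_{k:03d}",
                    "cohort": cohort,
                    "continent": cont,
                    "mean_coverage": float(np.round(rng.uniform(15, 40), 1)),
                }
            )
    return pd.DataFrame(rows).set_index("sample")


def simulate_neutral_panel(
    n_cohorts: int,
    samples_per_cohort: int,
    L: int,
    theta: float,
    F: float | Sequence[float] = 0.0,
    seed: int = 0,
    chrom: str = "1",
    continents: dict[str, str] | None = None,
) -> tuple[GenotypeMatrix, CohortPanel, SimTruth]:
    """Site-independent neutral cohorts with Balding--Nichols drift.

    The number of segregating sites is Poisson with mean ``theta * L * a1``
    where ``a1 = sum_{i=1}^{2n-1} 1/i`` (n = total diploids).  With no drift
    (all F = 0) each site's derived count i over the 2n sampled alleles is
    drawn with probability proportional to 1/i and carriers are assigned
    uniformly — the exact neutral equilibrium sample SFS, so E[sum pi] =
    theta*L and E[S] matches Watterson's estimator exactly.  With drift the
    ancestral frequency p has density proportional to 1/p truncated to
    [1/(4n), 1 - 1/(4n)]; cohort frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F)
    and dosages Binomial(2, cohort frequency).
    """
    if samples_per_cohort < 1:
        raise ValueError("samples_per_cohort must be >= 1")
    if np.isscalar(F):
        Fs = [float(F)] * n_cohorts
    else:
        Fs = [float(f) for f in F]
        if len(Fs) != n_cohorts:
            raise ValueError("one F per cohort required")
    for f in Fs:
        if not (0.0 <= f < 1.0):
            raise ValueError("F must satisfy 0 <= F < 1")

    rng = np.random.default_rng(seed)
    n_total = n_cohorts * samples_per_cohort
    two_n = 2 * n_total
    a1 = np.sum(1.0 / np.arange(1, two_n))
    lam = theta * L * a1
    if not np.isfinite(lam):
        raise ValueError("theta * L * a1 overflows")
    S = int(rng.poisson(lam))
    S = min(S, L)
    pos = _draw_positions(rng, S, L)

    cohorts = [f"cohort{c + 1}" for c in range(n_cohorts)]
    if all(f == 0.0 for f in Fs):
        # exact neutral sample SFS: P(count = i) proportional to 1/i
        w = 1.0 / np.arange(1, two_n)
        counts = rng.choice(np.arange(1, two_n), size=S, p=w / w.sum())
        keys = rng.random((S, two_n))
        if S:
            srt = np.sort(keys, axis=1)
            thr = np.take_along_axis(srt, counts[:, None] - 1, axis=1)
            carriers = keys <= thr
        else:
            carriers = np.zeros((0, two_n), dtype=bool)
        dosage = (carriers[:, 0::2].astype(np.int8)
                  + carriers[:, 1::2].astype(np.int8))
    else:
        # inverse-CDF draw from density proportional to 1/p on [eps, 1-eps]
        eps = 1.0 / (4.0 * n_total)
        u = rng.random(S)
        p = eps * np.exp(u * np.log((1.0 - eps) / eps))
        dosage = np.empty((S, n_total), dtype=np.int8)
        for c, (name, f) in enumerate(zip(cohorts, Fs)):
            if f == 0.0:
                q = p
            else:
                scale = (1.0 - f) / f
                q = rng.beta(np.maximum(p * scale, 1e-12),
                             np.maximum((1.0 - p) * scale, 1e-12))
            cols = slice(c * samples_per_cohort, (c + 1) * samples_per_cohort)
            dosage[:, cols] = rng.binomial(
                2, q[:, None], size=(S, samples_per_cohort)
            ).astype(np.int8)

    ref, alt = _random_alleles(rng, S)
    panel = CohortPanel(
        _panel_frame({c: samples_per_cohort for c in cohorts}, continents, rng)
    )
    gm = GenotypeMatrix(
        chrom=np.full(S, chrom, dtype=object),
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        dosage=dosage,
        gq=np.full((S, n_total), 99, dtype=np.int16),
        sample_ids=panel.sample_ids,
    )
    truth = SimTruth(
        seed=seed,
        kind="neutral_panel",
        params={"n_cohorts": n_cohorts, "samples_per_cohort": samples_per_cohort,
                "L": L, "theta": theta},
        cohort_F=dict(zip(cohorts, Fs)),
        theta=theta,
    )
    return gm, panel, truth


# ---------------------------------------------------------------------------
# forward Wright-Fisher simulation with selection and recombination


def _equilibrium_haplotypes(rng, n_hap: int, L: int, theta_pop: float):
    """Neutral-equilibrium haplotypes in linkage equilibrium.

    Site count Poisson(theta*L*a1); derived counts i with probability
    proportional to 1/i; carriers chosen uniformly per site.
    """
    a1 = np.sum(1.0 / np.arange(1, n_hap))
    S = int(rng.poisson(theta_pop * L * a1))
    S = min(S, L)
    pos = _draw_positions(rng, S, L)
    w = 1.0 / np.arange(1, n_hap)
    counts = rng.choice(np.arange(1, n_hap), size=S, p=w / w.sum())
    hap = np.zeros((n_hap, S), dtype=np.int8)
    for j in range(S):
        hap[rng.choice(n_hap, size=counts[j], replace=False), j] = 1
    return hap, pos


def simulate_wf_sweep(
    N: int,
    L: int,
    mu: float,
    r: float,
    s: float,
    sweep_pos: int,
    stop_freq: float = 1.0,
    sample_n: int = 25,
    seed: int = 0,
    max_restarts: int = 2000,
    n_generations: int | None = None,
    chrom: str = "1",
) -> tuple[np.ndarray, np.ndarray, GenotypeMatrix, SimTruth]:
    """Forward diploid Wright--Fisher simulation of a (partial) hard sweep.

    A beneficial mutation with multiplicative selection coefficient ``s`` is
    injected on one haplotype at ``sweep_pos`` and the population evolved
    until the allele reaches ``stop_freq``; runs where it is lost restart
    from the same initial population (rejection conditioning on
    establishment, restart count logged).  With ``s = 0`` no allele is
    injected and the population drifts for ``n_generations`` (default N/5)
    as a neutral control.

    Returns ``(haplotypes, positions, genotype_matrix, truth)`` where
    haplotypes is the phased (2*sample_n, S) sample so tests retain phased
    truth even though the pipeline itself is unphased.  The genotype matrix
    contains the sites segregating in the sample.  Recurrent mutation
    continues during the forward phase (new variants are singletons on a
    random gamete); columns lost from the population are pruned
    periodically to bound memory.
    """
    if N > 1000:
        raise ValueError("N > 1000 is outside the supported desk scale")
    if s < 0:
        raise ValueError("s must be >= 0")
    rng = np.random.default_rng(seed)
    n_hap = 2 * N
    theta_pop = 4.0 * N * mu
    hap0, pos0 = _equilibrium_haplotypes(rng, n_hap, L, theta_pop)

    # insert the sweep site column (derived allele on one haplotype)
    sweep_col0 = None
    if s > 0 or (s == 0 and n_generations is None and stop_freq < 1.0):
        k = int(np.searchsorted(pos0, sweep_pos))
        if k < len(pos0) and pos0[k] == sweep_pos:
            # an equilibrium site already occupies the sweep position;
            # the sweep column replaces it (infinite-sites bookkeeping)
            pos0 = np.delete(pos0, k)
            hap0 = np.delete(hap0, k, axis=1)
        pos0 = np.insert(pos0, k, sweep_pos)
        hap0 = np.insert(hap0, k, 0, axis=1)
        sweep_col0 = k

    rL = r * L
    mut_rate = n_hap * mu * L  # expected new mutations per generation
    fit = np.array([1.0, 1.0 + s, (1.0 + s) ** 2])

    def one_generation(pop, pos, sweep_col, rng):
        if sweep_col is not None and s > 0:
            dose = pop[0::2, sweep_col].astype(np.int64) + pop[1::2, sweep_col]
            w = fit[dose]
            parents = rng.choice(N, size=n_hap, p=w / w.sum())
        else:
            parents = rng.integers(0, N, size=n_hap)
        ncx = rng.poisson(rL, size=n_hap)
        coin = rng.integers(0, 2, size=n_hap)
        plain = ncx == 0
        children = np.empty_like(pop)
        children[plain] = pop[2 * parents[plain] + coin[plain]]
        for i in np.nonzero(~plain)[0]:
            bps = np.sort(rng.uniform(0, L, size=ncx[i]))
            seg = np.searchsorted(bps, pos.astype(float))
            use_b = (seg + coin[i]) % 2 == 1
            a = pop[2 * parents[i]]
            b = pop[2 * parents[i] + 1]
            children[i] = np.where(use_b, b, a)
        # recurrent mutation: each new variant is a singleton on one gamete
        n_new = int(rng.poisson(mut_rate))
        if n_new:
            newpos = rng.integers(1, L + 1, size=n_new)
            newpos = np.setdiff1d(np.unique(newpos), pos)
            if len(newpos):
                cols = np.zeros((n_hap, len(newpos)), dtype=np.int8)
                cols[rng.integers(0, n_hap, size=len(newpos)),
                     np.arange(len(newpos))] = 1
                children = np.concatenate([children, cols], axis=1)
                pos = np.concatenate([pos, newpos])
        return children, pos

    def prune(pop, pos, sweep_col):
        """Drop columns lost from the population (fixed columns kept: they
        are still polymorphic relative to the reference)."""
        alive = pop.any(axis=0)
        if sweep_col is not None:
            alive[sweep_col] = True
        if alive.all():
            return pop, pos, sweep_col
        new_sweep = (int(alive[:sweep_col].sum()) if sweep_col is not None
                     else None)
        return pop[:, alive], pos[alive], new_sweep

    restarts = 0
    if s == 0 and sweep_col0 is None:
        gens = int(n_generations if n_generations is not None else max(1, N // 5))
        pop, pos, sweep_col = hap0.copy(), pos0.copy(), None
        for g in range(gens):
            pop, pos = one_generation(pop, pos, None, rng)
            if g % 10 == 9:
                pop, pos, sweep_col = prune(pop, pos, None)
        final_freq = 0.0
    else:
        while True:
            pop, pos, sweep_col = hap0.copy(), pos0.copy(), sweep_col0
            carrier = int(rng.integers(0, n_hap))
            pop[:, sweep_col] = 0
            pop[carrier, sweep_col] = 1
            lost = False
            g = 0
            while True:
                pop, pos = one_generation(pop, pos, sweep_col, rng)
                g += 1
                freq = pop[:, sweep_col].mean()
                if freq == 0.0:
                    lost = True
                    break
                if freq >= stop_freq:
                    break
                if g % 10 == 9:
                    pop, pos, sweep_col = prune(pop, pos, sweep_col)
            if not lost:
                final_freq = float(freq)
                break
            restarts += 1
            if restarts > max_restarts:
                raise RuntimeError(
                    f"sweep not established after {max_restarts} restarts"
                )

    pick = rng.choice(N, size=sample_n, replace=False)
    rows = np.column_stack([2 * pick, 2 * pick + 1]).ravel()
    sample_hap = pop[rows]

    seg = sample_hap.any(axis=0) & ~sample_hap.all(axis=0)
    if sweep_col is not None:
        seg = seg.copy()
        seg[sweep_col] = True  # keep the sweep site even if fixed in the sample
    hap_out = sample_hap[:, seg]
    pos_out = pos[seg]
    order = np.argsort(pos_out, kind="stable")
    hap_out = hap_out[:, order]
    pos_out = pos_out[order]

    dosage = (hap_out[0::2] + hap_out[1::2]).T.astype(np.int8)
    Ssamp = dosage.shape[0]
    ref, alt = _random_alleles(np.random.default_rng(seed + 1), Ssamp)
    sample_ids = [f"wf_{i:03d}" for i in range(sample_n)]
    gm = GenotypeMatrix(
        chrom=np.full(Ssamp, chrom, dtype=object),
        pos=pos_out,
        ref_allele=ref,
        alt_allele=alt,
        dosage=dosage,
        gq=np.full((Ssamp, sample_n), 99, dtype=np.int16),
        sample_ids=sample_ids,
    )
    sweep_records = []
    if sweep_col is not None:
        sample_freq = float(hap_out[:, np.searchsorted(pos_out, sweep_pos)].mean()) \
            if sweep_pos in pos_out else 0.0
        sweep_records.append(
            {"position": int(sweep_pos), "s": s, "final_freq": final_freq,
             "sample_freq": sample_freq}
        )
    truth = SimTruth(
        seed=seed,
        kind="wf_sweep",
        params={"N": N, "L": L, "mu": mu, "r": r, "s": s,
                "stop_freq": stop_freq, "sample_n": sample_n},
        sweeps=sweep_records,
        theta=theta_pop,
        restarts=restarts,
    )
    return hap_out, pos_out, gm, truth


def sweep_haplotype_carriers(hap: np.ndarray, pos: np.ndarray,
                             sweep_pos: int) -> np.ndarray:
    """Boolean mask over haplotypes carrying the derived sweep allele."""
    k = int(np.searchsorted(pos, sweep_pos))
    if k >= len(pos) or pos[k] != sweep_pos:
        raise ValueError("sweep position not among the sampled sites")
    return hap[:, k] == 1


def inject_relatives(
    gm: GenotypeMatrix,
    parent_pairs: Sequence[tuple[str, str, str]],
    seed: int = 0,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Append offspring columns: one allele drawn Mendelianly from each parent.

    A self-pair (both parents identical) yields an exact duplicate of the
    parent, emulating a duplicated specimen.
    """
    rng = np.random.default_rng(seed)
    lookup = {s: k for k, s in enumerate(gm.sample_ids)}
    new_cols, new_gq, records = [], [], []
    for pa, pb, child in parent_pairs:
        if child in lookup:
            raise ValueError(f"child id {child!r} already present")
        ia, ib = lookup[pa], lookup[pb]
        if ia == ib:
            dose = gm.dosage[:, ia].copy()
        else:
            ga = gm.dosage[:, ia].astype(float)
            gb = gm.dosage[:, ib].astype(float)
            aa = rng.random(gm.n_sites) < ga / 2.0
            ab = rng.random(gm.n_sites) < gb / 2.0
            dose = (aa.astype(np.int8) + ab.astype(np.int8))
            bad = (gm.dosage[:, ia] == MISSING) | (gm.dosage[:, ib] == MISSING)
            dose[bad] = MISSING
        new_cols.append(dose.astype(np.int8))
        new_gq.append(np.full(gm.n_sites, 99, dtype=np.int16))
        records.append({"parents": [pa, pb], "child": child})
    out = GenotypeMatrix(
        chrom=gm.chrom,
        pos=gm.pos,
        ref_allele=gm.ref_allele,
        alt_allele=gm.alt_allele,
        dosage=np.column_stack([gm.dosage, *new_cols]),
        gq=np.column_stack([gm.gq, *new_gq]),
        sample_ids=gm.sample_ids + [rec["child"] for rec in records],
        is_snp=gm.is_snp,
        is_biallelic=gm.is_biallelic,
    )
    return out, SimTruth(seed=seed, kind="relatives", relatives=records)


# ---------------------------------------------------------------------------
# quality synthesis

# passing ranges for the six hard-filter statistics; a "bad" site is drawn
# to fail at least two of them so the 5-of-6 rule must reject it
_PASS_RANGES = {
    "qd": (2.0, 40.0),
    "fs": (0.0, 39.9),
    "sor": (0.1, 3.95),
    "mq": (40.0, 60.0),
    "mqrs": (-4.9, 4.9),
    "rprs": (-2.9, 2.9),
}
_FAIL_RANGES = {
    "qd": (0.0, 1.95),
    "fs": (40.5, 200.0),
    "sor": (4.05, 10.0),
    "mq": (0.0, 39.5),
    "mqrs": (5.1, 12.0),  # sign randomised at draw time
    "rprs": (3.1, 8.0),
}


def synthesize_site_quality(
    n_sites: int,
    bad_fraction: float,
    seed: int = 0,
    absent_rate: float = 0.0,
) -> tuple[SiteQuality, SimTruth]:
    """Six-statistic site qualities with a known good/bad truth labelling.

    Good sites fall inside all six passing ranges; bad sites fail at least
    two randomly chosen filters.  ``absent_rate`` blanks passing fields at
    random (absent statistics count as passing downstream, so truth labels
    are preserved exactly).
    """
    rng = np.random.default_rng(seed)
    good = rng.random(n_sites) >= bad_fraction
    vals = {}
    for f, (lo, hi) in _PASS_RANGES.items():
        vals[f] = rng.uniform(lo, hi, size=n_sites)
    fields = list(_PASS_RANGES)
    for i in np.nonzero(~good)[0]:
        n_fail = int(rng.integers(2, 7))
        for f in rng.choice(fields, size=n_fail, replace=False):
            lo, hi = _FAIL_RANGES[f]
            v = rng.uniform(lo, hi)
            if f in ("mqrs", "rprs") and rng.random() < 0.5:
                v = -v
            vals[f][i] = v
    if absent_rate > 0:
        for i in range(n_sites):
            failing = set()
            if not good[i]:
                for f in fields:
                    lo, hi = _PASS_RANGES[f]
                    if not (lo <= vals[f][i] <= hi):
                        failing.add(f)
            for f in fields:
                if f not in failing and rng.random() < absent_rate:
                    vals[f][i] = np.nan
    sq = SiteQuality(**vals)
    truth = SimTruth(
        seed=seed, kind="site_quality",
        params={"n_sites": n_sites, "bad_fraction": bad_fraction,
                "absent_rate": absent_rate},
        good_sites=good,
    )
    return sq, truth


def synthesize_gq(
    gm: GenotypeMatrix, low_fraction: float, seed: int = 0
) -> tuple[GenotypeMatrix, SimTruth]:
    """Populate genotype qualities; ``low_fraction`` of genotypes get GQ < 20."""
    rng = np.random.default_rng(seed)
    low = rng.random(gm.dosage.shape) < low_fraction
    gq = rng.integers(20, 100, size=gm.dosage.shape)
    gq[low] = rng.integers(0, 20, size=int(low.sum()))
    out = GenotypeMatrix(
        chrom=gm.chrom, pos=gm.pos, ref_allele=gm.ref_allele,
        alt_allele=gm.alt_allele, dosage=gm.dosage,
        gq=gq.astype(np.int16), sample_ids=list(gm.sample_ids),
        is_snp=gm.is_snp, is_biallelic=gm.is_biallelic,
    )
    truth = SimTruth(seed=seed, kind="gq",
                     params={"low_fraction": low_fraction,
                             "n_low": int(low.sum())})
    return out, truth


def make_gene_annotation(
    L: int,
    n_genes: int,
    cluster_spec: dict | None = None,
    seed: int = 0,
    chrom: str = "1",
    n_random_terms: int = 4,
    genes_per_term: int = 8,
) -> tuple[list[GeneModel], GeneSetCatalog]:
    """Random non-overlapping gene models plus a gene-set catalog.

    ``cluster_spec`` (keys: term, n_genes, span, optional start) plants a
    term whose member genes are physically adjacent within ``span`` bp —
    the linkage confound (e.g. a tandem histone cluster) that motivates the
    rotation permutation test.
    """
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    occupied: list[tuple[int, int]] = []

    def place(start, end):
        occupied.append((start, end))

    def free(start, end):
        return all(e < start or s > end for s, e in occupied)

    if cluster_spec:
        term = cluster_spec.get("term", "clustered_set")
        k = int(cluster_spec["n_genes"])
        span = int(cluster_spec["span"])
        c0 = int(cluster_spec.get("start", rng.integers(1, max(2, L - span))))
        gene_len = max(200, span // (2 * k))
        gap = (span - k * gene_len) // max(1, k - 1) if k > 1 else 0
        cluster_ids = []
        for i in range(k):
            s = c0 + i * (gene_len + gap)
            e = min(s + gene_len - 1, L)
            gid = f"clu{i + 1:03d}"
            genes.append(GeneModel(gid, chrom, s, e, "+" if i % 2 == 0 else "-"))
            place(s, e)
            cluster_ids.append(gid)
    else:
        term, cluster_ids = None, []

    n_scatter = n_genes - len(genes)
    tries = 0
    i = 0
    while i < n_scatter and tries < 100 * n_scatter:
        tries += 1
        length = int(rng.integers(500, 3000))
        s = int(rng.integers(1, max(2, L - length)))
        e = s + length - 1
        if free(s, e):
            genes.append(
                GeneModel(f"gene{i + 1:04d}", chrom, s, e,
                          "+" if rng.random() < 0.5 else "-")
            )
            place(s, e)
            i += 1
    if i < n_scatter:
        raise ValueError("could not place requested genes without overlap")

    genes.sort(key=lambda g: g.start)
    scatter_ids = [g.gene_id for g in genes if not g.gene_id.startswith("clu")]
    sets = {}
    if term:
        sets[term] = set(cluster_ids)
    for t in range(n_random_terms):
        k = min(genes_per_term, len(scatter_ids))
        sets[f"term{t + 1:03d}"] = set(rng.choice(scatter_ids, size=k, replace=False))
    return genes, GeneSetCatalog(sets)


def make_masks(
    L: int, masked_fraction: float, seed: int = 0, chrom: str = "1",
    kind: str = "repeat", mean_len: int = 800,
) -> MaskTrack:
    """Random interval track whose union covers ~masked_fraction of [0, L)."""
    rng = np.random.default_rng(seed)
    if masked_fraction <= 0:
        return MaskTrack.empty(kind=kind)
    target = masked_fraction * L
    covered = np.zeros(L, dtype=bool)
    rows = []
    while covered.sum() < target:
        length = max(50, int(rng.exponential(mean_len)))
        length = min(length, int(target - covered.sum()) + 50, L)
        s = int(rng.integers(0, max(1, L - length)))
        e = s + length
        rows.append((chrom, s, e))
        covered[s:e] = True
    return MaskTrack(pd.DataFrame(rows, columns=["chrom", "start", "end"]), kind=kind)


def make_reference(L: int, seed: int = 0, repeat: tuple[int, int, int] | None = None
                   ) -> str:
    """Random nucleotide sequence; ``repeat=(src, dst, length)`` copies a
    segment (0-based) to plant an exact duplication for mappability tests."""
    rng = np.random.default_rng(seed)
    seq = rng.choice(list("ACGT"), size=L)
    if repeat:
        src, dst, length = repeat
        seq[dst:dst + length] = seq[src:src + length]
    return "".join(seq)
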