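"""Site- and genotype-level filters.

The hard-filter rule follows standard short-variant hard-filtering practice
relaxed to a 5-of-6 vote: a site passes when at least five of the six
criteria pass (QD >= 2; FS < 40; SOR < 4; MQ >= 40; MQRS in [-5, 5];
RPRS in [-3, 3]).  An absent statistic counts as passing — the rank-sum
annotations are undefined at sites without heterozygous calls, and treating
absence as failure would discard valid sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import MISSING, CohortPanel, GenotypeMatrix, MaskTrack, SiteQuality

#: default hard-filter thresholds (pass condition per statistic)
DEFAULT_THRESHOLDS = {
    "qd_min": 2.0,
    "fs_max": 40.0,      # strict: FS < 40
    "sor_max": 4.0,      # strict: SOR < 4
    "mq_min": 40.0,
    "mqrs_abs": 5.0,     # inclusive: |MQRS| <= 5
    "rprs_abs": 3.0,     # inclusive: |RPRS| <= 3
}

MIN_PASSING = 5


@dataclass
class FilterReport:
    """Bookkeeping for a filtering run."""

    n_input: int
    failing_per_filter: dict[str, int] = field(default_factory=dict)
    n_passing_filters: np.ndarray | None = None  # per site, 0..6
    kept_mask: np.ndarray | None = None
    stage_counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def record_stage(self, name: str, before: int, after: int) -> None:
        self.stage_counts[name] = (before, after)

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum()) if self.kept_mask is not None else self.n_input


def hard_filter_mask(
    sq: SiteQuality, thresholds: dict | None = None, min_passing: int = MIN_PASSING
) -> tuple[np.ndarray, FilterReport]:
    """5-of-6 hard filter over the six site-quality statistics.

    Returns the per-site pass mask and a report with per-filter failure
    counts and the per-site number of passing filters.  Absent (NaN)
    statistics pass by convention; negative FS/SOR/MQ values indicate
    malformed input and raise.
    """
    thr = dict(DEFAULT_THRESHOLDS)
    thr.update(thresholds or {})
    for name in ("fs", "sor", "mq"):
        vals = getattr(sq, name)
        if np.any(vals[np.isfinite(vals)] < 0):
            raise ValueError(f"negative {name.upper()} value: malformed input")

    def _pass(vals, cond):
        out = cond(vals)
        out[~np.isfinite(vals)] = True  # ABSENT counts as a pass
        return out

    passes = {
        "qd": _pass(sq.qd, lambda v: v >= thr["qd_min"]),
        "fs": _pass(sq.fs, lambda v: v < thr["fs_max"]),
        "sor": _pass(sq.sor, lambda v: v < thr["sor_max"]),
        "mq": _pass(sq.mq, lambda v: v >= thr["mq_min"]),
        "mqrs": _pass(sq.mqrs, lambda v: np.abs(v) <= thr["mqrs_abs"]),
        "rprs": _pass(sq.rprs, lambda v: np.abs(v) <= thr["rprs_abs"]),
    }
    n_pass = np.sum(list(passes.values()), axis=0).astype(np.int8)
    keep = n_pass >= min_passing
    report = FilterReport(
        n_input=sq.n_sites,
        failing_per_filter={k: int((~v).sum()) for k, v in passes.items()},
        n_passing_filters=n_pass,
        kept_mask=keep,
    )
    report.record_stage("hard_filter", sq.n_sites, int(keep.sum()))
    return keep, report


def mask_low_gq(gm: GenotypeMatrix, min_gq: int = 20) -> GenotypeMatrix:
    """Set dosages with genotype quality below ``min_gq`` to MISSING.

    The gq field itself is untouched; genotypes with no recorded GQ
    (gq < 0) are left as called.
    """
    low = (gm.gq >= 0) & (gm.gq < min_gq)
    dosage = gm.dosage.copy()
    dosage[low] = MISSING
    return GenotypeMatrix(
        chrom=gm.chrom, pos=gm.pos, ref_allele=gm.ref_allele,
        alt_allele=gm.alt_allele, dosage=dosage, gq=gm.gq,
        sample_ids=list(gm.sample_ids), is_snp=gm.is_snp,
        is_biallelic=gm.is_biallelic,
    )


def biallelic_segregating_filter(gm: GenotypeMatrix) -> np.ndarray:
    """Keep biallelic SNPs that segregate among called genotypes."""
    x, n = gm.alt_counts()
    return gm.is_snp & gm.is_biallelic & (x > 0) & (x < n)


def call_rate_filter(
    gm: GenotypeMatrix,
    panel: CohortPanel,
    min_rate: float = 0.75,
    min_cohorts: int = 5,
    per_cohort: bool = True,
) -> np.ndarray:
    """Cohort-aware call-rate rule.

    Default (``per_cohort=True``): a site is kept when its within-cohort
    call rate is at least ``min_rate`` in at least ``min_cohorts`` cohorts.
    The alternative reading (``per_cohort=False``) requires a global call
    rate of ``min_rate`` AND at least one call in ``min_cohorts`` cohorts.
    """
    cohorts = panel.cohorts
    if min_cohorts > len(cohorts):
        raise ValueError(
            f"min_cohorts={min_cohorts} exceeds cohort count {len(cohorts)}"
        )
    called = gm.dosage != MISSING
    cols = {c: [gm.sample_ids.index(s) for s in panel.samples_in(c)
                if s in gm.sample_ids] for c in cohorts}
    if per_cohort:
        ok = np.zeros(gm.n_sites, dtype=np.int32)
        for c, idx in cols.items():
            if not idx:
                continue
            rate = called[:, idx].mean(axis=1)
            ok += rate >= min_rate
        return ok >= min_cohorts
    global_rate = called.mean(axis=1)
    present = np.zeros(gm.n_sites, dtype=np.int32)
    for c, idx in cols.items():
        if idx:
            present += called[:, idx].any(axis=1)
    return (global_rate >= min_rate) & (present >= min_cohorts)


def apply_mask_track(gm: GenotypeMatrix, track: MaskTrack) -> np.ndarray:
    """Keep-mask: True for sites outside the track's interval union."""
    return ~track.contains(gm.chrom, gm.pos)


def compute_nonunique_track(
    sequence: str,
    k: int = 150,
    max_mismatch: int = 2,
    include_reverse_complement: bool = True,
    chrom: str = "1",
) -> MaskTrack:
    """Mark positions covered by any k-mer that maps non-uniquely.

    A k-mer maps non-uniquely when it matches the sequence (or, by default,
    its reverse complement) at some other offset with at most
    ``max_mismatch`` mismatches.  Every position covered by such a k-mer is
    masked.  Brute-force all-pairs comparison; intended for synthetic-scale
    references (up to ~100 kb).
    """
    L = len(sequence)
    if k > L:
        raise ValueError(f"k={k} exceeds sequence length {L}")
    code = np.frombuffer(sequence.encode(), dtype=np.uint8)
    n_kmers = L - k + 1
    ambiguous = np.zeros(n_kmers, dtype=bool)

    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGT", b"TGCA"):
        comp[a] = b
    rc = comp[code][::-1]

    # mismatch counts between k-mer pairs at a given shift, vectorised per shift
    for shift in range(1, n_kmers):
        diff = code[:-shift] != code[shift:]
        mm = np.convolve(diff.astype(np.int32), np.ones(k, dtype=np.int32), "valid")
        close = mm <= max_mismatch  # kmer at i vs kmer at i+shift
        if close.any():
            idx = np.nonzero(close)[0]
            ambiguous[idx] = True
            ambiguous[idx + shift] = True
    if include_reverse_complement:
        for shift in range(0, L - k + 1):
            # forward kmer at i vs rc-strand kmer starting at shift
            n = L - shift
            diff = code[: n] != rc[shift: shift + n]
            if len(diff) < k:
                continue
            mm = np.convolve(diff.astype(np.int32), np.ones(k, dtype=np.int32), "valid")
            close = mm <= max_mismatch
            if close.any():
                idx = np.nonzero(close)[0]
                # the rc kmer starting at rc-index shift+i occupies forward
                # positions [L - (shift+i) - k, L - (shift+i)); a k-mer that
                # rc-matches its own location (palindrome) is still unique
                fwd = L - (shift + idx) - k
                ok = fwd != idx
                ambiguous[idx[ok]] = True
                ambiguous[fwd[ok]] = True

    masked = np.zeros(L, dtype=bool)
    for i in np.nonzero(ambiguous)[0]:
        masked[i: i + k] = True
    # collapse to intervals (0-based half-open)
    rows = []
    in_run, start = False, 0
    for i in range(L + 1):
        on = masked[i] if i < L else False
        if on and not in_run:
            in_run, start = True, i
        elif not on and in_run:
            rows.append((chrom, start, i))
            in_run = False
    return MaskTrack(pd.DataFrame(rows, columns=["chrom", "start", "end"]),
                     kind="nonunique")


def run_site_filters(
    gm: GenotypeMatrix,
    sq: SiteQuality,
    panel: CohortPanel | None = None,
    mask: MaskTrack | None = None,
    thresholds: dict | None = None,
    min_gq: int = 20,
    min_rate: float = 0.75,
    min_cohorts: int | None = None,
    per_cohort: bool = True,
) -> tuple[GenotypeMatrix, SiteQuality, FilterReport]:
    """Full filtering cascade: hard filters, GQ masking, biallelic SNPs,
    call rate, interval masks.  Returns the filtered matrix plus a report."""
    report = FilterReport(n_input=gm.n_sites)
    keep, hard_rep = hard_filter_mask(sq, thresholds)
    report.failing_per_filter = hard_rep.failing_per_filter
    report.n_passing_filters = hard_rep.n_passing_filters
    report.record_stage("hard_filter", gm.n_sites, int(keep.sum()))

    masked = mask_low_gq(gm, min_gq=min_gq)
    before = int(keep.sum())
    keep &= biallelic_segregating_filter(masked)
    report.record_stage("biallelic_segregating", before, int(keep.sum()))

    if panel is not None:
        if min_cohorts is None:
            min_cohorts = max(1, len(panel.cohorts) - 1)
        before = int(keep.sum())
        keep &= call_rate_filter(masked, panel, min_rate=min_rate,
                                 min_cohorts=min_cohorts, per_cohort=per_cohort)
        report.record_stage("call_rate", before, int(keep.sum()))
    if mask is not None:
        before = int(keep.sum())
        keep &= apply_mask_track(masked, mask)
        report.record_stage("mask_track", before, int(keep.sum()))

    report.kept_mask = keep
    return masked.take_sites(keep), sq.take(keep), report
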