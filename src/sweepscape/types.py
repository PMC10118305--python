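"""Core in-memory containers for the sweep-scan pipeline.

Genotypes are stored unphased as alternate-allele dosages (0 for homozygous
reference, 1 for heterozygous, 2 for homozygous alternate) with ``MISSING``
(-1) as a distinct sentinel for uncalled genotypes.  Site coordinates are
1-based (VCF convention) internally; interval masks are 0-based half-open
(BED convention) with tested conversion helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: sentinel for an uncalled genotype dosage; never conflated with dosage 0
MISSING: int = -1

#: sentinel for an absent per-site quality statistic (rank-sum annotations
#: are undefined at sites without heterozygous calls)
ABSENT = np.nan

_VALID_ALLELES = frozenset("ACGT")


@dataclass
class GenotypeMatrix:
    """Diploid allele-dosage matrix, sites x samples.

    Attributes
    ----------
    chrom : np.ndarray of str, shape (n_sites,)
        Chromosome identifier per site.
    pos : np.ndarray of int, shape (n_sites,)
        1-based coordinate per site; strictly increasing within chromosome.
    ref_allele, alt_allele : np.ndarray of str, shape (n_sites,)
        Single-nucleotide alleles.  Sites flagged non-SNP or multi-allelic
        keep placeholder alleles and are dropped downstream.
    dosage : np.ndarray of int8, shape (n_sites, n_samples)
        Alternate-allele counts in {0, 1, 2} or MISSING.
    gq : np.ndarray of int16, shape (n_sites, n_samples)
        Phred-scaled genotype quality; -1 where absent.
    sample_ids : list of str
    is_snp : np.ndarray of bool
        False for records whose REF/ALT are not single nucleotides.
    is_biallelic : np.ndarray of bool
        False for records with more than one ALT allele.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    dosage: np.ndarray
    gq: np.ndarray
    sample_ids: list[str]
    is_snp: np.ndarray = None
    is_biallelic: np.ndarray = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (sites x samples)")
        self.gq = np.asarray(self.gq, dtype=np.int16)
        if self.gq.shape != self.dosage.shape:
            raise ValueError("gq and dosage dimensions differ")
        if self.is_snp is None:
            self.is_snp = np.ones(self.n_sites, dtype=bool)
        else:
            self.is_snp = np.asarray(self.is_snp, dtype=bool)
        if self.is_biallelic is None:
            self.is_biallelic = np.ones(self.n_sites, dtype=bool)
        else:
            self.is_biallelic = np.asarray(self.is_biallelic, dtype=bool)
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid dosage {self.dosage[i, j]} at site {i}, sample {j}"
            )
        self._check_sorted()

    def _check_sorted(self) -> None:
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                k = int(np.argmax(np.diff(p) <= 0))
                raise ValueError(
                    f"positions not strictly increasing on {c} near {p[k + 1]}"
                )

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[1]

    def take_sites(self, index) -> "GenotypeMatrix":
        """Subset to a site index or boolean mask, preserving order."""
        index = np.asarray(index)
        return GenotypeMatrix(
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref_allele=self.ref_allele[index],
            alt_allele=self.alt_allele[index],
            dosage=self.dosage[index],
            gq=self.gq[index],
            sample_ids=list(self.sample_ids),
            is_snp=self.is_snp[index],
            is_biallelic=self.is_biallelic[index],
        )

    def take_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        """Subset to the named samples, in the order given."""
        lookup = {s: k for k, s in enumerate(self.sample_ids)}
        missing = [s for s in names if s not in lookup]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        cols = [lookup[s] for s in names]
        return GenotypeMatrix(
            chrom=self.chrom,
            pos=self.pos,
            ref_allele=self.ref_allele,
            alt_allele=self.alt_allele,
            dosage=self.dosage[:, cols],
            gq=self.gq[:, cols],
            sample_ids=list(names),
            is_snp=self.is_snp,
            is_biallelic=self.is_biallelic,
        )

    def alt_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele count, called allele count) over all samples."""
        called = self.dosage != MISSING
        x = np.where(called, self.dosage, 0).sum(axis=1)
        n = 2 * called.sum(axis=1)
        return x, n


@dataclass
class SiteQuality:
    """The six per-site hard-filter statistics, NaN where absent.

    Fields mirror the standard short-variant annotations: quality by depth
    (qd), Fisher strand bias (fs), symmetric odds-ratio strand bias (sor),
    RMS mapping quality (mq), mapping-quality rank sum (mqrs) and read
    position rank sum (rprs).
    """

    qd: np.ndarray
    fs: np.ndarray
    sor: np.ndarray
    mq: np.ndarray
    mqrs: np.ndarray
    rprs: np.ndarray

    FIELDS = ("qd", "fs", "sor", "mq", "mqrs", "rprs")

    def __post_init__(self) -> None:
        arrays = [np.asarray(getattr(self, f), dtype=float) for f in self.FIELDS]
        n = {a.shape for a in arrays}
        if len(n) != 1:
            raise ValueError("site-quality fields have differing lengths")
        for f, a in zip(self.FIELDS, arrays):
            setattr(self, f, a)

    @property
    def n_sites(self) -> int:
        return self.qd.shape[0]

    def take(self, index) -> "SiteQuality":
        index = np.asarray(index)
        return SiteQuality(**{f: getattr(self, f)[index] for f in self.FIELDS})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({f: getattr(self, f) for f in self.FIELDS})


@dataclass
class CohortPanel:
    """Sample metadata: cohort label, continent, mean sequencing coverage."""

    table: pd.DataFrame  # index: sample id; columns: cohort, continent, mean_coverage

    REQUIRED = ("cohort", "continent", "mean_coverage")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"panel missing column {col!r}")
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def cohorts(self) -> list[str]:
        return list(pd.unique(self.table["cohort"]))

    def samples_in(self, cohort: str) -> list[str]:
        return list(self.table.index[self.table["cohort"] == cohort])

    def cohort_of(self, sample: str) -> str:
        return self.table.loc[sample, "cohort"]

    def continent_of(self, sample: str) -> str:
        return self.table.loc[sample, "continent"]

    def coverage_of(self, sample: str) -> float:
        return float(self.table.loc[sample, "mean_coverage"])


@dataclass
class MaskTrack:
    """Genomic intervals to exclude, 0-based half-open, union semantics."""

    intervals: pd.DataFrame  # columns: chrom, start, end
    kind: str = "repeat"  # {repeat, nonunique}

    def __post_init__(self) -> None:
        df = self.intervals
        if len(df) and (df["end"] <= df["start"]).any():
            bad = df[df["end"] <= df["start"]].iloc[0]
            raise ValueError(f"empty/negative interval {bad.start}-{bad.end}")
        if len(df) and (df["start"] < 0).any():
            raise ValueError("negative interval coordinate")

    @classmethod
    def empty(cls, kind: str = "repeat") -> "MaskTrack":
        return cls(pd.DataFrame({"chrom": [], "start": [], "end": []}), kind=kind)

    def merged(self, chrom: str) -> np.ndarray:
        """Disjoint sorted (start, end) pairs covering the union on a chromosome."""
        sub = self.intervals[self.intervals["chrom"] == chrom]
        if not len(sub):
            return np.empty((0, 2), dtype=np.int64)
        ivs = sub[["start", "end"]].to_numpy(dtype=np.int64)
        ivs = ivs[np.argsort(ivs[:, 0], kind="stable")]
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        return np.asarray(out, dtype=np.int64)

    def contains(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Boolean mask: is each 1-based position inside the (half-open) union?"""
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        hit = np.zeros(pos.shape, dtype=bool)
        for c in pd.unique(chrom):
            sel = chrom == c
            merged = self.merged(c)
            if not len(merged):
                continue
            zero_based = pos[sel] - 1
            k = np.searchsorted(merged[:, 0], zero_based, side="right") - 1
            ok = k >= 0
            inside = np.zeros(zero_based.shape, dtype=bool)
            inside[ok] = zero_based[ok] < merged[k[ok], 1]
            hit[sel] = inside
        return hit

    def masked_bases(self, chrom: str, start: int, end: int) -> int:
        """Union-covered bases within the 1-based inclusive span [start, end]."""
        merged = self.merged(chrom)
        lo, hi = start - 1, end  # half-open
        if not len(merged):
            return 0
        s = np.clip(merged[:, 0], lo, hi)
        e = np.clip(merged[:, 1], lo, hi)
        return int(np.maximum(e - s, 0).sum())


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass
class GeneSetCatalog:
    """term id -> set of gene ids; members absent from an annotation warn only."""

    sets: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.sets.items():
            self.sets[term] = set(genes)

    def terms(self) -> list[str]:
        return list(self.sets)


@dataclass
class RecombinationMap:
    """Per-chromosome monotone table of physical position -> cumulative cM."""

    tables: dict[str, pd.DataFrame]  # columns: pos (bp), cm

    def __post_init__(self) -> None:
        for c, t in self.tables.items():
            p = t["pos"].to_numpy()
            g = t["cm"].to_numpy()
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"map positions not increasing on {c}")
            if np.any(np.diff(g) < 0):
                raise ValueError(f"genetic positions decrease on {c}")

    def genetic_position(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Linear interpolation in cM; constant extrapolation past the ends."""
        t = self.tables[chrom]
        return np.interp(
            np.asarray(pos, dtype=float),
            t["pos"].to_numpy(dtype=float),
            t["cm"].to_numpy(dtype=float),
        )


def bed_to_internal(start: int, end: int) -> tuple[int, int]:
    """0-based half-open [start, end) -> 1-based inclusive (start+1, end)."""
    return start + 1, end


def internal_to_bed(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end
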