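"""Readers and writers for the standard formats the pipeline touches.

VCF 4.2 (FORMAT GT and GQ; INFO QD, FS, SOR, MQ, MQRankSum, ReadPosRankSum),
BED, GFF3, tab-separated panel / gene-set / recombination-map tables, and the
sweep-scan site table (position, derived count x, called alleles n, folded).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import (
    ABSENT,
    MISSING,
    CohortPanel,
    GeneModel,
    GeneSetCatalog,
    GenotypeMatrix,
    MaskTrack,
    RecombinationMap,
    SiteQuality,
)

_INFO_KEYS = {
    "qd": "QD",
    "fs": "FS",
    "sor": "SOR",
    "mq": "MQ",
    "mqrs": "MQRankSum",
    "rprs": "ReadPosRankSum",
}

_SNP_ALLELES = frozenset("ACGT")


def read_vcf(path) -> tuple[GenotypeMatrix, SiteQuality]:
    """Read a VCF into a GenotypeMatrix plus per-site quality statistics.

    Non-SNP and multi-allelic records are retained but flagged (``is_snp``,
    ``is_biallelic``) for downstream filtering; they are never decomposed.
    Uncalled genotypes map to MISSING; absent INFO keys map to NaN.
    Records must be sorted by chromosome then position.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)

    chrom, pos, ref, alt = [], [], [], []
    is_snp, is_biallelic = [], []
    dosages, gqs = [], []
    quality = {k: [] for k in _INFO_KEYS}

    last = {}
    for line_no, v in enumerate(vcf, start=1):
        if v.CHROM in last and v.POS <= last[v.CHROM] and chrom and chrom[-1] == v.CHROM:
            raise ValueError(
                f"unsorted VCF: {v.CHROM}:{v.POS} follows {v.CHROM}:{last[v.CHROM]}"
            )
        last[v.CHROM] = v.POS
        chrom.append(v.CHROM)
        pos.append(v.POS)
        alts = [a for a in v.ALT if a != "<NON_REF>"]
        biallelic = len(alts) == 1
        snp = (
            len(v.REF) == 1
            and v.REF in _SNP_ALLELES
            and all(len(a) == 1 and a in _SNP_ALLELES for a in alts)
            and len(alts) >= 1
        )
        ref.append(v.REF if len(v.REF) == 1 and v.REF in _SNP_ALLELES else "N")
        a0 = alts[0] if alts else "N"
        alt.append(a0 if len(a0) == 1 and a0 in _SNP_ALLELES else "N")
        is_snp.append(snp)
        is_biallelic.append(biallelic)

        # gts012=True: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt = np.asarray(v.gt_types, dtype=np.int8)
        if gt.shape[0] != len(samples):
            raise ValueError(f"malformed GT at record {line_no} ({v.CHROM}:{v.POS})")
        gt[gt == 3] = MISSING
        dosages.append(gt)

        q = v.gt_quals
        if q is None:
            gq = np.full(len(samples), -1, dtype=np.int16)
        else:
            q = np.asarray(q, dtype=float)
            q = np.where(np.isfinite(q) & (q >= 0), q, -1)
            gq = q.astype(np.int16)
        gqs.append(gq)

        for field, key in _INFO_KEYS.items():
            val = v.INFO.get(key)
            quality[field].append(float(val) if val is not None else ABSENT)

    n = len(chrom)
    gm = GenotypeMatrix(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref_allele=np.array(ref, dtype=object),
        alt_allele=np.array(alt, dtype=object),
        dosage=np.vstack(dosages) if n else np.empty((0, len(samples)), dtype=np.int8),
        gq=np.vstack(gqs) if n else np.empty((0, len(samples)), dtype=np.int16),
        sample_ids=samples,
        is_snp=np.array(is_snp, dtype=bool),
        is_biallelic=np.array(is_biallelic, dtype=bool),
    )
    sq = SiteQuality(**{k: np.array(v, dtype=float) for k, v in quality.items()})
    return gm, sq


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=QD,Number=1,Type=Float,Description="Variant quality by depth">
##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias (phred)">
##INFO=<ID=SOR,Number=1,Type=Float,Description="Symmetric odds ratio strand bias">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, sq: SiteQuality | None, path,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write an uncompressed VCF 4.2 consumable by :func:`read_vcf`."""
    if sq is not None and sq.n_sites != gm.n_sites:
        raise ValueError("site-quality length does not match genotype matrix")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_VCF_HEADER)
        contigs = contig_lengths or {}
        seen = list(pd.unique(gm.chrom)) if gm.n_sites else list(contigs)
        for c in seen:
            # a generous default length keeps htslib-based readers happy
            length = contigs.get(c, int(gm.pos[gm.chrom == c].max()) + 1000 if gm.n_sites else 1000)
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.sample_ids) + "\n")
        for i in range(gm.n_sites):
            info = []
            if sq is not None:
                for field, key in _INFO_KEYS.items():
                    val = getattr(sq, field)[i]
                    if np.isfinite(val):
                        info.append(f"{key}={val:.4g}")
            info_str = ";".join(info) if info else "."
            cells = []
            for j in range(gm.n_samples):
                gt = _GT_STRING[int(gm.dosage[i, j])]
                gq = int(gm.gq[i, j])
                cells.append(f"{gt}:{gq}" if gq >= 0 else f"{gt}:.")
            fh.write(
                f"{gm.chrom[i]}\t{gm.pos[i]}\t.\t{gm.ref_allele[i]}\t"
                f"{gm.alt_allele[i]}\t.\tPASS\t{info_str}\tGT:GQ\t"
                + "\t".join(cells) + "\n"
            )


def read_intervals(path, format: str):
    """Read a BED file into a MaskTrack, or GFF3 gene features into GeneModels.

    BED is 0-based half-open; GFF3 is 1-based inclusive.  A file whose lines
    do not match the declared format raises ValueError.
    """
    if format == "BED":
        return _read_bed(path)
    if format == "GFF3":
        return _read_gff3_genes(path)
    raise ValueError(f"unknown interval format {format!r}")


def _read_bed(path) -> MaskTrack:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: not a BED line (need >=3 columns)")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-numeric BED coordinates") from exc
            if start < 0:
                raise ValueError(f"{path}:{ln}: negative coordinate")
            if end <= start:
                raise ValueError(f"{path}:{ln}: end <= start")
            rows.append((parts[0], start, end))
    return MaskTrack(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def _read_gff3_genes(path) -> list[GeneModel]:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:
        raise ValueError(f"{path}: not parseable as GFF3: {exc}") from exc
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=feat.seqid,
                start=int(feat.start),
                end=int(feat.end),
                strand=feat.strand if feat.strand in "+-" else "+",
            )
        )
    if not genes:
        raise ValueError(f"{path}: no gene features found")
    return genes


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tsweepscape\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


def write_bed(track: MaskTrack, path) -> None:
    track.intervals.to_csv(path, sep="\t", header=False, index=False)


def read_panel(path) -> CohortPanel:
    """Read the tab-separated sample panel (sample, cohort, continent, mean_coverage)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    required = {"sample", "cohort", "continent", "mean_coverage"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel missing columns: {sorted(missing)}")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"duplicate sample id {dup!r}")
    return CohortPanel(df.set_index("sample"))


def write_panel(panel: CohortPanel, path) -> None:
    panel.table.rename_axis("sample").reset_index().to_csv(path, sep="\t", index=False)


def read_geneset(path, known_genes: Iterable[str] | None = None) -> GeneSetCatalog:
    """Read a tab-separated gene-set table: term_id<TAB>comma-separated gene ids.

    Members absent from ``known_genes`` (when given) raise a warning, never
    an error — annotation releases and curated sets routinely disagree.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"term_id", "gene_ids"} <= set(df.columns):
        raise ValueError("gene-set table needs columns term_id, gene_ids")
    if df["term_id"].duplicated().any():
        dup = df.loc[df["term_id"].duplicated(), "term_id"].iloc[0]
        raise ValueError(f"duplicate term {dup!r}")
    sets = {
        row.term_id: {g for g in str(row.gene_ids).split(",") if g}
        for row in df.itertuples()
    }
    if known_genes is not None:
        known = set(known_genes)
        for term, genes in sets.items():
            unknown = genes - known
            if unknown:
                warnings.warn(
                    f"gene set {term!r} names genes absent from the annotation: "
                    f"{sorted(unknown)[:5]}"
                )
    return GeneSetCatalog(sets)


def write_geneset(catalog: GeneSetCatalog, path) -> None:
    pd.DataFrame(
        {
            "term_id": list(catalog.sets),
            "gene_ids": [",".join(sorted(g)) for g in catalog.sets.values()],
        }
    ).to_csv(path, sep="\t", index=False)


def read_recomb_map(path) -> RecombinationMap:
    """Tab-separated map: chrom, pos (bp), cm (cumulative genetic position)."""
    df = pd.read_csv(path, sep="\t")
    if not {"chrom", "pos", "cm"} <= set(df.columns):
        raise ValueError("recombination map needs columns chrom, pos, cm")
    return RecombinationMap(
        {c: sub[["pos", "cm"]].reset_index(drop=True) for c, sub in df.groupby("chrom")}
    )


def export_clr_sites(gm: GenotypeMatrix, panel: CohortPanel, cohort: str,
                     folded: bool = True) -> pd.DataFrame:
    """Per-segregating-site table (position, x, n, folded) for the sweep scan.

    x is the alternate (or minor, when folded) allele count among called
    alleles n within the cohort; monomorphic sites are excluded.
    """
    members = panel.samples_in(cohort)
    if not members:
        raise ValueError(f"cohort {cohort!r} has no samples")
    sub = gm.take_samples(members)
    x, n = sub.alt_counts()
    if not (n > 0).any():
        raise ValueError(f"cohort {cohort!r} has zero called samples at every site")
    seg = (x > 0) & (x < n) & sub.is_snp & sub.is_biallelic
    x, n, pos = x[seg], n[seg], sub.pos[seg]
    if folded:
        x = np.minimum(x, n - x)
    return pd.DataFrame(
        {"position": pos, "x": x, "n": n, "folded": 1 if folded else 0}
    )
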