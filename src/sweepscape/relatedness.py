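"""KING-robust pairwise kinship and greedy relative pruning.

The between-family robust estimator uses only heterozygote and
opposite-homozygote counts over jointly called sites:

    phi_hat = (n_het_het - 2 * n_opp_hom) / (2 * m) + 1/2
              - (n_het_i + n_het_j) / (4 * m),      m = min(n_het_i, n_het_j)

It requires no allele-frequency estimates, which is what makes it robust to
population structure: duplicates give 0.5, parent-offspring ~0.25, and
unrelated individuals from differentiated populations stay near 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .types import MISSING, CohortPanel, GenotypeMatrix

#: default kinship cutoffs per continent; American samples are more inbred,
#: so a higher cutoff avoids flagging background relatedness
DEFAULT_CUTOFFS = {"Americas": 0.20, "Africa": 0.05}


@dataclass
class KinshipEstimate:
    sample_i: str
    sample_j: str
    phi_hat: float  # NaN when not estimable (m = 0)
    n_het_het: int
    n_opp_hom: int
    n_het_i: int
    n_het_j: int
    n_joint: int

    @property
    def estimable(self) -> bool:
        return np.isfinite(self.phi_hat)


def king_robust_kinship(
    dosage_i: np.ndarray, dosage_j: np.ndarray,
    sample_i: str = "i", sample_j: str = "j",
) -> KinshipEstimate:
    """KING-robust kinship from two dosage vectors.

    Counts are taken over sites where both genotypes are called.  When
    either sample has no heterozygous calls the estimate is undefined and
    returned as NaN (never silently 0).
    """
    di = np.asarray(dosage_i)
    dj = np.asarray(dosage_j)
    if di.shape != dj.shape:
        raise ValueError("dosage vectors differ in length")
    joint = (di != MISSING) & (dj != MISSING)
    di, dj = di[joint], dj[joint]
    het_i = di == 1
    het_j = dj == 1
    n_het_het = int((het_i & het_j).sum())
    n_opp_hom = int((((di == 0) & (dj == 2)) | ((di == 2) & (dj == 0))).sum())
    n_het_i = int(het_i.sum())
    n_het_j = int(het_j.sum())
    m = min(n_het_i, n_het_j)
    if m == 0:
        phi = float("nan")
    else:
        phi = (n_het_het - 2.0 * n_opp_hom) / (2.0 * m) + 0.5 \
            - (n_het_i + n_het_j) / (4.0 * m)
    return KinshipEstimate(sample_i, sample_j, phi, n_het_het, n_opp_hom,
                           n_het_i, n_het_j, int(joint.sum()))


def kinship_table(
    gm: GenotypeMatrix, chromosomes: list[str] | None = None
) -> pd.DataFrame:
    """All pairwise KING-robust estimates, optionally restricted to a
    chromosome subset (e.g. autosomes 2-3 to dodge a sex-determining region)."""
    if chromosomes is not None:
        gm = gm.take_sites(np.isin(gm.chrom, chromosomes))
    rows = []
    for a, b in combinations(range(gm.n_samples), 2):
        est = king_robust_kinship(
            gm.dosage[:, a], gm.dosage[:, b],
            gm.sample_ids[a], gm.sample_ids[b],
        )
        rows.append(
            {
                "sample_i": est.sample_i, "sample_j": est.sample_j,
                "phi_hat": est.phi_hat, "n_het_het": est.n_het_het,
                "n_opp_hom": est.n_opp_hom, "n_het_i": est.n_het_i,
                "n_het_j": est.n_het_j, "n_joint": est.n_joint,
            }
        )
    return pd.DataFrame(rows)


def prune_related(
    kinship: pd.DataFrame,
    panel: CohortPanel,
    cutoffs: dict[str, float] | None = None,
) -> set[str]:
    """Greedy removal of one member per related pair above the continent cutoff.

    Pairs are processed in descending phi_hat (ties by lexicographic pair
    id); a pair already broken by an earlier removal is skipped.  Within a
    pair the lower-coverage member is removed (coverage ties: the
    lexicographically later id).  A pair uses the stricter (smaller) cutoff
    when its members' continents disagree.
    """
    cutoffs = dict(DEFAULT_CUTOFFS if cutoffs is None else cutoffs)
    flagged = []
    for row in kinship.itertuples():
        if not np.isfinite(row.phi_hat):
            continue
        ci = panel.continent_of(row.sample_i)
        cj = panel.continent_of(row.sample_j)
        cut = min(cutoffs.get(ci, np.inf), cutoffs.get(cj, np.inf))
        if row.phi_hat > cut:
            flagged.append((row.phi_hat, row.sample_i, row.sample_j))
    flagged.sort(key=lambda t: (-t[0], t[1], t[2]))

    removed: set[str] = set()
    for phi, a, b in flagged:
        if a in removed or b in removed:
            continue
        cov_a, cov_b = panel.coverage_of(a), panel.coverage_of(b)
        if not np.isfinite(cov_a) or not np.isfinite(cov_b):
            raise ValueError(f"missing coverage for pair ({a}, {b})")
        if cov_a < cov_b:
            removed.add(a)
        elif cov_b < cov_a:
            removed.add(b)
        else:
            removed.add(max(a, b))
    return removed
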