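"""The repulsion statistic H_R^(j) for unphased diploid genotypes.

For every unordered pair of variants with derived allele count ``j``, the
same functional annotation, and a physical distance of at most 10 kb, count
the number of individuals that are heterozygous at *both* loci (``n11``,
coding genotypes 0 = homozygous ancestral, 1 = heterozygous, 2 = homozygous
derived).  H_R^(j) is the mean of ``n11`` over the ``l_j`` qualifying pairs:

    H_R^(j) = (1 / l_j) * sum_i n11^(i)

Two derived alleles that sit on different haplotypes of the same individual
are doubly heterozygous, so a depletion of H_R^(j) for deleterious variants
relative to neutral ones mirrors the depletion of coupling haplotypes that
``D'`` measures on phased data - without requiring phase.  Variants observed
only as homozygotes (possible for j >= 2) still enter pair enumeration; they
simply cannot contribute to ``n11``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ld import DEFAULT_MAX_BP, summarize_decay

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Unphased genotypes: ``n`` individuals x ``m`` sites, entries 0/1/2
    (derived-allele dosage) or -1 for missing.  ``sites`` carries at least
    ``position``, ``annotation`` and ``derived_count`` columns; the derived
    count of fully observed columns equals the column sum."""

    matrix: np.ndarray
    sites: pd.DataFrame
    chrom: str = "1"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise ValueError("genotype matrix must be 2-D")
        bad = ~np.isin(self.matrix, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype entries must be in {0, 1, 2} or -1")
        if "derived_count" not in self.sites.columns:
            m = np.where(self.matrix == MISSING, 0, self.matrix)
            self.sites = self.sites.assign(derived_count=m.sum(axis=0))

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def to_tsv(self, path) -> None:
        """Write as TSV: site metadata columns then one ``ind<i>`` dosage
        column per individual (-1 = missing)."""
        df = self.sites.copy()
        df.insert(0, "chrom", self.chrom)
        for i in range(self.n):
            df[f"ind{i}"] = self.matrix[i]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t")
        ind_cols = [c for c in df.columns if c.startswith("ind")]
        matrix = df[ind_cols].to_numpy(dtype=np.int8).T
        sites = df.drop(columns=ind_cols + ["chrom"])
        chrom = str(df["chrom"].iloc[0]) if len(df) else "1"
        return cls(matrix=matrix, sites=sites.reset_index(drop=True), chrom=chrom)


@dataclass(frozen=True)
class PairGenotypeCounts:
    """Two-locus genotype tallies over individuals (homozygous-derived
    configurations are tallied separately and never counted in ``n11``)."""

    n11: int
    n10: int
    n01: int
    n00: int
    n_other: int = 0


def pair_genotype_counts(gA: np.ndarray, gB: np.ndarray) -> PairGenotypeCounts:
    """Tally doubly/singly heterozygous and double-ancestral individuals."""
    gA = np.asarray(gA)
    gB = np.asarray(gB)
    if gA.shape != gB.shape or gA.ndim != 1:
        raise ValueError("genotype columns must be 1-D and of equal length")
    for g in (gA, gB):
        if not np.isin(g, [MISSING, 0, 1, 2]).all():
            raise ValueError("genotype entries must be in {0, 1, 2} or -1")
    hetA, hetB = gA == 1, gB == 1
    n11 = int(np.count_nonzero(hetA & hetB))
    n10 = int(np.count_nonzero(hetA & (gB == 0)))
    n01 = int(np.count_nonzero((gA == 0) & hetB))
    n00 = int(np.count_nonzero((gA == 0) & (gB == 0)))
    n_other = gA.shape[0] - n11 - n10 - n01 - n00
    return PairGenotypeCounts(n11=n11, n10=n10, n01=n01, n00=n00, n_other=n_other)


def enumerate_hr_pairs(
    genotypes: GenotypeMatrix,
    j: int,
    max_bp: int = DEFAULT_MAX_BP,
    annotation: str | None = None,
) -> pd.DataFrame:
    """Qualifying pairs for H_R^(j) with their ``n11`` counts.

    Pairs require derived allele count ``j`` at both sites, the same
    annotation (restricted to ``annotation`` if given), and distance
    ``<= max_bp`` (distance-0 pairs excluded).  Pairs with a missing
    genotype in either column at any individual are excluded.
    """
    sites = genotypes.sites
    counts = sites["derived_count"].to_numpy()
    pos = sites["position"].to_numpy()
    ann = sites["annotation"].to_numpy()
    G = genotypes.matrix
    rows = []
    groups = [annotation] if annotation is not None else list(pd.unique(ann))
    for a in groups:
        idx = np.flatnonzero((ann == a) & (counts == j))
        if idx.size < 2:
            continue
        order = np.argsort(pos[idx], kind="stable")
        idx = idx[order]
        p = pos[idx]
        sub = G[:, idx]
        het = (sub == 1).astype(np.int32)
        ok = ~(sub == MISSING).any(axis=0)
        n11_mat = het.T @ het
        hi = np.searchsorted(p, p + max_bp, side="right")
        for i in range(idx.size - 1):
            for k in range(i + 1, hi[i]):
                if p[k] == p[i]:
                    continue
                if not (ok[i] and ok[k]):
                    continue
                rows.append((a, p[i], p[k], p[k] - p[i], int(n11_mat[i, k])))
    return pd.DataFrame(
        rows, columns=["annotation", "pos_a", "pos_b", "bp_distance", "n11"]
    )


def compute_HR(
    genotypes: GenotypeMatrix,
    j: int,
    max_bp: int = DEFAULT_MAX_BP,
    annotation: str | None = None,
) -> tuple[float, int]:
    """H_R^(j) and the number of qualifying pairs ``l_j``.

    Returns ``(nan, 0)`` when no pair qualifies.
    """
    pairs = enumerate_hr_pairs(genotypes, j, max_bp=max_bp, annotation=annotation)
    l_j = len(pairs)
    if l_j == 0:
        return float("nan"), 0
    return float(pairs["n11"].mean()), l_j


def hr_decay(
    pairs: pd.DataFrame,
    bin_width: int = 1500,
    max_bp: int = DEFAULT_MAX_BP,
) -> pd.DataFrame:
    """Binned mean H_R (mean ``n11``) by physical distance (1.5 kb bins)."""
    edges = np.arange(0, max_bp + bin_width, bin_width, dtype=float)
    return summarize_decay(pairs, stat="n11", bins=edges)
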