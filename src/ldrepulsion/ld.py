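"""Two-locus linkage disequilibrium statistics on phased haplotypes.

All statistics are computed between *derived* alleles, so the sign of ``D``
and ``D'`` is informative: positive values mean the derived alleles co-occur
on haplotypes more often than expected under independence (coupling),
negative values mean they avoid each other (repulsion).

With ``p_A``, ``p_B`` the derived allele frequencies, ``p_AB`` the frequency
of the haplotype carrying both derived alleles and ``p_a = 1 - p_A`` etc.:

    D   = p_AB - p_A p_B
    r^2 = D^2 / (p_A p_a p_B p_b)
    D'  = D / min(p_A p_B, p_a p_b)  if D < 0
        = D / min(p_A p_b, p_a p_B)  if D > 0
        = 0                          if D = 0

A pair of derived doubletons that always co-occur has ``D' = 1``; one whose
derived alleles never share a haplotype has ``D' = -1``.

Pair enumeration follows the frequency-matching protocol: only pairs with
the same derived allele count, the same functional annotation and a physical
distance of at most 10 kb (inclusive) are compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_MAX_BP = 10_000


@dataclass(frozen=True)
class TwoLocusCounts:
    """Derived-allele frequencies of a pair of segregating sites."""

    pA: float
    pB: float
    pAB: float
    n_chrom: int

    def __post_init__(self) -> None:
        if not (0.0 < self.pA < 1.0 and 0.0 < self.pB < 1.0):
            raise ValueError("both sites must be segregating (0 < p < 1)")
        lo = max(0.0, self.pA + self.pB - 1.0)
        hi = min(self.pA, self.pB)
        if not (lo - 1e-12 <= self.pAB <= hi + 1e-12):
            raise ValueError("pAB outside feasible Frechet bounds")

    @property
    def pa(self) -> float:
        return 1.0 - self.pA

    @property
    def pb(self) -> float:
        return 1.0 - self.pB


def two_locus_counts(hapA: np.ndarray, hapB: np.ndarray) -> TwoLocusCounts:
    """Tally two-locus haplotype frequencies from 0/1 haplotype columns."""
    hapA = np.asarray(hapA)
    hapB = np.asarray(hapB)
    if hapA.shape != hapB.shape or hapA.ndim != 1:
        raise ValueError("haplotype columns must be 1-D and of equal length")
    n = hapA.shape[0]
    cA, cB = int(hapA.sum()), int(hapB.sum())
    if cA in (0, n) or cB in (0, n):
        raise ValueError("monomorphic column: LD undefined")
    cAB = int(np.count_nonzero((hapA == 1) & (hapB == 1)))
    return TwoLocusCounts(pA=cA / n, pB=cB / n, pAB=cAB / n, n_chrom=n)


def compute_D(c: TwoLocusCounts) -> float:
    return c.pAB - c.pA * c.pB


def compute_r2(c: TwoLocusCounts) -> float:
    D = compute_D(c)
    return D * D / (c.pA * c.pa * c.pB * c.pb)


def compute_Dprime(c: TwoLocusCounts) -> float:
    D = compute_D(c)
    if D < 0:
        return D / min(c.pA * c.pB, c.pa * c.pb)
    if D > 0:
        return D / min(c.pA * c.pb, c.pa * c.pB)
    return 0.0


# ------------------------------------------------------------------ #
def _pair_stats_vectorized(j: int, n_chrom: int, nAB: np.ndarray):
    """D, D', r^2 for equal-count pairs (count j) given co-occurrence counts."""
    p = j / n_chrom
    pAB = nAB / n_chrom
    D = pAB - p * p
    q = 1.0 - p
    r2 = D * D / (p * p * q * q)
    denom_neg = min(p * p, q * q)
    denom_pos = p * q  # min(p*q, q*p)
    Dprime = np.where(D < 0, D / denom_neg, np.where(D > 0, D / denom_pos, 0.0))
    return D, Dprime, r2


def enumerate_matched_pairs(
    sample,
    max_bp: int = DEFAULT_MAX_BP,
    allele_counts=None,
    annotations=("NS", "S"),
) -> pd.DataFrame:
    """Enumerate frequency-matched SNP pairs and their LD statistics.

    Pairs must share the derived allele count, share the annotation, lie on
    the same chromosome and be at most ``max_bp`` apart (inclusive; pairs at
    distance 0 are excluded).  Returns one row per pair with columns
    ``chrom, idx_a, idx_b, pos_a, pos_b, bp_distance, allele_count,
    annotation, D, Dprime, r2, n11``.

    ``sample`` is a :class:`~ldrepulsion.wf.HaplotypeSample`.
    """
    H = sample.haplotypes
    sites = sample.sites
    n_chrom = H.shape[0]
    counts = sites["derived_count"].to_numpy()
    pos = sites["position"].to_numpy()
    ann = sites["annotation"].to_numpy()
    if allele_counts is not None:
        allele_counts = set(int(a) for a in allele_counts)

    rows = []
    geno = H[0::2].astype(np.int16) + H[1::2].astype(np.int16)
    for a in annotations:
        for j in np.unique(counts[ann == a]):
            j = int(j)
            if j in (0, n_chrom):
                continue
            if allele_counts is not None and j not in allele_counts:
                continue
            idx = np.flatnonzero((ann == a) & (counts == j))
            if idx.size < 2:
                continue
            order = np.argsort(pos[idx], kind="stable")
            idx = idx[order]
            p = pos[idx]
            X = H[:, idx].astype(np.int32)
            nAB_mat = X.T @ X
            E = (geno[:, idx] == 1).astype(np.int32)
            n11_mat = E.T @ E
            # two-pointer window over sorted positions
            hi = np.searchsorted(p, p + max_bp, side="right")
            for i in range(idx.size - 1):
                for k in range(i + 1, hi[i]):
                    if p[k] == p[i]:
                        continue
                    rows.append(
                        (
                            i,
                            k,
                            idx[i],
                            idx[k],
                            p[i],
                            p[k],
                            j,
                            a,
                            nAB_mat[i, k],
                            n11_mat[i, k],
                        )
                    )
    if not rows:
        return pd.DataFrame(
            columns=[
                "chrom", "idx_a", "idx_b", "pos_a", "pos_b", "bp_distance",
                "allele_count", "annotation", "D", "Dprime", "r2", "n11",
            ]
        )
    raw = pd.DataFrame(
        rows,
        columns=["_i", "_k", "idx_a", "idx_b", "pos_a", "pos_b",
                 "allele_count", "annotation", "nAB", "n11"],
    )
    out_parts = []
    for j, grp in raw.groupby("allele_count"):
        D, Dp, r2 = _pair_stats_vectorized(int(j), n_chrom, grp["nAB"].to_numpy())
        part = grp[["idx_a", "idx_b", "pos_a", "pos_b", "allele_count",
                    "annotation", "n11"]].copy()
        part["D"], part["Dprime"], part["r2"] = D, Dp, r2
        out_parts.append(part)
    out = pd.concat(out_parts, ignore_index=True)
    out["bp_distance"] = out["pos_b"] - out["pos_a"]
    out["chrom"] = getattr(sample, "chrom", "1")
    cols = ["chrom", "idx_a", "idx_b", "pos_a", "pos_b", "bp_distance",
            "allele_count", "annotation", "D", "Dprime", "r2", "n11"]
    return out[cols].sort_values(["pos_a", "pos_b"], ignore_index=True)


# ------------------------------------------------------------------ #
def summarize_decay(
    records: pd.DataFrame,
    stat: str = "Dprime",
    bins=None,
    bin_by: str = "bp_distance",
    n_quantile_bins: int | None = None,
) -> pd.DataFrame:
    """Mean, SE and pair count of an LD statistic per distance bin.

    ``bins`` are explicit bin edges for ``bin_by`` (default: 1.5 kb physical
    bins up to 10 kb); alternatively ``n_quantile_bins`` cuts ``bin_by`` into
    quantile bins computed on the pooled records.  The SE of a single-pair
    bin is reported as 0; empty bins get ``n_pairs = 0`` and NaN mean.
    """
    if records.empty:
        return pd.DataFrame(columns=["bin_left", "bin_right", "bin_mid",
                                     "mean", "se", "n_pairs"])
    x = records[bin_by].to_numpy(dtype=float)
    if n_quantile_bins is not None:
        edges = np.unique(np.quantile(x, np.linspace(0, 1, n_quantile_bins + 1)))
        edges[-1] = np.nextafter(edges[-1], np.inf)
    elif bins is None:
        edges = np.arange(0, DEFAULT_MAX_BP + 1500, 1500, dtype=float)
    else:
        edges = np.asarray(bins, dtype=float)
    which = np.digitize(x, edges) - 1
    vals = records[stat].to_numpy(dtype=float)
    out = []
    for b in range(len(edges) - 1):
        v = vals[which == b]
        mid = 0.5 * (edges[b] + edges[b + 1])
        if v.size == 0:
            out.append((edges[b], edges[b + 1], mid, np.nan, np.nan, 0))
        else:
            se = 0.0 if v.size == 1 else float(np.std(v, ddof=1) / np.sqrt(v.size))
            out.append((edges[b], edges[b + 1], mid, float(v.mean()), se, v.size))
    return pd.DataFrame(out, columns=["bin_left", "bin_right", "bin_mid",
                                      "mean", "se", "n_pairs"])


def normalized_difference_in_D(
    ns_records: pd.DataFrame,
    s_records: pd.DataFrame,
    n_quantile_bins: int = 5,
    bin_by: str = "bp_distance",
) -> pd.DataFrame:
    """Per-bin ``(mean D_NS - mean D_S) / mean D_S``.

    Quantile bin edges are computed on the pooled NS+S records so both
    groups share bins.  Bins where ``mean D_S == 0`` are flagged NaN.
    """
    pooled = pd.concat([ns_records[bin_by], s_records[bin_by]])
    edges = np.unique(np.quantile(pooled.to_numpy(dtype=float),
                                  np.linspace(0, 1, n_quantile_bins + 1)))
    if edges.size < 2:  # all distances identical: one degenerate bin
        edges = np.array([edges[0], edges[0]])
    edges[-1] = np.nextafter(edges[-1], np.inf)
    ns = summarize_decay(ns_records, stat="D", bins=edges, bin_by=bin_by)
    s = summarize_decay(s_records, stat="D", bins=edges, bin_by=bin_by)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = (ns["mean"] - s["mean"]) / s["mean"]
    norm = norm.where(s["mean"] != 0, np.nan)
    return pd.DataFrame(
        {
            "bin_left": ns["bin_left"],
            "bin_right": ns["bin_right"],
            "bin_mid": ns["bin_mid"],
            "mean_D_ns": ns["mean"],
            "mean_D_s": s["mean"],
            "normalized_difference": norm,
            "n_pairs_ns": ns["n_pairs"],
            "n_pairs_s": s["n_pairs"],
        }
    )


def complete_repulsion_fraction(records: pd.DataFrame, tol: float = 1e-9) -> float:
    """Fraction of pairs in complete repulsion (``D' = -1``)."""
    if records.empty:
        raise ValueError("complete repulsion fraction undefined for empty input")
    dp = records["Dprime"].to_numpy(dtype=float)
    return float(np.mean(np.abs(dp + 1.0) < tol))
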