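"""Matched-pairs construction and the one-sided permutation test.

Every pair of NS SNPs is matched to a pair of S SNPs on the same chromosome
with the identical allele count, a physical pair-distance within 50 bp, and
(where the covariates are available) a genetic distance and mean B-value
within configurable calipers.  Matching is greedy without replacement in
ascending |delta bp| order with a deterministic tie-break, so two NS pairs
competing for one S candidate resolve in favour of the closer match.

The test statistic is the mean within-match difference of an LD statistic
(NS minus S).  The null distribution is built by independently flipping the
sign of each difference with probability 1/2 (swapping the NS/S labels
within a match); the alternative is one-sided, "NS lower than S".  For 20 or
fewer matches all ``2^k`` sign assignments are enumerated exactly; otherwise
a Monte-Carlo sample of ``B`` permutations is drawn and the add-one estimator
``p = (1 + #{T_perm <= T_obs}) / (B + 1)`` avoids zero p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EXACT_ENUMERATION_LIMIT = 20


@dataclass(frozen=True)
class Calipers:
    """Maximum allowed covariate discrepancies within a match.

    ``bp`` is a strict bound on |delta pair-distance| in base pairs.  ``cm``
    and ``bvalue`` bound |delta cM| and |delta mean B|; when None they
    default to 0.25 pooled standard deviations of the covariate (computed on
    the union of NS and S records), and are skipped entirely if the
    covariate column is absent.
    """

    bp: float = 50.0
    cm: float | None = None
    bvalue: float | None = None
    sd_fraction: float = 0.25


@dataclass
class MatchedPairSet:
    """NS pair records matched 1:1 to S pair records without replacement."""

    matches: pd.DataFrame  # ns_* and s_* columns plus deltas
    report: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.matches)

    def differences(self, stat: str) -> np.ndarray:
        return (
            self.matches[f"ns_{stat}"].to_numpy(dtype=float)
            - self.matches[f"s_{stat}"].to_numpy(dtype=float)
        )


@dataclass(frozen=True)
class PermutationResult:
    stat: str
    observed: float
    n_matches: int
    n_permutations: int
    p_value: float
    exact: bool
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "stat": self.stat,
            "observed_mean_difference": self.observed,
            "n_matches": self.n_matches,
            "n_permutations": self.n_permutations,
            "p_value": self.p_value,
            "exact": self.exact,
            "seed": self.seed,
        }


def _resolve_caliper(value, ns, s, column, sd_fraction):
    if value is not None:
        return float(value)
    pooled = pd.concat([ns[column], s[column]]).to_numpy(dtype=float)
    pooled = pooled[~np.isnan(pooled)]
    sd = float(np.std(pooled, ddof=1)) if pooled.size > 1 else 0.0
    return sd_fraction * sd if sd > 0 else np.inf


def build_matched_pairs(
    ns_records: pd.DataFrame,
    s_records: pd.DataFrame,
    calipers: Calipers | None = None,
    match_across_chromosomes: bool = False,
) -> MatchedPairSet:
    """Greedily match each NS SNP pair to one S SNP pair.

    Exact on (chromosome, allele count); caliper on |delta bp| (< ``bp``)
    and, when present in both tables, on |delta cM| and |delta mean B|.
    ``match_across_chromosomes=True`` drops the same-chromosome requirement;
    appropriate for pooled independent simulation replicates where each
    replicate is its own chromosome.
    """
    calipers = calipers or Calipers()
    attempted = len(ns_records)
    use_cm = "cm_distance" in ns_records.columns and "cm_distance" in s_records.columns
    use_b = "mean_bvalue" in ns_records.columns and "mean_bvalue" in s_records.columns
    cal_cm = (
        _resolve_caliper(calipers.cm, ns_records, s_records, "cm_distance",
                         calipers.sd_fraction)
        if use_cm else None
    )
    cal_b = (
        _resolve_caliper(calipers.bvalue, ns_records, s_records, "mean_bvalue",
                         calipers.sd_fraction)
        if use_b else None
    )

    edges = []
    group_cols = ["allele_count"] if match_across_chromosomes else ["chrom", "allele_count"]
    s_grouped = dict(tuple(s_records.groupby(group_cols)))
    for ns_i, ns_row in ns_records.iterrows():
        key = tuple(ns_row[c] for c in group_cols)
        cand = s_grouped.get(key if len(key) > 1 else key[0], None)
        if cand is None:
            cand = s_grouped.get(key)
        if cand is None:
            continue
        dbp = np.abs(cand["bp_distance"].to_numpy(dtype=float)
                     - float(ns_row["bp_distance"]))
        ok = dbp < calipers.bp
        if use_cm:
            dcm = np.abs(cand["cm_distance"].to_numpy(dtype=float)
                         - float(ns_row["cm_distance"]))
            ok &= dcm <= cal_cm
        if use_b:
            db = np.abs(cand["mean_bvalue"].to_numpy(dtype=float)
                        - float(ns_row["mean_bvalue"]))
            ok &= db <= cal_b
        for pos_in_cand in np.flatnonzero(ok):
            s_i = cand.index[pos_in_cand]
            edges.append((dbp[pos_in_cand], ns_i, s_i))

    # ascending-delta greedy assignment, deterministic tie-break on indices
    edges.sort(key=lambda e: (e[0], e[1], e[2]))
    used_ns: set = set()
    used_s: set = set()
    picked = []
    for dbp, ns_i, s_i in edges:
        if ns_i in used_ns or s_i in used_s:
            continue
        used_ns.add(ns_i)
        used_s.add(s_i)
        picked.append((ns_i, s_i, dbp))

    if picked:
        ns_part = ns_records.loc[[p[0] for p in picked]].add_prefix("ns_")
        s_part = s_records.loc[[p[1] for p in picked]].add_prefix("s_")
        matches = pd.concat(
            [ns_part.reset_index(drop=True), s_part.reset_index(drop=True)], axis=1
        )
        matches["delta_bp"] = [p[2] for p in picked]
        if use_cm:
            matches["delta_cm"] = (
                matches["ns_cm_distance"] - matches["s_cm_distance"]
            ).abs()
        if use_b:
            matches["delta_bvalue"] = (
                matches["ns_mean_bvalue"] - matches["s_mean_bvalue"]
            ).abs()
        # every emitted match satisfies every caliper
        assert (matches["delta_bp"] < calipers.bp).all()
        assert (matches["ns_allele_count"] == matches["s_allele_count"]).all()
        if not match_across_chromosomes:
            assert (matches["ns_chrom"] == matches["s_chrom"]).all()
        if use_cm:
            assert (matches["delta_cm"] <= cal_cm).all()
        if use_b:
            assert (matches["delta_bvalue"] <= cal_b).all()
    else:
        cols = (
            [f"ns_{c}" for c in ns_records.columns]
            + [f"s_{c}" for c in s_records.columns]
            + ["delta_bp"]
        )
        matches = pd.DataFrame(columns=cols)
    report = {
        "attempted": attempted,
        "matched": len(picked),
        "unmatched": attempted - len(picked),
        "caliper_bp": calipers.bp,
        "caliper_cm": cal_cm,
        "caliper_bvalue": cal_b,
    }
    return MatchedPairSet(matches=matches, report=report)


# ------------------------------------------------------------------ #
def permutation_test_differences(
    differences: np.ndarray,
    n_permutations: int = 10_000,
    seed: int | None = None,
    exact_limit: int = EXACT_ENUMERATION_LIMIT,
) -> tuple[float, float, bool]:
    """One-sided sign-flip test on within-match differences.

    Returns ``(observed mean, p-value, exact?)``.  The alternative is that
    the mean difference is below zero, so small means give small p.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one matched pair")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    t_obs = float(d.mean())
    k = d.size
    if k <= exact_limit:
        signs = ((np.arange(2**k)[:, None] >> np.arange(k)) & 1) * 2 - 1
        t_perm = (signs * d).mean(axis=1)
        p = float(np.count_nonzero(t_perm <= t_obs + 1e-12) / 2**k)
        return t_obs, p, True
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_permutations, k)) * 2 - 1
    t_perm = (signs * d).mean(axis=1)
    hits = int(np.count_nonzero(t_perm <= t_obs + 1e-12))
    p = (1 + hits) / (n_permutations + 1)
    return t_obs, float(p), False


def matched_permutation_test(
    matches: MatchedPairSet,
    stat: str = "Dprime",
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> PermutationResult:
    """Run the one-sided matched-pairs permutation test on ``stat``.

    ``stat`` is any column present as ``ns_<stat>`` / ``s_<stat>`` in the
    matched table (``D``, ``Dprime``, ``r2``, ``n11``).
    """
    d = matches.differences(stat)
    t_obs, p, exact = permutation_test_differences(
        d, n_permutations=n_permutations, seed=seed
    )
    return PermutationResult(
        stat=stat,
        observed=t_obs,
        n_matches=d.size,
        n_permutations=n_permutations,
        p_value=p,
        exact=exact,
        seed=seed,
    )
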