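"""End-to-end studies: replicated simulation analyses and empirical runs.

A *simulation study* runs ``n_replicates`` independent forward replicates,
pools frequency-matched SNP pairs, reports decay curves per annotation with
the grouped min/max convention (replicates split into ``n_groups`` groups;
each group contributes one mean; the envelope of group means is reported),
and optionally runs the matched-pairs permutation test.

An *empirical study* consumes a VCF (phased or unphased) plus optional
genetic map, B-value and mask tracks, and runs the polarize -> filter ->
pair -> covariate -> match -> permutation pipeline, writing all
intermediates as TSV/JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import ld as ld_mod
from .annotate import GeneticMap, IntervalTrack
from .matching import Calipers
from .model import InterferenceLD
from .wf import SimulationConfig, simulate

logger = logging.getLogger("ldrepulsion")


@dataclasses.dataclass
class StudyConfig:
    """Configuration for one simulation or empirical study."""

    mode: str = "simulate"  # or "empirical"
    sim: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    n_replicates: int = 150
    n_groups: int = 3
    # empirical inputs
    vcf: str | None = None
    phased: bool = True
    genetic_map: str | None = None
    bvalues: str | None = None
    mask: str | None = None
    # analysis switches
    stat: str = "Dprime"
    max_bp: int = ld_mod.DEFAULT_MAX_BP
    allele_counts: tuple = (1, 2, 3, 4, 5)
    minor_allele_count_max: int | None = 5
    n_permutations: int = 10_000
    calipers: Calipers = dataclasses.field(default_factory=Calipers)
    output_dir: str | None = None
    seed: int = 1


def _write(df: pd.DataFrame, outdir: Path | None, name: str) -> None:
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / name, sep="\t", index=False)


def _snapshot_config(config: "StudyConfig", outdir: Path | None) -> None:
    """Write the resolved study configuration as YAML."""
    if outdir is None:
        return
    import yaml

    raw = dataclasses.asdict(config)
    raw["sim"] = config.sim.to_dict()
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(raw, sort_keys=False))


def grouped_decay(
    pairs: pd.DataFrame,
    rep_col: str = "chrom",
    stat: str = "Dprime",
    n_groups: int = 3,
    bins=None,
) -> pd.DataFrame:
    """Per-bin mean with min/max envelope over replicate groups.

    Replicates (identified by ``rep_col``) are split round-robin into
    ``n_groups`` groups; the group means per bin give the envelope.
    """
    reps = pd.unique(pairs[rep_col])
    group_of = {r: i % n_groups for i, r in enumerate(sorted(reps))}
    rows = []
    for g in range(n_groups):
        members = [r for r, gi in group_of.items() if gi == g]
        sub = pairs[pairs[rep_col].isin(members)]
        if sub.empty:
            continue
        dec = ld_mod.summarize_decay(sub, stat=stat, bins=bins)
        dec["group"] = g
        rows.append(dec)
    allg = pd.concat(rows, ignore_index=True)
    out = (
        allg.groupby(["bin_left", "bin_right", "bin_mid"])
        .agg(
            mean=("mean", "mean"),
            min=("mean", "min"),
            max=("mean", "max"),
            n_pairs=("n_pairs", "sum"),
        )
        .reset_index()
    )
    return out


def run_simulation_study(config: StudyConfig) -> dict:
    """Replicated forward-simulation analysis.

    Returns a dict with the pooled pair table, per-annotation grouped decay
    curves, the matched set and the permutation result (None when no matches
    could be made).
    """
    outdir = Path(config.output_dir) if config.output_dir else None
    _snapshot_config(config, outdir)
    model = InterferenceLD.from_simulation(
        config.sim,
        n_replicates=config.n_replicates,
        max_bp=config.max_bp,
        allele_counts=config.allele_counts,
    )
    pairs = model.pairs()
    logger.info("pairs enumerated: %d", len(pairs))
    _write(pairs, outdir, "pairs.tsv")
    decay = {}
    for annot in ("NS", "S"):
        sub = pairs[pairs["annotation"] == annot]
        if sub.empty:
            continue
        decay[annot] = grouped_decay(
            sub, stat=config.stat, n_groups=config.n_groups
        )
        _write(decay[annot], outdir, f"decay_{annot}.tsv")
    result = model.fit(
        stat=config.stat,
        n_permutations=config.n_permutations,
        calipers=config.calipers,
        seed=config.seed,
    )
    logger.info("matched %d pairs", len(result.matched))
    if outdir is not None and result.test is not None:
        _write(result.matched.matches, outdir, "matched_pairs.tsv")
        (outdir / "permutation.json").write_text(
            json.dumps(result.test.to_dict(), indent=2)
        )
    return {
        "pairs": pairs,
        "decay": decay,
        "matched": result.matched,
        "test": result.test,
        "result": result,
    }


# ------------------------------------------------------------------ #
def downsample_to_empirical(
    sim_records: pd.DataFrame,
    target_composition: pd.DataFrame,
    n_resamples: int = 100,
    n_quantile_bins: int = 5,
    seed: int | None = None,
) -> dict:
    """Resample simulated pairs to an empirical allele-count composition.

    ``target_composition`` has columns ``annotation, allele_count, n_pairs``
    (e.g. the composition of an empirical data set).  Each resample draws,
    per (annotation, allele count) stratum, ``n_pairs`` simulated pairs with
    replacement, then computes the normalized difference in D per distance
    quantile bin.  Strata with an empty simulated pool are skipped with a
    warning.  Returns the per-resample tables and their envelope.
    """
    rng = np.random.default_rng(seed)
    tables = []
    for b in range(n_resamples):
        parts = []
        for row in target_composition.itertuples():
            pool = sim_records[
                (sim_records["annotation"] == row.annotation)
                & (sim_records["allele_count"] == row.allele_count)
            ]
            if pool.empty:
                logger.warning(
                    "no simulated pairs for %s count %s; stratum skipped",
                    row.annotation, row.allele_count,
                )
                continue
            take = rng.integers(0, len(pool), size=int(row.n_pairs))
            parts.append(pool.iloc[take])
        res = pd.concat(parts, ignore_index=True)
        ns = res[res["annotation"] == "NS"]
        s = res[res["annotation"] == "S"]
        tab = ld_mod.normalized_difference_in_D(ns, s, n_quantile_bins=n_quantile_bins)
        tab["resample"] = b
        tables.append(tab)
    stacked = pd.concat(tables, ignore_index=True)
    envelope = (
        stacked.groupby("bin_mid")["normalized_difference"]
        .agg(["mean", "min", "max"])
        .reset_index()
    )
    return {"resamples": stacked, "envelope": envelope}


# ------------------------------------------------------------------ #
def run_empirical_study(config: StudyConfig) -> dict:
    """VCF-driven analysis: polarize, filter, pair, annotate, match, test."""
    if config.vcf is None:
        raise ValueError("empirical mode requires a VCF path")
    outdir = Path(config.output_dir) if config.output_dir else None
    _snapshot_config(config, outdir)
    gmap = GeneticMap.from_tsv(config.genetic_map) if config.genetic_map else None
    bvals = IntervalTrack.from_bed(config.bvalues) if config.bvalues else None
    mask = IntervalTrack.from_bed(config.mask, value_col=None) if config.mask else None
    model = InterferenceLD.from_vcf(
        config.vcf,
        phased=config.phased,
        max_bp=config.max_bp,
        allele_counts=config.allele_counts,
        genetic_map=gmap,
        bvalues=bvals,
        mask=mask,
    )
    sample = model.samples[0]
    logger.info("sites after polarization: %d", sample.sites.shape[0])
    if config.minor_allele_count_max is not None:
        n_chrom = (
            sample.haplotypes.shape[0]
            if model.phased
            else 2 * sample.matrix.shape[0]
        )
        counts = sample.sites["derived_count"].to_numpy()
        mac = np.minimum(counts, n_chrom - counts)
        keep = mac <= config.minor_allele_count_max
        model.samples[0] = _subset_sample(sample, keep, model.phased)
        logger.info("sites after minor-allele-count filter: %d", int(keep.sum()))
    pairs = model.pairs()
    _write(pairs, outdir, "pairs.tsv")
    n_ns = int((pairs["annotation"] == "NS").sum())
    logger.info("pairs: %d NS, %d S", n_ns, len(pairs) - n_ns)
    if n_ns == 0:
        logger.warning("no NS pairs: matched-pairs test skipped")
        return {"pairs": pairs, "matched": None, "test": None, "result": None}
    result = model.fit(
        stat=config.stat,
        n_permutations=config.n_permutations,
        calipers=config.calipers,
        seed=config.seed,
    )
    if outdir is not None:
        _write(result.matched.matches, outdir, "matched_pairs.tsv")
        if result.test is not None:
            (outdir / "permutation.json").write_text(
                json.dumps(result.test.to_dict(), indent=2)
            )
    return {
        "pairs": pairs,
        "matched": result.matched,
        "test": result.test,
        "result": result,
    }


def _subset_sample(sample, keep, phased: bool):
    from .hr import GenotypeMatrix
    from .wf import HaplotypeSample

    sites = sample.sites[keep].reset_index(drop=True)
    if phased:
        return HaplotypeSample(
            haplotypes=sample.haplotypes[:, keep], sites=sites,
            chrom=sample.chrom, config=getattr(sample, "config", None),
        )
    return GenotypeMatrix(matrix=sample.matrix[:, keep], sites=sites,
                          chrom=sample.chrom)
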