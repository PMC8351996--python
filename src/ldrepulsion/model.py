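"""Model / Results interface for the interference analysis.

:class:`InterferenceLD` bundles one dataset (phased haplotypes and/or
unphased genotypes, possibly pooled over several chromosomes or simulation
replicates) and the analysis settings; :meth:`InterferenceLD.fit` runs pair
enumeration, covariate annotation, NS-to-S matching and the one-sided
permutation test, returning an :class:`InterferenceLDResults` that carries
the matched set, the observed mean difference, its permutation p-value and
decay summaries, with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import hr as hr_mod
from . import ld as ld_mod
from .annotate import GeneticMap, IntervalTrack, annotate_pairs, apply_mask
from .matching import (
    Calipers,
    MatchedPairSet,
    PermutationResult,
    build_matched_pairs,
    matched_permutation_test,
)
from .wf import HaplotypeSample, SimulationConfig, simulate


class InterferenceLD:
    """Test whether NS derived alleles are in excess repulsion relative to S.

    Parameters
    ----------
    samples
        One or more :class:`HaplotypeSample` (phased mode) **or**
        :class:`~ldrepulsion.hr.GenotypeMatrix` (unphased mode).  Multiple
        entries are pooled; each keeps its own chromosome label.
    max_bp
        Pair distance threshold in bp (inclusive; default 10,000).
    allele_counts
        Derived allele counts analysed (default 1..5, the low-frequency
        range where selection is strongest in a sample of 50).
    genetic_map, bvalues, mask
        Optional covariate tracks.  Masked-out sites are removed before
        pair enumeration; map and B-values become matching covariates.
    """

    def __init__(
        self,
        samples,
        max_bp: int = ld_mod.DEFAULT_MAX_BP,
        allele_counts=range(1, 6),
        genetic_map: GeneticMap | None = None,
        bvalues: IntervalTrack | None = None,
        mask: IntervalTrack | None = None,
    ):
        if not isinstance(samples, (list, tuple)):
            samples = [samples]
        if not samples:
            raise ValueError("need at least one sample")
        self.samples = list(samples)
        self.phased = isinstance(self.samples[0], HaplotypeSample)
        self.max_bp = int(max_bp)
        self.allele_counts = list(allele_counts)
        self.genetic_map = genetic_map
        self.bvalues = bvalues
        self.mask = mask

    # -------------------------------------------------------------- #
    @classmethod
    def from_simulation(
        cls,
        config: SimulationConfig,
        n_replicates: int = 1,
        phased: bool = True,
        progress: bool = False,
        **kwargs,
    ) -> "InterferenceLD":
        """Simulate ``n_replicates`` independent forward replicates (seeds
        ``config.seed, config.seed + 1, ...``) and pool them."""
        import dataclasses

        samples = []
        for i in range(n_replicates):
            cfg = dataclasses.replace(config, seed=config.seed + i)
            samp = simulate(cfg)
            samples.append(samp if phased else samp.genotypes())
            if progress:
                print(f"replicate {i + 1}/{n_replicates}: {samp.n_sites} sites")
        return cls(samples, **kwargs)

    @classmethod
    def from_vcf(cls, path, phased: bool = True, **kwargs) -> "InterferenceLD":
        from .io import read_genotype_vcf, read_phased_vcf

        sample = read_phased_vcf(path) if phased else read_genotype_vcf(path)
        return cls([sample], **kwargs)

    # -------------------------------------------------------------- #
    def _apply_mask(self, sample):
        if self.mask is None:
            return sample
        keep = apply_mask(self.mask, sample.chrom, sample.sites["position"].to_numpy())
        if self.phased:
            return HaplotypeSample(
                haplotypes=sample.haplotypes[:, keep],
                sites=sample.sites[keep].reset_index(drop=True),
                chrom=sample.chrom,
                config=getattr(sample, "config", None),
            )
        return hr_mod.GenotypeMatrix(
            matrix=sample.matrix[:, keep],
            sites=sample.sites[keep].reset_index(drop=True),
            chrom=sample.chrom,
        )

    def pairs(self) -> pd.DataFrame:
        """Frequency-matched SNP pairs with LD statistics and covariates,
        pooled over samples."""
        frames = []
        for sample in self.samples:
            sample = self._apply_mask(sample)
            if self.phased:
                df = ld_mod.enumerate_matched_pairs(
                    sample, max_bp=self.max_bp, allele_counts=self.allele_counts
                )
            else:
                parts = []
                for j in self.allele_counts:
                    for a in ("NS", "S"):
                        p = hr_mod.enumerate_hr_pairs(
                            sample, j, max_bp=self.max_bp, annotation=a
                        )
                        p["allele_count"] = j
                        parts.append(p)
                df = pd.concat(parts, ignore_index=True)
                df["chrom"] = sample.chrom
            frames.append(df)
        pooled = pd.concat(frames, ignore_index=True)
        return annotate_pairs(pooled, genetic_map=self.genetic_map, bvalues=self.bvalues)

    def fit(
        self,
        stat: str = "Dprime",
        n_permutations: int = 10_000,
        calipers: Calipers | None = None,
        match_across_chromosomes: bool | None = None,
        seed: int | None = None,
    ) -> "InterferenceLDResults":
        """Match NS pairs to S pairs and run the one-sided permutation test.

        ``match_across_chromosomes`` defaults to True when the model pools
        more than one sample (independent replicates), else False.
        """
        if not self.phased and stat != "n11":
            stat = "n11"
        pairs = self.pairs()
        ns = pairs[pairs["annotation"] == "NS"]
        s = pairs[pairs["annotation"] == "S"]
        if match_across_chromosomes is None:
            match_across_chromosomes = len(self.samples) > 1
        matched = build_matched_pairs(
            ns, s, calipers=calipers,
            match_across_chromosomes=match_across_chromosomes,
        )
        test = None
        if len(matched):
            test = matched_permutation_test(
                matched, stat=stat, n_permutations=n_permutations, seed=seed
            )
        return InterferenceLDResults(
            model=self, stat=stat, pairs=pairs, matched=matched, test=test
        )


@dataclass
class InterferenceLDResults:
    """Fitted matched-pairs comparison of NS and S linkage disequilibrium."""

    model: InterferenceLD
    stat: str
    pairs: pd.DataFrame
    matched: MatchedPairSet
    test: PermutationResult | None = None

    @property
    def observed_difference(self) -> float:
        return self.test.observed if self.test else float("nan")

    @property
    def p_value(self) -> float:
        return self.test.p_value if self.test else float("nan")

    @property
    def mean_ns(self) -> float:
        return float(self.matched.matches[f"ns_{self.stat}"].mean()) if len(self.matched) else float("nan")

    @property
    def mean_s(self) -> float:
        return float(self.matched.matches[f"s_{self.stat}"].mean()) if len(self.matched) else float("nan")

    def decay(self, stat: str | None = None, annotation: str = "NS", **kwargs
              ) -> pd.DataFrame:
        """Binned decay of an LD statistic for one annotation class."""
        sub = self.pairs[self.pairs["annotation"] == annotation]
        return ld_mod.summarize_decay(sub, stat=stat or self.stat, **kwargs)

    def normalized_difference_in_D(self, **kwargs) -> pd.DataFrame:
        ns = self.pairs[self.pairs["annotation"] == "NS"]
        s = self.pairs[self.pairs["annotation"] == "S"]
        return ld_mod.normalized_difference_in_D(ns, s, **kwargs)

    def summary(self) -> str:
        """Human-readable summary of the matched-pairs test."""
        rep = self.matched.report
        counts = self.pairs.groupby("annotation").size().to_dict()
        lines = [
            "Matched-pairs permutation test (one-sided: NS < S)",
            "=" * 52,
            f"statistic:            {self.stat}",
            f"SNP pairs (NS / S):   {counts.get('NS', 0)} / {counts.get('S', 0)}",
            f"matches attempted:    {rep.get('attempted', 0)}",
            f"matches made:         {rep.get('matched', 0)}",
            f"mean {self.stat} NS:  {self.mean_ns:10.5f}",
            f"mean {self.stat} S:   {self.mean_s:10.5f}",
        ]
        if self.test is not None:
            kind = "exact" if self.test.exact else f"B={self.test.n_permutations}"
            lines += [
                f"observed mean diff:   {self.test.observed:10.5f}",
                f"p-value ({kind}):  {self.test.p_value:.4g}",
            ]
        else:
            lines.append("no matches made; test not run")
        return "\n".join(lines)
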