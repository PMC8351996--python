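"""VCF and table I/O.

Simulated samples are exported as uncompressed phased VCF with INFO tags
``ANN`` (NS / S / NC), ``S`` (selection coefficient) and ``AA`` (ancestral
allele; always REF for simulated data, where haplotype state 1 is the
derived allele).  Reading goes through ``cyvcf2``; sites are re-polarized
from the ``AA`` tag on input, so a VCF whose ALT is the ancestral allele is
flipped to derived-allele encoding and sites without a high-confidence
ancestral allele are dropped.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .annotate import polarize_sites
from .hr import GenotypeMatrix
from .wf import HaplotypeSample, SimulationConfig

_REF, _ALT = "A", "G"


def write_vcf(sample: HaplotypeSample, path) -> None:
    """Write a phased sample as VCF (positions are 0-based internally and
    1-based in the file)."""
    n = sample.n
    cfg = sample.config
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=ANN,Number=1,Type=String,Description="Functional annotation: NS, S or NC">',
        '##INFO=<ID=S,Number=1,Type=Float,Description="Selection coefficient (unscaled)">',
        '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        f"##contig=<ID={sample.chrom},length={cfg.length if cfg else int(sample.sites.position.max()) + 1}>",
        "##source=ldrepulsion forward simulator",
    ]
    if cfg is not None:
        lines.append(f"##ldrepulsion_seed={cfg.seed}")
        lines.append(f"##ldrepulsion_rescale_factor={cfg.rescale_factor}")
    header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
                   "FORMAT"] + [f"ind{i}" for i in range(n)]
    lines.append("\t".join(header_cols))
    H = sample.haplotypes
    for col, site in enumerate(sample.sites.itertuples()):
        gts = "\t".join(
            f"{H[2 * i, col]}|{H[2 * i + 1, col]}" for i in range(n)
        )
        info = f"ANN={site.annotation};S={site.s:.10g};AA={_REF}"
        lines.append(
            f"{sample.chrom}\t{site.position + 1}\t.\t{_REF}\t{_ALT}\t.\tPASS\t{info}\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _read_records(path, aa_field: str, ann_field: str):
    vcf = VCF(str(path))
    recs, gts, phased = [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            continue  # biallelic only
        aa = v.INFO.get(aa_field)
        ann = v.INFO.get(ann_field)
        s = v.INFO.get("S")
        recs.append(
            {
                "chrom": v.CHROM,
                "position": v.POS - 1,
                "ref": v.REF,
                "alt": v.ALT[0],
                "aa": "." if aa is None else str(aa),
                "annotation": "NC" if ann is None else str(ann),
                "s": 0.0 if s is None else float(s),
            }
        )
        g = np.array(v.genotypes)  # (n, 3): allele_a, allele_b, phased
        gts.append(g[:, :2])
        phased.append(bool(g[:, 2].all()))
    vcf.close()
    if not recs:
        raise ValueError(f"no biallelic records in {path}")
    sites = pd.DataFrame(recs)
    alleles = np.stack(gts, axis=2)  # (n, 2, m)
    return sites, alleles, all(phased)


def read_phased_vcf(path, aa_field: str = "AA", ann_field: str = "ANN"
                    ) -> HaplotypeSample:
    """Read a phased VCF into a derived-oriented haplotype sample.

    Sites are polarized against ``aa_field``; flipped where ALT is
    ancestral; sites without a high-confidence ancestral allele, or not
    segregating in the sample, are dropped.
    """
    sites, alleles, is_phased = _read_records(path, aa_field, ann_field)
    if not is_phased:
        raise ValueError("unphased genotypes: use read_genotype_vcf")
    if (alleles < 0).any():
        raise ValueError("missing genotypes unsupported in phased input")
    pol = polarize_sites(sites)
    n, _, _ = alleles.shape
    H = np.empty((2 * n, len(pol)), dtype=np.uint8)
    for out_col, (idx, flip) in enumerate(zip(pol.index, pol["flip"])):
        a = alleles[:, :, idx]
        col = (1 - a) if flip else a
        H[0::2, out_col] = col[:, 0]
        H[1::2, out_col] = col[:, 1]
    counts = H.sum(axis=0)
    seg = (counts > 0) & (counts < 2 * n)
    pol = pol.reset_index(drop=True)[seg]
    H = H[:, seg.to_numpy() if hasattr(seg, "to_numpy") else seg]
    meta = pol[["position", "annotation", "s"]].reset_index(drop=True)
    chrom = str(sites["chrom"].iloc[0])
    return HaplotypeSample(haplotypes=H, sites=meta, chrom=chrom)


def read_genotype_vcf(path, aa_field: str = "AA", ann_field: str = "ANN"
                      ) -> GenotypeMatrix:
    """Read an (un)phased VCF into a derived-dosage genotype matrix
    (missing genotypes become -1)."""
    sites, alleles, _ = _read_records(path, aa_field, ann_field)
    pol = polarize_sites(sites)
    n = alleles.shape[0]
    G = np.empty((n, len(pol)), dtype=np.int8)
    for out_col, (idx, flip) in enumerate(zip(pol.index, pol["flip"])):
        a = alleles[:, :, idx]
        missing = (a < 0).any(axis=1)
        dosage = a.sum(axis=1)
        if flip:
            dosage = 2 - dosage
        dosage[missing] = -1
        G[:, out_col] = dosage
    obs = np.where(G < 0, 0, G)
    counts = obs.sum(axis=0)
    seg = (counts > 0) & (counts < 2 * n)
    pol = pol.reset_index(drop=True)[seg]
    G = G[:, np.asarray(seg)]
    meta = pol[["position", "annotation", "s"]].reset_index(drop=True)
    chrom = str(sites["chrom"].iloc[0])
    return GenotypeMatrix(matrix=G, sites=meta, chrom=chrom)


# ------------------------------------------------------------------ #
def save_config(config: SimulationConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
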