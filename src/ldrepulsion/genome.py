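"""Synthetic genome structure: genes with exons and introns separated by
intergenic spans.

The layout follows the classic gene-structure recipe used in forward
simulators, calibrated to the empirical distribution of exon and intron
lengths in eukaryotic genes (Deutsch & Long 1999):

* intergenic spacers: uniform on [100, 5000) bp
* exon lengths: ``int(lognormal(mean=log 50, sd=log 2)) + 1``
* intron lengths: ``int(lognormal(mean=log 100, sd=log 1.5)) + 10``
* after each exon, another intron+exon pair follows with probability 0.8

Coordinates are 0-based half-open and the elements tile the region exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EXON = "exon"
INTRON = "intron"
INTERGENIC = "intergenic"


@dataclass(frozen=True)
class GenomeStructure:
    """An ordered, gap-free tiling of ``[0, total_length)`` by genomic elements.

    Attributes
    ----------
    total_length
        Chromosome length in base pairs.
    elements
        List of ``(start, end, kind)`` with 0-based half-open coordinates and
        ``kind`` one of ``"exon"``, ``"intron"``, ``"intergenic"``.
    """

    total_length: int
    elements: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.total_length <= 0:
            raise ValueError("total_length must be positive")
        pos = 0
        for start, end, kind in self.elements:
            if start != pos or end <= start:
                raise ValueError("elements must tile [0, L) without gaps or overlaps")
            if kind not in (EXON, INTRON, INTERGENIC):
                raise ValueError(f"unknown element class {kind!r}")
            pos = end
        if self.elements and pos != self.total_length:
            raise ValueError("elements do not cover the full region")

    @property
    def exons(self) -> np.ndarray:
        """Exon intervals as an ``(k, 2)`` integer array."""
        ex = [(s, e) for s, e, kind in self.elements if kind == EXON]
        return np.asarray(ex, dtype=np.int64).reshape(-1, 2)

    @property
    def exonic_length(self) -> int:
        ex = self.exons
        return int((ex[:, 1] - ex[:, 0]).sum()) if len(ex) else 0

    def classify(self, positions: np.ndarray) -> np.ndarray:
        """Classify base-pair positions as exon / intron / intergenic."""
        starts = np.asarray([s for s, _, _ in self.elements])
        kinds = np.asarray([k for _, _, k in self.elements], dtype=object)
        idx = np.searchsorted(starts, np.asarray(positions), side="right") - 1
        return kinds[idx]


def build_genome_structure(seed: int, target_length: int = 5_000_000) -> GenomeStructure:
    """Generate a gene/intergenic tiling of ``[0, target_length)``.

    Genes are drawn until the target length is reached; the final element is
    truncated so the tiling covers the region exactly.  Deterministic for a
    given ``seed``.
    """
    target_length = int(target_length)
    if target_length <= 0:
        raise ValueError("target_length must be positive")
    rng = np.random.default_rng(seed)
    elements: list[tuple[int, int, str]] = []
    pos = 0

    def emit(length: int, kind: str) -> bool:
        nonlocal pos
        end = min(pos + length, target_length)
        if end > pos:
            elements.append((pos, end, kind))
            pos = end
        return pos >= target_length

    while pos < target_length:
        nc = int(rng.uniform(100, 5000))
        if emit(nc, INTERGENIC):
            break
        ex = int(rng.lognormal(np.log(50), np.log(2))) + 1
        if emit(ex, EXON):
            break
        while rng.uniform() < 0.8:
            intron = int(rng.lognormal(np.log(100), np.log(1.5))) + 10
            if emit(intron, INTRON):
                break
            ex = int(rng.lognormal(np.log(50), np.log(2))) + 1
            if emit(ex, EXON):
                break
        else:
            continue
        break

    # if truncation left us short (loop exits), pad with intergenic
    if pos < target_length:
        elements.append((pos, target_length, INTERGENIC))
    return GenomeStructure(total_length=target_length, elements=tuple(elements))
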