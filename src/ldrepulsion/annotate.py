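"""Site and pair covariates: derived-allele polarization, genetic distance,
background-selection B-values, and accessibility masks.

Coordinate conventions: VCF positions are 1-based; BED intervals are 0-based
half-open.  All internal coordinates are 0-based; converters live at I/O
boundaries.  B-value intervals are treated half-open ``[start, end)`` to
match BED.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


# ------------------------------------------------------------------ #
def polarize_sites(sites: pd.DataFrame) -> pd.DataFrame:
    """Orient sites to the derived allele using the ancestral-allele field.

    ``sites`` needs columns ``ref``, ``alt``, ``aa``.  Only uppercase
    single-base ancestral alleles are treated as high-confidence; sites with
    a lowercase / missing / malformed ancestral allele, or an ancestral
    allele matching neither REF nor ALT, are dropped.  The returned frame
    adds ``derived`` (the derived base) and ``flip`` (True where ALT is the
    ancestral allele, so genotype encodings must be inverted).
    """
    required = {"ref", "alt", "aa"}
    if not required.issubset(sites.columns):
        raise ValueError(f"polarize_sites requires columns {sorted(required)}")
    aa = sites["aa"].astype(str)
    high_conf = aa.str.fullmatch("[ACGT]").fillna(False)
    out = sites[high_conf].copy()
    matches_ref = out["aa"] == out["ref"]
    matches_alt = out["aa"] == out["alt"]
    out = out[matches_ref | matches_alt].copy()
    out["flip"] = out["aa"] == out["alt"]
    out["derived"] = np.where(out["flip"], out["ref"], out["alt"])
    return out


def flip_genotypes(matrix: np.ndarray, flip: np.ndarray, ploidy: int = 2) -> np.ndarray:
    """Invert derived-allele dosage (0 <-> ploidy) at flipped columns;
    missing entries (-1) are preserved.  Involution: flipping twice is the
    identity."""
    out = np.array(matrix, copy=True)
    cols = np.flatnonzero(np.asarray(flip))
    sub = out[:, cols]
    out[:, cols] = np.where(sub >= 0, ploidy - sub, sub)
    return out


# ------------------------------------------------------------------ #
@dataclass
class GeneticMap:
    """Per-chromosome piecewise-linear genetic map.

    Anchors are (bp position, cM) pairs with non-decreasing cM.  When built
    from sex-specific maps, male and female cM are averaged at the anchor
    level before interpolation.  Positions outside the anchored span get NaN
    (pairs involving them are dropped from cM-based analyses).
    """

    anchors: dict  # chrom -> (positions ndarray, cms ndarray)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GeneticMap":
        """Build from columns ``chrom, pos`` and either ``cm`` or
        ``cm_male`` + ``cm_female``."""
        if "cm" in frame.columns:
            cm = frame["cm"].astype(float)
        elif {"cm_male", "cm_female"}.issubset(frame.columns):
            cm = (frame["cm_male"].astype(float) + frame["cm_female"].astype(float)) / 2.0
        else:
            raise ValueError("need 'cm' or 'cm_male'+'cm_female' columns")
        frame = frame.assign(_cm=cm)
        anchors = {}
        for chrom, grp in frame.groupby("chrom"):
            grp = grp.sort_values("pos")
            pos = grp["pos"].to_numpy(dtype=np.int64)
            if len(np.unique(pos)) != len(pos):
                raise ValueError(f"duplicate anchor positions on {chrom}")
            cms = grp["_cm"].to_numpy(dtype=float)
            if np.any(np.diff(cms) < 0):
                raise ValueError(f"cM must be non-decreasing on {chrom}")
            anchors[str(chrom)] = (pos, cms)
        return cls(anchors=anchors)

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    @classmethod
    def uniform(cls, chrom: str, length: int, cm_per_mb: float) -> "GeneticMap":
        """Constant-rate map over ``[0, length]`` (convenient for simulated
        chromosomes)."""
        pos = np.array([0, length], dtype=np.int64)
        cms = np.array([0.0, cm_per_mb * length / 1e6])
        return cls(anchors={str(chrom): (pos, cms)})

    def interpolate(self, chrom: str, positions) -> np.ndarray:
        """cM coordinate at base-pair positions (NaN outside the span)."""
        positions = np.atleast_1d(np.asarray(positions, dtype=float))
        if str(chrom) not in self.anchors:
            return np.full(positions.shape, np.nan)
        pos, cms = self.anchors[str(chrom)]
        out = np.interp(positions, pos, cms)
        out[(positions < pos[0]) | (positions > pos[-1])] = np.nan
        return out

    def distance(self, chrom: str, pos_a, pos_b) -> np.ndarray:
        """Genetic distance in cM between two positions (NaN if either is
        outside the anchored span or the chromosome is unknown)."""
        a = self.interpolate(chrom, pos_a)
        b = self.interpolate(chrom, pos_b)
        return np.abs(b - a)


# ------------------------------------------------------------------ #
@dataclass
class IntervalTrack:
    """Non-overlapping half-open intervals per chromosome with a value."""

    intervals: dict  # chrom -> (starts, ends, values)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, value_col: str | None = "value"
                   ) -> "IntervalTrack":
        intervals = {}
        for chrom, grp in frame.groupby("chrom"):
            grp = grp.sort_values("start")
            starts = grp["start"].to_numpy(dtype=np.int64)
            ends = grp["end"].to_numpy(dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping intervals on {chrom}")
            vals = (
                grp[value_col].to_numpy(dtype=float)
                if value_col and value_col in grp.columns
                else np.ones(len(grp))
            )
            intervals[str(chrom)] = (starts, ends, vals)
        return cls(intervals=intervals)

    @classmethod
    def from_bed(cls, path, value_col: int | None = 3) -> "IntervalTrack":
        """Read a BED(-like) file; column 4, when present, is the value
        (e.g. a B-value)."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        cols = {0: "chrom", 1: "start", 2: "end"}
        if value_col is not None and value_col < df.shape[1]:
            cols[value_col] = "value"
        df = df.rename(columns=cols)
        return cls.from_frame(df, value_col="value" if "value" in df.columns else None)

    def value_at(self, chrom: str, positions) -> np.ndarray:
        """Value of the covering interval at each position; NaN if uncovered."""
        positions = np.atleast_1d(np.asarray(positions, dtype=np.int64))
        if str(chrom) not in self.intervals:
            return np.full(positions.shape, np.nan)
        starts, ends, vals = self.intervals[str(chrom)]
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
        out = np.full(positions.shape, np.nan)
        out[ok] = vals[idx[ok]]
        return out

    def contains(self, chrom: str, positions) -> np.ndarray:
        return ~np.isnan(self.value_at(chrom, positions))


BValueTrack = IntervalTrack


def annotate_bvalue(track: IntervalTrack, chrom: str, pos_a, pos_b) -> np.ndarray:
    """Mean B-value of the two sites of each pair (NaN propagates, so pairs
    with an uncovered site drop out of B-matched analyses)."""
    return 0.5 * (track.value_at(chrom, pos_a) + track.value_at(chrom, pos_b))


def apply_mask(mask: IntervalTrack, chrom: str, positions) -> np.ndarray:
    """Boolean keep-vector: True where the site falls inside the mask."""
    return mask.contains(chrom, positions)


def annotate_pairs(
    pairs: pd.DataFrame,
    genetic_map: GeneticMap | None = None,
    bvalues: IntervalTrack | None = None,
) -> pd.DataFrame:
    """Attach ``cm_distance`` and ``mean_bvalue`` columns to a pair table."""
    out = pairs.copy()
    if genetic_map is not None:
        cm = np.empty(len(out))
        for chrom, grp in out.groupby("chrom"):
            cm[grp.index] = genetic_map.distance(
                chrom, grp["pos_a"].to_numpy(), grp["pos_b"].to_numpy()
            )
        out["cm_distance"] = cm
    if bvalues is not None:
        bv = np.empty(len(out))
        for chrom, grp in out.groupby("chrom"):
            bv[grp.index] = annotate_bvalue(
                bvalues, chrom, grp["pos_a"].to_numpy(), grp["pos_b"].to_numpy()
            )
        out["mean_bvalue"] = bv
    return out
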