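"""Distribution of fitness effects (DFE) for new nonsynonymous mutations.

Two kinds are supported:

``fixed``
    every deleterious mutation gets the same selection coefficient
    (including ``s = 0`` for neutral control runs);
``gamma``
    selection coefficients are ``-Gamma(shape, scale)`` distributed.  The
    default parameters (shape 0.186, E[s] = -0.01314833) are a widely used
    human DFE estimate fitted to exome frequency spectra.

Selection coefficients of deleterious classes are always <= 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: human nonsynonymous DFE defaults (gamma over |s|)
GAMMA_SHAPE = 0.186
MEAN_S = -0.01314833


@dataclass(frozen=True)
class DFEModel:
    """Distribution of selection coefficients for new NS mutations.

    Parameters
    ----------
    kind
        ``"fixed"`` or ``"gamma"``.
    s_fixed
        Selection coefficient used when ``kind == "fixed"``; must be <= 0.
    gamma_shape, mean_s
        Shape and (negative) mean of the gamma DFE.
    h
        Dominance coefficient: 0.5 additive, 0.0 fully recessive.
    """

    kind: str = "gamma"
    s_fixed: float = 0.0
    gamma_shape: float = GAMMA_SHAPE
    mean_s: float = MEAN_S
    h: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "gamma"):
            raise ValueError(f"unknown DFE kind {self.kind!r}")
        if self.kind == "fixed" and self.s_fixed > 0:
            raise ValueError("deleterious class requires s_fixed <= 0")
        if self.kind == "gamma":
            if self.gamma_shape <= 0:
                raise ValueError("gamma_shape must be positive")
            if self.mean_s >= 0:
                raise ValueError("gamma DFE mean_s must be negative")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError("dominance coefficient h must be in [0, 1]")

    @property
    def gamma_scale(self) -> float:
        """Scale of the gamma over |s| (mean |s| / shape)."""
        return -self.mean_s / self.gamma_shape

    @classmethod
    def neutral(cls, h: float = 0.5) -> "DFEModel":
        return cls(kind="fixed", s_fixed=0.0, h=h)

    @classmethod
    def fixed(cls, s: float, h: float = 0.5) -> "DFEModel":
        return cls(kind="fixed", s_fixed=s, h=h)


def draw_selection_coefficients(
    dfe: DFEModel, count: int, seed_or_rng: int | np.random.Generator
) -> np.ndarray:
    """Draw ``count`` selection coefficients from ``dfe``.

    Gamma draws are strictly negative; fixed draws repeat ``s_fixed``.
    """
    if count <= 0:
        raise ValueError("count must be positive")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    if dfe.kind == "fixed":
        return np.full(count, dfe.s_fixed, dtype=np.float64)
    return -rng.gamma(dfe.gamma_shape, dfe.gamma_scale, size=count)
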