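"""Genetic design codings shared by the simulator and the association models.

The classical F-infinity parameterisation: with genotypes coded as
minor-allele counts g in {0, 1, 2},

* additive code  x = g - 1 in {-1, 0, +1}, so the additive effect ``a`` is
  half the difference between the two homozygote means;
* dominance code z = +1/2 for heterozygotes and -1/2 for either homozygote,
  so the dominance effect ``d`` is the heterozygote deviation from the
  homozygote midpoint.

Epistatic design columns are products of these single-locus codes
(x1*x2 = AxA, x1*z2 = AxD, z1*x2 = DxA, z1*z2 = DxD).
"""

from __future__ import annotations

import numpy as np


def additive_code(genotypes: np.ndarray) -> np.ndarray:
    """Map minor-allele counts {0,1,2} to {-1, 0, +1} (NaN passes through)."""
    g = np.asarray(genotypes, dtype=float)
    return g - 1.0


def dominance_code(genotypes: np.ndarray) -> np.ndarray:
    """Map {0,1,2} to {-1/2, +1/2, -1/2} (NaN passes through)."""
    g = np.asarray(genotypes, dtype=float)
    z = np.where(g == 1.0, 0.5, -0.5)
    return np.where(np.isnan(g), np.nan, z)
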