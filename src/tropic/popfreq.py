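"""Population frequency of repeat expansions.

Discovery cohorts are sequenced at 100-bp reads; population references are
typically 150 bp, which changes the anchored-IRR scale.  Values are mapped
onto the 100-bp scale with the linear conversion
AIR_100 = 0.5 + 1.5 x AIR_150, loci are matched by padded-interval overlap
plus canonical-motif identity, and a population sample counts as expanded
when its converted AIR exceeds the 99th percentile of the reference normals.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .motifs import TandemRepeatLocus

__all__ = [
    "PopFreqConfig",
    "convert_air_read_length",
    "match_loci",
    "population_frequency",
]


@dataclasses.dataclass
class PopFreqConfig:
    conversion_intercept: float = 0.5
    conversion_slope: float = 1.5
    pad: int = 1000
    percentile: float = 99.0

    def __post_init__(self):
        if self.conversion_slope <= 0:
            raise ValueError("conversion slope must be positive")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must lie strictly between 0 and 100")


def convert_air_read_length(air_150, config: PopFreqConfig | None = None):
    """Map a 150-bp-read AIR value onto the 100-bp scale (0.5 + 1.5 x value)."""
    config = config or PopFreqConfig()
    a = np.asarray(air_150, dtype=float)
    if np.any(a < 0):
        raise ValueError("anchored-IRR values must be non-negative")
    out = config.conversion_intercept + config.conversion_slope * a
    return float(out) if out.ndim == 0 else out


def match_loci(
    rre_loci: list[TandemRepeatLocus],
    population_loci: list[TandemRepeatLocus],
    pad: int = 1000,
) -> pd.DataFrame:
    """All (discovery, population) locus pairs whose padded intervals overlap.

    Both intervals are padded by ``pad`` bp; overlap uses half-open
    semantics, and canonical motifs must be identical.  One discovery locus
    may match several population loci; every match is reported.  Catalogues
    must share one genome assembly.
    """
    rows = []
    for i, a in enumerate(rre_loci):
        for j, b in enumerate(population_loci):
            if a.chrom != b.chrom or a.motif != b.motif:
                continue
            if max(a.start - pad, 0) < b.end + pad and max(b.start - pad, 0) < a.end + pad:
                rows.append(
                    {
                        "rre_index": i,
                        "rre_locus": a.locus_id,
                        "population_index": j,
                        "population_locus": b.locus_id,
                    }
                )
    return pd.DataFrame(rows, columns=["rre_index", "rre_locus",
                                       "population_index", "population_locus"])


def population_frequency(
    population_airs,
    reference_normal_airs,
    config: PopFreqConfig | None = None,
) -> float:
    """Fraction of population samples with AIR above the reference percentile.

    The threshold is the ``config.percentile``-th percentile (linear
    interpolation between closest ranks) of the reference normals; the
    exceedance is strict.  Population values must already be on the
    reference read-length scale.
    """
    config = config or PopFreqConfig()
    ref = np.asarray(reference_normal_airs, dtype=float)
    pop = np.asarray(population_airs, dtype=float)
    if ref.size == 0:
        raise ValueError("reference normal values must be non-empty")
    threshold = float(np.percentile(ref, config.percentile, method="linear"))
    return float(np.count_nonzero(pop > threshold) / pop.size)
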