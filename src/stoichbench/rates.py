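"""Ground-truth modification rates from two separately mapped read pools.

The target stoichiometry at a position is estimated by counting, among all
reads covering that position, the fraction that originate from the fully
modified pool: ``rate = n_mod / (n_mod + n_unmod)``.  Positions with no
coverage have no rate at all — "unobserved" is distinct from "unmodified".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bedrmod import SiteRecord
from .simulate import PositionCounts

__all__ = ["RateVector", "pileup", "compute_rates", "rates_to_bedrmod"]


@dataclass
class RateVector:
    """Per-position modification rate (NaN where uncovered) plus coverage."""

    rate: np.ndarray
    coverage: np.ndarray

    def __len__(self) -> int:
        return len(self.rate)

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of positions with at least one covering read."""
        return self.coverage > 0


def pileup(reads: pd.DataFrame, reference_length: int) -> PositionCounts:
    """Count covering reads per position and origin pool, half-open spans.

    Rejects reads whose span leaves [0, reference_length), naming the read.
    """
    n_mod = np.zeros(reference_length + 1, dtype=np.int64)
    n_unmod = np.zeros(reference_length + 1, dtype=np.int64)
    for row in reads.itertuples(index=False):
        if not (0 <= row.start < row.end <= reference_length):
            raise ValueError(
                f"read '{row.read_id}' span [{row.start}, {row.end}) outside reference "
                f"of length {reference_length}"
            )
        target = n_mod if row.origin == "modified" else n_unmod
        target[row.start] += 1
        target[row.end] -= 1
    return PositionCounts(np.cumsum(n_mod[:-1]), np.cumsum(n_unmod[:-1]))


def compute_rates(counts: PositionCounts) -> RateVector:
    """Modification ratio per position: n_mod / (n_mod + n_unmod).

    Zero-coverage positions get NaN, not 0.
    """
    total = counts.n_mod + counts.n_unmod
    with np.errstate(invalid="ignore"):
        rate = np.where(total > 0, counts.n_mod / np.maximum(total, 1), np.nan)
    return RateVector(rate=rate, coverage=total)


def rates_to_bedrmod(
    rates: RateVector,
    mod_name: str,
    chrom: str,
    min_coverage: int = 10,
) -> list[SiteRecord]:
    """Emit one bedRMod record per covered position with rate > 0.

    The ``min_coverage`` gate (default 10 reads) suppresses positions whose
    ratio estimate rests on too few reads.
    """
    if min_coverage < 0:
        raise ValueError("min_coverage must be >= 0")
    records = []
    for pos in np.nonzero(rates.defined)[0]:
        rate = float(rates.rate[pos])
        cov = int(rates.coverage[pos])
        if rate > 0 and cov >= min_coverage:
            records.append(SiteRecord.from_frequency(chrom, int(pos), mod_name, cov, rate))
    return records
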