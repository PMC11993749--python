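"""Synthetic challenge datasets with known per-position stoichiometry.

The real challenge datasets mix reads from two sequencing runs of the same
construct — one with every target base carrying the modification, one fully
unmodified — so that each reference position ends up with a known fraction of
modified reads.  This module reproduces that setup at the read/alignment
abstraction: each simulated read records its origin pool and aligned span, and
stoichiometry emerges from the mixture.  A controlled-rate mode draws
per-position counts directly from a binomial, for estimator calibration.

Three packaged profiles mirror the published challenge layouts: a 2438-nt
reference whose core contains all 256 5-mers with the target base central,
with 243 of the 256 block positions carrying target frequencies drawn from the
per-challenge range (m5C 0.12-0.33, m6A 0.01-0.1, pseudouridine 0.31-0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bedrmod import SiteRecord
from .design import ReferenceDesign, build_reference, enumerate_central_kmers, random_dna

__all__ = [
    "RateProfile",
    "PositionCounts",
    "ChallengeSpec",
    "CHALLENGE_PROFILES",
    "make_rate_profile",
    "build_challenge",
    "simulate_controlled",
    "simulate_transcript_mixture",
    "split_reads",
    "perturb_truth",
]

READ_TABLE_COLUMNS = ["read_id", "origin", "start", "end"]


@dataclass
class RateProfile:
    """Per-position true modification rates; absent positions are unmodified."""

    reference_name: str
    length: int
    rates: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pos, rate in self.rates.items():
            if not 0 <= pos < self.length:
                raise ValueError(f"position {pos} outside reference of length {self.length}")
            if not 0.0 < rate <= 1.0:
                raise ValueError(f"rate {rate} at position {pos} outside (0, 1]")

    @property
    def positions(self) -> list[int]:
        return sorted(self.rates)

    def to_records(self, mod_name: str, coverage: int) -> list[SiteRecord]:
        """Truth sites as bedRMod records with a nominal coverage."""
        return [
            SiteRecord.from_frequency(self.reference_name, pos, mod_name, coverage, self.rates[pos])
            for pos in self.positions
        ]


@dataclass
class PositionCounts:
    """Per-position read counts from the modified and unmodified pools."""

    n_mod: np.ndarray
    n_unmod: np.ndarray

    def __post_init__(self) -> None:
        self.n_mod = np.asarray(self.n_mod, dtype=np.int64)
        self.n_unmod = np.asarray(self.n_unmod, dtype=np.int64)
        if self.n_mod.shape != self.n_unmod.shape:
            raise ValueError("count arrays differ in length")
        if (self.n_mod < 0).any() or (self.n_unmod < 0).any():
            raise ValueError("negative counts")

    def __len__(self) -> int:
        return len(self.n_mod)

    def __add__(self, other: "PositionCounts") -> "PositionCounts":
        return PositionCounts(self.n_mod + other.n_mod, self.n_unmod + other.n_unmod)


@dataclass(frozen=True)
class ChallengeSpec:
    """Layout parameters of one packaged challenge profile."""

    name: str
    mod_name: str
    central_base: str
    range_min: float
    range_max: float
    n_targets: int = 243
    ref_length: int = 2438
    k: int = 5


CHALLENGE_PROFILES: dict[str, ChallengeSpec] = {
    "challenge1": ChallengeSpec("challenge1", "m5C", "C", 0.12, 0.33),
    "challenge2": ChallengeSpec("challenge2", "m6A", "A", 0.01, 0.10),
    "challenge3": ChallengeSpec("challenge3", "psi", "T", 0.31, 0.50),
}


def make_rate_profile(
    positions: list[int],
    range_min: float,
    range_max: float,
    seed: int,
    reference_name: str = "ref",
    length: int | None = None,
    anchor_endpoints: bool = False,
) -> RateProfile:
    """Assign each position a rate drawn uniformly from [range_min, range_max].

    With ``anchor_endpoints`` two distinct positions (seeded choice) receive
    exactly ``range_min`` and ``range_max``, so the profile's extreme rates
    equal the declared range endpoints.
    """
    if not positions:
        raise ValueError("no positions given")
    if not 0.0 < range_min <= range_max <= 1.0:
        raise ValueError(f"invalid rate range [{range_min}, {range_max}]")
    if length is None:
        length = max(positions) + 1
    rng = np.random.default_rng(seed)
    draws = rng.uniform(range_min, range_max, size=len(positions))
    rates = dict(zip(positions, draws))
    if anchor_endpoints:
        if len(positions) < 2 and range_min != range_max:
            raise ValueError("endpoint anchoring needs at least two positions")
        lo_idx, hi_idx = (
            rng.choice(len(positions), size=2, replace=False)
            if len(positions) >= 2
            else (0, 0)
        )
        rates[positions[int(lo_idx)]] = range_min
        rates[positions[int(hi_idx)]] = range_max
    return RateProfile(reference_name=reference_name, length=length, rates=rates)


def build_challenge(
    profile: str | ChallengeSpec, seed: int, anchor_endpoints: bool = False
) -> tuple[ReferenceDesign, RateProfile]:
    """Instantiate a packaged challenge: reference design plus rate profile.

    The all-5-mer core (1280 nt) is padded with seeded random flanks to the
    published reference length, and a seeded subset of block positions is
    retained as modification targets.
    """
    spec = CHALLENGE_PROFILES[profile] if isinstance(profile, str) else profile
    rng = np.random.default_rng(seed)
    core_len = 4 ** (spec.k - 1) * spec.k
    pad = spec.ref_length - core_len
    if pad < 0:
        raise ValueError(f"reference length {spec.ref_length} smaller than core {core_len}")
    flank_5p = random_dna(pad // 2, rng)
    flank_3p = random_dna(pad - pad // 2, rng)
    design = build_reference(
        enumerate_central_kmers(spec.central_base, spec.k),
        name=spec.name,
        flank_5p=flank_5p,
        flank_3p=flank_3p,
    )
    chosen = rng.choice(len(design.block_positions), size=spec.n_targets, replace=False)
    target_positions = sorted(design.block_positions[i] for i in chosen)
    profile_seed = int(rng.integers(0, 2**31 - 1))
    rate_profile = make_rate_profile(
        target_positions,
        spec.range_min,
        spec.range_max,
        seed=profile_seed,
        reference_name=spec.name,
        length=spec.ref_length,
        anchor_endpoints=anchor_endpoints,
    )
    return design, rate_profile


def simulate_controlled(profile: RateProfile, coverage: int, seed: int) -> PositionCounts:
    """Draw per-position counts at fixed coverage: n_mod ~ Binomial(coverage, rate).

    Unprofiled positions get all-unmodified coverage.
    """
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    rng = np.random.default_rng(seed)
    n_mod = np.zeros(profile.length, dtype=np.int64)
    positions = profile.positions
    if positions:
        rates = np.array([profile.rates[p] for p in positions])
        n_mod[positions] = rng.binomial(coverage, rates)
    n_unmod = np.full(profile.length, coverage, dtype=np.int64) - n_mod
    return PositionCounts(n_mod, n_unmod)


def simulate_transcript_mixture(
    design: ReferenceDesign,
    n_mod_reads: int,
    n_unmod_reads: int,
    truncation_mean: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a mixed read pool over a designed reference.

    Direct RNA sequencing reads the transcript 3'->5', so incomplete reads
    lose their 5' end.  Each read here keeps the full 3' end (``end = L``) and
    starts at a geometric 5' offset with the given mean (0 disables
    truncation), which makes per-position mixing ratios vary along the
    reference.  Returns a ReadTable: columns read_id, origin, start, end.
    """
    if n_mod_reads < 0 or n_unmod_reads < 0:
        raise ValueError("read counts must be >= 0")
    if truncation_mean < 0:
        raise ValueError("truncation mean must be >= 0")
    rng = np.random.default_rng(seed)
    length = len(design)
    rows = []
    for origin, n in (("modified", n_mod_reads), ("unmodified", n_unmod_reads)):
        if truncation_mean > 0:
            offsets = rng.geometric(1.0 / (1.0 + truncation_mean), size=n) - 1
            offsets = np.minimum(offsets, length - 1)
        else:
            offsets = np.zeros(n, dtype=np.int64)
        for i, off in enumerate(offsets):
            rows.append((f"{origin[:5]}_{i:06d}", origin, int(off), length))
    return pd.DataFrame(rows, columns=READ_TABLE_COLUMNS)


def split_reads(
    reads: pd.DataFrame, train_frac: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded disjoint train/test partition of a ReadTable.

    ``|train| = round(train_frac * n)`` with round-half-away-from-zero; rows
    keep their input order within each part.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    n = len(reads)
    if n == 0:
        empty = reads.iloc[0:0]
        return empty.copy(), empty.copy()
    n_train = int(np.floor(train_frac * n + 0.5))
    rng = np.random.default_rng(seed)
    train_idx = np.sort(rng.permutation(n)[:n_train])
    mask = np.zeros(n, dtype=bool)
    mask[train_idx] = True
    return reads[mask].reset_index(drop=True), reads[~mask].reset_index(drop=True)


def perturb_truth(
    truth: list[SiteRecord],
    ref_length: int,
    pos_jitter_prob: float = 0.0,
    freq_noise_sd: float = 0.0,
    fp_rate: float = 0.0,
    fn_rate: float = 0.0,
    seed: int = 0,
) -> list[SiteRecord]:
    """Generate method-like predictions by degrading a truth site list.

    Each truth site is dropped with probability ``fn_rate``, shifted +-1 base
    with probability ``pos_jitter_prob``, and its frequency perturbed by
    clipped Gaussian noise.  Spurious sites with uniform(0.05, 0.95)
    frequencies are injected at each unmodified position with probability
    ``fp_rate``.  With all parameters zero the output equals the input.
    """
    for name, p in (("pos_jitter_prob", pos_jitter_prob), ("fp_rate", fp_rate), ("fn_rate", fn_rate)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if freq_noise_sd < 0:
        raise ValueError("freq_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    truth_positions = {r.start for r in truth}
    out: list[SiteRecord] = []
    for rec in truth:
        if fn_rate > 0 and rng.random() < fn_rate:
            continue
        start = rec.start
        if pos_jitter_prob > 0 and rng.random() < pos_jitter_prob:
            shift = 1 if rng.random() < 0.5 else -1
            start = min(max(start + shift, 0), ref_length - 1)
        freq = rec.frequency
        if freq_noise_sd > 0:
            freq = float(np.clip(freq + rng.normal(0.0, freq_noise_sd), 0.0, 1.0))
        out.append(
            SiteRecord.from_frequency(rec.chrom, start, rec.mod_name, rec.coverage, freq, rec.strand)
        )
    if fp_rate > 0 and truth:
        chrom = truth[0].chrom
        mod_name = truth[0].mod_name
        for pos in range(ref_length):
            if pos in truth_positions:
                continue
            if rng.random() < fp_rate:
                out.append(
                    SiteRecord.from_frequency(
                        chrom, pos, mod_name, truth[0].coverage, float(rng.uniform(0.05, 0.95))
                    )
                )
    out.sort(key=lambda r: r.start)
    return out
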