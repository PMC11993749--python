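"""Design of all-k-mer challenge reference sequences.

Nanopore current depends on the k-mer occupying the pore, so a reference that
contains every k-mer with the target base at its centre exercises a
modification caller across all sequence contexts.  The core construct
concatenates all 4^(k-1) such k-mers gap-free (1280 nt for k=5), one modified
position at the centre of each block; optional flanks pad the construct.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from io import StringIO

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["ReferenceDesign", "enumerate_central_kmers", "build_reference", "write_design"]

DNA = "ACGT"


@dataclass
class ReferenceDesign:
    """A designed reference sequence plus the layout of its modified positions."""

    name: str
    sequence: str
    k: int
    central_base: str
    block_positions: list[int] = field(default_factory=list)
    flank_5p: str = ""
    flank_3p: str = ""

    def __post_init__(self) -> None:
        n_blocks = 4 ** (self.k - 1)
        expected = len(self.flank_5p) + n_blocks * self.k + len(self.flank_3p)
        if len(self.sequence) != expected:
            raise ValueError(
                f"sequence length {len(self.sequence)} != flanks + {n_blocks} x {self.k} = {expected}"
            )
        if len(self.block_positions) != n_blocks:
            raise ValueError(f"expected {n_blocks} block positions, got {len(self.block_positions)}")
        for pos in self.block_positions:
            if self.sequence[pos] != self.central_base:
                raise ValueError(f"base at block position {pos} is not {self.central_base}")

    def __len__(self) -> int:
        return len(self.sequence)


def enumerate_central_kmers(central_base: str, k: int) -> list[str]:
    """All 4^(k-1) k-mers carrying ``central_base`` at the central index.

    Ordered lexicographically by the concatenated flanking bases, so
    ``enumerate_central_kmers("A", 5)[0] == "AAAAA"``.  k must be odd (a k-mer
    has a unique centre only then) and between 3 and 9.
    """
    if central_base not in DNA:
        raise ValueError(f"central base must be one of {DNA}, got '{central_base}'")
    if k % 2 == 0 or not 3 <= k <= 9:
        raise ValueError(f"k must be odd and in [3, 9], got {k}")
    half = (k - 1) // 2
    kmers = []
    for flanks in itertools.product(DNA, repeat=k - 1):
        kmers.append("".join(flanks[:half]) + central_base + "".join(flanks[half:]))
    return kmers


def build_reference(
    kmers: list[str],
    name: str = "design",
    order_seed: int | None = None,
    flank_5p: str = "",
    flank_3p: str = "",
) -> ReferenceDesign:
    """Concatenate k-mers gap-free into a reference, optionally seed-shuffled.

    Block positions are the central bases: ``len(flank_5p) + k*i + (k-1)//2``.
    """
    if not kmers:
        raise ValueError("no k-mers given")
    k = len(kmers[0])
    if any(len(m) != k for m in kmers):
        raise ValueError("k-mers have differing lengths")
    if len(set(kmers)) != len(kmers):
        raise ValueError("duplicate k-mers")
    half = (k - 1) // 2
    central = kmers[0][half]
    if order_seed is not None:
        rng = np.random.default_rng(order_seed)
        kmers = [kmers[i] for i in rng.permutation(len(kmers))]
    core = "".join(kmers)
    sequence = flank_5p + core + flank_3p
    positions = [len(flank_5p) + k * i + half for i in range(len(kmers))]
    return ReferenceDesign(
        name=name,
        sequence=sequence,
        k=k,
        central_base=central,
        block_positions=positions,
        flank_5p=flank_5p,
        flank_3p=flank_3p,
    )


def random_dna(length: int, rng: np.random.Generator) -> str:
    """Uniform random DNA, used for configurable reference flanks."""
    return "".join(rng.choice(list(DNA), size=length))


def write_design(design: ReferenceDesign) -> tuple[str, str]:
    """Serialize a design as (FASTA text, truth-layout BED text).

    The BED file has one 0-based half-open single-base row per expected
    modified position.
    """
    buf = StringIO()
    SeqIO.write(
        [SeqRecord(Seq(design.sequence), id=design.name, description="")], buf, "fasta"
    )
    bed_lines = [
        f"{design.name}\t{pos}\t{pos + 1}\tblock{i}\t0\t+"
        for i, pos in enumerate(design.block_positions)
    ]
    return buf.getvalue(), "\n".join(bed_lines) + "\n"


def read_fasta(text: str) -> dict[str, str]:
    """Parse FASTA text into ``{name: sequence}``."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(StringIO(text), "fasta")}
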