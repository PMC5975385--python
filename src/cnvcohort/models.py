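"""Core domain objects shared across the pipeline.

Coordinates are 1-based and fully closed throughout the package, so a call
spanning 136,813,001–136,815,100 has length ``end - start + 1 = 2100`` — the
convention of the read-depth caller's 100 bp bin grid.  BED files are the only
0-based half-open surface; the conversion happens exactly at the I/O boundary
in :mod:`cnvcohort.io_formats`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

CNV_TYPES = ("DUP", "DEL")
CALLERS = ("read_depth", "split_read")

#: Reference-database variant classes corresponding to the two CNV types.
CLASS_OF_TYPE = {"DUP": "gain", "DEL": "loss"}


@dataclass(frozen=True)
class GenomeBuild:
    """A genome build: named set of chromosomes with lengths in bp.

    ``total_length`` is the denominator *d* of the fold-coverage formula
    (for the UMD3.1 bovine assembly, 2,697,560,000 bp).
    """

    name: str
    chrom_lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("genome build needs at least one chromosome")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths


@dataclass(frozen=True)
class CNVCall:
    """One typed copy-number interval observed in one sample by one caller."""

    sample_id: str
    chrom: str
    start: int
    end: int
    cnv_type: str
    caller: str

    def __post_init__(self) -> None:
        if self.cnv_type not in CNV_TYPES:
            raise ValueError(f"unknown CNV type {self.cnv_type!r}")
        if self.caller not in CALLERS:
            raise ValueError(f"unknown caller {self.caller!r}")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end < start ({self.end} < {self.start})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def sort_key(self) -> Tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.cnv_type)


@dataclass
class SampleRecord:
    """One sequenced animal: identity, breed and alignment summary numbers."""

    sample_id: str
    breed: str
    n_reads: int
    read_length: int
    aligned_pct: float
    properly_paired_pct: float
    status: str = "kept"

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.read_length <= 0:
            raise ValueError("read_length must be > 0")
        for name in ("aligned_pct", "properly_paired_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} out of [0, 100]: {v}")


@dataclass(frozen=True)
class ReferenceCNV:
    """A previously reported gain/loss from a reference CNV database."""

    chrom: str
    start: int
    end: int
    variant_class: str  # gain | loss | other
    study_tag: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end < start ({self.end} < {self.start})")
        if self.variant_class not in ("gain", "loss", "other"):
            raise ValueError(f"unknown variant class {self.variant_class!r}")


@dataclass
class ConsensusSet:
    """Per-sample validated call set.

    The read-depth calls are the baseline; ``validated[i]`` marks baseline
    calls independently re-observed by the split-read caller under the
    breakpoint-tolerance rule, ``known[i]`` marks calls matching a reference
    CNV database record of the same class.
    """

    sample_id: str
    calls: Sequence[CNVCall]
    validated: Sequence[bool]
    known: Optional[Sequence[bool]] = None
    known_mode: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.validated) != len(self.calls):
            raise ValueError("validated flags must align with calls")
        if self.known is not None and len(self.known) != len(self.calls):
            raise ValueError("known flags must align with calls")
        for c in self.calls:
            if c.sample_id != self.sample_id:
                raise ValueError(f"call of sample {c.sample_id!r} in set {self.sample_id!r}")

    @property
    def validated_calls(self) -> list[CNVCall]:
        return [c for c, v in zip(self.calls, self.validated) if v]


@dataclass
class CNVCluster:
    """A cross-sample equivalence class of calls under the tolerance rule.

    The representative is the first member in (chrom, start, end, type) sort
    order; every member matches it under the active breakpoint tolerance.
    """

    representative: CNVCall
    members: list  # list of (sample_id, CNVCall)
    breed_counts: Optional[dict] = None

    @property
    def sharing_count(self) -> int:
        return len({s for s, _ in self.members})

    @property
    def samples(self) -> set:
        return {s for s, _ in self.members}

    @property
    def cnv_type(self) -> str:
        return self.representative.cnv_type


@dataclass
class BreedSpecificCNV:
    """A cluster carried by >=2 animals of exactly one breed and no other."""

    cluster: CNVCluster
    breed: str
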