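"""Per-sample genome coverage and the low-coverage exclusion rule.

Fold coverage is ``sum of aligned read lengths / genome length``; with one
read length *r* per sample this is ``N * r / d``.  Samples below the
threshold (default 7-fold) are excluded from all downstream analyses.
Alignment-rate percentages are reported in the QC table but never
auto-exclude: no threshold is imposed on them.
"""
from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .models import GenomeBuild, SampleRecord

DEFAULT_MIN_COVERAGE = 7.0


def compute_coverage(
    sample: SampleRecord,
    build: GenomeBuild,
    read_lengths: Optional[Sequence[int]] = None,
) -> float:
    """Average fold coverage of *sample* on *build*.

    With *read_lengths* given, the exact sum of per-read lengths is used;
    otherwise the uniform per-sample read length applies to all ``n_reads``.
    """
    d = build.total_length
    if d <= 0:
        raise ValueError("genome length must be positive")
    if read_lengths is not None:
        return sum(read_lengths) / d
    return sample.n_reads * sample.read_length / d


def filter_samples(
    samples: Iterable[SampleRecord],
    build: GenomeBuild,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> Tuple[List[SampleRecord], List[SampleRecord]]:
    """Partition samples into (kept, excluded) by the coverage rule.

    The boundary is strict: coverage exactly equal to the threshold is kept
    ("below seven" excludes).  Statuses are updated in place; the function is
    idempotent and order-independent.
    """
    kept, excluded = [], []
    for s in samples:
        if compute_coverage(s, build) < min_coverage:
            s.status = "excluded_low_coverage"
            excluded.append(s)
        else:
            s.status = "kept"
            kept.append(s)
    return kept, excluded


def qc_report(
    samples: Iterable[SampleRecord],
    build: GenomeBuild,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """QC table: coverage, alignment percentages and keep/exclude status."""
    samples = list(samples)
    filter_samples(samples, build, min_coverage)
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "breed": [s.breed for s in samples],
            "coverage": [compute_coverage(s, build) for s in samples],
            "aligned_pct": [s.aligned_pct for s in samples],
            "properly_paired_pct": [s.properly_paired_pct for s in samples],
            "status": [s.status for s in samples],
        }
    )


def exclusions_by_breed(excluded: Iterable[SampleRecord]) -> pd.Series:
    """Tally of excluded samples per breed."""
    breeds = pd.Series([s.breed for s in excluded], dtype=str)
    return breeds.value_counts()
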