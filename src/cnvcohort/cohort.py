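"""Cross-sample clustering, sharing statistics and breed-specific CNVs.

Clustering anchors every member to a cluster representative: calls are
visited in (chrom, start, end, type) sort order and each call joins the
first existing cluster whose representative it matches under the breakpoint
tolerance, else founds a new cluster.  Every member is therefore within
tolerance of one fixed interval — the pairwise "same CNV" rule applied
against the representative — rather than chained transitively.
"""
from __future__ import annotations

import bisect
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .consensus import DEFAULT_TOLERANCE, breakpoints_match
from .io_formats import HEADER_COMMENT
from .models import (
    BreedSpecificCNV,
    CNVCall,
    CNVCluster,
    ConsensusSet,
    GenomeBuild,
    SampleRecord,
)


def cluster_calls(
    consensus_sets: Iterable[ConsensusSet],
    tol: int = DEFAULT_TOLERANCE,
    validated_only: bool = True,
    manifest: Optional[Sequence[SampleRecord]] = None,
) -> List[CNVCluster]:
    """Partition calls across samples into tolerance equivalence classes.

    Deterministic for fixed input: seeding order is the canonical
    (chrom, start, end, type, sample) sort.  With *manifest* given, per-breed
    distinct-sample counts are attached to each cluster.
    """
    items: List[Tuple[str, CNVCall]] = []
    for cs in consensus_sets:
        calls = cs.validated_calls if validated_only else list(cs.calls)
        items.extend((cs.sample_id, c) for c in calls)
    items.sort(key=lambda sc: (*sc[1].sort_key(), sc[0]))

    clusters: List[CNVCluster] = []
    # Active window per (chrom, type): representatives with start >= current
    # start - tol, in creation order.  Input start order is non-decreasing
    # within a key, so stale representatives can be dropped permanently.
    windows: Dict[Tuple[str, str], List[CNVCluster]] = {}
    for sample_id, call in items:
        key = (call.chrom, call.cnv_type)
        window = windows.setdefault(key, [])
        while window and window[0].representative.start < call.start - tol:
            window.pop(0)
        target = None
        for cl in window:  # creation order within the window
            if breakpoints_match(cl.representative, call, tol):
                target = cl
                break
        if target is None:
            target = CNVCluster(representative=call, members=[])
            clusters.append(target)
            window.append(target)
        target.members.append((sample_id, call))

    if manifest is not None:
        attach_breed_counts(clusters, manifest)
    return clusters


def attach_breed_counts(clusters: Iterable[CNVCluster], manifest: Sequence[SampleRecord]) -> None:
    breed_of = {s.sample_id: s.breed for s in manifest}
    for cl in clusters:
        counts: Dict[str, int] = {}
        for sample in cl.samples:
            if sample not in breed_of:
                raise KeyError(f"sample {sample!r} missing from manifest")
            breed = breed_of[sample]
            counts[breed] = counts.get(breed, 0) + 1
        cl.breed_counts = counts


def singleton_fraction(clusters: Iterable[CNVCluster], cnv_type: str) -> float:
    """Percent of clusters of *cnv_type* observed in exactly one sample."""
    of_type = [c for c in clusters if c.cnv_type == cnv_type]
    if not of_type:
        raise ValueError(f"no clusters of type {cnv_type!r}: singleton fraction undefined")
    singletons = sum(1 for c in of_type if c.sharing_count == 1)
    return 100.0 * singletons / len(of_type)


def most_common(clusters: Iterable[CNVCluster], cnv_type: str, n: int = 20) -> List[CNVCluster]:
    """Top *n* clusters of a type by sharing count; ties by (chrom, start)."""
    of_type = [c for c in clusters if c.cnv_type == cnv_type]
    of_type.sort(key=lambda c: (-c.sharing_count, c.representative.chrom, c.representative.start))
    return of_type[:n]


def breed_specific(
    clusters: Sequence[CNVCluster],
    manifest: Sequence[SampleRecord],
    min_shared: int = 2,
    breeds_considered: Optional[Sequence[str]] = None,
    tol: int = DEFAULT_TOLERANCE,
) -> List[BreedSpecificCNV]:
    """Clusters carried by >= *min_shared* animals of exactly one breed.

    Absence elsewhere is strict: no call from a sample of any *other* breed
    (including breeds outside *breeds_considered*) may match the cluster
    representative under the tolerance, even if clustering placed that call
    in a neighbouring cluster.
    """
    breed_of = {s.sample_id: s.breed for s in manifest}
    for cl in clusters:
        for sample in cl.samples:
            if sample not in breed_of:
                raise KeyError(f"sample {sample!r} missing from manifest")
    attach_breed_counts(clusters, manifest)

    # index every member call by (chrom, type), sorted by start, with breed
    index: Dict[Tuple[str, str], Tuple[List[int], List[Tuple[CNVCall, str]]]] = {}
    for cl in clusters:
        for sample, call in cl.members:
            key = (call.chrom, call.cnv_type)
            index.setdefault(key, (None, []))[1].append((call, breed_of[sample]))
    for key, (_, entries) in list(index.items()):
        entries.sort(key=lambda e: e[0].start)
        index[key] = ([e[0].start for e in entries], entries)

    out: List[BreedSpecificCNV] = []
    for cl in clusters:
        if len(cl.breed_counts) != 1:
            continue
        (breed, count), = cl.breed_counts.items()
        if count < min_shared:
            continue
        if breeds_considered is not None and breed not in breeds_considered:
            continue
        rep = cl.representative
        starts, entries = index[(rep.chrom, rep.cnv_type)]
        lo = bisect.bisect_left(starts, rep.start - tol)
        hi = bisect.bisect_right(starts, rep.start + tol)
        leaked = any(
            other_breed != breed and breakpoints_match(rep, call, tol)
            for call, other_breed in entries[lo:hi]
        )
        if not leaked:
            out.append(BreedSpecificCNV(cluster=cl, breed=breed))
    return out


def breed_specific_percent(
    specific: Iterable[BreedSpecificCNV],
    clusters: Iterable[CNVCluster],
    breed: str,
    cnv_type: str,
) -> float:
    """Percent of a breed's observed clusters of a type that are specific to it.

    Denominator: clusters of the type with at least one member of the breed.
    """
    denom = sum(
        1
        for c in clusters
        if c.cnv_type == cnv_type and c.breed_counts and breed in c.breed_counts
    )
    num = sum(1 for s in specific if s.breed == breed and s.cluster.cnv_type == cnv_type)
    if denom == 0:
        return 0.0
    return 100.0 * num / denom


def sharing_percent(n_sharing: int, breed_size: int) -> float:
    """100 * n / breed size, to two decimals, half away from zero."""
    if breed_size <= 0:
        raise ValueError("breed size must be positive")
    pct = Decimal(100 * n_sharing) / Decimal(breed_size)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def union_length(intervals: Iterable[Tuple[int, int]]) -> int:
    """Total bp covered by the union of 1-based closed intervals."""
    ivs = sorted(intervals)
    total = 0
    cur_start, cur_end = None, None
    for s, e in ivs:
        if cur_end is None or s > cur_end + 1:
            if cur_end is not None:
                total += cur_end - cur_start + 1
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        total += cur_end - cur_start + 1
    return total


def genome_covered_pct(
    cset: ConsensusSet,
    build: GenomeBuild,
    cnv_type: str,
    validated_only: bool = True,
) -> float:
    """Percent of the genome covered by a sample's CNVs of one type.

    Overlapping intervals are counted once (union semantics).
    """
    calls = cset.validated_calls if validated_only else list(cset.calls)
    intervals = []
    for c in calls:
        if c.cnv_type != cnv_type:
            continue
        if c.chrom not in build:
            raise ValueError(f"call on chromosome {c.chrom!r} absent from build")
        if c.end > build.chrom_lengths[c.chrom]:
            raise ValueError(f"call {c.chrom}:{c.start}-{c.end} beyond chromosome end")
        intervals.append((c.chrom, c.start, c.end))
    covered = 0
    for chrom in {iv[0] for iv in intervals}:
        covered += union_length((s, e) for ch, s, e in intervals if ch == chrom)
    return 100.0 * covered / build.total_length


# --- report tables --------------------------------------------------------

def cluster_frame(clusters: Iterable[CNVCluster]) -> pd.DataFrame:
    rows = []
    for cl in clusters:
        rep = cl.representative
        rows.append(
            {
                "chrom": rep.chrom,
                "start": rep.start,
                "end": rep.end,
                "cnv_type": rep.cnv_type,
                "sharing_count": cl.sharing_count,
                "breed_counts": ";".join(
                    f"{b}:{n}" for b, n in sorted((cl.breed_counts or {}).items())
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "cnv_type", "sharing_count", "breed_counts"]
    )


def breed_specific_frame(specific: Iterable[BreedSpecificCNV]) -> pd.DataFrame:
    rows = []
    for s in specific:
        rep = s.cluster.representative
        rows.append(
            {
                "breed": s.breed,
                "chrom": rep.chrom,
                "start": rep.start,
                "end": rep.end,
                "cnv_type": rep.cnv_type,
                "n_sharing": s.cluster.sharing_count,
            }
        )
    return pd.DataFrame(rows, columns=["breed", "chrom", "start", "end", "cnv_type", "n_sharing"])


def write_table(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(HEADER_COMMENT + "\n")
        df.to_csv(fh, sep="\t", index=False)
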