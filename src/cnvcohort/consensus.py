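"""Length filtering, two-caller consensus validation and known-CNV flagging.

The read-depth caller's calls are the baseline set; a baseline call is
*validated* when the split-read caller independently observed the same CNV.
"Same CNV" is the breakpoint-tolerance rule: same chromosome, same type, and
both breakpoints within the tolerance (default 100 bp — the read-depth
caller's bin size, hence its breakpoint accuracy).
"""
from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .io_formats import HEADER_COMMENT
from .models import CLASS_OF_TYPE, CNVCall, ConsensusSet, ReferenceCNV

DEFAULT_TOLERANCE = 100

#: caller → (min length, max length); None means unbounded on that side.
#: Read-depth calls longer than 5 Mb are alignment artefacts and discarded;
#: split-read calls must lie in [50 bp, 5 Mb].
DEFAULT_LENGTH_RULES: Dict[str, Tuple[Optional[int], Optional[int]]] = {
    "read_depth": (None, 5_000_000),
    "split_read": (50, 5_000_000),
}


def filter_by_length(
    calls: Iterable[CNVCall],
    caller_rules: Optional[Dict[str, Tuple[Optional[int], Optional[int]]]] = None,
) -> List[CNVCall]:
    """Drop calls outside their caller's admissible length window.

    Boundaries are inclusive: a 5,000,000 bp read-depth call is kept, a
    5,000,001 bp call discarded; a 50 bp split-read call is kept, 49 bp
    discarded.  Order is preserved and the operation is idempotent.
    """
    rules = DEFAULT_LENGTH_RULES if caller_rules is None else caller_rules
    out = []
    for c in calls:
        if c.caller not in rules:
            raise ValueError(f"no length rule for caller {c.caller!r}")
        lo, hi = rules[c.caller]
        if lo is not None and c.length < lo:
            continue
        if hi is not None and c.length > hi:
            continue
        out.append(c)
    return out


def breakpoints_match(a: CNVCall, b: CNVCall, tol: int = DEFAULT_TOLERANCE) -> bool:
    """True iff *a* and *b* are the same CNV under the tolerance rule."""
    if tol < 0:
        raise ValueError("tolerance must be non-negative")
    return (
        a.chrom == b.chrom
        and a.cnv_type == b.cnv_type
        and abs(a.start - b.start) <= tol
        and abs(a.end - b.end) <= tol
    )


def build_consensus(
    rd_calls: Sequence[CNVCall],
    sr_calls: Sequence[CNVCall],
    tol: int = DEFAULT_TOLERANCE,
) -> ConsensusSet:
    """Validate baseline read-depth calls against split-read calls.

    Each split-read call validates at most one baseline call: candidate
    pairs are consumed greedily by smallest total breakpoint displacement,
    ties to the smaller baseline start (then smaller split-read start).
    On well-separated calls this equals exhaustive optimal matching.
    """
    sample_ids = {c.sample_id for c in rd_calls} | {c.sample_id for c in sr_calls}
    if len(sample_ids) > 1:
        raise ValueError(f"mixed sample_ids in consensus input: {sorted(sample_ids)}")
    sample_id = sample_ids.pop() if sample_ids else ""

    pairs = []
    for i, rd in enumerate(rd_calls):
        for j, sr in enumerate(sr_calls):
            if breakpoints_match(rd, sr, tol):
                dist = abs(rd.start - sr.start) + abs(rd.end - sr.end)
                pairs.append((dist, rd.start, sr.start, i, j))
    pairs.sort()

    validated = [False] * len(rd_calls)
    sr_used = [False] * len(sr_calls)
    for _, _, _, i, j in pairs:
        if validated[i] or sr_used[j]:
            continue
        validated[i] = True
        sr_used[j] = True
    return ConsensusSet(sample_id=sample_id, calls=list(rd_calls), validated=validated)


def flag_known(
    cset: ConsensusSet,
    refdb: Iterable[ReferenceCNV],
    tol: int = DEFAULT_TOLERANCE,
    mode: str = "overlap",
) -> ConsensusSet:
    """Flag calls matching a reference-database gain/loss record.

    Only gain/loss records are considered (inversions and other classes are
    excluded); a DUP can only match a gain, a DEL only a loss.  ``mode``
    selects the match rule: ``"overlap"`` needs >=1 bp intersection,
    ``"breakpoint"`` needs both breakpoints within *tol*.
    """
    if mode not in ("overlap", "breakpoint"):
        raise ValueError(f"unknown known-CNV mode {mode!r}")
    by_class: Dict[str, List[ReferenceCNV]] = {"gain": [], "loss": []}
    for r in refdb:
        if r.variant_class in by_class:
            by_class[r.variant_class].append(r)

    known = []
    for c in cset.calls:
        candidates = by_class[CLASS_OF_TYPE[c.cnv_type]]
        hit = False
        for r in candidates:
            if r.chrom != c.chrom:
                continue
            if mode == "overlap":
                hit = c.start <= r.end and r.start <= c.end
            else:
                hit = abs(c.start - r.start) <= tol and abs(c.end - r.end) <= tol
            if hit:
                break
        known.append(hit)
    return ConsensusSet(
        sample_id=cset.sample_id,
        calls=list(cset.calls),
        validated=list(cset.validated),
        known=known,
        known_mode=mode,
    )


def consensus_frame(csets: Iterable[ConsensusSet]) -> pd.DataFrame:
    """Flatten consensus sets into the consensus report table."""
    rows = []
    for cs in csets:
        known = cs.known if cs.known is not None else [None] * len(cs.calls)
        for c, v, k in zip(cs.calls, cs.validated, known):
            rows.append(
                {
                    "sample_id": cs.sample_id,
                    "chrom": c.chrom,
                    "start": c.start,
                    "end": c.end,
                    "cnv_type": c.cnv_type,
                    "length": c.length,
                    "validated": v,
                    "known": k,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "chrom", "start", "end", "cnv_type", "length", "validated", "known"],
    )


def write_consensus_tsv(csets: Iterable[ConsensusSet], path) -> None:
    df = consensus_frame(csets)
    with open(path, "w") as fh:
        fh.write(HEADER_COMMENT + "\n")
        df.to_csv(fh, sep="\t", index=False)
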