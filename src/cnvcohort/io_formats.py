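"""Readers and writers for every file dialect the pipeline touches.

Supported dialects
------------------
* read-depth caller text (whitespace columns: type, ``chrom:start-end``
  region, length, score columns) — the CNVnator output layout;
* split-read caller calls reduced to a TSV of typed intervals
  (chrom, start, end, type) — the Pindel-derived layout;
* sample manifest TSV;
* genome build table TSV (chromosome, length);
* BED (the only 0-based half-open surface; internal coordinates are 1-based
  closed and conversion happens here);
* reference-CNV TSV (chrom, start, end, variant_class, study_tag);
* GFF3 gene models (via :mod:`gffutils`);
* QTL BED with a trait-class name column;
* gene → term maps (TSV: gene_id, term).

All writers emit a leading comment line naming the tool version.  Parsers
never silently drop lines: every line is a record, a comment, or a reported
error with its line number.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Set

import gffutils
import pandas as pd

from . import __version__
from .models import CNVCall, GenomeBuild, ReferenceCNV, SampleRecord

HEADER_COMMENT = f"# cnvcohort v{__version__}"

_RD_TYPE_TOKENS = {"duplication": "DUP", "deletion": "DEL", "DUP": "DUP", "DEL": "DEL"}
_SR_TYPE_TOKENS = {"DUP": "DUP", "DEL": "DEL", "duplication": "DUP", "deletion": "DEL"}

MANIFEST_COLUMNS = [
    "sample_id",
    "breed",
    "n_reads",
    "read_length",
    "aligned_pct",
    "properly_paired_pct",
]


class ParseError(ValueError):
    """A malformed input line; the message names the file and line number."""


def _fail(path, lineno: int, msg: str):
    raise ParseError(f"{path}:{lineno}: {msg}")


def _parse_region(token: str, path, lineno: int):
    """Split a ``chrom:start-end`` region string; chrom kept verbatim."""
    chrom, sep, span = token.rpartition(":")
    if not sep or "-" not in span:
        _fail(path, lineno, f"malformed region string {token!r}")
    lo, _, hi = span.partition("-")
    try:
        start, end = int(lo), int(hi)
    except ValueError:
        _fail(path, lineno, f"non-integer coordinates in region {token!r}")
    return chrom, start, end


def read_read_depth_calls(path, sample_id: str) -> List[CNVCall]:
    """Read a read-depth caller's per-sample text output.

    Expected whitespace-separated columns: CNV type token
    (``duplication``/``deletion``), region ``chrom:start-end``, length,
    then any number of score columns (ignored).
    """
    calls: List[CNVCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                _fail(path, lineno, f"expected >=2 columns, got {len(fields)}")
            if fields[0] not in _RD_TYPE_TOKENS:
                _fail(path, lineno, f"unknown CNV type token {fields[0]!r}")
            chrom, start, end = _parse_region(fields[1], path, lineno)
            try:
                calls.append(
                    CNVCall(sample_id, chrom, start, end, _RD_TYPE_TOKENS[fields[0]], "read_depth")
                )
            except ValueError as exc:
                _fail(path, lineno, str(exc))
    return calls


def read_split_read_calls(path, sample_id: str) -> List[CNVCall]:
    """Read split-read calls from a reduced TSV: chrom, start, end, type."""
    calls: List[CNVCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                _fail(path, lineno, f"expected 4 tab-separated columns, got {len(fields)}")
            chrom, lo, hi, typ = fields[:4]
            if typ not in _SR_TYPE_TOKENS:
                _fail(path, lineno, f"unknown CNV type token {typ!r}")
            try:
                start, end = int(lo), int(hi)
            except ValueError:
                _fail(path, lineno, "non-integer coordinates")
            try:
                calls.append(CNVCall(sample_id, chrom, start, end, _SR_TYPE_TOKENS[typ], "split_read"))
            except ValueError as exc:
                _fail(path, lineno, str(exc))
    return calls


def write_split_read_calls(calls: Iterable[CNVCall], path) -> None:
    with open(path, "w") as fh:
        fh.write(HEADER_COMMENT + "\n")
        for c in calls:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.cnv_type}\n")


def write_read_depth_calls(calls: Iterable[CNVCall], path) -> None:
    token = {"DUP": "duplication", "DEL": "deletion"}
    with open(path, "w") as fh:
        fh.write(HEADER_COMMENT + "\n")
        for c in calls:
            fh.write(f"{token[c.cnv_type]}\t{c.chrom}:{c.start}-{c.end}\t{c.length}\t0\t0\t0\t0\n")


def validate_calls(calls: Iterable[CNVCall], build: GenomeBuild) -> None:
    """Raise if any call references a chromosome absent from *build* or runs
    past its end."""
    for c in calls:
        if c.chrom not in build:
            raise ValueError(f"call on chromosome {c.chrom!r} absent from build {build.name!r}")
        if c.end > build.chrom_lengths[c.chrom]:
            raise ValueError(
                f"call {c.chrom}:{c.start}-{c.end} runs past chromosome end "
                f"{build.chrom_lengths[c.chrom]}"
            )


# --- manifest -------------------------------------------------------------

def read_manifest(path) -> List[SampleRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str, "breed": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: manifest missing column(s) {missing}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise ParseError(f"{path}: duplicate sample_id(s): {sorted(set(dup))}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SampleRecord(
                sample_id=row.sample_id,
                breed=row.breed,
                n_reads=int(row.n_reads),
                read_length=int(row.read_length),
                aligned_pct=float(row.aligned_pct),
                properly_paired_pct=float(row.properly_paired_pct),
                status=getattr(row, "status", "kept"),
            )
        )
    return records


def write_manifest(samples: Iterable[SampleRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(HEADER_COMMENT + "\n")
        fh.write("\t".join(MANIFEST_COLUMNS + ["status"]) + "\n")
        for s in samples:
            fh.write(
                f"{s.sample_id}\t{s.breed}\t{s.n_reads}\t{s.read_length}\t"
                f"{s.aligned_pct}\t{s.properly_paired_pct}\t{s.status}\n"
            )


# --- genome build ---------------------------------------------------------

def read_genome_build(path, name: Optional[str] = None) -> GenomeBuild:
    """Read a two-column TSV of chromosome name and length."""
    lengths: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                _fail(path, lineno, "expected 2 columns: chrom, length")
            chrom, length = fields[0], fields[1]
            if chrom in lengths:
                _fail(path, lineno, f"duplicate chromosome {chrom!r}")
            lengths[chrom] = int(length)
    return GenomeBuild(name or Path(path).stem, lengths)


def write_genome_build(build: GenomeBuild, path) -> None:
    with open(path, "w") as fh:
        fh.write(HEADER_COMMENT + "\n")
        for chrom, length in build.chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")


# --- BED ------------------------------------------------------------------

def write_bed(calls: Iterable[CNVCall], path) -> None:
    """Write calls as 0-based half-open BED: (start-1, end, type, sample)."""
    with open(path, "w") as fh:
        fh.write(HEADER_COMMENT + "\n")
        for c in calls:
            bed_start = c.start - 1
            if bed_start < 0:
                raise ValueError(f"negative BED start for call at {c.chrom}:{c.start}")
            fh.write(f"{c.chrom}\t{bed_start}\t{c.end}\t{c.cnv_type}\t{c.sample_id}\n")


def read_bed(path, caller: str = "read_depth") -> List[CNVCall]:
    """Read BED written by :func:`write_bed` back to 1-based closed calls."""
    calls: List[CNVCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                _fail(path, lineno, "expected 5 BED columns")
            chrom, bed_start, bed_end, typ, sample = fields[:5]
            calls.append(CNVCall(sample, chrom, int(bed_start) + 1, int(bed_end), typ, caller))
    return calls


# --- reference CNV database ----------------------------------------------

def read_reference_cnvs(path) -> List[ReferenceCNV]:
    """Read a reference-CNV TSV: chrom, start, end, variant_class[, study_tag]."""
    records: List[ReferenceCNV] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                _fail(path, lineno, "expected >=4 columns: chrom, start, end, class")
            chrom, lo, hi, cls = fields[:4]
            tag = fields[4] if len(fields) > 4 else ""
            if cls not in ("gain", "loss", "other"):
                cls = "other"
            try:
                records.append(ReferenceCNV(chrom, int(lo), int(hi), cls, tag))
            except ValueError as exc:
                _fail(path, lineno, str(exc))
    return records


# --- QTL BED --------------------------------------------------------------

def read_qtl_bed(path) -> pd.DataFrame:
    """Read QTL intervals from BED with the trait class in the name column.

    Returns a DataFrame with 1-based closed ``start``/``end`` columns.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                _fail(path, lineno, "expected 4 BED columns: chrom, start, end, trait_class")
            rows.append(
                {
                    "chrom": fields[0],
                    "start": int(fields[1]) + 1,
                    "end": int(fields[2]),
                    "trait_class": fields[3],
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "trait_class"])


# --- gene models (GFF3) ---------------------------------------------------

def read_gene_models(path, build: Optional[GenomeBuild] = None):
    """Read gene models with exon intervals and coding flags from GFF3.

    Exons are marked coding when overlapped by a CDS feature of the same
    gene.  Genes on chromosomes absent from *build* are skipped with a
    warning; an exon outside its gene span is an error.
    """
    from .annotation import GeneModel  # local import to avoid a cycle

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes = []
    for g in db.features_of_type("gene"):
        if build is not None and g.seqid not in build:
            warnings.warn(
                f"gene {g.id} on chromosome {g.seqid!r} absent from build; skipped"
            )
            continue
        cds = [(c.start, c.end) for c in db.children(g, featuretype="CDS")]
        exons = []
        for e in db.children(g, featuretype="exon"):
            if e.start < g.start or e.end > g.end:
                raise ParseError(
                    f"{path}: exon {e.start}-{e.end} outside gene {g.id} span {g.start}-{g.end}"
                )
            coding = any(e.start <= ce and cs <= e.end for cs, ce in cds)
            exons.append((e.start, e.end, coding))
        exons.sort()
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                start=g.start,
                end=g.end,
                strand=g.strand if g.strand in ("+", "-") else "+",
                exons=exons,
            )
        )
    return genes


# --- term maps ------------------------------------------------------------

def read_term_map(path) -> Dict[str, Set[str]]:
    """Read a TSV of gene_id → term (one pair per line) into a mapping."""
    mapping: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                _fail(path, lineno, "expected 2 columns: gene_id, term")
            mapping.setdefault(fields[0], set()).add(fields[1])
    return mapping
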