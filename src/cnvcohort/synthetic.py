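"""Synthetic CNV cohort generator with known ground truth.

The generator emulates two callers observing the same underlying CNVs on a
toy genome: a read-depth caller whose breakpoints sit on a 100 bp bin grid
(minimum call 200 bp), and a split-read caller that re-observes each true
CNV with a configurable sensitivity and base-resolution breakpoint jitter.
True CNVs come in three pools — cohort-wide shared, breed-private shared,
and individual-private — plus uniform spurious read-depth calls.  Distinct
CNV loci are packed with gaps of at least 1 kb, so breakpoints of different
loci are separated by more than twice the 100 bp matching tolerance: greedy
representative clustering then provably equals transitive closure, and
breed-specific recovery has no false positives by construction.

All coordinates are drawn with integer arithmetic from a single seeded
generator, so output is byte-identical across platforms for a fixed config.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import io_formats
from .models import CNVCall, GenomeBuild, SampleRecord

RD_GRID = 100  # read-depth caller bin size, bp
RD_MIN_LEN = 200
MAX_LEN = 5_000_000
SR_MIN_LEN = 50
MIN_GAP = 1_000  # > 2 * tolerance + jitter margin


def toy_build(n_chroms: int = 5, chrom_length: int = 10_000_000) -> GenomeBuild:
    """A small genome (default 5 x 10 Mb) for fast full-pipeline runs."""
    return GenomeBuild("toy", {str(i + 1): chrom_length for i in range(n_chroms)})


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort.

    Defaults describe a scaled-down five-breed cohort: mostly
    individual-private CNVs, a core of cohort-wide shared loci, a few
    breed-private loci per breed (>=2 carriers each, the breed-specific
    definition), log-normal lengths, read-depth breakpoints on the bin grid
    and split-read re-observation with 80% sensitivity and up to one bin of
    breakpoint jitter.
    """

    seed: int = 0
    build: GenomeBuild = field(default_factory=toy_build)
    breeds: Dict[str, int] = field(
        default_factory=lambda: {
            "BrownSwiss": 12,
            "Fleckvieh": 8,
            "NorwegianRed": 7,
            "Guernsey": 5,
            "Simmental": 4,
        }
    )
    n_shared_global: int = 10
    n_shared_per_breed: int = 4
    n_private_per_sample: int = 20
    carrier_prob_shared: float = 0.8
    length_median_bp: float = 2_000.0
    length_sigma: float = 1.0
    jitter_rd_bins: int = 0  # read-depth jitter, in 100 bp bins per breakpoint
    jitter_sr_bp: int = 100  # split-read jitter magnitude upper bound, bp
    jitter_sr_min_bp: int = 0  # lower bound of jitter magnitude, bp
    validator_sensitivity: float = 0.8
    fp_rate_rd: float = 2.0  # expected spurious read-depth calls per sample
    read_length: int = 101
    coverage_kept: Tuple[float, float] = (7.5, 12.0)
    coverage_low: Tuple[float, float] = (4.0, 6.5)
    n_low_coverage: int = 2

    def __post_init__(self) -> None:
        for name in ("carrier_prob_shared", "validator_sensitivity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {v}")
        for name in (
            "n_shared_global",
            "n_shared_per_breed",
            "n_private_per_sample",
            "jitter_rd_bins",
            "jitter_sr_bp",
            "n_low_coverage",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.jitter_sr_min_bp > self.jitter_sr_bp:
            raise ValueError("jitter_sr_min_bp > jitter_sr_bp")


@dataclass(frozen=True)
class Placement:
    """One true CNV locus: coordinates, type, pool label, carriers."""

    cluster_id: str
    chrom: str
    start: int
    end: int
    cnv_type: str
    label: str  # global | breed:<name> | private
    carriers: Tuple[str, ...]


@dataclass
class SimTruth:
    placements: List[Placement]
    false_positives: List[CNVCall]
    low_coverage_samples: List[str]


@dataclass
class SimulatedCohort:
    config: SimConfig
    manifest: List[SampleRecord]
    rd_calls: Dict[str, List[CNVCall]]
    sr_calls: Dict[str, List[CNVCall]]
    truth: SimTruth

    def write(self, outdir) -> None:
        """Emit the dialects the readers understand, plus a truth TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "read_depth").mkdir(exist_ok=True)
        (outdir / "split_read").mkdir(exist_ok=True)
        io_formats.write_manifest(self.manifest, outdir / "manifest.tsv")
        io_formats.write_genome_build(self.config.build, outdir / "build.tsv")
        for s in self.manifest:
            io_formats.write_read_depth_calls(
                self.rd_calls[s.sample_id], outdir / "read_depth" / f"{s.sample_id}.txt"
            )
            io_formats.write_split_read_calls(
                self.sr_calls[s.sample_id], outdir / "split_read" / f"{s.sample_id}.tsv"
            )
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write(io_formats.HEADER_COMMENT + "\n")
            fh.write("cluster_id\tchrom\tstart\tend\tcnv_type\tlabel\tcarriers\n")
            for p in self.truth.placements:
                fh.write(
                    f"{p.cluster_id}\t{p.chrom}\t{p.start}\t{p.end}\t{p.cnv_type}\t"
                    f"{p.label}\t{','.join(p.carriers)}\n"
                )


def _draw_length(rng: np.random.Generator, cfg: SimConfig) -> int:
    """Log-normal length on the read-depth grid, truncated to [200, 5 Mb]."""
    raw = float(rng.lognormal(np.log(cfg.length_median_bp), cfg.length_sigma))
    raw = min(max(raw, RD_MIN_LEN), MAX_LEN)
    length = int(round(raw / RD_GRID)) * RD_GRID
    return min(max(length, RD_MIN_LEN), MAX_LEN)


def _pack_placements(
    rng: np.random.Generator, build: GenomeBuild, lengths: Sequence[int]
) -> List[Tuple[str, int, int]]:
    """Pack intervals left-to-right per chromosome with gaps >= MIN_GAP.

    Returns grid-aligned (chrom, start, end) per requested length, in
    request order; raises when the genome cannot hold them.
    """
    chroms = list(build.chrom_lengths)
    cursors = {c: 1 for c in chroms}
    order = list(rng.permutation(len(lengths)))
    placed: List[Optional[Tuple[str, int, int]]] = [None] * len(lengths)
    for idx in order:
        length = lengths[idx]
        candidates = list(rng.permutation(len(chroms)))
        done = False
        for ci in candidates:
            chrom = chroms[ci]
            gap = MIN_GAP + int(rng.integers(0, 4 * MIN_GAP))
            start = cursors[chrom] + gap
            start = ((start - 1 + RD_GRID - 1) // RD_GRID) * RD_GRID + 1  # next grid point
            end = start + length - 1
            if end + MIN_GAP <= build.chrom_lengths[chrom]:
                placed[idx] = (chrom, start, end)
                cursors[chrom] = end + 1
                done = True
                break
        if not done:
            raise RuntimeError(
                "infeasible placement density: toy genome cannot hold all CNV loci"
            )
    return placed  # type: ignore[return-value]


def _jitter_sr(rng: np.random.Generator, cfg: SimConfig, pos: int) -> int:
    if cfg.jitter_sr_bp == 0:
        return pos
    mag = int(rng.integers(cfg.jitter_sr_min_bp, cfg.jitter_sr_bp + 1))
    sign = 1 if rng.integers(0, 2) else -1
    return max(1, pos + sign * mag)


def simulate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Generate manifest, per-sample caller outputs and ground truth."""
    rng = np.random.default_rng(cfg.seed)
    d = cfg.build.total_length

    # --- samples and coverage ------------------------------------------
    sample_ids: List[str] = []
    breed_of: Dict[str, str] = {}
    abbrev = {b: "".join(ch for ch in b if ch.isupper())[:3] or b[:3].upper() for b in cfg.breeds}
    for breed, count in cfg.breeds.items():
        for i in range(count):
            sid = f"{abbrev[breed]}{i + 1:03d}"
            sample_ids.append(sid)
            breed_of[sid] = breed
    n_low = min(cfg.n_low_coverage, len(sample_ids))
    low_idx = set(rng.choice(len(sample_ids), size=n_low, replace=False).tolist()) if n_low else set()
    manifest: List[SampleRecord] = []
    for i, sid in enumerate(sample_ids):
        lo, hi = cfg.coverage_low if i in low_idx else cfg.coverage_kept
        coverage = float(rng.uniform(lo, hi))
        n_reads = int(round(coverage * d / cfg.read_length))
        manifest.append(
            SampleRecord(
                sample_id=sid,
                breed=breed_of[sid],
                n_reads=n_reads,
                read_length=cfg.read_length,
                aligned_pct=float(np.round(rng.uniform(96.0, 99.9), 2)),
                properly_paired_pct=float(np.round(rng.uniform(80.6, 99.1), 2)),
            )
        )
    low_samples = [sample_ids[i] for i in sorted(low_idx)]
    kept = [s for s in sample_ids if s not in set(low_samples)]
    kept_by_breed: Dict[str, List[str]] = {}
    for s in kept:
        kept_by_breed.setdefault(breed_of[s], []).append(s)

    # --- plan true loci and false positives ----------------------------
    plan: List[Tuple[str, Tuple[str, ...]]] = []  # (label, carriers)
    for g in range(cfg.n_shared_global):
        carriers = tuple(s for s in kept if rng.random() < cfg.carrier_prob_shared)
        if not carriers:
            carriers = (kept[int(rng.integers(0, len(kept)))],)
        plan.append(("global", carriers))
    for breed, members in kept_by_breed.items():
        if len(members) < 2:
            continue
        for b in range(cfg.n_shared_per_breed):
            carriers = [s for s in members if rng.random() < cfg.carrier_prob_shared]
            while len(carriers) < 2:  # breed-specific needs >=2 carriers
                extra = members[int(rng.integers(0, len(members)))]
                if extra not in carriers:
                    carriers.append(extra)
            plan.append((f"breed:{breed}", tuple(sorted(carriers))))
    for s in sample_ids:
        for _ in range(cfg.n_private_per_sample):
            plan.append(("private", (s,)))
    fp_counts = {s: int(rng.poisson(cfg.fp_rate_rd)) for s in sample_ids}
    n_fp = sum(fp_counts.values())

    lengths = [_draw_length(rng, cfg) for _ in range(len(plan) + n_fp)]
    coords = _pack_placements(rng, cfg.build, lengths)

    placements: List[Placement] = []
    for i, (label, carriers) in enumerate(plan):
        chrom, start, end = coords[i]
        cnv_type = "DUP" if rng.random() < 0.45 else "DEL"
        placements.append(
            Placement(f"cnv{i:05d}", chrom, start, end, cnv_type, label, carriers)
        )

    # --- emit caller observations --------------------------------------
    rd_calls: Dict[str, List[CNVCall]] = {s: [] for s in sample_ids}
    sr_calls: Dict[str, List[CNVCall]] = {s: [] for s in sample_ids}
    for p in placements:
        for carrier in p.carriers:
            if cfg.jitter_rd_bins:
                js = RD_GRID * int(rng.integers(-cfg.jitter_rd_bins, cfg.jitter_rd_bins + 1))
                je = RD_GRID * int(rng.integers(-cfg.jitter_rd_bins, cfg.jitter_rd_bins + 1))
            else:
                js = je = 0
            start = max(1, p.start + js)
            end = max(start + RD_MIN_LEN - 1, p.end + je)
            rd_calls[carrier].append(
                CNVCall(carrier, p.chrom, start, end, p.cnv_type, "read_depth")
            )
            if rng.random() < cfg.validator_sensitivity:
                s_ = _jitter_sr(rng, cfg, p.start)
                e_ = _jitter_sr(rng, cfg, p.end)
                if e_ - s_ + 1 >= SR_MIN_LEN:
                    sr_calls[carrier].append(
                        CNVCall(carrier, p.chrom, s_, e_, p.cnv_type, "split_read")
                    )

    false_positives: List[CNVCall] = []
    fp_coord_idx = len(plan)
    for s in sample_ids:
        for _ in range(fp_counts[s]):
            chrom, start, end = coords[fp_coord_idx]
            fp_coord_idx += 1
            cnv_type = "DUP" if rng.random() < 0.45 else "DEL"
            call = CNVCall(s, chrom, start, end, cnv_type, "read_depth")
            rd_calls[s].append(call)
            false_positives.append(call)

    for s in sample_ids:
        rd_calls[s].sort(key=lambda c: c.sort_key())
        sr_calls[s].sort(key=lambda c: c.sort_key())

    truth = SimTruth(placements, false_positives, low_samples)
    return SimulatedCohort(cfg, manifest, rd_calls, sr_calls, truth)


# --- evaluation against truth --------------------------------------------

def truth_eval(
    clusters,
    specific,
    consensus_sets,
    truth: SimTruth,
    tol: int = 100,
) -> Dict[str, float]:
    """Score pipeline output against the simulator's ground truth.

    Returns validated-fraction over true read-depth observations,
    breed-specific sensitivity (truth breed loci with >=2 kept carriers that
    were reported as breed-specific) and false-discovery proportion among
    reported breed-specific clusters.
    """
    from .consensus import breakpoints_match  # avoid import cycle at module load

    low = set(truth.low_coverage_samples)

    def matches(placement: Placement, chrom, start, end, cnv_type) -> bool:
        return (
            placement.chrom == chrom
            and placement.cnv_type == cnv_type
            and abs(placement.start - start) <= tol
            and abs(placement.end - end) <= tol
        )

    # validated fraction over true calls of kept samples
    by_key: Dict[Tuple[str, str], List[Placement]] = {}
    for p in truth.placements:
        by_key.setdefault((p.chrom, p.cnv_type), []).append(p)
    n_true = n_true_validated = 0
    for cs in consensus_sets:
        if cs.sample_id in low:
            continue
        for call, v in zip(cs.calls, cs.validated):
            cands = by_key.get((call.chrom, call.cnv_type), [])
            is_true = any(
                matches(p, call.chrom, call.start, call.end, call.cnv_type)
                and cs.sample_id in p.carriers
                for p in cands
            )
            if is_true:
                n_true += 1
                n_true_validated += v
    validated_fraction = n_true_validated / n_true if n_true else float("nan")

    # breed-specific recovery
    breed_truth = [
        p
        for p in truth.placements
        if p.label.startswith("breed:") and len([c for c in p.carriers if c not in low]) >= 2
    ]
    recovered = 0
    for p in breed_truth:
        breed = p.label.split(":", 1)[1]
        for s in specific:
            rep = s.cluster.representative
            if s.breed == breed and matches(p, rep.chrom, rep.start, rep.end, rep.cnv_type):
                recovered += 1
                break
    sensitivity = recovered / len(breed_truth) if breed_truth else float("nan")

    false_hits = 0
    for s in specific:
        rep = s.cluster.representative
        if not any(
            matches(p, rep.chrom, rep.start, rep.end, rep.cnv_type)
            and p.label == f"breed:{s.breed}"
            for p in breed_truth
        ):
            false_hits += 1
    fdp = false_hits / len(specific) if specific else 0.0

    return {
        "validated_fraction": validated_fraction,
        "n_true_calls": n_true,
        "breed_specific_sensitivity": sensitivity,
        "n_breed_truth": len(breed_truth),
        "breed_specific_fdp": fdp,
        "n_breed_reported": len(specific),
    }
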