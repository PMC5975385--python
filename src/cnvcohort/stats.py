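"""Cohort test statistics for CNV counts, lengths and genome coverage.

Four tests, applied per CNV type (duplication / deletion):

* a chi-square dispersion test of per-individual CNV counts against the
  cohort (or breed) mean — ``sum (O_i - E)^2 / E`` with m-1 df;
* the Kruskal–Wallis rank test for count and length differences between
  groups (breeds, or individuals for lengths);
* the Shapiro–Wilk normality test of CNV lengths, with Royston's
  approximation for the order-statistic coefficients and p-values;
* a multiple-proportion test comparing per-individual genome-covered
  proportions within a breed against a common-proportion null, with the
  F(l-1, t), t → ∞ limiting distribution (evaluated as chi-square on
  (l-1)·F), Bonferroni-corrected across breeds.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import genome_covered_pct
from .models import CNV_TYPES, ConsensusSet, GenomeBuild, SampleRecord

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    statistic: float
    df: Union[float, Tuple[float, float], None]
    p_value: float
    test_name: str
    p_adjusted: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")


def chi2_count_test(counts: Sequence[float], expected: Optional[float] = None) -> TestResult:
    """Dispersion of per-individual CNV counts around a common mean.

    *expected* defaults to the mean of *counts*.  The statistic is
    ``sum (O_i - E)^2 / E`` on m-1 degrees of freedom.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least 2 individuals")
    E = float(np.mean(counts)) if expected is None else float(expected)
    if E <= 0:
        raise ValueError("expected count must be positive")
    stat = float(np.sum((counts - E) ** 2) / E)
    df = counts.size - 1
    p = float(sps.chi2.sf(stat, df))
    return TestResult(stat, df, p, "chi2_count")


def kruskal_wallis(
    groups: Sequence[Sequence[float]], tie_correction: bool = True
) -> TestResult:
    """Kruskal–Wallis H across groups, mid-ranks for ties.

    ``H = 12 / (n (n+1)) * sum R_i^2 / k_i - 3 (n+1)`` with n the total
    number of observations and R_i the rank sum of group i; m-1 degrees of
    freedom on the chi-square null.  With *tie_correction*, H is divided by
    ``1 - sum(t^3 - t) / (n^3 - n)``; the uncorrected statistic is available
    for strict formula replication but is anti-conservative on heavily tied
    counts.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    values = np.concatenate(groups)
    n = values.size
    m = len(groups)
    if np.all(values == values[0]):
        return TestResult(0.0, m - 1, 1.0, "kruskal_wallis")
    ranks = sps.rankdata(values)
    H = 0.0
    offset = 0
    for g in groups:
        R = float(np.sum(ranks[offset : offset + g.size]))
        H += R * R / g.size
        offset += g.size
    H = 12.0 / (n * (n + 1)) * H - 3.0 * (n + 1)
    if tie_correction:
        _, tie_counts = np.unique(values, return_counts=True)
        correction = 1.0 - float(np.sum(tie_counts**3 - tie_counts)) / (n**3 - n)
        if correction <= 0:
            return TestResult(0.0, m - 1, 1.0, "kruskal_wallis")
        H /= correction
    H = max(H, 0.0)
    p = float(sps.chi2.sf(H, m - 1))
    return TestResult(float(H), m - 1, p, "kruskal_wallis")


# --- Shapiro–Wilk (Royston's approximation) -------------------------------

def _sw_coefficients(n: int) -> np.ndarray:
    """Royston's approximate coefficients a_1..a_n (a_i = -a_{n-i+1})."""
    if n == 3:  # exact: a = (-sqrt(1/2), 0, sqrt(1/2))
        r = math.sqrt(0.5)
        return np.array([-r, 0.0, r])
    m = sps.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    ssq = float(np.sum(m * m))
    c = m / math.sqrt(ssq)
    a = c.copy()
    u = 1.0 / math.sqrt(n)
    # polynomial corrections to the extreme coefficients
    a_n = c[-1] + 0.221157 * u - 0.147981 * u**2 - 2.071190 * u**3 + 4.434685 * u**4 - 2.706056 * u**5
    if n > 5:
        a_n1 = (
            c[-2]
            + 0.042981 * u
            - 0.293762 * u**2
            - 1.752461 * u**3
            + 5.682633 * u**4
            - 3.582633 * u**5
        )
        phi = (ssq - 2.0 * m[-1] ** 2 - 2.0 * m[-2] ** 2) / (1.0 - 2.0 * a_n**2 - 2.0 * a_n1**2)
        a = m / math.sqrt(phi)
        a[-1], a[0] = a_n, -a_n
        a[-2], a[1] = a_n1, -a_n1
    else:
        phi = (ssq - 2.0 * m[-1] ** 2) / (1.0 - 2.0 * a_n**2)
        a = m / math.sqrt(phi)
        a[-1], a[0] = a_n, -a_n
    return a


def shapiro_wilk(values: Sequence[float]) -> TestResult:
    """Shapiro–Wilk W for normality of a sample of 3 <= n <= 5000 values.

    W is the squared correlation between the sample order statistics and
    the expected normal order statistics; p-values come from Royston's
    normalizing transformation (exact for n = 3).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 3 or n > 5000:
        raise ValueError("Shapiro-Wilk needs 3 <= n <= 5000")
    denom = float(np.sum((x - x.mean()) ** 2))
    if denom == 0.0:
        raise ValueError("constant sample: W undefined")
    a = _sw_coefficients(n)
    W = float(np.dot(a, x)) ** 2 / denom
    W = min(W, 1.0)

    if n == 3:
        p = (6.0 / math.pi) * (math.asin(math.sqrt(W)) - math.asin(math.sqrt(0.75)))
        p = min(max(p, 0.0), 1.0)
    elif n <= 11:
        g = -2.273 + 0.459 * n
        mu = 0.5440 - 0.39978 * n + 0.025054 * n**2 - 0.0006714 * n**3
        sigma = math.exp(1.3822 - 0.77857 * n + 0.062767 * n**2 - 0.0020322 * n**3)
        if g - math.log1p(-W) <= 0:
            p = 0.0
        else:
            z = (-math.log(g - math.log1p(-W)) - mu) / sigma
            p = float(sps.norm.sf(z))
    else:
        ln_n = math.log(n)
        mu = -1.5861 - 0.31082 * ln_n - 0.083751 * ln_n**2 + 0.0038915 * ln_n**3
        sigma = math.exp(-0.4803 - 0.082676 * ln_n + 0.0030302 * ln_n**2)
        z = (math.log1p(-W) - mu) / sigma
        p = float(sps.norm.sf(z))
    return TestResult(W, None, p, "shapiro_wilk")


def multiprop_test(p_list: Sequence[float], d: float) -> TestResult:
    """Multiple-proportion test of per-individual genome-covered proportions.

    With l individuals carrying proportions p_i of a genome of length d,

        F = [ sum d (p_i - pbar)^2 / sum p_i (1 - p_i) ] * l / (l - 1)

    follows F(l-1, t) with t → ∞ under the common-proportion null; the
    p-value is taken from the chi-square distribution of (l-1)·F on l-1 df.
    Proportions must lie strictly inside (0, 1).
    """
    p = np.asarray(p_list, dtype=float)
    if p.size < 2:
        raise ValueError("need at least 2 individuals")
    if d <= 0:
        raise ValueError("genome length must be positive")
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("all proportions must be strictly inside (0, 1)")
    l = p.size
    pbar = float(p.mean())
    num = float(d * np.sum((p - pbar) ** 2))
    den = float(np.sum(p * (1.0 - p)))
    F = num / den * l / (l - 1)
    p_value = float(sps.chi2.sf((l - 1) * F, l - 1))
    return TestResult(F, (l - 1, math.inf), p_value, "multiprop")


def bonferroni(p_values: Sequence[float], m_tests: Optional[int] = None) -> List[float]:
    """Bonferroni adjustment: min(1, p * m); order preserved."""
    m = len(p_values) if m_tests is None else m_tests
    return [min(1.0, p * m) for p in p_values]


# --- the variation suite --------------------------------------------------

DEFAULT_SUITE_BREEDS = None  # None → the five most numerous kept breeds


def _suite_breeds(manifest: Sequence[SampleRecord], breeds: Optional[Sequence[str]]) -> List[str]:
    if breeds is not None:
        return list(breeds)
    kept = [s for s in manifest if s.status == "kept"]
    sizes = pd.Series([s.breed for s in kept]).value_counts()
    return list(sizes.index[:5])


def run_variation_suite(
    consensus_sets: Sequence[ConsensusSet],
    manifest: Sequence[SampleRecord],
    build: GenomeBuild,
    breeds: Optional[Sequence[str]] = None,
    validated_only: bool = True,
    tie_correction: bool = True,
    max_sw_n: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the full inter-individual / inter-breed variation analysis.

    Per CNV type: count dispersion across all kept individuals and within
    each breed; Kruskal–Wallis on counts across breeds, on lengths across
    individuals and across breeds; Shapiro–Wilk on pooled lengths
    (down-sampled to *max_sw_n* values with a seeded generator when larger);
    the multiple-proportion test within each breed, Bonferroni-corrected
    across breeds.  Breeds with fewer than 2 usable samples are skipped with
    a logged warning.  Deterministic for fixed input and seed.
    """
    breed_of = {s.sample_id: s.breed for s in manifest}
    kept_ids = {s.sample_id for s in manifest if s.status == "kept"}
    csets = [cs for cs in consensus_sets if cs.sample_id in kept_ids]
    suite_breeds = _suite_breeds(manifest, breeds)
    rng = np.random.default_rng(seed)

    rows: List[dict] = []

    def add(scope: str, cnv_type: str, res: TestResult, p_adj: Optional[float] = None) -> None:
        df = res.df
        rows.append(
            {
                "cnv_type": cnv_type,
                "test": res.test_name,
                "scope": scope,
                "statistic": res.statistic,
                "df": df if not isinstance(df, tuple) else f"{df[0]},inf",
                "p_value": res.p_value,
                "p_adjusted": p_adj,
            }
        )

    for cnv_type in CNV_TYPES:
        counts = {}
        lengths = {}
        for cs in csets:
            calls = cs.validated_calls if validated_only else list(cs.calls)
            of_type = [c for c in calls if c.cnv_type == cnv_type]
            counts[cs.sample_id] = len(of_type)
            lengths[cs.sample_id] = [c.length for c in of_type]

        # count dispersion across all individuals, then within breeds
        all_counts = list(counts.values())
        if len(all_counts) >= 2 and np.mean(all_counts) > 0:
            add("all_individuals", cnv_type, chi2_count_test(all_counts))
        for breed in suite_breeds:
            breed_counts = [counts[s] for s in counts if breed_of[s] == breed]
            if len(breed_counts) < 2 or np.mean(breed_counts) == 0:
                logger.warning("breed %s skipped for %s count dispersion", breed, cnv_type)
                continue
            add(f"within:{breed}", cnv_type, chi2_count_test(breed_counts))

        # counts across breeds (Kruskal-Wallis)
        count_groups = [
            [counts[s] for s in counts if breed_of[s] == breed] for breed in suite_breeds
        ]
        count_groups = [g for g in count_groups if len(g) >= 2]
        if len(count_groups) >= 2:
            add(
                "between_breeds",
                cnv_type,
                kruskal_wallis(count_groups, tie_correction=tie_correction),
            )

        # lengths across individuals and across breeds
        length_groups_ind = [v for v in lengths.values() if v]
        if len(length_groups_ind) >= 2:
            add(
                "between_individuals",
                cnv_type,
                kruskal_wallis(length_groups_ind, tie_correction=tie_correction),
            )
        length_groups_breed = [
            [x for s in lengths if breed_of[s] == breed for x in lengths[s]]
            for breed in suite_breeds
        ]
        length_groups_breed = [g for g in length_groups_breed if g]
        if len(length_groups_breed) >= 2:
            add(
                "between_breeds_lengths",
                cnv_type,
                kruskal_wallis(length_groups_breed, tie_correction=tie_correction),
            )

        # normality of pooled lengths
        pooled = np.asarray([x for v in lengths.values() for x in v], dtype=float)
        if pooled.size > max_sw_n:
            pooled = rng.choice(pooled, size=max_sw_n, replace=False)
        if pooled.size >= 3 and np.unique(pooled).size > 1:
            add("pooled_lengths", cnv_type, shapiro_wilk(pooled))

        # genome-covered proportions within breeds, Bonferroni across breeds
        prop_results = []
        for breed in suite_breeds:
            props = []
            for cs in csets:
                if breed_of[cs.sample_id] != breed:
                    continue
                pct = genome_covered_pct(cs, build, cnv_type, validated_only=validated_only)
                prop = pct / 100.0
                if prop <= 0.0 or prop >= 1.0:
                    logger.warning(
                        "sample %s dropped from %s proportion test (p_i=%g)",
                        cs.sample_id,
                        cnv_type,
                        prop,
                    )
                    continue
                props.append(prop)
            if len(props) < 2:
                logger.warning("breed %s skipped for %s proportion test", breed, cnv_type)
                continue
            prop_results.append((breed, multiprop_test(props, build.total_length)))
        adjusted = bonferroni([r.p_value for _, r in prop_results], len(prop_results))
        for (breed, res), p_adj in zip(prop_results, adjusted):
            add(f"coverage_within:{breed}", cnv_type, res, p_adj)

    return pd.DataFrame(
        rows,
        columns=["cnv_type", "test", "scope", "statistic", "df", "p_value", "p_adjusted"],
    )
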