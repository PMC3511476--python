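"""FST-based migration estimation and the binomial gene-flow test.

FST for a pair of populations is one minus the ratio of within- to
between-population diversity, where diversity is the mean number of
pairwise sequence differences.  Under the symmetric d-island
model on the coalescent timescale used throughout (pair coalescence rate 1
within a deme, per-lineage migration rate M/2), the expected pairwise
coalescence times are d within a deme and d + (d-1)/M between demes, so

    FST = 1 / (1 + M d / (d - 1)),   M = (d - 1) (1 - FST) / (d FST).

Gene-by-gene FST values give a genome-wide distribution of migration
estimates, summarized by percentiles weighted by gene length and by the
fraction of sites with complete data.

The gene-flow test asks whether the observed count of disrupting
recombination events ancestral to the outgroup clade (R_A) exceeds the
null fraction predicted by the coalescent model.  Because nearby events
within a gene are not independent, the binomial sample size is
conservatively rescaled from the event count down to the number of genes
scaled by the fraction of intervals in which the population is an
outgroup, rounding the sample size up and the observation down (both
shifts can only increase the one-tailed p-value); the Bonferroni factor
accounts for testing every population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .arg import PopulationMap


@dataclass(frozen=True)
class FstRecord:
    gene_id: str
    pop_a: str
    pop_b: str
    within: float
    between: float
    fst: float | None  # None when between-diversity is zero
    gene_length: int
    weight: float  # gene length x fraction of complete-data sites
    clamped: bool = False  # negative estimate clamped to zero

    @property
    def valid(self) -> bool:
        return self.fst is not None


@dataclass(frozen=True)
class MigrationEstimate:
    pair: tuple[str, str] | None
    m_per_gene: tuple[float, ...]
    weights: tuple[float, ...]
    percentiles: dict[float, float]
    pooled: float  # length-weighted median


@dataclass(frozen=True)
class BinomialTestResult:
    population: str
    x: int
    n: int
    x_eff: int
    n_eff: int
    p0: float
    p_value: float
    p_corrected: float
    n_tests: int


def _mean_pairwise_diff(a: np.ndarray, b: np.ndarray | None = None) -> float:
    """Mean pairwise differences within rows of ``a`` or between ``a``/``b``.

    Missing genotypes are encoded as negative values and skipped per
    pairwise site comparison.
    """
    if b is None:
        rows = [(a[i], a[j]) for i in range(len(a)) for j in range(i + 1, len(a))]
    else:
        rows = [(x, y) for x in a for y in b]
    if not rows:
        raise ValueError("need at least one pair")
    diffs = []
    for x, y in rows:
        ok = (x >= 0) & (y >= 0)
        diffs.append(float(np.sum((x != y) & ok)))
    return float(np.mean(diffs))


def fst_hudson(haplotypes: np.ndarray, sample_ids: list[str],
               popmap: PopulationMap, pair: tuple[str, str],
               gene_id: str = "", gene_length: int | None = None) -> FstRecord:
    """Hudson-style FST from a binary SNP incidence matrix.

    ``haplotypes`` has one row per sample and one 0/1 column per
    segregating site (negative = missing).  Within-diversity is the average
    of the two within-population mean pairwise difference values; between
    is the mean over cross-population pairs; FST = 1 - within/between.
    Negative estimates are clamped to zero and flagged.
    """
    pa, pb = pair
    rows = {s: haplotypes[i] for i, s in enumerate(sample_ids)}
    ga = np.array([rows[s] for s in sorted(popmap.samples_of(pa))])
    gb = np.array([rows[s] for s in sorted(popmap.samples_of(pb))])
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("need >= 2 samples per population")
    within = 0.5 * (_mean_pairwise_diff(ga) + _mean_pairwise_diff(gb))
    between = _mean_pairwise_diff(ga, gb)
    length = gene_length if gene_length is not None else haplotypes.shape[1]
    n_sites = haplotypes.shape[1]
    complete = float(np.mean((haplotypes >= 0).all(axis=0))) if n_sites else 1.0
    weight = length * complete
    if between <= 0:
        return FstRecord(gene_id, pa, pb, within, between, None,
                         length, weight)
    fst = 1.0 - within / between
    clamped = fst < 0
    return FstRecord(gene_id, pa, pb, within, between,
                     max(fst, 0.0), length, weight, clamped=clamped)


def fst_from_m(M: float, d: int = 5) -> float:
    """Forward map: equilibrium FST of the symmetric d-island model."""
    if M <= 0:
        return 1.0
    return 1.0 / (1.0 + M * d / (d - 1))


def m_from_fst(fst: float, d: int = 5) -> float:
    """Invert the island-model FST relationship to a migration estimate.

    Strictly decreasing in FST; FST >= 1 maps to 0 and FST <= 0 to
    infinity (no-differentiation sentinel).
    """
    if fst >= 1.0:
        return 0.0
    if fst <= 0.0:
        return math.inf
    return (d - 1) * (1.0 - fst) / (d * fst)


def migration_distribution(records: list[FstRecord], d: int = 5,
                           percentiles=(2.5, 25, 50, 75, 97.5)
                           ) -> MigrationEstimate:
    """Weighted percentile summary of per-gene migration estimates.

    Weights are gene length times the fraction of complete-data sites.
    Genes with undefined FST are dropped; an error is raised if none
    remain.
    """
    vals = []
    wts = []
    pairs = set()
    for r in records:
        if not r.valid:
            continue
        pairs.add((r.pop_a, r.pop_b))
        vals.append(m_from_fst(r.fst, d))
        wts.append(r.weight)
    if not vals:
        raise ValueError("no valid FST records")
    vals_a = np.asarray(vals)
    wts_a = np.asarray(wts, dtype=float)
    order = np.argsort(vals_a)
    vals_a = vals_a[order]
    wts_a = wts_a[order]
    cum = np.cumsum(wts_a)
    cum = cum / cum[-1]
    out = {}
    for q in percentiles:
        idx = int(np.searchsorted(cum, q / 100.0, side="left"))
        out[q] = float(vals_a[min(idx, len(vals_a) - 1)])
    pooled = out.get(50.0, out.get(50, None))
    if pooled is None:
        idx = int(np.searchsorted(cum, 0.5, side="left"))
        pooled = float(vals_a[min(idx, len(vals_a) - 1)])
    return MigrationEstimate(
        pair=next(iter(pairs)) if len(pairs) == 1 else None,
        m_per_gene=tuple(vals), weights=tuple(wts),
        percentiles=out, pooled=pooled)


def binomial_gene_flow_test(x: int, n: int, p0: float, n_genes: int,
                            frac_outgroup: float, n_tests: int = 5,
                            population: str = "") -> BinomialTestResult:
    """Conservatively rescaled one-tailed binomial test for excess R_A.

    The effective sample size is ``ceil(n_genes * frac_outgroup)`` (one
    effective trial per outgroup locus) and the effective observation is
    ``floor(x * n_eff / n)``, carrying the event-level R_A fraction over
    to the locus scale; the p-value is P(X >= x_eff) under
    Binomial(n_eff, p0), Bonferroni-multiplied by ``n_tests`` and capped
    at 1.
    """
    if not (0 <= x <= n):
        raise ValueError("need 0 <= x <= n")
    if not (0 < p0 < 1):
        raise ValueError("need 0 < p0 < 1")
    if n_genes < 1:
        raise ValueError("need n_genes >= 1")
    if n == 0:
        raise ValueError("no disrupting events: nothing to test")
    n_eff = max(1, math.ceil(n_genes * frac_outgroup))
    x_eff = min(math.floor(x * n_eff / n), n_eff)
    p = float(stats.binom.sf(x_eff - 1, n_eff, p0))
    return BinomialTestResult(
        population=population, x=x, n=n, x_eff=x_eff, n_eff=n_eff, p0=p0,
        p_value=p, p_corrected=min(1.0, p * n_tests), n_tests=n_tests)


def gene_flow_report(tally: pd.DataFrame, p0_by_k: dict[float, dict[int, float]],
                     n_tests: int | None = None) -> pd.DataFrame:
    """Per-population test report over a ladder of null fractions.

    ``tally`` is the genome-level table from :func:`argscan.scan.genome_tally`;
    ``p0_by_k`` maps a migration parameter to null R_A fractions per clade
    size (e.g. ``{1.0: {3: 0.316, 2: 0.307}}``).  Rows mirror the ladder of
    M values, columns the populations (Bonferroni-corrected p-values);
    populations with no disrupting events are reported as NA.  Since
    statistical power shrinks as the assumed M grows, testing against an
    overestimate of M is the conservative application.
    """
    if n_tests is None:
        n_tests = len(tally)
    rows = []
    for M, by_k in p0_by_k.items():
        row = {"M": M}
        for _, rec in tally.iterrows():
            n = int(rec["n_RA"] + rec["n_RO"])
            if n == 0:
                row[rec["population"]] = math.nan
                continue
            res = binomial_gene_flow_test(
                int(rec["n_RA"]), n, by_k[int(rec["k"])],
                int(rec["n_genes"]), float(rec["frac_outgroup"]),
                n_tests=n_tests, population=rec["population"])
            row[rec["population"]] = res.p_corrected
        rows.append(row)
    return pd.DataFrame(rows)
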