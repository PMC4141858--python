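"""Clone-aware standard population genetics on diploid microsatellite panels.

Long-term parthenogens carry a recognisable signature: heterozygosity is
frozen at the founding genotype, so observed heterozygosity exceeds the
Hardy-Weinberg expectation and F_IS is strongly negative.  This module
provides the estimators and tests used to detect it:

* allele frequencies and observed / unbiased expected heterozygosity,
* Weir & Cockerham (1984) f (within-population F_IS) and theta (pairwise
  F_ST), multi-allelic, combined over loci as ratios of summed variance
  components,
* seeded Monte-Carlo exact tests of Hardy-Weinberg equilibrium (two-sided on
  the conditional probability of the genotype table, one-sided on observed
  heterozygosity) with the (1 + k)/(1 + n_perm) estimator,
* the genic G-test of differentiation (allele x population contingency
  table per locus, summed over loci, p by permutation of individuals).

Analyses should normally run on the one-representative-per-MLG-per-sample
reduction of a clonal panel; running on a raw panel mixes in clonal
pseudo-replication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotype_io import MISSING, GenotypePanel

__all__ = [
    "allele_frequencies",
    "heterozygosity",
    "fis_estimate",
    "multilocus_fis",
    "hwe_test",
    "hwe_test_global",
    "pairwise_fst",
    "g_test_differentiation",
]


# ---------------------------------------------------------------------------
# grouping helpers
# ---------------------------------------------------------------------------

def _resolve_grouping(panel: GenotypePanel, grouping) -> pd.Series:
    """Normalise a grouping spec to a Series of population labels per row.

    ``grouping`` may be a metadata column name, a mapping individual id ->
    population, or a sequence of labels aligned with the panel rows.
    """
    if isinstance(grouping, str):
        if grouping not in panel.meta.columns:
            raise KeyError(f"no metadata column {grouping!r}")
        return panel.meta[grouping]
    if isinstance(grouping, Mapping):
        return pd.Series([grouping[i] for i in panel.individuals])
    labels = pd.Series(list(grouping))
    if len(labels) != panel.n_individuals:
        raise ValueError("grouping length does not match panel size")
    return labels


def _pop_genotypes(
    panel: GenotypePanel, grouping
) -> dict[str, np.ndarray]:
    """Split the allele array by population (row order preserved)."""
    labels = _resolve_grouping(panel, grouping)
    out: dict[str, np.ndarray] = {}
    for pop in pd.unique(labels):
        out[pop] = panel.alleles[np.asarray(labels == pop)]
    return out


def _locus_calls(genotypes: np.ndarray, locus: int, missing: int) -> np.ndarray:
    """Non-missing ``(n, 2)`` calls of one locus from an ``(n, L, 2)`` array."""
    g = genotypes[:, locus, :]
    keep = ~(g == missing).any(axis=1)
    return g[keep]


# ---------------------------------------------------------------------------
# frequencies and heterozygosity
# ---------------------------------------------------------------------------

@dataclass
class AlleleFrequencies:
    """Tidy per-(population, locus, allele) frequency table."""

    table: pd.DataFrame  # population, locus, allele, count, frequency
    gene_copies: pd.DataFrame  # population, locus, n_gene_copies

    def freqs(self, population, locus) -> dict[int, float]:
        sub = self.table[
            (self.table["population"] == population) & (self.table["locus"] == locus)
        ]
        return dict(zip(sub["allele"].astype(int), sub["frequency"]))


def allele_frequencies(panel: GenotypePanel, grouping) -> AlleleFrequencies:
    """Allele counts / 2n per population and locus (alleles ordered by size)."""
    pops = _pop_genotypes(panel, grouping)
    rows, copies = [], []
    for pop, geno in pops.items():
        if len(geno) == 0:
            raise ValueError(f"empty population {pop!r}")
        for j, locus in enumerate(panel.loci):
            calls = _locus_calls(geno, j, panel.missing).ravel()
            copies.append(
                {"population": pop, "locus": locus, "n_gene_copies": len(calls)}
            )
            if len(calls) == 0:
                continue
            vals, counts = np.unique(calls, return_counts=True)
            for v, c in zip(vals, counts):
                rows.append(
                    {
                        "population": pop,
                        "locus": locus,
                        "allele": int(v),
                        "count": int(c),
                        "frequency": c / len(calls),
                    }
                )
    return AlleleFrequencies(pd.DataFrame(rows), pd.DataFrame(copies))


def heterozygosity(panel: GenotypePanel, grouping) -> pd.DataFrame:
    """Observed and unbiased expected heterozygosity per (population, locus).

    ``He = 2n/(2n-1) * (1 - sum f_k^2)`` (Nei's unbiased gene diversity);
    undefined (NaN, flagged) for single-individual populations.
    """
    pops = _pop_genotypes(panel, grouping)
    rows = []
    for pop, geno in pops.items():
        for j, locus in enumerate(panel.loci):
            calls = _locus_calls(geno, j, panel.missing)
            n = len(calls)
            if n == 0:
                continue
            ho = float(np.mean(calls[:, 0] != calls[:, 1]))
            if n == 1:
                he = float("nan")
            else:
                f = np.unique(calls.ravel(), return_counts=True)[1] / (2 * n)
                he = (2 * n / (2 * n - 1)) * (1.0 - float(np.sum(f**2)))
            rows.append(
                {"population": pop, "locus": locus, "n": n, "Ho": ho, "He": he}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Weir & Cockerham estimators
# ---------------------------------------------------------------------------

def _wc_within_components(
    calls: np.ndarray,
) -> tuple[float, float]:
    """Summed (b, c) variance components over alleles for one population/locus.

    For allele u with frequency p and heterozygote-carrier frequency h in a
    sample of n individuals:
    ``b = n/(n-1) * (p(1-p) - (2n-1)/(4n) * h)`` and ``c = h/2``.
    The within-population inbreeding estimate is ``f = 1 - sum c / sum(b+c)``.
    """
    n = len(calls)
    alleles = np.unique(calls.ravel())
    b_sum = c_sum = 0.0
    for u in alleles:
        carries = calls == u
        p = carries.mean()
        h = float(np.mean(carries[:, 0] != carries[:, 1]))
        b = n / (n - 1) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
        c = h / 2.0
        b_sum += b
        c_sum += c
    return b_sum, c_sum


def fis_estimate(panel: GenotypePanel, grouping) -> tuple[pd.DataFrame, dict]:
    """Weir-Cockerham f (F_IS) per (population, locus) and multilocus.

    Monomorphic loci are undefined and excluded from the multilocus ratio of
    summed components.  Returns ``(per_locus_table, multilocus_per_pop)``.
    """
    pops = _pop_genotypes(panel, grouping)
    rows = []
    multilocus: dict = {}
    for pop, geno in pops.items():
        tot_b = tot_c = 0.0
        for j, locus in enumerate(panel.loci):
            calls = _locus_calls(geno, j, panel.missing)
            if len(calls) < 2 or len(np.unique(calls.ravel())) < 2:
                rows.append(
                    {"population": pop, "locus": locus, "f_is": float("nan")}
                )
                continue
            b, c = _wc_within_components(calls)
            tot_b += b
            tot_c += c
            denom = b + c
            f = 1.0 - c / denom if denom > 0 else float("nan")
            rows.append({"population": pop, "locus": locus, "f_is": f})
        multilocus[pop] = (
            1.0 - tot_c / (tot_b + tot_c) if (tot_b + tot_c) > 0 else float("nan")
        )
    return pd.DataFrame(rows), multilocus


def multilocus_fis(
    genotypes: np.ndarray, missing: int = MISSING
) -> float:
    """Multilocus Weir-Cockerham f for a bare ``(n, L, 2)`` genotype array."""
    genotypes = np.asarray(genotypes)
    tot_b = tot_c = 0.0
    for j in range(genotypes.shape[1]):
        calls = _locus_calls(genotypes, j, missing)
        if len(calls) < 2 or len(np.unique(calls.ravel())) < 2:
            continue
        b, c = _wc_within_components(calls)
        tot_b += b
        tot_c += c
    if tot_b + tot_c <= 0:
        return float("nan")
    return 1.0 - tot_c / (tot_b + tot_c)


def pairwise_fst(panel: GenotypePanel, pop_a, pop_b, grouping) -> float:
    """Weir & Cockerham (1984) theta between two populations.

    Multi-allelic a, b, c variance components summed over alleles and loci;
    theta = sum a / sum(a + b + c).  Loci with no data in either population
    are skipped; raises if no locus is usable.
    """
    pops = _pop_genotypes(panel, grouping)
    for p in (pop_a, pop_b):
        if p not in pops or len(pops[p]) == 0:
            raise ValueError(f"empty or unknown population {p!r}")
    num = den = 0.0
    usable = 0
    for j in range(panel.n_loci):
        calls = [
            _locus_calls(pops[p], j, panel.missing) for p in (pop_a, pop_b)
        ]
        if any(len(c) < 2 for c in calls):
            continue
        alleles = np.unique(np.concatenate([c.ravel() for c in calls]))
        if len(alleles) < 2:
            continue
        usable += 1
        r = 2
        n_i = np.array([len(c) for c in calls], dtype=float)
        nbar = n_i.mean()
        nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
        for u in alleles:
            p_i = np.array([(c == u).mean() for c in calls])
            h_i = np.array(
                [float(np.mean((c == u).sum(axis=1) == 1)) for c in calls]
            )
            pbar = (n_i * p_i).sum() / (r * nbar)
            s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n_i * h_i).sum() / (r * nbar)
            a = (nbar / nc) * (
                s2
                - (1.0 / (nbar - 1))
                * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - ((r - 1) / r) * s2
                - ((2 * nbar - 1) / (4 * nbar)) * hbar
            )
            c = hbar / 2.0
            num += a
            den += a + b + c
    if usable == 0 or den == 0:
        raise ValueError("no polymorphic locus usable for theta")
    return num / den


# ---------------------------------------------------------------------------
# Hardy-Weinberg Monte-Carlo exact tests
# ---------------------------------------------------------------------------

def _pair_up(pool: np.ndarray) -> np.ndarray:
    """View a flat allele pool of length 2n as n consecutive pairs."""
    return pool.reshape(-1, 2)


def _log_table_prob(pairs: np.ndarray) -> float:
    """Log conditional probability (up to allele-count constants) of a
    genotype table given its allele counts: ``h ln 2 - sum ln(n_g!)``."""
    het = int(np.sum(pairs[:, 0] != pairs[:, 1]))
    key = np.sort(pairs, axis=1)
    # encode pairs as single ints for counting
    enc = key[:, 0].astype(np.int64) * 100000 + key[:, 1]
    _, counts = np.unique(enc, return_counts=True)
    return het * np.log(2.0) - float(gammaln(counts + 1.0).sum())


def hwe_test(
    panel: GenotypePanel,
    pop,
    locus: str,
    grouping,
    alternative: str = "two_sided",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> float:
    """Monte-Carlo exact test of Hardy-Weinberg proportions in one population.

    Alleles at the locus are randomly re-paired ``n_perm`` times.  The
    statistic is the conditional probability of the genotype table
    (``two_sided``: tables no more probable than the observed count as
    extreme) or observed heterozygosity (``excess`` / ``deficit``).
    ``p = (1 + k)/(1 + n_perm)``; monomorphic loci return 1 with a warning.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if alternative not in ("two_sided", "excess", "deficit"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pops = _pop_genotypes(panel, grouping)
    if pop not in pops:
        raise ValueError(f"unknown population {pop!r}")
    j = panel.loci.index(locus)
    calls = _locus_calls(pops[pop], j, panel.missing)
    if len(np.unique(calls.ravel())) < 2:
        warnings.warn(f"locus {locus!r} monomorphic in {pop!r}; p = 1")
        return 1.0
    rng = np.random.default_rng(seed)
    pool = calls.ravel().copy()
    if alternative == "two_sided":
        obs = _log_table_prob(calls)
        k = 0
        for _ in range(n_perm):
            rng.shuffle(pool)
            if _log_table_prob(_pair_up(pool)) <= obs + 1e-12:
                k += 1
    else:
        obs_ho = float(np.mean(calls[:, 0] != calls[:, 1]))
        k = 0
        for _ in range(n_perm):
            rng.shuffle(pool)
            pairs = _pair_up(pool)
            ho = float(np.mean(pairs[:, 0] != pairs[:, 1]))
            if alternative == "excess":
                k += ho >= obs_ho - 1e-12
            else:
                k += ho <= obs_ho + 1e-12
    return (1 + k) / (1 + n_perm)


def hwe_test_global(
    panel: GenotypePanel,
    pop,
    grouping,
    alternative: str = "excess",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> float:
    """Multilocus heterozygote excess/deficit test for one population.

    Statistic: total observed heterozygote count over polymorphic loci;
    alleles are re-paired independently within each locus per permutation.
    Vectorised so n_perm = 10^4 is cheap.
    """
    if alternative not in ("excess", "deficit"):
        raise ValueError("global test is one-sided: 'excess' or 'deficit'")
    pops = _pop_genotypes(panel, grouping)
    if pop not in pops:
        raise ValueError(f"unknown population {pop!r}")
    rng = np.random.default_rng(seed)
    obs_total = 0.0
    perm_total = np.zeros(n_perm)
    any_locus = False
    for j in range(panel.n_loci):
        calls = _locus_calls(pops[pop], j, panel.missing)
        if len(calls) < 2 or len(np.unique(calls.ravel())) < 2:
            continue
        any_locus = True
        obs_total += float(np.sum(calls[:, 0] != calls[:, 1]))
        pool = calls.ravel()
        # one argsort of random keys per permutation row = a random shuffle
        order = np.argsort(rng.random((n_perm, len(pool))), axis=1)
        shuffled = pool[order].reshape(n_perm, -1, 2)
        perm_total += np.sum(shuffled[:, :, 0] != shuffled[:, :, 1], axis=1)
    if not any_locus:
        warnings.warn(f"no polymorphic locus in {pop!r}; p = 1")
        return 1.0
    if alternative == "excess":
        k = int(np.sum(perm_total >= obs_total - 1e-9))
    else:
        k = int(np.sum(perm_total <= obs_total + 1e-9))
    return (1 + k) / (1 + n_perm)


# ---------------------------------------------------------------------------
# G-test of genic differentiation
# ---------------------------------------------------------------------------

def _g_statistic(table: np.ndarray) -> float:
    """G = 2 sum o ln(o/e) over an observed contingency table."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    if total == 0:
        return 0.0
    e = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    mask = table > 0
    return float(2.0 * np.sum(table[mask] * np.log(table[mask] / e[mask])))


def _genic_tables(
    alleles_by_pop: Sequence[np.ndarray], locus: int, missing: int
) -> np.ndarray | None:
    """Allele x population count table for one locus (None if unusable)."""
    cols = []
    values = set()
    calls = []
    for geno in alleles_by_pop:
        c = _locus_calls(geno, locus, missing).ravel()
        calls.append(c)
        values.update(c.tolist())
    values = sorted(values)
    if len(values) < 2 or any(len(c) == 0 for c in calls):
        return None
    idx = {v: i for i, v in enumerate(values)}
    table = np.zeros((len(values), len(calls)), dtype=float)
    for p, c in enumerate(calls):
        for v in c:
            table[idx[v], p] += 1
    return table


def g_test_differentiation(
    panel: GenotypePanel,
    grouping,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Genic G-test of differentiation among populations.

    Per locus, G is computed on the allele x population contingency table;
    the global statistic sums per-locus G over loci (Fisher's additivity for
    independent loci).  P-values come from permuting individuals among
    populations (``(1 + k)/(1 + n_perm)``).  Returns a table with one row
    per locus plus a ``"global"`` row.
    """
    labels = np.asarray(_resolve_grouping(panel, grouping))
    pops = pd.unique(labels)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    rng = np.random.default_rng(seed)

    def stats_for(lbls: np.ndarray) -> np.ndarray:
        by_pop = [panel.alleles[lbls == p] for p in pops]
        out = np.full(panel.n_loci, np.nan)
        for j in range(panel.n_loci):
            table = _genic_tables(by_pop, j, panel.missing)
            if table is not None:
                out[j] = _g_statistic(table)
        return out

    obs = stats_for(labels)
    exceed = np.zeros(panel.n_loci)
    exceed_global = 0
    obs_global = np.nansum(obs)
    work = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(work)
        per = stats_for(work)
        exceed += per >= obs - 1e-12
        exceed_global += np.nansum(per) >= obs_global - 1e-12
    rows = []
    for j, locus in enumerate(panel.loci):
        if np.isnan(obs[j]):
            rows.append({"locus": locus, "G": float("nan"), "p": float("nan")})
        else:
            rows.append(
                {
                    "locus": locus,
                    "G": obs[j],
                    "p": (1 + exceed[j]) / (1 + n_perm),
                }
            )
    rows.append(
        {"locus": "global", "G": obs_global, "p": (1 + exceed_global) / (1 + n_perm)}
    )
    return pd.DataFrame(rows)
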