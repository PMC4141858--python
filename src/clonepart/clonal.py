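"""Clonal structure: MLG collapse, allelic distances, MLL delimitation, p_sex.

In a parthenogenetic aphid population, individuals sharing a multilocus
genotype (MLG) are presumed members of one clone.  MLGs that differ by only a
few allele steps are usually the same clone blurred by somatic stepwise
mutation or fragment-scoring error; they are grouped into multilocus lineages
(MLLs) by single-linkage clustering under a distance threshold read off the
first minimum of the (typically multimodal) pairwise-distance histogram.

The distance between two diploid genotypes is the number of allelic
differences: per locus ``2 - |multiset intersection|`` of the two allele
pairs, summed over loci.  A heterozygote sharing one allele with another
genotype therefore counts one difference, not two.

The clonal hypothesis is validated with ``p_sex``: the binomial tail
probability that the observed repeats of a genotype arose from that many
independent sexual events, given the genotype's probability ``p_gen`` under
random mating (with optional F_IS correction and round-robin allele
frequencies).  Clonal richness is summarised as ``R = (G-1)/(N-1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import binom
from sklearn.base import BaseEstimator, ClusterMixin

from .genotype_io import MISSING, GenotypePanel


class ThresholdNotFound(ValueError):
    """The distance histogram has no interior local minimum."""


# ---------------------------------------------------------------------------
# MLG collapse
# ---------------------------------------------------------------------------

@dataclass
class MLGPartition:
    """Individuals collapsed to unique multilocus genotypes.

    ``mlg_ids`` are deterministic (``MLG-001`` ... in lexicographic genotype
    order); ``representatives`` holds one ``(L, 2)`` genotype per MLG.
    """

    loci: list[str]
    mlg_ids: list[str]
    representatives: np.ndarray  # (G, L, 2)
    membership: dict  # individual id -> mlg id
    members: dict  # mlg id -> list of individual ids
    counts: pd.Series  # copies per mlg
    sample_counts: pd.DataFrame  # mlg x sample copy counts
    missing: int = MISSING

    @property
    def n_mlg(self) -> int:
        return len(self.mlg_ids)

    def mlg_of(self, individual: str) -> str:
        return self.membership[individual]


def collapse_mlg(panel: GenotypePanel) -> MLGPartition:
    """Collapse a panel to its unique multilocus genotypes.

    Individuals with missing calls at every locus are excluded with a
    warning.  MLG ids are assigned in lexicographic order of the genotype
    tuples so the result is reproducible regardless of row order.
    """
    if panel.n_individuals == 0:
        raise ValueError("empty panel")
    keys, keep = [], []
    for i in range(panel.n_individuals):
        key = panel.genotype_key(i)
        if all(a == panel.missing for pair in key for a in pair):
            warnings.warn(
                f"individual {panel.individuals[i]!r} has no scored locus; "
                "excluded from MLG collapse",
                stacklevel=2,
            )
            continue
        keys.append(key)
        keep.append(i)
    unique_keys = sorted(set(keys))
    width = max(3, len(str(len(unique_keys))))
    id_of_key = {k: f"MLG-{j + 1:0{width}d}" for j, k in enumerate(unique_keys)}

    membership: dict = {}
    members: dict = {mid: [] for mid in id_of_key.values()}
    samples = panel.meta["sample"]
    sample_ids = list(dict.fromkeys(samples))
    sc = pd.DataFrame(
        0, index=list(id_of_key.values()), columns=sample_ids, dtype=int
    )
    for i, key in zip(keep, keys):
        ind = panel.individuals[i]
        mid = id_of_key[key]
        membership[ind] = mid
        members[mid].append(ind)
        sc.at[mid, samples.iloc[i]] += 1
    counts = pd.Series({mid: len(m) for mid, m in members.items()})
    reps = np.asarray([unique_keys[j] for j in range(len(unique_keys))])
    return MLGPartition(
        loci=list(panel.loci),
        mlg_ids=list(id_of_key.values()),
        representatives=reps,
        membership=membership,
        members=members,
        counts=counts,
        sample_counts=sc,
        missing=panel.missing,
    )


def representative_per_sample(
    panel: GenotypePanel, mlgs: MLGPartition | None = None
) -> GenotypePanel:
    """Retain a single (first-seen) representative of each MLG in each sample.

    Repeats of an MLG within a sample are taken to be copies from local
    clonal reproduction; this reduction removes that pseudo-replication
    before diversity and population-genetic analysis.  Idempotent.
    """
    if mlgs is None:
        mlgs = collapse_mlg(panel)
    seen: set = set()
    rows = []
    for i in range(panel.n_individuals):
        ind = panel.individuals[i]
        if ind not in mlgs.membership:
            continue  # all-missing individuals were dropped
        key = (panel.meta.at[i, "sample"], mlgs.membership[ind])
        if key not in seen:
            seen.add(key)
            rows.append(i)
    return panel.subset(rows)


# ---------------------------------------------------------------------------
# allelic distance
# ---------------------------------------------------------------------------

def _pair_shared(a: Sequence[int], b: Sequence[int]) -> int:
    """Multiset intersection size of two sorted diploid allele pairs."""
    if a[0] == b[0] and a[1] == b[1]:
        return 2
    shared = 0
    if a[0] in (b[0], b[1]) or a[1] in (b[0], b[1]):
        shared = len({a[0], a[1]} & {b[0], b[1]})
    return shared


def pairwise_allele_distance(
    g1: np.ndarray,
    g2: np.ndarray,
    missing: int = MISSING,
    rescale_missing: bool = True,
) -> int:
    """Number of allelic differences between two multilocus genotypes.

    Per locus the contribution is ``2 - |multiset intersection|`` of the two
    allele pairs.  Loci where either genotype is missing are skipped; if
    ``rescale_missing`` the sum is rescaled by ``L/(L-m)`` and rounded to the
    nearest integer.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.shape != g2.shape:
        raise ValueError("genotypes are scored at different locus sets")
    L = g1.shape[0]
    total, used = 0, 0
    for j in range(L):
        if missing in (g1[j, 0], g1[j, 1], g2[j, 0], g2[j, 1]):
            continue
        used += 1
        total += 2 - _pair_shared(g1[j], g2[j])
    if used == 0:
        raise ValueError("no locus comparable between the two genotypes")
    if used < L and rescale_missing:
        return int(round(total * L / used))
    return total


@dataclass
class DistanceMatrix:
    """Symmetric integer matrix of pairwise allelic differences."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=np.int64)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if (self.d < 0).any() or (self.d != self.d.T).any():
            raise ValueError("distance matrix must be symmetric, non-negative")
        if np.diag(self.d).any():
            raise ValueError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


def distance_matrix(
    mlgs: MLGPartition, rescale_missing: bool = True
) -> DistanceMatrix:
    """Full allelic-difference matrix over MLG representatives."""
    if mlgs.n_mlg < 2:
        raise ValueError("need at least two MLGs")
    n = mlgs.n_mlg
    d = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_allele_distance(
                mlgs.representatives[i],
                mlgs.representatives[j],
                missing=mlgs.missing,
                rescale_missing=rescale_missing,
            )
    return DistanceMatrix(list(mlgs.mlg_ids), d)


def distance_histogram(matrix: DistanceMatrix) -> pd.Series:
    """Counts of off-diagonal pairwise distances, zero-filled over 1..max."""
    iu = np.triu_indices(matrix.n, k=1)
    vals = matrix.d[iu]
    top = int(vals.max()) if len(vals) else 0
    counts = np.bincount(vals, minlength=top + 1)
    idx = np.arange(1, top + 1)
    return pd.Series(counts[1:], index=idx, name="count")


def detect_threshold(histogram: pd.Series) -> int:
    """Location of the first local minimum of the distance histogram.

    Returns the smallest ``d >= 2`` with ``count(d) < count(d-1)`` and
    ``count(d) <= count(d+1)`` (ties broken toward smaller ``d``), scanning
    the zero-filled support.  MLL grouping then joins MLGs with chain
    distance strictly below the returned value.

    Raises
    ------
    ThresholdNotFound
        If the histogram is monotone or otherwise has no interior minimum;
        the caller must then supply a threshold explicitly.
    """
    if len(histogram) == 0:
        raise ThresholdNotFound("empty histogram")
    top = int(max(histogram.index))
    counts = np.zeros(top + 1, dtype=np.int64)
    for d, c in histogram.items():
        counts[int(d)] = int(c)
    for d in range(2, top):
        if counts[d] < counts[d - 1] and counts[d] <= counts[d + 1]:
            return d
    raise ThresholdNotFound(
        "no interior local minimum in the distance histogram; "
        "supply a threshold explicitly"
    )


# ---------------------------------------------------------------------------
# MLL assignment
# ---------------------------------------------------------------------------

@dataclass
class MLLPartition:
    """Single-linkage grouping of MLGs into multilocus lineages."""

    threshold: int
    mlg_ids: list[str]
    labels: np.ndarray  # int label per mlg, ordered by smallest member
    membership: dict = field(init=False)  # mlg id -> mll index

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.membership = dict(zip(self.mlg_ids, self.labels.tolist()))

    @property
    def n_mll(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def mll_names(self) -> list[str]:
        """Letter names A, B, ... in label order (AA.. beyond 26)."""
        names = []
        for k in range(self.n_mll):
            name = ""
            j = k
            while True:
                name = chr(ord("A") + j % 26) + name
                j = j // 26 - 1
                if j < 0:
                    break
            names.append(name)
        return names

    def members_of(self, label: int) -> list[str]:
        return [m for m, l in zip(self.mlg_ids, self.labels) if l == label]


def assign_mll(matrix: DistanceMatrix, threshold: int) -> MLLPartition:
    """Group MLGs into MLLs: connected components of ``d < threshold`` edges.

    Labels are renumbered so lineage 0 contains the first MLG in id order,
    lineage 1 the first MLG not in lineage 0, and so on (deterministic).
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    adj = sparse.csr_matrix(matrix.d < threshold)
    _, raw = connected_components(adj, directed=False)
    relabel: dict[int, int] = {}
    labels = np.empty(matrix.n, dtype=int)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = len(relabel)
        labels[i] = relabel[r]
    return MLLPartition(threshold=threshold, mlg_ids=list(matrix.ids), labels=labels)


class LineageDelimiter(BaseEstimator, ClusterMixin):
    """Sklearn-style clusterer delimiting multilocus lineages.

    Parameters
    ----------
    threshold : "auto" or int, default "auto"
        Allele-difference cutoff; "auto" locates the first minimum of the
        pairwise-distance histogram.  Grouping joins genotypes with chain
        distance strictly below the cutoff.
    metric : {"allele", "precomputed"}, default "allele"
        With "allele", ``X`` is an ``(n, L, 2)`` array of diploid allele
        sizes (or an ``(n, 2L)`` flat layout); with "precomputed", ``X`` is a
        square integer distance matrix.
    missing, rescale_missing
        Missing-allele sentinel and whether to rescale distances at loci
        with missing data (allele metric only).

    Attributes
    ----------
    distances_ : DistanceMatrix
    histogram_ : pd.Series
    threshold_ : int
    labels_ : ndarray of lineage labels
    n_lineages_ : int
    """

    def __init__(
        self,
        threshold="auto",
        metric: str = "allele",
        missing: int = MISSING,
        rescale_missing: bool = True,
    ):
        self.threshold = threshold
        self.metric = metric
        self.missing = missing
        self.rescale_missing = rescale_missing

    def fit(self, X, y=None):
        X = np.asarray(X)
        if self.metric == "precomputed":
            if X.ndim != 2 or X.shape[0] != X.shape[1]:
                raise ValueError("precomputed metric expects a square matrix")
            ids = [str(i) for i in range(X.shape[0])]
            dm = DistanceMatrix(ids, X.astype(np.int64))
        elif self.metric == "allele":
            if X.ndim == 2:
                if X.shape[1] % 2:
                    raise ValueError("flat allele layout needs an even column count")
                X = X.reshape(X.shape[0], -1, 2)
            if X.ndim != 3 or X.shape[2] != 2:
                raise ValueError("allele metric expects an (n, L, 2) array")
            n = X.shape[0]
            d = np.zeros((n, n), dtype=np.int64)
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = pairwise_allele_distance(
                        X[i], X[j], self.missing, self.rescale_missing
                    )
            dm = DistanceMatrix([str(i) for i in range(n)], d)
        else:
            raise ValueError(f"unknown metric {self.metric!r}")
        self.distances_ = dm
        self.histogram_ = distance_histogram(dm)
        if self.threshold == "auto":
            self.threshold_ = detect_threshold(self.histogram_)
        else:
            self.threshold_ = int(self.threshold)
        part = assign_mll(dm, self.threshold_)
        self.partition_ = part
        self.labels_ = part.labels
        self.n_lineages_ = part.n_mll
        return self


# ---------------------------------------------------------------------------
# p_gen / p_sex
# ---------------------------------------------------------------------------

def simple_allele_frequencies(
    genotypes: np.ndarray, missing: int = MISSING
) -> list[dict[int, float]]:
    """Per-locus allele frequencies from an ``(n, L, 2)`` genotype array."""
    genotypes = np.asarray(genotypes)
    freqs = []
    for j in range(genotypes.shape[1]):
        col = genotypes[:, j, :].ravel()
        col = col[col != missing]
        if len(col) == 0:
            freqs.append({})
            continue
        vals, counts = np.unique(col, return_counts=True)
        freqs.append({int(v): c / len(col) for v, c in zip(vals, counts)})
    return freqs


def round_robin_frequencies(
    genotypes: np.ndarray, missing: int = MISSING
) -> list[dict[int, float]]:
    """Round-robin allele-frequency estimator for clonal data.

    Frequencies at locus *l* are counted over the unique multilocus
    genotypes obtained when locus *l* itself is excluded from the collapse,
    so a large clone inflates its alleles at each locus only once per
    distinct background.  Alleles present in the data but absent from the
    round-robin subset are given one pseudo-copy so p_gen stays defined.
    """
    genotypes = np.asarray(genotypes)
    n, L, _ = genotypes.shape
    freqs: list[dict[int, float]] = []
    for j in range(L):
        others = [k for k in range(L) if k != j]
        seen: dict[tuple, int] = {}
        for i in range(n):
            key = tuple(tuple(p) for p in genotypes[i][others])
            if key not in seen:
                seen[key] = i
        counts: dict[int, int] = {}
        for i in seen.values():
            for a in genotypes[i, j]:
                if a != missing:
                    counts[a] = counts.get(a, 0) + 1
        for a in np.unique(genotypes[:, j, :]):
            a = int(a)
            if a != missing and a not in counts:
                counts[a] = 1
        tot = sum(counts.values())
        freqs.append({int(a): c / tot for a, c in counts.items()})
    return freqs


def p_gen(
    genotype: np.ndarray,
    freqs: Sequence[Mapping[int, float]],
    f_is: float = 0.0,
    loci_used: Sequence[int] | None = None,
    missing: int = MISSING,
) -> float:
    """Probability of a multilocus genotype under random mating.

    Per locus: ``f_i^2 + f_i (1 - f_i) F_IS`` for a homozygote and
    ``2 f_i f_j (1 - F_IS)`` for a heterozygote, multiplied over
    ``loci_used`` (all loci by default).  With ``f_is=0`` this is the
    Hardy-Weinberg product ``prod f_i f_j * 2^h``.
    """
    genotype = np.asarray(genotype)
    if loci_used is None:
        loci_used = range(genotype.shape[0])
    p = 1.0
    for j in loci_used:
        a, b = int(genotype[j, 0]), int(genotype[j, 1])
        if missing in (a, b):
            continue
        table = freqs[j]
        for allele in {a, b}:
            if allele not in table:
                raise ValueError(
                    f"allele {allele} at locus index {j} absent from the "
                    "frequency table; estimate frequencies on a dataset "
                    "containing the genotype"
                )
        if a == b:
            fa = table[a]
            p *= fa * fa + fa * (1.0 - fa) * f_is
        else:
            p *= 2.0 * table[a] * table[b] * (1.0 - f_is)
    return min(max(p, 0.0), 1.0)


def p_sex(p_gen_value: float, n_copies: int, N: int) -> float:
    """Probability that >= ``n_copies`` of a genotype arise sexually in ``N`` draws.

    The binomial upper tail ``P(X >= n_copies)`` with ``X ~ Bin(N, p_gen)``.
    Small values mean the repeats are copies of one clone.
    """
    if n_copies < 2:
        raise ValueError("a repeated genotype requires n_copies >= 2")
    if n_copies > N:
        raise ValueError("n_copies cannot exceed N")
    if not 0.0 <= p_gen_value <= 1.0:
        raise ValueError("p_gen must be a probability")
    return float(binom.sf(n_copies - 1, N, p_gen_value))


def psex_for_mlls(
    mlgs: MLGPartition,
    mlls: MLLPartition,
    f_is: float | None = None,
    frequency_method: str = "round_robin",
) -> pd.DataFrame:
    """p_sex for each multilocus lineage, on its set of identical loci.

    Each MLL is treated as one repeated genotype: ``loci_used`` are the loci
    at which every member MLG carries the identical allele pair,
    ``n_copies`` is the number of member MLG observations, and ``N`` the
    total number of MLG observations in the dataset.  Frequencies come from
    the MLG representatives (round-robin by default, plain counting with
    ``frequency_method="simple"``); ``f_is`` defaults to the multilocus
    Weir-Cockerham estimate on the MLG representatives.
    """
    from .popgen import multilocus_fis  # local import to avoid cycle at import time

    reps = mlgs.representatives
    if frequency_method == "round_robin":
        freqs = round_robin_frequencies(reps, mlgs.missing)
    elif frequency_method == "simple":
        freqs = simple_allele_frequencies(reps, mlgs.missing)
    else:
        raise ValueError(f"unknown frequency method {frequency_method!r}")
    if f_is is None:
        f_is = multilocus_fis(reps, missing=mlgs.missing)
    N = int(mlgs.counts.sum())
    index_of = {mid: i for i, mid in enumerate(mlgs.mlg_ids)}
    rows = []
    names = mlls.mll_names()
    for label in range(mlls.n_mll):
        member_ids = mlls.members_of(label)
        member_idx = [index_of[m] for m in member_ids]
        member_reps = reps[member_idx]
        identical = [
            j
            for j in range(member_reps.shape[1])
            if len({tuple(g[j]) for g in member_reps}) == 1
            and mlgs.missing not in member_reps[0, j]
        ]
        n_copies = int(mlgs.counts.loc[member_ids].sum())
        pg = p_gen(member_reps[0], freqs, f_is=f_is, loci_used=identical,
                   missing=mlgs.missing)
        ps = p_sex(pg, n_copies, N) if n_copies >= 2 else float("nan")
        rows.append(
            {
                "mll": names[label],
                "n_mlg": len(member_ids),
                "n_copies": n_copies,
                "N": N,
                "n_identical_loci": len(identical),
                "f_is": f_is,
                "p_gen": pg,
                "p_sex": ps,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# clonal richness
# ---------------------------------------------------------------------------

@dataclass
class ClonalRichness:
    """Genotypic richness ``R = (G-1)/(N-1)``: 0 = monoclonal, 1 = all distinct."""

    G: int
    N: int

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("richness undefined for N < 2")
        if not 1 <= self.G <= self.N:
            raise ValueError("need 1 <= G <= N")

    @property
    def R(self) -> float:
        return (self.G - 1) / (self.N - 1)

    def rounded(self, ndigits: int = 3) -> float:
        return round(self.R, ndigits)


def clonal_richness(G: int, N: int) -> ClonalRichness:
    """Clonal richness of ``G`` genotypes (MLGs or MLLs) among ``N`` units."""
    return ClonalRichness(G, N)
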