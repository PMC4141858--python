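"""Synthetic clonal microsatellite panels and COI alignments with ground truth.

The generator emulates a worldwide collection of an anholocyclic aphid:
a handful of founder clones (lineages), each seeding a block of field
samples, reproducing strictly apomictically so offspring are copies of the
founder genotype apart from stepwise microsatellite mutation (allele size
+-1 motif per event) and optional fragment-scoring error.  Founder
genotypes are drawn to be mutually distant (>= ``founder_min_distance``
allelic differences) and to mix heterozygous and homozygous loci, so a
simulated lineage shows the fixed-heterozygosity clonal signature.  Each
lineage also carries one COI founder haplotype at a configured substitution
distance from a root sequence.

Everything is deterministic given the config seed, and the returned
:class:`SimTruth` records lineage membership, founders and the full
mutation event log, so downstream recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coi import HaplotypePanel
from .genotype_io import MISSING, GenotypePanel


@dataclass
class SimConfig:
    """Study-design parameters of the clonal simulator.

    Defaults are the "paper-like" worldwide survey: 5 lineages, 10
    dinucleotide loci, 57 samples (from 42 localities on 2 main hosts) and
    1333 individuals, with mutation pressure that leaves members of a
    lineage within 1-4 allele steps of each other while founders sit >= 8
    steps apart.
    """

    seed: int = 0
    n_lineages: int = 5
    n_loci: int = 10
    founder_min_distance: int = 8
    allele_range: tuple[int, int] = (180, 260)
    motif: int = 2
    founder_het_fraction: float = 0.5
    generations: int = 60
    mutation_rate: float = 2e-4  # per allele per generation, stepwise +-1 motif
    max_mutations_per_individual: int | None = 2
    scoring_error_rate: float = 0.0
    n_samples: int = 57
    n_localities: int = 42
    individuals_per_sample: int = 23
    total_individuals: int | None = 1333
    sample_lineage_weights: tuple[int, ...] = (12, 7, 25, 12, 1)
    hosts: tuple[str, ...] = ("sorghum", "sugarcane")
    coi_length: int = 658
    coi_substitutions: tuple[int, ...] = (0, 1, 1, 1, 2)
    coi_individual_rate: float = 0.0

    def validate(self) -> None:
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if not 0 <= self.scoring_error_rate <= 1:
            raise ValueError("scoring_error_rate must be in [0, 1]")
        if self.n_lineages < 1 or self.n_loci < 1:
            raise ValueError("need at least one lineage and one locus")
        lo, hi = self.allele_range
        n_sizes = (hi - lo) // self.motif + 1
        if n_sizes * self.n_loci * 2 < self.founder_min_distance:
            raise ValueError("allele range too narrow for founder spacing")
        if len(self.sample_lineage_weights) != self.n_lineages:
            raise ValueError("one lineage weight per lineage required")
        if len(self.coi_substitutions) != self.n_lineages:
            raise ValueError("one COI substitution count per lineage required")
        if max(self.coi_substitutions) > self.coi_length:
            raise ValueError("substitution count exceeds alignment length")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated panel."""

    lineage_of: pd.Series  # individual id -> lineage index
    founders: np.ndarray  # (k, L, 2)
    events: pd.DataFrame  # individual, locus, slot, delta
    sample_composition: pd.DataFrame  # sample, lineage, n
    founder_haplotypes: list[str] = field(default_factory=list)


def _draw_founders(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Founder genotypes pairwise >= founder_min_distance apart, each with a
    mix of heterozygous and homozygous loci."""
    from .clonal import pairwise_allele_distance

    lo, hi = config.allele_range
    sizes = np.arange(lo, hi + 1, config.motif)
    founders: list[np.ndarray] = []
    for _ in range(config.n_lineages):
        for _attempt in range(1000):
            g = np.empty((config.n_loci, 2), dtype=np.int64)
            # at least one het and one hom locus when L allows it
            het = rng.random(config.n_loci) < config.founder_het_fraction
            if config.n_loci >= 2:
                if not het.any():
                    het[int(rng.integers(config.n_loci))] = True
                if het.all():
                    het[int(rng.integers(config.n_loci))] = False
            for j in range(config.n_loci):
                if het[j]:
                    g[j] = np.sort(rng.choice(sizes, size=2, replace=False))
                else:
                    a = rng.choice(sizes)
                    g[j] = (a, a)
            if all(
                pairwise_allele_distance(g, f) >= config.founder_min_distance
                for f in founders
            ):
                founders.append(g)
                break
        else:
            raise ValueError(
                "could not place founders at the requested spacing; "
                "widen allele_range or lower founder_min_distance"
            )
    return np.asarray(founders)


def _sample_counts(config: SimConfig) -> list[int]:
    base = [config.individuals_per_sample] * config.n_samples
    if config.total_individuals is not None:
        extra = config.total_individuals - sum(base)
        if extra < 0 or extra > config.n_samples:
            raise ValueError(
                "total_individuals incompatible with individuals_per_sample"
            )
        for i in range(extra):
            base[i] += 1
    return base


def simulate_clonal_dataset(config: SimConfig) -> tuple[GenotypePanel, SimTruth]:
    """Simulate an apomictic multi-lineage survey panel plus ground truth.

    Samples are assigned one lineage each, in blocks sized by
    ``sample_lineage_weights``; every individual copies its lineage founder
    and receives ``Binomial(2 L generations, mutation_rate)`` stepwise
    mutations (optionally capped), each shifting one uniformly chosen allele
    by one motif.  Deterministic for a given config.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    founders = _draw_founders(config, rng)
    lo, hi = config.allele_range

    weights = np.asarray(config.sample_lineage_weights, dtype=float)
    counts = np.floor(weights / weights.sum() * config.n_samples).astype(int)
    counts[0] += config.n_samples - counts.sum()
    sample_lineage = np.repeat(np.arange(config.n_lineages), counts)

    per_sample = _sample_counts(config)
    meta_rows, allele_rows, truth_rows, event_rows = [], [], [], []
    comp_rows = []
    ind = 0
    for s in range(config.n_samples):
        lineage = int(sample_lineage[s])
        sample_id = f"S{s + 1:02d}"
        locality = f"L{(s % config.n_localities) + 1:02d}"
        host = config.hosts[s % len(config.hosts)]
        comp_rows.append(
            {"sample": sample_id, "lineage": lineage, "n": per_sample[s]}
        )
        for _ in range(per_sample[s]):
            ind += 1
            ind_id = f"I{ind:05d}"
            g = founders[lineage].copy()
            n_mut = rng.binomial(2 * config.n_loci * config.generations,
                                 config.mutation_rate)
            if config.max_mutations_per_individual is not None:
                n_mut = min(n_mut, config.max_mutations_per_individual)
            for _m in range(n_mut):
                j = int(rng.integers(config.n_loci))
                slot = int(rng.integers(2))
                delta = config.motif * (1 if rng.random() < 0.5 else -1)
                new = int(np.clip(g[j, slot] + delta, lo, hi))
                event_rows.append(
                    {
                        "individual": ind_id,
                        "locus": j,
                        "slot": slot,
                        "delta": new - int(g[j, slot]),
                    }
                )
                g[j, slot] = new
            meta_rows.append(
                {
                    "individual": ind_id,
                    "sample": sample_id,
                    "locality": locality,
                    "host": host,
                }
            )
            allele_rows.append(np.sort(g, axis=1))
            truth_rows.append((ind_id, lineage))

    loci = [f"LOC{j + 1:02d}" for j in range(config.n_loci)]
    panel = GenotypePanel(
        loci, pd.DataFrame(meta_rows), np.asarray(allele_rows), MISSING
    )
    truth = SimTruth(
        lineage_of=pd.Series(dict(truth_rows)),
        founders=founders,
        events=pd.DataFrame(
            event_rows, columns=["individual", "locus", "slot", "delta"]
        ),
        sample_composition=pd.DataFrame(comp_rows),
    )
    return panel, truth


def apply_genotyping_error(
    panel: GenotypePanel, rate: float, seed: int | None = None
) -> GenotypePanel:
    """Shift each allele call +-1 motif independently with probability ``rate``.

    Emulates fragment-scoring error; the motif is inferred as the most
    common spacing between adjacent observed allele sizes (2 bp for
    dinucleotide loci).  Missing calls are untouched.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    alleles = panel.alleles.copy()
    present = alleles != panel.missing
    sizes = np.unique(alleles[present])
    motif = int(np.diff(sizes).min()) if len(sizes) > 1 else 2
    hit = present & (rng.random(alleles.shape) < rate)
    sign = np.where(rng.random(alleles.shape) < 0.5, 1, -1)
    alleles[hit] = alleles[hit] + motif * sign[hit]
    return GenotypePanel(panel.loci, panel.meta.copy(), alleles, panel.missing)


_BASES = np.array(list("ACGT"))


def simulate_coi(config: SimConfig, truth: SimTruth) -> HaplotypePanel:
    """COI alignment matching a simulated panel's lineage structure.

    A random root sequence is mutated at ``coi_substitutions[k]`` distinct
    sites (distinct across lineages, so pairwise substitution counts are the
    sums) to give each lineage its founder haplotype; individuals inherit
    their lineage's haplotype, with optional extra per-individual
    substitutions at rate ``coi_individual_rate`` per site.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    root = rng.choice(_BASES, size=config.coi_length)
    total_subs = int(np.sum(config.coi_substitutions))
    sites = rng.choice(config.coi_length, size=total_subs, replace=False)
    haplotypes = []
    used = 0
    for k in range(config.n_lineages):
        seq = root.copy()
        for site in sites[used : used + config.coi_substitutions[k]]:
            current = seq[site]
            choices = [b for b in _BASES if b != current]
            seq[site] = choices[int(rng.integers(3))]
        used += config.coi_substitutions[k]
        haplotypes.append("".join(seq))
    truth.founder_haplotypes = haplotypes

    ids, seqs = [], []
    for ind_id, lineage in truth.lineage_of.items():
        seq = haplotypes[int(lineage)]
        if config.coi_individual_rate > 0:
            arr = np.array(list(seq))
            hits = np.nonzero(rng.random(config.coi_length) < config.coi_individual_rate)[0]
            for site in hits:
                choices = [b for b in _BASES if b != arr[site]]
                arr[site] = choices[int(rng.integers(3))]
            seq = "".join(arr)
        ids.append(ind_id)
        seqs.append(seq)
    return HaplotypePanel(ids, seqs)


def paper_like_config(seed: int = 0, **overrides) -> SimConfig:
    """The default worldwide-survey preset with a chosen seed."""
    cfg = SimConfig(seed=seed)
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise AttributeError(f"unknown SimConfig field {key!r}")
        setattr(cfg, key, value)
    cfg.validate()
    return cfg
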