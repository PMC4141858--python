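"""COI barcode haplotypes: collapse, p-distance divergence, haplotype network.

Works on an aligned set of mitochondrial cytochrome c oxidase I sequences
(the standard 658 bp barcode fragment).  Identical sequences are collapsed
to haplotypes; divergence is the uncorrected p-distance — the proportion of
differing sites among positions unambiguous (A/C/G/T) in both sequences,
with N and gap characters excluded pairwise.  The haplotype network
delegates to the minimum-spanning-network builder on the integer
substitution-count matrix between distinct haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .clonal import DistanceMatrix
from .network import SpanningNetwork, build_msn

_UNAMBIGUOUS = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class HaplotypePanel:
    """Aligned sequences plus their collapse into distinct haplotypes."""

    ids: list[str]
    sequences: list[str]
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("ragged alignment: sequences differ in length")
        self.sequences = [s.upper() for s in self.sequences]
        alphabet = set("".join(self.sequences))
        bad = alphabet - set("ACGTN-")
        if bad:
            raise ValueError(f"unexpected characters in alignment: {sorted(bad)}")

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def alignment_length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def char_matrix(self) -> np.ndarray:
        """``(n, L)`` byte matrix view of the alignment."""
        return np.frombuffer(
            "".join(self.sequences).encode(), dtype="S1"
        ).reshape(self.n_sequences, self.alignment_length)


def read_fasta_alignment(path) -> HaplotypePanel:
    """Read an aligned FASTA file into a validated panel."""
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    if not ids:
        raise ValueError("empty FASTA file")
    return HaplotypePanel(ids, seqs)


def collapse_haplotypes(panel: HaplotypePanel) -> pd.DataFrame:
    """Collapse exact-duplicate sequences into haplotypes.

    Haplotype ids ``H1, H2, ...`` follow first occurrence.  Returns a table
    with columns ``haplotype, sequence, count, members``.  Idempotent by
    construction (collapsing the distinct sequences again changes nothing).
    """
    order: dict[str, int] = {}
    members: dict[str, list[str]] = {}
    for sid, seq in zip(panel.ids, panel.sequences):
        if seq not in order:
            order[seq] = len(order) + 1
            members[seq] = []
        members[seq].append(sid)
    rows = [
        {
            "haplotype": f"H{order[seq]}",
            "sequence": seq,
            "count": len(members[seq]),
            "members": ",".join(members[seq]),
        }
        for seq in order
    ]
    return pd.DataFrame(rows)


def _comparable_and_diff(a: np.ndarray, b: np.ndarray) -> tuple[int, int]:
    good = np.isin(a, _UNAMBIGUOUS) & np.isin(b, _UNAMBIGUOUS)
    comparable = int(good.sum())
    diff = int(np.sum(a[good] != b[good]))
    return comparable, diff


def pairwise_p_distance(seq_a: str, seq_b: str) -> float:
    """Uncorrected p-distance between two aligned sequences.

    Differing sites / comparable sites, where a site is comparable when both
    sequences carry an unambiguous base (N and '-' excluded pairwise).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    comparable, diff = _comparable_and_diff(a, b)
    if comparable == 0:
        raise ValueError("no site comparable between the two sequences")
    return diff / comparable


def substitution_count(seq_a: str, seq_b: str) -> int:
    """Integer number of differing unambiguous sites (network edge lengths)."""
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    return _comparable_and_diff(a, b)[1]


def mean_pairwise_divergence(
    panel: HaplotypePanel, weighting: str = "by_individual"
) -> tuple[float, float, float]:
    """Mean, min and max pairwise p-distance.

    ``by_individual`` averages over all sequence pairs (each haplotype
    weighted by its copy number); ``by_haplotype`` averages over distinct
    haplotype pairs only.
    """
    if panel.n_sequences < 2:
        raise ValueError("need at least two sequences")
    haps = collapse_haplotypes(panel)
    seqs = haps["sequence"].tolist()
    counts = haps["count"].to_numpy()
    h = len(seqs)
    if h == 1:
        return 0.0, 0.0, 0.0
    d = np.zeros((h, h))
    for i in range(h):
        for j in range(i + 1, h):
            d[i, j] = d[j, i] = pairwise_p_distance(seqs[i], seqs[j])
    iu = np.triu_indices(h, k=1)
    if weighting == "by_haplotype":
        vals = d[iu]
        mean = float(vals.mean())
        lo, hi = float(vals.min()), float(vals.max())
    elif weighting == "by_individual":
        w = np.outer(counts, counts)[iu].astype(float)
        vals = d[iu]
        # within-haplotype pairs contribute distance 0
        within = float(np.sum(counts * (counts - 1) / 2))
        total_pairs = within + w.sum()
        mean = float((vals * w).sum() / total_pairs)
        lo = 0.0 if within > 0 else float(vals.min())
        hi = float(vals.max())
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return mean, lo, hi


def haplotype_network(panel: HaplotypePanel) -> SpanningNetwork:
    """Minimum spanning network over distinct haplotypes.

    Edge lengths are substitution counts; node attributes carry the
    haplotype copy number.
    """
    haps = collapse_haplotypes(panel)
    if len(haps) < 2:
        raise ValueError("need at least two distinct haplotypes")
    ids = haps["haplotype"].tolist()
    seqs = haps["sequence"].tolist()
    n = len(ids)
    d = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = substitution_count(seqs[i], seqs[j])
    net = build_msn(DistanceMatrix(ids, d))
    for hap, count in zip(ids, haps["count"]):
        net.node_attrs[hap] = {"count": int(count)}
    return net
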