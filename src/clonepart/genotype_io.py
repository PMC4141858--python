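"""Reading, validating and writing codominant diploid microsatellite tables.

The central container is :class:`GenotypePanel`: per-individual metadata
(individual id, sample id, locality, host plant) plus an ``(n, L, 2)`` integer
array of allele sizes in bp, one sorted pair per locus.  A *sample* groups the
individuals collected from one host plant species in one locality on one date.

Two on-disk dialects are supported:

* ``wide_csv`` (native): columns ``individual,sample,locality,host`` followed
  by one ``a1/a2`` column per locus.
* ``genalex``: a GenAlEx-like layout with a leading counts row, a locus-name
  header row spanning two columns per locus, and two integer allele columns
  per locus.  Locality/host metadata are not representable in this dialect.

Missing data are stored as a configurable integer sentinel (default 0),
rendered as ``0/0`` on disk.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._data import TABLE1_CSV, TABLE1_LOCI, TABLE2_CSV, TABLE2_SAMPLES_CSV

#: Default missing-allele sentinel (allele sizes are positive, so 0 is free).
MISSING = 0

META_COLUMNS = ("individual", "sample", "locality", "host")

AllelePair = tuple[int, int]


class GenotypeFormatError(ValueError):
    """Raised when a genotype cell or table cannot be parsed."""


def parse_allele_pair(text: str, missing: int = MISSING) -> AllelePair:
    """Parse an ``a1/a2`` cell into a canonical (sorted ascending) allele pair.

    Tolerates the ``//`` separator variant and surrounding whitespace.  An
    empty cell, ``NA``, or ``missing/missing`` yields the missing sentinel for
    both alleles.

    >>> parse_allele_pair("203/189")
    (189, 203)
    """
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return (missing, missing)
    s = str(text).strip()
    if s in ("", "NA", "na", "-", f"{missing}", f"{missing}/{missing}"):
        return (missing, missing)
    tokens = [t for t in s.replace("//", "/").split("/") if t.strip() != ""]
    if len(tokens) != 2:
        raise GenotypeFormatError(
            f"expected two '/'-separated alleles, got {text!r}"
        )
    try:
        a1, a2 = (int(t) for t in tokens)
    except ValueError as exc:
        raise GenotypeFormatError(f"non-integer allele in {text!r}") from exc
    for a in (a1, a2):
        if a != missing and a <= 0:
            raise GenotypeFormatError(f"allele size must be positive: {text!r}")
    if a1 > a2:
        a1, a2 = a2, a1
    return (a1, a2)


def format_allele_pair(pair: Sequence[int], missing: int = MISSING) -> str:
    """Render a pair as ``a1/a2`` (missing pairs as ``missing/missing``)."""
    return f"{pair[0]}/{pair[1]}"


@dataclass
class GenotypePanel:
    """Diploid allele-size calls for *n* individuals at *L* loci.

    Attributes
    ----------
    loci
        Ordered locus names.
    meta
        DataFrame with at least the columns ``individual, sample, locality,
        host`` (extra annotation columns are preserved).
    alleles
        ``(n, L, 2)`` int array; each pair sorted ascending; ``missing``
        marks absent calls.
    missing
        Integer sentinel used in ``alleles``.
    """

    loci: list[str]
    meta: pd.DataFrame
    alleles: np.ndarray
    missing: int = MISSING

    def __post_init__(self) -> None:
        self.loci = list(self.loci)
        self.meta = self.meta.reset_index(drop=True)
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        n, L = len(self.meta), len(self.loci)
        if self.alleles.shape != (n, L, 2):
            raise GenotypeFormatError(
                f"allele array shape {self.alleles.shape} does not match "
                f"{n} individuals x {L} loci"
            )
        for col in META_COLUMNS:
            if col not in self.meta.columns:
                raise GenotypeFormatError(f"metadata column {col!r} missing")
        ids = self.meta["individual"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise GenotypeFormatError(f"duplicate individual id {dup!r}")
        present = self.alleles != self.missing
        if (self.alleles[present] <= 0).any():
            raise GenotypeFormatError("allele sizes must be positive integers")
        # canonical storage: sorted pairs
        self.alleles = np.sort(self.alleles, axis=2)

    # -- basic properties -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.meta)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def individuals(self) -> list[str]:
        return self.meta["individual"].tolist()

    def genotype(self, i: int) -> np.ndarray:
        """Return the ``(L, 2)`` allele array of individual *i* (by row)."""
        return self.alleles[i]

    def genotype_key(self, i: int) -> tuple[AllelePair, ...]:
        """Hashable multilocus genotype of individual *i*."""
        return tuple(tuple(p) for p in self.alleles[i])

    def subset(self, rows: Iterable[int]) -> "GenotypePanel":
        rows = list(rows)
        return GenotypePanel(
            self.loci, self.meta.iloc[rows], self.alleles[rows], self.missing
        )

    def equals(self, other: "GenotypePanel") -> bool:
        return (
            self.loci == other.loci
            and self.missing == other.missing
            and np.array_equal(self.alleles, other.alleles)
            and self.meta[list(META_COLUMNS)].equals(
                other.meta[list(META_COLUMNS)]
            )
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide one-column-per-locus view with ``a1/a2`` cells."""
        out = self.meta[list(META_COLUMNS)].copy()
        for j, locus in enumerate(self.loci):
            out[locus] = [
                format_allele_pair(p, self.missing) for p in self.alleles[:, j]
            ]
        return out


def panel_from_records(
    loci: Sequence[str],
    records: Iterable[tuple],
    missing: int = MISSING,
) -> GenotypePanel:
    """Build a panel from ``(individual, sample, locality, host, pairs)`` rows,
    where ``pairs`` is a sequence of one allele pair per locus."""
    meta_rows, allele_rows = [], []
    for individual, sample, locality, host, pairs in records:
        pairs = list(pairs)
        if len(pairs) != len(loci):
            raise GenotypeFormatError(
                f"individual {individual!r} has {len(pairs)} genotypes "
                f"for {len(loci)} loci"
            )
        meta_rows.append(
            {
                "individual": individual,
                "sample": sample,
                "locality": locality,
                "host": host,
            }
        )
        allele_rows.append([tuple(p) for p in pairs])
    if not meta_rows:
        raise GenotypeFormatError("no records")
    return GenotypePanel(
        list(loci), pd.DataFrame(meta_rows), np.asarray(allele_rows), missing
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

DIALECTS = ("wide_csv", "genalex")


def read_genotype_table(
    path, dialect: str = "wide_csv", missing: int = MISSING
) -> GenotypePanel:
    """Read a genotype table in the given dialect into a validated panel."""
    if dialect == "wide_csv":
        return _read_wide_csv(path, missing)
    if dialect == "genalex":
        return _read_genalex(path, missing)
    raise GenotypeFormatError(f"unknown dialect {dialect!r}")


def write_genotype_table(
    panel: GenotypePanel, path, dialect: str = "wide_csv"
) -> None:
    """Write *panel* so that reading it back reproduces the panel exactly."""
    if dialect == "wide_csv":
        panel.to_frame().to_csv(path, index=False)
    elif dialect == "genalex":
        _write_genalex(panel, path)
    else:
        raise GenotypeFormatError(f"unknown dialect {dialect!r}")


def _read_wide_csv(path, missing: int) -> GenotypePanel:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("individual", "sample"):
        if col not in df.columns:
            raise GenotypeFormatError(f"wide_csv requires a {col!r} column")
    for col in ("locality", "host"):
        if col not in df.columns:
            df[col] = ""
    loci = [c for c in df.columns if c not in META_COLUMNS]
    if not loci:
        raise GenotypeFormatError("no locus columns found")
    if df.empty:
        raise GenotypeFormatError("no records")
    records = []
    for idx, row in df.iterrows():
        pairs = []
        for locus in loci:
            try:
                pairs.append(parse_allele_pair(row[locus], missing))
            except GenotypeFormatError as exc:
                raise GenotypeFormatError(
                    f"row {idx + 2}, column {locus!r}: {exc}"
                ) from exc
        records.append(
            (row["individual"], row["sample"], row["locality"], row["host"], pairs)
        )
    return panel_from_records(loci, records, missing)


def _read_genalex(path, missing: int) -> GenotypePanel:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) < 3:
        raise GenotypeFormatError("no records")
    counts = lines[0].split(",")
    try:
        n_loci = int(counts[0])
        n_ind = int(counts[1])
    except (ValueError, IndexError) as exc:
        raise GenotypeFormatError("malformed genalex counts row") from exc
    header = lines[1].split(",")
    loci = [header[2 + 2 * j] for j in range(n_loci)]
    if any(not name for name in loci):
        raise GenotypeFormatError("malformed genalex locus header")
    records = []
    for idx, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        cells = line.split(",")
        if len(cells) < 2 + 2 * n_loci:
            raise GenotypeFormatError(f"row {idx}: ragged genalex row")
        pairs = []
        for j, locus in enumerate(loci):
            a, b = cells[2 + 2 * j], cells[3 + 2 * j]
            try:
                pairs.append(parse_allele_pair(f"{a}/{b}", missing))
            except GenotypeFormatError as exc:
                raise GenotypeFormatError(
                    f"row {idx}, locus {locus!r}: {exc}"
                ) from exc
        records.append((cells[0], cells[1], "", "", pairs))
    if not records:
        raise GenotypeFormatError("no records")
    if len(records) != n_ind:
        raise GenotypeFormatError(
            f"counts row declares {n_ind} individuals, found {len(records)}"
        )
    return panel_from_records(loci, records, missing)


def _write_genalex(panel: GenotypePanel, path) -> None:
    lines = [f"{panel.n_loci},{panel.n_individuals},{panel.meta['sample'].nunique()}"]
    header = ["individual", "sample"]
    for locus in panel.loci:
        header += [locus, ""]
    lines.append(",".join(header))
    for i in range(panel.n_individuals):
        row = [str(panel.meta.at[i, "individual"]), str(panel.meta.at[i, "sample"])]
        for j in range(panel.n_loci):
            row += [str(panel.alleles[i, j, 0]), str(panel.alleles[i, j, 1])]
        lines.append(",".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# shipped reference data
# ---------------------------------------------------------------------------

def load_table1_fixture() -> GenotypePanel:
    """The 36 published worldwide M. sacchari MLGs at 10 CIR-Ms loci.

    Each MLG appears as one individual in its own sample.  The published
    multilocus-lineage label (A-E) is exposed as the extra metadata column
    ``mll``.
    """
    df = pd.read_csv(io.StringIO(TABLE1_CSV), dtype=str)
    records = [
        (
            row["mlg"],
            f"S-{row['mlg']}",
            "",
            "",
            [parse_allele_pair(row[locus]) for locus in TABLE1_LOCI],
        )
        for _, row in df.iterrows()
    ]
    panel = panel_from_records(TABLE1_LOCI, records)
    panel.meta["mll"] = df["mll"].values
    return panel


def load_table2_fixture() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Published distribution of the 98 retained representatives.

    Returns ``(individuals, samples)``: counts per (state, host, MLL) and the
    number of field samples per (state, host).
    """
    individuals = pd.read_csv(io.StringIO(TABLE2_CSV))
    samples = pd.read_csv(io.StringIO(TABLE2_SAMPLES_CSV))
    return individuals, samples
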