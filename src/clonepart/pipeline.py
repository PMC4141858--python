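"""Full clonal-diversity workflow: one config in, one report directory out.

Stages, in analysis order: read panel -> collapse to MLGs -> retain one
representative per MLG per sample -> pairwise allelic distances ->
distance histogram -> threshold (auto or manual) -> MLL assignment ->
p_sex validation -> clonal richness (R_MLG, R_MLL) -> minimum spanning
network -> clone-aware population genetics per MLL -> optional COI
haplotype analysis.  All stage outputs are written as plain-text tables and
summarised in ``report.json`` / ``report.md``; the report repeats the
constituent modules' numbers verbatim (no recomputation).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clonal import (
    MLLPartition,
    assign_mll,
    clonal_richness,
    collapse_mlg,
    detect_threshold,
    distance_histogram,
    distance_matrix,
    psex_for_mlls,
    representative_per_sample,
)
from .coi import (
    collapse_haplotypes,
    haplotype_network,
    mean_pairwise_divergence,
    read_fasta_alignment,
)
from .genotype_io import load_table1_fixture, read_genotype_table
from .network import build_msn, expand_step_nodes, export_network
from .popgen import fis_estimate, g_test_differentiation, heterozygosity, hwe_test_global

log = logging.getLogger("clonepart")


class ConfigError(ValueError):
    """The analysis configuration is unusable."""


@dataclass
class AnalysisReport:
    """Aggregated numbers and file paths of one full run."""

    n_individuals: int
    n_samples: int
    n_loci: int
    n_mlg: int
    n_retained: int
    threshold: int
    threshold_mode: str
    n_mll: int
    r_mlg: float
    r_mll: float
    mll_sizes: dict
    psex: list
    histogram: dict
    files: dict = field(default_factory=dict)
    coi: dict | None = None

    def to_dict(self) -> dict:
        return {
            "version": __version__,
            "input": {
                "individuals": self.n_individuals,
                "samples": self.n_samples,
                "loci": self.n_loci,
            },
            "n_mlg": self.n_mlg,
            "n_retained": self.n_retained,
            "threshold": self.threshold,
            "threshold_mode": self.threshold_mode,
            "n_mll": self.n_mll,
            "r_mlg": self.r_mlg,
            "r_mll": self.r_mll,
            "mll_sizes": self.mll_sizes,
            "psex": self.psex,
            "histogram": self.histogram,
            "coi": self.coi,
            "files": self.files,
        }


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    return cfg


def cross_tabulate(panel, mlgs, mlls: MLLPartition, by: str) -> pd.DataFrame:
    """Counts of retained individuals per (metadata group, MLL).

    ``by`` is a panel metadata column (``host`` or ``locality``, typically).
    Row and column sums are conserved: the grand total is the number of
    individuals in ``panel`` that carry a scored MLG.
    """
    if by not in panel.meta.columns:
        raise KeyError(f"no metadata column {by!r}")
    names = mlls.mll_names()
    rows = []
    for i in range(panel.n_individuals):
        ind = panel.individuals[i]
        if ind not in mlgs.membership:
            continue
        label = mlls.membership[mlgs.membership[ind]]
        rows.append({by: panel.meta.at[i, by], "mll": names[label]})
    df = pd.DataFrame(rows)
    return df.groupby([by, "mll"]).size().unstack(fill_value=0)


def run_full_analysis(config: dict | str | Path, outdir=None) -> AnalysisReport:
    """Execute the whole workflow described by ``config``.

    Config keys: ``input`` (a panel CSV path, or ``"table1"`` for the
    shipped reference genotypes), ``dialect``, ``threshold`` ("auto" or an
    integer), ``seed``, ``n_perm``, optional ``fasta``, optional ``out``
    directory (overridden by *outdir*).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    if not config or "input" not in config:
        raise ConfigError("config must name an 'input' panel")
    outdir = Path(outdir or config.get("out", "clonepart_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    n_perm = int(config.get("n_perm", 1000))
    threshold_cfg = config.get("threshold", "auto")
    dialect = config.get("dialect", "wide_csv")

    log.info(
        "run: input=%s dialect=%s threshold=%s seed=%d n_perm=%d version=%s",
        config["input"], dialect, threshold_cfg, seed, n_perm, __version__,
    )

    # --- read -----------------------------------------------------------
    if config["input"] == "table1":
        panel = load_table1_fixture()
    else:
        panel = read_genotype_table(config["input"], dialect=dialect)
    log.info("panel: %d individuals, %d loci", panel.n_individuals, panel.n_loci)

    # --- clonal structure ----------------------------------------------
    mlgs = collapse_mlg(panel)
    retained = representative_per_sample(panel, mlgs)
    dm = distance_matrix(mlgs)
    hist = distance_histogram(dm)
    if threshold_cfg == "auto":
        threshold = detect_threshold(hist)
        mode = "auto"
    else:
        threshold = int(threshold_cfg)
        mode = "manual"
        log.warning("manual threshold %d overrides histogram detection", threshold)
    mlls = assign_mll(dm, threshold)
    psex = psex_for_mlls(mlgs, mlls)
    r_mlg = clonal_richness(mlgs.n_mlg, retained.n_individuals)
    r_mll = clonal_richness(mlls.n_mll, retained.n_individuals)

    # --- network --------------------------------------------------------
    net = build_msn(dm)
    names = mlls.mll_names()
    for mid in dm.ids:
        net.node_attrs[mid] = {"mll": names[mlls.membership[mid]]}
    expanded = expand_step_nodes(net)

    # --- outputs --------------------------------------------------------
    files = {}
    mlg_table = pd.DataFrame(
        {
            "mlg": mlgs.mlg_ids,
            "n_copies": [int(mlgs.counts[m]) for m in mlgs.mlg_ids],
            "mll": [names[mlls.membership[m]] for m in mlgs.mlg_ids],
            "members": [";".join(mlgs.members[m]) for m in mlgs.mlg_ids],
        }
    )
    files["mlg_table"] = str(outdir / "mlg_table.csv")
    mlg_table.to_csv(files["mlg_table"], index=False)
    files["distances"] = str(outdir / "distances.tsv")
    dm.to_frame().to_csv(files["distances"], sep="\t")
    files["histogram"] = str(outdir / "histogram.tsv")
    hist.rename_axis("distance").to_csv(files["histogram"], sep="\t")
    files["mll"] = str(outdir / "mll.csv")
    pd.DataFrame(
        {"mlg": mlls.mlg_ids, "mll": [names[l] for l in mlls.labels]}
    ).to_csv(files["mll"], index=False)
    files["psex"] = str(outdir / "psex.csv")
    psex.to_csv(files["psex"], index=False)
    files["network"] = str(outdir / "network.graphml")
    export_network(net, files["network"], "graphml")
    files["network_steps"] = str(outdir / "network_steps.tsv")
    export_network(expanded, files["network_steps"], "edge_list")

    # --- popgen per MLL on the retained representatives -----------------
    r_mlgs = collapse_mlg(retained)
    mll_of_individual = [
        names[mlls.membership[r_mlgs.membership[i]]] for i in retained.individuals
    ]
    retained.meta["mll"] = mll_of_individual
    stats_dir = outdir / "stats"
    stats_dir.mkdir(exist_ok=True)
    het = heterozygosity(retained, "mll")
    fis_tab, fis_multi = fis_estimate(retained, "mll")
    hwe_rows = []
    for pop in sorted(set(mll_of_individual)):
        if sum(m == pop for m in mll_of_individual) < 2:
            continue
        p_exc = hwe_test_global(
            retained, pop, "mll", "excess", n_perm=n_perm, seed=seed
        )
        hwe_rows.append(
            {"mll": pop, "fis_multilocus": fis_multi.get(pop), "p_excess": p_exc}
        )
    hwe_df = pd.DataFrame(hwe_rows)
    files["heterozygosity"] = str(stats_dir / "heterozygosity.tsv")
    het.to_csv(files["heterozygosity"], sep="\t", index=False)
    files["fis"] = str(stats_dir / "fis.tsv")
    fis_tab.to_csv(files["fis"], sep="\t", index=False)
    files["hwe"] = str(stats_dir / "hwe_excess.tsv")
    hwe_df.to_csv(files["hwe"], sep="\t", index=False)
    if len(set(mll_of_individual)) >= 2:
        gtab = g_test_differentiation(
            retained, "mll", n_perm=min(n_perm, 200), seed=seed
        )
        files["g_test"] = str(stats_dir / "g_test.tsv")
        gtab.to_csv(files["g_test"], sep="\t", index=False)

    for col in ("host", "locality"):
        if panel.meta[col].astype(str).str.len().max() > 0:
            tab = cross_tabulate(retained, r_mlgs, mlls, col)
            files[f"crosstab_{col}"] = str(outdir / f"crosstab_{col}.csv")
            tab.to_csv(files[f"crosstab_{col}"])

    # --- optional COI ---------------------------------------------------
    coi_summary = None
    if config.get("fasta"):
        hp = read_fasta_alignment(config["fasta"])
        haps = collapse_haplotypes(hp)
        mean, lo, hi = mean_pairwise_divergence(hp, "by_individual")
        files["haplotypes"] = str(outdir / "haplotypes.csv")
        haps.drop(columns="sequence").to_csv(files["haplotypes"], index=False)
        if len(haps) >= 2:
            files["coi_network"] = str(outdir / "coi_network.tsv")
            export_network(haplotype_network(hp), files["coi_network"], "edge_list")
        coi_summary = {
            "n_sequences": hp.n_sequences,
            "alignment_length": hp.alignment_length,
            "n_haplotypes": int(len(haps)),
            "mean_divergence": mean,
            "min_divergence": lo,
            "max_divergence": hi,
        }

    report = AnalysisReport(
        n_individuals=panel.n_individuals,
        n_samples=panel.meta["sample"].nunique(),
        n_loci=panel.n_loci,
        n_mlg=mlgs.n_mlg,
        n_retained=retained.n_individuals,
        threshold=threshold,
        threshold_mode=mode,
        n_mll=mlls.n_mll,
        r_mlg=r_mlg.rounded(),
        r_mll=r_mll.rounded(),
        mll_sizes={names[k]: len(mlls.members_of(k)) for k in range(mlls.n_mll)},
        psex=psex.to_dict("records"),
        histogram={int(k): int(v) for k, v in hist.items()},
        files=files,
        coi=coi_summary,
    )
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    _write_markdown_report(report, outdir / "report.md")
    log.info(
        "done: %d MLGs, threshold %d, %d MLLs, R_MLG=%.3f, R_MLL=%.3f",
        report.n_mlg, report.threshold, report.n_mll, report.r_mlg, report.r_mll,
    )
    return report


def _write_markdown_report(report: AnalysisReport, path) -> None:
    lines = [
        "# Clonal diversity report",
        "",
        f"- individuals: {report.n_individuals} in {report.n_samples} samples, "
        f"{report.n_loci} loci",
        f"- MLGs: {report.n_mlg}; retained representatives: {report.n_retained}",
        f"- distance threshold: {report.threshold} ({report.threshold_mode})",
        f"- MLLs: {report.n_mll} {report.mll_sizes}",
        f"- clonal richness: R_MLG = {report.r_mlg:.3f}, R_MLL = {report.r_mll:.3f}",
        "",
        "## p_sex per lineage",
        "",
        "| MLL | MLGs | copies | identical loci | p_gen | p_sex |",
        "|-----|------|--------|----------------|-------|-------|",
    ]
    for row in report.psex:
        lines.append(
            f"| {row['mll']} | {row['n_mlg']} | {row['n_copies']} | "
            f"{row['n_identical_loci']} | {row['p_gen']:.3g} | {row['p_sex']:.3g} |"
        )
    if report.coi:
        lines += [
            "",
            "## COI",
            "",
            f"- {report.coi['n_sequences']} sequences of "
            f"{report.coi['alignment_length']} bp, "
            f"{report.coi['n_haplotypes']} haplotypes",
            f"- mean pairwise divergence "
            f"{100 * report.coi['mean_divergence']:.2f}% "
            f"(range {100 * report.coi['min_divergence']:.2f}%-"
            f"{100 * report.coi['max_divergence']:.2f}%)",
        ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
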