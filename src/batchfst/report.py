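"""Summary document for a completed (possibly partial) pipeline run.

Renders ``report.md`` plus figure panels from whatever artifacts the run
directory contains: the CA biplot, per-population count boxplots by
center, the mean scaled-Fst MAF profile, the observed-vs-null slope panel,
and the mixed-model, slope and Wilcoxon tables.  Panels whose stage was
not run are replaced by a note saying so.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["render_report"]


def _md_table(df: pd.DataFrame, index_name: str = "") -> str:
    d = df.copy()
    d.insert(0, index_name or "", d.index)
    header = "| " + " | ".join(str(c) for c in d.columns) + " |"
    sep = "|" + "---|" * len(d.columns)
    rows = [
        "| " + " | ".join(
            f"{v:.4g}" if isinstance(v, float) else str(v) for v in row
        ) + " |"
        for row in d.itertuples(index=False)
    ]
    return "\n".join([header, sep, *rows])


def render_report(outdir: str | Path) -> list[str]:
    """Write report.md (+ PNG panels) into the run directory.

    Returns the list of files written.  Raises if the directory holds no
    run artifacts at all.
    """
    outdir = Path(outdir)
    artifacts = {p.name for p in outdir.iterdir()} if outdir.exists() else set()
    if not artifacts:
        raise FileNotFoundError(f"{outdir}: no run artifacts to report on")
    files: list[str] = []
    md: list[str] = ["# Sequencing-center batch-effect report", ""]

    # Panel 1: correspondence-analysis biplot
    md.append("## Population x center sampling bias (correspondence analysis)")
    if "ca.json" in artifacts:
        with open(outdir / "ca.json") as fh:
            ca = json.load(fh)
        rows = pd.read_csv(outdir / "ca_row_coords.tsv", sep="\t", index_col=0)
        cols = pd.read_csv(outdir / "ca_col_coords.tsv", sep="\t", index_col=0)
        def _xy(df):
            x = df.iloc[:, 0].to_numpy()
            y = (df.iloc[:, 1].to_numpy() if df.shape[1] > 1
                 else np.zeros(len(df)))
            return x, y

        fig, ax = plt.subplots(figsize=(6, 5))
        ax.axhline(0, color="grey", lw=0.5)
        ax.axvline(0, color="grey", lw=0.5)
        for df, color, marker, label in ((rows, "tab:blue", "o", "population"),
                                         (cols, "tab:red", "^", "center")):
            x, y = _xy(df)
            ax.scatter(x, y, c=color, marker=marker, label=label)
            for name, xi, yi in zip(df.index, x, y):
                ax.annotate(name, (xi, yi), fontsize=8, color=color)
        ax.set_xlabel("dim 1")
        ax.set_ylabel("dim 2")
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / "ca_biplot.png", dpi=100)
        plt.close(fig)
        files.append("ca_biplot.png")
        md += [
            f"Chi-square = {ca['chi2']:.4g} (df = {ca['dof']}, "
            f"p = {ca['pvalue']:.3g}); total inertia = "
            f"{ca['total_inertia']:.4g}.",
            "",
            "![CA biplot](ca_biplot.png)",
        ]
    else:
        md.append("*CA stage not run; panel omitted.*")
    md.append("")

    # Panel 2: per-population count boxplots by center
    md.append("## Rare-event counts per individual, by center")
    if "counts.tsv" in artifacts:
        counts = pd.read_csv(outdir / "counts.tsv", sep="\t", index_col="sample")
        response = next(
            (c for c in ("n_singletons", "n_lof") if c in counts), None
        )
        pops = sorted(counts["pop"].unique())
        fig, axes = plt.subplots(
            1, len(pops), figsize=(3 * len(pops), 4), sharey=True, squeeze=False
        )
        for ax, pop in zip(axes[0], pops):
            sub = counts[counts["pop"] == pop]
            centers = sorted(sub["center"].unique())
            ax.boxplot(
                [sub.loc[sub["center"] == c, response] for c in centers],
                tick_labels=centers,
            )
            ax.set_title(pop)
            ax.tick_params(axis="x", rotation=45)
        axes[0][0].set_ylabel(response)
        fig.tight_layout()
        fig.savefig(outdir / "counts_by_center.png", dpi=100)
        plt.close(fig)
        files.append("counts_by_center.png")
        md += [f"Response shown: `{response}`.", "",
               "![counts](counts_by_center.png)"]
    else:
        md.append("*Count stage not run; panel omitted.*")
    md.append("")

    # Panel 3: MAF profile of mean scaled Fst
    md.append("## Mean scaled Fst by MAF bin")
    per_bin = sorted(a for a in artifacts if a.startswith("fst_per_bin_"))
    if per_bin:
        fig, ax = plt.subplots(figsize=(6, 4))
        for name in per_bin:
            pop = name[len("fst_per_bin_"):-len(".tsv")]
            df = pd.read_csv(outdir / name, sep="\t")
            with np.errstate(divide="ignore"):
                ax.plot(df["maf_bin"], np.log(df["mean_fst_scaled"]),
                        marker="o", label=pop)
        ax.set_xlabel("MAF bin (left edge)")
        ax.set_ylabel("log mean scaled Fst")
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / "maf_profile.png", dpi=100)
        plt.close(fig)
        files.append("maf_profile.png")
        md += ["![MAF profile](maf_profile.png)"]
    else:
        md.append("*Fst stage not run; MAF panel omitted.*")
    md.append("")

    # Panel 4: observed vs null slope
    md.append("## Observed vs Monte Carlo null scaled Fst")
    null_files = sorted(a for a in artifacts
                        if a.startswith("null_") and a.endswith(".json"))
    if null_files:
        fig, ax = plt.subplots(figsize=(5, 5))
        for name in null_files:
            pop = name[len("null_"):-len(".json")]
            with open(outdir / name) as fh:
                ns = json.load(fh)
            ax.scatter(ns["null_mean"], ns["observed"], s=12,
                       label=f"{pop} (slope {ns['slope']:.2f})")
        lim = ax.get_xlim()
        ax.plot(lim, lim, "k--", lw=0.8, label="slope 1")
        ax.set_xlabel("null mean scaled Fst per MAF category")
        ax.set_ylabel("observed mean scaled Fst")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(outdir / "observed_vs_null.png", dpi=100)
        plt.close(fig)
        files.append("observed_vs_null.png")
        md.append("![observed vs null](observed_vs_null.png)")
        if "slopes.tsv" in artifacts:
            slopes = pd.read_csv(outdir / "slopes.tsv", sep="\t")
            md += ["", "### Slope table", "",
                   _md_table(slopes.set_index("pop"), "pop")]
    else:
        md.append("*Null stage not run; panel omitted.*")
    md.append("")

    # Panel 5: mixed-model tables
    md.append("## Mixed-model center contrasts")
    if "mixed_models.json" in artifacts:
        with open(outdir / "mixed_models.json") as fh:
            models = json.load(fh)
        for response, res in sorted(models.items()):
            tab = pd.read_csv(outdir / f"mixed_model_{response}.tsv",
                              sep="\t", index_col=0)
            md += [
                "",
                f"### {response} (LRT p = {res['lrt_p']:.3g}, "
                f"df = {res['lrt_df']}, reference "
                f"{res['reference_center']})",
                "",
                _md_table(tab, "term"),
            ]
    else:
        md.append("*Models stage not run; tables omitted.*")
    md.append("")

    # Panel 6: Wilcoxon tables
    md.append("## Pairwise Wilcoxon center contrasts")
    wil = sorted(a for a in artifacts if a.startswith("wilcoxon_"))
    if wil:
        for name in wil:
            tab = pd.read_csv(outdir / name, sep="\t", index_col=0)
            md += ["", f"### {name[:-4]}", "", _md_table(tab, "center")]
    else:
        md.append("*Models stage not run; tables omitted.*")
    md.append("")

    # Panel 7: Spearman MAF correlation summary
    md.append("## Spearman correlation of MAF with mean scaled Fst")
    per_maf = sorted(a for a in artifacts if a.startswith("fst_per_maf_"))
    if per_maf or null_files:
        rows = []
        for name in null_files:
            pop = name[len("null_"):-len(".json")]
            with open(outdir / name) as fh:
                ns = json.load(fh)
            rows.append((pop, ns["rho"], ns["rho_p"]))
        if rows:
            md.append(_md_table(
                pd.DataFrame(rows, columns=["pop", "rho", "rho_p"])
                .set_index("pop"), "pop"))
        else:
            md.append("*Null stage not run; rho values unavailable.*")
    else:
        md.append("*Fst stage not run; summary omitted.*")
    md.append("")

    (outdir / "report.md").write_text("\n".join(md))
    files.append("report.md")
    return files
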