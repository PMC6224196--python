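"""Markdown report generation for simulator / generator output directories."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_report"]


def _plot_profile(df: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(df["d_um"], df["C"], "o-", color="seagreen", label="internalized ligand C")
    ax.set_xlabel("distance from source (um)")
    ax.set_ylabel("steady C (AU)")
    ax2 = ax.twinx()
    for gene, color in (("P", "tab:orange"), ("K", "tab:blue"), ("Y", "tab:red")):
        if gene in df:
            ax2.plot(df["d_um"], df[gene], "--", color=color, label=gene, alpha=0.7)
    ax2.set_ylabel("gene level")
    fig.legend(loc="upper right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_rose(rose: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(projection="polar")
    centers = np.deg2rad((rose["bin_left_deg"] + rose["bin_right_deg"]) / 2.0)
    width = np.deg2rad(rose["bin_right_deg"] - rose["bin_left_deg"])
    ax.bar(centers, rose["count"], width=width, bottom=0.0, alpha=0.7,
           color="slateblue", edgecolor="k")
    ax.set_theta_zero_location("E")
    ax.set_title("cytoneme orientation (0 deg = toward source)", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_report(indir, out_path) -> Path:
    """Assemble a Markdown report from whatever tables ``indir`` contains.

    Recognized inputs: ``steady_state.csv`` (+ ``domains.csv``) from a
    simulation run; ``rose.csv`` or ``traces.csv`` from cytoneme
    quantification; ``fits.csv`` from gradient quantification.
    """
    indir = Path(indir)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["# cytograd report", "", f"source directory: `{indir}`", ""]

    ss = indir / "steady_state.csv"
    if ss.exists():
        df = pd.read_csv(ss)
        png = out_path.with_suffix("").name + "_profile.png"
        _plot_profile(df, out_path.parent / png)
        lines += ["## Steady-state gradient", "", f"![steady profile]({png})", ""]
        dom = indir / "domains.csv"
        if dom.exists():
            lines += ["## Expression domains (half-maximum ON rule)", "",
                      pd.read_csv(dom).to_markdown(index=False), ""]

    rose = indir / "rose.csv"
    if rose.exists():
        rdf = pd.read_csv(rose)
        png = out_path.with_suffix("").name + "_rose.png"
        _plot_rose(rdf, out_path.parent / png)
        lines += ["## Cytoneme orientation", "", f"![rose plot]({png})", ""]

    fits = indir / "fits.csv"
    if fits.exists():
        lines += ["## Gradient fits", "",
                  pd.read_csv(fits).to_markdown(index=False), ""]

    scaling = indir / "scaling.csv"
    if scaling.exists():
        lines += ["## Axis-length scaling", "",
                  pd.read_csv(scaling).to_markdown(index=False), ""]

    if len(lines) <= 4:
        lines += ["(no recognized tables found)", ""]
    out_path.write_text("\n".join(lines))
    return out_path
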