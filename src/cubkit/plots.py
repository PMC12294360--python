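"""Diagnostic plots: neutrality, ENC-GC3, PR2, CAI-ENC, RSCU heatmap.

Each function draws on a provided or fresh Axes and returns it, so figures
compose.  All use a non-interactive backend-friendly style.
"""

from __future__ import annotations

import numpy as np

from .cub_indices import enc_expected
from .pipeline import SpeciesBundle


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(5, 4))
    return ax


def neutrality_plot(bundle: SpeciesBundle, ax=None):
    """GC12 against GC3 with the OLS fit and the identity line."""
    ax = _ax(ax)
    df = bundle.composition
    ax.scatter(df["gc3"], df["gc12"], s=4, alpha=0.4, linewidths=0)
    xs = np.linspace(df["gc3"].min(), df["gc3"].max(), 50)
    fit = bundle.neutrality
    if not np.isnan(fit.slope):
        ax.plot(xs, fit.intercept + fit.slope * xs, "r-",
                label=f"slope={fit.slope:.3f}, r={fit.r:.3f}")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8, label="identity")
    ax.set(xlabel="GC3", ylabel="GC12", title=f"{bundle.label}: neutrality plot")
    ax.legend(fontsize=8)
    return ax


def enc_gc3_plot(bundle: SpeciesBundle, ax=None):
    """Observed ENC against GC3s with the mutation-only expected curve."""
    ax = _ax(ax)
    merged = bundle.composition[["gc3s"]].join(bundle.cub[["enc_obs"]]).dropna()
    ax.scatter(merged["gc3s"], merged["enc_obs"], s=4, alpha=0.4, linewidths=0)
    xs = np.linspace(0.01, 0.99, 200)
    ax.plot(xs, [enc_expected(x) for x in xs], "r-", lw=1.2, label="expected")
    ax.set(xlabel="GC3s", ylabel="ENC", ylim=(15, 63),
           title=f"{bundle.label}: ENC-GC3 plot")
    ax.legend(fontsize=8)
    return ax


def pr2_plot(bundle: SpeciesBundle, ax=None):
    """A3/(A3+U3) against G3/(G3+C3) with the parity midlines."""
    ax = _ax(ax)
    df = bundle.composition[["pr2_x", "pr2_y"]].dropna()
    ax.scatter(df["pr2_x"], df["pr2_y"], s=4, alpha=0.4, linewidths=0)
    ax.axhline(0.5, color="r", lw=0.8)
    ax.axvline(0.5, color="r", lw=0.8)
    ax.set(xlabel="G3/(G3+C3)", ylabel="A3/(A3+U3)", xlim=(0, 1), ylim=(0, 1),
           title=f"{bundle.label}: PR2 plot")
    return ax


def cai_enc_plot(bundle: SpeciesBundle, ax=None):
    """CAI (x) against ENC (y)."""
    ax = _ax(ax)
    ax.scatter(bundle.cai_enc["cai"], bundle.cai_enc["enc"], s=4, alpha=0.4,
               linewidths=0)
    rho = bundle.cai_enc_rho
    title = f"{bundle.label}: CAI-ENC"
    if not np.isnan(rho):
        title += f" (Spearman rho={rho:.3f})"
    ax.set(xlabel="CAI", ylabel="ENC", title=title)
    return ax


def rscu_heatmap(values, marks, ax=None):
    """Heatmap of the cross-species RSCU matrix with stop/non-synonymous
    cells annotated."""
    import seaborn as sns

    ax = _ax(ax)
    sns.heatmap(
        values.astype(float), ax=ax, cmap="vlag", center=1.0,
        annot=marks.to_numpy(), fmt="",
        annot_kws={"fontsize": 6},
        cbar_kws={"label": "RSCU"},
    )
    ax.set(xlabel="species / third base", ylabel="first two bases")
    return ax


def save_bundle_plots(bundle: SpeciesBundle, outdir, fmt: str = "svg") -> list:
    """Write the four per-species diagnostic plots; returns the paths."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, fn in [
        ("neutrality", neutrality_plot),
        ("enc_gc3", enc_gc3_plot),
        ("pr2", pr2_plot),
        ("cai_enc", cai_enc_plot),
    ]:
        fig, ax = plt.subplots(figsize=(5, 4))
        fn(bundle, ax=ax)
        path = outdir / f"{name}.{fmt}"
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths
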