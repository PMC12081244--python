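"""Static figure export for tornado, CE-plane, CEAC and EVPI results."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_tornado", "plot_ce_plane", "plot_ceac", "plot_evpi"]


def _save(fig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_tornado(tornado: pd.DataFrame, path: str | Path, top_n: int = 12):
    """Horizontal bars of ICER at each parameter's bounds, widest spread on top."""
    df = tornado.head(top_n).iloc[::-1]
    base = tornado.attrs.get("base_icer")
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(df) + 1.2))
    for i, (_, row) in enumerate(df.iterrows()):
        lo, hi = sorted((row["icer_at_low"], row["icer_at_high"]))
        ax.barh(i, hi - lo, left=lo, height=0.6, color="#4878a8")
    ax.set_yticks(range(len(df)), df["parameter"])
    if base is not None:
        ax.axvline(base, color="k", lw=1, ls="--", label="base-case ICER")
        ax.legend(loc="lower right", fontsize=8)
    ax.set_xlabel("ICER (USD/QALY)")
    return _save(fig, path)


def plot_ce_plane(plane: pd.DataFrame, path: str | Path, wtp: float | None = None):
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(plane["incremental_qalys"], plane["incremental_cost"], s=8, alpha=0.5)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    if wtp is not None:
        xs = pd.Series([plane["incremental_qalys"].min(), plane["incremental_qalys"].max()])
        ax.plot(xs, wtp * xs, "r--", lw=1, label=f"WTP {wtp:,.0f}/QALY")
        ax.legend(fontsize=8)
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental cost (USD)")
    return _save(fig, path)


def plot_ceac(curves: pd.DataFrame, path: str | Path):
    fig, ax = plt.subplots(figsize=(6, 4))
    for col in curves.columns:
        if col != "wtp":
            ax.plot(curves["wtp"], curves[col], label=col)
    ax.set_xlabel("willingness to pay (USD/QALY)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    return _save(fig, path)


def plot_evpi(curve: pd.DataFrame, path: str | Path):
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["wtp"], curve["evpi"])
    ax.set_xlabel("willingness to pay (USD/QALY)")
    ax.set_ylabel("per-patient EVPI (USD)")
    ax.set_ylim(bottom=0)
    return _save(fig, path)
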