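"""Minimal matplotlib rendering of serialized payloads (PNG/SVG).

Payloads are renderer-agnostic; this module gives them a default appearance
for the CLI ``plot --render`` path.  Suppressed cells/bins are simply absent
from the figure.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .errors import SchemaError  # noqa: E402


def render_payload(d: dict, path) -> None:
    """Render a payload dict to an image file (format from the extension)."""
    kind = d.get("kind")
    fig, ax = plt.subplots(figsize=(5, 4))
    try:
        if kind == "histogram":
            edges = np.asarray(d["edges"])
            for left, width, dens in zip(edges[:-1], np.diff(edges), d["density"]):
                if dens is not None:
                    ax.bar(left, dens, width=width, align="edge",
                           color="tab:blue", edgecolor="white")
            ax.set_ylabel("frequency density")
        elif kind == "sized-dot-scatter":
            dots = np.asarray(d["dots"], dtype=float)
            if len(dots):
                ax.scatter(dots[:, 0], dots[:, 1], s=10 * dots[:, 2], alpha=0.6)
            for trend, color in ((d.get("trend_raw"), "red"), (d.get("trend_weighted"), "grey")):
                if trend:
                    xs = np.asarray(d["x_edges"][:1] + d["x_edges"][-1:], dtype=float)
                    ax.plot(xs, trend[0] + trend[1] * xs, color=color, lw=1)
        elif kind == "anon-scatter":
            x = np.asarray(d["x"]); y = np.asarray(d["y"])
            mult = np.asarray(d["multiplicity"])
            ax.scatter(x, y, s=8, alpha=0.6)
            coincident = mult > 1
            if coincident.any():
                ax.scatter(x[coincident], y[coincident], s=12, color="black")
            if len(x):
                xs = np.array([x.min(), x.max()])
                for trend, color in ((d.get("trend_raw"), "red"), (d.get("trend_anon"), "grey")):
                    if trend:
                        ax.plot(xs, trend[0] + trend[1] * xs, color=color, lw=1)
        elif kind in ("heatmap", "contour"):
            counts = np.array(
                [[np.nan if c is None else c for c in row] for row in d["counts"]],
                dtype=float,
            )
            ex = np.asarray(d["x_edges"]); ey = np.asarray(d["y_edges"])
            if kind == "heatmap":
                ax.pcolormesh(ex, ey, counts.T, cmap="viridis")
            else:
                cx = 0.5 * (ex[:-1] + ex[1:]); cy = 0.5 * (ey[:-1] + ey[1:])
                ax.contour(cx, cy, np.nan_to_num(counts).T)
        elif kind == "boxplot":
            stats = [{
                "med": d["median"], "q1": d["q1"], "q3": d["q3"],
                "whislo": d["whisker_low"], "whishi": d["whisker_high"],
                "fliers": d["outliers"],
            }]
            ax.bxp(stats, showfliers=True)
        elif kind == "regression-diagnostics":
            plt.close(fig)
            fig, axes = plt.subplots(1, 3, figsize=(12, 4))
            titles = ("resid_vs_fitted", "qq", "resid_vs_leverage")
            for sub, name in zip(axes, titles):
                plot = d[name]
                if isinstance(plot, dict) and plot.get("kind") == "sized-dot-scatter":
                    dots = np.asarray(plot["dots"], dtype=float)
                    if len(dots):
                        sub.scatter(dots[:, 0], dots[:, 1], s=10 * dots[:, 2], alpha=0.6)
                else:
                    sub.scatter(plot["x"], plot["y"], s=8, alpha=0.6)
                sub.set_title(name.replace("_", " "))
            ax = axes[0]
        else:
            raise SchemaError(f"cannot render payload kind {kind!r}")
        fig.savefig(path, dpi=120, bbox_inches="tight")
    finally:
        plt.close(fig)
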