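"""Fusion-plot rendering: per-site mismatch rate along the reference
paralog, with background/foreground lines, the fitted sigmoid and the
called crossover interval.

Every plot also writes a ``<name>.plotdata.json`` sidecar holding the
exact plotted coordinates, so the visualisation can be asserted in tests
without image diffing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .crossover import FusionCall, MismatchProfile


@dataclass
class PlotSpec:
    path: str
    format: str = "png"
    width: float = 9.0
    height: float = 4.5
    show_fit: bool = True
    show_triangle: bool = True
    title: str = ""

    def __post_init__(self):
        if self.format not in ("png", "svg"):
            raise ValueError(f"unsupported plot format {self.format!r}")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("plot dimensions must be positive")


def render_fusion_plot(profile: MismatchProfile, call: FusionCall,
                       spec: PlotSpec) -> Path:
    """Render the fusion plot and its machine-readable sidecar.

    Discriminating sites are red, ambiguous sites grey; dashed lines mark
    the background (lower) and foreground (upper, when defined); the
    fitted sigmoid is overlaid when converged, and a triangle marks the
    called crossover interval for fused samples.
    """
    disc = profile.rates("discriminating")
    amb = profile.rates("ambiguous")

    fig, ax = plt.subplots(figsize=(spec.width, spec.height))
    ax.scatter(amb["position"] + 1, amb["rate"], s=8, c="0.6", label="ambiguous",
               zorder=2)
    ax.scatter(disc["position"] + 1, disc["rate"], s=14, c="crimson",
               label="discriminating", zorder=3)

    lines = {"background": call.background}
    ax.axhline(call.background, ls="--", c="0.3", lw=1)
    if call.foreground is not None:
        ax.axhline(call.foreground, ls="--", c="0.3", lw=1)
        lines["foreground"] = call.foreground

    fit_curve = None
    if spec.show_fit and call.fit.converged:
        xs = np.linspace(disc["position"].min(), disc["position"].max(), 400)
        ys = call.fit.predict(xs)
        ax.plot(xs + 1, ys, c="navy", lw=1.5, alpha=0.8)
        fit_curve = {"x": (xs + 1).tolist(), "y": ys.tolist()}

    triangle = None
    if spec.show_triangle and call.status == "fused" and call.crossover_interval:
        lo, hi = call.crossover_interval
        ax.plot([(lo + hi) / 2 + 1], [1.05], marker="v", ms=12, c="hotpink",
                clip_on=False)
        ax.axvspan(lo + 1, hi + 1, color="hotpink", alpha=0.2)
        triangle = [lo + 1, hi + 1]

    title = spec.title or "fusion plot"
    ax.set_title(f"{title} — {call.status}"
                 + (f" ({call.region_label})" if call.status == "fused" else ""))
    ax.set_xlabel(f"position on reference paralog {profile.reference} (bp)")
    ax.set_ylabel("mismatch rate")
    ax.set_ylim(-0.05, 1.1)
    ax.legend(loc="center left", fontsize=8)
    fig.tight_layout()

    out = Path(spec.path)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, format=spec.format, dpi=150)
    plt.close(fig)

    sidecar = {
        "discriminating": {"position": (disc["position"] + 1).tolist(),
                           "rate": disc["rate"].tolist()},
        "ambiguous": {"position": (amb["position"] + 1).tolist(),
                      "rate": amb["rate"].tolist()},
        "dashed_lines": lines,
        "fit_curve_drawn": fit_curve is not None,
        "triangle_interval": triangle,
        "status": call.status,
        "region_label": call.region_label,
    }
    side_path = out.parent / (out.stem + ".plotdata.json")
    with open(side_path, "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
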