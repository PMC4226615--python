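"""Circular (polar) coverage rendering.

A simplified two-ring polar plot of strand-resolved relative coverage: the
outer ring shows the plus strand, the inner ring the minus strand, with
optional feature annotations on an outermost ring.  This is a diagnostic
rendering, not a publication-grade circular-genomics figure; all numeric
assertions in the package are made on the underlying binned series, never
on pixels.
"""
from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .strand_coverage import RelativeCoverageProfile


def _binned(series: np.ndarray, n_bins: int) -> np.ndarray:
    L = len(series)
    edges = np.linspace(0, L, n_bins + 1).astype(int)
    return np.array([series[a:b].mean() if b > a else np.nan for a, b in zip(edges, edges[1:])])


def plot_circular_coverage(
    rc: RelativeCoverageProfile,
    annotations: list[tuple[int, int, str]] | None = None,
    out_path=None,
    n_bins: int = 360,
    log: bool = False,
    rc_cap: float = 3.0,
):
    """Render plus/minus relative coverage as two polar rings.

    ``annotations`` is a list of (start, end, label) 1-based intervals drawn
    on the outer rim.  ``log`` switches the radial value to log10(rc)
    (values clipped below at rc 1e-3); otherwise rc is clipped at
    ``rc_cap``.  Output format follows the ``out_path`` suffix (.png/.svg);
    the rendering is deterministic given its inputs.
    """
    L = len(rc)
    n_bins = min(n_bins, L)
    theta_edges = np.linspace(0, 2 * np.pi, n_bins + 1)
    theta = (theta_edges[:-1] + theta_edges[1:]) / 2

    def radial(series):
        vals = _binned(series, n_bins)
        if log:
            return np.log10(np.clip(vals, 1e-3, None)) - np.log10(1e-3)
        return np.clip(vals, 0, rc_cap)

    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="polar")
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)

    span = (np.log10(rc_cap) + 3) if log else rc_cap
    base_minus, base_plus = 1.0, 1.0 + span + 0.5
    for base, series, color, label in (
        (base_plus, rc.rc_plus, "tab:blue", "plus strand"),
        (base_minus, rc.rc_minus, "tab:red", "minus strand"),
    ):
        r = radial(series)
        ax.plot(theta, base + r, color=color, lw=0.8, label=label)
        ax.fill_between(theta, base, base + r, color=color, alpha=0.25)
        ax.plot(theta, np.full_like(theta, base), color="0.6", lw=0.4)

    rim = base_plus + span + 0.7
    if annotations:
        for start, end, label in annotations:
            t0 = 2 * np.pi * (start - 1) / L
            t1 = 2 * np.pi * end / L
            tt = np.linspace(t0, t1, 32)
            ax.plot(tt, np.full_like(tt, rim), lw=4, solid_capstyle="butt")
            ax.annotate(label, ((t0 + t1) / 2, rim + 0.3), fontsize=7, ha="center")

    ax.set_ylim(0, rim + 1)
    ax.set_yticks([])
    ax.set_xticks([])
    ax.legend(loc="lower left", bbox_to_anchor=(-0.1, -0.1), fontsize=8, frameon=False)
    if out_path is not None:
        fig.savefig(str(out_path), dpi=150, metadata=_no_date_metadata(str(out_path)))
        plt.close(fig)
        return None
    return fig


def _no_date_metadata(path: str) -> dict | None:
    # keep output byte-reproducible: SVG embeds a creation date unless told not to
    if path.endswith(".svg"):
        return {"Date": None}
    return None
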