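"""Overlay plot of the correlation-over-time summaries."""

from __future__ import annotations

from .correlation import CorrelationCurve

_STYLE = {
    "marginal": dict(color="C0", label="marginal"),
    "conditional": dict(color="C1", label="conditional"),
    "pointwise-pearson": dict(color="C2", label="pointwise Pearson"),
}


def plot_correlation_overlay(curves: list[CorrelationCurve], path=None, ax=None, title=None):
    """Plot marginal / conditional / pointwise curves on one axis.

    Solid lines are point estimates, broken lines the pointwise 95% bands;
    the naive pointwise Pearson values are drawn as markers.
    """
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for curve in curves:
        style = _STYLE.get(curve.flavor, dict(label=curve.flavor))
        if curve.flavor == "pointwise-pearson":
            ax.plot(curve.times, curve.rho, "o", ms=4, **style)
            continue
        ax.plot(curve.times, curve.rho, "-", **style)
        if curve.ci_lower is not None and curve.ci_upper is not None:
            ax.plot(curve.times, curve.ci_lower, "--", color=style.get("color"), lw=0.8)
            ax.plot(curve.times, curve.ci_upper, "--", color=style.get("color"), lw=0.8)
    ax.set_xlabel("years since index date")
    ax.set_ylabel("correlation")
    ax.set_ylim(-1, 1)
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.legend(frameon=False)
    if title:
        ax.set_title(title)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
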