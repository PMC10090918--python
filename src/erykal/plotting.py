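"""Optional matplotlib rendering of the interpretation nomogram.

The nomogram plots K_er.exc against pK_er.  Dashed reference lines mark the
neutral values (pK_er = 7, K_er.exc = 0); constant-chloride curves run
diagonally and split the plane into the cellular-acidosis zone (pK_er < 7,
potassium excess from eryptosis) and the cellular-alkalosis zone (pK_er > 7,
potassium deficit).
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from .core import BufferCurve, ErPanel, NEUTRAL_PKER


def plot_nomogram(
    curves: Sequence[BufferCurve] = (),
    samples: Iterable[ErPanel] = (),
    ax=None,
):
    """Draw buffer curves and sample points; returns the matplotlib Axes."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    for curve in curves:
        ax.plot(curve.p_k_er, curve.k_er_exc, lw=1.5, label=f"Cl = {curve.cl:g} mmol/L")
    xs = [p.p_k_er for p in samples if p.p_k_er is not None]
    ys = [p.k_er_exc for p in samples if p.k_er_exc is not None]
    if xs:
        ax.scatter(xs, ys, s=18, zorder=3, color="crimson", label="samples")
    ax.axvline(NEUTRAL_PKER, ls="--", lw=0.8, color="gray")
    ax.axhline(0.0, ls="--", lw=0.8, color="gray")
    ax.set_xlabel("pK$_{er}$ (dimensionless)")
    ax.set_ylabel("K$_{er.exc}$ (mmol/L)")
    ax.set_title("Intracellular potassium nomogram")
    if curves or xs:
        ax.legend(frameon=False, fontsize=8)
    return ax
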