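"""Optional static figures (requires matplotlib).

Two views the model is usually judged by: the carrot-shaped stylet profile
and the pressure-displacement curve with its divergence at the fold.
"""

from __future__ import annotations

import numpy as np

from . import mechanics as mech


def plot_stylet_shape(shape: mech.StyletShape, ax=None, n: int = 400):
    """Axisymmetric stylet outline beta(xi) (both sides of the axis)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xi = np.linspace(0.0, shape.l, n)
    beta = mech.stylet_radius(xi, shape)
    ax.plot(xi, beta, "k-")
    ax.plot(xi, -beta, "k-")
    apex = mech.stylet_apex(shape)
    ax.plot([apex.xi1], [apex.beta_x], "ro", ms=4)
    ax.set_xlabel(r"axial position $\xi$ [l]")
    ax.set_ylabel(r"radius $\beta$ [l]")
    ax.set_aspect("equal")
    return ax


def plot_displacement_curve(
    shape: mech.StyletShape,
    restraint: mech.ElasticRestraint,
    ax=None,
    n: int = 200,
    p_frac_max: float = 0.999,
):
    """|delta|(p) below the fold; the slope diverges at the threshold."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    p_thres = mech.threshold_pressure(shape, restraint, "numeric")
    ps = np.linspace(0.0, p_frac_max * p_thres, n)
    deltas = [abs(mech.displacement(p, shape, restraint)) for p in ps]
    ax.plot(ps, deltas, "b-")
    ax.axvline(p_thres, color="r", ls="--", label=f"threshold {p_thres:.4g}")
    ax.set_xlabel("pressure p [Y]")
    ax.set_ylabel(r"|displacement $\delta$| [l]")
    ax.legend()
    return ax
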