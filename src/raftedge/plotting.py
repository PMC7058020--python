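"""Cosmetic plotting helpers (matplotlib is imported lazily)."""

from __future__ import annotations

from .energy import DeformationField
from .scans import EnergyProfile


def plot_profile(profile: EnergyProfile, ax=None):
    """Plot W against the scan abscissa, with plateaus and minima marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xlab = "L (nm)" if profile.kind == "boundary_shift" else "$X_0$ (nm)"
    ax.plot(profile.abscissa, profile.W, lw=1.5)
    for p in (profile.plateau_left, profile.plateau_right):
        if p is not None:
            ax.axhline(p, ls=":", color="grey", lw=0.8)
    for m in profile.minima:
        ax.plot(m.position, m.W, "v", color="crimson", ms=5)
    ax.set_xlabel(xlab)
    ax.set_ylabel(r"$W$ ($k_BT$/nm)")
    return ax


def plot_shape(field: DeformationField, ax=None):
    """Draw the neutral surfaces and the monolayer interface."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(field.x, field.H_u, "k-", lw=1.2, label="$H_u$")
    ax.plot(field.x, field.H_l, "k-", lw=1.2, label="$H_l$")
    ax.plot(field.x, field.M, "k:", lw=1.0, label="$M$")
    ax.set_xlabel("x (nm)")
    ax.set_ylabel("z (nm)")
    ax.legend(frameon=False)
    return ax
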