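"""Quick-look figures: binned profiles, iso-concentration frame overlay."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .geometry import AverageFrame  # noqa: E402
from .profiles import BinnedProfile  # noqa: E402
from .stats import IsoContourSet  # noqa: E402

SIDE_COLORS = {"D": "tab:blue", "V": "tab:red"}


def plot_profiles(profiles: list[BinnedProfile], path: str | Path,
                  logy: bool = False) -> None:
    """Overlay binned mean profiles (one axis) with SD whiskers."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for p in profiles:
        ax.errorbar(p.centers, p.mean, yerr=p.sd, fmt="-",
                    color=SIDE_COLORS.get(p.side, "k"), ms=2, lw=1,
                    elinewidth=0.5, label=f"{p.side} ({p.channel})")
    ax.set_xlabel(f"{profiles[0].axis} distance from anterior (um)")
    ax.set_ylabel("mean intensity")
    if logy:
        ax.set_yscale("log")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_iso_frame(iso: IsoContourSet, frame: AverageFrame, L: float,
                   path: str | Path) -> None:
    """Iso-concentration connector lines on the average embryo frame."""
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.plot(frame.x_over_L * L, frame.yD_over_L * L, color="tab:blue", lw=1.5)
    ax.plot(frame.x_over_L * L, frame.yV_over_L * L, color="tab:blue", lw=1.5)
    for k in range(len(iso.thresholds)):
        ax.plot([iso.xD[k], iso.xV[k]], [iso.yD[k], iso.yV[k]],
                color="tab:red", lw=0.8)
    ax.set_aspect("equal")
    ax.set_xlabel("x (um), anterior left")
    ax.set_ylabel("y (um), dorsal up")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
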