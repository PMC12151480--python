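"""Mask outline, central cavity, and channel-network skeleton.

The mask is a flat rectangle (long edge ``L1`` horizontal, short edge ``L2``
vertical) with a central elliptical high-pressure cavity.  The periphery is
partitioned into straight channels that run from the cavity boundary to the
midpoint of their edge segment: ``nose`` channels end on the top edge,
``chin`` channels on the bottom edge, and ``cheek`` channels on the side
edges whose effective length is reduced to ``tau * L2`` by the tuck-in fold.

All lengths are SI metres; inch-based defaults are converted at construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

INCH = 0.0254

#: number of arclength samples used for per-channel height profiles
HEIGHT_GRID_SIZE = 101

#: warn when the channel aspect ratio K0/Lc exceeds this (thin-gap assumption)
KAPPA_WARN = 0.2


class GeometryError(ValueError):
    """Invalid mask/cavity/layout specification."""


@dataclass(frozen=True)
class MaskSpec:
    """Rectangular cloth mask.

    Parameters
    ----------
    L1 : float
        Long (horizontal) edge length in metres.  Default 9 in.
    L2 : float
        Short (vertical) edge length in metres.  Default 5.4 in.
    tuck_ratio : float
        Tuck-in ratio ``tau = L2' / L2`` in (0, 1]; the deployed side-edge
        length is ``L2' = tau * L2``.
    """

    L1: float = 9.0 * INCH
    L2: float = 5.4 * INCH
    tuck_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.L1 <= 0 or self.L2 <= 0:
            raise GeometryError("mask edge lengths must be positive")
        if not 0.0 < self.tuck_ratio <= 1.0:
            raise GeometryError("tuck_ratio must lie in (0, 1]")

    @property
    def side_edge_length(self) -> float:
        """Deployed (tuck-adjusted) side-edge length ``L2'``."""
        return self.tuck_ratio * self.L2

    @property
    def area(self) -> float:
        return self.L1 * self.L2


@dataclass(frozen=True)
class CavitySpec:
    """Elliptical high-pressure cavity in the mask plane.

    The cavity centre defaults to the mask centre; ``y_offset`` shifts it
    vertically (positive toward the nose edge).  Semi-axes default to
    ``(0.25 * L1, 0.30 * L2)``.
    """

    center: tuple[float, float] = (0.0, 0.0)
    y_offset: float = 0.0
    semi_axes: tuple[float, float] = (0.25 * 9.0 * INCH, 0.30 * 5.4 * INCH)

    def __post_init__(self) -> None:
        ax, ay = self.semi_axes
        if ax <= 0 or ay <= 0:
            raise GeometryError("cavity semi-axes must be positive")

    @classmethod
    def default_for(cls, mask: MaskSpec, y_offset: float = 0.0) -> "CavitySpec":
        return cls(center=(0.0, 0.0), y_offset=y_offset,
                   semi_axes=(0.25 * mask.L1, 0.30 * mask.L2))

    @property
    def effective_center(self) -> tuple[float, float]:
        return (self.center[0], self.center[1] + self.y_offset)

    @property
    def area(self) -> float:
        ax, ay = self.semi_axes
        return math.pi * ax * ay

    def validate_inside(self, mask: MaskSpec) -> None:
        cx, cy = self.effective_center
        ax, ay = self.semi_axes
        if not (abs(cx) + ax < mask.L1 / 2 and abs(cy) + ay < mask.L2 / 2):
            raise GeometryError("cavity must lie strictly inside the mask outline")
        if self.area >= mask.area:
            raise GeometryError("cavity area must be smaller than the mask area")


@dataclass(frozen=True)
class ChannelLayout:
    """Counts of periphery channels per region.

    With ``use_symmetry`` the right half of the mask is modelled and counts
    must be even; the default full network has 16 nose + 16 chin + 2 x 8
    cheek channels (48 total, 24 in the half model).
    """

    n_nose: int = 16
    n_chin: int = 16
    n_cheek_per_side: int = 8
    use_symmetry: bool = True

    def __post_init__(self) -> None:
        if min(self.n_nose, self.n_chin, self.n_cheek_per_side) <= 0:
            raise GeometryError("channel counts must be positive")
        if self.use_symmetry and (self.n_nose % 2 or self.n_chin % 2):
            raise GeometryError("nose/chin counts must be even with use_symmetry")

    @property
    def total_channels(self) -> int:
        """Channel count of the full (unmirrored) network."""
        return self.n_nose + self.n_chin + 2 * self.n_cheek_per_side

    @property
    def model_channels(self) -> int:
        """Channels actually solved (half model when symmetric)."""
        if self.use_symmetry:
            return self.total_channels // 2
        return self.total_channels


@dataclass
class ChannelGeometry:
    """One periphery channel of the face-mask flow network.

    ``x`` runs along the channel from the cavity boundary (``x = 0``) to the
    mask edge (``x = 1``); heights ``K(x_j)`` are sampled on a uniform grid.
    """

    index: int
    region: str  # 'nose' | 'chin' | 'cheek'
    width: float
    edge: str  # 'top' | 'bottom' | 'left' | 'right'
    exit_point: tuple[float, float]
    length: float | None = None
    cavity_point: tuple[float, float] | None = None
    heights: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise GeometryError(f"channel {self.index}: width must be positive")
        if self.region not in ("nose", "chin", "cheek"):
            raise GeometryError(f"channel {self.index}: unknown region {self.region!r}")

    # -- derived quantities -------------------------------------------------
    @property
    def x_grid(self) -> np.ndarray:
        n = HEIGHT_GRID_SIZE if self.heights is None else len(self.heights)
        return np.linspace(0.0, 1.0, n)

    @property
    def K0(self) -> float:
        """Mean channel height (trapezoidal average of K over x in [0, 1])."""
        if self.heights is None:
            raise GeometryError(f"channel {self.index}: heights not set")
        return float(np.trapezoid(self.heights, self.x_grid))

    @property
    def delta_h(self) -> np.ndarray:
        """Dimensionless height profile K(x)/K0 (unit mean)."""
        return self.heights / self.K0

    @property
    def kappa(self) -> float:
        """Average aspect ratio K0 / Lc."""
        if self.length is None:
            raise GeometryError(f"channel {self.index}: length not set")
        return self.K0 / self.length

    def with_heights(self, heights: np.ndarray) -> "ChannelGeometry":
        heights = np.asarray(heights, dtype=float)
        if heights.ndim != 1 or len(heights) < 2:
            raise GeometryError(f"channel {self.index}: heights must be a 1-D array")
        if np.any(heights <= 0):
            raise GeometryError(f"channel {self.index}: heights must be positive")
        out = replace(self, heights=heights)
        if out.length is not None and out.kappa > KAPPA_WARN:
            warnings.warn(
                f"channel {self.index}: aspect ratio kappa={out.kappa:.3f} > "
                f"{KAPPA_WARN}; thin-channel assumption degraded",
                stacklevel=2,
            )
        return out


# ---------------------------------------------------------------------------
# layout construction
# ---------------------------------------------------------------------------

def _edge_segments(start: tuple[float, float], stop: tuple[float, float],
                   n: int) -> tuple[list[tuple[float, float]], float]:
    """Midpoints of ``n`` equal segments walked from ``start`` to ``stop``."""
    sx, sy = start
    dx = (stop[0] - sx) / n
    dy = (stop[1] - sy) / n
    mids = [(sx + (j + 0.5) * dx, sy + (j + 0.5) * dy) for j in range(n)]
    width = math.hypot(dx, dy)
    return mids, width


def build_layout(mask: MaskSpec, cavity: CavitySpec,
                 layout: ChannelLayout) -> list[ChannelGeometry]:
    """Construct the channel skeleton (widths, exit points, regions).

    Channel numbering starts at the lower-edge midpoint and walks the
    periphery: chin -> (right) cheek -> nose; the full model continues over
    the mirrored left half.  Heights are left unset; lengths are assigned by
    :func:`channel_lengths`.
    """
    cavity.validate_inside(mask)
    hx, hy = mask.L1 / 2, mask.L2 / 2
    s = mask.side_edge_length  # tuck-adjusted side-edge length L2'

    chans: list[ChannelGeometry] = []

    def add(region: str, edge: str, mids: list[tuple[float, float]],
            width: float) -> None:
        for m in mids:
            chans.append(ChannelGeometry(index=len(chans) + 1, region=region,
                                         width=width, edge=edge, exit_point=m))

    if layout.use_symmetry:
        # right half only: chin 1..n/2, cheek, nose back toward the midline
        mids, w = _edge_segments((0.0, -hy), (hx, -hy), layout.n_chin // 2)
        add("chin", "bottom", mids, w)
        mids, w = _edge_segments((hx, -s / 2), (hx, s / 2), layout.n_cheek_per_side)
        add("cheek", "right", mids, w)
        mids, w = _edge_segments((hx, hy), (0.0, hy), layout.n_nose // 2)
        add("nose", "top", mids, w)
    else:
        n_chin_r = layout.n_chin // 2
        n_chin_l = layout.n_chin - n_chin_r
        mids, w = _edge_segments((0.0, -hy), (hx, -hy), n_chin_r)
        add("chin", "bottom", mids, w)
        mids, w = _edge_segments((hx, -s / 2), (hx, s / 2), layout.n_cheek_per_side)
        add("cheek", "right", mids, w)
        mids, w = _edge_segments((hx, hy), (-hx, hy), layout.n_nose)
        add("nose", "top", mids, w)
        mids, w = _edge_segments((-hx, s / 2), (-hx, -s / 2), layout.n_cheek_per_side)
        add("cheek", "left", mids, w)
        mids, w = _edge_segments((-hx, -hy), (0.0, -hy), n_chin_l)
        add("chin", "bottom", mids, w)
    return chans


def channel_lengths(mask: MaskSpec, cavity: CavitySpec,
                    channels: list[ChannelGeometry]) -> list[ChannelGeometry]:
    """Assign each channel its straight path length Lc.

    The path runs from the channel's edge midpoint toward the cavity centre
    and stops on the cavity (ellipse) boundary.
    """
    cavity.validate_inside(mask)
    cx, cy = cavity.effective_center
    ax, ay = cavity.semi_axes
    out = []
    for ch in channels:
        ex, ey = ch.exit_point
        dx, dy = ex - cx, ey - cy
        q = (dx / ax) ** 2 + (dy / ay) ** 2
        if q <= 1.0:
            raise GeometryError(
                f"channel {ch.index}: edge midpoint lies inside the cavity")
        t = 1.0 - 1.0 / math.sqrt(q)
        length = t * math.hypot(dx, dy)
        if length <= 0:
            raise GeometryError(f"channel {ch.index}: degenerate path")
        cav_pt = (ex - t * dx, ey - t * dy)
        out.append(replace(ch, length=length, cavity_point=cav_pt))
    return out


def build_channels(mask: MaskSpec, cavity: CavitySpec,
                   layout: ChannelLayout) -> list[ChannelGeometry]:
    """Convenience: skeleton plus lengths in one call (heights still unset)."""
    return channel_lengths(mask, cavity, build_layout(mask, cavity, layout))


def scale_cavity(cavity: CavitySpec, fraction: float) -> CavitySpec:
    """Scale the cavity area by ``(1 + fraction)`` about a fixed centre.

    Channel lengths must be recomputed afterwards (a larger cavity shortens
    every channel).
    """
    if fraction <= -1.0:
        raise GeometryError("fraction must exceed -1")
    s = math.sqrt(1.0 + fraction)
    ax, ay = cavity.semi_axes
    return replace(cavity, semi_axes=(ax * s, ay * s))


def layout_table(channels: list[ChannelGeometry]) -> pd.DataFrame:
    """Tidy table of the layout (one row per channel)."""
    rows = []
    for ch in channels:
        ex, ey = ch.exit_point
        rows.append({
            "channel_id": ch.index,
            "region": ch.region,
            "W_m": ch.width,
            "Lc_m": ch.length,
            "edge": ch.edge,
            "side": "left" if ex < 0 else "right",
            "exit_x_m": ex,
            "exit_y_m": ey,
        })
    return pd.DataFrame(rows)
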