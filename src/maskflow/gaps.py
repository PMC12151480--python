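"""Synthetic per-channel gap-height profiles K(x).

Stands in for deployed-mask gap fields measured on morphed faces: smooth
periphery modulation around region baselines, with every profile confined to
its region's gap envelope (nose 1.5-6 mm, chin 0.3-0.5 mm, cheek 0.7-1.2 mm).
A single facial feature can be emphasised through the shape coefficient
``alpha`` in [-1.2, 1.2]; ``alpha = 0`` is the mean face.

Profiles are deterministic in (layout, seed, config) and can be round-tripped
through a long-format CSV for use with externally measured gap fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from maskflow.geometry import ChannelGeometry

GENERATOR_VERSION = "maskflow-gaps-1"

ALPHA_MAX = 1.2

FEATURES = ("nose", "chin", "zygomatic_arch", "cheeks", "mean_face")

#: per-region gap envelope [min, max] in metres
ENVELOPES: dict[str, tuple[float, float]] = {
    "nose": (1.5e-3, 6.0e-3),
    "chin": (0.3e-3, 0.5e-3),
    "cheek": (0.7e-3, 1.2e-3),
}

#: per-region baseline gap (envelope midpoint) in metres
BASELINES: dict[str, float] = {
    "nose": 3.0e-3,
    "chin": 0.4e-3,
    "cheek": 0.95e-3,
}


class GapError(ValueError):
    """Invalid gap profile or feature specification."""


@dataclass(frozen=True)
class FeatureSpec:
    """One synthetic face: a facial feature emphasised by ``alpha``."""

    feature: str = "mean_face"
    alpha: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature not in FEATURES:
            raise GapError(f"unknown feature {self.feature!r}; one of {FEATURES}")
        if abs(self.alpha) > ALPHA_MAX:
            raise GapError(f"|alpha| must not exceed {ALPHA_MAX}")
        if self.feature == "mean_face" and self.alpha != 0.0:
            raise GapError("mean_face forces alpha = 0")


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic gap generator."""

    baselines: dict[str, float] = field(default_factory=lambda: dict(BASELINES))
    envelopes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(ENVELOPES))
    modulation_amplitude: float = 0.15  # fraction of the region baseline
    n_harmonics: int = 3
    taper_cavity_factor: float = 1.0  # K(cavity end) / K(exit); 1 = constant
    grid_size: int = 101


@dataclass
class GapProfileSet:
    """Gap heights for every channel of one synthetic (or measured) face."""

    channel_ids: np.ndarray  # (n_channels,)
    regions: list[str]
    x: np.ndarray  # (n_x,) normalised arclength, cavity (0) to edge (1)
    K: np.ndarray  # (n_channels, n_x) heights in metres
    upper_cheek: np.ndarray  # bool mask: cheek channels nearest the nose
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.K.shape != (len(self.channel_ids), len(self.x)):
            raise GapError("K must have shape (n_channels, n_x)")
        if np.any(self.K <= 0):
            raise GapError("gap heights must be positive")

    def region_mask(self, region: str) -> np.ndarray:
        return np.array([r == region for r in self.regions])

    def region_stats(self) -> pd.DataFrame:
        rows = []
        for region in ("nose", "chin", "cheek"):
            m = self.region_mask(region)
            if m.any():
                rows.append({"region": region,
                             "min_gap_m": float(self.K[m].min()),
                             "max_gap_m": float(self.K[m].max()),
                             "mean_gap_m": float(self.K[m].mean())})
        return pd.DataFrame(rows)


def _periphery_modulation(rng: np.random.Generator, s: np.ndarray,
                          n_harmonics: int) -> np.ndarray:
    """Smooth zero-mean modulation over the periphery coordinate, max |.| = 1."""
    g = np.zeros_like(s)
    for k in range(1, n_harmonics + 1):
        amp = rng.uniform(0.5, 1.0) / k
        phase = rng.uniform(0.0, 2.0 * math.pi)
        g += amp * np.cos(2.0 * math.pi * k * s + phase)
    peak = np.max(np.abs(g))
    return g / peak if peak > 0 else g


def mean_face_gaps(channels: list[ChannelGeometry], seed: int,
                   config: GeneratorConfig | None = None) -> GapProfileSet:
    """Generate the mean-face (alpha = 0) gap set for a channel layout."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    n = len(channels)
    if n == 0:
        raise GapError("empty channel layout")
    s = (np.arange(n) + 0.5) / n  # periphery coordinate of each exit
    g = _periphery_modulation(rng, s, cfg.n_harmonics)

    x = np.linspace(0.0, 1.0, cfg.grid_size)
    t = cfg.taper_cavity_factor
    taper = t + (1.0 - t) * x  # 1 at the exit, t at the cavity end

    K = np.empty((n, cfg.grid_size))
    regions = []
    for j, ch in enumerate(channels):
        base = cfg.baselines[ch.region]
        lo, hi = cfg.envelopes[ch.region]
        exit_gap = base * (1.0 + cfg.modulation_amplitude * g[j])
        K[j] = np.clip(exit_gap * taper, lo, hi)
        regions.append(ch.region)

    upper = np.array([ch.region == "cheek" and ch.exit_point[1] > 0
                      for ch in channels])
    prov = {
        "generator": GENERATOR_VERSION,
        "feature": "mean_face",
        "alpha": 0.0,
        "seed": int(seed),
        "modulation_amplitude": cfg.modulation_amplitude,
        "n_harmonics": cfg.n_harmonics,
        "taper_cavity_factor": cfg.taper_cavity_factor,
    }
    return GapProfileSet(channel_ids=np.array([c.index for c in channels]),
                         regions=regions, x=x, K=K, upper_cheek=upper,
                         provenance=prov)


def _feature_selector(gaps: GapProfileSet, feature: str) -> np.ndarray:
    """Boolean mask of the channels modulated by ``feature``."""
    if feature == "nose":
        return gaps.region_mask("nose")
    if feature == "chin":
        return gaps.region_mask("chin")
    if feature == "cheeks":
        return gaps.region_mask("cheek")
    if feature == "zygomatic_arch":
        return gaps.upper_cheek.copy()
    raise GapError(f"unknown feature {feature!r}")


def feature_gaps(base: GapProfileSet, spec: FeatureSpec,
                 config: GeneratorConfig | None = None,
                 clip: bool = True) -> GapProfileSet:
    """Modulate the gaps of the channels tied to one facial feature.

    The modulation is linear in ``alpha`` with a per-region slope that spans
    the envelope half-range at ``|alpha| = 1.2`` (positive alpha = larger
    gaps, the leakier face).  With ``clip`` the result is confined to the
    region envelope; ``clip=False`` exposes the raw linear map (used by the
    linearity property tests).
    """
    cfg = config or GeneratorConfig()
    if spec.feature == "mean_face" or spec.alpha == 0.0:
        out = replace(base, K=base.K.copy())
        out.provenance = dict(base.provenance, feature=spec.feature, alpha=0.0)
        return out

    sel = _feature_selector(base, spec.feature)
    K = base.K.copy()
    for j in np.flatnonzero(sel):
        region = base.regions[j]
        lo, hi = cfg.envelopes[region]
        # additive shift, linear in alpha: spans the envelope half-range at
        # |alpha| = 1.2 and keeps alpha -> -alpha an exact inverse (unclipped)
        slope = 0.5 * (hi - lo) / ALPHA_MAX
        K[j] = base.K[j] + spec.alpha * slope
        if clip:
            K[j] = np.clip(K[j], lo, hi)
    out = replace(base, K=K)
    out.provenance = dict(base.provenance, feature=spec.feature,
                          alpha=spec.alpha, seed=spec.seed)
    return out


def ensemble(channels: list[ChannelGeometry], features: list[str],
             alphas: list[float], seeds: list[int],
             config: GeneratorConfig | None = None) -> list[GapProfileSet]:
    """Cartesian product of features x alphas x seeds, provenance-tagged."""
    if not features or not alphas or not seeds:
        raise GapError("features, alphas and seeds must be non-empty")
    out = []
    for seed in seeds:
        base = mean_face_gaps(channels, seed, config)
        for feature in features:
            for alpha in alphas:
                a = 0.0 if feature == "mean_face" else alpha
                spec = FeatureSpec(feature=feature, alpha=a, seed=seed)
                out.append(feature_gaps(base, spec, config))
    return out


def apply_gaps(channels: list[ChannelGeometry],
               gaps: GapProfileSet) -> list[ChannelGeometry]:
    """Attach gap heights to the channel geometries (linear resampling)."""
    if len(channels) != len(gaps.channel_ids):
        raise GapError(
            f"gap set has {len(gaps.channel_ids)} channels, layout has "
            f"{len(channels)}")
    by_id = {int(cid): j for j, cid in enumerate(gaps.channel_ids)}
    out = []
    for ch in channels:
        if ch.index not in by_id:
            raise GapError(f"gap set missing channel {ch.index}")
        K = np.interp(ch.x_grid, gaps.x, gaps.K[by_id[ch.index]])
        out.append(ch.with_heights(K))
    return out


# ---------------------------------------------------------------------------
# CSV I/O (long format: channel_id, x_norm, K_m)
# ---------------------------------------------------------------------------

def write_gaps(gaps: GapProfileSet, path) -> None:
    frames = []
    for j, cid in enumerate(gaps.channel_ids):
        frames.append(pd.DataFrame({
            "channel_id": int(cid),
            "x_norm": gaps.x,
            "K_m": gaps.K[j],
            "region": gaps.regions[j],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_gaps(path, channels: list[ChannelGeometry] | None = None) -> GapProfileSet:
    """Read a long-format gap CSV; optionally validate against a layout."""
    df = pd.read_csv(path)
    required = {"channel_id", "x_norm", "K_m"}
    if not required.issubset(df.columns):
        raise GapError(f"gap CSV must have columns {sorted(required)}")
    ids = sorted(df["channel_id"].unique())
    grids, profiles, regions = [], [], []
    for cid in ids:
        sub = df[df["channel_id"] == cid]
        x = sub["x_norm"].to_numpy(dtype=float)
        if np.any(np.diff(x) <= 0):
            raise GapError(f"channel {cid}: x_norm must be strictly increasing")
        K = sub["K_m"].to_numpy(dtype=float)
        if np.any(K <= 0):
            raise GapError(f"channel {cid}: non-positive gap height")
        grids.append(x)
        profiles.append(K)
        regions.append(str(sub["region"].iloc[0]) if "region" in sub else "nose")
    n_x = len(grids[0])
    if any(len(g) != n_x for g in grids):
        raise GapError("all channels must share one x grid")
    x0 = grids[0]
    if any(not np.allclose(g, x0) for g in grids):
        raise GapError("all channels must share one x grid")

    upper = np.zeros(len(ids), dtype=bool)
    if channels is not None:
        if len(channels) != len(ids):
            raise GapError(
                f"gap CSV has {len(ids)} channels, layout has {len(channels)}")
        by_id = {ch.index: ch for ch in channels}
        for j, cid in enumerate(ids):
            if int(cid) not in by_id:
                raise GapError(f"gap CSV channel {cid} not in layout")
            ch = by_id[int(cid)]
            regions[j] = ch.region
            upper[j] = ch.region == "cheek" and ch.exit_point[1] > 0

    return GapProfileSet(channel_ids=np.array(ids, dtype=int), regions=regions,
                         x=x0, K=np.vstack(profiles), upper_cheek=upper,
                         provenance={"generator": "file", "path": str(path)})
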