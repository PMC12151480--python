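"""Headline experiments: jet-velocity ensembles and sensitivity studies.

These functions rebuild their scenarios from scratch (layout, synthetic
gaps, network solve) so that every reported number is recomputed at run
time; they back both the acceptance tests and ``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from maskflow import metrics as mx
from maskflow.channel import FabricModel
from maskflow.config import ScenarioConfig
from maskflow.gaps import FeatureSpec
from maskflow.network import BreathSpec


def channel_count() -> int:
    """Channels in the default full (unmirrored) network."""
    return ScenarioConfig().layout.total_channels


def _seeded_config(seed: int, **updates) -> ScenarioConfig:
    cfg = ScenarioConfig(seed=seed, face=FeatureSpec(seed=seed))
    return cfg.with_updates(**updates) if updates else cfg


def jet_velocity_ensemble(seeds, c_k: float = 500.0) -> pd.DataFrame:
    """Per-face maximum exit-jet velocity, no clip, exhale at 0.5 L/s.

    One mean-face synthetic gap set per seed on the default 48-channel
    layout; returns one row per seed with the max-over-channels jet speed.
    """
    rows = []
    for seed in seeds:
        cfg = _seeded_config(seed, fabric=FabricModel(c_k=c_k))
        sol = mx.run_scenario(cfg)
        rows.append({"seed": seed,
                     "U_jet_max": float(sol.U_jet.max()),
                     "argmax_region":
                         sol.channels[int(sol.U_jet.argmax())].region})
    return pd.DataFrame(rows)


def inhale_through_mask_pct(seed: int, c_k: float = 1000.0,
                            edge_k_L: float = 0.5,
                            alpha: float = 1.2) -> float:
    """Through-mask percentage for inward protection on a tall-nose face."""
    cfg = _seeded_config(
        seed,
        face=FeatureSpec(feature="nose", alpha=alpha, seed=seed),
        fabric=FabricModel(c_k=c_k),
        breath=BreathSpec(direction="inhale"),
        edge_k_L_inhale=edge_k_L,
    )
    sol = mx.run_scenario(cfg)
    return 100.0 * sol.Q_m / sol.Q_breath


def channel_share_of_through_mask(seed: int, c_k: float = 100.0) -> float:
    """Channel-network share of Q_m (%) for mean-face exhale."""
    cfg = _seeded_config(seed, fabric=FabricModel(c_k=c_k))
    sol = mx.run_scenario(cfg)
    return 100.0 * sol.Q_m_c / sol.Q_m


def cavity_sensitivity_worst_case(seed: int,
                                  alphas=(-1.2, 0.0, 1.2),
                                  ck_values=(100.0, 500.0, 1000.0),
                                  area_fraction: float = 0.075,
                                  edge_k_L_inhale: float = 0.5,
                                  ) -> tuple[float, pd.DataFrame]:
    """Worst-case |change of Q_m_pct| under a +-7.5% cavity-area change.

    Sweeps the nose-feature shape coefficient and the fabric resistance for
    both exhale and inhale; returns the max absolute percentage-point change
    and the full table.
    """
    rows = []
    worst = 0.0
    for direction in ("exhale", "inhale"):
        for alpha in alphas:
            feature = "mean_face" if alpha == 0.0 else "nose"
            for ck in ck_values:
                cfg = _seeded_config(
                    seed,
                    face=FeatureSpec(feature=feature, alpha=alpha, seed=seed),
                    fabric=FabricModel(c_k=ck),
                    breath=BreathSpec(direction=direction),
                    edge_k_L_inhale=edge_k_L_inhale,
                )
                base = mx.run_scenario(cfg)
                base_pct = 100.0 * base.Q_m / base.Q_breath
                for frac in (area_fraction, -area_fraction):
                    pert = mx.run_scenario(
                        cfg.with_updates(cavity_area_scale=frac))
                    pct = 100.0 * pert.Q_m / pert.Q_breath
                    d = pct - base_pct
                    worst = max(worst, abs(d))
                    rows.append({"direction": direction, "alpha": alpha,
                                 "c_k": ck, "area_fraction": frac,
                                 "Q_m_pct_base": base_pct,
                                 "Q_m_pct_perturbed": pct,
                                 "dQ_m_pct": d})
    return worst, pd.DataFrame(rows)
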