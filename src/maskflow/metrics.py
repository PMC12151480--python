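"""Decompositions, parameter sweeps and sensitivity analyses.

All percentages are reported relative to the breathing flux; regional leak
percentages are shares of the total peripheral leak Q_g, and the cavity /
channel-network split is reported as shares of the through-mask flux Q_m.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from maskflow.config import ScenarioConfig
from maskflow.gaps import FEATURES
from maskflow.network import (
    BreathSpec,
    ClipSpec,
    NetworkSolution,
    solve_network,
)

logger = logging.getLogger("maskflow.metrics")

CK_DEFAULT = (100.0, 500.0, 1000.0)
CLIP_KL_DEFAULT = (1.0, 10.0, 100.0, 1000.0)
INHALE_KL_DEFAULT = (0.2, 0.5)


def run_scenario(config: ScenarioConfig) -> NetworkSolution:
    """Build the geometry and gaps of ``config`` and solve the network."""
    channels = config.build_channels()
    gaps = config.build_gaps(channels)
    clip = config.clip if config.clip.k_L_clip > 0 else None
    return solve_network(channels, gaps, config.fluid, config.fabric,
                         config.breath, clip, config.cavity_spec(),
                         options=config.solver, edge_k_L=config.edge_k_L)


def decompose(sol: NetworkSolution, breath: BreathSpec) -> dict:
    """One tidy result row from a converged network solution."""
    if not sol.converged:
        raise ValueError("cannot decompose a non-converged solution")
    Q = breath.Q_breath
    Q_m = sol.Q_m
    Q_g = sol.Q_g
    row = {
        "direction": sol.direction,
        "P_cav": sol.P_cav,
        "Q_m_pct": 100.0 * Q_m / Q,
        "Q_g_pct": 100.0 * Q_g / Q,
        "Q_m_cav_share_pct": 100.0 * sol.Q_m_cav / Q_m if Q_m > 0 else 0.0,
        "Q_m_c_share_pct": 100.0 * sol.Q_m_c / Q_m if Q_m > 0 else 0.0,
        "Q_g_nose_pct": 100.0 * sol.Q_g_by_region["nose"] / Q_g if Q_g > 0 else 0.0,
        "Q_g_chin_pct": 100.0 * sol.Q_g_by_region["chin"] / Q_g if Q_g > 0 else 0.0,
        "Q_g_cheeks_pct": 100.0 * sol.Q_g_by_region["cheek"] / Q_g if Q_g > 0 else 0.0,
        "U_jet_max": float(sol.U_jet.max()),
    }
    return row


def _solve_row(config: ScenarioConfig) -> dict:
    sol = run_scenario(config)
    row = {
        "feature": config.face.feature,
        "alpha": config.face.alpha,
        "c_k": config.fabric.c_k,
        "k_L_clip": config.clip.k_L_clip,
        "k_L_edge": config.edge_k_L,
        "seed": config.seed,
    }
    row.update(decompose(sol, config.breath))
    return row


def sweep_ck(config: ScenarioConfig,
             ck_values=CK_DEFAULT,
             alphas=None,
             features=None,
             inhale_kL=INHALE_KL_DEFAULT) -> pd.DataFrame:
    """Fabric-resistance sweep (optionally crossed with features/alphas).

    For inhale scenarios each combination is solved at every edge-loss value
    in ``inhale_kL`` (paired rows).
    """
    if alphas is None:
        alphas = [config.face.alpha]
    if features is None:
        features = [config.face.feature]
    if not len(ck_values) or not len(alphas) or not len(features):
        raise ValueError("sweep grids must be non-empty")
    for f in features:
        if f not in FEATURES:
            raise ValueError(f"unknown feature {f!r}")

    inhale = config.breath.direction == "inhale"
    kL_values = list(inhale_kL) if inhale else [config.edge_k_L_exhale]
    rows = []
    for feature in features:
        for alpha in alphas:
            a = 0.0 if feature == "mean_face" else alpha
            face = replace(config.face, feature=feature, alpha=a)
            for ck in ck_values:
                for kL in kL_values:
                    cfg = config.with_updates(
                        face=face,
                        fabric=replace(config.fabric, c_k=float(ck)),
                        edge_k_L_inhale=kL if inhale else config.edge_k_L_inhale,
                    )
                    try:
                        rows.append(_solve_row(cfg))
                    except Exception as exc:  # annotate, do not hide
                        logger.error("sweep point failed: %s", exc)
                        rows.append({"feature": feature, "alpha": a,
                                     "c_k": float(ck), "k_L_edge": kL,
                                     "error": str(exc)})
    return pd.DataFrame(rows)


def sweep_clip(config: ScenarioConfig,
               kL_values=CLIP_KL_DEFAULT) -> pd.DataFrame:
    """Nose-clip sweep: rows ordered by the clip loss coefficient."""
    rows = []
    for kL in sorted(kL_values):
        cfg = config.with_updates(
            clip=ClipSpec(k_L_clip=float(kL),
                          target_region=config.clip.target_region))
        rows.append(_solve_row(cfg))
    return pd.DataFrame(rows)


def sensitivity_cavity(config: ScenarioConfig,
                       area_fractions=(0.075, -0.075),
                       y_shifts=(5e-3, -5e-3)) -> pd.DataFrame:
    """Cavity size/placement sensitivity relative to the base scenario.

    Reports the percentage-point change of Q_m_pct for each perturbation.
    """
    base_row = _solve_row(config)
    rows = [dict(base_row, perturbation="base", value=0.0, dQ_m_pct=0.0)]
    for frac in area_fractions:
        cfg = config.with_updates(cavity_area_scale=config.cavity_area_scale
                                  + frac)
        try:
            row = _solve_row(cfg)
            rows.append(dict(row, perturbation="area_scale", value=frac,
                             dQ_m_pct=row["Q_m_pct"] - base_row["Q_m_pct"]))
        except Exception as exc:
            rows.append({"perturbation": "area_scale", "value": frac,
                         "error": str(exc)})
    for dy in y_shifts:
        cfg = config.with_updates(cavity_y_offset=config.cavity_y_offset + dy)
        try:
            row = _solve_row(cfg)
            rows.append(dict(row, perturbation="y_offset", value=dy,
                             dQ_m_pct=row["Q_m_pct"] - base_row["Q_m_pct"]))
        except Exception as exc:
            rows.append({"perturbation": "y_offset", "value": dy,
                         "error": str(exc)})
    return pd.DataFrame(rows)


def jet_profile(sol: NetworkSolution) -> pd.DataFrame:
    """Per-channel exit-jet table in periphery order (chin -> cheek -> nose)."""
    rows = []
    for ch, s in zip(sol.channels, sol.channel_solutions):
        rows.append({
            "i": ch.index,
            "region": ch.region,
            "U_jet": s.U_jet,
            "q_g": s.Q_g / ch.width,
            "Q_g": s.Q_g,
            "K_exit": float(ch.heights[-1]),
        })
    return pd.DataFrame(rows).sort_values("i").reset_index(drop=True)


def per_channel_table(sol: NetworkSolution) -> pd.DataFrame:
    """Detailed per-channel CSV payload for run outputs."""
    rows = []
    for ch, s in zip(sol.channels, sol.channel_solutions):
        rows.append({
            "channel_id": ch.index,
            "region": ch.region,
            "W_m": ch.width,
            "Lc_m": ch.length,
            "K_exit_m": float(ch.heights[-1]),
            "U_in": s.U,
            "Q_in": s.Q_in,
            "Q_g": s.Q_g,
            "Q_m_c": s.Q_m_c,
            "U_jet": s.U_jet,
            "p_cavity_Pa": s.p_cavity,
        })
    return pd.DataFrame(rows)


def summary_dict(sol: NetworkSolution, config: ScenarioConfig) -> dict:
    """JSON-ready run summary."""
    row = decompose(sol, config.breath)
    return {
        "label": config.label,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "direction": sol.direction,
        "P_cav_Pa": sol.P_cav,
        "Q_breath_m3s": sol.Q_breath,
        "Q_g_m3s": sol.Q_g,
        "Q_m_m3s": sol.Q_m,
        "Q_m_cav_m3s": sol.Q_m_cav,
        "Q_m_c_m3s": sol.Q_m_c,
        "Q_g_by_region_m3s": {k: float(v)
                              for k, v in sol.Q_g_by_region.items()},
        "metrics": {k: float(v) for k, v in row.items()
                    if isinstance(v, (int, float, np.floating))},
        "mass_residual": sol.mass_residual,
        "n_outer_evals": len(sol.history),
    }
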