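"""Shared fixtures: one desk-scale synthetic experiment per session.

The `experiment` fixture runs the full chain once — fly-scan simulation
of the dissolving phantom, disjoint and overlapping window
reconstructions, progression analysis, plus the two control runs
(noise-free static scan for window invariance, noisy static scan for
the null volume distribution) — and hands the in-memory objects to the
analysis and acceptance tests.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from flytomo.analysis import progression_curve
from flytomo.config import demo_config
from flytomo.pipeline import reconstruct_series, static_window_invariance
from flytomo.acquisition import simulate_flyscan

SEED = 11


def make_disc(n: int, radius: float, mu: float = 0.01) -> np.ndarray:
    """Uniform disc phantom centered on an n x n grid."""
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[:n, :n]
    return np.where(np.hypot(yy - c, xx - c) <= radius, mu, 0.0)


@pytest.fixture(scope="session")
def demo_cfg():
    return demo_config(seed=SEED)


@pytest.fixture(scope="session")
def null_tomos(demo_cfg):
    """Windows of a noisy scan of a *static* phantom (no-change null)."""
    cfg = demo_cfg
    state = dataclasses.replace(
        cfg.phantom,
        dissolution=dataclasses.replace(cfg.phantom.dissolution, front_speed_um_per_s=0.0),
    )
    stack = simulate_flyscan(state, cfg.geometry, cfg.detector, seed=cfg.seed + 1)
    return reconstruct_series(stack, cfg.windows.n_window, cfg.windows.stride)


@pytest.fixture(scope="session")
def experiment(demo_cfg, null_tomos):
    """Full synthetic dissolution experiment at desk scale (run once)."""
    cfg = demo_cfg
    stack = simulate_flyscan(cfg.phantom, cfg.geometry, cfg.detector, seed=cfg.seed)
    tomos = reconstruct_series(stack, cfg.windows.n_window, cfg.windows.stride)
    fine_tomos = reconstruct_series(stack, cfg.windows.n_window, cfg.windows.fine_stride)
    lc = cfg.analysis.largest_component
    result = progression_curve(tomos, threshold_rule=cfg.analysis.threshold_rule,
                               largest_component=lc)
    fine_result = progression_curve(fine_tomos, threshold_rule=cfg.analysis.threshold_rule,
                                    largest_component=lc)
    tau = result.threshold_used["tau"]
    null_result = progression_curve(null_tomos, threshold_rule=tau, largest_component=lc)
    sigma = float(np.sqrt(np.mean(null_result.cavity_volume**2)))
    inv_nrmse = static_window_invariance(cfg)
    return {
        "cfg": cfg,
        "stack": stack,
        "tomos": tomos,
        "fine_tomos": fine_tomos,
        "result": result,
        "fine_result": fine_result,
        "null_sigma": sigma,
        "null_volumes": null_result.cavity_volume,
        "invariance_nrmse": inv_nrmse,
    }
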