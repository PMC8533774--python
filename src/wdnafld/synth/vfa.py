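"""Forward simulation of variable-flip-angle spoiled gradient-echo stacks."""

from __future__ import annotations

import numpy as np

from ..mrit1 import DEFAULT_FLIP_ANGLES_DEG, DEFAULT_TR_MS, VfaStack, spgr_signal


def simulate_vfa_stack(
    t1_map,
    m0_map,
    flip_angles_deg=DEFAULT_FLIP_ANGLES_DEG,
    tr_ms: float = DEFAULT_TR_MS,
    noise_sd: float = 0.0,
    seed: int = 0,
    mask=None,
) -> VfaStack:
    """SPGR signals from known T1/M0 maps plus optional Gaussian noise.

    Each pixel follows S = M0 sin(a) (1 - E1) / (1 - E1 cos(a)) with
    E1 = exp(-TR/T1); noise is additive Gaussian with standard deviation
    ``noise_sd`` (no magnitude/Rician bias is modeled).
    """
    t1 = np.asarray(t1_map, dtype=float)
    m0 = np.asarray(m0_map, dtype=float)
    if t1.shape != m0.shape:
        raise ValueError("t1_map and m0_map must share a shape")
    if tr_ms <= 0:
        raise ValueError("TR must be positive")
    angles = np.asarray(flip_angles_deg, dtype=float)
    if np.any(angles <= 0) or np.any(angles > 90):
        raise ValueError("flip angles must lie in (0, 90] degrees")
    if mask is None:
        mask = np.ones(t1.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if np.any(t1[mask] <= 0):
        raise ValueError("T1 must be positive inside the mask")

    t1_safe = np.where(mask, t1, 1.0)
    signals = np.stack(
        [np.where(mask, spgr_signal(t1_safe, m0, a, tr_ms), 0.0) for a in angles]
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signals = signals + rng.normal(0.0, noise_sd, size=signals.shape)
    return VfaStack(signals=signals, flip_angles_deg=tuple(angles), tr_ms=tr_ms, mask=mask)
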