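"""One-time calibration of the oxygen consumption-to-diffusion ratio.

The supplementary parameter table of the original study is not available,
so the free ratio kappa/D_oxy is calibrated once so that the reference
parameter set (omega_q = 0.6, omega_h = 0.34, tau = 31.25) reaches a mean
steady-state radius of about 14 cell diameters. All other parameter sets
are then run without retuning. Mechanics defaults (mu, beta, drag) are
fixed at documented values and are not part of the calibration.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .analysis import plateau_onset
from .engine import growth_curve, run_growth
from .state import make_config

__all__ = ["steady_state_radius", "calibrate_kappa", "REFERENCE_PARAMS", "TARGET_RADIUS"]

#: reference cell-line parameter set used for calibration
REFERENCE_PARAMS = {"omega_q": 0.6, "omega_h": 0.34, "tau": 31.25}
#: target mean steady-state radius, cell diameters
TARGET_RADIUS = 14.0


def steady_state_radius(
    cfg, n_replicates: int = 3, seed: int = 0, tail: float = 50.0
) -> float:
    """Mean spheroid radius over the last ``tail`` hours, replicate-averaged."""
    radii = []
    for rep in range(n_replicates):
        run_cfg = make_config(cfg.to_dict() | {"seed": seed + 1000 * rep})
        snaps = run_growth(run_cfg)
        t, r = growth_curve(snaps)
        radii.append(r[t >= t[-1] - tail].mean())
    return float(np.mean(radii))


def calibrate_kappa(
    target_radius: float = TARGET_RADIUS,
    kappa_lo: float = 0.01,
    kappa_hi: float = 0.2,
    n_iter: int = 6,
    n_replicates: int = 2,
    base_overrides: Optional[dict] = None,
    verbose: bool = False,
) -> Tuple[float, float]:
    """Bisection on kappa: steady radius decreases as consumption rises.

    Returns (kappa, achieved mean steady radius). Uses the reference
    parameter set plus any ``base_overrides`` (e.g. a larger pde_stride
    for speed).
    """
    overrides = dict(REFERENCE_PARAMS)
    if base_overrides:
        overrides.update(base_overrides)

    def radius_at(kappa: float) -> float:
        cfg = make_config(overrides | {"kappa": kappa})
        return steady_state_radius(cfg, n_replicates=n_replicates)

    lo, hi = kappa_lo, kappa_hi
    r_lo = radius_at(lo)
    r_hi = radius_at(hi)
    if verbose:
        print(f"kappa={lo:.4f} -> R={r_lo:.2f}; kappa={hi:.4f} -> R={r_hi:.2f}")
    if not (r_hi <= target_radius <= r_lo):
        # target outside the bracket; return the closer endpoint
        return (lo, r_lo) if abs(r_lo - target_radius) < abs(r_hi - target_radius) else (hi, r_hi)
    for _ in range(n_iter):
        mid = np.sqrt(lo * hi)
        r_mid = radius_at(mid)
        if verbose:
            print(f"kappa={mid:.4f} -> R={r_mid:.2f}")
        if r_mid > target_radius:
            lo = mid
        else:
            hi = mid
    kappa = float(np.sqrt(lo * hi))
    return kappa, radius_at(kappa)
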