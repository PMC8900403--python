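"""Independent brute-force reference for the behavior classifier.

Places all vectors on the unit circle and decides range membership and
betweenness purely with normalized signed-angle arithmetic in degrees — no
cross products, no radian geometry shared with the implementation.
"""

import numpy as np

TAU1_DEG = np.degrees(0.2)
TAU2_DEG = np.degrees(0.1)

LABELS = (
    "supported",
    "full_drift",
    "full_compensation",
    "partial_compensation",
    "overcompensation",
    "overdrift",
)


def _wrap(x):
    """Wrap degrees to (-180, 180]."""
    return -((180.0 - np.asarray(x, dtype=float)) % 360.0 - 180.0)


def _sign(a):
    """Rotation sign of a wrapped angle; 0 at 0 and at +/-180 (undefined)."""
    a = np.asarray(a)
    return np.where((a == 0.0) | (np.abs(a) == 180.0), 0, np.sign(a)).astype(int)


def oracle_classify(r_deg, w_deg, d_deg, half_width_deg,
                    tau1_deg=TAU1_DEG, tau2_deg=TAU2_DEG):
    """Vectorized reference classification; returns label strings."""
    a_r = _wrap(np.asarray(r_deg, float) - d_deg)   # track rel. midpoint
    a_w = _wrap(np.asarray(w_deg, float) - d_deg)   # wind rel. midpoint
    a_rw = _wrap(np.asarray(r_deg, float) - np.asarray(w_deg, float))

    near_wind = np.abs(a_rw) <= tau1_deg
    in_range = np.abs(a_r) <= np.asarray(half_width_deg, float) + tau2_deg

    s_r, s_w = _sign(a_r), _sign(a_w)
    opposite = s_r * s_w < 0
    rule3 = np.where(
        opposite,
        LABELS.index("overcompensation"),
        np.where(np.abs(a_r) <= np.abs(a_w),
                 LABELS.index("partial_compensation"),
                 LABELS.index("overdrift")),
    )
    idx = np.where(
        near_wind,
        np.where(in_range, LABELS.index("supported"), LABELS.index("full_drift")),
        np.where(in_range, LABELS.index("full_compensation"), rule3),
    )
    return np.asarray(LABELS, dtype=object)[idx]
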