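"""Reference coefficient tables bundled with the package.

``reference_kp_coefficients`` holds published Korsmeyer-Peppas fits for
sonosensitive liposomes conjugated with seven targeting moieties, insonated
at 20 kHz low-frequency ultrasound at three power densities (6.2, 9 and
10 mW/cm^2).  ``a`` is the power-law rate constant ``kkp`` (s^-n) and ``b``
the release exponent ``n`` (dimensionless).  These coefficients serve as
realistic ground truths for the synthetic study generator and as inputs for
mechanism summaries.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["MOIETIES", "POWER_DENSITIES_MW_CM2", "reference_kp_coefficients"]

#: Targeting moieties in the low-frequency reference study.
MOIETIES = ("albumin", "cRGD", "estrone", "HA", "Her2", "LA", "transferrin")

#: 20 kHz power densities, mW/cm^2.
POWER_DENSITIES_MW_CM2 = (6.2, 9.0, 10.0)

# (moiety, power density mW/cm^2) -> (a = kkp, b = n)
_KP_TABLE = [
    ("albumin", 6.2, 3.50e-3, 0.73),
    ("albumin", 9.0, 3.25e-3, 0.79),
    ("albumin", 10.0, 5.70e-3, 0.74),
    ("cRGD", 6.2, 1.32e-3, 0.86),
    ("cRGD", 9.0, 9.83e-4, 0.95),
    ("cRGD", 10.0, 9.40e-4, 0.99),
    ("estrone", 6.2, 5.33e-2, 0.41),
    ("estrone", 9.0, 8.32e-2, 0.36),
    ("estrone", 10.0, 1.11e-1, 0.32),
    ("HA", 6.2, 1.67e-3, 0.85),
    ("HA", 9.0, 2.52e-3, 0.85),
    ("HA", 10.0, 4.78e-3, 0.78),
    ("Her2", 6.2, 3.48e-3, 0.77),
    ("Her2", 9.0, 4.46e-3, 0.77),
    ("Her2", 10.0, 3.35e-3, 0.87),
    ("LA", 6.2, 3.33e-3, 0.72),
    ("LA", 9.0, 5.57e-3, 0.69),
    ("LA", 10.0, 9.45e-3, 0.64),
    ("transferrin", 6.2, 5.61e-3, 0.73),
    ("transferrin", 9.0, 6.64e-3, 0.75),
    ("transferrin", 10.0, 1.70e-2, 0.62),
]


def reference_kp_coefficients() -> pd.DataFrame:
    """Published 20 kHz Korsmeyer-Peppas coefficients, one row per
    (moiety, power density); columns ``moiety``, ``power_density``, ``a``, ``b``."""
    return pd.DataFrame(
        _KP_TABLE, columns=["moiety", "power_density", "a", "b"]
    )
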