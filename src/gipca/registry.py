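"""Canonical registry of the 11 gait-initiation (GI) kinetic variables.

The GI analysis characterises the transition from quiet standing to steady
walking with a small set of force-plate-derived quantities: the duration of
the anticipatory postural adjustments (APA) on each horizontal axis, the
centre-of-pressure (COP) excursion developed during the APA, the
centre-of-mass (COM) velocity at the three step landmarks (heel-off,
toe-off, heel-contact), the foot-lift duration and the vertical force peak
at heel contact.  Every feature table in this package uses these names, in
this order.
"""

from __future__ import annotations

#: Ordered names of the default 11-variable registry.
FEATURES: tuple[str, ...] = (
    "apa_ml",        # ML APA duration: ML COP onset -> heel-off (s)
    "apa_ap",        # AP APA duration: AP COP onset -> heel-off (s)
    "cop_shift_ap",  # max |AP COP displacement| during the APA window (m)
    "cop_shift_ml",  # max |ML COP displacement| during the APA window (m)
    "vcom_ap_ho",    # AP COM velocity at heel-off (m/s)
    "vcom_ap_to",    # AP COM velocity at toe-off (m/s)
    "vcom_ap_hc",    # AP COM velocity at heel-contact (m/s)
    "vcom_ml_ho",    # ML COM velocity at heel-off (m/s)
    "vcom_ml_to",    # ML COM velocity at toe-off (m/s)
    "foot_lift",     # heel-off -> toe-off duration (s)
    "fz_peak",       # vertical force peak at heel contact (N)
)

UNITS: dict[str, str] = {
    "apa_ml": "s",
    "apa_ap": "s",
    "cop_shift_ap": "m",
    "cop_shift_ml": "m",
    "vcom_ap_ho": "m/s",
    "vcom_ap_to": "m/s",
    "vcom_ap_hc": "m/s",
    "vcom_ml_ho": "m/s",
    "vcom_ml_to": "m/s",
    "foot_lift": "s",
    "fz_peak": "N",
}

#: Group labels used throughout (healthy controls vs. Parkinsonian patients).
GROUPS: tuple[str, str] = ("control", "pd")
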