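"""Shared vocabulary for the migraine sub-classification analysis.

The ten attack characteristics follow the modified ICHD-2 ascertainment
used in large questionnaire-based cohorts: aura, pulsating pain,
unilateral pain, phonophobia ("sound"), photophobia ("light"), attack
duration 4-72 h ("longdur"), nausea, aggravation by physical activity
("aggrphys"), inhibition of daily activities ("inhibit"), and attack
frequency >= 6/year ("freq").
"""

from __future__ import annotations

#: Canonical short names of the ten binary migraine characteristics.
CHARACTERISTICS: tuple[str, ...] = (
    "aura",
    "pulsation",
    "unipain",
    "sound",
    "light",
    "longdur",
    "nausea",
    "aggrphys",
    "inhibit",
    "freq",
)

#: Human-readable labels for reports.
CHARACTERISTIC_LABELS: dict[str, str] = {
    "aura": "aura",
    "pulsation": "pulsating pain",
    "unipain": "unilateral pain",
    "sound": "phonophobia",
    "light": "photophobia",
    "longdur": "duration of 4-72 hours",
    "nausea": "nausea",
    "aggrphys": "pain aggravation by physical activity",
    "inhibit": "inhibition of daily activities",
    "freq": "migraine attack frequency >=6/year",
}

#: Special pseudo-characteristic: partition active vs former migraineurs.
ACTIVE_VS_FORMER = "active_vs_former"

MIGRAINE_STATUSES: tuple[str, ...] = ("never", "former", "active")

#: Default cohort group sizes emulating a large women's health cohort
#: (active / former / never migraineurs).
DEFAULT_N_ACTIVE = 3003
DEFAULT_N_FORMER = 2119
DEFAULT_N_NEVER = 18108

#: Counts of active migraineurs reporting each characteristic, out of
#: DEFAULT_N_ACTIVE; the simulator's default prevalences are these ratios
#: (e.g. aura 1177/3003 = 0.39).
DEFAULT_CHARACTERISTIC_COUNTS: dict[str, int] = {
    "aura": 1177,
    "pulsation": 1591,
    "unipain": 1791,
    "sound": 1232,
    "light": 1976,
    "longdur": 2348,
    "nausea": 1958,
    "aggrphys": 1017,
    "inhibit": 1499,
    "freq": 1050,
}

DEFAULT_CHARACTERISTIC_PREVALENCES: dict[str, float] = {
    name: count / DEFAULT_N_ACTIVE
    for name, count in DEFAULT_CHARACTERISTIC_COUNTS.items()
}

#: Number of independent SNPs assumed by the second-stage Sidak correction.
DEFAULT_SIDAK_M = 12

#: Default size of the simulated null-SNP panel used to estimate the
#: covariance of selectivity vectors.
DEFAULT_N_NULL_SNPS = 1222
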