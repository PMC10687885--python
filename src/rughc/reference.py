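"""Published reference figures used as worked-example inputs and defaults.

The group counts below are the published classification of a cohort of
transitional hospital-to-home care episodes in Ontario into the 23 RUG-III/HC
groups: a "full" sample of 1,680 completed episodes and an "operational"
sample of 1,575 episodes after excluding the shortest 1% and longest 5% of
episode lengths. They drive the worked examples of
:func:`rughc.grouper.distribution_table` and the default category/group mix of
the synthetic cohort generator.

The relative group-effect sizes are the published operational-sample case-mix
indices for paid care time, used as the generator's default multiplicative
group effects; the two structurally empty groups (SE3, IA1) and the unobserved
SE1 get rank-consistent stand-in values.

The hourly billing rates are synthetic (no real rate card is public): a
realistic Ontario-style fee schedule in $/h whose only downstream role is the
ratio to the PSW rate.
"""

from __future__ import annotations

from .taxonomy import GROUP_ORDER

__all__ = [
    "REFERENCE_GROUP_COUNTS_FULL",
    "REFERENCE_GROUP_COUNTS_OPERATIONAL",
    "REFERENCE_CATEGORY_MIX",
    "REFERENCE_GROUP_EFFECTS",
    "REFERENCE_UNPAID_GROUP_EFFECTS",
    "DEFAULT_HOURLY_RATES",
]

#: Full-sample (n = 1,680) episode counts per RUG-III/HC group.
REFERENCE_GROUP_COUNTS_FULL: dict[str, int] = {
    "RB": 17, "RA2": 34, "RA1": 123,
    "SE3": 0, "SE2": 5, "SE1": 0,
    "SSB": 5, "SSA": 92,
    "CC": 41, "CB": 89, "CA2": 338, "CA1": 231,
    "IB": 10, "IA2": 24, "IA1": 0,
    "BB": 6, "BA2": 19, "BA1": 11,
    "PD": 46, "PC": 21, "PB": 59, "PA2": 270, "PA1": 239,
}

#: Operational-sample (n = 1,575) episode counts per RUG-III/HC group.
REFERENCE_GROUP_COUNTS_OPERATIONAL: dict[str, int] = {
    "RB": 17, "RA2": 34, "RA1": 113,
    "SE3": 0, "SE2": 4, "SE1": 0,
    "SSB": 4, "SSA": 87,
    "CC": 37, "CB": 85, "CA2": 317, "CA1": 212,
    "IB": 9, "IA2": 24, "IA1": 0,
    "BB": 6, "BA2": 17, "BA1": 10,
    "PD": 43, "PC": 20, "PB": 59, "PA2": 256, "PA1": 221,
}

#: Full-sample category shares in hierarchy order
#: (Rehabilitation, Extensive services, Special care, Clinically complex,
#: Impaired cognition, Behaviour problems, Reduced physical functions).
REFERENCE_CATEGORY_MIX: tuple[float, ...] = (0.104, 0.003, 0.058, 0.416, 0.020, 0.021, 0.378)

#: Relative per-group effects on expected care hours (paid-time CMI scale).
REFERENCE_GROUP_EFFECTS: dict[str, float] = {
    "RB": 1.14, "RA2": 1.03, "RA1": 1.21,
    "SE3": 1.50, "SE2": 0.88, "SE1": 0.90,   # SE3/SE1 unobserved: rank-consistent stand-ins
    "SSB": 1.83, "SSA": 1.16,
    "CC": 1.68, "CB": 1.32, "CA2": 0.99, "CA1": 0.81,
    "IB": 1.06, "IA2": 1.41, "IA1": 0.90,    # IA1 unobserved: stand-in
    "BB": 2.07, "BA2": 0.68, "BA1": 0.92,
    "PD": 1.39, "PC": 0.88, "PB": 1.33, "PA2": 0.87, "PA1": 0.76,
}

#: Relative per-group effects on expected unpaid care (combined paid+unpaid
#: time CMI scale, which is dominated by unpaid hours). Unobserved groups get
#: rank-consistent stand-ins.
REFERENCE_UNPAID_GROUP_EFFECTS: dict[str, float] = {
    "RB": 3.06, "RA2": 2.31, "RA1": 1.05,
    "SE3": 1.40, "SE2": 1.27, "SE1": 1.20,   # SE3/SE1 unobserved: stand-ins
    "SSB": 3.00, "SSA": 1.03,
    "CC": 1.68, "CB": 1.65, "CA2": 1.00, "CA1": 0.51,
    "IB": 2.91, "IA2": 1.36, "IA1": 1.00,    # IA1 unobserved: stand-in
    "BB": 0.86, "BA2": 1.41, "BA1": 0.54,
    "PD": 1.15, "PC": 0.95, "PB": 1.27, "PA2": 0.83, "PA1": 0.52,
}

#: Synthetic hourly billing rates, $/h. Only ratios to PSW matter downstream.
DEFAULT_HOURLY_RATES: dict[str, float] = {
    "RPN": 55.0,
    "RN": 75.0,
    "OT": 90.0,
    "PT": 90.0,
    "SLP": 95.0,
    "SW": 80.0,
    "RD": 85.0,
    "PTA": 50.0,
    "PSW": 30.0,
}

assert set(REFERENCE_GROUP_COUNTS_FULL) == set(GROUP_ORDER)
assert sum(REFERENCE_GROUP_COUNTS_FULL.values()) == 1680
assert sum(REFERENCE_GROUP_COUNTS_OPERATIONAL.values()) == 1575
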