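"""Worked-example report: the corticospinal-tract forward chain, computed
from scratch and set beside the published reference values.

Each row pairs a quantity the model computes with the value reported for the
hand representation of the corticospinal tract, at the precision it was
printed.  The tolerance for agreement is one unit in the last printed digit,
which also covers the small rounding inconsistencies present in the
published chain (e.g. a bidirectional mass flow printed as 4.71e-6 g/ms
where the components sum to 4.718e-6).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .bundle import (
    AxonBundle,
    ChannelBiophysics,
    channel_count_myelinated,
    channel_count_unmyelinated,
    water_mass_in_volume,
)
from .dwi import relative_signal_drop
from .tensor import ActivationParams, ActivationResult, activation_summary
from .flux import total_flux

__all__ = ["ReportRow", "worked_example_report", "reproduce"]


@dataclass(frozen=True)
class ReportRow:
    quantity: str
    unit: str
    computed: float
    reference: float
    tolerance: float  # one unit in the last printed digit of the reference

    @property
    def within_tolerance(self) -> bool:
        return abs(self.computed - self.reference) <= self.tolerance


# (key, unit, reference value, tolerance = 1 ulp of the printed figure)
_REFERENCE = [
    ("na_channels_myelinated", "channels", 1.61e12, 0.01e12),
    ("na_channels_unmyelinated", "channels", 1.98e12, 0.01e12),
    ("inflow_myelinated", "molecules/ms", 3.53e16, 0.01e16),
    ("inflow_unmyelinated", "molecules/ms", 4.35e16, 0.01e16),
    ("inflow_total", "molecules/ms", 7.89e16, 0.01e16),
    ("inflow_mass_myelinated", "g/ms", 1.06e-6, 0.01e-6),
    ("inflow_mass_unmyelinated", "g/ms", 1.30e-6, 0.01e-6),
    ("inflow_mass_total", "g/ms", 2.36e-6, 0.01e-6),
    ("f_w_mass_rate", "g/ms", 4.71e-6, 0.01e-6),
    ("resident_water_mass", "g", 0.039, 0.001),
    ("f_w_star", "", 4.28e-3, 0.01e-3),
    ("d_perp_star", "m^2/s", 2.13e-10, 0.01e-10),
    ("pct_change_d_perp", "%", 6.4, 0.1),
    ("d_app_star", "m^2/s", 4.75e-10, 0.01e-10),
    ("pct_change_d_app", "%", 1.8, 0.1),
    ("pct_signal_drop", "%", 0.77, 0.01),
    ("fa_inactive", "", 0.770, 0.001),
    ("fa_active", "", 0.754, 0.001),
    ("pct_change_fa", "%", -2.1, 0.1),
]


def _computed_chain(
    bundle: AxonBundle,
    chans: ChannelBiophysics,
    params: ActivationParams,
    b: float,
) -> tuple[dict[str, float], ActivationResult]:
    flux = total_flux(bundle, chans)
    water_mass = water_mass_in_volume(
        bundle.geometry.sample_length_mm,
        params.water_fraction,
        params.tissue_density_g_cm3,
    )
    result = activation_summary(bundle, chans, params)
    values = {
        "na_channels_myelinated": channel_count_myelinated(bundle, chans).total,
        "na_channels_unmyelinated": channel_count_unmyelinated(bundle, chans).total,
        "inflow_myelinated": flux.inflow_myelinated,
        "inflow_unmyelinated": flux.inflow_unmyelinated,
        "inflow_total": flux.inflow_total,
        "inflow_mass_myelinated": flux.mass_rate_myelinated,
        "inflow_mass_unmyelinated": flux.mass_rate_unmyelinated,
        "inflow_mass_total": flux.mass_rate_inflow,
        "f_w_mass_rate": flux.mass_rate,
        "resident_water_mass": water_mass,
        "f_w_star": result.f_w_star,
        "d_perp_star": result.active.lambda2,
        "pct_change_d_perp": 100 * result.rel_change_d_perp,
        "d_app_star": result.d_app_star,
        "pct_change_d_app": 100 * result.rel_change_d_app,
        "pct_signal_drop": 100
        * relative_signal_drop(b, result.inactive.lambda2, result.active.lambda2),
        "fa_inactive": result.fa,
        "fa_active": result.fa_star,
        "pct_change_fa": 100 * result.rel_change_fa,
    }
    return values, result


def worked_example_report(
    bundle: AxonBundle,
    chans: ChannelBiophysics | None = None,
    params: ActivationParams | None = None,
    b: float = 600.0,
) -> list[ReportRow]:
    """Compute the full forward chain and pair it with the reference values."""
    chans = chans or ChannelBiophysics()
    params = params or ActivationParams()
    values, _ = _computed_chain(bundle, chans, params, b)
    return [
        ReportRow(key, unit, values[key], ref, tol)
        for key, unit, ref, tol in _REFERENCE
    ]


def reproduce(
    bundle: AxonBundle,
    chans: ChannelBiophysics | None = None,
    params: ActivationParams | None = None,
    b: float = 600.0,
) -> pd.DataFrame:
    """Worked-example report as a DataFrame with an agreement column."""
    rows = worked_example_report(bundle, chans, params, b)
    return pd.DataFrame(
        {
            "quantity": [r.quantity for r in rows],
            "unit": [r.unit for r in rows],
            "computed": [r.computed for r in rows],
            "reference": [r.reference for r in rows],
            "within_tolerance": [r.within_tolerance for r in rows],
        }
    )
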