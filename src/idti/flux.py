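"""Activity-associated trans-membrane water flow per sample volume.

Each open sodium channel passes a fixed ion flux, and each sodium ion drags a
fixed number of water molecules inward.  By mass balance the potassium-driven
outward water flow equals the inward one, so the total (bidirectional) water
flow is exactly twice the inward flow.  All rates are per millisecond, the
natural time base of channel kinetics; conversions happen at interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass

from .bundle import (
    AxonBundle,
    ChannelBiophysics,
    channel_count_myelinated,
    channel_count_unmyelinated,
)
from .errors import InvalidParameterError

__all__ = ["FluxResult", "inflow", "molecules_to_grams", "total_flux"]

WATER_MOLAR_MASS_G = 18.0
AVOGADRO = 6.022e23


def inflow(channel_total: float, chans: ChannelBiophysics) -> float:
    """One-directional water inflow (molecules/ms) through the given channels."""
    if channel_total < 0:
        raise InvalidParameterError(
            f"channel_total must be >= 0, got {channel_total!r}"
        )
    return channel_total * chans.ion_flux_per_channel * chans.waters_per_na


def molecules_to_grams(n_molecules: float) -> float:
    """Convert a water-molecule count to grams (18 g/mol)."""
    if n_molecules < 0:
        raise InvalidParameterError(
            f"n_molecules must be >= 0, got {n_molecules!r}"
        )
    return n_molecules * WATER_MOLAR_MASS_G / AVOGADRO


@dataclass(frozen=True)
class FluxResult:
    """Water-flow budget of an active bundle.

    ``inflow_*`` are one-directional molecule rates; ``f_w`` is the
    bidirectional total (exactly ``2 * inflow_total``); ``mass_rate`` is
    ``f_w`` expressed in g/ms.
    """

    inflow_myelinated: float
    inflow_unmyelinated: float

    @property
    def inflow_total(self) -> float:
        return self.inflow_myelinated + self.inflow_unmyelinated

    @property
    def f_w(self) -> float:
        """Bidirectional molecular water flow, molecules/ms."""
        return 2.0 * self.inflow_total

    @property
    def mass_rate_myelinated(self) -> float:
        return molecules_to_grams(self.inflow_myelinated)

    @property
    def mass_rate_unmyelinated(self) -> float:
        return molecules_to_grams(self.inflow_unmyelinated)

    @property
    def mass_rate_inflow(self) -> float:
        return molecules_to_grams(self.inflow_total)

    @property
    def mass_rate(self) -> float:
        """Bidirectional water mass flow, g/ms."""
        return molecules_to_grams(self.f_w)

    def report(self) -> dict[str, float]:
        """Flat key/value summary (units embedded in the key names)."""
        return {
            "inflow_myelinated_molecules_per_ms": self.inflow_myelinated,
            "inflow_unmyelinated_molecules_per_ms": self.inflow_unmyelinated,
            "inflow_total_molecules_per_ms": self.inflow_total,
            "f_w_molecules_per_ms": self.f_w,
            "mass_rate_myelinated_g_per_ms": self.mass_rate_myelinated,
            "mass_rate_unmyelinated_g_per_ms": self.mass_rate_unmyelinated,
            "mass_rate_inflow_g_per_ms": self.mass_rate_inflow,
            "f_w_mass_rate_g_per_ms": self.mass_rate,
        }


def total_flux(bundle: AxonBundle, chans: ChannelBiophysics) -> FluxResult:
    """Water-flow budget of a fully active bundle.

    Combines node-of-Ranvier channels (myelinated classes) and whole-membrane
    channels (unmyelinated classes); the factor 2 for the compensating
    outward flow lives in :attr:`FluxResult.f_w`.
    """
    n_myel = channel_count_myelinated(bundle, chans).total
    n_unmyel = channel_count_unmyelinated(bundle, chans).total
    return FluxResult(
        inflow_myelinated=inflow(n_myel, chans),
        inflow_unmyelinated=inflow(n_unmyel, chans),
    )
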