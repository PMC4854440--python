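"""Reduced-unit system for the four-to-one coarse-grained DPD model.

Internally everything runs in reduced units with bead diameter r0, bead
mass m0, and thermal energy kBT all equal to 1.  With four water molecules
per bead (``Nm = 4``) one length unit corresponds to about 0.71 nm and one
time unit to about 143 ps; conversions to physical units happen only at
I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant times 298 K, in joules.
KBT_298K_J = 1.380649e-23 * 298.0


@dataclass(frozen=True)
class Units:
    """Mapping between reduced DPD units and physical units.

    Parameters
    ----------
    r0_nm
        Physical length of one DPD length unit, in nanometres.
    tau_ps
        Physical duration of one DPD time unit, in picoseconds.
    kBT_ref
        Reference thermal energy in reduced units (1 by construction).
    Nm
        Number of water molecules represented by a single bead.
    """

    r0_nm: float = 0.71
    tau_ps: float = 143.0
    kBT_ref: float = 1.0
    Nm: int = 4

    def __post_init__(self) -> None:
        if self.r0_nm <= 0 or self.tau_ps <= 0:
            raise ValueError("r0_nm and tau_ps must be positive")
        if self.Nm < 1:
            raise ValueError("Nm must be >= 1")

    # -- conversion factors (reduced -> physical) -------------------------
    def _factor(self, kind: str) -> tuple[float, str]:
        if kind == "length":
            return self.r0_nm, "nm"
        if kind == "area":
            return self.r0_nm**2, "nm^2"
        if kind == "time":
            return self.tau_ps, "ps"
        if kind == "energy":
            return KBT_298K_J, "J"
        if kind == "tension":
            # kBT / r0^2 expressed in mN/m (= dyn/cm)
            return KBT_298K_J / (self.r0_nm * 1e-9) ** 2 * 1e3, "mN/m"
        raise ValueError(f"unknown quantity kind: {kind!r}")

    def to_physical(self, value: float, kind: str) -> float:
        """Convert a reduced-unit quantity to physical units.

        ``kind`` is one of ``length`` (nm), ``area`` (nm^2), ``time`` (ps),
        ``energy`` (J, at 298 K), ``tension`` (mN/m).
        """
        factor, _ = self._factor(kind)
        return value * factor

    def from_physical(self, value: float, kind: str) -> float:
        """Inverse of :meth:`to_physical`."""
        factor, _ = self._factor(kind)
        return value / factor

    def physical_unit(self, kind: str) -> str:
        """Name of the physical unit used for ``kind``."""
        return self._factor(kind)[1]


DEFAULT_UNITS = Units()


def to_physical(value: float, kind: str, units: Units = DEFAULT_UNITS) -> float:
    """Module-level convenience wrapper around :meth:`Units.to_physical`."""
    return units.to_physical(value, kind)


def from_physical(value: float, kind: str, units: Units = DEFAULT_UNITS) -> float:
    """Module-level convenience wrapper around :meth:`Units.from_physical`."""
    return units.from_physical(value, kind)
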