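"""Mobility <-> collision-cross-section conversion (Mason-Schamp, single field).

The reduced inverse mobility 1/K0 reported by trapped-ion-mobility
instruments maps to a rotationally averaged collision cross-section via

    CCS = convertor * z * (1/K0) * sqrt(1/(T*M)) * sqrt((M+m)/m)

with T the drift-gas temperature (K), M the analyte ion exact mass (Da),
m the buffer-gas mass (Da, N2), z the charge, K0 in cm^2 V^-1 s^-1 and CCS
in A^2.  The two square-root factors together are sqrt(1/(mu*T)) with mu
the ion-gas reduced mass, i.e. the standard low-field Mason-Schamp
dependence; the convertor collects all physical constants and unit
conversions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CCSParams", "mobility_to_ccs", "ccs_to_mobility"]

#: Single-field Mason-Schamp constant for K0 in cm^2/(V*s), masses in Da,
#: CCS in A^2.
MASON_SCHAMP_CONVERTOR = 18509.8632163405

#: Exact mass of N2 (Da).
N2_MASS = 28.0061480


@dataclass(frozen=True)
class CCSParams:
    convertor: float = MASON_SCHAMP_CONVERTOR
    temperature: float = 305.0  # K
    buffer_gas_mass: float = N2_MASS  # Da
    charge: int = 1

    def __post_init__(self) -> None:
        if min(self.convertor, self.temperature, self.buffer_gas_mass, self.charge) <= 0:
            raise ValueError("all CCSParams fields must be positive")


def _reduced_mass_factor(ion_mass: float, p: CCSParams):
    return np.sqrt(1.0 / (p.temperature * ion_mass)) * np.sqrt(
        (ion_mass + p.buffer_gas_mass) / p.buffer_gas_mass
    )


def mobility_to_ccs(inv_k0, mz, p: CCSParams = CCSParams()):
    """CCS (A^2) from reduced inverse mobility; linear in 1/K0.

    The analyte ion mass is taken as ``mz * z`` (singly charged: M = mz).
    """
    inv_k0 = np.asarray(inv_k0, dtype=float)
    ion_mass = np.asarray(mz, dtype=float) * p.charge
    out = p.convertor * p.charge * inv_k0 * _reduced_mass_factor(ion_mass, p)
    return float(out) if out.ndim == 0 else out


def ccs_to_mobility(ccs, mz, p: CCSParams = CCSParams()):
    """Inverse of :func:`mobility_to_ccs`: 1/K0 from CCS."""
    ccs = np.asarray(ccs, dtype=float)
    ion_mass = np.asarray(mz, dtype=float) * p.charge
    out = ccs / (p.convertor * p.charge * _reduced_mass_factor(ion_mass, p))
    return float(out) if out.ndim == 0 else out
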