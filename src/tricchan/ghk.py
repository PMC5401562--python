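"""Goldman–Hodgkin–Katz (GHK) constant-field flux and voltage relations.

The GHK flux equation gives the current carried by an ion species S of
valence z through a membrane of constant field, per unit permeability:

    I_S = P_S * z^2 * (F^2 V / RT) * ([S]_in - [S]_out * exp(-zFV/RT))
                                     / (1 - exp(-zFV/RT))

Here "in" is the cytoplasmic side and "out" the extracellular side.  For an
inside-out excised patch the bath faces the cytoplasmic side and the pipette
the extracellular side, so membrane potential is taken as

    V = V_bath(cytoplasmic) - V_pipette(extracellular)

and positive current corresponds to cation flow from bath to pipette.  With
this convention a channel that prefers K+ over Na+ under a K+(pipette) /
Na+(bath) bi-ionic condition reverses at a positive potential.

Permeabilities are relative (K+ == 1); an overall scale factor converts the
dimensionless flux sum into picoamperes for a nominal patch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "DEFAULT_TEMPERATURE",
    "DEFAULT_PERMEABILITY_SCALE",
    "IonConditions",
    "thermal_voltage_mV",
    "ghk_current",
    "ghk_reversal",
]

#: Faraday constant, C/mol.
FARADAY = 96485.332
#: Molar gas constant, J/(mol K).
GAS_CONSTANT = 8.31446
#: Default temperature, K (22.5 C, midpoint of a 21-24 C room-temperature
#: recording session); RT/F is then 25.48 mV.
DEFAULT_TEMPERATURE = 295.65
#: Default conversion from the dimensionless GHK flux sum (concentrations in
#: mM) to pA.  Chosen so that symmetric 210 mM K+ gives a slope conductance
#: of ~330 pS near 0 mV -- a patch holding two fully open trimers, the
#: configuration seen in multi-channel recordings.
DEFAULT_PERMEABILITY_SCALE = 0.04


def thermal_voltage_mV(temperature: float) -> float:
    """RT/F in millivolts at the given temperature (K)."""
    return 1000.0 * GAS_CONSTANT * temperature / FARADAY


@dataclass(frozen=True)
class IonConditions:
    """Ionic composition on both membrane sides plus relative permeabilities.

    Parameters
    ----------
    pipette_side, bath_side
        Lists of ``(species, valence, concentration_mM)``.  The pipette faces
        the extracellular side and the bath the cytoplasmic side (inside-out
        patch configuration).
    permeabilities
        Relative permeability per species, K+ fixed at 1.  Species absent
        from the map are impermeant.
    temperature
        Kelvin, within [273, 320].
    """

    pipette_side: tuple = ()
    bath_side: tuple = ()
    permeabilities: dict = field(default_factory=dict)
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        if not 273.0 <= self.temperature <= 320.0:
            raise ValueError(f"temperature {self.temperature} K outside [273, 320]")
        object.__setattr__(self, "pipette_side", tuple(tuple(x) for x in self.pipette_side))
        object.__setattr__(self, "bath_side", tuple(tuple(x) for x in self.bath_side))
        for side in (self.pipette_side, self.bath_side):
            for name, z, conc in side:
                if conc < 0:
                    raise ValueError(f"negative concentration for {name}: {conc}")
                if int(z) != z or z == 0:
                    raise ValueError(f"valence of {name} must be a nonzero integer")
        for name, p in self.permeabilities.items():
            if p < 0:
                raise ValueError(f"negative permeability for {name}")
        if self.permeabilities.get("K", 1.0) != 1.0:
            raise ValueError("K+ is the permeability reference and must be exactly 1")

    @property
    def rt_over_f_mV(self) -> float:
        return thermal_voltage_mV(self.temperature)

    def species(self) -> dict:
        """Merge both sides into {name: (z, conc_pipette_mM, conc_bath_mM)}."""
        out: dict = {}
        for name, z, conc in self.pipette_side:
            out[name] = [int(z), conc, 0.0]
        for name, z, conc in self.bath_side:
            if name in out:
                if out[name][0] != int(z):
                    raise ValueError(f"inconsistent valence for {name}")
                out[name][2] = conc
            else:
                out[name] = [int(z), 0.0, conc]
        return {k: tuple(v) for k, v in out.items()}

    def permeability(self, name: str) -> float:
        return float(self.permeabilities.get(name, 0.0))


def bi_ionic_k_na(
    k_pipette_mM: float = 210.0,
    na_bath_mM: float = 210.0,
    p_na: float = 1.0,
    temperature: float = DEFAULT_TEMPERATURE,
) -> IonConditions:
    """Convenience constructor for the K+(pipette)/Na+(bath) bi-ionic setup."""
    return IonConditions(
        pipette_side=(("K", 1, k_pipette_mM), ("Cl", -1, k_pipette_mM)),
        bath_side=(("Na", 1, na_bath_mM), ("Cl", -1, na_bath_mM)),
        permeabilities={"K": 1.0, "Na": p_na},
        temperature=temperature,
    )


def symmetric_k(
    k_mM: float = 210.0,
    temperature: float = DEFAULT_TEMPERATURE,
    bath_extra: tuple = (),
    extra_permeabilities: dict | None = None,
) -> IonConditions:
    """Symmetric KCl on both sides; optional extra bath species (e.g. CaCl2)."""
    perms = {"K": 1.0}
    if extra_permeabilities:
        perms.update(extra_permeabilities)
    return IonConditions(
        pipette_side=(("K", 1, k_mM), ("Cl", -1, k_mM)),
        bath_side=(("K", 1, k_mM), ("Cl", -1, k_mM)) + tuple(bath_extra),
        permeabilities=perms,
        temperature=temperature,
    )


def _flux_sum(V_mV, conditions: IonConditions):
    """Dimensionless GHK flux summed over species (concentrations in mM)."""
    V = np.asarray(V_mV, dtype=float)
    u = V / conditions.rt_over_f_mV  # FV/RT
    total = np.zeros_like(u)
    any_permeant = False
    for name, (z, c_out, c_in) in conditions.species().items():
        p = conditions.permeability(name)
        if p == 0.0:
            continue
        any_permeant = True
        zu = z * u
        small = np.abs(zu) < 1e-6
        with np.errstate(over="ignore", invalid="ignore"):
            e = np.exp(-zu)
            full = z * z * u * (c_in - c_out * e) / (1.0 - e)
        # analytic continuation through the removable singularity at zu = 0
        series = z * (c_in - c_out) + z * z * u * (c_in + c_out) / 2.0
        total = total + p * np.where(small, series, full)
    if not any_permeant:
        raise ValueError("no permeant ion: all permeabilities are zero")
    return total


def ghk_current(
    V_mV,
    conditions: IonConditions,
    p_scale: float = DEFAULT_PERMEABILITY_SCALE,
) -> np.ndarray | float:
    """GHK current (pA) at membrane potential ``V_mV`` (scalar or array).

    ``p_scale`` sets the absolute permeability of the reference ion (pA per
    mM of dimensionless flux); relative permeabilities come from
    ``conditions``.  The removable singularity at V = 0 (and at zFV/RT = 0
    for each ion) is handled by its series limit, so the result is finite
    everywhere.
    """
    out = p_scale * _flux_sum(V_mV, conditions)
    return float(out) if np.isscalar(V_mV) else out


def ghk_reversal(conditions: IonConditions, bracket_mV: float = 500.0) -> float:
    """Zero-current (reversal) potential of the GHK current, in mV.

    Found by root bracketing of the flux sum; Cl- and any other species carry
    their own valence so anions enter with the correct sign, and impermeant
    species (permeability 0, e.g. divalents in this release) drop out.
    """
    f = lambda v: _flux_sum(v, conditions)
    lo, hi = -bracket_mV, bracket_mV
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return float(lo)
    if fhi == 0.0:
        return float(hi)
    if np.sign(flo) == np.sign(fhi):
        raise ValueError("GHK current does not reverse within the bracket")
    return float(brentq(f, lo, hi, xtol=1e-12))
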