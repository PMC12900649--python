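"""Energy model for the bead-spring nucleus simulation.

All energies are in units of kT and all lengths in units of the bead
diameter sigma.  The force field combines

* harmonic backbone bonds ``U = k/2 (r - r0)^2``;
* a purely repulsive Weeks-Chandler-Andersen core between all bead pairs;
* a short-range attractive well of depth ``E_AA`` (A-A pairs) or ``E_BB``
  (B-B pairs), acting within and across chains, truncated and shifted at
  ``attraction_cutoff``;
* a discrete bending energy ``K_theta(i) * (1 + cos theta_i)`` at every
  interior bead, with the modulus chosen by the bead's domain class;
* a hard reflecting confinement sphere.

Bending moduli for A and B domains are expressed as multiples of the
baseline modulus ``K_theta_base`` (the untreated-chromatin stiffness unit);
telomeric beads always use the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class EnergyModel:
    """Force-field parameters (energies in kT, lengths in sigma)."""

    E_AA: float = 0.8
    E_BB: float = 0.7
    K_theta_A: float = 1.0
    K_theta_B: float = 1.0
    K_theta_base: float = 1.0
    sigma: float = 1.0
    r_contact: float = 2.5
    bond_k: float = 100.0
    bond_r0: float = 1.0
    ev_epsilon: float = 1.0
    attraction_cutoff: float = 2.5

    def __post_init__(self) -> None:
        if self.E_AA < 0 or self.E_BB < 0:
            raise ValueError("attraction well depths must be >= 0")
        if min(self.K_theta_A, self.K_theta_B, self.K_theta_base) < 0:
            raise ValueError("bending moduli must be >= 0")
        if self.r_contact <= self.sigma:
            raise ValueError("r_contact must exceed the bead diameter sigma")

    @property
    def stiffness_ratio(self) -> float:
        return self.K_theta_A / self.K_theta_B

    def with_stiffness(self, K_A: float, K_B: float) -> "EnergyModel":
        return replace(self, K_theta_A=K_A, K_theta_B=K_B)

    def with_attraction(self, E_AA: float, E_BB: float) -> "EnergyModel":
        return replace(self, E_AA=E_AA, E_BB=E_BB)


# Untreated (vehicle) preset: uniform baseline stiffness; attraction energies
# are normally obtained from fit_attraction against a target compartment
# strength, the defaults here are a moderate A>B well-depth pair.
DMSO_PRESET = EnergyModel(K_theta_A=1.0, K_theta_B=1.0)

# HDAC-inhibited (TSA) preset: same attraction energies, stiffness raised
# 18x in A domains and 3x in B domains (ratio 6).
TSA_PRESET = EnergyModel(K_theta_A=18.0, K_theta_B=3.0)


def preset(name: str) -> EnergyModel:
    table = {"dmso": DMSO_PRESET, "tsa": TSA_PRESET}
    try:
        return table[name.lower()]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; expected 'dmso' or 'tsa'") from None
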