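"""Physical constants and unit conversions used throughout the package.

All internal computations use SI-derived units: correlation times in ns,
rates in s^-1, angular frequencies in rad/s. Conversions are centralized
here so that no module hard-codes a factor.
"""

from __future__ import annotations

from dataclasses import dataclass

# CODATA values
GAMMA_H = 2.6752218744e8  # 1H gyromagnetic ratio, rad s^-1 T^-1
GAMMA_N = -2.7126e7       # 15N gyromagnetic ratio, rad s^-1 T^-1 (negative)
HBAR = 1.054571817e-34    # J s
MU_0 = 4.0e-7 * 3.141592653589793  # N A^-2 (conventional exact value)
K_B = 1.380649e-23        # J K^-1
N_A = 6.02214076e23       # mol^-1
CAL_TO_J = 4.184

# k_B * T at 303.15 K (30 degrees C) expressed in kcal/mol; the reference
# temperature used for the entropy/affinity estimates.
T_30C = 303.15  # K


def kbt_kcal_per_mol(temperature_k: float) -> float:
    """k_B*T in kcal/mol at the given temperature."""
    return K_B * temperature_k * N_A / (CAL_TO_J * 1000.0)


def kcal_per_mol_to_kbt(value_kcal: float, temperature_k: float) -> float:
    return value_kcal / kbt_kcal_per_mol(temperature_k)


def kbt_to_kcal_per_mol(value_kbt: float, temperature_k: float) -> float:
    return value_kbt * kbt_kcal_per_mol(temperature_k)


@dataclass(frozen=True)
class NuclearConstants:
    """Interaction constants for the backbone amide 15N-1H spin pair.

    Defaults follow the historical Modelfree/FastModelFree conventions:
    an effective N-H bond length of 1.02 A and a 15N chemical shift
    anisotropy of -160 ppm. Both are configurable; order parameters
    scale roughly with r_NH^6 and CSA^2, so alternative conventions
    shift S^2 by a few percent (documented in the methods note).
    """

    r_nh_angstrom: float = 1.02
    csa_ppm: float = -160.0
    gamma_h: float = GAMMA_H
    gamma_n: float = GAMMA_N

    def __post_init__(self) -> None:
        if self.r_nh_angstrom <= 0:
            raise ValueError(f"r_NH must be positive, got {self.r_nh_angstrom}")

    @property
    def dipolar_d2(self) -> float:
        """Squared dipolar interaction constant d^2/4 term, (rad/s)^2.

        d = (mu0/4pi) * hbar * gamma_H * gamma_N / r_NH^3; the relaxation
        equations use d^2/4.
        """
        r = self.r_nh_angstrom * 1e-10
        d = MU_0 / (4.0 * 3.141592653589793) * HBAR * self.gamma_h * self.gamma_n / r**3
        return d * d / 4.0

    def csa_c2(self, omega_n: float) -> float:
        """Squared CSA interaction constant c^2 = (delta_sigma*omega_N)^2/3."""
        return (self.csa_ppm * 1e-6 * omega_n) ** 2 / 3.0


DEFAULT_CONSTANTS = NuclearConstants()
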