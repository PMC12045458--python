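"""Assembly of the 6x6 mass, damping and stiffness matrices.

Node order (fixed): X0 skull, X1 ear-canal air, X2 tympanic membrane,
X3 umbo (malleus tip), X4 incus tip, X5 stapes + cochlear fluid.  All
displacements are horizontal in a common positive direction; the malleus
and incus pendulum rotations are linearized via th3 = (X3 - X0)/L3 and
th4 = (X4 - X0)/L4, which converts the two torque balances into force
balances on the tip coordinates with effective masses I/L^2 and effective
stiffnesses K_t/L^2 (suspensions) and K_t/(L3*L4) (the joint coupling the
two pendulums).

The skull row keeps only its inertia (M0*X0'' = F0): the skull is so much
heavier than everything hanging from it that the reaction forces of the
suspensions are negligible, so rows X1..X5 feel X0 but not vice versa.
Consequently the 5x5 block over X1..X5 of [C] and [K] is symmetric while
column X0 is not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .parameters import ParameterSet

NODE_ORDER = ("X0", "X1", "X2", "X3", "X4", "X5")

#: Index aliases for the physically named nodes.
SKULL, CANAL, TM, UMBO, INCUS, STAPES = range(6)


@dataclass(frozen=True)
class SystemMatrices:
    """Dense 6x6 real matrices of the harmonic system (-w^2 M + iwC + K)X = F."""

    M: np.ndarray
    C: np.ndarray
    K: np.ndarray
    node_order: tuple[str, ...] = NODE_ORDER

    def impedance(self, f_hz: float) -> np.ndarray:
        """Dynamic stiffness matrix -w^2 M + i w C + K at frequency f_hz."""
        w = 2.0 * math.pi * f_hz
        return -w * w * self.M + 1j * w * self.C + self.K

    def to_csv(self, directory: str | Path, prefix: str = "") -> list[Path]:
        """Write M, C, K to ``<prefix>M.csv`` etc. with node-name headers."""
        import pandas as pd

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for label, mat in (("M", self.M), ("C", self.C), ("K", self.K)):
            p = directory / f"{prefix}{label}.csv"
            pd.DataFrame(mat, index=self.node_order, columns=self.node_order).to_csv(
                p, float_format="%.17g"
            )
            paths.append(p)
        return paths


def _fill_coupling(
    A: np.ndarray,
    L3: float,
    L4: float,
    K1: float, K2: float, K3: float,
    Km: float, Kmi: float, Ki: float,
    K6: float, K8: float, K9: float,
) -> None:
    """Fill rows X1..X5 of a stiffness or damping matrix.

    The two matrices share one topology; only the element values differ,
    so the same routine writes both (K symbols used for readability).
    """

    A[CANAL, CANAL] = K2
    A[CANAL, TM] = -K2

    A[TM, SKULL] = -K1
    A[TM, CANAL] = -K2
    A[TM, TM] = K1 + K2 + K3
    A[TM, UMBO] = -K3

    A[UMBO, SKULL] = Kmi / (L3 * L4) - (Km + Kmi) / L3**2
    A[UMBO, TM] = -K3
    A[UMBO, UMBO] = K3 + (Km + Kmi) / L3**2
    A[UMBO, INCUS] = -Kmi / (L3 * L4)

    A[INCUS, SKULL] = Kmi / (L3 * L4) - (Ki + Kmi) / L4**2
    A[INCUS, UMBO] = -Kmi / (L3 * L4)
    A[INCUS, INCUS] = K6 + (Ki + Kmi) / L4**2
    A[INCUS, STAPES] = -K6

    A[STAPES, SKULL] = -(K8 + K9)
    A[STAPES, INCUS] = -K6
    A[STAPES, STAPES] = K6 + K8 + K9


def assemble_matrices(params: ParameterSet) -> SystemMatrices:
    """Build the system matrices for a parameter set.

    Row contracts (stiffness shown; damping rows are identical with C
    symbols; unlisted entries are zero):

    * X0: ``M[0,0] = M0``; the C and K rows are zero (skull simplification).
    * X1: ``M1``; ``K2, -K2`` against the TM.
    * X2: ``M2``; ``-K1`` (skull), ``-K2`` (canal), ``K1+K2+K3``, ``-K3`` (umbo).
    * X3: effective mass ``I3/L3^2`` (with ``-I3/L3^2`` on X0);
      ``Kmi_t/(L3 L4) - (Km_t+Kmi_t)/L3^2`` on X0, ``-K3`` on X2,
      ``K3 + (Km_t+Kmi_t)/L3^2`` diagonal, ``-Kmi_t/(L3 L4)`` on X4.
    * X4: mirror of X3 with L4, Ki_t and the joint K6 to the stapes.
    * X5: mass ``M5+M6``; ``-(K8+K9)`` on X0, ``-K6`` on X4,
      ``K6+K8+K9`` diagonal.
    """
    vals = [getattr(params, f) for f in (
        "M0", "M1", "M2", "M5", "M6", "I3", "I4", "L3", "L4")]
    if not all(np.isfinite(vals)):
        raise ValueError(f"non-finite parameter in set {params.name!r}")

    M = np.zeros((6, 6))
    C = np.zeros((6, 6))
    K = np.zeros((6, 6))

    M[SKULL, SKULL] = params.M0
    M[CANAL, CANAL] = params.M1
    M[TM, TM] = params.M2
    M[UMBO, SKULL] = -params.I3 / params.L3**2
    M[UMBO, UMBO] = params.I3 / params.L3**2
    M[INCUS, SKULL] = -params.I4 / params.L4**2
    M[INCUS, INCUS] = params.I4 / params.L4**2
    M[STAPES, STAPES] = params.M5 + params.M6

    p = params
    _fill_coupling(K, p.L3, p.L4, p.K1, p.K2, p.K3,
                   p.Km_t, p.Kmi_t, p.Ki_t, p.K6, p.K8, p.K9)
    _fill_coupling(C, p.L3, p.L4, p.C1, p.C2, p.C3,
                   p.Cm_t, p.Cmi_t, p.Ci_t, p.C6, p.C8, p.C9)

    for mat in (M, C, K):
        if not np.all(np.isfinite(mat)):
            raise ValueError(f"assembled matrix is non-finite for set {params.name!r}")
    return SystemMatrices(M=M, C=C, K=K)
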