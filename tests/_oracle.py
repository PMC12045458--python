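"""Independent transcription of the six governing equations.

This oracle never touches the assembly code: each force/torque balance is
coded directly from the physics (springs and dashpots acting on pairwise
displacement differences; torque balances on the pendulum angles
th3 = (X3-X0)/L3, th4 = (X4-X0)/L4, divided through by the lever arm).
Under harmonic motion X e^{iwt}, d/dt -> iw and d2/dt2 -> -w^2.

``dynamic_force(params, omega, X)`` returns the 6-vector of generalized
forces that must equal [F0..F5]; it is the reference against which the
assembled matrix product (-w^2 M + iw C + K) X is checked row by row.
"""

from __future__ import annotations

import numpy as np


def dynamic_force(p, omega: float, X: np.ndarray) -> np.ndarray:
    iw = 1j * omega
    w2 = omega * omega
    X0, X1, X2, X3, X4, X5 = X

    def element(k, c, xa, xb):
        """Force exerted on a by the element between a and b."""
        return k * (xb - xa) + iw * c * (xb - xa)

    th3 = (X3 - X0) / p.L3
    th4 = (X4 - X0) / p.L4

    r = np.empty(6, dtype=complex)
    # skull: only its inertia survives the simplification
    r[0] = -w2 * p.M0 * X0
    # ear-canal air column
    r[1] = -w2 * p.M1 * X1 - element(p.K2, p.C2, X1, X2)
    # tympanic membrane
    r[2] = (
        -w2 * p.M2 * X2
        - element(p.K1, p.C1, X2, X0)
        - element(p.K2, p.C2, X2, X1)
        - element(p.K3, p.C3, X2, X3)
    )
    # malleus torque balance, divided by L3
    torque3 = (
        p.Kmi_t * (th4 - th3) + iw * p.Cmi_t * (th4 - th3)
        - p.Km_t * th3 - iw * p.Cm_t * th3
    )
    r[3] = (-w2 * p.I3 * th3 - torque3) / p.L3 - element(p.K3, p.C3, X3, X2)
    # incus torque balance, divided by L4
    torque4 = (
        p.Kmi_t * (th3 - th4) + iw * p.Cmi_t * (th3 - th4)
        - p.Ki_t * th4 - iw * p.Ci_t * th4
    )
    r[4] = (-w2 * p.I4 * th4 - torque4) / p.L4 - element(p.K6, p.C6, X4, X5)
    # stapes + cochlear fluid
    r[5] = (
        -w2 * (p.M5 + p.M6) * X5
        - element(p.K6, p.C6, X5, X4)
        - element(p.K8, p.C8, X5, X0)
        - element(p.K9, p.C9, X5, X0)
    )
    return r


def solve_by_oracle(p, omega: float, F: np.ndarray) -> np.ndarray:
    """Brute-force solve using only the oracle equations.

    The linear operator is probed column by column with unit displacement
    vectors, then inverted; nothing is shared with the assembly path.
    """
    A = np.empty((6, 6), dtype=complex)
    for j in range(6):
        e = np.zeros(6)
        e[j] = 1.0
        A[:, j] = dynamic_force(p, omega, e)
    return np.linalg.solve(A, np.asarray(F, dtype=complex))


def random_parameter_set(rng: np.random.Generator):
    """A physically plausible random ParameterSet for property tests."""
    from lumpedear import get_builtin

    base = get_builtin("fitted")
    changes = {}
    for f in (
        "M0", "M1", "M2", "M5", "M6", "I3", "I4", "L3", "L4",
        "K1", "C1", "K2", "C2", "K3", "C3",
        "Km_t", "Cm_t", "Kmi_t", "Cmi_t", "Ki_t", "Ci_t",
        "K6", "C6", "K8", "C8", "K9", "C9",
    ):
        scale = float(rng.uniform(0.2, 5.0))
        changes[f] = getattr(base, f) * scale
    return base.replace(name="random", **changes)
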