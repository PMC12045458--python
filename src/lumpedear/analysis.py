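"""Transfer functions, resonance extraction, and the condition matrix.

The quantities of interest are complex velocity ratios versus frequency:

* ``relative`` — (V_node - V_prom) / V_prom, the node's motion relative to
  the skull/promontory, the form in which bone-conduction middle-ear
  measurements are reported;
* ``absolute`` — V_node / V_prom (equal to relative + 1 pointwise);
* ``ac`` — V_node / P_ec, node velocity per unit ear-canal sound pressure,
  the conventional air-conduction transfer function.

Resonances are local maxima of the dB magnitude curve (prominence
>= 0.5 dB) with 3-point quadratic refinement of the peak frequency;
crossovers between two curves are sign changes of their dB difference,
located by linear interpolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .assembly import NODE_ORDER, SKULL, assemble_matrices
from .parameters import (
    DEFAULT_STAPES_MASS,
    ParameterSet,
    apply_chain,
    condition,
)
from .solver import FrequencyResponse, Stimulus, default_grid, solve_response

#: dB floor substituted for exact zeros of the ratio magnitude.
DB_FLOOR = -300.0

#: Minimum prominence [dB] for a local extremum to count as a peak/dip.
#: Low enough to catch the shallow resonance of a mass-loaded stapes,
#: high enough to ignore grid-level ripple.
DEFAULT_PROMINENCE_DB = 0.5

#: Crossovers below this frequency [Hz] are ignored by
#: :func:`first_crossover`: at the very bottom of the band both curves sit
#: near the rigid-body floor and their difference can flip sign spuriously.
CROSSOVER_FMIN = 200.0

TF_KINDS = ("relative", "absolute", "ac")


@dataclass(frozen=True)
class TransferFunction:
    """A complex velocity-ratio curve with its dB magnitude and phase."""

    frequencies: np.ndarray
    ratio: np.ndarray
    kind: str
    node: str
    condition: str = "normal"

    @property
    def magnitude_db(self) -> np.ndarray:
        mag = np.abs(self.ratio)
        with np.errstate(divide="ignore"):
            db = 20.0 * np.log10(mag)
        return np.where(mag > 0, db, DB_FLOOR)

    @property
    def phase_cycles(self) -> np.ndarray:
        """Phase unwrapped along increasing frequency, in cycles."""
        return np.unwrap(np.angle(self.ratio)) / (2.0 * np.pi)


@dataclass(frozen=True)
class ResonanceReport:
    """Local extrema of a transfer magnitude curve (sorted by frequency)."""

    peaks: tuple[tuple[float, float], ...]   # (frequency Hz, magnitude dB)
    dips: tuple[tuple[float, float], ...]
    condition: str = "normal"
    node: str = ""

    def to_json_dict(self, crossovers_vs_normal: Sequence[float] = ()) -> dict:
        return {
            "condition": self.condition,
            "node": self.node,
            "peaks": [{"f_hz": f, "mag_db": m} for f, m in self.peaks],
            "dips": [{"f_hz": f, "mag_db": m} for f, m in self.dips],
            "crossovers_vs_normal": list(crossovers_vs_normal),
        }


def transfer(
    resp: FrequencyResponse,
    node: str,
    kind: str = "relative",
    *,
    condition_name: str = "normal",
    any_node: bool = False,
) -> TransferFunction:
    """Compute a transfer function from a solved frequency response.

    ``node`` is normally the umbo (X3) or stapes (X5); other nodes require
    ``any_node=True``.  ``kind="ac"`` divides the node velocity by the
    ear-canal pressure and requires an AC stimulus.
    """
    if kind not in TF_KINDS:
        raise ValueError(f"kind must be one of {TF_KINDS}, got {kind!r}")
    if node not in NODE_ORDER:
        raise ValueError(f"node must be one of {NODE_ORDER}, got {node!r}")
    if node not in ("X3", "X5") and not any_node:
        raise ValueError(
            f"node {node!r} is not a conventional measurement point (X3 umbo, "
            "X5 stapes); pass any_node=True to compute it anyway"
        )
    Vn = resp.V[:, resp.node(node)]
    if kind == "ac":
        if resp.stimulus.mode != "AC":
            raise ValueError("kind='ac' requires a response driven by an AC stimulus")
        ratio = Vn / resp.stimulus.amplitude
    else:
        V0 = resp.V[:, SKULL]
        if np.any(V0 == 0):
            raise ValueError(
                "skull velocity is zero at some frequency; a relative transfer "
                "function is undefined (did you drive a node other than the skull?)"
            )
        # absolute is formed as relative + 1 so the pointwise identity
        # between the two kinds holds exactly in floating point
        ratio = (Vn - V0) / V0
        if kind == "absolute":
            ratio = ratio + 1.0
    return TransferFunction(
        frequencies=np.asarray(resp.frequencies, dtype=float),
        ratio=ratio,
        kind=kind,
        node=node,
        condition=condition_name,
    )


def _refine(f: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Quadratic refinement of extremum i through its three neighbours.

    Fit is done in log-frequency, matching the grid's spacing.
    """
    if i == 0 or i == len(f) - 1:
        return float(f[i]), float(y[i])
    x = np.log(f[i - 1:i + 2])
    v = y[i - 1:i + 2]
    denom = v[0] - 2.0 * v[1] + v[2]
    if denom == 0:
        return float(f[i]), float(y[i])
    delta = 0.5 * (v[0] - v[2]) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    x_pk = x[1] + delta * (x[2] - x[1] if delta > 0 else x[1] - x[0])
    y_pk = v[1] - 0.25 * (v[0] - v[2]) * delta
    return float(np.exp(x_pk)), float(y_pk)


def find_resonances(
    tf: TransferFunction, prominence_db: float = DEFAULT_PROMINENCE_DB
) -> ResonanceReport:
    """Locate resonance peaks and dips of a transfer magnitude curve."""
    mag = tf.magnitude_db
    if mag.size < 16:
        raise ValueError("resonance extraction needs a grid of at least 16 points")
    f = tf.frequencies
    pk_idx, _ = find_peaks(mag, prominence=prominence_db)
    dip_idx, _ = find_peaks(-mag, prominence=prominence_db)
    peaks = tuple(_refine(f, mag, i) for i in pk_idx)
    dips = tuple((fd, -md) for fd, md in (_refine(f, -mag, i) for i in dip_idx))
    return ResonanceReport(
        peaks=peaks, dips=dips, condition=tf.condition, node=tf.node
    )


def crossover(tf_a: TransferFunction, tf_b: TransferFunction) -> list[float]:
    """Frequencies where the dB magnitudes of two curves cross.

    Sign changes of ``mag_a - mag_b`` are located by linear interpolation
    in log-frequency between the bracketing samples; ascending order.
    """
    if tf_a.frequencies.shape != tf_b.frequencies.shape or not np.allclose(
        tf_a.frequencies, tf_b.frequencies
    ):
        raise ValueError("crossover requires identical frequency grids")
    f = tf_a.frequencies
    d = tf_a.magnitude_db - tf_b.magnitude_db
    out: list[float] = []
    prev: int | None = None  # last sample with a nonzero difference
    for i in range(len(f)):
        if d[i] == 0.0:
            continue
        if prev is not None and d[prev] * d[i] < 0:
            t = d[prev] / (d[prev] - d[i])
            lf = np.log(f[prev]) + t * (np.log(f[i]) - np.log(f[prev]))
            out.append(float(np.exp(lf)))
        prev = i
    return out


def first_crossover(
    tf_a: TransferFunction, tf_b: TransferFunction, fmin: float = CROSSOVER_FMIN
) -> float | None:
    """First crossover above ``fmin`` (None if the curves never cross)."""
    for fx in crossover(tf_a, tf_b):
        if fx > fmin:
            return fx
    return None


# ---------------------------------------------------------------------------
# The full measurement/condition matrix
# ---------------------------------------------------------------------------

#: (measured node, condition chain) pairs of the published protocol:
#: five umbo curves and seven stapes curves, the stapes-mass and
#: drained-cochlea manipulations performed after the joint cut.
CONDITION_MATRIX: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("X3", ("normal",)),
    ("X3", ("stapes_glued",)),
    ("X3", ("malleus_glued",)),
    ("X3", ("mass_100mg_umbo",)),
    ("X3", ("is_joint_cut",)),
    ("X5", ("normal",)),
    ("X5", ("stapes_glued",)),
    ("X5", ("malleus_glued",)),
    ("X5", ("mass_100mg_umbo",)),
    ("X5", ("is_joint_cut",)),
    ("X5", ("is_joint_cut", "mass_on_stapes")),
    ("X5", ("is_joint_cut", "cochlea_drained")),
)


@dataclass(frozen=True)
class ConditionResult:
    """One row of the condition matrix: both TF kinds plus resonances."""

    node: str
    chain: tuple[str, ...]
    relative: TransferFunction
    absolute: TransferFunction
    resonances: ResonanceReport

    @property
    def label(self) -> str:
        return "+".join(self.chain)


def run_condition_matrix(
    base: ParameterSet,
    frequencies: np.ndarray | None = None,
    *,
    stimulus: Stimulus | None = None,
    stapes_mass: float = DEFAULT_STAPES_MASS,
    isjc_variant: str = "k8",
    prominence_db: float = DEFAULT_PROMINENCE_DB,
) -> list[ConditionResult]:
    """Simulate the full 12-curve protocol under bone conduction.

    Returns one :class:`ConditionResult` per (node, condition) pair of
    :data:`CONDITION_MATRIX`, each holding the relative and absolute
    transfer functions and their resonance report.
    """
    if frequencies is None:
        frequencies = default_grid()
    if stimulus is None:
        stimulus = Stimulus(mode="BC", amplitude=1.0)
    results = []
    for node, chain in CONDITION_MATRIX:
        specs = [
            condition(c, stapes_mass=stapes_mass, isjc_variant=isjc_variant)
            for c in chain
        ]
        p = apply_chain(base, specs)
        resp = solve_response(assemble_matrices(p), stimulus, frequencies, p)
        label = "+".join(chain)
        rel = transfer(resp, node, "relative", condition_name=label)
        ab = transfer(resp, node, "absolute", condition_name=label)
        results.append(
            ConditionResult(
                node=node,
                chain=chain,
                relative=rel,
                absolute=ab,
                resonances=find_resonances(rel, prominence_db),
            )
        )
    return results


def condition_matrix_frame(results: Sequence[ConditionResult]):
    """Long-format DataFrame of the condition matrix (both TF kinds)."""
    import pandas as pd

    rows = []
    for r in results:
        for tf in (r.relative, r.absolute):
            rows.append(
                pd.DataFrame(
                    {
                        "condition": r.label,
                        "node": r.node,
                        "kind": tf.kind,
                        "frequency_Hz": tf.frequencies,
                        "magnitude_db": tf.magnitude_db,
                        "phase_cycles": tf.phase_cycles,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def resonances_to_json(
    results: Sequence[ConditionResult], path: str | Path | None = None
) -> list[dict]:
    """Resonance reports (with crossovers vs the same-node normal curve)."""
    normals = {r.node: r.relative for r in results if r.chain == ("normal",)}
    out = []
    for r in results:
        xs = crossover(r.relative, normals[r.node]) if r.chain != ("normal",) else []
        out.append(r.resonances.to_json_dict([x for x in xs if x > CROSSOVER_FMIN]))
    if path is not None:
        Path(path).write_text(json.dumps(out, indent=2))
    return out


def parameter_ratio_report(
    fitted: ParameterSet, reference: ParameterSet
):
    """Per-field ratio fitted/reference as a DataFrame.

    Fields whose reference value is zero get a NaN ratio and the note
    ``undefined ratio`` instead of an error.
    """
    import pandas as pd

    import dataclasses as _dc

    rows = []
    for f in _dc.fields(ParameterSet):
        if f.name == "name":
            continue
        fv = getattr(fitted, f.name)
        rv = getattr(reference, f.name)
        if rv == 0:
            rows.append((f.name, fv, rv, np.nan, "undefined ratio"))
        else:
            rows.append((f.name, fv, rv, fv / rv, ""))
    return pd.DataFrame(
        rows, columns=["field", "fitted", "reference", "ratio", "note"]
    ).set_index("field")
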