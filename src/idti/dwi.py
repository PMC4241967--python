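"""Stejskal-Tanner diffusion-weighted signal model and tensor estimation.

Covers the b-value of a pulsed-gradient spin echo, mono-exponential echo
attenuation, the activation-induced signal drop and its SNR-based
detectability, plus the measurement model used by the phantom: synthesis of
multi-direction signals from a tensor and the standard log-linear
least-squares tensor fit.

Unit conventions follow the field: b-values in s/mm^2 at every interface,
diffusivities in SI m^2/s (converted internally), gradient tables in the
two-file bval/bvec layout or a single four-column table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DegenerateSchemeError, InvalidParameterError
from .tensor import TensorState

__all__ = [
    "GAMMA_PROTON",
    "SequenceParams",
    "GradientScheme",
    "b_value",
    "echo_attenuation",
    "relative_signal_drop",
    "detectable",
    "uniform_directions",
    "default_scheme",
    "tensor_from_state",
    "synthesize_signal",
    "fit_tensor",
]

GAMMA_PROTON = 2.6752218744e8  # 1H gyromagnetic ratio, rad s^-1 T^-1

_MM2_PER_M2 = 1e6


@dataclass(frozen=True)
class SequenceParams:
    """Pulsed-gradient spin-echo timing and amplitude.

    Either give ``b`` (s/mm^2) directly, or the quartet (gamma, g, delta,
    Delta) from which the b-value follows as (gamma*g*delta)^2 (Delta -
    delta/3).  Times are in ms, gradient amplitude in T/m.
    """

    gamma: float = GAMMA_PROTON
    g_amplitude: float | None = None
    delta_ms: float | None = None
    Delta_ms: float | None = None
    b: float | None = None

    def __post_init__(self) -> None:
        if self.b is not None and self.b < 0:
            raise InvalidParameterError(f"b must be >= 0, got {self.b!r}")
        if self.delta_ms is not None and self.Delta_ms is not None:
            if self.delta_ms < 0:
                raise InvalidParameterError("delta_ms must be >= 0")
            if self.Delta_ms < self.delta_ms:
                raise InvalidParameterError(
                    "Delta_ms must be >= delta_ms (pulses cannot overlap)"
                )


def b_value(seq: SequenceParams) -> float:
    """Diffusion weighting in s/mm^2.

    Returns ``seq.b`` when set; otherwise evaluates
    (gamma*g*delta)^2 (Delta - delta/3) in SI and converts s/m^2 -> s/mm^2.
    """
    if seq.b is not None:
        return seq.b
    if seq.g_amplitude is None or seq.delta_ms is None or seq.Delta_ms is None:
        raise InvalidParameterError(
            "either b or all of g_amplitude, delta_ms, Delta_ms must be set"
        )
    delta_s = seq.delta_ms * 1e-3
    Delta_s = seq.Delta_ms * 1e-3
    b_si = (seq.gamma * seq.g_amplitude * delta_s) ** 2 * (Delta_s - delta_s / 3.0)
    return b_si / _MM2_PER_M2


def echo_attenuation(a0: float, b: float, d: float) -> float:
    """Echo amplitude A0 * exp(-b D); b in s/mm^2, D in m^2/s."""
    if a0 < 0:
        raise InvalidParameterError(f"a0 must be >= 0, got {a0!r}")
    if b < 0:
        raise InvalidParameterError(f"b must be >= 0, got {b!r}")
    if d < 0:
        raise InvalidParameterError(f"d must be >= 0, got {d!r}")
    return a0 * math.exp(-b * d * _MM2_PER_M2)


def relative_signal_drop(b: float, d_inactive: float, d_active: float) -> float:
    """Fractional echo-amplitude drop caused by a diffusivity increase.

    1 - exp(-b (D_active - D_inactive)); positive when diffusivity rises.
    """
    return 1.0 - math.exp(-b * (d_active - d_inactive) * _MM2_PER_M2)


def detectable(drop: float, snr: float, z: float = 3.0) -> tuple[bool, float]:
    """Whether a fractional signal drop clears the noise floor.

    The single-measurement detection limit is taken as z/SNR (z standard
    deviations of the normalized noise, default z=3).  Returns the verdict
    and the margin ``drop - z/snr``.
    """
    if not snr > 0:
        raise InvalidParameterError(f"snr must be > 0, got {snr!r}")
    threshold = z / snr
    margin = drop - threshold
    return margin >= 0, margin


# --------------------------------------------------------------------------
# gradient schemes


@dataclass(frozen=True)
class GradientScheme:
    """Diffusion gradient table: one (b, direction) pair per volume.

    ``bvals`` has shape (N,), s/mm^2; ``bvecs`` has shape (N, 3) with
    unit-norm rows wherever b > 0.  At least one b=0 entry is required for
    tensor fitting.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvals.ndim != 1 or bvecs.shape != (bvals.size, 3):
            raise InvalidParameterError(
                f"bvals (N,) and bvecs (N, 3) required; got {bvals.shape} "
                f"and {bvecs.shape}"
            )
        if np.any(bvals < 0):
            raise InvalidParameterError("b-values must be >= 0")
        norms = np.linalg.norm(bvecs, axis=1)
        weighted = bvals > 0
        if np.any(np.abs(norms[weighted] - 1.0) > 1e-6):
            raise InvalidParameterError(
                "direction vectors must be unit-norm where b > 0"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvals == 0))

    def to_bval_bvec(self, bval_path: str | Path, bvec_path: str | Path) -> None:
        """Write the conventional two-file layout: one row of b-values and
        three rows of direction components."""
        np.savetxt(bval_path, self.bvals[None, :], fmt="%.6g")
        np.savetxt(bvec_path, self.bvecs.T, fmt="%.8f")

    @classmethod
    def from_bval_bvec(
        cls, bval_path: str | Path, bvec_path: str | Path
    ) -> "GradientScheme":
        bvals = np.loadtxt(bval_path).reshape(-1)
        bvecs = np.loadtxt(bvec_path)
        if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
            bvecs = bvecs.T
        return cls(bvals=bvals, bvecs=bvecs)

    def to_table(self, path: str | Path) -> None:
        """Write the single-file four-column variant (b, gx, gy, gz)."""
        np.savetxt(
            path,
            np.column_stack([self.bvals, self.bvecs]),
            fmt="%.8g",
            header="b_s_mm2 gx gy gz",
        )

    @classmethod
    def from_table(cls, path: str | Path) -> "GradientScheme":
        data = np.atleast_2d(np.loadtxt(path))
        if data.shape[1] != 4:
            raise InvalidParameterError(
                f"expected 4 columns (b, gx, gy, gz), got {data.shape[1]}"
            )
        return cls(bvals=data[:, 0], bvecs=data[:, 1:])


def uniform_directions(n: int) -> np.ndarray:
    """Approximately uniform unit vectors on the hemisphere (golden-ratio
    spiral); adequate coverage for tensor estimation, deterministic."""
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n!r}")
    i = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    # z in (0, 1]: hemisphere only, DTI signals are antipodally symmetric
    z = (i + 0.5) / n
    r = np.sqrt(1.0 - z**2)
    vecs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return vecs / np.linalg.norm(vecs, axis=1, keepdims=True)


def default_scheme(b: float = 600.0, n_directions: int = 30) -> GradientScheme:
    """One b=0 volume plus ``n_directions`` uniform directions at fixed b."""
    dirs = uniform_directions(n_directions)
    bvals = np.concatenate([[0.0], np.full(n_directions, float(b))])
    bvecs = np.vstack([[0.0, 0.0, 0.0], dirs])
    return GradientScheme(bvals=bvals, bvecs=bvecs)


# --------------------------------------------------------------------------
# signal synthesis and tensor fitting


def _orientation_matrix(principal_axis: np.ndarray) -> np.ndarray:
    """Orthonormal basis whose first column is the given principal axis."""
    e1 = np.asarray(principal_axis, dtype=float)
    norm = np.linalg.norm(e1)
    if not np.isfinite(norm) or norm == 0:
        raise InvalidParameterError("principal axis must be a nonzero vector")
    e1 = e1 / norm
    helper = np.array([1.0, 0.0, 0.0])
    if abs(e1 @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3])


def tensor_from_state(
    state: TensorState, principal_axis: np.ndarray | None = None
) -> np.ndarray:
    """3x3 diffusion tensor (m^2/s) with lambda1 along ``principal_axis``
    (default: the z-axis, the conventional fiber orientation)."""
    axis = np.array([0.0, 0.0, 1.0]) if principal_axis is None else principal_axis
    v = _orientation_matrix(axis)
    return v @ np.diag(state.eigenvalues) @ v.T


def synthesize_signal(
    tensor: TensorState | np.ndarray,
    scheme: GradientScheme,
    a0: float = 1.0,
    principal_axis: np.ndarray | None = None,
) -> np.ndarray:
    """Noiseless signals A0 exp(-b g^T D g), one per scheme entry.

    ``tensor`` is either a :class:`TensorState` (oriented by
    ``principal_axis``) or a full 3x3 symmetric tensor in m^2/s.  For a
    gradient along an eigenvector the result reduces to mono-exponential
    attenuation with that eigenvalue.
    """
    if isinstance(tensor, TensorState):
        d = tensor_from_state(tensor, principal_axis)
    else:
        d = np.asarray(tensor, dtype=float)
        if d.shape != (3, 3):
            raise InvalidParameterError(f"tensor must be 3x3, got {d.shape}")
    # projected diffusivity per direction, m^2/s -> mm^2/s
    d_proj = np.einsum("ni,ij,nj->n", scheme.bvecs, d, scheme.bvecs)
    return a0 * np.exp(-scheme.bvals * d_proj * _MM2_PER_M2)


def _design_matrix(scheme: GradientScheme) -> np.ndarray:
    g = scheme.bvecs
    b = scheme.bvals
    return np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )


def _coeffs_to_tensor(coeffs: np.ndarray) -> np.ndarray:
    """Map fitted coefficients (mm^2/s) to a symmetric tensor in m^2/s."""
    dxx, dyy, dzz, dxy, dxz, dyz = coeffs[1:7] / _MM2_PER_M2
    return np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])


def fit_tensor(
    signals: np.ndarray, scheme: GradientScheme
) -> tuple[TensorState, np.ndarray]:
    """Log-linear least-squares diffusion-tensor estimate.

    Returns the eigenvalues (sorted descending) as a :class:`TensorState`
    and the eigenvector matrix (columns matching the eigenvalue order).
    Non-positive signals are masked out with a warning; eigenvalues are
    floored just above zero so downstream FA stays defined at high noise.
    Requires >= 6 non-collinear weighted directions plus a b=0 entry.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.shape != (len(scheme),):
        raise InvalidParameterError(
            f"signals shape {signals.shape} does not match scheme length "
            f"{len(scheme)}"
        )
    if scheme.n_b0 < 1:
        raise DegenerateSchemeError("scheme needs at least one b=0 entry")
    design = _design_matrix(scheme)
    mask = signals > 0
    if not np.all(mask):
        warnings.warn(
            f"masking {int(np.sum(~mask))} non-positive signal(s) in tensor fit",
            stacklevel=2,
        )
    if np.linalg.matrix_rank(design[mask]) < 7:
        raise DegenerateSchemeError(
            "gradient scheme is rank-deficient: need >= 6 non-collinear "
            "weighted directions plus b=0"
        )
    coeffs, *_ = np.linalg.lstsq(design[mask], np.log(signals[mask]), rcond=None)
    d = _coeffs_to_tensor(coeffs)
    eigvals, eigvecs = np.linalg.eigh(d)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    floor = 1e-16  # m^2/s; keeps FA defined when noise drives a fit negative
    eigvals = np.maximum(eigvals, floor)
    state = TensorState(*np.maximum.accumulate(eigvals[::-1])[::-1])
    return state, eigvecs
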