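"""Tunable Q-factor wavelet transform (TQWT).

An oversampled discrete wavelet transform built by iterating a two-channel
filter bank in the DFT domain.  The oscillatory character of the analysis
wavelet is set by the Q-factor and the overall oversampling by the
redundancy r, through the low/high-pass scaling factors

    beta = 2 / (Q + 1),        alpha = 1 - beta / r.

Each stage splits the current low-pass signal (length M) into a low-pass
part of length ~alpha*M and a high-pass sub-band of length ~beta*M.  Band
edges use the Daubechies-type transition pair

    theta0(v) = (1 + cos v) * sqrt(2 - cos v) / 2
    theta1(v) = (1 - cos v) * sqrt(2 + cos v) / 2

which satisfies theta0^2 + theta1^2 = 1, so the transform is a Parseval
frame: forward followed by inverse is the identity and sub-band energies
sum exactly to the input energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from .errors import (
    InputError,
    LevelError,
    ParameterError,
    SignalTooShortError,
    StructureError,
)

__all__ = [
    "TQWTParams",
    "SubbandSet",
    "FilterBankResponse",
    "compute_filter_scalings",
    "max_levels",
    "filter_bank_response",
    "tqwt_forward",
    "tqwt_inverse",
    "zeros_like_subbands",
]

_REL_TOL = 1e-12


def compute_filter_scalings(Q: float, r: float) -> tuple[float, float]:
    """Map (Q, r) to the filter scaling pair (alpha, beta).

    beta = 2/(Q+1) and alpha = 1 - beta/r; inverting these on the outputs
    recovers Q = (2-beta)/beta and r = beta/(1-alpha).
    """
    if not (np.isfinite(Q) and np.isfinite(r)):
        raise ParameterError("Q and r must be finite")
    if Q <= 0:
        raise ParameterError(f"Q must be > 0, got {Q}")
    if r <= 1:
        raise ParameterError(f"r must be > 1, got {r}")
    beta = 2.0 / (Q + 1.0)
    alpha = 1.0 - beta / r
    return alpha, beta


@dataclass(frozen=True)
class TQWTParams:
    """Parameter triple (Q, r, J) of the transform plus derived scalings."""

    Q: float
    r: float
    J: int
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not isinstance(self.J, (int, np.integer)) or self.J < 1:
            raise ParameterError(f"J must be an integer >= 1, got {self.J}")
        a, b = compute_filter_scalings(self.Q, self.r)
        if not math.isclose(self.beta, b, rel_tol=_REL_TOL):
            raise ParameterError(f"beta={self.beta} inconsistent with Q={self.Q}")
        if not math.isclose(self.alpha, a, rel_tol=_REL_TOL):
            raise ParameterError(
                f"alpha={self.alpha} inconsistent with (Q, r)=({self.Q}, {self.r})"
            )
        if not (0.0 < self.alpha < 1.0):
            raise ParameterError(f"alpha must lie in (0,1), got {self.alpha}")
        if not (0.0 < self.beta <= 1.0):
            raise ParameterError(f"beta must lie in (0,1], got {self.beta}")
        if self.alpha + self.beta <= 1.0:
            raise ParameterError(
                "alpha + beta must exceed 1 (oversampling condition)"
            )

    @classmethod
    def from_q(cls, Q: float, r: float, J: int) -> "TQWTParams":
        alpha, beta = compute_filter_scalings(Q, r)
        return cls(Q=float(Q), r=float(r), J=int(J), alpha=alpha, beta=beta)


@dataclass
class SubbandSet:
    """J high-pass sub-bands plus the final low-pass output."""

    highpass: List[np.ndarray]
    lowpass: np.ndarray
    params: TQWTParams
    input_length: int
    padded_length: int = field(default=0)

    def __post_init__(self) -> None:
        if len(self.highpass) != self.params.J:
            raise StructureError(
                f"expected {self.params.J} high-pass sub-bands, "
                f"got {len(self.highpass)}"
            )
        if self.padded_length == 0:
            self.padded_length = _padded_length(self.input_length)

    def __len__(self) -> int:
        return self.params.J + 1

    def copy(self) -> "SubbandSet":
        return SubbandSet(
            highpass=[d.copy() for d in self.highpass],
            lowpass=self.lowpass.copy(),
            params=self.params,
            input_length=self.input_length,
            padded_length=self.padded_length,
        )

    @property
    def total_samples(self) -> int:
        return sum(len(d) for d in self.highpass) + len(self.lowpass)

    def energy(self) -> float:
        return float(
            sum(np.dot(d, d) for d in self.highpass)
            + np.dot(self.lowpass, self.lowpass)
        )


@dataclass(frozen=True)
class FilterBankResponse:
    """Idealised equivalent frequency responses at one level."""

    level: int
    omega: np.ndarray
    h0: np.ndarray
    h1: np.ndarray


def max_levels(N: int, alpha: float, beta: float) -> int:
    """Largest admissible J for a length-N signal: floor(log(beta*N/8)/log(1/alpha))."""
    if N < 16:
        raise SignalTooShortError(f"need N >= 16, got {N}")
    if not (0.0 < alpha < 1.0 and 0.0 < beta <= 1.0):
        raise ParameterError("invalid (alpha, beta)")
    arg = beta * N / 8.0
    if arg <= 1.0:
        raise SignalTooShortError(
            f"signal too short for any decomposition level (beta*N/8 = {arg:.3g})"
        )
    return int(math.floor(math.log(arg) / math.log(1.0 / alpha)))


# ----------------------------------------------------------------------
# base transition responses

def _theta0(v: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.cos(v)) * np.sqrt(2.0 - np.cos(v))


def _theta1(v: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.cos(v)) * np.sqrt(2.0 + np.cos(v))


def _base_lowpass(omega: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Base H0 on |omega| <= pi: 1 on the passband, theta0 across the
    transition (1-beta)*pi..alpha*pi, 0 beyond."""
    w = np.abs(np.asarray(omega, dtype=float))
    lo = (1.0 - beta) * np.pi
    hi = alpha * np.pi
    out = np.zeros_like(w)
    out[w <= lo] = 1.0
    mid = (w > lo) & (w < hi)
    v = (w[mid] - lo) / (alpha + beta - 1.0)
    out[mid] = _theta0(v)
    return out


def _base_highpass(omega: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    w = np.abs(np.asarray(omega, dtype=float))
    lo = (1.0 - beta) * np.pi
    hi = alpha * np.pi
    out = np.zeros_like(w)
    out[w >= hi] = 1.0
    mid = (w > lo) & (w < hi)
    v = (w[mid] - lo) / (alpha + beta - 1.0)
    out[mid] = _theta1(v)
    return out


def filter_bank_response(
    params: TQWTParams, level: int, grid_size: int = 4096
) -> FilterBankResponse:
    """Equivalent level-`level` responses sampled on omega in [-pi, pi].

    h0 is the cascade prod_{m=0}^{j-1} H0(omega / alpha^m), supported on
    |omega| <= alpha^j * pi; h1 is H1(omega / alpha^{j-1}) times the
    cascade up to m = j-2, supported on
    (1-beta) * alpha^{j-1} * pi <= |omega| <= alpha^{j-1} * pi.
    """
    j = int(level)
    if not 1 <= j <= params.J:
        raise LevelError(f"level {level} outside 1..{params.J}")
    a, b = params.alpha, params.beta
    omega = np.linspace(-np.pi, np.pi, int(grid_size))

    h0 = np.ones_like(omega)
    for m in range(j):
        h0 *= _base_lowpass(omega / a**m, a, b)
    h0[np.abs(omega) > a**j * np.pi] = 0.0

    h1 = _base_highpass(omega / a ** (j - 1), a, b)
    for m in range(j - 1):
        h1 *= _base_lowpass(omega / a**m, a, b)
    w = np.abs(omega)
    h1[(w < (1.0 - b) * a ** (j - 1) * np.pi) | (w > a ** (j - 1) * np.pi)] = 0.0

    return FilterBankResponse(level=j, omega=omega, h0=h0, h1=h1)


# ----------------------------------------------------------------------
# forward / inverse implementation

def _padded_length(n: int) -> int:
    return n if n % 2 == 0 else n + 1


class _LevelGeometry:
    """Precomputed band-split geometry for one filter-bank stage."""

    __slots__ = ("m", "n0", "n1", "P", "T", "t0", "t1")

    def __init__(self, m: int, n0: int, n1: int):
        self.m = m
        self.n0 = n0
        self.n1 = n1
        self.P = (m - n1) // 2
        self.T = (n0 + n1 - m) // 2 - 1
        v = np.arange(1, self.T + 1) * (np.pi / (self.T + 1))
        self.t0 = _theta0(v)
        self.t1 = _theta1(v)


_PLAN_CACHE: dict = {}


def _plan(n_padded: int, params: TQWTParams) -> List[_LevelGeometry]:
    key = (n_padded, params.alpha, params.beta, params.J)
    plan = _PLAN_CACHE.get(key)
    if plan is not None:
        return plan
    a, b = params.alpha, params.beta
    plan = []
    m = n_padded
    for j in range(1, params.J + 1):
        n0 = 2 * int(round(a**j * n_padded / 2.0))
        n1 = 2 * int(round(b * a ** (j - 1) * n_padded / 2.0))
        n1 = min(max(n1, 2), m)
        # keep a non-negative transition band and valid stop band
        while n0 + n1 < m + 2:
            n0 += 2
        n0 = min(n0, m)
        if n0 + n1 < m + 2 or n0 < 2:
            raise LevelError(
                f"cannot split length {m} at level {j} with (alpha, beta)="
                f"({a:.4g}, {b:.4g})"
            )
        plan.append(_LevelGeometry(m, n0, n1))
        m = n0
    _PLAN_CACHE[key] = plan
    return plan


def _split(X: np.ndarray, g: _LevelGeometry) -> tuple[np.ndarray, np.ndarray]:
    """One analysis stage on a half-spectrum X (length m/2+1, unitary)."""
    P, T = g.P, g.T
    V0 = np.zeros(g.n0 // 2 + 1, dtype=complex)
    V0[: P + 1] = X[: P + 1]
    if T:
        V0[P + 1 : P + 1 + T] = X[P + 1 : P + 1 + T] * g.t0
    V1 = np.zeros(g.n1 // 2 + 1, dtype=complex)
    if T:
        V1[1 : T + 1] = X[P + 1 : P + 1 + T] * g.t1
    V1[T + 1 :] = X[P + T + 1 : g.m // 2 + 1]
    return V0, V1


def _merge(V0: np.ndarray, V1: np.ndarray, g: _LevelGeometry) -> np.ndarray:
    """One synthesis stage, the adjoint of :func:`_split`."""
    P, T = g.P, g.T
    X = np.zeros(g.m // 2 + 1, dtype=complex)
    X[: P + 1] = V0[: P + 1]
    if T:
        X[P + 1 : P + 1 + T] = V0[P + 1 : P + 1 + T] * g.t0 + V1[1 : T + 1] * g.t1
    X[P + T + 1 :] = V1[T + 1 :]
    return X


def tqwt_forward(signal: Sequence[float], params: TQWTParams) -> SubbandSet:
    """Decompose a real signal into J high-pass sub-bands plus a low-pass rest."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise InputError("signal must be a non-empty 1-D array")
    if not np.all(np.isfinite(x)):
        raise InputError("signal contains non-finite samples")
    n = x.size
    n_pad = _padded_length(n)
    jmax = max_levels(n_pad, params.alpha, params.beta)
    if params.J > jmax:
        raise LevelError(f"J={params.J} exceeds J_max={jmax} for length {n}")
    if n_pad != n:
        x = np.concatenate([x, np.zeros(n_pad - n)])

    plan = _plan(n_pad, params)
    X = np.fft.rfft(x) / math.sqrt(n_pad)
    highpass: List[np.ndarray] = []
    for g in plan:
        X, V1 = _split(X, g)
        highpass.append(np.fft.irfft(V1, g.n1) * math.sqrt(g.n1))
    lowpass = np.fft.irfft(X, plan[-1].n0) * math.sqrt(plan[-1].n0)
    return SubbandSet(
        highpass=highpass,
        lowpass=lowpass,
        params=params,
        input_length=n,
        padded_length=n_pad,
    )


def tqwt_inverse(subbands: SubbandSet) -> np.ndarray:
    """Reconstruct the signal; exact inverse of :func:`tqwt_forward`."""
    params = subbands.params
    n_pad = subbands.padded_length
    plan = _plan(n_pad, params)
    if len(subbands.lowpass) != plan[-1].n0:
        raise StructureError(
            f"low-pass length {len(subbands.lowpass)} != expected {plan[-1].n0}"
        )
    for g, d in zip(plan, subbands.highpass):
        if len(d) != g.n1:
            raise StructureError(
                f"sub-band length {len(d)} != expected {g.n1}"
            )
    X = np.fft.rfft(subbands.lowpass) / math.sqrt(plan[-1].n0)
    for g, d in zip(reversed(plan), reversed(subbands.highpass)):
        V1 = np.fft.rfft(d) / math.sqrt(g.n1)
        X = _merge(X, V1, g)
    y = np.fft.irfft(X, n_pad) * math.sqrt(n_pad)
    return y[: subbands.input_length]


def zeros_like_subbands(params: TQWTParams, input_length: int) -> SubbandSet:
    """All-zero coefficient set with the geometry of a length-N forward transform."""
    n_pad = _padded_length(input_length)
    plan = _plan(n_pad, params)
    return SubbandSet(
        highpass=[np.zeros(g.n1) for g in plan],
        lowpass=np.zeros(plan[-1].n0),
        params=params,
        input_length=input_length,
        padded_length=n_pad,
    )
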