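"""Spectral pretreatment operators and their ordered combinations.

Five operators are supported — Savitzky–Golay smoothing (SG), vector
normalization (VN), multiplicative scatter correction (MSC), and first /
second Savitzky–Golay derivatives (FD / SD) — composed left to right into
named chains such as ``"fd+msc+sg:17"``.  Only MSC carries data-dependent
state (the reference spectrum); that state is fitted on the calibration
set and frozen for validation and test data so no information leaks
across the split.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .spectra import SpectraSet, Spectrum

__all__ = [
    "SGStep",
    "VNStep",
    "MSCStep",
    "PretreatmentSpec",
    "FittedPretreatment",
    "parse_steps",
    "sg_filter",
    "vector_normalize",
    "msc",
    "apply_pretreatments",
]


@dataclass(frozen=True)
class SGStep:
    """Savitzky–Golay filter step; ``deriv`` 0 smooths, 1/2 differentiate."""

    window: int = 17
    polyorder: int = 2
    deriv: int = 0

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window < self.polyorder + 2:
            raise ValueError(
                f"window must be odd and >= polyorder + 2, got "
                f"window={self.window}, polyorder={self.polyorder}"
            )
        if not 0 <= self.deriv <= self.polyorder:
            raise ValueError("deriv must satisfy 0 <= deriv <= polyorder")

    @property
    def label(self) -> str:
        prefix = {0: "sg", 1: "fd", 2: "sd"}[self.deriv]
        return f"{prefix}:{self.window}" if self.deriv == 0 else prefix


@dataclass(frozen=True)
class VNStep:
    """Vector normalization: subtract the row mean, scale to unit norm."""

    label: str = field(default="vn", init=False)


@dataclass(frozen=True)
class MSCStep:
    """Multiplicative scatter correction against a reference spectrum.

    ``reference=None`` means "mean of the set being fitted"; an explicit
    :class:`~nirquant.spectra.Spectrum` pins the reference.
    """

    reference: Spectrum | None = None

    @property
    def label(self) -> str:
        return "msc"


PretreatmentStep = SGStep | VNStep | MSCStep
PretreatmentSpec = tuple  # ordered tuple of steps; empty tuple = identity


@dataclass(frozen=True)
class FittedPretreatment:
    """A pretreatment chain with its data-dependent state frozen.

    ``msc_references[i]`` holds the reference spectrum fitted for the
    i-th step when that step is an MSC with a mean-of-set reference.
    """

    steps: tuple
    msc_references: tuple

    def fingerprint(self) -> str:
        h = hashlib.sha1()
        for step, ref in zip(self.steps, self.msc_references):
            h.update(repr(step if not isinstance(step, MSCStep) else "msc").encode())
            if ref is not None:
                h.update(np.ascontiguousarray(ref, dtype=float).tobytes())
        return h.hexdigest()


def parse_steps(spec: str) -> tuple:
    """Parse a chain like ``"fd+msc+sg:17"`` into step objects.

    Tokens: ``sg[:window[:polyorder]]``, ``vn``, ``msc``,
    ``fd[:window[:polyorder]]``, ``sd[:window[:polyorder]]``.  The empty
    string is the identity chain.
    """
    if not spec.strip():
        return ()
    steps: list[PretreatmentStep] = []
    for token in spec.lower().split("+"):
        name, *args = token.strip().split(":")
        window = int(args[0]) if args else 17 if name == "sg" else 9
        polyorder = int(args[1]) if len(args) > 1 else 2
        if name == "sg":
            steps.append(SGStep(window, polyorder, 0))
        elif name == "fd":
            steps.append(SGStep(window, polyorder, 1))
        elif name == "sd":
            steps.append(SGStep(window, polyorder, 2))
        elif name == "vn":
            steps.append(VNStep())
        elif name == "msc":
            steps.append(MSCStep())
        else:
            raise ValueError(f"unknown pretreatment step {name!r}")
    return tuple(steps)


def _sg_matrix(matrix: np.ndarray, window: int, polyorder: int, deriv: int,
               step_cm: float) -> np.ndarray:
    """SG filter along rows with shrink-window boundary fits.

    Interior points use the standard convolution weights; within half a
    window of each edge the local polynomial is refitted on the available
    (truncated) window only, so no data outside the measured range is
    fabricated.  Derivatives are with respect to wavenumber: the grid is
    stored high->low, hence the (-1/step)^deriv scaling.
    """
    n = matrix.shape[1]
    if window > n:
        raise ValueError(f"window {window} exceeds {n} spectral points")
    out = savgol_filter(matrix, window, polyorder, deriv=deriv, axis=1,
                        mode="nearest")
    half = window // 2
    idx = np.arange(n)
    for i in list(range(half)) + list(range(n - half, n)):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        x = idx[lo:hi] - i
        deg = min(polyorder, len(x) - 1)
        # polyfit over the truncated window, all samples at once
        coefs = np.polynomial.polynomial.polyfit(x, matrix[:, lo:hi].T, deg)
        if deriv > deg:
            out[:, i] = 0.0
        else:
            fact = 1.0
            for k in range(1, deriv + 1):
                fact *= k
            out[:, i] = coefs[deriv] * fact
    return out * (-1.0 / step_cm) ** deriv if deriv else out


def sg_filter(spectra: SpectraSet, window: int, polyorder: int = 2,
              deriv: int = 0) -> SpectraSet:
    """Savitzky–Golay smooth (deriv=0) or differentiate (deriv=1, 2) per row.

    Derivative output is in AU·cm (first) or AU·cm² (second), i.e. with
    respect to wavenumber, not to the sample index.
    """
    SGStep(window, polyorder, deriv)  # validates the parameters
    out = _sg_matrix(spectra.absorbance, window, polyorder, deriv,
                     spectra.grid.step)
    return SpectraSet(spectra.sample_ids, spectra.grid, out, spectra.lineage)


def vector_normalize(spectra: SpectraSet) -> SpectraSet:
    """Per row: subtract the mean intensity, then divide by the root of the
    sum of squared centered intensities (unit Euclidean norm, zero mean)."""
    x = spectra.absorbance
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    bad = np.nonzero(norms < 1e-300)[0]
    if bad.size:
        raise ValueError(
            f"constant spectrum cannot be vector-normalized: sample "
            f"{spectra.sample_ids[bad[0]]!r}"
        )
    return SpectraSet(spectra.sample_ids, spectra.grid,
                      centered / norms[:, None], spectra.lineage)


def msc(spectra: SpectraSet,
        reference: np.ndarray | Spectrum | None = None
        ) -> tuple[SpectraSet, np.ndarray]:
    """Multiplicative scatter correction.

    Each spectrum x is regressed on the reference r by ordinary least
    squares, x ≈ a + b·r, and corrected to (x − a)/b.  With
    ``reference=None`` the column mean of ``spectra`` is used and returned
    so the same reference can be frozen for validation/test data.

    Returns
    -------
    (corrected SpectraSet, reference vector actually used)
    """
    x = spectra.absorbance
    if reference is None:
        ref = x.mean(axis=0)
    elif isinstance(reference, Spectrum):
        ref = np.asarray(reference.absorbance, dtype=float)
    else:
        ref = np.asarray(reference, dtype=float)
    if ref.shape != (x.shape[1],):
        raise ValueError("reference length does not match spectra")
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom < 1e-300:
        raise ValueError("MSC reference has zero variance")
    # per-row simple linear regression x ~ a + b * ref
    b = (x - x.mean(axis=1, keepdims=True)) @ ref_c / denom
    a = x.mean(axis=1) - b * ref.mean()
    bad = np.nonzero(np.abs(b) < 1e-12)[0]
    if bad.size:
        raise ValueError(
            f"degenerate MSC fit (slope ~ 0) for sample "
            f"{spectra.sample_ids[bad[0]]!r}"
        )
    corrected = (x - a[:, None]) / b[:, None]
    return (SpectraSet(spectra.sample_ids, spectra.grid, corrected,
                       spectra.lineage), ref)


def apply_pretreatments(spectra: SpectraSet, steps: Sequence[PretreatmentStep],
                        fitted_state: FittedPretreatment | None = None
                        ) -> tuple[SpectraSet, FittedPretreatment]:
    """Apply a pretreatment chain left to right.

    On the first (calibration) pass, call without ``fitted_state``: any
    mean-of-set MSC reference is fitted here and frozen in the returned
    state.  Pass that state when transforming validation or test spectra
    so they are corrected against the calibration reference, never their
    own mean.
    """
    steps = tuple(steps)
    if fitted_state is not None and fitted_state.steps != steps:
        raise ValueError("fitted_state was built for a different chain")
    refs: list[np.ndarray | None] = []
    out = spectra
    for i, step in enumerate(steps):
        if isinstance(step, SGStep):
            out = sg_filter(out, step.window, step.polyorder, step.deriv)
            refs.append(None)
        elif isinstance(step, VNStep):
            out = vector_normalize(out)
            refs.append(None)
        elif isinstance(step, MSCStep):
            if fitted_state is not None:
                frozen = fitted_state.msc_references[i]
                out, ref = msc(out, frozen)
            elif step.reference is not None:
                out, ref = msc(out, step.reference)
            else:
                out, ref = msc(out, None)
            refs.append(ref)
        else:
            raise TypeError(f"unknown pretreatment step {step!r}")
    state = fitted_state if fitted_state is not None else FittedPretreatment(
        steps, tuple(refs))
    return out.with_lineage(state.fingerprint()), state
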