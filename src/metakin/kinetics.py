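"""Polynomial kinetic signatures and response-pattern classification.

A metabolite's kinetic signature is an ordinary-least-squares polynomial
(default degree 9) fitted to its cohort median curve, expressed as the
relative concentration change (%) with respect to the fitted value at
rest.  Signatures are classified into the five kinetic response
patterns of graded exercise: sustained (flat within noise), early,
halving-interval, late and delayed (post-exercise) responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial

from .preprocess import MedianCurve
from .simulate import TEMPLATE_KINDS, TemplateSpec, template_value

DEFAULT_DEGREE = 9

#: Relative-workload boundaries of the pattern segments: early [0, 25),
#: halving [25, 75), late [75, 100], delayed (100, recovery].
SEGMENT_BOUNDS = (25.0, 75.0, 100.0)

#: A relative-curve range below this band (percentage points) is accepted
#: as biological/analytical variability, i.e. a sustained response
#: (+/-10% around rest).
SUSTAINED_BAND = 20.0

PATTERNS = ("sustained", "early", "halving", "late", "delayed")


@dataclass(frozen=True)
class KineticSignature:
    """A fitted kinetic signature on a common grid.

    ``coefficients`` are in the power basis on the abscissa linearly
    mapped to [0, 1] — a raw degree-9 Vandermonde on 0..117 is
    catastrophically ill-conditioned.  ``relative`` is the fitted curve
    as % change versus the fitted value at position 0.
    """

    metabolite: str
    degree: int
    coefficients: np.ndarray
    positions: np.ndarray
    fitted: np.ndarray  # uM on the grid
    relative: np.ndarray  # % vs rest, exactly 0 at position 0
    rss: float


def fit_polynomial(median: MedianCurve, degree: int = DEFAULT_DEGREE) -> KineticSignature:
    """Least-squares polynomial fit of a median curve.

    If the grid has fewer than ``degree + 1`` points the degree is
    reduced (with a warning) so the system stays overdetermined.
    """
    pos = np.asarray(median.grid.positions, dtype=float)
    y = np.asarray(median.values, dtype=float)
    if len(pos) <= degree:
        new_degree = len(pos) - 1
        warnings.warn(
            f"{median.metabolite}: grid of {len(pos)} points cannot support degree "
            f"{degree}; reduced to {new_degree}",
            stacklevel=2,
        )
        degree = new_degree
    poly = Polynomial.fit(pos, y, deg=degree, domain=[pos[0], pos[-1]], window=[0.0, 1.0])
    fitted = poly(pos)
    rss = float(np.sum((y - fitted) ** 2))
    relative = to_relative(fitted)
    return KineticSignature(
        metabolite=median.metabolite,
        degree=degree,
        coefficients=poly.coef.copy(),
        positions=pos,
        fitted=fitted,
        relative=relative,
        rss=rss,
    )


def to_relative(fitted: np.ndarray) -> np.ndarray:
    """Fitted curve as % change relative to its value at rest (index 0).

    rel(s) = 100 * (f(s) - f(0)) / f(0); exactly 0 at rest.  A
    non-positive fitted rest value is non-physical and raises.
    """
    fitted = np.asarray(fitted, dtype=float)
    f0 = fitted[0]
    if not f0 > 0:
        raise ValueError(f"fitted rest concentration {f0:g} is not positive")
    return 100.0 * (fitted - f0) / f0


def classify_kinetic_pattern(
    relative: np.ndarray,
    positions: np.ndarray,
    sustained_band: float = SUSTAINED_BAND,
    segment_bounds=SEGMENT_BOUNDS,
    early_frac: float = 0.4,
    halving_frac: float = 0.85,
) -> str:
    """Kinetic response pattern of a relative (%) curve.

    A curve whose total range stays below ``sustained_band`` percentage
    points is sustained — changes within ±10% of rest are accepted as
    biological/analytical variability.  Otherwise the call is made from
    where the concentration change accumulates along the axis (endpoint
    evaluations are insensitive to the ringing of a high-degree
    polynomial fit, unlike pointwise slopes):

    * the recovery change ``rel(recovery) − rel(end)`` exceeding the
      exercise change ``rel(end) − rel(0)`` in magnitude → **delayed**
      (the response happens after physical activity ends);
    * the largest excursion before the early boundary (position 25)
      reaching ``early_frac`` of the curve's total range → **early**
      (this also catches an early transient trough that recovers, the
      short-chain acylcarnitine signature);
    * at least ``halving_frac`` reached by the halving boundary
      (position 75), i.e. a mid-exercise transition with a plateau →
      **halving**;
    * otherwise the change keeps accumulating to the end of exercise →
      **late**.  (A uniform slope reaches exactly 25%/75% at the
      boundaries and is therefore late, matching the tie-toward-later
      convention.)
    """
    relative = np.asarray(relative, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if relative.max() - relative.min() < sustained_band:
        return "sustained"
    e, h, l = segment_bounds
    r0, re, rh, rl, rend = np.interp(
        [positions[0], e, h, l, positions[-1]], positions, relative
    )
    exercise_change = rl - r0
    recovery_change = rend - rl
    if abs(recovery_change) > abs(exercise_change):
        return "delayed"
    total_range = relative.max() - relative.min()
    early_excursion = np.abs(relative[positions <= e] - r0).max()
    if early_excursion >= early_frac * total_range:
        return "early"
    if exercise_change == 0:
        return "late"  # unreachable for non-sustained monotone curves
    if (rh - r0) / exercise_change >= halving_frac:
        return "halving"
    return "late"


def match_template(
    relative: np.ndarray,
    positions: np.ndarray,
    library: tuple[str, ...] = TEMPLATE_KINDS,
    parsimony_frac: float = 0.05,
) -> tuple[str, float]:
    """Best-matching kinetic basis shape by least-squares amplitude fit.

    Each candidate shape (unit amplitude, default shape parameters) is
    scaled by its optimal least-squares amplitude and compared by
    residual norm.  Because any shape strictly reduces the residual of a
    zero-mean noise curve by a little, a non-constant shape must beat
    the anchored-constant fit by more than ``parsimony_frac`` of its
    residual norm to be selected — so flat-plus-noise curves resolve to
    the constant shape.

    Returns ``(kind, residual_norm)``.
    """
    c = np.asarray(relative, dtype=float)
    const_res = float(np.linalg.norm(c))
    best_kind, best_res = "sustained_const", const_res
    for kind in library:
        if kind == "sustained_const":
            continue
        basis = np.asarray(
            template_value(TemplateSpec(kind, baseline=1.0, amplitude=1.0), positions)
        )
        bb = float(basis @ basis)
        amp = float(c @ basis) / bb if bb > 0 else 0.0
        res = float(np.linalg.norm(c - amp * basis))
        if res < best_res and res < (1.0 - parsimony_frac) * const_res:
            best_kind, best_res = kind, res
    return best_kind, best_res
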