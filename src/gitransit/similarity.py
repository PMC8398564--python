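"""Profile-similarity pipeline: normalization, Ta selection, the f2 factor.

Two permeation profiles (reference = ordinary-tablet role, test = the other
product) are compared as follows: both series are normalized to the
*reference* permeated amount at 120 min (= 100%); Ta is the sampled time at
which the normalized reference is closest to 85%; the similarity factor

    f2 = 50 * log10( 100 / sqrt(1 + sum_i (T_i - R_i)^2 / n) )

is evaluated at the four times {Ta/4, Ta/2, 3Ta/4, Ta}, with linear
interpolation for quarter points that fall between samples.  Profiles are
called similar when f2 >= 50 (inclusive; the regulatory convention phrases
acceptance as f2 >= 50).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transit import ProfileSet

__all__ = [
    "SimilarityResult",
    "ZeroReferenceError",
    "GridMismatchError",
    "FlatProfileError",
    "normalize_profile",
    "select_ta",
    "f2_similarity",
    "assess_similarity",
    "compare_profiles",
]

NORMALIZATION_TIME = 120.0  # min
TA_LEVEL = 85.0  # % (normalized)
TA_MINIMUM = 50.0  # reference must exceed this for Ta to be defined
DEFAULT_BORDER = 50.0


class ZeroReferenceError(ValueError):
    """Reference permeated amount at the normalization time is not positive."""


class GridMismatchError(ValueError):
    """Test and reference profiles are not on the same sampling grid."""


class FlatProfileError(ValueError):
    """The normalized reference never exceeds the minimum level; Ta undefined."""


@dataclass(frozen=True)
class SimilarityResult:
    ta: float  # min
    eval_times: tuple[float, float, float, float]
    t_values: tuple[float, ...]  # test, normalized %
    r_values: tuple[float, ...]  # reference, normalized %
    n: int
    f2: float
    border: float
    similar: bool

    def to_dict(self) -> dict:
        return {
            "Ta_min": self.ta,
            "eval_times_min": list(self.eval_times),
            "test_values_pct": list(self.t_values),
            "reference_values_pct": list(self.r_values),
            "n": self.n,
            "f2": self.f2,
            "border": self.border,
            "similar": self.similar,
        }


def _series(profile: ProfileSet | np.ndarray) -> np.ndarray:
    if isinstance(profile, ProfileSet):
        return np.asarray(profile.permeated_pct, dtype=float)
    return np.asarray(profile, dtype=float)


def normalize_profile(
    test: ProfileSet, reference: ProfileSet, at: float = NORMALIZATION_TIME
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize both permeation series to the reference value at ``at`` min.

    Returns ``(test_normalized, reference_normalized)``; the reference equals
    100 exactly at the normalization time.
    """
    t_times = np.asarray(test.times, dtype=float)
    r_times = np.asarray(reference.times, dtype=float)
    if t_times.shape != r_times.shape or not np.allclose(t_times, r_times):
        raise GridMismatchError("test and reference must share a sampling grid")
    idx = np.nonzero(np.isclose(r_times, at))[0]
    if idx.size == 0:
        raise GridMismatchError(f"sampling grid must include t = {at} min")
    ref_end = float(reference.permeated_pct[idx[0]])
    if ref_end <= 0.0:
        raise ZeroReferenceError("reference permeated amount at 120 min is zero")
    scale = 100.0 / ref_end
    return (
        _series(test) * scale,
        _series(reference) * scale,
    )


def select_ta(
    times: np.ndarray, reference_normalized: np.ndarray
) -> tuple[float, tuple[float, float, float, float]]:
    """Ta (sampled time with normalized reference closest to 85%) and the
    four evaluation times {Ta/4, Ta/2, 3Ta/4, Ta}.

    Ties break toward the earlier time.  Raises :class:`FlatProfileError`
    when the reference never exceeds 50% (Ta would be meaningless).
    """
    times = np.asarray(times, dtype=float)
    ref = np.asarray(reference_normalized, dtype=float)
    if ref.max() <= TA_MINIMUM:
        raise FlatProfileError("reference profile never exceeds 50%; Ta undefined")
    ta = float(times[int(np.argmin(np.abs(ref - TA_LEVEL)))])
    return ta, (ta / 4.0, ta / 2.0, 3.0 * ta / 4.0, ta)


def f2_similarity(t_values, r_values) -> float:
    """The f2 similarity factor; 100 at identity, lower as profiles diverge."""
    t = np.asarray(t_values, dtype=float)
    r = np.asarray(r_values, dtype=float)
    if t.shape != r.shape or t.size == 0:
        raise ValueError("t_values and r_values must be equal-length and non-empty")
    msd = float(np.mean((t - r) ** 2))
    return 50.0 * np.log10(100.0 / np.sqrt(1.0 + msd))


def assess_similarity(f2: float, border: float = DEFAULT_BORDER) -> bool:
    """Similar if and only if ``f2 >= border`` (inclusive)."""
    if not np.isfinite(f2):
        raise ValueError("f2 must be finite")
    return bool(f2 >= border)


def compare_profiles(
    test: ProfileSet, reference: ProfileSet, border: float = DEFAULT_BORDER
) -> SimilarityResult:
    """Run the full pipeline on two simulated or measured profile sets."""
    t_norm, r_norm = normalize_profile(test, reference)
    times = np.asarray(reference.times, dtype=float)
    ta, eval_times = select_ta(times, r_norm)
    t_vals = tuple(float(np.interp(et, times, t_norm)) for et in eval_times)
    r_vals = tuple(float(np.interp(et, times, r_norm)) for et in eval_times)
    f2 = f2_similarity(t_vals, r_vals)
    return SimilarityResult(
        ta=ta,
        eval_times=eval_times,
        t_values=t_vals,
        r_values=r_vals,
        n=len(eval_times),
        f2=f2,
        border=border,
        similar=assess_similarity(f2, border),
    )
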