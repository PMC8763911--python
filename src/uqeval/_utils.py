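"""Internal array-validation helpers."""

from __future__ import annotations

import numpy as np

from .errors import ValidationError

#: tolerance on row sums of internally produced probability vectors
PROB_TOL = 1e-6


def as_prob_array(probs, *, tol: float = PROB_TOL, name: str = "probs") -> np.ndarray:
    """Coerce to a float array of probability vectors and validate it.

    Accepts a single vector ``(C,)`` or a batch ``(..., C)``. Every vector
    must be non-negative and sum to 1 within ``tol``.
    """
    arr = np.asarray(probs, dtype=float)
    if arr.ndim == 0 or arr.shape[-1] < 2:
        raise ValidationError(f"{name} must have at least 2 classes on the last axis")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    if np.any(arr < -tol):
        raise ValidationError(f"{name} contains negative probabilities")
    sums = arr.sum(axis=-1)
    bad = np.abs(sums - 1.0) > tol
    if np.any(bad):
        first = tuple(np.argwhere(bad)[0])
        raise ValidationError(
            f"{name}: probability vector at index {first} sums to "
            f"{sums[bad].flat[0]:.6g}, outside 1 +/- {tol:g}"
        )
    return arr


def as_generator(rng) -> np.random.Generator:
    """Accept a seed, SeedSequence or Generator and return a Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)
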