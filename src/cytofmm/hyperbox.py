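"""Hyperbox primitives of the fuzzy min-max neural network.

A hyperbox is an axis-aligned box in the unit hypercube I^n given by a
min corner ``v`` and a max corner ``w``, committed to one class.  Four
operations define the learning dynamics:

* ``membership`` -- the fuzzy degree (0..1) to which a pattern ``a``
  belongs to a box; 1 on the closed box, decaying outside at a slope set
  by the sensitivity parameter gamma.  Per dimension the box contributes

      max(0, 1 - max(0, g * min(1, a_i - w_i)))
    + max(0, 1 - max(0, g * min(1, v_i - a_i)))

  and the membership is the average of these two-term sums over the n
  dimensions (divide by 2n).

* ``can_expand`` -- the expansion test.  A box may absorb a pattern only
  while the enclosing box's total edge-length sum stays within n*theta:

      n * theta >= sum_i [ max(w_i, a_i) - min(v_i, a_i) ]

* ``overlap_test`` -- detects positive-volume overlap between two boxes
  and identifies the dimension of least overlap (Delta) and the
  geometric case of that dimension.

* ``contract`` -- minimally adjusts the two boxes along Delta only, so
  that the overlap disappears (they may still share a face, which counts
  as non-overlap).

The four overlap/contraction cases, for boxes j and k in one dimension:

  case 1:  v_j < v_k <= w_j < w_k   (j leads, partial overlap)
  case 2:  v_k < v_j <= w_k < w_j   (k leads, partial overlap)
  case 3:  v_j <= v_k <= w_k <= w_j (j contains k)
  case 4:  v_k <= v_j <= w_j <= w_k (k contains j)

with contraction: case 1 splits the overlap at its midpoint between
w_j and v_k; case 2 symmetrically between w_k and v_j; cases 3 and 4 cut
the containing box on whichever side sacrifices less extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ContractViolationError, InvalidInputError, ShapeError

__all__ = [
    "Hyperbox",
    "OverlapResult",
    "membership",
    "can_expand",
    "expand",
    "overlap_test",
    "contract",
]


@dataclass(frozen=True)
class Hyperbox:
    """Axis-aligned box in [0,1]^n voting for one class.

    ``min_point`` and ``max_point`` are the corners V and W; invariants
    ``0 <= V <= W <= 1`` elementwise are enforced at construction.
    """

    min_point: np.ndarray
    max_point: np.ndarray
    class_id: int

    def __post_init__(self) -> None:
        v = np.asarray(self.min_point, dtype=float)
        w = np.asarray(self.max_point, dtype=float)
        object.__setattr__(self, "min_point", v)
        object.__setattr__(self, "max_point", w)
        if v.ndim != 1 or w.ndim != 1 or v.shape != w.shape:
            raise ShapeError("hyperbox corners must be 1-D vectors of equal length")
        if np.any(v > w):
            raise InvalidInputError("hyperbox min corner exceeds max corner")
        if v.min(initial=0.0) < 0.0 or w.max(initial=0.0) > 1.0:
            raise InvalidInputError("hyperbox corners outside the unit hypercube")

    @property
    def n_dims(self) -> int:
        return self.min_point.shape[0]

    @classmethod
    def point(cls, pattern: np.ndarray, class_id: int) -> "Hyperbox":
        """Degenerate box with min = max = pattern."""
        p = np.asarray(pattern, dtype=float)
        return cls(min_point=p.copy(), max_point=p.copy(), class_id=class_id)

    def contains(self, pattern: np.ndarray) -> bool:
        p = np.asarray(pattern, dtype=float)
        return bool(
            np.all(self.min_point <= p) and np.all(p <= self.max_point)
        )


@dataclass(frozen=True)
class OverlapResult:
    """Outcome of an overlap test between two hyperboxes.

    ``overlapping`` is true iff every dimension has strictly positive
    interval overlap.  When true, ``dim_index`` is the dimension Delta
    of smallest overlap (lowest index on ties), ``case_id`` its
    geometric case (1-4) and ``delta`` the smallest per-dimension
    overlap width.
    """

    overlapping: bool
    dim_index: int | None = None
    case_id: int | None = None
    delta: float | None = None
    case_per_dim: tuple[int, ...] = field(default=(), repr=False)


def _check_pattern(box: Hyperbox, pattern) -> np.ndarray:
    p = np.asarray(pattern, dtype=float)
    if p.shape != box.min_point.shape:
        raise ShapeError(
            f"pattern has {p.shape} shape, box is {box.n_dims}-dimensional"
        )
    return p


def membership(box: Hyperbox, pattern, gamma: float) -> float:
    """Fuzzy membership of ``pattern`` in ``box`` with sensitivity gamma.

    Equals 1 exactly when the pattern lies in the closed box; outside,
    each offending dimension subtracts up to 1/(2n) scaled by
    ``gamma * distance`` (saturated), so membership decays linearly with
    axis distance at slope gamma/(2n) until the penalty saturates.
    """
    if gamma <= 0:
        raise InvalidInputError(f"gamma must be positive, got {gamma}")
    a = _check_pattern(box, pattern)
    v, w = box.min_point, box.max_point
    n = box.n_dims
    upper = np.maximum(0.0, 1.0 - np.maximum(0.0, gamma * np.minimum(1.0, a - w)))
    lower = np.maximum(0.0, 1.0 - np.maximum(0.0, gamma * np.minimum(1.0, v - a)))
    return float((upper + lower).sum() / (2.0 * n))


def can_expand(box: Hyperbox, pattern, theta: float) -> bool:
    """Expansion test: may ``box`` grow to absorb ``pattern`` under theta?

    True iff the candidate enclosing box's summed edge lengths do not
    exceed ``n * theta``.
    """
    a = _check_pattern(box, pattern)
    span = np.maximum(box.max_point, a) - np.minimum(box.min_point, a)
    # tiny epsilon guards against float round-off denying an exactly-at-bound
    # expansion (e.g. theta=0 with a == corner)
    return bool(span.sum() <= box.n_dims * theta + 1e-12)


def expand(box: Hyperbox, pattern, theta: float | None = None) -> Hyperbox:
    """Grow ``box`` to the smallest box enclosing itself and ``pattern``.

    When ``theta`` is given the expansion test is re-checked and a
    violation raises ``ContractViolationError``.
    """
    a = _check_pattern(box, pattern)
    if theta is not None and not can_expand(box, a, theta):
        raise ContractViolationError(
            "expand called on a pattern that fails the expansion test"
        )
    return Hyperbox(
        min_point=np.minimum(box.min_point, a),
        max_point=np.maximum(box.max_point, a),
        class_id=box.class_id,
    )


def _classify_dim(vj: float, wj: float, vk: float, wk: float) -> tuple[int, float]:
    """Case id and overlap width delta for one overlapping dimension.

    Assumes positive interval overlap.  Equal-corner degeneracies are
    folded into the containment cases 3/4 so every overlapping pair is
    classified.
    """
    if vj < vk:
        if wj < wk:
            return 1, wj - vk
        return 3, min(wj - vk, wk - vj)
    if vk < vj:
        if wk < wj:
            return 2, wk - vj
        return 4, min(wj - vk, wk - vj)
    # equal min corners: the shorter box is contained
    if wj <= wk:
        return 4, min(wj - vk, wk - vj)
    return 3, min(wj - vk, wk - vj)


def overlap_test(box_j: Hyperbox, box_k: Hyperbox) -> OverlapResult:
    """Detect positive-volume overlap and locate the contraction dimension.

    Scans dimensions tracking the running minimum overlap delta
    (initialized to 1, the unit cube's maximum).  The pair overlaps only
    if every dimension's interval intersection has positive width; a
    shared face (zero width somewhere) is non-overlap.  Delta is the
    dimension of smallest overlap, lowest index on ties.
    """
    if box_j.n_dims != box_k.n_dims:
        raise ShapeError("hyperboxes differ in dimensionality")
    vj, wj = box_j.min_point, box_j.max_point
    vk, wk = box_k.min_point, box_k.max_point

    widths = np.minimum(wj, wk) - np.maximum(vj, vk)
    if np.any(widths <= 0.0):
        return OverlapResult(overlapping=False)

    delta_old = 1.0
    dim_index = 0
    cases = []
    for i in range(box_j.n_dims):
        case, delta_new = _classify_dim(vj[i], wj[i], vk[i], wk[i])
        cases.append(case)
        if delta_new < delta_old:
            delta_old = delta_new
            dim_index = i
    return OverlapResult(
        overlapping=True,
        dim_index=dim_index,
        case_id=cases[dim_index],
        delta=delta_old,
        case_per_dim=tuple(cases),
    )


def contract(
    box_j: Hyperbox, box_k: Hyperbox, result: OverlapResult
) -> tuple[Hyperbox, Hyperbox]:
    """Remove the overlap by adjusting only dimension Delta.

    Applies the case rule recorded in ``result``: partial overlaps
    (cases 1-2) are split at the midpoint of the overlap interval;
    containments (cases 3-4) cut the containing box back to the face of
    the contained one on the cheaper side.  After contraction the boxes
    at most share a face, so re-running ``overlap_test`` reports no
    overlap.
    """
    if not result.overlapping or result.dim_index is None:
        raise ContractViolationError(
            "contract called with a non-overlapping result"
        )
    d = result.dim_index
    vj = box_j.min_point.copy()
    wj = box_j.max_point.copy()
    vk = box_k.min_point.copy()
    wk = box_k.max_point.copy()
    case = result.case_id

    if case == 1:
        mid = (vk[d] + wj[d]) / 2.0
        wj[d] = mid
        vk[d] = mid
    elif case == 2:
        mid = (vj[d] + wk[d]) / 2.0
        wk[d] = mid
        vj[d] = mid
    elif case == 3:
        if (wk[d] - vj[d]) < (wj[d] - vk[d]):
            vj[d] = box_k.max_point[d]
        else:
            wj[d] = box_k.min_point[d]
    elif case == 4:
        if (wk[d] - vj[d]) < (wj[d] - vk[d]):
            wk[d] = box_j.min_point[d]
        else:
            vk[d] = box_j.max_point[d]
    else:  # pragma: no cover - OverlapResult invariant
        raise ContractViolationError(f"unknown overlap case {case}")

    new_j = Hyperbox(min_point=vj, max_point=wj, class_id=box_j.class_id)
    new_k = Hyperbox(min_point=vk, max_point=wk, class_id=box_k.class_id)
    return new_j, new_k
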