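"""Patient-specific optimal C-arm angulation prediction.

The working projection for appendage closure should show the landing
zone edge-on with the maximal diameter at true length.  Both are
achieved when the beam direction lies in the cross-section plane and is
perpendicular to the maximal-diameter direction, i.e.

    v = +- normalize(plane_normal x dmax_direction)

The sign ambiguity (the two antiparallel beams give the same image up to
mirroring) is resolved toward the clinically favored access quadrant,
anchored at the midpoint of the recommended range RAO25/CAUD25.
Predictions are compared against periprocedurally used angulations with
a 10 degree rule: inter-reader variability of such predictions is of
order 7-8 degrees, so smaller deviations are not meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .carm import CArmPose, angular_difference, pose_from_direction, viewing_direction

__all__ = [
    "RECOMMENDED_RANGE",
    "AngulationResult",
    "optimal_angulation",
    "in_recommended_range",
    "classify_agreement",
    "confusion_matrix",
]

# clinically recommended working projection RAO20-30/CAUD20-30,
# as (alpha_lo, alpha_hi, beta_lo, beta_hi) closed intervals
RECOMMENDED_RANGE = (-30.0, -20.0, -30.0, -20.0)

# anchor for disambiguating the beam sign: center of the recommended range
_ANCHOR_POSE = CArmPose(alpha_deg=-25.0, beta_deg=-25.0)


@dataclass(frozen=True)
class AngulationResult:
    """Both beam-sign solutions, the preferred one, and comparisons."""

    solutions: tuple[CArmPose, CArmPose]
    chosen: CArmPose
    in_recommended: bool
    delta_to_reference_deg: float | None = None


def optimal_angulation(
    plane_normal,
    dmax_direction,
    reference: CArmPose | None = None,
    range_cfg=RECOMMENDED_RANGE,
) -> AngulationResult:
    """Predict the tangential C-arm pose for a landing-zone plane.

    ``plane_normal`` and ``dmax_direction`` must be unit vectors with the
    diameter direction lying in the plane.  Returns both antiparallel
    beam solutions; ``chosen`` is the one angularly closer to RAO25/CAUD25.
    When a reference pose (e.g., the angulation used in the procedure) is
    given, ``delta_to_reference_deg`` reports the beam angle to it.
    """
    n = np.asarray(plane_normal, dtype=float).reshape(3)
    d = np.asarray(dmax_direction, dtype=float).reshape(3)
    for name, vec in (("plane_normal", n), ("dmax_direction", d)):
        if abs(np.linalg.norm(vec) - 1.0) > 1e-6:
            raise ValueError(f"{name} must be a unit vector")
    if abs(n @ d) > 1e-6:
        raise ValueError("dmax_direction must lie in the plane (orthogonal to normal)")
    v = np.cross(n, d)
    v /= np.linalg.norm(v)
    poses = (pose_from_direction(v), pose_from_direction(-v))
    dists = [angular_difference(p, _ANCHOR_POSE) for p in poses]
    chosen = poses[int(np.argmin(dists))]
    delta = None if reference is None else angular_difference(chosen, reference)
    return AngulationResult(
        solutions=poses,
        chosen=chosen,
        in_recommended=in_recommended_range(chosen, range_cfg),
        delta_to_reference_deg=delta,
    )


def in_recommended_range(pose: CArmPose, range_cfg=RECOMMENDED_RANGE) -> bool:
    """Whether both angles fall in the recommended closed intervals."""
    try:
        a_lo, a_hi, b_lo, b_hi = (float(x) for x in range_cfg)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"malformed angulation range {range_cfg!r}") from exc
    if a_lo > a_hi or b_lo > b_hi:
        raise ValueError(f"malformed angulation range {range_cfg!r}")
    return a_lo <= pose.alpha_deg <= a_hi and b_lo <= pose.beta_deg <= b_hi


def classify_agreement(
    predicted: CArmPose, used: CArmPose, threshold_deg: float = 10.0
) -> str:
    """Label two angulations ``"agree"`` or ``"differ"`` by the beam angle.

    ``"differ"`` requires the 3D angle to exceed the threshold strictly;
    a deviation of exactly the threshold still counts as agreement.
    """
    return "differ" if angular_difference(predicted, used) > threshold_deg else "agree"


def confusion_matrix(cases) -> dict:
    """Cross-tabulate predicted vs. used membership in the recommended range.

    ``cases`` is a sequence of ``(predicted_in_recommended,
    used_in_recommended)`` booleans.  Returns raw counts and percentages
    of the total; ``percent_display`` is rounded to whole percent, the
    clinical reporting convention (rows: used angulation, columns:
    prediction; order recommended, different).
    """
    cases = list(cases)
    if not cases:
        raise ValueError("confusion matrix needs at least one case")
    counts = np.zeros((2, 2), dtype=int)
    for pred_rec, used_rec in cases:
        counts[0 if used_rec else 1, 0 if pred_rec else 1] += 1
    pct = 100.0 * counts / counts.sum()
    return {
        "counts": counts,
        "percent": pct,
        "percent_display": np.round(pct).astype(int),
        "n": counts.sum(),
    }


def format_confusion_matrix(cm: dict) -> str:
    """Render the matrix as the standard 2x2 clinical report table."""
    p = cm["percent_display"]
    lines = [
        "Clinically chosen      Prediction",
        "                       Recommended   Different >10°",
        f"Recommended            {p[0, 0]:>3d}%          {p[0, 1]:>3d}%",
        f"Different >10°         {p[1, 0]:>3d}%          {p[1, 1]:>3d}%",
    ]
    return "\n".join(lines)
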