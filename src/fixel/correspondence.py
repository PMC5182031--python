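"""Angular correspondence between subject and template fixels.

After a subject's FOD image is warped to template space and segmented,
each template-mask fixel is assigned the metric value of the subject
fixel in the same voxel with the closest orientation.  If no subject
fixel lies within ``max_angle`` (default 30 degrees) of the template
fixel -- e.g. a lesion has displaced or destroyed the fibre population --
the template fixel is assigned a value of 0.  Directions are axial, so
the angle between u and v is arccos(|u . v|), in [0, 90] degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FixelGrid

__all__ = ["MatchResult", "angular_distance", "match_fixels"]


@dataclass
class MatchResult:
    """Outcome of matching one template fixel against a subject voxel."""

    template_fixel_index: int
    subject_fixel_index: int | None     # None means zero-filled
    angle: float                        # degrees, in [0, 90]


def angular_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Axial angle between two unit directions, degrees in [0, 90]."""
    d = float(np.abs(np.dot(u, v)))
    return float(np.degrees(np.arccos(min(d, 1.0))))


def match_fixels(template: FixelGrid, subject: FixelGrid,
                 metric: str | list[str] = "fd",
                 max_angle: float = 30.0,
                 ) -> tuple[FixelGrid, list[MatchResult]]:
    """Transfer subject fixel metrics onto the template fixel mask.

    Per template fixel, the angularly closest subject fixel in the same
    voxel supplies the value if its angle is within ``max_angle``
    (boundary inclusive); otherwise the value is 0.  Ties between
    equidistant candidates are broken toward the larger metric value
    (the dominant lobe).  The returned grid has the template's geometry
    and directions; only values change.
    """
    if template.shape != subject.shape or not np.allclose(
            template.affine, subject.affine):
        raise ValueError("template and subject grids must share shape and "
                         "affine (warp the subject to template space first)")
    metrics = [metric] if isinstance(metric, str) else list(metric)
    for m in metrics:
        if m not in subject.values:
            raise KeyError(f"subject has no value '{m}'")
    primary = subject.values[metrics[0]]

    out = {m: np.zeros(template.n_fixels) for m in metrics}
    results: list[MatchResult] = []
    for vox in zip(*np.nonzero(template.counts)):
        to, tc = int(template.offsets[vox]), int(template.counts[vox])
        so, sc = int(subject.offsets[vox]), int(subject.counts[vox])
        tdirs = template.directions[to:to + tc]
        sdirs = subject.directions[so:so + sc]
        for ti in range(tc):
            tf = to + ti
            if sc == 0:
                results.append(MatchResult(tf, None, 90.0))
                continue
            cosa = np.abs(sdirs @ tdirs[ti])
            ang = np.degrees(np.arccos(np.clip(cosa, 0.0, 1.0)))
            best = np.flatnonzero(np.isclose(ang, ang.min(), atol=1e-9))
            if len(best) > 1:   # equidistant: favour the dominant lobe
                j = best[np.argmax(primary[so + best])]
            else:
                j = best[0]
            if ang[j] <= max_angle + 1e-12:
                for m in metrics:
                    out[m][tf] = subject.values[m][so + j]
                results.append(MatchResult(tf, so + int(j), float(ang[j])))
            else:
                results.append(MatchResult(tf, None, float(ang[j])))
    return template.with_values(**out), results
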