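"""Body segment parameters for whole-body COM estimation.

The body is modelled as ten rigid segments: trunk (with head and neck),
pelvis, left/right upper limb, thigh, lower leg and foot. Each segment is
located by proximal and distal marker landmarks; its COM sits a fixed
fraction of the way from the proximal to the distal landmark and carries a
fixed fraction of body mass.

Default fractions are adapted from de Leva's (1996) adjustment of the
Zatsiorsky-Seluyanov tables (male), with head+neck mass folded into the
trunk segment and the hand/forearm/upper-arm combined into one upper-limb
segment. The table is configurable so a population-specific one can be
swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ValidationError


@dataclass(frozen=True)
class Segment:
    """One rigid segment located by marker landmarks.

    ``com_fraction`` is measured from the proximal landmark centroid
    toward the distal landmark centroid, in [0, 1].
    """

    name: str
    mass_fraction: float
    proximal: tuple[str, ...]
    distal: tuple[str, ...]
    com_fraction: float


class SegmentSet:
    """A full-body set of segments whose mass fractions sum to 1."""

    def __init__(self, segments: list[Segment]):
        total = sum(s.mass_fraction for s in segments)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"segment mass fractions must sum to 1, got {total:.6f}"
            )
        for s in segments:
            if s.mass_fraction <= 0:
                raise ValidationError(f"segment {s.name}: mass fraction must be > 0")
            if not 0.0 <= s.com_fraction <= 1.0:
                raise ValidationError(f"segment {s.name}: COM fraction outside [0,1]")
        self.segments = list(segments)

    def __iter__(self):
        return iter(self.segments)

    def __len__(self):
        return len(self.segments)

    def markers_used(self) -> set[str]:
        out: set[str] = set()
        for s in self.segments:
            out.update(s.proximal)
            out.update(s.distal)
        return out


def default_segments() -> SegmentSet:
    """The default 10-segment table (de Leva-adjusted fractions)."""
    segs = [
        # head + neck (0.0694) folded into upper+middle trunk (0.1596+0.1633)
        Segment("trunk", 0.3923,
                ("LFHD", "RFHD", "LBHD", "RBHD"), ("LHIP", "RHIP"), 0.45),
        Segment("pelvis", 0.1117,
                ("LPSI", "RPSI"), ("LASI", "RASI"), 0.5),
        Segment("upper_limb_l", 0.0494, ("LSHO",), ("LWRA", "LWRB"), 0.45),
        Segment("upper_limb_r", 0.0494, ("RSHO",), ("RWRA", "RWRB"), 0.45),
        Segment("thigh_l", 0.1416, ("LHIP",), ("LKNE",), 0.4095),
        Segment("thigh_r", 0.1416, ("RHIP",), ("RKNE",), 0.4095),
        Segment("shank_l", 0.0433, ("LKNE",), ("LANK",), 0.4459),
        Segment("shank_r", 0.0433, ("RKNE",), ("RANK",), 0.4459),
        Segment("foot_l", 0.0137, ("LHEE",), ("LTOE",), 0.4415),
        Segment("foot_r", 0.0137, ("RHEE",), ("RTOE",), 0.4415),
    ]
    return SegmentSet(segs)


def shift_sensitivity(segments: SegmentSet, shifted_markers: set[str]) -> float:
    """Fraction of body mass that follows a rigid shift of a marker subset.

    If every marker of a subset is translated by d, the whole-body COM
    moves by ``shift_sensitivity(...) * d``: each segment contributes its
    mass fraction weighted by how much of its COM interpolation rests on
    shifted landmarks.
    """
    kappa = 0.0
    for s in segments:
        p_in = np.mean([m in shifted_markers for m in s.proximal])
        d_in = np.mean([m in shifted_markers for m in s.distal])
        w = (1.0 - s.com_fraction) * p_in + s.com_fraction * d_in
        kappa += s.mass_fraction * w
    return float(kappa)
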