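"""En-face lesion overlap scoring.

The lesion appears as an IR-hyporeflective patch and, on en-face OCT
reconstructions, as an altered footprint at the photoreceptor ellipsoid
zone (EZ) and at the outer plexiform layer / Henle fiber junction (OPL).
Because Henle fibers run obliquely away from the fovea, the OPL footprint
is laterally displaced relative to the photoreceptor lesion, while the EZ
footprint co-localizes with the IR lesion.  The overlap of each en-face
footprint with the IR lesion is measured with the Sørensen–Dice score
2|A∩B| / (|A|+|B|); masks are taken literally, with no morphological
cleanup.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .cohort_stats import InsufficientEyesError, paired_t_test

PAIRS = ("EZ_vs_IR", "OPL_vs_IR")


@dataclass(frozen=True)
class DiceRecord:
    """Sørensen–Dice overlap of one en-face lesion footprint with the IR lesion."""

    eye_id: str
    pair: str
    dice: float
    area_a: int
    area_b: int
    area_intersection: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.dice <= 1.0):
            raise ValueError(f"dice out of [0,1]: {self.dice}")


def dice_score(mask_a: np.ndarray, mask_b: np.ndarray,
               eye_id: str = "", pair: str = "EZ_vs_IR") -> DiceRecord:
    """Sørensen–Dice score of two co-registered binary masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    area_a = int(a.sum())
    area_b = int(b.sum())
    if area_a == 0 and area_b == 0:
        raise ValueError("both masks empty: Dice undefined")
    inter = int((a & b).sum())
    return DiceRecord(eye_id=eye_id, pair=pair, dice=2.0 * inter / (area_a + area_b),
                      area_a=area_a, area_b=area_b, area_intersection=inter)


def enface_overlap_analysis(ir_lesion: np.ndarray, ez_lesion: np.ndarray,
                            opl_lesion: np.ndarray, eye_id: str) -> list[DiceRecord]:
    """Dice of the EZ and OPL en-face lesion footprints against the IR lesion."""
    return [dice_score(ez_lesion, ir_lesion, eye_id=eye_id, pair="EZ_vs_IR"),
            dice_score(opl_lesion, ir_lesion, eye_id=eye_id, pair="OPL_vs_IR")]


@dataclass(frozen=True)
class DiceComparison:
    """Cohort comparison of EZ-vs-IR against OPL-vs-IR Dice scores."""

    n_eyes: int
    mean_dice_ez: float
    sd_dice_ez: float
    mean_dice_opl: float
    sd_dice_opl: float
    t_stat: float
    p_value: float


def compare_dice_pairs(records: Iterable[DiceRecord]) -> DiceComparison:
    """Paired t-test of EZ-vs-IR against OPL-vs-IR Dice across eyes."""
    by_eye: dict[str, dict[str, float]] = {}
    for r in records:
        by_eye.setdefault(r.eye_id, {})[r.pair] = r.dice
    eyes = sorted(e for e, v in by_eye.items() if set(v) >= set(PAIRS))
    if len(eyes) < 2:
        raise InsufficientEyesError(f"insufficient eyes with both Dice pairs: {len(eyes)}")
    ez = np.array([by_eye[e]["EZ_vs_IR"] for e in eyes])
    opl = np.array([by_eye[e]["OPL_vs_IR"] for e in eyes])
    t, p = paired_t_test(ez, opl)
    return DiceComparison(
        n_eyes=len(eyes),
        mean_dice_ez=float(ez.mean()), sd_dice_ez=float(ez.std(ddof=1)),
        mean_dice_opl=float(opl.mean()), sd_dice_opl=float(opl.std(ddof=1)),
        t_stat=t, p_value=p)
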