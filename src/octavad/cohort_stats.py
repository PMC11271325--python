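"""Cohort-level statistics for intra-eye perfusion comparisons.

Each eye contributes one VAD value per (slab, region).  The cohort question
is whether lesion VAD differs from control VAD within the same eyes, so the
test is a two-sided paired-samples t-test of vad(AMN) against
vad(comparator) across eyes, with Bonferroni correction over the family of
comparisons (default m = 10: five slabs x two comparators).  Effect size is
reported as the percent reduction of the cohort mean lesion VAD relative to
the cohort mean control VAD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io_formats import VAD_LAYERS
from .vad_quant import REGION_NAMES, VADRecord

COMPARATORS = ("ATC", "RS")

#: Default Bonferroni family size: 5 slabs x 2 comparators.
DEFAULT_M_COMPARISONS = 10


class DegenerateDifferencesError(ValueError):
    """All paired differences are identical; the t statistic is undefined."""


class InsufficientEyesError(ValueError):
    """Fewer than two complete eyes; no paired test possible."""


@dataclass(frozen=True)
class CohortResult:
    """Paired lesion-vs-control comparison for one slab and one comparator."""

    layer: str
    comparator: str
    n_eyes: int
    mean_vad_amn: float
    mean_vad_comparator: float
    percent_reduction: float
    t_stat: float
    p_raw: float
    p_corrected: float
    m_comparisons: int

    def __post_init__(self) -> None:
        if self.n_eyes < 2:
            raise InsufficientEyesError(f"n_eyes={self.n_eyes}")
        if not (0.0 <= self.p_raw <= 1.0):
            raise ValueError(f"p_raw out of [0,1]: {self.p_raw}")


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired-samples t-test.

    d = a - b, t = mean(d) / (sd(d)/sqrt(n)) with the n-1 denominator in
    sd, df = n - 1.  Raises on degenerate inputs instead of returning a
    misleading p of 0 or nan.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise InsufficientEyesError(f"paired t-test needs n >= 2, got n={n}")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise DegenerateDifferencesError("all paired differences equal; t undefined")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p_raw)."""
    if not (0.0 <= p_raw <= 1.0):
        raise ValueError(f"p_raw out of [0,1]: {p_raw}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return min(1.0, m * p_raw)


def percent_reduction(mean_lesion: float, mean_control: float) -> float:
    """Percent reduction of the lesion mean relative to the control mean."""
    if mean_control <= 0:
        raise ValueError("percent reduction undefined for non-positive control mean")
    return 100.0 * (mean_control - mean_lesion) / mean_control


def _vad_by_eye(records: Iterable[VADRecord]) -> dict[str, dict[tuple[str, str], float]]:
    table: dict[str, dict[tuple[str, str], float]] = {}
    for r in records:
        table.setdefault(r.eye_id, {})[(r.layer, r.region)] = r.vad
    expected = {(l, rg) for l in VAD_LAYERS for rg in REGION_NAMES}
    for eye, vals in table.items():
        missing = expected - set(vals)
        if missing:
            raise ValueError(f"incomplete eye {eye}: missing {sorted(missing)}")
    return table


def summarize_cohort(records: Iterable[VADRecord],
                     m_comparisons: int = DEFAULT_M_COMPARISONS,
                     per_eye_reduction: bool = False) -> list[CohortResult]:
    """Aggregate per-eye VAD records into 10 paired cohort comparisons.

    ``per_eye_reduction`` switches the effect-size summary from the
    reduction of cohort means (default) to the mean of per-eye reductions.
    """
    table = _vad_by_eye(records)
    eyes = sorted(table)
    if len(eyes) < 2:
        raise InsufficientEyesError(f"insufficient eyes: {len(eyes)}")
    if len(eyes) == 2:
        warnings.warn("only 2 eyes: paired t-test has a single degree of freedom",
                      stacklevel=2)
    results: list[CohortResult] = []
    for layer in VAD_LAYERS:
        for comp in COMPARATORS:
            amn = [table[e][(layer, "AMN")] for e in eyes]
            ctl = [table[e][(layer, comp)] for e in eyes]
            t, p = paired_t_test(amn, ctl)
            mean_amn = float(np.mean(amn))
            mean_ctl = float(np.mean(ctl))
            if per_eye_reduction:
                red = float(np.mean([percent_reduction(a, c) for a, c in zip(amn, ctl)]))
            else:
                red = percent_reduction(mean_amn, mean_ctl)
            results.append(CohortResult(
                layer=layer, comparator=comp, n_eyes=len(eyes),
                mean_vad_amn=mean_amn, mean_vad_comparator=mean_ctl,
                percent_reduction=red, t_stat=t, p_raw=p,
                p_corrected=bonferroni(p, m_comparisons),
                m_comparisons=m_comparisons))
    return results
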