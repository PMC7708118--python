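"""Bland–Altman limits of agreement for repeated measurements."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Tuple

import numpy as np


@dataclass(frozen=True)
class AgreementResult:
    """Mean difference, SD of differences, and 95% limits of agreement."""

    mean_diff: float
    sd_diff: float
    loa_upper: float
    loa_lower: float
    n: int


def bland_altman(pairs: Iterable[Tuple[float, float]]) -> AgreementResult:
    """Limits of agreement between two raters / occasions.

    ``pairs`` are (measurement_1, measurement_2) per case. Differences are
    ``m1 − m2``; the SD uses the n−1 denominator and the limits are
    ``mean ± 1.96·SD``.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 measurement pairs")
    d = arr[:, 0] - arr[:, 1]
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(mean_diff=mean, sd_diff=sd,
                           loa_upper=mean + 1.96 * sd,
                           loa_lower=mean - 1.96 * sd,
                           n=len(d))


def limits_of_agreement(mean_diff: float, sd_diff: float) -> tuple:
    """Closed-form LoA from a printed mean difference and SD."""
    return mean_diff + 1.96 * sd_diff, mean_diff - 1.96 * sd_diff
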