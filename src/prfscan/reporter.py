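"""Quantification of -1 PRF from dual-reporter measurements.

Two reporter designs are supported. In the dual-luciferase construct the
firefly ORF lies downstream of the slippery sequence in the zero frame, so
a -1 slip introduces a premature stop and *diminishes* firefly signal;
Renilla, upstream, normalizes transfection and lysate amount. In the
dual-GST construct the second GST is translated only on a -1 slip, so the
upper (dual) band fraction reads out the frameshift product directly.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats

from .model import GstBands, LuciferasePair


def luciferase_readout(
    pairs: Sequence[LuciferasePair], test: str, control: str
) -> float:
    """Relative Renilla-normalized firefly activity, test over control.

    Each replicate is normalized as firefly/renilla (per-replicate
    normalization, standard dual-luciferase practice); the readout is
    mean(test ratios) / mean(control ratios). Lower readout means more
    frameshifting.
    """
    ratios: dict[str, list[float]] = {test: [], control: []}
    for p in pairs:
        if p.condition in ratios:
            ratios[p.condition].append(p.firefly / p.renilla)
    for condition in (test, control):
        if not ratios[condition]:
            raise ValueError(f"no replicates for condition {condition!r}")
    return float(np.mean(ratios[test]) / np.mean(ratios[control]))


def gst_prf_percent(bands: GstBands) -> float:
    """Percent -1 PRF: 100 * dual / (dual + single) band intensity."""
    return 100.0 * bands.dual_intensity / (
        bands.dual_intensity + bands.single_intensity
    )


def compare_two_groups(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Unpaired two-tailed Student's t test (pooled variance).

    Returns (t statistic, two-sided p) with n_x + n_y - 2 degrees of
    freedom. Both groups need at least two replicates and the pooled
    variance must be positive.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 replicates")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if float(x.mean()) == float(y.mean()):
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)
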