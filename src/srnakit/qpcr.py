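"""qPCR validation arithmetic: relative expression vs. U6 and a t-test."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import ttest_ind


@dataclass(frozen=True)
class QPCRMeasurement:
    sample: str
    strain: str
    ct_mirna: float
    ct_u6: float

    @property
    def relative_expression(self) -> float:
        return relative_expression(self.ct_mirna, self.ct_u6)


def relative_expression(ct_mirna: float, ct_u6: float) -> float:
    """2^-(CT_miRNA - CT_U6); invariant to a common shift of both CTs."""
    if not (math.isfinite(ct_mirna) and math.isfinite(ct_u6)):
        raise ValueError("CT values must be finite")
    return 2.0 ** -(ct_mirna - ct_u6)


def compare_strains(group_a: Sequence[float], group_b: Sequence[float],
                    equal_var: bool = True):
    """Two-sided two-sample t-test on relative expressions.

    Returns (t, p, significant at 0.05, significant at 0.01).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = ttest_ind(group_a, group_b, equal_var=equal_var)
    if math.isnan(p):  # identical constant groups
        t, p = 0.0, 1.0
    return float(t), float(p), bool(p < 0.05), bool(p < 0.01)
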