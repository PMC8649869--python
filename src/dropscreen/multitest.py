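"""Benjamini–Hochberg multiple-testing adjustment (shared by DE and enrichment)."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError


def bh_adjust(pvalues) -> np.ndarray:
    """Step-up BH adjusted p-values with monotonicity enforced, clipped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
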