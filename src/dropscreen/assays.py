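"""Closed-form bench-assay quantifications.

qPCR fold change by the comparative Ct method (2^-ddCt, assuming perfect
per-cycle doubling), ChIP-qPCR fold enrichment (IP/input normalized to the
IgG isotype control), and ellipsoid tumor volume from caliper length and
width (volume = length x width^2 x 0.52).
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .errors import ValidationError

TUMOR_SHAPE_FACTOR = 0.52


def ddct_fold(
    target_ct_sample: float,
    ref_ct_sample: float,
    target_ct_control: float,
    ref_ct_control: float,
) -> float:
    """Fold change by the comparative Ct method.

    ``fold = 2**(-[(target_s - ref_s) - (target_c - ref_c)])``; the
    reference gene (e.g. RPL19) normalizes loading in both conditions.
    """
    cts = (target_ct_sample, ref_ct_sample, target_ct_control, ref_ct_control)
    if not all(math.isfinite(c) for c in cts):
        raise ValidationError("all Ct values must be finite")
    ddct = (target_ct_sample - ref_ct_sample) - (target_ct_control - ref_ct_control)
    return 2.0 ** (-ddct)


def chip_fold_enrichment(ip_frac_input: float, igg_frac_input: float) -> float:
    """ChIP fold enrichment: (IP/input) over the IgG isotype (IgG/input)."""
    if not (ip_frac_input > 0 and math.isfinite(ip_frac_input)):
        raise ValidationError("IP/input ratio must be positive and finite")
    if not (igg_frac_input > 0 and math.isfinite(igg_frac_input)):
        raise ValidationError("IgG/input control ratio must be positive and finite")
    return ip_frac_input / igg_frac_input


def tumor_volume(length: float, width: float) -> float:
    """Tumor volume in mm^3 from caliper length and width (mm)."""
    length = float(length)
    width = float(width)
    if not (width > 0 and length > 0):
        raise ValidationError("length and width must be positive")
    if length < width:
        warnings.warn("length < width: caliper axes may be swapped", stacklevel=2)
    return length * width ** 2 * TUMOR_SHAPE_FACTOR


def tumor_volumes(lengths, widths) -> np.ndarray:
    """Vectorized tumor volume over paired caliper measurements."""
    lengths = np.asarray(lengths, dtype=float)
    widths = np.asarray(widths, dtype=float)
    if lengths.shape != widths.shape:
        raise ValidationError("length and width arrays must align")
    if (lengths <= 0).any() or (widths <= 0).any():
        raise ValidationError("length and width must be positive")
    if (lengths < widths).any():
        warnings.warn("some length < width: caliper axes may be swapped", stacklevel=2)
    return lengths * widths ** 2 * TUMOR_SHAPE_FACTOR
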