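"""The eight red-edge and broadband spectral indices used as GRU features.

All formulas are applied per pixel per date, exactly as specified:

    REP        = 700 + 40 * (((B7 - B4)/2 - B5) / (B6 - B5))
    CIred_edge = B7/B5 - 1
    MSR        = (B6 - B1) / (B5 - B1)
    MCARI      = ((B5 - B4) - 0.2*(B5 - B3)) * (B5/B4)
    NDVI       = (B8 - B4) / (B8 + B4)
    RDVI       = (B7 - B4) / (B7 + B4)
    NDRE1      = (B6 - B5) / (B6 + B5)
    NDRE2      = (B7 - B5) / (B7 + B5)

Two of these are implemented verbatim even though they differ from the
literature forms bearing the same names: RDVI here is a plain normalized
difference (the canonical renormalized difference index divides by
sqrt(B7+B4)), and MSR here involves the coastal-aerosol band B1. Fidelity to
the feature set as defined wins over nomenclature; see docs/methods.md.

Cells where a formula's denominator vanishes, or which the QA band flags as
cloud, are marked invalid — never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_scene import BANDS, ReflectanceStack

#: Index identifiers in storage order; this order is the GRU feature order
#: (input_size = 8) and must not change between training and prediction.
INDICES = ("REP", "CIred_edge", "MSR", "MCARI", "NDVI", "RDVI", "NDRE1", "NDRE2")


class MissingBandError(ValueError):
    """A band required by an index formula is absent from the stack."""


@dataclass
class IndexStack:
    """Index values shaped (date, index, row, col) plus per-cell validity.

    ``valid`` is broadcast over the index axis from QA plus per-formula
    denominator checks; invalid cells hold NaN and must be gap-filled (or
    dropped) before entering the classifier.
    """

    values: np.ndarray
    valid: np.ndarray
    dates: np.ndarray

    @property
    def n_dates(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[2], self.values.shape[3]

    def index(self, name: str) -> np.ndarray:
        return self.values[:, INDICES.index(name)]


def _safe_divide(num: np.ndarray, den: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ok = den != 0
    out = np.full(np.broadcast_shapes(num.shape, den.shape), np.nan)
    np.divide(num, den, out=out, where=ok)
    return out, ok


def compute_indices(stack: ReflectanceStack) -> IndexStack:
    """Compute all eight indices for every (date, pixel) of a reflectance stack.

    Returns an :class:`IndexStack` whose validity flag is False wherever the
    observation is cloud-flagged or an index denominator is exactly zero.
    """
    if stack.values.shape[1] != len(BANDS):
        raise MissingBandError(
            f"stack carries {stack.values.shape[1]} bands, need {len(BANDS)}: {BANDS}"
        )
    b = {name: stack.band(name) for name in BANDS}

    n_dates = stack.n_dates
    n_rows, n_cols = stack.shape
    values = np.empty((n_dates, len(INDICES), n_rows, n_cols))
    valid = np.empty((n_dates, len(INDICES), n_rows, n_cols), dtype=bool)

    rep, ok = _safe_divide((b["B7"] - b["B4"]) / 2.0 - b["B5"], b["B6"] - b["B5"])
    values[:, 0], valid[:, 0] = 700.0 + 40.0 * rep, ok
    ci, ok = _safe_divide(b["B7"], b["B5"])
    values[:, 1], valid[:, 1] = ci - 1.0, ok
    values[:, 2], valid[:, 2] = _safe_divide(b["B6"] - b["B1"], b["B5"] - b["B1"])
    ratio, ok = _safe_divide(b["B5"], b["B4"])
    values[:, 3] = ((b["B5"] - b["B4"]) - 0.2 * (b["B5"] - b["B3"])) * ratio
    valid[:, 3] = ok
    values[:, 4], valid[:, 4] = _safe_divide(b["B8"] - b["B4"], b["B8"] + b["B4"])
    values[:, 5], valid[:, 5] = _safe_divide(b["B7"] - b["B4"], b["B7"] + b["B4"])
    values[:, 6], valid[:, 6] = _safe_divide(b["B6"] - b["B5"], b["B6"] + b["B5"])
    values[:, 7], valid[:, 7] = _safe_divide(b["B7"] - b["B5"], b["B7"] + b["B5"])

    valid &= stack.qa[:, None, :, :]
    values[~valid] = np.nan
    return IndexStack(values=values, valid=valid, dates=stack.dates.copy())
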