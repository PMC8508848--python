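"""Numeric helpers for the wet-lab assay arm.

Covers mass/molar concentration conversion for 17beta-estradiol ELISA
readouts, mean +/- SD summaries, and relative qPCR quantification by the
double-delta Ct method.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np

#: standard molar mass of 17beta-estradiol (C18H24O2), g/mol
ESTRADIOL_MOLAR_MASS = 272.38


def pg_per_ml_to_nm(conc_pg_per_ml: float, molar_mass: float = ESTRADIOL_MOLAR_MASS) -> float:
    """Convert pg/mL to nmol/L.

    1 nM of a compound with molar mass M g/mol is M ng/L = M pg/mL, so the
    conversion is a plain division. Rounding is left to display.
    """
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    if conc_pg_per_ml < 0:
        raise ValueError("concentration must be non-negative")
    return conc_pg_per_ml / molar_mass


def nm_to_pg_per_ml(conc_nm: float, molar_mass: float = ESTRADIOL_MOLAR_MASS) -> float:
    """Inverse of :func:`pg_per_ml_to_nm`."""
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    if conc_nm < 0:
        raise ValueError("concentration must be non-negative")
    return conc_nm * molar_mass


def round_display(value: float, ndigits: int = 2) -> float:
    """Half-up rounding for display (banker's rounding would drift from
    printed tables)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CtRecord:
    """Cycle thresholds for a target and its endogenous control in one sample."""

    sample: str
    target_ct: float
    reference_ct: float

    def __post_init__(self) -> None:
        for name in ("target_ct", "reference_ct"):
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"{self.sample}: {name} must be positive")

    @property
    def delta_ct(self) -> float:
        return self.target_ct - self.reference_ct


def ddct_fold_change(sample: CtRecord, control: CtRecord) -> float:
    """Relative expression by the double-delta Ct method: 2**(-ddCt),
    where ddCt = (sample dCt) - (control dCt)."""
    ddct = sample.delta_ct - control.delta_ct
    return 2.0 ** (-ddct)


def summarize(values: Sequence[float]) -> tuple[float, Optional[float], int]:
    """(mean, sample SD, n); SD is None for a single observation."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 1:
        raise ValueError("need at least one value")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else None
    return float(np.mean(arr)), sd, int(arr.size)
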