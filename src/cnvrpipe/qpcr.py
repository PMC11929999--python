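"""Relative copy number from qPCR Ct triplicates (comparative Ct method).

The copy number of a target locus relative to a copy-number-stable
reference locus is CN = 2 * 2^(-dCt) with dCt = mean Ct(target) - mean
Ct(reference); dCt = 0 is calibrated to the diploid state, and each unit of
dCt corresponds to an exact halving of relative quantity.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Sequence

__all__ = ["QpcrMeasurement", "CopyNumberEstimate", "estimate_copy_number", "concordance"]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class QpcrMeasurement:
    sample_id: str
    assay_id: str
    ct_target: tuple[float, float, float]
    ct_reference: tuple[float, float, float]
    predicted_type: str | None = None  # loss | gain | None

    def __post_init__(self) -> None:
        for name, trip in (("target", self.ct_target), ("reference", self.ct_reference)):
            if len(trip) != 3 or any(v is None for v in trip):
                raise ValueError(
                    f"{self.sample_id}/{self.assay_id}: incomplete {name} triplicate"
                )
            if any(not math.isfinite(v) or v <= 0 for v in trip):
                raise ValueError(
                    f"{self.sample_id}/{self.assay_id}: Ct values must be finite and positive"
                )
        if self.predicted_type not in (None, "loss", "gain"):
            raise ValueError(f"bad predicted_type {self.predicted_type!r}")


@dataclass(frozen=True)
class CopyNumberEstimate:
    measurement: QpcrMeasurement
    delta_ct: float
    copy_number: float
    sd: float
    reliable: bool


def estimate_copy_number(
    m: QpcrMeasurement, max_ct_sd: float = 0.5
) -> CopyNumberEstimate:
    """CN = 2 * 2^(-dCt) with quadrature-propagated uncertainty.

    The dCt standard error combines the two triplicates' standard errors in
    quadrature; the CN standard deviation follows by the delta method
    (sd_CN = CN * ln2 * se_dCt).  A measurement whose target or reference
    triplicate has sample SD > ``max_ct_sd`` cycles is flagged unreliable.
    """
    mt = statistics.mean(m.ct_target)
    mr = statistics.mean(m.ct_reference)
    sd_t = statistics.stdev(m.ct_target)
    sd_r = statistics.stdev(m.ct_reference)
    dct = mt - mr
    cn = 2.0 * 2.0 ** (-dct)
    se_dct = math.sqrt(sd_t**2 / 3 + sd_r**2 / 3)
    sd_cn = cn * LN2 * se_dct
    reliable = sd_t <= max_ct_sd and sd_r <= max_ct_sd
    return CopyNumberEstimate(m, dct, cn, sd_cn, reliable)


def concordance(
    estimates: Sequence[CopyNumberEstimate],
    loss_max: float = 1.5,
    gain_min: float = 2.5,
) -> dict[tuple[str, str], str]:
    """Per (sample, assay) verdict against the predicted CNV type.

    A predicted loss is confirmed iff CN < ``loss_max``; a predicted gain
    iff CN > ``gain_min``; anything else is ``not_confirmed``.  Unreliable
    measurements are excluded from verdicts (``unreliable``).
    """
    verdicts: dict[tuple[str, str], str] = {}
    for e in estimates:
        key = (e.measurement.sample_id, e.measurement.assay_id)
        if e.measurement.predicted_type is None:
            continue
        if not e.reliable:
            verdicts[key] = "unreliable"
        elif e.measurement.predicted_type == "loss":
            verdicts[key] = "confirmed" if e.copy_number < loss_max else "not_confirmed"
        else:
            verdicts[key] = "confirmed" if e.copy_number > gain_min else "not_confirmed"
    return verdicts
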