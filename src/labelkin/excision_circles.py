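"""TREC content and KREC replication-history calculations from qPCR Ct
values.

Two printed formulas drive the KREC assay: the division count
``(Ct_signal - Ct_coding)_sample - (Ct_signal - Ct_coding)_control`` and
the coding-joint frequency
``2^[(Ct_albumin - Ct_coding)_sample - (Ct_albumin - Ct_coding)_control] x 100%``,
both referenced to the U698-DB01 control line. Out-of-range results
(negative divisions, fractions above 100%) are flagged, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "QpcrMeasurement",
    "FlaggedValue",
    "replication_history",
    "coding_joint_fraction",
    "trec_content",
    "cells_from_dna",
    "DNA_PG_PER_CELL",
]

#: Genomic DNA content of one diploid cell, picograms.
DNA_PG_PER_CELL = 6.6


@dataclass(frozen=True)
class QpcrMeasurement:
    """Mean Ct values (duplicate qPCR measurements) for one sample.

    Any of the three targets may be absent (None); operations that need
    a missing Ct raise. ``is_control_line`` marks the U698-DB01
    reference used for technical correction.
    """

    ct_signal_joint: float | None = None
    ct_coding_joint: float | None = None
    ct_albumin: float | None = None
    is_control_line: bool = False

    def __post_init__(self) -> None:
        for name in ("ct_signal_joint", "ct_coding_joint", "ct_albumin"):
            ct = getattr(self, name)
            if ct is not None and not (0.0 < ct < 45.0):
                raise ValueError(f"{name}={ct} outside plausible Ct range (0, 45)")


class FlaggedValue(NamedTuple):
    value: float
    flagged: bool


def _require(m: QpcrMeasurement, *targets: str) -> None:
    for t in targets:
        if getattr(m, t) is None:
            raise ValueError(f"missing Ct value {t!r}")


def replication_history(
    sample: QpcrMeasurement, control: QpcrMeasurement
) -> FlaggedValue:
    """Number of divisions since the excision circle was formed.

    Signal joints sit on the (undiluted) episome while coding joints
    double with each division, so the sample-vs-control difference of
    (Ct_signal - Ct_coding) counts doublings. Negative results (assay
    noise) are returned flagged.
    """
    _require(sample, "ct_signal_joint", "ct_coding_joint")
    _require(control, "ct_signal_joint", "ct_coding_joint")
    d = (sample.ct_signal_joint - sample.ct_coding_joint) - (
        control.ct_signal_joint - control.ct_coding_joint
    )
    return FlaggedValue(d, d < 0)


def coding_joint_fraction(
    sample: QpcrMeasurement, control: QpcrMeasurement
) -> FlaggedValue:
    """Percentage of cells carrying a coding joint.

    ``2^(delta_sample - delta_control) x 100`` with
    ``delta = Ct_albumin - Ct_coding``. Values above 100% (plausible
    assay noise) are flagged.
    """
    _require(sample, "ct_albumin", "ct_coding_joint")
    _require(control, "ct_albumin", "ct_coding_joint")
    exponent = (sample.ct_albumin - sample.ct_coding_joint) - (
        control.ct_albumin - control.ct_coding_joint
    )
    pct = 2.0**exponent * 100.0
    return FlaggedValue(pct, pct > 100.0)


def trec_content(trec_copies: float, cell_equivalents: float) -> FlaggedValue:
    """TRECs per cell: copy number divided by input cell equivalents.

    Flagged when >= 1 per cell (upper plausibility bound).
    """
    if trec_copies < 0:
        raise ValueError("TREC copy number must be >= 0")
    if cell_equivalents <= 0:
        raise ValueError("cell equivalents must be > 0")
    ratio = trec_copies / cell_equivalents
    return FlaggedValue(ratio, ratio >= 1.0)


def cells_from_dna(dna_pg: float, pg_per_cell: float = DNA_PG_PER_CELL) -> float:
    """Cell equivalents in a DNA input, assuming diploid genomes."""
    if dna_pg < 0:
        raise ValueError("DNA input must be >= 0")
    return dna_pg / pg_per_cell
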