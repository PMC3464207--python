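"""RT-PCR-style inclusion rates (PSI) and the 1.5-fold differential criterion."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["inclusion_rate", "differential_psi", "psi_table"]


def inclusion_rate(inclusion_band: float, skipping_band: float) -> float:
    """psi = inclusion / (inclusion + skipping); NaN when both bands are 0."""
    if inclusion_band < 0 or skipping_band < 0:
        raise ValueError("band intensities must be non-negative")
    total = inclusion_band + skipping_band
    if total == 0:
        return float("nan")
    return inclusion_band / total


def differential_psi(psi_a: float, psi_b: float, fold: float = 1.5) -> bool:
    """True when the inclusion rates differ at least ``fold``-fold (inclusive).

    One rate of exactly 0 against a positive rate counts as differential
    (complete skipping); two zero rates are undefined and raise.
    """
    if math.isnan(psi_a) or math.isnan(psi_b):
        raise ValueError("psi undefined")
    lo, hi = sorted((psi_a, psi_b))
    if hi == 0:
        raise ValueError("both inclusion rates are 0; fold change undefined")
    if lo == 0:
        return True
    # inclusive boundary, robust to float rounding at exactly `fold`
    return hi / lo >= fold * (1.0 - 1e-12)


def psi_table(bands: pd.DataFrame, fold: float = 1.5) -> pd.DataFrame:
    """Per-event mean psi per genotype and the fold-change call.

    Expects the long-form band table (columns ``event_id``, ``genotype``,
    ``inclusion_band``, ``skipping_band``); replicate lanes are aggregated as
    the mean psi per genotype before the fold comparison.
    """
    work = bands.copy()
    work["psi"] = [
        inclusion_rate(i, s) for i, s in zip(work["inclusion_band"], work["skipping_band"])
    ]
    agg = work.groupby(["event_id", "genotype"])["psi"].mean().unstack("genotype")
    out = pd.DataFrame(
        {
            "event_id": agg.index,
            "psi_control": agg["control"].to_numpy(),
            "psi_mutant": agg["mutant"].to_numpy(),
        }
    ).reset_index(drop=True)
    out["is_differential"] = [
        differential_psi(a, b, fold=fold) for a, b in zip(out["psi_control"], out["psi_mutant"])
    ]
    return out
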