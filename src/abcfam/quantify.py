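"""Downstream quantification formulas.

TPM normalization and per-gene Z-transform for expression heatmaps,
Schneider-Orelli control-corrected mortality for injection bioassays, and
the delta-delta-Ct method for relative qPCR quantification.  Read
mapping, counting and annotation are upstream of this module: raw counts
and effective gene lengths are caller-supplied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class MortalityRecord:
    """Observed mortality percentages in treated and control arms."""

    treated_pct: float
    control_pct: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.treated_pct <= 100.0):
            raise ValidationError("treated_pct outside [0, 100]")
        if not (0.0 <= self.control_pct < 100.0):
            raise ValidationError("control_pct must be in [0, 100)")


@dataclass(frozen=True)
class CtRecord:
    """qPCR cycle thresholds for target and reference gene, both conditions."""

    target_treated: float
    reference_treated: float
    target_control: float
    reference_control: float

    def __post_init__(self) -> None:
        for v in (
            self.target_treated,
            self.reference_treated,
            self.target_control,
            self.reference_control,
        ):
            if not math.isfinite(v) or v <= 0:
                raise ValidationError("Ct values must be finite and > 0")


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million normalization (genes x samples).

    Per sample: rate_g = count_g / (length_g / 1000); TPM_g =
    rate_g / sum(rates) * 1e6, so every column sums to one million.
    ``lengths`` are effective gene lengths in bases, indexed like the
    count rows.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValidationError(f"missing gene lengths for {missing}")
    if (lengths <= 0).any():
        raise ValidationError("gene lengths must be > 0")
    if (counts.to_numpy() < 0).any():
        raise ValidationError("counts must be non-negative")
    rates = counts.div(lengths / 1000.0, axis=0)
    totals = rates.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(f"all-zero sample(s): {zero.index.tolist()}")
    return rates.div(totals, axis=1) * 1e6


def zscore_by_gene(tpm_matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene Z-transform across samples ((x - mean) / sd, sd with ddof=1).

    Genes with zero variance get all-zero rows with a warning.
    """
    if tpm_matrix.shape[1] < 2:
        raise ValidationError("Z-transform needs at least 2 samples")
    means = tpm_matrix.mean(axis=1)
    sds = tpm_matrix.std(axis=1, ddof=1)
    constant = sds == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s) set to zero in Z-transform"
        )
    sds_safe = sds.replace(0.0, np.nan)
    z = tpm_matrix.sub(means, axis=0).div(sds_safe, axis=0)
    return z.fillna(0.0)


def schneider_orelli(rec: MortalityRecord | None = None, *,
                     treated_pct: float | None = None,
                     control_pct: float | None = None) -> float:
    """Control-corrected mortality: 100 * (treated - control) / (100 - control).

    Negative corrected mortality (treated below control) is clipped to 0
    with a warning.
    """
    if rec is None:
        rec = MortalityRecord(treated_pct=treated_pct, control_pct=control_pct)
    corrected = 100.0 * (rec.treated_pct - rec.control_pct) / (100.0 - rec.control_pct)
    if corrected < 0:
        warnings.warn("treated mortality below control; clipping corrected value to 0")
        return 0.0
    return corrected


@dataclass(frozen=True)
class DdctResult:
    delta_delta_ct: float
    fold_change: float
    knockdown_pct: Optional[float]  # only when fold < 1


def ddct(rec: CtRecord, efficiency: float = 2.0) -> DdctResult:
    """Relative expression by the delta-delta-Ct method.

    dCt = Ct_target - Ct_reference per condition; ddCt = dCt_treated -
    dCt_control; fold = efficiency**(-ddCt).  With the default perfect
    amplification efficiency of 2 this is the plain 2^-ddCt; per-assay
    efficiencies estimated from dilution series may be supplied instead.
    Knockdown percent (100 * (1 - fold)) is reported when fold < 1.
    """
    if efficiency <= 1.0:
        raise ValidationError("amplification efficiency must be > 1")
    d_treated = rec.target_treated - rec.reference_treated
    d_control = rec.target_control - rec.reference_control
    dd = d_treated - d_control
    fold = float(efficiency ** (-dd))
    knockdown = 100.0 * (1.0 - fold) if fold < 1.0 else None
    return DdctResult(delta_delta_ct=float(dd), fold_change=fold, knockdown_pct=knockdown)
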