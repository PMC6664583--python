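"""Relative quantification of qPCR data by the comparative-Ct (ΔΔCt) method.

Fold change is ``2^(−ΔΔCt)`` with ΔCt = mean Ct(target) − mean Ct(reference
gene, default GAPDH) within each condition and ΔΔCt = ΔCt(test) −
ΔCt(calibrator).  Amplification efficiency is fixed at 2 per cycle — the
classical assumption; no standard-curve efficiency correction is applied.

Replicate spread is propagated from Ct-level SEM of the test condition to the
fold scale by the delta method: SEM(fold) = fold · ln2 · SEM(ΔCt).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ValidationError

DEFAULT_REFERENCE_GENE = "GAPDH"


@dataclass
class QpcrPlate:
    """Replicate Ct values per (gene, condition) well group.

    ``wells`` has columns gene, condition, replicate, ct.  Ct values must be
    finite and positive (PCR cycle numbers).
    """

    wells: pd.DataFrame
    reference_gene: str = DEFAULT_REFERENCE_GENE
    calibrator: str = "NC"

    def __post_init__(self) -> None:
        required = {"gene", "condition", "replicate", "ct"}
        missing = required - set(self.wells.columns)
        if missing:
            raise ValidationError(f"plate missing column(s) {sorted(missing)}")
        ct = self.wells["ct"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ct)) or (ct <= 0).any():
            raise ValidationError("Ct values must be finite and > 0")
        if self.wells.empty:
            raise ValidationError("plate has no wells")

    def ct_values(self, gene: str, condition: str) -> np.ndarray:
        sel = (self.wells["gene"] == gene) & (self.wells["condition"] == condition)
        ct = self.wells.loc[sel, "ct"].to_numpy(dtype=float)
        if ct.size == 0:
            raise ValidationError(f"no wells for gene {gene!r} in condition {condition!r}")
        return ct


def read_qpcr_plate(
    path: str | Path,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    calibrator: str = "NC",
) -> QpcrPlate:
    t = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    return QpcrPlate(t, reference_gene=reference_gene, calibrator=calibrator)


@dataclass
class RelativeExpression:
    gene: str
    condition: str
    calibrator: str
    delta_ct_test: float
    delta_ct_calibrator: float
    delta_delta_ct: float
    fold_change: float
    fold_sem: float  # NaN when any test well group has a single replicate


def _sem(x: np.ndarray) -> float:
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / math.sqrt(x.size))


def relative_expression(plate: QpcrPlate, target: str, test_condition: str) -> RelativeExpression:
    """Fold change of ``target`` in ``test_condition`` relative to the calibrator.

    Both target and reference gene must be measured in both conditions.  With
    a single replicate in the test condition the fold is still computed but
    its SEM is reported as NaN (undefined).
    """
    ct_tt = plate.ct_values(target, test_condition)
    ct_rt = plate.ct_values(plate.reference_gene, test_condition)
    ct_tc = plate.ct_values(target, plate.calibrator)
    ct_rc = plate.ct_values(plate.reference_gene, plate.calibrator)

    d_test = float(ct_tt.mean() - ct_rt.mean())
    d_cal = float(ct_tc.mean() - ct_rc.mean())
    ddct = d_test - d_cal
    fold = 2.0 ** (-ddct)

    sem_dct = math.sqrt(_sem(ct_tt) ** 2 + _sem(ct_rt) ** 2) \
        if ct_tt.size > 1 and ct_rt.size > 1 else float("nan")
    fold_sem = fold * math.log(2.0) * sem_dct

    return RelativeExpression(
        gene=target,
        condition=test_condition,
        calibrator=plate.calibrator,
        delta_ct_test=d_test,
        delta_ct_calibrator=d_cal,
        delta_delta_ct=ddct,
        fold_change=fold,
        fold_sem=fold_sem,
    )
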