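"""Field-reconstruction error metrics: range-normalised MAE and RMSE.

Both metrics compare a reconstructed field against its ground truth node by
node and normalise by the range of the field over the *full* dataset (all
meshes, train and test), expressed in percent:

    NMAE  = sum_j |f_ML_j - f_GT_j| / (N * (max f - min f)) * 100
    NRMSE = sqrt(sum_j (f_ML_j - f_GT_j)^2 / N) / (max f - min f) * 100

NMAE <= NRMSE always holds per mesh (power-mean inequality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["nmae", "nrmse", "ErrorReport", "evaluate_test_set", "field_range"]


def _check(f_ml: np.ndarray, f_gt: np.ndarray, value_range: float):
    f_ml = np.asarray(f_ml, dtype=float)
    f_gt = np.asarray(f_gt, dtype=float)
    if f_ml.shape != f_gt.shape:
        raise ValueError("field vectors must have equal length")
    if value_range <= 0:
        raise ValueError("normalisation range must be positive")
    return f_ml, f_gt


def nmae(f_ml, f_gt, value_range: float) -> float:
    """Normalised mean absolute error, percent of the dataset-wide range."""
    f_ml, f_gt = _check(f_ml, f_gt, value_range)
    return 100.0 * float(np.abs(f_ml - f_gt).mean()) / value_range


def nrmse(f_ml, f_gt, value_range: float) -> float:
    """Normalised root-mean-square error, percent of the dataset-wide range."""
    f_ml, f_gt = _check(f_ml, f_gt, value_range)
    return 100.0 * float(np.sqrt(np.mean((f_ml - f_gt) ** 2))) / value_range


def field_range(values: np.ndarray) -> float:
    """max - min over all node values of all meshes (the full dataset)."""
    values = np.asarray(values, dtype=float)
    return float(values.max() - values.min())


@dataclass(frozen=True)
class ErrorReport:
    """Per-mesh and ensemble reconstruction errors for one field."""

    field: str
    mesh_ids: list[str]
    nmae_pct: np.ndarray          # per mesh, %
    nrmse_pct: np.ndarray         # per mesh, %
    value_range: float            # normalisation range, field units (Pa)

    @property
    def nmae_mean(self) -> float:
        return float(self.nmae_pct.mean())

    @property
    def nmae_std(self) -> float:
        return float(self.nmae_pct.std())

    @property
    def nrmse_mean(self) -> float:
        return float(self.nrmse_pct.mean())

    @property
    def nrmse_std(self) -> float:
        return float(self.nrmse_pct.std())

    def summary(self) -> str:
        return (
            f"{self.field}: NMAE {self.nmae_mean:.2f}±{self.nmae_std:.2f} %, "
            f"NRMSE {self.nrmse_mean:.2f}±{self.nrmse_std:.2f} %"
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "field": self.field,
                "mesh_id": self.mesh_ids,
                "nmae_pct": self.nmae_pct,
                "nrmse_pct": self.nrmse_pct,
            }
        )
        summary = pd.DataFrame(
            {
                "field": [self.field],
                "mesh_id": ["__mean±std__"],
                "nmae_pct": [self.nmae_mean],
                "nrmse_pct": [self.nrmse_mean],
                "nmae_std_pct": [self.nmae_std],
                "nrmse_std_pct": [self.nrmse_std],
            }
        )
        return pd.concat([df, summary], ignore_index=True)


def evaluate_test_set(
    truth: np.ndarray,
    reconstructed: np.ndarray,
    mesh_ids: list[str],
    field: str,
    value_range: float,
) -> ErrorReport:
    """Per-mesh NMAE/NRMSE of reconstructed fields against ground truth.

    ``truth`` and ``reconstructed`` are (M_test, N) matrices with matching
    row order; ``value_range`` is the field range over the full dataset.
    """
    truth = np.asarray(truth, dtype=float)
    reconstructed = np.asarray(reconstructed, dtype=float)
    if truth.shape != reconstructed.shape:
        raise ValueError("truth and reconstruction matrices must match")
    if len(mesh_ids) != truth.shape[0]:
        raise ValueError("mesh id count does not match the row count")
    nm = np.array([nmae(r, t, value_range) for r, t in zip(reconstructed, truth)])
    nr = np.array([nrmse(r, t, value_range) for r, t in zip(reconstructed, truth)])
    return ErrorReport(
        field=field,
        mesh_ids=list(mesh_ids),
        nmae_pct=nm,
        nrmse_pct=nr,
        value_range=value_range,
    )
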