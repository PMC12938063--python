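"""Biomechanical summary statistics over wall-stress fields.

Summaries are computed over element-centroid first principal stresses:
the 99th-percentile wall stress (99th WS), the arithmetic mean (Mean WS)
and the spatially averaged (area-weighted) wall stress (SAWS), all in
N/cm^2.  Group comparisons use the coefficient of determination R^2 and
the Friedman rank test for paired repeated measures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats


@dataclass(frozen=True)
class StressSummary:
    ws99: float
    mean_ws: float
    saws: float
    n_elements: int

    def as_dict(self) -> dict:
        return {"ws99": self.ws99, "mean_ws": self.mean_ws,
                "saws": self.saws, "n_elements": self.n_elements}


def saws(principal_1: np.ndarray, areas: np.ndarray) -> float:
    """Spatially averaged wall stress: area-weighted mean of element
    stresses, sum(s_e A_e) / sum(A_e)."""
    s = np.asarray(principal_1, dtype=float)
    a = np.asarray(areas, dtype=float)
    if s.shape != a.shape:
        raise ValueError(f"length mismatch: {s.shape} vs {a.shape}")
    if np.any(a <= 0):
        raise ValueError("element areas must be positive")
    return float(np.sum(s * a) / np.sum(a))


def percentile_ws(principal_1: np.ndarray, q: float = 99.0) -> float:
    """q-th percentile wall stress, linear interpolation between closest
    ranks (numpy's default convention)."""
    s = np.asarray(principal_1, dtype=float)
    if s.size == 0:
        raise ValueError("empty stress field")
    return float(np.percentile(s, q, method="linear"))


def summarize(principal_1: np.ndarray, areas: np.ndarray) -> StressSummary:
    s = np.asarray(principal_1, dtype=float)
    return StressSummary(
        ws99=percentile_ws(s, 99.0),
        mean_ws=float(np.mean(s)),
        saws=saws(s, areas),
        n_elements=int(s.size),
    )


def mean_arterial_pressure(sbp: float, dbp: float) -> float:
    """Mean arterial pressure (mmHg) from systolic/diastolic pressures:
    DBP + 1/3 pulse pressure = (SBP + 2 DBP)/3, rounded to 0.1 mmHg."""
    if dbp <= 0:
        raise ValueError("diastolic pressure must be positive")
    if sbp < dbp:
        raise ValueError(f"systolic {sbp} below diastolic {dbp}")
    return round((sbp + 2.0 * dbp) / 3.0, 1)


def r_squared(predicted, truth, mode: str = "pearson") -> float:
    """Coefficient of determination between paired series.

    ``pearson``: squared Pearson correlation of the scatter (default);
    ``identity``: 1 - SS_res/SS_tot about the identity line y = x.
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(truth, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    if mode == "pearson":
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError("zero variance in a series")
        r = np.corrcoef(x, y)[0, 1]
        return float(r * r)
    if mode == "identity":
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            raise ValueError("zero variance in ground truth")
        return float(1.0 - np.sum((y - x) ** 2) / ss_tot)
    raise ValueError(f"unknown mode {mode!r}")


def friedman_test(*groups) -> tuple[float, float]:
    """Friedman rank test for k >= 3 paired groups of equal length.

    Returns (FS, p) with mid-rank tie handling and the chi-square
    approximation for the p-value.  Identical groups (all ranks tied)
    give FS = 0, p = 1.
    """
    if len(groups) < 3:
        raise ValueError("Friedman test needs at least 3 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("groups must have equal length (paired design)")
    data = np.column_stack(arrays)
    if np.all(np.ptp(data, axis=1) == 0):  # every subject fully tied
        return 0.0, 1.0
    fs, p = _stats.friedmanchisquare(*arrays)
    return float(fs), float(p)
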