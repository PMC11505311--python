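"""Mode scoring by correlation with the source beat, and the
lead-by-mode correspondence analysis used to visualize that structure.

The per-case score is the Pearson correlation between each decomposed mode
and the beat it came from; averaging over cases (heartbeats) gives a
12-lead x 10-mode table of mean "energy correlation" coefficients. Mode
selection itself is positional — keep the first five modes — justified by
the observed decay of the mean correlations; a consistency flag reports
whether the first n modes really do carry the n largest means per lead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ecg_io import LEAD_NAMES

logger = logging.getLogger(__name__)


def mode_correlation(mode: np.ndarray, original: np.ndarray) -> float:
    """Pearson correlation between a mode and its source signal.

    Returns NaN (and logs) for constant inputs, where the coefficient is
    undefined; callers exclude NaNs from means.
    """
    mode = np.asarray(mode, dtype=float)
    original = np.asarray(original, dtype=float)
    if mode.shape != original.shape or mode.size < 2:
        raise ValueError("inputs must share a length >= 2")
    mc = mode - mode.mean()
    oc = original - original.mean()
    denom = np.sqrt(np.sum(mc**2) * np.sum(oc**2))
    if denom == 0:
        logger.warning("constant input to mode_correlation; returning NaN")
        return float("nan")
    return float(np.sum(mc * oc) / denom)


@dataclass
class CorrelationTable:
    """Mean mode-signal correlations, leads x modes."""

    method: str
    matrix: pd.DataFrame  # index: lead, columns: mode number 1..n_modes
    n_cases: pd.DataFrame  # observations behind each mean

    def to_csv(self, path) -> None:
        self.matrix.to_csv(path)


def correlation_table(
    beats_by_lead: dict[str, list],
    modesets_by_lead: dict[str, list],
    method: str,
    n_modes: int = 10,
) -> CorrelationTable:
    """Build the lead x mode table of mean correlations.

    ``beats_by_lead[lead][i]`` must be the Beat whose decomposition is
    ``modesets_by_lead[lead][i]``. Cases are individual heartbeats. Modes a
    decomposition did not produce (EMD can stop early) are skipped and the
    per-cell case counts record how many observations each mean used.
    """
    if not beats_by_lead or all(len(v) == 0 for v in beats_by_lead.values()):
        raise ValueError("no beats supplied")
    leads = [l for l in LEAD_NAMES if l in beats_by_lead] or list(beats_by_lead)
    mat = np.full((len(leads), n_modes), np.nan)
    counts = np.zeros((len(leads), n_modes), dtype=int)
    for li, lead in enumerate(leads):
        sums = np.zeros(n_modes)
        for beat, ms in zip(beats_by_lead[lead], modesets_by_lead[lead]):
            x = getattr(beat, "samples", beat)
            for k in range(min(n_modes, ms.n_modes)):
                r = mode_correlation(ms.modes[k], x)
                if np.isfinite(r):
                    sums[k] += r
                    counts[li, k] += 1
        skipped = sum(
            max(0, n_modes - ms.n_modes) for ms in modesets_by_lead[lead]
        )
        if skipped:
            logger.info("lead %s: %d mode slots absent from decompositions", lead, skipped)
        with np.errstate(invalid="ignore"):
            mat[li] = np.where(counts[li] > 0, sums / np.maximum(counts[li], 1), np.nan)
    cols = list(range(1, n_modes + 1))
    return CorrelationTable(
        method=method,
        matrix=pd.DataFrame(mat, index=leads, columns=cols),
        n_cases=pd.DataFrame(counts, index=leads, columns=cols),
    )


@dataclass
class ModeSelection:
    indices: list[int]  # 1-based mode numbers
    consistent: bool  # do the first n modes carry the n largest means per lead?


def select_modes(table: CorrelationTable, n: int = 5) -> ModeSelection:
    """Select the first n modes (positional rule).

    The selection is always {1..n}; the ``consistent`` flag reports whether
    in every lead those first n modes are also the n largest mean
    correlations, i.e. whether the positional rule agrees with a purely
    rank-based one.
    """
    n_avail = table.matrix.shape[1]
    if n > n_avail:
        raise ValueError(f"requested {n} modes but table has {n_avail}")
    mat = table.matrix.to_numpy()
    consistent = True
    for row in mat:
        finite = np.nan_to_num(row, nan=-np.inf)
        top = set(np.argsort(finite)[::-1][:n])
        if top != set(range(n)):
            consistent = False
            break
    return ModeSelection(indices=list(range(1, n + 1)), consistent=consistent)


@dataclass
class CaResult:
    """Two-dimensional correspondence analysis of a nonnegative table."""

    row_coords: pd.DataFrame  # principal coordinates, dims 1..2
    col_coords: pd.DataFrame
    inertia_proportions: np.ndarray  # all dimensions, sums to 1
    total_inertia: float

    @property
    def cumulative_contribution_2d(self) -> float:
        return float(np.sum(self.inertia_proportions[:2]))


def correspondence_analysis(table: pd.DataFrame | np.ndarray) -> CaResult:
    """Correspondence analysis of a nonnegative two-way table.

    Standard chi-square-metric decomposition: correspondence matrix
    P = table / total, standardized residuals
    S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}, SVD of S, principal coordinates
    = mass-scaled singular vectors times singular values. Total inertia
    equals the table's Pearson chi-square statistic divided by its grand
    total. Negative entries are clamped to zero with a warning.
    """
    if isinstance(table, pd.DataFrame):
        rows, cols = list(table.index), list(table.columns)
        arr = table.to_numpy(dtype=float)
    else:
        arr = np.asarray(table, dtype=float)
        rows = list(range(arr.shape[0]))
        cols = list(range(arr.shape[1]))
    if np.any(arr < 0):
        logger.warning("negative entries clamped to 0 for correspondence analysis")
        arr = np.clip(arr, 0.0, None)
    total = arr.sum()
    if total <= 0:
        raise ValueError("table grand total must be positive")

    P = arr / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    with np.errstate(divide="ignore"):
        dr = np.where(r > 0, 1.0 / np.sqrt(r), 0.0)
        dc = np.where(c > 0, 1.0 / np.sqrt(c), 0.0)
    S = dr[:, None] * (P - np.outer(r, c)) * dc[None, :]
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    total_inertia = float(np.sum(sv**2))
    if total_inertia > 0:
        proportions = sv**2 / total_inertia
    else:
        proportions = np.zeros_like(sv)
    row_pc = dr[:, None] * U * sv[None, :]
    col_pc = dc[:, None] * Vt.T * sv[None, :]
    ndim = min(2, len(sv))
    return CaResult(
        row_coords=pd.DataFrame(
            row_pc[:, :ndim], index=rows, columns=[f"dim{i+1}" for i in range(ndim)]
        ),
        col_coords=pd.DataFrame(
            col_pc[:, :ndim], index=cols, columns=[f"dim{i+1}" for i in range(ndim)]
        ),
        inertia_proportions=proportions,
        total_inertia=total_inertia,
    )
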