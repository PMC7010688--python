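"""Pseudotime, developmental-stage assignment, and sliding windows.

Pseudotime is the first principal component of the top highly variable
genes, oriented to correlate positively with the day of collection and
linearly rescaled to [0, 1]. Stages (iPSC, mesendoderm, definitive
endoderm) combine the collection day with pseudotime windows. Sliding
windows hold a fixed fraction of cells, stepping by a fixed fraction of
cell ranks, and are the substrate for dynamic-eQTL visualisation and ASE
binning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

STAGES = ("iPSC", "mesendo", "defendo", "unassigned")

# stage rule: (days, closed pseudotime interval)
MESENDO_DAYS = ("day1", "day2")
MESENDO_PT = (0.15, 0.5)  # closed interval
DEFENDO_DAYS = ("day2", "day3")
DEFENDO_PT_MIN = 0.7  # open lower bound


@dataclass
class PseudotimeAssignment:
    """Per-cell pseudotime in [0, 1] with the raw PC1 score and the
    orientation sign applied to it."""

    pseudotime: pd.Series
    pc1: pd.Series
    orientation: int


def _numeric_day(days: pd.Series) -> np.ndarray:
    out = days.astype(str).str.extract(r"(\d+)", expand=False)
    if out.isna().any():
        bad = days[out.isna()].iloc[0]
        raise ValueError(f"day label {bad!r} carries no numeric part")
    return out.astype(int).to_numpy()


def compute_pseudotime(
    logcpm: pd.DataFrame,
    hvg_ranked: pd.Index,
    days: pd.Series,
    n_genes: int = 500,
) -> PseudotimeAssignment:
    """PC1 pseudotime from the top ``n_genes`` highly variable genes.

    Genes are standardised (zero mean, unit variance across cells)
    before the principal component analysis; PC1 is sign-oriented so
    that pseudotime correlates positively (Spearman) with the numeric
    day of collection, then rescaled so the observed minimum is 0 and
    the maximum 1.
    """
    if len(logcpm) < 3:
        raise ValueError("need at least 3 cells for pseudotime")
    top = hvg_ranked[: min(n_genes, len(hvg_ranked))]
    x = logcpm[top].to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    x = x[:, keep] / sd[keep]
    if x.shape[1] == 0:
        raise ValueError("all selected genes have zero variance")

    # PC1 via SVD; deterministic sign fixed afterwards by the day rule
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    pc1 = u[:, 0] * s[0]
    if s[0] == 0:
        raise ValueError("expression matrix is degenerate (no variance)")

    day_num = _numeric_day(days.loc[logcpm.index])
    rho = stats.spearmanr(pc1, day_num).statistic
    orientation = -1 if rho < 0 else 1
    pc1 = pc1 * orientation

    lo, hi = pc1.min(), pc1.max()
    pt = (pc1 - lo) / (hi - lo)
    return PseudotimeAssignment(
        pseudotime=pd.Series(pt, index=logcpm.index, name="pseudotime"),
        pc1=pd.Series(pc1, index=logcpm.index, name="pc1"),
        orientation=orientation,
    )


def assign_stages(pt: pd.Series, days: pd.Series) -> pd.Series:
    """Assign each cell to iPSC / mesendo / defendo / unassigned.

    - iPSC: all day0 cells;
    - mesendo: day1 or day2 with pseudotime in the closed interval
      [0.15, 0.5];
    - defendo: day2 or day3 with pseudotime strictly above 0.7;
    - otherwise unassigned.
    """
    days = days.loc[pt.index]
    known = {"day0", "day1", "day2", "day3"}
    unknown = set(days.astype(str)) - known
    if unknown:
        raise ValueError(f"unknown day labels: {sorted(unknown)}")

    day = days.astype(str).to_numpy()
    p = pt.to_numpy(dtype=float)
    stage = np.full(len(pt), "unassigned", dtype=object)
    stage[day == "day0"] = "iPSC"
    mes = np.isin(day, MESENDO_DAYS) & (p >= MESENDO_PT[0]) & (p <= MESENDO_PT[1])
    stage[mes] = "mesendo"
    de = np.isin(day, DEFENDO_DAYS) & (p > DEFENDO_PT_MIN)
    stage[de] = "defendo"
    return pd.Series(
        pd.Categorical(stage, categories=list(STAGES)), index=pt.index, name="stage"
    )


@dataclass
class Window:
    index: int
    start_rank: int
    end_rank: int  # exclusive
    cells: pd.Index
    center: float  # mean pseudotime of member cells


@dataclass
class WindowSet:
    """Ordered sliding windows over pseudotime-ranked cells."""

    windows: list[Window]
    frac: float
    step: float

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def membership(self) -> pd.DataFrame:
        """Long frame (window, cell) of window memberships."""
        rows = [
            (w.index, c, w.center) for w in self.windows for c in w.cells
        ]
        return pd.DataFrame(rows, columns=["window", "cell", "center"])


def sliding_windows(
    pt: pd.Series, frac: float = 0.25, step: float = 0.025
) -> WindowSet:
    """Windows of ``round(frac * N)`` cells stepping by ``round(step * N)``.

    Cells are sorted by pseudotime with ties broken by cell id for
    reproducibility; window ``i`` covers ranks
    ``[round(i * step * N), round(i * step * N) + round(frac * N))`` for
    every start where the window still fits.
    """
    if not (0 < step <= frac < 1):
        raise ValueError("need 0 < step <= frac < 1")
    n = len(pt)
    width = int(round(frac * n))
    if width < 1 or n < width:
        raise ValueError("fewer cells than one window")

    order = pt.reset_index(drop=False)
    order.columns = ["cell", "pt"]
    order = order.sort_values(["pt", "cell"], kind="stable")
    cells_sorted = pd.Index(order["cell"])
    pt_sorted = order["pt"].to_numpy()

    # starts at round(i * step * n): exact strides when n divides evenly.
    # Clamping to the previous window's end keeps the union of windows
    # gap-free when rounding would otherwise skip a rank.
    starts: list[int] = []
    i = 0
    while True:
        s = int(round(i * step * n))
        if starts:
            s = min(s, starts[-1] + width)
        if s + width > n:
            break
        if not starts or s > starts[-1]:
            starts.append(s)
        i += 1
    # boundary window so the union always reaches the last rank
    if starts and starts[-1] + width < n:
        starts.append(n - width)

    windows = [
        Window(
            index=k,
            start_rank=s,
            end_rank=s + width,
            cells=cells_sorted[s:s + width],
            center=float(pt_sorted[s:s + width].mean()),
        )
        for k, s in enumerate(starts)
    ]
    return WindowSet(windows=windows, frac=frac, step=step)
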