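"""Screen-wide score distribution and target selection.

Inverse-screen docking scores over many unrelated proteins are treated as
draws from a normal background; candidate targets are the proteins whose
best score falls below the lower edge of the central 95% probability
interval of the fitted normal (mean - 1.96 sd).  A normal Q-Q check
supports the distributional assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ScreenResult:
    """Best docking score per (protein, site)."""

    rows: pd.DataFrame  # columns: protein_id, site_id, score
    ligand_name: str = ""
    params_hash: str = ""

    def __post_init__(self) -> None:
        required = {"protein_id", "site_id", "score"}
        if not required.issubset(self.rows.columns):
            raise ValueError(f"rows must have columns {sorted(required)}")
        if not np.all(np.isfinite(self.rows["score"])):
            raise ValueError("scores must be finite")
        if self.rows.duplicated(["protein_id", "site_id"]).any():
            raise ValueError("one best score per (protein, site) expected")

    @classmethod
    def from_records(cls, records, ligand_name: str = "", params_hash: str = "") -> "ScreenResult":
        df = pd.DataFrame(records, columns=["protein_id", "site_id", "score"])
        return cls(df, ligand_name, params_hash)


@dataclass(frozen=True)
class NormalFit:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least two scores")
        if not self.sd > 0:
            raise ValueError("sd must be positive (degenerate score list?)")


@dataclass
class ThresholdReport:
    level: float
    low: float
    high: float
    selected: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("interval must satisfy low < high")


def fit_normal(scores, sample_sd: bool = False) -> NormalFit:
    """Maximum-likelihood normal fit (population sd by default; set
    ``sample_sd`` for the n-1 unbiased estimate)."""
    x = np.asarray(list(scores), dtype=float)
    if x.size < 2:
        raise ValueError("need at least two scores")
    if not np.all(np.isfinite(x)):
        raise ValueError("scores must be finite")
    sd = float(np.std(x, ddof=1 if sample_sd else 0))
    if sd == 0:
        raise ValueError("zero variance: all scores identical")
    return NormalFit(float(np.mean(x)), sd, int(x.size))


def central_interval(fit: NormalFit, level: float = 0.95) -> tuple[float, float]:
    """Central probability interval of the fitted normal: mean +/- z(level)*sd.

    This is the interval that contains ``level`` of the fitted score
    distribution (z(0.95) = 1.959964), not a confidence interval of the
    mean; scores below the lower edge are threshold-selected.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    z = float(stats.norm.ppf(0.5 + level / 2))
    return (fit.mean - z * fit.sd, fit.mean + z * fit.sd)


def qq_points(scores) -> np.ndarray:
    """Normal Q-Q points: standard-normal quantiles at plotting positions
    (i - 0.5)/n against the sample order statistics.  Column 0 is the
    theoretical quantile, column 1 the sample quantile."""
    x = np.sort(np.asarray(list(scores), dtype=float))
    n = x.size
    if n < 3:
        raise ValueError("need at least three scores for a Q-Q plot")
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return np.column_stack([theo, x])


def select_targets(result: ScreenResult, low: float, level: float = 0.95, high: float | None = None) -> ThresholdReport:
    """Rows with score strictly below ``low``, sorted ascending (best
    first) with ties broken by protein id."""
    df = result.rows
    sel = df[df["score"] < low].sort_values(["score", "protein_id"], kind="mergesort")
    report = ThresholdReport(
        level=level,
        low=low,
        high=high if high is not None else float(np.inf),
        selected=sel.reset_index(drop=True),
    )
    return report
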