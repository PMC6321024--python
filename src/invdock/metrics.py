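"""Early-recognition validation metrics for ranked screens.

Given a score-ranked protein list with active/inactive labels (actives =
experimentally confirmed targets of the ligand), this module computes ROC
curve and AUC, enrichment factors, robust initial enhancement (RIE),
BEDROC, and the predictiveness curve with its standardized total gain.

RIE and BEDROC weight early ranks exponentially with parameter alpha
(default 20, the conventional choice weighting roughly the top 8% of the
list); BEDROC is RIE rescaled to [0, 1] by a closed-form conversion that
depends only on alpha and the active fraction Ra = n/N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class LabeledRanking:
    """Entries sorted ascending by score (best first), ties broken by id."""

    ids: list[str]
    scores: np.ndarray
    labels: np.ndarray  # 1 = active

    def __post_init__(self) -> None:
        order = np.lexsort((np.asarray(self.ids, dtype=object), np.asarray(self.scores, float)))
        self.ids = [self.ids[i] for i in order]
        self.scores = np.asarray(self.scores, float)[order]
        self.labels = np.asarray(self.labels, int)[order]
        if self.n < 1:
            raise ValueError("need at least one active")

    @property
    def N(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return int(self.labels.sum())

    @property
    def ra(self) -> float:
        return self.n / self.N

    @classmethod
    def from_entries(cls, entries) -> "LabeledRanking":
        ids, scores, labels = zip(*entries)
        return cls(list(ids), np.array(scores, float), np.array(labels, int))

    @classmethod
    def from_tsv(cls, path) -> "LabeledRanking":
        df = pd.read_csv(path, sep="\t")
        return cls(df["id"].astype(str).tolist(), df["score"].to_numpy(float),
                   df["active"].to_numpy(int))


@dataclass(frozen=True)
class MetricParams:
    alpha: float = 20.0
    fractions: tuple = (0.01,)

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if any(not (0 < f <= 1) for f in self.fractions):
            raise ValueError("fractions must lie in (0, 1]")


def _check_two_classes(r: LabeledRanking) -> None:
    if r.n == 0 or r.n == r.N:
        raise ValueError("ranking must contain both actives and inactives")


def roc_auc(r: LabeledRanking) -> tuple[np.ndarray, float]:
    """Stepwise ROC curve (FPF, TPF) and trapezoidal AUC.

    Tied scores advance the curve jointly (a diagonal segment), so the
    AUC equals the tie-corrected Mann-Whitney rank statistic.
    """
    _check_two_classes(r)
    n_act, n_inact = r.n, r.N - r.n
    pts = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < r.N:
        j = i
        while j < r.N and r.scores[j] == r.scores[i]:
            j += 1
        tp += int(r.labels[i:j].sum())
        fp += (j - i) - int(r.labels[i:j].sum())
        pts.append((fp / n_inact, tp / n_act))
        i = j
    curve = np.array(pts)
    auc = float(np.trapezoid(curve[:, 1], curve[:, 0]))
    return curve, auc


def enrichment(r: LabeledRanking, fractions=(0.01,)) -> tuple[dict[float, float], np.ndarray]:
    """EF per requested fraction plus the full enrichment curve.

    EF(chi) = [actives in top ceil(chi*N) / ceil(chi*N)] / (n/N); the
    curve gives (k/N, TPF after k) for every rank k.
    """
    _check_two_classes(r)
    cum = np.cumsum(r.labels)
    curve = np.column_stack([np.arange(1, r.N + 1) / r.N, cum / r.n])
    efs = {}
    for chi in fractions:
        if not 0 < chi <= 1:
            raise ValueError(f"fraction {chi} outside (0, 1]")
        top = int(np.ceil(chi * r.N))
        efs[chi] = (cum[top - 1] / top) / r.ra
    return efs, curve


def rie(r: LabeledRanking, p: MetricParams = MetricParams()) -> float:
    """Robust initial enhancement.

    RIE = sum over actives of exp(-alpha * rank_i / N), divided by the
    expectation of that sum under a uniformly random ranking,
    (n/N) * (1 - e^-alpha) / (e^(alpha/N) - 1).  Higher = earlier
    recognition; rank-based, hence invariant under monotone score
    transforms.
    """
    _check_two_classes(r)
    a = p.alpha
    ranks = np.flatnonzero(r.labels == 1) + 1  # 1-based
    num = float(np.sum(np.exp(-a * ranks / r.N)))
    denom = r.ra * (1 - np.exp(-a)) / (np.exp(a / r.N) - 1)
    return num / denom


def rie_to_bedroc(rie_value: float, alpha: float, ra: float) -> float:
    """Closed-form conversion from RIE to BEDROC.

    BEDROC = RIE * Ra*sinh(a/2) / (cosh(a/2) - cosh(a/2 - a*Ra))
             + 1 / (1 - e^(a*(1-Ra)))
    """
    a = alpha
    scale = (ra * np.sinh(a / 2)) / (np.cosh(a / 2) - np.cosh(a / 2 - a * ra))
    return float(rie_value * scale + 1.0 / (1.0 - np.exp(a * (1.0 - ra))))


def bedroc(r: LabeledRanking, p: MetricParams = MetricParams()) -> float:
    """BEDROC in [0, 1]: RIE mapped through the closed-form rescaling;
    approaches 1 for perfect early ranking at small active fraction."""
    return rie_to_bedroc(rie(r, p), p.alpha, r.ra)


@dataclass
class PredictivenessResult:
    points: np.ndarray  # (rank fraction, calibrated probability)
    total_gain: float
    intercept: float
    slope: float
    separation_flag: bool = False


def predictiveness_total_gain(r: LabeledRanking) -> PredictivenessResult:
    """Predictiveness curve and standardized total gain.

    A logistic regression of the active flag on the raw score (ML fit,
    deterministic Newton solver) issues calibrated activity probabilities
    p_i; the curve plots them against the rank fraction ordered by
    increasing probability.  TG = mean|p_i - pbar| / (2*pbar*(1-pbar))
    with pbar = n/N: 0 when scores carry no label information, 1 in the
    perfectly separated limit.

    Perfect or quasi-perfect separation is handled by a ridge-stabilized
    refit and flagged in the result.
    """
    import warnings

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    _check_two_classes(r)
    if np.all(r.scores == r.scores[0]):
        raise ValueError("scores are all equal; no model can be fit")
    x = sm.add_constant((r.scores - r.scores.mean()) / max(r.scores.std(), 1e-12))
    y = r.labels.astype(float)
    flag = False
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fit = sm.Logit(y, x).fit(method="newton", disp=0, maxiter=200, tol=1e-10)
        flag = any(issubclass(w.category, PerfectSeparationWarning) for w in caught)
        params = fit.params
        if not np.all(np.isfinite(params)) or np.abs(params).max() > 1e3:
            raise ValueError("diverged")
    except Exception:
        flag = True
        fit = sm.Logit(y, x).fit_regularized(alpha=1e-3, L1_wt=0.0, disp=0, maxiter=500)
        params = np.asarray(fit.params)
    p_hat = 1.0 / (1.0 + np.exp(-(x @ params)))
    pbar = r.ra
    tg = float(np.mean(np.abs(p_hat - pbar)) / (2 * pbar * (1 - pbar)))
    order = np.argsort(p_hat, kind="mergesort")
    points = np.column_stack([(np.arange(1, r.N + 1)) / r.N, p_hat[order]])
    return PredictivenessResult(points, tg, float(params[0]), float(params[1]), flag)


def metrics_report(r: LabeledRanking, p: MetricParams = MetricParams()) -> dict:
    """All validation metrics in one JSON-ready dict."""
    _, auc = roc_auc(r)
    efs, _ = enrichment(r, p.fractions)
    rie_v = rie(r, p)
    pc = predictiveness_total_gain(r)
    return {
        "N": r.N,
        "n_active": r.n,
        "roc_auc": auc,
        "enrichment": {f"EF{int(chi * 100)}%": v for chi, v in efs.items()},
        "rie": rie_v,
        "bedroc": rie_to_bedroc(rie_v, p.alpha, r.ra),
        "alpha": p.alpha,
        "total_gain": pc.total_gain,
        "separation_flag": pc.separation_flag,
    }
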