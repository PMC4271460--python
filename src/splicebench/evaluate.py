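"""Evaluation harness: restricted ROC/AUC, recall/precision, rank
concordance and overlap tables against a simulated ground truth.

Because differential-splicing tools control the false-positive rate
tightly, discrimination is summarized by the *restricted* (partial) AUC
over FPR in [0, ``fpr_max``], default 0.2.  The standardized (McClish)
form rescales the partial area so that a random ranking scores 0.5 and
a perfect one 1.0, making values comparable across ``fpr_max`` choices;
the raw trapezoidal area is always reported alongside.

Ranking scores follow the convention ``1 - p_adj`` for methods that
report adjusted p-values, and the raw test statistic otherwise; targets
a method does not report rank last.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RocCurve",
    "EvalReport",
    "ranking_scores",
    "roc_points",
    "restricted_auc",
    "recall_precision",
    "adjust_pvalues",
    "spearman_matrix",
    "overlap_table",
    "evaluate_scores",
]


@dataclass(frozen=True)
class RocCurve:
    """Threshold-sweep ROC curve; tied scores form one diagonal step."""

    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self):
        f, t = np.asarray(self.fpr, float), np.asarray(self.tpr, float)
        if f[0] != 0 or t[0] != 0 or f[-1] != 1 or t[-1] != 1:
            raise ValueError("ROC curve must run from (0,0) to (1,1)")
        if (np.diff(f) < -1e-12).any() or (np.diff(t) < -1e-12).any():
            raise ValueError("ROC coordinates must be non-decreasing")
        object.__setattr__(self, "fpr", f)
        object.__setattr__(self, "tpr", t)


@dataclass
class EvalReport:
    pauc_standardized: float
    pauc_raw: float
    fpr_max: float
    recall: float
    precision: float | None  # None when nothing was called
    n_called: int
    alpha: float
    n_targets: int
    n_positives: int
    roc: RocCurve = field(repr=False, default=None)

    def to_dict(self) -> dict:
        d = {
            "pauc_standardized": self.pauc_standardized,
            "pauc_raw": self.pauc_raw,
            "fpr_max": self.fpr_max,
            "recall": self.recall,
            "precision": self.precision,
            "n_called": self.n_called,
            "alpha": self.alpha,
            "n_targets": self.n_targets,
            "n_positives": self.n_positives,
        }
        return d

    def to_json(self, path: str):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------


def ranking_scores(table: pd.DataFrame) -> pd.Series:
    """Per-target ranking score: ``1 - p_adj`` if available, else the
    raw statistic; higher means more evidence for differential
    splicing.  NaN entries stay NaN (they will rank last)."""
    if "target_id" not in table.columns:
        raise ValueError("score table lacks a target_id column")
    if "p_adj" in table.columns and table["p_adj"].notna().any():
        s = 1.0 - table["p_adj"].astype(float)
    elif "statistic" in table.columns:
        s = table["statistic"].astype(float)
    else:
        raise ValueError("score table has neither p_adj nor statistic")
    s.index = table["target_id"]
    return s.rename("ranking_score")


def _align_scores(scores: pd.Series, truth: pd.DataFrame):
    """Align scores to the truth targets; unscored targets get -inf."""
    y = truth.set_index("gene_id")["is_true_as"].astype(bool)
    s = scores.reindex(y.index)
    s = s.fillna(-np.inf)
    return s.to_numpy(float), y.to_numpy()


def roc_points(scores: pd.Series, truth: pd.DataFrame) -> RocCurve:
    """Exact ROC curve from a threshold sweep over distinct scores.

    ``scores`` is indexed by target id; ``truth`` is a TruthTable (or
    any frame with gene_id / is_true_as).  Targets absent from
    ``scores`` are treated as ranked last.  Tie groups contribute a
    single (diagonal) segment.
    """
    s, y = _align_scores(scores, truth)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("undefined ROC: need at least one positive and one negative")
    order = np.argsort(-s, kind="mergesort")
    s, y = s[order], y[order]
    fpr = [0.0]
    tpr = [0.0]
    tp = fp = 0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        tp += int(y[i:j].sum())
        fp += (j - i) - int(y[i:j].sum())
        fpr.append(fp / n_neg)
        tpr.append(tp / n_pos)
        i = j
    return RocCurve(np.array(fpr), np.array(tpr))


def restricted_auc(
    curve: RocCurve, fpr_max: float = 0.2, standardized: bool = True
) -> float:
    """Partial AUC over FPR in [0, fpr_max] by the trapezoid rule.

    The curve is linearly interpolated at ``fpr_max``.  The
    standardized (McClish) form maps the raw area onto the usual AUC
    scale, ``0.5 * (1 + (pAUC - pAUC_min) / (pAUC_max - pAUC_min))``
    with ``pAUC_max = fpr_max`` (perfect) and
    ``pAUC_min = fpr_max**2 / 2`` (the chance diagonal), so random ~ 0.5
    and perfect = 1.
    """
    if not 0.0 < fpr_max <= 1.0:
        raise ValueError(f"fpr_max must be in (0, 1], got {fpr_max}")
    f, t = curve.fpr, curve.tpr
    keep = f <= fpr_max + 1e-15
    fk, tk = f[keep], t[keep]
    if fk[-1] < fpr_max:
        t_at = float(np.interp(fpr_max, f, t))
        fk = np.append(fk, fpr_max)
        tk = np.append(tk, t_at)
    raw = float(np.trapezoid(tk, fk))
    if not standardized:
        return raw
    pmin = fpr_max**2 / 2.0
    pmax = fpr_max
    return 0.5 * (1.0 + (raw - pmin) / (pmax - pmin))


def recall_precision(
    table: pd.DataFrame, truth: pd.DataFrame, alpha: float = 0.05
):
    """Recall, precision and number of calls at ``p_adj <= alpha``.

    Precision is None (undefined) when nothing is called.  Targets in
    the truth but missing from the table count as not called.
    """
    if "p_adj" not in table.columns:
        raise ValueError("score table lacks a p_adj column")
    y = truth.set_index("gene_id")["is_true_as"].astype(bool)
    padj = table.set_index("target_id")["p_adj"].reindex(y.index)
    called = padj.notna() & (padj <= alpha)
    tp = int((called & y).sum())
    n_called = int(called.sum())
    n_pos = int(y.sum())
    recall = tp / n_pos if n_pos else float("nan")
    precision = (tp / n_called) if n_called else None
    return recall, precision, n_called


def adjust_pvalues(pvalues, method: str = "BH") -> list[float]:
    """Multiple-testing adjustment: Benjamini-Hochberg step-up or
    Bonferroni.  Order-preserving."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    key = {"BH": "fdr_bh", "Bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"method must be 'BH' or 'Bonferroni', got {method!r}")
    return multipletests(p, method=key)[1].tolist()


def spearman_matrix(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise Spearman rho of ranking scores over the common targets.

    All tables are restricted to the intersection of their target ids
    (ties get average ranks, scipy's default).
    """
    if len(tables) < 2:
        raise ValueError("need at least two score tables")
    scores = {name: ranking_scores(t) for name, t in tables.items()}
    names = list(scores)
    common = None
    for name in names:
        idx = set(scores[name].dropna().index)
        common = idx if common is None else (common & idx)
    names_pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    if not common:
        a, b = names_pairs[0]
        raise ValueError(f"no common targets between {a!r} and {b!r}")
    common = sorted(common)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for a, b in names_pairs:
        rho = spearmanr(scores[a][common], scores[b][common]).statistic
        mat.loc[a, b] = mat.loc[b, a] = rho
    return mat


def overlap_table(call_sets: dict[str, set]) -> pd.DataFrame:
    """Symmetric matrix of significant-call overlaps: diagonal = set
    sizes, off-diagonal = pairwise intersection sizes."""
    names = list(call_sets)
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for i, a in enumerate(names):
        mat.loc[a, a] = len(call_sets[a])
        for b in names[i + 1:]:
            k = len(call_sets[a] & call_sets[b])
            mat.loc[a, b] = mat.loc[b, a] = k
    return mat


def evaluate_scores(
    table: pd.DataFrame,
    truth: pd.DataFrame,
    fpr_max: float = 0.2,
    alpha: float = 0.05,
) -> EvalReport:
    """Full evaluation of one method's ScoreTable against the truth."""
    scores = ranking_scores(table)
    curve = roc_points(scores, truth)
    pauc_s = restricted_auc(curve, fpr_max, standardized=True)
    pauc_r = restricted_auc(curve, fpr_max, standardized=False)
    if "p_adj" in table.columns and table["p_adj"].notna().any():
        rec, prec, n_called = recall_precision(table, truth, alpha)
    else:
        rec, prec, n_called = float("nan"), None, 0
    y = truth["is_true_as"].astype(bool)
    return EvalReport(
        pauc_standardized=pauc_s,
        pauc_raw=pauc_r,
        fpr_max=fpr_max,
        recall=rec,
        precision=prec,
        n_called=n_called,
        alpha=alpha,
        n_targets=len(truth),
        n_positives=int(y.sum()),
        roc=curve,
    )
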