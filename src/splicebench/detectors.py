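"""Reference detectors for differential alternative splicing.

These implement the count-based statistics that the major published
tools build on, in their simplest defensible form, so the evaluation
harness can be exercised end to end without running any external
package:

* a gene-wise *unit-fraction* statistic — the variance-adjusted mean
  squared difference of per-unit read-count fractions between
  conditions — with label-permutation p-values;
* a Jensen-Shannon-divergence statistic on the mean unit-fraction
  vectors, with the same permutation scheme;
* an exon-inclusion-level (psi) bootstrap test on a single splice
  event's inclusion/exclusion counts;
* Bonferroni aggregation of unit-level p-values to a gene-level one.

They are reference detectors, not re-implementations of DSGseq, SeqGSEA,
MATS or DiffSplice.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import comb

from splicebench.evaluate import adjust_pvalues

__all__ = [
    "UnitFractions",
    "PsiResult",
    "EPSILON",
    "unit_fractions",
    "unit_fraction_stat",
    "permutation_pvalues",
    "jsd",
    "sqrt_jsd",
    "jsd_proportion_test",
    "psi_test",
    "gene_level_bonferroni",
    "write_scores",
    "read_scores",
]

EPSILON = 1e-8  # variance floor in the unit-fraction statistic

SCORE_COLUMNS = ["target_id", "statistic", "p_value", "p_adj", "ranking_score"]


@dataclass(frozen=True)
class UnitFractions:
    """Per-unit read-count fraction estimates of one gene.

    ``p_hat[i, j]`` is the mean fraction of the gene's reads on unit i
    in condition j; ``var_hat`` holds the matching across-replicate
    variances.
    """

    gene_id: str
    unit_ids: tuple[str, ...]
    conditions: tuple[str, ...]
    p_hat: np.ndarray  # units x conditions
    var_hat: np.ndarray


@dataclass(frozen=True)
class PsiResult:
    """Exon inclusion level of one event with a bootstrap difference score."""

    event_id: str
    psi: pd.Series  # per-sample inclusion level, NaN where uncovered
    c: float
    score: float  # bootstrap P(|mean psi_1 - mean psi_2| > c); NaN if flagged
    flagged: bool


# ---------------------------------------------------------------------------
# unit fractions and the gene-wise statistic
# ---------------------------------------------------------------------------


def _gene_fraction_matrix(counts: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Fractions F (units x samples) and validity mask of samples.

    Samples where the gene total is zero carry no information about the
    within-gene read distribution and are dropped (mask False).
    """
    x = counts.to_numpy(dtype=float)
    totals = x.sum(axis=0)
    valid = totals > 0
    frac = np.zeros_like(x)
    frac[:, valid] = x[:, valid] / totals[valid]
    return frac, valid


def unit_fractions(counts: pd.DataFrame, design: pd.Series,
                   gene_id: str = "") -> UnitFractions:
    """Estimate p_hat / var_hat per unit and condition for one gene."""
    frac, valid = _gene_fraction_matrix(counts)
    conds = tuple(pd.unique(design))
    p = np.full((counts.shape[0], len(conds)), np.nan)
    v = np.full_like(p, np.nan)
    labels = design.reindex(counts.columns).to_numpy()
    for j, c in enumerate(conds):
        sel = (labels == c) & valid
        if sel.sum() >= 1:
            p[:, j] = frac[:, sel].mean(axis=1)
        if sel.sum() >= 2:
            v[:, j] = frac[:, sel].var(axis=1, ddof=1)
    return UnitFractions(gene_id, tuple(counts.index), conds, p, v)


def unit_fraction_stat(
    counts: pd.DataFrame, design: pd.Series, epsilon: float = EPSILON
) -> float:
    """Gene-wise unit-fraction statistic T for one gene's count block.

    T averages, over counting units, the squared difference of the two
    conditions' mean read-count fractions, adjusted by the sum of the
    across-replicate variances (floored at ``epsilon``).  Symmetric in
    the condition labels.  Returns NaN when either condition has fewer
    than two samples with non-zero gene totals.
    """
    if counts.shape[0] < 2:
        raise ValueError("gene must have >= 2 counting units")
    uf = unit_fractions(counts, design)
    if len(uf.conditions) != 2:
        raise ValueError(f"need exactly 2 conditions, got {uf.conditions}")
    if np.isnan(uf.var_hat).any():
        return float("nan")
    d2 = (uf.p_hat[:, 0] - uf.p_hat[:, 1]) ** 2
    return float(np.mean(d2 / (uf.var_hat[:, 0] + uf.var_hat[:, 1] + epsilon)))


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------


def _entropy2(p: np.ndarray) -> np.ndarray:
    """Column-wise Shannon entropy in bits; 0 log 0 = 0."""
    logs = np.zeros_like(p)
    np.log2(p, where=p > 0, out=logs)
    return -(p * logs).sum(axis=0)


def _stat_from_masks(
    frac: np.ndarray, masks: np.ndarray, statistic: str, epsilon: float
) -> np.ndarray:
    """Evaluate the statistic for every label split.

    ``frac``: units x samples fractions (invalid samples removed);
    ``masks``: splits x samples boolean, True = first group.  Splits with
    fewer than two samples in either group yield NaN.
    """
    m = masks.astype(float)
    n1 = m.sum(axis=1)
    n2 = masks.shape[1] - n1
    with np.errstate(invalid="ignore", divide="ignore"):
        s1 = frac @ m.T  # units x splits
        s2 = frac.sum(axis=1, keepdims=True) - s1
        m1 = s1 / n1
        m2 = s2 / n2
        if statistic == "unit_fraction":
            q = frac**2
            q1 = q @ m.T
            q2 = q.sum(axis=1, keepdims=True) - q1
            v1 = (q1 - n1 * m1**2) / (n1 - 1)
            v2 = (q2 - n2 * m2**2) / (n2 - 1)
            v1 = np.maximum(v1, 0.0)
            v2 = np.maximum(v2, 0.0)
            t = ((m1 - m2) ** 2 / (v1 + v2 + epsilon)).mean(axis=0)
        elif statistic == "jsd":
            mid = 0.5 * (m1 + m2)
            t = np.sqrt(
                np.maximum(_entropy2(mid)
                           - 0.5 * (_entropy2(m1) + _entropy2(m2)), 0.0)
            )
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
    t = np.where((n1 >= 2) & (n2 >= 2), t, np.nan)
    return t


def _label_masks(
    labels: np.ndarray, n_perm: int, seed: int, exact: str
) -> tuple[np.ndarray, bool]:
    """Boolean split matrix (splits x samples) for the permutation test.

    ``exact='auto'`` enumerates every distinct label split when there
    are no more of them than ``n_perm``; ``'always'`` forces
    enumeration; ``'never'`` always Monte-Carlo samples ``n_perm``
    splits with replacement.  Returns (masks, is_exact).
    """
    base = labels == pd.unique(labels)[0]
    n = len(labels)
    n1 = int(base.sum())
    n_distinct = int(comb(n, n1, exact=True))
    if exact == "always" or (exact == "auto" and n_distinct <= n_perm):
        masks = np.zeros((n_distinct, n), dtype=bool)
        for i, idx in enumerate(itertools.combinations(range(n), n1)):
            masks[i, list(idx)] = True
        return masks, True
    rng = np.random.default_rng(seed)
    masks = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        masks[i] = base[rng.permutation(n)]
    return masks, False


def permutation_pvalues(
    counts: pd.DataFrame,
    units,
    design: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    statistic: str = "unit_fraction",
    exact: str = "never",
    ties: str = "randomized",
    epsilon: float = EPSILON,
) -> pd.DataFrame:
    """Gene-level permutation test of differential unit usage.

    Condition labels are permuted jointly across all genes per
    iteration.  Monte-Carlo p-values use the add-one convention
    ``(1 + #{T* > T} + U * #{T* = T}) / (n_perm + 1)``, where U is a
    per-gene Uniform(0,1) draw: randomizing over permutation ties keeps
    null p-values uniform even when the design is so small that the
    statistic's permutation distribution is coarse (a 3 vs 3 design has
    only 20 label splits).  ``ties='count'`` counts ties fully instead
    (p = (1 + #{T* >= T}) / (n_perm + 1), conservative on small
    designs).  With ``exact='always'`` (or ``'auto'`` when the design
    is small enough) all distinct label splits are enumerated and the
    p-value is the exact tail fraction #{T* >= T} / n_splits.  Genes
    with fewer than two usable replicates in a condition, or fewer than
    two counting units, are flagged with NaN and excluded from the BH
    adjustment.

    ``units`` maps gene_id -> list of CountingUnit (or is a flat list);
    it defines which count-matrix rows belong to which gene.
    Returns a ScoreTable with ``ranking_score = 1 - p_adj``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if exact not in ("never", "auto", "always"):
        raise ValueError(f"exact must be never/auto/always, got {exact!r}")
    if ties not in ("randomized", "count"):
        raise ValueError(f"ties must be randomized/count, got {ties!r}")
    by_gene: dict[str, list[str]] = {}
    flat = itertools.chain.from_iterable(units.values()) if isinstance(
        units, dict) else units
    for u in flat:
        by_gene.setdefault(u.gene_id, []).append(u.unit_id)

    labels = design.reindex(counts.columns).to_numpy()
    if len(pd.unique(labels)) != 2:
        raise ValueError("design must have exactly two non-empty conditions")
    obs_mask = (labels == pd.unique(labels)[0])[None, :]
    masks, is_exact = _label_masks(labels, n_perm, seed, exact)
    tie_rng = np.random.default_rng(seed + 0x5EED)

    x_all = counts.to_numpy(dtype=float)
    row_of = {uid: i for i, uid in enumerate(counts.index)}

    rows = []
    for gene_id, unit_ids in by_gene.items():
        try:
            ridx = [row_of[uid] for uid in unit_ids]
        except KeyError as e:
            raise KeyError(f"unit {e.args[0]!r} missing from count matrix") from None
        x = x_all[ridx]
        if x.shape[0] < 2:
            rows.append((gene_id, np.nan, np.nan))
            continue
        totals = x.sum(axis=0)
        valid = totals > 0
        frac = x[:, valid] / totals[valid]
        t_obs = _stat_from_masks(frac, obs_mask[:, valid], statistic, epsilon)[0]
        if np.isnan(t_obs):
            rows.append((gene_id, np.nan, np.nan))
            continue
        t_perm = _stat_from_masks(frac, masks[:, valid], statistic, epsilon)
        tv = t_perm[~np.isnan(t_perm)]
        n_ok = len(tv)
        # the statistic is label-swap symmetric, so complementary splits
        # give the same value up to float rounding: detect ties tolerantly
        eq = np.isclose(tv, t_obs, rtol=1e-9, atol=1e-12)
        greater = int((tv > t_obs).sum() - (eq & (tv > t_obs)).sum())
        n_eq = int(eq.sum())
        if is_exact:
            p = (greater + n_eq) / n_ok
        elif ties == "count":
            p = (1 + greater + n_eq) / (n_ok + 1)
        else:
            u = float(tie_rng.random())
            p = (1 + greater + u * n_eq) / (n_ok + 1)
        rows.append((gene_id, float(t_obs), float(p)))

    table = pd.DataFrame(rows, columns=["target_id", "statistic", "p_value"])
    padj = np.full(len(table), np.nan)
    scored = table["p_value"].notna().to_numpy()
    if scored.any():
        padj[scored] = adjust_pvalues(table.loc[scored, "p_value"].tolist(), "BH")
    table["p_adj"] = padj
    table["ranking_score"] = 1.0 - table["p_adj"]
    return table


# ---------------------------------------------------------------------------
# Jensen-Shannon divergence
# ---------------------------------------------------------------------------


def jsd(p, q, tol: float = 1e-6) -> float:
    """Jensen-Shannon divergence in bits: H((p+q)/2) - (H(p)+H(q))/2."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    for name, v in (("p", p), ("q", q)):
        if (v < 0).any() or abs(v.sum() - 1.0) > tol:
            raise ValueError(f"{name} must be a proportion vector summing to 1")
    mid = 0.5 * (p + q)
    val = _entropy2(mid[:, None]) - 0.5 * (
        _entropy2(p[:, None]) + _entropy2(q[:, None])
    )
    return float(max(val[0], 0.0))


def sqrt_jsd(p, q) -> float:
    """Square root of the Jensen-Shannon divergence (a metric)."""
    return math.sqrt(jsd(p, q))


def jsd_proportion_test(
    counts: pd.DataFrame,
    units,
    design: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    exact: str = "never",
    ties: str = "randomized",
) -> pd.DataFrame:
    """Permutation test on sqrt(JSD) between the conditions' mean
    unit-fraction vectors; same schema and conventions as
    :func:`permutation_pvalues`."""
    return permutation_pvalues(
        counts, units, design, n_perm=n_perm, seed=seed, statistic="jsd",
        exact=exact, ties=ties,
    )


# ---------------------------------------------------------------------------
# exon inclusion level (psi)
# ---------------------------------------------------------------------------


def psi_test(
    counts: pd.DataFrame,
    event,
    design: pd.Series,
    units=None,
    c: float = 0.1,
    n_boot: int = 1000,
    seed: int = 0,
    length_normalize: bool = True,
) -> PsiResult:
    """Bootstrap test that an event's inclusion level shifts by more
    than ``c`` between conditions.

    Per sample, psi = inclusion / (inclusion + exclusion) after dividing
    each side's summed counts by its summed effective length (the
    normalization corrects for inclusion forms simply being longer; pass
    ``length_normalize=False`` for the raw count ratio).  The score is
    the bootstrap probability, over within-condition resampling of
    replicates, that |mean psi_1 - mean psi_2| > c.
    """
    if event.type not in ("SE", "IR", "A3SS", "A5SS", "MXE"):
        raise ValueError(f"{event.event_id}: psi is defined for simple events only")
    if not 0.0 <= c < 1.0:
        raise ValueError(f"cutoff c must be in [0, 1), got {c}")
    inc_ids = sorted(event.inclusion_units)
    exc_ids = sorted(event.exclusion_units)
    for uid in inc_ids + exc_ids:
        if uid not in counts.index:
            raise KeyError(f"unit {uid!r} missing from count matrix")
    inc = counts.loc[inc_ids].sum(axis=0).to_numpy(dtype=float)
    exc = counts.loc[exc_ids].sum(axis=0).to_numpy(dtype=float)
    if length_normalize:
        if units is None:
            raise ValueError("length_normalize=True requires the counting units")
        flat = itertools.chain.from_iterable(units.values()) if isinstance(
            units, dict) else units
        eff = {u.unit_id: u.effective_length for u in flat}
        inc = inc / sum(eff[u] for u in inc_ids)
        exc = exc / sum(eff[u] for u in exc_ids)
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(inc + exc > 0, inc / (inc + exc), np.nan)
    psi_s = pd.Series(psi, index=counts.columns, name="psi")

    labels = design.reindex(counts.columns).to_numpy()
    conds = pd.unique(labels)
    if len(conds) != 2:
        raise ValueError("design must have exactly two conditions")
    groups = [psi[(labels == cond) & ~np.isnan(psi)] for cond in conds]
    if any(len(g) == 0 for g in groups):
        return PsiResult(event.event_id, psi_s, c, float("nan"), True)
    rng = np.random.default_rng(seed)
    draws = [
        g[rng.integers(0, len(g), size=(n_boot, len(g)))].mean(axis=1)
        for g in groups
    ]
    score = float(np.mean(np.abs(draws[0] - draws[1]) > c))
    return PsiResult(event.event_id, psi_s, c, score, False)


def gene_level_bonferroni(unit_pvalues) -> float:
    """Bonferroni aggregation: min(1, k * min(p)) over k unit p-values."""
    ps = list(unit_pvalues)
    if not ps:
        raise ValueError("no unit-level p-values given")
    if any(p < 0 or p > 1 for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    return min(1.0, len(ps) * min(ps))


# ---------------------------------------------------------------------------
# ScoreTable I/O
# ---------------------------------------------------------------------------


def write_scores(table: pd.DataFrame, path: str, comment: str | None = None):
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_scores(path: str) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", comment="#")
    if "target_id" not in t.columns:
        raise ValueError(f"{path}: score table lacks a target_id column")
    return t
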