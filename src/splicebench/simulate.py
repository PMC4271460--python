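"""Two-condition negative-binomial count simulation with controlled
differential splicing.

The simulator works at the counting-unit level.  For each sample the
gene total is drawn from a negative binomial (mean ``mu * depth_factor``,
variance ``mu + alpha * mu**2``), split into per-transcript counts by a
multinomial over the gene's isoform proportions, and each transcript's
reads are scattered over its counting units with probabilities
proportional to unit effective length.  Differential splicing is
injected through PALT, the relative abundance of one designated
alternative isoform: true-AS genes carry ``palt_control`` in condition 1
and ``palt_treatment`` in condition 2, with the remaining mass split
equally among the standard isoforms.  Non-AS multi-isoform genes reuse
one Dirichlet-drawn proportion vector in both conditions, so their
condition labels are exchangeable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from splicebench.gene_models import CountingUnit, GeneModel, flatten_gene

__all__ = [
    "NBGeneParams",
    "ScenarioConfig",
    "IsoformProportions",
    "SimulationResult",
    "estimate_nb",
    "default_nb_params",
    "choose_true_as_genes",
    "assign_proportions",
    "simulate_counts",
    "simulate_scenario",
    "event_counts",
    "make_design",
    "write_counts",
    "read_counts",
    "write_truth",
    "read_truth",
]

CONDITIONS = ("control", "treatment")


@dataclass(frozen=True)
class NBGeneParams:
    """Negative-binomial parameters of one gene's total read count.

    ``mu`` is the mean total count at baseline depth; ``alpha_control``
    and ``alpha_treatment`` are the per-condition dispersions
    (Var = mu + alpha * mu**2; alpha = 0 is the Poisson limit).
    """

    gene_id: str
    mu: float
    alpha_control: float
    alpha_treatment: float

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError(f"{self.gene_id}: mu must be >= 0")
        if self.alpha_control < 0 or self.alpha_treatment < 0:
            raise ValueError(f"{self.gene_id}: alpha must be >= 0")

    def alpha(self, condition: str, pattern: str) -> float:
        """Dispersion used for ``condition`` under a dispersion pattern.

        ``Same`` forces both conditions onto the control dispersion;
        ``Diff`` uses each condition's own estimate.
        """
        if pattern == "Same":
            return self.alpha_control
        if pattern == "Diff":
            return (
                self.alpha_control if condition == "control" else self.alpha_treatment
            )
        raise ValueError(f"dispersion_pattern must be 'Diff' or 'Same', got {pattern!r}")


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation design cell.

    ``palt_control``/``palt_treatment`` set the alternative-isoform
    fraction of true-AS genes in the two conditions (0.2 vs 0.4/0.6/0.8
    are the canonical low/medium/high contrasts).  ``depth_factor``
    scales gene means multiplicatively (1.0 is the 100x baseline, 0.6
    and 0.25 the shallower libraries).
    """

    palt_control: float = 0.2
    palt_treatment: float = 0.8
    dispersion_pattern: str = "Diff"
    depth_factor: float = 1.0
    n_replicates: tuple[int, int] = (3, 3)
    n_true_as: int = 0
    read_length: int = 100
    seed: int = 0

    def __post_init__(self):
        for p in (self.palt_control, self.palt_treatment):
            if not 0.0 < p < 1.0:
                raise ValueError(f"PALT must be in (0, 1), got {p}")
        if self.dispersion_pattern not in ("Diff", "Same"):
            raise ValueError(
                f"dispersion_pattern must be 'Diff' or 'Same', "
                f"got {self.dispersion_pattern!r}"
            )
        if self.depth_factor < 0:
            raise ValueError("depth_factor must be >= 0")
        n1, n2 = self.n_replicates
        if n1 < 1 or n2 < 1:
            raise ValueError("need at least one replicate per condition")
        if self.read_length < 2:
            raise ValueError("read_length must be >= 2")


@dataclass(frozen=True)
class IsoformProportions:
    """Per-condition isoform proportion vectors of one gene."""

    gene_id: str
    theta: dict[str, dict[str, float]]  # condition -> transcript_id -> fraction

    def __post_init__(self):
        for cond, th in self.theta.items():
            tot = sum(th.values())
            if any(v < 0 for v in th.values()) or abs(tot - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.gene_id}/{cond}: proportions must be >= 0 and sum to 1"
                )


def make_design(n_control: int, n_treatment: int) -> pd.Series:
    """Condition label per sample id, e.g. control_1 ... treatment_3."""
    idx, vals = [], []
    for cond, n in zip(CONDITIONS, (n_control, n_treatment)):
        for r in range(1, n + 1):
            idx.append(f"{cond}_{r}")
            vals.append(cond)
    return pd.Series(vals, index=idx, name="condition")


# ---------------------------------------------------------------------------
# NB parameter estimation and defaults
# ---------------------------------------------------------------------------


def estimate_nb(
    counts: pd.DataFrame,
    design: pd.Series | None = None,
    pooling: str = "per_condition",
) -> list[NBGeneParams]:
    """Method-of-moments NB fits per gene (rows) from a count matrix.

    Per gene, ``mu`` is the grand sample mean.  With
    ``pooling='per_condition'`` each condition's dispersion is
    ``max(0, (s^2 - m) / m^2)`` from its own replicates; with
    ``pooling='pooled'`` one dispersion is estimated from all samples
    after centering each condition at its own mean, and shared by both
    conditions.  Genes with zero mean are returned with mu = alpha = 0
    (unexpressed).
    """
    if pooling not in ("per_condition", "pooled"):
        raise ValueError(f"pooling must be per_condition or pooled, got {pooling!r}")
    if design is None:
        design = pd.Series("control", index=counts.columns, name="condition")
    groups = {c: design.index[design == c].tolist() for c in design.unique()}
    for cond, cols in groups.items():
        if len(cols) < 2:
            raise ValueError(f"need >= 2 samples per group, {cond} has {len(cols)}")

    def mom_alpha(x: np.ndarray) -> float:
        m = x.mean()
        if m == 0:
            return 0.0
        s2 = x.var(ddof=1)
        return max(0.0, float((s2 - m) / m**2))

    out = []
    conds = list(groups)
    for gene_id, row in counts.iterrows():
        x = row.to_numpy(dtype=float)
        mu = float(x.mean())
        if mu == 0:
            out.append(NBGeneParams(gene_id, 0.0, 0.0, 0.0))
            continue
        if pooling == "per_condition":
            alphas = {c: mom_alpha(row[groups[c]].to_numpy(float)) for c in conds}
        else:
            resid, n_used = [], 0
            for c in conds:
                xc = row[groups[c]].to_numpy(float)
                resid.append(xc - xc.mean())
                n_used += len(xc)
            r = np.concatenate(resid)
            s2 = float((r**2).sum() / (n_used - len(conds)))
            a = max(0.0, (s2 - mu) / mu**2)
            alphas = {c: a for c in conds}
        a1 = alphas.get("control", alphas[conds[0]])
        a2 = alphas.get("treatment", alphas[conds[-1]])
        out.append(NBGeneParams(gene_id, mu, a1, a2))
    return out


def default_nb_params(
    gene_ids: list[str],
    seed: int = 0,
    mu_median: float = 200.0,
    sigma_log: float = 1.5,
    alpha_range: tuple[float, float] = (0.05, 0.5),
) -> list[NBGeneParams]:
    """Synthetic baseline NB parameters for use without calibration data.

    Gene means are log-normal (median ``mu_median``, log-sd
    ``sigma_log``), a right-skewed shape typical of bulk RNA-seq totals;
    per-condition dispersions are uniform on ``alpha_range``.  These are
    synthetic defaults, intended for self-contained benchmarking runs.
    """
    rng = np.random.default_rng(seed)
    mus = np.exp(rng.normal(np.log(mu_median), sigma_log, size=len(gene_ids)))
    a1 = rng.uniform(*alpha_range, size=len(gene_ids))
    a2 = rng.uniform(*alpha_range, size=len(gene_ids))
    return [
        NBGeneParams(g, float(m), float(x), float(y))
        for g, m, x, y in zip(gene_ids, mus, a1, a2)
    ]


# ---------------------------------------------------------------------------
# truth and proportions
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = [
    "gene_id",
    "is_true_as",
    "alt_transcript_id",
    "palt_control",
    "palt_treatment",
]


def choose_true_as_genes(
    genes: list[GeneModel],
    params: list[NBGeneParams],
    n: int,
    seed: int = 0,
    palt_control: float = 0.2,
    palt_treatment: float = 0.8,
) -> pd.DataFrame:
    """Pick ``n`` true-AS genes and their alternative isoforms.

    Eligible genes have at least two transcripts and non-zero expression;
    the sample is uniform without replacement and one transcript per
    selected gene is drawn uniformly as the alternative isoform.
    Returns the TruthTable with one row per input gene.
    """
    mu = {p.gene_id: p.mu for p in params}
    eligible = [
        g.gene_id for g in genes if g.n_transcripts >= 2 and mu.get(g.gene_id, 0) > 0
    ]
    if n > len(eligible):
        raise ValueError(
            f"sampling error: requested {n} true-AS genes, only "
            f"{len(eligible)} eligible"
        )
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(eligible, size=n, replace=False)) if n else set()
    by_id = {g.gene_id: g for g in genes}
    rows = []
    for g in genes:
        if g.gene_id in chosen:
            tids = [t.transcript_id for t in by_id[g.gene_id].transcripts]
            alt = tids[int(rng.integers(len(tids)))]
            rows.append((g.gene_id, True, alt, palt_control, palt_treatment))
        else:
            rows.append((g.gene_id, False, None, np.nan, np.nan))
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def assign_proportions(
    gene: GeneModel,
    truth_row,
    scenario: ScenarioConfig,
    rng: np.random.Generator,
) -> IsoformProportions:
    """Build the per-condition isoform proportion vectors of one gene.

    True-AS genes give the alternative transcript PALT_control /
    PALT_treatment and split the remainder equally among standard
    isoforms.  Non-AS multi-isoform genes draw one symmetric
    Dirichlet(1) vector and use it in both conditions; single-isoform
    genes are degenerate at 1.
    """
    tids = [t.transcript_id for t in gene.transcripts]
    if len(tids) == 1:
        th = {tids[0]: 1.0}
        return IsoformProportions(gene.gene_id, {c: dict(th) for c in CONDITIONS})
    if bool(truth_row.is_true_as):
        alt = truth_row.alt_transcript_id
        if alt not in tids:
            raise ValueError(
                f"{gene.gene_id}: alternative transcript {alt!r} not in gene"
            )
        theta = {}
        for cond, palt in zip(
            CONDITIONS, (scenario.palt_control, scenario.palt_treatment)
        ):
            rest = (1.0 - palt) / (len(tids) - 1)
            theta[cond] = {t: (palt if t == alt else rest) for t in tids}
        return IsoformProportions(gene.gene_id, theta)
    v = rng.dirichlet(np.ones(len(tids)))
    th = {t: float(p) for t, p in zip(tids, v)}
    return IsoformProportions(gene.gene_id, {c: dict(th) for c in CONDITIONS})


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mean: float, alpha: float) -> int:
    if mean <= 0:
        return 0
    if alpha <= 0:
        return int(rng.poisson(mean))
    size = 1.0 / alpha
    p = size / (size + mean)
    return int(rng.negative_binomial(size, p))


@dataclass
class SimulationResult:
    counts: pd.DataFrame  # units x samples, integer
    design: pd.Series  # sample -> condition
    truth: pd.DataFrame  # TruthTable
    units: dict[str, list[CountingUnit]]  # gene_id -> counting units
    proportions: dict[str, IsoformProportions]
    scenario: ScenarioConfig = field(default=None)


def simulate_counts(
    genes: list[GeneModel],
    units: dict[str, list[CountingUnit]],
    params: list[NBGeneParams],
    proportions: dict[str, IsoformProportions],
    scenario: ScenarioConfig,
    truth: pd.DataFrame | None = None,
) -> SimulationResult:
    """Draw the unit x sample count matrix for one scenario.

    Two-step scheme per gene and sample: the gene total is NB with mean
    ``mu * depth_factor`` and the condition's dispersion; transcript
    counts are multinomial on the condition's isoform proportions; each
    transcript's reads land on its member units with probability
    proportional to effective length.  Counts of shared units add up
    across transcripts, so per-sample totals are conserved exactly.
    """
    par = {p.gene_id: p for p in params}
    missing = [g.gene_id for g in genes if g.gene_id not in par]
    if missing:
        raise ValueError(f"NB parameters missing for genes: {missing[:5]}")
    design = make_design(*scenario.n_replicates)
    rng = np.random.default_rng(scenario.seed)

    unit_index: list[str] = []
    for g in genes:
        unit_index.extend(u.unit_id for u in units[g.gene_id])
    mat = np.zeros((len(unit_index), len(design)), dtype=np.int64)
    row_of = {uid: i for i, uid in enumerate(unit_index)}

    for g in genes:
        gunits = units[g.gene_id]
        tids = {t.transcript_id for t in g.transcripts}
        for u in gunits:
            if not u.member_transcripts <= tids:
                raise ValueError(
                    f"consistency error: unit {u.unit_id} references unknown "
                    f"transcripts of {g.gene_id}"
                )
        # per transcript: unit row indices and effective-length weights
        alloc = {}
        for t in g.transcripts:
            mine = [u for u in gunits if t.transcript_id in u.member_transcripts]
            w = np.array([u.effective_length for u in mine], dtype=float)
            alloc[t.transcript_id] = (
                np.array([row_of[u.unit_id] for u in mine]),
                w / w.sum(),
            )
        theta = proportions[g.gene_id].theta
        p = par[g.gene_id]
        for s, (sample, cond) in enumerate(design.items()):
            total = _nb_draw(
                rng,
                p.mu * scenario.depth_factor,
                p.alpha(cond, scenario.dispersion_pattern),
            )
            if total == 0:
                continue
            th = theta[cond]
            tid_list = list(th)
            tcounts = rng.multinomial(total, [th[t] for t in tid_list])
            for tid, n_t in zip(tid_list, tcounts):
                if n_t == 0:
                    continue
                rows, w = alloc[tid]
                mat[rows, s] += rng.multinomial(int(n_t), w)

    counts = pd.DataFrame(mat, index=pd.Index(unit_index, name="unit_id"),
                          columns=design.index)
    if truth is None:
        truth = pd.DataFrame(
            [(g.gene_id, False, None, np.nan, np.nan) for g in genes],
            columns=TRUTH_COLUMNS,
        )
    return SimulationResult(counts, design, truth, units, proportions, scenario)


def simulate_scenario(
    genes: list[GeneModel],
    scenario: ScenarioConfig,
    params: list[NBGeneParams] | None = None,
) -> SimulationResult:
    """Convenience wrapper: pick truth, assign proportions, simulate.

    All randomness (gene choice, proportions, counts) derives from
    ``scenario.seed``.
    """
    if params is None:
        params = default_nb_params(
            [g.gene_id for g in genes], seed=scenario.seed + 1_000_003
        )
    truth = choose_true_as_genes(
        genes,
        params,
        scenario.n_true_as,
        seed=scenario.seed + 7,
        palt_control=scenario.palt_control,
        palt_treatment=scenario.palt_treatment,
    )
    rng = np.random.default_rng(scenario.seed + 13)
    props = {}
    truth_by_gene = {r.gene_id: r for r in truth.itertuples()}
    for g in genes:
        props[g.gene_id] = assign_proportions(g, truth_by_gene[g.gene_id],
                                              scenario, rng)
    units = {g.gene_id: flatten_gene(g, scenario.read_length) for g in genes}
    return simulate_counts(genes, units, params, props, scenario, truth)


def event_counts(counts: pd.DataFrame, event) -> pd.DataFrame:
    """Per-sample inclusion/exclusion read counts of one splice event."""
    if not event.inclusion_units or not event.exclusion_units:
        raise ValueError(
            f"{event.event_id}: event has no counting units on one side "
            "(complex events are not countable)"
        )
    for uid in event.inclusion_units | event.exclusion_units:
        if uid not in counts.index:
            raise KeyError(f"unit {uid!r} missing from count matrix")
    inc = counts.loc[sorted(event.inclusion_units)].sum(axis=0)
    exc = counts.loc[sorted(event.exclusion_units)].sum(axis=0)
    return pd.DataFrame({"inclusion": inc, "exclusion": exc})


# ---------------------------------------------------------------------------
# TSV I/O (seed-stamped headers)
# ---------------------------------------------------------------------------


def write_counts(res: SimulationResult, path: str, comment: str | None = None):
    with open(path, "w") as fh:
        sc = res.scenario
        stamp = f"seed={sc.seed}" if sc is not None else "seed=NA"
        fh.write(f"# splicebench counts {stamp}"
                 + (f" {comment}" if comment else "") + "\n")
        fh.write("# conditions: "
                 + " ".join(f"{s}={c}" for s, c in res.design.items()) + "\n")
        res.counts.to_csv(fh, sep="\t")


def read_counts(path: str) -> tuple[pd.DataFrame, pd.Series]:
    design = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# conditions:"):
                pairs = line.split(":", 1)[1].split()
                design = pd.Series(
                    {k: v for k, v in (p.split("=") for p in pairs)},
                    name="condition",
                )
            if not line.startswith("#"):
                break
    counts = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if design is None:
        design = pd.Series(
            [c.rsplit("_", 1)[0] for c in counts.columns],
            index=counts.columns,
            name="condition",
        )
    return counts, design


def write_truth(truth: pd.DataFrame, path: str, seed: int | None = None):
    with open(path, "w") as fh:
        fh.write(f"# splicebench truth seed={'NA' if seed is None else seed}\n")
        truth.to_csv(fh, sep="\t", index=False)


def read_truth(path: str) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", comment="#")
    t["is_true_as"] = t["is_true_as"].astype(bool)
    return t
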