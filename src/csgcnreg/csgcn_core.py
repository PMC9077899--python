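"""Condition-specific co-expression network construction.

The KINC-style procedure: for every gene pair, cluster the 2-D scatter of
paired expression values with Gaussian mixture models (k = 1..5, minimum
BIC), compute Spearman correlation within each sufficiently large cluster
(>= 30 samples), keep clusters with |rho| > 0.5 that survive a Fisher-z
power screen (alpha 0.001, power 0.8), test each cluster for association
with sample conditions (two one-sided z-tests of proportions for
categorical labels, simple linear regression for quantitative covariates),
and remove biased edges (no differential cluster expression, or unbalanced
missingness).  Surviving condition-labeled edges are ranked by similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture
from statsmodels.stats.proportion import proportions_ztest

from .gem_io import GEM, SampleAnnotation

__all__ = [
    "PairCluster",
    "ConditionTestResult",
    "CsgcnEdge",
    "CsgcnParams",
    "prefilter_values",
    "fit_pair_gmm",
    "cluster_spearman",
    "correlation_power",
    "test_condition_categorical",
    "test_condition_quantitative",
    "filter_dce",
    "filter_missingness_bias",
    "rank_edges",
    "build_csgcn",
    "edges_to_frame",
]


@dataclass
class PairCluster:
    """One mixture component of a gene pair's 2-D expression scatter."""

    gene_a: str
    gene_b: str
    component_id: int
    member_samples: list[str]
    k_selected: int
    spearman_rho: float | None = None

    @property
    def n(self) -> int:
        return len(self.member_samples)


@dataclass
class ConditionTestResult:
    condition: str
    p_in_cluster: float = float("nan")  # z-test 1: condition fraction in vs out
    p_capture: float = float("nan")  # z-test 2: cluster capture of condition
    labeled: bool = False
    r_square: float | None = None  # quantitative covariates only
    p_reg: float | None = None
    quantitative: bool = False


@dataclass
class CsgcnEdge:
    """A retained co-expression edge with its provenance and test results."""

    gene_a: str
    gene_b: str
    cluster: PairCluster
    similarity: float
    conditions: dict[str, ConditionTestResult]
    power: float
    dce_fail: bool = False
    missingness_fail: bool = False
    rank: int | None = None

    @property
    def labeled_conditions(self) -> list[str]:
        return [c for c, r in self.conditions.items() if r.labeled]


@dataclass
class CsgcnParams:
    """All thresholds of the construction, at their standard defaults."""

    low: float = 0.0
    high: float = 15.0
    max_k: int = 5
    min_cluster: int = 30
    min_similarity: float = 0.5
    power_alpha: float = 0.001
    min_power: float = 0.8
    cond_alpha: float = 0.001
    r2_min: float = 0.30
    welch_alpha: float = 0.001
    miss_p_cut: float = 0.1
    seed: int = 0
    genes: Sequence[str] | None = None  # optional gene subset
    max_pairs: int | None = None


def prefilter_values(
    x: pd.Series, y: pd.Series, low: float = 0.0, high: float = 15.0
) -> pd.Index:
    """Samples where both genes are non-missing and both values lie in
    [low, high].  Values outside the usable log2 range are ignored."""
    ok = (
        x.notna()
        & y.notna()
        & (x >= low)
        & (x <= high)
        & (y >= low)
        & (y <= high)
    )
    return x.index[ok]


def _pair_seed(global_seed: int, i: int, j: int) -> int:
    # deterministic per-pair stream, independent of enumeration order
    return (global_seed * 1_000_003 + i * 131_071 + j * 8191) % (2**31 - 1)


def fit_pair_gmm(
    x: pd.Series,
    y: pd.Series,
    max_k: int = 5,
    min_cluster: int = 30,
    seed: int = 0,
) -> list[PairCluster]:
    """Cluster a gene pair's paired expression values with 2-D GMMs.

    Fits k = 1..max_k full-covariance mixtures, selects k by minimum BIC,
    assigns samples to their maximum-responsibility component, and returns
    the components with at least ``min_cluster`` members.  Pairs with
    fewer than ``min_cluster`` usable samples are skipped entirely.
    """
    if len(x) != len(y) or not x.index.equals(y.index):
        raise ValueError("x and y must be aligned over the same samples")
    n = len(x)
    if n < min_cluster:
        return []
    data = np.column_stack([x.to_numpy(), y.to_numpy()])
    best_bic = np.inf
    best: GaussianMixture | None = None
    for k in range(1, max_k + 1):
        if k > n:
            break
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            init_params="k-means++",
            n_init=1,
            random_state=seed,
            reg_covar=1e-6,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm.fit(data)
        except ValueError:
            warnings.warn(f"GMM fit failed at k={k}; skipped")
            continue
        if not gm.converged_:
            warnings.warn(f"GMM did not converge at k={k}; skipped")
            continue
        bic = gm.bic(data)
        if bic < best_bic:
            best_bic, best = bic, gm
    if best is None:
        return []
    labels = best.predict(data)
    clusters: list[PairCluster] = []
    for comp in range(best.n_components):
        members = x.index[labels == comp]
        if len(members) < min_cluster:
            continue
        clusters.append(
            PairCluster(
                gene_a=str(x.name),
                gene_b=str(y.name),
                component_id=comp,
                member_samples=list(members),
                k_selected=best.n_components,
            )
        )
    return clusters


def cluster_spearman(
    cluster: PairCluster,
    x: pd.Series,
    y: pd.Series,
    threshold: float = 0.5,
) -> PairCluster | None:
    """Spearman correlation over cluster members; the cluster becomes an
    edge candidate iff |rho| > threshold."""
    xv = x.loc[cluster.member_samples].to_numpy()
    yv = y.loc[cluster.member_samples].to_numpy()
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return None  # zero variance: correlation undefined
    rho = stats.spearmanr(xv, yv).statistic
    if np.isnan(rho) or abs(rho) <= threshold:
        return None
    cluster.spearman_rho = float(rho)
    return cluster


def correlation_power(n: int, r: float, alpha: float = 0.001) -> float:
    """Power of the two-sided correlation test via the Fisher z
    approximation: Phi(|atanh r| * sqrt(n - 3) - z_{1-alpha/2})."""
    if abs(r) >= 1.0:
        return 1.0
    if n < 4:
        raise ValueError("need n >= 4 for the Fisher z approximation")
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.cdf(abs(np.arctanh(r)) * np.sqrt(n - 3) - z_crit))


def test_condition_categorical(
    cluster: PairCluster,
    annot: SampleAnnotation,
    condition: str,
    analyzable: Iterable[str],
    alpha: float = 0.001,
) -> ConditionTestResult:
    """Two one-sided z-tests of proportions for one condition label.

    Test 1: the fraction of in-cluster samples carrying ``condition``
    against the same fraction among the pair's out-of-cluster samples.
    Test 2: the fraction of ``condition`` samples captured by the cluster
    against the capture rate of non-``condition`` samples.  The cluster is
    labeled with the condition iff both enrichment p-values < alpha.
    """
    analyzable = pd.Index(analyzable)
    in_cluster = pd.Index(cluster.member_samples)
    out_cluster = analyzable.difference(in_cluster)
    labels = annot.condition.loc[analyzable]
    is_cond = labels == condition

    n_in, n_out = len(in_cluster), len(out_cluster)
    x_in = int(is_cond.loc[in_cluster].sum())
    x_out = int(is_cond.loc[out_cluster].sum())
    n_cond = x_in + x_out
    n_not = (n_in + n_out) - n_cond

    res = ConditionTestResult(condition=condition)
    if n_cond == 0 or n_out == 0 or n_not == 0:
        return res  # degenerate: p-values undefined, not labeled
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p1 = proportions_ztest(
            [x_in, x_out], [n_in, n_out], alternative="larger"
        )
        _, p2 = proportions_ztest(
            [x_in, n_in - x_in], [n_cond, n_not], alternative="larger"
        )
    res.p_in_cluster = float(p1) if np.isfinite(p1) else float("nan")
    res.p_capture = float(p2) if np.isfinite(p2) else float("nan")
    res.labeled = bool(
        np.isfinite(p1) and np.isfinite(p2) and p1 < alpha and p2 < alpha
    )
    return res


def test_condition_quantitative(
    cluster: PairCluster,
    covariate: pd.Series,
    analyzable: Iterable[str],
    name: str = "covariate",
    r2_min: float = 0.30,
    alpha: float = 0.001,
) -> ConditionTestResult:
    """Simple linear regression between the cluster-membership indicator
    and a quantitative covariate over the pair's analyzable samples.
    Labeled iff r^2 > r2_min and slope p < alpha.  (r^2 and the slope
    p-value are identical in both regression orientations.)"""
    analyzable = pd.Index(analyzable)
    member = analyzable.isin(cluster.member_samples).astype(float)
    cov = covariate.loc[analyzable].to_numpy(dtype=float)
    res = ConditionTestResult(condition=name, quantitative=True)
    ok = np.isfinite(cov)
    if ok.sum() < 3 or np.ptp(cov[ok]) == 0 or np.ptp(member[ok]) == 0:
        return res
    fit = stats.linregress(cov[ok], member[ok])
    res.r_square = float(fit.rvalue**2)
    res.p_reg = float(fit.pvalue)
    res.labeled = bool(res.r_square > r2_min and res.p_reg < alpha)
    return res


def filter_dce(
    cluster: PairCluster,
    x: pd.Series,
    y: pd.Series,
    analyzable: Iterable[str],
    alpha: float = 0.001,
) -> tuple[bool, float, float]:
    """Differential-cluster-expression screen (Welch test per gene).

    Both genes must shift expression between in-cluster and out-of-cluster
    samples (p <= alpha for each); with two groups Welch's one-way ANOVA
    reduces to Welch's t-test.  Returns (keep, p_gene_a, p_gene_b).
    """
    analyzable = pd.Index(analyzable)
    in_idx = pd.Index(cluster.member_samples)
    out_idx = analyzable.difference(in_idx)
    ps: list[float] = []
    for v in (x, y):
        a = v.loc[in_idx].dropna().to_numpy()
        b = v.loc[out_idx].dropna().to_numpy()
        if a.size < 2 or b.size < 2 or (np.ptp(a) == 0 and np.ptp(b) == 0):
            ps.append(float("nan"))  # undefined -> gene fails the screen
            continue
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
        ps.append(float(p))
    keep = all(np.isfinite(p) and p <= alpha for p in ps)
    return keep, ps[0], ps[1]


def filter_missingness_bias(
    cluster: PairCluster,
    x_full: pd.Series,
    y_full: pd.Series,
    annot: SampleAnnotation,
    conditions: Sequence[str],
    p_cut: float = 0.1,
) -> tuple[bool, float]:
    """Unbalanced-missingness screen.

    Within the samples of each labeled condition, the per-sample
    missingness indicators of the two genes are compared by Student's
    t-test; a significant difference (p < p_cut) means missing values hit
    one gene but not the other in that condition — the sample removal that
    preceded correlation would then bias the condition association, so the
    edge is dropped.  With no missing values at all (or identical
    patterns) the test is undefined and the edge is trivially kept.
    Returns (keep, smallest p over labeled conditions).
    """
    p_min = float("nan")
    for cond in conditions:
        samples = annot.samples_of(cond)
        ma = x_full.loc[samples].isna().to_numpy(dtype=float)
        mb = y_full.loc[samples].isna().to_numpy(dtype=float)
        if ma.size < 2:
            continue
        if np.ptp(ma) == 0 and np.ptp(mb) == 0:
            continue  # constant (e.g. no missingness): balanced
        p = stats.ttest_ind(ma, mb, equal_var=True).pvalue
        if np.isfinite(p) and (np.isnan(p_min) or p < p_min):
            p_min = float(p)
    keep = np.isnan(p_min) or p_min >= p_cut
    return keep, p_min


def rank_edges(edges: list[CsgcnEdge]) -> list[CsgcnEdge]:
    """Stable sort by |similarity| desc, then r^2 desc (when present),
    then smallest condition p ascending.  No edges are removed."""

    def key(e: CsgcnEdge):
        r2s = [
            r.r_square
            for r in e.conditions.values()
            if r.labeled and r.r_square is not None
        ]
        ps = [
            p
            for r in e.conditions.values()
            if r.labeled
            for p in (r.p_in_cluster, r.p_capture, r.p_reg)
            if p is not None and np.isfinite(p)
        ]
        return (-abs(e.similarity), -(max(r2s) if r2s else -np.inf), min(ps) if ps else np.inf)

    ranked = sorted(edges, key=key)
    for i, e in enumerate(ranked, start=1):
        e.rank = i
    return ranked


def build_csgcn(
    gem: GEM,
    annot: SampleAnnotation,
    params: CsgcnParams | None = None,
) -> list[CsgcnEdge]:
    """Run the full per-pair pipeline and return the ranked edge list.

    Pairs are enumerated over the upper triangle of the (optionally
    subset) gene list, each with its own seed stream so results do not
    depend on enumeration order or sample column order.
    """
    p = params or CsgcnParams()
    annot.validate_against(gem)
    genes = list(p.genes) if p.genes is not None else list(gem.gene_ids)
    gene_pos = {g: i for i, g in enumerate(gem.gene_ids)}
    # canonical sample order from the annotation, for column-order invariance
    sample_order = [s for s in annot.sample_ids if s in set(gem.sample_ids)]
    values = gem.values.loc[:, sample_order]
    conditions = annot.conditions
    covariates = annot.covariates.columns

    edges: list[CsgcnEdge] = []
    n_pairs = 0
    for ga, gb in combinations(sorted(genes), 2):
        if p.max_pairs is not None and n_pairs >= p.max_pairs:
            break
        n_pairs += 1
        x_full = values.loc[ga]
        y_full = values.loc[gb]
        keep_idx = prefilter_values(x_full, y_full, p.low, p.high)
        if len(keep_idx) < p.min_cluster:
            continue
        x = x_full.loc[keep_idx]
        y = y_full.loc[keep_idx]
        seed = _pair_seed(p.seed, gene_pos[ga], gene_pos[gb])
        clusters = fit_pair_gmm(
            x, y, max_k=p.max_k, min_cluster=p.min_cluster, seed=seed
        )
        for cluster in clusters:
            cand = cluster_spearman(cluster, x, y, threshold=p.min_similarity)
            if cand is None:
                continue
            power = correlation_power(cand.n, cand.spearman_rho, p.power_alpha)
            if power < p.min_power:
                continue
            results: dict[str, ConditionTestResult] = {}
            for cond in conditions:
                results[cond] = test_condition_categorical(
                    cand, annot, cond, keep_idx, alpha=p.cond_alpha
                )
            for cov in covariates:
                results[cov] = test_condition_quantitative(
                    cand,
                    annot.covariates[cov],
                    keep_idx,
                    name=cov,
                    r2_min=p.r2_min,
                    alpha=p.cond_alpha,
                )
            if not any(r.labeled for r in results.values()):
                continue
            edge = CsgcnEdge(
                gene_a=ga,
                gene_b=gb,
                cluster=cand,
                similarity=cand.spearman_rho,
                conditions=results,
                power=power,
            )
            keep_dce, _, _ = filter_dce(cand, x, y, keep_idx, alpha=p.welch_alpha)
            if not keep_dce:
                edge.dce_fail = True
                continue
            labeled = [c for c in edge.labeled_conditions if c in conditions]
            keep_miss, _ = filter_missingness_bias(
                cand, x_full, y_full, annot, labeled, p_cut=p.miss_p_cut
            )
            if not keep_miss:
                edge.missingness_fail = True
                continue
            edges.append(edge)
    return rank_edges(edges)


def edges_to_frame(edges: list[CsgcnEdge]) -> pd.DataFrame:
    """KINC-like edge table, one row per (edge, labeled condition)."""
    rows = []
    for e in edges:
        for cond in e.labeled_conditions:
            r = e.conditions[cond]
            rows.append(
                {
                    "source": e.gene_a,
                    "target": e.gene_b,
                    "similarity": e.similarity,
                    "cluster_index": e.cluster.component_id,
                    "cluster_size": e.cluster.n,
                    "power": e.power,
                    "condition": cond,
                    "p_test1": r.p_in_cluster,
                    "p_test2": r.p_capture,
                    "r_square": r.r_square,
                    "p_reg": r.p_reg,
                    "rank": e.rank,
                }
            )
    cols = [
        "source", "target", "similarity", "cluster_index", "cluster_size",
        "power", "condition", "p_test1", "p_test2", "r_square", "p_reg", "rank",
    ]
    return pd.DataFrame(rows, columns=cols)
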