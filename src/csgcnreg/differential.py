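"""Differential expression, the TF/TR ratio statistic, and
regulatory-edge categorization.

Differential expression between two conditions is computed either by a
negative-binomial Wald test (counts/abundance-scale input, method-of-
moments dispersion — the usual NB-GLM formulation) or by Welch's t-test on
log2 values, with Benjamini-Hochberg adjustment across genes; a gene is a
DEG at adjusted p < 0.001.

The TF/TR ratio statistic captures regulatory rewiring: for each
TF -> target (TR) regulatory edge, the per-sample expression ratio
(TF + eps) / (TR + eps) is computed on the linear scale and compared
between conditions with a classical equal-variance Student's t-test.  An
edge where both genes are DEGs *and* the ratio shifts significantly is
"doubly significant", and falls into one of four directional categories
(TF up/down x TR up/down), which partition the doubly-significant edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gem_io import GEM, LOG2, SampleAnnotation

__all__ = [
    "DeResult",
    "RatioTestResult",
    "RegulatoryEdgeAssessment",
    "CATEGORIES",
    "de_test",
    "tf_tr_ratio_test",
    "assess_regulatory_edges",
]

CATEGORIES = (
    "TF & TR Up",
    "TF & TR Down",
    "TF Up & TR Down",
    "TF Down & TR Up",
)


@dataclass
class DeResult:
    gene: str
    log2_fc: float
    p: float
    adj_p: float
    is_deg: bool
    direction: str  # up | down | none


@dataclass
class RatioTestResult:
    tf: str
    tr: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_stat: float
    p: float
    significant: bool
    note: str = ""


@dataclass
class RegulatoryEdgeAssessment:
    tf: str
    tr: str
    tf_de: DeResult | None
    tr_de: DeResult | None
    ratio: RatioTestResult | None
    doubly_significant: bool
    category: str  # one of CATEGORIES or "none"
    assessable: bool = True


def _nb_wald_gene(y: np.ndarray, group: np.ndarray) -> tuple[float, float]:
    """NB Wald test for one gene: log2 fold change and p-value.

    Dispersion is a pooled method-of-moments estimate
    alpha = (var - mean) / mean^2 within each group, clipped at a small
    positive floor (Poisson-like genes)."""
    alphas = []
    for g in (0, 1):
        v = y[group == g]
        m = v.mean()
        if m > 0:
            alphas.append(max((v.var(ddof=1) - m) / m**2, 0.0))
    alpha = max(float(np.mean(alphas)) if alphas else 0.0, 1e-8)
    X = sm.add_constant(group.astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
    beta = fit.params[1]  # natural-log fold change
    return float(beta / np.log(2.0)), float(fit.pvalues[1])


def de_test(
    gem: GEM,
    annot: SampleAnnotation,
    cond_a: str,
    cond_b: str,
    alpha: float = 0.001,
    method: str = "auto",
) -> pd.DataFrame:
    """Per-gene differential expression of ``cond_b`` relative to ``cond_a``.

    ``method``: ``"nb_wald"`` (linear/counts scale), ``"welch_log2"``
    (log2 scale), or ``"auto"`` which picks by the GEM's scale marker.
    Returns a DataFrame indexed by gene with columns ``log2_fc``, ``p``,
    ``adj_p`` (BH across tested genes), ``is_deg`` and ``direction``;
    ``df.attrs["method"]`` records which test ran.  Genes fully missing in
    either group are excluded and listed in ``df.attrs["excluded"]``.
    """
    if method == "auto":
        method = "welch_log2" if gem.scale == LOG2 else "nb_wald"
    sa = annot.samples_of(cond_a)
    sb = annot.samples_of(cond_b)
    if len(sa) < 3 or len(sb) < 3:
        raise ValueError("each condition needs at least 3 samples")
    A = gem.values.loc[:, sa].to_numpy()
    B = gem.values.loc[:, sb].to_numpy()

    genes, lfcs, ps, excluded = [], [], [], []
    for i, gene in enumerate(gem.gene_ids):
        a = A[i][~np.isnan(A[i])]
        b = B[i][~np.isnan(B[i])]
        if a.size < 2 or b.size < 2:
            excluded.append(gene)
            continue
        if method == "welch_log2":
            lfc = float(b.mean() - a.mean())
            if np.ptp(a) == 0 and np.ptp(b) == 0:
                p = 1.0 if lfc == 0 else 0.0
            else:
                p = float(stats.ttest_ind(b, a, equal_var=False).pvalue)
        elif method == "nb_wald":
            y = np.concatenate([a, b])
            grp = np.concatenate([np.zeros(a.size), np.ones(b.size)])
            if y.sum() == 0:
                excluded.append(gene)
                continue
            lfc, p = _nb_wald_gene(y, grp)
        else:
            raise ValueError(f"unknown DE method: {method!r}")
        genes.append(gene)
        lfcs.append(lfc)
        ps.append(p)

    ps_arr = np.array(ps)
    adj = multipletests(ps_arr, method="fdr_bh")[1] if len(ps) else np.array([])
    is_deg = adj < alpha
    direction = np.where(
        ~is_deg, "none", np.where(np.array(lfcs) > 0, "up", "down")
    )
    df = pd.DataFrame(
        {
            "log2_fc": lfcs,
            "p": ps,
            "adj_p": adj,
            "is_deg": is_deg,
            "direction": direction,
        },
        index=pd.Index(genes, name="gene"),
    )
    df.attrs["method"] = method
    df.attrs["excluded"] = excluded
    df.attrs["comparison"] = (cond_a, cond_b)
    return df


def de_result(df: pd.DataFrame, gene: str) -> DeResult | None:
    if gene not in df.index:
        return None
    r = df.loc[gene]
    return DeResult(
        gene=gene,
        log2_fc=float(r.log2_fc),
        p=float(r.p),
        adj_p=float(r.adj_p),
        is_deg=bool(r.is_deg),
        direction=str(r.direction),
    )


def tf_tr_ratio_test(
    gem: GEM,
    tf: str,
    tr: str,
    annot: SampleAnnotation,
    cond_a: str,
    cond_b: str,
    alpha: float = 0.001,
    eps: float = 0.01,
) -> RatioTestResult:
    """Student's t-test on per-sample TF/TR expression ratios between two
    conditions.  Ratios are formed on the linear scale with pseudocount
    ``eps`` in numerator and denominator; log2-scale GEMs are
    exponentiated first.  Significant iff p < alpha."""
    for g in (tf, tr):
        if g not in gem.gene_ids:
            raise KeyError(f"gene absent from GEM: {g!r}")
    vt = gem.values.loc[tf]
    vr = gem.values.loc[tr]
    if gem.scale == LOG2:
        vt, vr = np.exp2(vt), np.exp2(vr)
    ratio = (vt + eps) / (vr + eps)

    def cond_ratios(c: str) -> np.ndarray:
        r = ratio.loc[annot.samples_of(c)]
        return r[np.isfinite(r)].to_numpy()

    ra, rb = cond_ratios(cond_a), cond_ratios(cond_b)
    res = RatioTestResult(
        tf=tf,
        tr=tr,
        mean_a=float(ra.mean()) if ra.size else float("nan"),
        sd_a=float(ra.std(ddof=1)) if ra.size > 1 else float("nan"),
        mean_b=float(rb.mean()) if rb.size else float("nan"),
        sd_b=float(rb.std(ddof=1)) if rb.size > 1 else float("nan"),
        t_stat=float("nan"),
        p=float("nan"),
        significant=False,
    )
    if ra.size < 3 or rb.size < 3:
        res.note = "insufficient computable ratios"
        return res
    if np.ptp(ra) == 0 and np.ptp(rb) == 0:
        res.note = "degenerate: constant ratios"
        res.t_stat = 0.0
        res.p = 1.0 if ra[0] == rb[0] else 0.0
        res.significant = bool(res.p < alpha)
        return res
    t = stats.ttest_ind(ra, rb, equal_var=True)
    res.t_stat = float(t.statistic)
    res.p = float(t.pvalue)
    res.significant = bool(res.p < alpha)
    return res


def _categorize(tf_dir: str, tr_dir: str) -> str:
    return {
        ("up", "up"): "TF & TR Up",
        ("down", "down"): "TF & TR Down",
        ("up", "down"): "TF Up & TR Down",
        ("down", "up"): "TF Down & TR Up",
    }[(tf_dir, tr_dir)]


def assess_regulatory_edges(
    grn_edges: Sequence[tuple[str, str]],
    de_results: pd.DataFrame,
    ratio_results: Mapping[tuple[str, str], RatioTestResult],
) -> tuple[list[RegulatoryEdgeAssessment], dict[str, int]]:
    """Assess each TF -> TR regulatory edge and tally the categories.

    Returns the per-edge assessments and a summary with total edges,
    both-DEG count, ratio-significant count, doubly-significant count and
    the four directional category counts (which partition the
    doubly-significant edges).
    """
    assessments: list[RegulatoryEdgeAssessment] = []
    counts = {"total": 0, "both_deg": 0, "ratio_significant": 0, "doubly_significant": 0}
    counts.update({c: 0 for c in CATEGORIES})
    for tf, tr in grn_edges:
        counts["total"] += 1
        tf_de = de_result(de_results, tf)
        tr_de = de_result(de_results, tr)
        ratio = ratio_results.get((tf, tr))
        if tf_de is None or tr_de is None:
            assessments.append(
                RegulatoryEdgeAssessment(
                    tf, tr, tf_de, tr_de, ratio, False, "none", assessable=False
                )
            )
            continue
        both_deg = tf_de.is_deg and tr_de.is_deg
        ratio_sig = ratio is not None and ratio.significant
        if both_deg:
            counts["both_deg"] += 1
        if ratio_sig:
            counts["ratio_significant"] += 1
        doubly = both_deg and ratio_sig
        category = "none"
        if doubly:
            counts["doubly_significant"] += 1
            category = _categorize(tf_de.direction, tr_de.direction)
            counts[category] += 1
        assessments.append(
            RegulatoryEdgeAssessment(tf, tr, tf_de, tr_de, ratio, doubly, category)
        )
    return assessments, counts
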