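"""Covariate-adjusted group inference on connectivity metrics.

Three complementary procedures:

* per-edge logistic regressions between diagnosis pairs, adjusting for
  sex, age, head-coil and motion (unadjusted p-values by design; a
  Bonferroni column is reported alongside);
* a multinomial logit of diagnosis on whole-brain metastability plus the
  same covariates, with a configurable reference group;
* the network-based statistic (NBS): per-edge ANCOVA F for the group
  factor, thresholding at a primary p, connected components over the node
  graph, and family-wise-error control via Freedman-Lane permutation of
  covariate-adjusted residuals.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .static_fc import index_to_pair, n_edges

__all__ = [
    "DesignMatrix",
    "MultinomialFit",
    "NBSResult",
    "edgewise_pairwise_logistic",
    "metastability_multinomial",
    "nbs",
    "node_contribution",
]

COVARIATES = ("sex", "age", "headcoil", "motion")


@dataclass
class DesignMatrix:
    """Outcome labels plus nuisance covariates for one analysis.

    ``covariates`` holds sex, age, head-coil dummy (1 = 8-channel) and
    mean relative motion; ``reference`` names the baseline diagnosis.
    """

    outcome: pd.Series
    covariates: pd.DataFrame
    reference: str = "SCI"

    def __post_init__(self) -> None:
        self.outcome = pd.Series(self.outcome).reset_index(drop=True)
        self.covariates = pd.DataFrame(self.covariates).reset_index(drop=True)
        if len(self.outcome) != len(self.covariates):
            raise ValueError("outcome and covariates disagree in length")
        if self.covariates.isna().any().any() or self.outcome.isna().any():
            raise ValueError("design matrix must not contain missing values")
        if self.reference not in set(self.outcome):
            raise ValueError(
                f"reference group {self.reference!r} absent from the outcome"
            )

    @classmethod
    def from_cohort(
        cls,
        cohort,
        reference: str = "SCI",
        covariates: Sequence[str] = COVARIATES,
    ) -> "DesignMatrix":
        table = cohort.table if hasattr(cohort, "table") else cohort
        return cls(
            outcome=table["group"],
            covariates=table[list(covariates)],
            reference=reference,
        )

    @property
    def classes(self) -> list[str]:
        other = sorted(set(self.outcome) - {self.reference})
        return [self.reference] + other

    def subset(self, mask: np.ndarray) -> "DesignMatrix":
        ref = self.reference
        out = self.outcome[mask]
        if ref not in set(out):
            ref = sorted(set(out))[0]
        return DesignMatrix(
            outcome=out, covariates=self.covariates[mask], reference=ref
        )


def _covariate_block(design: DesignMatrix) -> np.ndarray:
    z = design.covariates.to_numpy(dtype=float)
    z = np.column_stack([np.ones(len(z)), z])
    if np.linalg.matrix_rank(z) < z.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    return z


def edgewise_pairwise_logistic(
    edge_matrix: pd.DataFrame,
    design: DesignMatrix,
    pair: tuple[str, str],
    maxiter: int = 100,
) -> pd.DataFrame:
    """Per-edge logistic regression for one diagnosis pair.

    The outcome is membership of ``pair[1]`` versus ``pair[0]``; each edge
    metric enters as the predictor of interest alongside the covariates.
    P-values are unadjusted Wald tests (no multiple-testing correction at
    this stage); a Bonferroni-adjusted column is included for reference.
    Degenerate edges (no variance) and perfectly separated fits are
    flagged rather than reported as converged estimates.
    """
    g0, g1 = pair
    labels = design.outcome.to_numpy()
    mask = np.isin(labels, [g0, g1])
    if not (np.any(labels == g0) and np.any(labels == g1)):
        raise ValueError(f"both classes of {pair} must be present")
    y = (labels[mask] == g1).astype(float)
    z = _covariate_block(design)[mask]
    x_edges = edge_matrix.to_numpy(dtype=float)[mask]
    m = x_edges.shape[1]
    coefs = np.full(m, np.nan)
    ses = np.full(m, np.nan)
    ps = np.full(m, np.nan)
    status = np.array(["ok"] * m, dtype=object)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        llf_null = sm.Logit(y, z).fit(disp=0, maxiter=maxiter).llf
    for e in range(m):
        xe = x_edges[:, e]
        if np.ptp(xe) == 0:
            status[e] = "degenerate"
            continue
        xmat = np.column_stack([z, xe])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, xmat).fit(disp=0, maxiter=maxiter)
            # p from the likelihood-ratio test of the edge term: unlike the
            # Wald test it does not collapse under near-separation
            lr = max(2.0 * (res.llf - llf_null), 0.0)
            ps[e] = stats.chi2.sf(lr, 1)
            coefs[e] = res.params[-1]
            ses[e] = res.bse[-1]
            if not res.mle_retvals.get("converged", False) or not np.all(
                np.isfinite(res.bse)
            ):
                status[e] = "nonconverged"
        except (PerfectSeparationError, np.linalg.LinAlgError):
            # separated fit: the coefficient diverges (reported as NaN) but
            # the LR statistic attains its supremum 2*(0 - llf_null)
            status[e] = "separation"
            ps[e] = stats.chi2.sf(max(-2.0 * llf_null, 0.0), 1)
    out = pd.DataFrame(
        {
            "edge": list(edge_matrix.columns),
            "coef": coefs,
            "se": ses,
            "p": ps,
            "p_bonferroni": np.minimum(ps * m, 1.0),
            "status": status,
        }
    )
    return out


@dataclass
class MultinomialFit:
    """Multinomial-logit summary for the metric of interest."""

    summary: pd.DataFrame  # index: non-reference groups; coef/se/p of the metric
    reference: str
    pseudo_r2: float
    log_likelihood: float
    params: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]
    converged: bool = True


def metastability_multinomial(
    metric: np.ndarray,
    design: DesignMatrix,
    maxiter: int = 200,
) -> MultinomialFit:
    """Multinomial logit of diagnosis on a scalar metric plus covariates.

    The reference category is ``design.reference``; one coefficient set is
    reported per non-reference group.  Returns McFadden pseudo-R2 and the
    model log-likelihood alongside per-contrast Wald tests for the metric.
    """
    metric = np.asarray(metric, dtype=float)
    classes = design.classes
    if len(classes) < 2:
        raise ValueError("group inference needs at least two outcome classes")
    counts = design.outcome.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"class(es) with fewer than 2 subjects: {list(small.index)}")
    codes = pd.Categorical(design.outcome, categories=classes).codes
    z = _covariate_block(design)
    xmat = np.column_stack([z, metric])
    names = ["const", *design.covariates.columns, "metric"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.MNLogit(codes, xmat).fit(disp=0, maxiter=maxiter, method="newton")
    converged = bool(res.mle_retvals.get("converged", False))
    params = pd.DataFrame(res.params, index=names, columns=classes[1:])
    bse = pd.DataFrame(res.bse, index=names, columns=classes[1:])
    pvals = pd.DataFrame(res.pvalues, index=names, columns=classes[1:])
    summary = pd.DataFrame(
        {
            "coef": params.loc["metric"],
            "se": bse.loc["metric"],
            "p": pvals.loc["metric"],
        }
    )
    summary.index.name = "group"
    return MultinomialFit(
        summary=summary,
        reference=design.reference,
        pseudo_r2=float(res.prsquared),
        log_likelihood=float(res.llf),
        params=params,
        converged=converged,
    )


@dataclass
class NBSResult:
    """Network-based-statistic output.

    ``components`` is a list of dicts with 1-based ``edges``, ``nodes``,
    ``size`` (edge count) and family-wise-error ``p``.  ``node_f_sums``
    sums F over significant-component edges incident to each node.
    """

    f_stats: np.ndarray
    threshold_f: float
    components: list[dict]
    node_f_sums: np.ndarray
    n_permutations: int
    seed: Optional[int]
    n_nodes: int
    status: str = "ok"


def _edge_node_arrays(n_nodes: int):
    iu, ju = np.triu_indices(n_nodes, k=1)
    return iu + 1, ju + 1


def _rss(x: np.ndarray, y: np.ndarray):
    """Residual sum of squares of each column of y on design x."""
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return np.einsum("ij,ij->j", resid, resid), beta, resid


def _f_stats(z: np.ndarray, x_full: np.ndarray, y: np.ndarray, q: int, df_e: int):
    rss_r, _, _ = _rss(z, y)
    rss_f, _, _ = _rss(x_full, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss_r - rss_f) / q) / (rss_f / df_e)
    return np.where(np.isfinite(f), np.maximum(f, 0.0), 0.0)


def _components(f: np.ndarray, thr: float, n_nodes: int):
    """Connected components of the suprathreshold edge graph."""
    ii, jj = _edge_node_arrays(n_nodes)
    above = np.flatnonzero(f > thr)
    g = nx.Graph()
    for e in above:
        g.add_edge(int(ii[e]), int(jj[e]), edge=int(e + 1))
    comps = []
    for nodes in nx.connected_components(g):
        edges = sorted(
            d["edge"] for _, _, d in g.subgraph(nodes).edges(data=True)
        )
        comps.append({"nodes": sorted(nodes), "edges": edges, "size": len(edges)})
    comps.sort(key=lambda c: -c["size"])
    return comps


def _max_component_size(f: np.ndarray, thr: float, n_nodes: int) -> int:
    comps = _components(f, thr, n_nodes)
    return comps[0]["size"] if comps else 0


def nbs(
    edge_matrix,
    design: DesignMatrix,
    primary_p: float = 0.05,
    n_perm: int = 5000,
    seed: Optional[int] = 0,
    alpha: float = 0.05,
    exhaustive: bool = False,
) -> NBSResult:
    """Network-based statistic with ANCOVA edge tests and FWE permutation.

    Per edge, the F statistic tests the group factor after adjusting for
    the design covariates.  Edges with F above the parametric quantile at
    ``primary_p`` form a graph whose connected components are evaluated
    against the permutation null of the maximum component extent (edge
    count).  Covariates are handled under permutation by the
    Freedman-Lane scheme: residuals of the covariates-only fit are
    permuted and added back to the covariate fit.  Component p-values use
    the (1 + #{null >= observed}) / (1 + n_perm) convention.

    ``exhaustive=True`` enumerates every distinct assignment of the group
    labels instead of sampling; it requires an intercept-only nuisance
    model (no covariates) and reports p as the plain proportion over all
    assignments.
    """
    if isinstance(edge_matrix, pd.DataFrame):
        y = edge_matrix.to_numpy(dtype=float)
    else:
        y = np.asarray(edge_matrix, dtype=float)
    n_subj, m = y.shape
    n_nodes_ = _infer_n_nodes(m)
    labels = design.outcome.to_numpy()
    classes = np.unique(labels)
    counts = pd.Series(labels).value_counts()
    if counts.min() < 3:
        raise ValueError("NBS needs at least 3 subjects per group")
    if not exhaustive and n_perm < 100:
        raise ValueError("use at least 100 permutations (or exhaustive=True)")

    if exhaustive:
        if design.covariates.shape[1] > 0:
            raise ValueError(
                "exhaustive enumeration is only supported without covariates"
            )
        z = np.ones((n_subj, 1))
    else:
        z = _covariate_block(design)
    dummies = pd.get_dummies(pd.Categorical(labels, categories=classes), drop_first=True)
    g = dummies.to_numpy(dtype=float)
    q = g.shape[1]
    x_full = np.column_stack([z, g])
    df_e = n_subj - np.linalg.matrix_rank(x_full)
    if df_e < 1:
        raise ValueError("no residual degrees of freedom in the full model")
    thr = float(stats.f.isf(primary_p, q, df_e))
    f_obs = _f_stats(z, x_full, y, q, df_e)
    comps = _components(f_obs, thr, n_nodes_)
    status = "ok" if comps else "no suprathreshold edges"

    # permutation null of the maximum component extent
    if exhaustive:
        null_sizes = []
        seen = set()
        for perm_labels in itertools.permutations(labels):
            if perm_labels in seen:
                continue
            seen.add(perm_labels)
            gp = pd.get_dummies(
                pd.Categorical(list(perm_labels), categories=classes),
                drop_first=True,
            ).to_numpy(dtype=float)
            xp = np.column_stack([z, gp])
            fp = _f_stats(z, xp, y, q, df_e)
            null_sizes.append(_max_component_size(fp, thr, n_nodes_))
        null_sizes = np.array(null_sizes)
        n_eff = len(null_sizes)
        for c in comps:
            c["p"] = float((null_sizes >= c["size"]).mean())
    else:
        rng = np.random.default_rng(seed)
        _, beta_r, resid_r = _rss(z, y)
        fitted_r = z @ beta_r
        null_sizes = np.empty(n_perm, dtype=int)
        for b in range(n_perm):
            y_star = fitted_r + resid_r[rng.permutation(n_subj)]
            f_star = _f_stats(z, x_full, y_star, q, df_e)
            null_sizes[b] = _max_component_size(f_star, thr, n_nodes_)
        n_eff = n_perm
        for c in comps:
            c["p"] = float((1 + (null_sizes >= c["size"]).sum()) / (1 + n_perm))

    node_sums = np.zeros(n_nodes_)
    ii, jj = _edge_node_arrays(n_nodes_)
    for c in comps:
        if c["p"] < alpha:
            for e in c["edges"]:
                node_sums[ii[e - 1] - 1] += f_obs[e - 1]
                node_sums[jj[e - 1] - 1] += f_obs[e - 1]
    return NBSResult(
        f_stats=f_obs,
        threshold_f=thr,
        components=comps,
        node_f_sums=node_sums,
        n_permutations=n_eff,
        seed=seed,
        n_nodes=n_nodes_,
        status=status,
    )


def node_contribution(
    result: NBSResult, alpha: float = 0.05, others: Sequence[NBSResult] = ()
) -> np.ndarray:
    """Per-node sum of F over edges in significant components.

    With ``others`` given (e.g. the sFC and dFC runs), returns the mean of
    the per-node sums across all results.  A result without significant
    components contributes zeros.
    """
    def sums(res: NBSResult) -> np.ndarray:
        out = np.zeros(res.n_nodes)
        for c in res.components:
            if c.get("p", 1.0) < alpha:
                for e in c["edges"]:
                    i, j = index_to_pair(e, res.n_nodes)
                    out[i - 1] += res.f_stats[e - 1]
                    out[j - 1] += res.f_stats[e - 1]
        return out

    stack = [sums(result)] + [sums(r) for r in others]
    return np.mean(stack, axis=0)


def _infer_n_nodes(m: int) -> int:
    n = int((1 + np.sqrt(1 + 8 * m)) / 2)
    if n_edges(n) != m:
        raise ValueError(f"{m} edges is not a triangular number")
    return n
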