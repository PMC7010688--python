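"""Co-expression modules, per-cell factor scores and term enrichment.

Modules are found by affinity propagation on the gene-gene Pearson
correlation over all cells (the correlation itself acting as the
similarity), on the top expressed genes. A module's per-cell score —
the normalised mean expression of its member genes — serves as a
quantitative cellular factor for the GxE interaction tests. Modules are
labelled by Fisher-exact enrichment against a user-supplied annotation
table (e.g. cell-cycle or metabolic gene sets).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AffinityPropagation
from statsmodels.stats.multitest import multipletests


@dataclass
class CoexpressionModules:
    """Partition of clustered genes into modules with exemplar genes."""

    membership: pd.Series  # gene -> module id
    exemplars: pd.Series  # module id -> exemplar gene

    def genes(self, module: int) -> pd.Index:
        return self.membership.index[self.membership == module]

    @property
    def module_ids(self) -> list[int]:
        return sorted(self.exemplars.index)


def select_top_expressed(logcpm: pd.DataFrame, n: int = 8000) -> pd.Index:
    """Top ``n`` genes by mean log2(CPM+1) across all cells (ties by id)."""
    means = logcpm.mean(axis=0)
    order = sorted(means.index, key=lambda g: (-means[g], g))
    return pd.Index(order[: min(n, len(order))])


def affinity_propagation_modules(
    logcpm: pd.DataFrame,
    seed: int = 0,
    preference: float | None = None,
    damping: float = 0.7,
    max_iter: int = 500,
) -> CoexpressionModules:
    """Affinity propagation with Pearson correlation as the similarity.

    The preference defaults to the median off-diagonal similarity.
    Damping 0.7 stabilises the message passing without freezing it:
    heavier damping slows the updates enough that the stability-based
    convergence criterion can fire before block structure is resolved.
    """
    if logcpm.shape[1] < 2:
        raise ValueError("need at least 2 genes to cluster")
    x = logcpm.to_numpy(dtype=float).T  # genes x cells
    sd = x.std(axis=1)
    if (sd == 0).any():
        raise ValueError("constant-expression genes cannot be clustered")
    S = np.corrcoef(x)
    if preference is None:
        off = S[~np.eye(len(S), dtype=bool)]
        preference = float(np.median(off))
    model = AffinityPropagation(
        affinity="precomputed",
        preference=preference,
        damping=damping,
        max_iter=max_iter,
        random_state=seed,
    )
    labels = model.fit_predict(S)
    if model.cluster_centers_indices_ is None or len(
        model.cluster_centers_indices_
    ) == 0:
        raise RuntimeError(
            "affinity propagation did not converge; increase damping or "
            "max_iter"
        )
    genes = logcpm.columns
    membership = pd.Series(labels, index=genes, name="module")
    exemplars = pd.Series(
        {m: genes[i] for m, i in enumerate(model.cluster_centers_indices_)},
        name="exemplar",
    )
    return CoexpressionModules(membership=membership, exemplars=exemplars)


def module_scores(
    logcpm: pd.DataFrame,
    modules: CoexpressionModules,
    module_ids: list[int] | None = None,
) -> pd.DataFrame:
    """Per-cell module scores: z-scored mean of z-scored member expression.

    Member genes are z-scored per gene across cells, averaged per cell,
    and the resulting score is itself z-scored across cells, so every
    factor has mean 0 and unit variance.
    """
    module_ids = module_ids if module_ids is not None else modules.module_ids
    out = {}
    for m in module_ids:
        genes = [g for g in modules.genes(m) if g in logcpm.columns]
        if not genes:
            raise ValueError(f"module {m} has no expressed member genes")
        x = logcpm[genes].to_numpy(dtype=float)
        mu = x.mean(axis=0, keepdims=True)
        sd = x.std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0
        raw = ((x - mu) / sd).mean(axis=1)
        s = raw.std()
        out[f"module{m}"] = (raw - raw.mean()) / (s if s > 0 else 1.0)
    return pd.DataFrame(out, index=logcpm.index)


def term_enrichment(
    module_genes,
    annotation: pd.DataFrame,
    universe,
    fdr: float = 0.10,
) -> pd.DataFrame:
    """One-sided Fisher-exact enrichment of annotation terms in a module.

    ``annotation`` maps genes to terms (columns ``gene``, ``term``);
    the universe is typically all clustered genes. Terms with no
    annotated gene in the universe are skipped. The odds ratio of a
    module that exhausts a term within the universe is reported as
    ``inf``.
    """
    module_genes = set(module_genes)
    universe = pd.Index(universe)
    ann = annotation[annotation["gene"].isin(universe)]
    rows = []
    for term, sub in ann.groupby("term", observed=True):
        term_genes = set(sub["gene"])
        a = len(module_genes & term_genes)
        b = len(module_genes - term_genes)
        c = len(term_genes - module_genes)
        d = len(universe) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((term, a, len(term_genes), odds, p))
    out = pd.DataFrame(
        rows, columns=["term", "n_overlap", "n_term", "odds_ratio", "p"]
    )
    if len(out):
        out["p_bh"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out["significant"] = out["p_bh"] < fdr
        out = out.sort_values("p", ignore_index=True)
    return out
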