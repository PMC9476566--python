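"""Coupling methylation patterns to expression, tissue clustering, and GO.

Expression enters as TPM and is analysed as log2(TPM+1).  Pattern–expression
differences are tested with Kruskal–Wallis plus Dunn's pairwise post-hoc
(tie-corrected, Bonferroni-adjusted over pairs by default).  Tissue
transcriptomes are clustered hierarchically (Euclidean distance on row
z-scores, complete linkage) and over-representation of GO terms uses the
upper-tail hypergeometric test with Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


def log_expression(tpm: pd.DataFrame) -> pd.DataFrame:
    """log2(TPM + 1) transform; zero iff TPM is zero."""
    return np.log2(tpm + 1.0)


def expressed_set(tpm: pd.DataFrame, threshold: float = 0.0) -> set:
    """Transcripts with TPM above ``threshold`` in at least one sample."""
    mask = (tpm > threshold).any(axis=1)
    return set(tpm.index[mask])


def percentile_methylation_curve(
    expr: pd.Series, body_means: pd.DataFrame, n_groups: int = 100
) -> pd.DataFrame:
    """Mean gene-body methylation per expression-percentile group.

    Transcripts with both an expression value and a body mean are ranked by
    expression (average ranks for ties; residual ties broken by transcript
    id for determinism) and split into ``n_groups`` equal-frequency groups
    whose sizes differ by at most one.  Returns ``percentile, n,
    mean_expression, mean_methylation``.
    """
    merged = body_means.merge(
        expr.rename("expr"), left_on="transcript_id", right_index=True, how="inner"
    ).dropna(subset=["expr", "body_mean"])
    if len(merged) < n_groups:
        raise ValueError(
            f"only {len(merged)} transcripts for {n_groups} groups; "
            "use a smaller n_groups"
        )
    merged = merged.assign(rank=merged["expr"].rank(method="average"))
    merged = merged.sort_values(["rank", "transcript_id"]).reset_index(drop=True)
    groups = np.array_split(np.arange(len(merged)), n_groups)
    rows = []
    for g, idx in enumerate(groups, 1):
        sub = merged.iloc[idx]
        rows.append(
            {
                "percentile": g,
                "n": len(sub),
                "mean_expression": float(sub["expr"].mean()),
                "mean_methylation": float(sub["body_mean"].mean()),
            }
        )
    return pd.DataFrame(rows)


def _dunn_pairwise(groups: dict, p_adjust: str) -> pd.DataFrame:
    """Dunn's z tests on pooled ranks with tie correction."""
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g in labels:
        k = len(groups[g])
        mean_ranks[g] = ranks[start : start + k].mean()
        sizes[g] = k
        start += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for a, b in combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p": p})
    out = pd.DataFrame(rows)
    m = len(out)
    if p_adjust == "bonferroni":
        out["padj"] = np.minimum(out["p"] * m, 1.0)
    elif p_adjust == "fdr_bh":
        from statsmodels.stats.multitest import multipletests

        out["padj"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown p_adjust {p_adjust!r}")
    return out


def mp_expression_test(
    expr: pd.Series, assignment, p_adjust: str = "bonferroni"
) -> dict:
    """Kruskal–Wallis across methylation patterns plus Dunn's post-hoc.

    ``assignment`` is a PatternAssignment (or its table).  Patterns with
    fewer than 2 expressed members are excluded from the pairwise tests
    with a warning.  Returns ``{"kw_h", "kw_p", "per_group", "pairwise"}``.
    """
    import warnings

    table = getattr(assignment, "table", assignment)
    merged = table.merge(
        expr.rename("expr"), left_on="transcript_id", right_index=True, how="inner"
    ).dropna(subset=["expr"])
    groups = {
        int(mp): grp["expr"].to_numpy() for mp, grp in merged.groupby("mp_label")
    }
    usable = {g: v for g, v in groups.items() if len(v) >= 2}
    if len(usable) < len(groups):
        warnings.warn("patterns with <2 members excluded from pairwise tests")
    if len(usable) < 2:
        raise ValueError("need at least two non-empty patterns")
    h, p = sps.kruskal(*usable.values())
    per_group = pd.DataFrame(
        [
            {
                "mp_label": g,
                "n": len(v),
                "median": float(np.median(v)),
                "q1": float(np.percentile(v, 25)),
                "q3": float(np.percentile(v, 75)),
            }
            for g, v in sorted(usable.items())
        ]
    )
    pairwise = _dunn_pairwise(usable, p_adjust)
    return {"kw_h": float(h), "kw_p": float(p), "per_group": per_group, "pairwise": pairwise}


def zscore_rows(mat: pd.DataFrame) -> pd.DataFrame:
    """Row z-scores; rows with zero variance are dropped."""
    mu = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=1)
    keep = sd > 0
    return mat[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)


def zscore_cluster(
    tpm: pd.DataFrame, k: int = 13, linkage_method: str = "complete"
) -> tuple[pd.Series, pd.DataFrame]:
    """Hierarchically cluster transcripts on row-z-scored log expression.

    Rows are z-scored across samples, clustered with Euclidean distance and
    the given linkage (complete by default), and the tree is cut into ``k``
    clusters.  Returns (labels Series 1..k in dendrogram order of the
    z-matrix, z-scored matrix ordered by dendrogram leaves).  Rows with
    zero variance are excluded.
    """
    from scipy.cluster.hierarchy import dendrogram, fcluster, linkage

    z = zscore_rows(log_expression(tpm))
    if len(z) < k:
        raise ValueError(f"only {len(z)} usable rows for k={k}")
    link = linkage(z.to_numpy(), method=linkage_method, metric="euclidean")
    labels = pd.Series(
        fcluster(link, t=k, criterion="maxclust"), index=z.index, name="cluster"
    )
    order = dendrogram(link, no_plot=True)["leaves"]
    return labels, z.iloc[order]


def topn_overlap(
    tpm: pd.DataFrame, samples: list[str] | None = None, n: int = 1000
) -> dict:
    """Union and Venn membership of per-sample top-n expressed transcripts.

    Per sample, the top ``n`` transcripts by TPM (ties broken by transcript
    id, ascending, for determinism).  Returns ``{"union", "membership",
    "per_sample", "counts"}`` where membership is a boolean frame indexed by
    the union and counts maps each membership signature to its size.
    """
    if samples is None:
        samples = list(tpm.columns)
    per_sample = {}
    for s in samples:
        if len(tpm) < n:
            raise ValueError(f"sample {s} has fewer than {n} transcripts")
        ranked = tpm[[s]].reset_index().sort_values(
            [s, "transcript_id"], ascending=[False, True]
        )
        per_sample[s] = set(ranked["transcript_id"].head(n))
    union = sorted(set().union(*per_sample.values()))
    membership = pd.DataFrame(
        {s: [t in per_sample[s] for t in union] for s in samples}, index=union
    )
    counts = (
        membership.groupby(samples).size().rename("n_transcripts").reset_index()
    )
    return {
        "union": set(union),
        "membership": membership,
        "per_sample": per_sample,
        "counts": counts,
    }


def go_enrichment(
    gene_list: set,
    universe: set,
    term_map: dict[str, set],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of terms in ``gene_list``.

    For each term with K genes in the universe, the upper-tail probability
    of observing >= k_obs of them in a list of size n drawn from a universe
    of size N, BH-adjusted across all tested terms.  ``gene_ratio`` is
    observed / expected where expected = n * K / N.  Terms with
    ``padj < alpha`` are flagged significant.
    """
    from statsmodels.stats.multitest import multipletests

    offenders = gene_list - universe
    if offenders:
        raise ValueError(f"gene_list not within universe: {sorted(offenders)[:5]}")
    n_univ = len(universe)
    n_list = len(gene_list)
    rows = []
    for term, genes in sorted(term_map.items()):
        k_univ = len(genes & universe)
        if k_univ == 0:
            continue
        k_obs = len(genes & gene_list)
        p = float(sps.hypergeom.sf(k_obs - 1, n_univ, k_univ, n_list))
        expected = n_list * k_univ / n_univ
        rows.append(
            {
                "term_id": term,
                "k_obs": k_obs,
                "n_list": n_list,
                "K_universe": k_univ,
                "N_universe": n_univ,
                "p": p,
                "gene_ratio": k_obs / expected if expected > 0 else np.nan,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["term_id", "k_obs", "n_list", "K_universe", "N_universe", "p", "gene_ratio"],
    )
    if len(out):
        out["padj"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["padj"] < alpha
    else:
        out["padj"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out.sort_values("p").reset_index(drop=True)
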