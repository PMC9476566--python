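"""Gene-body methylation patterns: per-transcript means and k-means.

The per-transcript mean methylation over the gene body (TSS→TTS) is
clustered by one-dimensional k-means (Lloyd's algorithm with k-means++
seeding, best of several restarts).  Clusters are relabelled 1..k by
descending center, so pattern 1 is the most methylated archetype and
pattern k the unmethylated one; ties in nearest-center assignment break
toward the lower (more methylated) label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PatternAssignment:
    """Result of clustering per-transcript gene-body means.

    ``table`` has columns ``transcript_id, body_mean, n_cpgs_body,
    mp_label``; ``centers`` are strictly descending, so ``centers[j-1]``
    is the center of pattern ``j``.
    """

    table: pd.DataFrame
    centers: np.ndarray
    inertia: float
    seed: int
    restarts: int
    excluded: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.centers)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def centers_json(self) -> dict:
        return {
            "centers": [float(c) for c in self.centers],
            "inertia": float(self.inertia),
            "seed": self.seed,
            "restarts": self.restarts,
            "k": self.k,
        }


def transcript_mean_methylation(
    cpgs: pd.DataFrame, features: pd.DataFrame, min_cpgs: int = 1
) -> tuple[pd.DataFrame, list]:
    """Mean gene-body methylation per transcript.

    Averages ``meth_pct`` over all covered CpGs (either strand) inside the
    transcript span [start, end).  Returns (frame with ``transcript_id,
    body_mean, n_cpgs_body``, list of transcript ids excluded for having
    fewer than ``min_cpgs`` covered CpGs).
    """
    by_scaf = {scaf: grp.sort_values("pos") for scaf, grp in cpgs.groupby("scaffold")}
    rows, excluded = [], []
    for row in features.itertuples(index=False):
        grp = by_scaf.get(row.scaffold)
        n = 0
        mean = np.nan
        if grp is not None:
            pos = grp["pos"].to_numpy()
            i0, i1 = np.searchsorted(pos, [row.start, row.end])
            n = i1 - i0
            if n > 0:
                mean = float(grp["meth_pct"].to_numpy()[i0:i1].mean())
        if n >= min_cpgs and n > 0:
            rows.append(
                {"transcript_id": row.transcript_id, "body_mean": mean, "n_cpgs_body": n}
            )
        else:
            excluded.append(row.transcript_id)
    out = pd.DataFrame(rows, columns=["transcript_id", "body_mean", "n_cpgs_body"])
    return out, excluded


def _kmeanspp_seed(xs: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Classic k-means++: first center uniform, then D^2-weighted draws."""
    centers = [xs[rng.integers(len(xs))]]
    for _ in range(k - 1):
        d2 = np.min((xs[:, None] - np.asarray(centers)[None, :]) ** 2, axis=1)
        total = d2.sum()
        if total <= 0:
            centers.append(xs[rng.integers(len(xs))])
        else:
            centers.append(xs[rng.choice(len(xs), p=d2 / total)])
    return np.asarray(centers, dtype=float)


def _kmeans_1d(x: np.ndarray, k: int, seed: int, restarts: int):
    """Best-of-``restarts`` 1-D k-means.

    Each restart runs Lloyd's algorithm from a k-means++ seeding and then
    polishes the converged solution with single-point transfers across
    adjacent cluster boundaries (in 1-D every k-means solution is an
    interval partition of the sorted values, so a transfer just shifts a
    boundary; moves are accepted while they lower the within-cluster sum of
    squares, as in Hartigan–Wong).  The polish step is what lets a small
    number of restarts reach the global optimum reliably on unstructured
    data, where plain Lloyd has many shallow local optima.
    Returns (inertia, centers ascending, boundaries, sort order).
    """
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(xs)
    s1 = np.concatenate([[0.0], np.cumsum(xs)])
    s2 = np.concatenate([[0.0], np.cumsum(xs**2)])

    def seg_cost(a: int, b: int) -> float:  # SSE of xs[a:b]
        s = s1[b] - s1[a]
        return (s2[b] - s2[a]) - s * s / (b - a)

    def total_cost(bounds) -> float:
        edges = [0, *bounds, n]
        return sum(seg_cost(a, b) for a, b in zip(edges[:-1], edges[1:]))

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        centers = np.sort(_kmeanspp_seed(xs, k, rng))
        labels = None
        for _ in range(300):
            new = np.argmin(np.abs(xs[:, None] - centers[None, :]), axis=1)
            for j in range(k):  # re-seed empty clusters at the farthest point
                if not (new == j).any():
                    d = np.min(np.abs(xs[:, None] - centers[None, :]), axis=1)
                    new[np.argmax(d)] = j
            if labels is not None and np.array_equal(new, labels):
                break
            labels = new
            centers = np.array([xs[labels == j].mean() for j in range(k)])
        sizes = np.bincount(labels, minlength=k)[np.argsort(centers)]
        bounds = list(np.cumsum(sizes[:-1]))
        improved = True
        while improved:
            improved = False
            for bi in range(len(bounds)):
                for delta in (-1, 1):
                    nb = bounds[bi] + delta
                    lo = bounds[bi - 1] + 1 if bi > 0 else 1
                    hi = (bounds[bi + 1] if bi < len(bounds) - 1 else n) - 1
                    if not lo <= nb <= hi:
                        continue
                    trial = [*bounds[:bi], nb, *bounds[bi + 1 :]]
                    if total_cost(trial) < total_cost(bounds) - 1e-12:
                        bounds = trial
                        improved = True
        inertia = total_cost(bounds)
        if best is None or inertia < best[0]:
            best = (inertia, bounds)
    inertia, bounds = best
    edges = [0, *bounds, n]
    centers = np.array(
        [(s1[b] - s1[a]) / (b - a) for a, b in zip(edges[:-1], edges[1:])]
    )
    return float(inertia), centers


def kmeans_patterns(
    means: pd.DataFrame,
    k: int = 4,
    seed: int = 0,
    restarts: int = 10,
) -> PatternAssignment:
    """Cluster per-transcript body means into k methylation patterns.

    One-dimensional k-means (Lloyd iterations from k-means++ seedings with
    a boundary-transfer polish, best of ``restarts`` runs by within-cluster
    sum of squares).  Labels are 1..k by descending center; every
    transcript is assigned to its nearest ordered center, ties toward the
    smaller label (the more methylated pattern).
    """
    x = means["body_mean"].to_numpy(dtype=float)
    if len(x) < k:
        raise ValueError(f"need at least k={k} transcripts, got {len(x)}")
    if len(np.unique(x)) < k:
        raise ValueError(
            f"degenerate input: only {len(np.unique(x))} distinct body means for k={k}"
        )
    inertia, centers_asc = _kmeans_1d(x, k, seed, restarts)
    centers = centers_asc[::-1]
    if np.any(np.diff(centers) >= 0):
        raise ValueError("degenerate clustering: centers not strictly descending")
    # Nearest ordered center; argmin takes the first (lower label) on ties.
    labels = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1) + 1
    table = means.copy()
    table["mp_label"] = labels
    return PatternAssignment(table, centers, inertia, seed, restarts)


def apply_reference_order(
    reference: PatternAssignment, other_samples: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Report other samples' body means under the reference pattern labels.

    No re-clustering: each transcript keeps the pattern label assigned in
    the reference sample, and other samples' means are merged in by id
    (missing transcripts get NaN).  ``other_samples`` maps sample name →
    per-transcript means frame.
    """
    out = reference.table[["transcript_id", "body_mean", "mp_label"]].rename(
        columns={"body_mean": "reference"}
    )
    overlap = False
    for name, means in other_samples.items():
        cols = means[["transcript_id", "body_mean"]].rename(columns={"body_mean": name})
        out = out.merge(cols, on="transcript_id", how="left")
        if out[name].notna().any():
            overlap = True
    if other_samples and not overlap:
        raise ValueError("no transcript overlap between reference and other samples")
    return out


def pattern_length_stats(
    assignment: PatternAssignment, features: pd.DataFrame
) -> pd.DataFrame:
    """log10 transcript length (TSS→TTS span, bp) summarized per pattern.

    Returns per-pattern n, median and quartiles of log10(length); zero- or
    negative-length features are excluded with a warning.
    """
    import warnings

    lengths = features.assign(length=features["end"] - features["start"])[
        ["transcript_id", "length"]
    ]
    merged = assignment.table.merge(lengths, on="transcript_id", how="left")
    bad = merged["length"] <= 0
    if bad.any():
        warnings.warn(f"excluded {int(bad.sum())} zero-length transcripts")
        merged = merged[~bad]
    merged["log10_length"] = np.log10(merged["length"])
    rows = []
    for mp, grp in merged.groupby("mp_label"):
        q1, med, q3 = np.percentile(grp["log10_length"], [25, 50, 75])
        rows.append(
            {"mp_label": mp, "n": len(grp), "q1": q1, "median": med, "q3": q3}
        )
    return pd.DataFrame(rows)
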