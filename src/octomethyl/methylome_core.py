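"""CpG-level classification, per-sample summaries, joins, and down-sampling.

Sites are classified by their percent methylation ``m`` into three
categories with strict thresholds: unmethylated (``m < lo``, default 20),
methylated (``m > hi``, default 80), intermediate otherwise.  Values exactly
at a threshold are intermediate.  In a sparsely methylated invertebrate
genome the intermediate band (~7% of covered sites) carries real signal —
cellular heterogeneity or stochastic methylation — so it is kept as its own
category rather than folded into either extreme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

CATEGORIES = ("methylated", "intermediate", "unmethylated")


@dataclass
class MethylomeSummary:
    """Per-sample counts and percentages of covered CpGs by category."""

    n_covered: int
    n_methylated: int
    n_intermediate: int
    n_unmethylated: int
    pct_methylated: float
    pct_intermediate: float
    pct_unmethylated: float
    pct_genome_covered: float | None = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def count_genome_cpgs(genome) -> int:
    """Count CpG cytosines in a genome, both strands.

    ``genome`` is a mapping of scaffold → sequence, or a FASTA path.  Each CG
    dinucleotide contributes two sites (the C on Watson and the C on Crick),
    matching per-strand CpG tables.  Ambiguous bases never match.
    """
    import warnings

    if isinstance(genome, (str, bytes)) or hasattr(genome, "__fspath__"):
        from .formats_io import read_fasta

        genome = read_fasta(genome)
    total = 0
    for seq in genome.values():
        total += str(seq).upper().count("CG")
    if total == 0:
        warnings.warn("no CpG dinucleotides found in genome")
    return 2 * total


def classify_cpgs(table: pd.DataFrame, lo: float = 20.0, hi: float = 80.0) -> pd.DataFrame:
    """Add a ``category`` column using strict thresholds.

    ``meth_pct > hi`` → methylated, ``meth_pct < lo`` → unmethylated, else
    intermediate (boundary values are intermediate).
    """
    if not 0 <= lo < hi <= 100:
        raise ValueError(f"need 0 <= lo < hi <= 100, got lo={lo}, hi={hi}")
    out = table.copy()
    m = out["meth_pct"].to_numpy()
    cat = np.full(len(out), "intermediate", dtype=object)
    cat[m > hi] = "methylated"
    cat[m < lo] = "unmethylated"
    out["category"] = pd.Categorical(cat, categories=list(CATEGORIES))
    return out


def summarize_methylome(
    classified: pd.DataFrame, genome_cpg_count: int | None = None
) -> MethylomeSummary:
    """Summarize a classified CpG table into counts and percentages.

    ``pct_genome_covered`` requires the total genome CpG count (both
    strands); with zero covered sites the percentage fields are NaN.
    """
    n = len(classified)
    counts = classified["category"].value_counts()
    n_meth = int(counts.get("methylated", 0))
    n_int = int(counts.get("intermediate", 0))
    n_unmeth = int(counts.get("unmethylated", 0))
    if n > 0:
        pm, pi, pu = (100.0 * x / n for x in (n_meth, n_int, n_unmeth))
    else:
        pm = pi = pu = float("nan")
    pct_cov = None
    if genome_cpg_count is not None:
        if genome_cpg_count < n:
            raise ValueError("genome CpG count smaller than covered-site count")
        pct_cov = 100.0 * n / genome_cpg_count if genome_cpg_count else float("nan")
    return MethylomeSummary(n, n_meth, n_int, n_unmeth, pm, pi, pu, pct_cov)


def join_common_cpgs(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Inner-join CpG tables on (scaffold, pos, strand).

    Returns one row per site detected in *all* input samples, with one
    ``meth_pct`` column per sample, sorted by (scaffold, pos, strand).
    """
    if len(tables) < 2:
        raise ValueError("need at least two tables to join")
    merged = None
    seen: dict[str, int] = {}
    for t in tables:
        sample = str(t["sample"].iloc[0]) if len(t) else "sample"
        seen[sample] = seen.get(sample, 0) + 1
        if seen[sample] > 1:
            sample = f"{sample}_{seen[sample]}"
        cols = t[["scaffold", "pos", "strand", "meth_pct"]].rename(
            columns={"meth_pct": str(sample)}
        )
        if merged is None:
            merged = cols
        else:
            merged = merged.merge(cols, on=["scaffold", "pos", "strand"], how="inner")
    return merged.sort_values(["scaffold", "pos", "strand"]).reset_index(drop=True)


def downsample_cpgs(table: pd.DataFrame, n: int, seed: int) -> pd.DataFrame:
    """Uniform sample of ``n`` rows without replacement, seeded.

    Used to compare repeat classes at matched site counts (e.g. matching the
    number of CpGs found in satellite arrays).  Row order of the original
    table is preserved.
    """
    if n > len(table):
        raise ValueError(f"cannot sample {n} rows from a table of {len(table)}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(table), size=n, replace=False))
    return table.iloc[idx].reset_index(drop=True)


def destrand(table: pd.DataFrame) -> pd.DataFrame:
    """Merge the two strands of each CpG by summing read counts (optional).

    The Crick-strand cytosine at ``pos`` is paired with the Watson cytosine
    at ``pos - 1``; the merged site keeps the Watson coordinate and ``+``
    strand, with ``meth_pct`` recomputed from the pooled counts.  Off the
    default analysis path: per-strand sites are the unit everywhere else.
    """
    t = table.copy()
    t["cpg_start"] = np.where(t["strand"].to_numpy() == "-", t["pos"] - 1, t["pos"])
    grouped = t.groupby(["scaffold", "cpg_start", "sample"], as_index=False).agg(
        n_meth=("n_meth", "sum"), n_total=("n_total", "sum")
    )
    grouped["meth_pct"] = np.where(
        grouped["n_total"] > 0, 100.0 * grouped["n_meth"] / grouped["n_total"], np.nan
    )
    grouped["strand"] = "+"
    grouped = grouped.rename(columns={"cpg_start": "pos"})
    return grouped[["scaffold", "pos", "strand", "meth_pct", "n_meth", "n_total", "sample"]]
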