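"""Scaled-bin metaplots, CpG-density tracks, and flanked per-gene matrices.

Regions of unequal length are rescaled to a fixed number of bins
(30 for genes, 15 for repeats by convention); position ``pos`` inside a
region of length ``L`` maps to bin ``floor(B * d / L)`` where ``d`` is the
distance from the strand-aware 5' end, clamped to ``B - 1``.  Bin summaries
use the winsorized mean (values outside the 1st–99th percentile of the
bin's pooled values are clipped to those percentiles) with a normal-theory
95% confidence band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class BinnedProfile:
    """Per-bin winsorized-mean profile.

    ``table`` has columns ``bin, mean, ci_halfwidth, n`` (mean is NaN for
    empty bins); ``b`` is the bin count and ``winsor`` the percentile pair
    the means were clipped at.
    """

    table: pd.DataFrame
    b: int
    winsor: tuple[float, float]
    region_kind: str = "regions"

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def assign_bin(start: int, end: int, strand: str, pos: int, b: int) -> int:
    """Bin index of ``pos`` in a 0-based half-open region, strand-aware.

    Distance from the 5' end is ``pos - start`` on + and ``end - 1 - pos``
    on -; the index ``floor(b * d / L)`` is clamped to ``b - 1`` (only
    relevant for the final base).
    """
    if not start <= pos < end:
        raise ValueError(f"position {pos} outside [{start}, {end})")
    length = end - start
    d = pos - start if strand == "+" else end - 1 - pos
    return min(b * d // length, b - 1)


def _assign_bins_vec(starts, ends, strands, pos, b):
    lengths = ends - starts
    d = np.where(strands == "+", pos - starts, ends - 1 - pos)
    return np.minimum((b * d) // lengths, b - 1)


def winsorized_mean(values: np.ndarray, w_lo: float, w_hi: float):
    """Mean, CI half-width and sd after clipping to the (w_lo, w_hi)
    percentiles (linear interpolation).

    With limits (0, 100) this is exactly the arithmetic mean.  The CI
    half-width is 1.96 * sd / sqrt(n) on the clipped values (0 when n <= 1).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        return np.nan, np.nan, 0
    lo, hi = np.percentile(values, [w_lo, w_hi])
    clipped = np.clip(values, lo, hi)
    mean = float(clipped.mean())
    if n > 1:
        sd = float(clipped.std(ddof=1))
        ci = 1.96 * sd / np.sqrt(n)
    else:
        ci = 0.0
    return mean, ci, n


def _pool_region_values(cpgs: pd.DataFrame, regions: pd.DataFrame, b: int):
    """Per-bin pooled meth_pct values across all regions.

    CpGs on either strand contribute to every region they fall in; a CpG
    inside k overlapping regions contributes k times.
    """
    pools: list[list] = [[] for _ in range(b)]
    by_scaf = {
        scaf: grp.sort_values("pos") for scaf, grp in cpgs.groupby("scaffold")
    }
    for row in regions.itertuples(index=False):
        grp = by_scaf.get(row.scaffold)
        if grp is None:
            continue
        pos = grp["pos"].to_numpy()
        i0, i1 = np.searchsorted(pos, [row.start, row.end])
        if i1 <= i0:
            continue
        sub_pos = pos[i0:i1]
        vals = grp["meth_pct"].to_numpy()[i0:i1]
        bins = _assign_bins_vec(
            np.full(len(sub_pos), row.start),
            np.full(len(sub_pos), row.end),
            np.full(len(sub_pos), row.strand, dtype=object),
            sub_pos,
            b,
        )
        for bin_idx, v in zip(bins, vals):
            pools[bin_idx].append(v)
    return pools


def metaplot(
    cpgs: pd.DataFrame,
    regions: pd.DataFrame,
    b: int = 30,
    winsor: tuple[float, float] = (1.0, 99.0),
    region_kind: str = "regions",
) -> BinnedProfile:
    """Winsorized-mean methylation profile over length-scaled regions.

    Values are pooled per bin across all regions, then clipped to the bin's
    ``winsor`` percentiles before averaging.  Genes conventionally use
    ``b=30``, repeats ``b=15``.
    """
    if b < 1:
        raise ValueError("bin count must be >= 1")
    pools = _pool_region_values(cpgs, regions, b)
    rows = []
    for i, vals in enumerate(pools):
        mean, ci, n = winsorized_mean(np.asarray(vals), *winsor)
        rows.append({"bin": i, "mean": mean, "ci_halfwidth": ci if n else 0.0, "n": n})
    return BinnedProfile(pd.DataFrame(rows), b, winsor, region_kind)


def cpg_density(regions: pd.DataFrame, genome, b: int = 30) -> BinnedProfile:
    """Per-bin CpG density: CG-dinucleotide starts per base, pooled.

    Each base of each region is assigned to a bin (strand-aware), and the
    density of a bin is (CG starts in it) / (bases in it) across all
    regions.
    """
    if isinstance(genome, (str, bytes)) or hasattr(genome, "__fspath__"):
        from .formats_io import read_fasta

        genome = read_fasta(genome)
    cg_counts = np.zeros(b)
    base_counts = np.zeros(b)
    for row in regions.itertuples(index=False):
        seq = genome[row.scaffold]
        if row.end > len(seq):
            raise ValueError(
                f"region {row.scaffold}:{row.start}-{row.end} beyond scaffold end"
            )
        length = row.end - row.start
        pos = np.arange(row.start, row.end)
        d = pos - row.start if row.strand == "+" else row.end - 1 - pos
        bins = np.minimum((b * d) // length, b - 1)
        np.add.at(base_counts, bins, 1)
        # one base past the region end so a CG starting on the last base counts
        sub = str(seq[row.start : row.end + 1]).upper()
        arr = np.frombuffer(sub.encode(), dtype="S1")
        pair = (arr[:-1] == b"C") & (arr[1:] == b"G")
        is_cg = np.zeros(length, dtype=bool)
        is_cg[: len(pair)] = pair[:length]
        if is_cg.any():
            np.add.at(cg_counts, bins[is_cg], 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dens = np.where(base_counts > 0, cg_counts / base_counts, np.nan)
    table = pd.DataFrame(
        {
            "bin": np.arange(b),
            "mean": dens,
            "ci_halfwidth": 0.0,
            "n": base_counts.astype(int),
        }
    )
    return BinnedProfile(table, b, (0.0, 100.0), "density")


def flanked_matrix(
    cpgs: pd.DataFrame,
    features: pd.DataFrame,
    flank_len: int = 2000,
    body_bins: int = 30,
    flank_bins: int = 20,
) -> pd.DataFrame:
    """Per-transcript methylation matrix over upstream flank, scaled body,
    downstream flank.

    Flanks are fixed-width windows of ``flank_len / flank_bins`` bp; the
    body is length-scaled into ``body_bins`` bins.  Orientation is
    strand-aware: column u1 is the far upstream end, d<n> far downstream.
    Cells with no covered CpG are NaN.  Columns are ``u1..u<f>, b1..b<B>,
    d1..d<f>``.
    """
    cols = (
        [f"u{i + 1}" for i in range(flank_bins)]
        + [f"b{i + 1}" for i in range(body_bins)]
        + [f"d{i + 1}" for i in range(flank_bins)]
    )
    win = flank_len / flank_bins if flank_bins else 0
    by_scaf = {scaf: grp.sort_values("pos") for scaf, grp in cpgs.groupby("scaffold")}
    sums = np.zeros((len(features), len(cols)))
    counts = np.zeros_like(sums)
    for r, row in enumerate(features.itertuples(index=False)):
        grp = by_scaf.get(row.scaffold)
        if grp is None:
            continue
        pos_all = grp["pos"].to_numpy()
        lo = row.start - flank_len
        hi = row.end + flank_len
        i0, i1 = np.searchsorted(pos_all, [lo, hi])
        pos = pos_all[i0:i1]
        vals = grp["meth_pct"].to_numpy()[i0:i1]
        length = row.end - row.start
        for p, v in zip(pos, vals):
            if row.start <= p < row.end:
                d = p - row.start if row.strand == "+" else row.end - 1 - p
                col = flank_bins + min(body_bins * d // length, body_bins - 1)
            elif p < row.start:
                # genomic left flank: upstream on +, downstream on -
                d = row.start - 1 - p  # 0 = nearest to the body
                w = min(int(d // win), flank_bins - 1)
                col = (flank_bins - 1 - w) if row.strand == "+" else (
                    flank_bins + body_bins + w
                )
            else:
                d = p - row.end
                w = min(int(d // win), flank_bins - 1)
                col = (flank_bins + body_bins + w) if row.strand == "+" else (
                    flank_bins - 1 - w
                )
            sums[r, col] += v
            counts[r, col] += 1
    with np.errstate(invalid="ignore"):
        mat = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(mat, index=features["transcript_id"].to_numpy(), columns=cols)
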