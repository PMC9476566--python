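"""Genomic-context annotation of CpGs and partition of intergenic space.

Each CpG gets exactly one context with precedence
promoter > exon > intron > intergenic over the union of all transcripts.
Promoters are ``promoter_len`` bp upstream of the TSS on the feature's
strand.  Intergenic CpGs are further split into TE (overlapping a
DNA/LTR/LINE/SINE transposon), nonTE_repeat (Satellite/SimpleRepeat/OtherRE
only) and repeat_free; a CpG under both a transposon and a non-transposon
repeat counts as TE.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .formats_io import TE_GROUPS

CONTEXTS = ("promoter", "exon", "intron", "intergenic")
INTERGENIC_CLASSES = ("TE", "nonTE_repeat", "repeat_free")

#: deterministic priority when a CpG overlaps repeats of several groups
_REPEAT_PRIORITY = ("DNA", "LTR", "LINE", "SINE", "Satellite", "SimpleRepeat", "OtherRE")


class _IntervalStabber:
    """Point-in-any-interval queries on possibly overlapping intervals.

    Intervals are sorted by start; a point x is covered iff some interval
    with start <= x has end > x, i.e. the running maximum of ends over the
    sorted prefix up to searchsorted(starts, x, 'right') exceeds x.
    """

    def __init__(self, starts: np.ndarray, ends: np.ndarray):
        order = np.argsort(starts, kind="stable")
        self.starts = np.asarray(starts)[order]
        ends = np.asarray(ends)[order]
        self.cummax_ends = np.maximum.accumulate(ends) if len(ends) else ends

    def covers(self, pos: np.ndarray) -> np.ndarray:
        if len(self.starts) == 0:
            return np.zeros(len(pos), dtype=bool)
        idx = np.searchsorted(self.starts, pos, side="right")
        out = np.zeros(len(pos), dtype=bool)
        nz = idx > 0
        out[nz] = self.cummax_ends[idx[nz] - 1] > pos[nz]
        return out


def _stabbers_by_scaffold(intervals: pd.DataFrame) -> dict[str, _IntervalStabber]:
    out = {}
    for scaf, grp in intervals.groupby("scaffold"):
        out[scaf] = _IntervalStabber(grp["start"].to_numpy(), grp["end"].to_numpy())
    return out


def _promoter_intervals(features: pd.DataFrame, promoter_len: int) -> pd.DataFrame:
    """Strand-aware upstream windows: [start-L, start) on +, [end, end+L) on -."""
    plus = features["strand"] == "+"
    starts = np.where(plus, features["start"] - promoter_len, features["end"])
    ends = np.where(plus, features["start"], features["end"] + promoter_len)
    return pd.DataFrame(
        {"scaffold": features["scaffold"], "start": np.maximum(starts, 0), "end": ends}
    )


def _exon_intervals(features: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for row in features.itertuples(index=False):
        for es, ee in row.exons:
            rows.append((row.scaffold, es, ee))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end"])


def annotate_cpgs(
    cpgs: pd.DataFrame, features: pd.DataFrame, promoter_len: int = 2000
) -> pd.DataFrame:
    """Assign a genomic context to every CpG.

    Precedence when a CpG overlaps several annotation layers (of the same or
    different transcripts): promoter > exon > intron > intergenic.  CpGs on
    scaffolds without features are intergenic.
    """
    out = cpgs.copy()
    n = len(out)
    context = np.full(n, "intergenic", dtype=object)
    if len(features):
        prom = _stabbers_by_scaffold(_promoter_intervals(features, promoter_len))
        exon = _stabbers_by_scaffold(_exon_intervals(features))
        body = _stabbers_by_scaffold(features[["scaffold", "start", "end"]])
        for scaf, idx in out.groupby("scaffold").indices.items():
            pos = out["pos"].to_numpy()[idx]
            in_prom = prom[scaf].covers(pos) if scaf in prom else np.zeros(len(idx), bool)
            in_exon = exon[scaf].covers(pos) if scaf in exon else np.zeros(len(idx), bool)
            in_body = body[scaf].covers(pos) if scaf in body else np.zeros(len(idx), bool)
            ctx = np.full(len(idx), "intergenic", dtype=object)
            ctx[in_body] = "intron"
            ctx[in_exon] = "exon"
            ctx[in_prom] = "promoter"
            context[idx] = ctx
    out["context"] = pd.Categorical(context, categories=list(CONTEXTS))
    return out


def partition_intergenic(annotated: pd.DataFrame, repeats: pd.DataFrame) -> pd.DataFrame:
    """Attach repeat overlap and split intergenic CpGs into TE / nonTE / free.

    ``repeat_group`` is set for every CpG under a repeat record (genic or
    not, transposon groups taking priority); ``intergenic_class`` is defined
    only where context == intergenic.  Genic CpGs are never relabelled.
    """
    if "context" not in annotated.columns:
        raise ValueError("run annotate_cpgs before partition_intergenic")
    out = annotated.copy()
    n = len(out)
    repeat_group = np.full(n, None, dtype=object)
    if len(repeats):
        stab = {
            g: _stabbers_by_scaffold(grp[["scaffold", "start", "end"]])
            for g, grp in repeats.groupby("group")
        }
        for scaf, idx in out.groupby("scaffold").indices.items():
            pos = out["pos"].to_numpy()[idx]
            assigned = repeat_group[idx]
            # lowest-priority groups first so later (higher-priority) wins
            for group in reversed(_REPEAT_PRIORITY):
                by_scaf = stab.get(group)
                if not by_scaf or scaf not in by_scaf:
                    continue
                hit = by_scaf[scaf].covers(pos)
                assigned[hit] = group
            repeat_group[idx] = assigned
    out["repeat_group"] = repeat_group
    is_intergenic = (out["context"] == "intergenic").to_numpy()
    iclass = np.full(n, None, dtype=object)
    has_repeat = np.array([g is not None for g in repeat_group])
    is_te = np.array([g in TE_GROUPS for g in repeat_group])
    iclass[is_intergenic] = "repeat_free"
    iclass[is_intergenic & has_repeat] = "nonTE_repeat"
    iclass[is_intergenic & is_te] = "TE"
    out["intergenic_class"] = iclass
    return out


def context_composition(
    annotated: pd.DataFrame, by_category: bool = True
) -> pd.DataFrame:
    """Per-context proportions, overall and per methylation category.

    Returns a tidy frame (subset, context, n, proportion); proportions sum
    to 1 within each subset.  ``subset`` is ``all`` plus each category
    present when ``by_category`` and the table is classified.
    """
    rows = []

    def _one(label: str, sub: pd.DataFrame):
        total = len(sub)
        counts = sub["context"].value_counts()
        for ctx in CONTEXTS:
            c = int(counts.get(ctx, 0))
            rows.append(
                {
                    "subset": label,
                    "context": ctx,
                    "n": c,
                    "proportion": c / total if total else np.nan,
                }
            )

    _one("all", annotated)
    if by_category and "category" in annotated.columns:
        for cat, sub in annotated.groupby("category", observed=True):
            if len(sub):
                _one(str(cat), sub)
    return pd.DataFrame(rows)


def export_bed_like(annotated: pd.DataFrame, path) -> None:
    """BED-like TSV export: scaffold, start, end, strand, plus annotation."""
    out = annotated.copy()
    out["start"] = out["pos"]
    out["end"] = out["pos"] + 1
    cols = ["scaffold", "start", "end", "strand", "meth_pct", "context"]
    for extra in ("category", "repeat_group", "intergenic_class", "sample"):
        if extra in out.columns:
            cols.append(extra)
    out[cols].to_csv(path, sep="\t", index=False)
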