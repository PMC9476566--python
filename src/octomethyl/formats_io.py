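"""Readers and writers for the external formats the pipeline touches.

All genomic intervals are 0-based half-open internally; the 1-based
conventions of CGmap, Bismark coverage, GFF/GTF and RepeatMasker are
converted at this boundary and nowhere else.

A *CpG table* is a :class:`pandas.DataFrame` with columns
``scaffold, pos, strand, meth_pct, n_meth, n_total, sample`` — one row per
strand-specific cytosine in CpG context.  ``pos`` is the 0-based position of
the cytosine itself, ``meth_pct`` the methylation level in percent.
"""

from __future__ import annotations

import gzip
import io
import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CPG_COLUMNS = ["scaffold", "pos", "strand", "meth_pct", "n_meth", "n_total", "sample"]

#: RepeatMasker class/family prefixes → repeat group.  Transposon groups are
#: DNA/LTR/LINE/SINE; Satellite, SimpleRepeat and OtherRE are non-transposons.
REPEAT_GROUPS = ("DNA", "LTR", "LINE", "SINE", "Satellite", "SimpleRepeat", "OtherRE")
TE_GROUPS = frozenset({"DNA", "LTR", "LINE", "SINE"})


class FormatError(ValueError):
    """A file violated the dialect this reader expects."""


def _open_text(path):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def _empty_cpg_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scaffold": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "meth_pct": pd.Series(dtype=float),
            "n_meth": pd.Series(dtype=np.int64),
            "n_total": pd.Series(dtype=np.int64),
            "sample": pd.Series(dtype=str),
        }
    )


# ---------------------------------------------------------------------------
# CGmap
# ---------------------------------------------------------------------------

def read_cgmap(path, min_total: int = 1, sample: str | None = None) -> pd.DataFrame:
    """Read a CGmap file, keeping CpG-context cytosines only.

    CGmap columns: chrom, Watson nucleotide (C/G), 1-based position, context
    (CG/CHG/CHH), dinucleotide, methylation level in [0, 1], methylated read
    count, total read count.  Strand is derived from the nucleotide column
    (C → ``+``, G → ``-``), the level is scaled ×100 into percent, and rows
    with fewer than ``min_total`` reads are dropped.  ``min_total`` defaults
    to 1 (no depth filter) because deposited whole-genome CGmaps are
    typically already depth-handled upstream; pass 10 to mirror the reduced-
    representation filter.
    """
    if sample is None:
        sample = os.path.basename(os.fspath(path))
    recs = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise FormatError(
                    f"{path}:{lineno}: expected >=8 tab-separated columns, got {len(parts)}"
                )
            chrom, nuc, pos1, context, _dinuc, level, n_meth, n_total = parts[:8]
            if context != "CG":
                continue
            level = float(level)
            if not 0.0 <= level <= 1.0:
                raise FormatError(
                    f"{path}:{lineno}: methylation level {level} outside [0, 1]"
                )
            if nuc not in ("C", "G"):
                raise FormatError(f"{path}:{lineno}: nucleotide column must be C or G")
            recs.append(
                (
                    chrom,
                    int(pos1) - 1,
                    "+" if nuc == "C" else "-",
                    100.0 * level,
                    int(n_meth),
                    int(n_total),
                )
            )
    if not recs:
        return _empty_cpg_table()
    df = pd.DataFrame(recs, columns=["scaffold", "pos", "strand", "meth_pct", "n_meth", "n_total"])
    df["sample"] = sample
    df = df[df["n_total"] >= min_total].reset_index(drop=True)
    return df


def write_cgmap(table: pd.DataFrame, path) -> None:
    """Write a CpG table in CGmap dialect (inverse of :func:`read_cgmap`)."""
    with open(path, "w") as fh:
        for row in table.itertuples(index=False):
            nuc = "C" if row.strand == "+" else "G"
            level = row.meth_pct / 100.0
            fh.write(
                f"{row.scaffold}\t{nuc}\t{row.pos + 1}\tCG\tCG\t{level:.6f}\t"
                f"{row.n_meth}\t{row.n_total}\n"
            )


# ---------------------------------------------------------------------------
# Bismark coverage
# ---------------------------------------------------------------------------

def read_bismark_coverage(
    path,
    min_total: int = 10,
    sample: str | None = None,
    genome: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a Bismark-style coverage file (chrom, start, end, %meth, n_meth, n_unmeth).

    Coordinates are 1-based with start == end for a single cytosine.  Rows
    with total depth (n_meth + n_unmeth) below ``min_total`` are dropped; the
    default of 10 mirrors the standard reduced-representation depth filter.

    Coverage rows carry no strand.  If ``genome`` (a mapping of scaffold →
    sequence) is supplied, strand is resolved by base lookup (C → ``+``,
    G → ``-``); otherwise strand is recorded as ``+`` and the returned
    frame's ``attrs['strand_resolved']`` is False.
    """
    if sample is None:
        sample = os.path.basename(os.fspath(path))
    recs = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(
                    f"{path}:{lineno}: expected 6 tab-separated columns, got {len(parts)}"
                )
            chrom, start1, end1, pct, n_meth, n_unmeth = parts[:6]
            if int(start1) != int(end1):
                raise FormatError(
                    f"{path}:{lineno}: coverage rows must have start == end "
                    f"(got {start1}..{end1})"
                )
            recs.append((chrom, int(start1) - 1, float(pct), int(n_meth), int(n_unmeth)))
    if not recs:
        out = _empty_cpg_table()
        out.attrs["strand_resolved"] = genome is not None
        return out
    df = pd.DataFrame(recs, columns=["scaffold", "pos", "meth_pct", "n_meth", "n_unmeth"])
    df["n_total"] = df["n_meth"] + df["n_unmeth"]
    df = df[df["n_total"] >= min_total].reset_index(drop=True)
    if genome is not None:
        strands = []
        for row in df.itertuples(index=False):
            base = str(genome[row.scaffold][row.pos : row.pos + 1]).upper()
            strands.append("+" if base == "C" else "-")
        df["strand"] = strands
        resolved = True
    else:
        df["strand"] = "+"
        resolved = False
    df["sample"] = sample
    df = df[CPG_COLUMNS].copy()
    df.attrs["strand_resolved"] = resolved
    return df


def write_bismark_coverage(table: pd.DataFrame, path) -> None:
    """Write (chrom, 1-based pos, pos, %meth, n_meth, n_unmeth) rows."""
    with open(path, "w") as fh:
        for row in table.itertuples(index=False):
            n_unmeth = row.n_total - row.n_meth
            fh.write(
                f"{row.scaffold}\t{row.pos + 1}\t{row.pos + 1}\t{row.meth_pct:.6f}\t"
                f"{row.n_meth}\t{n_unmeth}\n"
            )


# ---------------------------------------------------------------------------
# Gene models (GFF3 / GTF)
# ---------------------------------------------------------------------------

def read_gene_models(path) -> pd.DataFrame:
    """Read transcript models from GFF3 or GTF into a feature table.

    Returns a DataFrame with columns ``transcript_id, scaffold, start, end,
    strand, exons`` where start/end are 0-based half-open and ``exons`` is a
    sorted list of 0-based half-open (start, end) tuples.  Feature rows of
    type mRNA/transcript define transcripts; exon rows attach via their
    Parent (GFF3) or transcript_id (GTF) attribute.  Exons without a known
    parent are skipped with a warning.
    """
    import warnings

    import gffutils

    empty = pd.DataFrame(
        columns=["transcript_id", "scaffold", "start", "end", "strand", "exons"]
    )
    try:
        db = gffutils.create_db(
            os.fspath(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return empty
    transcripts: dict[str, dict] = {}
    for ftype in ("mRNA", "transcript"):
        for feat in db.features_of_type(ftype):
            if feat.end < feat.start:
                raise FormatError(f"{feat.id}: start > end")
            transcripts[feat.id] = {
                "transcript_id": feat.id,
                "scaffold": feat.seqid,
                "start": feat.start - 1,
                "end": feat.end,
                "strand": feat.strand,
                "exons": [],
            }
    for exon in db.features_of_type("exon"):
        parents = list(exon.attributes.get("Parent", []))
        if not parents and "transcript_id" in exon.attributes:
            parents = list(exon.attributes["transcript_id"])
        attached = False
        for pid in parents:
            if pid in transcripts:
                transcripts[pid]["exons"].append((exon.start - 1, exon.end))
                attached = True
        if not attached:
            warnings.warn(f"exon at {exon.seqid}:{exon.start} has no parent transcript; skipped")
    rows = []
    for rec in transcripts.values():
        rec["exons"] = sorted(rec["exons"])
        rows.append(rec)
    if not rows:
        return empty
    df = pd.DataFrame(rows)
    return df.sort_values(["scaffold", "start", "transcript_id"]).reset_index(drop=True)


def write_gff3(features: pd.DataFrame, path) -> None:
    """Write a feature table as GFF3 (mRNA + exon records)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in features.itertuples(index=False):
            fh.write(
                f"{row.scaffold}\t.\tmRNA\t{row.start + 1}\t{row.end}\t.\t{row.strand}\t.\t"
                f"ID={row.transcript_id}\n"
            )
            for i, (es, ee) in enumerate(row.exons, 1):
                fh.write(
                    f"{row.scaffold}\t.\texon\t{es + 1}\t{ee}\t.\t{row.strand}\t.\t"
                    f"ID={row.transcript_id}.exon{i};Parent={row.transcript_id}\n"
                )


def feature_tss(row) -> int:
    """0-based TSS of a feature row: ``start`` on +, ``end - 1`` on -."""
    return row.start if row.strand == "+" else row.end - 1


def feature_tts(row) -> int:
    """0-based TTS of a feature row: ``end - 1`` on +, ``start`` on -."""
    return row.end - 1 if row.strand == "+" else row.start


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

def classify_repeat(raw_class: str) -> str:
    """Map a RepeatMasker class/family string to its repeat group.

    Transposons (DNA, LTR, LINE, SINE) keep their class prefix; Satellite and
    Simple_repeat map to the two non-transposon repeat groups and anything
    else (rRNA, snRNA, Unknown, Low_complexity, ...) falls through to
    OtherRE.  Total on its input: never raises.
    """
    for prefix, group in (
        ("DNA", "DNA"),
        ("LTR", "LTR"),
        ("LINE", "LINE"),
        ("SINE", "SINE"),
        ("Satellite", "Satellite"),
        ("Simple_repeat", "SimpleRepeat"),
    ):
        if raw_class.startswith(prefix):
            return group
    return "OtherRE"


def read_repeatmasker(path) -> pd.DataFrame:
    """Read a RepeatMasker ``.out`` file into a repeat table.

    Returns columns ``scaffold, start, end, strand, raw_class, group`` with
    0-based half-open coordinates.  The standard layout has 3 header lines
    and whitespace-separated columns with query name in column 5,
    1-based begin/end in 6/7, strand (+ or C) in 9, and class/family in 11.
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            # Header lines start with "SW"/"score" or are blank.
            if parts[0] in ("SW", "score") or not parts[0][0].isdigit():
                continue
            if len(parts) < 11:
                raise FormatError(f"{path}:{lineno}: expected >=11 columns, got {len(parts)}")
            try:
                begin1, end1 = int(parts[5]), int(parts[6])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable coordinate") from exc
            raw_class = parts[10]
            rows.append(
                {
                    "scaffold": parts[4],
                    "start": begin1 - 1,
                    "end": end1,
                    "strand": "-" if parts[8] == "C" else "+",
                    "raw_class": raw_class,
                    "group": classify_repeat(raw_class),
                }
            )
    if not rows:
        return pd.DataFrame(columns=["scaffold", "start", "end", "strand", "raw_class", "group"])
    return pd.DataFrame(rows)


def write_repeatmasker(repeats: pd.DataFrame, path) -> None:
    """Write a repeat table in RepeatMasker ``.out`` layout."""
    with open(path, "w") as fh:
        fh.write(
            "   SW  perc perc perc  query      position in query           matching"
            "       repeat              position in  repeat\n"
            "score  div. del. ins.  sequence    begin     end    (left)    repeat"
            "         class/family         begin  end (left)   ID\n\n"
        )
        for i, row in enumerate(repeats.itertuples(index=False), 1):
            strand = "C" if row.strand == "-" else "+"
            fh.write(
                f"  {200 + i} 10.0  0.0  0.0  {row.scaffold} {row.start + 1} {row.end} "
                f"(0) {strand} rep{i} {row.raw_class} 1 {row.end - row.start} (0) {i}\n"
            )


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_tpm_matrix(path) -> pd.DataFrame:
    """Read a transcript-by-sample TPM matrix from TSV (first column = id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate transcript ids: {dups}")
    if df.columns.has_duplicates:
        raise FormatError("duplicate sample names")
    vals = df.to_numpy()
    if (vals < 0).any():
        bad = df.index[(vals < 0).any(axis=1)].tolist()
        raise FormatError(f"negative TPM values for transcripts: {bad[:5]}")
    df.index.name = "transcript_id"
    return df


def write_tpm_matrix(tpm: pd.DataFrame, path) -> None:
    tpm.to_csv(path, sep="\t", index_label="transcript_id")


# ---------------------------------------------------------------------------
# GO term maps and FASTA
# ---------------------------------------------------------------------------

def read_term_map(path) -> dict[str, set]:
    """Read a 2-column TSV (term_id, gene_id) into term → gene-set mapping."""
    mapping: dict[str, set] = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            term, gene = line.split("\t")[:2]
            mapping.setdefault(term, set()).add(gene)
    return mapping


def write_term_map(mapping: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for term in sorted(mapping):
            for gene in sorted(mapping[term]):
                fh.write(f"{term}\t{gene}\n")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into a name → sequence dict (uppercased)."""
    from Bio import SeqIO

    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
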