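"""Synthetic genomes, methylomes and expression with known ground truth.

The generator emulates the statistical structure of a sparsely methylated
mollusk genome so that every pipeline stage can be exercised and checked
against truth without any downloads:

* a large, mostly intergenic genome (~85% of CpGs outside genes and
  promoters) with CpG-enriched gene bodies and repeat elements;
* four gene-body methylation archetypes — fully methylated (MP1),
  methylated except promoter/5' segment (MP2), methylated only over the 3'
  half at a lower level (MP3), unmethylated (MP4) — as piecewise-constant
  methylation-probability profiles in relative body coordinates;
* methylation-depleted transposons with a relatively higher-methylated
  satellite exception;
* an overall methylome that is <10% methylated with a ~7% intermediate
  (20–80%) band, arising from per-CpG beta heterogeneity around archetype
  levels;
* WGBS-dense vs RRBS-sparse coverage (Poisson depth; RRBS retains a ~3%
  CpG subset);
* expression coupled to methylation pattern: MP1/MP2 high in all tissues,
  MP3 intermediate, MP4 zero-inflated with tissue-specific bursts, and a
  mid-range band where expression rises with body methylation.

All randomness flows from ``GeneratorConfig.seed`` through named
``numpy.random`` child generators, so equal configs give byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import formats_io

ARCHETYPES = (1, 2, 3, 4)


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic methylome; defaults define the study conditions.

    ``archetype_levels`` are the methylation probabilities of the
    *methylated segment* of each archetype's gene body;
    ``archetype_low_fraction`` is the 5' fraction of the body left at the
    unmethylated floor (0 for MP1, whose promoter is also methylated; 1/3
    for MP2; 1/2 for MP3 so its realized body mean lands near 30%; MP4 is
    unmethylated throughout).  ``archetype_level_sd`` is the per-gene
    scatter applied to the segment level.
    """

    # genome layout
    n_scaffolds: int = 8
    scaffold_len: int = 7_000_000
    n_genes: int = 2000
    gene_len: int = 1200
    exons_per_gene: int = 3
    flank_margin: int = 2000  # repeat-free margin kept on each side of a gene
    te_counts: dict = field(
        default_factory=lambda: {"DNA": 400, "LTR": 300, "LINE": 400, "SINE": 200}
    )
    te_len: int = 500
    n_satellites: int = 60
    satellite_len: int = 1500
    n_simple_repeats: int = 150
    simple_repeat_len: int = 200
    n_other_re: int = 100
    other_re_len: int = 300
    # CpG placement (per-base probability of a CpG start)
    cpg_rate_intergenic: float = 0.006
    cpg_rate_genic: float = 0.015
    cpg_rate_repeat: float = 0.012
    # methylation truth
    archetype_weights: tuple = (0.142, 0.233, 0.170, 0.455)
    archetype_levels: tuple = (0.75, 0.75, 0.60, 0.02)
    archetype_low_fraction: tuple = (0.0, 1.0 / 3.0, 0.5, 0.0)
    archetype_level_sd: float = 0.05
    low_level: float = 0.02
    te_level: float = 0.05
    satellite_level: float = 0.15
    intergenic_level: float = 0.03
    cpg_concentration: float = 12.0  # truth heterogeneity around the level
    read_concentration: float = 200.0  # per-sample beta dispersion of reads
    # coverage models
    wgbs_depth: float = 30.0
    rrbs_depth: float = 40.0
    rrbs_retention: float = 0.03
    # expression
    n_tissues: int = 13
    expr_floor: float = 0.5
    expr_span: float = 5.5
    expr_midpoint: float = 25.0  # percent methylation at the coupling midpoint
    expr_scale: float = 12.0
    expr_gene_sd: float = 0.8
    expr_tissue_sd: float = 0.3
    mp4_zero_inflation: float = 0.55
    mp4_burst_prob: float = 0.35
    mp4_burst_sd: float = 1.0
    seed: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def _rng(config: GeneratorConfig, stream: str, extra: int = 0) -> np.random.Generator:
    # Independent, reproducible child stream per purpose (stable across
    # processes: zlib.crc32, not the salted built-in hash).
    import zlib

    tag = zlib.crc32(stream.encode()) % (2**16)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(tag, extra))
    )


@dataclass
class SyntheticDataset:
    """Generated layout plus ground truth (the test oracle).

    ``sites`` holds one row per CpG site (CG start) with its true
    methylation probability ``p_true`` and region label; ``genes`` holds
    per-transcript archetype, segment level and realized true body mean (in
    percent).  Sequences are materialized lazily because most analyses only
    need coordinates.
    """

    config: GeneratorConfig
    features: pd.DataFrame
    repeats: pd.DataFrame
    sites: pd.DataFrame
    genes: pd.DataFrame
    _sequences: dict | None = None

    # -- sequence materialization -------------------------------------------
    def sequences(self) -> dict[str, str]:
        """Scaffold sequences with CG dinucleotides exactly at the planted
        CpG sites (filler bases never form CG)."""
        if self._sequences is None:
            self._sequences = _materialize_sequences(self)
        return self._sequences

    def write_fasta(self, path) -> None:
        formats_io.write_fasta(self.sequences(), path)

    def write_gff3(self, path) -> None:
        formats_io.write_gff3(self.features, path)

    def write_repeatmasker(self, path) -> None:
        formats_io.write_repeatmasker(self.repeats, path)

    def truth_summary(self) -> dict:
        """Category fractions and archetype means implied by ``p_true``."""
        p = self.sites["p_true"].to_numpy()
        arch_means = (
            self.genes.groupby("archetype")["body_mean_true"].mean().to_dict()
        )
        return {
            "frac_methylated": float((p > 0.8).mean()),
            "frac_intermediate": float(((p >= 0.2) & (p <= 0.8)).mean()),
            "frac_unmethylated": float((p < 0.2).mean()),
            "archetype_body_means": {int(k): float(v) for k, v in arch_means.items()},
        }


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

def _pack_scaffold(items, scaffold_len, flank_margin, rng):
    """Place items (dicts with 'kind' and 'length') at random non-overlapping
    positions, genes keeping a repeat-free margin on both sides."""
    needed = sum(
        it["length"] + (2 * flank_margin if it["kind"] == "gene" else 0) for it in items
    )
    leftover = scaffold_len - needed - 2
    if leftover < 0:
        raise ValueError(
            f"infeasible packing: need {needed + 2} bp but scaffold is "
            f"{scaffold_len} bp; use longer scaffolds"
        )
    order = rng.permutation(len(items))
    spacers = rng.multinomial(leftover, np.full(len(items) + 1, 1.0 / (len(items) + 1)))
    cursor = 1
    placed = []
    for j, idx in enumerate(order):
        it = items[idx]
        cursor += int(spacers[j])
        if it["kind"] == "gene":
            cursor += flank_margin
        start = cursor
        cursor += it["length"]
        if it["kind"] == "gene":
            cursor += flank_margin
        placed.append({**it, "start": start, "end": start + it["length"]})
    return placed


def generate(config: GeneratorConfig | None = None) -> SyntheticDataset:
    """Build the genome layout and per-CpG methylation truth."""
    config = config or GeneratorConfig()
    rng = _rng(config, "layout")
    weights = np.asarray(config.archetype_weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("archetype weights must sum to 1")

    # assemble the item lists, round-robin across scaffolds
    items_by_scaffold: list[list] = [[] for _ in range(config.n_scaffolds)]
    archetypes = rng.choice(ARCHETYPES, size=config.n_genes, p=weights)
    level_jitter = rng.normal(0.0, config.archetype_level_sd, size=config.n_genes)
    gene_strands = rng.choice(["+", "-"], size=config.n_genes)
    for i in range(config.n_genes):
        a = int(archetypes[i])
        level = float(
            np.clip(config.archetype_levels[a - 1] + level_jitter[i], 0.0, 1.0)
        )
        items_by_scaffold[i % config.n_scaffolds].append(
            {
                "kind": "gene",
                "length": config.gene_len,
                "gene_idx": i,
                "archetype": a,
                "level": level,
                "strand": str(gene_strands[i]),
            }
        )
    rep_specs = [(g, config.te_len, n) for g, n in config.te_counts.items()]
    rep_specs += [
        ("Satellite", config.satellite_len, config.n_satellites),
        ("Simple_repeat", config.simple_repeat_len, config.n_simple_repeats),
        ("rRNA", config.other_re_len, config.n_other_re),
    ]
    j = 0
    for raw_class, length, count in rep_specs:
        for _ in range(count):
            items_by_scaffold[j % config.n_scaffolds].append(
                {"kind": "repeat", "length": length, "raw_class": raw_class}
            )
            j += 1

    feature_rows, repeat_rows, gene_rows = [], [], []
    site_frames = []
    for s in range(config.n_scaffolds):
        scaf = f"scaffold_{s + 1}"
        placed = _pack_scaffold(
            items_by_scaffold[s], config.scaffold_len, config.flank_margin, rng
        )
        # per-base CpG-start rate and methylation level
        rate = np.full(config.scaffold_len, config.cpg_rate_intergenic)
        level = np.full(config.scaffold_len, config.intergenic_level)
        region = {}
        for it in placed:
            start, end = it["start"], it["end"]
            if it["kind"] == "gene":
                rate[start:end] = config.cpg_rate_genic
                _paint_gene_levels(level, it, config)
            else:
                rate[start:end] = config.cpg_rate_repeat
                group = formats_io.classify_repeat(it["raw_class"])
                if group == "Satellite":
                    level[start:end] = config.satellite_level
                else:
                    level[start:end] = config.te_level
        # plant CpG starts (>= 2 bp apart, away from the scaffold edge)
        mask = rng.random(config.scaffold_len) < rate
        mask[-1] = False
        pos = np.flatnonzero(mask)
        if len(pos) > 1:
            # enforce >=2 bp spacing: within each run of consecutive
            # positions keep every other site (equivalent to a greedy scan)
            run_start = np.ones(len(pos), dtype=bool)
            run_start[1:] = np.diff(pos) >= 2
            run_id = np.cumsum(run_start) - 1
            first_idx = np.flatnonzero(run_start)
            idx_in_run = np.arange(len(pos)) - first_idx[run_id]
            pos = pos[idx_in_run % 2 == 0]
        mu = level[pos].copy()
        # archetype low segments are defined over each gene's body CpGs
        # (first `round(frac * n)` sites from the 5' end), so the realized
        # low-segment share is exact rather than binomially noisy
        for it in placed:
            if it["kind"] != "gene":
                continue
            low_frac = config.archetype_low_fraction[it["archetype"] - 1]
            if low_frac <= 0:
                continue
            i0, i1 = np.searchsorted(pos, [it["start"], it["end"]])
            n_body = i1 - i0
            k = int(round(low_frac * n_body))
            if it["strand"] == "+":
                mu[i0 : i0 + k] = config.low_level
            else:
                mu[i1 - k : i1] = config.low_level
        mu = np.clip(mu, 1e-4, 1 - 1e-4)
        nu = config.cpg_concentration
        p_true = rng.beta(mu * nu, (1.0 - mu) * nu)
        labels = np.full(len(pos), "intergenic", dtype=object)
        gene_of = np.full(len(pos), -1, dtype=np.int64)
        for it in placed:
            i0, i1 = np.searchsorted(pos, [it["start"], it["end"]])
            if it["kind"] == "gene":
                labels[i0:i1] = "gene"
                gene_of[i0:i1] = it["gene_idx"]
            else:
                labels[i0:i1] = formats_io.classify_repeat(it["raw_class"])
        site_frames.append(
            pd.DataFrame(
                {
                    "scaffold": scaf,
                    "start": pos,
                    "p_true": p_true,
                    "region": labels,
                    "gene_idx": gene_of,
                }
            )
        )
        # feature / repeat records
        rep_i = len(repeat_rows)
        for it in placed:
            if it["kind"] == "gene":
                tid = f"t{it['gene_idx'] + 1:05d}"
                exons = _exon_layout(it["start"], it["end"], config.exons_per_gene)
                feature_rows.append(
                    {
                        "transcript_id": tid,
                        "scaffold": scaf,
                        "start": it["start"],
                        "end": it["end"],
                        "strand": it["strand"],
                        "exons": exons,
                    }
                )
                gene_rows.append(
                    {
                        "transcript_id": tid,
                        "gene_idx": it["gene_idx"],
                        "scaffold": scaf,
                        "start": it["start"],
                        "end": it["end"],
                        "strand": it["strand"],
                        "archetype": it["archetype"],
                        "level": it["level"],
                    }
                )
            else:
                rep_i += 1
                repeat_rows.append(
                    {
                        "scaffold": scaf,
                        "start": it["start"],
                        "end": it["end"],
                        "strand": "+",
                        "raw_class": it["raw_class"],
                        "group": formats_io.classify_repeat(it["raw_class"]),
                    }
                )

    features = (
        pd.DataFrame(feature_rows)
        .sort_values(["scaffold", "start"])
        .reset_index(drop=True)
        if feature_rows
        else pd.DataFrame(
            columns=["transcript_id", "scaffold", "start", "end", "strand", "exons"]
        )
    )
    repeats = (
        pd.DataFrame(repeat_rows).sort_values(["scaffold", "start"]).reset_index(drop=True)
        if repeat_rows
        else pd.DataFrame(columns=["scaffold", "start", "end", "strand", "raw_class", "group"])
    )
    sites = pd.concat(site_frames, ignore_index=True)
    genes = pd.DataFrame(gene_rows).sort_values("transcript_id").reset_index(drop=True)
    # realized true body mean per gene, in percent
    body = sites[sites["gene_idx"] >= 0].groupby("gene_idx")["p_true"].mean() * 100.0
    genes["body_mean_true"] = genes["gene_idx"].map(body)
    return SyntheticDataset(config, features, repeats, sites, genes)


def _paint_gene_levels(level: np.ndarray, it: dict, config: GeneratorConfig) -> None:
    """Write a gene's flank/body base levels into the per-base level array.

    The body is painted at the gene's segment level; the archetype's
    unmethylated 5' fraction is applied afterwards over the body's CpG
    sites (see ``generate``).  MP1's upstream margin (promoter) is
    methylated; MP1–MP3 keep downstream-of-TTS methylation, MP4 none.
    """
    start, end = it["start"], it["end"]
    a, lvl, strand = it["archetype"], it["level"], it["strand"]
    level[start:end] = lvl
    m = config.flank_margin
    up = (start - m, start) if strand == "+" else (end, end + m)
    down = (end, end + m) if strand == "+" else (start - m, start)
    if a == 1:
        level[max(up[0], 0) : up[1]] = lvl
    if a in (1, 2, 3):
        level[max(down[0], 0) : down[1]] = lvl


def _exon_layout(start: int, end: int, n_exons: int) -> list[tuple[int, int]]:
    """Alternate exon/intron blocks of equal width within [start, end)."""
    n_blocks = 2 * n_exons - 1
    edges = np.linspace(start, end, n_blocks + 1).astype(int)
    return [(int(edges[2 * i]), int(edges[2 * i + 1])) for i in range(n_exons)]


def _materialize_sequences(ds: SyntheticDataset) -> dict[str, str]:
    config = ds.config
    rng = _rng(config, "sequence")
    out = {}
    codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    C, G, A = ord("C"), ord("G"), ord("A")
    for s in range(config.n_scaffolds):
        scaf = f"scaffold_{s + 1}"
        arr = codes[rng.integers(0, 4, size=config.scaffold_len)].copy()
        pos = ds.sites.loc[ds.sites["scaffold"] == scaf, "start"].to_numpy()
        arr[pos] = C
        arr[pos + 1] = G
        # break accidental CG dinucleotides outside the planted sites
        planted = np.zeros(config.scaffold_len, dtype=bool)
        planted[pos] = True
        acc = (arr[:-1] == C) & (arr[1:] == G) & ~planted[:-1]
        arr[1:][acc] = A
        out[scaf] = arr.tobytes().decode("ascii")
    return out


# ---------------------------------------------------------------------------
# methylome simulation
# ---------------------------------------------------------------------------

def simulate_methylome(
    ds: SyntheticDataset,
    mode: str = "WGBS",
    sample_id: str = "wgbs_1",
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a per-strand CpG table from the truth under a coverage model.

    WGBS covers every CpG site at Poisson(``wgbs_depth``); RRBS retains a
    random ``rrbs_retention`` fraction of sites at Poisson(``rrbs_depth``).
    Per strand, depth c, methylation probability q ~ Beta centered on the
    site's ``p_true`` with the read-level concentration, and
    n_meth ~ Binomial(c, q); sites drawn at depth 0 are unobserved.  Both
    strands of a site share ``p_true`` but get independent draws.
    """
    mode = mode.upper()
    if mode not in ("WGBS", "RRBS"):
        raise ValueError(f"mode must be WGBS or RRBS, got {mode!r}")
    config = ds.config
    rng = _rng(config, f"methylome:{mode}:{sample_id}", extra=seed)
    sites = ds.sites
    if mode == "RRBS":
        keep = rng.random(len(sites)) < config.rrbs_retention
        sites = sites[keep]
        depth_mean = config.rrbs_depth
    else:
        depth_mean = config.wgbs_depth
    n = len(sites)
    p = np.clip(sites["p_true"].to_numpy(), 1e-6, 1 - 1e-6)
    nu = config.read_concentration
    frames = []
    for strand, offset in (("+", 0), ("-", 1)):
        c = rng.poisson(depth_mean, size=n)
        q = rng.beta(p * nu, (1.0 - p) * nu)
        n_meth = rng.binomial(c, q)
        obs = c > 0
        frames.append(
            pd.DataFrame(
                {
                    "scaffold": sites["scaffold"].to_numpy()[obs],
                    "pos": sites["start"].to_numpy()[obs] + offset,
                    "strand": strand,
                    "meth_pct": 100.0 * n_meth[obs] / c[obs],
                    "n_meth": n_meth[obs],
                    "n_total": c[obs],
                    "sample": sample_id,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["scaffold", "pos", "strand"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

def _expected_log_expression(body_mean: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    """Coupling curve: log2(TPM+1) rising with body methylation (logistic)."""
    z = (body_mean - config.expr_midpoint) / config.expr_scale
    return config.expr_floor + config.expr_span / (1.0 + np.exp(-z))


def simulate_expression(
    ds: SyntheticDataset, tissues: int | None = None, seed: int = 0
) -> pd.DataFrame:
    """Draw a transcript-by-tissue TPM matrix coupled to the truth.

    Expected log2(TPM+1) rises with true body methylation, so MP1/MP2 genes
    are high in all tissues, MP3 intermediate and MP4 low; additionally a
    ``mp4_zero_inflation`` fraction of MP4 genes is fully silent and the
    rest burst in random tissue subsets, giving the zero-inflated,
    tissue-variable tail.
    """
    config = ds.config
    tissues = tissues or config.n_tissues
    rng = _rng(config, "expression", extra=seed)
    genes = ds.genes
    n = len(genes)
    e_base = _expected_log_expression(genes["body_mean_true"].to_numpy(), config)
    e_base = e_base + rng.normal(0.0, config.expr_gene_sd, size=n)
    e = e_base[:, None] + rng.normal(0.0, config.expr_tissue_sd, size=(n, tissues))
    is_mp4 = (genes["archetype"] == 4).to_numpy()
    silent = is_mp4 & (rng.random(n) < config.mp4_zero_inflation)
    bursty = is_mp4 & ~silent
    burst_on = rng.random((n, tissues)) < config.mp4_burst_prob
    e[bursty] = np.where(
        burst_on[bursty],
        e[bursty] + rng.normal(0.0, config.mp4_burst_sd, size=(bursty.sum(), tissues)),
        0.0,
    )
    e[silent] = 0.0
    e = np.maximum(e, 0.0)
    tpm = np.exp2(e) - 1.0
    cols = [f"tissue_{i + 1:02d}" for i in range(tissues)]
    return pd.DataFrame(tpm, index=pd.Index(genes["transcript_id"], name="transcript_id"), columns=cols)


def simulate_go_terms(
    ds: SyntheticDataset, n_terms: int = 30, seed: int = 0
) -> dict[str, set]:
    """A toy GO map: some terms biased toward one methylation pattern.

    The first 8 terms draw 70% of their genes from a single archetype
    (cycling MP1..MP4), the rest uniformly; term sizes 20–120 genes.
    """
    config = ds.config
    rng = _rng(config, "go", extra=seed)
    genes = ds.genes
    ids = genes["transcript_id"].to_numpy()
    mapping: dict[str, set] = {}
    for t in range(n_terms):
        size = int(rng.integers(20, 121))
        size = min(size, len(ids))
        if t < 8:
            mp = (t % 4) + 1
            in_mp = ids[(genes["archetype"] == mp).to_numpy()]
            n_bias = min(int(round(0.7 * size)), len(in_mp))
            chosen = set(rng.choice(in_mp, size=n_bias, replace=False))
            rest = ids[~np.isin(ids, list(chosen))]
            chosen |= set(rng.choice(rest, size=size - n_bias, replace=False))
        else:
            chosen = set(rng.choice(ids, size=size, replace=False))
        mapping[f"GO:{7000000 + t}"] = chosen
    return mapping
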