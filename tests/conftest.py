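import numpy as np
import pandas as pd
import pytest

import octomethyl as om


def make_cpg_table(rows, sample="s"):
    """rows: iterable of (scaffold, pos, strand, meth_pct, n_meth, n_total)."""
    df = pd.DataFrame(
        rows, columns=["scaffold", "pos", "strand", "meth_pct", "n_meth", "n_total"]
    )
    df["sample"] = sample
    return df


def make_features(rows):
    """rows: iterable of (transcript_id, scaffold, start, end, strand[, exons])."""
    recs = []
    for r in rows:
        tid, scaf, start, end, strand = r[:5]
        exons = r[5] if len(r) > 5 else [(start, end)]
        recs.append(
            {
                "transcript_id": tid,
                "scaffold": scaf,
                "start": start,
                "end": end,
                "strand": strand,
                "exons": exons,
            }
        )
    return pd.DataFrame(recs)


def make_repeats(rows):
    """rows: iterable of (scaffold, start, end, raw_class)."""
    recs = [
        {
            "scaffold": scaf,
            "start": start,
            "end": end,
            "strand": "+",
            "raw_class": raw,
            "group": om.classify_repeat(raw),
        }
        for scaf, start, end, raw in rows
    ]
    return pd.DataFrame(recs)


@pytest.fixture(scope="session")
def tiny_config():
    return om.GeneratorConfig(
        n_scaffolds=2,
        scaffold_len=200_000,
        n_genes=40,
        te_counts={"DNA": 8, "LTR": 6, "LINE": 8, "SINE": 4},
        n_satellites=4,
        n_simple_repeats=6,
        n_other_re=4,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return om.generate(tiny_config)


@pytest.fixture(scope="session")
def study():
    """The default synthetic study: genome truth, a WGBS methylome, the
    per-transcript means, the k-means pattern assignment and expression."""
    ds = om.generate(om.GeneratorConfig(seed=11))
    wgbs = om.simulate_methylome(ds, "WGBS", "wgbs_1", seed=1)
    means, excluded = om.transcript_mean_methylation(wgbs, ds.features)
    assignment = om.kmeans_patterns(means, k=4, seed=3)
    tpm = om.simulate_expression(ds, seed=1)
    return {
        "ds": ds,
        "wgbs": wgbs,
        "means": means,
        "excluded": excluded,
        "assignment": assignment,
        "tpm": tpm,
    }
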