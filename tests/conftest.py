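import numpy as np
import pandas as pd
import pytest

from tfcoreg import ExpressionTable, GeneModel, peak_frame


def make_peaks(intervals, chrom="chr1", q=0.0, prefix="p"):
    """Build a canonical peak frame from (start, end) tuples."""
    rows = [
        {"chrom": chrom, "start": s, "end": e, "name": f"{prefix}{i}", "q_value": q}
        for i, (s, e) in enumerate(intervals)
    ]
    return peak_frame(rows)


def random_peaks(rng, n, chrom_length=100_000, chroms=("chr1",), prefix="p"):
    rows = []
    for i in range(n):
        start = int(rng.integers(0, chrom_length - 500))
        width = int(rng.integers(50, 500))
        rows.append({
            "chrom": str(rng.choice(list(chroms))),
            "start": start,
            "end": start + width,
            "name": f"{prefix}{i}",
            "q_value": float(rng.uniform(0, 0.01)),
        })
    return peak_frame(rows)


def random_genes(rng, n, chrom_length=100_000, chrom="chr1"):
    genes = []
    for i in range(n):
        start = int(rng.integers(3000, chrom_length - 10_000))
        length = int(rng.integers(500, 5000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"g{i}", chrom, strand, start, start + length,
                               ((start, start + length),)))
    return genes


def make_table(gene_values, conditions=("A", "A", "B", "B")):
    """Expression table from {gene: (v1, v2, v3, v4)} with default 2x2 design."""
    samples = [f"{c}_r{i}" for i, c in enumerate(conditions)]
    values = pd.DataFrame.from_dict(gene_values, orient="index", columns=samples)
    values.index.name = "gene_id"
    return ExpressionTable(values=values, conditions=dict(zip(samples, conditions)))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
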