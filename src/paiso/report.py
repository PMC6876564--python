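"""Summary tables across samples/replicates.

All outputs are deterministic TSV-ready DataFrames; figure drawing is
optional and imports matplotlib lazily.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sequtils import non_a_count
from .tails import GeneTailSummary, TailCall, length_distribution, long_tail_table


def gene_summary_frame(summaries: Sequence[GeneTailSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": s.gene_id,
                "n_reads": s.n_reads,
                "geo_mean_length": s.geo_mean_length,
                "non_a_ratio": s.non_a_ratio,
            }
            for s in summaries
        ],
        columns=["gene_id", "n_reads", "geo_mean_length", "non_a_ratio"],
    )


def replicate_correlation(
    a: pd.DataFrame, b: pd.DataFrame, min_reads: int = 10, value: str = "geo_mean_length"
) -> dict:
    """Pearson and Spearman correlation of per-gene values across replicates.

    Only genes present in both frames with ``n_reads >= min_reads`` in
    each enter the correlation; with fewer than two common genes the
    correlations are NA.
    """
    fa = a[a["n_reads"] >= min_reads].set_index("gene_id")[value]
    fb = b[b["n_reads"] >= min_reads].set_index("gene_id")[value]
    common = fa.index.intersection(fb.index)
    n = len(common)
    if n < 2:
        return {"n_genes": n, "pearson": float("nan"), "spearman": float("nan")}
    x, y = fa.loc[common].to_numpy(), fb.loc[common].to_numpy()
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return {"n_genes": n, "pearson": float("nan"), "spearman": float("nan")}
    return {
        "n_genes": n,
        "pearson": float(stats.pearsonr(x, y).statistic),
        "spearman": float(stats.spearmanr(x, y).statistic),
    }


def non_a_frequency_panel(tails_by_sample: dict[str, Sequence[TailCall]]) -> pd.DataFrame:
    """Overall non-A base frequency within tails, per dataset."""
    rows = []
    for sample, tails in tails_by_sample.items():
        total = sum(t.tail_length for t in tails)
        non_a = sum(non_a_count(t.tail_seq) for t in tails)
        rows.append(
            {
                "sample": sample,
                "n_tails": len(tails),
                "tail_bases": total,
                "non_a_bases": non_a,
                "non_a_frequency": non_a / total if total else 0.0,
            }
        )
    return pd.DataFrame(rows)


def global_length_report(
    tails_by_sample: dict[str, Sequence[TailCall]], bin_width: int = 10
) -> pd.DataFrame:
    frames = []
    for sample, tails in tails_by_sample.items():
        df = length_distribution([t.tail_length for t in tails], bin_width=bin_width)
        df.insert(0, "sample", sample)
        frames.append(df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def long_tail_report(
    tails_by_sample: dict[str, Sequence[TailCall]], threshold: int = 200
) -> pd.DataFrame:
    frames = []
    for sample, tails in tails_by_sample.items():
        lengths = [t.tail_length for t in tails]
        df = long_tail_table(lengths, threshold=threshold)
        df.insert(0, "sample", sample)
        n = len(lengths)
        df["fraction_of_all"] = df["count"] / n if n else 0.0
        frames.append(df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def plot_length_distributions(
    tails_by_sample: dict[str, Sequence[TailCall]], path: str | Path
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for sample, tails in tails_by_sample.items():
        lengths = [t.tail_length for t in tails]
        ax.hist(lengths, bins=50, histtype="step", density=True, label=sample)
    ax.set_xlabel("poly(A) tail length (nt)")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
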