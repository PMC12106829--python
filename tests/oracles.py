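"""Independent brute-force oracles used by unit and acceptance tests."""

from __future__ import annotations

import numpy as np
import pandas as pd


def brute_force_regions(binned: pd.DataFrame, gap_bp: int,
                        min_kmers: int) -> list[dict]:
    """Literal interval construction for the gap/min-k-mer region rules.

    Walks every bin with a significant k-mer, grouping consecutive bins
    whose start is within ``gap_bp`` of the previous bin's end; implemented
    independently of the production scanner.
    """
    out = []
    df = binned[binned["count"] > 0]
    for chrom in sorted(df["chrom"].unique()):
        sub = (df[df["chrom"] == chrom]
               .groupby(["bin_start", "bin_end"], as_index=False)["count"]
               .sum().sort_values("bin_start").to_numpy())
        i = 0
        while i < len(sub):
            start, end, total = sub[i]
            j = i + 1
            while j < len(sub) and sub[j][0] - end <= gap_bp:
                end = sub[j][1]
                total += sub[j][2]
                j += 1
            out.append({"chrom": chrom, "start": int(start), "end": int(end),
                        "n_kmers": int(total),
                        "significant": bool(total >= min_kmers)})
            i = j
    return out


def random_bin_layout(rng: np.random.Generator, bin_bp: int = 10_000
                      ) -> pd.DataFrame:
    """Random sparse per-bin significant-k-mer counts over 1-2 chromosomes."""
    rows = []
    for chrom in ["c1", "c2"][: int(rng.integers(1, 3))]:
        n_bins = int(rng.integers(1, 400))
        n_occ = int(rng.integers(1, min(n_bins, 24) + 1))
        occupied = rng.choice(n_bins, size=n_occ, replace=False)
        for b in occupied:
            rows.append({
                "chrom": chrom,
                "bin_start": int(b) * bin_bp + 1,
                "bin_end": (int(b) + 1) * bin_bp,
                "level": 8,
                "direction": int(rng.choice([-1, 1])),
                "count": int(rng.integers(1, 400)),
            })
    return pd.DataFrame(rows)
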