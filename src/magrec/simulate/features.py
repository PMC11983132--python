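"""Synthetic chromatin-feature tracks.

Emulates the meiotic chromatin inputs consumed by the statistics layer:
MNase nucleosome coverage with zero-coverage nucleosome-depleted regions
(NDRs), Spo11-oligo coverage and called peaks (a subset of NDRs are
DSB-hot), and Rec8 axis peaks.  NDRs are spaced like yeast promoters
(roughly one per 2 kb); about 40% carry a Spo11-oligo peak (hot), 40%
have zero oligo signal (cold), and the rest have sub-peak oligo reads
(unclassified by either rule).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from magrec.params import SimParams
from magrec.simulate.genome import GenomeBuild


def emit_feature_tracks(
    build: GenomeBuild, params: SimParams, rng: np.random.Generator | None = None
) -> dict[str, pd.DataFrame]:
    """Returns nucleosome coverage, Spo11-oligo coverage/peaks, Rec8 peaks.

    Coverage tracks are bedGraph-style interval tables
    (chrom, start, end, value); peaks are BED-style (chrom, start, end, name).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 2)
    nuc_rows, oligo_rows, peak_rows, rec8_rows = [], [], [], []
    ndr_truth = []
    nuc_level = 20.0
    for chrom in build.chrom_names:
        L = build.chrom_lengths[chrom]
        pos = 0
        prev_end = 0
        i = 0
        while True:
            gap = int(rng.exponential(2000)) + 500
            ndr_len = int(rng.integers(80, 250))
            start = pos + gap
            end = start + ndr_len
            if end >= L - 500:
                break
            cls = ("hot", "cold", "unclassified")[
                int(rng.choice(3, p=[0.4, 0.4, 0.2]))
            ]
            nuc_rows.append((chrom, prev_end, start, nuc_level))
            nuc_rows.append((chrom, start, end, 0.0))
            if cls == "hot":
                peak_rows.append((chrom, max(0, start - 50), end + 50, f"{chrom}_peak{i}"))
                oligo_rows.append((chrom, max(0, start - 50), end + 50, 50.0))
            elif cls == "unclassified":
                # a few oligo reads but no called peak
                oligo_rows.append((chrom, start, end, 2.0))
            ndr_truth.append((chrom, start, end, cls))
            prev_end = end
            pos = end
            i += 1
        nuc_rows.append((chrom, prev_end, L, nuc_level))
        for c in range(5000, L - 5000, 10_000):
            center = c + int(rng.integers(-2000, 2000))
            rec8_rows.append((chrom, center - 75, center + 75, f"{chrom}_rec8_{c}"))
    cols_cov = ["chrom", "start", "end", "value"]
    cols_bed = ["chrom", "start", "end", "name"]
    return {
        "nucleosome": pd.DataFrame(nuc_rows, columns=cols_cov),
        "spo11_coverage": pd.DataFrame(oligo_rows, columns=cols_cov),
        "spo11_peaks": pd.DataFrame(peak_rows, columns=cols_bed),
        "rec8_peaks": pd.DataFrame(rec8_rows, columns=cols_bed),
        "ndr_truth": pd.DataFrame(
            ndr_truth, columns=["chrom", "start", "end", "cls"]
        ),
    }
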