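"""Chromatin-feature statistics of crossover positions.

Implements the comparison layer between CO positions and meiotic
chromatin features: NDR calling from nucleosome coverage (zero-coverage
runs), DSB-hot/cold classification of NDRs against Spo11-oligo data,
distance-to-feature samples, Mann-Whitney U with an exact enumeration
for small samples, per-chromosome genetic map length (cM defined as
100 x mean CO switches per gamete) and its correlation with chromosome
length, CO fractions in centromere-proximal/rDNA regions against the
length-expected fractions, and the NAHR share of recombination events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from magrec.events import RecombEvent

#: total genome length used for expected region fractions (bp).  The
#: S. cerevisiae assembly total; 160 kb of centromere-proximal sequence is
#: 1.3% of it and a 1365-kb rDNA array 11.3%.
DEFAULT_GENOME_LENGTH = 12_071_326


@dataclass
class StatsConfig:
    max_breakpoint_width: int = 1_000  # COs with wider marker intervals excluded
    ndr_min_len: int = 50
    centromere_halfwidth: int = 5_000
    genome_length: int = DEFAULT_GENOME_LENGTH

    def __post_init__(self) -> None:
        if min(
            self.max_breakpoint_width,
            self.ndr_min_len,
            self.centromere_halfwidth,
            self.genome_length,
        ) <= 0:
            raise ValueError("all StatsConfig fields must be positive")


# --------------------------------------------------------------------- NDRs
def call_ndrs(
    nucleosome_coverage: pd.DataFrame,
    cfg: StatsConfig,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Maximal zero-coverage runs of length >= ``ndr_min_len``.

    Gaps in the coverage track count as zero coverage.  Returns a BED-like
    frame (chrom, start, end, cls="unclassified").
    """
    rows = []
    for chrom, grp in nucleosome_coverage.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        L = (
            chrom_lengths[chrom]
            if chrom_lengths is not None
            else int(grp["end"].max())
        )
        # merge covered (value > 0) intervals, then take the complement
        covered = []
        for r in grp.itertuples(index=False):
            if r.value > 0:
                if covered and r.start <= covered[-1][1]:
                    covered[-1][1] = max(covered[-1][1], r.end)
                else:
                    covered.append([r.start, r.end])
        prev = 0
        for s, e in covered + [[L, L]]:
            if s - prev >= cfg.ndr_min_len:
                rows.append((chrom, prev, s, "unclassified"))
            prev = max(prev, e)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "cls"])


def _overlaps_any(iv: pd.DataFrame, chrom: str, start: int, end: int) -> bool:
    sub = iv[iv["chrom"] == chrom]
    return bool(((sub["start"] < end) & (sub["end"] > start)).any())


def classify_ndrs(
    ndrs: pd.DataFrame,
    spo11_peaks: pd.DataFrame,
    spo11_coverage: pd.DataFrame,
) -> pd.DataFrame:
    """Hot = NDR overlapping a Spo11-oligo peak; cold = NDR with zero
    Spo11-oligo coverage over its whole span; otherwise unclassified."""
    out = ndrs.copy()
    cls = []
    for r in out.itertuples(index=False):
        if _overlaps_any(spo11_peaks, r.chrom, r.start, r.end):
            cls.append("hot")
        else:
            cov = spo11_coverage[
                (spo11_coverage["chrom"] == r.chrom)
                & (spo11_coverage["start"] < r.end)
                & (spo11_coverage["end"] > r.start)
                & (spo11_coverage["value"] > 0)
            ]
            cls.append("cold" if not len(cov) else "unclassified")
    out["cls"] = cls
    return out


# ---------------------------------------------------------------- distances
def co_feature_distances(
    co_events: list[RecombEvent],
    feature_centers: pd.DataFrame,
    cfg: StatsConfig,
) -> np.ndarray:
    """One distance per CO: breakpoint-interval midpoint to the nearest
    feature center.  COs with breakpoint intervals wider than
    ``max_breakpoint_width`` are excluded (marker-resolution filter)."""
    if not len(feature_centers):
        raise ValueError("empty feature set")
    centers = {
        chrom: np.sort(((grp["start"] + grp["end"]) // 2).to_numpy())
        for chrom, grp in feature_centers.groupby("chrom", sort=False)
    }
    dists = []
    for ev in co_events:
        if ev.kind != "CO" or ev.width > cfg.max_breakpoint_width:
            continue
        cs = centers.get(ev.chrom)
        if cs is None or not len(cs):
            continue
        mid = ev.midpoint
        i = np.searchsorted(cs, mid)
        best = min(
            abs(mid - cs[j]) for j in (i - 1, i) if 0 <= j < len(cs)
        )
        dists.append(best)
    return np.asarray(dists, dtype=float)


# ------------------------------------------------------------- Mann-Whitney
def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: pairs where a > b, ties counting half."""
    gt = np.sum(a[:, None] > b[None, :])
    eq = np.sum(a[:, None] == b[None, :])
    return float(gt + 0.5 * eq)


def mann_whitney_u(
    sample_a, sample_b, exact_limit: int = 12
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact p by enumeration over all label assignments of the pooled
    values (valid under ties) when n_a + n_b <= ``exact_limit``; normal
    approximation with tie correction otherwise.  The U distribution is
    symmetric about n_a*n_b/2, so the two-sided exact p is the
    probability of a deviation at least as large as observed.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("samples must be non-empty")
    u = _u_statistic(a, b)
    n, m = len(a), len(b)
    if n + m <= exact_limit:
        pooled = np.concatenate([a, b])
        center = n * m / 2.0
        dev = abs(u - center)
        idx = range(n + m)
        hits = total = 0
        for pick in combinations(idx, n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(pick)] = True
            uu = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(uu - center) >= dev - 1e-12:
                hits += 1
        return u, hits / total
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u, float(res.pvalue)


# --------------------------------------------------------------- CO density
def co_density_stats(
    co_counts: pd.DataFrame,
    chrom_lengths: dict[str, int],
    n_spores: int,
) -> pd.DataFrame:
    """Per-chromosome map length and density.

    ``co_counts`` has columns (chrom, count) holding total CO switches
    summed over spores.  cM = 100 x mean switches per spore; density is
    cM per kb.  Returns a table with one row per chromosome.
    """
    if n_spores <= 0:
        raise ValueError("n_spores must be positive")
    rows = []
    for chrom, L in chrom_lengths.items():
        total = int(co_counts.loc[co_counts["chrom"] == chrom, "count"].sum())
        cm = 100.0 * total / n_spores
        rows.append(
            {
                "chrom": chrom,
                "length_bp": L,
                "total_switches": total,
                "cM": cm,
                "cM_per_kb": cm / (L / 1000.0),
            }
        )
    return pd.DataFrame(rows)


def density_length_correlation(density_table: pd.DataFrame) -> tuple[float, float]:
    """Pearson r (and two-sided p) of CO density versus chromosome length.

    Degenerate inputs (zero variance) return (nan, nan)."""
    x = density_table["length_bp"].to_numpy(dtype=float)
    y = density_table["cM_per_kb"].to_numpy(dtype=float)
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ------------------------------------------------------------ region shares
def region_co_fraction(
    co_events: list[RecombEvent],
    regions: pd.DataFrame,
    cfg: StatsConfig,
    rdna: tuple[str, int, int] | None = None,
) -> tuple[float, float]:
    """Observed vs expected percentage of COs in a region set.

    Observed: COs whose breakpoint midpoint falls in a region; for the
    rDNA array (no internal markers) an origin shift whose breakpoint
    interval spans the array boundary counts as a single rDNA event.
    Expected: region length as a share of the configured genome length.
    """
    if cfg.genome_length <= 0:
        raise ValueError("genome_length must be positive")
    cos = [e for e in co_events if e.kind == "CO"]
    if not cos:
        return 0.0, _expected_pct(regions, cfg)
    n_in = 0
    for ev in cos:
        mid = ev.midpoint
        if _contains_point(regions, ev.chrom, mid):
            n_in += 1
        elif rdna is not None and ev.chrom == rdna[0] and (
            ev.start < rdna[2] and ev.end > rdna[1]
        ):
            n_in += 1  # shift across the array counted once
    return 100.0 * n_in / len(cos), _expected_pct(regions, cfg)


def _contains_point(regions: pd.DataFrame, chrom: str, pos: float) -> bool:
    sub = regions[regions["chrom"] == chrom]
    return bool(((sub["start"] <= pos) & (pos < sub["end"])).any())


def _expected_pct(regions: pd.DataFrame, cfg: StatsConfig) -> float:
    region_len = int((regions["end"] - regions["start"]).sum())
    return 100.0 * region_len / cfg.genome_length


def expected_region_pct(region_length_bp: int, genome_length_bp: int) -> float:
    """Length-expected CO percentage of a chromosomal region."""
    if genome_length_bp <= 0:
        raise ValueError("genome_length must be positive")
    return 100.0 * region_length_bp / genome_length_bp


def fold_change(numerator_pct: float, denominator_pct: float) -> float:
    """Ratio of two frequencies (suppression/enrichment fold)."""
    if denominator_pct == 0:
        raise ValueError("zero denominator frequency")
    return numerator_pct / denominator_pct


def centromere_windows(
    centromeres: dict[str, tuple[int, int]],
    chrom_lengths: dict[str, int],
    halfwidth: int,
) -> pd.DataFrame:
    """Centromere-proximal windows (center +/- halfwidth, clipped)."""
    rows = []
    for chrom, (s, e) in centromeres.items():
        c = (s + e) // 2
        rows.append(
            (chrom, max(0, c - halfwidth), min(chrom_lengths[chrom], c + halfwidth))
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ------------------------------------------------------------ NAHR fraction
def nahr_fraction_from_counts(n_nahr: int, n_hr_other: int) -> float:
    """Percentage of NAHR among recombination events, two decimals.

    ``n_hr_other`` is CO+NCO for spore sets and SGC+BIR for diploid
    return-to-growth sets (NAHR per HR)."""
    denom = n_nahr + n_hr_other
    if denom == 0:
        raise ValueError("no recombination events")
    return round(100.0 * n_nahr / denom, 2)


def nahr_fraction(events: list[RecombEvent], diploid: bool = False) -> float:
    """NAHR share of typed events (see ``nahr_fraction_from_counts``)."""
    kinds = [e.kind for e in events]
    n_nahr = kinds.count("NAHR")
    if diploid:
        other = kinds.count("SGC") + kinds.count("BIR")
    else:
        other = kinds.count("CO") + kinds.count("NCO")
    return nahr_fraction_from_counts(n_nahr, other)
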