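"""Chromosome copy number, aneuploidy/haploidization, and interstitial CNV.

Copy number comes from binned depth normalised to the genome-wide median
(repeat and rDNA bins masked from the baseline — their depth reflects
array copy number, not chromosome dosage).  Haploidization is
distinguished from genome-wide LOH by parental origin: a haploidized
clone keeps one copy of every chromosome with origins mixed between the
parents, whereas uniform single-parent origin with normal dosage is
flagged for review instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from magrec.events import RecombEvent
from magrec.segment import MarkerState


@dataclass
class PloidyConfig:
    gain_threshold: float = 1.25  # normalised-depth midpoint between CN2 and CN3
    min_bins: int = 8  # smallest credible duplication, in depth bins
    smooth_bins: int = 5  # median-filter window (odd)
    homog_af: float = 0.9  # marker homogeneity threshold for haploidization
    junction_link_bp: int = 8_000  # CNV end to junction endpoint tolerance
    # (bin quantisation plus median-filter edge wobble under count noise;
    # linkage stays specific because the junction must bracket the run)


def _masked_bins(depth: pd.DataFrame, mask: pd.DataFrame | None) -> np.ndarray:
    """Boolean: bin overlaps a masked (repeat/rDNA) interval."""
    flag = np.zeros(len(depth), dtype=bool)
    if mask is None or not len(mask):
        return flag
    for chrom, sub in mask.groupby("chrom"):
        sel = (depth["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        bs = depth.loc[sel, "start"].to_numpy()
        be = depth.loc[sel, "end"].to_numpy()
        hit = np.zeros(len(bs), dtype=bool)
        for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
            hit |= (bs < e) & (be > s)
        flag[sel] = hit
    return flag


def chromosome_copy_number(
    depth: pd.DataFrame,
    states: list[MarkerState],
    expected_ploidy: int,
    mask: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-chromosome copy number and parental composition.

    CN = round(expected_ploidy * chromosome median depth / baseline),
    baseline being the genome-wide median over unmasked bins.  Parental
    composition is the S fraction among informative (S/K) markers; the
    HET marker fraction is carried for disomy detection in spores.
    """
    masked = _masked_bins(depth, mask)
    usable = depth.loc[~masked]
    # median of per-chromosome medians, absent (zero-depth) chromosomes
    # excluded: robust to whole-chromosome losses and nullisomy
    med_by_chrom = usable.groupby("chrom")["depth"].median()
    baseline = float(med_by_chrom[med_by_chrom > 0].median())
    if not baseline > 0:
        raise ValueError("zero baseline depth")
    rows = []
    state_by_chrom: dict[str, list[MarkerState]] = {}
    for st in states:
        state_by_chrom.setdefault(st.chrom, []).append(st)
    for chrom, grp in usable.groupby("chrom", sort=False):
        med = float(grp["depth"].median())
        cn = int(round(expected_ploidy * med / baseline))
        sts = state_by_chrom.get(chrom, [])
        n_s = sum(1 for s in sts if s.state == "S")
        n_k = sum(1 for s in sts if s.state == "K")
        n_het = sum(1 for s in sts if s.state == "HET")
        informative = n_s + n_k
        rows.append(
            {
                "chrom": chrom,
                "median_depth": med,
                "copy_number": cn,
                "frac_S": n_s / informative if informative else float("nan"),
                "frac_het": n_het / max(1, informative + n_het),
                "baseline": baseline,
            }
        )
    return pd.DataFrame(rows)


def detect_aneuploidy_and_haploidization(
    cn: pd.DataFrame, expected_ploidy: int, cfg: PloidyConfig | None = None
) -> tuple[list[RecombEvent], bool]:
    """Aneuploidy events per chromosome, plus a genome haploidization flag.

    Haploidization requires uniform dosage (no chromosome deviating from
    the genome mode), marker homogeneity on every chromosome, and mixed
    parental origins across chromosomes; it then replaces the
    per-chromosome loss calls with a single genome-wide event.  A genome
    that is single-parent on every chromosome is genome-wide LOH, not
    haploidization, and is only flagged in the event attributes.
    """
    cfg = cfg or PloidyConfig()
    events: list[RecombEvent] = []
    homog = (cn["frac_S"] >= cfg.homog_af) | (cn["frac_S"] <= 1 - cfg.homog_af)
    no_het = cn["frac_het"] <= 0.1
    uniform_cn = cn["copy_number"].nunique() == 1
    origins = set()
    for row in cn.itertuples(index=False):
        if row.frac_S >= cfg.homog_af:
            origins.add("S")
        elif row.frac_S <= 1 - cfg.homog_af:
            origins.add("K")
    haploid = bool(
        expected_ploidy >= 2
        and uniform_cn
        and homog.all()
        and no_het.all()
        and origins == {"S", "K"}
    )
    if haploid:
        events.append(
            RecombEvent(
                "HAPLOIDIZATION",
                str(cn.iloc[0]["chrom"]),
                0,
                1,
                attrs={"n_chromosomes": int(len(cn))},
            )
        )
        return events, True
    for row in cn.itertuples(index=False):
        if row.copy_number > expected_ploidy:
            kind = "ANEUPLOID_GAIN"
        elif row.copy_number < expected_ploidy:
            kind = "ANEUPLOID_LOSS"
        else:
            continue
        events.append(
            RecombEvent(
                kind,
                row.chrom,
                0,
                1,
                attrs={
                    "copy_number": int(row.copy_number),
                    "expected": expected_ploidy,
                    "frac_S": None if np.isnan(row.frac_S) else round(float(row.frac_S), 3),
                    "het": bool(row.frac_het > 0.5),
                },
            )
        )
    return events, False


def _median_filter(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1 or len(x) == 0:
        return x
    half = w // 2
    padded = np.pad(x, half, mode="edge")
    return np.median(
        np.lib.stride_tricks.sliding_window_view(padded, w), axis=1
    )


def detect_cnv_segments(
    depth: pd.DataFrame,
    expected_ploidy: int = 2,
    cfg: PloidyConfig | None = None,
    mask: pd.DataFrame | None = None,
    junctions: list | None = None,
) -> list[RecombEvent]:
    """Interstitial duplications from elevated depth and dup-type junctions.

    Junction-first: a same-chromosome junction call in duplication
    orientation (right flank retained at the lower position, left flank
    at the higher) defines a candidate tract; it becomes a CNV_DUP when
    the raw depth summed over the tract exceeds the Poisson
    likelihood-ratio boundary between CN = ploidy and CN = ploidy + 1
    (sum* = (l1 - l0) / ln(l1 / l0)).  This is the signature of a tandem
    duplication formed by recombination between flanking repeat copies,
    with the junction giving base-precise bounds.

    Depth-only fallback: maximal runs of >= ``min_bins`` median-smoothed
    bins at or above ``gain_threshold`` that also pass the
    likelihood-ratio test (chance fluctuations essentially never do);
    runs already explained by a junction-defined tract are dropped.
    """
    cfg = cfg or PloidyConfig()
    masked = _masked_bins(depth, mask)
    usable = depth.loc[~masked]
    med_by_chrom = usable.groupby("chrom")["depth"].median()
    baseline = float(med_by_chrom[med_by_chrom > 0].median())
    if not baseline > 0:
        raise ValueError("zero baseline depth")

    def lr_boundary(nbins: int) -> float:
        lam0 = nbins * baseline
        lam1 = lam0 * (expected_ploidy + 1) / expected_ploidy
        return (lam1 - lam0) / np.log(lam1 / lam0)

    by_chrom = {c: g for c, g in depth.groupby("chrom", sort=False)}
    events: list[RecombEvent] = []

    # junction-defined candidates
    if junctions:
        for c in junctions:
            if c.chromA != c.chromB or c.chromA not in by_chrom:
                continue
            lo, hi = sorted([(c.posA, c.strandA), (c.posB, c.strandB)])
            if (lo[1], hi[1]) != ("-", "+"):
                continue  # not duplication orientation
            grp = by_chrom[c.chromA]
            inner = grp[(grp["start"] >= lo[0]) & (grp["end"] <= hi[0])]
            if len(inner) < cfg.min_bins:
                continue
            if float(inner["depth"].sum()) > lr_boundary(len(inner)):
                events.append(
                    RecombEvent(
                        "CNV_DUP",
                        c.chromA,
                        lo[0],
                        hi[0],
                        attrs={
                            "n_bins": int(len(inner)),
                            "mean_ratio": float(inner["depth"].mean() / baseline),
                            "junction": c.name,
                            "repeat_ids": list(c.repeat_ids),
                        },
                    )
                )

    # depth-only runs
    for chrom, grp in by_chrom.items():
        norm = grp["depth"].to_numpy() / baseline
        smooth = _median_filter(norm, cfg.smooth_bins)
        above = smooth >= cfg.gain_threshold
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        i = 0
        while i < len(above):
            if not above[i]:
                i += 1
                continue
            j = i
            while j < len(above) and above[j]:
                j += 1
            nbins = j - i
            run = RecombEvent(
                "CNV_DUP",
                chrom,
                int(starts[i]),
                int(ends[j - 1]),
                attrs={"n_bins": int(nbins), "mean_ratio": float(np.mean(norm[i:j]))},
            )
            explained = any(
                e.chrom == chrom
                and run.start < e.end + cfg.junction_link_bp
                and run.end > e.start - cfg.junction_link_bp
                for e in events
            )
            if (
                not explained
                and nbins >= cfg.min_bins
                and float(grp["depth"].to_numpy()[i:j].sum()) > lr_boundary(nbins)
            ):
                events.append(run)
            i = j
    events.sort(key=lambda e: (e.chrom, e.start))
    return events
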