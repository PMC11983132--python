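"""Marker-state calling, genotype segmentation and HR-event classification.

The substrate is a table of per-SNP parental allele counts from a hybrid
(S x K) sample.  Markers are called S / K / HET / MISSING from the allele
fraction; maximal same-state runs become genotype segments; segments are
then classified per sample type:

* haploid spores — parental-origin switches are crossovers (COs, counted
  as switches, not segments) and short interstitial tracts flanked by the
  opposite parent are noncrossovers (NCOs) when their marker span is
  below the CO/NCO interval-size threshold (5 kb by default);
* diploids — loss-of-heterozygosity runs are break-induced replication
  (BIR) when the tract reaches a chromosome end and short gene
  conversions (SGCs) when interstitial.

Events identical to control-sample events are subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from magrec.events import RecombEvent


@dataclass
class ClassifierConfig:
    nco_max_len: int = 5_000  # CO/NCO interval-size threshold (bp)
    min_support: int = 2  # markers needed to call a state change
    het_band: tuple[float, float] = (0.25, 0.75)
    loh_af: float = 0.9  # allele fraction at/above which a state is pure
    min_depth: int = 5  # reads below which a marker is MISSING
    control_tolerance: int = 0  # bp for control-event matching

    def __post_init__(self) -> None:
        if self.nco_max_len <= 0:
            raise ValueError("nco_max_len must be positive")
        lo, hi = self.het_band
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("het_band must be within (0, 1)")
        if not (0.5 < self.loh_af <= 1.0):
            raise ValueError("loh_af must be in (0.5, 1]")


@dataclass
class MarkerState:
    chrom: str
    pos: int
    state: str  # S | K | HET | MISSING
    allele_fraction: float  # fraction of K reads
    total_depth: int


@dataclass
class GenotypeSegment:
    """Maximal run of markers in one state; 0-based half-open marker span."""

    chrom: str
    start: int
    end: int
    state: str
    n_markers: int
    touches_start: bool = False
    touches_end: bool = False
    low_confidence: bool = False
    first_pos: int = 0
    last_pos: int = 0


def call_marker_states(markers: pd.DataFrame, cfg: ClassifierConfig) -> list[MarkerState]:
    """Assign one state per marker from its parental allele counts.

    The allele fraction (K reads over total) is recorded even for MISSING
    markers.  Fractions between the pure-allele and heterozygous bands are
    treated as MISSING (unclassifiable).
    """
    if (markers[["count_S", "count_K"]].to_numpy() < 0).any():
        raise ValueError("negative allele counts")
    for chrom, grp in markers.groupby("chrom", sort=False):
        if not grp["pos"].is_monotonic_increasing:
            raise ValueError(f"marker table not sorted on {chrom}")
    out: list[MarkerState] = []
    lo, hi = cfg.het_band
    for row in markers.itertuples(index=False):
        total = int(row.count_S + row.count_K)
        af = row.count_K / total if total > 0 else float("nan")
        if total < cfg.min_depth:
            state = "MISSING"
        elif af >= cfg.loh_af:
            state = "K"
        elif af <= 1.0 - cfg.loh_af:
            state = "S"
        elif lo <= af <= hi:
            state = "HET"
        else:
            state = "MISSING"
        out.append(MarkerState(row.chrom, int(row.pos), state, af, total))
    return out


def segment_genotypes(
    states: list[MarkerState], cfg: ClassifierConfig
) -> list[GenotypeSegment]:
    """Collapse marker states into maximal same-state runs per chromosome.

    MISSING markers never break a run.  Runs shorter than ``min_support``
    are absorbed into the flanking state when both flanks agree, otherwise
    retained with a low-confidence flag.
    """
    segments: list[GenotypeSegment] = []
    by_chrom: dict[str, list[MarkerState]] = {}
    for st in states:
        by_chrom.setdefault(st.chrom, []).append(st)
    for chrom, sts in by_chrom.items():
        informative = [s for s in sts if s.state != "MISSING"]
        if not informative:
            continue
        # raw runs
        runs: list[list[MarkerState]] = []
        for s in informative:
            if runs and runs[-1][0].state == s.state:
                runs[-1].append(s)
            else:
                runs.append([s])
        # absorb short runs whose flanks agree; iterate to fixpoint
        changed = True
        while changed:
            changed = False
            for i, run in enumerate(runs):
                if len(run) >= cfg.min_support:
                    continue
                left = runs[i - 1][0].state if i > 0 else None
                right = runs[i + 1][0].state if i < len(runs) - 1 else None
                if left is not None and left == right:
                    merged = runs[i - 1] + run + runs[i + 1]
                    # absorbed markers keep the flanking state
                    runs[i - 1 : i + 2] = [merged]
                    changed = True
                    break
        for i, run in enumerate(runs):
            segments.append(
                GenotypeSegment(
                    chrom=chrom,
                    start=run[0].pos,
                    end=run[-1].pos + 1,
                    state=run[0].state,
                    n_markers=sum(1 for s in run if s.state == run[0].state),
                    touches_start=(i == 0),
                    touches_end=(i == len(runs) - 1),
                    low_confidence=len(run) < cfg.min_support,
                    first_pos=run[0].pos,
                    last_pos=run[-1].pos,
                )
            )
    return segments


def _confident(segments: list[GenotypeSegment]) -> list[GenotypeSegment]:
    """Drop low-confidence runs and re-merge flanking same-state segments.

    Works on copies; the input list is left untouched.
    """
    out: list[GenotypeSegment] = []
    for seg in segments:
        if seg.low_confidence:
            continue
        seg = replace(seg)
        if out and out[-1].chrom == seg.chrom and out[-1].state == seg.state:
            prev = out[-1]
            prev.end = seg.end
            prev.last_pos = seg.last_pos
            prev.n_markers += seg.n_markers
            prev.touches_end = seg.touches_end
        else:
            out.append(seg)
    # terminal flags reflect the retained segments: a run is terminal when
    # no confidently-called segment lies beyond it on that chromosome
    for i, seg in enumerate(out):
        seg.touches_start = i == 0 or out[i - 1].chrom != seg.chrom
        seg.touches_end = i == len(out) - 1 or out[i + 1].chrom != seg.chrom
    return out


def classify_spore_recombination(
    segments: list[GenotypeSegment], cfg: ClassifierConfig
) -> tuple[list[RecombEvent], dict[str, int]]:
    """CO/NCO classification for a haploid spore.

    An interstitial segment flanked on both sides by the opposite parent
    whose marker span is below ``nco_max_len`` is one NCO (its borders do
    not count as switches); every remaining state change between
    consecutive retained segments is one CO switch whose breakpoint
    interval runs from the last marker of the left segment to the first
    marker of the right.  Returns the events plus per-chromosome CO switch
    counts.

    HET segments indicate disomy: the chromosome is skipped here and must
    be routed to ploidy analysis.
    """
    events: list[RecombEvent] = []
    co_counts: dict[str, int] = {}
    by_chrom: dict[str, list[GenotypeSegment]] = {}
    for seg in _confident(segments):
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        co_counts[chrom] = 0
        if any(s.state == "HET" for s in segs):
            continue  # disomic chromosome; ploidy module's business
        # NCO detection on the parental-state sequence
        keep: list[GenotypeSegment] = []
        for i, seg in enumerate(segs):
            interstitial = 0 < i < len(segs) - 1
            if (
                interstitial
                and segs[i - 1].state != seg.state
                and segs[i + 1].state == segs[i - 1].state
                and (seg.last_pos - seg.first_pos) < cfg.nco_max_len
            ):
                events.append(
                    RecombEvent(
                        "NCO",
                        chrom,
                        seg.first_pos,
                        seg.last_pos + 1,
                        attrs={
                            "donor": seg.state,
                            "n_markers": seg.n_markers,
                            "left_flank": segs[i - 1].last_pos,
                            "right_flank": segs[i + 1].first_pos,
                        },
                    )
                )
            else:
                keep.append(seg)
        # merge same-state neighbours left after NCO removal, then count switches
        merged: list[GenotypeSegment] = []
        for seg in keep:
            if merged and merged[-1].state == seg.state:
                merged[-1].end = seg.end
                merged[-1].last_pos = seg.last_pos
            else:
                merged.append(
                    GenotypeSegment(
                        seg.chrom, seg.start, seg.end, seg.state, seg.n_markers,
                        seg.touches_start, seg.touches_end, False,
                        seg.first_pos, seg.last_pos,
                    )
                )
        for left, right in zip(merged, merged[1:]):
            co_counts[chrom] += 1
            events.append(
                RecombEvent(
                    "CO",
                    chrom,
                    left.last_pos,
                    right.first_pos + 1,
                    attrs={"from": left.state, "to": right.state},
                )
            )
    return events, co_counts


def classify_diploid_loh(
    segments: list[GenotypeSegment], cfg: ClassifierConfig
) -> tuple[list[RecombEvent], bool]:
    """SGC/BIR classification for a diploid sample (baseline HET).

    Each maximal LOH run is BIR when it contains the chromosome's first or
    last informative marker, otherwise SGC.  Returns
    ``(events, haploidization_candidate)`` where the flag is raised when
    no HET segment exists anywhere (whole-genome single-parent signal to
    be resolved by the ploidy module).
    """
    confident = _confident(segments)
    if confident and not any(s.state == "HET" for s in confident):
        return [], True
    events: list[RecombEvent] = []
    for seg in confident:
        if seg.state not in ("S", "K"):
            continue
        kind = "BIR" if (seg.touches_start or seg.touches_end) else "SGC"
        events.append(
            RecombEvent(
                kind,
                seg.chrom,
                seg.first_pos,
                seg.last_pos + 1,
                attrs={
                    "donor": seg.state,
                    "n_markers": seg.n_markers,
                    "terminal": "start" if seg.touches_start else
                                ("end" if seg.touches_end else "no"),
                },
            )
        )
    return events, False


def subtract_control_events(
    events: list[RecombEvent],
    control_events: list[RecombEvent],
    cfg: ClassifierConfig,
) -> tuple[list[RecombEvent], list[RecombEvent]]:
    """Remove events also present (same kind, coordinates within tolerance)
    in a control sample.  Returns (kept, removed)."""
    tol = cfg.control_tolerance
    kept, removed = [], []
    for ev in events:
        hit = any(
            c.kind == ev.kind
            and c.chrom == ev.chrom
            and abs(c.start - ev.start) <= tol
            and abs(c.end - ev.end) <= tol
            for c in control_events
        )
        (removed if hit else kept).append(ev)
    return kept, removed
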