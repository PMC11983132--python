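"""Junction-evidence clustering, depth verification, classification and
junction-sequence reconstruction.

Translocation calls are classified by their breakpoint context: NMTL
(NHEJ-mediated translocation, both endpoints in unique sequence — the
junction directly ligates two cut sites and restores the enzyme motif
with no indel) versus NAHR (both endpoints inside copies of one repeat
family).  Depth-shift verification flags rather than filters, because
reciprocal translocations legitimately change no copy number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from magrec.events import RecombEvent


@dataclass
class CallerConfig:
    cluster_window: int = 10  # bp
    min_split: int = 3  # split reads required to keep a candidate
    flank: int = 1_000  # bp for the depth-ratio test
    depth_shift_min: float = 1.3  # fold change called a "marked" shift
    motif: str = "GATC"

    def __post_init__(self) -> None:
        if min(self.cluster_window, self.min_split, self.flank) <= 0:
            raise ValueError("cluster_window, min_split and flank must be positive")
        if self.depth_shift_min <= 1.0:
            raise ValueError("depth_shift_min must exceed 1")


@dataclass
class JunctionCall:
    chromA: str
    posA: int
    strandA: str
    chromB: str
    posB: int
    strandB: str
    n_split: int = 0
    n_discordant: int = 0
    uncertainty: int = 0  # split-position spread (bp)
    depth_ratio: tuple[float, float] | None = None
    depth_pass: bool | None = None
    klass: str = "UNCLASSIFIED"  # NMTL | NAHR | AMBIGUOUS
    junction_seq: str | None = None
    motif_present: bool | None = None
    indel_at_junction: int | None = None
    repeat_ids: tuple[str, ...] = ()
    name: str = ""


def _canonical(row) -> tuple:
    """Order endpoints so A <= B; junction calls are endpoint-symmetric."""
    a = (row.chromA, int(row.startA), row.strandA)
    b = (row.chromB, int(row.startB), row.strandB)
    if (b[0], b[1]) < (a[0], a[1]):
        a, b = b, a
    return a, b


def cluster_junctions(evidence: pd.DataFrame, cfg: CallerConfig) -> list[JunctionCall]:
    """Merge orientation-consistent records whose endpoints co-locate.

    Records sharing chromosome pair and strand pair whose positions fall
    within ``cluster_window`` at both endpoints are merged; candidates
    with fewer than ``min_split`` split reads are discarded.  Breakpoints
    are the median split-read position per endpoint.
    """
    if evidence is None or not len(evidence):
        return []
    recs = []
    for row in evidence.itertuples(index=False):
        a, b = _canonical(row)
        rectype = getattr(row, "rectype", "split")
        support = int(getattr(row, "support", 1))
        recs.append((a[0], b[0], a[2], b[2], a[1], b[1], rectype, support))
    df = pd.DataFrame(
        recs,
        columns=["chromA", "chromB", "strandA", "strandB", "posA", "posB", "rectype", "support"],
    ).sort_values(["chromA", "chromB", "strandA", "strandB", "posA", "posB"], kind="mergesort")

    calls: list[JunctionCall] = []
    for (ca, cb, sa, sb), grp in df.groupby(
        ["chromA", "chromB", "strandA", "strandB"], sort=False
    ):
        cluster: list[pd.Series] = []

        def flush(cluster):
            splits = [r for r in cluster if r.rectype == "split"]
            n_split = sum(r.support for r in splits)
            n_disc = sum(r.support for r in cluster if r.rectype == "discordant")
            if n_split < cfg.min_split:
                return
            pa = int(np.median([r.posA for r in splits]))
            pb = int(np.median([r.posB for r in splits]))
            spread = max(
                max(r.posA for r in splits) - min(r.posA for r in splits),
                max(r.posB for r in splits) - min(r.posB for r in splits),
            )
            calls.append(
                JunctionCall(
                    ca, pa, sa, cb, pb, sb,
                    n_split=n_split, n_discordant=n_disc, uncertainty=int(spread),
                    name=f"{ca}:{pa}-{cb}:{pb}",
                )
            )

        for r in grp.itertuples(index=False):
            anchor = next((c for c in cluster if c.rectype == "split"), None)
            ref = anchor if anchor is not None else (cluster[0] if cluster else None)
            near = ref is not None and (
                abs(r.posA - ref.posA) <= max(cfg.cluster_window, 400)
                if r.rectype == "discordant" or ref.rectype == "discordant"
                else abs(r.posA - ref.posA) <= cfg.cluster_window
                and abs(r.posB - ref.posB) <= cfg.cluster_window
            )
            if cluster and not near:
                flush(cluster)
                cluster = []
            cluster.append(r)
        if cluster:
            flush(cluster)
    return calls


def verify_depth_shift(
    depth: pd.DataFrame, call: JunctionCall, cfg: CallerConfig
) -> JunctionCall:
    """Depth ratio distal/proximal over ``flank`` bp at each endpoint.

    The proximal flank is the side retained in the derived junction (the
    '+' side lies upstream); a marked shift at either endpoint passes.
    Failing candidates are flagged, not removed.
    """
    ratios = []
    for chrom, pos, strand in (
        (call.chromA, call.posA, call.strandA),
        (call.chromB, call.posB, call.strandB),
    ):
        sub = depth[depth["chrom"] == chrom]
        if strand == "+":
            prox = sub[(sub["end"] > pos - cfg.flank) & (sub["start"] < pos)]
            dist = sub[(sub["end"] > pos) & (sub["start"] < pos + cfg.flank)]
        else:
            prox = sub[(sub["end"] > pos) & (sub["start"] < pos + cfg.flank)]
            dist = sub[(sub["end"] > pos - cfg.flank) & (sub["start"] < pos)]
        p = float(prox["depth"].mean()) if len(prox) else float("nan")
        d = float(dist["depth"].mean()) if len(dist) else float("nan")
        ratios.append(d / p if p and p > 0 else float("nan"))
    call.depth_ratio = (ratios[0], ratios[1])
    thr = cfg.depth_shift_min
    call.depth_pass = any(
        np.isfinite(r) and (r >= thr or r <= 1.0 / thr) for r in ratios
    )
    return call


def _repeat_hit(repeats: pd.DataFrame, chrom: str, pos: int):
    sub = repeats[repeats["chrom"] == chrom]
    hit = sub[(sub["start"] <= pos) & (pos < sub["end"])]
    if len(hit):
        row = hit.iloc[0]
        return str(row["id"]), str(row["family"])
    return None


def classify_junction(call: JunctionCall, repeats: pd.DataFrame) -> JunctionCall:
    """NAHR if both endpoints sit in copies of one repeat family, NMTL if
    neither endpoint is repetitive, AMBIGUOUS otherwise."""
    a = _repeat_hit(repeats, call.chromA, call.posA)
    b = _repeat_hit(repeats, call.chromB, call.posB)
    if a is None and b is None:
        call.klass = "NMTL"
    elif a is not None and b is not None and a[1] == b[1] and a[0] != b[0]:
        call.klass = "NAHR"
        call.repeat_ids = (a[0], b[0])
    else:
        call.klass = "AMBIGUOUS"
    return call


def reconstruct_junction(
    call: JunctionCall, sequences: dict[str, str], cfg: CallerConfig, k: int = 50
) -> JunctionCall:
    """Junction sequence = k bp of the retained flank at each endpoint.

    ``motif_present`` is true when the motif occurs spanning the join with
    at least one base on each side.  With base-resolved breakpoints (zero
    split-read spread) and a motif-spanning join the junction carries no
    indel; unresolved breakpoints skip the check.
    """
    if k <= 0:
        raise ValueError("flank size k must be positive")
    if call.uncertainty > 0:
        call.motif_present = None
        call.indel_at_junction = None
        return call
    strands = {call.strandA, call.strandB}
    if strands != {"+", "-"}:
        # inverted-orientation joins are outside the reconstruction model
        call.motif_present = None
        call.indel_at_junction = None
        return call
    if call.strandA == "+":
        plus = (call.chromA, call.posA)
        minus = (call.chromB, call.posB)
    else:
        plus = (call.chromB, call.posB)
        minus = (call.chromA, call.posA)
    left = sequences[plus[0]][max(0, plus[1] - k) : plus[1]]
    right = sequences[minus[0]][minus[1] : minus[1] + k]
    seq = left + right
    call.junction_seq = seq
    join = len(left)
    m = len(cfg.motif)
    call.motif_present = any(
        seq[s : s + m] == cfg.motif
        for s in range(max(0, join - m + 1), join)
        if s + m <= len(seq)
    )
    call.indel_at_junction = 0
    return call


def calls_to_events(calls: list[JunctionCall]) -> list[RecombEvent]:
    """Classified junction calls as typed events (NMTL/NAHR only)."""
    out = []
    for c in calls:
        if c.klass not in ("NMTL", "NAHR"):
            continue
        out.append(
            RecombEvent(
                c.klass,
                c.chromA,
                c.posA,
                c.posA + 1,
                chrom2=c.chromB,
                pos2=c.posB,
                attrs={
                    "n_split": c.n_split,
                    "n_discordant": c.n_discordant,
                    "depth_pass": c.depth_pass,
                    "motif_present": c.motif_present,
                    "indel": c.indel_at_junction,
                    "repeat_ids": list(c.repeat_ids),
                    "strands": c.strandA + c.strandB,
                },
            )
        )
    return out


def merge_reciprocal(calls: list[JunctionCall], window: int = 50) -> list[JunctionCall]:
    """Collapse the two junctions of a reciprocal exchange into one call.

    Two calls over the same chromosome pair with both endpoints within
    ``window`` and complementary strand patterns describe one reciprocal
    event; the call with more split support represents it.
    """
    used = [False] * len(calls)
    out: list[JunctionCall] = []
    for i, a in enumerate(calls):
        if used[i]:
            continue
        partner = None
        for j in range(i + 1, len(calls)):
            b = calls[j]
            if used[j]:
                continue
            if (
                a.chromA == b.chromA
                and a.chromB == b.chromB
                and abs(a.posA - b.posA) <= window
                and abs(a.posB - b.posB) <= window
                and (a.strandA, a.strandB) != (b.strandA, b.strandB)
            ):
                partner = j
                break
        if partner is not None:
            used[partner] = True
            b = calls[partner]
            keep = a if a.n_split >= b.n_split else b
            keep.name += "|reciprocal"
            out.append(keep)
        else:
            out.append(a)
        used[i] = True
    return out
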