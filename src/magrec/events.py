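"""Typed recombination/rearrangement events shared across modules."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import pandas as pd

#: Event kinds emitted by the calling pipeline.
EVENT_KINDS = (
    "CO",
    "NCO",
    "SGC",
    "BIR",
    "NMTL",
    "NAHR",
    "ANEUPLOID_GAIN",
    "ANEUPLOID_LOSS",
    "HAPLOIDIZATION",
    "CNV_DUP",
)


@dataclass
class RecombEvent:
    """One classified event.

    ``start``/``end`` are 0-based half-open and hold the breakpoint interval
    (CO/NMTL/NAHR) or the tract interval (NCO/SGC/BIR/CNV_DUP).  Two-locus
    events (translocations) carry the partner locus in ``chrom2``/``pos2``.
    """

    kind: str
    chrom: str
    start: int
    end: int
    chrom2: str | None = None
    pos2: int | None = None
    attrs: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind: {self.kind!r}")
        if self.end < self.start:
            raise ValueError(f"event end < start: {self}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    @property
    def width(self) -> int:
        return self.end - self.start


def events_to_frame(events: list[RecombEvent]) -> pd.DataFrame:
    """Events as a sorted BED-compatible table (attrs as a JSON column)."""
    rows = [
        {
            "chrom": e.chrom,
            "start": e.start,
            "end": e.end,
            "kind": e.kind,
            "chrom2": e.chrom2 if e.chrom2 is not None else ".",
            "pos2": e.pos2 if e.pos2 is not None else -1,
            "attrs": json.dumps(e.attrs, sort_keys=True),
        }
        for e in events
    ]
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "kind", "chrom2", "pos2", "attrs"]
    )
    if len(df):
        df = df.sort_values(["chrom", "start", "end", "kind"], kind="mergesort")
        df = df.reset_index(drop=True)
    return df


def frame_to_events(df: pd.DataFrame) -> list[RecombEvent]:
    out: list[RecombEvent] = []
    for row in df.itertuples(index=False):
        out.append(
            RecombEvent(
                kind=row.kind,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                chrom2=None if row.chrom2 == "." else row.chrom2,
                pos2=None if int(row.pos2) < 0 else int(row.pos2),
                attrs=json.loads(row.attrs),
            )
        )
    return out
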