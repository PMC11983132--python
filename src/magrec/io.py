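"""Dataset loading/validation and format round-tripping.

All on-disk formats are plain text in their native conventions: FASTA for
haplotype genomes, BED for annotations (0-based half-open), bedGraph for
depth/coverage, BEDPE for junction evidence, a tab-separated marker table
(CHROM POS REF_S ALT_K COUNT_S COUNT_K, POS 1-based like a VCF), and JSON
for simulation truth.  Internally everything is 0-based half-open.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from magrec.simulate.observe import JUNCTION_COLUMNS

MARKER_FILE_COLUMNS = ["CHROM", "POS", "REF_S", "ALT_K", "COUNT_S", "COUNT_K"]


class FormatError(ValueError):
    """Malformed record, reported with file and line number."""


# ------------------------------------------------------------------- FASTA
def write_fasta(path: str | Path, seqs: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


# ------------------------------------------------------------ BED/bedGraph
def read_bed(path: str | Path, extra: list[str] | None = None) -> pd.DataFrame:
    cols = ["chrom", "start", "end"] + (extra or ["name"])
    types = [str, int, int] + [str] * len(extra or ["name"])
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            vals = []
            for i, (c, t) in enumerate(zip(cols, types)):
                if i < len(parts):
                    try:
                        vals.append(t(parts[i]))
                    except ValueError:
                        raise FormatError(f"{path}:{ln}: bad value {parts[i]!r}") from None
                else:
                    vals.append("" if t is str else 0)
            if vals[2] <= vals[1]:
                raise FormatError(f"{path}:{ln}: interval end <= start")
            rows.append(vals)
    return pd.DataFrame(rows, columns=cols)


def write_bed(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: expected 4 fields")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError:
                raise FormatError(f"{path}:{ln}: bad numeric field") from None
            if rows[-1][2] <= rows[-1][1]:
                raise FormatError(f"{path}:{ln}: interval end <= start")
            if rows[-1][3] < 0:
                raise FormatError(f"{path}:{ln}: negative value")
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(path: str | Path, df: pd.DataFrame, value_col: str = "value") -> None:
    df[["chrom", "start", "end", value_col]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ------------------------------------------------------------------- BEDPE
def read_bedpe(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise FormatError(f"{path}:{ln}: expected >=10 BEDPE fields")
            try:
                rows.append(
                    (
                        parts[0], int(parts[1]), int(parts[2]),
                        parts[3], int(parts[4]), int(parts[5]),
                        parts[6], int(parts[7]), parts[8], parts[9],
                        parts[10] if len(parts) > 10 else "split",
                    )
                )
            except ValueError:
                raise FormatError(f"{path}:{ln}: bad coordinate") from None
    return pd.DataFrame(rows, columns=JUNCTION_COLUMNS)


def write_bedpe(path: str | Path, df: pd.DataFrame) -> None:
    df[JUNCTION_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# ------------------------------------------------------------ marker table
def read_marker_table(path: str | Path) -> pd.DataFrame:
    """Marker table with 1-based POS converted to internal 0-based pos."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(MARKER_FILE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = pd.DataFrame(
        {
            "chrom": df["CHROM"].astype(str),
            "pos": df["POS"].astype(int) - 1,
            "allele_S": df["REF_S"].astype(str),
            "allele_K": df["ALT_K"].astype(str),
            "count_S": df["COUNT_S"].astype(int),
            "count_K": df["COUNT_K"].astype(int),
        }
    )
    if (out[["count_S", "count_K"]].to_numpy() < 0).any():
        raise FormatError(f"{path}: negative allele counts")
    return out


def write_marker_table(path: str | Path, markers: pd.DataFrame, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("\t".join(MARKER_FILE_COLUMNS) + "\n")
        for r in markers.itertuples(index=False):
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t{r.allele_S}\t{r.allele_K}"
                f"\t{r.count_S}\t{r.count_K}\n"
            )


# ------------------------------------------------------------------ events
def write_events(path: str | Path, events_df: pd.DataFrame, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        events_df.to_csv(fh, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"chrom": str, "chrom2": str, "attrs": str},
    )


# ----------------------------------------------------------------- dataset
def config_hash(obj) -> str:
    """Stable short hash of a configuration object."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class Dataset:
    """In-memory view of one sample plus its genome annotations."""

    chrom_lengths: dict[str, int]
    markers: pd.DataFrame  # chrom, pos(0-based), allele_S, allele_K, count_S, count_K
    depth: pd.DataFrame  # chrom, start, end, depth
    junctions: pd.DataFrame  # JUNCTION_COLUMNS
    repeats: pd.DataFrame  # chrom, start, end + id, family
    centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)
    rdna: tuple[str, int, int] | None = None
    sequences: dict[str, str] | None = None  # reference (S haplotype)
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        known = set(self.chrom_lengths)
        for name, df in (
            ("markers", self.markers),
            ("depth", self.depth),
            ("repeats", self.repeats),
        ):
            bad = sorted(set(df["chrom"]) - known)
            if bad:
                raise FormatError(f"{name}: unknown chromosomes {bad}")
        if len(self.junctions):
            bad = sorted(
                (set(self.junctions["chromA"]) | set(self.junctions["chromB"])) - known
            )
            if bad:
                raise FormatError(f"junctions: unknown chromosomes {bad}")

    @property
    def mask(self) -> pd.DataFrame:
        """Repeat + rDNA intervals masked from depth baselines."""
        parts = [self.repeats[["chrom", "start", "end"]]]
        if self.rdna is not None:
            parts.append(
                pd.DataFrame([self.rdna], columns=["chrom", "start", "end"])
            )
        return pd.concat(parts, ignore_index=True)


def load_dataset(paths: dict[str, str | Path]) -> Dataset:
    """Load and cross-validate a sample from its files.

    ``paths`` keys: fasta, markers, depth, junctions (optional), repeats,
    centromeres (BED, optional), rdna (BED, optional).
    """
    seqs = read_fasta(paths["fasta"]) if "fasta" in paths else None
    markers = read_marker_table(paths["markers"])
    depth_bg = read_bedgraph(paths["depth"])
    depth = depth_bg.rename(columns={"value": "depth"})
    junctions = (
        read_bedpe(paths["junctions"])
        if "junctions" in paths
        else pd.DataFrame(columns=JUNCTION_COLUMNS)
    )
    repeats = (
        read_bed(paths["repeats"], extra=["id", "family"])
        if "repeats" in paths
        else pd.DataFrame(columns=["chrom", "start", "end", "id", "family"])
    )
    if seqs is not None:
        chrom_lengths = {c: len(s) for c, s in seqs.items()}
    else:
        lengths = {}
        for df, end_col in ((depth, "end"), (markers, "pos")):
            for chrom, grp in df.groupby("chrom"):
                lengths[chrom] = max(lengths.get(chrom, 0), int(grp[end_col].max()) + 1)
        chrom_lengths = lengths
    centromeres = {}
    if "centromeres" in paths:
        for r in read_bed(paths["centromeres"]).itertuples(index=False):
            centromeres[r.chrom] = (r.start, r.end)
    rdna = None
    if "rdna" in paths:
        row = read_bed(paths["rdna"]).iloc[0]
        rdna = (row["chrom"], int(row["start"]), int(row["end"]))
    ds = Dataset(
        chrom_lengths=chrom_lengths,
        markers=markers,
        depth=depth,
        junctions=junctions,
        repeats=repeats,
        centromeres=centromeres,
        rdna=rdna,
        sequences=seqs,
        provenance={k: str(v) for k, v in paths.items()},
    )
    ds.validate()
    return ds
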