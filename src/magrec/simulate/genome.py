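"""Hybrid diploid genome construction.

Two parental haplotypes ("S" for the SK1-like parent, "K" for the
S288C-like parent) share coordinates and differ only at planted SNP
markers, so every position is directly comparable between parents.  A
dispersed repeat family with identical copies provides the NAHR substrate,
and a tandem rDNA-like array sits on the last chromosome.  Repeat and
array unit sequences are generated free of the cut motif so that
enzyme-induced breakpoints always fall in unique sequence; markers are
likewise planted outside repeats (copies stay identical between parents
and between copies).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from magrec.params import SimParams

BASES = np.frombuffer(b"ACGT", dtype="S1")
HAPS = ("S", "K")

#: width of the functional centromere interval (bp)
CEN_WIDTH = 120


def seq_to_str(seq: np.ndarray) -> str:
    """uint8 base codes (0..3) -> ACGT string."""
    return BASES[seq].tobytes().decode("ascii")


@dataclass
class GenomeBuild:
    """The simulated hybrid genome: sequences, annotations, marker truth.

    Coordinates are 0-based half-open throughout.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: dict[str, int]
    seqs: dict[str, dict[str, np.ndarray]]  # hap -> chrom -> uint8 codes
    centromeres: dict[str, tuple[int, int]]
    repeats: pd.DataFrame  # columns: id, chrom, start, end, family
    rdna: tuple[str, int, int] | None
    markers: pd.DataFrame  # columns: chrom, pos, allele_S, allele_K
    cut_sites: dict[str, np.ndarray] = field(default_factory=dict)
    params: SimParams | None = None

    def validate(self) -> None:
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if len(pos) and not np.all(np.diff(pos) > 0):
                raise ValueError(f"markers not strictly increasing on {chrom}")
        if (self.markers["allele_S"] == self.markers["allele_K"]).any():
            raise ValueError("marker with identical parental alleles")
        for chrom in self.chrom_names:
            if chrom not in self.centromeres:
                raise ValueError(f"missing centromere for {chrom}")
        for row in self.repeats.itertuples(index=False):
            if not (0 <= row.start < row.end <= self.chrom_lengths[row.chrom]):
                raise ValueError(f"repeat {row.id} outside chromosome bounds")

    def centromere_point(self, chrom: str) -> int:
        s, e = self.centromeres[chrom]
        return (s + e) // 2

    def sequence(self, hap: str, chrom: str) -> str:
        return seq_to_str(self.seqs[hap][chrom])

    def marker_positions(self, chrom: str) -> np.ndarray:
        return self.markers.loc[self.markers["chrom"] == chrom, "pos"].to_numpy()


def _motif_free_unit(rng: np.random.Generator, length: int, motif: str) -> np.ndarray:
    """Random unit sequence with every motif occurrence edited away."""
    unit = rng.integers(0, 4, size=length).astype(np.uint8)
    pat = re.compile(motif.encode("ascii"))
    for _ in range(50):
        s = BASES[unit].tobytes()
        hits = [m.start() for m in pat.finditer(s)]
        if not hits:
            return unit
        for h in hits:
            unit[h] = (unit[h] + 1 + rng.integers(0, 3)) % 4
    raise RuntimeError("failed to purge motif from repeat unit")  # pragma: no cover


def _place_repeats(
    rng: np.random.Generator, params: SimParams, rdna_iv: tuple[str, int, int] | None
) -> pd.DataFrame:
    """Place dispersed repeat copies round-robin over chromosomes.

    Round-robin assignment guarantees same-chromosome pairs (tandem
    duplication substrate) whenever copies > chromosomes.  Copies keep
    >=12 kb spacing so a duplication between neighbours spans enough
    depth bins to be seen, stay clear of the rDNA array and chromosome
    ends, and all copies of one chromosome share a chromosome arm — a
    duplication between them can then never capture the centromere.
    """
    names = params.chrom_names
    rows = []
    min_gap = 12_000
    edge = 10_000
    arm_choice = {}
    for i in range(params.repeat_copies):
        chrom = names[i % params.n_chromosomes]
        L = params.chrom_lengths[names.index(chrom)]
        cen = params.centromere_positions[names.index(chrom)]
        if chrom not in arm_choice:
            left = (edge, cen - 2000 - params.repeat_length)
            right = (cen + CEN_WIDTH + 2000, L - edge - params.repeat_length)
            arm_choice[chrom] = max(left, right, key=lambda a: a[1] - a[0])
        lo, hi = arm_choice[chrom]
        for attempt in range(1000):
            start = int(rng.integers(lo, max(lo + 1, hi)))
            end = start + params.repeat_length
            if rdna_iv and chrom == rdna_iv[0] and start < rdna_iv[2] + 2000 and end > rdna_iv[1] - 2000:
                continue
            clash = any(
                r["chrom"] == chrom and start < r["end"] + min_gap and end > r["start"] - min_gap
                for r in rows
            )
            if not clash:
                break
        else:  # pragma: no cover - only tiny genomes
            raise ValueError("chromosome too short to place repeats")
        rows.append(
            {"id": f"Ty_{i + 1}", "chrom": chrom, "start": start, "end": end, "family": "Ty"}
        )
    return pd.DataFrame(rows, columns=["id", "chrom", "start", "end", "family"])


def _masked_intervals(build_repeats: pd.DataFrame, rdna: tuple[str, int, int] | None):
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for row in build_repeats.itertuples(index=False):
        by_chrom.setdefault(row.chrom, []).append((row.start, row.end))
    if rdna is not None:
        by_chrom.setdefault(rdna[0], []).append((rdna[1], rdna[2]))
    return {c: sorted(v) for c, v in by_chrom.items()}


def _find_shared_cut_sites(
    build: GenomeBuild, motif: str, masked: dict[str, list[tuple[int, int]]]
) -> dict[str, np.ndarray]:
    """Motif occurrences intact on both haplotypes, away from repeats.

    The cut coordinate is the motif midpoint (blunt-equivalent model), so a
    junction formed by ligating two cut ends carries exactly one restored
    motif copy spanning the join.
    """
    pat = re.compile(motif.encode("ascii"))
    half = len(motif) // 2
    pad = 100
    out = {}
    for chrom in build.chrom_names:
        s_hits = np.array(
            [m.start() for m in pat.finditer(BASES[build.seqs["S"][chrom]].tobytes())],
            dtype=np.int64,
        )
        k_hits = np.array(
            [m.start() for m in pat.finditer(BASES[build.seqs["K"][chrom]].tobytes())],
            dtype=np.int64,
        )
        shared = np.intersect1d(s_hits, k_hits) + half
        keep = np.ones(len(shared), dtype=bool)
        for s, e in masked.get(chrom, []):
            keep &= ~((shared >= s - pad) & (shared < e + pad))
        # keep breakpoints marker-flankable: stay off the extreme ends
        L = build.chrom_lengths[chrom]
        keep &= (shared >= 1000) & (shared <= L - 1000)
        out[chrom] = shared[keep]
    return out


def build_hybrid_genome(params: SimParams, rng: np.random.Generator | None = None) -> GenomeBuild:
    """Construct the two-haplotype hybrid genome with planted markers.

    Deterministic for a fixed ``params.seed``.  SNPs are planted as a
    per-base Bernoulli draw at ``snp_density`` outside repeat/rDNA
    intervals; the K haplotype is the S haplotype with the K alleles
    substituted, so haplotypes differ only at markers.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    names = params.chrom_names
    lengths = dict(zip(names, params.chrom_lengths))

    # rDNA-like array on the last chromosome
    rdna = None
    array_len = params.rdna_unit_length * params.rdna_copy_number
    if array_len > 0:
        chrom = names[-1]
        L = lengths[chrom]
        start = int(0.6 * L)
        if start + array_len > L - 5000:
            raise ValueError("last chromosome too short for the rDNA array")
        rdna = (chrom, start, start + array_len)

    repeats = (
        _place_repeats(rng, params, rdna)
        if params.repeat_copies > 0
        else pd.DataFrame(columns=["id", "chrom", "start", "end", "family"])
    )

    repeat_unit = (
        _motif_free_unit(rng, params.repeat_length, params.cut_motif)
        if params.repeat_copies > 0
        else None
    )
    rdna_unit = (
        _motif_free_unit(rng, params.rdna_unit_length, params.cut_motif)
        if rdna is not None
        else None
    )

    seqs_S: dict[str, np.ndarray] = {}
    for chrom in names:
        seq = rng.integers(0, 4, size=lengths[chrom]).astype(np.uint8)
        seqs_S[chrom] = seq
    for row in repeats.itertuples(index=False):
        seqs_S[row.chrom][row.start : row.end] = repeat_unit
    if rdna is not None:
        chrom, s, e = rdna
        tiled = np.tile(rdna_unit, params.rdna_copy_number)
        seqs_S[chrom][s:e] = tiled

    masked = _masked_intervals(repeats, rdna)

    # plant SNP markers outside masked intervals
    marker_rows = []
    seqs_K: dict[str, np.ndarray] = {}
    for chrom in names:
        L = lengths[chrom]
        eligible = np.ones(L, dtype=bool)
        for s, e in masked.get(chrom, []):
            eligible[s:e] = False
        draw = rng.random(L) < params.snp_density
        pos = np.nonzero(draw & eligible)[0]
        k_seq = seqs_S[chrom].copy()
        if len(pos):
            shift = rng.integers(1, 4, size=len(pos)).astype(np.uint8)
            k_seq[pos] = (k_seq[pos] + shift) % 4
        seqs_K[chrom] = k_seq
        for p in pos:
            marker_rows.append(
                {
                    "chrom": chrom,
                    "pos": int(p),
                    "allele_S": seq_to_str(seqs_S[chrom][p : p + 1]),
                    "allele_K": seq_to_str(k_seq[p : p + 1]),
                }
            )
    markers = pd.DataFrame(marker_rows, columns=["chrom", "pos", "allele_S", "allele_K"])

    centromeres = {
        c: (p - CEN_WIDTH // 2, p + CEN_WIDTH // 2)
        for c, p in zip(names, params.centromere_positions)
    }
    build = GenomeBuild(
        chrom_names=names,
        chrom_lengths=lengths,
        seqs={"S": seqs_S, "K": seqs_K},
        centromeres=centromeres,
        repeats=repeats,
        rdna=rdna,
        markers=markers,
        params=params,
    )
    build.cut_sites = _find_shared_cut_sites(build, params.cut_motif, masked)
    build.validate()
    return build
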