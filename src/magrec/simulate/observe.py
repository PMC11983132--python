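"""Emission of pipeline inputs from a simulated (derived) genome.

Models the read mapping/counting layer a short-read pipeline performs:
per-marker parental allele counts, uniformly binned depth, and
split/discordant junction evidence.  With ``params.exact_depth`` and zero
``marker_noise`` every value is the exact expectation (the noise-free
oracle regime); otherwise depth is Poisson per bin, marker counts are
Poisson/binomial with per-read allele miscalls, and junction support is
Poisson around ``junction_support``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from magrec.params import SimParams
from magrec.simulate.genome import GenomeBuild
from magrec.simulate.rearrange import Molecule

JUNCTION_COLUMNS = [
    "chromA",
    "startA",
    "endA",
    "chromB",
    "startB",
    "endB",
    "name",
    "support",
    "strandA",
    "strandB",
    "rectype",
]


def _marker_copy_numbers(
    build: GenomeBuild, mols: list[Molecule]
) -> dict[str, dict[str, np.ndarray]]:
    """Copies of each parental allele over markers, per chromosome."""
    cn = {
        hap: {
            c: np.zeros(len(build.marker_positions(c)), dtype=np.int32)
            for c in build.chrom_names
        }
        for hap in ("S", "K")
    }
    pos_cache = {c: build.marker_positions(c) for c in build.chrom_names}
    for mol in mols:
        for seg in mol.segs:
            pos = pos_cache[seg.chrom]
            lo, hi = np.searchsorted(pos, [seg.start, seg.end])
            cn[seg.hap][seg.chrom][lo:hi] += 1
    return cn


def _bin_copy_number(build: GenomeBuild, mols: list[Molecule], bin_size: int):
    """Mean total copy number per depth bin, reference coordinates."""
    out = {}
    for chrom in build.chrom_names:
        L = build.chrom_lengths[chrom]
        cov = np.zeros(L, dtype=np.int32)
        for mol in mols:
            for seg in mol.segs:
                if seg.chrom == chrom:
                    cov[seg.start : seg.end] += 1
        edges = np.arange(0, L, bin_size)
        sums = np.add.reduceat(cov, edges)
        widths = np.minimum(edges + bin_size, L) - edges
        out[chrom] = (edges, np.minimum(edges + bin_size, L), sums / widths)
    return out


def emit_observables(
    build: GenomeBuild,
    mols: list[Molecule],
    params: SimParams,
    rng: np.random.Generator,
    base_ploidy: int,
) -> dict[str, pd.DataFrame]:
    """Observables for one sample (a diploid clone or a single spore).

    Returns ``{"markers": ..., "depth": ..., "junctions": ...}``.
    Marker table positions are internal 0-based.
    """
    per_copy = params.mean_depth / base_ploidy
    exact = params.exact_depth and params.marker_noise == 0.0

    # ------------------------------------------------- marker allele counts
    cn = _marker_copy_numbers(build, mols)
    frames = []
    for chrom in build.chrom_names:
        sub = build.markers[build.markers["chrom"] == chrom].copy()
        cs, ck = cn["S"][chrom].astype(float), cn["K"][chrom].astype(float)
        if exact:
            reads_s = np.rint(per_copy * cs).astype(int)
            reads_k = np.rint(per_copy * ck).astype(int)
        else:
            reads_s = rng.poisson(per_copy * cs)
            reads_k = rng.poisson(per_copy * ck)
            if params.marker_noise > 0:
                s2k = rng.binomial(reads_s, params.marker_noise)
                k2s = rng.binomial(reads_k, params.marker_noise)
                reads_s = reads_s - s2k + k2s
                reads_k = reads_k - k2s + s2k
        sub["count_S"] = reads_s
        sub["count_K"] = reads_k
        frames.append(sub)
    markers = pd.concat(frames, ignore_index=True)

    # --------------------------------------------------------- binned depth
    rows = []
    for chrom, (starts, ends, mean_cn) in _bin_copy_number(
        build, mols, params.depth_bin
    ).items():
        lam = per_copy * mean_cn
        depth = lam if exact else rng.poisson(lam).astype(float)
        rows.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "depth": depth}
            )
        )
    depth_df = pd.concat(rows, ignore_index=True)

    # ----------------------------------------------------- junction evidence
    ev_rows = []
    jid = 0
    for mol in mols:
        for a, b in zip(mol.segs, mol.segs[1:]):
            if a.chrom == b.chrom and a.end == b.start:
                continue  # allelic switch: reads map across seamlessly
            jid += 1
            n_split = (
                int(round(params.junction_support))
                if exact
                else int(rng.poisson(params.junction_support))
            )
            n_disc = (
                int(round(params.junction_support / 2))
                if exact
                else int(rng.poisson(params.junction_support / 2))
            )
            pa, pb = a.end, b.start
            for k in range(n_split):
                ev_rows.append(
                    (a.chrom, pa, pa + 1, b.chrom, pb, pb + 1,
                     f"j{jid}_s{k}", 1, "+", "-", "split")
                )
            for k in range(n_disc):
                off_a = int(rng.integers(80, 300))
                off_b = int(rng.integers(80, 300))
                ev_rows.append(
                    (a.chrom, max(0, pa - off_a), max(0, pa - off_a) + 1,
                     b.chrom, pb + off_b, pb + off_b + 1,
                     f"j{jid}_d{k}", 1, "+", "-", "discordant")
                )
    junctions = pd.DataFrame(ev_rows, columns=JUNCTION_COLUMNS)
    return {"markers": markers, "depth": depth_df, "junctions": junctions}


def emit_all(
    build: GenomeBuild,
    samples: dict[str, list[Molecule]],
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> dict[str, dict[str, pd.DataFrame]]:
    """Observables for every sample of a simulation."""
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    base_ploidy = 2 if params.mode == "mitotic" else 1
    return {
        name: emit_observables(build, mols, params, rng, base_ploidy)
        for name, mols in samples.items()
    }
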