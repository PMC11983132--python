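"""Break/repair simulation on a segment-list genome representation.

Each molecule (a derived chromosome, or a chromatid in meiotic mode) is a
list of segments referencing intervals of the parental haplotype
sequences.  Cuts happen only at motif occurrences shared by both
haplotypes; the cut coordinate is the motif midpoint, so a junction that
ligates two cut ends restores exactly one intact motif spanning the join
with no inserted or deleted bases.

Event identifiability constraints (documented in the methods note): copy
number events are applied first and their chromosomes are excluded from
later events; allelic breakpoints keep a minimum spacing on a chromosome
and never fall inside previously converted tracts; dicentric or acentric
products are rejected and resampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from magrec.params import OUTCOMES, SimParams
from magrec.simulate.genome import GenomeBuild

MAX_ATTEMPTS = 100

#: outcomes that change whole-chromosome copy number
_CN_OUTCOMES = ("chrom_loss", "chrom_gain")
#: outcomes that rearrange sequence between loci
_STRUCT_OUTCOMES = ("NHEJ_TL", "NAHR", "tandem_DUP")
#: allelic outcomes (exchange/copy between homologues at one locus)
_ALLELIC_OUTCOMES = ("CO", "NCO", "SGC", "BIR")


@dataclass(frozen=True)
class Seg:
    """A slice [start, end) of parental haplotype ``hap`` on ``chrom``."""

    hap: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty segment {self}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Molecule:
    name: str
    segs: list[Seg]

    @property
    def length(self) -> int:
        return sum(s.length for s in self.segs)

    def split(self, p: int) -> tuple[list[Seg], list[Seg]]:
        """Split at derived position ``p`` (0 < p < length)."""
        if not (0 < p < self.length):
            raise ValueError(f"split position {p} outside molecule {self.name}")
        left: list[Seg] = []
        off = 0
        for i, s in enumerate(self.segs):
            if p < off + s.length:
                cut = s.start + (p - off)
                if cut > s.start:
                    left.append(replace(s, end=cut))
                right = [replace(s, start=cut)] if cut < s.end else []
                return left, right + self.segs[i + 1 :]
            left.append(s)
            off += s.length
        raise AssertionError  # pragma: no cover

    def locate(self, hap: str, chrom: str, x: int) -> int | None:
        """Derived position of source base (hap, chrom, x), if present."""
        off = 0
        for s in self.segs:
            if s.hap == hap and s.chrom == chrom and s.start <= x < s.end:
                return off + (x - s.start)
            off += s.length
        return None

    def containing_seg(self, p: int) -> tuple[Seg, int]:
        """Segment covering derived position ``p`` and its derived offset."""
        off = 0
        for s in self.segs:
            if p < off + s.length:
                return s, off
            off += s.length
        raise ValueError(f"position {p} outside molecule {self.name}")

    def centromere_count(self, build: GenomeBuild) -> int:
        n = 0
        for s in self.segs:
            cen = build.centromere_point(s.chrom)
            if s.start <= cen < s.end:
                n += 1
        return n


@dataclass
class TruthEvent:
    """Ground truth for one simulated event."""

    kind: str
    chrom: str
    pos: int
    end: int | None = None  # tract end for tract events
    chrom2: str | None = None
    pos2: int | None = None
    hap: str | None = None  # recipient / affected haplotype
    donor: str | None = None
    repeat_ids: tuple[str, ...] = ()
    molecules: tuple[str, ...] = ()
    sample: str | None = None  # spore id in meiotic mode
    cn_delta: int = 0


@dataclass
class SimTruth:
    """Exact simulated events; the oracle for recovery tests."""

    seed: int
    mode: str
    events: list[TruthEvent] = field(default_factory=list)

    def of_kind(self, kind: str) -> list[TruthEvent]:
        return [e for e in self.events if e.kind == kind]


class _Reserver:
    """Per-chromosome reserved intervals enforcing event spacing."""

    def __init__(self, spacing: int):
        self.spacing = spacing
        self._iv: dict[str, list[tuple[int, int]]] = {}

    def free(self, chrom: str, start: int, end: int) -> bool:
        s, e = start - self.spacing, end + self.spacing
        return not any(s < b and e > a for a, b in self._iv.get(chrom, []))

    def reserve(self, chrom: str, start: int, end: int) -> None:
        self._iv.setdefault(chrom, []).append((start - self.spacing, end + self.spacing))


def _molecule_sites(mol: Molecule, build: GenomeBuild, excluded: set[str]):
    """(derived_pos, seg, source_pos) for every shared cut site in the molecule."""
    out = []
    off = 0
    for s in mol.segs:
        if s.chrom not in excluded:
            sites = build.cut_sites.get(s.chrom)
            if sites is not None and len(sites):
                lo, hi = np.searchsorted(sites, [s.start, s.end])
                for x in sites[lo:hi]:
                    out.append((off + int(x) - s.start, s, int(x)))
        off += s.length
    return out


def _pick_cut(rng, mols: list[Molecule], build: GenomeBuild, excluded: set[str]):
    """Uniform draw over all available (molecule, cut site) pairs."""
    pools = [(_molecule_sites(m, build, excluded), m) for m in mols]
    total = sum(len(p) for p, _ in pools)
    if total == 0:
        return None
    k = int(rng.integers(total))
    for pool, m in pools:
        if k < len(pool):
            p, seg, x = pool[k]
            return m, p, seg, x
        k -= len(pool)
    raise AssertionError  # pragma: no cover


def _geometric_len(rng, mean: int) -> int:
    return int(rng.geometric(1.0 / mean))


class _Simulator:
    def __init__(self, build: GenomeBuild, params: SimParams, rng: np.random.Generator):
        self.build = build
        self.params = params
        self.rng = rng
        self.reserver = _Reserver(params.min_event_spacing)
        self.excluded: set[str] = set()
        self.truth = SimTruth(seed=params.seed, mode=params.mode)

    # ------------------------------------------------------------------ setup
    def initial_molecules(self) -> list[Molecule]:
        mols = []
        copies = ("S", "K") if self.params.mode == "mitotic" else ("S1", "S2", "K1", "K2")
        for name in copies:
            hap = name[0]
            for chrom in self.build.chrom_names:
                L = self.build.chrom_lengths[chrom]
                mols.append(Molecule(f"{name}.{chrom}", [Seg(hap, chrom, 0, L)]))
        return mols

    def draw_outcomes(self, n_molecule_copies: int) -> list[str]:
        n_sites = sum(len(v) for v in self.build.cut_sites.values())
        n_cuts = int(self.rng.binomial(n_sites * n_molecule_copies, self.params.cut_probability))
        w = np.array([self.params.outcome_weights.get(k, 0.0) for k in OUTCOMES])
        drawn = [OUTCOMES[i] for i in self.rng.choice(len(OUTCOMES), size=n_cuts, p=w)]
        # canonical application order: CN events, structural, allelic
        order = {k: i for i, k in enumerate(_CN_OUTCOMES + _STRUCT_OUTCOMES + _ALLELIC_OUTCOMES)}
        return sorted(
            (o for o in drawn if o != "religation"), key=lambda o: order[o]
        )

    # --------------------------------------------------------------- mitotic
    def apply_mitotic(self, mols: list[Molecule], outcome: str) -> None:
        handler = {
            "chrom_loss": self._chrom_loss,
            "chrom_gain": self._chrom_gain,
            "NHEJ_TL": self._nhej_tl,
            "NAHR": self._nahr,
            "tandem_DUP": self._tandem_dup,
            "SGC": self._sgc,
            "BIR": self._bir,
            "CO": self._sgc,  # interhomolog CO is invisible in a mitotic clone
            "NCO": self._sgc,
        }[outcome]
        dicentric_fails = 0
        for _ in range(MAX_ATTEMPTS):
            result = handler(mols)
            if result == "ok":
                return
            if result == "dicentric":
                dicentric_fails += 1
        if dicentric_fails == MAX_ATTEMPTS:
            raise RuntimeError(f"could not form a monocentric product for {outcome}")
        warnings.warn(f"no valid configuration for {outcome}; event skipped")

    def _chrom_loss(self, mols: list[Molecule]) -> str:
        cands = [c for c in self.build.chrom_names if c not in self.excluded]
        if not cands:
            return "skip"
        chrom = cands[int(self.rng.integers(len(cands)))]
        hap = ("S", "K")[int(self.rng.integers(2))]
        name = f"{hap}.{chrom}"
        idx = next((i for i, m in enumerate(mols) if m.name == name), None)
        if idx is None:
            return "skip"
        mols.pop(idx)
        self.excluded.add(chrom)
        self.reserver.reserve(chrom, 0, self.build.chrom_lengths[chrom])
        self.truth.events.append(
            TruthEvent("chrom_loss", chrom, 0, self.build.chrom_lengths[chrom], hap=hap, cn_delta=-1)
        )
        return "ok"

    def _chrom_gain(self, mols: list[Molecule]) -> str:
        cands = [c for c in self.build.chrom_names if c not in self.excluded]
        if not cands:
            return "skip"
        chrom = cands[int(self.rng.integers(len(cands)))]
        hap = ("S", "K")[int(self.rng.integers(2))]
        name = f"{hap}.{chrom}"
        src = next((m for m in mols if m.name == name), None)
        if src is None:
            return "skip"
        mols.append(Molecule(f"{name}+", list(src.segs)))
        self.excluded.add(chrom)
        self.reserver.reserve(chrom, 0, self.build.chrom_lengths[chrom])
        self.truth.events.append(
            TruthEvent("chrom_gain", chrom, 0, self.build.chrom_lengths[chrom], hap=hap, cn_delta=1)
        )
        return "ok"

    def _nhej_tl(self, mols: list[Molecule]) -> str:
        cut1 = _pick_cut(self.rng, mols, self.build, self.excluded)
        cut2 = _pick_cut(self.rng, mols, self.build, self.excluded)
        if cut1 is None or cut2 is None:
            return "skip"
        m1, p1, seg1, x1 = cut1
        m2, p2, seg2, x2 = cut2
        if m1 is m2 or seg1.chrom == seg2.chrom:
            return "skip"
        if not (
            self.reserver.free(seg1.chrom, x1, x1) and self.reserver.free(seg2.chrom, x2, x2)
        ):
            return "skip"
        l1, r1 = m1.split(p1)
        l2, r2 = m2.split(p2)
        a = Molecule(m1.name, l1 + r2)
        b = Molecule(m2.name, l2 + r1)
        if a.centromere_count(self.build) != 1 or b.centromere_count(self.build) != 1:
            return "dicentric"
        m1.segs, m2.segs = a.segs, b.segs
        self.reserver.reserve(seg1.chrom, x1, x1)
        self.reserver.reserve(seg2.chrom, x2, x2)
        self.truth.events.append(
            TruthEvent(
                "NHEJ_TL",
                seg1.chrom,
                x1,
                chrom2=seg2.chrom,
                pos2=x2,
                hap=seg1.hap,
                donor=seg2.hap,
                molecules=(m1.name, m2.name),
            )
        )
        return "ok"

    def _nahr(self, mols: list[Molecule]) -> str:
        reps = self.build.repeats
        reps = reps[(reps["family"] == "Ty") & (~reps["chrom"].isin(self.excluded))]
        if len(reps) < 2:
            return "skip"
        i, j = self.rng.choice(len(reps), size=2, replace=False)
        a, b = reps.iloc[int(i)], reps.iloc[int(j)]
        if a["chrom"] == b["chrom"]:
            return "skip"  # same-chromosome geometry handled by tandem_DUP
        o = self.params.repeat_length // 2
        xa, xb = int(a["start"]) + o, int(b["start"]) + o
        hap_a = ("S", "K")[int(self.rng.integers(2))]
        hap_b = ("S", "K")[int(self.rng.integers(2))]
        ma = next((m for m in mols if m.locate(hap_a, a["chrom"], xa) is not None), None)
        mb = next((m for m in mols if m.locate(hap_b, b["chrom"], xb) is not None), None)
        if ma is None or mb is None or ma is mb:
            return "skip"
        if not (
            self.reserver.free(a["chrom"], a["start"], a["end"])
            and self.reserver.free(b["chrom"], b["start"], b["end"])
        ):
            return "skip"
        pa = ma.locate(hap_a, a["chrom"], xa)
        pb = mb.locate(hap_b, b["chrom"], xb)
        la, ra = ma.split(pa)
        lb, rb = mb.split(pb)
        prod1 = Molecule(ma.name, la + rb)
        prod2 = Molecule(mb.name, lb + ra)
        if (
            prod1.centromere_count(self.build) != 1
            or prod2.centromere_count(self.build) != 1
        ):
            return "dicentric"
        ma.segs, mb.segs = prod1.segs, prod2.segs
        self.reserver.reserve(a["chrom"], a["start"], a["end"])
        self.reserver.reserve(b["chrom"], b["start"], b["end"])
        self.truth.events.append(
            TruthEvent(
                "NAHR",
                a["chrom"],
                xa,
                chrom2=b["chrom"],
                pos2=xb,
                hap=hap_a,
                donor=hap_b,
                repeat_ids=(a["id"], b["id"]),
                molecules=(ma.name, mb.name),
            )
        )
        return "ok"

    def _tandem_dup(self, mols: list[Molecule]) -> str:
        reps = self.build.repeats
        reps = reps[(reps["family"] == "Ty") & (~reps["chrom"].isin(self.excluded))]
        pairs = [
            (ra, rb)
            for c, grp in reps.groupby("chrom")
            for k, ra in enumerate(grp.itertuples(index=False))
            for rb in list(grp.itertuples(index=False))[k + 1 :]
        ]
        if not pairs:
            return "skip"
        ra, rb = pairs[int(self.rng.integers(len(pairs)))]
        if ra.start > rb.start:
            ra, rb = rb, ra
        o = self.params.repeat_length // 2
        xa, xb = ra.start + o, rb.start + o
        hap = ("S", "K")[int(self.rng.integers(2))]
        mol = next(
            (
                m
                for m in mols
                if m.locate(hap, ra.chrom, xa) is not None
                and m.locate(hap, rb.chrom, xb) is not None
            ),
            None,
        )
        if mol is None:
            return "skip"
        if not self.reserver.free(ra.chrom, xa, xb):
            return "skip"
        cen = self.build.centromere_point(ra.chrom)
        if xa <= cen < xb:
            return "dicentric"  # duplicating the centromere
        pa = mol.locate(hap, ra.chrom, xa)
        pb = mol.locate(hap, rb.chrom, xb)
        if pa is None or pb is None or pa >= pb:
            return "skip"
        if pb - pa != xb - xa:
            return "skip"  # intervening material not contiguous source sequence
        left, _ = mol.split(pb)
        _, right = mol.split(pa)
        prod = Molecule(mol.name, left + right)
        if prod.centromere_count(self.build) != 1:
            return "dicentric"
        mol.segs = prod.segs
        self.reserver.reserve(ra.chrom, xa, xb)
        self.truth.events.append(
            TruthEvent(
                "tandem_DUP",
                ra.chrom,
                xa,
                end=xb,
                chrom2=ra.chrom,
                pos2=xa,
                hap=hap,
                repeat_ids=(ra.id, rb.id),
                molecules=(mol.name,),
            )
        )
        return "ok"

    def _sgc(self, mols: list[Molecule]) -> str:
        cut = _pick_cut(self.rng, mols, self.build, self.excluded)
        if cut is None:
            return "skip"
        mol, p, seg, x = cut
        L = _geometric_len(self.rng, self.params.nco_mean_len)
        if x + L >= seg.end:
            return "skip"
        if not self.reserver.free(seg.chrom, x, x + L):
            return "skip"
        donor = "K" if seg.hap == "S" else "S"
        left, rest = mol.split(p)
        tract = Seg(donor, seg.chrom, x, x + L)
        right = Molecule("tmp", rest).split(L)[1]
        mol.segs = left + [tract] + right
        self.reserver.reserve(seg.chrom, x, x + L)
        self.truth.events.append(
            TruthEvent(
                "SGC", seg.chrom, x, end=x + L, hap=seg.hap, donor=donor, molecules=(mol.name,)
            )
        )
        return "ok"

    def _bir(self, mols: list[Molecule]) -> str:
        cut = _pick_cut(self.rng, mols, self.build, self.excluded)
        if cut is None:
            return "skip"
        mol, p, seg, x = cut
        chrom = seg.chrom
        L_c = self.build.chrom_lengths[chrom]
        donor = "K" if seg.hap == "S" else "S"
        to_end = bool(self.rng.integers(2))
        # the replaced arm must be plain (h, chrom) material out to the
        # chromosome end, or the tract would not read as terminal LOH
        if to_end:
            if seg is not mol.segs[-1] or seg.end != L_c:
                return "skip"
            if not self.reserver.free(chrom, x, L_c):
                return "skip"
            left, _ = mol.split(p)
            cand = Molecule(mol.name, left + [Seg(donor, chrom, x, L_c)])
            tract = (x, L_c)
        else:
            if seg is not mol.segs[0] or seg.start != 0:
                return "skip"
            if not self.reserver.free(chrom, 0, x):
                return "skip"
            _, right = mol.split(p)
            cand = Molecule(mol.name, [Seg(donor, chrom, 0, x)] + right)
            tract = (0, x)
        if cand.centromere_count(self.build) != 1:
            return "dicentric"
        mol.segs = cand.segs
        self.reserver.reserve(chrom, *tract)
        self.truth.events.append(
            TruthEvent(
                "BIR", chrom, tract[0], end=tract[1], hap=seg.hap, donor=donor, molecules=(mol.name,)
            )
        )
        return "ok"

    # --------------------------------------------------------------- meiotic
    def run_meiotic(self, mols: list[Molecule]) -> dict[str, list[Molecule]]:
        outcomes = self.draw_outcomes(n_molecule_copies=4)
        nd_chroms: list[str] = []
        by_chrom: dict[str, dict[str, Molecule]] = {c: {} for c in self.build.chrom_names}
        for m in mols:
            cid, chrom = m.name.split(".")
            by_chrom[chrom][cid] = m

        for outcome in outcomes:
            if outcome in _CN_OUTCOMES:
                # at most two nondisjoined chromosomes per meiosis: viable
                # spores carry few aneuploidies, and chromosome dosage from
                # relative depth needs a euploid majority to be identifiable
                if len(nd_chroms) >= 2:
                    continue
                cands = [c for c in self.build.chrom_names if c not in self.excluded]
                if not cands:
                    continue
                chrom = cands[int(self.rng.integers(len(cands)))]
                nd_chroms.append(chrom)
                self.excluded.add(chrom)
                self.reserver.reserve(chrom, 0, self.build.chrom_lengths[chrom])
            elif outcome == "CO":
                self._meiotic_co(by_chrom)
            elif outcome == "NCO":
                self._meiotic_nco(by_chrom)
            # structural outcomes carry zero weight in the default meiotic
            # spectrum; the mitotic path exercises those classifiers

        # segregate chromatids into four spores
        spores: dict[str, list[Molecule]] = {f"spore{i + 1}": [] for i in range(4)}
        spore_names = list(spores)
        for chrom in self.build.chrom_names:
            chromatids = [by_chrom[chrom][cid] for cid in ("S1", "S2", "K1", "K2")]
            if chrom in nd_chroms:
                perm = self.rng.permutation(4)
                disomic = [spore_names[perm[0]], spore_names[perm[1]]]
                nullisomic = [spore_names[perm[2]], spore_names[perm[3]]]
                s_ids = self.rng.permutation([0, 1])
                k_ids = self.rng.permutation([2, 3])
                for sp, si, ki in zip(disomic, s_ids, k_ids):
                    spores[sp].extend([chromatids[si], chromatids[ki]])
                    self.truth.events.append(
                        TruthEvent(
                            "chrom_gain",
                            chrom,
                            0,
                            self.build.chrom_lengths[chrom],
                            sample=sp,
                            cn_delta=1,
                        )
                    )
                for sp in nullisomic:
                    self.truth.events.append(
                        TruthEvent(
                            "chrom_loss",
                            chrom,
                            0,
                            self.build.chrom_lengths[chrom],
                            sample=sp,
                            cn_delta=-1,
                        )
                    )
            else:
                perm = self.rng.permutation(4)
                for i, sp in enumerate(spore_names):
                    spores[sp].append(chromatids[perm[i]])
        # attach spore ids to chromatid-level truth events
        owner = {
            m.name: sp for sp, ms in spores.items() for m in ms
        }
        for ev in self.truth.events:
            if ev.kind == "CO" and ev.sample is None:
                ev.sample = ",".join(sorted(owner[m] for m in ev.molecules if m in owner))
            elif ev.kind == "NCO" and ev.sample is None:
                ev.sample = owner.get(ev.molecules[0])
        return spores

    def _meiotic_co(self, by_chrom) -> None:
        for _ in range(MAX_ATTEMPTS):
            cands = [c for c in self.build.chrom_names if c not in self.excluded]
            if not cands:
                return
            chrom = cands[int(self.rng.integers(len(cands)))]
            sites = self.build.cut_sites[chrom]
            if not len(sites):
                continue
            x = int(sites[int(self.rng.integers(len(sites)))])
            if not self.reserver.free(chrom, x, x):
                continue
            s_id = ("S1", "S2")[int(self.rng.integers(2))]
            k_id = ("K1", "K2")[int(self.rng.integers(2))]
            ms, mk = by_chrom[chrom][s_id], by_chrom[chrom][k_id]
            ls, rs = ms.split(x)
            lk, rk = mk.split(x)
            ms.segs = ls + rk
            mk.segs = lk + rs
            self.reserver.reserve(chrom, x, x)
            self.truth.events.append(
                TruthEvent("CO", chrom, x, molecules=(ms.name, mk.name))
            )
            return
        warnings.warn("no valid CO placement; event skipped")

    def _meiotic_nco(self, by_chrom) -> None:
        for _ in range(MAX_ATTEMPTS):
            cands = [c for c in self.build.chrom_names if c not in self.excluded]
            if not cands:
                return
            chrom = cands[int(self.rng.integers(len(cands)))]
            sites = self.build.cut_sites[chrom]
            if not len(sites):
                continue
            x = int(sites[int(self.rng.integers(len(sites)))])
            L = _geometric_len(self.rng, self.params.nco_mean_len)
            if x + L >= self.build.chrom_lengths[chrom]:
                continue
            if not self.reserver.free(chrom, x, x + L):
                continue
            cid = ("S1", "S2", "K1", "K2")[int(self.rng.integers(4))]
            mol = by_chrom[chrom][cid]
            # derived position == source position: meiotic events are
            # length-preserving and stay on one chromosome
            seg, _ = mol.containing_seg(x)
            if x + L >= seg.end:
                continue
            donor = "K" if seg.hap == "S" else "S"
            left, rest = mol.split(x)
            right = Molecule("tmp", rest).split(L)[1]
            mol.segs = left + [Seg(donor, chrom, x, x + L)] + right
            self.reserver.reserve(chrom, x, x + L)
            self.truth.events.append(
                TruthEvent(
                    "NCO", chrom, x, end=x + L, hap=seg.hap, donor=donor, molecules=(mol.name,)
                )
            )
            return
        warnings.warn("no valid NCO placement; event skipped")


def simulate_rearrangements(
    build: GenomeBuild, params: SimParams, rng: np.random.Generator | None = None
) -> tuple[dict[str, list[Molecule]], SimTruth]:
    """Apply the drawn repair-outcome spectrum to the hybrid genome.

    Returns ``(samples, truth)`` where ``samples`` maps sample name to its
    molecule list: ``{"diploid": [...]}`` in mitotic mode, four spores in
    meiotic mode.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    sim = _Simulator(build, params, rng)
    mols = sim.initial_molecules()
    if params.mode == "mitotic":
        for outcome in sim.draw_outcomes(n_molecule_copies=2):
            sim.apply_mitotic(mols, outcome)
        for m in mols:
            assert m.centromere_count(build) == 1
        for ev in sim.truth.events:
            ev.sample = "diploid"
        return {"diploid": mols}, sim.truth
    spores = sim.run_meiotic(mols)
    for ms in spores.values():
        for m in ms:
            assert m.centromere_count(build) == 1
    return spores, sim.truth
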