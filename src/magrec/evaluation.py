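"""Recovery scoring of pipeline calls against simulation ground truth.

Generative truth is first translated into the set of events an ideal
observer of the marker/depth/junction data could recover (the
"expected" set): tracts need enough markers to be called, crossover
switches need flanking marker support, events on whole-chromosome
aneuploid molecules are invisible to allele-fraction calling, and a
gene-conversion tract whose marker span reaches the CO/NCO threshold is
indistinguishable from two crossovers.  Precision is measured against
the full truth (so borderline-undetectable events are not counted as
false positives), recall against the detectable subset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from magrec.events import RecombEvent
from magrec.segment import ClassifierConfig
from magrec.simulate.genome import GenomeBuild
from magrec.simulate.rearrange import SimTruth, TruthEvent

_TRUTH_TO_CALL = {
    "SGC": "SGC",
    "BIR": "BIR",
    "NHEJ_TL": "NMTL",
    "NAHR": "NAHR",
    "tandem_DUP": "CNV_DUP",
    "chrom_gain": "ANEUPLOID_GAIN",
    "chrom_loss": "ANEUPLOID_LOSS",
    "CO": "CO",
    "NCO": "NCO",
}


def _markers_in(build: GenomeBuild, chrom: str, start: int, end: int) -> np.ndarray:
    pos = build.marker_positions(chrom)
    return pos[(pos >= start) & (pos < end)]


@dataclass
class ExpectedEvent:
    sample: str
    kind: str
    chrom: str
    pos: int
    end: int | None = None
    chrom2: str | None = None
    pos2: int | None = None
    repeat_ids: tuple[str, ...] = ()


def expected_events(
    truth: SimTruth,
    build: GenomeBuild,
    cfg: ClassifierConfig | None = None,
    samples: dict | None = None,
) -> list[ExpectedEvent]:
    """Translate generative truth into recoverable expected calls.

    Meiotic translation walks the final chromatid structure per spore
    (``samples`` from the simulator is then required): successive
    crossovers sharing a chromatid can cancel observably, so the
    generative event list alone does not define what marker data show.
    """
    cfg = cfg or ClassifierConfig()
    if truth.mode == "mitotic":
        return _expected_mitotic(truth, build, cfg)
    if samples is None:
        raise ValueError("meiotic expected events need the simulated spores")
    return _expected_meiotic(truth, build, cfg, samples)


def full_truth_events(
    truth: SimTruth,
    build: GenomeBuild,
    cfg: ClassifierConfig | None = None,
    samples: dict | None = None,
) -> list[ExpectedEvent]:
    """Truth translation without marker-support filters (precision target)."""
    cfg = dataclasses.replace(cfg or ClassifierConfig(), min_support=0)
    return expected_events(truth, build, cfg, samples)


def _expected_mitotic(
    truth: SimTruth, build: GenomeBuild, cfg: ClassifierConfig
) -> list[ExpectedEvent]:
    out: list[ExpectedEvent] = []
    for ev in truth.events:
        kind = _TRUTH_TO_CALL.get(ev.kind)
        if kind is None:
            continue
        if kind in ("SGC", "BIR"):
            m = _markers_in(build, ev.chrom, ev.pos, ev.end)
            if len(m) < cfg.min_support:
                continue
            s, e = (int(m[0]), int(m[-1]) + 1) if len(m) else (ev.pos, ev.end)
            out.append(ExpectedEvent(ev.sample, kind, ev.chrom, s, e))
        elif kind == "NMTL":
            out.append(
                ExpectedEvent(
                    ev.sample, kind, ev.chrom, ev.pos, chrom2=ev.chrom2, pos2=ev.pos2
                )
            )
        elif kind == "NAHR":
            out.append(
                ExpectedEvent(
                    ev.sample,
                    kind,
                    ev.chrom,
                    ev.pos,
                    chrom2=ev.chrom2,
                    pos2=ev.pos2,
                    repeat_ids=ev.repeat_ids,
                )
            )
        elif kind == "CNV_DUP":
            out.append(
                ExpectedEvent(
                    ev.sample, kind, ev.chrom, ev.pos, ev.end, repeat_ids=ev.repeat_ids
                )
            )
        else:  # aneuploidy
            out.append(ExpectedEvent(ev.sample, kind, ev.chrom, 0, ev.end))
    return out


def _hap_runs(mol) -> list[list]:
    """Merge adjacent same-haplotype segments into [hap, start, end] runs."""
    runs: list[list] = []
    for seg in mol.segs:
        if runs and runs[-1][0] == seg.hap:
            runs[-1][2] = seg.end
        else:
            runs.append([seg.hap, seg.start, seg.end])
    return runs


def _visible_spore_events(
    mol, build: GenomeBuild, cfg: ClassifierConfig, sample: str
) -> list[ExpectedEvent]:
    """NCO tracts and CO switches an ideal observer sees on one chromatid.

    Mirrors the classifier's absorb rules on the *true* haplotype
    structure: runs without enough markers are invisible (interstitial
    runs merge into their flanks, terminal ones drop), interstitial runs
    whose marker span is under the CO/NCO threshold are NCOs, remaining
    run boundaries are CO switches.
    """
    chrom = mol.segs[0].chrom
    runs = _hap_runs(mol)

    def n_markers(r):
        return len(_markers_in(build, chrom, r[1], r[2]))

    changed = True
    while changed:
        changed = False
        for i, r in enumerate(runs):
            if len(runs) == 1 or n_markers(r) >= max(1, cfg.min_support):
                continue
            if 0 < i < len(runs) - 1:
                merged = [runs[i - 1][0], runs[i - 1][1], runs[i + 1][2]]
                runs[i - 1 : i + 2] = [merged]
            elif i == 0:
                runs[1][1] = r[1]
                runs.pop(0)
            else:
                runs[-2][2] = r[2]
                runs.pop()
            changed = True
            break
    out: list[ExpectedEvent] = []
    keep: list[list] = []
    for i, r in enumerate(runs):
        m = _markers_in(build, chrom, r[1], r[2])
        interstitial = 0 < i < len(runs) - 1
        if interstitial and len(m) and int(m[-1]) - int(m[0]) < cfg.nco_max_len:
            out.append(ExpectedEvent(sample, "NCO", chrom, int(m[0]), int(m[-1]) + 1))
        else:
            keep.append(r)
    merged: list[list] = []
    for r in keep:
        if merged and merged[-1][0] == r[0]:
            merged[-1][2] = r[2]
        else:
            merged.append(list(r))
    for left, right in zip(merged, merged[1:]):
        out.append(ExpectedEvent(sample, "CO", chrom, left[2]))
    return out


def _expected_meiotic(
    truth: SimTruth, build: GenomeBuild, cfg: ClassifierConfig, samples: dict
) -> list[ExpectedEvent]:
    out: list[ExpectedEvent] = []
    aneuploid: set[tuple[str, str]] = set()
    for ev in truth.events:
        if ev.kind in ("chrom_gain", "chrom_loss"):
            kind = _TRUTH_TO_CALL[ev.kind]
            out.append(ExpectedEvent(ev.sample, kind, ev.chrom, 0, ev.end))
            aneuploid.add((ev.sample, ev.chrom))
    for sp, mols in samples.items():
        by_chrom: dict[str, list] = {}
        for mol in mols:
            by_chrom.setdefault(mol.segs[0].chrom, []).append(mol)
        for chrom, cmols in by_chrom.items():
            if (sp, chrom) in aneuploid or len(cmols) != 1:
                continue
            out.extend(_visible_spore_events(cmols[0], build, cfg, sp))
    return out


# ---------------------------------------------------------------- matching
def _match(call: RecombEvent, exp: ExpectedEvent, tol: int) -> bool:
    if call.kind != exp.kind:
        return False
    kind = call.kind
    if kind in ("NMTL", "NAHR"):
        # endpoint-symmetric: compare unordered endpoint pairs
        if kind == "NAHR" and exp.repeat_ids:
            called_ids = set(call.attrs.get("repeat_ids", []))
            if called_ids:
                return called_ids == set(exp.repeat_ids)
        pairs_called = {(call.chrom, call.start), (call.chrom2, call.pos2)}
        for c, p in ((exp.chrom, exp.pos), (exp.chrom2, exp.pos2)):
            if not any(
                cc == c and pp is not None and abs(pp - p) <= max(tol, 100)
                for cc, pp in pairs_called
            ):
                return False
        return True
    if kind == "HAPLOIDIZATION":
        return True
    if call.chrom != exp.chrom:
        return False
    if kind == "CO":
        return call.start - tol <= exp.pos <= call.end + tol
    if kind in ("NCO", "SGC", "BIR", "CNV_DUP"):
        return call.start < (exp.end or exp.pos + 1) + tol and call.end > exp.pos - tol
    if kind in ("ANEUPLOID_GAIN", "ANEUPLOID_LOSS"):
        return True  # chrom equality already checked
    return False


@dataclass
class RecoveryScore:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        if not np.isfinite(p) or not np.isfinite(r) or p + r == 0:
            return float("nan")
        return 2 * p * r / (p + r)


def score_recovery(
    called: dict[str, list[RecombEvent]],
    expected: list[ExpectedEvent],
    full_truth: list[ExpectedEvent] | None = None,
    tol: int = 100,
) -> dict[str, RecoveryScore]:
    """Per-kind precision/recall over samples.

    ``called`` maps sample name to its pipeline events.  ``full_truth``
    (default: ``expected``) is the match target for precision, so calls
    recovering a sub-threshold truth event are not penalised.
    """
    full_truth = expected if full_truth is None else full_truth
    scores: dict[str, RecoveryScore] = {}

    def sc(kind: str) -> RecoveryScore:
        return scores.setdefault(kind, RecoveryScore())

    # recall: greedy one-to-one against the detectable set
    matched_calls: set[int] = set()
    call_list = [
        (sample, ev) for sample, evs in called.items() for ev in evs
    ]
    for exp in expected:
        hit = None
        for i, (sample, ev) in enumerate(call_list):
            if i in matched_calls or sample != exp.sample:
                continue
            if _match(ev, exp, tol):
                hit = i
                break
        if hit is None:
            sc(exp.kind).fn += 1
        else:
            matched_calls.add(hit)
            sc(exp.kind).tp += 1
    # precision: unmatched calls are false positives unless they hit any
    # truth event (including undetectable ones)
    for i, (sample, ev) in enumerate(call_list):
        if i in matched_calls:
            continue
        if not any(
            t.sample == sample and _match(ev, t, tol) for t in full_truth
        ):
            sc(ev.kind).fp += 1
    return scores


def simulate_and_score(
    params, classifier_cfg: ClassifierConfig | None = None
) -> dict[str, RecoveryScore]:
    """Simulate one experiment, run the pipeline, score the recovery."""
    from magrec.pipeline import run_pipeline, simulate_all

    sim = simulate_all(params)
    call_mode = "diploid" if params.mode == "mitotic" else "spore"
    called = {
        name: run_pipeline(ds, call_mode, classifier_cfg=classifier_cfg).events
        for name, ds in sim.datasets.items()
    }
    cfg = classifier_cfg or ClassifierConfig()
    exp = expected_events(sim.truth, sim.build, cfg, samples=sim.molecules)
    full = full_truth_events(sim.truth, sim.build, cfg, samples=sim.molecules)
    return score_recovery(called, exp, full)


def pool_scores(score_dicts: list[dict[str, RecoveryScore]]) -> dict[str, RecoveryScore]:
    """Sum per-kind counts over replicate simulations."""
    out: dict[str, RecoveryScore] = {}
    for d in score_dicts:
        for kind, s in d.items():
            agg = out.setdefault(kind, RecoveryScore())
            agg.tp += s.tp
            agg.fp += s.fp
            agg.fn += s.fn
    return out
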