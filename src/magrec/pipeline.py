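"""End-to-end workflow: simulate -> observe -> call -> summarise.

``run_pipeline`` executes the calling stages in order (marker states,
segmentation, junction calling, ploidy/CNV, event classification,
control subtraction) on a :class:`~magrec.io.Dataset`; the companions
``simulate_dataset``/``simulate_all`` bridge the forward simulator into
that same in-memory dataset form so simulated and loaded data follow one
code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from magrec import breakpoints as bp
from magrec import ploidy as pl
from magrec import segment as sg
from magrec.events import RecombEvent, events_to_frame
from magrec.io import Dataset, config_hash
from magrec.params import SimParams
from magrec.simulate.genome import GenomeBuild, build_hybrid_genome
from magrec.simulate.observe import emit_all
from magrec.simulate.rearrange import SimTruth, simulate_rearrangements


@dataclass
class PipelineResult:
    sample: str
    mode: str
    events: list[RecombEvent]
    co_switch_counts: dict[str, int]
    cn_table: pd.DataFrame
    junction_calls: list[bp.JunctionCall]
    removed_by_control: list[RecombEvent] = field(default_factory=list)
    log: list[str] = field(default_factory=list)
    config_hash: str = ""

    @property
    def events_frame(self) -> pd.DataFrame:
        return events_to_frame(self.events)


def _junction_stage(
    ds: Dataset, caller_cfg: bp.CallerConfig, log: list[str]
) -> list[bp.JunctionCall]:
    calls = bp.cluster_junctions(ds.junctions, caller_cfg)
    calls = bp.merge_reciprocal(calls)
    for c in calls:
        bp.verify_depth_shift(ds.depth, c, caller_cfg)
        bp.classify_junction(c, ds.repeats)
        if ds.sequences is not None:
            bp.reconstruct_junction(c, ds.sequences, caller_cfg)
    if calls:
        log.append(f"junctions: {len(calls)} calls after reciprocal merge")
    return calls


def run_pipeline(
    ds: Dataset,
    mode: str,
    classifier_cfg: sg.ClassifierConfig | None = None,
    caller_cfg: bp.CallerConfig | None = None,
    ploidy_cfg: pl.PloidyConfig | None = None,
    control: "PipelineResult | list[RecombEvent] | None" = None,
) -> PipelineResult:
    """Run the full calling workflow on one sample.

    ``mode`` is ``diploid`` (mitotic isolate), ``rtg`` (return-to-growth
    diploid; identical calling, NAHR-per-HR semantics downstream) or
    ``spore`` (haploid meiotic product).  Deterministic given inputs and
    configuration.
    """
    if mode not in ("diploid", "rtg", "spore"):
        raise ValueError(f"unknown mode {mode!r}")
    classifier_cfg = classifier_cfg or sg.ClassifierConfig()
    caller_cfg = caller_cfg or bp.CallerConfig()
    ploidy_cfg = ploidy_cfg or pl.PloidyConfig()
    expected_ploidy = 1 if mode == "spore" else 2
    log: list[str] = []

    states = sg.call_marker_states(ds.markers, classifier_cfg)
    segments = sg.segment_genotypes(states, classifier_cfg)
    calls = _junction_stage(ds, caller_cfg, log)

    events: list[RecombEvent] = []
    co_counts: dict[str, int] = {}

    cnv = pl.detect_cnv_segments(
        ds.depth, expected_ploidy, ploidy_cfg, mask=ds.mask, junctions=calls
    )
    # junction-confirmed duplication tracts are excluded from the
    # chromosome dosage medians: a large tandem duplication must not read
    # as a whole-chromosome gain
    cn_mask = ds.mask
    dup_iv = [
        (e.chrom, e.start, e.end) for e in cnv if "junction" in e.attrs
    ]
    if dup_iv:
        cn_mask = pd.concat(
            [cn_mask, pd.DataFrame(dup_iv, columns=["chrom", "start", "end"])],
            ignore_index=True,
        )
    cn = pl.chromosome_copy_number(ds.depth, states, expected_ploidy, mask=cn_mask)

    aneu, haploid = pl.detect_aneuploidy_and_haploidization(
        cn, expected_ploidy, ploidy_cfg
    )
    abnormal = {
        e.chrom for e in aneu if e.kind in ("ANEUPLOID_GAIN", "ANEUPLOID_LOSS")
    }
    # whole-chromosome dosage changes are aneuploidies, not interstitial CNVs
    cnv = [e for e in cnv if e.chrom not in abnormal]
    linked = {ev.attrs.get("junction") for ev in cnv if "junction" in ev.attrs}
    junction_events = []
    for c in calls:
        if c.klass in ("NMTL", "NAHR") and c.name not in linked:
            junction_events.extend(bp.calls_to_events([c]))
        elif c.name in linked:
            log.append(f"junction {c.name} consumed by CNV_DUP")

    if mode == "spore":
        rec, co_counts = sg.classify_spore_recombination(segments, classifier_cfg)
        het_chroms = {s.chrom for s in segments if s.state == "HET" and not s.low_confidence}
        for c in sorted(het_chroms):
            log.append(f"{c}: heterozygous markers in a spore; routed to ploidy (disomy)")
        rec = [e for e in rec if e.chrom not in abnormal]
        events.extend(rec)
    else:
        loh, hap_candidate = sg.classify_diploid_loh(segments, classifier_cfg)
        if hap_candidate:
            log.append("no heterozygosity anywhere: haploidization candidate")
        if haploid:
            loh = []
        loh = [e for e in loh if e.chrom not in abnormal]
        events.extend(loh)

    events.extend(junction_events)
    events.extend(cnv)
    events.extend(aneu)

    removed: list[RecombEvent] = []
    if control is not None:
        control_events = control.events if isinstance(control, PipelineResult) else control
        events, removed = sg.subtract_control_events(
            events, control_events, classifier_cfg
        )
        if removed:
            log.append(f"control subtraction removed {len(removed)} events")

    events.sort(key=lambda e: (e.chrom, e.start, e.end, e.kind))
    return PipelineResult(
        sample=ds.provenance.get("sample", "sample"),
        mode=mode,
        events=events,
        co_switch_counts=co_counts,
        cn_table=cn,
        junction_calls=calls,
        removed_by_control=removed,
        log=log,
        config_hash=config_hash(
            {
                "classifier": classifier_cfg,
                "caller": caller_cfg,
                "ploidy": ploidy_cfg,
                "mode": mode,
            }
        ),
    )


# ----------------------------------------------------------------- bridges
@dataclass
class Simulation:
    """One simulated experiment: genome, per-sample datasets, truth."""

    build: GenomeBuild
    datasets: dict[str, Dataset]
    truth: SimTruth
    molecules: dict[str, list]  # sample -> final derived molecules

    def __iter__(self):  # (build, datasets, truth) unpacking
        return iter((self.build, self.datasets, self.truth))


def simulate_all(params: SimParams) -> Simulation:
    """Simulate one experiment and expose every sample as a Dataset."""
    rng = np.random.default_rng(params.seed)
    build = build_hybrid_genome(params, rng)
    samples, truth = simulate_rearrangements(build, params, rng)
    obs = emit_all(build, samples, params, rng)
    ref_seqs = {c: build.sequence("S", c) for c in build.chrom_names}
    datasets = {}
    for name, tables in obs.items():
        ds = Dataset(
            chrom_lengths=dict(build.chrom_lengths),
            markers=tables["markers"],
            depth=tables["depth"].rename(columns={"value": "depth"}),
            junctions=tables["junctions"],
            repeats=build.repeats,
            centromeres=build.centromeres,
            rdna=build.rdna,
            sequences={c: build.sequence("S", c) for c in build.chrom_names},
            provenance={"sample": name, "seed": params.seed},
        )
        datasets[name] = ds
    return Simulation(build, datasets, truth, samples)


def simulate_dataset(params: SimParams, sample: str | None = None) -> tuple[
    GenomeBuild, Dataset, SimTruth
]:
    """Simulate and return a single sample (the diploid, or one spore)."""
    sim = simulate_all(params)
    if sample is None:
        sample = "diploid" if params.mode == "mitotic" else "spore1"
    return sim.build, sim.datasets[sample], sim.truth
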