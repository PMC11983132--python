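"""Forward-simulator contracts: genome construction, event application,
observable emission."""

import numpy as np
import pytest

from magrec.params import SimParams
from magrec.simulate.genome import build_hybrid_genome
from magrec.simulate.observe import emit_observables
from magrec.simulate.rearrange import Molecule, Seg, simulate_rearrangements

from conftest import tiny_params


def _weights(**kw):
    w = {k: 0.0 for k in (
        "religation", "NHEJ_TL", "CO", "NCO", "SGC", "BIR", "NAHR",
        "tandem_DUP", "chrom_loss", "chrom_gain",
    )}
    w.update(kw)
    return w


class TestGenomeBuild:
    def test_marker_count_within_binomial_bounds(self):
        # 2 x 100 kb at density 0.007: Binomial(200000, 0.007),
        # mean 1400, sd 37.3 -> +/-3 sd is [1288, 1512]
        params = tiny_params(
            chrom_lengths=(100_000, 100_000), repeat_copies=0,
            rdna_copy_number=0, seed=1,
        )
        build = build_hybrid_genome(params)
        n = 200_000
        mean = n * 0.007
        sd = (n * 0.007 * 0.993) ** 0.5
        assert mean - 3 * sd <= len(build.markers) <= mean + 3 * sd

    def test_zero_density_gives_identical_haplotypes(self):
        params = tiny_params(snp_density=0.0, repeat_copies=0, rdna_copy_number=0)
        build = build_hybrid_genome(params)
        assert len(build.markers) == 0
        for chrom in build.chrom_names:
            assert np.array_equal(build.seqs["S"][chrom], build.seqs["K"][chrom])

    def test_same_seed_reproduces_sequences_exactly(self):
        b1 = build_hybrid_genome(tiny_params(seed=5))
        b2 = build_hybrid_genome(tiny_params(seed=5))
        for chrom in b1.chrom_names:
            assert b1.sequence("S", chrom) == b2.sequence("S", chrom)
            assert b1.sequence("K", chrom) == b2.sequence("K", chrom)
        assert b1.markers.equals(b2.markers)

    def test_repeat_copies_identical_within_family(self, small_build):
        seqs = [
            small_build.sequence("S", r.chrom)[r.start : r.end]
            for r in small_build.repeats.itertuples(index=False)
        ]
        assert len(set(seqs)) == 1
        # and identical between haplotypes (no markers inside repeats)
        r = small_build.repeats.iloc[0]
        assert (
            small_build.sequence("K", r["chrom"])[r["start"] : r["end"]] == seqs[0]
        )

    def test_markers_differ_between_parents(self, small_build):
        assert (small_build.markers["allele_S"] != small_build.markers["allele_K"]).all()

    def test_cut_sites_are_shared_motif_midpoints(self, small_build):
        motif = small_build.params.cut_motif
        half = len(motif) // 2
        for chrom, sites in small_build.cut_sites.items():
            for x in sites[:25]:
                s = small_build.sequence("S", chrom)[x - half : x - half + len(motif)]
                k = small_build.sequence("K", chrom)[x - half : x - half + len(motif)]
                assert s == motif and k == motif

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimParams(snp_density=1.5)
        with pytest.raises(ValueError):
            SimParams(cut_motif="")
        with pytest.raises(ValueError):
            SimParams(cut_motif="GAXC")
        with pytest.raises(ValueError):
            SimParams(outcome_weights=_weights(religation=0.7))


class TestRearrangements:
    def test_religation_only_leaves_genome_unchanged(self):
        params = tiny_params(outcome_weights=_weights(religation=1.0))
        build = build_hybrid_genome(params)
        samples, truth = simulate_rearrangements(build, params)
        assert truth.events == []
        for mol in samples["diploid"]:
            assert len(mol.segs) == 1

    def test_nhej_junction_restores_single_motif_no_indel(self):
        params = tiny_params(
            outcome_weights=_weights(religation=0.5, NHEJ_TL=0.5),
            cut_probability=0.01, seed=23,
        )
        build = build_hybrid_genome(params)
        samples, truth = simulate_rearrangements(build, params)
        tls = truth.of_kind("NHEJ_TL")
        assert tls, "no NHEJ translocation simulated"
        motif = params.cut_motif
        n_junctions = 0
        for mol in samples["diploid"]:
            off = 0
            for a, b in zip(mol.segs, mol.segs[1:]):
                off += a.length
                if a.chrom != b.chrom:
                    left = build.sequence(a.hap, a.chrom)[a.end - 2 : a.end]
                    right = build.sequence(b.hap, b.chrom)[b.start : b.start + 2]
                    assert left + right == motif
                    n_junctions += 1
        assert n_junctions == 2 * len(tls)  # reciprocal exchange

    def test_reciprocal_translocation_conserves_total_length(self):
        params = tiny_params(
            outcome_weights=_weights(religation=0.4, NHEJ_TL=0.3, NAHR=0.3),
            cut_probability=0.01, seed=31,
        )
        build = build_hybrid_genome(params)
        samples, truth = simulate_rearrangements(build, params)
        total = sum(m.length for m in samples["diploid"])
        assert total == 2 * sum(build.chrom_lengths.values())

    def test_tandem_duplication_length_equals_repeat_start_distance(self):
        params = tiny_params(
            outcome_weights=_weights(religation=0.5, tandem_DUP=0.5),
            cut_probability=0.02, seed=3,
        )
        build = build_hybrid_genome(params)
        samples, truth = simulate_rearrangements(build, params)
        dups = truth.of_kind("tandem_DUP")
        assert dups
        expected_extra = sum(d.end - d.pos for d in dups)
        total = sum(m.length for m in samples["diploid"])
        assert total == 2 * sum(build.chrom_lengths.values()) + expected_extra
        for d in dups:
            ra = build.repeats.set_index("id").loc[d.repeat_ids[0]]
            rb = build.repeats.set_index("id").loc[d.repeat_ids[1]]
            assert d.end - d.pos == abs(int(rb["start"]) - int(ra["start"]))

    def test_monocentricity_across_seeds(self):
        # every derived chromosome keeps exactly one centromere
        for seed in range(40):
            params = tiny_params(
                seed=seed, cut_probability=0.01,
                outcome_weights=_weights(
                    religation=0.3, NHEJ_TL=0.2, NAHR=0.15, tandem_DUP=0.1,
                    SGC=0.1, BIR=0.1, chrom_loss=0.03, chrom_gain=0.02,
                ),
            )
            build = build_hybrid_genome(params)
            samples, _ = simulate_rearrangements(build, params)
            for mols in samples.values():
                for mol in mols:
                    assert mol.centromere_count(build) == 1

    def test_determinism_of_full_simulation(self):
        params = tiny_params(seed=17, cut_probability=0.01)
        outs = []
        for _ in range(2):
            build = build_hybrid_genome(params)
            samples, truth = simulate_rearrangements(build, params)
            outs.append(
                (
                    [(m.name, tuple(m.segs)) for m in samples["diploid"]],
                    [(e.kind, e.chrom, e.pos, e.end) for e in truth.events],
                )
            )
        assert outs[0] == outs[1]

    def test_meiotic_mode_yields_four_spores(self):
        params = tiny_params(mode="meiotic", seed=2)
        build = build_hybrid_genome(params)
        spores, truth = simulate_rearrangements(build, params)
        assert sorted(spores) == ["spore1", "spore2", "spore3", "spore4"]
        # without nondisjunction every spore has one chromatid per chromosome
        nd = {e.chrom for e in truth.events if e.kind in ("chrom_gain", "chrom_loss")}
        for mols in spores.values():
            counts = {}
            for m in mols:
                counts[m.segs[0].chrom] = counts.get(m.segs[0].chrom, 0) + 1
            for chrom in build.chrom_names:
                if chrom not in nd:
                    assert counts.get(chrom, 0) == 1


class TestObservables:
    def test_diploid_het_marker_counts_are_symmetric_in_exact_mode(self, small_build, rng):
        params = small_build.params
        L = {c: small_build.chrom_lengths[c] for c in small_build.chrom_names}
        mols = [
            Molecule(f"{h}.{c}", [Seg(h, c, 0, L[c])])
            for h in ("S", "K")
            for c in small_build.chrom_names
        ]
        obs = emit_observables(small_build, mols, params, rng, base_ploidy=2)
        assert (obs["markers"]["count_S"] == 15).all()
        assert (obs["markers"]["count_K"] == 15).all()

    def test_bir_tract_is_pure_donor_allele(self, small_build, rng):
        params = small_build.params
        c = small_build.chrom_names[0]
        L = small_build.chrom_lengths[c]
        x = 60_000
        mols = [
            Molecule(f"S.{c}", [Seg("S", c, 0, L)]),
            Molecule(f"K.{c}", [Seg("K", c, 0, x), Seg("S", c, x, L)]),
        ]
        obs = emit_observables(small_build, mols, params, rng, base_ploidy=2)
        m = obs["markers"]
        tract = m[(m["chrom"] == c) & (m["pos"] >= x)]
        frac_s = tract["count_S"] / (tract["count_S"] + tract["count_K"])
        assert (frac_s == 1.0).all()

    def test_junction_evidence_emitted_at_true_coordinates(self, small_build):
        params = small_build.params.with_(junction_support=6.0, exact_depth=False)
        rng = np.random.default_rng(7)
        c1, c2 = small_build.chrom_names[:2]
        L = small_build.chrom_lengths
        xa, xb = 50_000, 80_000
        mols = [
            Molecule(f"S.{c1}", [Seg("S", c1, 0, xa), Seg("S", c2, xb, L[c2])]),
            Molecule(f"S.{c2}", [Seg("S", c2, 0, xb), Seg("S", c1, xa, L[c1])]),
            Molecule(f"K.{c1}", [Seg("K", c1, 0, L[c1])]),
            Molecule(f"K.{c2}", [Seg("K", c2, 0, L[c2])]),
        ]
        obs = emit_observables(small_build, mols, params, rng, base_ploidy=2)
        j = obs["junctions"]
        splits = j[j["rectype"] == "split"]
        assert len(splits) >= 1
        assert ((splits["startA"] == xa) | (splits["startA"] == xb)).all()

    def test_exact_depth_reflects_local_copy_number(self, small_build, rng):
        params = small_build.params
        c = small_build.chrom_names[0]
        L = small_build.chrom_lengths[c]
        mols = [Molecule(f"S.{c}", [Seg("S", c, 0, L)])] * 3  # CN 3
        obs = emit_observables(small_build, mols, params, rng, base_ploidy=2)
        d = obs["depth"]
        assert np.allclose(d.loc[d["chrom"] == c, "depth"], 45.0)
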