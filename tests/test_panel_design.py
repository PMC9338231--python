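"""Design pipeline: discriminatory windows, candidate enumeration,
specificity screening, size-ladder assignment and end-to-end recovery."""

import itertools
import math
import random

import pytest

from flymplex.fixtures import FixtureSpec, synth_alignment, synth_template
from flymplex.gel_sim import DEFAULT_GEL, resolvable
from flymplex.identify import call_species
from flymplex.insilico_pcr import simulate_multiplex
from flymplex.gel_sim import make_lanes
from flymplex.panel_design import (
    Alignment,
    CandidatePair,
    DesignConstraints,
    DesignError,
    Window,
    assign_size_ladder,
    check_specificity,
    design_panel,
    discriminatory_windows,
    enumerate_candidates,
    read_alignment,
    write_alignment,
)
from flymplex.seq_core import Primer


@pytest.fixture(scope="module")
def aln_and_manifest():
    return synth_alignment(n_per_species=2, diag_per_species=3, seed=42)


@pytest.fixture(scope="module")
def designed(aln_and_manifest):
    aln, _ = aln_and_manifest
    return design_panel(aln, list(aln.species))


class TestAlignment:
    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError):
            Alignment(rows=(("a", "ACGT"), ("b", "ACG")))

    def test_single_species_rejected(self):
        with pytest.raises(ValueError):
            Alignment(rows=(("a", "ACGT"), ("a", "ACGT")))

    def test_consensus_majority_and_ties(self):
        aln = Alignment(
            rows=(("x", "AAAC"), ("x", "AAAG"), ("x", "ATAG"), ("y", "CCCC"))
        )
        # col 1: A,A,T -> A; col 3: C,G,G -> G
        assert aln.consensus("x") == "AAAG"
        aln2 = Alignment(rows=(("x", "AC"), ("x", "GC"), ("y", "TT")))
        assert aln2.consensus("x") == "RC"  # A/G tie -> R

    def test_consensus_gap_majority(self):
        aln = Alignment(rows=(("x", "A-"), ("x", "--"), ("y", "AA")))
        assert aln.consensus("x") == "A-"

    def test_fasta_round_trip(self, tmp_path, aln_and_manifest):
        aln, _ = aln_and_manifest
        p = tmp_path / "aln.fasta"
        write_alignment(aln, p)
        back = read_alignment(p)
        assert back.rows == aln.rows


class TestDiscriminatoryWindows:
    def test_implanted_cluster_ranks_first(self, aln_and_manifest):
        aln, manifest = aln_and_manifest
        for sp in aln.species:
            windows = discriminatory_windows(aln, sp, min_diag_positions=2)
            assert windows
            implanted = set(
                manifest["species"][sp]["forward_diag_columns"]
                + manifest["species"][sp]["reverse_diag_columns"]
            )
            # the top-ranked window is anchored on an implanted cluster
            assert set(windows[0].diag_columns) <= implanted

    def test_identical_species_yield_nothing(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGTACGT" * 3
        aln = Alignment(rows=(("a", seq), ("b", seq)))
        assert discriminatory_windows(aln, "a", 1) == []

    def test_min_diag_zero_returns_every_window(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGTACGT" * 3
        aln = Alignment(rows=(("a", seq), ("b", seq)))
        windows = discriminatory_windows(aln, "a", 0, width=25)
        assert len(windows) == len(seq) - 25 + 1

    def test_absent_species_rejected(self, aln_and_manifest):
        aln, _ = aln_and_manifest
        with pytest.raises(KeyError):
            discriminatory_windows(aln, "nope", 2)


class TestEnumerateCandidates:
    def test_anchor_covers_implanted_snp(self, aln_and_manifest):
        aln, manifest = aln_and_manifest
        sp = "capitata"
        windows = discriminatory_windows(aln, sp, 2)
        cands = enumerate_candidates(aln, windows[0], sp)
        assert cands
        implanted = set(
            manifest["species"][sp]["forward_diag_columns"]
            + manifest["species"][sp]["reverse_diag_columns"]
        )
        for c in cands:
            assert set(c.diag_columns_3p) & implanted

    def test_gap_columns_do_not_change_candidates(self, aln_and_manifest):
        aln, _ = aln_and_manifest
        sp = "cosyra"
        w = discriminatory_windows(aln, sp, 2)[0]
        # insert two all-gap columns inside the window
        cut = w.start + 3
        rows = tuple((s, seq[:cut] + "--" + seq[cut:]) for s, seq in aln.rows)
        gapped = Alignment(rows=rows)
        w2 = Window(
            start=w.start,
            end=w.end + 2,
            diag_columns=tuple(c + 2 if c >= cut else c for c in w.diag_columns),
            orientations=w.orientations,
            best_3p_distance=w.best_3p_distance,
        )
        a = [c.primer.sequence for c in enumerate_candidates(aln, w, sp)]
        b = [c.primer.sequence for c in enumerate_candidates(gapped, w2, sp)]
        assert a == b

    def test_infeasible_tm_window_empty(self, aln_and_manifest):
        aln, _ = aln_and_manifest
        sp = "cosyra"
        w = discriminatory_windows(aln, sp, 2)[0]
        constraints = DesignConstraints(tm_range=(90.0, 95.0))
        assert enumerate_candidates(aln, w, sp, constraints) == []


def _pair(species, size, name="x"):
    f = Primer(name=f"{species}_{name}_F", sequence="ACGTACGTACGTACGTAC")
    r = Primer(name=f"{species}_{name}_R", sequence="TGCATGCATGCATGCATG")
    return CandidatePair(
        species=species, forward=f, reverse=r, predicted_size=size,
        tm_f=50.0, tm_r=50.0, fwd_span=(0, 18), rev_span=(size - 18, size),
        fwd_diag_3p=(1,), rev_diag_3p=(2,),
    )


class TestAssignSizeLadder:
    def test_published_size_set_is_the_unique_selection(self):
        per = {
            sp: [_pair(sp, s)]
            for sp, s in zip(
                ["capitata", "cosyra", "quilicii", "rosa", "dorsalis"],
                [327, 183, 128, 249, 676],
            )
        }
        sel = assign_size_ladder(per)
        sizes = sorted(p.predicted_size for p in sel.values())
        assert sizes == [128, 183, 249, 327, 676]

    def test_unresolvable_candidates_error_names_blockers(self):
        per = {"a": [_pair("a", 300)], "b": [_pair("b", 302)]}
        with pytest.raises(DesignError) as err:
            assign_size_ladder(per)
        assert set(err.value.species) == {"a", "b"}

    def test_single_species_vacuous(self):
        sel = assign_size_ladder({"a": [_pair("a", 200)]})
        assert sel["a"].predicted_size == 200

    def test_min_gap_optimal_vs_exhaustive(self):
        """Randomized sets: selection is resolvable and min-gap optimal."""
        rng = random.Random(99)
        for _ in range(15):
            per = {
                sp: [
                    _pair(sp, rng.randint(100, 700), name=str(i))
                    for i in range(rng.randint(1, 6))
                ]
                for sp in ("a", "b", "c", "d")
            }
            combos = list(
                itertools.product(*(per[sp] for sp in sorted(per)))
            )

            def min_gap(combo):
                logs = sorted(math.log10(p.predicted_size) for p in combo)
                return min((y - x for x, y in zip(logs, logs[1:])), default=math.inf)

            best = max(min_gap(c) for c in combos)
            if best < DEFAULT_GEL.resolvability_delta:
                with pytest.raises(DesignError):
                    assign_size_ladder(per)
                continue
            sel = assign_size_ladder(per)
            sizes = [p.predicted_size for p in sel.values()]
            assert all(
                resolvable(x, y) for x, y in itertools.combinations(sizes, 2)
            )
            assert min_gap(sel.values()) == pytest.approx(best)


class TestSpecificity:
    def test_target_pairs_clean_on_fixture_alignment(self, designed, aln_and_manifest):
        aln, _ = aln_and_manifest
        for _, pair in designed.selected:
            report = check_specificity(pair, aln)
            assert report.at_risk_species == ()

    def test_region_identical_across_species_flagged(self):
        # two species identical except one private SNP far from the shared region
        base = (
            "GCTAAAGCCATAACAATTCAGATTTACCAGGTCAATGGGTAC"
            "CAGACTGTTCTTTTGGGC"[::-1]  # filler, not a real site
            + "ATCGGCTAGCTAGGATCCAATGCTTAGGCTAACTGATCCATG" * 6
        )
        a = base + "A"
        b = base + "C"
        aln = Alignment(rows=(("a", a), ("b", b)))
        f = Primer(name="f", sequence=a[0:20])
        r_seq = a[220:240]
        from flymplex.seq_core import reverse_complement

        r = Primer(name="r", sequence=reverse_complement(r_seq))
        pair = CandidatePair(
            species="a", forward=f, reverse=r, predicted_size=240,
            tm_f=50, tm_r=50, fwd_span=(0, 20), rev_span=(220, 240),
            fwd_diag_3p=(), rev_diag_3p=(),
        )
        report = check_specificity(pair, aln)
        (entry,) = report.per_species
        assert entry[0] == "b" and entry[1].at_risk

    def test_out_of_range_product_not_flagged(self, aln_and_manifest):
        aln, _ = aln_and_manifest
        # a pair whose primers bind every species but 5 kb apart cannot
        # produce an in-range product; emulate with a tiny amplicon range
        sp = "rosa"
        res = design_panel(aln, [sp])
        pair = res.selected_for(sp)
        tight = DesignConstraints(amplicon_range=(100, 101))
        report = check_specificity(pair, aln, tight)
        assert all(not cb.at_risk for _, cb in report.per_species)


class TestDesignPanel:
    def test_recovery_five_species(self, designed, aln_and_manifest):
        _, manifest = aln_and_manifest
        assert len(designed.panel) == 5
        sizes = [p.predicted_size for _, p in designed.selected]
        assert all(
            resolvable(a, b) for a, b in itertools.combinations(sizes, 2)
        )
        for sp, pair in designed.selected:
            m = manifest["species"][sp]
            assert set(pair.fwd_diag_3p) & set(m["forward_diag_columns"])
            assert set(pair.rev_diag_3p) & set(m["reverse_diag_columns"])
            assert pair.specificity.at_risk_species == ()

    def test_design_assay_round_trip(self, designed):
        """Templates built from the designed panel are all identified."""
        panel = designed.panel
        recs = [
            synth_template(panel.entry(sp), FixtureSpec(seed=100 + i), panel)
            for i, sp in enumerate(panel.species)
        ]
        lanes = make_lanes(simulate_multiplex(panel, recs))
        for sp, lane in zip(panel.species, lanes):
            call = call_species([b.size for b in lane.bands], panel)
            assert (call.status, call.species) == ("identified", sp)

    def test_single_target(self, aln_and_manifest):
        aln, _ = aln_and_manifest
        res = design_panel(aln, ["quilicii"])
        assert res.panel.species == ("quilicii",)

    def test_indistinguishable_species_fail_at_windows(self):
        seq = "ACGTTGCAATCGGATCCATG" * 40
        aln = Alignment(rows=(("a", seq), ("b", seq)))
        with pytest.raises(DesignError) as err:
            design_panel(aln, ["a"])
        assert err.value.stage == "discriminatory_windows"

    def test_determinism(self, aln_and_manifest):
        aln, _ = aln_and_manifest
        r1 = design_panel(aln, list(aln.species))
        r2 = design_panel(aln, list(aln.species))
        assert r1.selected == r2.selected
        assert r1.rejection_log == r2.rejection_log

    def test_published_sizes_pass_resolvability(self, panel):
        sizes = [e.expected_size for e in panel.entries]
        assert all(
            resolvable(a, b) for a, b in itertools.combinations(sizes, 2)
        )
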