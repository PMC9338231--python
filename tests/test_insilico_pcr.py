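"""Binding-site search against a brute-force two-strand Hamming oracle, and
amplicon prediction invariants."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flymplex.insilico_pcr import (
    DEFAULT_POLICY,
    MismatchPolicy,
    amplicons_to_tsv,
    find_binding_sites,
    simulate_multiplex,
    simulate_pcr,
)
from flymplex.seq_core import (
    IUPAC_SETS,
    Panel,
    PanelEntry,
    Primer,
    SeqRecord,
    reverse_complement,
)


def _oracle_sites(primer_seq, template_seq, policy):
    """Sliding-window IUPAC-Hamming scan on both strands (independent path)."""
    out = []
    lp = len(primer_seq)
    w = min(policy.three_prime_window, lp)

    def match(t, p):
        return bool(IUPAC_SETS[t] & IUPAC_SETS[p])

    for strand, probe in (("plus", primer_seq), ("minus", reverse_complement(primer_seq))):
        for off in range(len(template_seq) - lp + 1):
            miss = [
                i for i in range(lp) if not match(template_seq[off + i], probe[i])
            ]
            if strand == "plus":
                mm3 = sum(1 for i in miss if i >= lp - w)
            else:
                mm3 = sum(1 for i in miss if i < w)
            if len(miss) <= policy.max_total and mm3 <= policy.max_3prime:
                out.append((strand, off, len(miss), mm3))
    return sorted(out, key=lambda s: (s[1], s[0] != "plus"))


def _as_tuples(sites):
    return sorted(
        [(s.strand, s.start, s.mismatches, s.mismatches_3p) for s in sites],
        key=lambda s: (s[1], s[0] != "plus"),
    )


def _primer(seq, name="p"):
    return Primer(name=name, sequence=seq)


class TestFindBindingSites:
    def test_exact_embed_plus(self):
        primer = _primer("GCTGTGACTTTGTTACAG")
        t = "A" * 100 + primer.sequence + "C" * 50
        sites = find_binding_sites(primer, SeqRecord(id="t", sequence=t))
        assert [(s.strand, s.start, s.end) for s in sites] == [("plus", 100, 118)]

    def test_reverse_complement_embed_minus(self):
        primer = _primer("GCTGTGACTTTGTTACAG")
        t = "A" * 40 + reverse_complement(primer.sequence) + "C" * 40
        sites = find_binding_sites(primer, SeqRecord(id="t", sequence=t))
        assert [(s.strand, s.start) for s in sites] == [("minus", 40)]

    def test_primer_longer_than_template(self):
        primer = _primer("GCTGTGACTTTGTTACAG")
        assert find_binding_sites(primer, SeqRecord(id="t", sequence="ACGT")) == []

    def test_3prime_mismatch_blocks_site(self):
        primer = _primer("GCTGTGACTTTGTTACAG")
        exact = "T" * 30 + primer.sequence + "T" * 30
        mutated = exact[:30 + 17] + "C" + exact[30 + 18:]  # 3'-terminal base
        assert find_binding_sites(primer, SeqRecord(id="t", sequence=exact))
        assert not find_binding_sites(primer, SeqRecord(id="t", sequence=mutated))

    def test_oracle_equivalence_random_instances(self):
        """>=200 random (primer, template, policy) cases match the oracle."""
        rng = random.Random(123)
        policies = [
            MismatchPolicy(0, 5, 0),
            MismatchPolicy(2, 5, 0),
            MismatchPolicy(2, 5, 1),
            MismatchPolicy(3, 3, 2),
        ]
        for case in range(220):
            lp = rng.randint(15, 24)
            primer = _primer("".join(rng.choice("ACGT") for _ in range(lp)))
            tlen = rng.randint(50, 300)
            tmpl = "".join(rng.choice("ACGT") for _ in range(tlen))
            # half the cases: embed a (possibly mutated) copy of the primer
            if case % 2:
                probe = list(primer.sequence)
                for _ in range(rng.randint(0, 3)):
                    probe[rng.randrange(lp)] = rng.choice("ACGT")
                probe = "".join(probe)
                if rng.random() < 0.5:
                    probe = reverse_complement(probe)
                pos = rng.randint(0, tlen - lp)
                tmpl = tmpl[:pos] + probe + tmpl[pos + lp:]
            policy = rng.choice(policies)
            got = _as_tuples(
                find_binding_sites(primer, SeqRecord(id="t", sequence=tmpl), policy)
            )
            assert got == _oracle_sites(primer.sequence, tmpl, policy)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=30)
    def test_policy_relaxation_monotone(self, seed):
        rng = random.Random(seed)
        primer = _primer("".join(rng.choice("ACGT") for _ in range(18)))
        tmpl = SeqRecord(
            id="t", sequence="".join(rng.choice("ACGT") for _ in range(250))
        )
        tight = {
            (s.strand, s.start)
            for s in find_binding_sites(primer, tmpl, MismatchPolicy(1, 5, 0))
        }
        loose = {
            (s.strand, s.start)
            for s in find_binding_sites(primer, tmpl, MismatchPolicy(3, 5, 0))
        }
        assert tight <= loose


class TestSimulatePcr:
    def test_capitata_fixture_single_product(self, panel, species_templates):
        amps = simulate_pcr(panel, species_templates["capitata"])
        assert len(amps) == 1
        assert amps[0].length == 327
        assert amps[0].fwd_primer == "Opsin4_capitata_F"
        assert amps[0].rev_primer == "Opsin4_capitata_R"

    def test_no_template_control(self, panel):
        ntc = SeqRecord(id="ntc", sequence="ACGT" * 30)
        assert simulate_pcr(panel, ntc) == []

    def test_two_forward_sites_pair_with_one_reverse(self, panel):
        e = panel.entry("cosyra")
        f, r = e.forward.sequence, e.reverse.sequence
        t = "TGCA" * 10 + f + "GATC" * 10 + f + "CTAG" * 20 + reverse_complement(r) + "TGCA" * 10
        amps = simulate_pcr(panel, SeqRecord(id="t", sequence=t))
        fwd_starts = sorted(a.fwd_site.start for a in amps)
        assert len(amps) == 2
        # every (plus site, downstream minus site) pair is enumerated
        assert fwd_starts == [40, 40 + len(f) + 40]

    def test_length_arithmetic(self, panel, species_templates):
        for sp, t in species_templates.items():
            for a in simulate_pcr(panel, t):
                assert a.length == len(a.sequence) == a.rev_site.end - a.fwd_site.start

    def test_strand_symmetry(self, panel, species_templates):
        for t in species_templates.values():
            flipped = SeqRecord(id=t.id, sequence=reverse_complement(t.sequence))
            a = sorted(x.length for x in simulate_pcr(panel, t))
            b = sorted(x.length for x in simulate_pcr(panel, flipped))
            assert a == b

    def test_max_len_cap(self, panel, duplex_template):
        capped = simulate_pcr(panel, duplex_template, max_len=3000)
        uncapped = simulate_pcr(panel, duplex_template, max_len=10000)
        assert sorted(a.length for a in capped) == [128, 183]
        assert len(uncapped) > len(capped)


class TestSimulateMultiplex:
    def test_five_fixture_templates(self, panel, species_templates):
        res = simulate_multiplex(panel, list(species_templates.values()))
        lengths = {tid: [a.length for a in amps] for tid, amps in res.items()}
        assert sorted(sum(lengths.values(), [])) == [128, 183, 249, 327, 676]
        assert all(len(v) == 1 for v in lengths.values())

    def test_ntc_like_template_empty(self, panel):
        res = simulate_multiplex(
            panel, [SeqRecord(id="r", sequence="ACGTTGCA" * 40)]
        )
        assert res == {"r": []}

    def test_duplex_fixture(self, panel, duplex_template):
        res = simulate_multiplex(panel, [duplex_template])
        assert sorted(a.length for a in res[duplex_template.id]) == [128, 183]

    def test_duplicate_ids_rejected(self, panel, species_templates):
        t = species_templates["capitata"]
        with pytest.raises(ValueError, match="duplicate"):
            simulate_multiplex(panel, [t, t])

    def test_tsv_serialization(self, panel, species_templates):
        res = simulate_multiplex(panel, [species_templates["capitata"]])
        tsv = amplicons_to_tsv(res)
        assert "Opsin4_capitata_F" in tsv and "\t327\t" in tsv
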