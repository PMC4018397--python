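import numpy as np
import pytest

from capmir.io import SequenceRecord, reverse_complement
from capmir.simulate import random_sequence, simulate_utrs
from capmir.targets import (
    DEFAULT_RULES,
    TargetRules,
    duplex_energy,
    duplex_score,
    scan_utr,
)

MIR = "TGGAATGTAAAGAAGTATGTAT"  # 22 nt
PERFECT_SITE = reverse_complement(MIR)


def mutate_site(mir_pos_1based: int, to_base: str | None = None) -> str:
    """Perfect site with the base facing the given miRNA position changed."""
    site = list(PERFECT_SITE)
    si = len(MIR) - mir_pos_1based  # site index pairing that miRNA position
    mir_base = MIR[mir_pos_1based - 1]
    complement = {"A": "T", "C": "G", "G": "C", "T": "A"}[mir_base]
    wobble = {"G": "T", "T": "G"}.get(mir_base)
    if to_base is None:
        to_base = next(
            b for b in "ACGT" if b not in {site[si], complement, wobble}
        )
    site[si] = to_base
    return "".join(site)


class TestDuplexScore:
    def test_perfect_site_penalty_zero(self):
        pen, aln = duplex_score(MIR, PERFECT_SITE)
        assert pen == 0.0
        assert aln == "M" * 22

    def test_wobble_at_position5_doubled(self):
        # G at miRNA position 5 facing T gives a G·U wobble, inside 2-13
        assert MIR[4] == "A"
        mir = MIR[:4] + "G" + MIR[5:]
        pen, aln = duplex_score(mir, PERFECT_SITE)
        assert pen == 1.0  # 0.5 x 2
        assert aln[4] == "G" and aln.count("M") == 21

    def test_mismatch_at_position20_not_doubled(self):
        site = mutate_site(20)
        pen, aln = duplex_score(MIR, site)
        assert pen == 1.0
        assert aln[19] == "X"

    def test_mismatch_inside_window_doubled(self):
        site = mutate_site(5)
        pen, _ = duplex_score(MIR, site)
        assert pen == 2.0

    def test_site_bulge_alignment(self):
        # insert one extra site base: best alignment bulges it out
        site = PERFECT_SITE[:5] + "A" + PERFECT_SITE[5:]
        pen, aln = duplex_score(MIR, site)
        assert aln.count("B") == 1
        assert len(aln) == 23
        assert pen >= 2.0  # at least the bulge cost

    def test_mirna_bulge_alignment(self):
        site = PERFECT_SITE[:5] + PERFECT_SITE[6:]  # one site base deleted
        pen, aln = duplex_score(MIR, site)
        assert aln.count("B") == 1
        assert len(aln) == 22

    def test_swap_symmetry_of_states(self):
        # reading the same duplex from the site strand reverses the states
        pen_a, aln_a = duplex_score(MIR, mutate_site(20))
        rules_flat = TargetRules(double_from=0, double_to=0)
        pen_f, aln_f = duplex_score(MIR, mutate_site(20), rules_flat)
        pen_r, aln_r = duplex_score(mutate_site(20), MIR, rules_flat)
        assert aln_f == aln_r[::-1]
        assert pen_f == pen_r

    def test_monotone_in_mismatch_count(self):
        pens = []
        site = list(PERFECT_SITE)
        for n_mut in range(4):
            pens.append(duplex_score(MIR, "".join(site))[0])
            # mutate one more position (outside 10-11 handling irrelevant here)
            site = list(mutate_site(14 + n_mut))
            for k in range(n_mut):
                prev = mutate_site(14 + k)
                idx = len(MIR) - (14 + k)
                site[idx] = prev[idx]
        assert pens == sorted(pens)

    def test_incompatible_window_length_rejected(self):
        with pytest.raises(ValueError):
            duplex_score(MIR, PERFECT_SITE[:10])

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            duplex_score("ACGN", "ACGT")


class TestDuplexEnergy:
    def test_fully_mismatched_is_zero(self):
        pen, aln = duplex_score("GGGG" * 5 + "GG", "GGGG" * 5 + "GG")
        assert set(aln) == {"X"}
        assert duplex_energy("GGGG" * 5 + "GG", "GGGG" * 5 + "GG", aln) == 0.0

    def test_gc_duplex_lower_than_au(self):
        gc_mir = "GCGCGCGCGCGCGCGCGCGCGC"
        au_mir = "ATATATATATATATATATATAT"
        e_gc = duplex_energy(gc_mir, reverse_complement(gc_mir), "M" * 22)
        e_au = duplex_energy(au_mir, reverse_complement(au_mir), "M" * 22)
        assert e_gc < e_au < 0

    def test_matches_stack_summation_oracle(self, rng):
        from capmir.fold import STACK_ENERGY, _PAIR_ID

        for _ in range(10):
            mir = random_sequence(20, rng)
            site = reverse_complement(mir)
            pen, aln = duplex_score(mir, site)
            # independent summation over consecutive pairs
            m = mir.replace("T", "U")
            t = site.replace("T", "U")[::-1]
            total = 0
            for p in range(19):
                a = _PAIR_ID[m[p] + t[p]]
                b = _PAIR_ID[m[p + 1] + t[p + 1]]
                total += int(STACK_ENERGY[a, b])
            assert duplex_energy(mir, site, aln) == pytest.approx(total / 100.0)


class TestScanUtr:
    def test_planted_perfect_sites_found_exactly(self):
        mir = SequenceRecord("m", MIR)
        utrs, truth = simulate_utrs([mir], n_utrs=8, mutation_count=0, seed=9)
        for utr, planted in zip(utrs, truth.sites):
            hits = [s for s in scan_utr(mir, utr) if s.penalty == 0.0]
            assert (hits[0].utr_start, hits[0].utr_end) == (
                planted["start"],
                planted["end"],
            )

    def test_one_mutation_site_scores_by_rule_table(self):
        mir = SequenceRecord("m", MIR)
        utrs, truth = simulate_utrs([mir], n_utrs=6, mutation_count=1, seed=21)
        rules = DEFAULT_RULES
        for utr, planted in zip(utrs, truth.sites):
            (pos,) = planted["mutated_positions"]
            expected = 1.0 * (2.0 if rules.double_from <= pos <= rules.double_to else 1.0)
            hits = {
                (s.utr_start, s.utr_end): s.penalty for s in scan_utr(mir, utr)
            }
            key = (planted["start"], planted["end"])
            if pos in rules.no_mismatch_positions:
                assert key not in hits  # rejected by the 10-11 rule
            else:
                assert hits[key] == expected

    def test_mutation_at_position10_rejected(self):
        mir = SequenceRecord("m", MIR)
        site = mutate_site(10)
        utr = SequenceRecord("u", "A" * 40 + site + "A" * 40)
        hits = scan_utr(mir, utr)
        assert all((s.utr_start, s.utr_end) != (40, 62) for s in hits)

    def test_short_utr_empty(self):
        mir = SequenceRecord("m", MIR)
        assert scan_utr(mir, SequenceRecord("u", "ACGT")) == []

    def test_random_utr_stringent_cutoff_mostly_empty(self, rng):
        mir = SequenceRecord("m", MIR)
        rules = TargetRules(max_penalty=0.0)
        n_hits = 0
        for i in range(10):
            utr = SequenceRecord(f"u{i}", random_sequence(300, rng))
            n_hits += len(scan_utr(mir, utr, rules))
        assert n_hits == 0

    def test_matches_naive_window_scan(self, rng):
        # the vectorized lattice must agree with scoring every window directly
        rules = TargetRules(
            max_penalty=30.0, no_mismatch_positions=(), max_consecutive_mismatches=99
        )
        for _ in range(5):
            mir = SequenceRecord("m", random_sequence(int(rng.integers(16, 23)), rng))
            utr = SequenceRecord("u", random_sequence(60, rng))
            m = len(mir.seq)
            naive = []
            for start in range(len(utr.seq)):
                for L in (m - 1, m, m + 1):
                    if L < 1 or start + L > len(utr.seq):
                        continue
                    pen, _ = duplex_score(mir.seq, utr.seq[start : start + L], rules)
                    if pen <= rules.max_penalty:
                        naive.append((start, start + L, pen))
            fast = [(s.utr_start, s.utr_end, s.penalty) for s in scan_utr(mir, utr, rules)]
            assert sorted(fast) == sorted(naive)

    def test_sites_sorted_by_penalty(self, rng):
        mir = SequenceRecord("m", MIR)
        seq = random_sequence(100, rng) + PERFECT_SITE + random_sequence(40, rng) + mutate_site(20)
        utr = SequenceRecord("u", seq)
        sites = scan_utr(mir, utr)
        pens = [s.penalty for s in sites]
        assert pens == sorted(pens)
        assert pens[0] == 0.0
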