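import numpy as np
import pandas as pd
import pytest

from tyshuffle import genome_model as gm
from tyshuffle import synthetic_data as sd

from conftest import brute_force_profile, profile_as_rows


def find_pair(genome, same_chrom=True, same_homolog=True, same_arm=None,
              same_orientation=None, family="Ty1", min_snps_between=1):
    """First element pair satisfying the geometric constraints."""
    pool = [t for t in genome.ty_elements if t.family == family]
    for i, a in enumerate(pool):
        ca = genome.chromosome(a.chromosome)
        for b in pool[i + 1 :]:
            cb = genome.chromosome(b.chromosome)
            if same_chrom and (
                a.chromosome != b.chromosome or a.homolog != b.homolog
            ):
                continue
            if not same_chrom and a.chromosome == b.chromosome:
                continue
            if same_arm is True and a.arm(ca) != b.arm(cb):
                continue
            if same_arm is False and a.arm(ca) == b.arm(cb):
                continue
            if same_orientation is True and a.orientation != b.orientation:
                continue
            if same_orientation is False and a.orientation == b.orientation:
                continue
            if same_chrom and min_snps_between:
                lo = min(a.end, b.end) + 1
                hi = max(a.start, b.start) - 1
                if hi < lo or genome.count_snps_between(a.chromosome, lo, hi) < min_snps_between:
                    continue
            return (a, b) if a.start < b.start or a.chromosome != b.chromosome else (b, a)
    raise AssertionError("no pair with requested geometry in fixture genome")


def snp_interval_dosage(genome, profile, chromosome, lo, hi):
    sub = profile[(profile.chromosome == chromosome)
                  & (profile.position >= lo) & (profile.position <= hi)]
    return sub


class TestSsaPopout:
    def test_molecule_shortened_by_internal_span(self, mini_genome, baseline):
        ty = next(t for t in mini_genome.ty_elements if t.family == "Ty1")
        before = sum(s.length for m in baseline.molecules for s in m.segments)
        k2, event = sd.apply_ssa_popout(baseline, ty)
        after = sum(s.length for m in k2.molecules for s in m.segments)
        assert before - after == ty.span - sd.SOLO_DELTA_LENGTH
        assert event.expected_call_class == "silent"

    def test_double_popout_rejected(self, mini_genome, baseline):
        ty = next(t for t in mini_genome.ty_elements if t.family == "Ty1")
        k2, _ = sd.apply_ssa_popout(baseline, ty)
        with pytest.raises(ValueError, match="already popped"):
            sd.apply_ssa_popout(k2, ty)

    def test_solo_delta_rejected(self, mini_genome, baseline):
        solo = gm.TyElement("d", "solo_delta", "Watson", "W", "I", 50, 380)
        with pytest.raises(ValueError, match="solo delta"):
            sd.apply_ssa_popout(baseline, solo)

    def test_profile_unchanged(self, mini_genome, baseline):
        ty = next(t for t in mini_genome.ty_elements if t.family == "Ty1")
        k2, _ = sd.apply_ssa_popout(baseline, ty)
        assert profile_as_rows(sd.copy_number_profile(k2)) == brute_force_profile(k2)
        prof = sd.copy_number_profile(k2)
        assert (prof.W_copies == 1).all() and (prof.Y_copies == 1).all()


class TestUnequalCrossover:
    def test_deletion_zeroes_interval(self, mini_genome, baseline):
        a, b = find_pair(mini_genome, same_arm=True, same_orientation=True)
        k2, event = sd.apply_unequal_xover(baseline, a, b, keep="del")
        assert event.expected_call_class == "I-DEL"
        prof = sd.copy_number_profile(k2)
        (lo, hi) = event.call_spans[0][0]
        inside = snp_interval_dosage(mini_genome, prof, a.chromosome, lo, hi)
        col = "W_copies" if a.homolog == "W" else "Y_copies"
        assert (inside[col] == 0).all()
        outside = prof[(prof.chromosome != a.chromosome)]
        assert (outside.W_copies == 1).all() and (outside.Y_copies == 1).all()

    def test_duplication_doubles_interval(self, mini_genome, baseline):
        a, b = find_pair(mini_genome, same_arm=True, same_orientation=True)
        k2, event = sd.apply_unequal_xover(baseline, a, b, keep="dup")
        assert event.expected_call_class == "I-DUP"
        prof = sd.copy_number_profile(k2)
        (lo, hi) = event.call_spans[0][0]
        inside = snp_interval_dosage(mini_genome, prof, a.chromosome, lo, hi)
        col = "W_copies" if a.homolog == "W" else "Y_copies"
        assert (inside[col] == 2).all()

    def test_opposite_orientation_rejected(self, mini_genome, baseline):
        a, b = find_pair(mini_genome, same_arm=True, same_orientation=False)
        with pytest.raises(ValueError, match="orientation"):
            sd.apply_unequal_xover(baseline, a, b, keep="del")

    def test_zero_snp_interval_is_silent(self):
        # custom genome: adjacent direct pair with no SNP in between
        genome = gm.DiploidGenome(
            chromosomes=[gm.ChromosomeDef("I", 200_000, 90_000, 90_200)],
            snps=[gm.SnpDef("I", 5_000, "A", "C"), gm.SnpDef("I", 150_000, "G", "T")],
            ty_elements=[
                gm.TyElement("a", "Ty1", "Watson", "W", "I", 100_000, 105_999, True),
                gm.TyElement("b", "Ty1", "Watson", "W", "I", 110_000, 115_999, True),
            ],
        )
        a, b = genome.ty_elements
        k2, event = sd.apply_unequal_xover(
            sd.baseline_karyotype(genome), a, b, keep="del"
        )
        assert event.expected_call_class == "silent"
        assert event.expected_calls == []

    def test_brute_force_oracle(self, mini_genome, baseline):
        a, b = find_pair(mini_genome, same_arm=True, same_orientation=True)
        k2, _ = sd.apply_unequal_xover(baseline, a, b, keep="dup")
        assert profile_as_rows(sd.copy_number_profile(k2)) == brute_force_profile(k2)


class TestCircle:
    def test_double_terminal_deletion(self, mini_genome, baseline):
        a, b = find_pair(mini_genome, same_arm=False, same_orientation=True)
        k2, event = sd.apply_intrachromatid_circle(baseline, a, b)
        assert event.expected_call_class == "CIRCLE"
        prof = sd.copy_number_profile(k2)
        col = "W_copies" if a.homolog == "W" else "Y_copies"
        for lo, hi in event.call_spans[0]:
            sub = snp_interval_dosage(mini_genome, prof, a.chromosome, lo, hi)
            assert (sub[col] == 0).all()

    def test_circle_has_one_centromere(self, mini_genome, baseline):
        a, b = find_pair(mini_genome, same_arm=False, same_orientation=True)
        k2, _ = sd.apply_intrachromatid_circle(baseline, a, b)
        circle = next(m for m in k2.molecules if m.circular)
        assert circle.centromere_count(mini_genome) == 1

    def test_lost_dosage_equals_distal_snps(self, mini_genome, baseline):
        a, b = find_pair(mini_genome, same_arm=False, same_orientation=True)
        before = sd.copy_number_profile(baseline)
        k2, event = sd.apply_intrachromatid_circle(baseline, a, b)
        after = sd.copy_number_profile(k2)
        lost = int((before.W_copies + before.Y_copies).sum()
                   - (after.W_copies + after.Y_copies).sum())
        distal = sum(
            mini_genome.count_snps_between(a.chromosome, lo, hi)
            for lo, hi in event.call_spans[0]
        )
        assert lost == distal

    def test_same_arm_rejected(self, mini_genome, baseline):
        a, b = find_pair(mini_genome, same_arm=True, same_orientation=True)
        with pytest.raises(ValueError, match="opposite arms"):
            sd.apply_intrachromatid_circle(baseline, a, b)


class TestIsochromosome:
    def _pair(self, genome):
        return find_pair(genome, same_arm=False, same_orientation=False)

    def test_mirror_dosage(self, mini_genome, baseline):
        a, b = self._pair(mini_genome)
        k2, event = sd.apply_isochromosome(baseline, a, b)
        assert event.expected_call_class == "ISO"
        prof = sd.copy_number_profile(k2)
        col = "W_copies" if a.homolog == "W" else "Y_copies"
        (dup_lo, dup_hi), (del_lo, del_hi) = event.call_spans[0]
        dup = snp_interval_dosage(mini_genome, prof, a.chromosome, dup_lo, dup_hi)
        dele = snp_interval_dosage(mini_genome, prof, a.chromosome, del_lo, del_hi)
        mid = snp_interval_dosage(mini_genome, prof, a.chromosome,
                                  dup_hi + 1, del_lo - 1)
        assert (dup[col] == 2).all()
        assert (dele[col] == 0).all()
        assert (mid[col] == 1).all()

    def test_single_centromere(self, mini_genome, baseline):
        a, b = self._pair(mini_genome)
        k2, _ = sd.apply_isochromosome(baseline, a, b)
        k2.validate()

    def test_same_arm_rejected(self, mini_genome, baseline):
        a, b = find_pair(mini_genome, same_arm=True, same_orientation=False)
        with pytest.raises(ValueError, match="opposite arms"):
            sd.apply_isochromosome(baseline, a, b)

    def test_oracle(self, mini_genome, baseline):
        a, b = self._pair(mini_genome)
        k2, _ = sd.apply_isochromosome(baseline, a, b)
        assert profile_as_rows(sd.copy_number_profile(k2)) == brute_force_profile(k2)


class TestInversion:
    def _pair(self, genome):
        return find_pair(genome, same_arm=True, same_orientation=False)

    def test_dosage_silent(self, mini_genome, baseline):
        a, b = self._pair(mini_genome)
        k2, event = sd.apply_inversion(baseline, a, b)
        assert event.expected_call_class == "silent"
        prof = sd.copy_number_profile(k2)
        assert (prof.W_copies == 1).all() and (prof.Y_copies == 1).all()

    def test_involution(self, mini_genome, baseline):
        a, b = self._pair(mini_genome)
        k2, _ = sd.apply_inversion(baseline, a, b)
        k3, _ = sd.apply_inversion(k2, a, b)
        original = [m.segments for m in baseline.molecules]
        restored = [m.segments for m in k3.molecules]
        assert restored == original

    def test_two_novel_adjacencies(self, mini_genome, baseline):
        a, b = self._pair(mini_genome)
        k2, _ = sd.apply_inversion(baseline, a, b)
        novel = k2.adjacencies() - baseline.adjacencies()
        assert len(novel) == 2

    def test_direct_orientation_rejected(self, mini_genome, baseline):
        a, b = find_pair(mini_genome, same_arm=True, same_orientation=True)
        with pytest.raises(ValueError, match="inverted"):
            sd.apply_inversion(baseline, a, b)


class TestTranslocation:
    def _pair(self, genome):
        return find_pair(genome, same_chrom=False, same_arm=True)

    def test_unbalanced_dup_and_del(self, mini_genome, baseline):
        a, b = self._pair(mini_genome)
        k2, event = sd.apply_translocation(baseline, a, b, "unbalanced")
        assert event.expected_calls == [
            ("T-DUP", a.chromosome),
            ("T-DEL", b.chromosome),
        ]
        prof = sd.copy_number_profile(k2)
        col_a = "W_copies" if a.homolog == "W" else "Y_copies"
        col_b = "W_copies" if b.homolog == "W" else "Y_copies"
        (dup_lo, dup_hi) = event.call_spans[0][0]
        (del_lo, del_hi) = event.call_spans[1][0]
        dup = snp_interval_dosage(mini_genome, prof, a.chromosome, dup_lo, dup_hi)
        dele = snp_interval_dosage(mini_genome, prof, b.chromosome, del_lo, del_hi)
        assert (dup[col_a] == 2).all()
        assert (dele[col_b] == 0).all()

    def test_balanced_is_dosage_silent(self, mini_genome, baseline):
        a, b = self._pair(mini_genome)
        k2, event = sd.apply_translocation(baseline, a, b, "balanced")
        assert event.expected_call_class == "silent"
        prof = sd.copy_number_profile(k2)
        assert (prof.W_copies == 1).all() and (prof.Y_copies == 1).all()
        k2.validate()

    def test_recombinant_size_oracle(self, mini_genome, baseline):
        a, b = self._pair(mini_genome)
        k2, event = sd.apply_translocation(baseline, a, b, "balanced")
        pa = dict(event.true_breakpoints)[a.chromosome]
        pb = dict(event.true_breakpoints)[b.chromosome]
        la = mini_genome.chromosome(a.chromosome).length
        lb = mini_genome.chromosome(b.chromosome).length
        expected_sizes = {pa + (lb - pb), pb + (la - pa)}
        recombinants = {
            sum(s.length for s in m.segments)
            for m in k2.molecules
            if len({seg.chromosome for seg in m.segments}) > 1
        }
        assert recombinants == expected_sizes

    def test_same_chromosome_rejected(self, mini_genome, baseline):
        a, b = find_pair(mini_genome, same_chrom=True)
        with pytest.raises(ValueError, match="same chromosome"):
            sd.apply_translocation(baseline, a, b, "unbalanced")


class TestAllelicEvents:
    def test_crossover_terminal_loh(self, mini_genome, baseline):
        chrom = mini_genome.chromosome("IV")
        pos = int(mini_genome.snp_positions("IV")[-30])
        k2, event = sd.apply_allelic_event(
            baseline, "IV", pos, "crossover", lost_homolog="W"
        )
        assert event.expected_call_class == "T-LOH"
        prof = sd.copy_number_profile(k2)
        distal = prof[(prof.chromosome == "IV") & (prof.position > pos)]
        assert (distal.W_copies == 0).all() and (distal.Y_copies == 2).all()

    def test_conversion_interstitial(self, mini_genome, baseline):
        pos = int(mini_genome.snp_positions("IV")[20])
        k2, event = sd.apply_allelic_event(
            baseline, "IV", pos - 1, "conversion", tract_len=10_000,
            lost_homolog="Y",
        )
        assert event.expected_call_class == "I-LOH"
        prof = sd.copy_number_profile(k2)
        (lo, hi) = event.call_spans[0][0]
        inside = prof[(prof.chromosome == "IV")
                      & prof.position.between(lo, hi)]
        outside = prof[(prof.chromosome == "IV")
                       & ~prof.position.between(lo, hi)]
        assert (inside.Y_copies == 0).all() and (inside.W_copies == 2).all()
        assert (outside.Y_copies == 1).all() and (outside.W_copies == 1).all()

    def test_tract_clipped_at_telomere_relabeled(self, mini_genome, baseline):
        chrom = mini_genome.chromosome("I")
        pos = chrom.length - 5_000
        k2, event = sd.apply_allelic_event(
            baseline, "I", pos, "conversion", tract_len=50_000, lost_homolog="W"
        )
        assert event.expected_call_class in {"T-LOH", "silent"}

    @pytest.mark.parametrize("kind", ["crossover", "BIR", "conversion"])
    def test_dosage_conservation(self, mini_genome, baseline, kind):
        pos = int(mini_genome.snp_positions("X")[40])
        kwargs = {"tract_len": 20_000} if kind == "conversion" else {}
        k2, _ = sd.apply_allelic_event(baseline, "X", pos, kind,
                                       lost_homolog="W", **kwargs)
        prof = sd.copy_number_profile(k2)
        assert ((prof.W_copies + prof.Y_copies) == 2).all()


class TestAneuploidy:
    def test_monosomy(self, mini_genome, baseline):
        k2, event = sd.apply_aneuploidy(baseline, "III", "monosomy", "W")
        prof = sd.copy_number_profile(k2)
        iii = prof[prof.chromosome == "III"]
        assert (iii.W_copies == 0).all() and (iii.Y_copies == 1).all()

    def test_monosomy_twice_rejected(self, mini_genome, baseline):
        k2, _ = sd.apply_aneuploidy(baseline, "III", "monosomy", "W")
        with pytest.raises(ValueError):
            sd.apply_aneuploidy(k2, "III", "monosomy", "W")

    def test_upd_conserves_total(self, mini_genome, baseline):
        k2, _ = sd.apply_aneuploidy(baseline, "V", "UPD", "Y")
        prof = sd.copy_number_profile(k2)
        v = prof[prof.chromosome == "V"]
        rest = prof[prof.chromosome != "V"]
        assert (v.W_copies == 0).all() and (v.Y_copies == 2).all()
        assert (rest.W_copies == 1).all() and (rest.Y_copies == 1).all()

    def test_trisomy_then_monosomy_restores(self, mini_genome, baseline):
        before = profile_as_rows(sd.copy_number_profile(baseline))
        k2, _ = sd.apply_aneuploidy(baseline, "VII", "trisomy", "Y")
        k3, _ = sd.apply_aneuploidy(k2, "VII", "monosomy", "Y")
        assert profile_as_rows(sd.copy_number_profile(k3)) == before


class TestSimulateIsolate:
    def test_zero_events(self, mini_genome):
        params = sd.SimParams(seed=1)
        k, truth = sd.simulate_isolate(mini_genome, params, 0)
        assert truth == []
        prof = sd.copy_number_profile(k)
        assert (prof.W_copies == 1).all() and (prof.Y_copies == 1).all()

    def test_three_events(self, mini_genome):
        params = sd.SimParams(seed=2)
        k, truth = sd.simulate_isolate(mini_genome, params, 3)
        assert len(truth) == 3
        assert profile_as_rows(sd.copy_number_profile(k)) != profile_as_rows(
            sd.copy_number_profile(sd.baseline_karyotype(mini_genome))
        ) or all(t.expected_call_class == "silent" for t in truth)

    def test_deterministic(self, mini_genome):
        params = sd.SimParams(seed=3)
        _, t1 = sd.simulate_isolate(mini_genome, params, 3)
        _, t2 = sd.simulate_isolate(mini_genome, params, 3)
        assert t1 == t2

    def test_expected_class_mapping_total(self, mini_genome):
        # every produced mechanism maps to exactly one call class or silent
        valid = {"I-LOH", "T-LOH", "I-DEL", "I-DUP", "T-DEL", "T-DUP",
                 "CIRCLE", "ISO", "MONOSOMY", "TRISOMY", "UPD",
                 "T-DUP+T-DEL", "silent"}
        rng = np.random.default_rng(0)
        params = sd.SimParams(seed=0)
        for _ in range(10):
            _, truth = sd.simulate_isolate(mini_genome, params, 3, rng=rng)
            for t in truth:
                assert t.expected_call_class in valid

    def test_negative_events_rejected(self, mini_genome):
        with pytest.raises(ValueError):
            sd.simulate_isolate(mini_genome, sd.SimParams(), -1)


class TestCopyNumberProfile:
    def test_baseline_all_heterozygous(self, baseline):
        prof = sd.copy_number_profile(baseline)
        assert (prof.W_copies == 1).all() and (prof.Y_copies == 1).all()

    def test_random_karyotype_matches_brute_force(self, mini_genome):
        rng = np.random.default_rng(9)
        params = sd.SimParams(seed=9)
        k, _ = sd.simulate_isolate(mini_genome, params, 5, rng=rng)
        assert profile_as_rows(sd.copy_number_profile(k)) == brute_force_profile(k)


class TestConservationBySignature:
    """W+Y copy sums per event family."""

    def test_allelic_and_upd_preserve_sum(self, mini_genome, baseline):
        pos = int(mini_genome.snp_positions("II")[50])
        for kind in ("crossover", "BIR"):
            k2, _ = sd.apply_allelic_event(baseline, "II", pos, kind,
                                           lost_homolog="Y")
            prof = sd.copy_number_profile(k2)
            assert ((prof.W_copies + prof.Y_copies) == 2).all()
        k2, _ = sd.apply_aneuploidy(baseline, "II", "UPD", "W")
        prof = sd.copy_number_profile(k2)
        assert ((prof.W_copies + prof.Y_copies) == 2).all()

    def test_del_dup_change_sum_by_one_over_span(self, mini_genome, baseline):
        a, b = find_pair(mini_genome, same_arm=True, same_orientation=True)
        for keep, delta in (("del", -1), ("dup", 1)):
            k2, event = sd.apply_unequal_xover(baseline, a, b, keep=keep)
            prof = sd.copy_number_profile(k2)
            (lo, hi) = event.call_spans[0][0]
            inside = prof[(prof.chromosome == a.chromosome)
                          & prof.position.between(lo, hi)]
            assert ((inside.W_copies + inside.Y_copies) == 2 + delta).all()


class TestSnpCounts:
    def test_mean_rc_near_half_at_baseline(self, mini_genome, baseline):
        params = sd.SimParams(mean_depth=40, seed=11)
        counts = sd.synthesize_snp_counts(sd.copy_number_profile(baseline), params)
        site_mean = counts.groupby(["chromosome", "position"]).read_count.sum().mean()
        rc = counts.read_count / site_mean
        assert 0.48 <= rc.mean() <= 0.52

    def test_zero_copy_draws_zero(self, mini_genome, baseline):
        k2, _ = sd.apply_aneuploidy(baseline, "III", "monosomy", "W")
        params = sd.SimParams(mean_depth=40, seed=12)
        counts = sd.synthesize_snp_counts(sd.copy_number_profile(k2), params)
        gone = counts[(counts.chromosome == "III") & (counts.parental_class == "W")]
        assert (gone.read_count == 0).all()

    def test_depth_doubling_halves_cv(self, mini_genome, baseline):
        prof = sd.copy_number_profile(baseline)
        cvs = {}
        for depth in (40.0, 80.0):
            params = sd.SimParams(mean_depth=depth, seed=13)
            counts = sd.synthesize_snp_counts(prof, params)
            rc = counts.read_count / counts.read_count.mean()
            cvs[depth] = rc.std() / rc.mean()
        # Poisson: CV scales as 1/sqrt(depth)
        ratio = cvs[80.0] / cvs[40.0]
        assert abs(ratio - 1 / np.sqrt(2)) < 0.1 / np.sqrt(2)

    def test_negative_binomial_overdisperses(self, mini_genome, baseline):
        prof = sd.copy_number_profile(baseline)
        pois = sd.synthesize_snp_counts(prof, sd.SimParams(mean_depth=40, seed=14))
        nb = sd.synthesize_snp_counts(
            prof, sd.SimParams(mean_depth=40, seed=14,
                               depth_noise="negative_binomial", nb_dispersion=5.0)
        )
        assert nb.read_count.var() > pois.read_count.var()


class TestTyReads:
    def test_no_miscall_unanimous(self):
        mat = sd.synthesize_ty_reads(range(100, 2000, 100), (500, 900), 700,
                                     n_reads=10, miscall=0.0, seed=1)
        for j in range(mat.calls.shape[1]):
            assert len(set(mat.calls[:, j])) == 1

    def test_unanimous_fraction_closed_form(self):
        n_reads, miscall = 15, 0.1
        positions = list(range(0, 60_000, 10))
        mat = sd.synthesize_ty_reads(positions, None, 0, n_reads=n_reads,
                                     miscall=miscall, seed=2)
        unanimous = sum(
            len(set(mat.calls[:, j])) == 1 for j in range(mat.calls.shape[1])
        ) / mat.calls.shape[1]
        expected = (1 - miscall) ** n_reads + miscall**n_reads
        se = np.sqrt(expected * (1 - expected) / len(positions))
        assert abs(unanimous - expected) < 5 * se

    def test_empty_tract_all_parent_a(self):
        mat = sd.synthesize_ty_reads(range(100, 1000, 100), (5000, 6000), 700,
                                     n_reads=5, miscall=0.0, seed=3)
        assert (mat.calls == "A").all()

    def test_matrix_invariants(self):
        with pytest.raises(ValueError, match="increasing"):
            sd.TyReadMatrix(positions=[5, 5], calls=[["A", "B"]], dsb_offset=1)
        with pytest.raises(ValueError, match="non-missing"):
            sd.TyReadMatrix(positions=[1, 2], calls=[[".", "."]], dsb_offset=1)


class TestFluctuation:
    def test_zero_rate(self):
        exp = sd.simulate_fluctuation(0.0, 2**16, 50, seed=1)
        assert (exp.counts == 0).all()

    def test_deterministic(self):
        a = sd.simulate_fluctuation(1e-5, 2**18, 100, seed=2)
        b = sd.simulate_fluctuation(1e-5, 2**18, 100, seed=2)
        assert (a.counts == b.counts).all()

    def test_heavy_tail_mean_exceeds_median(self):
        exp = sd.simulate_fluctuation(1e-5, 2**20, 1000, seed=3)
        assert exp.counts.mean() > np.median(exp.counts)

    def test_against_per_lineage_oracle(self):
        """Independent oracle: mutations arise Poisson per generation and
        expand deterministically 2^(G-g-1); compare distribution means."""
        rate, generations, n = 2e-4, 12, 3000
        rng = np.random.default_rng(7)
        oracle_counts = np.zeros(n)
        for i in range(n):
            total = 0
            for g in range(generations):
                new = rng.poisson(rate * 2**g)
                total += new * 2 ** (generations - g - 1)
            oracle_counts[i] = total
        exp = sd.simulate_fluctuation(rate, 2**generations, n, seed=8)
        assert abs(exp.counts.mean() - oracle_counts.mean()) < 0.25 * max(
            oracle_counts.mean(), 1.0
        )

    def test_non_power_of_two_rounds_up(self):
        exp = sd.simulate_fluctuation(0.0, 1000, 5, seed=1)
        assert exp.n_final == 1024


class TestSerializationRoundTrips:
    def test_counts_round_trip(self, mini_genome, baseline, tmp_path):
        params = sd.SimParams(mean_depth=30, seed=5)
        counts = sd.synthesize_snp_counts(sd.copy_number_profile(baseline), params)
        path = tmp_path / "counts.tsv"
        sd.write_counts_table(counts, path)
        back = sd.read_counts_table(path)
        pd.testing.assert_frame_equal(
            back, counts[["chromosome", "position", "parental_class", "read_count"]],
            check_dtype=False,
        )

    def test_truth_round_trip(self, mini_genome, tmp_path):
        rng = np.random.default_rng(6)
        _, truth = sd.simulate_isolate(mini_genome, sd.SimParams(seed=6), 3, rng=rng)
        path = tmp_path / "truth.tsv"
        sd.write_truth(truth, path)
        back = sd.read_truth(path)
        assert back == truth

    def test_corrupt_counts_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chromosome\tposition\tparental_class\tread_count\n"
                        "I\t100\tW\t-3\n")
        with pytest.raises(ValueError, match="line 2"):
            sd.read_counts_table(path)


class TestKaryotypeValidation:
    def test_baseline_validates(self, baseline):
        baseline.validate()

    def test_dicentric_flagged(self, mini_genome, baseline):
        # stitch two centromere-containing molecules together manually
        m = baseline.molecules
        bad = sd.DerivedChromosome("bad", m[0].segments + m[2].segments)
        k = sd.Karyotype(genome=mini_genome, molecules=[bad])
        with pytest.raises(ValueError, match="dicentric"):
            k.validate()
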