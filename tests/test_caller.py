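import itertools

import pytest

from qfpcr.caller import (
    CallerError,
    MarkerCall,
    call_chromosome,
    call_marker,
    call_sample,
    call_sex,
    detect_mcc,
    detect_triploidy,
    triage_category_map,
    triage_mcc,
)
from qfpcr.genotyping import preprocess
from qfpcr.simulate import SimulationConfig, simulate_batch, simulate_sample
from qfpcr.tables import PeakRecord


def geno(marker, *pairs, sample="S"):
    peaks = [PeakRecord(size=s, height=h, marker=marker) for s, h in pairs]
    return preprocess(sample, marker, peaks)


def genotypes_of(sample):
    return {
        m: preprocess(sample.sample_id, m, pk)
        for m, pk in sample.peaks.items()
        if pk
    }


def mk_call(status, marker="M", chrom="13"):
    return MarkerCall(marker, chrom, status)


class TestCallMarker:
    def test_balanced_triallelic_is_trisomic(self, model):
        obs = geno("D21S11", (220.0, 1500), (228.0, 1480), (236.0, 1390))
        call = call_marker(obs, model, "21")
        assert call.status == "trisomic_triallelic"

    def test_unbalanced_triallelic_is_suspicious(self, model):
        obs = geno("D21S11", (220.0, 1500), (228.0, 300), (236.0, 1390))
        assert call_marker(obs, model, "21").status == "suspicious_multiallelic"

    def test_single_peak_uninformative(self, model):
        assert call_marker(geno("D13S258", (240.0, 900)), model, "13").status == \
            "uninformative_homozygous"

    def test_four_peaks_flagged(self, model):
        obs = geno("D13S258", (240.0, 900), (244.0, 850), (250.0, 400), (256.0, 380))
        assert call_marker(obs, model, "13").status == "suspicious_multiallelic"

    def test_simulated_trisomic_diallelic(self, model):
        cfg = SimulationConfig(karyotype="T21")
        found = 0
        for s in simulate_batch(30, cfg, seed=42):
            for m in ("D21S11", "D21S1411", "D21S1435", "D21S1270"):
                g = genotypes_of(s).get(m)
                if g is None or g.pattern != "diallelic":
                    continue
                doses = sorted(s.fetal_alleles[m].values())
                if doses == [1, 2]:
                    status = call_marker(g, model, "21",
                                         decay_lines=model.decay_lines).status
                    assert status in ("trisomic_diallelic_2_1",
                                      "trisomic_diallelic_1_2")
                    found += 1
        assert found > 10


class TestCallChromosome:
    def test_all_homozygous_needs_backup(self):
        calls = [mk_call("uninformative_homozygous", f"M{i}") for i in range(3)]
        cc = call_chromosome("13", calls)
        assert cc.verdict == "inconclusive_needs_backup"
        assert "backup" in cc.note

    def test_two_trisomic_with_homozygous_rest_is_trisomy(self):
        calls = [
            mk_call("trisomic_triallelic", "Ma", "21"),
            mk_call("trisomic_diallelic_2_1", "Mb", "21"),
            mk_call("uninformative_homozygous", "Mc", "21"),
            mk_call("uninformative_homozygous", "Md", "21"),
        ]
        cc = call_chromosome("21", calls)
        assert cc.verdict == "trisomy"
        assert cc.informative_count == 2

    def test_single_informative_insufficient(self):
        calls = [mk_call("normal_heterozygous", "Ma"),
                 mk_call("uninformative_homozygous", "Mb")]
        cc = call_chromosome("13", calls)
        assert cc.verdict == "insufficient_informative"

    def test_discordant_markers_never_majority_voted(self):
        calls = [
            mk_call("normal_heterozygous", "Ma"),
            mk_call("trisomic_diallelic_2_1", "Mb"),
            mk_call("trisomic_triallelic", "Mc"),
        ]
        assert call_chromosome("18", calls).verdict == "mcc_suspected"

    def test_no_calls_is_error(self):
        with pytest.raises(CallerError):
            call_chromosome("13", [])

    def test_verdict_requires_two_informative(self):
        """No trisomy/normal verdict is ever issued with < 2 informative."""
        statuses = [
            "normal_heterozygous", "trisomic_triallelic",
            "uninformative_homozygous", "uninformative_absent",
        ]
        for combo in itertools.product(statuses, repeat=3):
            cc = call_chromosome("13", [mk_call(s, f"M{i}")
                                        for i, s in enumerate(combo)])
            informative = sum(s in ("normal_heterozygous", "trisomic_triallelic")
                              for s in combo)
            if cc.verdict in ("normal", "trisomy"):
                assert informative >= 2


class TestCallSex:
    @pytest.mark.parametrize(
        "karyotype,label",
        [("46XY", "XY"), ("46XX", "XX"), ("XXY", "XXY"), ("X0", "X0"),
         ("XXX", "XXX"), ("XYY", "XYY")],
    )
    def test_karyotype_recovery(self, panel, karyotype, label):
        cfg = SimulationConfig(karyotype=karyotype)
        hits = 0
        n = 25
        for s in simulate_batch(n, cfg, seed=500):
            sc = call_sex(genotypes_of(s), panel)
            hits += sc.karyotype_label == label
        assert hits >= round(0.95 * n)

    def test_sry_amelogenin_conflict_undetermined(self, panel):
        obs = {
            "SRY": geno("SRY", (463.0, 800)),
            "AMELX/Y": geno("AMELX/Y", (104.0, 1500)),  # X only
        }
        sc = call_sex(obs, panel)
        assert sc.sex == "undetermined"
        assert "SRY" in sc.note

    def test_needs_some_sex_evidence(self, panel):
        with pytest.raises(CallerError):
            call_sex({}, panel)


class TestTriploidy:
    @staticmethod
    def chrom_calls(verdicts):
        return {
            c: call_chromosome(c, [mk_call(
                "trisomic_triallelic" if v == "trisomy" else "normal_heterozygous",
                f"M{i}", c) for i in range(2)])
            for c, v in verdicts.items()
        }

    def test_fires_iff_all_evaluable_trisomic(self):
        for verdicts in itertools.product(["normal", "trisomy"], repeat=3):
            calls = self.chrom_calls(dict(zip(("13", "18", "21"), verdicts)))
            expected = all(v == "trisomy" for v in verdicts)
            assert detect_triploidy(calls) == expected

    def test_simulated_triploid_flagged(self, model, panel):
        cfg = SimulationConfig(karyotype="69XXX")
        flagged = 0
        for s in simulate_batch(10, cfg, seed=9):
            rep = call_sample(s.sample_id, genotypes_of(s), panel, model)
            flagged += rep.triploidy_flag
        assert flagged >= 9


class TestDetectMcc:
    def test_admixture_detected_and_clean_sample_clean(self, panel):
        for frac, want in ((0.0, "clean"), (0.2, "contaminated")):
            cfg = SimulationConfig(karyotype="46XY", mcc_fraction=frac)
            hits = 0
            for s in simulate_batch(20, cfg, seed=33):
                res = detect_mcc(genotypes_of(s), s.maternal_profile, panel)
                hits += res.status == want
            assert hits >= 19

    def test_unrelated_profile_is_mixup_not_mcc(self, panel):
        cfg = SimulationConfig(karyotype="46XY")
        s = simulate_sample(cfg, seed=1)
        other = simulate_sample(cfg, seed=987654)
        res = detect_mcc(genotypes_of(s), other.maternal_profile, panel)
        assert res.mixup_warning
        assert res.status != "contaminated"

    def test_sparse_maternal_profile_not_assessed(self, panel):
        cfg = SimulationConfig(karyotype="46XY")
        s = simulate_sample(cfg, seed=2)
        small = dict(list(s.maternal_profile.items())[:3])
        assert detect_mcc(genotypes_of(s), small, panel).status == \
            "no_maternal_profile"


class TestTriage:
    @staticmethod
    def fractions(seed, sup_mcc, prec_mcc):
        """Supernatant/precipitate genotype dicts for one pregnancy."""
        cfg_clean = SimulationConfig(karyotype="46XY")
        base = simulate_sample(cfg_clean, seed=seed)
        out = []
        for frac in (sup_mcc, prec_mcc):
            cfg = SimulationConfig(karyotype="46XY", mcc_fraction=frac)
            s = simulate_sample(cfg, seed=seed)  # same seed: same genotypes
            out.append(genotypes_of(s))
        return out[0], out[1], base.maternal_profile

    def test_paper_classes_map_to_abc(self, panel):
        sup, prec, mom = self.fractions(11, 0.0, 0.0)
        assert triage_mcc(sup, prec, mom, panel).category == "A_fetal_blood"
        sup, prec, mom = self.fractions(12, 0.0, 0.35)
        res = triage_mcc(sup, prec, mom, panel)
        assert res.category == "B_resolved_by_supernatant"
        assert res.conclusive
        sup, prec, mom = self.fractions(13, 0.35, 0.35)
        res = triage_mcc(sup, prec, mom, panel)
        assert res.category == "C_unresolved"
        assert not res.conclusive

    def test_missing_fraction_is_error(self, panel):
        sup, _, mom = self.fractions(14, 0.0, 0.0)
        with pytest.raises(CallerError):
            triage_mcc(sup, None, mom, panel)

    def test_state_enumeration_is_total(self):
        mapping = triage_category_map()
        states = ("single_fetal", "mixed", "single_maternal")
        assert set(mapping) == set(itertools.product(states, states))
        assert set(mapping.values()) <= {
            "A_fetal_blood", "B_resolved_by_supernatant", "C_unresolved"
        }
        assert mapping[("single_fetal", "single_fetal")] == "A_fetal_blood"
        assert mapping[("single_fetal", "mixed")] == "B_resolved_by_supernatant"
        assert mapping[("mixed", "mixed")] == "C_unresolved"


class TestCallSample:
    def test_normal_sample_report(self, model, panel):
        cfg = SimulationConfig(karyotype="46XY")
        s = simulate_sample(cfg, seed=21)
        rep = call_sample(s.sample_id, genotypes_of(s), panel, model)
        assert rep.sex == "male"
        line = rep.summary_line()
        assert line.startswith(s.sample_id)
        assert "triploidy:no" in line
        assert "13:" in rep.summary_line()
        assert "sex\tmale" in rep.to_text()

    def test_trisomy_sample_verdict(self, model, panel):
        cfg = SimulationConfig(karyotype="T18")
        s = simulate_sample(cfg, seed=22)
        rep = call_sample(s.sample_id, genotypes_of(s), panel, model)
        assert rep.calls["18"].verdict == "trisomy"
        assert rep.calls["18"].informative_count >= 2

    def test_contaminated_sample_flagged(self, model, panel):
        cfg = SimulationConfig(karyotype="46XX", mcc_fraction=0.25)
        s = simulate_sample(cfg, seed=23)
        rep = call_sample(s.sample_id, genotypes_of(s), panel, model,
                          maternal_profile=s.maternal_profile)
        assert rep.mcc_flag
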