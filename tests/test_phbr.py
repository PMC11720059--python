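from __future__ import annotations

import random
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import harmonic_mean_exact
from spliceneo.peptides import KmerSet
from spliceneo.phbr import (
    ExternalRankPredictor,
    HLAGenotype,
    MockRankPredictor,
    PredictorError,
    classify_binder,
    compute_phbr,
    load_genotypes,
    sample_phbr,
    summarize_event,
)


def kmer_set(peptides, sample="P1", event="ev1", mode="I") -> KmerSet:
    return KmerSet(
        event_id=event,
        sample_id=sample,
        kmers=[(p, i + 1, len(p)) for i, p in enumerate(peptides)],
        class_mode=mode,
    )


class TestComputePHBR:
    @pytest.mark.parametrize("r", [0.1, 1.0, 7.5, 50.0])
    def test_equal_values(self, r):
        assert compute_phbr([r, r, r]) == pytest.approx(r)

    def test_two_values(self):
        assert compute_phbr([0.5, 2]) == pytest.approx(0.8)

    def test_one_nonbinder_barely_moves(self):
        assert compute_phbr([1, 1, 1, 1, 1, 100]) == pytest.approx(6 / 5.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_phbr([])

    def test_nonpositive_clamped(self, caplog):
        with caplog.at_level("WARNING"):
            value = compute_phbr([0.0, 1.0])
        assert value == pytest.approx(2 / (1 / 0.001 + 1))
        assert any("clamped" in r.message for r in caplog.records)

    @given(
        seed=st.integers(0, 1_000_000),
        n=st.integers(1, 6),
    )
    @settings(max_examples=200, deadline=None)
    def test_exact_rational_oracle(self, seed, n):
        rng = random.Random(seed)
        fracs = [
            Fraction(rng.randint(1, 10_000), rng.randint(1, 100))
            for _ in range(n)
        ]
        expected = harmonic_mean_exact(fracs)
        got = compute_phbr([float(f) for f in fracs])
        assert abs(got - float(expected)) < 1e-12 * max(1.0, float(expected))

    def test_bounds_and_monotonicity(self):
        rng = random.Random(0)
        for _ in range(200):
            ranks = [rng.uniform(0.05, 100) for _ in range(rng.randint(1, 6))]
            value = compute_phbr(ranks)
            assert min(ranks) <= value + 1e-12
            assert value <= min(ranks) * len(ranks) + 1e-9
            i = rng.randrange(len(ranks))
            lowered = list(ranks)
            lowered[i] *= 0.5
            assert compute_phbr(lowered) <= value + 1e-12


class TestClassify:
    @pytest.mark.parametrize(
        "phbr,mode,expected",
        [
            (0.38, "I", "strong"),
            (0.5, "I", "weak"),
            (1.35, "I", "weak"),
            (2.0, "I", "non"),
            (3.12, "I", "non"),
            (0.99, "II", "strong"),
            (1.0, "II", "relevant"),
            (4.9, "II", "relevant"),
            (5.0, "II", "non"),
        ],
    )
    def test_thresholds(self, phbr, mode, expected):
        assert classify_binder(phbr, mode) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            classify_binder(0.0)
        with pytest.raises(ValueError):
            classify_binder(1.0, "III")


GENO6 = HLAGenotype(
    patient_id="P1",
    class1_alleles=[
        "A02:01", "A03:01", "B27:05", "B07:02", "C07:01", "C07:02",
    ],
)


class TestSamplePHBR:
    def test_planted_best_combination(self):
        kmers = kmer_set(["QRWDSHFLL", "AAAAAAAA", "CCCCCCCC"])
        predictor = MockRankPredictor(
            plants={("QRWDSHFLL", "B27:05"): 0.2}, default_rank=50.0
        )
        res = sample_phbr(kmers, GENO6, predictor)
        assert res.best_peptide == "QRWDSHFLL"
        assert res.best_allele == "B27:05"
        assert res.phbr == pytest.approx(6 / (1 / 0.2 + 5 / 50))

    def test_single_allele_single_kmer(self):
        geno = HLAGenotype(patient_id="P1", class1_alleles=["A02:01"])
        predictor = MockRankPredictor(plants={("PEPTIDEX", "A02:01"): 0.38})
        res = sample_phbr(kmer_set(["PEPTIDEX"]), geno, predictor)
        assert res.phbr == pytest.approx(0.38)

    def test_homozygous_counts_twice(self):
        geno = HLAGenotype(patient_id="P1",
                           class1_alleles=["A02:01", "A02:01"])
        predictor = MockRankPredictor(default_rank=1.0)
        res = sample_phbr(kmer_set(["PEPTIDEY"]), geno, predictor)
        assert res.phbr == pytest.approx(1.0)

    def test_order_invariance(self):
        predictor = MockRankPredictor(seed=5)
        kmers_a = kmer_set(["AAAWWWKK", "CCCWWWKK", "DDDWWWKK"])
        kmers_b = kmer_set(["DDDWWWKK", "AAAWWWKK", "CCCWWWKK"])
        geno_shuffled = HLAGenotype(
            patient_id="P1", class1_alleles=list(reversed(GENO6.class1_alleles))
        )
        a = sample_phbr(kmers_a, GENO6, predictor)
        b = sample_phbr(kmers_b, geno_shuffled, predictor)
        assert a.phbr == pytest.approx(b.phbr)
        assert (a.best_peptide, a.best_allele) == (b.best_peptide, b.best_allele)

    def test_planted_binder_recovery_property(self):
        rng = random.Random(1)
        peptides = ["".join(rng.choice("ACDEFGHIK") for _ in range(9))
                    for _ in range(8)]
        for trial in range(20):
            target_pep = rng.choice(peptides)
            target_allele = rng.choice(GENO6.class1_alleles)
            predictor = MockRankPredictor(
                plants={(target_pep, target_allele): rng.uniform(0.01, 0.49)},
                default_rank=rng.uniform(50, 100),
            )
            res = sample_phbr(kmer_set(sorted(set(peptides))), GENO6, predictor)
            assert (res.best_peptide, res.best_allele) == (
                target_pep, target_allele,
            )

    def test_empty_kmers_rejected(self):
        with pytest.raises(ValueError):
            sample_phbr(kmer_set([]), GENO6, MockRankPredictor())

    def test_missing_genotype_class(self):
        geno = HLAGenotype(patient_id="P1")
        with pytest.raises(ValueError):
            sample_phbr(kmer_set(["PEPTIDEZ"]), geno, MockRankPredictor())


class TestSummarizeEvent:
    def _result(self, sample, phbr, rank=None):
        from spliceneo.phbr import PHBRResult

        return PHBRResult(
            event_id="ev1", sample_id=sample, phbr=phbr,
            best_peptide="PEP", best_allele="A02:01",
            best_rank=rank if rank is not None else phbr,
            binder_class=classify_binder(phbr),
        )

    def test_mean(self):
        s = summarize_event(
            [self._result("T1", 0.3), self._result("T2", 0.5)],
            [], cohort_size=2,
        )
        assert s.ase_avg_phbr == pytest.approx(0.4)

    def test_pct_samples(self):
        per_sample = [self._result(f"T{i}", 1.0) for i in range(46)]
        s = summarize_event(per_sample, [], cohort_size=47)
        assert s.pct_samples * 100 == pytest.approx(97.87, abs=0.05)

    def test_wt_average(self):
        wt = [self._result(f"T{i}", v) for i, v in enumerate([3.0, 3.1, 3.26])]
        s = summarize_event([self._result("T1", 0.4)], wt, cohort_size=3)
        assert s.wt_avg_phbr == pytest.approx(3.12)

    def test_all_excluded_unreportable(self):
        s = summarize_event(
            [], [], cohort_size=3,
            exclusions=[("T1", "premature_stop"), ("T2", "short_peptide")],
        )
        assert not s.reportable
        assert s.exclusions == {"premature_stop": 1, "short_peptide": 1}


class TestMockPredictor:
    def test_plant_lookup(self):
        p = MockRankPredictor(plants={("QRWDSHFLL", "B27:05"): 0.1})
        assert p.rank("QRWDSHFLL", "B27:05") == 0.1

    def test_stability(self):
        p = MockRankPredictor(seed=3)
        assert p.rank("PEPTIDE", "A02:01") == p.rank("PEPTIDE", "A02:01")

    def test_range(self):
        p = MockRankPredictor(seed=1)
        for i in range(100):
            r = p.rank(f"PEP{i}", "A02:01")
            assert 0.05 <= r <= 100

    def test_seed_changes_ranks(self):
        a = MockRankPredictor(seed=1).rank("PEPTIDE", "A02:01")
        b = MockRankPredictor(seed=2).rank("PEPTIDE", "A02:01")
        assert a != b

    def test_nonpositive_plant_rejected(self):
        with pytest.raises(ValueError):
            MockRankPredictor(plants={("P", "A"): 0.0})


class TestExternalPredictor:
    def test_adapter_round_trip(self, tmp_path):
        script = tmp_path / "pred.py"
        script.write_text(
            "import sys\n"
            "peps = open(sys.argv[1]).read().split()\n"
            "alleles = sys.argv[2].split(',')\n"
            "with open(sys.argv[3], 'w') as out:\n"
            "    for p in peps:\n"
            "        for a in alleles:\n"
            "            out.write(f'{p}\\t{a}\\t{(len(p)+len(a))/10}\\n')\n"
        )
        pred = ExternalRankPredictor(
            f"python {script} {{peptides}} {{alleles}} {{output}}"
        )
        table = pred.predict(["PEPTIDE"], ["A02:01"])
        assert table[("PEPTIDE", "A02:01")] == pytest.approx(1.3)

    def test_missing_pair_is_hard_error(self, tmp_path):
        script = tmp_path / "pred.py"
        script.write_text("import sys\nopen(sys.argv[3], 'w').close()\n")
        pred = ExternalRankPredictor(
            f"python {script} {{peptides}} {{alleles}} {{output}}"
        )
        with pytest.raises(PredictorError, match="PEPTIDE"):
            pred.predict(["PEPTIDE"], ["A02:01"])

    def test_bad_template(self):
        with pytest.raises(ValueError):
            ExternalRankPredictor("cmd {peptides}")


def test_load_genotypes(tmp_path):
    path = tmp_path / "geno.tsv"
    path.write_text(
        "patient_id\tclass\tallele\n"
        "P1\tI\tA02:01\nP1\tI\tA02:01\nP1\tII\tDRB1_01:01\n"
        "P2\tI\tB07:02\n"
    )
    genotypes = load_genotypes(path)
    assert genotypes["P1"].class1_alleles == ["A02:01", "A02:01"]
    assert genotypes["P1"].class2_alleles == ["DRB1_01:01"]
    assert genotypes["P2"].class1_alleles == ["B07:02"]


def test_load_genotypes_bad_header(tmp_path):
    path = tmp_path / "geno.tsv"
    path.write_text("id\tklass\tallele\nP1\tI\tA02:01\n")
    with pytest.raises(ValueError):
        load_genotypes(path)
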