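"""Generator correctness: templates, PCR products, traces, reads, kinetics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from ubpseq import synthetic_data as sd


class TestTemplates:
    @pytest.mark.parametrize(
        "design,n_ubp", [("natural", 0), ("1N", 1), ("2N", 2), ("3N", 3), ("UN", 1)]
    )
    def test_presets_have_expected_ubp_count(self, design, n_ubp):
        seq = sd.make_template(design, seed=1)
        assert len(seq) == 134
        assert len(seq.ubp_positions) == n_ubp

    def test_ubp_positions_are_exactly_the_xy_indices(self):
        seq = sd.make_template("3N")
        assert all(seq.bases[i] in "XY" for i in seq.ubp_positions)
        assert all(b not in "XY" for i, b in enumerate(seq.bases) if i not in seq.ubp_positions)

    def test_custom_all_natural(self):
        seq = sd.make_template("custom", length=10, ubp_positions=[])
        assert len(seq) == 10 and seq.ubp_positions == ()

    def test_unknown_preset_raises(self):
        with pytest.raises(sd.UnknownPresetError):
            sd.make_template("5N")

    def test_ubp_position_outside_sequence_raises(self):
        with pytest.raises(ValueError):
            sd.make_template("custom", length=10, ubp_positions=[10])

    def test_context_conflicting_with_letter_raises(self):
        with pytest.raises(ValueError):
            sd.make_template("custom", length=20, ubp_positions=[5], flank_triples={5: "GYA"})

    def test_plasmid_b_contexts(self):
        seq = sd.make_template("plasmid-B")
        triples = [seq.bases[p - 1] + "X" + seq.bases[p + 1] for p in seq.ubp_positions]
        assert triples == ["GXA", "TXT", "CXT"]

    def test_un_flanks_uniform_over_seeds(self):
        """Per-molecule NNN flanks approach uniformity over 4^3 per side."""
        counts = {}
        for seed in range(1, 101):
            seq = sd.make_template("UN", seed=seed)
            p = seq.ubp_positions[0]
            for triple in (seq.bases[p - 3 : p], seq.bases[p + 1 : p + 4]):
                counts[triple] = counts.get(triple, 0) + 1
        observed = np.array([counts.get(t, 0) for t in _all_triples()])
        assert observed.sum() == 200
        chi = stats.chisquare(observed)
        assert chi.pvalue > 0.01

    def test_deterministic_given_seed(self):
        assert sd.make_template("UN", seed=42).bases == sd.make_template("UN", seed=42).bases


def _all_triples():
    return [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]


class TestReverseComplement:
    @given(
        st.text(alphabet="ACGTXY", min_size=0, max_size=60),
    )
    def test_involution_and_pairing_rules(self, bases):
        seq = sd.UbpSequence(bases)
        rc = seq.reverse_complement()
        assert rc.reverse_complement().bases == bases
        for i, b in enumerate(bases):
            partner = rc.bases[len(bases) - 1 - i]
            assert partner == dict(zip("ACGTXY", "TGCAYX"))[b]

    def test_strand_flips(self):
        assert sd.UbpSequence("ACX").reverse_complement().strand is sd.Strand.ANTISENSE


class TestTransformationModel:
    def test_probability_vectors_validated(self):
        with pytest.raises(ValueError):
            sd.TransformationModel(sd.TransformationMode.BRIDGE, default=[0.5, 0.5, 0.5, 0.5])

    @pytest.mark.parametrize(
        "factory",
        [
            sd.TransformationModel.bridge_default,
            sd.TransformationModel.nam_only_default,
            sd.TransformationModel.bridge_context_biased,
            sd.TransformationModel.nam_context_biased,
        ],
    )
    def test_stock_models_rows_sum_to_one(self, factory):
        mat = factory().prob_matrix()
        assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-9)
        assert (mat >= 0).all()

    def test_context_code_roundtrip(self):
        for code in (0, 1, 4095, 1234):
            up, down = sd.decode_context(code)
            assert sd.context_code(up, down) == code


class TestPcrProduct:
    def test_bridge_point_mass_writes_g(self):
        t = sd.make_template("1N")
        pool = sd.simulate_pcr_product(t, sd.TransformationModel.bridge_default(), 50, seed=1)
        assert pool.n_unconverted == 0
        (seq,) = pool.products
        assert seq[66] == "G"
        assert set(seq) <= set("ACGT")

    def test_natural_template_is_copied_verbatim(self):
        t = sd.make_template("custom", length=30, ubp_positions=[])
        pool = sd.simulate_pcr_product(t, sd.TransformationModel.bridge_default(), 10, seed=1)
        assert pool.products == {t.bases: 10}

    def test_natural_mode_rejects_ubp_template(self):
        t = sd.make_template("1N")
        model = sd.TransformationModel(sd.TransformationMode.NATURAL)
        with pytest.raises(ValueError):
            sd.simulate_pcr_product(t, model, 10, seed=1)

    def test_tpt3_only_uniform_outcomes_within_binomial_bounds(self):
        t = sd.make_template("1N")
        pool = sd.simulate_pcr_product(t, sd.TransformationModel.tpt3_only_default(), 4000, seed=3)
        counts = {b: 0 for b in "ACGT"}
        for seq, n in pool.products.items():
            counts[seq[66]] += n
        sigma = np.sqrt(4000 * 0.25 * 0.75)
        for b in "ACGT":
            assert abs(counts[b] - 1000) < 3 * sigma

    def test_retention_splits_molecules(self):
        t = sd.make_template("1N")
        model = sd.TransformationModel.bridge_default(retention=0.4)
        pool = sd.simulate_pcr_product(t, model, 2000, seed=5)
        assert pool.n_unconverted + pool.n_converted == 2000
        sigma = np.sqrt(2000 * 0.4 * 0.6)
        assert abs(pool.n_unconverted - 800) < 3 * sigma

    def test_bit_reproducible(self):
        t = sd.make_template("3N")
        m = sd.TransformationModel.bridge_context_biased()
        a = sd.simulate_pcr_product(t, m, 500, seed=9)
        b = sd.simulate_pcr_product(t, m, 500, seed=9)
        assert a.products == b.products and a.n_unconverted == b.n_unconverted


class TestTraceSimulation:
    def test_noiseless_single_sequence(self):
        trace = sd.simulate_trace([("ACGT", 1.0)], noise_sd=0.0)
        assert trace.primary == ["A", "C", "G", "T"]
        assert (np.count_nonzero(trace.channels, axis=1) == 1).all()

    def test_linear_mixing_ratio(self):
        trace = sd.simulate_trace([("AGA", 0.7), ("AAA", 0.3)], noise_sd=0.0)
        assert trace.intensity(1, "G") / trace.intensity(1, "A") == pytest.approx(7 / 3)

    def test_secondary_call_recorded_for_mixture(self):
        trace = sd.simulate_trace([("G", 0.7), ("A", 0.3)], noise_sd=0.0)
        assert trace.primary[0] == "G" and trace.secondary[0] == "A"

    def test_mixed_site_mean_fraction_under_noise(self):
        fractions = []
        for seed in range(200):
            trace = sd.simulate_trace([("G", 0.5), ("A", 0.5)], noise_sd=0.05, seed=seed)
            total = trace.intensity(0, "G") + trace.intensity(0, "A")
            fractions.append(trace.intensity(0, "G") / total)
        assert 0.48 <= np.mean(fractions) <= 0.52

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_trace([("ACG", 0.5), ("AC", 0.5)])

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_trace([("ACG", 1.0)], noise_sd=-0.1)

    def test_terminated_member_attenuates_downstream_signal(self):
        members = [
            sd.PopulationMember("AAAA", 0.4),
            sd.PopulationMember("AAAA", 0.6, stop=2),
        ]
        trace = sd.simulate_trace(members, noise_sd=0.0, amplitude=1000)
        assert trace.intensity(1, "A") == pytest.approx(1000)
        assert trace.intensity(3, "A") == pytest.approx(400)


class TestUnReads:
    def test_point_mass_center_base(self):
        reads = sd.simulate_un_reads(4096, sd.TransformationModel.bridge_default(), seed=1)
        k = len(sd.UN_LEFT_ANCHOR)
        assert all(r[k + 3] == "G" for r in reads)

    def test_read_layout(self):
        reads = sd.simulate_un_reads(10, sd.TransformationModel.nam_only_default(), seed=2)
        for r in reads:
            assert r.startswith(sd.UN_LEFT_ANCHOR) and r.endswith(sd.UN_RIGHT_ANCHOR)
            assert len(r) == len(sd.UN_LEFT_ANCHOR) + 7 + len(sd.UN_RIGHT_ANCHOR)

    def test_read_length_shorter_than_core_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_un_reads(5, sd.TransformationModel.bridge_default(), read_length=20)

    def test_context_marginals_converge_to_model(self):
        """Empirical per-context outcome distribution approaches the model
        table (mean KL divergence small at n = 10^5)."""
        model = sd.TransformationModel.bridge_context_biased()
        codes, outcomes = sd.simulate_un_context_draws(100_000, model, seed=6)
        pmat = model.prob_matrix()
        kls = []
        for code in range(0, 4096, 64):  # a deterministic subsample of contexts
            mask = codes == code
            n = mask.sum()
            if n < 10:
                continue
            emp = np.bincount(outcomes[mask], minlength=4) / n
            p = pmat[code]
            kl = np.sum([e * np.log(e / q) for e, q in zip(emp, p) if e > 0 and q > 0])
            kls.append(kl)
        assert np.mean(kls) < 0.1

    def test_fastq_writer_roundtrip(self, tmp_path):
        reads = sd.simulate_un_reads(5, sd.TransformationModel.bridge_default(), seed=3)
        path = tmp_path / "r.fastq"
        reads.to_fastq(path)
        lines = path.read_text().splitlines()
        assert len(lines) == 20 and lines[1] == reads.sequences[0]


class TestLesionReads:
    REF = "ACGTAGGTCA" * 5

    def test_zero_fraction_sets_statistically_identical(self):
        lr = sd.simulate_lesion_reads(self.REF, [10], 0.0, "BRIDGE", 4000, seed=1)
        diff = np.abs(lr.pileup("damaged") - lr.pileup("control"))
        # both sets are independent draws from the same background process;
        # the difference of two error counts has variance ~ 2 n p
        assert diff.max() < 5 * np.sqrt(2 * 4000 * 0.005)

    def test_signature_fraction_exact_without_background(self):
        lr = sd.simulate_lesion_reads(self.REF, [4], 0.3, "BRIDGE", 10_000, seed=2, background=0.0)
        pile = lr.pileup("damaged")
        frac = pile[4, 1] / pile[4].sum()  # C channel
        assert frac == pytest.approx(0.3, abs=3 * np.sqrt(0.3 * 0.7 / 10_000))

    def test_unobservable_site_flagged(self):
        lr = sd.simulate_lesion_reads("ACCA", [1], 0.2, "BRIDGE", 10, seed=3)
        assert lr.unobservable_sites == (1,)

    def test_recovered_fractions_within_binomial_bounds(self):
        lr = sd.simulate_lesion_reads(
            self.REF, [3, 22], [0.1, 0.3], "NAM_ONLY", 50_000, seed=4, background=0.0
        )
        pile = lr.pileup("damaged")
        for site, f in [(3, 0.1), (22, 0.3)]:
            frac = pile[site, 0] / pile[site].sum()  # A channel
            assert abs(frac - f) < 3 * np.sqrt(f * (1 - f) / 50_000)


class TestKineticsTable:
    def test_half_saturation_identity(self):
        df = sd.simulate_kinetics(10.0, 2.0, concentrations=[2.0], cv=0.0)
        assert df["velocity_pct_per_min"].iloc[0] == pytest.approx(5.0)

    def test_asymptote(self):
        df = sd.simulate_kinetics(10.0, 2.0, concentrations=[1e9], cv=0.0)
        assert df["velocity_pct_per_min"].iloc[0] == pytest.approx(10.0, rel=1e-6)

    def test_default_series_is_eight_twofold_dilutions(self):
        c = sd.default_dilution_series()
        assert len(c) == 8 and np.allclose(c[:-1] / c[1:], 2.0)

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_kinetics(0.0, 1.0)
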