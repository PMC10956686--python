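import numpy as np
import pandas as pd
import pytest

from evtrf import (
    FragmentTable,
    SimulationConfig,
    collapse,
    modal_length,
    pfaffl_relative_expression,
    preprocess_fastq,
    simulate_cohort,
    simulate_counts,
    simulate_references,
    simulate_validation_plate,
)
from evtrf.simulate import build_fragment_universe


def small_config(seed=1, **kw):
    defaults = dict(
        n_case=2,
        n_control=2,
        n_refs={"tRNA": 10, "miRNA": 10, "piRNA": 5, "snoRNA": 5, "rRNA": 3},
        n_fragments={"tRNA": 20, "miRNA": 12, "piRNA": 8, "snoRNA": 5, "rRNA": 10},
        library_size=2000,
    )
    defaults.update(kw)
    return SimulationConfig(seed=seed, **defaults)


class TestSimulateReferences:
    def test_deterministic_for_fixed_seed(self):
        cfg = small_config()
        a = simulate_references(cfg)
        b = simulate_references(small_config())
        for cls in a:
            assert [r.sequence for r in a[cls]] == [r.sequence for r in b[cls]]

    def test_requested_counts(self):
        refs = simulate_references(small_config())
        assert len(refs["tRNA"]) == 10
        assert len(refs["miRNA"]) == 10

    def test_different_seeds_differ(self):
        a = simulate_references(small_config(seed=1))
        b = simulate_references(small_config(seed=2))
        sa = {r.sequence for r in a["tRNA"]}
        sb = {r.sequence for r in b["tRNA"]}
        assert sa != sb

    def test_class_length_ranges(self):
        refs = simulate_references(small_config())
        for rec in refs["tRNA"]:
            assert 72 <= len(rec.sequence) <= 93
            assert rec.sequence.endswith("CCA")
        for rec in refs["miRNA"]:
            assert 20 <= len(rec.sequence) <= 24
        for rec in refs["rRNA"]:
            assert 100 <= len(rec.sequence) <= 200

    def test_nonpositive_count_error(self):
        with pytest.raises(ValueError):
            simulate_references(small_config(n_refs={"tRNA": 0}))


class TestConfigValidation:
    def test_zero_case_samples_error(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, n_case=0)

    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, class_mix={"tRNA": 0.5, "miRNA": 0.4})

    def test_negative_fold_error(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, de_spec=[("ACGT", -2.0)])


class TestFragmentUniverse:
    def test_trf_fragments_are_prefixes_of_their_source(self):
        cfg = small_config()
        refs = simulate_references(cfg)
        truth = build_fragment_universe(cfg, refs)
        trf = truth[(truth["rna_class"] == "tRNA") & (truth["edit_count"] == 0)]
        for frag, row in trf.iterrows():
            assert refs["tRNA"][row["source_ref"]].sequence.startswith(frag)
            assert row["trf_type"] == "five_prime"

    def test_weights_sum_to_one_per_class(self):
        cfg = small_config()
        refs = simulate_references(cfg)
        truth = build_fragment_universe(cfg, refs)
        sums = truth.groupby("rna_class")["weight"].sum()
        assert np.allclose(sums, 1.0)

    def test_unknown_de_fragment_error(self):
        cfg = small_config(de_spec=[("NOTAFRAGMENT", 2.0)])
        refs = simulate_references(cfg)
        with pytest.raises(ValueError):
            build_fragment_universe(cfg, refs)

    def test_variant_fragments_differ_from_prefix(self):
        cfg = small_config(variant_fraction=0.6)
        refs = simulate_references(cfg)
        truth = build_fragment_universe(cfg, refs)
        variants = truth[truth["edit_count"] > 0]
        assert len(variants) > 0
        for frag, row in variants.iterrows():
            # never an exact prefix of the source (degenerate indels rejected)
            assert not refs["tRNA"][row["source_ref"]].sequence.startswith(frag)


class TestSimulateCounts:
    def test_fold_change_recovered_across_seeds(self):
        """Case/control mean ratio converges to the configured fold change."""
        case_means, ctrl_means = [], []
        for seed in range(100):
            cfg = small_config(
                seed=seed, n_case=4, n_control=4, n_de=1, de_fold=4.0,
                de_min_rpm=500.0, library_size=5000,
            )
            refs = simulate_references(cfg)
            truth = build_fragment_universe(cfg, refs)
            counts = simulate_counts(cfg, truth)
            de_frag = truth.index[truth["fold_change"] > 1][0]
            base = cfg.library_size * cfg.class_mix["tRNA"] * truth.loc[de_frag, "weight"]
            # normalise by the fragment's own base mean so seeds are comparable
            case_means.append(counts.loc[de_frag, cfg.groups == "case"].mean() / base)
            ctrl_means.append(counts.loc[de_frag, cfg.groups == "control"].mean() / base)
        assert np.mean(case_means) / np.mean(ctrl_means) == pytest.approx(4.0, rel=0.10)

    def test_deterministic(self):
        cfg = small_config()
        refs = simulate_references(cfg)
        truth = build_fragment_universe(cfg, refs)
        assert simulate_counts(cfg, truth).equals(simulate_counts(cfg, truth))


class TestSimulateCohort:
    def test_fixed_seed_byte_identical_fastq(self, tmp_path):
        cfg = small_config(substitution_error_rate=0.001)
        refs = simulate_references(cfg)
        p1, _, _ = simulate_cohort(cfg, refs, tmp_path / "a")
        p2, _, _ = simulate_cohort(cfg, refs, tmp_path / "b")
        for s in cfg.samples:
            assert p1[s].read_bytes() == p2[s].read_bytes()

    def test_clean_reads_are_reference_prefixes(self, tmp_path):
        """No noise, no adapter: every tRF read is an exact reference prefix."""
        cfg = small_config(
            variant_fraction=0.0, substitution_error_rate=0.0, adapter="",
            class_mix={"tRNA": 1.0},
            n_fragments={"tRNA": 10},
            read_length=34,
        )
        refs = simulate_references(cfg)
        paths, truth, _ = simulate_cohort(cfg, refs, tmp_path)
        seqs = {r.sequence for r in refs["tRNA"]}
        from evtrf.preprocess import read_fastq

        n = 0
        for seq, _q in read_fastq(paths[cfg.samples[0]]):
            n += 1
            assert any(s.startswith(seq[:30]) for s in seqs)
        assert n > 0

    def test_class_mixture_converges(self, tmp_path):
        # at 1e5 reads with Poisson counting noise only, the emitted class
        # mixture matches the configured proportions within 2%
        cfg = small_config(library_size=100_000, dispersion=0.0,
                           n_case=1, n_control=1)
        refs = simulate_references(cfg)
        truth = build_fragment_universe(cfg, refs)
        counts = simulate_counts(cfg, truth)
        frac = counts.iloc[:, 0].groupby(truth["rna_class"]).sum() / counts.iloc[:, 0].sum()
        for cls, expected in cfg.class_mix.items():
            assert frac[cls] == pytest.approx(expected, abs=0.02)

    def test_sample_sheet_structure(self, tmp_path):
        cfg = small_config()
        refs = simulate_references(cfg)
        _, _, sheet = simulate_cohort(cfg, refs, tmp_path)
        assert list(sheet.columns) == ["sample_id", "group", "compartment"]
        assert (sheet["group"] == "case").sum() == 2

    def test_ev_and_tissue_modal_lengths(self, tmp_path):
        for profile, check in [("ev", lambda m: 30 <= m <= 34),
                               ("tissue", lambda m: m == 22)]:
            # default fragment diversity so length distributions are expressed
            cfg = SimulationConfig(seed=9, profile=profile, n_case=1,
                                   n_control=1, library_size=15000)
            refs = simulate_references(cfg)
            paths, _, _ = simulate_cohort(cfg, refs, tmp_path / profile)
            reads = preprocess_fastq(paths[cfg.samples[0]], adapter=cfg.adapter)
            table = collapse({"s": reads})
            assert check(modal_length(table, "s"))


class TestSimulateQpcrPlate:
    def test_noiseless_plate_recovers_fold_exactly(self):
        rec = simulate_validation_plate(fold=1.4, noise_sd=0.0, seed=3)
        out = pfaffl_relative_expression(rec, "target", "reference")
        med = out.groupby("group")["relative_expression"].median()
        assert med["case"] == pytest.approx(1.4)
        assert med["control"] == pytest.approx(1.0)

    def test_spike_assay_constant_without_noise(self):
        rec = simulate_validation_plate(fold=2.0, noise_sd=0.0, seed=4)
        spike = rec[rec["assay"] == "spike"]["Cq"]
        assert spike.nunique() == 1
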