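"""Simulator: mutation accumulation, recombination, selection mask, determinism."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from rtevolve import (
    EvolutionConfig,
    ExtinctionError,
    MutationSpectrum,
    ReferenceGene,
    apply_mutations,
    per_clone_counts,
    positional_fit_test,
    simulate_library,
    simulate_recombination,
    summarize_spectrum,
)
from rtevolve.spectrum import sample_events


def test_zero_rate_yields_identical_clones(reference):
    cfg = EvolutionConfig(mutation_rate=0.0, generations=5, population_size=20, seed=1)
    lib = simulate_library(cfg, reference)
    assert all(c.sequence == reference.sequence for c in lib.clones)
    assert all(c.n_mutations == 0 for c in lib.clones)
    assert lib.generations[-1].mean_mutations_per_genome == 0.0


def test_generation_labels_follow_cycle_convention(reference):
    cfg = EvolutionConfig(mutation_rate=1e-4, generations=3, population_size=5, seed=2)
    lib = simulate_library(cfg, reference)
    assert [g.generation_label for g in lib.generations] == ["F0", "F1", "F2"]
    assert all(g.cycle_count == int(g.generation_label[1:]) + 1
               for g in lib.generations)
    assert lib.clones[0].clone_id.startswith("F2_clone")


def test_seed_determinism_is_byte_identical(reference):
    cfg = dict(mutation_rate=1e-3, generations=6, population_size=100, seed=33,
               heterozygous_virion_fraction=0.3, recombination_switch_rate=0.01)
    lib1 = simulate_library(EvolutionConfig(**cfg), reference)
    lib2 = simulate_library(EvolutionConfig(**cfg), reference)
    assert [c.sequence for c in lib1.clones] == [c.sequence for c in lib2.clones]
    assert lib1.generations == lib2.generations
    assert [c.mutations for c in lib1.clones] == [c.mutations for c in lib2.clones]


def test_poisson_moments_at_derived_scale():
    """rate 1e-3, 1000 nt, 5 cycles: mean and variance both ~5, dispersion ~1."""
    ref = ReferenceGene.random(1000, seed=5)
    cfg = EvolutionConfig(mutation_rate=1e-3, generations=5, population_size=10_000,
                          seed=55)
    counts = per_clone_counts(simulate_library(cfg, ref))
    expected = 1e-3 * 1000 * 5
    se_mean = np.sqrt(expected / counts.size)
    assert abs(counts.mean() - expected) <= 3 * se_mean + 0.05  # small multi-hit bias
    assert 4.5 <= counts.var(ddof=1) <= 5.5
    assert 0.9 <= counts.var(ddof=1) / counts.mean() <= 1.1


def test_mean_mutations_match_binomial_expectation(big_library):
    """10k lineages, 783 nt, 16 cycles at 1.14e-4: mean within 3 SE of n*g*m."""
    counts = per_clone_counts(big_library)
    expected = 1.14e-4 * 783 * 16
    se = np.sqrt(expected / counts.size)
    assert abs(counts.mean() - expected) <= 3 * se


def test_positions_follow_process_law(big_library):
    """Mutated positions spread over the gene per the base-dependent hazard.

    With a G>A-dominated spectrum, positions are uniform within a base class
    but G sites mutate faster, so the chi-square is against the process's own
    positional law.
    """
    events = [ev for c in big_library.clones for ev in c.mutations]
    assert len(events) >= 10_000
    sp = big_library.config.spectrum
    mult = sp.site_rate_multipliers(big_library.reference.base_composition())
    site_w = mult[big_library.reference.codes()]
    res = positional_fit_test(events, big_library.reference.length, bins=10,
                              expected_site_weights=site_w)
    assert res.pvalue > 0.01


def test_positions_uniform_under_uniform_spectrum():
    """With a uniform spectrum and balanced composition, positions are uniform."""
    ref = ReferenceGene.balanced(780, seed=8)
    cfg = EvolutionConfig(mutation_rate=1e-3, generations=5, population_size=2_500,
                          spectrum=MutationSpectrum.uniform(), seed=88)
    lib = simulate_library(cfg, ref)
    events = [ev for c in lib.clones for ev in c.mutations]
    res = positional_fit_test(events, ref.length, bins=10)
    assert res.pvalue > 0.01


def test_simulated_spectrum_converges_to_configuration(big_library):
    events = [ev for c in big_library.clones for ev in c.mutations]
    summary = summarize_spectrum(events)
    sp = big_library.config.spectrum
    for (r, a), frac in summary.fractions.items():
        w = sp.type_fraction(r, a)
        se = np.sqrt(w * (1 - w) / summary.total)
        assert abs(frac - w) <= 3 * se + 1e-12


def test_clone_records_are_consistent(big_library):
    """Applying the recorded mutations to the reference reproduces the clone."""
    for clone in big_library.clones[:200]:
        assert apply_mutations(big_library.reference, clone.mutations) == clone.sequence
        assert 1 <= min((m.position for m in clone.mutations), default=1)
        cycles = clone.mutation_cycles
        assert all(1 <= cyc <= 16 for cyc in cycles)


def test_cis_lethal_mask_purges_masked_mutations(reference):
    mask = frozenset(range(1, 41))
    cfg = EvolutionConfig(mutation_rate=5e-3, generations=6, population_size=400,
                          cis_lethal_mask=mask, seed=17)
    lib = simulate_library(cfg, reference)
    for clone in lib.clones:
        assert not any(m.position in mask for m in clone.mutations)
    assert all(g.genomes_surviving >= 1 for g in lib.generations)


def test_mask_extinction_raises_naming_generation():
    ref = ReferenceGene.random(50, seed=3)
    cfg = EvolutionConfig(mutation_rate=0.3, generations=2, population_size=4,
                          cis_lethal_mask=frozenset(range(1, 51)), seed=4)
    with pytest.raises(ExtinctionError, match="cycle 1"):
        simulate_library(cfg, ref)


def test_config_validation():
    with pytest.raises(ValueError):
        EvolutionConfig(mutation_rate=1.5, generations=1, population_size=1, seed=0)
    with pytest.raises(ValueError):
        EvolutionConfig(mutation_rate=1e-4, generations=-1, population_size=1, seed=0)
    with pytest.raises(TypeError):
        EvolutionConfig(mutation_rate=1e-4, generations=1, population_size=1)  # no seed
    with pytest.raises(ValueError):
        ReferenceGene("empty", "")


# -- recombination ----------------------------------------------------------

def test_recombination_no_switch_copies_one_parent():
    a, b = "AAAAAAAAAA", "CCCCCCCCCC"
    child = simulate_recombination(a, b, 0.0, seed=12)
    assert child in (a, b)


def test_recombination_identical_parents_is_identity():
    a = "ACGTACGTAC" * 5
    assert simulate_recombination(a, a, 0.5, seed=1) == a


def test_recombination_rejects_unequal_lengths():
    with pytest.raises(ValueError):
        simulate_recombination("AAAA", "CC", 0.1, seed=1)


def test_recombination_symmetric_stationarity():
    """switch 0.5 makes positions iid fair draws between the parents."""
    n = 10_000
    child = simulate_recombination("A" * n, "C" * n, 0.5, seed=21)
    frac_a = child.count("A") / n
    se = 0.5 / np.sqrt(n)
    assert abs(frac_a - 0.5) <= 3 * se


@given(st.integers(min_value=0, max_value=10 ** 6),
       st.floats(min_value=0.0, max_value=1.0))
def test_recombination_offspring_is_mosaic(seed, rate):
    a = "ACGTACGTACGTACGT"
    b = "TGCATGCATGCATGCA"
    child = simulate_recombination(a, b, rate, seed=seed)
    assert all(c in (x, y) for c, x, y in zip(child, a, b))


def test_in_library_recombination_mixes_lineages(reference):
    cfg = EvolutionConfig(mutation_rate=2e-3, generations=6, population_size=500,
                          heterozygous_virion_fraction=0.8,
                          recombination_switch_rate=0.005, seed=91)
    lib = simulate_library(cfg, reference)
    # still a valid library: clones reproduce from their recorded events
    for clone in lib.clones[:50]:
        assert apply_mutations(reference, clone.mutations) == clone.sequence


def test_event_sampler_and_simulator_agree_on_g_to_a(reference):
    """Direct event sampling and the generation loop share one spectrum law."""
    sp = MutationSpectrum.default()
    direct = summarize_spectrum(sample_events(sp, reference, 10_000, seed=5))
    assert direct.fraction("G", "A") == pytest.approx(0.623, abs=0.02)
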