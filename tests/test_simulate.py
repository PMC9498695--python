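"""Synthetic-data generator: moments, determinism, implants, toy genome."""

import numpy as np
import pytest

from selsweep.diversity import WindowScheme, windowed_pi
from selsweep.io import MISSING
from selsweep.simulate import (
    SimulationConfig, SpecificAlleleSpec, SweepSpec, generate_toy_genome,
    implant_specific_snps, implant_sweep, simulate_genotypes,
    simulate_neutral_coalescent, simulate_population_frequencies,
)


def two_pop_config(**kw):
    base = dict(
        n_pops=2, samples_per_pop=(16, 16), pop_names=("p1", "p2"),
        chrom_lengths={"chr1": 1_000_000}, n_sites=2_000,
        F_per_pop=(0.1, 0.1), missing_rate=0.0, inbreeding=0.0, seed=0,
    )
    base.update(kw)
    return SimulationConfig(**base)


# ---------------------------------------------------------------------------
# frequencies


def test_config_rejects_degenerate_f():
    with pytest.raises(ValueError):
        two_pop_config(F_per_pop=(0.0, 0.1))
    with pytest.raises(ValueError):
        two_pop_config(F_per_pop=(1.0, 0.1))


def test_near_zero_f_gives_ancestral_frequencies():
    cfg = two_pop_config(F_per_pop=(1e-6, 1e-6), n_sites=500)
    fr = simulate_population_frequencies(cfg)
    assert np.abs(fr.freqs - fr.ancestral[:, None]).max() < 1e-2


def test_balding_nichols_variance_moment():
    # Var(p_pop | p) = F * p * (1-p); check at fixed p = 0.5
    cfg = two_pop_config(
        F_per_pop=(0.08, 0.08), n_sites=6_000,
        ancestral_beta=(1e6, 1e6),  # p concentrated at 0.5
        ancestral_truncation=(0.05, 0.95), seed=2,
    )
    fr = simulate_population_frequencies(cfg)
    v = fr.freqs[:, 0].var()
    assert v == pytest.approx(0.08 * 0.25, rel=0.10)


def test_frequencies_deterministic_under_seed():
    cfg = two_pop_config(seed=9)
    a = simulate_population_frequencies(cfg)
    b = simulate_population_frequencies(cfg)
    assert np.array_equal(a.pos, b.pos)
    assert np.array_equal(a.freqs, b.freqs)


# ---------------------------------------------------------------------------
# genotypes


def test_fixed_frequency_monomorphic_genotypes():
    cfg = two_pop_config(n_sites=50)
    fr = simulate_population_frequencies(cfg)
    fr.freqs[:] = 0.0
    m = simulate_genotypes(fr, cfg)
    assert (m.dosage == 0).all()


def test_no_missing_when_rate_zero():
    cfg = two_pop_config(missing_rate=0.0)
    m = simulate_genotypes(simulate_population_frequencies(cfg), cfg)
    assert (m.dosage != MISSING).all()


def test_missing_rate_realized():
    cfg = two_pop_config(missing_rate=0.1, n_sites=3_000)
    m = simulate_genotypes(simulate_population_frequencies(cfg), cfg)
    frac = (m.dosage == MISSING).mean()
    assert frac == pytest.approx(0.1, abs=0.01)


def test_transition_fraction_follows_kappa():
    cfg = two_pop_config(n_sites=10_000, ts_tv_kappa=2.0,
                        chrom_lengths={"chr1": 10_000_000})
    m = simulate_genotypes(simulate_population_frequencies(cfg), cfg)
    ts_pairs = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    frac = np.mean([
        (r, a) in ts_pairs for r, a in zip(m.ref, m.alt)
    ])
    assert frac == pytest.approx(2 / 3, abs=0.02)


def test_inbreeding_reduces_heterozygosity():
    # IBD mixture: E[het] = (1-f) * 2 E[p_pop(1-p_pop)]
    # = (1-f) * (1-F) * 2 p(1-p) under Balding-Nichols drift at level F
    f, F = 0.3, 0.1
    cfg = two_pop_config(n_sites=4_000, inbreeding=f, F_per_pop=(F, F),
                         ancestral_beta=(1e6, 1e6), seed=6)
    m = simulate_genotypes(simulate_population_frequencies(cfg), cfg)
    het = (m.dosage == 1).mean()
    assert het == pytest.approx((1 - f) * (1 - F) * 0.5, rel=0.05)


def test_vcf_deterministic_under_seed(tmp_path):
    from selsweep.io import write_vcf

    cfg = two_pop_config(missing_rate=0.05, seed=21)
    paths = []
    for name in ("a.vcf", "b.vcf"):
        m = simulate_genotypes(simulate_population_frequencies(cfg), cfg)
        p = tmp_path / name
        write_vcf(m, p, cfg.chrom_lengths)
        paths.append(p)
    assert paths[0].read_bytes() == paths[1].read_bytes()


# ---------------------------------------------------------------------------
# sweep implant


def test_identity_sweep_spec_returns_matrix_unchanged():
    cfg = two_pop_config()
    m = simulate_genotypes(simulate_population_frequencies(cfg), cfg)
    spec = SweepSpec("chr1", 1, 1_000_000, "p1",
                     diversity_reduction=1.0, divergence_boost=0.0)
    assert implant_sweep(m, spec, cfg.popmap()) is m


def test_sweep_region_without_sites_warns_and_is_identity():
    cfg = two_pop_config(n_sites=10, chrom_lengths={"chr1": 1_000_000})
    m = simulate_genotypes(simulate_population_frequencies(cfg), cfg)
    far = int(m.pos.max()) + 1
    spec = SweepSpec("chr1", far, far, "p1")
    with pytest.warns(UserWarning):
        out = implant_sweep(m, spec, cfg.popmap())
    assert np.array_equal(out.dosage, m.dosage)


def test_sweep_implant_collapses_focal_diversity():
    # 5 Mb chromosome, one 200 kb implant, 5x reduction:
    # windowed focal pi inside the implant falls below 1/3 of the
    # chromosome-wide median
    cfg = two_pop_config(
        chrom_lengths={"chr1": 5_000_000}, n_sites=10_000, seed=3,
    )
    m = simulate_genotypes(simulate_population_frequencies(cfg), cfg)
    pm = cfg.popmap()
    spec = SweepSpec("chr1", 2_000_001, 2_200_000, "p1",
                     diversity_reduction=5.0, divergence_boost=0.0)
    swept = implant_sweep(m, spec, pm, seed=3)
    idx = pm.indices("p1", m.samples)
    pi = windowed_pi(swept, {"p1": idx}, WindowScheme(),
                     {"chr1": 5_000_000})
    inside = pi[(pi.start >= spec.start - 1) & (pi.end <= spec.end)]
    assert inside.pi.mean() < pi.pi.median() / 3
    # sites outside the region untouched
    outside = (m.pos < spec.start) | (m.pos > spec.end)
    assert np.array_equal(swept.dosage[outside], m.dosage[outside])


# ---------------------------------------------------------------------------
# specific-SNP implant


def test_specific_implant_realizes_frequencies():
    cfg = two_pop_config()
    m = simulate_genotypes(simulate_population_frequencies(cfg), cfg)
    pm = cfg.popmap()
    pos = int(m.pos[10])
    spec = SpecificAlleleSpec("chr1", pos, "p1", "hom_alt",
                              focal_freq=0.85)
    out = implant_specific_snps(m, [spec], pm)
    focal = pm.indices("p1", m.samples)
    other = pm.indices("p2", m.samples)
    # 16 focal samples at target 0.85 -> 14/16 = 0.875 hom-alt
    assert (out.dosage[10, focal] == 2).sum() == 14
    assert (out.dosage[10, other] == 2).sum() == 0


def test_specific_implant_empty_list_is_identity():
    cfg = two_pop_config()
    m = simulate_genotypes(simulate_population_frequencies(cfg), cfg)
    assert implant_specific_snps(m, [], cfg.popmap()) is m


def test_specific_implant_infeasible_focal_size_errors():
    cfg = two_pop_config(samples_per_pop=(3, 16))
    m = simulate_genotypes(simulate_population_frequencies(cfg), cfg)
    # 3 focal samples: ceil(0.81*3)=3 -> 3/3 = 1.0 fine; force failure with
    # a low target where ceil(0.5*3)=2 -> 2/3 < 0.8
    spec = SpecificAlleleSpec("chr1", int(m.pos[0]), "p1", "hom_alt",
                              focal_freq=0.5)
    with pytest.raises(ValueError):
        implant_specific_snps(m, [spec], cfg.popmap())


def test_specific_implants_recovered_by_classifier():
    from selsweep.specific import call_population_specific

    cfg = two_pop_config(seed=8)
    m = simulate_genotypes(simulate_population_frequencies(cfg), cfg)
    pm = cfg.popmap()
    rng = np.random.default_rng(0)
    picks = sorted(rng.choice(m.n_sites, size=25, replace=False))
    specs = [
        SpecificAlleleSpec("chr1", int(m.pos[i]), "p1",
                           ("hom_ref", "het", "hom_alt")[j % 3])
        for j, i in enumerate(picks)
    ]
    out = implant_specific_snps(m, specs, pm)
    calls = call_population_specific(
        out, pm.indices("p1", m.samples), pm.indices("p2", m.samples)
    )
    called = set(zip(calls.pos, calls.genotype_class))
    for s in specs:
        assert (s.pos, s.genotype_class) in called


# ---------------------------------------------------------------------------
# neutral coalescent


def test_coalescent_pairwise_differences_match_theta():
    theta = 4.0
    diffs = [
        simulate_neutral_coalescent(2, theta, seed=i).shape[0]
        for i in range(500)
    ]
    # for n=2 every segregating site is a pairwise difference; E = theta
    assert np.mean(diffs) == pytest.approx(theta, rel=0.15)


def test_coalescent_segregating_sites_match_watterson():
    n, theta = 10, 3.0
    a1 = sum(1.0 / i for i in range(1, n))
    S = [
        simulate_neutral_coalescent(n, theta, seed=10_000 + i).shape[0]
        for i in range(500)
    ]
    assert np.mean(S) == pytest.approx(theta * a1, rel=0.15)


def test_coalescent_deterministic_and_validates():
    a = simulate_neutral_coalescent(6, 2.0, seed=5)
    b = simulate_neutral_coalescent(6, 2.0, seed=5)
    assert np.array_equal(a, b)
    with pytest.raises(ValueError):
        simulate_neutral_coalescent(1, 2.0, seed=1)
    with pytest.raises(ValueError):
        simulate_neutral_coalescent(4, 0.0, seed=1)


# ---------------------------------------------------------------------------
# toy genome


def test_toy_genome_cds_translates_cleanly(toy_genome):
    from Bio.Seq import Seq

    from selsweep.annotate import extract_cds

    for gm in toy_genome.genes:
        cds = extract_cds(gm, toy_genome.sequences)
        assert len(cds) % 3 == 0
        prot = str(Seq(cds).translate())
        assert prot.startswith("M") and prot.endswith("*")
        assert "*" not in prot[:-1]


def test_toy_genome_gff_round_trip(tmp_path, toy_genome):
    from selsweep.io import read_gff, write_gff

    path = tmp_path / "toy.gff3"
    write_gff(toy_genome.genes, path)
    models = read_gff(path)
    assert len(models) == len(toy_genome.genes)
    key = lambda g: (g.chrom, g.start)  # noqa: E731
    for a, b in zip(sorted(toy_genome.genes, key=key),
                    sorted(models, key=key)):
        assert (a.chrom, a.strand, a.start, a.end) == \
            (b.chrom, b.strand, b.start, b.end)
        assert sorted(a.exons) == sorted(b.exons)
        assert sorted(a.cds) == sorted(b.cds)
        assert sorted(a.utr5) == sorted(b.utr5)
        assert sorted(a.utr3) == sorted(b.utr3)


def test_toy_genome_rejects_too_short_chromosome():
    with pytest.raises(ValueError):
        generate_toy_genome({"c": 500}, seed=0)


def test_mid_intron_site_classifies_intronic(toy_genome):
    from selsweep.annotate import classify_location
    from selsweep.io import Variant

    gm = toy_genome.genes[0]
    exons = sorted(gm.exons)
    mid = (exons[0][1] + exons[1][0]) // 2
    v = Variant(gm.chrom, mid, "A", ("G",), [])
    assert classify_location(v, toy_genome.genes).category == "intronic"
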