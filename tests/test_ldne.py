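"""r² machinery, haplotype-frequency EM, decay bins and N_e estimation."""

import numpy as np
import pytest

from herdchar import (
    HaplotypeFreqs,
    LdBin,
    WrightFisherSpec,
    estimate_haplotype_freqs,
    ld_decay,
    ne_trajectory,
    r2_from_haplotypes,
    simulate_wright_fisher,
    sved_f,
)
from herdchar.ldne import DECAY_BIN_EDGES_BP, ne_bin_edges

from conftest import make_dataset


# --- r² closed forms -------------------------------------------------------

def test_r2_independence_zero():
    assert r2_from_haplotypes(HaplotypeFreqs(0.5, 0.5, 0.25)) == pytest.approx(0.0)


def test_r2_complete_association_one():
    assert r2_from_haplotypes(HaplotypeFreqs(0.5, 0.5, 0.5)) == pytest.approx(1.0)


def test_r2_hand_computed():
    h = HaplotypeFreqs(0.4, 0.3, 0.2)
    assert r2_from_haplotypes(h) == pytest.approx(0.0064 / 0.0504)


def test_r2_monomorphic_raises():
    with pytest.raises(ValueError):
        r2_from_haplotypes(HaplotypeFreqs(1.0, 0.5, 0.5))


def test_haplotype_freqs_frechet_bounds_enforced():
    with pytest.raises(ValueError):
        HaplotypeFreqs(0.2, 0.2, 0.3)


# --- haplotype EM ----------------------------------------------------------

def test_em_no_double_heterozygotes_closed_form():
    # genotypes chosen so phase is always known
    g1 = np.array([0, 0, 2, 2, 1, 1])
    g2 = np.array([0, 2, 0, 2, 0, 2])
    h = estimate_haplotype_freqs(g1, g2)
    # haplotype (minor,minor) count: inds 3 (2 copies), 5 (1 copy) -> 3/12
    assert h.p_ab == pytest.approx(3 / 12)
    assert h.p_a == pytest.approx(0.5) and h.p_b == pytest.approx(0.5)


def test_em_recovers_known_haplotype_counts():
    """Construct genotypes from explicit haplotypes and check the MLE."""
    rng = np.random.default_rng(61)
    # haplotype pool with D != 0
    haps = np.array([[1, 1]] * 30 + [[1, 0]] * 10 + [[0, 1]] * 10 + [[0, 0]] * 50)
    rng.shuffle(haps)
    h1, h2 = haps[:50], haps[50:]
    g1 = h1[:, 0] + h2[:, 0]
    g2 = h1[:, 1] + h2[:, 1]
    est = estimate_haplotype_freqs(g1, g2)
    true_pab = haps[:, 0] @ haps[:, 1] / 100
    # EM MLE from unphased data approaches the phased count
    assert est.p_ab == pytest.approx(true_pab, abs=0.03)
    assert est.p_a == pytest.approx(haps[:, 0].mean())


def test_em_double_het_only_equilibrium_fixed_point():
    g1 = np.ones(20, dtype=int)
    g2 = np.ones(20, dtype=int)
    h = estimate_haplotype_freqs(g1, g2)
    assert h.p_ab == pytest.approx(h.p_a * h.p_b)


def test_em_matches_phased_r2_when_phase_unambiguous():
    """Dual route: dosage-correlation r2 equals EM r2 on data without
    double heterozygotes."""
    rng = np.random.default_rng(62)
    g1 = rng.choice([0, 2], size=200)
    g2 = np.where(rng.random(200) < 0.8, g1, rng.choice([0, 2], size=200))
    h = estimate_haplotype_freqs(g1, g2)
    r = np.corrcoef(g1, g2)[0, 1]
    assert r2_from_haplotypes(h) == pytest.approx(r * r, abs=1e-9)


# --- decay bins ------------------------------------------------------------

def test_decay_bin_edges_are_the_twenty_intervals():
    assert len(DECAY_BIN_EDGES_BP) == 21
    assert DECAY_BIN_EDGES_BP[:4] == (0, 1_000, 10_000, 20_000)
    assert DECAY_BIN_EDGES_BP[-2:] == (900_000, 1_000_000)


def test_duplicated_snp_contributes_r2_one_to_first_bin():
    col = np.array([0, 1, 2, 1, 0, 2, 1, 1, 0, 2], dtype=np.int8)
    ds = make_dataset(
        np.column_stack([col, col]), ["p"] * 10, positions=[1000, 1500]
    )
    bins = ld_decay(ds, "p", 10_000)
    assert bins[0].n_pairs == 1
    assert bins[0].mean_r2 == pytest.approx(1.0)


def test_decay_r2_bounded_and_monotone_under_recombination():
    from scipy.stats import spearmanr

    ds = simulate_wright_fisher(
        WrightFisherSpec(
            ne_trajectory=((200, 100),), chrom_length_bp=2_000_000,
            recomb_rate=1e-8, n_loci=300, n_sample=50, n_generations=200,
            seed=63, init_maf_range=(0.2, 0.8),
        )
    )
    bins = ld_decay(ds, "wf", 1_000_000)
    pts = [(b.representative_distance, b.mean_r2) for b in bins if b.n_pairs > 0]
    means = np.array([m for _, m in pts])
    assert ((means >= 0) & (means <= 1)).all()
    rho = spearmanr([d for d, _ in pts], means).statistic
    assert rho < 0


def test_empty_bins_reported():
    col = np.array([0, 1, 2, 1], dtype=np.int8)
    ds = make_dataset(np.column_stack([col, col]), ["p"] * 4, positions=[1000, 1500])
    bins = ld_decay(ds, "p", 1_000_000)
    assert sum(b.n_pairs for b in bins) == 1
    assert all(np.isnan(b.mean_r2) for b in bins if b.n_pairs == 0)


# --- Sved f(c) and N_e -----------------------------------------------------

def test_sved_f_closed_forms():
    assert sved_f(0.5) == pytest.approx(1.5)
    assert sved_f(0.1) == pytest.approx(0.1 * 0.95 / 0.81)
    # small-c limit f(c)/c -> 1
    assert sved_f(1e-6) / 1e-6 == pytest.approx(1.0, abs=1e-4)
    with pytest.raises(ValueError):
        sved_f(1.0)


def test_ne_closed_form_small_c():
    # r2_adj = 0.25, alpha = 2, c = 0.001 -> N ~ 2/(4c) = 500
    n = 1000  # large n so the sample-size correction is negligible
    b = LdBin(lo_bp=90_000, hi_bp=110_000, mean_r2=0.25 + 1 / (2 * n),
              n_pairs=10, representative_distance=100_000)
    traj = ne_trajectory([b], n_sample=n, alpha=2.0, cm_per_mb=1.0)
    assert traj.t[0] == 500
    assert traj.ne[0] == pytest.approx(500, rel=5e-3)
    # exact formula
    assert traj.ne[0] == pytest.approx((1 / (4 * sved_f(0.001))) * 2)


def test_ne_monotone_in_alpha():
    b = LdBin(0, 10_000, 0.3, 5, 5_000)
    nes = [ne_trajectory([b], 50, alpha=a).ne[0] for a in (1.0, 2.0, 2.2)]
    assert nes[0] > nes[1] > nes[2]


def test_ne_drops_uninformative_bins():
    good = LdBin(0, 10_000, 0.3, 5, 5_000)
    bad = LdBin(10_000, 20_000, 0.005, 5, 15_000)  # r2_adj <= 0 at n=50
    traj = ne_trajectory([good, bad], n_sample=50, alpha=2.0)
    assert traj.t.size == 1


def test_ne_bin_edges_log_spaced():
    edges = ne_bin_edges()
    assert edges[0] == 10_000 and edges[-1] == 4_000_000
    ratios = np.diff(np.log(np.array(edges, float)))
    assert np.allclose(ratios, ratios[0], rtol=0.01)


def test_constant_ne_recovery_within_factor_two():
    ds = simulate_wright_fisher(
        WrightFisherSpec(
            ne_trajectory=((250, 100),), chrom_length_bp=50_000_000,
            recomb_rate=1e-8, n_loci=1500, n_sample=60, n_generations=250,
            seed=64, init_maf_range=(0.2, 0.8),
        )
    )
    bins = ld_decay(ds, "wf", 4_000_000, bin_edges_bp=ne_bin_edges())
    traj = ne_trajectory(bins, n_sample=60, alpha=2.0)
    recent = traj.ne[traj.t <= 60]
    assert recent.size >= 3
    geo = float(np.exp(np.log(recent).mean()))
    assert 50 <= geo <= 200


def test_msprime_cross_check_decay_magnitude():
    """Independent simulator oracle: under a coalescent with the same N_e,
    the EM-based r2 at short range exceeds r2 at long range and both lie
    in the plausible drift-recombination band."""
    msprime = pytest.importorskip("msprime")
    ts = msprime.sim_ancestry(
        samples=50, population_size=100, sequence_length=2_000_000,
        recombination_rate=1e-8, random_seed=65,
    )
    ts = msprime.sim_mutations(ts, rate=2e-7, random_seed=66)
    geno = ts.genotype_matrix()  # sites x haplotypes
    g = (geno[:, 0::2] + geno[:, 1::2]).T.astype(np.int8)
    g = np.clip(g, 0, 2)
    pos = np.array([int(s.position) + 1 for s in ts.sites()])
    keep = np.flatnonzero((g.min(axis=0) < g.max(axis=0)))
    # thin to at most 200 segregating sites with unique positions
    seen, idx = set(), []
    for j in keep:
        if pos[j] not in seen:
            seen.add(pos[j])
            idx.append(j)
    idx = idx[:200]
    freq = g[:, idx].mean(axis=0) / 2
    flip = freq > 0.5
    gm = g[:, idx].copy()
    gm[:, flip] = 2 - gm[:, flip]
    ds = make_dataset(gm, ["c"] * gm.shape[0], positions=[int(pos[j]) for j in idx])
    bins = ld_decay(ds, "c", 1_000_000)
    filled = [b for b in bins if b.n_pairs >= 20]
    short = np.mean([b.mean_r2 for b in filled[:3]])
    long = np.mean([b.mean_r2 for b in filled[-3:]])
    assert short > long
    assert 0.0 < long < short <= 1.0
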