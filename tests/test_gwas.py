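"""Synthetic two-disease cohorts and the case-swap mix-scan."""

import numpy as np
import pytest
from scipy import stats

from hetgwas import (
    CohortSpec,
    SNPSpec,
    default_snp_panel,
    generate_cohorts,
    mix_cases,
    mixscan,
    scan,
)
from hetgwas._rng import substream
from hetgwas.gwas import shared_control_dist, write_ped_map


def small_spec(**kw) -> CohortSpec:
    snps = [
        SNPSpec("a_strong", 0.2, rr_a=2.0),
        SNPSpec("b_strong", 0.3, rr_b=2.0),
        SNPSpec("shared", 0.25, rr_a=3.0, rr_b=3.0),
        SNPSpec("null1", 0.1),
        SNPSpec("null2", 0.4),
    ]
    kw.setdefault("snps", snps)
    kw.setdefault("n_case_a", 400)
    kw.setdefault("n_case_b", 400)
    kw.setdefault("n_controls", 600)
    return CohortSpec(**kw)


def test_default_panel_composition():
    panel = default_snp_panel()
    assert len(panel) == 500
    a = [s for s in panel if s.rr_a > 1 and s.rr_b == 1]
    b = [s for s in panel if s.rr_b > 1 and s.rr_a == 1]
    shared = [s for s in panel if s.rr_a > 1 and s.rr_b > 1]
    null = [s for s in panel if s.rr_a == 1 and s.rr_b == 1]
    assert (len(a), len(b), len(shared), len(null)) == (20, 20, 1, 459)
    assert all(1.3 <= s.rr_a <= 2.0 for s in a)
    assert shared[0].rr_a == shared[0].rr_b == 3.0
    assert all(0.05 <= s.maf <= 0.5 for s in panel)
    # the default panel is a constant
    assert [s.id for s in panel] == [s.id for s in default_snp_panel()]


def test_shared_control_dist_limits():
    spec = small_spec()
    null = shared_control_dist(SNPSpec("n", 0.2), spec)
    assert null.as_array() == pytest.approx([0.64, 0.32, 0.04], abs=1e-12)


def test_generate_cohorts_determinism_and_frequencies():
    spec = small_spec(seed=21)
    a1, b1, c1 = generate_cohorts(spec)
    a2, _, _ = generate_cohorts(spec)
    assert np.array_equal(a1.dosages, a2.dosages)
    assert a1.n == 400 and b1.n == 400 and c1.n == 600

    def sample_maf(mat, j):
        return mat.dosages[:, j].mean() / 2

    # null SNP: all groups near population MAF (3 binomial SEs on 2n alleles)
    j = a1.snp_ids.index("null1")
    for mat in (a1, b1, c1):
        se = np.sqrt(0.1 * 0.9 / (2 * mat.n))
        assert abs(sample_maf(mat, j) - 0.1) < 3.5 * se
    # A-specific SNP (rr_a=2, maf .2, multiplicative): case_A MAF near 1/3,
    # case_B near the control frequency
    j = a1.snp_ids.index("a_strong")
    assert abs(sample_maf(a1, j) - 1 / 3) < 3.5 * np.sqrt((1 / 3) * (2 / 3) / 800)
    assert abs(sample_maf(b1, j) - 0.2) < 4 * np.sqrt(0.2 * 0.8 / 800)


def test_generate_cohorts_names_offending_snp():
    bad = CohortSpec(
        snps=[SNPSpec("ok", 0.2), SNPSpec("explodes", 0.01, rr_a=10.0)],
        prevalence_a=0.1,
        n_case_a=10, n_case_b=10, n_controls=10,
    )
    with pytest.raises(Exception, match="explodes"):
        generate_cohorts(bad)


def test_mix_cases_row_accounting():
    spec = small_spec(seed=3, n_case_a=1963, n_case_b=1970)
    a, b, _ = generate_cohorts(spec)
    rng = substream(1, "mix")
    assert mix_cases(a, b, 0.0, rng) is a
    mixed = mix_cases(a, b, 0.1, rng)
    assert mixed.n == 1963
    # k = round(1963 * 0.1) = 196 donor rows
    donor_rows = {tuple(r) for r in b.dosages}
    n_donor = sum(tuple(r) in donor_rows for r in mixed.dosages)
    assert n_donor >= 196  # donors plus chance collisions
    full = mix_cases(a, b, 1.0, rng)
    assert full.n == 1963
    assert all(tuple(r) in donor_rows for r in full.dosages)


def test_mix_cases_insufficient_donors_raises():
    spec = small_spec(seed=4, n_case_a=400, n_case_b=100)
    a, b, _ = generate_cohorts(spec)
    with pytest.raises(ValueError, match="donor"):
        mix_cases(a, b, 0.9, substream(2, "mix"))


def test_scan_self_comparison_is_null():
    spec = small_spec(seed=5)
    a, _, _ = generate_cohorts(spec)
    res = scan(a, a)
    assert np.allclose(res.statistic, 0.0)
    assert np.allclose(res.p_value, 1.0)


def test_scan_null_pvalues_uniform():
    snps = [SNPSpec(f"null{i}", 0.2) for i in range(500)]
    spec = CohortSpec(
        n_case_a=2000, n_case_b=10, n_controls=2000, snps=snps, seed=6
    )
    a, _, c = generate_cohorts(spec)
    res = scan(a, c)
    ks = stats.kstest(res.p_value, "uniform")
    assert ks.pvalue > 0.01


def test_scan_detects_specific_snp():
    spec = small_spec(seed=7, n_case_a=1963, n_controls=2938)
    a, _, c = generate_cohorts(spec)
    res = scan(a, c).set_index("snp")
    assert res.loc["a_strong", "p_value"] < 5e-8
    assert res.loc["shared", "p_value"] < 5e-8


def test_mixscan_decay_and_robustness():
    spec = small_spec(seed=8, n_case_a=1000, n_case_b=1000, n_controls=1500)
    betas = [0.0, 0.3, 0.6, 0.9]
    res = mixscan(spec, betas=betas, n_resamples=30)
    piv = res.pivot(index="snp", columns="beta", values="mean_neglog10p")
    a_curve = piv.loc["a_strong"].to_numpy()
    # A-specific signal decays monotonically (one noise inversion allowed)
    assert ((a_curve[:-1] - a_curve[1:]) < 0).sum() <= 1
    assert a_curve[-1] < 0.5 * a_curve[0]
    # shared-effect SNP stays far above the null SNPs at extreme admixture
    null_mean = piv.loc[["null1", "null2"], betas[-1]].mean()
    assert piv.loc["shared", betas[-1]] > 10 * null_mean
    # nulls hover around E[-log10 U] = 1/ln(10)
    assert 0.2 < null_mean < 0.8


def test_mixscan_deterministic_and_beta0_degenerate():
    spec = small_spec(seed=9)
    res1, p1 = mixscan(spec, betas=[0.0, 0.5], n_resamples=5, keep_pvalues=True)
    res2 = mixscan(spec, betas=[0.0, 0.5], n_resamples=5)
    assert res1.equals(res2)
    # beta=0 swaps nothing: all resamples identical
    assert np.allclose(p1[0], p1[0, 0])
    assert not np.allclose(p1[1], p1[1, 0])


def test_ped_map_writer(tmp_path):
    spec = small_spec(seed=10, n_case_a=5, n_case_b=4, n_controls=6)
    a, b, c = generate_cohorts(spec)
    prefix = str(tmp_path / "cohorts")
    write_ped_map([a, b, c], spec, prefix)
    ped = (tmp_path / "cohorts.ped").read_text().splitlines()
    mp = (tmp_path / "cohorts.map").read_text().splitlines()
    assert len(ped) == 15
    assert len(mp) == len(spec.snps)
    fields = ped[0].split()
    assert len(fields) == 6 + 2 * len(spec.snps)
    assert fields[5] == "2"  # case phenotype
    assert ped[-1].split()[5] == "1"  # control phenotype
    assert set("".join(f.split()[6] for f in map(str, ped))) <= set("AG")
    assert mp[0].split("\t")[1] == spec.snps[0].id
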