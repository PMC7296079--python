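"""Mixed-model machinery: REML, per-SNP GLS, the genome scan."""

import numpy as np
import pytest

from admixscan import synthpop as sp
from admixscan.ancestry import eut_dosage
from admixscan.assoc import (
    SnpTester,
    _neg2_rll,
    fit_null_reml,
    fit_reml,
    gwa_scan,
)
from admixscan.panel import PhenotypeTable
from admixscan.relatedness import build_grm


@pytest.fixture(scope="module")
def cohort(toy_cohort):
    panel, anc = toy_cohort["panel"], toy_cohort["ancestry"]
    grm = build_grm(panel)
    return panel, anc, grm


def _dense_neg2_rll(theta, grm_sub, pheno, animals):
    """Record-level restricted likelihood, computed the long way.

    Independent of the animal-collapse path: builds the full N x N
    covariance and evaluates log|V| + log|X'V^-1 X| + y'Py directly.
    """
    sg2, spe2, se2 = theta
    lut = {a: i for i, a in enumerate(animals)}
    idx = np.array([lut[a] for a in pheno.animal])
    n = pheno.n_records
    w = np.zeros((n, len(animals)))
    w[np.arange(n), idx] = 1.0
    v = sg2 * w @ grm_sub @ w.T + spe2 * w @ w.T + se2 * np.eye(n)
    x = np.ones((n, 1))
    vi = np.linalg.inv(v)
    xvx = x.T @ vi @ x
    beta = np.linalg.solve(xvx, x.T @ vi @ pheno.value)
    r = pheno.value - x @ beta
    return (
        np.linalg.slogdet(v)[1]
        + np.linalg.slogdet(xvx)[1]
        + float(r @ vi @ r)
    )


def test_collapsed_likelihood_matches_dense_record_level(cohort):
    """The animal-mean collapse is exact up to a theta-independent constant."""
    panel, anc, grm = cohort
    small = panel.take_animals(list(range(12)))
    g = build_grm(small)
    rng = np.random.default_rng(3)
    counts = rng.integers(1, 5, size=12)
    animal = np.repeat(small.samples, counts)
    ph = PhenotypeTable(animal=animal, value=rng.normal(size=counts.sum()))
    from admixscan.assoc import _Collapsed

    col = _Collapsed(ph, g)
    thetas = [(1.0, 0.5, 1.0), (0.3, 0.1, 2.0), (2.0, 0.01, 0.5)]
    collapsed = [
        _neg2_rll(
            np.log(np.array(t)),
            col.grm.matrix,
            col.ybar,
            1.0 / col.counts,
            np.ones((col.m, 1)),
            col.N,
            col.m,
            col.ssw,
        )
        for t in thetas
    ]
    dense = [_dense_neg2_rll(t, col.grm.matrix, ph, col.animals) for t in thetas]
    offsets = np.array(dense) - np.array(collapsed)
    assert np.ptp(offsets) < 1e-6


def test_reml_recovers_simulated_components(cohort):
    panel, anc, grm = cohort
    var = sp.VarianceSpec(1.0, 0.5, 1.0, 5)
    ph = sp.simulate_phenotypes(
        anc, panel, sp.QtlSpec([]), var, grm=grm.matrix, seed=200
    )
    vc = fit_null_reml(ph, grm)
    # 60 animals x 5 records: generous simulation-calibrated bounds
    assert vc.sigma_e2 == pytest.approx(1.0, abs=0.15)
    assert vc.sigma_g2 + vc.sigma_pe2 == pytest.approx(1.5, abs=0.8)


def test_pure_noise_gives_null_heritability(cohort):
    panel, anc, grm = cohort
    rng = np.random.default_rng(7)
    animal = np.repeat(panel.samples, 3)
    ph = PhenotypeTable(animal=animal, value=rng.normal(size=3 * panel.n_animals))
    vc = fit_null_reml(ph, grm)
    assert vc.sigma_g2 < 0.15
    assert vc.sigma_e2 == pytest.approx(1.0, abs=0.3)


def test_wald_null_identity():
    from admixscan.assoc import _wald

    p, neglog = _wald(0.0, 1.0)
    assert p == 1.0
    assert neglog == pytest.approx(0.0)


def test_noise_free_effects_recovered_exactly(cohort):
    panel, anc, grm = cohort
    qtl = sp.QtlSpec([sp.QtlEffect(snp_index=20, origin_effect=0.5, allele_effect=-0.3)])
    ph = sp.simulate_phenotypes(
        anc, panel, qtl, sp.VarianceSpec(0, 0, 0, 2), seed=201
    )
    # degenerate noise-free fit: fix tiny variance structure by hand
    from admixscan.assoc import VarianceComponents

    vc = VarianceComponents(0.0, 0.0, 1.0, loglik=0.0)
    tester = SnpTester(ph, grm, vc)
    rec = tester.test(
        eut_dosage(anc)[20], panel.dosages()[20].astype(float), "qtl"
    )
    assert rec.origin_effect == pytest.approx(0.5, abs=1e-8)
    assert rec.allele_effect == pytest.approx(-0.3, abs=1e-8)


def test_constant_origin_dosage_flagged_not_estimable(cohort):
    panel, anc, grm = cohort
    var = sp.VarianceSpec(0.0, 0.0, 1.0, 2)
    ph = sp.simulate_phenotypes(anc, panel, sp.QtlSpec([]), var, seed=202)
    vc = fit_null_reml(ph, grm)
    tester = SnpTester(ph, grm, vc)
    const = np.full(panel.n_animals, 2.0)
    varying = panel.dosages()[5].astype(float)
    rec = tester.test(const, varying, "snp")
    assert not rec.origin_estimable
    assert np.isnan(rec.origin_effect)
    assert rec.allele_estimable
    assert np.isfinite(rec.allele_p)


def test_collinear_pair_keeps_origin_drops_allele(cohort):
    panel, anc, grm = cohort
    var = sp.VarianceSpec(0.0, 0.0, 1.0, 2)
    ph = sp.simulate_phenotypes(anc, panel, sp.QtlSpec([]), var, seed=203)
    vc = fit_null_reml(ph, grm)
    tester = SnpTester(ph, grm, vc)
    x = panel.dosages()[5].astype(float)
    rec = tester.test(x, x.copy(), "snp")
    assert rec.origin_estimable
    assert not rec.allele_estimable


def test_scan_deterministic_and_complete(cohort):
    panel, anc, grm = cohort
    var = sp.VarianceSpec(0.5, 0.2, 1.0, 3)
    ph = sp.simulate_phenotypes(
        anc, panel, sp.QtlSpec([]), var, grm=grm.matrix, seed=204
    )
    scans = gwa_scan(ph, panel, anc, attach_q=False)
    scans2 = gwa_scan(ph, panel, anc, attach_q=False)
    for name in ("origin", "allele"):
        assert len(scans[name]) == panel.n_snps
        a = scans[name]["p"].to_numpy()
        b = scans2[name]["p"].to_numpy()
        assert np.allclose(a, b, equal_nan=True)


def test_permutation_destroys_signal(cohort):
    panel, anc, grm = cohort
    qtl = sp.QtlSpec([sp.QtlEffect(snp_index=30, origin_effect=1.5)])
    var = sp.VarianceSpec(0.0, 0.0, 0.5, 3)
    ph = sp.simulate_phenotypes(anc, panel, qtl, var, seed=205)
    vc = fit_null_reml(ph, grm)
    tester = SnpTester(ph, grm, vc)
    odos = eut_dosage(anc)[30]
    ados = panel.dosages()[30].astype(float)
    rec = tester.test(odos, ados)
    rng = np.random.default_rng(8)
    # shuffle whole animals' record blocks onto other animals
    blocks = ph.value.reshape(panel.n_animals, 3)
    ph_perm = PhenotypeTable(
        animal=ph.animal,
        value=blocks[rng.permutation(panel.n_animals)].reshape(-1),
    )
    vc_p = fit_null_reml(ph_perm, grm)
    tester_p = SnpTester(ph_perm, grm, vc_p)
    rec_p = tester_p.test(odos, ados)
    assert -np.log10(rec.origin_p) > 5
    assert -np.log10(rec_p.origin_p) < 3


def test_missing_grm_animal_rejected(cohort):
    panel, anc, grm = cohort
    ph = PhenotypeTable(animal=np.array(["ghost"]), value=np.array([1.0]))
    with pytest.raises(ValueError, match="absent"):
        fit_null_reml(ph, grm)
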