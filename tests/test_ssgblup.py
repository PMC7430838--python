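"""Pedigree A matrix, H-inverse against the closed-form oracle, ssGBLUP MME."""

import numpy as np
import pandas as pd
import pytest

from wblup.gblup import gblup_predict
from wblup.grm import Grm, WeightVector, build_design, standardized_grm, weighted_grm
from wblup.io_formats import PedigreeTable
from wblup.ssgblup import AMatrix, SsModelSpec, a_matrix, h_inverse, ssgblup_solve
from wblup.varcomp import VarianceComponents


def ped_from_rows(rows):
    return PedigreeTable(records=pd.DataFrame(rows, columns=["id", "sire", "dam"]))


def test_tabular_rules_on_textbook_cases():
    A = a_matrix(ped_from_rows([("a", "0", "0"), ("b", "0", "0")]))
    assert np.allclose(A.values, np.eye(2))

    A = a_matrix(ped_from_rows([("s", "0", "0"), ("d", "0", "0"),
                                ("o", "s", "d")]))
    i = A.index
    assert A.values[i["o"], i["s"]] == pytest.approx(0.5)
    assert A.values[i["o"], i["o"]] == pytest.approx(1.0)

    # offspring of full sibs has inbred diagonal 1 + 0.5 * 0.5
    rows = [("s", "0", "0"), ("d", "0", "0"), ("x", "s", "d"),
            ("y", "s", "d"), ("z", "x", "y")]
    A = a_matrix(ped_from_rows(rows))
    i = A.index
    assert A.values[i["x"], i["y"]] == pytest.approx(0.5)
    assert A.values[i["z"], i["z"]] == pytest.approx(1.25)


def random_pedigree(rng, n_founders=10, n_desc=20):
    rows = [(f"f{i}", "0", "0") for i in range(n_founders)]
    ids = [r[0] for r in rows]
    for k in range(n_desc):
        s, d = rng.choice(len(ids), size=2, replace=False)
        rows.append((f"x{k}", ids[s], ids[d]))
        ids.append(f"x{k}")
    return ped_from_rows(rows)


def test_h_inverse_matches_closed_form_oracle():
    rng = np.random.default_rng(5)
    ped = random_pedigree(rng)
    A = a_matrix(ped)
    n = len(A.ids)
    geno_ids = list(rng.choice(A.ids, size=15, replace=False))
    gpos = np.array([A.index[s] for s in geno_ids])
    B = rng.normal(size=(15, 40))
    G = Grm(values=B @ B.T / 40 + 0.3 * A.values[np.ix_(gpos, gpos)],
            samples=geno_ids)
    spec = SsModelSpec(sigma2_g=1.0, sigma2_e=1.0, tune_to_a22=False,
                       blend_a22=0.0)
    Hinv = h_inverse(A, G, spec)
    H = np.linalg.inv(Hinv)
    # joint-distribution oracle
    other = np.setdiff1d(np.arange(n), gpos)
    A11 = A.values[np.ix_(other, other)]
    A12 = A.values[np.ix_(other, gpos)]
    A22 = A.values[np.ix_(gpos, gpos)]
    A22i = np.linalg.inv(A22)
    H_oracle = np.zeros((n, n))
    H_oracle[np.ix_(other, other)] = A11 + A12 @ A22i @ (G.values - A22) @ A22i @ A12.T
    H_oracle[np.ix_(other, gpos)] = A12 @ A22i @ G.values
    H_oracle[np.ix_(gpos, other)] = G.values @ A22i @ A12.T
    H_oracle[np.ix_(gpos, gpos)] = G.values
    assert np.allclose(H, H_oracle, atol=1e-6)


def test_h_inverse_degenerate_cases():
    rng = np.random.default_rng(6)
    ped = random_pedigree(rng, n_founders=6, n_desc=6)
    A = a_matrix(ped)
    spec = SsModelSpec(sigma2_g=1.0, sigma2_e=1.0, tune_to_a22=False,
                       blend_a22=0.0)
    assert np.allclose(h_inverse(A, None, spec), np.linalg.inv(A.values))
    G_eq_A = Grm(values=A.values.copy(), samples=list(A.ids))
    assert np.allclose(h_inverse(A, G_eq_A, spec), np.linalg.inv(A.values),
                       atol=1e-8)


def test_tuning_matches_first_two_moments():
    rng = np.random.default_rng(7)
    ped = random_pedigree(rng)
    A = a_matrix(ped)
    gpos = np.arange(10)
    A22 = A.values[np.ix_(gpos, gpos)]
    B = rng.normal(size=(10, 30))
    G = Grm(values=B @ B.T / 30, samples=[A.ids[i] for i in gpos])
    from wblup.ssgblup import _adjust_g
    Gt = _adjust_g(G.values, A22, SsModelSpec(1.0, 1.0, blend_a22=0.0))
    off = ~np.eye(10, dtype=bool)
    assert np.diag(Gt).mean() == pytest.approx(np.diag(A22).mean())
    assert Gt[off].mean() == pytest.approx(A22[off].mean())


def test_ssgblup_equals_gblup_when_all_genotyped(bundle, design, split):
    tr, va = split
    ids = list(bundle.genotypes.samples)
    y = bundle.phenotypes.trait("qtl").reindex([ids[i] for i in tr]).to_numpy()
    Graw = standardized_grm(design)
    G = Grm(values=Graw.blended(), samples=ids)  # PD for direct inversion
    vc = VarianceComponents(sigma2=[0.4], sigma2_e=0.6)
    pred = gblup_predict(y, [G], vc, train_idx=tr, val_idx=va, samples=ids)

    founder_ped = PedigreeTable(records=pd.DataFrame(
        {"id": ids, "sire": "0", "dam": "0"}))
    spec = SsModelSpec(sigma2_g=0.4, sigma2_e=0.6, tune_to_a22=False,
                       blend_a22=0.0)
    ebv, _ = ssgblup_solve(y, [ids[i] for i in tr], founder_ped, G, spec)
    assert np.allclose(ebv.reindex(ids).to_numpy(), pred.ghat, atol=1e-6)


def test_unphenotyped_offspring_gets_parent_average():
    rows = [("s", "0", "0"), ("d", "0", "0"), ("u", "0", "0"), ("o", "s", "d")]
    ped = ped_from_rows(rows)
    rng = np.random.default_rng(8)
    y = rng.normal(size=3)
    spec = SsModelSpec(sigma2_g=0.5, sigma2_e=0.5)
    ebv, _ = ssgblup_solve(y, ["s", "d", "u"], ped, None, spec)
    assert ebv["o"] == pytest.approx(0.5 * (ebv["s"] + ebv["d"]), abs=1e-10)


def test_strong_shrinkage_drives_ebvs_to_zero():
    rows = [("a", "0", "0"), ("b", "0", "0")]
    y = np.array([1.0, -2.0])
    ebv, _ = ssgblup_solve(y, ["a", "b"], ped_from_rows(rows), None,
                           SsModelSpec(sigma2_g=1e-8, sigma2_e=1.0))
    assert np.max(np.abs(ebv.to_numpy())) < 1e-4


def test_uniformly_weighted_g_equals_unweighted_ssgblup(bundle, design, split):
    tr, _ = split
    ids = list(bundle.genotypes.samples)
    y = bundle.phenotypes.trait("poly").reindex([ids[i] for i in tr]).to_numpy()
    spec = SsModelSpec(sigma2_g=0.4, sigma2_e=0.6)
    G1 = standardized_grm(design)
    G2 = weighted_grm(design, WeightVector(d=np.ones(design.m)))
    e1, _ = ssgblup_solve(y, [ids[i] for i in tr], bundle.pedigree, G1, spec)
    e2, _ = ssgblup_solve(y, [ids[i] for i in tr], bundle.pedigree, G2, spec)
    assert np.allclose(e1.to_numpy(), e2.to_numpy())
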